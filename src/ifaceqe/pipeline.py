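"""End-to-end plumbing: featurize, label, train, score, evaluate.

Ties the individual stages together for the CLI, the acceptance script and
the test suite. A model with an empty interface (no inter-chain pair under
10 A) is assigned quality 0 rather than skipped when scoring, and is
excluded from training (it has no edges to regress on).
"""

from __future__ import annotations

import logging

import numpy as np

from .edge_features import compute_edge_features
from .evaluation import RankingTable, evaluate_dataset
from .gat_network import GATConfig, GATParams, model_forward
from .interface_graph import (EmptyInterfaceError, InterfaceGraph,
                              build_interface_graph)
from .labeling import label_graph
from .msa_features import node_evolutionary_features
from .node_features import compute_node_features
from .structure_model import ComplexStructure
from .synthetic_data import DecoySet, SyntheticSpec, generate_decoys, \
    generate_native, target_msas
from .training import TrainingConfig, TrainingLog, train

logger = logging.getLogger("ifaceqe")


def featurize_model(model: ComplexStructure,
                    msas: tuple = (None, None, None),
                    native: ComplexStructure | None = None,
                    dssp_path: str | None = None,
                    sasa_points: int | None = None) -> InterfaceGraph:
    """Build, featurize and (when a native is given) label a model's graph."""
    graph = build_interface_graph(model)
    neff = node_evolutionary_features(*msas)
    kwargs = {} if sasa_points is None else {"sasa_points": sasa_points}
    graph.node_features = compute_node_features(
        model, graph.nodes, neff=neff, dssp_path=dssp_path, **kwargs)
    graph.edge_features = compute_edge_features(
        graph.nodes, graph.edges, graph.edge_distance)
    if native is not None:
        label_graph(graph, native)
    return graph


def score_model(model: ComplexStructure, params: GATParams,
                msas: tuple = (None, None, None)) -> float:
    """Overall interface quality Q of one model; 0 for an empty interface."""
    try:
        graph = featurize_model(model, msas=msas)
    except EmptyInterfaceError as err:
        logger.warning("%s: %s -> Q = 0", model.target_id, err)
        return 0.0
    _, q = model_forward(graph, params)
    return q


def build_synthetic_dataset(spec: SyntheticSpec,
                            ) -> tuple[dict[str, list[InterfaceGraph]],
                                       dict[str, DecoySet]]:
    """Labeled, featurized decoy graphs grouped by target, plus decoy sets."""
    graphs: dict[str, list[InterfaceGraph]] = {}
    sets: dict[str, DecoySet] = {}
    for t in range(spec.n_targets):
        native = generate_native(spec, t)
        msas = target_msas(native, spec, t)
        dset = generate_decoys(native, spec, t)
        sets[native.target_id] = dset
        tgraphs = []
        for decoy_id, decoy, _ in dset.decoys:
            try:
                tgraphs.append(featurize_model(decoy, msas=msas,
                                               native=native))
            except EmptyInterfaceError:
                logger.info("%s: empty interface, excluded from training",
                            decoy_id)
        if tgraphs:
            graphs[native.target_id] = tgraphs
    return graphs, sets


def score_decoy_sets(sets: dict[str, DecoySet], params: GATParams,
                     spec: SyntheticSpec) -> list[RankingTable]:
    """Ranking tables (decoy, predicted Q, true DockQ) per target."""
    tables = []
    target_ids = sorted(sets)
    for t, target_id in enumerate(target_ids):
        dset = sets[target_id]
        msas = target_msas(dset.native, spec, int(target_id[1:]))
        rows = []
        for decoy_id, decoy, dockq in dset.decoys:
            q = score_model(decoy, params, msas=msas)
            rows.append((decoy_id, q, dockq.dockq))
        tables.append(RankingTable(target_id=target_id, rows=rows))
    return tables


def train_and_evaluate(graphs: dict[str, list[InterfaceGraph]],
                       sets: dict[str, DecoySet], spec: SyntheticSpec,
                       training: TrainingConfig,
                       holdout_fraction: float = 0.2,
                       ) -> tuple[GATParams, TrainingLog, dict]:
    """Train on a target split of a prebuilt dataset; evaluate on holdout.

    The held-out targets never enter training or early-stopping validation.
    Returns (trained parameters, training log, held-out summary metrics).
    """
    target_ids = sorted(graphs)
    rng = np.random.default_rng(training.seed)
    order = list(rng.permutation(target_ids))
    n_hold = max(1, int(round(holdout_fraction * len(target_ids))))
    holdout, train_ids = order[:n_hold], order[n_hold:]
    params, log = train({t: graphs[t] for t in train_ids}, training,
                        gat_config=GATConfig(random_seed=training.seed))
    tables = score_decoy_sets({t: sets[t] for t in holdout}, params, spec)
    metrics = evaluate_dataset(tables)
    metrics["heldout_targets"] = [str(t) for t in holdout]
    return params, log, metrics


def run_experiment(spec: SyntheticSpec, training: TrainingConfig,
                   holdout_fraction: float = 0.2,
                   ) -> tuple[GATParams, TrainingLog, dict]:
    """Simulate, featurize, train and evaluate in one call."""
    graphs, sets = build_synthetic_dataset(spec)
    return train_and_evaluate(graphs, sets, spec, training, holdout_fraction)
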