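"""Interface detection and graph construction.

The interaction interface of a dimer is represented as a graph whose nodes
are interface residues and whose edges are inter-chain residue pairs with
interaction coordinates (C-beta; C-alpha for glycine) closer than a cutoff
(10 A by default, strict inequality). Edges are only ever inter-chain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .structure_model import ComplexStructure, Residue, interaction_coordinate

logger = logging.getLogger("ifaceqe")

INTERFACE_CUTOFF = 10.0


class EmptyInterfaceError(ValueError):
    """No inter-chain residue pair within the cutoff.

    Carries the minimum inter-chain distance so the caller can decide
    whether to assign quality 0 or skip the model.
    """

    def __init__(self, min_distance: float):
        self.min_distance = min_distance
        super().__init__(
            f"empty interface: closest inter-chain pair at "
            f"{min_distance:.2f} A"
        )


class CorrespondenceError(ValueError):
    """Model and native structures cannot be matched residue-by-residue."""


@dataclass
class InterfaceGraph:
    """Graph over interface residues of one dimeric model.

    ``nodes`` are (chain_index, residue) pairs, chain 1 nodes first, each
    chain ordered by sequence index. ``edges`` are (i, j) indices into
    ``nodes`` with i on chain 1 and j on chain 2, in lexicographic order.
    """

    nodes: list[tuple[int, Residue]]
    edges: list[tuple[int, int]]
    edge_distance: np.ndarray          # model C-beta distances d_ij, (E,)
    node_features: np.ndarray | None = None   # (V, 17) when populated
    edge_features: np.ndarray | None = None   # (E, 27) when populated
    edge_label: np.ndarray | None = None      # ground-truth z_ij in (0, 1]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def build_interface_graph(cplx: ComplexStructure,
                          cutoff: float = INTERFACE_CUTOFF) -> InterfaceGraph:
    """Detect the inter-chain interface and build its graph.

    Raises :class:`EmptyInterfaceError` when no inter-chain pair lies
    strictly within ``cutoff``.
    """
    coords1 = np.array([interaction_coordinate(r) for r in cplx.chains[0]])
    coords2 = np.array([interaction_coordinate(r) for r in cplx.chains[1]])
    # all-pairs distance matrix; chains are short enough for dense computation
    diff = coords1[:, None, :] - coords2[None, :, :]
    dmat = np.sqrt((diff ** 2).sum(axis=2))
    pairs = np.argwhere(dmat < cutoff)
    if pairs.size == 0:
        raise EmptyInterfaceError(float(dmat.min()))

    iface1 = sorted(set(pairs[:, 0].tolist()))
    iface2 = sorted(set(pairs[:, 1].tolist()))
    nodes = [(0, cplx.chains[0][i]) for i in iface1]
    nodes += [(1, cplx.chains[1][j]) for j in iface2]
    index1 = {i: k for k, i in enumerate(iface1)}
    index2 = {j: k + len(iface1) for k, j in enumerate(iface2)}

    order = np.lexsort((pairs[:, 1], pairs[:, 0]))
    pairs = pairs[order]
    edges = [(index1[i], index2[j]) for i, j in pairs]
    dist = dmat[pairs[:, 0], pairs[:, 1]]
    return InterfaceGraph(nodes=nodes, edges=edges,
                          edge_distance=np.asarray(dist, float))


def _check_correspondence(graph: InterfaceGraph,
                          native: ComplexStructure) -> None:
    for chain_idx, res in graph.nodes:
        chain = native.chains[chain_idx]
        if res.seq_index > len(chain):
            raise CorrespondenceError(
                f"residue (chain {chain_idx + 1}, index {res.seq_index}) "
                f"absent from native (chain length {len(chain)})"
            )
        if chain[res.seq_index - 1].aa != res.aa:
            raise CorrespondenceError(
                f"sequence mismatch at (chain {chain_idx + 1}, "
                f"index {res.seq_index}): model {res.aa} vs native "
                f"{chain[res.seq_index - 1].aa}"
            )


def native_edge_distances(graph: InterfaceGraph,
                          native: ComplexStructure) -> np.ndarray:
    """Native C-beta (C-alpha for Gly) distance for each model edge.

    Residue correspondence is by (chain, sequential index); sequences must
    match, guarding against misaligned model/native inputs.
    """
    for c in (0, 1):
        model_len = sum(1 for ci, _ in graph.nodes if ci == c)
        if model_len > len(native.chains[c]):
            raise CorrespondenceError(
                f"model chain {c + 1} has more interface residues than "
                f"native chain length {len(native.chains[c])}"
            )
    _check_correspondence(graph, native)
    out = np.empty(graph.n_edges)
    for e, (i, j) in enumerate(graph.edges):
        ci, ri = graph.nodes[i]
        cj, rj = graph.nodes[j]
        pi = interaction_coordinate(native.chains[ci][ri.seq_index - 1])
        pj = interaction_coordinate(native.chains[cj][rj.seq_index - 1])
        out[e] = np.linalg.norm(pi - pj)
    return out


def dump_edges_tsv(graph: InterfaceGraph, path: str,
                   native_distances: np.ndarray | None = None) -> None:
    """Write the edge list (and labels when present) as TSV for inspection."""
    with open(path, "w") as fh:
        cols = ["chain1_idx", "chain2_idx", "d_model"]
        if native_distances is not None:
            cols.append("d_native")
        if graph.edge_label is not None:
            cols.append("z_ij")
        fh.write("\t".join(cols) + "\n")
        for e, (i, j) in enumerate(graph.edges):
            row = [str(graph.nodes[i][1].seq_index),
                   str(graph.nodes[j][1].seq_index),
                   f"{graph.edge_distance[e]:.4f}"]
            if native_distances is not None:
                row.append(f"{native_distances[e]:.4f}")
            if graph.edge_label is not None:
                row.append(f"{graph.edge_label[e]:.6f}")
            fh.write("\t".join(row) + "\n")
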