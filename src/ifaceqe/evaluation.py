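"""Ground-truth quality (DockQ) and ranking/assessment metrics.

DockQ combines three CAPRI-style measures of a docked model against its
native structure:

* Fnat  -- fraction of the native's inter-chain residue contacts (any
  heavy-atom pair < 5 A) reproduced in the model;
* LRMS  -- backbone RMSD of the ligand (chain 2) after superposing the
  model on the native receptor (chain 1) backbone;
* iRMS  -- backbone RMSD over native interface residues (cross-chain
  C-beta/C-alpha pair < 10 A) after superposing on exactly those residues;

    DockQ = ( Fnat + 1/(1+(LRMS/8.5)^2) + 1/(1+(iRMS/1.5)^2) ) / 3

CAPRI classes: incorrect < 0.23 <= acceptable < 0.49 <= medium < 0.80 <= high.

Ranking metrics over per-target decoy tables ranked by predicted score:
top-N success rate SR(N) = S(N)/K x 100 (targets with >= 1 acceptable decoy
in their top N, over K targets) and top-N hit rate HR(N) = H(N)/M x 100
(acceptable decoys captured in per-target top-N lists, over all M
acceptable decoys). Spearman correlation and ROC-AUC (acceptable vs
incorrect at DockQ >= 0.23) complete the assessment, plus the min-max
normalization used to map raw energy scores (lower = better) onto [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial.transform import Rotation
from sklearn.metrics import roc_auc_score

from .structure_model import ComplexStructure, interaction_coordinate

D1 = 8.5   # LRMS scaling, A
D2 = 1.5   # iRMS scaling, A
FNAT_CONTACT_CUTOFF = 5.0
IFACE_CUTOFF = 10.0
ACCEPTABLE_DOCKQ = 0.23

CAPRI_THRESHOLDS = (("high", 0.80), ("medium", 0.49), ("acceptable", 0.23))


@dataclass
class DockQResult:
    fnat: float
    lrms: float
    irms: float
    dockq: float
    capri_class: str


@dataclass
class RankingTable:
    """Scored decoys of one target: (decoy id, predicted score, true DockQ)."""

    target_id: str
    rows: list[tuple[str, float, float]]

    def ranked(self) -> list[tuple[str, float, float]]:
        # stable sort by descending score: ties keep input order
        return sorted(self.rows, key=lambda r: -r[1])


# ---------------------------------------------------------------------------
# DockQ components
# ---------------------------------------------------------------------------

def _contact_set(cplx: ComplexStructure, cutoff: float) -> set[tuple[int, int]]:
    """Inter-chain residue pairs with any heavy-atom distance < cutoff."""
    atoms1 = [r.heavy_atom_coords() for r in cplx.chains[0]]
    atoms2 = [r.heavy_atom_coords() for r in cplx.chains[1]]
    contacts = set()
    for i, a1 in enumerate(atoms1):
        for j, a2 in enumerate(atoms2):
            d2 = ((a1[:, None, :] - a2[None, :, :]) ** 2).sum(axis=2)
            if d2.min() < cutoff ** 2:
                contacts.add((i, j))
    return contacts


def compute_fnat(model: ComplexStructure, native: ComplexStructure,
                 contact_cutoff: float = FNAT_CONTACT_CUTOFF) -> float:
    """Fraction of native inter-chain contacts present in the model.

    With backbone-only decoys the heavy-atom set is whatever atoms exist.
    """
    native_contacts = _contact_set(native, contact_cutoff)
    if not native_contacts:
        raise ValueError(
            f"{native.target_id}: native has no inter-chain contacts"
        )
    model_contacts = _contact_set(model, contact_cutoff)
    return len(native_contacts & model_contacts) / len(native_contacts)


def superpose_kabsch(mobile: np.ndarray, reference: np.ndarray,
                     ) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of mobile onto reference.

    Returns (rotation matrix with determinant +1, translation, rmsd) such
    that mobile @ R.T + t approximates reference.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if mobile.shape != reference.shape or mobile.shape[0] < 3:
        raise ValueError("need >= 3 corresponding points")
    mc, rc = mobile.mean(axis=0), reference.mean(axis=0)
    rot, rssd = Rotation.align_vectors(reference - rc, mobile - mc)
    R = rot.as_matrix()
    t = rc - mc @ R.T
    rmsd = rssd / np.sqrt(mobile.shape[0])
    return R, t, float(rmsd)


def _backbone(cplx: ComplexStructure, chain: int,
              residues: list[int] | None = None) -> np.ndarray:
    res_list = cplx.chains[chain]
    if residues is not None:
        res_list = [res_list[r] for r in residues]
    return np.concatenate([r.backbone_coords() for r in res_list])


def compute_lrms(model: ComplexStructure, native: ComplexStructure) -> float:
    """Ligand RMSD: superpose on receptor backbone, measure ligand backbone."""
    R, t, _ = superpose_kabsch(_backbone(model, 0), _backbone(native, 0))
    lig_model = _backbone(model, 1) @ R.T + t
    lig_native = _backbone(native, 1)
    return float(np.sqrt(((lig_model - lig_native) ** 2).sum(axis=1).mean()))


def native_interface_residues(native: ComplexStructure,
                              cutoff: float = IFACE_CUTOFF,
                              ) -> tuple[list[int], list[int]]:
    """Indices (0-based) of native interface residues on each chain."""
    c1 = np.array([interaction_coordinate(r) for r in native.chains[0]])
    c2 = np.array([interaction_coordinate(r) for r in native.chains[1]])
    d = np.sqrt(((c1[:, None, :] - c2[None, :, :]) ** 2).sum(axis=2))
    mask = d < cutoff
    return (sorted(set(np.where(mask)[0].tolist())),
            sorted(set(np.where(mask)[1].tolist())))


def compute_irms(model: ComplexStructure, native: ComplexStructure,
                 iface_cutoff: float = IFACE_CUTOFF) -> float:
    """Interface RMSD over native-interface residues after superposing on them."""
    if1, if2 = native_interface_residues(native, iface_cutoff)
    model_pts = np.concatenate([_backbone(model, 0, if1),
                                _backbone(model, 1, if2)])
    native_pts = np.concatenate([_backbone(native, 0, if1),
                                 _backbone(native, 1, if2)])
    _, _, rmsd = superpose_kabsch(model_pts, native_pts)
    return rmsd


def rms_scaled(rms: float, d: float) -> float:
    return 1.0 / (1.0 + (rms / d) ** 2)


def capri_class(dockq: float) -> str:
    for name, threshold in CAPRI_THRESHOLDS:
        if dockq >= threshold:
            return name
    return "incorrect"


def compute_dockq(fnat: float, lrms: float, irms: float) -> DockQResult:
    dockq = (fnat + rms_scaled(lrms, D1) + rms_scaled(irms, D2)) / 3.0
    return DockQResult(fnat=fnat, lrms=lrms, irms=irms, dockq=dockq,
                       capri_class=capri_class(dockq))


def dockq_for_model(model: ComplexStructure,
                    native: ComplexStructure) -> DockQResult:
    """Full DockQ evaluation of one model/native pair."""
    return compute_dockq(compute_fnat(model, native),
                         compute_lrms(model, native),
                         compute_irms(model, native))


# ---------------------------------------------------------------------------
# ranking metrics
# ---------------------------------------------------------------------------

def success_rate(tables: list[RankingTable], N: int,
                 threshold: float = ACCEPTABLE_DOCKQ) -> float:
    """SR(N): % of targets with >= 1 acceptable decoy among their top N."""
    if not tables:
        raise ValueError("no targets")
    hits = sum(
        any(dockq >= threshold for _, _, dockq in t.ranked()[:N])
        for t in tables
    )
    return 100.0 * hits / len(tables)


def hit_rate(tables: list[RankingTable], N: int,
             threshold: float = ACCEPTABLE_DOCKQ) -> float:
    """HR(N): % of all acceptable decoys captured within per-target top-Ns."""
    M = sum(
        sum(dockq >= threshold for _, _, dockq in t.rows) for t in tables
    )
    if M == 0:
        raise ValueError("no acceptable decoys in the dataset (M = 0)")
    H = sum(
        sum(dockq >= threshold for _, _, dockq in t.ranked()[:N])
        for t in tables
    )
    return 100.0 * H / M


def score_correlation(pred: np.ndarray, truth: np.ndarray) -> float:
    """Spearman rank correlation with average-rank tie handling."""
    pred, truth = np.asarray(pred, float), np.asarray(truth, float)
    if pred.size < 3:
        raise ValueError("need >= 3 pairs for a rank correlation")
    if np.ptp(pred) == 0 or np.ptp(truth) == 0:
        raise ValueError("zero variance: correlation undefined")
    rho, _ = stats.spearmanr(pred, truth)
    return float(rho)


def roc_auc(pred: np.ndarray, labels: np.ndarray) -> float:
    """AUC separating acceptable (True) from incorrect decoys; ties half."""
    labels = np.asarray(labels, bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present for ROC analysis")
    return float(roc_auc_score(labels, np.asarray(pred, float)))


def minmax_normalize(raw: np.ndarray) -> np.ndarray:
    """Map raw per-target energies onto [0, 1]: (X - Xmax)/(Xmin - Xmax).

    Energies are lower-is-better, so the minimum maps to 1 and the maximum
    to 0, aligning them with probability-like quality scores.
    """
    raw = np.asarray(raw, float)
    xmin, xmax = raw.min(), raw.max()
    if xmin == xmax:
        raise ValueError("all scores equal: min-max normalization undefined")
    return (raw - xmax) / (xmin - xmax)


def evaluate_dataset(tables: list[RankingTable],
                     top_n: tuple[int, ...] = (1, 5, 10, 15, 20, 25, 30),
                     threshold: float = ACCEPTABLE_DOCKQ) -> dict:
    """Summary metrics over a scored dataset (the standard reporting grid)."""
    pred = np.array([s for t in tables for _, s, _ in t.rows])
    truth = np.array([q for t in tables for _, _, q in t.rows])
    out = {
        "spearman": score_correlation(pred, truth),
        "auc": roc_auc(pred, truth >= threshold),
    }
    for n in top_n:
        out[f"SR{n}"] = success_rate(tables, n, threshold)
        out[f"HR{n}"] = hit_rate(tables, n, threshold)
    return out


def write_target_tsv(table: RankingTable, results: dict[str, DockQResult],
                     path: str) -> None:
    """Per-target report: decoy, predicted Q, Fnat, LRMS, iRMS, DockQ, class."""
    with open(path, "w") as fh:
        fh.write("decoy\tpredicted_Q\tfnat\tlrms\tirms\tdockq\tcapri_class\n")
        for decoy, score, _ in table.ranked():
            r = results[decoy]
            fh.write(f"{decoy}\t{score:.4f}\t{r.fnat:.4f}\t{r.lrms:.3f}\t"
                     f"{r.irms:.3f}\t{r.dockq:.4f}\t{r.capri_class}\n")
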