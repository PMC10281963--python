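"""Per-node (interface residue) features.

Each node carries 17 features in fixed order:

=====================  ======  ==========================================
block                  width   content
=====================  ======  ==========================================
residue class          5       one-hot: polar / non-polar / positively
                               charged / negatively charged / non-standard
relative position      1       seq_index / chain length, in (0, 1]
secondary structure    3       one-hot: helix / strand / coil
burial                 2       one-hot: buried / exposed (rSASA < 0.25)
backbone torsions      4       sin phi, cos phi, sin psi, cos psi
                               (0, 0) where an angle is undefined
evolutionary depth     2       normalized Neff of the residue's monomer
                               MSA and of the paired MSA (see msa_features)
=====================  ======  ==========================================

Secondary structure and solvent accessibility come from a precomputed DSSP
file when one is supplied; otherwise an internal torsion-window secondary
structure assignment and a Shrake-Rupley solvent-accessible surface area
computation keep the pipeline self-contained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .structure_model import ComplexStructure, Residue, backbone_torsions

NODE_FEATURE_DIM = 17

#: physicochemical partition of the 20 standard residues; anything else
#: (e.g. 'X') falls in the non-standard bin. Configurable via
#: ``encode_residue_class(table=...)``.
DEFAULT_RESIDUE_CLASSES = {
    "polar": set("STNQCYW"),
    "nonpolar": set("AVLIMFPG"),
    "positive": set("KRH"),
    "negative": set("DE"),
}
_CLASS_ORDER = ("polar", "nonpolar", "positive", "negative")

BURIAL_THRESHOLD = 0.25

#: maximum accessible surface areas per residue (A^2), Sander & Rost style,
#: used to normalize absolute SASA into relative SASA
MAX_ASA = {
    "A": 106.0, "R": 248.0, "N": 157.0, "D": 163.0, "C": 135.0,
    "Q": 198.0, "E": 194.0, "G": 84.0, "H": 184.0, "I": 169.0,
    "L": 164.0, "K": 205.0, "M": 188.0, "F": 197.0, "P": 136.0,
    "S": 130.0, "T": 142.0, "W": 227.0, "Y": 222.0, "V": 142.0,
    "X": 180.0,
}

#: van der Waals radii by atom name for the Shrake-Rupley computation
_VDW = {"N": 1.55, "CA": 1.70, "C": 1.70, "O": 1.52, "CB": 1.70}
_PROBE = 1.4
SASA_POINTS = 240

#: DSSP 8-state to 3-state grouping: helices / strands / coils
SS8_TO_SS3 = {
    "H": 0, "G": 0, "I": 0,
    "E": 1, "B": 1,
    "T": 2, "S": 2, "-": 2, " ": 2, "P": 2, "C": 2,
}


def encode_residue_class(aa: str, table: dict | None = None) -> np.ndarray:
    """5-bin one-hot over [polar, non-polar, positive, negative, non-standard]."""
    table = table or DEFAULT_RESIDUE_CLASSES
    out = np.zeros(5)
    for k, name in enumerate(_CLASS_ORDER):
        if aa in table[name]:
            out[k] = 1.0
            return out
    out[4] = 1.0
    return out


def relative_position(seq_index: int, chain_length: int) -> float:
    """Fractional position n / L of a residue within its own chain."""
    if not 1 <= seq_index <= chain_length:
        raise ValueError(
            f"seq_index {seq_index} outside [1, {chain_length}]"
        )
    return seq_index / chain_length


def torsion_features(phi: float | None, psi: float | None) -> np.ndarray:
    """[sin phi, cos phi, sin psi, cos psi]; (0, 0) for an absent angle.

    The zero encoding is distinguishable from any real angle, whose pair
    satisfies sin^2 + cos^2 = 1.
    """
    out = np.zeros(4)
    if phi is not None:
        out[0], out[1] = math.sin(phi), math.cos(phi)
    if psi is not None:
        out[2], out[3] = math.sin(psi), math.cos(psi)
    return out


# ---------------------------------------------------------------------------
# secondary structure and burial
# ---------------------------------------------------------------------------

def _fibonacci_sphere(n: int) -> np.ndarray:
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = math.pi * (1 + 5 ** 0.5) * k
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


def shrake_rupley_sasa(cplx: ComplexStructure,
                       n_points: int = SASA_POINTS) -> list[np.ndarray]:
    """Per-residue absolute SASA (A^2) over all present heavy atoms.

    Deterministic Fibonacci-lattice sampling on each atom sphere; a point
    counts as accessible if no other atom's probe-expanded sphere covers it.
    """
    atoms = []  # (chain, res_idx, center, radius)
    for c, chain in enumerate(cplx.chains):
        for r, res in enumerate(chain):
            named = [("N", res.coords_N), ("CA", res.coords_CA),
                     ("C", res.coords_C)]
            if res.coords_O is not None:
                named.append(("O", res.coords_O))
            if res.coords_CB is not None:
                named.append(("CB", res.coords_CB))
            for name, xyz in named:
                atoms.append((c, r, xyz, _VDW[name] + _PROBE))
    centers = np.array([a[2] for a in atoms])
    radii = np.array([a[3] for a in atoms])
    sphere = _fibonacci_sphere(n_points)

    out = [np.zeros(len(chain)) for chain in cplx.chains]
    for k, (c, r, center, radius) in enumerate(atoms):
        pts = center + radius * sphere
        # neighbours whose expanded spheres could occlude points of atom k
        d = np.linalg.norm(centers - center, axis=1)
        near = np.where((d < radii + radius) & (np.arange(len(atoms)) != k))[0]
        if near.size:
            diff = pts[:, None, :] - centers[near][None, :, :]
            covered = (diff ** 2).sum(axis=2) < radii[near] ** 2
            accessible = ~covered.any(axis=1)
            frac = accessible.mean()
        else:
            frac = 1.0
        out[c][r] += 4 * math.pi * radius ** 2 * frac
    return out


def _torsion_window_ss(chain: list) -> list[int]:
    """3-state secondary structure from phi/psi regions with run smoothing.

    Helix region: phi in (-110, -35), psi in (-75, -5). Strand region:
    phi in (-180, -80), psi in (85, 180) or psi < -170. Assignments are
    kept only in runs of >= 3 (helix) or >= 2 (strand); everything else
    is coil.
    """
    torsions = backbone_torsions(chain)
    raw = []
    for phi, psi in torsions:
        if phi is None or psi is None:
            raw.append(2)
            continue
        phi_d, psi_d = math.degrees(phi), math.degrees(psi)
        if -110 < phi_d < -35 and -75 < psi_d < -5:
            raw.append(0)
        elif -180 <= phi_d < -80 and (85 < psi_d <= 180 or psi_d < -170):
            raw.append(1)
        else:
            raw.append(2)
    out = [2] * len(raw)
    i = 0
    while i < len(raw):
        j = i
        while j < len(raw) and raw[j] == raw[i]:
            j += 1
        run = j - i
        if raw[i] == 0 and run >= 3 or raw[i] == 1 and run >= 2:
            for k in range(i, j):
                out[k] = raw[i]
        i = j
    return out


@dataclass
class DsspRecord:
    chain_id: str
    ss8: str
    acc: float  # absolute accessibility, A^2


def parse_dssp(path: str) -> list[DsspRecord]:
    """Parse the classic fixed-column DSSP output format."""
    records = []
    with open(path) as fh:
        in_data = False
        for line in fh:
            if line.startswith("  #  RESIDUE"):
                in_data = True
                continue
            if not in_data or len(line) < 39:
                continue
            if line[13] == "!":  # chain break marker
                continue
            records.append(DsspRecord(
                chain_id=line[11].strip(),
                ss8=line[16],
                acc=float(line[34:38]),
            ))
    return records


def secondary_structure_features(
    cplx: ComplexStructure,
    dssp_path: str | None = None,
    burial_threshold: float = BURIAL_THRESHOLD,
    sasa_points: int = SASA_POINTS,
) -> list[list[tuple[np.ndarray, np.ndarray]]]:
    """Per-residue (ss3 one-hot, burial one-hot) for both chains.

    With a DSSP file: 8-state codes grouped H/G/I -> helix, E/B -> strand,
    rest -> coil; burial from DSSP's absolute accessibility normalized by
    per-residue maxima. Without: internal torsion-window assignment and
    Shrake-Rupley SASA.
    """
    n_total = cplx.L1 + cplx.L2
    if dssp_path is not None:
        records = parse_dssp(dssp_path)
        if len(records) != n_total:
            raise ValueError(
                f"DSSP file has {len(records)} residues, structure has "
                f"{n_total}"
            )
        ss3_codes = [SS8_TO_SS3.get(rec.ss8, 2) for rec in records]
        rsasa = []
        k = 0
        for chain in cplx.chains:
            vals = []
            for res in chain:
                vals.append(records[k].acc / MAX_ASA.get(res.aa, 180.0))
                k += 1
            rsasa.append(np.array(vals))
        ss3_by_chain = [ss3_codes[:cplx.L1], ss3_codes[cplx.L1:]]
    else:
        ss3_by_chain = [_torsion_window_ss(chain) for chain in cplx.chains]
        abs_sasa = shrake_rupley_sasa(cplx, n_points=sasa_points)
        rsasa = []
        for c, chain in enumerate(cplx.chains):
            maxes = np.array([MAX_ASA.get(r.aa, 180.0) for r in chain])
            rsasa.append(abs_sasa[c] / maxes)

    out = []
    for c, chain in enumerate(cplx.chains):
        per_chain = []
        for r, res in enumerate(chain):
            ss = np.zeros(3)
            ss[ss3_by_chain[c][r]] = 1.0
            burial = np.zeros(2)
            burial[0 if rsasa[c][r] < burial_threshold else 1] = 1.0
            per_chain.append((ss, burial))
        out.append(per_chain)
    return out


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def assemble_node_features(residue_class: np.ndarray, rel_pos: float,
                           ss3: np.ndarray, burial: np.ndarray,
                           torsions: np.ndarray, neff_monomer: float,
                           neff_paired: float) -> np.ndarray:
    """Concatenate the blocks into the fixed-order 17-vector."""
    if len(residue_class) != 5 or len(ss3) != 3 or len(burial) != 2 \
            or len(torsions) != 4:
        raise ValueError("node feature block length mismatch")
    vec = np.concatenate([
        residue_class, [rel_pos], ss3, burial, torsions,
        [neff_monomer, neff_paired],
    ])
    assert vec.shape == (NODE_FEATURE_DIM,)
    return vec


def compute_node_features(cplx: ComplexStructure,
                          graph_nodes: list[tuple[int, Residue]],
                          neff: tuple[float, float, float] = (0.0, 0.0, 0.0),
                          dssp_path: str | None = None,
                          sasa_points: int = SASA_POINTS) -> np.ndarray:
    """The (V, 17) node feature matrix for an interface graph.

    ``neff`` holds the normalized effective sequence counts
    (chain-1 monomer, chain-2 monomer, paired); see
    :func:`ifaceqe.msa_features.node_evolutionary_features`.
    """
    ss_burial = secondary_structure_features(cplx, dssp_path,
                                             sasa_points=sasa_points)
    torsions = [backbone_torsions(chain) for chain in cplx.chains]
    lengths = (cplx.L1, cplx.L2)
    rows = []
    for chain_idx, res in graph_nodes:
        r = res.seq_index - 1
        phi, psi = torsions[chain_idx][r]
        ss3, burial = ss_burial[chain_idx][r]
        rows.append(assemble_node_features(
            encode_residue_class(res.aa),
            relative_position(res.seq_index, lengths[chain_idx]),
            ss3, burial,
            torsion_features(phi, psi),
            neff[chain_idx], neff[2],
        ))
    return np.array(rows)
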