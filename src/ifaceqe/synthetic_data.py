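"""Self-contained synthetic fixtures: toy dimers, decoy sets, MSAs.

The generator emulates a docking decoy benchmark at desk scale. A "native"
is a pair of ideal-geometry alpha-helical chains (built by natural
extension from standard backbone internal coordinates, with small random
torsion jitter so targets differ) docked side by side so the inter-chain
interface holds at least ten residue pairs under 8 A. Decoys are the
native with the ligand chain rigidly rotated/translated by graded
magnitudes plus small backbone jitter, spanning incorrect through
high-quality models; each decoy's true DockQ is attached by the
evaluation module. Synthetic MSAs of controllable depth and per-position
mutation rate provide inputs for the evolutionary features.

Rigid-body perturbation (rather than re-docking) gives analytic control
over ligand RMSD and keeps the DockQ spread wide: the artifact under test
is the scorer, not a docking engine.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np

from .evaluation import DockQResult, dockq_for_model
from .msa_features import MultipleSequenceAlignment
from .structure_model import (ComplexStructure, Residue, place_atom,
                              reconstruct_cbeta)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# ideal backbone internal coordinates (bond lengths A, angles deg)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.2, 116.2, 121.7
_A_CA_C_O = 120.5
_HELIX_PHI, _HELIX_PSI, _OMEGA = -57.0, -47.0, 180.0

#: perturbation grid levels: (max rotation deg, max translation A); the
#: first level is near-native (<= 2 deg, <= 1 A) per the study conditions
DEFAULT_PERTURBATION_GRID = (
    (1.0, 0.3),
    (4.0, 1.0),
    (8.0, 2.0),
    (15.0, 4.0),
    (30.0, 8.0),
    (60.0, 15.0),
    (180.0, 30.0),
)


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic benchmark bundle."""

    n_targets: int = 20
    chain_length_range: tuple[int, int] = (40, 60)
    decoys_per_target: int = 30
    perturbation_grid: tuple[tuple[float, float], ...] = DEFAULT_PERTURBATION_GRID
    msa_depth: int = 30
    msa_mutation_rate: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_targets, self.decoys_per_target, self.msa_depth) < 1:
            raise ValueError("all counts must be >= 1")
        if not any(r <= 2.0 and t <= 1.0 for r, t in self.perturbation_grid):
            raise ValueError(
                "perturbation grid must include a near-native level "
                "(<= 2 deg, <= 1 A)"
            )


@dataclass
class DecoySet:
    """One target's native plus its scored decoys."""

    target_id: str
    native: ComplexStructure
    decoys: list[tuple[str, ComplexStructure, DockQResult]]


# ---------------------------------------------------------------------------
# backbone construction
# ---------------------------------------------------------------------------

def _build_chain(sequence: str, phis: np.ndarray, psis: np.ndarray,
                 chain_id: str) -> list[Residue]:
    """Natural-extension backbone build from per-residue phi/psi (degrees)."""
    n_res = len(sequence)
    rad = math.radians
    # seed atoms for residue 1
    N = np.zeros(3)
    CA = np.array([_B_N_CA, 0.0, 0.0])
    C = place_atom(np.array([-1.0, 1.0, 0.0]), N, CA, _B_CA_C,
                   rad(_A_N_CA_C), rad(120.0))
    atoms = [(N, CA, C)]
    for i in range(1, n_res):
        pN, pCA, pC = atoms[-1]
        Nn = place_atom(pN, pCA, pC, _B_C_N, rad(_A_CA_C_N), rad(psis[i - 1]))
        CAn = place_atom(pCA, pC, Nn, _B_N_CA, rad(_A_C_N_CA), rad(_OMEGA))
        Cn = place_atom(pC, Nn, CAn, _B_CA_C, rad(_A_N_CA_C), rad(phis[i]))
        atoms.append((Nn, CAn, Cn))

    residues = []
    for i, (aa, (Ni, CAi, Ci)) in enumerate(zip(sequence, atoms)):
        psi = psis[i] if i < n_res - 1 else _HELIX_PSI
        O = place_atom(Ni, CAi, Ci, _B_C_O, rad(_A_CA_C_O), rad(psi + 180.0))
        res = Residue(chain_id=chain_id, seq_index=i + 1, aa=aa,
                      coords_N=Ni, coords_CA=CAi, coords_C=Ci, coords_O=O,
                      author_number=str(i + 1))
        if aa != "G":
            res.coords_CB = reconstruct_cbeta(res)
        residues.append(res)
    return residues


def _random_rotation(rng: np.random.Generator,
                     max_angle_deg: float | None = None) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    if max_angle_deg is None:
        angle = rng.uniform(0, 2 * math.pi)
    else:
        angle = math.radians(rng.uniform(0, max_angle_deg))
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(angle) * K + (1 - math.cos(angle)) * K @ K


def transform_chain(chain: list[Residue], R: np.ndarray, t: np.ndarray,
                    ) -> list[Residue]:
    out = []
    for r in chain:
        out.append(Residue(
            chain_id=r.chain_id, seq_index=r.seq_index, aa=r.aa,
            coords_N=r.coords_N @ R.T + t,
            coords_CA=r.coords_CA @ R.T + t,
            coords_C=r.coords_C @ R.T + t,
            coords_CB=None if r.coords_CB is None else r.coords_CB @ R.T + t,
            coords_O=None if r.coords_O is None else r.coords_O @ R.T + t,
            author_number=r.author_number,
        ))
    return out


def _interface_pair_count(chain1, chain2, cutoff: float = 8.0) -> int:
    from .structure_model import interaction_coordinate
    c1 = np.array([interaction_coordinate(r) for r in chain1])
    c2 = np.array([interaction_coordinate(r) for r in chain2])
    d = np.sqrt(((c1[:, None, :] - c2[None, :, :]) ** 2).sum(axis=2))
    return int((d < cutoff).sum())


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(AMINO_ACIDS[k] for k in rng.integers(0, 20, size=length))


def generate_native(spec: SyntheticSpec, target_index: int,
                    ) -> ComplexStructure:
    """Deterministic toy native dimer for (spec.seed, target_index).

    Two jittered alpha-helices packed antiparallel; the ligand helix is
    pulled in until the interface holds >= 10 residue pairs under 8 A.
    """
    rng = np.random.default_rng([spec.seed, target_index, 7])
    lo, hi = spec.chain_length_range
    L1, L2 = int(rng.integers(lo, hi + 1)), int(rng.integers(lo, hi + 1))
    seq1, seq2 = _random_sequence(rng, L1), _random_sequence(rng, L2)
    if target_index == 0:
        # plant one non-standard residue per bundle to exercise the
        # fifth residue-class bin
        seq1 = "X" + seq1[1:]

    def jittered(n):
        return (np.full(n, _HELIX_PHI) + rng.uniform(-6, 6, n),
                np.full(n, _HELIX_PSI) + rng.uniform(-6, 6, n))

    phis1, psis1 = jittered(L1)
    phis2, psis2 = jittered(L2)
    chain1 = _build_chain(seq1, phis1, psis1, "A")
    chain2 = _build_chain(seq2, phis2, psis2, "B")

    # centre both helices with principal axes along z, flip the ligand
    # antiparallel, then pack along x until the interface is large enough
    def centred_on_z(chain):
        cas = np.array([r.coords_CA for r in chain])
        centre = cas.mean(axis=0)
        _, _, vt = np.linalg.svd(cas - centre)
        axis = vt[0]
        z = np.array([0.0, 0.0, 1.0])
        v = np.cross(axis, z)
        s, c = np.linalg.norm(v), float(axis @ z)
        if s < 1e-12:
            R = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
        else:
            K = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]],
                          [-v[1], v[0], 0]])
            R = np.eye(3) + K + K @ K * (1 - c) / s ** 2
        return transform_chain(chain, R, -centre @ R.T)

    chain1 = centred_on_z(chain1)
    chain2 = centred_on_z(chain2)
    flip = np.diag([1.0, -1.0, -1.0])  # 180 deg about x: antiparallel packing
    chain2 = transform_chain(chain2, flip, np.zeros(3))

    for attempt in range(30):
        dx = 10.5 - 0.5 * attempt
        cand = transform_chain(chain2, np.eye(3), np.array([dx, 0.0, 0.0]))
        if _interface_pair_count(chain1, cand) >= 10:
            chain2 = cand
            break
    else:
        raise RuntimeError(
            f"target {target_index}: could not pack an interface with >= 10 "
            "residue pairs under 8 A"
        )

    # random global orientation for variety
    Rg = _random_rotation(rng)
    tg = rng.uniform(-5, 5, size=3)
    chain1 = transform_chain(chain1, Rg, tg)
    chain2 = transform_chain(chain2, Rg, tg)
    for r in chain1:
        r.chain_id = "A"
    for r in chain2:
        r.chain_id = "B"
    return ComplexStructure(chains=(chain1, chain2),
                            target_id=f"T{target_index:03d}")


def generate_decoys(native: ComplexStructure, spec: SyntheticSpec,
                    target_index: int = 0) -> DecoySet:
    """Graded rigid-body decoys of one native, with true DockQ attached.

    Decoy d uses perturbation level d mod len(grid): the ligand chain is
    rotated about a random axis through its centroid by an angle uniform in
    [0, level rotation] and translated by a random vector of magnitude
    uniform in [0, level translation]; all backbone atoms then receive
    Gaussian jitter (sigma 0.1 A), small enough that residue correspondence
    by index always holds.
    """
    rng = np.random.default_rng([spec.seed, target_index, 13])
    grid = spec.perturbation_grid
    decoys = []
    for d in range(spec.decoys_per_target):
        max_rot, max_trans = grid[d % len(grid)]
        R = _random_rotation(rng, max_rot)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        t = direction * rng.uniform(0, max_trans)
        centroid = np.array([r.coords_CA for r in native.chains[1]]).mean(axis=0)
        # rotate about the ligand centroid, then translate
        ligand = transform_chain(native.chains[1], R,
                                 centroid - centroid @ R.T + t)
        receptor = [Residue(
            chain_id=r.chain_id, seq_index=r.seq_index, aa=r.aa,
            coords_N=r.coords_N.copy(), coords_CA=r.coords_CA.copy(),
            coords_C=r.coords_C.copy(),
            coords_CB=None if r.coords_CB is None else r.coords_CB.copy(),
            coords_O=None if r.coords_O is None else r.coords_O.copy(),
            author_number=r.author_number) for r in native.chains[0]]
        for chain in (receptor, ligand):
            for r in chain:
                for attr in ("coords_N", "coords_CA", "coords_C",
                             "coords_CB", "coords_O"):
                    v = getattr(r, attr)
                    if v is not None:
                        setattr(r, attr, v + rng.normal(0, 0.1, 3))
        decoy_id = f"{native.target_id}_d{d:03d}"
        decoy = ComplexStructure(chains=(receptor, ligand),
                                 target_id=decoy_id)
        decoys.append((decoy_id, decoy, dockq_for_model(decoy, native)))
    return DecoySet(target_id=native.target_id, native=native, decoys=decoys)


# ---------------------------------------------------------------------------
# synthetic MSAs
# ---------------------------------------------------------------------------

def generate_msa(sequence: str, depth: int, mutation_rate: float,
                 seed: int) -> MultipleSequenceAlignment:
    """Query plus depth-1 mutated copies.

    Each non-query row substitutes every position independently with
    probability ``mutation_rate`` by a uniformly chosen *different* residue,
    so the expected identity to the query is exactly 1 - rate.
    """
    if not 0 <= mutation_rate < 1:
        raise ValueError("mutation rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    rows = [sequence]
    alphabet = np.array(list(AMINO_ACIDS))
    seq_arr = np.array(list(sequence))
    for _ in range(depth - 1):
        mutate = rng.random(len(sequence)) < mutation_rate
        row = seq_arr.copy()
        for p in np.where(mutate)[0]:
            choices = alphabet[alphabet != row[p]]
            row[p] = choices[rng.integers(len(choices))]
        rows.append("".join(row))
    return MultipleSequenceAlignment(rows)


def paired_msa(msa1: MultipleSequenceAlignment,
               msa2: MultipleSequenceAlignment) -> MultipleSequenceAlignment:
    """Column-wise concatenation, rows matched by index (toy pairing)."""
    n = min(msa1.n_rows, msa2.n_rows)
    return MultipleSequenceAlignment(
        [msa1.sequences[k] + msa2.sequences[k] for k in range(n)]
    )


def target_msas(native: ComplexStructure, spec: SyntheticSpec,
                target_index: int):
    """(chain-1, chain-2, paired) MSAs for one target."""
    m1 = generate_msa(native.sequence(0), spec.msa_depth,
                      spec.msa_mutation_rate,
                      seed=spec.seed * 100003 + target_index * 2 + 1)
    m2 = generate_msa(native.sequence(1), spec.msa_depth,
                      spec.msa_mutation_rate,
                      seed=spec.seed * 100003 + target_index * 2 + 2)
    return m1, m2, paired_msa(m1, m2)


# ---------------------------------------------------------------------------
# file output
# ---------------------------------------------------------------------------

_PDB_ATOM = ("ATOM  {serial:5d} {name:^4s}{alt:1s}{resn:3s} {chain:1s}"
             "{resseq:4d}{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}"
             "{occ:6.2f}{b:6.2f}          {element:>2s}\n")

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
    "X": "UNK",
}


def write_pdb(cplx: ComplexStructure, path: str) -> None:
    """Write the complex as minimal single-model two-chain ATOM records."""
    serial = 1
    with open(path, "w") as fh:
        for chain in cplx.chains:
            for res in chain:
                named = [("N", res.coords_N, "N"), ("CA", res.coords_CA, "C"),
                         ("C", res.coords_C, "C")]
                if res.coords_O is not None:
                    named.append(("O", res.coords_O, "O"))
                if res.coords_CB is not None:
                    named.append(("CB", res.coords_CB, "C"))
                for name, xyz, element in named:
                    fh.write(_PDB_ATOM.format(
                        serial=serial, name=name, alt=" ",
                        resn=_ONE_TO_THREE.get(res.aa, "UNK"),
                        chain=res.chain_id, resseq=res.seq_index, icode=" ",
                        x=xyz[0], y=xyz[1], z=xyz[2], occ=1.0, b=0.0,
                        element=element))
                    serial += 1
            fh.write("TER\n")
        fh.write("END\n")


def write_msa_fasta(msa: MultipleSequenceAlignment, path: str) -> None:
    with open(path, "w") as fh:
        for k, seq in enumerate(msa.sequences):
            fh.write(f">{'query' if k == 0 else f'seq{k}'}\n{seq}\n")


def write_fixture_bundle(spec: SyntheticSpec, out_dir: str) -> list[DecoySet]:
    """Write the full bundle: natives, decoys, MSAs, and a manifest TSV."""
    os.makedirs(out_dir, exist_ok=True)
    manifest = os.path.join(out_dir, "manifest.tsv")
    sets = []
    with open(manifest, "w") as mh:
        mh.write("target\tdecoy\tfnat\tlrms\tirms\tdockq\tcapri_class\n")
        for t in range(spec.n_targets):
            native = generate_native(spec, t)
            tdir = os.path.join(out_dir, native.target_id)
            os.makedirs(tdir, exist_ok=True)
            write_pdb(native, os.path.join(tdir, "native.pdb"))
            m1, m2, mp = target_msas(native, spec, t)
            for chain_no, msa in (("1", m1), ("2", m2)):
                write_msa_fasta(
                    MultipleSequenceAlignment([msa.sequences[0]]),
                    os.path.join(tdir, f"chain{chain_no}.fasta"))
                write_msa_fasta(msa, os.path.join(tdir, f"chain{chain_no}.a3m"))
            write_msa_fasta(mp, os.path.join(tdir, "paired.a3m"))
            dset = generate_decoys(native, spec, t)
            for decoy_id, decoy, res in dset.decoys:
                write_pdb(decoy, os.path.join(tdir, f"{decoy_id}.pdb"))
                mh.write(f"{native.target_id}\t{decoy_id}\t{res.fnat:.4f}\t"
                         f"{res.lrms:.3f}\t{res.irms:.3f}\t{res.dockq:.6f}\t"
                         f"{res.capri_class}\n")
            sets.append(dset)
    return sets
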