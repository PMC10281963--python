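"""Dimeric complex structures and coordinate primitives.

Reads two-chain protein complex models from PDB files into a lightweight
residue container and exposes the geometric primitives every downstream
stage needs: the interaction coordinate (C-beta, falling back to C-alpha
for glycine), ideal virtual C-beta reconstruction, backbone phi/psi
torsions, and the four-point dihedral itself.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBParser

logger = logging.getLogger("ifaceqe")

#: residues with any of these atoms missing are unusable for featurization
BACKBONE_ATOMS = ("N", "CA", "C")

#: ideal tetrahedral C-beta internal coordinates (bond to CA, angle N-CA-CB,
#: dihedral C-N-CA-CB)
CB_BOND_LENGTH = 1.522
CB_BOND_ANGLE = math.radians(110.4)
CB_DIHEDRAL = math.radians(-122.6)

#: maximum CA-CA distance between sequence neighbours before the chain is
#: considered broken (torsions across the break are undefined)
CHAIN_BREAK_CUTOFF = 4.5

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # selenomethionine is treated as methionine; decoys are predictions
    "MSE": "M",
}


class StructureError(ValueError):
    """Raised when a structure file cannot provide a usable dimer."""


@dataclass
class Residue:
    """One amino-acid residue with backbone (and optionally C-beta) coordinates.

    ``seq_index`` is the internal 1-based sequential index within its chain;
    the original author numbering is retained in ``author_number`` for
    reporting only.
    """

    chain_id: str
    seq_index: int
    aa: str
    coords_N: np.ndarray
    coords_CA: np.ndarray
    coords_C: np.ndarray
    coords_CB: np.ndarray | None = None
    coords_O: np.ndarray | None = None
    author_number: str = ""

    def heavy_atom_coords(self) -> np.ndarray:
        """All present heavy atoms as an (n, 3) array."""
        pts = [self.coords_N, self.coords_CA, self.coords_C]
        if self.coords_O is not None:
            pts.append(self.coords_O)
        if self.coords_CB is not None:
            pts.append(self.coords_CB)
        return np.asarray(pts, dtype=float)

    def backbone_coords(self) -> np.ndarray:
        """N, CA, C (and O when present) as an (n, 3) array."""
        pts = [self.coords_N, self.coords_CA, self.coords_C]
        if self.coords_O is not None:
            pts.append(self.coords_O)
        return np.asarray(pts, dtype=float)


@dataclass
class ComplexStructure:
    """A dimeric complex: chain 1 is the receptor, chain 2 the ligand."""

    chains: tuple[list[Residue], list[Residue]]
    target_id: str = ""

    def __post_init__(self) -> None:
        if len(self.chains) != 2:
            raise StructureError(
                f"{self.target_id or 'complex'}: exactly two chains required, "
                f"got {len(self.chains)}"
            )
        for c, chain in enumerate(self.chains):
            if not chain:
                raise StructureError(
                    f"{self.target_id or 'complex'}: chain {c + 1} is empty"
                )
            idx = [r.seq_index for r in chain]
            if idx != sorted(idx):
                raise StructureError("residues must be sorted by seq_index")

    @property
    def L1(self) -> int:
        return len(self.chains[0])

    @property
    def L2(self) -> int:
        return len(self.chains[1])

    def sequence(self, chain: int) -> str:
        return "".join(r.aa for r in self.chains[chain])


# ---------------------------------------------------------------------------
# geometric primitives
# ---------------------------------------------------------------------------

def _cross3(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    # np.cross has high call overhead for single 3-vectors
    return np.array([u[1] * v[2] - u[2] * v[1],
                     u[2] * v[0] - u[0] * v[2],
                     u[0] * v[1] - u[1] * v[0]])


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray,
             p3: np.ndarray) -> float:
    """Signed dihedral angle of four points, in (-pi, pi]."""
    b0 = np.asarray(p1, float) - np.asarray(p0, float)
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    n1 = _cross3(b0, b1)
    n2 = _cross3(b1, b2)
    x = float(n1 @ n2)
    # IUPAC sign: positive for a clockwise far-bond rotation viewed along
    # the central bond (matches Bio.PDB.vectors.calc_dihedral)
    y = float(_cross3(n1, n2) @ (b1 / np.linalg.norm(b1)))
    ang = math.atan2(y, x)
    return math.pi if ang == -math.pi else ang


def planar_angle(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> float:
    """Angle at vertex p1, in [0, pi]."""
    v1 = np.asarray(p0, float) - np.asarray(p1, float)
    v2 = np.asarray(p2, float) - np.asarray(p1, float)
    cosang = float(v1 @ v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return math.acos(min(1.0, max(-1.0, cosang)))


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place a fourth atom from three anchors and internal coordinates.

    Standard natural-extension construction: the new atom sits ``bond``
    angstroms from ``c``, with bond angle ``angle`` at c (relative to b) and
    dihedral ``torsion`` about the b-c axis (relative to a).
    """
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([
        -bond * math.cos(angle),
        bond * math.sin(angle) * math.cos(torsion),
        bond * math.sin(angle) * math.sin(torsion),
    ])
    return c + d[0] * bc + d[1] * m + d[2] * n


def reconstruct_cbeta(res: Residue) -> np.ndarray:
    """Ideal tetrahedral C-beta from the residue's N, CA, C atoms."""
    return place_atom(res.coords_C, res.coords_N, res.coords_CA,
                      CB_BOND_LENGTH, CB_BOND_ANGLE, CB_DIHEDRAL)


def interaction_coordinate(res: Residue, reconstruct: bool = True) -> np.ndarray:
    """The point used for interface detection: C-beta, C-alpha for glycine.

    Non-glycine residues lacking a C-beta get an ideal reconstructed one
    unless ``reconstruct`` is disabled, in which case this is an error:
    docking decoys frequently omit side chains, but the caller may insist
    on observed atoms.
    """
    if res.aa == "G":
        return res.coords_CA
    if res.coords_CB is not None:
        return res.coords_CB
    if reconstruct:
        return reconstruct_cbeta(res)
    raise StructureError(
        f"residue {res.chain_id}{res.seq_index} ({res.aa}) has no C-beta "
        "and reconstruction is disabled"
    )


def orientation_cbeta(res: Residue) -> np.ndarray:
    """C-beta used for orientation angles: virtual for glycine.

    The interaction *distance* uses C-alpha for glycine, but the orientation
    angles need a C-alpha -> C-beta direction, so glycine gets an ideal
    virtual C-beta.
    """
    if res.coords_CB is not None and res.aa != "G":
        return res.coords_CB
    return reconstruct_cbeta(res)


def backbone_torsions(chain: list[Residue]) -> list[tuple[float | None, float | None]]:
    """Per-residue (phi, psi) in radians; None where undefined.

    phi(i) = dihedral C(i-1)-N(i)-CA(i)-C(i); psi(i) = N(i)-CA(i)-C(i)-N(i+1).
    Undefined at chain termini and across chain breaks (CA-CA > 4.5 A).
    """
    n = len(chain)
    out: list[tuple[float | None, float | None]] = []

    def connected(i: int, j: int) -> bool:
        d = np.linalg.norm(chain[i].coords_CA - chain[j].coords_CA)
        ok = d <= CHAIN_BREAK_CUTOFF
        if not ok:
            logger.warning(
                "chain break between %s%d and %s%d (CA-CA %.1f A)",
                chain[i].chain_id, chain[i].seq_index,
                chain[j].chain_id, chain[j].seq_index, d,
            )
        return ok

    for i, res in enumerate(chain):
        phi: float | None = None
        psi: float | None = None
        if i > 0 and connected(i - 1, i):
            prev = chain[i - 1]
            phi = dihedral(prev.coords_C, res.coords_N, res.coords_CA,
                           res.coords_C)
        if i < n - 1 and connected(i, i + 1):
            nxt = chain[i + 1]
            psi = dihedral(res.coords_N, res.coords_CA, res.coords_C,
                           nxt.coords_N)
        out.append((phi, psi))
    return out


# ---------------------------------------------------------------------------
# PDB input
# ---------------------------------------------------------------------------

def read_complex_pdb(path: str, chain_ids: tuple[str, str] | None = None,
                     target_id: str | None = None) -> ComplexStructure:
    """Read a dimeric complex from a PDB file.

    Only ATOM records of the first model are used; HETATM is ignored except
    MSE, which Biopython returns as a standard residue when present as ATOM.
    Altloc conflicts are resolved by Biopython (highest occupancy). If
    ``chain_ids`` is not given, the two largest chains by residue count are
    taken in file order. Residues missing any of N, CA, C are dropped with a
    warning. Residues are renumbered sequentially 1-based per chain;
    insertion codes are folded into that renumbering.
    """
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure("cplx", path)
    model = next(iter(structure))

    chains: dict[str, list[Residue]] = {}
    for bio_chain in model:
        residues: list[Residue] = []
        for bio_res in bio_chain:
            hetflag, resseq, icode = bio_res.get_id()
            resname = bio_res.get_resname().strip()
            if hetflag.strip() and resname != "MSE":
                continue  # skip waters/ligands
            coords = {}
            for name in ("N", "CA", "C", "CB", "O"):
                if name in bio_res:
                    coords[name] = np.asarray(bio_res[name].get_coord(), float)
            if any(a not in coords for a in BACKBONE_ATOMS):
                logger.warning(
                    "%s: dropping residue %s %s%s%s (incomplete backbone)",
                    path, resname, bio_chain.id, resseq, icode.strip(),
                )
                continue
            aa = THREE_TO_ONE.get(resname, "X")
            residues.append(Residue(
                chain_id=bio_chain.id,
                seq_index=len(residues) + 1,
                aa=aa,
                coords_N=coords["N"],
                coords_CA=coords["CA"],
                coords_C=coords["C"],
                coords_CB=coords.get("CB"),
                coords_O=coords.get("O"),
                author_number=f"{resseq}{icode.strip()}",
            ))
        if residues:
            chains[bio_chain.id] = residues

    if chain_ids is not None:
        missing = [c for c in chain_ids if c not in chains]
        if missing:
            raise StructureError(
                f"{path}: chain(s) {missing} not found; available: "
                f"{sorted(chains)}"
            )
        selected = [chains[c] for c in chain_ids]
    else:
        if len(chains) < 2:
            raise StructureError(
                f"{path}: fewer than two parseable chains "
                f"(found {sorted(chains)})"
            )
        # two largest by residue count, ties broken by file order
        order = sorted(chains, key=lambda c: -len(chains[c]))[:2]
        order = [c for c in chains if c in order]
        selected = [chains[c] for c in order]

    return ComplexStructure(
        chains=(selected[0], selected[1]),
        target_id=target_id or path,
    )
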