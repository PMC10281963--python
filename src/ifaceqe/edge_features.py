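"""Per-edge (interacting residue pair) features.

Each edge carries 27 features: a 17-bin one-hot of the C-beta--C-beta
distance (16 half-open 0.5 A bins covering [2, 10) plus one catch-all bin
for sub-2 A clashes) followed by sine/cosine transforms of five
inter-residue orientation angles describing the relative geometry of the
two residues' C-alpha -> C-beta vectors across the interface:

* Omega  -- torsion about the virtual C-beta_i -- C-beta_j axis
  (CA_i, CB_i, CB_j, CA_j); symmetric under residue-order swap.
* tau_12 -- torsion N_i, CA_i, CB_i, CB_j;  tau_21 is its mirror with the
  roles of i and j exchanged.
* lambda_12 -- planar angle CA_i, CB_i, CB_j; lambda_21 the mirror.

The tau/lambda pairs are asymmetric and exchange under order swap.
Glycine uses an ideal virtual C-beta for the angles even though its
interaction *distance* uses C-alpha.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .structure_model import (Residue, _cross3, dihedral, orientation_cbeta,
                              planar_angle)

EDGE_FEATURE_DIM = 27
N_DISTANCE_BINS = 17
_BIN_MIN, _BIN_MAX, _BIN_WIDTH = 2.0, 10.0, 0.5
_DEGENERACY_EPS = 1e-9


@dataclass
class OrientationFrame:
    """The three atoms defining a residue's orientation: N, CA, CB."""

    N: np.ndarray
    CA: np.ndarray
    CB: np.ndarray

    @classmethod
    def from_residue(cls, res: Residue) -> "OrientationFrame":
        return cls(N=res.coords_N, CA=res.coords_CA,
                   CB=orientation_cbeta(res))


def bin_distance(d: float) -> np.ndarray:
    """17-bin one-hot: bins 1-16 cover [2, 10) in 0.5 A steps, bin 17 is
    the sub-2 A clash bin. Distances >= 10 A cannot be edges."""
    if d <= 0:
        raise ValueError(f"distance must be positive, got {d}")
    if d >= _BIN_MAX:
        raise ValueError(f"distance {d} >= {_BIN_MAX} A cannot be an edge")
    out = np.zeros(N_DISTANCE_BINS)
    if d < _BIN_MIN:
        out[16] = 1.0
    else:
        out[int((d - _BIN_MIN) // _BIN_WIDTH)] = 1.0
    return out


def _degenerate(*triples) -> bool:
    """True if any bond-angle triple is (near-)collinear."""
    for a, b, c in triples:
        v1, v2 = a - b, c - b
        cross = _cross3(v1, v2)
        denom = np.linalg.norm(v1) * np.linalg.norm(v2)
        if denom < _DEGENERACY_EPS or \
                np.linalg.norm(cross) / denom < _DEGENERACY_EPS:
            return True
    return False


def orientation_angles(frame_i: OrientationFrame, frame_j: OrientationFrame,
                       ) -> tuple[float, ...] | None:
    """(Omega, tau_12, tau_21, lambda_12, lambda_21) in radians.

    Dihedrals lie in (-pi, pi], planar angles in [0, pi]. Returns None for
    degenerate (collinear) geometry, which the feature assembly encodes as
    all-zero sine/cosine pairs.
    """
    Ni, CAi, CBi = frame_i.N, frame_i.CA, frame_i.CB
    Nj, CAj, CBj = frame_j.N, frame_j.CA, frame_j.CB
    if _degenerate((CAi, CBi, CBj), (CAj, CBj, CBi),
                   (Ni, CAi, CBi), (Nj, CAj, CBj)):
        return None
    omega = dihedral(CAi, CBi, CBj, CAj)
    tau12 = dihedral(Ni, CAi, CBi, CBj)
    tau21 = dihedral(Nj, CAj, CBj, CBi)
    lam12 = planar_angle(CAi, CBi, CBj)
    lam21 = planar_angle(CAj, CBj, CBi)
    return omega, tau12, tau21, lam12, lam21


def assemble_edge_features(d: float,
                           angles: tuple[float, ...] | None) -> np.ndarray:
    """Concatenate [distance one-hot (17), sin/cos of the 5 angles (10)]."""
    onehot = bin_distance(d)
    orient = np.zeros(10)
    if angles is not None:
        for k, ang in enumerate(angles):
            orient[2 * k] = math.sin(ang)
            orient[2 * k + 1] = math.cos(ang)
    vec = np.concatenate([onehot, orient])
    assert vec.shape == (EDGE_FEATURE_DIM,)
    return vec


def compute_edge_features(graph_nodes, edges, edge_distance) -> np.ndarray:
    """The (E, 27) edge feature matrix for an interface graph."""
    frames = [OrientationFrame.from_residue(res) for _, res in graph_nodes]
    rows = []
    for e, (i, j) in enumerate(edges):
        angles = orientation_angles(frames[i], frames[j])
        rows.append(assemble_edge_features(float(edge_distance[e]), angles))
    return np.array(rows)
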