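"""Structure-derived geometric quantities for residue pairs.

Five quantities describe the local geometry of a residue pair without
reference to the laboratory frame, which makes them invariant under rigid
motion of the whole chain:

* ``d1_mean`` - mean Euclidean distance over all heavy-atom cross pairs;
* ``d1_sd``   - population standard deviation of those distances;
* ``d_alpha`` - the Calpha-Calpha distance;
* ``delta``   - angle between the two residue-plane normals (the plane of a
  residue is spanned by the Calpha->N and Calpha->C vectors), degrees;
* ``theta``   - inter-helical tilt angle between the axes of the two helices
  carrying the residues, degrees.

The axis of a helix follows the alignment of its backbone dipoles: it is the
(re-normalised) mean of the unit vectors from the carbonyl oxygen O(i) to the
amide nitrogen N(i+4) - the alpha-helical hydrogen-bond partner - over all
residues i of the segment for which both atoms exist.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Tuple

import numpy as np
from scipy.spatial.distance import cdist

from .errors import AxisUndefinedError, DegeneratePlaneError, MissingAtomsError
from .structure_io import ChainStructure, ResidueRecord

__all__ = [
    "HelixAxis",
    "PairGeometry",
    "helix_axis",
    "tilt_angle",
    "residue_plane_normal",
    "relative_residue_angle",
    "d1_mean",
    "d1_sd",
    "d_alpha",
    "pair_geometry",
]


@dataclasses.dataclass(frozen=True)
class HelixAxis:
    helix_index: int
    direction: np.ndarray  # unit 3-vector
    n_vectors: int

    def __post_init__(self) -> None:
        norm = float(np.linalg.norm(self.direction))
        if abs(norm - 1.0) > 1e-9:
            raise ValueError("axis direction must be a unit vector")
        if self.n_vectors < 1:
            raise ValueError("axis requires at least one O->N vector")


@dataclasses.dataclass(frozen=True)
class PairGeometry:
    d1_mean: float
    d1_sd: float
    d_alpha: float
    delta: float
    theta: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.d1_mean, self.d1_sd, self.d_alpha, self.delta, self.theta]
        )


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    # clamp guards against |dot| creeping past 1 by rounding
    cosang = float(np.clip(np.dot(u, v), -1.0, 1.0))
    return float(np.degrees(np.arccos(cosang)))


def helix_axis(
    chain: ChainStructure, segment: Tuple[int, int], helix_index: int = 0
) -> HelixAxis:
    """Axis of the helix spanning inclusive positions ``segment``.

    Averages unit O(i) -> N(i+4) vectors over every i in [start, end-4]
    where both atoms exist, then re-normalises the mean.
    """
    start, end = segment
    if end - start + 1 < 5:
        raise AxisUndefinedError(
            f"segment {segment}: need at least 5 residues for an O(i)->N(i+4) vector"
        )
    vectors = []
    for i in range(start, end - 3):
        r_i = chain.residue(i)
        r_i4 = chain.residue(i + 4)
        if r_i is None or r_i4 is None:
            continue
        o = r_i.get("O")
        n = r_i4.get("N")
        if o is None or n is None:
            continue
        v = n - o
        norm = np.linalg.norm(v)
        if norm == 0:
            continue
        vectors.append(v / norm)
    if not vectors:
        raise AxisUndefinedError(f"segment {segment}: no valid O(i)->N(i+4) pair")
    mean = np.mean(vectors, axis=0)
    norm = np.linalg.norm(mean)
    if norm == 0:
        raise AxisUndefinedError(f"segment {segment}: O->N vectors cancel")
    return HelixAxis(helix_index, mean / norm, len(vectors))


def tilt_angle(a: HelixAxis, b: HelixAxis) -> float:
    """Angle between two helix axes, degrees in [0, 180]."""
    return _angle_deg(a.direction, b.direction)


def residue_plane_normal(r: ResidueRecord) -> np.ndarray:
    """Unit normal of the residue plane: cross(N - CA, C - CA)."""
    n, ca, c = r.get("N"), r.get("CA"), r.get("C")
    if n is None or ca is None or c is None:
        raise MissingAtomsError(
            f"residue {r.position}: needs N, CA and C for a plane normal"
        )
    normal = np.cross(n - ca, c - ca)
    norm = np.linalg.norm(normal)
    if norm < 1e-12:
        raise DegeneratePlaneError(f"residue {r.position}: N-CA and C-CA collinear")
    return normal / norm


def relative_residue_angle(r1: ResidueRecord, r2: ResidueRecord) -> float:
    """delta: angle between the two residue-plane normals, degrees in [0, 180]."""
    return _angle_deg(residue_plane_normal(r1), residue_plane_normal(r2))


def _cross_distances(r1: ResidueRecord, r2: ResidueRecord) -> np.ndarray:
    a, b = r1.heavy_coords(), r2.heavy_coords()
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise MissingAtomsError(
            f"residues {r1.position}/{r2.position}: need heavy atoms"
        )
    return cdist(a, b).ravel()


def d1_mean(r1: ResidueRecord, r2: ResidueRecord) -> float:
    """Mean heavy-atom cross distance (over all M*N atom pairs)."""
    return float(_cross_distances(r1, r2).mean())


def d1_sd(r1: ResidueRecord, r2: ResidueRecord) -> float:
    """Population standard deviation of the M*N heavy-atom cross distances."""
    return float(_cross_distances(r1, r2).std(ddof=0))


def d_alpha(r1: ResidueRecord, r2: ResidueRecord) -> float:
    """Calpha-Calpha distance."""
    ca1, ca2 = r1.get("CA"), r2.get("CA")
    if ca1 is None or ca2 is None:
        raise MissingAtomsError(
            f"residues {r1.position}/{r2.position}: both need a CA atom"
        )
    return float(np.linalg.norm(ca1 - ca2))


def pair_geometry(
    r1: ResidueRecord,
    r2: ResidueRecord,
    axis1: HelixAxis,
    axis2: HelixAxis,
) -> PairGeometry:
    """All five quantities for one residue pair."""
    dists = _cross_distances(r1, r2)
    return PairGeometry(
        d1_mean=float(dists.mean()),
        d1_sd=float(dists.std(ddof=0)),
        d_alpha=d_alpha(r1, r2),
        delta=relative_residue_angle(r1, r2),
        theta=tilt_angle(axis1, axis2),
    )
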