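"""Per-pair feature assembly and min-max scaling.

Two feature sets describe a candidate pair (i, j) through its 3x3 sequence
neighbourhood - the eight positions (i+-1, j+-1), (i, j+-1), (i+-1, j), the
centre itself excluded so the classifier cannot read off the defining
distance:

* SDF (structure-derived features): per neighbour the 5-tuple
  [d1_mean, d1_sd, d_alpha, delta, theta] -> 40 values. Rigid-invariant.
* CF (coordinates as features): per neighbour the raw x,y,z of the N, CA, O
  and CB atoms of both residues -> 24 values -> 192 total. Frame-dependent
  by construction; serves as the baseline.

Neighbour positions that fall outside the chain (or lack the required atoms)
contribute a zero block, recorded in a per-neighbour validity mask; the
candidate pair itself is always kept, so row counts equal candidate counts.

SDF values are quantised to 1e-6 (Angstrom / degrees) so that the feature
matrix is exactly reproducible regardless of the laboratory frame the chain
happens to be expressed in.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import contacts as _contacts
from .contacts import CandidatePair
from .errors import MissingResidueError, TmhcError
from .geometry import HelixAxis, helix_axis, pair_geometry
from .structure_io import ChainStructure, HelixAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "SDF_DIM",
    "CF_DIM",
    "PairFeatureSet",
    "ScalerParams",
    "neighbor_window",
    "compute_helix_axes",
    "sdf_vector",
    "cf_vector",
    "fit_scaler",
    "apply_scaler",
    "build_dataset",
    "write_feature_table",
]

SDF_DIM = 40
CF_DIM = 192
_SDF_QUANTUM = 1e-6
_CF_ATOMS = ("N", "CA", "O", "CB")


@dataclasses.dataclass
class ScalerParams:
    """Per-column min/max fitted on training data; maps to [-1, 1]."""

    minimum: np.ndarray
    maximum: np.ndarray
    fitted_on: str = ""

    def __post_init__(self) -> None:
        self.minimum = np.asarray(self.minimum, dtype=float)
        self.maximum = np.asarray(self.maximum, dtype=float)
        if self.minimum.shape != self.maximum.shape:
            raise ValueError("min/max shape mismatch")
        if np.any(self.maximum < self.minimum):
            raise ValueError("scaler max < min")


@dataclasses.dataclass
class PairFeatureSet:
    """Feature matrix for an ordered list of candidate pairs.

    ``chain_ids`` keeps per-row provenance so evaluation can aggregate per
    sequence; ``mask`` flags, per row and neighbour, which of the 8 window
    blocks were actually computed (False = zero-imputed).
    """

    chain_ids: List[str]
    pairs: List[CandidatePair]
    X: np.ndarray
    mask: np.ndarray
    feature_kind: str  # "SDF" | "CF"
    labels: Optional[np.ndarray] = None
    tm_lengths: Optional[Dict[str, int]] = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        expected = SDF_DIM if self.feature_kind == "SDF" else CF_DIM
        if self.feature_kind not in ("SDF", "CF"):
            raise ValueError(f"unknown feature kind {self.feature_kind!r}")
        if self.X.ndim != 2 or self.X.shape[1] != expected:
            raise ValueError(
                f"{self.feature_kind} matrix must have {expected} columns"
            )
        if not (len(self.chain_ids) == len(self.pairs) == self.X.shape[0]):
            raise ValueError("row count mismatch")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=bool)
            if len(self.labels) != self.X.shape[0]:
                raise ValueError("label count mismatch")
        if not np.isfinite(self.X).all():
            raise ValueError("non-finite feature values")

    def subset_chains(self, chain_ids: Sequence[str]) -> "PairFeatureSet":
        wanted = set(chain_ids)
        idx = [k for k, c in enumerate(self.chain_ids) if c in wanted]
        return PairFeatureSet(
            [self.chain_ids[k] for k in idx],
            [self.pairs[k] for k in idx],
            self.X[idx],
            self.mask[idx],
            self.feature_kind,
            None if self.labels is None else self.labels[idx],
            None
            if self.tm_lengths is None
            else {c: l for c, l in self.tm_lengths.items() if c in wanted},
        )


def neighbor_window(i: int, j: int) -> List[Tuple[int, int]]:
    """The 8 window positions around (i, j), row-major, centre excluded."""
    return [
        (i - 1, j - 1), (i - 1, j), (i - 1, j + 1),
        (i, j - 1), (i, j + 1),
        (i + 1, j - 1), (i + 1, j), (i + 1, j + 1),
    ]


def compute_helix_axes(
    chain: ChainStructure, helices: HelixAnnotation
) -> Dict[int, HelixAxis]:
    """Axis per annotated helix, keyed by 1-based helix index."""
    return {
        idx: helix_axis(chain, seg, idx)
        for idx, seg in enumerate(helices.segments, start=1)
    }


def sdf_vector(
    chain: ChainStructure,
    helices: HelixAnnotation,
    pair: CandidatePair,
    axes: Mapping[int, HelixAxis],
) -> Tuple[np.ndarray, np.ndarray]:
    """The 40-dim SDF vector for one candidate pair, plus 8-slot validity mask.

    For each window position the block is [d1_mean, d1_sd, d_alpha, delta,
    theta]; theta uses the axes of the helices containing the neighbour
    residues, falling back to the central pair's helices at segment edges.
    """
    if chain.residue(pair.i) is None or chain.residue(pair.j) is None:
        raise MissingResidueError(
            f"chain {chain.chain_id!r}: central pair ({pair.i},{pair.j}) missing"
        )
    vector = np.zeros(SDF_DIM)
    mask = np.zeros(8, dtype=bool)
    for k, (p, q) in enumerate(neighbor_window(pair.i, pair.j)):
        r1, r2 = chain.residue(p), chain.residue(q)
        if r1 is None or r2 is None:
            continue
        h1 = helices.helix_of(p) or pair.helix_i
        h2 = helices.helix_of(q) or pair.helix_j
        try:
            geom = pair_geometry(r1, r2, axes[h1], axes[h2])
        except TmhcError:
            continue
        block = np.round(geom.as_array() / _SDF_QUANTUM) * _SDF_QUANTUM
        vector[5 * k : 5 * k + 5] = block
        mask[k] = True
    return vector, mask


def cf_vector(
    chain: ChainStructure, pair: CandidatePair
) -> Tuple[np.ndarray, np.ndarray]:
    """The 192-dim raw-coordinate vector for one candidate pair.

    Per window position: lower-position residue first, atoms N, CA, O, CB,
    each as raw x, y, z. A missing CB (glycine) repeats the CA coordinates;
    a missing residue or missing N/CA/O zeroes the 24-block.
    """
    if chain.residue(pair.i) is None or chain.residue(pair.j) is None:
        raise MissingResidueError(
            f"chain {chain.chain_id!r}: central pair ({pair.i},{pair.j}) missing"
        )
    vector = np.zeros(CF_DIM)
    mask = np.zeros(8, dtype=bool)
    for k, (p, q) in enumerate(neighbor_window(pair.i, pair.j)):
        block: List[np.ndarray] = []
        ok = True
        for pos in (p, q):  # p < q always since j - i >= 5
            res = chain.residue(pos)
            if res is None:
                ok = False
                break
            for atom in _CF_ATOMS:
                coords = res.get(atom)
                if coords is None and atom == "CB":
                    coords = res.get("CA")
                if coords is None:
                    ok = False
                    break
                block.append(coords)
            if not ok:
                break
        if ok:
            vector[24 * k : 24 * (k + 1)] = np.concatenate(block)
            mask[k] = True
    return vector, mask


def fit_scaler(X_train: np.ndarray, fitted_on: str = "") -> ScalerParams:
    """Record per-column min/max of the training matrix."""
    X_train = np.asarray(X_train, dtype=float)
    if X_train.size == 0:
        raise ValueError("cannot fit a scaler on an empty matrix")
    return ScalerParams(X_train.min(axis=0), X_train.max(axis=0), fitted_on)


def apply_scaler(X: np.ndarray, params: ScalerParams) -> np.ndarray:
    """Map v -> -1 + 2 (v - min) / (max - min) per column.

    Constant columns map to -1; values outside the fitted range (test data)
    land outside [-1, 1] - the scaler is never re-fitted.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[1] != params.minimum.shape[0]:
        raise ValueError(
            f"matrix has {X.shape[1]} columns, scaler was fitted on "
            f"{params.minimum.shape[0]}"
        )
    span = params.maximum - params.minimum
    safe = np.where(span == 0, 1.0, span)
    return -1.0 + 2.0 * (X - params.minimum) / safe


def build_dataset(
    structures: Mapping[str, ChainStructure],
    annotations: Mapping[str, HelixAnnotation],
    feature_kind: str,
    label_structures: Optional[Mapping[str, ChainStructure]] = None,
    threshold: float = _contacts.DEFAULT_CONTACT_THRESHOLD,
    min_separation: int = _contacts.DEFAULT_MIN_SEPARATION,
) -> PairFeatureSet:
    """Assemble a PairFeatureSet over several chains.

    Candidate pairs and contact labels are derived from ``label_structures``
    (default: the feature structures themselves) - this is what lets features
    come from a predicted/noisy structure while the truth stays with the
    experimental one. Rows are ordered by (chain_id, i, j); chains without an
    annotation are skipped with a warning.
    """
    label_structures = label_structures or structures
    chain_ids: List[str] = []
    pairs: List[CandidatePair] = []
    rows: List[np.ndarray] = []
    masks: List[np.ndarray] = []
    labels: List[bool] = []
    tm_lengths: Dict[str, int] = {}
    for cid in sorted(structures):
        if cid not in annotations:
            logger.warning("chain %s has no helix annotation; skipped", cid)
            continue
        chain = structures[cid]
        helices = annotations[cid]
        label_chain = label_structures.get(cid, chain)
        cand = _contacts.enumerate_candidates(label_chain, helices, min_separation)
        labelled = _contacts.label_contacts(label_chain, cand, threshold)
        axes = compute_helix_axes(chain, helices) if feature_kind == "SDF" else None
        tm_lengths[cid] = helices.tm_length()
        for pair, lab in zip(labelled.pairs, labelled.labels):
            if feature_kind == "SDF":
                vec, mask = sdf_vector(chain, helices, pair, axes)
            else:
                vec, mask = cf_vector(chain, pair)
            chain_ids.append(cid)
            pairs.append(pair)
            rows.append(vec)
            masks.append(mask)
            labels.append(bool(lab))
    dim = SDF_DIM if feature_kind == "SDF" else CF_DIM
    X = np.stack(rows) if rows else np.empty((0, dim))
    mask = np.stack(masks) if masks else np.empty((0, 8), dtype=bool)
    return PairFeatureSet(
        chain_ids, pairs, X, mask, feature_kind, np.array(labels, dtype=bool),
        tm_lengths,
    )


def write_feature_table(features: PairFeatureSet, path: str | Path) -> None:
    """Dump features as TSV: chain_id, i, j, label, f1..fD."""
    dim = features.X.shape[1]
    columns = {
        "chain_id": features.chain_ids,
        "i": [p.i for p in features.pairs],
        "j": [p.j for p in features.pairs],
        "label": (
            features.labels.astype(int)
            if features.labels is not None
            else [""] * len(features.pairs)
        ),
    }
    frame = pd.DataFrame(columns)
    for d in range(dim):
        frame[f"f{d + 1}"] = [f"{v:.6f}" for v in features.X[:, d]]
    frame.to_csv(path, sep="\t", index=False)
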