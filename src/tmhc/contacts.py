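"""Candidate-pair enumeration and contact labelling.

A candidate pair is two residues on *different* TM helices separated by at
least ``min_separation`` positions in sequence; it is a contact when the
minimum distance over all heavy-atom cross pairs is strictly below the
threshold (default 5.5 A). The contact ratio CR = #contacts / #candidates
summarises the class imbalance of a chain.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import List, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import EvaluationError, MissingAtomsError, MissingResidueError
from .structure_io import ChainStructure, HelixAnnotation, ResidueRecord

__all__ = [
    "CandidatePair",
    "ContactLabelSet",
    "enumerate_candidates",
    "min_heavy_atom_distance",
    "label_contacts",
    "contact_ratio",
    "write_contact_table",
    "read_contact_table",
    "DEFAULT_CONTACT_THRESHOLD",
    "DEFAULT_MIN_SEPARATION",
]

DEFAULT_CONTACT_THRESHOLD = 5.5  # Angstrom, strict '<'
DEFAULT_MIN_SEPARATION = 5  # |j - i| >= 5


@dataclasses.dataclass(frozen=True, order=True)
class CandidatePair:
    i: int
    j: int
    helix_i: int
    helix_j: int

    def __post_init__(self) -> None:
        if self.i >= self.j:
            raise ValueError(f"pair ({self.i},{self.j}): requires i < j")
        if self.helix_i == self.helix_j:
            raise ValueError(f"pair ({self.i},{self.j}): same helix")


@dataclasses.dataclass
class ContactLabelSet:
    pairs: List[CandidatePair]
    labels: np.ndarray  # bool, parallel to pairs
    min_distances: np.ndarray  # Angstrom, parallel to pairs
    threshold: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=bool)
        self.min_distances = np.asarray(self.min_distances, dtype=float)
        if not (len(self.pairs) == len(self.labels) == len(self.min_distances)):
            raise ValueError("pairs, labels and distances must have equal length")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")

    def n_contacts(self) -> int:
        return int(self.labels.sum())


def enumerate_candidates(
    chain: ChainStructure,
    helices: HelixAnnotation,
    min_separation: int = DEFAULT_MIN_SEPARATION,
) -> List[CandidatePair]:
    """All inter-helical pairs (i, j), i < j, with j - i >= min_separation.

    Both positions must lie in annotated TM segments and be present in the
    chain; output is sorted lexicographically by (i, j).
    """
    positions = [
        (p, helices.helix_of(p))
        for p in helices.tm_positions()
        if chain.residue(p) is not None
    ]
    pairs: List[CandidatePair] = []
    for a, (i, hi) in enumerate(positions):
        for j, hj in positions[a + 1 :]:
            if hj != hi and j - i >= min_separation:
                pairs.append(CandidatePair(i, j, hi, hj))
    pairs.sort(key=lambda p: (p.i, p.j))
    return pairs


def min_heavy_atom_distance(r1: ResidueRecord, r2: ResidueRecord) -> float:
    """Minimum Euclidean distance over all heavy-atom cross pairs."""
    a, b = r1.heavy_coords(), r2.heavy_coords()
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise MissingAtomsError(
            f"residues {r1.position}/{r2.position}: need at least one heavy atom each"
        )
    return float(cdist(a, b).min())


def label_contacts(
    chain: ChainStructure,
    pairs: Sequence[CandidatePair],
    threshold: float = DEFAULT_CONTACT_THRESHOLD,
) -> ContactLabelSet:
    """Label each candidate pair: contact iff min heavy-atom distance < threshold."""
    labels = np.zeros(len(pairs), dtype=bool)
    dists = np.zeros(len(pairs), dtype=float)
    for k, pair in enumerate(pairs):
        r1 = chain.residue(pair.i)
        r2 = chain.residue(pair.j)
        if r1 is None or r2 is None:
            raise MissingResidueError(
                f"chain {chain.chain_id!r}: pair ({pair.i},{pair.j}) references a "
                "residue absent from the chain"
            )
        dists[k] = min_heavy_atom_distance(r1, r2)
        labels[k] = dists[k] < threshold
    return ContactLabelSet(list(pairs), labels, dists, threshold)


def contact_ratio(labels: ContactLabelSet) -> float:
    """CR = #contacts / #candidate pairs."""
    if len(labels.pairs) == 0:
        raise EvaluationError("contact ratio undefined for an empty pair set")
    return labels.n_contacts() / len(labels.pairs)


def write_contact_table(
    chain_id: str, labels: ContactLabelSet, path: str | Path
) -> None:
    rows = [
        {
            "chain_id": chain_id,
            "i": p.i,
            "j": p.j,
            "label": int(l),
            "min_distance": f"{d:.4f}",
        }
        for p, l, d in zip(labels.pairs, labels.labels, labels.min_distances)
    ]
    pd.DataFrame(
        rows, columns=["chain_id", "i", "j", "label", "min_distance"]
    ).to_csv(path, sep="\t", index=False)


def read_contact_table(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype={"chain_id": str})
    required = {"chain_id", "i", "j", "label"}
    if not required <= set(frame.columns):
        raise EvaluationError(f"{path}: expected columns {sorted(required)}")
    return frame
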