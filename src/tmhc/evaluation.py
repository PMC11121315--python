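"""Per-sequence evaluation metrics and cross-validation orchestration.

Metrics follow the standard ranked-retrieval definitions: average precision
as the threshold-sweep sum AP = sum_n (R_n - R_{n-1}) P_n (for a single
binary annotation this reduces to P x R), AUC-ROC by the trapezoidal rule,
and precision/recall at the top L, L/2, L/5 and L/10 ranked pairs, where L is
the combined length of the chain's TM helices. Every metric is computed per
sequence and then averaged across sequences; chains for which a metric is
undefined (no positive labels, single-class labels) are excluded from that
metric's average with a logged count.

Cross-validation splits by *sequence*, never by pair: in each fold the scaler
and the classifier see only training chains, and validation chains may be
swapped for structurally perturbed twins (features from the noisy structure,
labels from the clean one) to mimic testing on predicted structures.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .contacts import (
    DEFAULT_CONTACT_THRESHOLD,
    DEFAULT_MIN_SEPARATION,
    CandidatePair,
)
from .errors import EvaluationError
from .features import PairFeatureSet, apply_scaler, build_dataset, fit_scaler
from .model import ModelConfig, TrainedContactModel, init_model, predict_scores, train
from .structure_io import ChainStructure, HelixAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "RankedPredictions",
    "EvalReport",
    "average_precision",
    "binary_average_precision",
    "auc_roc",
    "topk_precision_recall",
    "feature_statistics",
    "evaluate_ranked",
    "binary_annotation_report",
    "crossvalidate",
    "TOPK_FRACTIONS",
]

TOPK_FRACTIONS: Dict[str, float] = {"L": 1.0, "L/2": 0.5, "L/5": 0.2, "L/10": 0.1}


@dataclasses.dataclass
class RankedPredictions:
    """Scores (or binary annotations) with labels for one chain."""

    chain_id: str
    pairs: List[CandidatePair]
    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels, dtype=bool)
        if not (len(self.pairs) == len(self.scores) == len(self.labels)):
            raise ValueError("pairs/scores/labels length mismatch")
        if not np.isfinite(self.scores).all():
            raise ValueError("non-finite scores")


def average_precision(scores: np.ndarray, labels: np.ndarray) -> float:
    """AP = sum_n (R_n - R_{n-1}) P_n over descending-score thresholds."""
    labels = np.asarray(labels, dtype=bool)
    if labels.sum() == 0:
        raise EvaluationError("average precision undefined without positives")
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


def binary_average_precision(labels: np.ndarray, annotations: np.ndarray) -> float:
    """P x R for a single-threshold binary annotation (a read-off contact map).

    With zero predicted positives the precision is taken as 0.
    """
    labels = np.asarray(labels, dtype=bool)
    annotations = np.asarray(annotations).astype(bool)
    predicted = annotations.sum()
    if labels.sum() == 0:
        raise EvaluationError("undefined without true positives")
    tp = int((labels & annotations).sum())
    if predicted == 0:
        logger.warning("binary annotation has no predicted positives; AP = 0")
        return 0.0
    precision = tp / int(predicted)
    recall = tp / int(labels.sum())
    return precision * recall


def auc_roc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Trapezoidal area under the ROC curve."""
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise EvaluationError("AUC-ROC undefined for single-class labels")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def topk_precision_recall(
    rp: RankedPredictions,
    tm_length: int,
    fractions: Mapping[str, float] = TOPK_FRACTIONS,
) -> Dict[str, Tuple[float, float]]:
    """Precision/recall with the top k = floor(L*f) pairs set positive.

    k is clamped to [1, n_pairs]; ties in score are broken by (i, j) order
    for determinism. Recall is NaN when the chain has no true contact.
    """
    if tm_length < 1:
        raise EvaluationError("tm_length must be >= 1")
    order = sorted(
        range(len(rp.scores)),
        key=lambda k: (-rp.scores[k], rp.pairs[k].i, rp.pairs[k].j),
    )
    n_pairs = len(order)
    n_contacts = int(rp.labels.sum())
    out: Dict[str, Tuple[float, float]] = {}
    for name, frac in fractions.items():
        k = min(max(1, math.floor(tm_length * frac)), n_pairs)
        tp = int(rp.labels[order[:k]].sum())
        precision = tp / k
        recall = tp / n_contacts if n_contacts > 0 else float("nan")
        out[name] = (precision, recall)
    return out


def feature_statistics(X: np.ndarray) -> Tuple[float, float]:
    """Pooled mean and SD over every entry of a (scaled) feature matrix."""
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        raise EvaluationError("empty feature matrix")
    return float(X.mean()), float(X.std(ddof=0))


@dataclasses.dataclass
class EvalReport:
    """Per-sequence metric rows plus their aggregate mean +- SD."""

    per_sequence: pd.DataFrame
    metadata: Dict[str, object] = dataclasses.field(default_factory=dict)

    _METRICS = (
        ["ap", "auc"]
        + [f"p_at_{n}" for n in ("L", "L2", "L5", "L10")]
        + [f"r_at_{n}" for n in ("L", "L2", "L5", "L10")]
    )

    def aggregate(self) -> Dict[str, Tuple[float, float]]:
        out = {}
        for metric in self._METRICS:
            if metric not in self.per_sequence.columns:
                continue
            values = self.per_sequence[metric].dropna()
            if len(values) == 0:
                out[metric] = (float("nan"), float("nan"))
            else:
                out[metric] = (float(values.mean()), float(values.std(ddof=0)))
        return out

    def mean(self, metric: str) -> float:
        return self.aggregate()[metric][0]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "metadata": self.metadata,
            "aggregate": {
                m: {"mean": a, "sd": s} for m, (a, s) in self.aggregate().items()
            },
            "per_sequence": json.loads(
                self.per_sequence.to_json(orient="records", double_precision=10)
            ),
        }
        Path(path).write_text(json.dumps(payload, indent=2, allow_nan=True))

    def summary(self) -> str:
        lines = []
        for metric, (mean, sd) in self.aggregate().items():
            lines.append(f"{metric:>8s}: {mean:.4f} +- {sd:.4f}")
        return "\n".join(lines)


_TOPK_COLS = {"L": "L", "L/2": "L2", "L/5": "L5", "L/10": "L10"}


def _chain_row(rp: RankedPredictions, tm_length: int) -> Dict[str, object]:
    n_contacts = int(rp.labels.sum())
    row: Dict[str, object] = {
        "chain_id": rp.chain_id,
        "L": tm_length,
        "n_pairs": len(rp.pairs),
        "n_contacts": n_contacts,
    }
    if n_contacts == 0:
        logger.warning("chain %s has no contacts; AP/recall undefined", rp.chain_id)
        row["ap"] = float("nan")
    else:
        row["ap"] = average_precision(rp.scores, rp.labels)
    try:
        row["auc"] = auc_roc(rp.scores, rp.labels)
    except EvaluationError:
        logger.warning("chain %s is single-class; AUC undefined", rp.chain_id)
        row["auc"] = float("nan")
    for name, (p, r) in topk_precision_recall(rp, tm_length).items():
        row[f"p_at_{_TOPK_COLS[name]}"] = p
        row[f"r_at_{_TOPK_COLS[name]}"] = r
    return row


def evaluate_ranked(
    predictions: Sequence[RankedPredictions],
    tm_lengths: Mapping[str, int],
    metadata: Optional[Dict[str, object]] = None,
) -> EvalReport:
    """Per-sequence metrics for a collection of ranked prediction sets."""
    rows = [_chain_row(rp, tm_lengths[rp.chain_id]) for rp in predictions]
    return EvalReport(pd.DataFrame(rows), metadata or {})


def binary_annotation_report(
    clean: Mapping[str, ChainStructure],
    noisy: Mapping[str, ChainStructure],
    annotations: Mapping[str, HelixAnnotation],
    threshold: float = DEFAULT_CONTACT_THRESHOLD,
    min_separation: int = DEFAULT_MIN_SEPARATION,
) -> pd.DataFrame:
    """The contact map read directly off a predicted/noisy structure.

    For every chain, candidate pairs are labelled on the clean structure
    (truth) and on the noisy twin (annotation); AP is then P x R.
    """
    from .contacts import enumerate_candidates, label_contacts

    rows = []
    for cid in sorted(clean):
        helices = annotations[cid]
        pairs = enumerate_candidates(clean[cid], helices, min_separation)
        truth = label_contacts(clean[cid], pairs, threshold).labels
        predicted = label_contacts(noisy[cid], pairs, threshold).labels
        if truth.sum() == 0:
            logger.warning("chain %s has no contacts; skipped", cid)
            continue
        tp = int((truth & predicted).sum())
        precision = tp / int(predicted.sum()) if predicted.sum() else 0.0
        recall = tp / int(truth.sum())
        rows.append(
            {
                "chain_id": cid,
                "ap": precision * recall,
                "precision": precision,
                "recall": recall,
                "n_pairs": len(pairs),
                "n_contacts": int(truth.sum()),
            }
        )
    return pd.DataFrame(rows)


def crossvalidate(
    structures: Mapping[str, ChainStructure],
    annotations: Mapping[str, HelixAnnotation],
    feature_kind: str,
    config: ModelConfig,
    k: int = 5,
    repeats: int = 5,
    base_seed: int = 0,
    test_structures: Optional[Mapping[str, ChainStructure]] = None,
    threshold: float = DEFAULT_CONTACT_THRESHOLD,
    min_separation: int = DEFAULT_MIN_SEPARATION,
) -> EvalReport:
    """Sequence-level k-fold cross-validation, repeated ``repeats`` times.

    Per fold: features and labels of the training chains come from the clean
    ``structures``; a scaler and model are fitted on those chains only. Each
    validation chain is evaluated with features from ``test_structures`` (its
    noisy/predicted twin; defaults to the clean chain) against labels from
    the clean chain.
    """
    import dataclasses as _dc

    ids = sorted(structures)
    if len(ids) < k:
        raise EvaluationError(f"need at least {k} chains for {k}-fold CV")
    all_rows: List[Dict[str, object]] = []
    for rep in range(repeats):
        rng = np.random.default_rng((base_seed, rep))
        perm = [ids[t] for t in rng.permutation(len(ids))]
        folds = np.array_split(np.arange(len(ids)), k)
        for fold_no, fold_idx in enumerate(folds):
            val_ids = [perm[t] for t in fold_idx]
            train_ids = [c for c in perm if c not in val_ids]
            train_fs = build_dataset(
                {c: structures[c] for c in train_ids},
                annotations,
                feature_kind,
                threshold=threshold,
                min_separation=min_separation,
            )
            scaler = fit_scaler(train_fs.X, fitted_on=f"rep{rep}/fold{fold_no}")
            seed = (base_seed * 10000 + rep * 100 + fold_no) % (2**31)
            fold_config = _dc.replace(config, seed=seed)
            if feature_kind == "SDF":
                fold_config = _dc.replace(
                    fold_config, input_projection="static_40_to_192"
                )
            model = init_model(fold_config, input_dim=train_fs.X.shape[1])
            train(model, apply_scaler(train_fs.X, scaler), train_fs.labels, fold_config)
            for cid in val_ids:
                feat_chain = (
                    test_structures.get(cid, structures[cid])
                    if test_structures
                    else structures[cid]
                )
                val_fs = build_dataset(
                    {cid: feat_chain},
                    annotations,
                    feature_kind,
                    label_structures={cid: structures[cid]},
                    threshold=threshold,
                    min_separation=min_separation,
                )
                scores = predict_scores(model, apply_scaler(val_fs.X, scaler))
                rp = RankedPredictions(cid, val_fs.pairs, scores, val_fs.labels)
                row = _chain_row(rp, annotations[cid].tm_length())
                row["repeat"] = rep
                row["fold"] = fold_no
                row["seed"] = seed
                all_rows.append(row)
    metadata = {
        "feature_kind": feature_kind,
        "k": k,
        "repeats": repeats,
        "base_seed": base_seed,
        "fold_seeds": sorted({r["seed"] for r in all_rows}),
        "test_source": "provided" if test_structures else "same-as-train",
    }
    return EvalReport(pd.DataFrame(all_rows), metadata)
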