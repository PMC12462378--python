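"""Evaluation harness: residue-level metrics and structural-pattern accuracy.

Seven standard binary metrics (ACC, Precision, Recall, F1, MCC, AUROC,
AUPRC) plus the accuracy of reproducing the four sequence patterns "01",
"10" (segment boundaries) and "010", "101" (isolated residues): an
occurrence is an exact (overlapping) window match in the TRUE label string,
and it counts as a hit when the predicted calls reproduce the window
character for character.  Dataset-level aggregation pools occurrence and hit
counts across proteins (micro) before dividing; a macro (per-protein mean)
variant is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = [
    "PatternStats",
    "PATTERNS",
    "confusion_metrics",
    "rank_metrics",
    "pattern_accuracy",
    "aggregate_pattern_stats",
    "evaluate_predictions",
]

PATTERNS = ("01", "10", "010", "101")


@dataclass
class PatternStats:
    pattern: str
    occurrences: int
    hits: int

    def __post_init__(self):
        if not 0 <= self.hits <= self.occurrences:
            raise ValueError("hits must satisfy 0 <= hits <= occurrences")

    @property
    def accuracy(self) -> float | None:
        """hits/occurrences; None (reported NA) when the pattern never occurs."""
        if self.occurrences == 0:
            return None
        return self.hits / self.occurrences


def _check_binary(vec, name: str) -> np.ndarray:
    vec = np.asarray(vec)
    if not np.isin(vec, (0, 1)).all():
        raise ValueError(f"{name} must be binary 0/1")
    return vec.astype(int)


def confusion_metrics(true, calls) -> dict[str, float]:
    """ACC/Precision/Recall/F1/MCC from the 2x2 table.

    Degenerate conventions: MCC = 0 when any marginal is zero; F1 = 0 when
    precision + recall = 0; precision/recall = 0 on empty denominators.
    """
    true = _check_binary(true, "true")
    calls = _check_binary(calls, "calls")
    if true.shape != calls.shape:
        raise ValueError("length mismatch between true and calls")
    tp = int(np.sum((true == 1) & (calls == 1)))
    tn = int(np.sum((true == 0) & (calls == 0)))
    fp = int(np.sum((true == 0) & (calls == 1)))
    fn = int(np.sum((true == 1) & (calls == 0)))
    n = tp + tn + fp + fn
    acc = (tp + tn) / n if n else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall
        else 0.0
    )
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom else 0.0
    return {
        "ACC": acc,
        "Precision": precision,
        "Recall": recall,
        "F1": f1,
        "MCC": float(mcc),
    }


def rank_metrics(true, probs) -> dict[str, float | None]:
    """AUROC (tie-corrected Mann-Whitney) and AUPRC (step interpolation).

    Single-class input yields None for both, with a warning.
    """
    true = _check_binary(true, "true")
    probs = np.asarray(probs, dtype=float)
    if true.shape != probs.shape:
        raise ValueError("length mismatch between true and probs")
    if len(np.unique(true)) < 2:
        warnings.warn("rank metrics undefined with a single class present")
        return {"AUROC": None, "AUPRC": None}
    return {
        "AUROC": float(roc_auc_score(true, probs)),
        "AUPRC": float(average_precision_score(true, probs)),
    }


def _as_string(vec) -> str:
    return "".join(str(int(v)) for v in np.asarray(vec, dtype=int))


def pattern_accuracy(true, calls, pattern: str) -> PatternStats:
    """Occurrence/hit counts for one pattern (overlapping windows)."""
    if pattern not in PATTERNS:
        raise ValueError(f"pattern must be one of {PATTERNS}, got {pattern!r}")
    true = _check_binary(true, "true")
    calls = _check_binary(calls, "calls")
    if true.shape != calls.shape:
        raise ValueError("length mismatch between true and calls")
    true_s = _as_string(true)
    calls_s = _as_string(calls)
    w = len(pattern)
    occurrences = hits = 0
    for start in range(len(true_s) - w + 1):
        if true_s[start : start + w] == pattern:
            occurrences += 1
            if calls_s[start : start + w] == pattern:
                hits += 1
    return PatternStats(pattern=pattern, occurrences=occurrences, hits=hits)


def aggregate_pattern_stats(
    per_protein: list[dict[str, PatternStats]], macro: bool = False
) -> dict[str, dict]:
    """Combine per-protein pattern stats across a dataset.

    Micro (default) pools counts; macro averages the per-protein accuracies
    over proteins where the pattern occurs.
    """
    report = {}
    for pattern in PATTERNS:
        stats = [stats_map[pattern] for stats_map in per_protein]
        occ = sum(s.occurrences for s in stats)
        hits = sum(s.hits for s in stats)
        if macro:
            defined = [s.accuracy for s in stats if s.accuracy is not None]
            accuracy = float(np.mean(defined)) if defined else None
        else:
            accuracy = hits / occ if occ else None
        report[pattern] = {
            "occurrences": occ,
            "hits": hits,
            "accuracy": accuracy,
        }
    return report


def evaluate_predictions(
    true_list, prob_list, threshold: float = 0.5, macro_patterns: bool = False
) -> dict:
    """Full report for a set of proteins: pooled residue metrics + patterns.

    ``true_list`` / ``prob_list`` are per-protein label vectors and
    positive-class probability vectors in sequence order.
    """
    true_all = np.concatenate([np.asarray(t) for t in true_list])
    prob_all = np.concatenate([np.asarray(p) for p in prob_list])
    calls_all = (prob_all >= threshold).astype(int)
    report = confusion_metrics(true_all, calls_all)
    report.update(rank_metrics(true_all, prob_all))
    per_protein = []
    for t, p in zip(true_list, prob_list):
        calls = (np.asarray(p) >= threshold).astype(int)
        per_protein.append(
            {pat: pattern_accuracy(t, calls, pat) for pat in PATTERNS}
        )
    report["patterns"] = aggregate_pattern_stats(per_protein, macro=macro_patterns)
    return report
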