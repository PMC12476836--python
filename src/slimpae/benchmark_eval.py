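"""Screening-performance evaluation under class imbalance.

Given scores for known binders (positives) and shuffled non-binders
(negatives), this module computes:

* ROC curves and AUC (rank-based, ties half-credit);
* precision-recall curves with PR-AUC by trapezoidal integration over
  recall, via scikit-learn's ``precision_recall_curve``;
* ratio-subsampled PR analysis — repeatedly sample ``ratio * n_pos``
  negatives, compute the PR curve, and average AUC and curves over
  iterations, emulating blind screens where non-binders vastly outnumber
  binders;
* TPR at FDR = 0 — the fraction of positives scoring strictly better than
  the best-scoring negative, i.e. recall with zero false discoveries
  allowed;
* shuffled-negative benchmark construction from a positive motif-partner
  table, with regex-based exclusion of accidentally functional pairs.

Score orientation is always explicit: ``lower_is_better=True`` for
PAE/distance-derived metrics (MiniPAE, MinD), False for confidence-like
metrics (MC, AlphaSLiM).  It is never inferred from the data.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import precision_recall_curve, roc_auc_score, roc_curve

from .errors import DegenerateInputError, ExhaustionError, SamplingError
from .scoring import ScoredPair  # noqa: F401  (re-exported container)

__all__ = [
    "EvalCurve",
    "BenchmarkInstance",
    "ScoredPair",
    "roc",
    "pr_curve",
    "unbalanced_pr",
    "tpr_at_zero_fdr",
    "build_shuffled_negatives",
    "split_scored_pairs",
]

#: Recall grid used when averaging PR curves across subsample iterations.
RECALL_GRID = np.linspace(0.0, 1.0, 101)


@dataclass
class EvalCurve:
    """An evaluation curve (ROC or PR) with its area.

    ``points`` is an (x, y) pair of arrays — (FPR, TPR) for ROC, (recall,
    precision) for PR — with x non-decreasing.  ``lower_is_better`` records
    the score orientation the curve was computed under.
    """

    kind: str
    points: tuple[np.ndarray, np.ndarray]
    auc: float
    lower_is_better: bool

    def __post_init__(self) -> None:
        if self.kind not in ("roc", "pr"):
            raise DegenerateInputError(f"unknown curve kind {self.kind!r}")
        x, y = self.points
        self.points = (np.asarray(x, dtype=float), np.asarray(y, dtype=float))
        if not 0.0 <= self.auc <= 1.0 + 1e-12:
            raise DegenerateInputError(f"AUC {self.auc} outside [0, 1]")


@dataclass(frozen=True)
class BenchmarkInstance:
    """One motif-partner pair of the benchmark.

    ``motif_regexes`` are the motif-class patterns associated with this
    instance (ELM-style, unanchored search semantics).  For generated
    negatives, the motif matches none of the new partner's regexes and the
    combined sequence length stays under the cap.
    """

    motif_protein_id: str
    motif_sequence: str
    motif_regexes: tuple[str, ...]
    partner_id: str
    motif_len: int
    partner_len: int
    label: str = "binder"

    def __post_init__(self) -> None:
        if self.label not in ("binder", "non_binder"):
            raise DegenerateInputError(f"invalid label {self.label!r}")


def _oriented(scores: Sequence[float], lower_is_better: bool) -> np.ndarray:
    """Map scores so that larger always means 'more binder-like'."""
    arr = np.asarray(scores, dtype=float)
    return -arr if lower_is_better else arr


def _check_classes(pos: Sequence[float], neg: Sequence[float]) -> None:
    if len(pos) == 0 or len(neg) == 0:
        raise DegenerateInputError(
            f"need scores in both classes, got {len(pos)} positives and "
            f"{len(neg)} negatives"
        )


def _stack(pos: Sequence[float], neg: Sequence[float], lower_is_better: bool):
    y_true = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    y_score = np.concatenate(
        [_oriented(pos, lower_is_better), _oriented(neg, lower_is_better)]
    )
    return y_true, y_score


def roc(
    pos_scores: Sequence[float],
    neg_scores: Sequence[float],
    lower_is_better: bool,
) -> EvalCurve:
    """ROC curve and AUC over all score thresholds.

    The AUC is the rank (Mann-Whitney) statistic: ties between a positive
    and a negative contribute half credit.
    """
    _check_classes(pos_scores, neg_scores)
    y_true, y_score = _stack(pos_scores, neg_scores, lower_is_better)
    fpr, tpr, _ = roc_curve(y_true, y_score)
    auc = float(roc_auc_score(y_true, y_score))
    return EvalCurve(
        kind="roc", points=(fpr, tpr), auc=auc, lower_is_better=lower_is_better
    )


def pr_curve(
    pos_scores: Sequence[float],
    neg_scores: Sequence[float],
    lower_is_better: bool,
) -> EvalCurve:
    """Precision-recall curve with PR-AUC by trapezoidal integration.

    Precision = TP/(TP+FP), Recall = TP/(TP+FN) at every threshold; the
    area is integrated over recall (trapezoid), including the conventional
    (recall=0, precision=1) anchor.
    """
    _check_classes(pos_scores, neg_scores)
    y_true, y_score = _stack(pos_scores, neg_scores, lower_is_better)
    precision, recall, _ = precision_recall_curve(y_true, y_score)
    # sklearn emits recall descending to 0; integrate over ascending recall
    rec_asc = recall[::-1]
    prec_asc = precision[::-1]
    auc = float(np.trapezoid(prec_asc, rec_asc))
    return EvalCurve(
        kind="pr",
        points=(rec_asc, prec_asc),
        auc=min(auc, 1.0),
        lower_is_better=lower_is_better,
    )


def _interp_precision(curve: EvalCurve, grid: np.ndarray) -> np.ndarray:
    rec, prec = curve.points
    return np.interp(grid, rec, prec)


def unbalanced_pr(
    pos_scores: Sequence[float],
    neg_pool: Sequence[float],
    ratio: int,
    iterations: int = 10,
    seed: int = 0,
    lower_is_better: bool = True,
) -> tuple[EvalCurve, float]:
    """Ratio-subsampled precision-recall analysis.

    Per iteration: draw ``ratio * n_pos`` negatives from the pool without
    replacement, combine with all positives, compute the PR curve.  AUCs
    are averaged over iterations; curves are averaged after interpolating
    precision onto a fixed 101-point recall grid.  Returns (averaged
    curve, mean AUC); the averaged curve's ``auc`` is the mean AUC of the
    per-iteration trapezoids, not the area of the averaged polyline.
    """
    _check_classes(pos_scores, neg_pool)
    pool = np.asarray(neg_pool, dtype=float)
    n_draw = int(ratio) * len(pos_scores)
    if n_draw > pool.size:
        raise SamplingError(
            f"ratio {ratio} needs {n_draw} negatives but the pool has "
            f"{pool.size}"
        )
    if iterations < 1:
        raise DegenerateInputError("iterations must be >= 1")
    rng = np.random.default_rng(seed)
    aucs = np.empty(iterations)
    prec_stack = np.empty((iterations, RECALL_GRID.size))
    for it in range(iterations):
        draw = rng.choice(pool, size=n_draw, replace=False)
        curve = pr_curve(pos_scores, draw, lower_is_better)
        aucs[it] = curve.auc
        prec_stack[it] = _interp_precision(curve, RECALL_GRID)
    mean_auc = float(aucs.mean())
    avg_curve = EvalCurve(
        kind="pr",
        points=(RECALL_GRID.copy(), prec_stack.mean(axis=0)),
        auc=mean_auc,
        lower_is_better=lower_is_better,
    )
    return avg_curve, mean_auc


def tpr_at_zero_fdr(
    pos_scores: Sequence[float],
    neg_scores: Sequence[float],
    lower_is_better: bool,
) -> float:
    """True-positive rate (%) at FDR = 0.

    The percentage of positives scoring strictly better than the
    best-scoring negative.  Strict: a positive tied with the best negative
    is not counted, since calling it would already admit a false discovery.
    """
    _check_classes(pos_scores, neg_scores)
    pos = _oriented(pos_scores, lower_is_better)
    neg = _oriented(neg_scores, lower_is_better)
    best_neg = neg.max()
    return float(100.0 * np.mean(pos > best_neg))


def build_shuffled_negatives(
    instances: Sequence[BenchmarkInstance],
    n_out: int,
    max_total_len: int = 1000,
    seed: int = 0,
) -> list[BenchmarkInstance]:
    """Generate shuffled non-binder pairs from a positive benchmark.

    Every motif is re-paired with every partner it is not known to bind; a
    shuffled pair is admissible when (i) it is absent from the positive
    set, (ii) the motif sequence matches none of the regexes associated
    with the new partner (patterns of motifs known to bind that partner,
    unanchored search), and (iii) motif_len + partner_len <
    ``max_total_len``.  ``n_out`` pairs are drawn uniformly without
    replacement from the admissible set.
    """
    positives = [i for i in instances if i.label == "binder"]
    if len({i.partner_id for i in positives}) < 2:
        raise DegenerateInputError(
            "need >= 2 distinct partners to shuffle pairs"
        )
    positive_pairs = {(i.motif_protein_id, i.partner_id) for i in positives}
    # regexes associated with a partner: patterns of the motifs that bind it
    partner_regex: dict[str, list[re.Pattern]] = {}
    partner_len: dict[str, int] = {}
    for inst in positives:
        partner_len[inst.partner_id] = inst.partner_len
        bucket = partner_regex.setdefault(inst.partner_id, [])
        bucket.extend(re.compile(rx) for rx in inst.motif_regexes)

    admissible: list[BenchmarkInstance] = []
    for motif in positives:
        for pid in sorted(partner_len):
            if (motif.motif_protein_id, pid) in positive_pairs:
                continue
            if motif.motif_len + partner_len[pid] >= max_total_len:
                continue
            if any(rx.search(motif.motif_sequence) for rx in partner_regex[pid]):
                continue
            admissible.append(
                BenchmarkInstance(
                    motif_protein_id=motif.motif_protein_id,
                    motif_sequence=motif.motif_sequence,
                    motif_regexes=motif.motif_regexes,
                    partner_id=pid,
                    motif_len=motif.motif_len,
                    partner_len=partner_len[pid],
                    label="non_binder",
                )
            )
    if n_out > len(admissible):
        raise ExhaustionError(
            f"requested {n_out} shuffled negatives but only "
            f"{len(admissible)} pairs are admissible",
            admissible=len(admissible),
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(admissible), size=n_out, replace=False)
    return [admissible[i] for i in sorted(idx)]


def split_scored_pairs(
    pairs: Sequence[ScoredPair], metric: str
) -> tuple[list[float], list[float], int]:
    """Split ScoredPairs into (positive scores, negative scores) for one
    metric; returns the count of 'unknown'-labelled pairs excluded."""
    pos, neg, skipped = [], [], 0
    for p in pairs:
        if p.label == "binder":
            pos.append(p.value(metric))
        elif p.label == "non_binder":
            neg.append(p.value(metric))
        else:
            skipped += 1
    return pos, neg, skipped
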