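"""Evaluation: per-head correlations, thresholded ROC/PR, and rank tests.

Predictions and observations are percent triples (valid, unedited, erroneous).
Correlation metrics are Spearman (average ranks for ties) and Pearson per
head. For classification-style evaluation, efficiencies are binarized at a
strictly-greater 50% threshold; ROC uses the continuous predicted efficiency
as the score against the binarized truth, with AUROC computed through the
rank (Mann-Whitney) identity U/(n1*n2).

The epigenetic group analyses split records into "completely open" vs
"presence of closure" (every wild-sequence base accessible, or not) and
"with" vs "without methylation" (any methylated base), then compare each
head's efficiencies between groups with a two-sided Mann-Whitney U test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .epitracks import PerBaseAnnotation
from .network import HEAD_NAMES

__all__ = ["MetricsReport", "GroupComparison", "correlations",
           "binarize_at_threshold", "roc_pr_auc", "epigenetic_group_split",
           "mann_whitney_u", "evaluate_predictions", "compare_epigenetic_groups"]


def correlations(pred: np.ndarray, obs: np.ndarray) -> tuple[float, float]:
    """(Spearman rho, Pearson r) of two paired vectors; NaN on zero variance."""
    pred, obs = np.asarray(pred, float), np.asarray(obs, float)
    if pred.shape != obs.shape or pred.ndim != 1 or len(pred) < 3:
        raise ValueError("need two equal-length 1-D vectors with n >= 3")
    if np.ptp(pred) == 0 or np.ptp(obs) == 0:
        return float("nan"), float("nan")
    rho = stats.spearmanr(pred, obs).statistic
    r = stats.pearsonr(pred, obs).statistic
    return float(rho), float(r)


def binarize_at_threshold(values, threshold: float = 50.0) -> np.ndarray:
    """Positive iff strictly greater than the threshold (50.0 -> negative)."""
    return np.asarray(values, float) > threshold


def mann_whitney_u(group_a, group_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of group A, p-value).

    U counts pairs where a > b, with half credit for ties. The p-value is
    exact (distribution enumeration) when n1*n2 <= 400 and the pooled sample
    is tie-free, otherwise a normal approximation with tie and continuity
    corrections.
    """
    a, b = np.asarray(group_a, float), np.asarray(group_b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(a) * len(b) <= 400 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def roc_pr_auc(scores, labels) -> dict:
    """AUROC (rank identity), step-interpolated AUPRC, and both curves.

    Returns {"auroc", "auprc", "roc_points", "pr_points"}; the AUCs are NaN
    with a "single_class" flag when only one label value is present.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        return {"auroc": float("nan"), "auprc": float("nan"),
                "roc_points": None, "pr_points": None, "single_class": True}
    # AUROC via the rank identity: U(positives over negatives) / (n_pos*n_neg)
    ranks = stats.rankdata(scores)
    u_pos = ranks[labels].sum() - n_pos * (n_pos + 1) / 2
    auroc = float(u_pos / (n_pos * n_neg))

    order = np.argsort(-scores, kind="mergesort")
    sorted_labels = labels[order]
    sorted_scores = scores[order]
    tp = np.cumsum(sorted_labels)
    fp = np.cumsum(~sorted_labels)
    # collapse threshold ties: keep the last index of each distinct score
    distinct = np.nonzero(np.diff(sorted_scores))[0]
    keep = np.r_[distinct, len(sorted_scores) - 1]
    tp, fp = tp[keep], fp[keep]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    precision = tp / (tp + fp)
    recall = tp / n_pos
    # step interpolation (right-continuous), equals average precision
    rec = np.r_[0.0, recall]
    auprc = float(np.sum((rec[1:] - rec[:-1]) * precision))
    return {
        "auroc": auroc,
        "auprc": auprc,
        "roc_points": np.column_stack([fpr, tpr]),
        "pr_points": np.column_stack([recall, precision]),
        "single_class": False,
    }


@dataclass
class MetricsReport:
    per_head: dict
    threshold: float = 50.0
    n: int = 0

    def to_dict(self) -> dict:
        return {"threshold": self.threshold, "n": self.n, "per_head": self.per_head}


def evaluate_predictions(pred: np.ndarray, obs: np.ndarray,
                         threshold: float = 50.0) -> MetricsReport:
    """Full per-head report: Spearman, Pearson, AUROC, AUPRC at the threshold."""
    pred, obs = np.asarray(pred, float), np.asarray(obs, float)
    report = {}
    for h, name in enumerate(HEAD_NAMES):
        rho, r = correlations(pred[:, h], obs[:, h])
        aucs = roc_pr_auc(pred[:, h], binarize_at_threshold(obs[:, h], threshold))
        report[name] = {
            "spearman": rho,
            "pearson": r,
            "auroc": aucs["auroc"],
            "auprc": aucs["auprc"],
            "n": int(len(pred)),
        }
    return MetricsReport(per_head=report, threshold=threshold, n=len(pred))


def epigenetic_group_split(
    annotations: dict[str, PerBaseAnnotation],
) -> tuple[dict[str, str], dict[str, str]]:
    """Assign each record to openness and methylation groups.

    Openness: "completely open" iff every wild-sequence position is
    accessible, else "presence of closure". Methylation: "with methylation"
    iff at least one position is methylated, else "without methylation".
    """
    openness, methylation = {}, {}
    for rid, annot in annotations.items():
        openness[rid] = (
            "completely open" if bool(annot.dnase.all()) else "presence of closure"
        )
        methylation[rid] = (
            "with methylation" if bool(annot.methyl.any()) else "without methylation"
        )
    return openness, methylation


@dataclass
class GroupComparison:
    grouping: str
    group_names: tuple
    group_sizes: tuple
    per_head: dict  # head -> {"U": float, "p": float}
    excluded: int = 0

    def to_dict(self) -> dict:
        return {
            "grouping": self.grouping,
            "groups": {n: s for n, s in zip(self.group_names, self.group_sizes)},
            "per_head": self.per_head,
            "excluded": self.excluded,
        }


def compare_epigenetic_groups(
    records, annotations: dict[str, PerBaseAnnotation],
    efficiencies: dict[str, np.ndarray] | None = None,
) -> list[GroupComparison]:
    """Mann-Whitney U per head for the openness and methylation groupings.

    Efficiencies default to each record's observed triple; records lacking an
    annotation or a triple are excluded and counted.
    """
    openness, methylation = epigenetic_group_split(annotations)
    rows = []
    excluded = 0
    for rec in records:
        eff = None
        if efficiencies is not None:
            eff = efficiencies.get(rec.record_id)
        elif rec.observed is not None:
            eff = rec.observed.as_array()
        if eff is None or rec.record_id not in annotations:
            excluded += 1
            continue
        rows.append((rec.record_id, np.asarray(eff, float)))

    out = []
    for grouping, labels, names in (
        ("openness", openness, ("completely open", "presence of closure")),
        ("methylation", methylation, ("with methylation", "without methylation")),
    ):
        a = np.array([eff for rid, eff in rows if labels[rid] == names[0]])
        b = np.array([eff for rid, eff in rows if labels[rid] == names[1]])
        per_head = {}
        for h, head in enumerate(HEAD_NAMES):
            if len(a) == 0 or len(b) == 0:
                per_head[head] = {"U": float("nan"), "p": float("nan")}
            else:
                u, p = mann_whitney_u(a[:, h], b[:, h])
                per_head[head] = {"U": u, "p": p}
        out.append(GroupComparison(
            grouping=grouping, group_names=names,
            group_sizes=(len(a), len(b)), per_head=per_head, excluded=excluded,
        ))
    return out
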