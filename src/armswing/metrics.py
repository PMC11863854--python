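"""Evaluation layer: timestamp-level classification metrics, prevalence
adjustment, and agreement statistics (ICC, Bland-Altman, median-difference
effects).

Conventions: the Bland-Altman bias line is the MEDIAN of the pairwise
differences (robust to the few large discrepancies typical of misclassified
segments), not the classical mean; the intraclass correlation is the
two-way random-effects, absolute-agreement, single-measure form (ICC2); the
unpaired median difference is the Hodges-Lehmann estimate (median of all
pairwise differences) with a seeded bootstrap confidence interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

ICC_FORM = "ICC2"  # two-way random, absolute agreement, single measures
_PINGOUIN_TYPE = "ICC(A,1)"  # pingouin's label for the same form


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionCounts":
        y_true = np.asarray(y_true, dtype=bool)
        y_pred = np.asarray(y_pred, dtype=bool)
        return cls(
            tp=int(np.sum(y_true & y_pred)),
            fp=int(np.sum(~y_true & y_pred)),
            tn=int(np.sum(~y_true & ~y_pred)),
            fn=int(np.sum(y_true & ~y_pred)),
        )


@dataclass(frozen=True)
class ClassificationMetrics:
    """Sensitivity/specificity/balanced accuracy; None marks an undefined
    metric (zero denominator) rather than propagating NaN."""

    sensitivity: float | None
    specificity: float | None
    balanced_accuracy: float | None


def classification_metrics(counts: ConfusionCounts) -> ClassificationMetrics:
    if counts.tp + counts.fp + counts.tn + counts.fn == 0:
        raise ValueError("empty confusion counts")
    sens = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn > 0 else None
    spec = counts.tn / (counts.tn + counts.fp) if counts.tn + counts.fp > 0 else None
    ba = (sens + spec) / 2 if sens is not None and spec is not None else None
    return ClassificationMetrics(sensitivity=sens, specificity=spec, balanced_accuracy=ba)


def prevalence_adjusted_sensitivity(
    sensitivities: Mapping[str, float],
    weights: Mapping[str, float],
) -> float:
    """Weighted mean of per-stratum sensitivities with group-level prevalence
    weights (e.g. gait-segment duration categories), so behavioral
    differences between compared groups do not confound the comparison."""
    total = float(sum(weights.values()))
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ValueError("prevalence weights must sum to 1")
    out = 0.0
    for stratum, w in weights.items():
        if w < 0:
            raise ValueError("weights must be non-negative")
        if w == 0:
            continue
        if stratum not in sensitivities:
            raise ValueError(f"missing sensitivity for stratum {stratum!r} with nonzero weight")
        out += w * sensitivities[stratum]
    return out


@dataclass(frozen=True)
class IccResult:
    icc: float | None
    ci95: tuple[float, float] | None
    form: str
    n_pairs: int


def icc_agreement(predicted, annotated) -> IccResult:
    """Two-way random, absolute-agreement, single-measure ICC with 95% CI.

    Used for agreement between aggregates derived from predicted vs
    annotated gait segments across subjects.
    """
    a = np.asarray(predicted, dtype=float)
    b = np.asarray(annotated, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("predicted and annotated must be equal-length 1-D arrays")
    n = len(a)
    if n < 5:
        raise ValueError("need at least 5 pairs for a meaningful ICC")
    if np.var(a) == 0 and np.var(b) == 0:
        return IccResult(icc=None, ci95=None, form=ICC_FORM, n_pairs=n)
    import pingouin as pg

    data = pd.DataFrame(
        {
            "target": np.tile(np.arange(n), 2),
            "rater": ["pred"] * n + ["annot"] * n,
            "rating": np.concatenate([a, b]),
        }
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = pg.intraclass_corr(data=data, targets="target", raters="rater", ratings="rating")
    table = table.set_index("Type")
    key = _PINGOUIN_TYPE if _PINGOUIN_TYPE in table.index else ICC_FORM
    row = table.loc[key]
    ci_col = "CI95" if "CI95" in table.columns else "CI95%"
    lo, hi = row[ci_col]
    return IccResult(icc=float(row["ICC"]), ci95=(float(lo), float(hi)), form=ICC_FORM, n_pairs=n)


@dataclass
class BlandAltman:
    mean: np.ndarray  # per-pair mean of the two methods
    diff: np.ndarray  # predicted - annotated
    bias: float  # median difference (the plotted horizontal line)


def bland_altman(predicted, annotated) -> BlandAltman:
    """Per-pair (mean, difference) table with the median-difference bias line."""
    a = np.asarray(predicted, dtype=float)
    b = np.asarray(annotated, dtype=float)
    if a.shape != b.shape or len(a) < 2:
        raise ValueError("need at least 2 equal-length pairs")
    diff = a - b
    return BlandAltman(mean=(a + b) / 2, diff=diff, bias=float(np.median(diff)))


@dataclass(frozen=True)
class GroupComparison:
    delta: float  # median difference (paired) / Hodges-Lehmann (unpaired)
    ci95: tuple[float, float]
    statistic: float
    p_value: float
    test: str


def group_compare(
    values_a,
    values_b,
    paired: bool,
    n_boot: int = 2000,
    seed: int = 0,
) -> GroupComparison:
    """Median-difference effect (a - b) with a seeded bootstrap 95% CI.

    The test statistic and p-value delegate to the Wilcoxon signed-rank test
    (paired) or the rank-sums test (independent samples).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 values per sample")
    rng = np.random.default_rng(seed)
    if paired:
        if len(a) != len(b):
            raise ValueError("paired comparison needs equal-length samples")
        d = a - b
        delta = float(np.median(d))
        if np.allclose(d, 0):
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.wilcoxon(a, b)
        idx = rng.integers(0, len(d), size=(n_boot, len(d)))
        boots = np.median(d[idx], axis=1)
    else:
        pairwise = np.subtract.outer(a, b).ravel()
        delta = float(np.median(pairwise))
        stat, p = stats.ranksums(a, b)
        boots = np.empty(n_boot)
        for k in range(n_boot):
            ra = a[rng.integers(0, len(a), size=len(a))]
            rb = b[rng.integers(0, len(b), size=len(b))]
            boots[k] = np.median(np.subtract.outer(ra, rb))
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return GroupComparison(
        delta=delta,
        ci95=(float(lo), float(hi)),
        statistic=float(stat),
        p_value=float(p),
        test="wilcoxon_signed_rank" if paired else "rank_sums",
    )


def auc_score(y_true, scores) -> float:
    """Area under the ROC curve (descriptive, for parity with reported tables)."""
    from sklearn.metrics import roc_auc_score

    return float(roc_auc_score(np.asarray(y_true, dtype=int), np.asarray(scores, dtype=float)))
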