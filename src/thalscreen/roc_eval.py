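"""Empirical ROC analysis for algorithm development.

Implements the discriminator-evaluation procedure used to develop the
composite score: per-parameter empirical ROC curves, the Mann-Whitney
AUC (ties half-credited), DeLong and bootstrap confidence intervals,
operating-point (cutoff) selection, and the AUC / p-value shortlisting
rule that narrows the candidate analyzer parameters.

Conventions
-----------
* Candidate thresholds are the midpoints between consecutive distinct
  sorted score values, plus -inf / +inf sentinels; a subject is called
  positive when its (oriented) score is strictly above the threshold.
* The AUC equals the probability that a random positive-class score
  exceeds a random negative-class one, ties counting one half; it is
  identical to the trapezoidal area under the empirical ROC polygon.
* When a parameter runs the "wrong way" (AUC < 0.5) its sign is flipped
  so the reported AUC is always >= 0.5, and the flip is recorded in
  ``orientation``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel_io import Cohort

__all__ = [
    "RocCurve",
    "ShortlistReport",
    "empirical_roc",
    "trapezoid_auc",
    "auc_ci",
    "select_cutoff",
    "shortlist_parameters",
]


@dataclass(frozen=True)
class RocCurve:
    """Empirical ROC for one candidate discriminator.

    ``thresholds`` descend from +inf to -inf so sensitivity is
    non-decreasing (and specificity non-increasing) along the arrays.
    ``orientation`` is "higher_in_positive" when raw scores run high in
    the positive class; "higher_in_negative" means the scores were
    negated internally and reported thresholds refer to raw values.
    """

    parameter_name: str
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    n_pos: int
    n_neg: int
    orientation: str = "higher_in_positive"
    auc_ci: Optional[tuple[float, float]] = None
    degenerate: bool = False
    # raw per-class scores retained for CI computation (oriented)
    pos_scores: np.ndarray = field(default=None, repr=False)
    neg_scores: np.ndarray = field(default=None, repr=False)

    @property
    def flipped(self) -> bool:
        return self.orientation == "higher_in_negative"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            }
        )


def _mann_whitney_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUC as the rank statistic: (wins + half-ties) / (n_pos * n_neg)."""
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    u = r_pos - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def empirical_roc(
    scores: Sequence[float],
    labels: Sequence,
    positive_class,
    parameter_name: str = "score",
) -> RocCurve:
    """Build the empirical ROC curve of ``scores`` against binary labels.

    Requires at least one subject per class and finite scores. If every
    score is identical the curve is degenerate: AUC 0.5 with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align one-to-one")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    is_pos = labels == positive_class
    pos, neg = scores[is_pos], scores[~is_pos]
    if pos.size == 0 or neg.size == 0:
        raise ValueError(
            f"need both classes: n_pos={pos.size}, n_neg={neg.size}"
        )

    degenerate = np.unique(scores).size == 1
    if degenerate:
        warnings.warn(
            f"{parameter_name}: all scores identical; degenerate ROC (AUC 0.5)",
            stacklevel=2,
        )

    auc = _mann_whitney_auc(pos, neg)
    orientation = "higher_in_positive"
    if auc < 0.5:
        orientation = "higher_in_negative"
        pos, neg = -pos, -neg
        scores = -scores
        auc = 1.0 - auc

    distinct = np.unique(scores)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    thr = np.concatenate([[np.inf], mids[::-1], [-np.inf]])
    # predicted positive iff oriented score > threshold
    sens = np.array([(pos > t).mean() for t in thr])
    spec = np.array([(neg <= t).mean() for t in thr])

    if orientation == "higher_in_negative":
        # report thresholds on the raw-score scale (negated back);
        # positive call is then raw score < reported threshold
        thr = -thr

    return RocCurve(
        parameter_name=parameter_name,
        thresholds=thr,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        n_pos=int(pos.size),
        n_neg=int(neg.size),
        orientation=orientation,
        degenerate=degenerate,
        pos_scores=pos,
        neg_scores=neg,
    )


def trapezoid_auc(curve: RocCurve) -> float:
    """Area under the ROC polygon in (FPR, TPR) space.

    Equals the Mann-Whitney AUC exactly; kept as an independent route
    for the equivalence invariant.
    """
    fpr = 1.0 - curve.specificity
    tpr = curve.sensitivity
    order = np.argsort(fpr, kind="stable")
    return float(np.trapezoid(tpr[order], fpr[order]))


def _delong_variance(pos: np.ndarray, neg: np.ndarray) -> float:
    """DeLong structural-component variance of the Mann-Whitney AUC."""
    m, n = pos.size, neg.size
    # placement of each positive among negatives (ties half)
    order = np.sort(neg)
    v10 = (
        np.searchsorted(order, pos, side="left")
        + np.searchsorted(order, pos, side="right")
    ) / (2.0 * n)
    order = np.sort(pos)
    v01 = (
        (m - np.searchsorted(order, neg, side="right"))
        + (m - np.searchsorted(order, neg, side="left"))
    ) / (2.0 * m)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(s10 / m + s01 / n)


def auc_ci(
    curve: RocCurve,
    method: str = "delong",
    level: float = 0.95,
    seed: Optional[int] = None,
    n_boot: int = 2000,
) -> tuple[float, float]:
    """Confidence interval for the AUC, clipped to [0, 1].

    ``delong`` uses the structural-component variance (deterministic);
    ``bootstrap`` resamples subjects within class (percentile interval,
    seeded). Both classes need at least 2 subjects.
    """
    if curve.n_pos < 2 or curve.n_neg < 2:
        raise ValueError("auc_ci requires at least 2 subjects per class")
    pos, neg = curve.pos_scores, curve.neg_scores
    if method == "delong":
        var = _delong_variance(pos, neg)
        if var == 0.0:
            warnings.warn(
                "zero DeLong variance (perfect or constant separation); "
                "degenerate zero-width interval",
                stacklevel=2,
            )
        z = stats.norm.ppf(0.5 + level / 2.0)
        half = z * math.sqrt(var)
        lo, hi = curve.auc - half, curve.auc + half
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        aucs = np.empty(n_boot)
        for b in range(n_boot):
            p = rng.choice(pos, size=pos.size, replace=True)
            q = rng.choice(neg, size=neg.size, replace=True)
            aucs[b] = _mann_whitney_auc(p, q)
        alpha = 1.0 - level
        lo, hi = np.quantile(aucs, [alpha / 2.0, 1.0 - alpha / 2.0])
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return (max(0.0, float(lo)), min(1.0, float(hi)))


def select_cutoff(
    curve: RocCurve, rule: str = "youden"
) -> tuple[float, float, float]:
    """Pick the operating threshold: (threshold, sensitivity, specificity).

    ``youden`` maximises sensitivity + specificity - 1;
    ``closest_topleft`` minimises (1-sens)^2 + (1-spec)^2. Ties break
    toward higher specificity, then the lower threshold value. On a
    degenerate curve the median score is returned with a warning.
    """
    if curve.degenerate:
        med = float(np.median(np.concatenate([curve.pos_scores, curve.neg_scores])))
        warnings.warn("degenerate curve; cutoff placed at the median score",
                      stacklevel=2)
        sens = float((curve.pos_scores > med).mean())
        spec = float((curve.neg_scores <= med).mean())
        if curve.flipped:
            med = -med
        return med, sens, spec

    finite = np.isfinite(curve.thresholds)
    thr = curve.thresholds[finite]
    sens = curve.sensitivity[finite]
    spec = curve.specificity[finite]
    if rule == "youden":
        objective = sens + spec - 1.0
        best = objective.max()
        ok = objective >= best - 1e-15
    elif rule == "closest_topleft":
        objective = (1.0 - sens) ** 2 + (1.0 - spec) ** 2
        best = objective.min()
        ok = objective <= best + 1e-15
    else:
        raise ValueError(f"unknown cutoff rule {rule!r}")

    idx = np.flatnonzero(ok)
    # tie-break: higher specificity, then lower threshold
    idx = idx[spec[idx] == spec[idx].max()]
    i = idx[np.argmin(thr[idx])]
    return float(thr[i]), float(sens[i]), float(spec[i])


@dataclass(frozen=True)
class ShortlistRow:
    parameter: str
    auc: float
    p_value: float
    kept: bool
    note: str = ""


@dataclass(frozen=True)
class ShortlistReport:
    """Per-parameter discrimination screen, sorted by AUC descending."""

    rows: tuple[ShortlistRow, ...]
    alpha_level: float
    auc_min: float
    positive_label: str
    negative_label: str

    def kept(self) -> list[str]:
        return [r.parameter for r in self.rows if r.kept]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.rows])


def shortlist_parameters(
    cohort: Cohort,
    parameters: Sequence[str],
    alpha_level: float = 0.05,
    auc_min: float = 0.8,
    positive_label: str = "beta_trait",
    negative_label: str = "alpha_trait",
) -> ShortlistReport:
    """Screen candidate parameters by class difference and discrimination.

    A parameter is kept when its two-sided Welch t-test p-value is below
    ``alpha_level`` and its (orientation-corrected) AUC exceeds
    ``auc_min``. A parameter absent from the cohort is recorded as not
    evaluable rather than failing the run. No multiple-testing
    correction is applied.
    """
    pos_recs = cohort.by_label(positive_label)
    neg_recs = cohort.by_label(negative_label)
    if not pos_recs or not neg_recs:
        raise ValueError(
            f"cohort must contain both {positive_label!r} and {negative_label!r}"
        )

    rows: list[ShortlistRow] = []
    for name in parameters:
        pos = np.array(
            [getattr(r, name) for r in pos_recs if r.has(name)], dtype=float
        )
        neg = np.array(
            [getattr(r, name) for r in neg_recs if r.has(name)], dtype=float
        )
        if pos.size < 2 or neg.size < 2:
            rows.append(
                ShortlistRow(name, math.nan, math.nan, False, "not_evaluable")
            )
            continue
        t = stats.ttest_ind(pos, neg, equal_var=False)
        scores = np.concatenate([pos, neg])
        labels = np.array([1] * pos.size + [0] * neg.size)
        curve = empirical_roc(scores, labels, positive_class=1,
                              parameter_name=name)
        kept = bool(t.pvalue < alpha_level) and bool(curve.auc > auc_min)
        note = "orientation_flipped" if curve.flipped else ""
        rows.append(ShortlistRow(name, curve.auc, float(t.pvalue), kept, note))

    rows.sort(key=lambda r: (-(r.auc if math.isfinite(r.auc) else -1.0)))
    return ShortlistReport(
        rows=tuple(rows),
        alpha_level=alpha_level,
        auc_min=auc_min,
        positive_label=positive_label,
        negative_label=negative_label,
    )
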