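"""2x2 contingency statistics with binomial confidence intervals.

The interlaboratory-validation arithmetic: cross-tabulate predicted
against true carrier state (beta-thalassaemia trait as the positive
condition, alpha-trait negative), then report sensitivity, specificity
and the predictive values, each with a binomial confidence interval
(Wilson score by default; Clopper-Pearson exact and Wald available).

Subjects whose call is not evaluable are excluded from the table but
always counted — silent dropping is forbidden.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Optional, Sequence

import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .scoring import NOT_EVALUABLE

__all__ = [
    "ContingencyTable",
    "DiagnosticAccuracy",
    "build_contingency",
    "accuracy_stats",
]

_CI_METHODS = {"wilson": "wilson", "exact": "beta", "wald": "normal"}


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts of prediction (rows) against condition (columns)."""

    tp: int
    fp: int
    fn: int
    tn: int
    positive_label: str = "beta_trait"
    rule: str = ""
    n_excluded: int = 0

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.total == 0:
            raise ValueError("contingency table is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def predicted_positive(self) -> int:
        return self.tp + self.fp

    @property
    def predicted_negative(self) -> int:
        return self.fn + self.tn

    @property
    def condition_present(self) -> int:
        return self.tp + self.fn

    @property
    def condition_absent(self) -> int:
        return self.fp + self.tn

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "condition_absent": [self.fp, self.tn],
                "condition_present": [self.tp, self.fn],
            },
            index=["predicted_positive", "predicted_negative"],
        )


def build_contingency(
    calls: Sequence,
    truth: Sequence,
    positive_class,
    not_evaluable=NOT_EVALUABLE,
    rule: str = "",
) -> ContingencyTable:
    """Cross-tabulate aligned predictions and true conditions.

    Calls equal to ``not_evaluable`` are excluded from the counts and
    tallied in ``n_excluded``.
    """
    if len(calls) != len(truth):
        raise ValueError("calls and truth must align one-to-one")
    if len(calls) == 0:
        raise ValueError("empty input")
    tp = fp = fn = tn = excluded = 0
    for call, cond in zip(calls, truth):
        if call == not_evaluable:
            excluded += 1
            continue
        pred_pos = call == positive_class
        cond_pos = cond == positive_class
        if pred_pos and cond_pos:
            tp += 1
        elif pred_pos:
            fp += 1
        elif cond_pos:
            fn += 1
        else:
            tn += 1
    return ContingencyTable(
        tp=tp, fp=fp, fn=fn, tn=tn,
        positive_label=str(positive_class),
        rule=rule,
        n_excluded=excluded,
    )


def _round2(x: float) -> float:
    """Half-up rounding to 2 decimals for display on the % scale."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), ROUND_HALF_UP))


@dataclass(frozen=True)
class DiagnosticAccuracy:
    """Sensitivity / specificity / PPV / NPV with confidence intervals.

    Point estimates are exact ratios in [0, 1]; ``ci`` maps each
    statistic to its (low, high) interval. A statistic with a zero
    denominator is NaN and listed in ``undefined``.
    """

    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    ci: dict[str, tuple[float, float]]
    ci_method: str
    level: float
    undefined: tuple[str, ...] = ()

    def as_percentages(self) -> dict[str, float]:
        """Display form: percentages rounded half-up to 2 decimals."""
        return {
            k: _round2(getattr(self, k) * 100.0)
            for k in ("sensitivity", "specificity", "ppv", "npv")
            if math.isfinite(getattr(self, k))
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k in ("sensitivity", "specificity", "ppv", "npv"):
            lo, hi = self.ci.get(k, (math.nan, math.nan))
            rows.append(
                {
                    "statistic": k,
                    "estimate": getattr(self, k),
                    "percent": _round2(getattr(self, k) * 100.0)
                    if math.isfinite(getattr(self, k))
                    else math.nan,
                    "ci_low": lo,
                    "ci_high": hi,
                }
            )
        return pd.DataFrame(rows)


def _one_stat(
    k: int, n: int, method: str, level: float
) -> tuple[float, tuple[float, float]]:
    if n == 0:
        return math.nan, (math.nan, math.nan)
    est = k / n
    lo, hi = proportion_confint(k, n, alpha=1.0 - level, method=_CI_METHODS[method])
    return est, (max(0.0, float(lo)), min(1.0, float(hi)))


def accuracy_stats(
    table: ContingencyTable,
    ci_method: str = "wilson",
    level: float = 0.95,
) -> DiagnosticAccuracy:
    """Diagnostic accuracy of the 2x2 table with binomial CIs.

    sensitivity = tp/(tp+fn); specificity = tn/(tn+fp);
    ppv = tp/(tp+fp); npv = tn/(tn+fn). A zero denominator leaves that
    statistic undefined (NaN) and the others computed.
    """
    if ci_method not in _CI_METHODS:
        raise ValueError(
            f"unknown ci_method {ci_method!r}; choose from {sorted(_CI_METHODS)}"
        )
    parts = {
        "sensitivity": (table.tp, table.condition_present),
        "specificity": (table.tn, table.condition_absent),
        "ppv": (table.tp, table.predicted_positive),
        "npv": (table.tn, table.predicted_negative),
    }
    est: dict[str, float] = {}
    cis: dict[str, tuple[float, float]] = {}
    undefined: list[str] = []
    for name, (k, n) in parts.items():
        e, ci = _one_stat(k, n, ci_method, level)
        est[name] = e
        cis[name] = ci
        if n == 0:
            undefined.append(name)
    return DiagnosticAccuracy(
        sensitivity=est["sensitivity"],
        specificity=est["specificity"],
        ppv=est["ppv"],
        npv=est["npv"],
        ci=cis,
        ci_method=ci_method,
        level=level,
        undefined=tuple(undefined),
    )
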