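"""End-to-end orchestration: develop, validate, simulate.

``run_develop`` reproduces the algorithm-development stage on a labelled
carrier cohort: shortlist the candidate analyzer parameters by class
difference and AUC, build the ROC of the fixed composite score, and
re-derive its operating cutoff. The composite's *form* is fixed
(scatter-channel x RDW - MCH); only the cutoff and its performance are
re-derived from data.

``run_validate`` reproduces the validation stage: per-group score
summaries and interquartile overlap across all labelled disorder groups,
then the alpha-vs-beta 2x2 contingency table and diagnostic accuracy at
the configured cutoff, with an exclusion count for non-evaluable
records.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from .datamodel_io import CPD_FIELDS, Cohort, write_results
from .diag_accuracy import (
    ContingencyTable,
    DiagnosticAccuracy,
    accuracy_stats,
    build_contingency,
)
from .roc_eval import (
    RocCurve,
    ShortlistReport,
    auc_ci,
    empirical_roc,
    select_cutoff,
    shortlist_parameters,
)
from .scoring import BETA_CALL, NOT_EVALUABLE, ScreeningConfig, score_cohort
from .synthetic_data import GroupDistribution, overlap_report, summarize

__all__ = ["RunConfig", "DevelopmentReport", "ValidationReport",
           "run_develop", "run_validate", "DEFAULT_CANDIDATES"]

log = logging.getLogger("thalscreen")

#: Candidate discriminators screened during development: the routine
#: indices that differ between the carrier states plus the reticulocyte
#: CPD channels.
DEFAULT_CANDIDATES = ("mcv", "mch", "rdw") + CPD_FIELDS

SMALL_N = 10  # per-class size below which a small-sample warning fires


@dataclass(frozen=True)
class RunConfig:
    """Resolved options for a pipeline run; serializable to JSON/YAML."""

    screening: ScreeningConfig = field(default_factory=ScreeningConfig)
    positive_label: str = "beta_trait"
    negative_label: str = "alpha_trait"
    candidates: tuple[str, ...] = DEFAULT_CANDIDATES
    alpha_level: float = 0.05
    auc_min: float = 0.8
    cutoff_rule: str = "youden"
    auc_ci_method: str = "delong"
    ci_method: str = "wilson"
    ci_level: float = 0.95
    seed: Optional[int] = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "screening" in d and isinstance(d["screening"], dict):
            d["screening"] = ScreeningConfig(**d["screening"])
        if "candidates" in d:
            d["candidates"] = tuple(d["candidates"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in {".yaml", ".yml"}:
            import yaml

            return cls.from_dict(yaml.safe_load(text) or {})
        return cls.from_dict(json.loads(text))


@dataclass
class DevelopmentReport:
    shortlist: ShortlistReport
    composite_curve: RocCurve
    cutoff: float
    sensitivity: float
    specificity: float
    warnings: tuple[str, ...] = ()

    def summary(self) -> dict:
        return {
            "composite_auc": self.composite_curve.auc,
            "composite_auc_ci": self.composite_curve.auc_ci,
            "cutoff": self.cutoff,
            "sensitivity_at_cutoff": self.sensitivity,
            "specificity_at_cutoff": self.specificity,
            "shortlisted": self.shortlist.kept(),
        }


@dataclass
class ValidationReport:
    summaries: dict[str, GroupDistribution]
    overlap: pd.DataFrame
    contingency: Optional[ContingencyTable]
    accuracy: Optional[DiagnosticAccuracy]
    n_excluded: int
    scores: pd.DataFrame

    def summary(self) -> dict:
        out: dict = {"n_excluded": self.n_excluded,
                     "groups": {k: v.n for k, v in self.summaries.items()}}
        if self.contingency is not None:
            t = self.contingency
            out["contingency"] = {"tp": t.tp, "fp": t.fp, "fn": t.fn, "tn": t.tn}
        if self.accuracy is not None:
            out["accuracy_percent"] = self.accuracy.as_percentages()
        return out


def _score_frame_for_labels(cohort, config, labels):
    frame = score_cohort(cohort, config.screening)
    if "label" not in frame.columns:
        raise ValueError("cohort must be labelled")
    return frame[frame["label"].isin(labels)]


def run_develop(
    cohort: Cohort, config: RunConfig = RunConfig(), out_dir: Optional[Path] = None
) -> DevelopmentReport:
    """Shortlist parameters, evaluate the composite, re-derive the cutoff."""
    notes: list[str] = []
    shortlist = shortlist_parameters(
        cohort,
        list(config.candidates),
        alpha_level=config.alpha_level,
        auc_min=config.auc_min,
        positive_label=config.positive_label,
        negative_label=config.negative_label,
    )
    log.info("develop: shortlisted %d/%d parameters",
             len(shortlist.kept()), len(config.candidates))

    frame = _score_frame_for_labels(
        cohort, config, [config.positive_label, config.negative_label]
    )
    evaluable = frame[frame["score"].notna()]
    n_pos = int((evaluable["label"] == config.positive_label).sum())
    n_neg = int((evaluable["label"] == config.negative_label).sum())
    if min(n_pos, n_neg) < SMALL_N:
        msg = f"small sample: n_pos={n_pos}, n_neg={n_neg}"
        warnings.warn(msg, stacklevel=2)
        notes.append(msg)

    curve = empirical_roc(
        evaluable["score"].to_numpy(),
        evaluable["label"].to_numpy(),
        positive_class=config.positive_label,
        parameter_name="composite_score",
    )
    if curve.flipped:
        notes.append("composite orientation flipped (score ran higher in the "
                     "negative class)")
    ci = auc_ci(curve, method=config.auc_ci_method, seed=config.seed,
                level=config.ci_level)
    curve = dataclasses.replace(curve, auc_ci=ci)
    thr, sens, spec = select_cutoff(curve, rule=config.cutoff_rule)
    log.info("develop: composite AUC %.4f (%s CI %.4f-%.4f), cutoff %.4f "
             "(sens %.3f, spec %.3f)", curve.auc, config.auc_ci_method,
             ci[0], ci[1], thr, sens, spec)

    report = DevelopmentReport(
        shortlist=shortlist,
        composite_curve=curve,
        cutoff=thr,
        sensitivity=sens,
        specificity=spec,
        warnings=tuple(notes),
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        meta = {"config": config.to_dict(), "stage": "develop"}
        write_results(shortlist.to_frame(), out_dir / "shortlist.csv",
                      metadata=meta, seed=config.seed)
        write_results(curve.to_frame(), out_dir / "composite_roc.csv",
                      metadata=meta, seed=config.seed)
        (out_dir / "develop_summary.json").write_text(
            json.dumps(report.summary(), indent=2, default=str)
        )
    return report


def run_validate(
    cohort: Cohort, config: RunConfig = RunConfig(), out_dir: Optional[Path] = None
) -> ValidationReport:
    """Score a labelled cohort, assess group overlap, tabulate accuracy."""
    frame = score_cohort(cohort, config.screening)
    if "label" not in frame.columns:
        raise ValueError("cohort must be labelled")

    summaries: dict[str, GroupDistribution] = {}
    for label in cohort.labels_present:
        summaries[label] = summarize(cohort, label)
    overlap = overlap_report(summaries)
    log.info("validate: %d groups summarised", len(summaries))

    pair = frame[frame["label"].isin([config.positive_label,
                                      config.negative_label])]
    contingency = None
    accuracy = None
    n_excluded = int((pair["call"] == NOT_EVALUABLE).sum())
    if (pair["label"] == config.positive_label).any():
        contingency = build_contingency(
            pair["call"].tolist(),
            pair["label"].tolist(),
            positive_class=config.positive_label,
            rule=f"score > {config.screening.cutoff} calls {BETA_CALL}",
        )
        accuracy = accuracy_stats(contingency, ci_method=config.ci_method,
                                  level=config.ci_level)
        log.info("validate: tp=%d fp=%d fn=%d tn=%d (excluded %d)",
                 contingency.tp, contingency.fp, contingency.fn,
                 contingency.tn, contingency.n_excluded)
    else:
        log.warning("validate: no %s records; accuracy undefined, "
                    "summaries still emitted", config.positive_label)

    report = ValidationReport(
        summaries=summaries,
        overlap=overlap,
        contingency=contingency,
        accuracy=accuracy,
        n_excluded=n_excluded,
        scores=frame,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        meta = {"config": config.to_dict(), "stage": "validate"}
        write_results(frame, out_dir / "scores.csv", metadata=meta,
                      seed=config.seed)
        write_results(overlap, out_dir / "overlap.csv", metadata=meta,
                      seed=config.seed)
        if accuracy is not None:
            write_results(accuracy.to_frame(), out_dir / "accuracy.csv",
                          metadata=meta, seed=config.seed)
        (out_dir / "validate_summary.json").write_text(
            json.dumps(report.summary(), indent=2, default=str)
        )
    return report
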