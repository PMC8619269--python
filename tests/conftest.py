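"""Shared fixtures: small deterministic cohorts built in memory."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from thalscreen import Cohort, SubjectRecord

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def record_with_score(subject_id: str, score: float, label=None,
                      rdw: float = 15.0, mch: float = 22.0) -> SubjectRecord:
    """A record whose composite score equals ``score`` by construction."""
    return SubjectRecord(
        subject_id=subject_id,
        rdw=rdw,
        mch=mch,
        mn_lmals_ret=(score + mch) / rdw,
        label=label,
    )


def cohort_from_scores(scores_by_label: dict[str, list[float]]) -> Cohort:
    records = []
    for label, scores in scores_by_label.items():
        for i, s in enumerate(scores):
            records.append(record_with_score(f"{label}-{i}", s, label=label))
    return Cohort(records, provenance="constructed")


@pytest.fixture
def interlab_cohort() -> Cohort:
    """95-subject cohort with the interlaboratory misclassification pattern.

    28 beta-trait subjects of whom 26 score above the 1742.5 cutoff, and
    67 alpha-trait subjects of whom 63 score at or below it.
    """
    rng = np.random.default_rng(42)
    beta = list(1750.0 + 40.0 * rng.random(26) * 10) + [1700.0, 1650.0]
    alpha = list(1742.5 - 300.0 * rng.random(63)) + list(
        1742.6 + 100.0 * rng.random(4)
    )
    return cohort_from_scores({"beta_trait": beta, "alpha_trait": alpha})


@pytest.fixture
def toy_roc_scores():
    """The 3-vs-3 toy with one tie pair per class: AUC = 7/9."""
    scores = np.array([1.0, 2.0, 3.0, 2.0, 3.0, 4.0])
    labels = np.array(["a", "a", "a", "b", "b", "b"])
    return scores, labels
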