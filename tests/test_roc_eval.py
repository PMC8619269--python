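"""Empirical ROC machinery against brute-force and closed-form oracles."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thalscreen import (
    auc_ci,
    binormal_auc,
    empirical_roc,
    select_cutoff,
    shortlist_parameters,
    trapezoid_auc,
)
from thalscreen.datamodel_io import Cohort, SubjectRecord


def exhaustive_auc(pos, neg):
    """Brute-force pair count: (wins + half-ties) / (n_pos * n_neg)."""
    pos = np.asarray(pos)[:, None]
    neg = np.asarray(neg)[None, :]
    wins = (pos > neg).sum()
    ties = (pos == neg).sum()
    return (wins + 0.5 * ties) / (pos.size * neg.size)


def roc_from(pos, neg, **kw):
    scores = np.concatenate([pos, neg])
    labels = np.array([1] * len(pos) + [0] * len(neg))
    return empirical_roc(scores, labels, positive_class=1, **kw)


class TestEmpiricalRoc:
    def test_perfect_separation_gives_auc_one(self):
        curve = roc_from([10.0, 11.0, 12.0], [1.0, 2.0, 3.0])
        assert curve.auc == 1.0

    def test_toy_with_ties_matches_pair_enumeration(self, toy_roc_scores):
        scores, labels = toy_roc_scores
        curve = empirical_roc(scores, labels, positive_class="b")
        # 6 wins + 2 half-credit ties over 9 pairs
        assert curve.auc == pytest.approx(7.0 / 9.0, abs=1e-15)

    def test_null_distribution_auc_near_half(self):
        rng = np.random.default_rng(5)
        curve = roc_from(rng.normal(size=500), rng.normal(size=500))
        assert curve.auc == pytest.approx(0.5, abs=0.06)

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="both classes"):
            empirical_roc([1.0, 2.0], [1, 1], positive_class=1)

    def test_identical_scores_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            curve = roc_from([3.0, 3.0], [3.0, 3.0])
        assert curve.auc == 0.5
        assert curve.degenerate

    def test_orientation_autoflip_records_flip(self):
        curve = roc_from([1.0, 2.0], [5.0, 6.0])  # positives run LOW
        assert curve.flipped
        assert curve.auc == 1.0

    def test_monotone_operating_points(self):
        rng = np.random.default_rng(9)
        curve = roc_from(rng.normal(1, 1, 40), rng.normal(0, 1, 30))
        assert np.all(np.diff(curve.sensitivity) >= 0)
        assert np.all(np.diff(curve.specificity) <= 0)

    @settings(max_examples=150, deadline=None)
    @given(
        st.lists(st.integers(0, 9), min_size=1, max_size=30),
        st.lists(st.integers(0, 9), min_size=1, max_size=30),
    )
    def test_pair_oracle_and_trapezoid_equivalence(self, pos, neg):
        # integer scores force heavy ties, the hard case
        curve = roc_from(np.array(pos, float), np.array(neg, float))
        oracle = exhaustive_auc(pos, neg)
        oracle = max(oracle, 1.0 - oracle)  # orientation-corrected
        assert curve.auc == pytest.approx(oracle, abs=1e-12)
        assert trapezoid_auc(curve) == pytest.approx(curve.auc, abs=1e-12)

    @settings(max_examples=100, deadline=None)
    @given(
        st.lists(st.floats(-50, 50), min_size=2, max_size=20),
        st.lists(st.floats(-50, 50), min_size=2, max_size=20),
        st.floats(-100, 100),
    )
    def test_shift_invariance_of_operating_points(self, pos, neg, shift):
        # quantise so the shift cannot merge almost-equal scores at the
        # floating-point resolution limit
        pos = np.round(np.array(pos), 3)
        neg = np.round(np.array(neg), 3)
        shift = round(shift, 1)
        a = roc_from(pos, neg)
        b = roc_from(pos + shift, neg + shift)
        assert np.array_equal(a.sensitivity, b.sensitivity)
        assert np.array_equal(a.specificity, b.specificity)

    def test_flip_complement(self):
        rng = np.random.default_rng(3)
        pos, neg = rng.normal(1, 1, 25), rng.normal(0, 1, 25)
        from thalscreen.roc_eval import _mann_whitney_auc

        assert _mann_whitney_auc(pos, neg) == pytest.approx(
            1.0 - _mann_whitney_auc(-pos, -neg), abs=1e-12
        )

    def test_matches_sklearn_cross_check(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(17)
        scores = np.round(rng.normal(size=200), 1)  # induce ties
        labels = rng.integers(0, 2, 200)
        while labels.sum() in (0, 200):  # pragma: no cover
            labels = rng.integers(0, 2, 200)
        curve = empirical_roc(scores, labels, positive_class=1)
        ref = roc_auc_score(labels, scores)
        assert curve.auc == pytest.approx(max(ref, 1 - ref), abs=1e-12)


class TestAucCi:
    def test_delong_deterministic_and_contains_auc(self):
        rng = np.random.default_rng(2)
        curve = roc_from(rng.normal(1, 1, 60), rng.normal(0, 1, 80))
        lo, hi = auc_ci(curve, method="delong")
        assert lo <= curve.auc <= hi
        assert (lo, hi) == auc_ci(curve, method="delong")

    def test_perfect_separation_zero_width_flagged(self):
        curve = roc_from([10.0, 11.0], [1.0, 2.0])
        with pytest.warns(UserWarning, match="zero DeLong variance"):
            lo, hi = auc_ci(curve, method="delong")
        assert lo == hi == 1.0

    def test_bootstrap_seed_reproducible(self):
        rng = np.random.default_rng(4)
        curve = roc_from(rng.normal(1, 1, 30), rng.normal(0, 1, 30))
        a = auc_ci(curve, method="bootstrap", seed=99, n_boot=200)
        b = auc_ci(curve, method="bootstrap", seed=99, n_boot=200)
        assert a == b
        assert 0.0 <= a[0] <= curve.auc <= a[1] <= 1.0

    def test_minimum_class_size_enforced(self):
        curve = roc_from([1.0], [0.0, 2.0])
        with pytest.raises(ValueError, match="at least 2"):
            auc_ci(curve)

    def test_coverage_on_binormal_cohorts(self):
        # both interval flavours should cover the closed-form AUC in the
        # vast majority of replicates and overlap each other
        true_auc = binormal_auc(0.0, 1.0, 1.0, 1.0)
        rng = np.random.default_rng(12)
        cover_d = cover_b = overlap = 0
        reps = 200
        for _ in range(reps):
            curve = roc_from(rng.normal(1, 1, 100), rng.normal(0, 1, 100))
            d = auc_ci(curve, method="delong")
            b = auc_ci(curve, method="bootstrap",
                       seed=int(rng.integers(2**31)), n_boot=300)
            cover_d += d[0] <= true_auc <= d[1]
            cover_b += b[0] <= true_auc <= b[1]
            overlap += max(d[0], b[0]) <= min(d[1], b[1])
        assert cover_d / reps >= 0.90
        assert cover_b / reps >= 0.90
        assert overlap == reps


class TestSelectCutoff:
    def test_perfect_separation_returns_gap_midpoint(self):
        curve = roc_from([10.0, 12.0], [2.0, 4.0])
        thr, sens, spec = select_cutoff(curve)
        assert thr == pytest.approx(7.0)  # midpoint of the 4..10 gap
        assert sens == 1.0 and spec == 1.0

    @pytest.mark.parametrize("rule", ["youden", "closest_topleft"])
    def test_toy_matches_exhaustive_sweep(self, rule, toy_roc_scores):
        scores, labels = toy_roc_scores
        pos = scores[labels == "b"]
        neg = scores[labels == "a"]
        # exhaustive sweep with the documented tie-break: best objective,
        # then highest specificity, then lowest threshold
        best = None
        for t in np.linspace(scores.min() - 1, scores.max() + 1, 2001):
            sens = (pos > t).mean()
            spec = (neg <= t).mean()
            obj = (sens + spec - 1.0 if rule == "youden"
                   else -((1 - sens) ** 2 + (1 - spec) ** 2))
            key = (obj, spec, -t)
            if best is None or key > best:
                best = key
        curve = empirical_roc(scores, labels, positive_class="b")
        _, sens, spec = select_cutoff(curve, rule=rule)
        obj = (sens + spec - 1.0 if rule == "youden"
               else -((1 - sens) ** 2 + (1 - spec) ** 2))
        assert obj == pytest.approx(best[0], abs=1e-12)
        assert spec == best[1]

    def test_rank_invariance_under_scaling(self):
        rng = np.random.default_rng(8)
        pos, neg = rng.normal(2, 1, 30), rng.normal(0, 1, 30)
        t1, s1, p1 = select_cutoff(roc_from(pos, neg))
        t2, s2, p2 = select_cutoff(roc_from(pos * 10, neg * 10))
        assert (s1, p1) == (s2, p2)
        assert t2 == pytest.approx(t1 * 10)

    def test_degenerate_curve_threshold_at_median(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            curve = roc_from([5.0, 5.0], [5.0, 5.0])
            thr, _, _ = select_cutoff(curve)
        assert thr == 5.0


class TestShortlist:
    @staticmethod
    def _cohort(pos_vals, neg_vals, param="rdw"):
        recs = [
            SubjectRecord(f"b{i}", label="beta_trait", **{param: float(v)})
            for i, v in enumerate(pos_vals)
        ] + [
            SubjectRecord(f"a{i}", label="alpha_trait", **{param: float(v)})
            for i, v in enumerate(neg_vals)
        ]
        return Cohort(recs)

    def test_pure_noise_parameter_dropped(self):
        rng = np.random.default_rng(21)
        cohort = self._cohort(rng.normal(15, 2, 100), rng.normal(15, 2, 100))
        report = shortlist_parameters(cohort, ["rdw"])
        assert report.rows[0].kept is False

    def test_strong_signal_kept(self):
        rng = np.random.default_rng(22)
        cohort = self._cohort(rng.normal(21, 2, 100), rng.normal(15, 2, 100))
        report = shortlist_parameters(cohort, ["rdw"])
        row = report.rows[0]
        assert row.kept and row.p_value < 1e-10 and row.auc > 0.9

    def test_absent_parameter_not_fatal(self):
        rng = np.random.default_rng(23)
        cohort = self._cohort(rng.normal(21, 2, 20), rng.normal(15, 2, 20))
        report = shortlist_parameters(cohort, ["rdw", "maf"])
        notes = {r.parameter: r.note for r in report.rows}
        assert notes["maf"] == "not_evaluable"

    def test_rdw_auc_recovers_binormal_oracle(self):
        # published carrier RDW summaries, realistic class sizes
        oracle = binormal_auc(15.43, 1.45, 17.31, 2.01)
        rng = np.random.default_rng(30)
        aucs = []
        for _ in range(200):
            pos = rng.normal(17.31, 2.01, 48)
            neg = rng.normal(15.43, 1.45, 155)
            aucs.append(roc_from(pos, neg).auc)
        assert np.mean(aucs) == pytest.approx(oracle, abs=0.03)

    def test_report_sorted_by_auc_descending(self):
        rng = np.random.default_rng(31)
        recs = []
        for i in range(60):
            recs.append(
                SubjectRecord(
                    f"b{i}", label="beta_trait",
                    rdw=float(rng.normal(19, 2)),
                    mch=float(rng.normal(21, 2)),
                )
            )
            recs.append(
                SubjectRecord(
                    f"a{i}", label="alpha_trait",
                    rdw=float(rng.normal(15, 2)),
                    mch=float(rng.normal(24, 2)),
                )
            )
        report = shortlist_parameters(Cohort(recs), ["mch", "rdw"])
        aucs = [r.auc for r in report.rows]
        assert aucs == sorted(aucs, reverse=True)
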