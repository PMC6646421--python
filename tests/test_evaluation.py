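"""Metrics against a brute-force oracle, plus LODO and replicate summaries."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from combosyn.evaluation import (
    MetricsReport,
    compute_metrics,
    lodo_summary,
    replicate_variability,
    stratified_report,
)
from combosyn.models import Prediction
from combosyn.scoring import SingleAgentRecord


def brute_force_metrics(y_obs, y_pred):
    """Independent loop-based RMSE/R2/Pearson/Spearman (no shared code)."""
    n = len(y_obs)
    sq = 0.0
    for a, b in zip(y_obs, y_pred):
        sq += (a - b) ** 2
    rmse = math.sqrt(sq / n)
    mean_obs = sum(y_obs) / n
    var = sum((a - mean_obs) ** 2 for a in y_obs) / n
    r2 = 1 - (rmse**2) / var

    def pearson(u, v):
        mu = sum(u) / n
        mv = sum(v) / n
        num = sum((a - mu) * (b - mv) for a, b in zip(u, v))
        du = math.sqrt(sum((a - mu) ** 2 for a in u))
        dv = math.sqrt(sum((b - mv) ** 2 for b in v))
        return num / (du * dv)

    def ranks(u):
        order = sorted(range(n), key=lambda i: u[i])
        r = [0.0] * n
        i = 0
        while i < n:
            j = i
            while j + 1 < n and u[order[j + 1]] == u[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    return rmse, r2, pearson(y_obs, y_pred), pearson(ranks(y_obs), ranks(y_pred))


class TestComputeMetrics:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 5.0, -3.0])
        r = compute_metrics(y, y)
        assert (r.rmse, r.r2, r.r_p, r.r_s) == (0.0, 1.0, 1.0, 1.0)

    def test_shifted_hand_case(self):
        r = compute_metrics([0, 1, 2, 3], [0.5, 1.5, 2.5, 3.5])
        assert r.rmse == pytest.approx(0.5)
        assert r.r2 == pytest.approx(0.8)  # 1 - 0.25/1.25, population variance
        assert r.r_p == pytest.approx(1.0)
        assert r.r_s == pytest.approx(1.0)

    def test_reversed_hand_case(self):
        r = compute_metrics([1, 2, 3], [3, 2, 1])
        assert r.r_p == pytest.approx(-1.0)
        assert r.r_s == pytest.approx(-1.0)
        assert r.r2 == pytest.approx(-3.0)

    def test_constant_observations_flagged(self):
        r = compute_metrics([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])
        assert r.degenerate
        assert math.isnan(r.r2) and math.isnan(r.r_p) and math.isnan(r.r_s)
        assert r.rmse == pytest.approx(math.sqrt(2 / 3))

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            n = int(rng.integers(5, 1000))
            y = rng.normal(size=n) * rng.uniform(1, 50)
            yhat = y * rng.uniform(0.2, 1.5) + rng.normal(size=n)
            r = compute_metrics(y, yhat)
            rmse, r2, rp, rs = brute_force_metrics(list(y), list(yhat))
            assert r.rmse == pytest.approx(rmse, abs=1e-10)
            assert r.r2 == pytest.approx(r2, abs=1e-10)
            assert r.r_p == pytest.approx(rp, abs=1e-10)
            assert r.r_s == pytest.approx(rs, abs=1e-10)

    def test_r2_identity_holds_exactly(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=50)
        yhat = rng.normal(size=50)
        r = compute_metrics(y, yhat)
        assert r.r2 == 1.0 - r.rmse**2 / np.var(y)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        st.lists(st.floats(-100, 100), min_size=4, max_size=30, unique=True),
        st.floats(0.1, 10),
        st.floats(-50, 50),
    )
    def test_pearson_affine_and_spearman_monotone_invariance(self, ys, a, b):
        rng = np.random.default_rng(0)
        y = np.array(ys)
        yhat = y + rng.normal(size=len(y))
        base = compute_metrics(y, yhat)
        affine = compute_metrics(y, a * yhat + b)
        assert affine.r_p == pytest.approx(base.r_p, abs=1e-9)
        monotone = compute_metrics(y, np.exp(yhat / 100.0))
        assert monotone.r_s == pytest.approx(base.r_s, abs=1e-9)

    def test_length_checks(self):
        with pytest.raises(ValueError):
            compute_metrics([1.0], [1.0])
        with pytest.raises(ValueError):
            compute_metrics([1.0, 2.0], [1.0])


class TestStratifiedReport:
    def _make(self, errors, sds):
        y = np.arange(len(errors), dtype=float) * 10
        preds = [
            Prediction("A", f"B{i}", "CL", y[i] + errors[i], sds[i])
            for i in range(len(errors))
        ]
        return preds, y

    def test_heteroscedastic_ordering(self):
        rng = np.random.default_rng(5)
        sds = np.concatenate([np.full(20, 1.0), np.full(20, 20.0)])
        errors = rng.normal(scale=sds)
        preds, y = self._make(errors, sds)
        from combosyn.models import reliability_strata

        strata = reliability_strata(preds, q=0.25)
        reports = stratified_report(preds, y, strata)
        assert reports["most_reliable"].rmse <= reports["all"].rmse
        assert reports["all"].rmse <= reports["least_reliable"].rmse

    def test_contexts_and_sizes(self):
        preds, y = self._make(np.zeros(8), np.arange(8.0))
        from combosyn.models import reliability_strata

        strata = reliability_strata(preds, q=0.25)
        reports = stratified_report(preds, y, strata, context={"cell_line": "CL"})
        assert all(r.context["cell_line"] == "CL" for r in reports.values())
        assert reports["most_reliable"].n == 2

    def test_tiny_stratum_flagged(self):
        preds, y = self._make(np.zeros(3), [1.0, 2.0, 3.0])
        from combosyn.models import reliability_strata

        strata = reliability_strata(preds, q=0.25)  # floor(0.75) = 0
        reports = stratified_report(preds, y, strata)
        assert reports["most_reliable"].degenerate


class TestLodoSummary:
    def _report(self, r_p, cell, drug, rmse=10.0):
        return MetricsReport(
            n=5, rmse=rmse, r2=0.5, r_p=r_p, r_s=r_p,
            context={"cell_line": cell, "left_out_drug": drug},
        )

    def test_quartiles_by_hand(self):
        reports = [
            self._report(rp, "CL1", f"d{i}") for i, rp in enumerate([0.1, 0.2, 0.3, 0.4])
        ]
        out = lodo_summary(reports)
        q = out["per_cell_line"]["CL1"]["r_p"]
        assert q["median"] == pytest.approx(0.25)
        assert q["min"] == 0.1 and q["max"] == 0.4

    def test_single_fold_degenerate_quartiles(self):
        out = lodo_summary([self._report(0.7, "CL1", "d0")])
        q = out["per_cell_line"]["CL1"]["r_p"]
        assert q["min"] == q["median"] == q["max"] == 0.7

    def test_per_drug_median_cell_order_invariant(self):
        reports = [
            self._report(0.2, "CL1", "d0"),
            self._report(0.6, "CL2", "d0"),
            self._report(0.4, "CL3", "d0"),
        ]
        a = lodo_summary(reports)["per_drug"]["d0"]["r_p_median"]
        b = lodo_summary(reports[::-1])["per_drug"]["d0"]["r_p_median"]
        assert a == b == pytest.approx(0.4)


class TestReplicateVariability:
    def _records(self, center, growths, drug="d1", conc=1.0, cell="CL1"):
        return [
            SingleAgentRecord(center, drug, conc, cell, f"t{i}", g)
            for i, g in enumerate(growths)
        ]

    def test_constant_replicates_sd_zero(self):
        out = replicate_variability(self._records("FG", [50, 50, 50]))
        assert out["sets"][0].sd == 0.0

    def test_two_replicates_population_sd(self):
        out = replicate_variability(self._records("FG", [40, 60]))
        assert out["sets"][0].sd == 10.0

    def test_singleton_flagged(self):
        out = replicate_variability(self._records("FG", [42]))
        assert out["sets"][0].singleton and out["sets"][0].sd == 0.0

    def test_average_test_dates_per_center(self):
        recs = self._records("FG", [1, 2, 3]) + self._records("FG", [1, 2], drug="d2")
        out = replicate_variability(recs)
        assert out["avg_tests_per_drug_cell_line"]["FG"] == pytest.approx(2.5)

    def test_matched_sets_paired_across_centers(self):
        recs = self._records("FG", [50, 52]) + self._records("FF", [30, 70])
        out = replicate_variability(recs)
        assert len(out["paired_sets"]) == 1
        sds = out["paired_sets"][0]["sd_by_center"]
        assert sds["FF"] > sds["FG"]
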