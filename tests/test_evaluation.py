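"""Evaluation statistics vs independent brute-force references."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from deepsuvr import evaluation as ev


class TestNegativePeak:
    def test_recovers_generating_mixture(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(0, 6, 1400), rng.normal(70, 20, 600)])
        peak = ev.fit_negative_peak(x, seed=0)
        assert abs(peak.peak_mean - 0.0) < 1.0
        assert abs(peak.peak_sd - 6.0) < 1.0

    def test_unimodal_still_returns_defined_peak(self):
        rng = np.random.default_rng(1)
        x = rng.normal(50, 5, 500)
        peak = ev.fit_negative_peak(x, seed=0)
        assert 40 < peak.peak_mean < 60

    def test_matches_plain_em_oracle(self):
        """Independent EM written from the update equations, on a small
        well-separated fixture where both must find the same optimum."""
        rng = np.random.default_rng(2)
        x = np.sort(np.concatenate([rng.normal(0, 2, 25), rng.normal(60, 5, 25)]))

        # brute-force EM, deliberately simple
        mu = np.array([x[12], x[37]])
        var = np.array([4.0, 25.0])
        pi = np.array([0.5, 0.5])
        for _ in range(500):
            dens = pi / np.sqrt(2 * np.pi * var) * np.exp(-((x[:, None] - mu) ** 2) / (2 * var))
            resp = dens / dens.sum(axis=1, keepdims=True)
            nk = resp.sum(axis=0)
            mu = (resp * x[:, None]).sum(axis=0) / nk
            var = (resp * (x[:, None] - mu) ** 2).sum(axis=0) / nk
            pi = nk / len(x)
        lower = int(np.argmin(mu))
        peak = ev.fit_negative_peak(x, seed=0)
        assert peak.peak_mean == pytest.approx(mu[lower], abs=1e-6)
        assert peak.peak_sd == pytest.approx(np.sqrt(var[lower]), abs=1e-6)

    def test_small_sample_raises(self):
        with pytest.raises(ValueError, match="20"):
            ev.fit_negative_peak(np.arange(10.0))


def _hsic_bruteforce(x, y):
    """Direct double-sum evaluation of the normalized HSIC V-statistic."""
    def gram(v):
        d = squareform(pdist(np.asarray(v, float).reshape(-1, 1)))
        med = np.median(d[d > 0])
        return np.exp(-(d**2) / (2 * med**2))

    def hs(k, l):
        n = k.shape[0]
        term1 = (k * l).sum() / n**2
        term2 = k.mean() * l.mean()
        term3 = 2.0 / n**3 * (k.sum(axis=1) @ l.sum(axis=1))
        return term1 + term2 - term3

    k, l = gram(x), gram(y)
    return hs(k, l) / np.sqrt(hs(k, k) * hs(l, l))


class TestHsic:
    def test_self_dependence_is_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        assert ev.hsic(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_shift_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=40)
        y = rng.normal(size=40)
        assert ev.hsic(x + 5.0, y) == pytest.approx(ev.hsic(x, y), abs=1e-12)

    def test_matches_double_sum_brute_force(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=40)
        y = x**2 + rng.normal(0, 0.5, 40)
        assert ev.hsic(x, y) == pytest.approx(_hsic_bruteforce(x, y), abs=1e-10)

    def test_independent_below_permutation_null(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=300)
        y = rng.normal(size=300)
        observed = ev.hsic(x, y)
        null = [ev.hsic(x, rng.permutation(y)) for _ in range(200)]
        assert observed < np.quantile(null, 0.95)

    def test_strong_nonlinear_dependence_detected(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(-2, 2, 200)
        y = x**2  # nonmonotone: Pearson/Spearman would miss this
        assert ev.hsic(x, y) > 0.3

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError, match="variance|bandwidth"):
            ev.hsic(np.ones(20), np.arange(20.0))


class TestOutliers:
    def test_threshold_rule(self):
        neg, pos = ev.outlier_rates([12.0, -6.0, 0.0, 5.0])
        assert neg == pytest.approx(25.0)
        assert pos == pytest.approx(25.0)

    def test_all_stable(self):
        assert ev.outlier_rates(np.zeros(10)) == (0.0, 0.0)

    def test_default_reference_range(self):
        th = ev.OutlierThresholds()
        assert th.lower == -5.8 and th.upper == 11.2

    def test_derive_normal_quantiles(self):
        rng = np.random.default_rng(0)
        th = ev.derive_thresholds(rng.normal(0, 1, 100_000), coverage=0.90)
        assert th.lower == pytest.approx(-1.645, abs=0.03)
        assert th.upper == pytest.approx(1.645, abs=0.03)

    def test_derive_widens_with_spread(self):
        rng = np.random.default_rng(1)
        narrow = ev.derive_thresholds(rng.normal(0, 1, 5000))
        wide = ev.derive_thresholds(rng.normal(0, 3, 5000))
        assert wide.lower < narrow.lower and wide.upper > narrow.upper

    def test_derive_degenerate_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            ev.derive_thresholds(np.zeros(100))


class TestCohensD:
    def test_hand_arithmetic(self):
        assert ev.cohens_d([2.0, 4.0], [0.0, 2.0]) == pytest.approx(np.sqrt(2.0))

    def test_identical_groups_zero(self):
        x = [1.0, 2.0, 3.0]
        assert ev.cohens_d(x, x) == pytest.approx(0.0)

    def test_antisymmetric(self):
        a = [1.0, 3.0, 4.0]
        b = [2.0, 2.5, 6.0]
        assert ev.cohens_d(a, b) == pytest.approx(-ev.cohens_d(b, a))

    def test_matches_pooled_formula_brute_force(self):
        rng = np.random.default_rng(0)
        a = rng.normal(1, 2, 30)
        b = rng.normal(0, 1.5, 20)
        na, nb = len(a), len(b)
        pooled = np.sqrt(((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2))
        assert ev.cohens_d(a, b) == pytest.approx((a.mean() - b.mean()) / pooled, abs=1e-12)


class TestAucF1:
    def test_perfect_separation(self):
        auc, thr = ev.auc_and_f1_threshold([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert auc == 1.0
        assert 3 < thr < 10

    def test_four_point_fixture(self):
        auc, thr = ev.auc_and_f1_threshold([1.0, 2.0, 3.0, 4.0], [0, 0, 1, 1])
        assert 2.0 < thr < 3.0
        assert auc == 1.0

    def test_random_labels_near_half(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=1000)
        y = rng.integers(0, 2, 1000)
        auc, _ = ev.auc_and_f1_threshold(x, y)
        assert abs(auc - 0.5) < 0.05

    def test_matches_pair_counting_brute_force(self):
        rng = np.random.default_rng(1)
        x = np.round(rng.normal(size=50), 1)  # ties included
        y = rng.integers(0, 2, 50)
        if y.sum() in (0, 50):
            y[0] = 1 - y[0]
        pos = x[y == 1]
        neg = x[y == 0]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert ev.auc_and_f1_threshold(x, y)[0] == pytest.approx(
            wins / (len(pos) * len(neg)), abs=1e-10
        )

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="class"):
            ev.auc_and_f1_threshold([1.0, 2.0], [1, 1])


class TestPairedBootstrap:
    @pytest.fixture()
    def spreads(self):
        rng = np.random.default_rng(0)
        ref = rng.normal(10, 3, 8)
        return pd.DataFrame(
            {"standard": ref, "identical": ref, "tighter": ref * 0.5}
        )

    def test_identical_method_null(self, spreads):
        out = ev.paired_bootstrap_stability(spreads, "standard", n_boot=2000, seed=0)
        assert out.loc["identical", "mean_difference"] == pytest.approx(0.0, abs=1e-12)
        assert 0.4 <= out.loc["identical", "p_value"] <= 0.6

    def test_dominated_method_significant(self, spreads):
        out = ev.paired_bootstrap_stability(spreads, "standard", n_boot=10_000, seed=0)
        assert out.loc["tighter", "mean_difference"] < 0
        assert out.loc["tighter", "p_value"] < 0.001
        assert out.loc["tighter", "ci_high"] < 0

    def test_seed_reproducible(self, spreads):
        a = ev.paired_bootstrap_stability(spreads, "standard", n_boot=500, seed=3)
        b = ev.paired_bootstrap_stability(spreads, "standard", n_boot=500, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_matches_loop_brute_force(self, spreads):
        """Same resampling indices replayed through an explicit loop."""
        out = ev.paired_bootstrap_stability(spreads, "standard", n_boot=200, seed=7)
        rng = np.random.default_rng(7)
        idx = rng.integers(0, len(spreads), size=(200, len(spreads)))
        diffs = []
        for row in idx:
            boot = spreads.iloc[row]
            diffs.append(boot["tighter"].std(ddof=1) - boot["standard"].std(ddof=1))
        assert out.loc["tighter", "mean_difference"] == pytest.approx(np.mean(diffs), abs=1e-12)


class TestEmergence:
    def _traj(self, sid, times, cls):
        return pd.DataFrame({"subject_id": sid, "time_years": times, "CL": cls})

    def test_rule_application(self):
        df = pd.concat(
            [
                self._traj("emergent", [0, 2.5, 5], [25, 28, 31]),
                self._traj("stable", [0, 3, 6], [25, 26, 27]),
                self._traj("baseline_pos", [0, 5], [32, 40]),
                self._traj("short_fu", [0, 2], [25, 35]),
            ]
        )
        labels, brackets, excluded = ev.classify_emergent(df)
        got = labels.set_index("subject_id")["emergent"]
        assert bool(got["emergent"]) is True
        assert bool(got["stable"]) is False
        assert "baseline_pos" not in got.index
        assert excluded == 2
        row = brackets[brackets["bracket"] == "[25,30)"]
        assert row["proportion_emergent"].iloc[0] == pytest.approx(0.5)


class TestTrajectoryPolynomial:
    def test_exact_degree5_recovery(self):
        rng = np.random.default_rng(0)
        coefs = np.array([1.0, 0.05, -0.003, 1e-5, 2e-7, -1e-9])
        mean = rng.uniform(0, 100, 60)
        rate = np.polynomial.polynomial.polyval(mean, coefs)
        out = ev.fit_trajectory_polynomial(
            pd.DataFrame({"mean_CL": mean, "rate_CL_per_year": rate})
        )
        np.testing.assert_allclose(out["coefficients"], coefs, atol=1e-6)

    def test_unimodal_peak_location(self):
        rng = np.random.default_rng(1)
        mean = rng.uniform(0, 120, 400)
        rate = 5 * np.exp(-(((mean - 60) / 30) ** 2)) + rng.normal(0, 0.1, 400)
        out = ev.fit_trajectory_polynomial(
            pd.DataFrame({"mean_CL": mean, "rate_CL_per_year": rate})
        )
        assert abs(out["peak_CL"] - 60) < 5

    def test_peak_restricted_to_support(self):
        rng = np.random.default_rng(2)
        mean = rng.uniform(20, 40, 50)
        rate = mean * 0.1  # increasing: unrestricted max would extrapolate
        out = ev.fit_trajectory_polynomial(
            pd.DataFrame({"mean_CL": mean, "rate_CL_per_year": rate})
        )
        assert 20 <= out["peak_CL"] <= 40

    def test_bootstrap_ci_brackets_peak(self):
        rng = np.random.default_rng(3)
        mean = rng.uniform(0, 100, 300)
        rate = 4 * np.exp(-(((mean - 50) / 25) ** 2)) + rng.normal(0, 0.2, 300)
        out = ev.fit_trajectory_polynomial(
            pd.DataFrame({"mean_CL": mean, "rate_CL_per_year": rate}), n_boot=100, seed=0
        )
        lo, hi = out["peak_rate_ci"]
        assert lo <= out["peak_rate"] <= hi
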