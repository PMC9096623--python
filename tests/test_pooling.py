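"""Pooling estimators against hand and brute-force oracles."""

import numpy as np
import pytest
from scipy import stats

import metacurve as mc
from metacurve.pooling import tau2_dl, tau2_reml
from metacurve.transforms import TransformedEffect
from conftest import make_record


def eff(values, variances, scale="fisher_z"):
    return [
        TransformedEffect(float(y), float(v), scale, max(4, int(round(1 / v + 3))))
        for y, v in zip(values, variances)
    ]


def brute_force_dl_pool(y, v):
    """Independent spelled-out DL random-effects fit (no shared code)."""
    y = np.asarray(y, float)
    v = np.asarray(v, float)
    w = 1.0 / v
    mu_fe = (w * y).sum() / w.sum()
    Q = (w * (y - mu_fe) ** 2).sum()
    c = w.sum() - (w * w).sum() / w.sum()
    tau2 = (Q - (len(y) - 1)) / c
    tau2 = tau2 if tau2 > 0 else 0.0
    wr = 1.0 / (v + tau2)
    return (wr * y).sum() / wr.sum(), tau2


class TestTau2:
    def test_identical_effects_give_zero(self):
        e = eff([0.3] * 5, [0.04] * 5)
        assert mc.tau2_estimate(e, "DL") == 0.0
        assert mc.tau2_estimate(e, "REML") == 0.0

    def test_hand_example_dl(self):
        # z = {0, 1}, v = {0.25, 0.25}: Q = 2, tau2 = (2-1)/(8 - 32/8) = 0.25
        e = eff([0.0, 1.0], [0.25, 0.25])
        assert mc.tau2_estimate(e, "DL") == pytest.approx(0.25, abs=1e-12)

    def test_reml_recovers_simulated_tau(self, rng):
        tau = 0.15
        k = 500
        v = rng.uniform(0.005, 0.05, size=k)
        y = rng.normal(0.2, np.sqrt(v + tau**2))
        assert np.sqrt(tau2_reml(y, v)) == pytest.approx(tau, abs=0.02)

    def test_k1_error(self):
        with pytest.raises(ValueError):
            mc.tau2_estimate(eff([0.1], [0.1]), "DL")


class TestPoolRandom:
    def test_matches_brute_force_dl_on_random_instances(self, rng):
        for _ in range(100):
            k = rng.integers(3, 20)
            v = rng.uniform(0.002, 0.3, size=k)
            y = rng.normal(0.2, 0.3, size=k)
            fit = mc.pool_random(eff(y, v), estimator="DL", kh=False)
            mu, t2 = brute_force_dl_pool(y, v)
            assert fit.estimate_working == pytest.approx(mu, abs=1e-10)
            assert fit.tau2 == pytest.approx(t2, abs=1e-10)

    def test_degenerate_constant_set(self):
        fit = mc.pool_random(eff([0.3, 0.3, 0.3], [0.04, 0.04, 0.04]))
        assert fit.estimate_working == pytest.approx(0.3)
        assert fit.tau2 == 0.0 and fit.I2 == 0.0
        assert fit.ci_low == fit.ci_high == fit.estimate_r

    def test_estimate_within_convex_hull(self, rng):
        for _ in range(20):
            k = rng.integers(2, 15)
            y = rng.normal(0, 0.5, size=k)
            v = rng.uniform(0.01, 0.2, size=k)
            fit = mc.pool_random(eff(y, v))
            assert y.min() - 1e-12 <= fit.estimate_working <= y.max() + 1e-12
            assert 0 <= fit.I2 < 100
            assert fit.tau2 >= 0

    def test_kh_wider_than_normal_at_k2(self, rng):
        e = eff([0.1, 0.5], [0.04, 0.09])
        kh = mc.pool_random(e, kh=True)
        plain = mc.pool_random(e, kh=False)
        assert (kh.ci_high - kh.ci_low) > (plain.ci_high - plain.ci_low)

    def test_back_transform_ordering(self, rng):
        fit = mc.pool_random(eff([0.1, 0.3, 0.2], [0.02, 0.05, 0.04]))
        assert fit.ci_low < fit.estimate_r < fit.ci_high

    def test_mixed_scales_rejected(self):
        bad = [
            TransformedEffect(0.2, 0.04, "fisher_z", 28),
            TransformedEffect(0.2, 0.04, "raw_r", 28),
        ]
        with pytest.raises(ValueError, match="mixed scales"):
            mc.pool_random(bad)


class TestPoolHS:
    def test_equal_n_is_arithmetic_mean(self):
        recs = [make_record(r=0.2, n=50), make_record(r=0.4, n=50)]
        assert mc.pool_hs(recs).estimate_r == pytest.approx(0.3)

    def test_n_weighted_mean(self):
        recs = [make_record(r=0.2, n=100), make_record(r=0.4, n=300)]
        assert mc.pool_hs(recs).estimate_r == pytest.approx(0.35)

    def test_residual_variance_vanishes_when_homogeneous(self, rng):
        # one common true effect: the observed variance should be explained
        # by sampling error as k grows
        rho = 0.3
        k = 400
        n = rng.integers(30, 200, size=k)
        r = np.tanh(rng.normal(np.arctanh(rho), np.sqrt(1 / (n - 3))))
        recs = [make_record(r=float(ri), n=int(ni)) for ri, ni in zip(r, n)]
        fit = mc.pool_hs(recs)
        assert fit.tau2 < 0.25 * fit.extra["var_observed"]

    def test_corrected_mode_needs_params(self, toy_records):
        with pytest.raises(ValueError):
            mc.pool_hs(toy_records, corrected=True)
        params = {rec.sample_key(): mc.RangeRestrictionParams(u=1.3)
                  for rec in toy_records}
        fit = mc.pool_hs(toy_records, corrected=True, params=params)
        assert fit.estimate_r > mc.pool_hs(toy_records).estimate_r  # u > 1 inflates


class TestPoolUnweighted:
    def test_simple_mean(self):
        fit = mc.pool_unweighted(eff([0.1, 0.3], [0.04, 0.04], scale="raw_r"))
        assert fit.estimate_r == pytest.approx(0.2)

    def test_constant_set_collapses_ci(self):
        fit = mc.pool_unweighted(eff([0.2, 0.2, 0.2], [0.04, 0.02, 0.01]))
        assert fit.ci_low == fit.ci_high == fit.estimate_r

    def test_equals_random_effects_with_equal_variances_no_tau(self, rng):
        y = rng.normal(0.3, 0.001, size=6)  # tiny spread so tau2 = 0
        e = eff(y, [0.05] * 6)
        un = mc.pool_unweighted(e)
        re = mc.pool_random(e, estimator="DL")
        assert re.tau2 == 0.0
        assert un.estimate_working == pytest.approx(re.estimate_working, abs=1e-12)


class TestLeaveOneOut:
    def test_matches_explicit_subsets(self, rng):
        y = rng.normal(0.2, 0.2, size=6)
        v = rng.uniform(0.01, 0.1, size=6)
        e = eff(y, v)
        loo = mc.leave_one_out(e, estimator="DL")
        for i, fit in enumerate(loo):
            direct = mc.pool_random(e[:i] + e[i + 1:], estimator="DL")
            assert fit.estimate_working == pytest.approx(direct.estimate_working, abs=1e-14)

    def test_identical_effects_identical_results(self):
        loo = mc.leave_one_out(eff([0.3] * 3, [0.04] * 3))
        assert len({round(f.estimate_r, 12) for f in loo}) == 1

    def test_fixture_stability(self, fs_independent):
        e = [mc.transform_record(r) for r in fs_independent]
        full = mc.pool_random(e, estimator="DL")
        loo = mc.leave_one_out(e, estimator="DL")
        max_shift = max(abs(f.estimate_r - full.estimate_r) for f in loo)
        assert max_shift < 0.01  # no single leverage point moves the summary


class TestInfluence:
    def test_planted_outlier_flagged(self, rng):
        k = 30
        v = np.full(k, 0.01)
        y = rng.normal(0.2, 0.05, size=k)
        y[7] = 0.2 + 6 * np.sqrt(0.01 + 0.05**2)  # six sigma out
        rows = mc.influence_diagnostics(eff(y, v), estimator="DL")
        assert rows[7]["flagged"]

    def test_homogeneous_set_rarely_flags(self, rng):
        flags = 0
        for rep in range(20):
            y = rng.normal(0.2, 0.0, size=20) + rng.normal(0, 0.1, 20)
            v = np.full(20, 0.01)
            rows = mc.influence_diagnostics(eff(y, v), estimator="DL")
            flags += sum(r["flagged"] for r in rows)
        assert flags / (20 * 20) < 0.08  # near the nominal false-positive rate

    def test_fixture_has_few_leverage_points(self, fs_independent):
        rows = mc.influence_diagnostics(
            [mc.transform_record(r) for r in fs_independent], estimator="DL"
        )
        assert sum(r["flagged"] for r in rows) <= 5
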