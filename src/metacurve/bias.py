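"""Dissemination-bias battery.

Eight families of checks on a set of independent correlation effects:

* study power at the observed random-effects summary, median power, sunset
  thresholds, the test of excess significance (TES) and the R-index;
* Egger–Sterne regression of the standard normal deviate on precision;
* Duval–Tweedie trim-and-fill with random-effects refit;
* p-curve (right-skew tests and KS-loss effect estimation);
* p-uniform (conditional-p estimator, method P) and p-uniform* (ML over all
  effects with between-study variance);
* a-priori weight-function selection models (Vevea–Woods step presets);
* the Henmi–Copas hybrid (fixed-effect weights, random-effects
  heterogeneity) compared to the conventional DerSimonian–Laird interval;
* cumulative meta-analysis by publication year or sample size.

By convention the battery runs on reported (journal-published), healthy,
independent effects; zero-imputed records are excluded from the p-value
based methods because their p-values would be fabrications.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .pooling import PooledResult, pool_random, tau2_dl, tau2_reml
from .records import EffectSet
from .transforms import back_transform, fisher_z, transform_record, z_variance


@dataclass
class BiasReport:
    method: str
    statistics: dict[str, float]
    p: Optional[float] = None
    adjusted: Optional[PooledResult] = None
    n_imputed: Optional[int] = None
    notes: str = ""


@dataclass
class PowerProfile:
    per_study_power: np.ndarray
    median_power: float
    success_rate: float
    expected_sig: float
    observed_sig: int
    k: int
    summary_z: float


def bias_default_subset(effect_set: EffectSet) -> EffectSet:
    """The battery's default restriction: reported (published) effects only.

    The healthy-samples restriction is applied by the caller (it is a data
    subset, not a method property); this helper only drops grey-literature
    and personal-communication effects and logs nothing else.
    """
    from .records import filter_subset

    return filter_subset(effect_set, {"reporting": "reported"})


# --------------------------------------------------------------- power / TES

def study_power(n: int, true_z: float, alpha: float = 0.05) -> float:
    """Two-tailed power of the Fisher-z test of r = 0 at a true effect.

    Both rejection tails are counted:
    P(Z > z_crit - lambda) + P(Z < -z_crit - lambda), lambda = z sqrt(n-3).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n < 4:
        raise ValueError("study_power requires n >= 4")
    zc = stats.norm.ppf(1 - alpha / 2)
    lam = true_z * np.sqrt(n - 3.0)
    return float(stats.norm.sf(zc - lam) + stats.norm.cdf(-zc - lam))


def power_profile(
    effect_set: EffectSet,
    true_z: Optional[float] = None,
    alpha: float = 0.05,
) -> PowerProfile:
    """Per-study power at the random-effects summary of the set itself.

    ``true_z`` overrides the summary (useful for sunset thresholds).
    """
    eff = [transform_record(r, "fisher_z") for r in effect_set.records]
    if true_z is None:
        true_z = pool_random(eff, estimator="REML").estimate_working
    ns = np.array([r.n for r in effect_set.records], float)
    pw = np.array([study_power(int(n), true_z, alpha) for n in ns])
    y = np.array([e.value for e in eff])
    v = np.array([e.variance for e in eff])
    pvals = 2 * stats.norm.sf(np.abs(y) / np.sqrt(v))
    obs = int(np.sum(pvals < alpha))
    return PowerProfile(
        per_study_power=pw,
        median_power=float(np.median(pw)),
        success_rate=obs / len(pw),
        expected_sig=float(pw.sum()),
        observed_sig=obs,
        k=len(pw),
        summary_z=float(true_z),
    )


def sunset_threshold(effect_set: EffectSet, target: float, alpha: float = 0.05) -> float:
    """True correlation at which the median study power equals ``target``.

    ``target`` is a proportion in (alpha, 1); root-solved on the r scale.
    """
    if not alpha < target < 1:
        raise ValueError("target must lie in (alpha, 1)")
    ns = [r.n for r in effect_set.records]

    def med_power(r):
        z = fisher_z(r)
        return float(np.median([study_power(n, z, alpha) for n in ns])) - target

    return float(optimize.brentq(med_power, 1e-9, 0.999))


def tes(profile: PowerProfile) -> BiasReport:
    """Test of excess significance: observed vs power-expected significant counts."""
    O, E, k = profile.observed_sig, profile.expected_sig, profile.k
    if E <= 0 or E >= k:
        return BiasReport("TES", {"observed": O, "expected": E}, p=None,
                          notes="degenerate expected count; chi-square undefined")
    chi2 = (O - E) ** 2 / E + (O - E) ** 2 / (k - E)
    p = float(stats.chi2.sf(chi2, 1))
    p_binom = float(stats.binomtest(O, k, E / k, alternative="greater").pvalue)
    return BiasReport("TES", {"observed": O, "expected": E, "chi2": chi2,
                              "p_binomial": p_binom}, p=p)


def r_index(profile: PowerProfile, use_mean: bool = False) -> float:
    """Expected replicability: power minus the inflation of the success rate.

    R = power - (success_rate - power), in percent.  Median power by default
    to match the battery's median-power reporting; mean-power variant via
    ``use_mean``.
    """
    pw = float(np.mean(profile.per_study_power)) if use_mean else profile.median_power
    return 100.0 * (pw - (profile.success_rate - pw))


# ------------------------------------------------------------ Egger / Sterne

def egger_sterne(effect_set: EffectSet, alpha_flag: float = 0.10) -> BiasReport:
    """Regression of the standard normal deviate (z/SE) on precision (1/SE).

    The funnel-asymmetry test is the t-test of the intercept; p < .10 is
    conventionally taken as indicative of small-study effects.
    """
    eff = [transform_record(r, "fisher_z") for r in effect_set.records]
    if len(eff) < 3:
        raise ValueError("egger_sterne needs k >= 3")
    y = np.array([e.value for e in eff])
    se = np.sqrt([e.variance for e in eff])
    snd = y / se
    prec = 1.0 / se
    X = np.column_stack([np.ones_like(prec), prec])
    b, *_ = np.linalg.lstsq(X, snd, rcond=None)
    resid = snd - X @ b
    k = len(y)
    s2 = np.sum(resid ** 2) / (k - 2)
    cov = np.linalg.inv(X.T @ X) * s2
    t = b[0] / np.sqrt(cov[0, 0])
    p = float(2 * stats.t.sf(abs(t), k - 2))
    return BiasReport(
        "egger_sterne",
        {"intercept": float(b[0]), "slope": float(b[1]),
         "intercept_se": float(np.sqrt(cov[0, 0])), "flagged": float(p < alpha_flag)},
        p=p,
    )


# ------------------------------------------------------------- trim and fill

def trim_and_fill(
    effect_set: EffectSet,
    side: Literal["left", "right"] = "left",
    estimator: Literal["L0", "R0"] = "L0",
    model_estimator: str = "REML",
    max_iter: int = 50,
) -> BiasReport:
    """Duval–Tweedie trim-and-fill on the Fisher-z scale.

    Iteratively trims the most extreme effects on the unsuppressed side
    until the missing-study estimator stabilizes, imputes mirror images of
    the trimmed effects, and refits the random-effects model on the
    augmented set.
    """
    eff = [transform_record(r, "fisher_z") for r in effect_set.records]
    if len(eff) < 3:
        raise ValueError("trim_and_fill needs k >= 3")
    y = np.array([e.value for e in eff])
    v = np.array([e.variance for e in eff])
    if side == "right":
        y = -y
    k = len(y)
    k0 = 0
    mu = 0.0
    for it in range(max_iter):
        order = np.argsort(y)
        keep = order[: k - k0] if k0 > 0 else order
        t2 = tau2_reml(y[keep], v[keep]) if model_estimator.upper() == "REML" else tau2_dl(y[keep], v[keep])
        w = 1.0 / (v[keep] + t2)
        mu = float(np.sum(w * y[keep]) / np.sum(w))
        dev = y - mu
        ranks = stats.rankdata(np.abs(dev))
        if estimator == "L0":
            Sr = np.sum(ranks[dev > 0])
            est = (4.0 * Sr - k * (k + 1.0)) / (2.0 * k - 1.0)
        else:  # R0: rightmost run of the largest |deviation| ranks, minus one
            by_rank = np.argsort(ranks)
            gamma = 0
            for j in range(k - 1, -1, -1):
                if dev[by_rank[j]] > 0:
                    gamma += 1
                else:
                    break
            est = gamma - 1.0
        new_k0 = int(min(max(0, round(est)), k - 2))
        if new_k0 == k0:
            break
        k0 = new_k0
    else:
        raise RuntimeError("trim-and-fill did not converge within max_iter")

    if k0 > 0:
        order = np.argsort(y)
        top = order[-k0:]
        y_aug = np.concatenate([y, 2 * mu - y[top]])
        v_aug = np.concatenate([v, v[top]])
    else:
        y_aug, v_aug = y, v
    if side == "right":
        y_aug = -y_aug
    from .transforms import TransformedEffect

    aug = [TransformedEffect(float(yy), float(vv), "fisher_z", max(4, int(1 / vv + 3)))
           for yy, vv in zip(y_aug, v_aug)]
    adjusted = pool_random(aug, estimator=model_estimator)
    return BiasReport("trim_and_fill",
                      {"k0_estimator": estimator, "adjusted_r": adjusted.estimate_r},
                      adjusted=adjusted, n_imputed=k0)


# ----------------------------------------------------------- p-value methods

def _pvalue_inputs(effect_set: EffectSet):
    """t statistics and dfs of the correlation tests, zero-imputed excluded."""
    recs = [r for r in effect_set.records if not r.zero_imputed]
    r = np.array([rec.r for rec in recs])
    n = np.array([rec.n for rec in recs], float)
    t = r * np.sqrt(n - 2.0) / np.sqrt(1.0 - r ** 2)
    return recs, r, n, t, n - 2.0


def p_curve(effect_set: EffectSet, alpha: float = 0.05) -> BiasReport:
    """p-curve analysis of the significant (p < .05, positive) effects.

    Reports Stouffer right-skew tests for the full (p < .05) and half
    (p < .025) curves, binomial variants, the 33%-power flatness test, and
    the effect estimate minimizing the KS distance between the implied
    pp-values and the uniform distribution.
    """
    recs, r, n, t, df = _pvalue_inputs(effect_set)
    p2 = 2 * stats.t.sf(t, df)  # two-tailed p in the positive direction
    sig = p2 < alpha
    if sig.sum() < 2:
        raise ValueError("p_curve needs at least two significant effects")
    ts, dfs, ns = t[sig], df[sig], n[sig]
    pp_full = np.clip(p2[sig] / alpha, 1e-12, 1 - 1e-12)
    z_full = np.sum(stats.norm.ppf(pp_full)) / np.sqrt(len(pp_full))
    p_right_full = float(stats.norm.cdf(z_full))
    half = p2[sig] < alpha / 2
    out_stats = {"k_significant": int(sig.sum()), "z_full": float(z_full)}
    p_right_half = None
    if half.sum() >= 2:
        pp_half = np.clip(p2[sig][half] / (alpha / 2), 1e-12, 1 - 1e-12)
        z_half = np.sum(stats.norm.ppf(pp_half)) / np.sqrt(half.sum())
        p_right_half = float(stats.norm.cdf(z_half))
        out_stats["z_half"] = float(z_half)
    # binomial: share of significant p-values below alpha/2 vs 0.5
    p_binom = float(stats.binomtest(int(half.sum()), int(sig.sum()), 0.5,
                                    alternative="greater").pvalue)

    def pp_at(d):
        ncp = d / np.sqrt(1.0 - d ** 2) * np.sqrt(ns)
        tcrit = stats.t.ppf(1 - alpha / 2, dfs)
        num = stats.nct.sf(ts, dfs, ncp)
        den = stats.nct.sf(tcrit, dfs, ncp)
        return np.clip(num / np.clip(den, 1e-300, None), 1e-12, 1 - 1e-12)

    def ks_loss(d):
        return stats.kstest(pp_at(d), "uniform").statistic

    grid = np.linspace(-0.5, 0.9, 141)
    d0 = grid[int(np.argmin([ks_loss(d) for d in grid]))]
    res = optimize.minimize_scalar(
        ks_loss, bounds=(max(-0.5, d0 - 0.02), min(0.9, d0 + 0.02)), method="bounded"
    )
    est = float(res.x)
    # 33%-power flatness test: pp-values under the effect giving each study 1/3 power
    def ncp_for_power(nn, dd, power=1.0 / 3.0):
        tcrit = stats.t.ppf(1 - alpha / 2, dd)
        f = lambda ncp: stats.nct.sf(tcrit, dd, ncp) - power
        return optimize.brentq(f, 0.0, 40.0)

    ncp33 = np.array([ncp_for_power(nn, dd) for nn, dd in zip(ns, dfs)])
    tcrit = stats.t.ppf(1 - alpha / 2, dfs)
    num = stats.nct.sf(ts, dfs, ncp33)
    den = stats.nct.sf(tcrit, dfs, ncp33)
    pp33 = np.clip(num / np.clip(den, 1e-300, None), 1e-12, 1 - 1e-12)
    # flatter than 33% power => evidence of inadequate evidential value
    z33 = np.sum(stats.norm.ppf(1 - pp33)) / np.sqrt(len(pp33))
    p33 = float(stats.norm.cdf(z33))
    out_stats.update({"estimate_r": est, "p_binomial_right": p_binom, "p_power33": p33})
    if p_right_half is not None:
        out_stats["p_right_half"] = p_right_half
    return BiasReport("p_curve", out_stats, p=p_right_full)


def _puniform_logq(y, se, mu, zc):
    """log conditional exceedance probabilities q_i(mu) on the Fisher scale."""
    return stats.norm.logsf((y - mu) / se) - stats.norm.logsf((zc * se - mu) / se)


def p_uniform(effect_set: EffectSet, alpha: float = 0.05,
              method: Literal["P", "LNP"] = "P") -> BiasReport:
    """p-uniform effect estimate from the significant effects.

    Finds the effect at which the conditional p-values are uniform.  Method
    ``P`` (default) equates the sum of conditional exceedance probabilities
    to k/2 (Irwin–Hall); ``LNP`` equates -sum(log q) to k.  Also reports the
    publication-bias test comparing the conditional p distribution at the
    fixed-effect estimate against uniformity, and a profile CI.
    """
    recs, r, n, t, df = _pvalue_inputs(effect_set)
    p2 = 2 * stats.t.sf(t, df)
    sig = p2 < alpha
    if sig.sum() < 2:
        raise ValueError("p_uniform needs at least two significant effects")
    y = np.arctanh(r[sig])
    se = np.sqrt(1.0 / (n[sig] - 3.0))
    zc = stats.norm.ppf(1 - alpha / 2)
    k = len(y)

    if method == "P":
        f = lambda mu: float(np.sum(np.exp(_puniform_logq(y, se, mu, zc))) - k / 2.0)
        center, spread = k / 2.0, np.sqrt(k / 12.0)
    else:
        f = lambda mu: float(-np.sum(_puniform_logq(y, se, mu, zc)) - k)
        center, spread = float(k), np.sqrt(k)
    try:
        est = optimize.brentq(f, -2.0, 3.0)
    except ValueError:
        return BiasReport("p_uniform", {"k_significant": k},
                          notes="estimator not identified on the search interval")

    # profile CI: values of mu at which the statistic hits center +/- 1.96 spread
    def stat(mu):
        if method == "P":
            return float(np.sum(np.exp(_puniform_logq(y, se, mu, zc))))
        return float(-np.sum(_puniform_logq(y, se, mu, zc)))

    zq = stats.norm.ppf(0.975)
    ci = [np.nan, np.nan]
    try:
        # the statistic is monotone increasing in mu for P
        ci[0] = optimize.brentq(lambda m: stat(m) - (center - zq * spread), -2.0, est)
        ci[1] = optimize.brentq(lambda m: stat(m) - (center + zq * spread), est, 3.0)
    except ValueError:
        pass
    # bias test: conditional p's evaluated at the fixed-effect estimate
    w = (n - 3.0)
    mu_fe = float(np.sum(w * np.arctanh(r)) / np.sum(w))
    s_fe = stat(mu_fe)
    z_bias = (s_fe - center) / spread if method == "P" else (s_fe - center) / spread
    p_bias = float(stats.norm.sf(z_bias)) if method == "P" else float(stats.norm.sf(-z_bias))
    return BiasReport(
        "p_uniform",
        {"estimate_z": float(est), "estimate_r": float(back_transform(est)),
         "ci_low_r": float(back_transform(ci[0])), "ci_high_r": float(back_transform(ci[1])),
         "k_significant": k, "method": 0.0 if method == "P" else 1.0},
        p=p_bias,
    )


def p_uniform_star(effect_set: EffectSet, alpha: float = 0.05) -> BiasReport:
    """p-uniform*: ML over significant and non-significant effects.

    Assumes equal publication probability within (but not across) the
    significant and non-significant groups; the likelihood of each effect is
    its density conditional on falling in its own significance region, with
    between-study variance tau^2 estimated jointly with the effect.
    """
    recs, r, n, t, df = _pvalue_inputs(effect_set)
    if len(recs) < 2:
        raise ValueError("p_uniform_star needs at least two effects")
    y = np.arctanh(r)
    v = 1.0 / (n - 3.0)
    zc = stats.norm.ppf(1 - alpha / 2)
    ycrit = zc * np.sqrt(v)
    sig = y > ycrit

    def nll(params):
        mu, log_t2 = params
        t2 = np.exp(log_t2)
        sd = np.sqrt(v + t2)
        logf = stats.norm.logpdf(y, mu, sd)
        logden = np.where(
            sig,
            stats.norm.logsf(ycrit, mu, sd),
            stats.norm.logcdf(ycrit, mu, sd),
        )
        return -np.sum(logf - logden)

    best = None
    for t2_0 in (1e-4, 0.01, 0.05):
        res = optimize.minimize(nll, x0=[np.mean(y), np.log(t2_0)], method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    mu, t2 = best.x[0], float(np.exp(best.x[1]))
    # Wald CI from the numerical Hessian in mu
    h = 1e-4
    d2 = (nll([mu + h, best.x[1]]) - 2 * best.fun + nll([mu - h, best.x[1]])) / h ** 2
    se = 1.0 / np.sqrt(d2) if d2 > 0 else np.nan
    return BiasReport(
        "p_uniform_star",
        {"estimate_z": float(mu), "estimate_r": float(back_transform(mu)),
         "tau2": t2,
         "ci_low_r": float(back_transform(mu - 1.96 * se)),
         "ci_high_r": float(back_transform(mu + 1.96 * se)),
         "k": len(y), "k_significant": int(sig.sum())},
        notes="" if np.isfinite(se) else "flat likelihood; CI not identified",
    )


# ---------------------------------------------------------- selection models

#: Vevea–Woods a-priori step weight functions on one-tailed p-values.
SELECTION_CUTPOINTS = np.array(
    [0.005, 0.010, 0.050, 0.100, 0.250, 0.350, 0.500,
     0.650, 0.750, 0.900, 0.950, 0.990, 0.995, 1.000]
)
SELECTION_PRESETS: dict[str, np.ndarray] = {
    "moderate_one_tailed": np.array(
        [1.00, 0.99, 0.95, 0.80, 0.75, 0.65, 0.60, 0.55, 0.50, 0.50, 0.50, 0.50, 0.50, 0.50]),
    "severe_one_tailed": np.array(
        [1.00, 0.99, 0.90, 0.75, 0.60, 0.50, 0.40, 0.35, 0.30, 0.25, 0.10, 0.10, 0.10, 0.10]),
    "moderate_two_tailed": np.array(
        [1.00, 0.99, 0.95, 0.90, 0.80, 0.75, 0.60, 0.60, 0.75, 0.80, 0.90, 0.95, 0.99, 1.00]),
    "severe_two_tailed": np.array(
        [1.00, 0.99, 0.90, 0.75, 0.60, 0.50, 0.25, 0.25, 0.50, 0.60, 0.75, 0.90, 0.99, 1.00]),
}


def selection_model(
    effect_set: EffectSet,
    weight_scheme: str | np.ndarray = "moderate_one_tailed",
    cutpoints: Optional[np.ndarray] = None,
) -> BiasReport:
    """Weighted ML estimate of (mu, tau^2) under a-priori step weights.

    The weight function acts on the one-tailed p-value of each effect; the
    likelihood of each observation is w(p_i) f(y_i) normalized by the
    weighted total probability, computed analytically from the normal CDF at
    the p-cutpoint thresholds.  With all weights equal to one the estimate
    reduces to the ML random-effects fit.
    """
    if isinstance(weight_scheme, str):
        try:
            weights = SELECTION_PRESETS[weight_scheme]
        except KeyError:
            raise ValueError(f"unknown weight scheme: {weight_scheme!r}") from None
    else:
        weights = np.asarray(weight_scheme, float)
    cut = SELECTION_CUTPOINTS if cutpoints is None else np.asarray(cutpoints, float)
    if len(weights) != len(cut):
        raise ValueError("weights and cutpoints must have equal length")
    eff = [transform_record(r, "fisher_z") for r in effect_set.records]
    if len(eff) < 10:
        raise ValueError("selection_model needs k >= 10 for stability")
    y = np.array([e.value for e in eff])
    v = np.array([e.variance for e in eff])
    se = np.sqrt(v)
    # one-tailed p (positive direction): p = P(Z > y/se)
    p1 = stats.norm.sf(y / se)
    idx = np.searchsorted(cut, p1, side="left")
    idx = np.clip(idx, 0, len(weights) - 1)
    occupancy = np.bincount(idx, minlength=len(weights))
    w_obs = weights[idx]
    if not np.all(weights == weights[0]) and np.sum(occupancy[weights < 1]) == 0:
        raise ValueError("no effects fall in down-weighted p intervals; model degenerate")
    # y thresholds per study for each cutpoint: p1 <= c  <=>  y >= se * z_{1-c}
    zq = stats.norm.isf(cut[:-1])  # interval bounds excluding the final p = 1

    def nll(params):
        mu, log_t2 = params
        t2 = np.exp(log_t2)
        sd = np.sqrt(v + t2)
        logf = stats.norm.logpdf(y, mu, sd) + np.log(w_obs)
        # normalizer: sum_m w_m P(p in interval m) per study
        upper = np.concatenate([[np.inf], zq])  # y-space upper bounds per interval
        lower = np.concatenate([zq, [-np.inf]])
        A = np.zeros(len(y))
        for mth in range(len(weights)):
            hi = upper[mth] * se if np.isfinite(upper[mth]) else np.inf
            lo = lower[mth] * se if np.isfinite(lower[mth]) else -np.inf
            probs = stats.norm.cdf((hi - mu) / sd) - stats.norm.cdf((lo - mu) / sd)
            A += weights[mth] * probs
        return -np.sum(logf - np.log(np.clip(A, 1e-300, None)))

    res = optimize.minimize(nll, x0=[np.average(y, weights=1 / v), np.log(0.01)],
                            method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
    mu, t2 = res.x[0], float(np.exp(res.x[1]))
    return BiasReport(
        "selection_model",
        {"estimate_z": float(mu), "estimate_r": float(back_transform(mu)),
         "tau2": t2,
         "scheme": float(np.sum(weights < 1))},
        notes=str(weight_scheme),
    )


# ------------------------------------------------------------- Henmi & Copas

def henmi_copas(effect_set: EffectSet) -> BiasReport:
    """Hybrid estimate: fixed-effect weights, random-effects heterogeneity.

    Point estimate uses weights 1/v_i; its variance is
    sum(w^2 (v + tau2_DL)) / (sum w)^2.  The CI uses the normal quantile
    (documented fallback for the method's adjusted quantile) and is reported
    next to the conventional DerSimonian–Laird interval.
    """
    eff = [transform_record(r, "fisher_z") for r in effect_set.records]
    if len(eff) < 2:
        raise ValueError("henmi_copas needs k >= 2")
    y = np.array([e.value for e in eff])
    v = np.array([e.variance for e in eff])
    t2 = tau2_dl(y, v)
    w = 1.0 / v
    mu_fe = float(np.sum(w * y) / np.sum(w))
    var_h = float(np.sum(w ** 2 * (v + t2)) / np.sum(w) ** 2)
    wr = 1.0 / (v + t2)
    mu_dl = float(np.sum(wr * y) / np.sum(wr))
    se_dl = float(np.sqrt(1.0 / np.sum(wr)))
    z = stats.norm.ppf(0.975)
    return BiasReport(
        "henmi_copas",
        {
            "estimate_r": float(back_transform(mu_fe)),
            "ci_low_r": float(back_transform(mu_fe - z * np.sqrt(var_h))),
            "ci_high_r": float(back_transform(mu_fe + z * np.sqrt(var_h))),
            "dl_estimate_r": float(back_transform(mu_dl)),
            "dl_ci_low_r": float(back_transform(mu_dl - z * se_dl)),
            "dl_ci_high_r": float(back_transform(mu_dl + z * se_dl)),
            "tau2": float(t2),
        },
    )


# ------------------------------------------------------- cumulative analyses

def cumulative_meta(
    effect_set: EffectSet,
    order_by: Literal["year", "n"] = "year",
    estimator: str = "REML",
) -> list[PooledResult]:
    """Cumulative meta-analysis by year (ascending) or sample size (descending).

    The i-th entry pools the first i effects of the ordering; the final entry
    equals the full pooled result.
    """
    recs = list(effect_set.records)
    if order_by == "year":
        recs.sort(key=lambda rec: rec.year)
    elif order_by == "n":
        recs.sort(key=lambda rec: -rec.n)
    else:
        raise ValueError("order_by must be 'year' or 'n'")
    eff = [transform_record(r, "fisher_z") for r in recs]
    return [pool_random(eff[: i + 1], estimator=estimator) for i in range(1, len(eff))]
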