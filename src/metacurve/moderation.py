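"""Mixed-effects subgroup analyses and precision-weighted meta-regressions.

Subgroup analyses fit a separate random-effects model per factor level (each
with its own tau^2) and test the Wald-type Q_between statistic against a
chi-square with levels-1 df.  Meta-regressions are weighted mixed-effects
regressions on the Fisher-z scale with residual tau^2 by REML and
Knapp–Hartung-type adjusted standard errors; hierarchical block models are
compared with likelihood-ratio tests on ML (not REML) refits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .pooling import PooledResult, pool_random, tau2_reml
from .records import EffectSet
from .transforms import transform_record


@dataclass
class SubgroupResult:
    per_group: dict[str, PooledResult]
    Q_between: float
    df: int
    p: float
    dropped_levels: list[str] = field(default_factory=list)


@dataclass
class RegressionResult:
    b: dict[str, float]
    se: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    p: dict[str, float]
    R2: float
    tau2_residual: float
    loglik_ml: float
    k: int
    vif: dict[str, float]


def _effects_arrays(effect_set: EffectSet):
    eff = [transform_record(r, "fisher_z") for r in effect_set.records]
    y = np.array([e.value for e in eff])
    v = np.array([e.variance for e in eff])
    return eff, y, v


def subgroup_analysis(
    effect_set: EffectSet,
    factor: str,
    estimator: str = "REML",
    kh: bool = True,
) -> SubgroupResult:
    """Mixed-effects subgroup comparison for one categorical moderator.

    Levels with fewer than two effects are dropped with a warning and the
    between-groups df reduced accordingly.
    """
    groups: dict[str, list] = {}
    for rec in effect_set.records:
        val = getattr(rec, factor)
        if val is None:
            continue
        groups.setdefault(str(val), []).append(rec)
    dropped = [lv for lv, recs in groups.items() if len(recs) < 2]
    for lv in dropped:
        warnings.warn(f"subgroup level {lv!r} has k < 2 and was dropped")
        del groups[lv]
    if len(groups) < 2:
        raise ValueError("subgroup analysis needs at least two non-empty levels")
    per_group = {}
    mus, ses = [], []
    for lv, recs in groups.items():
        eff = [transform_record(r, "fisher_z") for r in recs]
        fit = pool_random(eff, estimator=estimator, kh=kh)
        per_group[lv] = fit
        mus.append(fit.estimate_working)
        ses.append(fit.se)
    mus = np.array(mus)
    wl = 1.0 / np.maximum(np.array(ses), 1e-10) ** 2
    mbar = np.sum(wl * mus) / np.sum(wl)
    Qb = float(np.sum(wl * (mus - mbar) ** 2))
    df = len(groups) - 1
    p = float(stats.chi2.sf(Qb, df))
    return SubgroupResult(per_group, Qb, df, p, dropped)


def _ml_loglik(y, v, X, beta, t2):
    w = 1.0 / (v + t2)
    e = y - X @ beta
    return float(-0.5 * np.sum(np.log(2 * np.pi * (v + t2))) - 0.5 * np.sum(w * e ** 2))


def _fit_wls(y, v, X, t2):
    w = 1.0 / (v + t2)
    M = np.linalg.inv(X.T @ (w[:, None] * X))
    beta = M @ (X.T @ (w * y))
    return beta, M


def _ml_tau2(y, v, X):
    def nll(log_t2):
        t2 = np.exp(log_t2)
        beta, _ = _fit_wls(y, v, X, t2)
        return -_ml_loglik(y, v, X, beta, t2)

    res = optimize.minimize_scalar(nll, bounds=(-30, 3), method="bounded")
    t2 = float(np.exp(res.x))
    # compare against the boundary tau2 = 0
    beta0, _ = _fit_wls(y, v, X, 0.0)
    if _ml_loglik(y, v, X, beta0, 0.0) >= -res.fun:
        return 0.0
    return t2


def vif(X: np.ndarray, names: Sequence[str]) -> dict[str, float]:
    """Variance inflation factors of the (unweighted) moderator columns."""
    X = np.asarray(X, float)
    out = {}
    for j, name in enumerate(names):
        others = np.column_stack([np.ones(len(X))] + [X[:, i] for i in range(X.shape[1]) if i != j])
        xj = X[:, j]
        bhat, *_ = np.linalg.lstsq(others, xj, rcond=None)
        resid = xj - others @ bhat
        sst = np.sum((xj - xj.mean()) ** 2)
        r2 = 1.0 - np.sum(resid ** 2) / sst if sst > 0 else 0.0
        out[name] = float(1.0 / (1.0 - r2)) if r2 < 1 else np.inf
    return out


def meta_regression(
    effect_set: EffectSet,
    moderators: Sequence[str] | np.ndarray,
    kh: bool = True,
    names: Optional[list[str]] = None,
) -> RegressionResult:
    """Precision-weighted mixed-effects meta-regression on Fisher-z effects.

    ``moderators`` may be field names of the effect records (numeric or
    boolean; records with missing values drop out, complete-case) or an
    explicit design matrix.  Weights are 1/(v_i + tau^2_res) with tau^2_res
    by REML; with ``kh=True`` standard errors carry the Knapp–Hartung-type
    scaling and t-tests use k - p df.
    """
    recs = effect_set.records
    if isinstance(moderators, (list, tuple)) and all(isinstance(s, str) for s in moderators):
        cols, keep = [], []
        for i, rec in enumerate(recs):
            vals = [getattr(rec, mname) for mname in moderators]
            if any(val is None for val in vals):
                continue
            keep.append(i)
            cols.append([float(val) for val in vals])
        X_raw = np.array(cols, dtype=float)
        names = list(moderators)
        recs = [recs[i] for i in keep]
    else:
        X_raw = np.atleast_2d(np.asarray(moderators, float))
        if X_raw.shape[0] != len(recs):
            X_raw = X_raw.T
        names = names or [f"x{i}" for i in range(X_raw.shape[1])]
    k = len(recs)
    if k <= X_raw.shape[1] + 1:
        raise ValueError("meta-regression needs k > number of coefficients + 1")
    eff = [transform_record(r, "fisher_z") for r in recs]
    y = np.array([e.value for e in eff])
    v = np.array([e.variance for e in eff])
    X = np.column_stack([np.ones(k), X_raw])
    all_names = ["intercept"] + list(names)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        u, s, vt = np.linalg.svd(X)
        bad = [all_names[i] for i in np.where(np.abs(vt[-1]) > 0.5)[0]]
        raise ValueError(f"rank-deficient design; offending columns: {bad}")
    p = X.shape[1]

    t2 = tau2_reml(y, v, X)
    beta, M = _fit_wls(y, v, X, t2)
    w = 1.0 / (v + t2)
    e = y - X @ beta
    if kh:
        s2 = float(np.sum(w * e ** 2) / (k - p))
        covb = M * s2
        dfres = k - p
        crit = stats.t.ppf(0.975, dfres)
        se = np.sqrt(np.diag(covb))
        pv = 2 * stats.t.sf(np.abs(beta / se), dfres)
    else:
        covb = M
        se = np.sqrt(np.diag(covb))
        crit = stats.norm.ppf(0.975)
        pv = 2 * stats.norm.sf(np.abs(beta / se))

    t2_null = tau2_reml(y, v)
    R2 = max(0.0, min(1.0, (t2_null - t2) / t2_null)) * 100.0 if t2_null > 0 else 0.0
    t2_ml = _ml_tau2(y, v, X)
    beta_ml, _ = _fit_wls(y, v, X, t2_ml)
    ll = _ml_loglik(y, v, X, beta_ml, t2_ml)
    if X_raw.shape[1] > 1:
        vifs = vif(X_raw, names)
    elif X_raw.shape[1] == 1:
        vifs = {names[0]: 1.0}
    else:
        vifs = {}

    return RegressionResult(
        b=dict(zip(all_names, map(float, beta))),
        se=dict(zip(all_names, map(float, se))),
        ci_low=dict(zip(all_names, map(float, beta - crit * se))),
        ci_high=dict(zip(all_names, map(float, beta + crit * se))),
        p=dict(zip(all_names, map(float, pv))),
        R2=float(R2),
        tau2_residual=float(t2),
        loglik_ml=ll,
        k=k,
        vif=vifs,
    )


@dataclass
class BlockComparison:
    block: int
    compared_to: int
    chi2: float
    df: int
    p: float


def hierarchical_blocks(
    effect_set: EffectSet,
    blocks: Sequence[Sequence[str]],
    kh: bool = True,
) -> tuple[list[RegressionResult], list[BlockComparison]]:
    """Hierarchical (nested) multiple meta-regressions with LRT comparison.

    ``blocks`` is an ordered list of moderator-name groups; block m fits the
    union of groups 1..m on the shared complete-case rows.  Likelihood-ratio
    tests use ML refits (REML log-likelihoods are not comparable across fixed
    effects).  When a block is not a significant improvement (p >= .05), the
    next block is compared against the last block that was.
    """
    all_mods: list[str] = []
    cum: list[list[str]] = []
    for g in blocks:
        all_mods.extend(g)
        cum.append(list(all_mods))
    # complete cases across the union of moderators
    keep = [
        r for r in effect_set.records
        if all(getattr(r, mname) is not None for mname in all_mods)
    ]
    shared = EffectSet(keep, domain=effect_set.domain, independence=effect_set.independence)

    fits = [meta_regression(shared, mods, kh=kh) for mods in cum]
    comparisons: list[BlockComparison] = []
    ref = 0  # index of the reference block for the next LRT
    for m in range(1, len(cum)):
        added = len(cum[m]) - len(cum[ref])
        chi2 = max(0.0, 2.0 * (fits[m].loglik_ml - fits[ref].loglik_ml))
        p = float(stats.chi2.sf(chi2, added))
        comparisons.append(BlockComparison(m + 1, ref + 1, chi2, added, p))
        if p < 0.05:
            ref = m
    return fits, comparisons
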