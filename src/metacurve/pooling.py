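"""Random-effects, Hunter–Schmidt and unweighted effect synthesis.

The Hedges–Olkin random-effects model pools Fisher-z (or r-scale) effects
with inverse-variance weights 1/(v_i + tau^2); tau^2 comes from either the
DerSimonian–Laird moment estimator or restricted maximum likelihood, and
confidence intervals use the Knapp–Hartung adjustment (t distribution with
k-1 df and a weighted residual variance estimator) by default.  The
Hunter–Schmidt estimator pools raw correlations with n-weights and
decomposes the observed variance into sampling error and true variation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import stats

from .transforms import (
    RangeRestrictionParams,
    TransformedEffect,
    back_transform,
    case2_correct,
    corrected_se,
)

Method = Literal["HO_REML", "HO_DL", "HS", "unweighted", "RVE"]


@dataclass
class PooledResult:
    """A summary estimate with heterogeneity and inference fields."""

    estimate_working: float
    estimate_r: float
    se: float
    ci_low: float
    ci_high: float
    tau2: float
    Q: float
    Q_df: int
    I2: float
    k: int
    total_n: int
    method: Method
    kh_adjusted: bool
    scale: str = "fisher_z"
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def _as_arrays(effects: Sequence[TransformedEffect]):
    scales = {e.scale for e in effects}
    if len(scales) > 1:
        raise ValueError(f"cannot pool mixed scales: {sorted(scales)}")
    y = np.array([e.value for e in effects], dtype=float)
    v = np.array([e.variance for e in effects], dtype=float)
    n = np.array([e.n for e in effects], dtype=int)
    return y, v, n, scales.pop()


def cochran_q(y: np.ndarray, v: np.ndarray) -> float:
    w = 1.0 / v
    mu = np.sum(w * y) / np.sum(w)
    return float(np.sum(w * (y - mu) ** 2))


def tau2_dl(y: np.ndarray, v: np.ndarray) -> float:
    """DerSimonian–Laird moment estimator, truncated at zero."""
    k = len(y)
    if k < 2:
        raise ValueError("tau2 estimation needs k >= 2")
    w = 1.0 / v
    q = cochran_q(y, v)
    c = np.sum(w) - np.sum(w ** 2) / np.sum(w)
    return max(0.0, (q - (k - 1)) / c)


def tau2_reml(
    y: np.ndarray,
    v: np.ndarray,
    X: Optional[np.ndarray] = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> float:
    """Restricted maximum-likelihood tau^2 by Fisher scoring.

    Supports a fixed design matrix ``X`` (intercept-only when omitted), in
    which case the residual heterogeneity of the mixed-effects model is
    estimated.  Raises on non-convergence, naming the last iterate.
    """
    k = len(y)
    if k < 2:
        raise ValueError("tau2 estimation needs k >= 2")
    if X is None:
        X = np.ones((k, 1))
    p = X.shape[1]
    if np.allclose(y - X @ np.linalg.lstsq(X, y, rcond=None)[0], 0):
        return 0.0
    t2 = max(tau2_dl(y, v) if p == 1 else 0.01, 1e-4)
    for _ in range(max_iter):
        w = 1.0 / (v + t2)
        XtW = X.T * w
        M = np.linalg.inv(XtW @ X)
        beta = M @ (XtW @ y)
        e = y - X @ beta
        # P = W - W X (X'WX)^-1 X'W applied implicitly
        Pe = w * e
        PX = (w[:, None] * X) @ M
        # score and expected information of the restricted likelihood
        WX = w[:, None] * X
        diagP = w - np.einsum("ij,ij->i", PX, WX)
        score = -0.5 * np.sum(diagP) + 0.5 * np.sum(Pe ** 2)
        P = np.diag(w) - WX @ M @ WX.T
        info = 0.5 * np.trace(P @ P)
        if info <= 0:
            break
        step = score / info
        new = t2 + step
        if new < 0:
            new = t2 / 2 if t2 > 1e-12 else 0.0
        if abs(new - t2) < tol * (1 + t2):
            return max(0.0, new)
        t2 = new
    else:
        # Fisher scoring can oscillate near a flat optimum; fall back to a
        # direct bounded search of the restricted likelihood
        from scipy import optimize

        def nll(t2v):
            w = 1.0 / (v + t2v)
            XtWX = X.T @ (X * w[:, None])
            beta = np.linalg.solve(XtWX, X.T @ (w * y))
            e = y - X @ beta
            return 0.5 * (
                np.sum(np.log(v + t2v))
                + np.linalg.slogdet(XtWX)[1]
                + np.sum(w * e * e)
            )

        res = optimize.minimize_scalar(
            nll, bounds=(0.0, max(10.0, 10 * t2)), method="bounded",
            options={"xatol": 1e-12},
        )
        if not res.success:
            raise RuntimeError(
                f"REML tau^2 did not converge; last iterate tau2={t2:.6g}"
            )
        t2 = float(res.x)
        if nll(0.0) <= nll(t2):
            t2 = 0.0
    return max(0.0, t2)


def tau2_estimate(effects: Sequence[TransformedEffect], estimator: str = "REML") -> float:
    y, v, _, _ = _as_arrays(effects)
    if estimator.upper() == "DL":
        return tau2_dl(y, v)
    if estimator.upper() == "REML":
        return tau2_reml(y, v)
    raise ValueError(f"unknown tau2 estimator: {estimator!r}")


def _heterogeneity(y: np.ndarray, v: np.ndarray) -> tuple[float, int, float]:
    q = cochran_q(y, v)
    df = len(y) - 1
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    return q, df, i2


def pool_random(
    effects: Sequence[TransformedEffect],
    estimator: str = "REML",
    kh: bool = True,
    level: float = 0.95,
) -> PooledResult:
    """Hedges–Olkin random-effects synthesis with Knapp–Hartung inference.

    When the common scale is Fisher z, the estimate and CI bounds are
    back-transformed to the r metric for reporting.
    """
    y, v, n, scale = _as_arrays(effects)
    k = len(y)
    if k < 2:
        raise ValueError("pool_random needs k >= 2")
    if np.ptp(y) == 0 and np.ptp(v) == 0:
        # degenerate constant set: point estimate with a collapsed CI
        mu = float(y[0])
        q, df, i2 = 0.0, k - 1, 0.0
        est_r = back_transform(mu) if scale == "fisher_z" else mu
        return PooledResult(mu, est_r, 0.0, est_r, est_r, 0.0, q, df, i2, k,
                            int(n.sum()), "HO_REML" if estimator.upper() == "REML" else "HO_DL",
                            kh, scale)
    t2 = tau2_dl(y, v) if estimator.upper() == "DL" else tau2_reml(y, v)
    w = 1.0 / (v + t2)
    sw = np.sum(w)
    mu = float(np.sum(w * y) / sw)
    if kh:
        se2 = float(np.sum(w * (y - mu) ** 2) / ((k - 1) * sw))
        crit = stats.t.ppf(0.5 + level / 2, k - 1)
    else:
        se2 = float(1.0 / sw)
        crit = stats.norm.ppf(0.5 + level / 2)
    se = np.sqrt(se2)
    lo, hi = mu - crit * se, mu + crit * se
    q, df, i2 = _heterogeneity(y, v)
    if scale == "fisher_z":
        est_r, lo_r, hi_r = back_transform(mu), back_transform(lo), back_transform(hi)
    else:
        est_r, lo_r, hi_r = mu, lo, hi
    return PooledResult(mu, float(est_r), float(se), float(lo_r), float(hi_r),
                        float(t2), q, df, i2, k, int(n.sum()),
                        "HO_REML" if estimator.upper() == "REML" else "HO_DL", kh, scale)


def pool_hs(
    records,
    corrected: bool = False,
    params: Optional[dict] = None,
    level: float = 0.95,
) -> PooledResult:
    """Hunter–Schmidt n-weighted synthesis of raw correlations.

    ``records`` are effect records (with .r and .n).  In corrected mode each
    correlation is first corrected for direct range restriction (Case II)
    using per-record u ratios supplied in ``params`` (a mapping from the
    record's sample key or index to :class:`RangeRestrictionParams`); records
    with no parameters drop out, mirroring the reduced k of corrected
    analyses when primary studies fail to report score SDs.
    """
    recs = list(records)
    rs, ns = [], []
    if corrected:
        if not params:
            raise ValueError("corrected HS pooling needs range-restriction parameters")
        for i, rec in enumerate(recs):
            key = getattr(rec, "sample_key", lambda: i)()
            p = params.get(key, params.get(i))
            if p is None:
                continue
            rs.append(case2_correct(rec.r, p))
            ns.append(rec.n)
        if len(rs) < 2:
            raise ValueError("fewer than two records carry range-restriction parameters")
    else:
        rs = [rec.r for rec in recs]
        ns = [rec.n for rec in recs]
    r = np.asarray(rs, float)
    n = np.asarray(ns, float)
    k = len(r)
    if k < 2:
        raise ValueError("pool_hs needs k >= 2")
    rbar = float(np.sum(n * r) / np.sum(n))
    var_obs = float(np.sum(n * (r - rbar) ** 2) / np.sum(n))
    var_err = float(k * (1.0 - rbar ** 2) ** 2 / np.sum(n))
    var_res = max(0.0, var_obs - var_err)
    se = float(np.sqrt(var_obs / k))
    z = stats.norm.ppf(0.5 + level / 2)
    yv = np.arctanh(np.clip(r, -0.999999, 0.999999))
    vv = 1.0 / (n - 3.0)
    q, df, i2 = _heterogeneity(yv, vv)
    return PooledResult(rbar, rbar, se, rbar - z * se, rbar + z * se, var_res,
                        q, df, i2, k, int(n.sum()), "HS", False, "raw_r",
                        extra={"var_observed": var_obs, "var_sampling": var_err})


def pool_unweighted(effects: Sequence[TransformedEffect], level: float = 0.95) -> PooledResult:
    """Arithmetic-mean synthesis; CI from t(k-1) on the sample SD."""
    y, v, n, scale = _as_arrays(effects)
    k = len(y)
    if k < 2:
        raise ValueError("pool_unweighted needs k >= 2")
    mu = float(np.mean(y))
    sd = float(np.std(y, ddof=1))
    if sd <= 1e-13 * max(1.0, abs(mu)):
        sd = 0.0
    se = sd / np.sqrt(k)
    crit = stats.t.ppf(0.5 + level / 2, k - 1) if se > 0 else 0.0
    lo, hi = mu - crit * se, mu + crit * se
    q, df, i2 = _heterogeneity(y, v)
    if scale == "fisher_z":
        est_r, lo_r, hi_r = back_transform(mu), back_transform(lo), back_transform(hi)
    else:
        est_r, lo_r, hi_r = mu, lo, hi
    return PooledResult(mu, float(est_r), se, float(lo_r), float(hi_r), 0.0,
                        q, df, i2, k, int(n.sum()), "unweighted", False, scale)


def leave_one_out(effects: Sequence[TransformedEffect], estimator: str = "REML") -> list[PooledResult]:
    """Pooled results omitting each effect in turn (input order preserved)."""
    effects = list(effects)
    if len(effects) < 3:
        raise ValueError("leave_one_out needs k >= 3")
    return [
        pool_random(effects[:i] + effects[i + 1:], estimator=estimator)
        for i in range(len(effects))
    ]


def influence_diagnostics(effects: Sequence[TransformedEffect], estimator: str = "REML"):
    """Outlier / leverage diagnostics for the random-effects model.

    Returns one row per study with the studentized deleted residual, Cook's
    distance, hat value, DFFITS, and covariance ratio, following the
    case-deletion approach for random-effects models.  A study is flagged
    when its |studentized residual| exceeds 1.96 AND at least one leverage
    criterion exceeds its conventional cutoff (hat > 2 * mean hat,
    |DFFITS| > 3 * sqrt(1/(k-1)), Cook's D > 0.45, or covariance ratio < 1
    jointly with the residual criterion).
    """
    effects = list(effects)
    y, v, n, _ = _as_arrays(effects)
    k = len(y)
    if k < 3:
        raise ValueError("influence_diagnostics needs k >= 3")
    full = pool_random(effects, estimator=estimator, kh=False)
    mu, t2 = full.estimate_working, full.tau2
    w = 1.0 / (v + t2)
    hat = w / np.sum(w)
    var_mu = 1.0 / np.sum(w)
    rows = []
    for i in range(k):
        rest = effects[:i] + effects[i + 1:]
        fit_i = pool_random(rest, estimator=estimator, kh=False)
        mu_i, t2_i = fit_i.estimate_working, fit_i.tau2
        var_mu_i = fit_i.se ** 2
        rstud = (y[i] - mu_i) / np.sqrt(v[i] + t2_i + var_mu_i)
        dffits = (mu - mu_i) / np.sqrt(var_mu_i) if var_mu_i > 0 else 0.0
        cook = (mu - mu_i) ** 2 / var_mu if var_mu > 0 else 0.0
        covr = var_mu_i / var_mu if var_mu > 0 else 1.0
        flag = abs(rstud) > 1.96 and (
            hat[i] > 2.0 / k
            or abs(dffits) > 3.0 * np.sqrt(1.0 / (k - 1))
            or cook > 0.45
        )
        rows.append(
            {
                "rstudent": float(rstud),
                "dffits": float(dffits),
                "cook_d": float(cook),
                "hat": float(hat[i]),
                "cov_ratio": float(covr),
                "flagged": bool(flag),
            }
        )
    return rows
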