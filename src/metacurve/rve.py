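"""Robust variance estimation for dependent effect sizes.

Implements the correlated-effects working model: multiple effects from the
same independent sample are assumed equicorrelated (working correlation
rho, default 0.8), weights are 1/(k_j (vbar_j + tau^2 + omega^2)), and
inference uses a cluster-robust sandwich with small-sample adjustment and
Satterthwaite-style degrees of freedom.  The pooled estimate is known to be
nearly insensitive to rho; the robust variance is valid whatever the true
dependence structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .transforms import back_transform


@dataclass
class RVEResult:
    coefficients: dict[str, float]
    robust_se: dict[str, float]
    df: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    p: dict[str, float]
    tau2: float
    omega2: float
    I2: float
    k_effects: int
    k_clusters: int
    rho: float
    unreliable: list[str] = field(default_factory=list)  # coefficients with df < 4

    def estimate_r(self, name: str = "intercept") -> float:
        return float(back_transform(self.coefficients[name]))


def _cluster_index(cluster):
    labels = []
    seen: dict = {}
    for c in cluster:
        if c not in seen:
            seen[c] = len(seen)
        labels.append(seen[c])
    return np.asarray(labels), len(seen)


def _ce_tau2_mom(y, v, cid, m, X, rho):
    """Method-of-moments tau^2 for the correlated-effects model.

    Preliminary weights 1/(k_j vbar_j); tau^2 solves
    E[Q_E] = tr(P V_rho) + tau^2 tr(P B) where B is the within-cluster
    block-of-ones matrix and P the weighted residual projector.
    """
    kj = np.bincount(cid, minlength=m).astype(float)
    vbar = np.bincount(cid, weights=v, minlength=m) / kj
    w = 1.0 / (kj[cid] * vbar[cid])
    WX = w[:, None] * X
    M = np.linalg.inv(X.T @ WX)
    beta = M @ (WX.T @ y)
    e = y - X @ beta
    QE = float(np.sum(w * e ** 2))
    # traces computed blockwise
    P_diag_term = 0.0
    trPV = 0.0
    trPB = 0.0
    # P = W - WX M (WX)'; tr(P A) = sum w_i A_ii - tr(M (WX)' A WX)
    sv = np.sqrt(v)
    for j in range(m):
        idx = np.where(cid == j)[0]
        Vj = rho * np.outer(sv[idx], sv[idx])
        np.fill_diagonal(Vj, v[idx])
        Bj = np.ones((len(idx), len(idx)))
        trPV += np.sum(w[idx] * v[idx]) - np.trace(M @ WX[idx].T @ Vj @ WX[idx])
        trPB += np.sum(w[idx]) - np.trace(M @ WX[idx].T @ Bj @ WX[idx])
        # cross-cluster part of tr(M (WX)' A WX) is zero because A is block diagonal
    # subtract the cross-cluster correction of the projector for B and V:
    # handled above since V and B are block diagonal.
    tau2 = max(0.0, (QE - trPV) / trPB)
    return tau2


def rve_fit(
    y: Sequence[float],
    v: Sequence[float],
    cluster: Sequence,
    X: Optional[np.ndarray] = None,
    names: Optional[list[str]] = None,
    intercept: bool = True,
    rho: float = 0.8,
    tau2_method: str = "ce_mom",
    level: float = 0.95,
) -> RVEResult:
    """Fit a correlated-effects RVE (meta-regression) model.

    Parameters are the effect values ``y`` (Fisher-z scale by convention),
    their sampling variances ``v``, a cluster label per effect, and an
    optional moderator matrix ``X`` (columns are moderators; an intercept
    column is prepended unless ``intercept=False``).  With one effect per
    cluster and omega^2 = 0 the fit reduces to an ordinary precision-weighted
    regression.
    """
    y = np.asarray(y, float)
    v = np.asarray(v, float)
    if np.any(v <= 0):
        raise ValueError("variances must be positive")
    cid, m = _cluster_index(cluster)
    if m < 2:
        raise ValueError("rve_fit needs at least 2 clusters")
    if X is None:
        Xm = np.ones((len(y), 1))
        names = names or ["intercept"]
    else:
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[0] != len(y):
            X = X.T
        if intercept:
            Xm = np.column_stack([np.ones(len(y)), X])
            names = ["intercept"] + (names or [f"x{i}" for i in range(X.shape[1])])
        else:
            Xm = X
            names = names or [f"x{i}" for i in range(X.shape[1])]
    p = Xm.shape[1]
    # collinearity check
    if np.linalg.matrix_rank(Xm) < p:
        u, s, vt = np.linalg.svd(Xm)
        bad = [names[i] for i in np.where(np.abs(vt[-1]) > 0.5)[0]]
        raise ValueError(f"collinear moderator columns: {bad}")

    kj = np.bincount(cid, minlength=m).astype(float)
    vbar = np.bincount(cid, weights=v, minlength=m) / kj

    if tau2_method == "ce_mom":
        tau2 = _ce_tau2_mom(y, v, cid, m, Xm, rho)
        omega2 = 0.0
    elif tau2_method == "cluster_reml":
        # tau^2 by REML on cluster means; omega^2 by within-cluster MoM
        from .pooling import tau2_reml

        sv = np.sqrt(v)
        num = den = 0.0
        for j in range(m):
            idx = np.where(cid == j)[0]
            k = len(idx)
            if k < 2:
                continue
            Vj = rho * np.outer(sv[idx], sv[idx])
            np.fill_diagonal(Vj, v[idx])
            C = np.eye(k) - np.ones((k, k)) / k
            num += np.sum((y[idx] - y[idx].mean()) ** 2) - np.trace(C @ Vj)
            den += k - 1
        omega2 = max(0.0, num / den) if den > 0 else 0.0
        ybar = np.bincount(cid, weights=y, minlength=m) / kj
        vmean = np.empty(m)
        for j in range(m):
            idx = np.where(cid == j)[0]
            Vj = rho * np.outer(sv[idx], sv[idx])
            np.fill_diagonal(Vj, v[idx])
            vmean[j] = Vj.sum() / len(idx) ** 2 + omega2 / len(idx)
        tau2 = tau2_reml(ybar, vmean) if m >= 2 else 0.0
    else:
        raise ValueError(f"unknown tau2_method: {tau2_method!r}")

    w = 1.0 / (kj[cid] * (vbar[cid] + tau2 + omega2))
    WX = w[:, None] * Xm
    M = np.linalg.inv(Xm.T @ WX)
    beta = M @ (WX.T @ y)
    e = y - Xm @ beta

    # cluster-robust sandwich with CR2-style adjustment matrices
    meat = np.zeros((p, p))
    contrib = []  # per-cluster contribution to each coefficient's variance
    for j in range(m):
        idx = np.where(cid == j)[0]
        Xj, wj, ej = Xm[idx], w[idx], e[idx]
        WXj = wj[:, None] * Xj
        Hjj = Xj @ M @ WXj.T
        Aj = np.linalg.inv(_sqrtm_psd(np.eye(len(idx)) - Hjj))
        gj = WXj.T @ Aj @ ej
        meat += np.outer(gj, gj)
        contrib.append(M @ (WXj.T @ Aj @ Aj.T @ WXj) @ M)
    Vb = M @ meat @ M
    se = np.sqrt(np.diag(Vb))

    # Satterthwaite-style df per coefficient from the per-cluster variance shares
    dfs = np.empty(p)
    for c in range(p):
        shares = np.array([cj[c, c] for cj in contrib])
        tot = shares.sum()
        dfs[c] = tot ** 2 / np.sum(shares ** 2) if np.any(shares > 0) else m - p
    dfs = np.minimum(dfs, m - p if m > p else m - 1)

    crit = stats.t.ppf(0.5 + level / 2, dfs)
    lo = beta - crit * se
    hi = beta + crit * se
    pv = 2 * stats.t.sf(np.abs(beta / se), dfs)

    wfe = 1.0 / v
    mu_fe = np.sum(wfe * y) / np.sum(wfe)
    Q = float(np.sum(wfe * (y - mu_fe) ** 2))
    I2 = max(0.0, (Q - (len(y) - 1)) / Q) * 100.0 if Q > 0 else 0.0

    unreliable = [names[i] for i in range(p) if dfs[i] < 4]
    return RVEResult(
        coefficients=dict(zip(names, map(float, beta))),
        robust_se=dict(zip(names, map(float, se))),
        df=dict(zip(names, map(float, dfs))),
        ci_low=dict(zip(names, map(float, lo))),
        ci_high=dict(zip(names, map(float, hi))),
        p=dict(zip(names, map(float, pv))),
        tau2=float(tau2),
        omega2=float(omega2),
        I2=float(I2),
        k_effects=len(y),
        k_clusters=m,
        rho=rho,
        unreliable=unreliable,
    )


def _sqrtm_psd(A: np.ndarray) -> np.ndarray:
    """Symmetric PSD matrix square root (eigen decomposition)."""
    vals, vecs = np.linalg.eigh((A + A.T) / 2)
    vals = np.clip(vals, 1e-10, None)
    return (vecs * np.sqrt(vals)) @ vecs.T


def rve_domain_compare(
    y, v, cluster, domain: Sequence[str], rho: float = 0.8, intercept: bool = True
) -> RVEResult:
    """RVE meta-regression comparing effect strength across IQ domains.

    With an intercept, full_scale is the reference level and the remaining
    coefficients are domain contrasts with robust p-values; without an
    intercept each coefficient is that domain's pooled effect.
    """
    domain = list(domain)
    levels = sorted(set(domain), key=lambda d: (d != "full_scale", d))
    if len(levels) < 2:
        raise ValueError("domain comparison needs at least two domains")
    if intercept:
        X = np.column_stack([[1.0 if d == lv else 0.0 for d in domain] for lv in levels[1:]])
        names = [f"domain[{lv}]" for lv in levels[1:]]
        return rve_fit(y, v, cluster, X, names=names, intercept=True, rho=rho)
    X = np.column_stack([[1.0 if d == lv else 0.0 for d in domain] for lv in levels])
    names = [f"domain[{lv}]" for lv in levels]
    return rve_fit(y, v, cluster, X, names=names, intercept=False, rho=rho)
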