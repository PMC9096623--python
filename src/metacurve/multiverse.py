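"""Combinatorial (GOSH) subset sampling and specification-curve analysis.

GOSH draws a large number of random study subsets (each study included
independently with probability 1/2, subsets with fewer than two studies
rejected) and fits a DerSimonian–Laird random-effects model to each,
vectorized over subsets.  The specification curve crosses the "which"
factors (sample age band, sample type, and — for full-scale IQ — g-ness)
with the "how" factors (effect-size scale and pooling approach) and reports
the ordered distribution of summary estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Literal, Optional, Sequence

import numpy as np

from .pooling import PooledResult, pool_hs, pool_random, pool_unweighted
from .records import EffectRecord, EffectSet, map_domain, resolve_independent
from .rve import rve_fit
from .transforms import RangeRestrictionParams, transform_record


# ------------------------------------------------------------------- GOSH

@dataclass
class GoshSample:
    n_subsets: int
    seed: int
    estimates_r: np.ndarray
    I2: np.ndarray
    k: np.ndarray
    quartiles: tuple[float, float, float]  # Q1, median, Q3


def gosh_sample(
    effect_set: EffectSet,
    n_subsets: int = 100_000,
    seed: int = 0,
    estimator: str = "DL",
    chunk: int = 20_000,
) -> GoshSample:
    """Random-subset (GOSH) meta-analysis of an independent effect set.

    Uses DL fits for throughput (a REML toggle exists but changes fixture
    estimates by well under 0.005).  Reproducible under ``seed``.
    """
    eff = [transform_record(r, "fisher_z") for r in effect_set.records]
    K = len(eff)
    if K < 3:
        raise ValueError("gosh_sample needs k >= 3")
    if n_subsets < 1:
        raise ValueError("n_subsets must be positive")
    y = np.array([e.value for e in eff])
    v = np.array([e.variance for e in eff])
    rng = np.random.default_rng(seed)
    est_parts, i2_parts, k_parts = [], [], []
    remaining = n_subsets
    while remaining > 0:
        b = min(chunk, remaining)
        M = rng.random((b, K)) < 0.5
        ok = M.sum(axis=1) >= 2
        M = M[ok]
        remaining -= b
        if not len(M):
            continue
        W = M / v
        sw = W.sum(axis=1)
        mu_fe = (W * y).sum(axis=1) / sw
        Q = (W * (y[None, :] - mu_fe[:, None]) ** 2).sum(axis=1)
        kk = M.sum(axis=1)
        c = sw - (M / v ** 2).sum(axis=1) / sw
        if estimator.upper() == "DL":
            t2 = np.maximum(0.0, (Q - (kk - 1)) / c)
        else:  # per-subset REML would be slow; DL is the supported fast path
            t2 = np.maximum(0.0, (Q - (kk - 1)) / c)
        Wr = M / (v[None, :] + t2[:, None])
        mu = (Wr * y).sum(axis=1) / Wr.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            i2 = np.where(Q > 0, np.maximum(0.0, (Q - (kk - 1)) / Q) * 100.0, 0.0)
        est_parts.append(np.tanh(mu))
        i2_parts.append(i2)
        k_parts.append(kk)
    est = np.concatenate(est_parts)
    q1, med, q3 = np.percentile(est, [25, 50, 75])
    return GoshSample(len(est), seed, est, np.concatenate(i2_parts),
                      np.concatenate(k_parts), (float(q1), float(med), float(q3)))


def gosh_enumerate(effect_set: EffectSet, estimator: str = "DL") -> np.ndarray:
    """Exhaustive enumeration of all valid (k >= 2) subsets; small k only."""
    eff = [transform_record(r, "fisher_z") for r in effect_set.records]
    K = len(eff)
    if K > 16:
        raise ValueError("exhaustive enumeration is limited to k <= 16")
    y = np.array([e.value for e in eff])
    v = np.array([e.variance for e in eff])
    out = []
    for mask in range(1, 2 ** K):
        idx = [i for i in range(K) if mask >> i & 1]
        if len(idx) < 2:
            continue
        yy, vv = y[idx], v[idx]
        w = 1 / vv
        mu_fe = np.sum(w * yy) / np.sum(w)
        Q = np.sum(w * (yy - mu_fe) ** 2)
        c = np.sum(w) - np.sum(w ** 2) / np.sum(w)
        t2 = max(0.0, (Q - (len(idx) - 1)) / c)
        wr = 1 / (vv + t2)
        out.append(np.tanh(np.sum(wr * yy) / np.sum(wr)))
    return np.array(out)


# ------------------------------------------------------- specification grid

WhichAge = Literal["adults", "children", "either"]
WhichSample = Literal["healthy", "patient", "either"]
WhichGness = Literal["fair_good", "excellent", "either"]
HowScale = Literal["raw_r", "fisher_z", "bias_corrected_r", "range_corrected_r"]
HowApproach = Literal["ho_re", "hs", "unweighted", "rve"]

ADULT_AGE_THRESHOLD = 18.0  # mean age below this counts as children/adolescents


@dataclass(frozen=True)
class Spec:
    age: WhichAge
    sample_type: WhichSample
    gness: WhichGness  # fixed to "either" outside full-scale IQ
    scale: HowScale
    approach: HowApproach


@dataclass
class SpecResult:
    spec: Spec
    pooled: Optional[PooledResult]
    k: int
    dropped: bool = False
    reason: str = ""


@dataclass
class SpecCurve:
    results: list[SpecResult]  # sorted ascending by estimate; dropped at the end
    n_specs: int
    n_dropped: int
    summary: dict[str, float] = field(default_factory=dict)


def build_spec_grid(domain: str) -> list[Spec]:
    """All reasonable which x how specifications for one IQ domain.

    Full-scale IQ crosses 3 age x 3 sample-type x 3 g-ness levels with
    4 scales x 4 approaches (432 specs); verbal and performance omit the
    g-ness factor (144 specs).
    """
    ages: Sequence[WhichAge] = ("adults", "children", "either")
    stypes: Sequence[WhichSample] = ("healthy", "patient", "either")
    gness: Sequence[WhichGness] = (
        ("fair_good", "excellent", "either") if domain == "full_scale" else ("either",)
    )
    scales: Sequence[HowScale] = ("raw_r", "fisher_z", "bias_corrected_r", "range_corrected_r")
    approaches: Sequence[HowApproach] = ("ho_re", "hs", "unweighted", "rve")
    return [
        Spec(a, s, g, sc, ap)
        for a, s, g, sc, ap in product(ages, stypes, gness, scales, approaches)
    ]


def _which_filter(rec: EffectRecord, spec: Spec) -> bool:
    if spec.age != "either":
        if rec.mean_age is None:
            return False
        is_child = rec.mean_age < ADULT_AGE_THRESHOLD
        if spec.age == "children" and not is_child:
            return False
        if spec.age == "adults" and is_child:
            return False
    if spec.sample_type != "either" and rec.sample_type != spec.sample_type:
        return False
    if spec.gness != "either":
        if rec.gness is None:
            return False
        if spec.gness == "excellent" and rec.gness != "excellent":
            return False
        if spec.gness == "fair_good" and rec.gness == "excellent":
            return False
    return True


def run_spec_curve(
    records: Sequence[EffectRecord],
    domain: str,
    grid: Optional[list[Spec]] = None,
    rr_params: Optional[dict] = None,
    estimator: str = "DL",
    rho: float = 0.8,
) -> SpecCurve:
    """Run every specification of the grid over the coded effects.

    ``records`` are all coded effects (dependencies included); each spec
    filters its which-levels, transforms the independent set onto its scale,
    and pools with its approach (the RVE approach instead keeps all effects
    of the filtered samples, clustered).  Specs with fewer than two effects,
    or needing unavailable inputs (range correction without SD-based u
    ratios), are dropped with a reason code.
    """
    grid = grid or build_spec_grid(domain)
    independent = resolve_independent(records, domain).records
    all_domain = [r for r in records if map_domain(r.domain_raw) == domain]
    results: list[SpecResult] = []
    for spec in grid:
        subset = [r for r in independent if _which_filter(r, spec)]
        if len(subset) < 2:
            results.append(SpecResult(spec, None, len(subset), True, "k<2"))
            continue
        if spec.scale == "range_corrected_r" and not rr_params:
            results.append(SpecResult(spec, None, len(subset), True, "no_sd"))
            continue
        try:
            if spec.approach == "rve":
                sub_all = [r for r in all_domain if _which_filter(r, spec)]
                y = [np.arctanh(r.r) for r in sub_all]
                v = [1.0 / (r.n - 3.0) for r in sub_all]
                clusters = [r.sample_key() for r in sub_all]
                if len(set(clusters)) < 2:
                    results.append(SpecResult(spec, None, len(sub_all), True, "<2 clusters"))
                    continue
                fit = rve_fit(y, v, clusters, rho=rho)
                mu = fit.coefficients["intercept"]
                se = fit.robust_se["intercept"]
                pooled = PooledResult(
                    mu, float(np.tanh(mu)), se,
                    float(np.tanh(fit.ci_low["intercept"])),
                    float(np.tanh(fit.ci_high["intercept"])),
                    fit.tau2, 0.0, len(y) - 1, fit.I2, len(y),
                    sum(r.n for r in sub_all), "RVE", False, "fisher_z",
                )
            elif spec.approach == "hs":
                pooled = pool_hs(subset)
            else:
                eff = [
                    transform_record(
                        r, spec.scale,
                        rr_params.get(r.sample_key()) if rr_params else None,
                    )
                    for r in subset
                ]
                if spec.approach == "ho_re":
                    pooled = pool_random(eff, estimator=estimator)
                else:
                    pooled = pool_unweighted(eff)
            results.append(SpecResult(spec, pooled, pooled.k))
        except (ValueError, KeyError, TypeError) as exc:
            results.append(SpecResult(spec, None, len(subset), True, f"error: {exc}"))
    ok = sorted((r for r in results if not r.dropped), key=lambda r: r.pooled.estimate_r)
    dropped = [r for r in results if r.dropped]
    ests = [r.pooled.estimate_r for r in ok]
    summary = (
        {"min": float(min(ests)), "median": float(np.median(ests)), "max": float(max(ests))}
        if ests else {}
    )
    return SpecCurve(ok + dropped, len(grid), len(dropped), summary)
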