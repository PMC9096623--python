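# metacurve

Multiverse meta-analysis of correlation effect sizes, built around the
brain-volume–IQ literature: a coded table of 454 Pearson correlations from
86 studies ships with the package, and every analysis layer needed to
synthesize it — and to ask how much the answer depends on analytic choices —
is implemented and tested.

**Who it is for.**  Meta-analysts and methodologists who want, in Python:
Hedges–Olkin random-effects pooling on the Fisher-z scale with
Knapp–Hartung intervals; Hunter–Schmidt psychometric pooling with Case II
range-restriction correction; robust variance estimation (RVE) for
dependent effect sizes; subgroup and meta-regression moderator analyses; an
eight-method dissemination-bias battery (study power, TES, R-index,
Egger–Sterne regression, trim-and-fill, p-curve, p-uniform and p-uniform*,
a-priori step-weight selection models, Henmi–Copas, cumulative
meta-analysis); combinatorial (GOSH) subset meta-analysis; and
specification-curve analysis over *which*-data × *how*-analyzed factors.

**The core model.**  Study i contributes a correlation r_i from n_i
participants.  On the Fisher scale y_i = atanh(r_i), with sampling variance
v_i = 1/(n_i − 3), the random-effects model is

    y_i = μ + u_i + e_i,   u_i ~ N(0, τ²),   e_i ~ N(0, v_i)

pooled with weights w_i = 1/(v_i + τ²) (τ² by REML or DerSimonian–Laird)
and a Knapp–Hartung t interval; the summary is reported as
r = tanh(μ̂).  Around this core sit the psychometric, robust-variance,
bias-adjustment and multiverse layers described in `docs/methods.md`.

## A worked example

```python
import metacurve as mc

records = mc.load_table1()                       # 454 coded correlations
fs = mc.resolve_independent(records, "full_scale")
fit = mc.pool_random([mc.transform_record(r) for r in fs])
print(f"k={fit.k}  r={fit.estimate_r:.3f}  "
      f"95% CI [{fit.ci_low:.3f}, {fit.ci_high:.3f}]  I2={fit.I2:.1f}%")

healthy = mc.filter_subset(fs, {"sample_type": "healthy"})
gosh = mc.gosh_sample(healthy, n_subsets=100_000, seed=1)
print("GOSH quartiles:", [round(q, 3) for q in gosh.quartiles])
```

Output:

```
k=198  r=0.228  95% CI [0.204, 0.251]  I2=55.5%
GOSH quartiles: [0.231, 0.239, 0.247]
```

The first line is the headline synthesis: across 198 independent samples,
brain volume and full-scale IQ correlate at r ≈ 0.23, with moderate
between-study heterogeneity.  The second line shows how stable that summary
is over 100 000 random subsets of the healthy samples: half of all possible
study selections land within an interquartile band ~0.016 wide — the
conclusion barely depends on which studies are included.

The `examples/` directory holds one short script per capability (pooling,
moderators, bias battery, GOSH, specification curve, synthetic-data
recovery), each printing its numbers with a line on what they mean.  A thin
CLI exposes the same stages:

```bash
metacurve pool --domain full_scale --healthy-only
metacurve speccurve --domain verbal --out verbal_curve.json
metacurve reproduce-paper
```

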