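"""Synthetic-data check: does the pipeline recover known parameters?

Simulates study tables with a known true correlation, heterogeneity and
selective reporting, then measures estimator bias, coverage, and the
inflation produced by publication selection.
"""

import metacurve as mc

cfg = mc.SyntheticConfig(k_studies=200, true_rho=0.25, tau=0.1, seed=11)
rep = mc.recovery_report(cfg, estimators=["REML"], n_reps=100)
print(f"REML over 100 replicates (true rho=0.25, tau=0.1, k=200):")
print(f"  bias={rep['REML']['bias']:+.4f}  rmse={rep['REML']['rmse']:.4f}  "
      f"coverage={rep['REML']['coverage']:.2f}")

sel = mc.SyntheticConfig(k_studies=200, true_rho=0.2, tau=0.1, seed=12,
                         selection_weights=mc.SEVERE_SELECTION,
                         zero_imputation_prob=0.2)
recs = mc.simulate_dataset(sel)
pub = [r for r in recs if r.reporting == "reported" and not r.zero_imputed]
fp = mc.pool_random([mc.transform_record(r) for r in pub])
fa = mc.pool_random([mc.transform_record(r) for r in recs])
print(f"\nsevere selection: published-only r={fp.estimate_r:.3f} vs "
      f"all-effects r={fa.estimate_r:.3f} (true 0.200)")

print("\nUnbiased estimates with ~95% coverage show the estimators work under")
print("the assumed model; the published-only inflation reproduces the pattern")
print("the bias battery is designed to detect.")
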