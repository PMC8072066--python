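"""Joint inference of shared stem-cell kinetics from two synthetic cohorts.

Generates Tie2-like and Fgd5-like cross-sectional cohorts from one set of
reference kinetics (differing only in initial Cre labeling), runs the full
preprocessing pipeline (time-zero shift, 40-week window, pooling,
pooled-variance SEMs, bin-level HSC normalization), fits both datasets
simultaneously by weighted least squares, and reports profile-likelihood
confidence intervals plus the inferred labeling specificities.
"""

import numpy as np
import pandas as pd

import labelflux as lf

rates, init = lf.default_truth()
designs = lf.preset_designs()
pair = [designs["tie2-like"], designs["fgd5-like"]]

tables = lf.generate_multi_dataset(rates, init, pair, seed=7)
df = pd.concat(tables, ignore_index=True)
df = lf.validate_observations(df)
df = lf.adjust_time_zero(df, {"tie2": 2.0, "fgd5": 2.0})
df = lf.restrict_window(df, max_days=280.0)
pooled = lf.pooled_variance_sem(lf.pool_timepoints(df))
pooled = lf.normalize_pooled_to_hsc(pooled)

datasets = lf.fit_datasets_from_pooled(pooled)
spec = lf.make_fitspec([d.dataset_id for d in datasets])
fit = lf.fit_joint(datasets, spec, n_starts=16, seed=0)

kinetic = [n for n in fit.free_names if n.split(".")[0] in ("alpha", "kappa")]
lf.profile_all(fit, kinetic + [n for n in fit.free_names if ".HSC-" in n])

print(fit.summary())
print()
truth = dict(zip(kinetic, list(rates.alpha[:3]) + list(rates.kappa)))
print("kinetic parameter    truth      estimate   (per day)")
for n in kinetic:
    print(f"  {n:15s} {truth[n]:9.5f}  {fit.values[n]:9.5f}")
print()
print("labeling specificity (HSC-U : HSC-D initial labeling):")
print(lf.labeling_specificity(fit).round(3).to_string())
print()
print("The two cohorts look qualitatively different yet are explained by a")
print("single kinetics block; the specificity table shows the Tie2-like")
print("driver is several-fold more HSC-U-specific than the Fgd5-like one")
print("(generator truth: 21:1 vs 4:1, ratio 5.25).")
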