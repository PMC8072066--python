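"""Label propagation through a heterogeneous HSC pool.

Simulates the four-compartment model (HSC-U, HSC-D, ST-HSC, MPP) under two
hypothetical Cre drivers that share identical kinetics but label the hidden
HSC subcompartments differently: driver I labels (50%, 0%), driver J labels
(50%, 50%).  Although the population dynamics are the same, the observed
(HSC-normalized) ST-HSC labeling curves differ qualitatively — the signature
of hidden stem-cell heterogeneity.
"""

import numpy as np

import labelflux as lf

rates, init = lf.default_truth()
times = np.linspace(0.0, 280.0, 11)

print("kinetics (per day):")
print(f"  alpha = {np.round(rates.alpha, 5)}")
print(f"  kappa = {np.round(rates.kappa, 5)}")
print()

for name, f0 in [("driver I (50%, 0%)", [0.5, 0.0, 0.0, 0.0]),
                 ("driver J (50%, 50%)", [0.5, 0.5, 0.0, 0.0])]:
    traj = lf.solve_label_frequencies(
        rates, lf.InitialState(n0=init.n0, f0=np.array(f0)), times)
    _, f_hsc = lf.aggregate_hsc(traj)
    norm_st = lf.normalize_to_hsc(traj)["ST-HSC"]
    print(name)
    print("  t (weeks)         :", np.array2string(times / 7, precision=0))
    print("  observed HSC freq :", np.array2string(f_hsc, precision=3))
    print("  normalized ST-HSC :", np.array2string(norm_st, precision=3))
    print()

print("Driver J's ST-HSC normalized labeling rises much faster because its")
print("label starts in the active HSC-D subcompartment, which feeds ST-HSC")
print("directly; the same kinetics cannot be told apart from the HSC gate")
print("alone, where both drivers start at the same pooled frequency.")
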