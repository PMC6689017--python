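"""Simulate a cohort and detect diurnally rhythmic genes.

Generates a synthetic control cohort in which 15% of genes follow a 24-h
sinusoid on zeitgeber time (amplitude 1.5 log2 units over noise sd 1.0),
fits y = A sin(pi/12 t + p) + b to every gene, and scores rhythmicity
against the pooled null built from 200 time-of-death shuffles.
"""

import numpy as np

from todrhythm import CohortSpec, generate_cohort
from todrhythm.rhythm import rhythmicity_analysis

spec = CohortSpec(n_ctrl=46, n_case=0, n_genes=1000, f_shared=0.15,
                  amplitude=1.5, noise_sd=1.0, tod_mode="uniform",
                  n_sites=1, seed=42)
expr, records, truth = generate_cohort(spec)
zt = np.array([r.zt for r in records])

res = rhythmicity_analysis(expr, zt, n_shuffles=200, seed=1, cohort="control")

n_rhythmic = int((res.empirical_p < 0.05).sum())
true_rhythmic = np.array(truth.rhythm_class) != "none"
recovered = int(((res.empirical_p < 0.05) & true_rhythmic).sum())
print(f"genes called rhythmic at p < 0.05: {n_rhythmic} / {spec.n_genes}")
print(f"of the {int(true_rhythmic.sum())} truly rhythmic genes, "
      f"{recovered} were recovered")
top = np.argsort(res.empirical_p)[:3]
for g in top:
    f = res.fits[g]
    print(f"  {res.gene_ids[g]}: A={f.amplitude:.2f} peak=ZT{f.peak_hour:.1f} "
          f"R2={f.r2:.2f} p={res.empirical_p[g]:.4f}")
# The call count is the truly rhythmic fraction plus the ~5% false-positive
# rate the p < 0.05 threshold implies; top genes should show peak hours
# spread over the day and R2 well above the shuffled-null background.
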