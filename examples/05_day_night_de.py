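"""Day/night-stratified differential expression with BIC covariate selection.

Simulates a cohort where most disease effects exist only in night-death
subjects (5% of genes, delta = 1 log2 unit, 16 + 16 per stratum) plus a
small day-and-night component (1%), then runs the stratified DE procedure
— per-gene BIC selection of up to two covariates, label-permutation
corrected p, Storey q — separately on the day and night strata.
"""

import numpy as np

from todrhythm import CohortSpec, generate_cohort
from todrhythm.destrat import de_stratum, split_day_night

spec = CohortSpec(n_ctrl=32, n_case=32, n_night_ctrl=16, n_night_case=16,
                  n_genes=200, f_shared=0, f_gain=0, f_loss=0,
                  f_de_night=0.05, de_effect=1.0, noise_sd=1.0,
                  n_sites=1, seed=11)
expr, records, truth = generate_cohort(spec)
day, night = split_day_night(records)
print(f"day stratum: {len(day)} subjects, night stratum: {len(night)}")

for name, stratum in (("day", day), ("night", night)):
    res = de_stratum(expr, stratum, n_perm=500, seed=5, stratum=name)
    n_q = int((res.storey_q < 0.3).sum())
    print(f"{name}: {n_q} genes at Storey q < 0.3")
    if n_q:
        for i in np.argsort(res.storey_q)[:3]:
            cls = truth.de_class[expr.gene_ids.index(res.gene_ids[i])]
            print(f"  {res.gene_ids[i]}: effect {res.effect_size[i]:+.2f} log2 "
                  f"(fold {2**res.effect_size[i]:.2f}), q = {res.storey_q[i]:.3f}, "
                  f"truth: {cls}")
# The night stratum lights up with the night-only genes (plus the shared
# day-and-night component); the day stratum sees only the small shared
# component - the signature of rhythm-driven disease differences that
# time-of-death-blind analyses dilute.
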