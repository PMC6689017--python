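"""Detect genes that gain or lose rhythmicity in the case group.

Simulates a 46 + 46 case/control cohort in which 5% of genes cycle only
in cases (gain) and 5% only in controls (loss), runs the per-cohort
rhythmicity analysis, and classifies each gene with the delta-R2
permutation test (R2_case - R2_ctrl against a paired shuffled null).
"""

import numpy as np

from todrhythm import CohortSpec, generate_cohort
from todrhythm.rhythm import delta_r2_test, rhythmicity_analysis

spec = CohortSpec(n_ctrl=46, n_case=46, n_genes=1000,
                  f_shared=0.05, f_gain=0.05, f_loss=0.05,
                  amplitude=1.5, noise_sd=1.0, tod_mode="uniform",
                  n_sites=1, seed=7)
expr, records, truth = generate_cohort(spec)
zt = np.array([r.zt for r in records])

results = {}
for grp in ("case", "control"):
    idx = [i for i, r in enumerate(records) if r.diagnosis == grp]
    sub = expr.subset_subjects([records[i].subject_id for i in idx])
    results[grp] = rhythmicity_analysis(sub, zt[idx], n_shuffles=200,
                                        seed=hash(grp) % 2**31, cohort=grp)

delta = delta_r2_test(results["case"], results["control"], alpha=0.05)
calls = np.array(delta.classification)
tr = np.array(truth.rhythm_class)
for cls in ("gain", "loss"):
    hit = (calls[tr == cls] == cls).mean()
    print(f"{cls}: {int((calls == cls).sum())} genes called, "
          f"sensitivity on truth = {hit:.2f}")
fp = (calls[(tr != 'gain') & (tr != 'loss')] != 'unchanged').mean()
print(f"false calls among unchanged genes: {fp:.3f}")
# Sensitivities near 1 and false-call rates below ~0.1 mean the paired
# delta-R2 null separates real rhythm changes from fitting noise.
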