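"""Gene-set Z-score profile: a coherent set cycling in cases only.

Simulates a 100-gene set (tagged "mito") that cycles with a shared peak
at ZT 3.5 only in cases. Each gene is Z-scored across subjects, set genes
are averaged per subject, and a sinusoid is fitted to the resulting
profile in each diagnosis group.
"""

import numpy as np

from todrhythm import CohortSpec, generate_cohort
from todrhythm.summaries import zscore_geneset

spec = CohortSpec(n_ctrl=46, n_case=46, n_genes=300,
                  f_shared=0, f_gain=0, f_loss=0,
                  coherent_set_size=100, coherent_set_peak=3.5,
                  coherent_set_amp=0.8, noise_sd=1.0,
                  tod_mode="uniform", n_sites=1, seed=21)
expr, records, truth = generate_cohort(spec)
gene_set = truth.gene_sets["mito"]

for grp in ("control", "case"):
    idx = [i for i, r in enumerate(records) if r.diagnosis == grp]
    sub = expr.subset_subjects([records[i].subject_id for i in idx])
    zt = np.array([records[i].zt for i in idx])
    prof = zscore_geneset(sub, gene_set, zt=zt)
    print(f"{grp}: set-score R2 = {prof.fit.r2:.3f}, "
          f"peak = ZT {prof.fit.peak_hour:.1f}, "
          f"amplitude = {prof.fit.amplitude:.3f}")
# The case profile should peak near the true ZT 3.5 with a much higher R2
# than the control profile, whose genes carry no rhythm.
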