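"""Compare two ranked gene lists threshold-free with RRHO.

Builds two p-value lists over one universe — first strongly concordant,
then independent — ranks both by -log10(p), and prints the maximum
-log10 hypergeometric enrichment across all rank-threshold pairs.
"""

import numpy as np

from todrhythm.rrho import rank_genes, rrho_map

rng = np.random.default_rng(3)
genes = [f"g{i:04d}" for i in range(2000)]

# concordant: second list is a noisy copy of the first
base = rng.uniform(size=2000)
noisy = np.clip(base + rng.normal(0, 0.05, 2000), 1e-9, 1.0)
m_conc = rrho_map(rank_genes(dict(zip(genes, base))),
                  rank_genes(dict(zip(genes, noisy))))

# independent: unrelated p-values
other = rng.uniform(size=2000)
m_null = rrho_map(rank_genes(dict(zip(genes, base))),
                  rank_genes(dict(zip(genes, other))))

print(f"map resolution: {m_conc.matrix.shape}, step {m_conc.step} genes")
print(f"max -log10(p), concordant lists:  {m_conc.matrix.max():8.1f}")
print(f"max -log10(p), independent lists: {m_null.matrix.max():8.1f}")
# Concordant rankings light up the map's significant corner by hundreds
# of log units; independent rankings stay near the chance level (< ~4).
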