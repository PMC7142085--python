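"""Recover the planted ordered-locale bias of glycosites and test it.

Each protein contributes a matched pair (fraction of its glycosites in
ordered sequence, fraction in disordered sequence); the Wilcoxon
matched-pairs signed-rank test asks whether glycosites avoid disorder.
"""

import numpy as np

from glycolocale import (
    GeneratorParams,
    gen_cohort,
    metric_glycosite_ordered_fraction,
    wilcoxon_signed_rank,
)

cohort = gen_cohort(GeneratorParams(n_proteins=200, p_glycosite_ordered=0.8, seed=3))
fractions = np.array(
    [metric_glycosite_ordered_fraction(r) for r in cohort.records]
)
pairs = np.column_stack([fractions, 1.0 - fractions])
res = wilcoxon_signed_rank(pairs)

print(f"planted ordered bias:        0.80")
print(f"recovered mean fraction:     {fractions.mean():.3f}")
print(f"Wilcoxon ({res.method}): W = {res.statistic:.0f}, "
      f"n = {res.n_effective}, p = {res.p_two_sided:.3g}")
# A mean near 0.8 and a vanishing p-value show per-protein glycosite locales
# are strongly biased toward ordered sequence, as planted.
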