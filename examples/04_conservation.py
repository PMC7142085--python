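"""Entropy and evolutionary-trace conservation of glycosite neighborhoods.

Simulates 4-taxon ortholog alignments with region-specific substitution
rates (neighborhoods slowest, disordered sequence fastest), then contrasts
mean per-column Shannon entropy and mean trace rank across region classes.
"""

import numpy as np

from glycolocale import (
    GeneratorParams,
    et_rank,
    extract_neighborhoods,
    gen_cohort,
    gen_orthologs,
    region_mean_entropy,
    sample_control_windows,
)
from glycolocale.regions import DISORDERED_CONTROL, ORDERED_CONTROL
from glycolocale.synthetic import ortholog_rng

params = GeneratorParams(n_proteins=50, seed=8)
cohort = gen_cohort(params)
rng = np.random.default_rng(8)

entropies = {"neighborhood": [], "ordered_control": [], "disordered_control": []}
ranks = {k: [] for k in entropies}
for i, rec in enumerate(cohort.records):
    aln, tree = gen_orthologs(rec, params, ortholog_rng(params.seed, i))
    et = et_rank(aln, tree)
    regions = {}
    hoods = extract_neighborhoods(rec)
    if hoods:
        regions["neighborhood"] = sorted(
            {p for w in hoods for p in range(w.start, w.start + 11)}
        )
    controls = sample_control_windows(rec, rng)
    for key, kind in (("ordered_control", ORDERED_CONTROL),
                      ("disordered_control", DISORDERED_CONTROL)):
        if controls[kind]:
            w = controls[kind][0]
            regions[key] = list(range(w.start, w.start + 11))
    for key, positions in regions.items():
        entropies[key].append(region_mean_entropy(aln, positions))
        ranks[key].append(et.region_mean_rank(positions))

print("region               mean entropy (bits)   mean trace rank")
for key in entropies:
    print(f"{key:<22}{np.mean(entropies[key]):>10.3f}{np.mean(ranks[key]):>18.3f}")
# Substitution rates 0.02 / 0.05 / 0.2 per site per lineage produce the
# expected ordering: neighborhoods most conserved (lowest entropy and rank),
# disordered controls least.
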