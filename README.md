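# glycolocale

Where do N-linked glycosylation sites sit relative to intrinsic disorder?

N-linked glycans are conjugated to asparagines inside the sequon
**N-X-S/T** (X any residue except proline). Although many post-translational
modifications concentrate in intrinsically disordered regions (IDRs),
experimentally mapped N-glycosites tend to do the opposite: they cluster in
ordered sequence. `glycolocale` is a pipeline for quantifying that spatial
exclusion on a cohort of glycoproteins, for users who have (or simulate)
three annotations per protein: the sequence, its N-glycosite positions, and
its disorder intervals (from any disorder predictor — prediction itself is
out of scope).

The pipeline computes, per protein and per cohort:

* **Locale statistics** — the fraction of glycosites in ordered vs
  disordered sequence, compared with the Wilcoxon matched-pairs signed-rank
  test (exact null distribution for small untied samples, normal
  approximation with tie/continuity correction otherwise).
* **Sequon statistics** — N(X-P)S/T density and the fraction of asparagines
  participating in sequons per region, plus the property-class profile
  (acidic/basic/hydrophobic/bulky/small) of the sequon X position.
* **Composition enrichment** — for 11-residue glycosite-centered
  neighborhoods vs glycosite-free ordered and disordered control windows,
  the fractional difference `D(a) = (C_q(a) − C_b(a)) / C_b(a)` per amino
  acid and composition-weighted property scores
  `S = Σ_a scale(a)·C(a)` over ≥10 literature-mirroring scales, with
  bootstrap z-tests (default 10,000 iterations) and Bonferroni correction.
* **Conservation** — per-column Shannon entropy `H = −Σ p_i log₂ p_i` over
  ortholog alignments and classic integer evolutionary-trace ranks given a
  tree, contrasted between neighborhoods, controls, and full-length
  sequence.
* **Synthetic cohorts** — a generator that plants every signal with known
  ground truth (segment architecture, composition biases, glycosite locale
  bias, region-specific ortholog substitution rates), so each stage is
  verifiable end to end without downloads.

## Worked example

```bash
python examples/02_locale_bias.py
```

```
planted ordered bias:        0.80
recovered mean fraction:     0.833
Wilcoxon (normal_approx): W = 16211, n = 188, p = 2.28e-25
```

A 200-protein synthetic cohort is planted so each glycosite falls in an
ordered segment with probability 0.8. The per-protein ordered fraction
averages 0.833 (sampling noise around the planted 0.8), and the paired
Wilcoxon test on (ordered, disordered) fraction pairs rejects the no-bias
null decisively — the same analysis that establishes glycosite/disorder
exclusion on real annotations. The other scripts under `examples/` walk
through sequon scanning (`01`), neighborhood composition enrichment (`03`),
entropy and trace-rank conservation (`04`), and the full config-driven
pipeline (`05`).

The same stages are exposed as a CLI over TSV inputs/outputs:

```bash
glycolocale run-all --config cfg.yaml          # or: simulate / annotate /
                                               # metrics / enrich / conserve / report
```

with a strict YAML config (`seed`, `outdir`, and either a `simulate:` block
or `inputs:` paths to FASTA + glycosite/disorder TSVs + optional MSAs and a
newick tree).

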