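# Methods

This note documents the models, conventions and design choices behind
`glycolocale`, in the spirit of a statistical-software methods appendix.

## Records, coordinates and locales

External files follow database conventions: FASTA sequences, a glycosite
TSV (`protein_id`, `position`, 1-based) and a disorder TSV (`protein_id`,
`start`, `end`, 1-based inclusive). Internally everything is 0-based
half-open, converted once at assembly. Overlapping or adjacent disorder
intervals — common in meta-predictor exports — are merged with a logged
warning rather than rejected. A residue's *locale* is ORDERED or DISORDERED
according to the merged intervals; glycosites must fall on asparagines or
assembly fails. `X` (unknown residue) is allowed in sequences but excluded
from all composition counts, with logged counts. Proteins with no disorder,
or with no glycosites, are valid records; paired analyses drop them
explicitly (see below). The thresholding of per-residue disorder scores
into intervals is the annotator's concern: intervals are taken as given.

## Sequons and the X position

A sequon is any position `i` with `seq[i]=='N'`, `seq[i+1]!='P'`,
`seq[i+2] in {S,T}`; overlapping matches are all reported. A sequon takes
the locale of its asparagine; if its three residues straddle a boundary
that fact is recorded (`spans_boundary`) but the sequon is not excluded.
Experimental glycosites that do not sit at a sequon asparagine are retained
in locale analyses and counted in the QC report.

The X residue is classified into overlapping property classes defined in an
editable YAML table (`data/residue_classes.yaml`): acidic {D,E}, basic
{K,R,H}, small {G,A,S,C,T,P,N,D}, bulky = top half of the Zimmerman
bulkiness scale, hydrophobic = positive Kyte–Doolittle hydropathy plus W
(tryptophan is near-universally treated as hydrophobic; its mildly negative
KD value reflects only the indole NH), hydrophilic = the complement. These
are explicit conventions, not reconstructions of any particular published
threshold set, and can be swapped wholesale via the YAML file.

## Windows and paired metrics

Neighborhoods are fixed 11-mers (5+1+5) centered on glycosites; glycosites
closer than 5 residues to a terminus are skipped and logged rather than
truncated, so all windows are length-comparable. Neighborhoods spanning a
boundary are kept with their locale purity recorded. Control windows are
glycosite-free 11-mers whose residues all share one locale and which never
intersect a glycosite neighborhood (equivalently: no position within 5 of
any glycosite); one per class per protein is drawn uniformly from the
eligible starts (configurable `controls_per_protein` for power studies). A
class with no eligible start yields NA for that protein.

Per-protein metrics (glycosite ordered fraction, Asn/Ser/Thr percentages,
sequon density per 100 residues, sequon-Asn participation fraction) form
matched (ordered, disordered) pairs tested with the Wilcoxon signed-rank
test. Sequon abundance is reported under *both* denominators — per 100
region residues and per region asparagine — because "relative proportion"
is ambiguous between them. Conventions: NA pairs are dropped with a logged
count (preserving the matched design), zero differences are dropped, the
exact null distribution (computed by a subset-sum dynamic programme over
the 2^n sign assignments) is used when the effective n ≤ 25 with no ties in
|difference|, and otherwise the normal approximation with tie correction
and continuity correction. All p-values are two-sided and reported raw;
significance flags never replace them.

## Composition and property enrichment

Pools are flattened residue multisets of windows (the residue, not the
window, is the resampling unit, matching how composition-profiling tools
operate; a window-level block bootstrap was considered and rejected as the
default because the windows themselves are short and internally iid under
the generator). The statistic per amino acid is the fractional difference
`D(a) = (C_q(a) − C_b(a))/C_b(a)`, NA when the background lacks the residue.
Each bootstrap iteration resamples N_q residues from the query and N_b from
the background with replacement and recomputes D; this is implemented as
multinomial count resampling, which is the identical distribution and
vectorizes. Significance is a two-sided z-test of `D_obs / SE_bootstrap`
against the standard normal; Bonferroni divisor 20 for amino-acid runs and
the number of scales for property runs (the correction family is the
analysis family). A label-permutation p-value
(multivariate-hypergeometric reallocation of the combined pool) is provided
as an independent cross-check and tracks the bootstrap p-values in rank on
null data. Default 10,000 iterations, α = 0.05.

Property scores are composition-weighted means `S = Σ_a scale(a)·C(a)` over
eleven editable scales (aromaticity, Zimmerman polarity and bulkiness,
net charge at pH 7, Kyte–Doolittle hydropathy, Bhaskaran–Ponnuswamy
flexibility, a Janin-derived exposure scale, Chou–Fasman β and turn/coil
frequencies, TOP-IDP disorder propensity and its negation). The numeric
tables mirror the named literature scales but are shipped as labeled,
swappable stand-ins in `data/property_scales.yaml`; no analysis depends on
their absolute calibration, only on cross-pool differences.

## Conservation

Ortholog alignments carry a designated reference (human) row; region
positions defined on the reference map to columns through `ref_map`, so
columns where the reference is gapped cannot enter a region. Column
conservation is Shannon entropy in bits with the gap as a 21st symbol by
default (`skip_gapped_rows` is available; the choice is recorded in output
headers), giving bounds [0, log₂21].

The evolutionary-trace rank is the classic integer variant: internal nodes
sorted by distance from the root (missing branch lengths count 1, ties
broken by preorder order — documented and deterministic) define partition
levels 1..L; at level k the first k−1 nodes are "opened" and the leaf
groups are the maximal unopened subtrees; a column's rank is the smallest
level at which every group is internally invariant (gaps distinct). Rank 1
⇔ invariant column; a column unique per leaf gets rank = #leaves. Trees are
inputs; unrooted trees are midpoint-rooted with a warning. Real-valued
trace weighting and homolog search are out of scope.

Neighborhood entropy is compared against both control windows and the
full-length sequence, since either background is defensible; both rows are
emitted.

## Synthetic generator

The generator defines the study conditions under which the pipeline is
validated. Defaults, chosen once as a realistic glycoprotein cohort:

| parameter | default | rationale |
|---|---|---|
| n_proteins | 200 | cohort large enough for stable paired tests |
| length | U(300, 600) | typical secreted/membrane glycoprotein range |
| disordered fraction | 0.30 | a protein set with substantial but minority disorder |
| disordered segment length | U(15, 45) | IDR-like stretches that can host 11-mer controls |
| ordered segment length | disordered draw × (1−f)/f | hits the target fraction in expectation |
| glycosites/protein | U{1..4} | at least one, as in curated glycoprotein sets |
| p(glycosite ordered) | 0.8 | the planted locale bias the analysis must recover |
| substitution rates | 0.02 / 0.05 / 0.2 | neighborhood / ordered / disordered, per site per lineage unit |
| taxa | human, chimp (0.15), mouse (1.0), chicken (2.0) | fixed (((human,chimp),mouse),chicken) topology, amniote-like relative depths |

Ordered segments draw residues iid from a composition up-weighting
W,F,Y,I,L,V,C; disordered segments up-weight P,E,S,R,Q (×2.5) and N,M
(×1.8), echoing the residues empirically enriched in disorder. Glycosites
are planted only by rewriting an interior position (≥5 from termini,
sequon fully inside one segment, ≥3 apart) to N-X-S/T with X ≠ P drawn from
the segment composition — so plant/scan cross-checks are exact and the
locale of every planted site is unambiguous. The locale of each site is an
independent Bernoulli(p) draw, so realized cohort fractions concentrate
binomially around p and, at p = 0.5, the paired locale test is an exact
symmetric null. Ortholog rows substitute each site independently with
probability rate × branch factor (capped at 0.95), replacement drawn from
the segment composition excluding the current residue; there are no indels,
so alignments are gapless and `ref_map` is the identity. All randomness
derives from one cohort seed via `SeedSequence` spawning (protein i = child
i; its ortholog stream = that child's first spawn), making any protein
reproducible in isolation and cohort files byte-identical across re-runs.

What the generator does **not** emulate: indels and alignment uncertainty,
site-to-site rate heterogeneity beyond the three region classes, realistic
substitution matrices (replacement is composition resampling, adequate for
entropy/rank contrasts but not for phylogenetic inference), non-sequon
glycosites, and any correlation structure along the sequence beyond
segments. One consequence worth noting: because disordered composition
up-weights N and S, *accidental* sequon density is higher in disordered
segments even though glycosites are planted preferentially in ordered ones —
synthetic cohorts validate the machinery, not every directional finding
expected of real annotations.

## Validation scale and numerical choices

The test suite validates: scanner equivalence to a triple-loop oracle
(exhaustively over a 4-letter alphabet to length 6, plus 10,000 random
100-mers); Wilcoxon exact p against full 2^n enumeration (n ≤ 10) and
against an independent implementation; bias recovery (±0.05 of the planted
0.8 at n = 200) and type-I calibration of the paired test (200 null
cohorts); bootstrap type-I rate in [0.03, 0.07] over 500 null runs at
1,000 iterations with pools of 2,000, and ≥95% Bonferroni power for a
5%→10% proline shift; entropy contrast recovery in ≥95/100 cohorts at
rates 0.02 vs 0.2 (and a ~50/50 sign split at equal rates); trace-rank
equivalence to a brute-force partition oracle on random 6-leaf trees; and
100% truth/annotation locale agreement on round-trip. Simulation sizes were
chosen so the whole suite completes in a few minutes on one CPU while
keeping binomial error bands well inside the asserted tolerances.

Degenerate inputs are handled as NA-with-warning wherever the quantity is
undefined (no glycosites, no disordered run ≥ 11, zero asparagines in a
region, all-zero differences) and as errors where the input violates a
contract (glycosite off an asparagine, ragged alignments, unknown config
keys).

## Known limitations

* Bootstrap-SE z-tests are asymptotically calibrated; for rare residues in
  small pools (expected count ≲ 5) p-values become conservative/unstable —
  the permutation cross-check is the fallback there.
* The exact Wilcoxon branch requires untied |differences|; heavily discrete
  metrics always route to the corrected normal approximation.
* Entropy with 4 taxa is coarse (only 5 distinct column multisets up to
  symmetry); contrasts are meaningful in aggregate, not per column.
* The integer trace rank ignores branch-length magnitudes beyond their
  ordering of internal nodes.
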