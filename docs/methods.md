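# Methods

This note documents the models and procedures implemented in era3d, the
parameters that matter, the numerical decisions taken where the design
was genuinely open, and what the synthetic-data generator does and does
not emulate.

## Gene-age model

A gene's *minimal evolutionary age* is inferred from its taxonomic
lineage restriction: the most distant species containing a sufficiently
similar protein places a lower bound on the gene's age. The lineage is
discretized into 31 phylostrata (PS 1 = cellular organisms, the most
ancient; PS 31 = restricted to the query species), supplied as an
explicit species→phylostratum table rather than a hard-coded lineage, so
the machinery applies to any query species.

Assignment rules, in order:

- **Protein-length filter.** Isoforms with protein length < 40 AA or
  ≥ 4,000 AA are removed (retained iff 40 ≤ length < 4,000). Very short
  proteins cannot be assigned a restriction level reliably; the upper
  bound mirrors the boundary convention of the length filter.
- **Hit filter.** Only hits with e-value strictly below the cutoff
  (default 10⁻³) count. Self-species hits are ignored: they carry no
  lineage information.
- **Minimum rule.** The isoform's phylostratum is the minimum PS among
  qualifying hits; with none, it is PS 31. Adding a more distant
  sub-cutoff hit can therefore only decrease (never increase) the
  assigned PS — a property test pins this monotonicity.
- **Representative isoform.** Per gene, the longest of the oldest
  isoforms; equal lengths break ties by lexicographically smallest
  isoform id so the choice is deterministic.

Two era groupings are provided: the five-era scheme (Ancient PS 1–3,
Metazoan 4–7, Chordate 8–17, Mammal 18–22, Primate 23–31) and the
four-era scheme (Early PS 1–13, Vertebrate 14–17, Mammal 18–22, Primate
23–31) used when comparing against synteny-based assignments whose oldest
branch spans PS 1–13. Both are total over PS 1–31 and agree on PS 18–31.

`compare_age_methods` classifies each shared gene (intersection of the
two inputs) as `same`, `younger_by_a` or `younger_by_b` by era rank, not
phylostratum, because method comparisons are reported at era level;
summary fractions and each method's oldest-era fraction are returned.

## Interval algebra

Coordinates are 0-based half-open throughout (BED convention). `merge`
collapses overlapping **and bookended** intervals (end == next start),
matching the common merge-tool default; this affects region counts, so it
is pinned by tests against a per-base mask oracle. `pool_datasets` is the
merged union across datasets — the "pooled" track construction in which
any given region is counted once. `coverage_stats` reports region count,
median region size (average-of-middle-two for even counts; undefined and
reported as unavailable for empty sets), coverage in bp and percent of
genome. `intersect_unique` returns the records of `a` overlapping any
record of `b` by ≥1 bp, each written at most once and **not** merged with
one another (record-level `-u` semantics). Assembly liftover is out of
scope; all inputs are assumed on one assembly.

## Binned density correlation

`make_bins` tiles each chromosome with ⌈L/bin⌉ fixed-size bins, the last
truncated. Per-bin track density is covered bp / bin length, computed on
the merged track via prefix sums (exactly conservative: Σ fraction × bin
length equals track coverage, asserted in tests). Decisions:

- **All bins enter the correlation**, including zero-density bins, pooled
  across chromosomes ("global" binning). Dropping empty bins would bias
  rank correlations between sparse tracks.
- **Truncated terminal bins** are included with their true length as
  denominator.
- **Spearman ρ** uses average ranks for ties (essential: density vectors
  have many tied zeros) and a two-sided p from the t approximation with
  n−2 df, appropriate at thousands of bins. Constant input raises an
  error rather than silently reporting 0; inside `correlation_matrix`
  such pairs carry NaN plus the error message so one degenerate track
  does not abort a matrix.
- **p values are raw** across pairs by default; a BH option exists but is
  off, matching the convention of reporting per-pair correlation
  significance directly.

Default bin sizes are 20/50/100 kb; on strongly planted signals the three
sizes give concordant signs (checked in tests at reduced scale).

## Intergenic controls

An Igen ORF is a maximal open reading frame in eligible sequence:
uppercase (unmasked), non-N, outside exclusion intervals (genes, prior
controls). The scanner covers both strands and all three frames per
strand; from each ATG it extends to the first in-frame stop (TAA/TAG/
TGA), reports the ORF when it has ≥ `min_codons` (default 40) non-stop
codons, and ignores ATGs nested inside an open ORF so no region is
reported twice. Two conventions were open and are pinned here: **Met
counts among the 40 non-stop codons** (minimum span 41 codons = 123 bp),
and **nested ORFs are not reported**. Repeat-like sequence is encoded as
soft-masking (lowercase), and "non-repetitive" is enforced as mask
exclusion.

Igen Non-ORFs are sampled to match a requested length multiset exactly
(Kolmogorov–Smirnov distance 0 by construction): eligible runs are
tracked dynamically (placing a window splits its run, so overlap between
picks is impossible), candidate starts are drawn uniformly over all
remaining slots, and windows beginning with ATG on the plus strand are
rejected and redrawn. The ATG constraint applies to the plus strand only.
The pipeline samples controls for a seeded subset of ORF lengths
(default 200) — on small genomes accidental ORFs are dense enough that
exhaustive one-per-ORF matching is infeasible, and control sets are
conventionally random subsets anyway — and places longest-first so large
eligible runs are consumed before fragmentation.

## Expression statistics

- **Size factors** are median-of-ratios: per gene with all-nonzero
  counts, the geometric mean across samples; a sample's factor is the
  median of count/geometric-mean over those genes. Note an exact
  property of this estimator: scaling one sample's counts by c multiplies
  its factor *relative to every other sample's* by c, while the absolute
  factors shift because the geometric-mean reference moves by c^(1/m);
  normalized counts are invariant up to one global constant. The test
  suite asserts this exact form.
- **Aggregation**: per gene, mean over each tissue's samples, then mean
  of tissue means within a category. Categories may share tissues (cortex
  and cerebellum belong to both ectoderm and brain by default), and
  shared tissues contribute to each category.
- **Group comparisons**: two-sided Mann–Whitney U (tie- and
  continuity-corrected normal approximation; sidedness was an open
  choice, two-sided is the conservative default), BH-corrected across
  exactly the comparisons requested in one invocation — the family is the
  call, since no canonical family structure is implied by the data.
  Group summaries (mean, SEM, median, n) are computed on untransformed
  normalized counts. Reported p values are floored at 2.225×10⁻³⁰⁸, the
  smallest positive normal double.
- **Length deciles**: deciles of the pooled gene set by coding length,
  ties broken by stable rank so decile sizes differ by at most one;
  all-identical lengths are flagged degenerate rather than erroring.
- **log10 display**: with m the smallest nonzero value, every value maps
  to log10(value + m) — m is added to *every* argument, keeping the
  transform strictly increasing. Display only; no statistic uses it.

## Synthetic data: what it emulates, and what it does not

The generator produces toy genomes whose structure mirrors the study
design so that downstream inference can be checked for parameter
recovery:

- **Genome/genes**: by default two 5-Mb chromosomes and 100 genes per
  era with lognormal lengths (median 2 kb, σ = 0.5 on the log scale,
  whole codons), placed uniformly without overlap; era labels are
  seed-shuffled across positions. ~20% of intergenic sequence is
  soft-masked in 200–2,000 bp patches, emulating repeats.
- **Feature tracks**: the genome is tiled into 1-kb candidate windows;
  a window overlapping a gene of era e has its keep-odds multiplied by
  `track_enrichment[e]` (largest multiplier wins where eras overlap a
  window), with base marginal coverage 0.25; kept windows merge. A
  multiplier of 1 everywhere yields a track independent of all eras —
  the null case used for calibration.
- **Hit tables**: each gene's most distant sub-cutoff hit falls at a PS
  drawn uniformly within its planted era's range (e-values 10⁻⁵⁰–10⁻⁴),
  plus closer sub-cutoff hits and, at rate 0.5, an above-cutoff decoy in
  a more distant stratum that a correct assignment must ignore. A
  31-stratum toy taxonomy with one species per stratum (anchored by the
  usual representative species) backs this.
- **Expression**: counts are negative binomial with mean
  μ_era × gene-effect × sample-depth and dispersion 0.5
  (var = μ + 0.5 μ²), with lognormal gene effects (σ = 0.5) and sample
  depths (σ = 0.2). Default era means 2,700 / 1,200 / 550 / 260 / 120
  anchor the gradient at magnitudes typical of adult-tissue mean counts
  for ancient and primate genes, log-interpolated between. Default
  design: 6 categories over 9 tissues, 3 samples per tissue.

Not emulated: realistic Hi-C contact matrices (tracks are planted
interval sets, not called from contacts), realistic protein sequences,
phylogenetic sequence evolution, linkage between gene length and era,
and tissue-specific expression programs beyond a global depth/mean model.
Passing recovery tests therefore demonstrates the *inference machinery*
is correct and calibrated — not that real data meet its assumptions.

## Problem sizes and calibration checks

The standing validation runs use: 2,000 genome-wide bins for correlation
recovery (20 planted seeds, 200 null seeds; the null significance count
is checked against the binomial 99% interval around the nominal 5%);
500 genes per era over 100 seeds for the expression gradient (median
ordering in every category plus BH-significant ancient-vs-primate); a
1-Mb sequence with 50 compliant ORFs and 50 39-codon decoys for scanner
exactness; and 500 genes for the age round trip (100% era recovery
required, invariance to decoys). Published summary counts (per-era gene
counts; the 18,098-gene method-comparison marginals) are used as inputs
and re-run through the real machinery rather than re-derived, since the
underlying accessions are outside desk scale.

## Known limitations

- Age assignment trusts the hit table; running similarity searches,
  low-complexity masking and orthology inference are out of scope.
- The Spearman p value is asymptotic; no exact permutation is exposed in
  the API (tests use enumeration at tiny n where needed).
- `intersect_unique` reports `a`'s records verbatim; if `a` contains
  duplicate records, duplicates overlapping `b` are all reported.
- The Non-ORF strand constraint (no leading ATG) applies to the plus
  strand only.
- The pipeline's manifest records checksums and parameters but not
  hardware or BLAS details; bitwise reproducibility is guaranteed only
  for the seeded generators and deterministic algebra, which is what the
  determinism tests cover.
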