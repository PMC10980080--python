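# era3d

Genes differ enormously in evolutionary age: some are detectable in
bacteria and predate cellular life's major splits, others are restricted
to primates or to a single species. `era3d` is a pipeline for asking how
genes of different evolutionary ages sit within 3D-genome features
(topologically associating domains, chromatin-loop anchors, domain
boundaries) and how their expression scales with age. It is aimed at
researchers in regulatory genomics and molecular evolution who have
gene-age assignments (or homology hit tables to derive them), BED interval
tracks of 3D-genome annotations, and expression count matrices.

The package covers five analysis stages plus a synthetic-data generator
that plants known structure so every stage can be validated end to end:

1. **Age assignment (phylostratigraphy).** Each species on the query
   lineage maps to a phylostratum PS 1–31 (PS 1 = cellular organisms,
   PS 31 = query-species-restricted). An isoform's minimal age is the
   minimum PS among homology hits with e-value < 10⁻³; a gene is
   represented by the longest of its oldest isoforms, and phylostrata are
   grouped into eras (Ancient PS 1–3, Metazoan PS 4–7, Chordate PS 8–17,
   Mammal PS 18–22, Primate PS 23–31; or the four-era scheme Early
   PS 1–13 / Vertebrate PS 14–17 / Mammal / Primate used when comparing
   against synteny-based ages).
2. **Interval algebra.** BED tracks are collapsed so each base is counted
   once (bookended intervals merge), pooled across cell-type datasets,
   summarized (region count, median size, coverage, % of genome), and
   subset by overlap with `bedtools intersect -u` semantics.
3. **Density correlation** — the core statistic. The genome is split into
   fixed-size bins (20/50/100 kb conventionally); each bin gets the
   covered fraction of every track; track pairs are correlated with
   Spearman's ρ over all genome-wide bins (average ranks for ties,
   two-sided p from the t approximation on n−2 df).
4. **Intergenic controls.** Igen ORFs — ATG, ≥40 non-stop codons, then a
   stop — found by a six-frame scan of unmasked intergenic sequence, and
   Igen Non-ORFs, length-matched windows that do not begin with ATG.
5. **Expression statistics.** Median-of-ratios (DESeq2-style) size
   factors, tissue-category aggregation (germ layers, germ line, brain),
   two-sided Mann–Whitney U comparisons between eras with
   Benjamini–Hochberg correction, length-decile stratification, and the
   log10 display transform that adds the smallest nonzero value to every
   argument.

## Worked example

```python
from era3d import (SyntheticSpec, gen_genome, gen_feature_track, gen_hit_table,
                   gen_expression, toy_taxonomy, assign_ages, era_counts,
                   make_bins, BinDensityTable, correlation_matrix,
                   normalize_counts, aggregate_by_category, compare_groups)

# a 10 Mb toy genome, 100 genes per era, domains enriched 5x around
# ancient genes
spec = SyntheticSpec(seed=42, track_enrichment={"Ancient": 5.0})
synth = gen_genome(spec, with_sequence=False)

taxonomy = toy_taxonomy()
ages = assign_ages(synth.genes, gen_hit_table(synth.genes, taxonomy, seed=43),
                   taxonomy)
print(era_counts(ages).to_dict())

track = gen_feature_track(synth.genes, synth.genome, spec.track_enrichment,
                          seed=44, name="domains")
grid = make_bins(synth.genome, 5_000)
table = BinDensityTable.from_tracks(
    grid, [track, synth.gene_intervals(era="Ancient"),
           synth.gene_intervals(era="Primate")])
results, _ = correlation_matrix(table)
for r in results:
    print(f"{r.track_a} vs {r.track_b}: rho={r.rho:+.3f} p={r.p:.2e}")

expr = gen_expression(synth.genes, spec)
cat_means = aggregate_by_category(normalize_counts(expr))
(comp,) = compare_groups(cat_means[["testis"]],
                         {g.gene_id: g.era for g in synth.genes},
                         pairs=[("Ancient", "Primate")])
print(f"testis Ancient median={comp.summary_a.median:.0f} "
      f"Primate median={comp.summary_b.median:.0f} p_adj={comp.p_adjusted:.2e}")
```

Output:

```
{'Ancient': 100, 'Metazoan': 100, 'Chordate': 100, 'Mammal': 100, 'Primate': 100}
domains vs Ancient_genes: rho=+0.205 p=1.76e-20
domains vs Primate_genes: rho=-0.036 p=1.09e-01
Ancient_genes vs Primate_genes: rho=-0.049 p=2.90e-02
testis Ancient median=2195 Primate median=109 p_adj=3.56e-34
```

Reading it: age assignment recovered every planted era label (100 genes
per era). The domain track, built with 5× odds around ancient genes,
correlates positively and significantly with ancient-gene density over
the 2,000 genome-wide 5-kb bins (ρ = +0.205) but not with primate-gene
density — the planted association, and only it, is detected. The
expression comparison shows the planted age gradient: ancient genes'
median normalized testis count is ~20× the primate-gene median, and the
Mann–Whitney comparison is significant after Benjamini–Hochberg.

## Command line

```sh
era3d synth --seed 1 --outdir data/            # synthetic dataset
era3d age assign --genes data/genes.tsv --hits data/hits.tsv \
      --taxonomy data/taxonomy.tsv --out ages.tsv
era3d intervals merge --chrom-sizes data/chrom.sizes data/track.bed --out merged.bed
era3d intervals stats --chrom-sizes data/chrom.sizes merged.bed
era3d corr --chrom-sizes data/chrom.sizes --track merged.bed --track genes.bed \
      --bin-size 50000 --out corr.tsv
era3d controls orfs --fasta data/genome.fa --chrom-sizes data/chrom.sizes \
      --exclude genes.bed --out orfs.bed
era3d run --config run.yaml                    # full pipeline + manifest
```

Exit codes: 0 success, 1 user error, 2 internal error.

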