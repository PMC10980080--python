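"""The synthetic-data generators: determinism, sizing, planted-signal
consistency, and round trips through the assignment machinery."""

import numpy as np
import pandas as pd
import pytest

from era3d.ages import assign_ages
from era3d.binning import bin_density, make_bins, spearman
from era3d.errors import ConfigError, SizingError
from era3d.expression import (aggregate_by_category, compare_groups,
                              normalize_counts)
from era3d.synthetic import (ERAS, SyntheticSpec, gen_expression,
                             gen_feature_track, gen_genome, gen_hit_table,
                             toy_taxonomy)

SMALL = dict(chrom_lengths={"chrA": 400_000},
             genes_per_era={e: 10 for e in ERAS})


class TestSpecValidation:
    def test_negative_gene_count_rejected(self):
        with pytest.raises(ConfigError):
            SyntheticSpec(genes_per_era={"Ancient": -1})

    def test_nonpositive_multiplier_rejected(self):
        with pytest.raises(ConfigError):
            SyntheticSpec(track_enrichment={"Ancient": 0.0})

    def test_nonpositive_dispersion_rejected(self):
        with pytest.raises(ConfigError):
            SyntheticSpec(dispersion=0.0)


class TestGenGenome:
    def test_zero_genes_empty_set(self):
        spec = SyntheticSpec(genes_per_era={e: 0 for e in ERAS},
                             chrom_lengths={"chrA": 10_000})
        synth = gen_genome(spec)
        assert synth.genes == []
        assert set(synth.sequence) == {"chrA"}

    def test_seed_determinism_byte_identical(self):
        spec = SyntheticSpec(seed=9, **SMALL)
        a, b = gen_genome(spec), gen_genome(spec)
        assert a.genes == b.genes
        assert a.sequence == b.sequence
        assert list(a.mask) == list(b.mask)

    def test_different_seeds_differ(self):
        a = gen_genome(SyntheticSpec(seed=1, **SMALL), with_sequence=False)
        b = gen_genome(SyntheticSpec(seed=2, **SMALL), with_sequence=False)
        assert a.genes != b.genes

    def test_fixed_length_placement_coverage(self):
        spec = SyntheticSpec(
            chrom_lengths={"chr1": 100_000},
            genes_per_era={"Ancient": 10},
            gene_length_log_mean=float(np.log(300.0)),
            gene_length_log_sigma=0.0,
            min_gene_length=300,
            seed=3,
        )
        synth = gen_genome(spec, with_sequence=False)
        assert len(synth.genes) == 10
        assert all(g.length == 300 for g in synth.genes)
        assert synth.gene_intervals().merge().coverage == 3000  # disjoint

    def test_genes_never_overlap(self):
        synth = gen_genome(SyntheticSpec(seed=5, **SMALL), with_sequence=False)
        by_chrom = {}
        for g in synth.genes:
            by_chrom.setdefault(g.chrom, []).append((g.start, g.end))
        for spans in by_chrom.values():
            spans.sort()
            assert all(a[1] <= b[0] for a, b in zip(spans, spans[1:]))

    def test_too_small_genome_raises_sizing_error(self):
        spec = SyntheticSpec(chrom_lengths={"chrA": 5_000},
                             genes_per_era={"Ancient": 50},
                             gene_length_log_mean=float(np.log(2000.0)))
        with pytest.raises(SizingError):
            gen_genome(spec, with_sequence=False)

    def test_unmasked_intergenic_sequence_exists(self):
        synth = gen_genome(SyntheticSpec(seed=2, **SMALL))
        seq = synth.sequence["chrA"]
        genic = np.zeros(len(seq), dtype=bool)
        for g in synth.genes:
            if g.chrom == "chrA":
                genic[g.start:g.end] = True
        upper_intergenic = sum(
            1 for i, c in enumerate(seq) if not genic[i] and c.isupper()
        )
        assert upper_intergenic > 0


class TestGenFeatureTrack:
    def test_enriched_era_has_higher_gene_coverage(self):
        """Odds multiplier 10 for ancient genes: over 20 seeds, mean track
        coverage of ancient genes exceeds that of primate genes."""
        cov = {"Ancient": [], "Primate": []}
        for seed in range(20):
            synth = gen_genome(SyntheticSpec(seed=seed, **SMALL),
                               with_sequence=False)
            track = gen_feature_track(
                synth.genes, synth.genome, {"Ancient": 10.0}, seed=seed + 900)
            grid = make_bins(synth.genome, 2000)
            dens = bin_density(grid, track)
            for era in cov:
                gene_dens = bin_density(grid, synth.gene_intervals(era=era))
                cov[era].append(float(dens[gene_dens > 0].mean()))
        assert np.mean(cov["Ancient"]) > np.mean(cov["Primate"])

    def test_depleted_era_gives_negative_correlation(self):
        spec = SyntheticSpec(seed=40, chrom_lengths={"chrA": 10_000_000},
                             genes_per_era={e: 100 for e in ERAS})
        synth = gen_genome(spec, with_sequence=False)
        track = gen_feature_track(
            synth.genes, synth.genome, {"Chordate": 0.1}, seed=41)
        grid = make_bins(synth.genome, 5000)  # 2,000 bins
        r = spearman(bin_density(grid, track),
                     bin_density(grid, synth.gene_intervals(era="Chordate")))
        assert r.rho < 0 and r.p < 0.05

    def test_determinism(self):
        synth = gen_genome(SyntheticSpec(seed=1, **SMALL), with_sequence=False)
        t1 = gen_feature_track(synth.genes, synth.genome, {"Ancient": 2.0}, seed=5)
        t2 = gen_feature_track(synth.genes, synth.genome, {"Ancient": 2.0}, seed=5)
        assert list(t1) == list(t2)


class TestGenHitTable:
    def test_roundtrip_full_era_recovery(self):
        spec = SyntheticSpec(seed=11, chrom_lengths={"chrA": 4_000_000},
                             genes_per_era={e: 100 for e in ERAS})
        synth = gen_genome(spec, with_sequence=False)
        taxonomy = toy_taxonomy()
        hits = gen_hit_table(synth.genes, taxonomy, seed=12)
        ages = assign_ages(synth.genes, hits, taxonomy)
        assigned = dict(zip(ages["gene_id"], ages["era_five"]))
        assert all(assigned[g.gene_id] == g.era for g in synth.genes)

    def test_decoys_present_and_above_cutoff(self):
        synth = gen_genome(SyntheticSpec(seed=13, **SMALL), with_sequence=False)
        hits = gen_hit_table(synth.genes, toy_taxonomy(), seed=14, decoy_rate=1.0)
        assert (hits["evalue"] >= 1e-3).any()

    def test_assignments_invariant_to_decoys(self):
        synth = gen_genome(SyntheticSpec(seed=15, **SMALL), with_sequence=False)
        taxonomy = toy_taxonomy()
        clean = gen_hit_table(synth.genes, taxonomy, seed=16, decoy_rate=0.0)
        ages_clean = assign_ages(synth.genes, clean, taxonomy)
        # append supra-cutoff decoys in the most distant stratum
        decoys = clean.iloc[:50].copy()
        decoys["species"] = "Escherichia coli"
        decoys["evalue"] = 0.5
        ages_noisy = assign_ages(synth.genes, pd.concat([clean, decoys]), taxonomy)
        pd.testing.assert_frame_equal(ages_clean, ages_noisy)

    def test_determinism(self):
        synth = gen_genome(SyntheticSpec(seed=17, **SMALL), with_sequence=False)
        t = toy_taxonomy()
        pd.testing.assert_frame_equal(
            gen_hit_table(synth.genes, t, seed=18),
            gen_hit_table(synth.genes, t, seed=18),
        )


class TestGenExpression:
    def test_zero_gene_input_empty_matrix(self):
        spec = SyntheticSpec(genes_per_era={e: 0 for e in ERAS},
                             chrom_lengths={"chrA": 10_000})
        expr = gen_expression([], spec)
        assert expr.counts.shape[0] == 0 and expr.counts.shape[1] > 0

    def test_planted_gradient_recovered_in_medians(self):
        spec = SyntheticSpec(seed=23, chrom_lengths={"chrA": 8_000_000},
                             genes_per_era={e: 200 for e in ERAS})
        synth = gen_genome(spec, with_sequence=False)
        expr = gen_expression(synth.genes, spec)
        cat_means = aggregate_by_category(normalize_counts(expr))
        era = pd.Series({g.gene_id: g.era for g in synth.genes}, name="era")
        med = cat_means.join(era).groupby("era").median().loc[list(ERAS)]
        for category in cat_means.columns:
            v = med[category].to_numpy()
            assert (v[:-1] > v[1:]).all(), f"ordering broken in {category}"

    def test_null_means_calibrated(self):
        """With identical means across eras, the ancient-vs-primate test is
        non-significant at alpha=0.05 in at least 90% of 100 seeds."""
        nonsig = 0
        for seed in range(100):
            spec = SyntheticSpec(
                seed=seed, chrom_lengths={"chrA": 3_000_000},
                genes_per_era={"Ancient": 100, "Primate": 100},
                expression_means={"Ancient": 100.0, "Primate": 100.0},
                categories={"ectoderm": ["cortex"]}, samples_per_tissue=3,
            )
            synth = gen_genome(spec, with_sequence=False)
            expr = gen_expression(synth.genes, spec)
            cat = aggregate_by_category(normalize_counts(expr))
            grouping = {g.gene_id: g.era for g in synth.genes}
            comp = compare_groups(cat, grouping, pairs=[("Ancient", "Primate")])
            nonsig += comp[0].p >= 0.05
        assert nonsig >= 90

    def test_determinism(self):
        spec = SyntheticSpec(seed=29, **SMALL)
        synth = gen_genome(spec, with_sequence=False)
        pd.testing.assert_frame_equal(
            gen_expression(synth.genes, spec).counts,
            gen_expression(synth.genes, spec).counts,
        )
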