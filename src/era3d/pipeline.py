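"""End-to-end orchestration under a single run configuration.

A run executes: age assignment from hit tables, interval pooling and
coverage statistics, binned density correlations at every configured bin
size, intergenic control construction (when sequence is available), and
era-wise expression comparisons. Every output is a TSV/BED/JSON file in
the output directory, accompanied by a manifest recording versions, seed,
parameter echo and input/output checksums so a run is fully reproducible.

Inputs come either from files named in the config or from the synthetic
generator (``synthetic:`` section), which is the default demonstration
mode.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ages import (FIVE_ERA, SCHEMES, assign_ages, compare_age_methods,
                   era_counts, filter_proteins, load_hit_table, Taxonomy)
from .binning import (BinDensityTable, correlation_matrix,
                      correlation_results_frame, make_bins)
from .errors import ConfigError, Era3dError
from .expression import (aggregate_by_category, compare_groups,
                         comparisons_frame, normalize_counts, ExpressionMatrix)
from .genome import GenomeModel
from .intervals import coverage_stats, pool_datasets, read_bed, write_bed
from .io import (read_fasta, read_gene_table, write_fasta, write_gene_table,
                 write_hit_table)
from .orfs import (find_intergenic_orfs, sample_non_orfs, orfs_to_intervals,
                   write_non_orfs_bed, write_orfs_bed)
from .synthetic import (SyntheticSpec, gen_expression, gen_feature_track,
                        gen_genome, gen_hit_table, toy_taxonomy)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Parameters of one pipeline run."""

    outdir: str = "era3d_run"
    seed: int = 0
    bin_sizes: list[int] = field(default_factory=lambda: [20_000, 50_000, 100_000])
    era_scheme: str = "five_era"
    evalue_cutoff: float = 1e-3
    min_aa: int = 40
    max_aa: int = 4000
    min_codons: int = 40
    # how many Non-ORF controls to sample (a seeded subset of ORF lengths,
    # mirroring the random-subset convention for control sets); None = all
    n_non_orfs: int | None = 200
    # synthetic-mode settings; None switches to file inputs
    synthetic: dict[str, Any] | None = field(default_factory=dict)
    # feature tracks to synthesize: name -> {era: multiplier}
    synthetic_tracks: dict[str, dict[str, float]] = field(
        default_factory=lambda: {"domains": {"Ancient": 4.0},
                                 "boundaries": {"Primate": 0.5}}
    )
    inputs: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(b <= 0 for b in self.bin_sizes):
            raise ConfigError(f"bin sizes must be positive: {self.bin_sizes}")
        if self.era_scheme not in SCHEMES:
            raise ConfigError(
                f"unknown era scheme {self.era_scheme!r}; "
                f"choose from {sorted(SCHEMES)}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Stage:
    """Context manager tagging errors with the failing stage name."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        logger.info("stage[%s] start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None and isinstance(exc, Era3dError):
            raise type(exc)(f"stage[{self.name}]: {exc}") from exc
        logger.info("stage[%s] done", self.name)
        return False


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the full pipeline; returns the manifest dictionary."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "era3d_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "parameters": {k: v for k, v in asdict(config).items()},
        "inputs": {},
        "outputs": {},
    }
    synthetic_mode = config.synthetic is not None

    with _Stage("config"):
        if not synthetic_mode:
            required = ["chrom_sizes", "genes", "hits", "taxonomy"]
            for key in required:
                if key not in config.inputs:
                    raise ConfigError(f"missing required input {key!r}")
            for key, path in config.inputs.items():
                if isinstance(path, str) and not Path(path).exists():
                    raise ConfigError(f"input file for {key!r} not found: {path}")
                if isinstance(path, list):
                    for p in path:
                        if not Path(p).exists():
                            raise ConfigError(f"input file for {key!r} not found: {p}")

    # ------------------------------------------------------------------ data
    with _Stage("data"):
        if synthetic_mode:
            spec = SyntheticSpec(seed=config.seed, **(config.synthetic or {}))
            synth = gen_genome(spec, with_sequence=True)
            genome, genes = synth.genome, synth.genes
            sequence = synth.sequence
            taxonomy = toy_taxonomy()
            hits = gen_hit_table(genes, taxonomy, seed=config.seed + 101,
                                 evalue_cutoff=config.evalue_cutoff)
            tracks = [
                gen_feature_track(genes, genome, enrichment, name=name,
                                  seed=config.seed + 211 + i,
                                  window=spec.track_window,
                                  base_coverage=spec.track_base_coverage)
                for i, (name, enrichment) in enumerate(config.synthetic_tracks.items())
            ]
            expr = gen_expression(genes, spec)
            write_gene_table(genes, outdir / "genes.tsv")
            write_hit_table(hits, outdir / "hits.tsv")
            taxonomy.to_tsv(outdir / "taxonomy.tsv")
            write_fasta(sequence, outdir / "genome.fa")
            expr.counts.to_csv(outdir / "counts.tsv", sep="\t")
            for t in tracks:
                write_bed(t, outdir / f"track_{t.name}.bed")
        else:
            genome = GenomeModel.from_chrom_sizes(config.inputs["chrom_sizes"])
            genes = read_gene_table(config.inputs["genes"])
            taxonomy = Taxonomy.from_tsv(
                config.inputs["taxonomy"],
                query_species=config.inputs.get("query_species", "Homo sapiens"),
            )
            hits = load_hit_table(config.inputs["hits"], taxonomy)
            tracks = [read_bed(p, genome) for p in config.inputs.get("tracks", [])]
            sequence = (read_fasta(config.inputs["sequence"])
                        if "sequence" in config.inputs else None)
            expr = None
            if "counts" in config.inputs:
                expr = ExpressionMatrix.from_tsv(
                    config.inputs["counts"],
                    config.inputs["sample_map"],
                    config.inputs.get("categories", {}),
                )
            for key, path in config.inputs.items():
                if isinstance(path, str) and Path(path).exists():
                    manifest["inputs"][key] = _sha256(Path(path))

    # ------------------------------------------------------------------- age
    with _Stage("age"):
        kept = filter_proteins(genes, config.min_aa, config.max_aa)
        ages = assign_ages(kept, hits, taxonomy, config.evalue_cutoff)
        ages.to_csv(outdir / "ages.tsv", sep="\t", index=False)
        counts = era_counts(ages)
        counts.to_frame("n_genes").to_csv(outdir / "era_counts.tsv", sep="\t")
        if synthetic_mode:
            planted = {g.gene_id: g.era for g in kept}
            assigned = dict(zip(ages["gene_id"], ages["era_five"]))
            cmp = compare_age_methods(planted, assigned, FIVE_ERA.labels)
            manifest["age_recovery_fraction_same"] = cmp.fraction_same

    # --------------------------------------------------------------- intervals
    with _Stage("intervals"):
        stats_rows = []
        for t in tracks:
            st = coverage_stats(t.merge(), genome)
            stats_rows.append({"track": t.name, **st.as_dict()})
        if len(tracks) > 1:
            pooled = pool_datasets(tracks, name="pooled")
            stats_rows.append({"track": "pooled",
                               **coverage_stats(pooled, genome).as_dict()})
        pd.DataFrame(stats_rows).to_csv(outdir / "track_stats.tsv", sep="\t",
                                        index=False)

    # ------------------------------------------------------------ correlation
    with _Stage("correlation"):
        scheme = SCHEMES[config.era_scheme]
        era_col = "era_five" if scheme.name == "five_era" else "era_four"
        gene_pos = {g.gene_id: (g.chrom, g.start, g.end) for g in genes}
        era_tracks = []
        from .intervals import IntervalSet
        for era in scheme.labels:
            ids = ages.loc[ages[era_col] == era, "gene_id"]
            recs = [gene_pos[g] for g in ids if g in gene_pos]
            if recs:
                era_tracks.append(IntervalSet.from_records(
                    recs, genome, name=f"{era}_genes"))
        all_results = []
        for bin_size in config.bin_sizes:
            grid = make_bins(genome, bin_size)
            table = BinDensityTable.from_tracks(grid, tracks + era_tracks)
            results, mat = correlation_matrix(table)
            all_results.append(correlation_results_frame(results))
            mat.to_csv(outdir / f"corr_matrix_{bin_size}.tsv", sep="\t")
        pd.concat(all_results, ignore_index=True).to_csv(
            outdir / "correlations.tsv", sep="\t", index=False)

    # ---------------------------------------------------------------- controls
    with _Stage("controls"):
        if sequence is not None:
            from .intervals import IntervalSet
            gene_iv = IntervalSet.from_records(
                [(g.chrom, g.start, g.end) for g in genes], genome, name="genes")
            orfs = find_intergenic_orfs(sequence, genome, exclusions=gene_iv,
                                        min_codons=config.min_codons)
            write_orfs_bed(orfs, outdir / "igen_orfs.bed")
            if orfs:
                exclusions = pool_datasets(
                    [gene_iv, orfs_to_intervals(orfs, genome)], name="excl")
                lengths = [o.length for o in orfs]
                if config.n_non_orfs is not None and len(lengths) > config.n_non_orfs:
                    rng = np.random.default_rng(config.seed + 308)
                    idx = rng.choice(len(lengths), config.n_non_orfs, replace=False)
                    lengths = [lengths[i] for i in np.sort(idx)]
                # longest first: large eligible runs are consumed before
                # placements fragment them
                non_orfs = sample_non_orfs(
                    sequence, genome, sorted(lengths, reverse=True),
                    exclusions=exclusions, seed=config.seed + 307)
                write_non_orfs_bed(non_orfs, outdir / "igen_non_orfs.bed")
            manifest["n_igen_orfs"] = len(orfs)

    # -------------------------------------------------------------- expression
    with _Stage("expression"):
        if expr is not None and len(expr.counts):
            normalized = normalize_counts(expr)
            cat_means = aggregate_by_category(normalized)
            cat_means.to_csv(outdir / "category_means.tsv", sep="\t")
            grouping = dict(zip(ages["gene_id"], ages[era_col]))
            comparisons = compare_groups(cat_means, grouping)
            comparisons_frame(comparisons).to_csv(
                outdir / "expression_comparisons.tsv", sep="\t", index=False)

    with _Stage("manifest"):
        for p in sorted(outdir.iterdir()):
            if p.is_file() and p.name != "manifest.json":
                manifest["outputs"][p.name] = _sha256(p)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                         default=str))
    return manifest
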