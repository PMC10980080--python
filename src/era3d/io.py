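"""File I/O helpers: FASTA sequence and TSV gene/hit tables.

FASTA reading goes through Biopython; soft-masking (lowercase) is
preserved verbatim. Gene tables are plain TSV with the columns
``gene_id isoform_id chrom start end protein_length [era]``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .ages import GeneRecord

GENE_COLUMNS = ["gene_id", "isoform_id", "chrom", "start", "end",
                "protein_length", "era"]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read sequences keyed by record id, preserving case."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequence: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequence.items()]
    SeqIO.write(records, str(path), "fasta")


def write_gene_table(genes: Sequence[GeneRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "isoform_id": [g.isoform_id for g in genes],
            "chrom": [g.chrom for g in genes],
            "start": [g.start for g in genes],
            "end": [g.end for g in genes],
            "protein_length": [g.protein_length for g in genes],
            "era": [g.era if g.era is not None else "" for g in genes],
        }
    ).to_csv(path, sep="\t", index=False)


def read_gene_table(path: str | Path) -> list[GeneRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "isoform_id": str,
                                            "chrom": str})
    genes = []
    for row in df.itertuples(index=False):
        era = getattr(row, "era", None)
        if pd.isna(era) or era == "":
            era = None
        plen = getattr(row, "protein_length", None)
        genes.append(
            GeneRecord(
                gene_id=row.gene_id,
                isoform_id=row.isoform_id,
                chrom=row.chrom,
                start=int(row.start),
                end=int(row.end),
                protein_length=None if pd.isna(plen) else int(plen),
                era=era,
            )
        )
    return genes


def write_hit_table(hits: pd.DataFrame, path: str | Path) -> None:
    hits.to_csv(path, sep="\t", index=False, header=False)
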