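"""Readers and writers for the on-disk formats.

FASTA via Biopython; gene TSS anchors as BED6 (0-based half-open, the
interval is the single TSS base, name = gene id, strand in column 6);
probe manifests, scans, truth manifests and gene sets as headered TSV;
enriched regions as BED6+ with extra columns.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .design import GeneModel


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_gene_bed(path: str | Path) -> list[GeneModel]:
    """Read gene TSS anchors from BED6: chrom, tss, tss+1, gene_id, score, strand."""
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"BED6 line has {len(fields)} fields: {line!r}")
            chrom, start, _end, name, _score, strand = fields[:6]
            genes.append(GeneModel(gene_id=name, chrom=chrom, tss=int(start), strand=strand))
    return genes


def write_gene_bed(genes: list[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.tss}\t{g.tss + 1}\t{g.gene_id}\t0\t{g.strand}\n")


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_gene_set(path: str | Path) -> set[str]:
    """One gene id per line."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def write_gene_set(genes: set[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(g + "\n")


def write_regions_bed(regions: pd.DataFrame, path: str | Path, strand: str = ".") -> None:
    """Enriched regions as BED6+2: chrom start end gene_id peak_signal strand n_probes mean_signal."""
    with open(path, "w") as fh:
        for _, r in regions.iterrows():
            fh.write(
                f"{r['chrom']}\t{r['start']}\t{r['end']}\t{r['gene_id']}\t"
                f"{r['peak_signal']:.4f}\t{strand}\t{r['n_probes']}\t{r['mean_signal']:.4f}\n"
            )
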