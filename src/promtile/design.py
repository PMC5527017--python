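"""Promoter tiling-probe design.

Each gene is anchored at its (putative) transcription start site and a
design window spanning 5.5 kb upstream to 2.5 kb downstream of the TSS is
tiled with 60-mer probes at an average start-to-start spacing of 205 bp.
For a full-length 8000 bp window this places exactly 40 probes: candidate
starts fall at multiples of the spacing, and the final probe — which would
otherwise overrun the window — is left-shifted to end flush with the
window edge. All coordinates are 0-based, half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

DEFAULT_UPSTREAM = 5500
DEFAULT_DOWNSTREAM = 2500
DEFAULT_PROBE_LEN = 60
DEFAULT_SPACING = 205

PROBE_COLUMNS = [
    "probe_id",
    "gene_id",
    "chrom",
    "start",
    "end",
    "offset_from_tss",
    "sequence",
]


@dataclass(frozen=True)
class GeneModel:
    """A gene's TSS anchor: chromosome, 0-based TSS coordinate, strand."""

    gene_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError(f"gene {self.gene_id}: tss must be >= 0, got {self.tss}")
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )


@dataclass(frozen=True)
class DesignWindow:
    """Genomic interval tiled for one gene, oriented by its strand."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    upstream_extent: int = DEFAULT_UPSTREAM
    downstream_extent: int = DEFAULT_DOWNSTREAM

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ProbeRecord:
    """One tiling probe; sequence is read from the + genomic strand."""

    probe_id: str
    gene_id: str
    chrom: str
    start: int
    end: int
    offset_from_tss: int
    sequence: str = ""


def design_window(
    gene: GeneModel,
    upstream: int = DEFAULT_UPSTREAM,
    downstream: int = DEFAULT_DOWNSTREAM,
    chrom_length: int | None = None,
) -> DesignWindow:
    """Compute the tiling window around a gene's TSS.

    For a + strand gene the window is ``[tss - upstream, tss + downstream)``;
    for a - strand gene the extents mirror: ``[tss - downstream, tss + upstream)``.
    Windows overhanging a chromosome edge are clipped with a warning; a window
    entirely off-chromosome is an error.
    """
    if gene.strand == "+":
        start, end = gene.tss - upstream, gene.tss + downstream
    else:
        start, end = gene.tss - downstream, gene.tss + upstream

    clipped_start = max(start, 0)
    clipped_end = end if chrom_length is None else min(end, chrom_length)
    if clipped_end <= clipped_start:
        raise ValueError(
            f"design window for gene {gene.gene_id} lies entirely outside "
            f"chromosome {gene.chrom}"
        )
    if clipped_start != start or clipped_end != end:
        warnings.warn(
            f"design window for gene {gene.gene_id} clipped to "
            f"[{clipped_start}, {clipped_end}) at chromosome bounds",
            stacklevel=2,
        )
    return DesignWindow(
        gene_id=gene.gene_id,
        chrom=gene.chrom,
        start=clipped_start,
        end=clipped_end,
        strand=gene.strand,
        upstream_extent=upstream,
        downstream_extent=downstream,
    )


def _candidate_starts(length: int, probe_len: int, spacing: int) -> list[int]:
    """Window-relative probe starts: k*spacing, final probe shifted flush."""
    starts = []
    for k in range(0, (length - 1) // spacing + 1):
        s = k * spacing
        if s + probe_len > length:
            s = length - probe_len
        if not starts or s != starts[-1]:
            starts.append(s)
    return starts


def tile_probes(
    window: DesignWindow,
    chrom_sequence: str | None = None,
    probe_len: int = DEFAULT_PROBE_LEN,
    spacing: int = DEFAULT_SPACING,
    tss: int | None = None,
) -> list[ProbeRecord]:
    """Tile probes across a design window.

    Candidate starts are ``k * spacing`` for ``k = 0 .. floor((L-1)/spacing)``;
    a probe that would overrun the window end is left-shifted to end exactly
    at the window end, and duplicate starts are collapsed. An 8000 bp window
    with 60-mers at 205 bp spacing therefore yields 40 probes, the last one
    shifted from start 7995 to 7940.

    Tiling is anchored at the window's 5' end in gene orientation, so the
    design of a - strand gene is the exact mirror image of a + strand one;
    probes are nonetheless reported sorted by genomic start, with sequences
    read from the + strand (the array hybridizes both).

    ``tss`` (genomic) is needed to fill ``offset_from_tss``; when omitted it
    is reconstructed from the window extents. Offsets are strand-aware:
    negative values lie upstream of the TSS in gene orientation.
    """
    length = window.length
    if length < probe_len:
        warnings.warn(
            f"window for gene {window.gene_id} shorter than probe length "
            f"({length} < {probe_len}); no probes designed",
            stacklevel=2,
        )
        return []

    if tss is None:
        if window.strand == "+":
            tss = window.start + window.upstream_extent
        else:
            tss = window.start + window.downstream_extent

    rel_starts = _candidate_starts(length, probe_len, spacing)
    if window.strand == "-":
        rel_starts = sorted({length - probe_len - s for s in rel_starts})

    probes = []
    for i, rel_start in enumerate(rel_starts):
        start = window.start + rel_start
        end = start + probe_len
        if window.strand == "+":
            offset = start - tss
        else:
            offset = tss - end
        seq = "" if chrom_sequence is None else chrom_sequence[start:end]
        probes.append(
            ProbeRecord(
                probe_id=f"{window.gene_id}_p{i:02d}",
                gene_id=window.gene_id,
                chrom=window.chrom,
                start=start,
                end=end,
                offset_from_tss=offset,
                sequence=seq,
            )
        )
    return probes


def uniqueness_filter(
    probes: list[ProbeRecord],
    max_base_fraction: float = 0.70,
) -> tuple[list[ProbeRecord], pd.DataFrame]:
    """Drop duplicate and low-complexity probes across the whole design.

    A probe is dropped when its sequence occurs more than once anywhere in
    the design space (every copy is dropped), or when a single nucleotide
    makes up more than ``max_base_fraction`` of the sequence. Returns the
    retained probes and a drop report (probe_id, gene_id, reason).
    """
    counts: dict[str, int] = {}
    for p in probes:
        counts[p.sequence.upper()] = counts.get(p.sequence.upper(), 0) + 1

    retained, dropped = [], []
    for p in probes:
        seq = p.sequence.upper()
        if counts[seq] > 1:
            dropped.append((p.probe_id, p.gene_id, "duplicate"))
            continue
        if seq and max(seq.count(b) for b in "ACGT") / len(seq) > max_base_fraction:
            dropped.append((p.probe_id, p.gene_id, "low-complexity"))
            continue
        retained.append(p)
    report = pd.DataFrame(dropped, columns=["probe_id", "gene_id", "reason"])
    return retained, report


def design_probes(
    genes: list[GeneModel],
    genome: dict[str, str],
    upstream: int = DEFAULT_UPSTREAM,
    downstream: int = DEFAULT_DOWNSTREAM,
    probe_len: int = DEFAULT_PROBE_LEN,
    spacing: int = DEFAULT_SPACING,
    apply_uniqueness_filter: bool = True,
) -> pd.DataFrame:
    """Design the full probe set for a gene list against a genome.

    Convenience wrapper: windows each gene, tiles it, and (optionally)
    applies the cross-design uniqueness/complexity filter. Returns a probe
    manifest DataFrame with :data:`PROBE_COLUMNS`.
    """
    all_probes: list[ProbeRecord] = []
    for gene in genes:
        if gene.chrom not in genome:
            raise KeyError(f"gene {gene.gene_id} references unknown chromosome {gene.chrom}")
        win = design_window(gene, upstream, downstream, chrom_length=len(genome[gene.chrom]))
        all_probes.extend(
            tile_probes(win, genome[gene.chrom], probe_len, spacing, tss=gene.tss)
        )
    if apply_uniqueness_filter:
        all_probes, _ = uniqueness_filter(all_probes)
    return probes_to_frame(all_probes)


def probes_to_frame(probes: list[ProbeRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (p.probe_id, p.gene_id, p.chrom, p.start, p.end, p.offset_from_tss, p.sequence)
            for p in probes
        ],
        columns=PROBE_COLUMNS,
    )
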