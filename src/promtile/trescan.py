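"""Nuclear-receptor response-element scanning.

Thyroid hormone receptor binds DNA (as a heterodimer with RXR) at response
elements built from two AGGTCA-family hexamer half-sites. The canonical
thyroid-hormone response element (TRE) is a DR4: a direct repeat of the two
half-sites separated by a 4 bp spacer. This module is a transparent
consensus/PWM scanner over direct (DR), inverted (IR) and everted (ER)
arrangements with configurable spacer range and per-half / total mismatch
budgets, scanning both strands. The default budgets (<= 3 mismatches per
half-site, <= 4 total against AGGTCA) accept the classically reported
functional DR4 variants while rejecting random sequence at a useful rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONSENSUS_HALFSITE = "AGGTCA"
HIT_COLUMNS = [
    "sequence_id",
    "start",
    "strand",
    "arrangement",
    "spacer",
    "half1_seq",
    "half2_seq",
    "mm1",
    "mm2",
    "total_score",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class HalfSiteMotif:
    """Hexamer half-site model: consensus string or 4x6 weight matrix.

    ``mode`` selects scoring: "mismatch" (Hamming distance to the consensus,
    N always counts as a mismatch) or "log-odds" (sum of column
    log(weight / 0.25); needs ``matrix`` with columns summing to 1, rows in
    A, C, G, T order).
    """

    consensus: str = CONSENSUS_HALFSITE
    matrix: np.ndarray | None = None
    mode: str = "mismatch"

    def __post_init__(self) -> None:
        if len(self.consensus) != 6:
            raise ValueError(f"consensus must be a hexamer, got {self.consensus!r}")
        if self.mode not in ("mismatch", "log-odds"):
            raise ValueError(f"unknown scoring mode {self.mode!r}")
        if self.mode == "log-odds":
            if self.matrix is None:
                raise ValueError("log-odds mode requires a weight matrix")
            m = np.asarray(self.matrix, dtype=float)
            if m.shape != (4, 6) or (m < 0).any():
                raise ValueError("weight matrix must be 4x6 nonnegative")
            if not np.allclose(m.sum(axis=0), 1.0):
                raise ValueError("weight matrix columns must sum to 1")

    def reverse_complement(self) -> "HalfSiteMotif":
        matrix = None
        if self.matrix is not None:
            matrix = np.asarray(self.matrix)[::-1, ::-1].copy()
        return HalfSiteMotif(reverse_complement(self.consensus), matrix, self.mode)


@dataclass(frozen=True)
class ArrangementSpec:
    """Half-site geometry: direct, inverted or everted repeat plus spacer range."""

    kind: str = "DR"
    spacer_min: int = 4
    spacer_max: int = 4

    def __post_init__(self) -> None:
        if self.kind not in ("DR", "IR", "ER"):
            raise ValueError(f"arrangement must be DR, IR or ER, got {self.kind!r}")
        if not (0 <= self.spacer_min <= self.spacer_max <= 10):
            raise ValueError(
                f"spacer range must satisfy 0 <= min <= max <= 10, got "
                f"[{self.spacer_min}, {self.spacer_max}]"
            )

    @property
    def label(self) -> str:
        return self.kind


DR4 = ArrangementSpec("DR", 4, 4)

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def score_halfsite(hexamer: str, motif: HalfSiteMotif = HalfSiteMotif()) -> float:
    """Score one hexamer against the half-site model.

    Mismatch mode returns the Hamming distance to the consensus (N counts
    as a mismatch); log-odds mode returns the summed column log-odds
    against a uniform background, with N taking each column's worst score.
    """
    hexamer = hexamer.upper()
    if len(hexamer) != 6:
        raise ValueError(f"half-site must be 6 bp, got {len(hexamer)}")
    if motif.mode == "mismatch":
        return float(sum(a != b for a, b in zip(hexamer, motif.consensus.upper())))
    m = np.asarray(motif.matrix, dtype=float)
    with np.errstate(divide="ignore"):
        logodds = np.log(m / 0.25)
    score = 0.0
    for j, base in enumerate(hexamer):
        idx = _BASE_INDEX.get(base)
        score += logodds[:, j].min() if idx is None else logodds[idx, j]
    return float(score)


def _halfsite_models(motif: HalfSiteMotif, arrangement: ArrangementSpec):
    """Half-site models for positions 1 and 2 under an arrangement.

    DR: both half-sites read in the motif orientation on the scanned strand.
    IR (palindrome): the downstream half is the reverse complement.
    ER (everted): the upstream half is the reverse complement.
    """
    if arrangement.kind == "DR":
        return motif, motif
    if arrangement.kind == "IR":
        return motif, motif.reverse_complement()
    return motif.reverse_complement(), motif


def _scan_one_strand(
    sequence: str,
    motif: HalfSiteMotif,
    arrangement: ArrangementSpec,
    max_mm_per_half: int,
    max_mm_total: int,
) -> list[tuple]:
    seq = sequence.upper()
    m1_model, m2_model = _halfsite_models(motif, arrangement)
    hits = []
    for spacer in range(arrangement.spacer_min, arrangement.spacer_max + 1):
        span = 12 + spacer
        for i in range(0, len(seq) - span + 1):
            h1 = seq[i : i + 6]
            h2 = seq[i + 6 + spacer : i + 12 + spacer]
            mm1 = score_halfsite(h1, m1_model)
            mm2 = score_halfsite(h2, m2_model)
            if motif.mode == "mismatch":
                if mm1 > max_mm_per_half or mm2 > max_mm_per_half:
                    continue
                if mm1 + mm2 > max_mm_total:
                    continue
                total = -(mm1 + mm2)
            else:
                total = mm1 + mm2
            hits.append((i, spacer, h1, h2, mm1, mm2, total))
    return hits


def scan_sequence(
    sequence: str,
    motif: HalfSiteMotif = HalfSiteMotif(),
    arrangement: ArrangementSpec = DR4,
    max_mm_per_half: int = 3,
    max_mm_total: int = 4,
    both_strands: bool = True,
    sequence_id: str = "seq",
) -> pd.DataFrame:
    """Report every qualifying two-half-site element in a sequence.

    All (offset, spacer) combinations in range are tested; overlapping hits
    are all reported. The minus strand is scanned on the reverse complement
    and hit starts are mapped back to plus-strand coordinates (``start`` is
    always the leftmost base of the hit on the plus strand; the hit spans
    ``12 + spacer`` bp). In mismatch mode ``total_score`` is the negated
    total mismatch count, so larger is always better.
    """
    rows = []
    for i, spacer, h1, h2, mm1, mm2, total in _scan_one_strand(
        sequence, motif, arrangement, max_mm_per_half, max_mm_total
    ):
        rows.append((sequence_id, i, "+", arrangement.label, spacer, h1, h2, mm1, mm2, total))
    if both_strands:
        rc = reverse_complement(sequence)
        for i, spacer, h1, h2, mm1, mm2, total in _scan_one_strand(
            rc, motif, arrangement, max_mm_per_half, max_mm_total
        ):
            start = len(sequence) - (i + 12 + spacer)
            rows.append(
                (sequence_id, start, "-", arrangement.label, spacer, h1, h2, mm1, mm2, total)
            )
    hits = pd.DataFrame(rows, columns=HIT_COLUMNS)
    return hits.sort_values(["start", "strand", "spacer"], kind="stable").reset_index(
        drop=True
    )


def scan_gene_set(
    sequences: dict[str, str],
    motif: HalfSiteMotif = HalfSiteMotif(),
    arrangement: ArrangementSpec = DR4,
    max_mm_per_half: int = 3,
    max_mm_total: int = 4,
    both_strands: bool = True,
    max_n_fraction: float = 0.10,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Scan one promoter window per gene and tabulate element presence.

    Returns (per-gene table, all hits, summary). The per-gene table carries
    n_hits, the best hit's position/score, and a flag for sequences with
    more than ``max_n_fraction`` ambiguous bases. The summary counts genes
    with at least one hit and the corresponding fraction.
    """
    ids = list(sequences)
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate sequence ids")
    per_gene_rows = []
    all_hits = []
    for seq_id, seq in sequences.items():
        hits = scan_sequence(
            seq, motif, arrangement, max_mm_per_half, max_mm_total, both_strands, seq_id
        )
        all_hits.append(hits)
        n_frac = (seq.upper().count("N") / len(seq)) if seq else 0.0
        if hits.empty:
            per_gene_rows.append((seq_id, 0, None, None, None, n_frac > max_n_fraction))
        else:
            best = hits.loc[hits["total_score"].idxmax()]
            per_gene_rows.append(
                (
                    seq_id,
                    len(hits),
                    int(best["start"]),
                    best["strand"],
                    float(best["total_score"]),
                    n_frac > max_n_fraction,
                )
            )
    per_gene = pd.DataFrame(
        per_gene_rows,
        columns=["gene_id", "n_hits", "best_start", "best_strand", "best_score", "high_n"],
    )
    hits_table = (
        pd.concat(all_hits, ignore_index=True) if all_hits else pd.DataFrame(columns=HIT_COLUMNS)
    )
    n_genes = len(per_gene)
    n_with_hit = int((per_gene["n_hits"] > 0).sum())
    summary = {
        "n_genes": n_genes,
        "n_with_hit": n_with_hit,
        "frac_with_hit": n_with_hit / n_genes if n_genes else 0.0,
        "pct_with_hit": round(100 * n_with_hit / n_genes) if n_genes else 0,
    }
    return per_gene, hits_table, summary
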