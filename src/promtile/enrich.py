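"""Enriched-region calling on smoothed promoter tracks.

The replicate-averaged log-ratio of each gene's probe track is smoothed
with a 1400 bp sliding window centered on each probe, an array-wide
threshold of ``center + 2.5 * SD`` of the smoothed signal is computed
(median center by default — robust to the enriched tail), and maximal runs
of at least 3 consecutive above-threshold probes within one gene's window
are reported as enriched regions. A gene is called bound when it carries at
least one region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_WINDOW_BP = 1400
DEFAULT_SD_MULTIPLIER = 2.5
DEFAULT_MIN_RUN = 3

REGION_COLUMNS = [
    "gene_id",
    "chrom",
    "start",
    "end",
    "n_probes",
    "peak_signal",
    "mean_signal",
]


@dataclass(frozen=True)
class ThresholdSpec:
    """How the enrichment threshold is derived from the smoothed signal.

    threshold = center(values) + sd_multiplier * sd(values), where the
    values are all smoothed probe signals on the array (array-wide scope:
    a per-gene SD on ~40 probes would be unstable and inflated by true
    peaks). ``center_statistic`` is "median" (default) or "mean".
    """

    sd_multiplier: float = DEFAULT_SD_MULTIPLIER
    min_run: int = DEFAULT_MIN_RUN
    center_statistic: str = "median"

    def __post_init__(self) -> None:
        if self.sd_multiplier <= 0:
            raise ValueError(f"sd_multiplier must be > 0, got {self.sd_multiplier}")
        if self.min_run < 1:
            raise ValueError(f"min_run must be >= 1, got {self.min_run}")
        if self.center_statistic not in ("median", "mean"):
            raise ValueError(f"unknown center_statistic {self.center_statistic!r}")


def smooth_track(
    centers: np.ndarray, values: np.ndarray, window_bp: float = DEFAULT_WINDOW_BP
) -> np.ndarray:
    """Sliding-window mean over one gene's probe track.

    Each probe's smoothed value is the mean of ``values`` over all probes
    whose centers lie within ``window_bp / 2`` of that probe's center
    (inclusive). ``centers`` must be sorted ascending.
    """
    centers = np.asarray(centers, dtype=float)
    values = np.asarray(values, dtype=float)
    if window_bp <= 0:
        raise ValueError(f"window_bp must be > 0, got {window_bp}")
    if len(centers) == 0:
        return np.empty(0)
    if np.any(np.diff(centers) < 0):
        raise ValueError("probe centers must be sorted ascending")
    half = window_bp / 2.0
    lo = np.searchsorted(centers, centers - half, side="left")
    hi = np.searchsorted(centers, centers + half, side="right")
    csum = np.concatenate([[0.0], np.cumsum(values)])
    return (csum[hi] - csum[lo]) / (hi - lo)


def compute_threshold(
    smoothed_values: np.ndarray, spec: ThresholdSpec = ThresholdSpec()
) -> float:
    """Array-wide enrichment threshold: center + multiplier * SD."""
    v = np.asarray(smoothed_values, dtype=float)
    if len(v) < 2:
        raise ValueError("need at least 2 smoothed values to set a threshold")
    center = np.median(v) if spec.center_statistic == "median" else np.mean(v)
    sd = np.std(v)
    if sd == 0:
        warnings.warn("zero variance in smoothed signal; threshold = center", stacklevel=2)
        return float(center)
    return float(center + spec.sd_multiplier * sd)


def _runs_above(values: np.ndarray, threshold: float, merge_gap: int = 0):
    """Maximal runs of strictly above-threshold positions, optionally merging
    runs separated by at most ``merge_gap`` below-threshold positions."""
    above = np.asarray(values) > threshold
    runs = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(above)))
    if merge_gap > 0 and len(runs) > 1:
        merged = [runs[0]]
        for s, e in runs[1:]:
            if s - merged[-1][1] <= merge_gap:
                merged[-1] = (merged[-1][0], e)
            else:
                merged.append((s, e))
        runs = merged
    return runs


def call_enriched_regions(
    gene_probes: pd.DataFrame,
    threshold: float,
    min_run: int = DEFAULT_MIN_RUN,
    merge_gap: int = 0,
    signal_col: str = "smoothed",
) -> pd.DataFrame:
    """Call enriched regions in one gene's position-sorted probe track.

    "Consecutive" means adjacent in the gene's tiling order; runs never
    cross gene boundaries. Each maximal run of at least ``min_run`` probes
    with signal strictly above ``threshold`` becomes a region spanning the
    first qualifying probe's start to the last qualifying probe's end. Two
    runs separated by a sub-threshold probe are distinct regions unless
    ``merge_gap`` > 0 allows bridging.
    """
    if gene_probes.empty:
        return pd.DataFrame(columns=REGION_COLUMNS)
    if gene_probes["gene_id"].nunique() > 1:
        raise ValueError("call_enriched_regions operates on a single gene's probes")
    values = gene_probes[signal_col].to_numpy(dtype=float)
    rows = []
    for s, e in _runs_above(values, threshold, merge_gap):
        if e - s < min_run:
            continue
        block = gene_probes.iloc[s:e]
        rows.append(
            (
                block["gene_id"].iloc[0],
                block["chrom"].iloc[0],
                int(block["start"].min()),
                int(block["end"].max()),
                e - s,
                float(block[signal_col].max()),
                float(block[signal_col].mean()),
            )
        )
    return pd.DataFrame(rows, columns=REGION_COLUMNS)


def assign_genes(regions: pd.DataFrame) -> tuple[set[str], pd.DataFrame]:
    """Deduplicate regions to a bound-gene set, keeping each gene's best region.

    A gene is bound iff it carries >= 1 enriched region; the region with the
    highest peak signal represents the gene in reports.
    """
    if regions.empty:
        return set(), pd.DataFrame(columns=REGION_COLUMNS)
    best = (
        regions.sort_values("peak_signal", ascending=False)
        .drop_duplicates("gene_id")
        .sort_values("gene_id")
        .reset_index(drop=True)
    )
    return set(best["gene_id"]), best


def call_bound_genes(
    probe_table: pd.DataFrame,
    window_bp: float = DEFAULT_WINDOW_BP,
    spec: ThresholdSpec = ThresholdSpec(),
    merge_gap: int = 0,
) -> dict:
    """Full calling pass over a replicate-averaged, normalized probe table.

    ``probe_table`` needs columns probe_id, gene_id, chrom, start, end, M.
    Smoothing runs per gene over position-sorted probes; the threshold is
    computed once over all smoothed values on the array. Returns a dict with
    the smoothed table, threshold, regions, bound gene set, and best region
    per gene.
    """
    table = probe_table.copy()
    table["center"] = (table["start"] + table["end"]) / 2.0
    table = table.sort_values(["gene_id", "center"], kind="stable").reset_index(drop=True)
    parts = [
        pd.Series(smooth_track(g["center"].to_numpy(), g["M"].to_numpy(), window_bp), index=g.index)
        for _, g in table.groupby("gene_id", sort=False)
    ]
    table["smoothed"] = pd.concat(parts)
    threshold = compute_threshold(table["smoothed"].to_numpy(), spec)
    region_frames = [
        call_enriched_regions(g, threshold, min_run=spec.min_run, merge_gap=merge_gap)
        for _, g in table.groupby("gene_id", sort=False)
    ]
    regions = (
        pd.concat([r for r in region_frames if not r.empty], ignore_index=True)
        if any(not r.empty for r in region_frames)
        else pd.DataFrame(columns=REGION_COLUMNS)
    )
    bound, best = assign_genes(regions)
    return {
        "smoothed": table,
        "threshold": threshold,
        "regions": regions,
        "bound_genes": bound,
        "best_regions": best,
    }
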