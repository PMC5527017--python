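"""Two-channel array preprocessing.

The raw measurement for each probe is a pair of channel intensities: Cy5
(immunoprecipitated ChIP material) and Cy3 (input genomic DNA), each with a
foreground and a local-background estimate, plus a scanner quality flag.
Preprocessing follows the standard two-color workflow: drop flagged probes,
subtract background with a floor so logs stay finite, convert to (M, A)
log-ratio/log-intensity pairs, remove intensity-dependent dye bias by loess
regression of M on A within each array, match A distributions between
replicate arrays of the same treatment by quantile normalization (M values
untouched), and average replicates probe-wise.

All operations take and return pandas DataFrames with documented columns;
probe identity travels in a ``probe_id`` column.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

logger = logging.getLogger(__name__)

FLAG_OK = "ok"
FLAG_LOW_QUALITY = "low_quality"

MEASUREMENT_COLUMNS = [
    "probe_id",
    "gene_id",
    "chrom",
    "start",
    "end",
    "cy3_fg",
    "cy3_bg",
    "cy5_fg",
    "cy5_bg",
    "flag",
]

DEFAULT_FLOOR = 1.0
DEFAULT_LOESS_SPAN = 0.3
MIN_PROBES_FOR_LOESS = 50


def filter_flagged(measurements: pd.DataFrame) -> pd.DataFrame:
    """Retain only probes whose quality flag is ``ok``.

    Raises ``ValueError`` when every probe is flagged (nothing to analyze).
    """
    retained = measurements[measurements["flag"] == FLAG_OK].reset_index(drop=True)
    n_removed = len(measurements) - len(retained)
    if retained.empty:
        raise ValueError(
            f"all {len(measurements)} probes are flagged low-quality; nothing to analyze"
        )
    if n_removed:
        logger.info("removed %d flagged probes (%d retained)", n_removed, len(retained))
    return retained


def subtract_background(
    measurements: pd.DataFrame, floor_value: float = DEFAULT_FLOOR
) -> pd.DataFrame:
    """Per-channel ``fg - bg`` with a floor.

    Background over-subtraction (bg > fg) would produce non-positive
    intensities whose logarithm is undefined; such values are replaced by
    ``floor_value``. Adds ``cy5_corr`` and ``cy3_corr`` columns.
    """
    out = measurements.copy()
    out["cy5_corr"] = np.maximum(out["cy5_fg"] - out["cy5_bg"], floor_value)
    out["cy3_corr"] = np.maximum(out["cy3_fg"] - out["cy3_bg"], floor_value)
    return out


def compute_ma(cy5_corr, cy3_corr) -> tuple[np.ndarray, np.ndarray]:
    """M = log2(Cy5/Cy3), A = mean log2 intensity of the two channels."""
    l5 = np.log2(np.asarray(cy5_corr, dtype=float))
    l3 = np.log2(np.asarray(cy3_corr, dtype=float))
    return l5 - l3, 0.5 * (l5 + l3)


def loess_normalize_within(
    M: np.ndarray, A: np.ndarray, span: float = DEFAULT_LOESS_SPAN
) -> np.ndarray:
    """Within-array dye-bias correction: ``M' = M - loess(M ~ A)``.

    Locally weighted regression of M on A captures the smooth
    intensity-dependent trend produced by unequal dye incorporation and
    scanner response; subtracting the fit centers M on zero across the whole
    intensity range. Arrays with fewer than 50 probes are returned unchanged
    with a warning — the fit would be meaningless.
    """
    M = np.asarray(M, dtype=float)
    A = np.asarray(A, dtype=float)
    if not (0 < span <= 1):
        raise ValueError(f"loess span must be in (0, 1], got {span}")
    if not (np.isfinite(M).all() and np.isfinite(A).all()):
        raise ValueError("non-finite M or A values; apply background floor first")
    if len(M) < MIN_PROBES_FOR_LOESS:
        warnings.warn(
            f"only {len(M)} probes (< {MIN_PROBES_FOR_LOESS}); skipping loess",
            stacklevel=2,
        )
        return M.copy()
    trend = lowess(M, A, frac=span, return_sorted=False)
    return M - trend


def normalize_between_arrays(arrays: list[pd.DataFrame]) -> list[pd.DataFrame]:
    """Quantile-match A values across replicate arrays; M is untouched.

    Each array's sorted A vector is replaced by the across-array mean of the
    sorted vectors, values being assigned back by rank. Tied A values within
    an array all receive the mean of the reference values at the tied
    positions, so the result is order-independent and deterministic.

    Every array must carry the same probe set (``probe_id`` column);
    a mismatch raises ``ValueError`` listing the offending probes.
    """
    if len(arrays) < 2:
        raise ValueError("between-array normalization needs at least 2 arrays")
    ref_ids = set(arrays[0]["probe_id"])
    for i, arr in enumerate(arrays[1:], start=1):
        ids = set(arr["probe_id"])
        if ids != ref_ids:
            offenders = sorted((ids ^ ref_ids))[:20]
            raise ValueError(
                f"array {i} probe set differs from array 0; offending probes "
                f"(up to 20): {offenders}"
            )

    n = len(arrays[0])
    sorted_A = np.column_stack([np.sort(arr["A"].to_numpy(dtype=float)) for arr in arrays])
    reference = sorted_A.mean(axis=1)

    out = []
    for arr in arrays:
        A = arr["A"].to_numpy(dtype=float)
        order = np.argsort(A, kind="stable")
        assigned = np.empty(n, dtype=float)
        assigned[order] = reference
        # ties: average the reference values assigned to equal A
        tied = pd.Series(assigned).groupby(pd.Series(A)).transform("mean").to_numpy()
        new = arr.copy()
        new["A"] = tied
        out.append(new)
    return out


def average_replicates(arrays: list[pd.DataFrame]) -> pd.DataFrame:
    """Probe-wise mean of M (and A) over replicate arrays of one treatment.

    A probe absent from some replicates (e.g. flagged on one slide only) is
    averaged over the replicates that retain it; a note is logged. Returns
    columns probe_id, M, A, n_replicates.
    """
    if not arrays:
        raise ValueError("no arrays to average")
    stacked = pd.concat(
        [arr[["probe_id", "M", "A"]] for arr in arrays], ignore_index=True
    )
    grouped = stacked.groupby("probe_id", sort=False).agg(
        M=("M", "mean"), A=("A", "mean"), n_replicates=("M", "size")
    )
    partial = (grouped["n_replicates"] < len(arrays)).sum()
    if partial:
        logger.info(
            "%d probes missing from some replicates; averaged over available ones",
            partial,
        )
    return grouped.reset_index()


def normalize_array(
    measurements: pd.DataFrame,
    floor_value: float = DEFAULT_FLOOR,
    span: float = DEFAULT_LOESS_SPAN,
) -> pd.DataFrame:
    """Full within-array pipeline for one scan: flags -> background -> MA -> loess.

    Returns the retained probes with normalized ``M`` and ``A`` columns,
    preserving any annotation columns (gene_id, coordinates) present in the
    input.
    """
    kept = filter_flagged(measurements)
    corrected = subtract_background(kept, floor_value=floor_value)
    M, A = compute_ma(corrected["cy5_corr"], corrected["cy3_corr"])
    corrected["A"] = A
    corrected["M"] = loess_normalize_within(M, A, span=span)
    return corrected.drop(columns=["cy5_corr", "cy3_corr"])


def normalize_condition(
    scans: list[pd.DataFrame],
    floor_value: float = DEFAULT_FLOOR,
    span: float = DEFAULT_LOESS_SPAN,
) -> pd.DataFrame:
    """Normalize all replicate scans of one treatment and average them.

    Within-array steps run per scan; the between-array A-quantile step runs
    on the probes common to every replicate (flag filtering can differ
    between slides), after which M (and A) are averaged probe-wise over all
    replicates each probe survived in. Annotation columns are re-attached
    from the first scan that carries each probe.
    """
    normalized = [normalize_array(s, floor_value=floor_value, span=span) for s in scans]

    if len(normalized) > 1:
        common = set(normalized[0]["probe_id"])
        for arr in normalized[1:]:
            common &= set(arr["probe_id"])
        subsets = [
            arr[arr["probe_id"].isin(common)].sort_values("probe_id").reset_index(drop=True)
            for arr in normalized
        ]
        matched = normalize_between_arrays(subsets)
        rest = [
            arr[~arr["probe_id"].isin(common)] for arr in normalized
        ]
        normalized = [
            pd.concat([m, r], ignore_index=True) for m, r in zip(matched, rest)
        ]

    averaged = average_replicates(normalized)

    annot_cols = [c for c in ("gene_id", "chrom", "start", "end") if c in scans[0].columns]
    if annot_cols:
        annotations = (
            pd.concat([s[["probe_id"] + annot_cols] for s in scans], ignore_index=True)
            .drop_duplicates("probe_id")
        )
        averaged = averaged.merge(annotations, on="probe_id", how="left")
    return averaged
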