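"""Call-level and variant-level quality filters, plus a depth-track scanner.

Filter semantics follow strict "lower than" thresholds: a call with DP 10
and GQ 30 passes the default filters. The canonical order is call filters
first, then variant-level filters (call rate, indel exclusion); variant
call rates are computed on the post-call-filter matrix.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .core import GenotypeMatrix, Interval, MISSING

logger = logging.getLogger(__name__)


def apply_call_filters(
    matrix: GenotypeMatrix, min_depth: int = 10, min_quality: int = 30
) -> GenotypeMatrix:
    """Set dosage to missing for calls with depth < min_depth or
    quality < min_quality; dimensions unchanged."""
    if min_depth < 0 or min_quality < 0:
        raise ValueError("filter thresholds must be non-negative")
    out = matrix.copy()
    fail = (out.depth < min_depth) | (out.quality < min_quality)
    out.dosage[fail] = MISSING
    if out.phased is not None:
        out.phased = None  # phase is no longer trustworthy once calls are masked
    return out


def filter_variants_for_ld(
    matrix: GenotypeMatrix,
    min_call_rate: float = 1.0,
    exclude_indels: bool = True,
) -> GenotypeMatrix:
    """Drop variants with a call rate below ``min_call_rate`` and, by
    default, all indels. The sample set is unchanged."""
    if not 0.0 <= min_call_rate <= 1.0:
        raise ValueError("min_call_rate must be in [0, 1]")
    if matrix.n_variants == 0:
        return matrix.copy()
    keep = matrix.call_rate() >= min_call_rate
    if exclude_indels:
        keep &= ~matrix.variants["is_indel"].to_numpy(dtype=bool)
    logger.info(
        "variant filter: %d of %d variants retained (call rate >= %.3g%s)",
        int(keep.sum()),
        matrix.n_variants,
        min_call_rate,
        ", indels excluded" if exclude_indels else "",
    )
    return matrix.subset_variants(keep)


def filter_report(matrix: GenotypeMatrix, min_call_rate: float = 1.0,
                  exclude_indels: bool = True) -> pd.DataFrame:
    """Per-dropped-variant reasons for the variant-level filter (TSV-ready)."""
    rates = matrix.call_rate()
    rows = []
    for i in range(matrix.n_variants):
        reasons = []
        if rates[i] < min_call_rate:
            reasons.append(f"call_rate={rates[i]:.4f}")
        if exclude_indels and bool(matrix.variants["is_indel"].iloc[i]):
            reasons.append("indel")
        if reasons:
            rows.append((matrix.variants["id"].iloc[i], ";".join(reasons)))
    return pd.DataFrame(rows, columns=["variant_id", "reason"])


def extract_region(matrix: GenotypeMatrix, region: Interval) -> GenotypeMatrix:
    """Retain variants with region.start <= pos <= region.end (inclusive)."""
    chrom = matrix.variants["chrom"].to_numpy()
    pos = matrix.variants["pos"].to_numpy()
    keep = (chrom == region.chrom) & (pos >= region.start) & (pos <= region.end)
    if matrix.n_variants and not (chrom == region.chrom).any():
        logger.warning(
            "no variants on %s (matrix contigs: %s); returning empty matrix",
            region.chrom,
            sorted(set(chrom)),
        )
    return matrix.subset_variants(keep)


def scan_low_coverage(
    depth_track: np.ndarray,
    threshold: float,
    min_span: int = 1000,
    chrom: str = "chr17",
    start_pos: int = 1,
) -> list[Interval]:
    """Maximal runs of positions with mean depth below ``threshold`` that are
    at least ``min_span`` bp long, as 1-based inclusive intervals.

    ``depth_track[i]`` is the depth at position ``start_pos + i``.
    """
    track = np.asarray(depth_track, dtype=float)
    if track.size == 0:
        return []
    low = track < threshold
    # run boundaries of the boolean mask
    edges = np.flatnonzero(np.diff(np.concatenate(([False], low, [False])).astype(np.int8)))
    out = []
    for lo, hi in zip(edges[::2], edges[1::2]):  # hi is exclusive
        if hi - lo >= min_span:
            out.append(Interval(chrom, start_pos + int(lo), start_pos + int(hi) - 1))
    return out
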