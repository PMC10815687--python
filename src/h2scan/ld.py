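"""Tag-SNV LD scanning and minimal-interval haplotype fine-mapping.

The LD statistic is the composite (genotypic) r-squared: the squared Pearson
correlation between dosage vectors, computed over samples non-missing at
both sites. Under phase certainty this equals the haplotype r-squared, and
it is exactly 1 between the tag SNV and any variant fixed for different
alleles on the two haplotype classes.

Fine-mapping logic: among tag-homozygous individuals, each sample's maximal
contiguous run of dosage-2 divergent sites around the tag is its
"consistent" segment; a recombinant allele truncates the run on one side.
The minimal LD interval is the intersection of all consistent segments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GenotypeMatrix, Interval, MISSING


@dataclass(frozen=True)
class RecombinantSegment:
    """Per tag-homozygote maximal haplotype-consistent span."""

    sample_id: str
    consistent_interval: Interval
    breakpoint_side: str  # "proximal" | "distal" | "both" | "none"


def composite_r2(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Squared Pearson correlation of two dosage vectors over pairwise
    complete entries. Returns (r2, n_used); r2 is NaN if either vector is
    monomorphic over the shared samples."""
    ok = (x != MISSING) & (y != MISSING)
    n = int(ok.sum())
    if n < 2:
        return float("nan"), n
    xv = x[ok].astype(float)
    yv = y[ok].astype(float)
    sx = xv.std()
    sy = yv.std()
    if sx == 0 or sy == 0:
        return float("nan"), n
    r = float(np.corrcoef(xv, yv)[0, 1])
    return min(r * r, 1.0), n


def r2_scan(
    matrix: GenotypeMatrix, tag_id: str, window_kb: float = 1200
) -> pd.DataFrame:
    """r2 between the tag SNV and every other SNV within ``window_kb`` of it.

    Monomorphic partners get r2 = NaN and ``excluded = True``. Raises if the
    tag itself is monomorphic (correlation undefined).
    """
    tag_idx = matrix.variant_index(tag_id)
    tag_pos = int(matrix.variants["pos"].iloc[tag_idx])
    tag_chrom = matrix.variants["chrom"].iloc[tag_idx]
    tag = matrix.dosage[:, tag_idx]
    tag_called = tag[tag != MISSING]
    if tag_called.size == 0 or np.all(tag_called == tag_called[0]):
        raise ValueError(f"tag variant {tag_id!r} is monomorphic; r2 undefined")

    pos = matrix.variants["pos"].to_numpy()
    chrom = matrix.variants["chrom"].to_numpy()
    is_indel = matrix.variants["is_indel"].to_numpy(dtype=bool)
    in_window = (
        (chrom == tag_chrom)
        & (np.abs(pos - tag_pos) <= window_kb * 1000)
        & ~is_indel
    )

    rows = []
    for j in np.flatnonzero(in_window):
        r2, n = composite_r2(tag, matrix.dosage[:, j])
        rows.append(
            (
                matrix.variants["id"].iloc[j],
                chrom[j],
                int(pos[j]),
                r2,
                n,
                bool(np.isnan(r2)),
            )
        )
    return pd.DataFrame(
        rows, columns=["variant_id", "chrom", "pos", "r2", "n_samples_used", "excluded"]
    )


def call_divergent_snvs(
    stats: pd.DataFrame, tag_id: str, r2_min: float = 0.99
) -> set[str]:
    """Variants with r2 >= r2_min; the tag SNV is always included."""
    keep = stats.loc[stats["r2"] >= r2_min, "variant_id"]
    return set(keep) | {tag_id}


def find_tag_homozygotes(matrix: GenotypeMatrix, tag_id: str) -> list[str]:
    """Samples homozygous for the tag's alternate (H2-tagging) allele."""
    tag = matrix.dosage[:, matrix.variant_index(tag_id)]
    return [s for s, d in zip(matrix.samples, tag) if d == 2]


def detect_recombinant_segments(
    matrix: GenotypeMatrix,
    homozygotes: list[str],
    divergent_ids: list[str],
    tag_id: str,
) -> list[RecombinantSegment]:
    """Per tag-homozygote, the maximal contiguous run of dosage-2 divergent
    sites extended outward from the tag; dosage < 2 beyond the run marks a
    recombination breakpoint on that side.

    Samples with any missing call among the divergent sites are skipped
    (call-rate filtering upstream should make this a no-op).
    """
    cols = np.array([matrix.variant_index(v) for v in divergent_ids])
    pos = matrix.variants["pos"].to_numpy()[cols]
    if np.any(np.diff(pos) <= 0):
        raise ValueError("divergent variant set must be sorted by position")
    chrom = matrix.variants["chrom"].iloc[cols[0]]
    tag_offset = divergent_ids.index(tag_id)

    sample_pos = {s: i for i, s in enumerate(matrix.samples)}
    segments = []
    for sid in homozygotes:
        d = matrix.dosage[sample_pos[sid], cols]
        if d[tag_offset] != 2:
            raise ValueError(f"sample {sid} is not homozygous at the tag SNV")
        if np.any(d == MISSING):
            continue
        lo = tag_offset
        while lo > 0 and d[lo - 1] == 2:
            lo -= 1
        hi = tag_offset
        while hi < len(d) - 1 and d[hi + 1] == 2:
            hi += 1
        prox_broken = lo > 0
        dist_broken = hi < len(d) - 1
        side = {
            (False, False): "none",
            (True, False): "proximal",
            (False, True): "distal",
            (True, True): "both",
        }[(prox_broken, dist_broken)]
        segments.append(
            RecombinantSegment(
                sample_id=sid,
                consistent_interval=Interval(chrom, int(pos[lo]), int(pos[hi])),
                breakpoint_side=side,
            )
        )
    return segments


def minimal_ld_interval(segments: list[RecombinantSegment]) -> Interval:
    """Intersection of all consistent intervals; its endpoints are positions
    of the outermost divergent SNVs consistent in every tag-homozygote."""
    if not segments:
        raise ValueError("no segments provided")
    result: Interval | None = segments[0].consistent_interval
    for seg in segments[1:]:
        result = result.intersect(seg.consistent_interval)
        if result is None:
            raise ValueError(
                "consistent intervals have empty intersection; "
                "the tag SNV or input genotypes are inconsistent"
            )
    return result
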