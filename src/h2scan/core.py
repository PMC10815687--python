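"""Core containers shared across the pipeline.

Coordinates are 1-based inclusive everywhere in memory, matching the
convention of printed genomic spans (e.g. ``chr17:45,394,449-46,808,970``).
Conversion to 0-based half-open happens only in the BED writer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING = -1  # sentinel dosage for a missing / filtered call

VARIANT_COLUMNS = ["chrom", "pos", "id", "ref", "alt", "is_indel"]


@dataclass(frozen=True)
class Interval:
    """1-based inclusive genomic span."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end

    def intersect(self, other: "Interval") -> "Interval | None":
        if other.chrom != self.chrom:
            return None
        lo, hi = max(self.start, other.start), min(self.end, other.end)
        if lo > hi:
            return None
        return Interval(self.chrom, lo, hi)

    def to_bed_line(self) -> str:
        """BED is 0-based half-open; the conversion lives here and only here."""
        return f"{self.chrom}\t{self.start - 1}\t{self.end}"

    @classmethod
    def parse(cls, text: str) -> "Interval":
        """Parse ``chr17:45394449-46808970`` (commas tolerated)."""
        chrom, _, span = text.partition(":")
        if not span:
            raise ValueError(f"cannot parse region {text!r}")
        lo, _, hi = span.replace(",", "").partition("-")
        return cls(chrom, int(lo), int(hi))


@dataclass
class GenotypeMatrix:
    """Samples x variants grid of dosage calls with per-call depth and quality.

    ``dosage`` counts alternate alleles (0/1/2), with :data:`MISSING` for
    absent or filtered calls. ``variants`` is a DataFrame with columns
    ``chrom, pos, id, ref, alt, is_indel`` sorted by (chrom, pos).
    """

    samples: list[str]
    variants: pd.DataFrame
    dosage: np.ndarray   # int8  (n_samples, n_variants)
    depth: np.ndarray    # int32 (n_samples, n_variants)
    quality: np.ndarray  # int32 (n_samples, n_variants)
    phased: np.ndarray | None = None  # uint8 (n_samples, 2, n_variants), optional

    def __post_init__(self) -> None:
        n, m = len(self.samples), len(self.variants)
        for name in ("dosage", "depth", "quality"):
            arr = getattr(self, name)
            if arr.shape != (n, m):
                raise ValueError(f"{name} has shape {arr.shape}, expected {(n, m)}")
        missing_cols = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing_cols:
            raise ValueError(f"variants table lacks columns {missing_cols}")
        if m > 1:
            # ties allowed: split multi-allelic records share a position
            key = list(zip(self.variants["chrom"], self.variants["pos"]))
            if any(b < a for a, b in zip(key, key[1:])):
                raise ValueError("variants must be sorted by (chrom, pos)")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_index(self, variant_id: str) -> int:
        idx = np.flatnonzero((self.variants["id"] == variant_id).to_numpy())
        if idx.size == 0:
            raise KeyError(f"variant {variant_id!r} not in matrix")
        return int(idx[0])

    def call_rate(self) -> np.ndarray:
        """Per-variant fraction of non-missing calls (1.0 for an empty cohort)."""
        if self.n_samples == 0:
            return np.ones(self.n_variants)
        return (self.dosage != MISSING).mean(axis=0)

    def subset_variants(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask, dtype=bool)
        return replace(
            self,
            variants=self.variants.loc[mask].reset_index(drop=True),
            dosage=self.dosage[:, mask],
            depth=self.depth[:, mask],
            quality=self.quality[:, mask],
            phased=None if self.phased is None else self.phased[:, :, mask],
        )

    def copy(self) -> "GenotypeMatrix":
        return replace(
            self,
            variants=self.variants.copy(),
            dosage=self.dosage.copy(),
            depth=self.depth.copy(),
            quality=self.quality.copy(),
            phased=None if self.phased is None else self.phased.copy(),
        )


def empty_matrix(variants: pd.DataFrame | None = None) -> GenotypeMatrix:
    if variants is None:
        variants = pd.DataFrame(columns=VARIANT_COLUMNS)
    m = len(variants)
    return GenotypeMatrix(
        samples=[],
        variants=variants.reset_index(drop=True),
        dosage=np.empty((0, m), dtype=np.int8),
        depth=np.empty((0, m), dtype=np.int32),
        quality=np.empty((0, m), dtype=np.int32),
    )
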