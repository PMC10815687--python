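"""Synthetic Ashkenazi-like PD cohort generator.

Emulates the genetic structure that the downstream analysis assumes: a
chr17q21-style inversion region where a block of "haplotype-divergent" SNVs
is in perfect LD with a tag SNV (two non-recombining haplotype classes, H1
and H2), background SNVs and indels segregating independently of the
haplotype, rare recombinant haplotypes with planted breakpoints, per-call
depth/quality noise, founder-mutation subgroup labels, and age at motor
symptom onset (AMSO) drawn from a linear model with a sex effect.

The H2 class is optionally protective: case inclusion is rejection-sampled
against H2 carrier status so that the realized carrier-versus-expected odds
ratio targets a configurable value under a dominant mechanism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Interval, GenotypeMatrix, MISSING, VARIANT_COLUMNS

DEFAULT_REGION = Interval("chr17", 45_394_449, 46_808_970)

#: founder-mutation subgroup frequencies in the cohort (fraction of cases)
DEFAULT_CARRIER_FREQS = {
    "GBA1": 0.196,
    "LRRK2": 0.121,
    "dual": 0.021,
    "SMPD1": 0.007,
}

SUBGROUPS = ["GBA1", "LRRK2", "dual", "SMPD1", "NC"]


@dataclass
class CohortConfig:
    """All generative parameters of the synthetic cohort.

    Defaults mirror the cohort structure the analysis targets: 1200 cases,
    H2 allele frequency 0.256 in the source population, subgroup fractions
    GBA1 0.196 / LRRK2 0.121 / dual 0.021 / SMPD1 0.007, AMSO 60.5 +/- 11.2
    years, 39.6% female, and a dominant protective odds ratio of 0.75 for
    H2 carriers.
    """

    n_samples: int = 1200
    region: Interval = field(default_factory=lambda: DEFAULT_REGION)
    n_divergent_snvs: int = 60
    n_background_snvs: int = 120
    n_indels: int = 10
    h2_allele_freq: float = 0.256
    recombinant_rate: float = 0.0
    recombinant_breakpoints: list[int] | None = None
    carrier_freqs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CARRIER_FREQS)
    )
    h2_protective_or: float = 0.75
    amso_mean: float = 60.5
    amso_sd: float = 11.2
    female_frac: float = 0.396
    dp_mean: float = 40.0
    dp_dispersion: float = 30.0  # negative-binomial size; larger = tighter
    gq_mean: float = 80.0
    gq_sd: float = 10.0
    low_dp_mean: float = 4.0
    low_coverage_regions: list[tuple[int, int]] | None = None  # default: two flanking spans
    missing_rate: float = 0.0
    plant_recombinants: bool = False
    tag_id: str = "rs8070723"
    bg_af_range: tuple[float, float] = (0.05, 0.5)
    indel_af_range: tuple[float, float] = (0.01, 0.2)
    seed: int = 0

    def validate(self) -> None:
        probs = {
            "h2_allele_freq": self.h2_allele_freq,
            "recombinant_rate": self.recombinant_rate,
            "female_frac": self.female_frac,
            "missing_rate": self.missing_rate,
            **{f"carrier_freqs[{k}]": v for k, v in self.carrier_freqs.items()},
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.n_samples < 0:
            raise ValueError("n_samples must be non-negative")
        if self.n_divergent_snvs < 1:
            raise ValueError("at least one divergent SNV is required (tag undefined)")
        total = self.n_divergent_snvs + self.n_background_snvs + self.n_indels
        if self.region.length < total:
            raise ValueError("region too short for the requested variant count")
        if sum(self.carrier_freqs.values()) > 1.0 + 1e-12:
            raise ValueError("carrier_freqs sum exceeds 1")
        if self.h2_protective_or <= 0:
            raise ValueError("h2_protective_or must be positive")
        if self.dp_mean <= 0 or self.dp_dispersion <= 0 or self.gq_sd < 0:
            raise ValueError("invalid DP/GQ noise parameters")

    def resolved_low_coverage_regions(self) -> list[tuple[int, int]]:
        """Two low-coverage spans flanking the divergent block (inside the
        region margins), emulating the hard-to-map sequence that borders an
        inversion; explicit config wins."""
        if self.low_coverage_regions is not None:
            return [(int(a), int(b)) for a, b in self.low_coverage_regions]
        L = self.region.length
        s, e = self.region.start, self.region.end
        return [
            (s + int(0.01 * L), s + int(0.05 * L)),
            (e - int(0.05 * L), e - int(0.01 * L)),
        ]


@dataclass
class TruthLabels:
    """Ground truth emitted alongside the synthetic data for recovery tests."""

    hap_h2: np.ndarray            # bool, one per haplotype (2 per sample)
    hap_recombinant: np.ndarray   # bool
    hap_breakpoint: np.ndarray    # int position, -1 where not recombinant
    tag_id: str
    divergent_ids: list[str]
    divergent_pos: np.ndarray
    subgroup: list[str] = field(default_factory=list)     # per sample
    h2_carrier: np.ndarray = field(default_factory=lambda: np.empty(0, bool))
    inner_interval: Interval | None = None  # planted minimal-LD truth

    def homozygote_samples(self) -> np.ndarray:
        """Indices of samples whose two haplotypes are both labelled H2."""
        pairs = self.hap_h2.reshape(-1, 2)
        return np.flatnonzero(pairs.all(axis=1))


# ---------------------------------------------------------------------------
# variant layout

def _layout_variants(config: CohortConfig, rng: np.random.Generator):
    """Place divergent, background and indel variants; returns the variant
    table, per-variant allele frequencies for non-divergent sites, and the
    index of the divergent block columns."""
    region = config.region
    margin = max(1, int(round(0.07 * region.length)))
    block_lo, block_hi = region.start + margin, region.end - margin

    div_pos = np.sort(
        rng.choice(block_hi - block_lo + 1, size=config.n_divergent_snvs, replace=False)
        + block_lo
    )
    taken = set(int(p) for p in div_pos)
    n_other = config.n_background_snvs + config.n_indels
    other: list[int] = []
    while len(other) < n_other:
        cand = rng.integers(region.start, region.end + 1, size=n_other * 2)
        for p in cand:
            p = int(p)
            if p not in taken:
                taken.add(p)
                other.append(p)
                if len(other) == n_other:
                    break
    bg_pos = np.array(sorted(other[: config.n_background_snvs]), dtype=int)
    indel_pos = np.array(sorted(other[config.n_background_snvs:]), dtype=int)

    tag_idx_in_div = config.n_divergent_snvs // 2
    rows = []
    for i, p in enumerate(div_pos):
        vid = config.tag_id if i == tag_idx_in_div else f"div{i + 1:04d}"
        rows.append((region.chrom, int(p), vid, "A", "G", False, "divergent"))
    for i, p in enumerate(bg_pos):
        rows.append((region.chrom, int(p), f"bg{i + 1:04d}", "C", "T", False, "background"))
    for i, p in enumerate(indel_pos):
        rows.append((region.chrom, int(p), f"indel{i + 1:03d}", "AT", "A", True, "indel"))
    variants = (
        pd.DataFrame(rows, columns=VARIANT_COLUMNS + ["role"])
        .sort_values(["chrom", "pos"], kind="mergesort")
        .reset_index(drop=True)
    )

    afs = np.zeros(len(variants))
    role = variants["role"].to_numpy()
    afs[role == "background"] = rng.uniform(*config.bg_af_range, (role == "background").sum())
    afs[role == "indel"] = rng.uniform(*config.indel_af_range, (role == "indel").sum())
    return variants, afs


def default_breakpoints(divergent_pos: np.ndarray) -> list[int]:
    """Two breakpoints near the ends of the divergent block: the proximal one
    cuts off the 3 outermost proximal divergent sites, the distal one the 3
    outermost distal sites (fewer if the block is tiny)."""
    k = 3 if len(divergent_pos) >= 8 else 1
    return [int(divergent_pos[k]), int(divergent_pos[-k - 1])]


def _hap_alleles(
    labels: np.ndarray,
    recomb: np.ndarray,
    breakpoints: np.ndarray,
    variants: pd.DataFrame,
    afs: np.ndarray,
    tag_pos: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Allele matrix (n_haplotypes x n_variants); divergent-site alleles are
    the haplotype label except on the far side of a recombination breakpoint."""
    n_hap, m = len(labels), len(variants)
    pos = variants["pos"].to_numpy()
    role = variants["role"].to_numpy()
    haps = np.zeros((n_hap, m), dtype=np.uint8)

    div_mask = role == "divergent"
    haps[:, div_mask] = labels[:, None].astype(np.uint8)
    for h in np.flatnonzero(recomb):
        b = breakpoints[h]
        if b <= tag_pos:
            flip = div_mask & (pos < b)
        else:
            flip = div_mask & (pos > b)
        haps[h, flip] = 1 - haps[h, flip]

    other = ~div_mask
    if other.any():
        haps[:, other] = (rng.random((n_hap, other.sum())) < afs[other]).astype(np.uint8)
    return haps


def simulate_haplotypes(
    config: CohortConfig, n_haplotypes: int | None = None
) -> tuple[np.ndarray, pd.DataFrame, TruthLabels]:
    """Draw phased haplotypes: H1/H2 labels, optional recombinants, and
    allele matrix over the full variant layout."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    variants, afs = _layout_variants(config, rng)
    div_pos = variants.loc[variants["role"] == "divergent", "pos"].to_numpy()
    tag_pos = int(variants.loc[variants["id"] == config.tag_id, "pos"].iloc[0])
    breakpoint_menu = config.recombinant_breakpoints or default_breakpoints(div_pos)

    n_hap = 2 * config.n_samples if n_haplotypes is None else n_haplotypes
    labels = rng.random(n_hap) < config.h2_allele_freq
    recomb = rng.random(n_hap) < config.recombinant_rate
    bps = np.full(n_hap, -1, dtype=np.int64)
    if recomb.any():
        bps[recomb] = rng.choice(breakpoint_menu, size=int(recomb.sum()))

    haps = _hap_alleles(labels, recomb, bps, variants, afs, tag_pos, rng)
    div_ids = variants.loc[variants["role"] == "divergent", "id"].tolist()
    truth = TruthLabels(
        hap_h2=labels,
        hap_recombinant=recomb,
        hap_breakpoint=bps,
        tag_id=config.tag_id,
        divergent_ids=div_ids,
        divergent_pos=div_pos,
    )
    return haps, variants, truth


# ---------------------------------------------------------------------------
# diploid cohort

def _rejection_sample_labels(
    config: CohortConfig, rng: np.random.Generator
) -> np.ndarray:
    """Sample-level haplotype labels (n_samples x 2) after biasing case
    inclusion against H2 carriers.

    Carriers are accepted with relative probability equal to the target odds
    ratio, which makes the realized case carrier odds equal OR times the
    source-population (HWE) carrier odds in expectation.
    """
    n = config.n_samples
    or_target = config.h2_protective_or
    p_carrier = min(1.0, or_target)
    p_noncarrier = min(1.0, 1.0 / or_target)
    out = np.empty((0, 2), dtype=bool)
    while len(out) < n:
        batch = max(64, 2 * (n - len(out)))
        labels = rng.random((batch, 2)) < config.h2_allele_freq
        carrier = labels.any(axis=1)
        accept_p = np.where(carrier, p_carrier, p_noncarrier)
        keep = rng.random(batch) < accept_p
        out = np.vstack([out, labels[keep]])
    return out[:n]


def simulate_cohort(
    config: CohortConfig,
) -> tuple[GenotypeMatrix, pd.DataFrame, TruthLabels]:
    """Generate a diploid case cohort: genotype matrix with DP/GQ noise,
    sample metadata (sex, founder-mutation subgroup, GBA1 severity flags),
    and ground-truth labels."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    variants, afs = _layout_variants(config, rng)
    div_mask = (variants["role"] == "divergent").to_numpy()
    div_pos = variants.loc[div_mask, "pos"].to_numpy()
    tag_pos = int(variants.loc[variants["id"] == config.tag_id, "pos"].iloc[0])
    breakpoint_menu = config.recombinant_breakpoints or default_breakpoints(div_pos)

    n = config.n_samples
    labels = _rejection_sample_labels(config, rng).reshape(-1)  # 2n haplotypes
    recomb = rng.random(2 * n) < config.recombinant_rate
    bps = np.full(2 * n, -1, dtype=np.int64)
    if recomb.any():
        bps[recomb] = rng.choice(breakpoint_menu, size=int(recomb.sum()))

    inner: Interval | None = None
    if config.plant_recombinants:
        if len(breakpoint_menu) < 2:
            raise ValueError("planting recombinants needs two breakpoints")
        b_prox, b_dist = min(breakpoint_menu), max(breakpoint_menu)
        if not (b_prox <= tag_pos <= b_dist):
            raise ValueError("breakpoints must flank the tag SNV")
        pairs = labels.reshape(-1, 2)
        clean_hom = np.flatnonzero(
            pairs.all(axis=1) & ~recomb.reshape(-1, 2).any(axis=1)
        )
        if len(clean_hom) < 3:
            raise ValueError(
                "too few H2/H2 samples to plant recombinants; increase n_samples"
            )
        for sample_idx, b in ((clean_hom[0], b_prox), (clean_hom[1], b_dist)):
            h = 2 * sample_idx  # first haplotype of the sample
            recomb[h] = True
            bps[h] = b
        inner = Interval(
            config.region.chrom,
            int(div_pos[div_pos >= b_prox].min()),
            int(div_pos[div_pos <= b_dist].max()),
        )

    haps = _hap_alleles(labels, recomb, bps, variants, afs, tag_pos, rng)
    phased = haps.reshape(n, 2, len(variants))
    dosage = phased.sum(axis=1).astype(np.int8)

    m = len(variants)
    # depth is site-structured: good sites have high mean depth, sites inside
    # the planted flanking low-coverage regions collapse and fail call QC
    pos_all = variants["pos"].to_numpy()
    site_mean = np.full(m, config.dp_mean)
    for lo, hi in config.resolved_low_coverage_regions():
        site_mean[(pos_all >= lo) & (pos_all <= hi)] = config.low_dp_mean
    nb_p = config.dp_dispersion / (config.dp_dispersion + site_mean)
    depth = rng.negative_binomial(config.dp_dispersion, nb_p, size=(n, m)).astype(np.int32)
    quality = np.clip(
        np.rint(rng.normal(config.gq_mean, config.gq_sd, (n, m))), 0, 99
    ).astype(np.int32)
    if config.missing_rate > 0:
        dosage = dosage.copy()
        dosage[rng.random((n, m)) < config.missing_rate] = MISSING

    sample_ids = [f"S{i + 1:05d}" for i in range(n)]
    subgroup_names = SUBGROUPS
    probs = [config.carrier_freqs.get(g, 0.0) for g in subgroup_names[:-1]]
    probs.append(1.0 - sum(probs))
    subgroup = rng.choice(subgroup_names, size=n, p=probs) if n else np.array([], dtype=object)
    female = rng.random(n) < config.female_frac
    carrier = labels.reshape(-1, 2).any(axis=1)

    # GBA1 severity structure: only meaningful for GBA1/dual carriers.
    has_gba1 = np.isin(subgroup, ["GBA1", "dual"])
    gba1_class = np.where(
        has_gba1,
        rng.choice(["severe", "mild", "risk"], size=n, p=[0.20, 0.55, 0.25]),
        "none",
    )
    compound_het = has_gba1 & (rng.random(n) < 0.04)
    n370s_hom = has_gba1 & (gba1_class == "mild") & (rng.random(n) < 0.03)

    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "sex": np.where(female, "F", "M"),
            "subgroup": subgroup,
            "gba1_class": gba1_class,
            "compound_het": compound_het,
            "n370s_hom": n370s_hom,
            "h2_dosage": phased[:, :, variants.index[variants["id"] == config.tag_id][0]].sum(axis=1)
            if n
            else np.array([], dtype=int),
            "h2_carrier": carrier,
        }
    )

    matrix = GenotypeMatrix(
        samples=sample_ids,
        variants=variants,
        dosage=dosage,
        depth=depth,
        quality=quality,
        phased=phased,
    )
    truth = TruthLabels(
        hap_h2=labels,
        hap_recombinant=recomb,
        hap_breakpoint=bps,
        tag_id=config.tag_id,
        divergent_ids=variants.loc[div_mask, "id"].tolist(),
        divergent_pos=div_pos,
        subgroup=list(subgroup),
        h2_carrier=carrier,
        inner_interval=inner,
    )
    return matrix, meta, truth


def simulate_amso(
    metadata: pd.DataFrame,
    beta_h2: float = 0.0,
    beta_sex: float = -1.0,
    sigma: float = 11.2,
    seed: int = 0,
    mean: float = 60.5,
) -> pd.DataFrame:
    """Append an AMSO column: intercept + beta_h2*[carrier] + beta_sex*[female]
    + N(0, sigma). The intercept is set so the cohort mean equals ``mean``."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    for col in ("sex", "h2_carrier"):
        if col not in metadata.columns:
            raise ValueError(f"metadata lacks required column {col!r}")
    rng = np.random.default_rng(seed)
    female = (metadata["sex"] == "F").to_numpy(dtype=float)
    carrier = metadata["h2_carrier"].to_numpy(dtype=float)
    n = len(metadata)
    intercept = mean
    if n:
        intercept = mean - beta_sex * female.mean() - beta_h2 * carrier.mean()
    amso = intercept + beta_h2 * carrier + beta_sex * female + rng.normal(0, sigma, n)
    out = metadata.copy()
    out["amso"] = amso
    return out
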