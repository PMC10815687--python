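import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

from h2scan.core import GenotypeMatrix, MISSING, VARIANT_COLUMNS
from h2scan.synth import CohortConfig, simulate_cohort

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")


def make_matrix(
    dosage,
    pos=None,
    ids=None,
    is_indel=None,
    depth=None,
    quality=None,
    chrom="chr17",
):
    """Small-fixture GenotypeMatrix builder: dosage is (n_samples, n_variants)."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    if pos is None:
        pos = list(range(100, 100 + 10 * m, 10))
    if ids is None:
        ids = [f"v{j}" for j in range(m)]
    if is_indel is None:
        is_indel = [False] * m
    variants = pd.DataFrame(
        {
            "chrom": [chrom] * m,
            "pos": pos,
            "id": ids,
            "ref": ["A"] * m,
            "alt": ["AT" if f else "G" for f in is_indel],
            "is_indel": is_indel,
        },
        columns=VARIANT_COLUMNS,
    )
    depth = np.full((n, m), 50, np.int32) if depth is None else np.asarray(depth, np.int32)
    quality = np.full((n, m), 90, np.int32) if quality is None else np.asarray(quality, np.int32)
    return GenotypeMatrix(
        samples=[f"S{i}" for i in range(n)],
        variants=variants,
        dosage=dosage,
        depth=depth,
        quality=quality,
    )


def matrices_equal(a: GenotypeMatrix, b: GenotypeMatrix) -> bool:
    return (
        a.samples == b.samples
        and a.variants.reset_index(drop=True).equals(b.variants.reset_index(drop=True))
        and np.array_equal(a.dosage, b.dosage)
        and np.array_equal(a.depth, b.depth)
        and np.array_equal(a.quality, b.quality)
    )


def quiet_noise_kwargs():
    """Generator settings with effectively zero call-filter failures, for
    tests that exercise haplotype logic rather than QC noise."""
    return dict(dp_mean=60.0, dp_dispersion=60.0, gq_mean=85.0, gq_sd=6.0,
                missing_rate=0.0)


@pytest.fixture(scope="session")
def planted_cohort():
    """Medium synthetic cohort with planted recombinant tag-homozygotes."""
    cfg = CohortConfig(
        n_samples=500, plant_recombinants=True, seed=20240046, **quiet_noise_kwargs()
    )
    matrix, meta, truth = simulate_cohort(cfg)
    return cfg, matrix, meta, truth
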