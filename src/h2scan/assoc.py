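"""Case-versus-external-frequency association and the dual-carrier null.

Cases are compared against external control *allele counts* (e.g. a gnomAD
population stratum) rather than genotyped controls. For the dominant and
recessive contrasts the control genotype cells are the Hardy-Weinberg
expectations implied by the control allele frequency, with the control
individual count taken as total_alleles / 2 (cells may be fractional).

Inference on every 2x2 table is the Woolf log-odds-ratio normal
approximation: SE = sqrt(sum of reciprocal cells), a two-sided z test, and
exp(ln OR +/- z * SE) confidence limits.

The dual-carrier analysis asks whether founder-mutation carriers (e.g.
GBA1-mutation PD cases) carry the protective H2 haplotype less often than
independence at population frequencies predicts; the null expectation comes
either from the closed-form HWE carrier rate or from a Monte-Carlo draw of
independent Bernoulli carrier states.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

MODELS = ("allelic", "dominant", "recessive")


@dataclass(frozen=True)
class ControlFrequencies:
    """External control allele counts (alternate of total)."""

    alt_alleles: float
    total_alleles: float

    def __post_init__(self) -> None:
        if not 0 <= self.alt_alleles <= self.total_alleles:
            raise ValueError("need 0 <= alt_alleles <= total_alleles")

    @property
    def alt_freq(self) -> float:
        return self.alt_alleles / self.total_alleles

    @property
    def n_individuals(self) -> float:
        return self.total_alleles / 2


@dataclass(frozen=True)
class Assoc2x2:
    """Exposure-by-status table; fractional cells allowed (HWE expectations)."""

    case_exposed: float
    case_unexposed: float
    control_exposed: float
    control_unexposed: float

    def cells(self) -> dict[str, float]:
        return {
            "case_exposed": self.case_exposed,
            "case_unexposed": self.case_unexposed,
            "control_exposed": self.control_exposed,
            "control_unexposed": self.control_unexposed,
        }


@dataclass(frozen=True)
class AssociationResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    z: float
    p_value: float
    model: str = ""
    subgroup: str = ""


@dataclass(frozen=True)
class DualCarrierResult:
    observed_carriers: int
    group_size: int
    expected_carrier_freq: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    n_simulated: int = 0
    seed: int | None = None


def hwe_genotype_freqs(alt_freq: float) -> tuple[float, float, float]:
    """Hardy-Weinberg genotype fractions ((1-p)^2, 2p(1-p), p^2)."""
    if not 0.0 <= alt_freq <= 1.0:
        raise ValueError(f"allele frequency must be in [0, 1], got {alt_freq}")
    p, q = alt_freq, 1.0 - alt_freq
    return q * q, 2 * p * q, p * p


def hwe_carrier_freq(alt_freq: float) -> float:
    """Fraction of individuals carrying at least one alternate allele."""
    _, het, hom = hwe_genotype_freqs(alt_freq)
    return het + hom


def odds_ratio_test(table: Assoc2x2, ci_level: float = 0.95) -> AssociationResult:
    """Woolf log-OR estimate with normal-approximation CI and z test.

    No continuity correction: a zero cell raises, naming the cell, so the
    caller can apply a Haldane correction explicitly if wanted.
    """
    cells = table.cells()
    for name, v in cells.items():
        if v < 0:
            raise ValueError(f"negative cell {name}={v}")
        if v == 0:
            raise ValueError(f"zero cell {name}; OR undefined without correction")
    orr = (table.case_exposed / table.case_unexposed) / (
        table.control_exposed / table.control_unexposed
    )
    se = math.sqrt(sum(1.0 / v for v in cells.values()))
    z_crit = sps.norm.ppf(0.5 + ci_level / 2)
    log_or = math.log(orr)
    z = log_or / se
    p = 2 * sps.norm.sf(abs(z))
    return AssociationResult(
        odds_ratio=orr,
        ci_low=math.exp(log_or - z_crit * se),
        ci_high=math.exp(log_or + z_crit * se),
        z=z,
        p_value=p,
    )


def model_tables(
    case_genotype_counts: tuple[float, float, float],
    controls: ControlFrequencies,
    model: str,
) -> Assoc2x2:
    """Build the 2x2 for a genetic model from case genotype counts
    (n0, n1, n2 = ref-hom, het, alt-hom) and control allele counts.

    allelic:   case alt alleles vs ref alleles, control alt vs ref alleles.
    dominant:  case carriers (n1+n2) vs n0; control cells are the HWE
               carrier/noncarrier expectations among total_alleles/2 people.
    recessive: case alt-homs (n2) vs rest; control cells from p^2 analogously.
    """
    n0, n1, n2 = case_genotype_counts
    if min(n0, n1, n2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n_ctrl = controls.n_individuals
    p = controls.alt_freq
    if model == "allelic":
        alt = n1 + 2 * n2
        ref = 2 * n0 + n1
        return Assoc2x2(alt, ref, controls.alt_alleles,
                        controls.total_alleles - controls.alt_alleles)
    if model == "dominant":
        carrier = hwe_carrier_freq(p)
        return Assoc2x2(n1 + n2, n0, n_ctrl * carrier, n_ctrl * (1 - carrier))
    if model == "recessive":
        hom = p * p
        return Assoc2x2(n2, n0 + n1, n_ctrl * hom, n_ctrl * (1 - hom))
    raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")


def genotype_counts(dosages: np.ndarray) -> tuple[int, int, int]:
    """(n0, n1, n2) from a dosage vector; missing (<0) calls are dropped."""
    d = np.asarray(dosages)
    d = d[d >= 0]
    return int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum())


def stratified_association(
    metadata: pd.DataFrame,
    controls: ControlFrequencies,
    models: tuple[str, ...] = MODELS,
    strata: dict[str, list[str]] | None = None,
    dosage_col: str = "h2_dosage",
) -> list[AssociationResult]:
    """Per-stratum, per-model association against the same external controls.

    ``strata`` maps stratum label -> list of subgroup labels it contains;
    the default mirrors the founder-mutation stratification: the full
    cohort plus GBA1-only, LRRK2-only and non-carrier strata (dual-mutation
    carriers appear only in the full cohort). Within the stratified set,
    each case must fall in at most one stratum.
    """
    if strata is None:
        strata = {
            "ALL": list(dict.fromkeys(metadata["subgroup"])),
            "GBA1": ["GBA1"],
            "LRRK2": ["LRRK2"],
            "NC": ["NC"],
        }
    exclusive = [k for k in strata if k != "ALL"]
    seen: dict[str, str] = {}
    for label in exclusive:
        for sub in strata[label]:
            if sub in seen:
                raise ValueError(
                    f"subgroup {sub!r} assigned to both {seen[sub]!r} and {label!r}"
                )
            seen[sub] = label

    results = []
    for label, subs in strata.items():
        sel = metadata["subgroup"].isin(subs)
        counts = genotype_counts(metadata.loc[sel, dosage_col].to_numpy())
        for model in models:
            res = odds_ratio_test(model_tables(counts, controls, model))
            results.append(
                AssociationResult(
                    odds_ratio=res.odds_ratio,
                    ci_low=res.ci_low,
                    ci_high=res.ci_high,
                    z=res.z,
                    p_value=res.p_value,
                    model=model,
                    subgroup=label,
                )
            )
    return results


def association_table(results: list[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group": r.subgroup,
                "model": r.model,
                "odds_ratio": r.odds_ratio,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p_value": r.p_value,
            }
            for r in results
        ]
    )


def simulate_dual_carriers(
    n_sim: int,
    mutation_carrier_freq: float,
    h2_carrier_freq: float,
    seed: int = 0,
) -> tuple[int, int]:
    """Draw ``n_sim`` individuals with independent Bernoulli carrier states;
    returns (mutation carriers, H2 carriers among them)."""
    if n_sim <= 0:
        raise ValueError("n_sim must be positive")
    for name, f in (("mutation_carrier_freq", mutation_carrier_freq),
                    ("h2_carrier_freq", h2_carrier_freq)):
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    rng = np.random.default_rng(seed)
    mut = rng.random(n_sim) < mutation_carrier_freq
    h2 = rng.random(n_sim) < h2_carrier_freq
    return int(mut.sum()), int((mut & h2).sum())


def dual_carrier_test(
    observed_carriers: int,
    group_size: int,
    expected_carrier_freq: float | None = None,
    simulated_counts: tuple[int, int] | None = None,
    ci_level: float = 0.95,
    n_simulated: int = 0,
    seed: int | None = None,
) -> DualCarrierResult:
    """Observed H2-carrier odds among founder-mutation carriers versus the
    independence expectation.

    Exactly one of ``expected_carrier_freq`` (closed-form HWE path; the
    expected cells are group_size * freq and group_size * (1 - freq)) or
    ``simulated_counts = (mutation_carriers, dual_carriers)`` from
    :func:`simulate_dual_carriers` must be given.
    """
    k, n = observed_carriers, group_size
    if n <= 0:
        raise ValueError("group_size must be positive")
    if not 0 < k < n:
        raise ValueError("observed carriers must satisfy 0 < k < n (odds undefined)")
    if (expected_carrier_freq is None) == (simulated_counts is None):
        raise ValueError("give exactly one of expected_carrier_freq or simulated_counts")
    if expected_carrier_freq is not None:
        freq = expected_carrier_freq
        exp_carrier = n * freq
        exp_non = n * (1 - freq)
    else:
        s_mut, s_dual = simulated_counts
        if not 0 < s_dual < s_mut:
            raise ValueError("degenerate simulated counts")
        freq = s_dual / s_mut
        exp_carrier, exp_non = float(s_dual), float(s_mut - s_dual)
    res = odds_ratio_test(Assoc2x2(k, n - k, exp_carrier, exp_non), ci_level)
    return DualCarrierResult(
        observed_carriers=k,
        group_size=n,
        expected_carrier_freq=freq,
        odds_ratio=res.odds_ratio,
        ci_low=res.ci_low,
        ci_high=res.ci_high,
        p_value=res.p_value,
        n_simulated=n_simulated,
        seed=seed,
    )
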