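"""Age at Motor Symptom Onset (AMSO) regression.

Ordinary least squares of AMSO on a dominant H2-carrier indicator, adjusted
for sex, fitted separately within founder-mutation strata. GBA1 mutation
class confounds onset age, so severe-mutation carriers, compound
heterozygotes and N370S homozygotes are excluded before fitting.
Confidence intervals and p-values use the t distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

EXCLUSION_REASONS = ("gba1_severe", "compound_het", "n370s_hom")


@dataclass(frozen=True)
class RegressionResult:
    stratum: str
    n_used: int
    terms: pd.DataFrame  # index: term; columns: beta, ci_low, ci_high, p_value

    def beta(self, term: str) -> float:
        return float(self.terms.loc[term, "beta"])

    def p(self, term: str) -> float:
        return float(self.terms.loc[term, "p_value"])


def amso_exclusion_filter(
    meta: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop severe-GBA1 carriers, compound heterozygotes and N370S
    homozygotes; the report counts each reason (overlaps counted once in
    the total)."""
    severe = (meta.get("gba1_class", pd.Series("none", index=meta.index)) == "severe")
    chet = meta.get("compound_het", pd.Series(False, index=meta.index)).astype(bool)
    nhom = meta.get("n370s_hom", pd.Series(False, index=meta.index)).astype(bool)
    drop = severe | chet | nhom
    report = {
        "gba1_severe": int(severe.sum()),
        "compound_het": int(chet.sum()),
        "n370s_hom": int(nhom.sum()),
        "total_excluded": int(drop.sum()),
    }
    return meta.loc[~drop].reset_index(drop=True), report


def fit_amso_regression(
    meta: pd.DataFrame,
    stratum: str = "ALL",
    subgroups: list[str] | None = None,
    ci_level: float = 0.95,
) -> RegressionResult:
    """OLS of amso on [H2 carrier (dosage >= 1), female, intercept] within a
    stratum. Samples with missing amso or missing tag dosage are dropped.
    Raises on a degenerate (collinear or single-class) design."""
    df = meta
    if subgroups is not None:
        df = df[df["subgroup"].isin(subgroups)]
    df = df.dropna(subset=["amso"])
    df = df[df["h2_dosage"] >= 0]
    n_dropped = len(meta) - len(df) if subgroups is None else None
    if n_dropped:
        logger.info("dropped %d samples with missing amso/genotype", n_dropped)
    if len(df) < 3:
        raise ValueError(f"stratum {stratum!r} has fewer than 3 usable samples")

    carrier = (df["h2_dosage"] >= 1).to_numpy(dtype=float)
    female = (df["sex"] == "F").to_numpy(dtype=float)
    for name, col in (("h2_carrier", carrier), ("female", female)):
        if np.all(col == col[0]):
            raise ValueError(f"design column {name!r} is constant in stratum {stratum!r}")

    X = sm.add_constant(
        pd.DataFrame({"h2_carrier": carrier, "female": female}), has_constant="add"
    )
    fit = sm.OLS(df["amso"].to_numpy(dtype=float), X).fit()
    ci = fit.conf_int(alpha=1 - ci_level)
    terms = pd.DataFrame(
        {
            "beta": fit.params,
            "ci_low": ci[0],
            "ci_high": ci[1],
            "p_value": fit.pvalues,
        }
    )
    terms.index = ["intercept" if t == "const" else t for t in terms.index]
    return RegressionResult(stratum=stratum, n_used=len(df), terms=terms)


def stratified_amso(
    meta: pd.DataFrame,
    strata: dict[str, list[str]] | None = None,
    apply_exclusions: bool = True,
) -> tuple[list[RegressionResult], dict[str, int]]:
    """Exclusion filter followed by per-stratum fits (GBA1, LRRK2, NC by
    default)."""
    report: dict[str, int] = {}
    if apply_exclusions:
        meta, report = amso_exclusion_filter(meta)
    if strata is None:
        strata = {"GBA1": ["GBA1"], "LRRK2": ["LRRK2"], "NC": ["NC"]}
    results = [
        fit_amso_regression(meta, stratum=label, subgroups=subs)
        for label, subs in strata.items()
    ]
    return results, report


def regression_table(results: list[RegressionResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        for term, row in r.terms.iterrows():
            rows.append(
                {
                    "stratum": r.stratum,
                    "term": term,
                    "beta": row["beta"],
                    "ci_low": row["ci_low"],
                    "ci_high": row["ci_high"],
                    "p_value": row["p_value"],
                    "n": r.n_used,
                }
            )
    return pd.DataFrame(rows)
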