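"""Annotation and QTL threshold filters with a cross-tissue consistency
summary.

Deleteriousness filtering uses CADD Phred scores with an inclusive
threshold ("score >= cutoff"). eQTL records pass at m-value >= 0.9 AND
p < 0.0005; sQTL records pass at p < 0.0001 (strict inequalities on p,
per the thresholds' wording). Cross-tissue consistency asks, per gene and
QTL type, whether a significant effect with one direction is present in
every required brain tissue.
"""

from __future__ import annotations

import pandas as pd

#: the 13 GTEx brain tissues used for the consistency criterion
BRAIN_TISSUES = [
    "amygdala",
    "anterior_cingulate_cortex",
    "caudate",
    "cerebellar_hemisphere",
    "cerebellum",
    "cortex",
    "frontal_cortex",
    "hippocampus",
    "hypothalamus",
    "nucleus_accumbens",
    "putamen",
    "spinal_cord_cervical_c1",
    "substantia_nigra",
]

#: haplotype-proxy SNVs treated as interchangeable H2 representatives
H2_PROXY_SNVS = ["rs4528616", "rs62071573", "rs17651549"]

ANNOTATION_COLUMNS = [
    "variant_id", "chrom", "pos", "cadd_phred", "gene", "consequence",
    "aa_change", "in_ecr", "ccre_class", "ccre_accession",
]


def filter_cadd(records: pd.DataFrame, phred_min: float) -> pd.DataFrame:
    """Records with cadd_phred >= phred_min, sorted descending by score."""
    if phred_min < 0:
        raise ValueError("CADD Phred threshold must be non-negative")
    out = records[records["cadd_phred"] >= phred_min]
    return out.sort_values("cadd_phred", ascending=False, kind="mergesort").reset_index(
        drop=True
    )


def candidate_table(records: pd.DataFrame) -> pd.DataFrame:
    """One row per candidate variant with all annotation columns; missing
    annotations rendered as ``N.A``."""
    out = records.reindex(columns=ANNOTATION_COLUMNS).copy()
    for col in out.columns:
        if col in ("chrom", "pos", "cadd_phred"):
            continue
        out[col] = out[col].where(out[col].notna() & (out[col] != ""), "N.A")
    return out.reset_index(drop=True)


def _check_qtl_type(records: pd.DataFrame, expected: str) -> None:
    bad = set(records["qtl_type"]) - {expected}
    if bad:
        raise ValueError(f"expected only {expected!r} records, found {sorted(bad)}")


def filter_eqtl(
    records: pd.DataFrame, m_min: float = 0.9, p_max: float = 0.0005
) -> pd.DataFrame:
    """Expression QTLs with m_value >= m_min and p_value < p_max."""
    _check_qtl_type(records, "expression")
    keep = (records["m_value"] >= m_min) & (records["p_value"] < p_max)
    return records[keep].reset_index(drop=True)


def filter_sqtl(records: pd.DataFrame, p_max: float = 0.0001) -> pd.DataFrame:
    """Splicing QTLs with p_value < p_max."""
    _check_qtl_type(records, "splicing")
    return records[records["p_value"] < p_max].reset_index(drop=True)


def collapse_proxies(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse the haplotype-proxy SNVs to one record per
    (gene, tissue, qtl_type), keeping the best (smallest) p."""
    idx = records.groupby(["gene", "tissue", "qtl_type"])["p_value"].idxmin()
    return records.loc[idx].reset_index(drop=True)


def cross_tissue_consistency(
    records: pd.DataFrame,
    required_tissues: int | list[str] = 13,
) -> pd.DataFrame:
    """Per (gene, qtl_type): number of significant tissues, whether all
    effect directions agree, and whether the effect is significant with a
    single direction in every required tissue.

    ``records`` must already be significance-filtered. Duplicate
    (gene, tissue, variant_id, qtl_type) rows raise; proxy SNVs should be
    collapsed first (:func:`collapse_proxies`).
    """
    key = ["gene", "tissue", "variant_id", "qtl_type"]
    if records.duplicated(subset=key).any():
        dup = records[records.duplicated(subset=key, keep=False)]
        raise ValueError(f"duplicate QTL rows:\n{dup[key].to_string(index=False)}")
    n_required = (
        len(required_tissues) if isinstance(required_tissues, list) else required_tissues
    )
    rows = []
    for (gene, qtl_type), grp in records.groupby(["gene", "qtl_type"]):
        tissues = grp["tissue"].nunique()
        consistent = grp["effect_sign"].nunique() == 1
        rows.append(
            {
                "gene": gene,
                "qtl_type": qtl_type,
                "n_tissues_significant": tissues,
                "direction_consistent": consistent,
                "all_tissues_consistent": consistent and tissues >= n_required,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene", "qtl_type", "n_tissues_significant",
            "direction_consistent", "all_tissues_consistent",
        ],
    )
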