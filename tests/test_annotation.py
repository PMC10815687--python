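import numpy as np
import pandas as pd
import pytest

from h2scan.annotation import (
    BRAIN_TISSUES,
    candidate_table,
    collapse_proxies,
    cross_tissue_consistency,
    filter_cadd,
    filter_eqtl,
    filter_sqtl,
)

CANDIDATES = pd.DataFrame(
    {
        "variant_id": ["rs2532404", "rs17651549", "rs12373123", "rs12185233", "rs4341787"],
        "chrom": "17",
        "pos": [46225515, 45983912, 45846707, 45846288, 45825139],
        "cadd_phred": [20.70, 24.90, 24.80, 23.50, 21.70],
        "gene": ["KANSL1", "MAPT", "SPPL2C", "SPPL2C", "CRHR1"],
        "consequence": ["upstream", "missense", "missense", "missense", "intron"],
        "aa_change": [None, "p.Arg445Trp", "p.Ser601Pro", "p.Arg461Pro", None],
        "in_ecr": [None, "Yes", "Yes", "Yes", None],
        "ccre_class": ["promoter-like", None, None, None, "distal-enhancer-like"],
        "ccre_accession": ["EH38E1866648", None, None, None, "EH38E1866300"],
    }
)


def qtl_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["variant_id", "gene", "tissue", "qtl_type", "effect_sign",
                 "p_value", "m_value"],
    )


class TestCaddFilter:
    def test_high_scoring_missense_retained_at_20(self):
        out = filter_cadd(CANDIDATES, 20.0)
        assert "rs17651549" in set(out["variant_id"])
        assert len(out) == 5

    def test_just_below_threshold_excluded(self):
        df = pd.DataFrame({"variant_id": ["x"], "cadd_phred": [19.99]})
        assert len(filter_cadd(df, 20.0)) == 0

    def test_inclusive_threshold_and_descending_sort(self):
        out = filter_cadd(CANDIDATES, 20.70)
        assert out["cadd_phred"].is_monotonic_decreasing
        assert 20.70 in set(out["cadd_phred"])

    def test_top_decile_matches_sort_oracle(self):
        rng = np.random.default_rng(0)
        scores = rng.uniform(0, 40, 100)
        df = pd.DataFrame({"variant_id": [f"v{i}" for i in range(100)],
                           "cadd_phred": scores})
        cutoff = np.quantile(scores, 0.9, method="higher")
        out = filter_cadd(df, cutoff)
        expected = set(df.sort_values("cadd_phred").tail(10)["variant_id"])
        assert set(out["variant_id"]) == expected

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            filter_cadd(CANDIDATES, -1.0)

    def test_lower_threshold_returns_superset(self):
        strict = set(filter_cadd(CANDIDATES, 24.0)["variant_id"])
        relaxed = set(filter_cadd(CANDIDATES, 12.37)["variant_id"])
        assert strict <= relaxed

    def test_idempotent(self):
        once = filter_cadd(CANDIDATES, 21.0)
        twice = filter_cadd(once, 21.0)
        assert once.equals(twice)


class TestCandidateTable:
    def test_five_records_give_five_rows(self):
        assert len(candidate_table(CANDIDATES)) == 5

    def test_empty_input_gives_header_only(self):
        out = candidate_table(CANDIDATES.iloc[0:0])
        assert len(out) == 0
        assert "cadd_phred" in out.columns

    def test_missing_fields_rendered_as_na(self):
        out = candidate_table(CANDIDATES)
        row = out[out["variant_id"] == "rs17651549"].iloc[0]
        assert row["ccre_class"] == "N.A"
        assert row["aa_change"] == "p.Arg445Trp"
        row2 = out[out["variant_id"] == "rs2532404"].iloc[0]
        assert row2["aa_change"] == "N.A"
        assert row2["ccre_accession"] == "EH38E1866648"


class TestQTLFilters:
    def test_eqtl_conjunction_semantics(self):
        records = qtl_frame(
            [
                ("rs1", "LRRC37A", "cortex", "expression", "+", 1e-5, 0.95),
                ("rs1", "LRRC37A", "caudate", "expression", "+", 1e-6, 0.89),
                ("rs1", "LRRC37A", "putamen", "expression", "+", 6e-4, 0.95),
            ]
        )
        out = filter_eqtl(records)
        assert list(out["tissue"]) == ["cortex"]

    def test_sqtl_strict_p(self):
        records = qtl_frame(
            [
                ("rs1", "KANSL1", "cortex", "splicing", "-", 5e-5, np.nan),
                ("rs1", "KANSL1", "caudate", "splicing", "-", 1e-4, np.nan),
            ]
        )
        out = filter_sqtl(records)
        assert list(out["tissue"]) == ["cortex"]

    def test_wrong_qtl_type_rejected(self):
        records = qtl_frame([("rs1", "G", "cortex", "splicing", "+", 1e-9, np.nan)])
        with pytest.raises(ValueError, match="expression"):
            filter_eqtl(records)

    def test_random_table_matches_predicate_oracle(self):
        rng = np.random.default_rng(1)
        n = 200
        records = qtl_frame(
            [
                (f"rs{i}", "G", f"t{i}", "expression", "+",
                 float(rng.uniform(1e-6, 1e-3)), float(rng.uniform(0.8, 1.0)))
                for i in range(n)
            ]
        )
        out = filter_eqtl(records)
        oracle = {
            r.variant_id
            for r in records.itertuples()
            if r.m_value >= 0.9 and r.p_value < 0.0005
        }
        assert set(out["variant_id"]) == oracle

    def test_filters_idempotent(self):
        rng = np.random.default_rng(2)
        records = qtl_frame(
            [
                (f"rs{i}", "G", f"t{i}", "splicing", "-",
                 float(rng.uniform(1e-6, 1e-3)), np.nan)
                for i in range(50)
            ]
        )
        once = filter_sqtl(records)
        assert once.equals(filter_sqtl(once))


class TestCrossTissueConsistency:
    def gene_rows(self, gene, tissues, sign="+", qtl_type="expression"):
        return [
            ("rs17651549", gene, t, qtl_type,
             sign if not isinstance(sign, list) else sign[i], 1e-6, 0.99)
            for i, t in enumerate(tissues)
        ]

    def test_all_thirteen_same_sign_flagged(self):
        records = qtl_frame(self.gene_rows("LRRC37A", BRAIN_TISSUES))
        out = cross_tissue_consistency(records, required_tissues=13)
        assert bool(out.loc[out["gene"] == "LRRC37A", "all_tissues_consistent"].iloc[0])

    def test_twelve_of_thirteen_not_flagged(self):
        records = qtl_frame(self.gene_rows("LRRC37A", BRAIN_TISSUES[:12]))
        out = cross_tissue_consistency(records, required_tissues=13)
        row = out.iloc[0]
        assert row["n_tissues_significant"] == 12
        assert not row["all_tissues_consistent"]

    def test_mixed_signs_counted_but_not_flagged(self):
        signs = ["+"] * 7 + ["-"] * 6
        records = qtl_frame(self.gene_rows("LINC02210", BRAIN_TISSUES, sign=signs))
        out = cross_tissue_consistency(records, required_tissues=13)
        row = out.iloc[0]
        assert row["n_tissues_significant"] == 13
        assert not row["direction_consistent"]
        assert not row["all_tissues_consistent"]

    def test_duplicate_rows_rejected(self):
        records = qtl_frame(self.gene_rows("G", ["cortex", "cortex"]))
        with pytest.raises(ValueError, match="duplicate"):
            cross_tissue_consistency(records)

    def test_proxy_collapse_keeps_best_p(self):
        records = qtl_frame(
            [
                ("rs17651549", "G", "cortex", "expression", "+", 1e-6, 0.99),
                ("rs4528616", "G", "cortex", "expression", "+", 1e-8, 0.99),
            ]
        )
        out = collapse_proxies(records)
        assert len(out) == 1
        assert out["variant_id"].iloc[0] == "rs4528616"

    def test_counts_match_brute_force_groupby(self):
        rng = np.random.default_rng(3)
        rows = []
        for gene in ["A", "B", "C"]:
            for t in rng.choice(BRAIN_TISSUES, size=rng.integers(3, 13), replace=False):
                rows.append(("rs1", gene, t, "expression", "+", 1e-6, 0.99))
        records = qtl_frame(rows)
        out = cross_tissue_consistency(records, required_tissues=13)
        brute = records.groupby("gene")["tissue"].nunique()
        for _, row in out.iterrows():
            assert row["n_tissues_significant"] == brute[row["gene"]]
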