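import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from h2scan.core import Interval, MISSING
from h2scan.ld import (
    composite_r2,
    r2_scan,
    call_divergent_snvs,
    find_tag_homozygotes,
    detect_recombinant_segments,
    minimal_ld_interval,
    RecombinantSegment,
)
from h2scan.qc import apply_call_filters, filter_variants_for_ld

from conftest import make_matrix


def pearson_r2_oracle(x, y):
    """Plain-Python Pearson r^2, kept independent of the implementation."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y)) / n
    vx = sum((a - mx) ** 2 for a in x) / n
    vy = sum((b - my) ** 2 for b in y) / n
    return cov * cov / (vx * vy)


class TestCompositeR2:
    def test_identical_vectors_give_one(self):
        r2, n = composite_r2(np.array([0, 1, 2, 1]), np.array([0, 1, 2, 1]))
        assert r2 == pytest.approx(1.0, abs=1e-12)
        assert n == 4

    def test_orthogonal_vectors_give_zero(self):
        r2, _ = composite_r2(np.array([0, 0, 1, 1]), np.array([0, 1, 0, 1]))
        assert r2 == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_example(self):
        x = np.array([0, 1, 2, 2, 0])
        y = np.array([0, 1, 1, 2, 0])
        r2, _ = composite_r2(x, y)
        # cov 0.6, variances 0.8 and 0.56 -> 0.36/0.448
        assert r2 == pytest.approx(0.36 / 0.448, abs=1e-12)
        assert r2 == pytest.approx(0.8036, abs=5e-5)

    def test_symmetric(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 3, 50)
        y = rng.integers(0, 3, 50)
        assert composite_r2(x, y)[0] == pytest.approx(composite_r2(y, x)[0], abs=1e-12)

    def test_invariant_under_allele_coding_flip(self):
        rng = np.random.default_rng(4)
        x = rng.integers(0, 3, 50)
        y = rng.integers(0, 3, 50)
        base = composite_r2(x, y)[0]
        assert composite_r2(2 - x, y)[0] == pytest.approx(base, abs=1e-12)
        assert composite_r2(x, 2 - y)[0] == pytest.approx(base, abs=1e-12)

    def test_missing_calls_excluded_pairwise(self):
        x = np.array([0, 1, 2, MISSING, 2])
        y = np.array([0, 1, 2, 2, MISSING])
        r2, n = composite_r2(x, y)
        assert n == 3
        assert r2 == pytest.approx(1.0, abs=1e-12)

    @given(st.lists(st.tuples(st.integers(0, 2), st.integers(0, 2)),
                    min_size=3, max_size=10))
    def test_matches_pearson_oracle_on_small_fixtures(self, pairs):
        x = np.array([a for a, _ in pairs])
        y = np.array([b for _, b in pairs])
        if x.std() == 0 or y.std() == 0:
            assert math.isnan(composite_r2(x, y)[0])
        else:
            assert composite_r2(x, y)[0] == pytest.approx(
                pearson_r2_oracle(list(x), list(y)), abs=1e-10
            )


class TestR2Scan:
    def test_monomorphic_tag_raises(self):
        m = make_matrix([[0, 1], [0, 2], [0, 0]])
        with pytest.raises(ValueError, match="monomorphic"):
            r2_scan(m, "v0")

    def test_monomorphic_partner_reported_excluded(self):
        m = make_matrix([[0, 1], [1, 1], [2, 1]])
        stats = r2_scan(m, "v0")
        row = stats[stats["variant_id"] == "v1"].iloc[0]
        assert row["excluded"]
        assert np.isnan(row["r2"])

    def test_window_limits_partners(self):
        m = make_matrix([[0, 0, 0], [1, 1, 1], [2, 2, 2]],
                        pos=[1_000_000, 2_000_000, 3_500_000])
        stats = r2_scan(m, "v1", window_kb=1200)
        assert set(stats["variant_id"]) == {"v0", "v1"}  # v2 is 1.5 Mb away

    def test_indel_partners_excluded_from_scan(self):
        m = make_matrix([[0, 0], [1, 1], [2, 2]], is_indel=[False, True])
        stats = r2_scan(m, "v0")
        assert set(stats["variant_id"]) == {"v0"}


class TestDivergentCalls:
    def test_threshold_inclusion(self):
        import pandas as pd
        stats = pd.DataFrame(
            {"variant_id": ["a", "b"], "r2": [1.0, 0.98]}
        )
        out = call_divergent_snvs(stats, tag_id="tag")
        assert out == {"a", "tag"}

    def test_clean_cohort_recovers_planted_set(self, planted_cohort):
        cfg, matrix, _, truth = planted_cohort
        fm = filter_variants_for_ld(apply_call_filters(matrix))
        stats = r2_scan(fm, cfg.tag_id)
        divergent = call_divergent_snvs(stats, cfg.tag_id)
        assert divergent == set(truth.divergent_ids)


class TestHomozygotesAndSegments:
    def test_tag_homozygote_set_matches_truth(self, planted_cohort):
        cfg, matrix, _, truth = planted_cohort
        homs = find_tag_homozygotes(matrix, cfg.tag_id)
        expected = {matrix.samples[i] for i in truth.homozygote_samples()}
        assert set(homs) == expected

    def test_full_consistency_spans_everything(self):
        m = make_matrix(np.full((1, 5), 2, dtype=np.int8))
        segs = detect_recombinant_segments(m, ["S0"], [f"v{j}" for j in range(5)], "v2")
        assert segs[0].breakpoint_side == "none"
        assert (segs[0].consistent_interval.start, segs[0].consistent_interval.end) == (
            100, 140,
        )

    def test_proximal_truncation(self):
        dosage = np.full((1, 8), 2, dtype=np.int8)
        dosage[0, :3] = 1
        m = make_matrix(dosage)
        segs = detect_recombinant_segments(m, ["S0"], [f"v{j}" for j in range(8)], "v5")
        assert segs[0].breakpoint_side == "proximal"
        assert segs[0].consistent_interval.start == 130  # 4th site

    def test_non_homozygote_at_tag_raises(self):
        m = make_matrix([[2, 1, 2]])
        with pytest.raises(ValueError, match="homozygous"):
            detect_recombinant_segments(m, ["S0"], ["v0", "v1", "v2"], "v1")

    @given(st.lists(st.sampled_from([1, 2]), min_size=20, max_size=20))
    def test_matches_brute_force_maximal_run(self, mask):
        tag_idx = 10
        mask = list(mask)
        mask[tag_idx] = 2
        m = make_matrix(np.array([mask], dtype=np.int8))
        segs = detect_recombinant_segments(
            m, ["S0"], [f"v{j}" for j in range(20)], f"v{tag_idx}"
        )
        # brute force: widest window of all-2 sites containing the tag
        best = None
        for i in range(tag_idx + 1):
            for j in range(tag_idx, 20):
                if all(v == 2 for v in mask[i:j + 1]):
                    if best is None or (j - i) > (best[1] - best[0]):
                        best = (i, j)
        start, end = best
        iv = segs[0].consistent_interval
        assert (iv.start, iv.end) == (100 + 10 * start, 100 + 10 * end)


class TestMinimalInterval:
    def seg(self, start, end, side="none"):
        return RecombinantSegment("S", Interval("chr17", start, end), side)

    def test_single_segment_identity(self):
        iv = minimal_ld_interval([self.seg(100, 1000)])
        assert (iv.start, iv.end) == (100, 1000)

    def test_pairwise_intersection(self):
        iv = minimal_ld_interval([self.seg(200, 1000), self.seg(100, 900)])
        assert (iv.start, iv.end) == (200, 900)

    def test_empty_intersection_raises(self):
        with pytest.raises(ValueError, match="intersection"):
            minimal_ld_interval([self.seg(100, 200), self.seg(300, 400)])

    def test_monotone_adding_segments_never_widens(self):
        segs = [self.seg(100, 1000), self.seg(150, 950), self.seg(120, 800)]
        prev = minimal_ld_interval(segs[:1])
        for k in range(2, len(segs) + 1):
            cur = minimal_ld_interval(segs[:k])
            assert cur.start >= prev.start and cur.end <= prev.end
            prev = cur

    def test_planted_scenario_recovers_inner_block(self, planted_cohort):
        cfg, matrix, _, truth = planted_cohort
        fm = filter_variants_for_ld(apply_call_filters(matrix))
        stats = r2_scan(fm, cfg.tag_id)
        divergent = call_divergent_snvs(stats, cfg.tag_id)
        ordered = (
            stats[stats["variant_id"].isin(divergent)]
            .sort_values("pos")["variant_id"]
            .tolist()
        )
        homs = find_tag_homozygotes(fm, cfg.tag_id)
        segs = detect_recombinant_segments(fm, homs, ordered, cfg.tag_id)
        assert minimal_ld_interval(segs) == truth.inner_interval
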