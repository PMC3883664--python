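"""Shared-space restriction, three-way partition, percentages, coverage and VAF summaries."""

import math

import numpy as np
import pytest

from wgaconcord import (Callset, CoverageTrack, IntervalSet, coverage_by_class,
                        partition, partition_percentages, restrict,
                        shared_target_space, vaf_pairs, vaf_r2,
                        wga_shared_fraction)
from wgaconcord.concordance import ConcordancePartition

from conftest import make_call, random_calls


def _part(n_wga_only, n_shared, n_unamp_only):
    """Partition carrying only counts (calls irrelevant to percentage math)."""
    def call_at(i):
        return make_call(pos=i + 1)
    wga_only = {(f"chr1", i + 1, "G"): call_at(i) for i in range(n_wga_only)}
    off = n_wga_only
    shared = {("chr1", off + i + 1, "G"): (call_at(off + i), call_at(off + i))
              for i in range(n_shared)}
    off += n_shared
    unamp_only = {("chr1", off + i + 1, "G"): call_at(off + i)
                  for i in range(n_unamp_only)}
    return ConcordancePartition("P", wga_only, shared, unamp_only)


class TestSharedTargetSpace:
    def test_idempotent_on_identical_inputs(self):
        a = IntervalSet([("chr1", 0, 100), ("chr2", 50, 80)])
        assert shared_target_space(a, a, a) == a

    def test_disjoint_designs_empty(self):
        a = IntervalSet([("chr1", 0, 50)])
        b = IntervalSet([("chr1", 60, 100)])
        coding = IntervalSet([("chr1", 0, 100)])
        assert len(shared_target_space(a, b, coding)) == 0

    def test_matches_position_enumeration(self):
        rng = np.random.default_rng(8)
        def rand_set():
            return IntervalSet([("chr1", int(s), int(s + l)) for s, l in
                                zip(rng.integers(0, 150, 6), rng.integers(1, 40, 6))])
        for _ in range(10):
            a, b, c = rand_set(), rand_set(), rand_set()
            space = shared_target_space(a, b, c)
            for p in range(1, 210):
                assert space.contains("chr1", p) == (
                    a.contains("chr1", p) and b.contains("chr1", p)
                    and c.contains("chr1", p))


class TestPartition:
    def _callsets(self, wga_calls, unamp_calls):
        return (Callset("P", "wga_tumor", tuple(wga_calls)),
                Callset("P", "unamplified_tumor", tuple(unamp_calls)))

    def test_identical_callsets_all_shared(self):
        calls = [make_call(pos=p) for p in (5, 10, 15)]
        wga, unamp = self._callsets(calls, calls)
        space = IntervalSet([("chr1", 0, 100)])
        p = partition(wga, unamp, space)
        assert p.counts == (0, 3, 0)

    def test_disjoint_callsets_no_shared(self):
        wga, unamp = self._callsets([make_call(pos=5)], [make_call(pos=10)])
        p = partition(wga, unamp, IntervalSet([("chr1", 0, 100)]))
        assert p.counts == (1, 0, 1)

    def test_wrong_assay_labels_rejected(self):
        wga = Callset("P", "wga_normal", (make_call(),))
        unamp = Callset("P", "unamplified_tumor", (make_call(),))
        with pytest.raises(ValueError):
            partition(wga, unamp, IntervalSet([("chr1", 0, 1000)]))

    def test_matches_brute_force_set_algebra_and_conservation(self):
        rng = np.random.default_rng(12)
        space = IntervalSet([("chr1", 0, 60_000), ("chr2", 10_000, 90_000)])
        for _ in range(5):
            wga, unamp = self._callsets(random_calls(rng, 200),
                                        random_calls(rng, 200))
            p = partition(wga, unamp, space)
            in_space = lambda c: space.contains(c.chrom, c.pos)
            wk = {c.key for c in wga if in_space(c)}
            uk = {c.key for c in unamp if in_space(c)}
            assert set(p.shared) == wk & uk
            assert set(p.wga_only) == wk - uk
            assert set(p.unamp_only) == uk - wk
            # conservation + disjointness
            assert len(p.wga_only) + len(p.shared) == len(wk)
            assert len(p.unamp_only) + len(p.shared) == len(uk)
            assert not (set(p.wga_only) & set(p.unamp_only))

    def test_restriction_monotonicity(self):
        rng = np.random.default_rng(21)
        wga, unamp = self._callsets(random_calls(rng, 150), random_calls(rng, 150))
        big = IntervalSet([("chr1", 0, 100_000), ("chr2", 0, 100_000)])
        small = IntervalSet([("chr1", 0, 40_000)])
        p_big = partition(wga, unamp, big)
        p_small = partition(wga, unamp, small)
        assert all(s <= b for s, b in zip(p_small.counts, p_big.counts))


class TestPercentages:
    def test_union_convention_cohort_average_row(self):
        """Counts (1397, 11432, 2594) give 9/74/17 under the union denominator."""
        assert partition_percentages(_part(1397, 11432, 2594), "union") == (9, 74, 17)

    def test_method_specific_convention_per_patient_row(self):
        """Counts (759, 11781, 1953) give 6/81/14 under method-specific denominators."""
        p = _part(759, 11781, 1953)
        assert partition_percentages(p, "method_specific") == (6, 81, 14)

    def test_degenerate_all_shared(self):
        p = _part(0, 50, 0)
        assert partition_percentages(p, "union") == (0, 100, 0)
        assert partition_percentages(p, "method_specific") == (0, 100, 0)

    def test_union_percentages_sum_to_100(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            p = _part(int(rng.integers(0, 500)), int(rng.integers(1, 5000)),
                      int(rng.integers(0, 500)))
            assert sum(partition_percentages(p, "union")) in (99, 100, 101)

    def test_wga_shared_fraction(self):
        assert wga_shared_fraction(_part(1397, 11432, 0)) == 89
        assert wga_shared_fraction(_part(0, 10, 0)) == 100
        assert wga_shared_fraction(_part(1, 1, 0)) == 50

    def test_empty_union_error(self):
        with pytest.raises(ValueError):
            partition_percentages(_part(0, 0, 0))


class TestCoverageByClass:
    def test_single_member_class_all_summaries_equal_depth(self):
        p = ConcordancePartition("P", {("chr1", 7, "G"): make_call(pos=7)}, {}, {})
        cov = CoverageTrack.from_pairs("P", "wga_tumor", {("chr1", 7): 42})
        df = coverage_by_class(p, cov, cov)
        row = df[(df["class"] == "wga_only") & (df["track"] == "wga")].iloc[0]
        assert [row[c] for c in ("min", "q1", "median", "q3", "max")] == [42.0] * 5

    def test_empty_class_flagged(self):
        p = ConcordancePartition("P", {}, {}, {})
        cov = CoverageTrack.from_pairs("P", "wga_tumor", {("chr1", 1): 1})
        df = coverage_by_class(p, cov, cov)
        assert df["empty"].all() and df["n"].eq(0).all()

    def test_dropout_lowers_unique_class_coverage(self, small_cohort):
        """Unique variants sit at lower depth than shared ones on simulated data."""
        from wgaconcord import run_pipeline  # noqa: F401  (report tested elsewhere)
        from wgaconcord import concordance as conc
        sim = small_cohort
        space = conc.shared_target_space(sim.capture_a, sim.capture_b, sim.coding)
        pdata = sim.patients["P01"]
        p = partition(pdata.callsets["wga_tumor"],
                      pdata.callsets["unamplified_tumor"], space)
        df = coverage_by_class(p, pdata.coverage["wga_tumor"],
                               pdata.coverage["unamplified_tumor"])
        med = {(r["class"], r["track"]): r["median"] for _, r in df.iterrows()}
        # unamp-unique calls were missed by WGA: low WGA depth at those sites
        assert med[("unamp_only", "wga")] < med[("shared", "wga")]


class TestVaf:
    def test_identical_vectors_r2_one(self):
        pairs = vaf_pairs(ConcordancePartition("P", {}, {
            ("chr1", i, "G"): (make_call(pos=i, depth=20, alt_depth=d),
                               make_call(pos=i, depth=20, alt_depth=d))
            for i, d in [(1, 5), (2, 10), (3, 15)]}, {}))
        assert vaf_r2(pairs).r2 == pytest.approx(1.0)

    def test_anticorrelated_r2_one(self):
        pairs = vaf_pairs(ConcordancePartition("P", {}, {
            ("chr1", i, "G"): (make_call(pos=i, depth=20, alt_depth=d),
                               make_call(pos=i, depth=20, alt_depth=20 - d))
            for i, d in [(1, 5), (2, 10), (3, 15)]}, {}))
        fit = vaf_r2(pairs)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.slope == pytest.approx(-1.0)

    def test_zero_variance_flagged_nan(self):
        pairs = vaf_pairs(ConcordancePartition("P", {}, {
            ("chr1", i, "G"): (make_call(pos=i, depth=20, alt_depth=10),
                               make_call(pos=i, depth=20, alt_depth=i))
            for i in (1, 2, 3)}, {}))
        assert math.isnan(vaf_r2(pairs).r2)

    def test_r2_matches_noise_closed_form(self):
        """For y = x + N(0, sigma), R^2 -> var(x) / (var(x) + sigma^2)."""
        rng = np.random.default_rng(4)
        n, sigma = 4000, 0.05
        x = rng.uniform(0.2, 0.8, n)
        y = np.clip(x + rng.normal(0, sigma, n), 0, 1)
        shared = {}
        for i, (xi, yi) in enumerate(zip(x, y)):
            d = 1000
            shared[("chr1", i + 1, "G")] = (
                make_call(pos=i + 1, depth=d, alt_depth=int(round(xi * d))),
                make_call(pos=i + 1, depth=d, alt_depth=int(round(yi * d))))
        fit = vaf_r2(vaf_pairs(ConcordancePartition("P", {}, shared, {})))
        expect = np.var(x) / (np.var(x) + sigma ** 2)
        assert fit.r2 == pytest.approx(expect, abs=0.03)
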