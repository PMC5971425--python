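"""ARE derivation, specificity, establishment, state, TSS and overlap fractions."""

from __future__ import annotations

import math

import pytest

import commitpoint as cp

from conftest import random_peakset


def ps(*ivs, chrom="chr1", label="x"):
    return cp.PeakSet(tuple(cp.Interval(chrom, s, e) for s, e in ivs), label)


class TestDeriveAres:
    def test_single_overlap_keeps_k27ac_footprint(self):
        ares, frac = cp.derive_ares(ps((0, 500)), ps((400, 900)))
        assert [(iv.start, iv.end) for iv in ares] == [(0, 500)]
        assert frac == 1.0

    def test_disjoint_sets_drop_everything(self):
        ares, frac = cp.derive_ares(ps((0, 100)), ps((500, 600)))
        assert len(ares) == 0 and frac == 0.0

    def test_empty_h3k27ac_flagged(self):
        with pytest.warns(UserWarning, match="undefined"):
            ares, frac = cp.derive_ares(ps(), ps((0, 100)))
        assert len(ares) == 0 and math.isnan(frac)

    def test_retained_members_match_all_pairs_scan(self, rng):
        k27 = random_peakset(rng, 60, 30_000)
        atac = random_peakset(rng, 60, 30_000)
        ares, frac = cp.derive_ares(k27, atac)
        expected = tuple(
            iv
            for iv in k27
            if any(iv.start < jv.end and jv.start < iv.end for jv in atac)
        )
        assert ares.intervals == expected
        assert frac == len(expected) / len(k27)


class TestPartitionSpecificity:
    def test_identical_sets_all_shared(self, rng):
        a = random_peakset(rng, 40, 10_000)
        a_s, b_s, shared = cp.partition_specificity(a, a)
        assert len(a_s) == 0 and len(b_s) == 0
        assert shared.intervals == cp.merge(a).intervals

    def test_disjoint_sets_all_specific(self):
        a, b = ps((0, 100)), ps((500, 600))
        a_s, b_s, shared = cp.partition_specificity(a, b)
        assert a_s.intervals == a.intervals and b_s.intervals == b.intervals
        assert len(shared) == 0

    def test_symmetry_and_partition_identity(self, rng):
        a = random_peakset(rng, 50, 20_000)
        b = random_peakset(rng, 50, 20_000)
        a_s, b_s, shared = cp.partition_specificity(a, b)
        b_s2, a_s2, shared2 = cp.partition_specificity(b, a)
        assert a_s.intervals == a_s2.intervals and b_s.intervals == b_s2.intervals
        assert shared.intervals == shared2.intervals
        # every a member is either a-specific or lands in a shared cluster
        a_in = cp.intersect_any(a, b)
        assert len(a_s) + len(a_in) == len(a)
        assert cp.overlap_flags(a_in, shared).all()


class TestEstablishmentProfile:
    def test_present_everywhere_established_at_root(self):
        are = ps((100, 200))
        stages = [("s1", ps((50, 250))), ("s2", ps((100, 150))), ("s3", ps((120, 220)))]
        prof = cp.establishment_profile(are, stages)
        assert prof.establishment_stage == ("s1",)
        assert prof.de_novo == (False,)

    def test_final_stage_only_is_de_novo(self):
        are = ps((100, 200))
        stages = [("s1", ps((500, 600))), ("s2", ps()), ("s3", ps((150, 160)))]
        prof = cp.establishment_profile(are, stages)
        assert prof.establishment_stage == ("s3",)
        assert prof.de_novo == (True,)

    def test_empty_stage_list_rejected(self):
        with pytest.raises(ValueError):
            cp.establishment_profile(ps((0, 10)), [])

    def test_presence_fractions_non_decreasing_on_nested_stages(self, rng):
        # nested accessibility: each later stage covers everything before it
        base = random_peakset(rng, 30, 50_000)
        extra = random_peakset(rng, 20, 50_000)
        later = cp.PeakSet(base.intervals + extra.intervals)
        ares = random_peakset(rng, 60, 50_000)
        prof = cp.establishment_profile(ares, [("early", base), ("late", later)])
        fr = prof.presence_fractions
        assert fr["early"] <= fr["late"]


class TestChromatinState:
    def test_definitions(self):
        ares = ps((0, 100), (200, 300), (400, 500), (600, 700))
        me1 = ps((0, 50), (200, 250))
        k27 = ps((0, 50), (400, 450))
        states, fractions = cp.classify_chromatin_state(ares, me1, k27)
        assert states == ["active", "poised", "acetylated_only", "open"]
        assert sum(fractions.values()) == pytest.approx(1.0)

    def test_counts_match_flag_contingency_oracle(self, rng):
        ares = random_peakset(rng, 100, 50_000)
        me1 = random_peakset(rng, 60, 50_000)
        k27 = random_peakset(rng, 60, 50_000)
        states, fractions = cp.classify_chromatin_state(ares, me1, k27)
        for i, iv in enumerate(ares):
            m = any(iv.start < j.end and j.start < iv.end for j in me1)
            k = any(iv.start < j.end and j.start < iv.end for j in k27)
            expected = "active" if m and k else "poised" if m else "acetylated_only" if k else "open"
            assert states[i] == expected
        assert sum(fractions.values()) == pytest.approx(1.0)


class TestNearestTss:
    def tss(self, *recs):
        return cp.TssAnnotation(tuple(recs))

    def test_tss_inside_are_distance_zero(self):
        t = self.tss(("geneA", "chr1", 150, "+"))
        assert cp.assign_nearest_tss(ps((100, 200)), t) == [("geneA", 0)]

    def test_equidistant_tie_broken_lexicographically(self):
        t = self.tss(("geneB", "chr1", 90, "+"), ("geneA", "chr1", 309, "-"))
        # both 10 bp from the interval edges
        assert cp.assign_nearest_tss(ps((100, 300)), t) == [("geneA", 10)]

    def test_chromosome_without_tss_unassigned(self):
        t = self.tss(("geneA", "chr2", 100, "+"))
        assert cp.assign_nearest_tss(ps((0, 50)), t) == [(None, None)]

    def test_matches_exhaustive_scan(self, rng):
        recs = tuple(
            (f"g{i:03d}", "chr1", int(rng.integers(0, 100_000)), "+") for i in range(120)
        )
        t = self.tss(*recs)
        ares = random_peakset(rng, 80, 100_000)
        got = cp.assign_nearest_tss(ares, t)
        for iv, (gene, dist) in zip(ares, got):
            dists = {g: cp.nearest_point_distance(iv, p) for g, _, p, _ in recs}
            best = min(dists.values())
            best_gene = min(g for g, d in dists.items() if d == best)
            assert (gene, dist) == (best_gene, best)


class TestProximityAndFractions:
    @pytest.mark.parametrize("d, expected", [(0, "cPE"), (1000, "cPE"), (1001, "cEE")])
    def test_proximity_boundary(self, d, expected):
        assert cp.classify_proximity(d) == expected

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            cp.classify_proximity(-1)

    def test_target_expressed_fraction_counts_unique_genes(self):
        assignments = [("g1", 0), ("g1", 5), ("g2", 10), (None, None)]
        te = cp.target_expressed_fraction(assignments, {"g1"})
        assert (te.n_ares, te.n_unassigned, te.n_target_genes, te.n_expressed) == (4, 1, 2, 1)
        assert te.percent == 50.0

    def test_target_expressed_printed_rounding(self):
        te = cp.target_expressed_fraction(
            [(f"g{i}", 0) for i in range(1853)], {f"g{i}" for i in range(1527)}
        )
        assert (te.n_target_genes, te.n_expressed, te.percent) == (1853, 1527, 82.0)

    def test_methylation_overlap_disjoint_and_oracle(self, rng):
        ares = random_peakset(rng, 50, 20_000)
        meth = random_peakset(rng, 40, 20_000)
        k, n, pct = cp.methylation_overlap_fraction(ares, meth)
        expected_k = sum(
            1 for iv in ares if any(iv.start < j.end and j.start < iv.end for j in meth)
        )
        assert (k, n) == (expected_k, len(ares))
        assert pct == cp.rounded_percent(expected_k, len(ares), 1)
        k0, n0, pct0 = cp.methylation_overlap_fraction(ares, ps((100_000, 100_100)))
        assert (k0, pct0) == (0, 0.0)
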