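"""Interval algebra against brute-force oracles and format contracts."""

from __future__ import annotations

import subprocess

import numpy as np
import pytest

import commitpoint as cp
from commitpoint.intervals import overlap_bp

from conftest import coverage_mask, random_peakset


class TestReadBed:
    def test_parses_basic_line(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t200\n")
        ps = cp.read_bed(p)
        assert ps.intervals == (cp.Interval("chr1", 100, 200),)

    def test_sorts_unsorted_input_with_warning(self, tmp_path, caplog):
        p = tmp_path / "a.bed"
        p.write_text("chr2\t5\t10\nchr1\t50\t60\nchr1\t10\t20\n")
        with caplog.at_level("WARNING"):
            ps = cp.read_bed(p)
        assert len(ps) == 3
        assert ps.intervals == tuple(sorted(ps.intervals))
        assert any("not coordinate-sorted" in r.message for r in caplog.records)

    def test_rejects_inverted_coordinates_naming_line(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t1\t2\nchr1\t200\t100\n")
        with pytest.raises(ValueError, match=":2"):
            cp.read_bed(p)

    def test_rejects_non_integer_coordinates(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\tx\t200\n")
        with pytest.raises(ValueError, match="non-integer"):
            cp.read_bed(p)

    def test_unknown_chromosome_with_genome(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chrZ\t1\t2\n")
        genome = cp.GenomeAssembly.from_items([("chr1", 1000)])
        with pytest.raises(ValueError, match="chrZ"):
            cp.read_bed(p, genome)

    def test_extra_columns_ignored(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t10\t20\tpeak1\t960\t+\n")
        assert cp.read_bed(p).intervals == (cp.Interval("chr1", 10, 20),)


class TestMerge:
    def test_empty(self):
        assert len(cp.merge(cp.PeakSet(()))) == 0

    @pytest.mark.parametrize(
        "ivs, expected",
        [
            ([(0, 10), (5, 15)], [(0, 15)]),  # overlap coalesces
            ([(0, 10), (10, 20)], [(0, 20)]),  # abutting coalesces
            ([(0, 10), (11, 20)], [(0, 10), (11, 20)]),  # gap preserved
        ],
    )
    def test_small_examples(self, ivs, expected):
        ps = cp.PeakSet(tuple(cp.Interval("chr1", s, e) for s, e in ivs))
        got = [(iv.start, iv.end) for iv in cp.merge(ps)]
        assert got == expected

    def test_matches_boolean_mask_oracle(self, rng):
        ps = random_peakset(rng, 200, 10_000)
        merged = cp.merge(ps)
        assert np.array_equal(
            coverage_mask(merged, "chr1", 10_000), coverage_mask(ps, "chr1", 10_000)
        )
        # merged output is disjoint and non-abutting
        arr = merged.arrays("chr1")
        assert (arr[1:, 0] > arr[:-1, 1]).all()

    def test_idempotent_and_base_conserving(self, rng):
        ps = random_peakset(rng, 150, 50_000)
        merged = cp.merge(ps)
        assert cp.merge(merged).intervals == merged.intervals
        assert merged.total_bases == int(coverage_mask(ps, "chr1", 50_000).sum())


class TestIntersectSubtract:
    def test_identity_and_disjoint(self):
        a = cp.PeakSet((cp.Interval("chr1", 0, 100),))
        b = cp.PeakSet((cp.Interval("chr1", 200, 300),))
        assert cp.intersect_any(a, a).intervals == a.intervals
        assert len(cp.intersect_any(a, b)) == 0
        assert cp.subtract_any(a, b).intervals == a.intervals
        assert len(cp.subtract_any(a, a)) == 0

    def test_min_bp_argument_validation(self):
        a = cp.PeakSet((cp.Interval("chr1", 0, 100),))
        with pytest.raises(ValueError):
            cp.intersect_any(a, a, min_bp=0)

    def test_empty_subtrahend_returns_a(self, rng):
        a = random_peakset(rng, 30, 5_000)
        assert cp.subtract_any(a, cp.PeakSet(())).intervals == a.intervals

    def test_against_all_pairs_oracle_and_partition(self, rng):
        for trial in range(5):
            a = random_peakset(rng, 80, 20_000, chroms=("chr1", "chr2"))
            b = random_peakset(rng, 60, 20_000, chroms=("chr1", "chr2"))
            kept = cp.intersect_any(a, b)
            dropped = cp.subtract_any(a, b)
            expected = tuple(
                iv
                for iv in a
                if any(
                    iv.chrom == jv.chrom and iv.start < jv.end and jv.start < iv.end
                    for jv in b
                )
            )
            assert kept.intervals == expected
            assert len(kept) + len(dropped) == len(a)
            assert tuple(sorted(kept.intervals + dropped.intervals)) == a.intervals

    def test_min_bp_counts_merged_coverage(self, rng):
        # overlap bp is measured against the union of b, not per b-interval
        a = cp.PeakSet((cp.Interval("chr1", 0, 100),))
        b = cp.PeakSet((cp.Interval("chr1", 0, 30), cp.Interval("chr1", 30, 60)))
        assert overlap_bp(a, b)[0] == 60
        assert len(cp.intersect_any(a, b, min_bp=60)) == 1
        assert len(cp.intersect_any(a, b, min_bp=61)) == 0

    def test_overlap_bp_matches_mask_oracle(self, rng):
        a = random_peakset(rng, 100, 30_000)
        b = random_peakset(rng, 100, 30_000)
        bp = overlap_bp(a, b)
        mask_b = coverage_mask(b, "chr1", 30_000)
        expected = [int(mask_b[iv.start : iv.end].sum()) for iv in a]
        assert bp.tolist() == expected


class TestNearestPointDistance:
    @pytest.mark.parametrize(
        "start, end, p, expected",
        [(100, 200, 150, 0), (100, 200, 90, 10), (100, 200, 210, 11), (100, 200, 199, 0)],
    )
    def test_examples(self, start, end, p, expected):
        assert cp.nearest_point_distance(cp.Interval("chr1", start, end), p) == expected

    def test_per_base_oracle(self, rng):
        for _ in range(200):
            s = int(rng.integers(0, 500))
            e = s + int(rng.integers(1, 50))
            p = int(rng.integers(0, 600))
            brute = min(abs(p - base) for base in range(s, e))
            assert cp.nearest_point_distance(cp.Interval("chr1", s, e), p) == brute


def test_against_bedtools_reference(tmp_path, rng):
    """merge and >=1 bp intersection agree with bedtools on random input."""
    a = random_peakset(rng, 120, 40_000, chroms=("chr1", "chr2"))
    b = random_peakset(rng, 90, 40_000, chroms=("chr1", "chr2"))
    pa, pb = tmp_path / "a.bed", tmp_path / "b.bed"
    cp.write_bed(a, pa)
    cp.write_bed(b, pb)
    merged = subprocess.run(
        ["bedtools", "merge", "-i", str(pa)], capture_output=True, text=True, check=True
    ).stdout
    ours = "".join(f"{iv.chrom}\t{iv.start}\t{iv.end}\n" for iv in cp.merge(a))
    assert merged == ours
    hits = subprocess.run(
        ["bedtools", "intersect", "-u", "-a", str(pa), "-b", str(pb)],
        capture_output=True,
        text=True,
        check=True,
    ).stdout
    ours = "".join(f"{iv.chrom}\t{iv.start}\t{iv.end}\n" for iv in cp.intersect_any(a, b))
    assert hits == ours
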