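"""Incidence, locus autozygosity F_L and common-ROH island detection."""

import math

import numpy as np
import pytest

import autozyg as az
from autozyg.caller import ROHParams, ROHSegment, ROHSet, call_roh_population
from autozyg.islands import (
    GRID_GAP_KB,
    GRID_HET,
    GRID_MIN_SNPS,
    IncidenceTrack,
    find_islands,
    incidence,
    locus_autozygosity,
    n_min_from_fraction,
    sensitivity_grid,
    snp_roh_coverage_summary,
)

from conftest import make_markers


def seg(sample, start, end, chrom="1"):
    return ROHSegment(sample, chrom, start, end, 50, 0, 0)


def brute_force_islands(counts, pos, s_min_bp, n_min):
    """Independent enumeration: maximal True-runs of counts >= n_min."""
    out = []
    i = 0
    n = len(counts)
    while i < n:
        if counts[i] >= n_min:
            j = i
            while j + 1 < n and counts[j + 1] >= n_min:
                j += 1
            if pos[j] - pos[i] > s_min_bp:
                out.append((int(pos[i]), int(pos[j])))
            i = j + 1
        else:
            i += 1
    return out


class TestIncidence:
    def test_no_roh_all_zero(self):
        markers = make_markers(np.arange(1, 11) * 1000)
        track = incidence(ROHSet({"a": [], "b": []}), markers)
        assert track.counts.sum() == 0 and track.n_samples == 2

    def test_single_segment_counts_enclosed_markers_inclusively(self):
        markers = make_markers(np.arange(1, 11) * 1000)
        track = incidence(ROHSet({"a": [seg("a", 3000, 7000)]}), markers)
        assert list(track.counts) == [0, 0, 1, 1, 1, 1, 1, 0, 0, 0]

    def test_shared_planted_interval_counts_carriers(self):
        markers = make_markers(np.arange(1, 101) * 10_000)
        rohset = ROHSet(
            {f"s{i}": ([seg(f"s{i}", 200_000, 500_000)] if i < 6 else []) for i in range(10)}
        )
        track = incidence(rohset, markers)
        inside = (markers.position_bp >= 200_000) & (markers.position_bp <= 500_000)
        assert (track.counts[inside] == 6).all() and (track.counts[~inside] == 0).all()


class TestLocusAutozygosity:
    def test_paper_scale_fraction(self):
        track = IncidenceTrack(np.array([639, 0, 1278]), 1278)
        fl = locus_autozygosity(track)
        assert fl[0] == 0.5 and fl[1] == 0.0 and fl[2] == 1.0

    def test_zero_samples_rejected(self):
        with pytest.raises(ValueError):
            locus_autozygosity(IncidenceTrack(np.array([], dtype=int), 0))


class TestFindIslands:
    def test_flat_track_below_threshold_is_empty(self):
        markers = make_markers(np.arange(1, 101) * 10_000)
        track = IncidenceTrack(np.full(100, 3), 10)
        assert find_islands(track, markers, n_min=4) == []

    def test_span_must_strictly_exceed_s_min(self):
        # 41 qualifying markers spanning exactly 0.4 Mb -> rejected at 0.5 Mb
        markers = make_markers(np.arange(1, 101) * 10_000)
        counts = np.zeros(100, int)
        counts[10:51] = 5
        assert find_islands(IncidenceTrack(counts, 10), markers, n_min=5) == []
        # exactly s_min is also rejected (strict >)
        counts = np.zeros(100, int)
        counts[10:61] = 5
        assert find_islands(
            IncidenceTrack(counts, 10), markers, s_min_bp=500_000, n_min=5
        ) == []

    def test_qualifying_stretch_bounds(self):
        markers = make_markers(np.arange(1, 101) * 10_000)
        counts = np.zeros(100, int)
        counts[10:91] = 7
        (isl,) = find_islands(IncidenceTrack(counts, 10), markers, n_min=5)
        assert (isl.start_bp, isl.end_bp) == (11 * 10_000, 91 * 10_000)
        assert isl.n_markers == 81 and isl.peak_count == 7

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(606)
        for _ in range(30):
            m = int(rng.integers(50, 300))
            markers = make_markers(np.cumsum(rng.integers(1_000, 40_000, size=m)))
            counts = rng.integers(0, 8, size=m)
            n_min = int(rng.integers(1, 6))
            s_min = int(rng.choice([100_000, 500_000]))
            got = find_islands(IncidenceTrack(counts, 10), markers, s_min, n_min)
            assert [(i.start_bp, i.end_bp) for i in got] == brute_force_islands(
                counts, markers.position_bp, s_min, n_min
            )

    def test_maximality_and_nesting(self):
        rng = np.random.default_rng(17)
        markers = make_markers(np.cumsum(rng.integers(5_000, 20_000, size=400)))
        counts = rng.integers(0, 10, size=400)
        track = IncidenceTrack(counts, 12)
        for n_min in (2, 3, 5):
            islands = find_islands(track, markers, 100_000, n_min)
            looser = find_islands(track, markers, 100_000, n_min - 1) if n_min > 1 else []
            pos = markers.position_bp
            for isl in islands:
                i = int(np.searchsorted(pos, isl.start_bp))
                j = int(np.searchsorted(pos, isl.end_bp))
                assert (counts[i : j + 1] >= n_min).all()
                if i > 0:
                    assert counts[i - 1] < n_min
                if j + 1 < len(counts):
                    assert counts[j + 1] < n_min
                if looser:
                    assert any(
                        L.start_bp <= isl.start_bp and L.end_bp >= isl.end_bp
                        for L in looser
                    )

    def test_islands_never_span_chromosomes(self):
        m = az.MarkerMap.from_arrays(
            ["1"] * 50 + ["2"] * 50,
            [f"m{i}" for i in range(100)],
            list(np.arange(1, 51) * 10_000) * 2,
            warn_on_sort=False,
        )
        track = IncidenceTrack(np.full(100, 5), 10)
        islands = find_islands(track, m, 100_000, 2)
        assert [i.chromosome for i in islands] == ["1", "2"]


class TestFractionThresholds:
    def test_reproduces_cohort_counts(self):
        assert [n_min_from_fraction(f, 1278) for f in (0.10, 0.20, 0.25, 0.50)] == [
            127, 255, 319, 639,
        ]

    def test_floor_with_minimum_of_one(self):
        assert n_min_from_fraction(0.01, 50) == 1


class TestSensitivityGrid:
    @pytest.fixture(scope="class")
    def grid_inputs(self, island_sim):
        ds, truth, shared, carriers = island_sim
        sets = {}
        for ms in GRID_MIN_SNPS:
            for gap in GRID_GAP_KB:
                for het in GRID_HET:
                    p = ROHParams(min_snps=ms, max_gap_kb=gap, max_het_long=het, max_het_short=0)
                    sets[(ms, gap, het)] = call_roh_population(ds, p)
        return ds, sets

    def test_universal_island_found_at_every_combination(self, grid_inputs):
        ds, sets = grid_inputs
        grid = sensitivity_grid(sets, ds.markers, ds.n_samples, fractions=(0.10, 0.5))
        shared_rows = grid[grid["fraction"] == 0.5]
        # 18/30 carriers of a 2 Mb interval: >= 1 island at 50% everywhere
        assert (shared_rows["n_islands"] >= 1).all()

    def test_counts_non_increasing_in_fraction(self, grid_inputs):
        ds, sets = grid_inputs
        grid = sensitivity_grid(sets, ds.markers, ds.n_samples)
        for _, sub in grid.groupby(["min_snps", "max_gap_kb", "het_allowance"]):
            counts = sub.sort_values("fraction")["n_islands"].to_numpy()
            assert (np.diff(counts) <= 0).all()

    def test_het_allowance_islands_nest(self, grid_inputs):
        ds, sets = grid_inputs
        for ms in GRID_MIN_SNPS:
            for gap in GRID_GAP_KB:
                t0 = incidence(sets[(ms, gap, 0)], ds.markers)
                t2 = incidence(sets[(ms, gap, 2)], ds.markers)
                n_min = n_min_from_fraction(0.5, ds.n_samples)
                i0 = find_islands(t0, ds.markers, n_min=n_min)
                i2 = find_islands(t2, ds.markers, n_min=n_min)
                for isl in i0:
                    assert any(
                        j.chromosome == isl.chromosome
                        and j.start_bp <= isl.start_bp
                        and j.end_bp >= isl.end_bp
                        for j in i2
                    )

    def test_missing_combination_reported(self, grid_inputs):
        ds, sets = grid_inputs
        partial = {k: v for k, v in sets.items() if k != (30, 100, 0)}
        with pytest.raises(ValueError, match=r"\(30, 100, 0\)"):
            sensitivity_grid(partial, ds.markers, ds.n_samples)


class TestCoverageSummary:
    def test_saturated_and_empty_cohorts(self):
        markers = make_markers(np.arange(1, 61) * 10_000)
        full = ROHSet({f"s{i}": [seg(f"s{i}", 10_000, 600_000)] for i in range(5)})
        assert snp_roh_coverage_summary(full, markers) == (1.0, 1.0)
        empty = ROHSet({f"s{i}": [] for i in range(5)})
        assert snp_roh_coverage_summary(empty, markers) == (0.0, 0.0)

    def test_matches_direct_enumeration(self, island_sim):
        ds, truth, shared, carriers = island_sim
        rohset = call_roh_population(ds)
        any_frac, common_frac = snp_roh_coverage_summary(rohset, ds.markers, 0.10)
        track = incidence(rohset, ds.markers)
        n_min = n_min_from_fraction(0.10, ds.n_samples)
        assert any_frac == (track.counts >= 1).mean()
        assert common_frac == (track.counts >= n_min).mean()
        # the shared interval is common by construction
        sl = ds.markers.chrom_slice("1")
        pos = ds.markers.position_bp[sl]
        inside = (pos >= shared[0]) & (pos <= shared[1])
        assert (track.counts[sl][inside] >= len(carriers)).all()
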