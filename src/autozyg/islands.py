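"""Common ROH: per-marker incidence, locus autozygosity F_L, and island calls.

For each marker, a sample scores 1 when one of its ROH encloses the
marker (inclusive of both run endpoints); the locus autozygosity
F_L = sum_i S_i / n is the fraction of samples scoring 1.  ROH islands
are maximal stretches of consecutive markers where at least ``n_min``
samples present a run, retained when the bp span (last minus first
marker) strictly exceeds ``s_min``.  Sample-count thresholds derived
from a cohort fraction use the floor of fraction x n (e.g. 10/20/25/50%
of 1,278 samples give 127/255/319/639).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .caller import ROHSet
from .io import MarkerMap

__all__ = [
    "IncidenceTrack",
    "ROHIsland",
    "incidence",
    "locus_autozygosity",
    "find_islands",
    "n_min_from_fraction",
    "sensitivity_grid",
    "snp_roh_coverage_summary",
]


@dataclass
class IncidenceTrack:
    """Per-marker count of samples whose ROH encloses the marker."""

    counts: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.size and (
            self.counts.min() < 0 or self.counts.max() > self.n_samples
        ):
            raise ValueError("counts must lie in [0, n_samples]")


@dataclass(frozen=True)
class ROHIsland:
    """A maximal cluster of consecutive markers shared by >= n_min samples."""

    chromosome: str
    start_bp: int
    end_bp: int
    n_markers: int
    min_samples_required: int
    peak_count: int

    @property
    def span_bp(self) -> int:
        return self.end_bp - self.start_bp


def incidence(rohset: ROHSet, markers: MarkerMap) -> IncidenceTrack:
    """Count, per marker, the samples with a ROH spanning it."""
    counts = np.zeros(markers.n_markers, dtype=np.int64)
    for segs in rohset.segments.values():
        for seg in segs:
            if seg.chromosome not in markers.chromosomes:
                continue
            sl = markers.chrom_slice(seg.chromosome)
            pos = markers.position_bp[sl]
            lo = sl.start + int(np.searchsorted(pos, seg.start_bp, side="left"))
            hi = sl.start + int(np.searchsorted(pos, seg.end_bp, side="right"))
            counts[lo:hi] += 1
    return IncidenceTrack(counts, rohset.n_samples)


def locus_autozygosity(track: IncidenceTrack) -> np.ndarray:
    """F_L per marker: the fraction of samples autozygous at the locus."""
    if track.n_samples <= 0:
        raise ValueError("locus autozygosity requires at least one sample")
    return track.counts / track.n_samples


def locus_autozygosity_frame(track: IncidenceTrack, markers: MarkerMap) -> pd.DataFrame:
    """Tidy per-marker table (chrom, position, marker_id, count, f_l)."""
    return pd.DataFrame(
        {
            "chrom": markers.chromosome,
            "position_bp": markers.position_bp,
            "marker_id": markers.marker_id,
            "count": track.counts,
            "f_l": locus_autozygosity(track),
        }
    )


def find_islands(
    track: IncidenceTrack,
    markers: MarkerMap,
    s_min_bp: int = 500_000,
    n_min: int = 1,
) -> list[ROHIsland]:
    """Maximal runs of consecutive markers with count >= n_min, span > s_min."""
    if n_min < 1:
        raise ValueError("n_min must be at least 1")
    if len(track.counts) != markers.n_markers:
        raise ValueError("incidence track does not match the marker map")
    out: list[ROHIsland] = []
    for chrom in markers.chromosomes:
        sl = markers.chrom_slice(chrom)
        pos = markers.position_bp[sl]
        mask = track.counts[sl] >= n_min
        if not mask.any():
            continue
        edges = np.flatnonzero(np.diff(np.r_[0, mask.astype(np.int8), 0]))
        for a, b in zip(edges[::2], edges[1::2]):  # [a, b) runs of True
            span = int(pos[b - 1] - pos[a])
            if span > s_min_bp:
                out.append(
                    ROHIsland(
                        chromosome=chrom,
                        start_bp=int(pos[a]),
                        end_bp=int(pos[b - 1]),
                        n_markers=int(b - a),
                        min_samples_required=n_min,
                        peak_count=int(track.counts[sl][a:b].max()),
                    )
                )
    return out


def islands_to_frame(islands: Sequence[ROHIsland]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (i.chromosome, i.start_bp, i.end_bp, i.span_bp, i.n_markers,
             i.min_samples_required, i.peak_count)
            for i in islands
        ],
        columns=["chrom", "start_bp", "end_bp", "span_bp", "n_markers",
                 "n_min", "peak_count"],
    )


def n_min_from_fraction(fraction: float, n_samples: int) -> int:
    """Minimum sample count for a cohort fraction: floor(fraction x n), >= 1."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    return max(1, math.floor(fraction * n_samples))


GRID_MIN_SNPS: tuple[int, ...] = (30, 150)
GRID_GAP_KB: tuple[int, ...] = (100, 500)
GRID_HET: tuple[int, ...] = (0, 2)


def sensitivity_grid(
    rohsets_by_params: Mapping[tuple[int, int, int], ROHSet],
    markers: MarkerMap,
    n_samples: int,
    fractions: Sequence[float] = (0.10, 0.20, 0.25, 0.50),
    s_min_bp: int = 500_000,
) -> pd.DataFrame:
    """Island counts over the calling-parameter grid.

    ``rohsets_by_params`` maps (min_snps, max_gap_kb, het_allowance) — the
    2 x 2 x 2 grid of 30/150 SNPs, 100/500 kb gaps and 0/2 heterozygotes —
    to the ROHSet called under those parameters.  For each combination and
    cohort fraction, islands are counted at n_min = floor(fraction x n).
    """
    required = list(product(GRID_MIN_SNPS, GRID_GAP_KB, GRID_HET))
    missing = [k for k in required if k not in rohsets_by_params]
    if missing:
        raise ValueError(f"missing ROH sets for parameter combinations: {missing}")
    rows = []
    for key in required:
        track = incidence(rohsets_by_params[key], markers)
        for f in fractions:
            n_min = n_min_from_fraction(f, n_samples)
            rows.append(
                {
                    "min_snps": key[0],
                    "max_gap_kb": key[1],
                    "het_allowance": key[2],
                    "fraction": f,
                    "n_min": n_min,
                    "n_islands": len(find_islands(track, markers, s_min_bp, n_min)),
                }
            )
    return pd.DataFrame(rows)


def snp_roh_coverage_summary(
    rohset: ROHSet,
    markers: MarkerMap,
    common_fraction: float = 0.10,
) -> tuple[float, float]:
    """(fraction of markers inside >= 1 sample's ROH, fraction inside common ROH).

    "Common" means covered in at least floor(common_fraction x n) samples.
    """
    track = incidence(rohset, markers)
    if markers.n_markers == 0:
        return 0.0, 0.0
    n_min = n_min_from_fraction(common_fraction, rohset.n_samples)
    any_frac = float((track.counts >= 1).mean())
    common_frac = float((track.counts >= n_min).mean())
    return any_frac, common_frac
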