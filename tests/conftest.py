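"""Shared fixtures: hand-built marker maps and session-scoped simulations."""

from __future__ import annotations

import numpy as np
import pytest

import autozyg as az
from autozyg.caller import ROHParams
from autozyg.io import MISSING, MarkerMap


def make_markers(positions, chrom="1"):
    """A single-chromosome map at the given positions."""
    positions = list(positions)
    return MarkerMap.from_arrays(
        [chrom] * len(positions),
        [f"{chrom}_m{i}" for i in range(len(positions))],
        positions,
        warn_on_sort=False,
    )


def random_caller_instance(rng):
    """A random small chromosome + random paper-range ROH parameters.

    Mixes spacings (some gaps above 500 kb), het/missing rates and
    parameter values so that every criterion of the caller is exercised.
    """
    m = int(rng.integers(40, 301))
    gaps = rng.choice(
        [5_000, 20_000, 60_000, 120_000, 600_000],
        size=m - 1,
        p=[0.35, 0.3, 0.2, 0.1, 0.05],
    )
    pos = np.cumsum(np.concatenate([[1 + int(rng.integers(0, 1000))], gaps])).astype(np.int64)
    markers = make_markers(pos)
    het = rng.choice([0.0, 0.05, 0.2, 0.5])
    mis = rng.choice([0.0, 0.05, 0.15])
    row = rng.choice(
        np.array([0, 1, 2, MISSING], dtype=np.int8),
        size=m,
        p=[(1 - het - mis) / 2, het, (1 - het - mis) / 2, mis],
    )
    params = ROHParams(
        min_snps=int(rng.choice([5, 10, 30])),
        max_density_kb_per_snp=float(rng.choice([100.0, 300.0])),
        max_gap_kb=float(rng.choice([100.0, 500.0])),
        max_missing=int(rng.choice([0, 2, 5])),
        max_het_long=int(rng.choice([0, 2])),
        long_threshold_mb=float(rng.choice([0.5, 4.0])),
        max_het_short=0,
    )
    return row, markers, params


@pytest.fixture(scope="session")
def recovery_sim():
    """Noise-free 200-sample x ~30k-marker simulation with planted segments.

    All planted lengths sit comfortably above the 1 Mb tier so the tier-1
    F_ROH estimate is comparable with the planted truth.
    """
    cfg = az.nellore_like_config(n_samples=200, seed=20240917)
    markers = az.simulate_map(cfg)
    ds, truth = az.simulate_population(cfg, markers)
    rohset = az.call_roh_population(ds)
    return cfg, markers, ds, truth, rohset


@pytest.fixture(scope="session")
def island_sim():
    """Small population where 60% of samples share one planted island.

    Built directly (background + a shared homozygous interval) so the
    incidence structure is known exactly.
    """
    rng = np.random.default_rng(4242)
    n, spacing = 30, 10_000
    cfg = az.nellore_like_config(
        n_samples=n,
        n_chromosomes=2,
        chromosome_length_bp=30_000_000,
        segment_spec=((2.0, 1.0),),
        seed=99,
    )
    markers = az.simulate_map(cfg)
    ds, truth = az.simulate_population(cfg, markers)
    # plant a shared 2 Mb segment on chromosome 1 in the first 18 samples
    shared = (5_000_000, 7_000_000)
    sl = ds.markers.chrom_slice("1")
    pos = ds.markers.position_bp[sl]
    lo = sl.start + int(np.searchsorted(pos, shared[0]))
    hi = sl.start + int(np.searchsorted(pos, shared[1], side="right"))
    carriers = list(range(18))
    for i in carriers:
        ds.genotypes[i, lo:hi] = 2
        ds.genotypes[i, lo - 1] = 1
        ds.genotypes[i, hi] = 1
    return ds, truth, shared, carriers
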