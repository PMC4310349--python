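"""Synthetic diploid SNP-array genotypes with planted autozygous segments.

The generator emulates the data regime the analysis assumes: a dense
array over multiple chromosomes, a heterozygous background, and long
identical-by-descent homozygous tracts of controlled length planted per
individual.  Segments are planted directly (not via pedigree forward
simulation): the downstream statistics depend only on tract length and
position, and direct planting yields exact, deterministic ground truth.

Each planted segment is delimited by heterozygous calls at the three
nearest markers on either side, emulating the haplotype divergence at
the recombination breakpoints that terminate a real IBD tract.  Without
the demarcation a caller would extend runs over homozygous background
markers beyond the true boundary, making boundary recovery ill-posed;
the demarcation is three markers wide so that a long run cannot absorb
it through a two-heterozygote error allowance.

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .autozygosity import genome_coverage
from .io import MISSING, GenotypeDataset, MarkerMap, chromosome_sort_key

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_map",
    "simulate_population",
    "nellore_like_config",
]

# expected planted-ROH burden per individual: lengths (Mb) spanning the
# studied tiers, totalling ~13.5 Mb expected, i.e. a few percent of a
# few-hundred-Mb simulated genome — the magnitude reported for indicine
# cattle cohorts
_DEFAULT_SEGMENTS: tuple[tuple[float, float], ...] = (
    (1.5, 1.0),
    (2.0, 1.0),
    (4.0, 0.5),
    (8.0, 0.5),
    (16.0, 0.25),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the generator; all rates are per-genotype probabilities."""

    n_samples: int
    chromosome_lengths_bp: Mapping[str, int]
    marker_spacing_bp: int = 10_000
    segment_spec: tuple[tuple[float, float], ...] = _DEFAULT_SEGMENTS
    background_het_rate: float = 0.30
    genotyping_error_rate: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "chromosome_lengths_bp", dict(self.chromosome_lengths_bp)
        )
        object.__setattr__(
            self,
            "segment_spec",
            tuple((float(a), float(b)) for a, b in self.segment_spec),
        )
        for r in (self.background_het_rate, self.genotyping_error_rate, self.missing_rate):
            if not 0 <= r <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if self.n_samples < 0 or self.marker_spacing_bp <= 0:
            raise ValueError("sample count and spacing must be positive")
        if any(v <= 0 for v in self.chromosome_lengths_bp.values()):
            raise ValueError("chromosome lengths must be positive")
        if any(l <= 0 or c < 0 for l, c in self.segment_spec):
            raise ValueError("segment lengths must be positive, counts non-negative")


@dataclass
class SimulationTruth:
    """Planted segments and the implied true F_ROH per individual."""

    segments: dict[str, list[tuple[str, int, int]]]
    true_froh: dict[str, float]

    def write_bed(self, path) -> None:
        """0-based half-open BED: chrom, start-1, end, sample."""
        with open(path, "w") as fh:
            for sid, segs in self.segments.items():
                for chrom, start, end in segs:
                    fh.write(f"{chrom}\t{start - 1}\t{end}\t{sid}\n")


def nellore_like_config(
    n_samples: int = 200,
    n_chromosomes: int = 5,
    chromosome_length_bp: int = 60_000_000,
    include_x: bool = False,
    **overrides,
) -> SimulationConfig:
    """A desk-scale config with the study's statistical structure.

    Defaults give 200 diploid samples on ~30k markers over 300 Mb (10 kb
    mean spacing, well inside the 100 kb density and 500 kb gap criteria).
    """
    chroms = {str(i + 1): chromosome_length_bp for i in range(n_chromosomes)}
    if include_x:
        chroms["X"] = chromosome_length_bp
    return SimulationConfig(
        n_samples=n_samples, chromosome_lengths_bp=chroms, **overrides
    )


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(cfg.seed), stream]))


def simulate_map(cfg: SimulationConfig) -> MarkerMap:
    """Marker positions per chromosome with mean gap ~ marker_spacing_bp.

    Gaps are uniform on [spacing/2, 3*spacing/2]; the first marker lies
    within one spacing of position 1 and the last within ~one spacing of
    the chromosome end.
    """
    rng = _rng(cfg, 1)
    chroms, ids, pos = [], [], []
    s = cfg.marker_spacing_bp
    for chrom in sorted(cfg.chromosome_lengths_bp, key=chromosome_sort_key):
        length = cfg.chromosome_lengths_bp[chrom]
        if s >= length:
            raise ValueError(
                f"marker spacing {s} is not below chromosome {chrom} length {length}"
            )
        p = 1 + int(rng.integers(0, max(1, s // 2)))
        k = 0
        while p <= length:
            chroms.append(chrom)
            ids.append(f"snp_{chrom}_{k}")
            pos.append(p)
            p += int(rng.integers(max(1, s // 2), (3 * s) // 2 + 1))
            k += 1
    return MarkerMap.from_arrays(chroms, ids, pos, warn_on_sort=False)


def simulate_population(
    cfg: SimulationConfig, markers: MarkerMap
) -> tuple[GenotypeDataset, SimulationTruth]:
    """Draw genotypes, plant autozygous segments, then apply noise.

    Background genotypes are iid per marker: heterozygous with probability
    ``background_het_rate``, otherwise homozygous split evenly between 0
    and 2.  Planted segments are homozygous for a single allele, flanked
    by three heterozygous markers per side, and non-overlapping within an
    individual (separated by several marker spacings).  Segment
    boundaries are snapped to marker positions — truth is defined at the
    resolution the array can observe — so each planted length matches its
    target to within one inter-marker gap.  Noise then flips
    each genotype to a uniformly chosen different state with probability
    ``genotyping_error_rate`` and masks to missing with probability
    ``missing_rate``.  Truth records the planted intervals exactly and
    true_froh = planted length / marker-covered genome.
    """
    rng = _rng(cfg, 2)
    n, m = cfg.n_samples, markers.n_markers
    h = cfg.background_het_rate
    geno = rng.choice(
        np.array([0, 1, 2], dtype=np.int8),
        size=(n, m),
        p=[(1 - h) / 2, h, (1 - h) / 2],
    )

    cov = genome_coverage(markers)
    l_total = cov.l_total_with_x  # spans every simulated chromosome
    chrom_span = {
        c: (int(markers.positions_of(c)[0]), int(markers.positions_of(c)[-1]))
        for c in markers.chromosomes
    }
    max_span = max((e - s for s, e in chrom_span.values()), default=0)
    for length_mb, _count in cfg.segment_spec:
        if length_mb * 1e6 > max_span:
            raise ValueError(
                f"requested {length_mb} Mb segments exceed every chromosome's "
                f"marker-covered span ({max_span} bp)"
            )

    flank_markers = 3  # wider than the default two-heterozygote allowance
    buffer_bp = 12 * cfg.marker_spacing_bp  # keeps flank clusters distinct
    samples = [f"ind{i:04d}" for i in range(n)]
    truth_segs: dict[str, list[tuple[str, int, int]]] = {}
    truth_froh: dict[str, float] = {}
    for i, sid in enumerate(samples):
        placed: list[tuple[str, int, int]] = []
        for length_mb, mean_count in cfg.segment_spec:
            seg_bp = int(length_mb * 1e6)
            fitting = [c for c, (s0, e0) in chrom_span.items() if e0 - s0 >= seg_bp]
            for _ in range(rng.poisson(mean_count)):
                for _try in range(200):
                    weights = np.array(
                        [chrom_span[c][1] - chrom_span[c][0] for c in fitting], float
                    )
                    c = fitting[rng.choice(len(fitting), p=weights / weights.sum())]
                    pos = markers.positions_of(c)
                    a_max = int(np.searchsorted(pos, pos[-1] - seg_bp, side="right")) - 1
                    a = int(rng.integers(0, a_max + 1))
                    start = int(pos[a])
                    target = start + seg_bp
                    b = int(np.searchsorted(pos, target))
                    if b >= len(pos) or (b > a + 1 and target - pos[b - 1] <= pos[b] - target):
                        b -= 1
                    end = int(pos[b])
                    if all(
                        cc != c or end + buffer_bp < ps or start - buffer_bp > pe
                        for cc, ps, pe in placed
                    ):
                        placed.append((c, start, end))
                        break
                else:
                    raise RuntimeError(
                        f"could not place a {length_mb} Mb segment for {sid}; "
                        "requested segments exceed chromosome capacity"
                    )
        allele_choices = rng.choice(np.array([0, 2], dtype=np.int8), size=max(len(placed), 1))
        for k, (c, start, end) in enumerate(placed):
            sl = markers.chrom_slice(c)
            pos = markers.position_bp[sl]
            lo = sl.start + int(np.searchsorted(pos, start, side="left"))
            hi = sl.start + int(np.searchsorted(pos, end, side="right"))
            geno[i, lo:hi] = allele_choices[k]
            geno[i, max(lo - flank_markers, sl.start) : lo] = 1
            geno[i, hi : min(hi + flank_markers, sl.stop)] = 1
        placed.sort(key=lambda t: (t[0], t[1]))
        truth_segs[sid] = placed
        truth_froh[sid] = sum(e - s for _, s, e in placed) / l_total

    if cfg.genotyping_error_rate > 0:
        flip = rng.random((n, m)) < cfg.genotyping_error_rate
        shift = rng.integers(1, 3, size=(n, m), dtype=np.int8)
        geno = np.where(flip, (geno + shift) % 3, geno).astype(np.int8)
    if cfg.missing_rate > 0:
        miss = rng.random((n, m)) < cfg.missing_rate
        geno = np.where(miss, np.int8(MISSING), geno).astype(np.int8)

    ds = GenotypeDataset(markers, samples, geno)
    return ds, SimulationTruth(truth_segs, truth_froh)
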