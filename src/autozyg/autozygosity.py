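"""Per-individual genomic autozygosity.

F_ROH is the fraction of the marker-covered genome inside ROH above a
minimum length: F_ROH = sum_j L_ROH_j / L_total, with L_total the sum of
per-chromosome spans (last minus first marker position).  Minimum-length
tiers of 0.5, 1, 2, 4, 8 and 16 Mb probe autozygosity of decreasing age
(roughly 100, 50, 25, 13, 6 and 3 generations back via the expected-IBD-
segment-length relation L = 100/(2g) cM with 1 Mb ~ 1 cM).

The diagonal of the realized genomic relationship matrix,
G = Z Z' / (2 sum_l p_l (1 - p_l)) with Z the genotype matrix centred by
2 p_l, is an alternative autozygosity proxy.  With allele frequencies
fixed at p = 0.5 (the default, preferable when base-population
frequencies are unknowable), G_ii reduces to twice the individual's
homozygous fraction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .caller import ROHSegment, ROHSet
from .io import MISSING, GenotypeDataset, MarkerMap, is_autosome

__all__ = [
    "AUTOSOMAL",
    "AUTOSOMAL_X",
    "TIERS_MB",
    "GenomeCoverage",
    "FrohProfile",
    "GrmDiagonal",
    "genome_coverage",
    "compute_froh",
    "froh_profile",
    "profiles_to_frame",
    "grm_diagonal",
    "generations_from_length",
    "years_before_present",
    "tier_label",
]

logger = logging.getLogger(__name__)

AUTOSOMAL = "autosomal"
AUTOSOMAL_X = "autosomal_x"

TIERS_MB: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0, 8.0, 16.0)


@dataclass(frozen=True)
class GenomeCoverage:
    """Marker-covered extent per chromosome and in total (L_total)."""

    covered_bp: Mapping[str, int]
    l_total_autosomal: int
    l_total_with_x: int


def genome_coverage(markers: MarkerMap) -> GenomeCoverage:
    """Span covered by markers per chromosome (last - first position) and totals."""
    cov: dict[str, int] = {}
    for chrom in markers.chromosomes:
        pos = markers.positions_of(chrom)
        if len(pos) < 2:
            logger.warning("chromosome %s has a single marker; covered span is 0", chrom)
            cov[chrom] = 0
        else:
            cov[chrom] = int(pos[-1] - pos[0])
    aut = sum(v for c, v in cov.items() if is_autosome(c))
    return GenomeCoverage(cov, aut, sum(cov.values()))


def _scope_total(coverage: GenomeCoverage, scope: str) -> int:
    if scope == AUTOSOMAL:
        return coverage.l_total_autosomal
    if scope == AUTOSOMAL_X:
        return coverage.l_total_with_x
    raise ValueError(f"unknown scope {scope!r}")


def compute_froh(
    segments: Iterable[ROHSegment],
    coverage: GenomeCoverage,
    min_length_mb: float,
    scope: str = AUTOSOMAL,
) -> float:
    """F_ROH of one sample: summed length of segments >= the tier, over L_total."""
    if min_length_mb <= 0:
        raise ValueError("minimum length must be positive")
    thr_bp = min_length_mb * 1e6
    total = 0
    for seg in segments:
        if seg.chromosome not in coverage.covered_bp:
            raise ValueError(f"segment on chromosome {seg.chromosome!r} absent from coverage")
        if scope == AUTOSOMAL and not is_autosome(seg.chromosome):
            continue
        if seg.length_bp >= thr_bp:
            total += seg.length_bp
    return total / _scope_total(coverage, scope)


@dataclass
class FrohProfile:
    """One sample's F_ROH at every tier plus chromosome-wise values."""

    sample_id: str
    scope: str
    froh_by_threshold: dict[float, float]
    chromosome_froh: dict[str, float]


def froh_profile(
    rohset: ROHSet,
    coverage: GenomeCoverage,
    tiers_mb: Sequence[float] = TIERS_MB,
    scope: str = AUTOSOMAL,
    chromosome_tier_mb: float = 0.5,
) -> list[FrohProfile]:
    """Tiered and chromosome-wise F_ROH for every sample.

    Chromosome-wise values divide by the chromosome's own covered span.
    """
    chroms = [
        c
        for c in coverage.covered_bp
        if scope == AUTOSOMAL_X or is_autosome(c)
    ]
    out = []
    for sid, segs in rohset.segments.items():
        tiered = {t: compute_froh(segs, coverage, t, scope) for t in tiers_mb}
        chrom_froh = {}
        thr_bp = chromosome_tier_mb * 1e6
        for c in chroms:
            cov = coverage.covered_bp[c]
            tot = sum(
                s.length_bp
                for s in segs
                if s.chromosome == c and s.length_bp >= thr_bp
            )
            chrom_froh[c] = tot / cov if cov else 0.0
        out.append(FrohProfile(sid, scope, tiered, chrom_froh))
    return out


def tier_label(t: float) -> str:
    return f"froh_gt_{t:g}mb"


def profiles_to_frame(profiles: Sequence[FrohProfile]) -> pd.DataFrame:
    """One row per sample, tier columns labelled froh_gt_0.5mb ... froh_gt_16mb."""
    rows = []
    for p in profiles:
        row = {"sample": p.sample_id, "scope": p.scope}
        row.update({tier_label(t): v for t, v in p.froh_by_threshold.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def chromosome_froh_frame(profiles: Sequence[FrohProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        for c, v in p.chromosome_froh.items():
            rows.append({"sample": p.sample_id, "chrom": c, "froh": v})
    return pd.DataFrame(rows)


@dataclass
class GrmDiagonal:
    """Self-relationship G_ii per sample (unitless; in [0, 2] when p = 0.5)."""

    g_ii: dict[str, float]
    mode: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample": list(self.g_ii), "g_ii": list(self.g_ii.values())}
        )


def grm_diagonal(ds: GenotypeDataset, mode: str = "fixed_half") -> GrmDiagonal:
    """Diagonal of the realized genomic relationship matrix.

    ``fixed_half``: allele frequencies fixed at 0.5; G_ii = 2 x the
    homozygous fraction of the sample's non-missing genotypes.
    ``observed``: frequencies estimated from the data; monomorphic markers
    are excluded.  Missing genotypes are dropped from the sample's own
    numerator and denominator (per-sample renormalization, unbiased under
    random missingness).
    """
    if ds.n_markers < 1:
        raise ValueError("at least one marker is required")
    g = ds.genotypes
    nonmiss = g != MISSING
    out: dict[str, float] = {}
    if mode == "fixed_half":
        hom = (g == 0) | (g == 2)
        denom = nonmiss.sum(axis=1) / 2.0  # 2 * sum p(1-p) = n/2 at p = 0.5
        for k, sid in enumerate(ds.samples):
            if denom[k] == 0:
                raise ValueError(f"sample {sid!r} has no usable genotypes")
            out[sid] = float(hom[k].sum() / denom[k])
    elif mode == "observed":
        with np.errstate(invalid="ignore"):
            p = np.where(
                nonmiss.sum(axis=0) > 0,
                np.where(nonmiss, g, 0).sum(axis=0) / (2.0 * np.maximum(nonmiss.sum(axis=0), 1)),
                np.nan,
            )
        poly = (p > 0) & (p < 1)
        w = p * (1.0 - p)
        z2 = (np.where(nonmiss, g, 0) - 2.0 * p[None, :]) ** 2
        use = nonmiss & poly[None, :]
        num = np.where(use, z2, 0.0).sum(axis=1)
        den = 2.0 * np.where(use, w[None, :], 0.0).sum(axis=1)
        for k, sid in enumerate(ds.samples):
            if den[k] == 0:
                raise ValueError(f"sample {sid!r} has no usable polymorphic genotypes")
            out[sid] = float(num[k] / den[k])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return GrmDiagonal(out, mode)


def generations_from_length(length_mb: float) -> int:
    """Expected generations to the common ancestor for a ROH of this length.

    Uses the expected IBD-segment length L = 100/(2g) cM with 1 Mb = 1 cM,
    so g = 100/(2 L), rounded half-up to the nearest generation (which maps
    the 0.5/1/2/4/8/16 Mb tiers to 100/50/25/13/6/3 generations).
    """
    if length_mb <= 0:
        raise ValueError("length must be positive")
    return int(math.floor(100.0 / (2.0 * length_mb) + 0.5))


def years_before_present(generations: int, generation_interval_years: float = 5) -> float:
    """Calendar age of an autozygosity event given a generation interval."""
    if generations < 0 or generation_interval_years < 0:
        raise ValueError("inputs must be non-negative")
    return generations * generation_interval_years
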