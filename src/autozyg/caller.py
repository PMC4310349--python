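"""Run-of-homozygosity (ROH) detection.

A run is a *maximal admissible window* of consecutive map markers.  A
window [i, j] is admissible when:

* its first and last markers carry homozygous calls;
* it contains at least ``min_snps`` genotyped (non-missing) markers;
* no two consecutive markers inside it are more than ``max_gap_kb`` apart;
* at most ``max_missing`` calls inside it are missing (missing calls
  neither break a run nor count toward ``min_snps``; they contribute to
  span and density only through their positions);
* its marker density satisfies span_bp / n_markers_spanned <=
  ``max_density_kb_per_snp`` x 1000, counting every map marker in the span;
* heterozygous calls obey a length-conditional allowance: up to
  ``max_het_long`` (default 2) for windows spanning at least
  ``long_threshold_mb`` (default 4 Mb), and up to ``max_het_short``
  (default 0) otherwise — a tolerance for genotyping error that avoids
  undercalling long runs while keeping short runs strictly homozygous.

A window is *maximal* when no admissible window strictly contains it.
Overlapping maximal windows are resolved greedily, longest first with
ties broken toward the smaller start position, so segments of one sample
never overlap.  Runs never span chromosome boundaries.  Segment length
is ``end_bp - start_bp`` (last minus first marker position).

``call_roh_individual`` scans each chromosome in (near) linear time;
``oracle_call_roh`` brute-forces every (start, end) pair and exists only
as an independent reference for testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeDataset, MarkerMap, chromosome_sort_key

__all__ = [
    "ROHParams",
    "ROHSegment",
    "ROHSet",
    "call_roh_individual",
    "call_roh_population",
    "oracle_call_roh",
]

_HOM, _HET, _MISS = 0, 1, 2

_ORACLE_MAX_MARKERS = 2000


@dataclass(frozen=True)
class ROHParams:
    """Criteria under which a window of markers is declared a ROH."""

    min_snps: int = 30
    max_density_kb_per_snp: float = 100.0
    max_gap_kb: float = 500.0
    max_missing: int = 5
    max_het_long: int = 2
    long_threshold_mb: float = 4.0
    max_het_short: int = 0

    def __post_init__(self) -> None:
        if min(self.min_snps, self.max_missing, self.max_het_long, self.max_het_short) < 0:
            raise ValueError("ROH parameters must be non-negative")
        if self.min_snps < 2:
            raise ValueError("min_snps must be at least 2")
        if min(self.max_density_kb_per_snp, self.max_gap_kb, self.long_threshold_mb) <= 0:
            raise ValueError("density, gap and length thresholds must be positive")
        if self.max_het_short > self.max_het_long:
            raise ValueError("max_het_short cannot exceed max_het_long")


@dataclass(frozen=True)
class ROHSegment:
    """One called homozygous run of one sample."""

    sample_id: str
    chromosome: str
    start_bp: int
    end_bp: int
    n_snps: int
    n_het: int
    n_missing: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp

    def __post_init__(self) -> None:
        if self.end_bp <= self.start_bp:
            raise ValueError("segment end must exceed its start")


@dataclass
class ROHSet:
    """Per-sample inventories of called segments, sorted by (chromosome, start)."""

    segments: dict[str, list[ROHSegment]]

    def __post_init__(self) -> None:
        for sid, segs in self.segments.items():
            self.segments[sid] = sorted(
                segs, key=lambda s: (chromosome_sort_key(s.chromosome), s.start_bp)
            )

    @property
    def n_samples(self) -> int:
        return len(self.segments)

    @property
    def n_segments(self) -> int:
        return sum(len(v) for v in self.segments.values())

    def all_segments(self) -> Iterator[ROHSegment]:
        for segs in self.segments.values():
            yield from segs

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (s.sample_id, s.chromosome, s.start_bp, s.end_bp, s.length_bp,
             s.n_snps, s.n_het, s.n_missing)
            for s in self.all_segments()
        ]
        return pd.DataFrame(
            rows,
            columns=["sample", "chrom", "start_bp", "end_bp", "length_bp",
                     "n_snps", "n_het", "n_missing"],
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path, samples: Iterable[str] | None = None) -> "ROHSet":
        """Read a segment table; ``samples`` adds segment-free sample entries."""
        tab = pd.read_csv(path, sep="\t", dtype={"sample": str, "chrom": str})
        segs: dict[str, list[ROHSegment]] = {str(s): [] for s in (samples or [])}
        for r in tab.itertuples(index=False):
            segs.setdefault(r.sample, []).append(
                ROHSegment(r.sample, r.chrom, int(r.start_bp), int(r.end_bp),
                           int(r.n_snps), int(r.n_het), int(r.n_missing))
            )
        return cls(segs)

    def write_bed(self, path) -> None:
        """0-based half-open BED: chrom, start-1, end, sample."""
        with open(path, "w") as fh:
            for s in sorted(
                self.all_segments(),
                key=lambda s: (chromosome_sort_key(s.chromosome), s.start_bp, s.sample_id),
            ):
                fh.write(f"{s.chromosome}\t{s.start_bp - 1}\t{s.end_bp}\t{s.sample_id}\n")


def _states(row: np.ndarray) -> np.ndarray:
    row = np.asarray(row)
    ok = np.isin(row, (0, 1, 2, MISSING))
    if not ok.all():
        raise ValueError(f"unknown genotype state {row[~ok][0]!r}")
    st = np.full(row.shape, _HOM, dtype=np.int8)
    st[row == 1] = _HET
    st[row == MISSING] = _MISS
    return st


def _gap_blocks(pos: np.ndarray, max_gap_bp: float) -> Iterator[tuple[int, int]]:
    """Maximal index ranges whose internal inter-marker gaps are all <= max_gap_bp."""
    if len(pos) == 0:
        return
    cut = np.flatnonzero(np.diff(pos) > max_gap_bp)
    start = 0
    for c in cut:
        yield start, int(c)
        start = int(c) + 1
    yield start, len(pos) - 1


def _scan_block(pos: np.ndarray, st: np.ndarray, p: ROHParams) -> list[tuple[int, int, int, int]]:
    """Maximal admissible windows of one gap-block, as (i, j, n_het, n_missing).

    For each homozygous start i the largest admissible end j*(i) is found
    under a monotone two-pointer frontier (het and missing caps); a window
    is maximal exactly when j*(i) exceeds every earlier j*, so a single
    left-to-right pass with a running best suffices.
    """
    n = len(pos)
    out: list[tuple[int, int, int, int]] = []
    if n < p.min_snps:
        return out
    H = np.concatenate(([0], np.cumsum(st == _HET, dtype=np.int64)))
    M = np.concatenate(([0], np.cumsum(st == _MISS, dtype=np.int64)))
    hom = st == _HOM
    het_idx = np.flatnonzero(st == _HET)
    dens_bp = p.max_density_kb_per_snp * 1000.0
    long_bp = p.long_threshold_mb * 1e6
    best = -1
    jm = 0
    for i in range(n):
        if not hom[i]:
            continue
        if jm < i:
            jm = i
        while jm + 1 < n and H[jm + 2] - H[i] <= p.max_het_long and M[jm + 2] - M[i] <= p.max_missing:
            jm += 1
        if jm <= best:
            continue
        if (jm - i + 1) - (M[jm + 1] - M[i]) < p.min_snps:
            continue  # even the widest window lacks genotyped markers
        j = jm
        found = -1
        while j > max(i, best):
            nm = M[j + 1] - M[i]
            if (j - i + 1) - nm < p.min_snps:
                break  # shrinking j only loses genotyped markers
            if not hom[j]:
                j -= 1
                continue
            nh = H[j + 1] - H[i]
            span = pos[j] - pos[i]
            if nh > p.max_het_short and span < long_bp:
                # too short for the long-run allowance: every end at or past
                # the (max_het_short+1)-th het fails, so jump below it
                k = int(np.searchsorted(het_idx, i))
                j = int(het_idx[k + p.max_het_short]) - 1
                continue
            if span > dens_bp * (j - i + 1):
                j -= 1
                continue
            found = j
            break
        if found > best:
            out.append((i, found, int(H[found + 1] - H[i]), int(M[found + 1] - M[i])))
            best = found
    return out


def _oracle_block(pos: np.ndarray, st: np.ndarray, p: ROHParams) -> list[tuple[int, int, int, int]]:
    """Brute-force transcription of the criteria over every (start, end) pair."""
    n = len(pos)
    H = np.concatenate(([0], np.cumsum(st == _HET, dtype=np.int64)))
    M = np.concatenate(([0], np.cumsum(st == _MISS, dtype=np.int64)))
    hom = st == _HOM
    jstar = np.full(n, -1, dtype=np.int64)
    for i in range(n):
        if not hom[i]:
            continue
        j = np.arange(i + 1, n)
        if len(j) == 0:
            continue
        nh = H[j + 1] - H[i]
        nm = M[j + 1] - M[i]
        cnt = j - i + 1
        span = pos[j] - pos[i]
        ok = (
            hom[j]
            & (nh <= p.max_het_long)
            & (nm <= p.max_missing)
            & (cnt - nm >= p.min_snps)
            & (span <= p.max_density_kb_per_snp * 1000.0 * cnt)
            & ((nh <= p.max_het_short) | (span >= p.long_threshold_mb * 1e6))
        )
        hits = np.flatnonzero(ok)
        if len(hits):
            jstar[i] = j[hits[-1]]
    out = []
    best = -1
    for i in range(n):
        if jstar[i] > best:
            best = int(jstar[i])
            out.append((i, best, int(H[best + 1] - H[i]), int(M[best + 1] - M[i])))
    return out


def _select_nonoverlapping(
    cands: list[tuple[str, int, int, int, int, int]]
) -> list[tuple[str, int, int, int, int, int]]:
    """Greedy longest-first, ties to smaller start, then drop overlaps."""
    order = sorted(
        cands, key=lambda c: (-(c[2] - c[1]), c[1], chromosome_sort_key(c[0]))
    )
    kept: dict[str, list[tuple[int, int]]] = {}
    chosen = []
    for c in order:
        spans = kept.setdefault(c[0], [])
        if all(c[2] < s or c[1] > e for s, e in spans):
            spans.append((c[1], c[2]))
            chosen.append(c)
    return sorted(chosen, key=lambda c: (chromosome_sort_key(c[0]), c[1]))


def _call_row(
    row: np.ndarray,
    markers: MarkerMap,
    params: ROHParams,
    sample_id: str,
    block_fn,
) -> list[ROHSegment]:
    if len(row) != markers.n_markers:
        raise ValueError("genotype row length does not match marker count")
    st_all = _states(row)
    cands: list[tuple[str, int, int, int, int, int]] = []
    for chrom in markers.chromosomes:
        sl = markers.chrom_slice(chrom)
        pos = markers.position_bp[sl]
        st = st_all[sl]
        for b0, b1 in _gap_blocks(pos, params.max_gap_kb * 1000.0):
            if b1 - b0 + 1 < params.min_snps:
                continue
            for i, j, nh, nm in block_fn(pos[b0 : b1 + 1], st[b0 : b1 + 1], params):
                cands.append(
                    (chrom, int(pos[b0 + i]), int(pos[b0 + j]), j - i + 1, nh, nm)
                )
    return [
        ROHSegment(sample_id, c[0], c[1], c[2], c[3], c[4], c[5])
        for c in _select_nonoverlapping(cands)
    ]


def call_roh_individual(
    genotype_row: np.ndarray,
    markers: MarkerMap,
    params: ROHParams = ROHParams(),
    sample_id: str = "0",
) -> list[ROHSegment]:
    """Call ROH for one sample with the scanning algorithm."""
    return _call_row(genotype_row, markers, params, sample_id, _scan_block)


def oracle_call_roh(
    genotype_row: np.ndarray,
    markers: MarkerMap,
    params: ROHParams = ROHParams(),
    sample_id: str = "0",
) -> list[ROHSegment]:
    """Exhaustive-enumeration reference caller (testing only, quadratic cost)."""
    if markers.n_markers > _ORACLE_MAX_MARKERS:
        raise ValueError(
            f"oracle caller is quadratic; use call_roh_individual for more than "
            f"{_ORACLE_MAX_MARKERS} markers"
        )
    return _call_row(genotype_row, markers, params, sample_id, _oracle_block)


def call_roh_population(ds: GenotypeDataset, params: ROHParams = ROHParams()) -> ROHSet:
    """Call ROH independently for every sample of a dataset."""
    return ROHSet(
        {
            sid: call_roh_individual(ds.genotypes[k], ds.markers, params, sample_id=sid)
            for k, sid in enumerate(ds.samples)
        }
    )
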