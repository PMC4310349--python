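"""PLINK-format genotype I/O and marker/sample quality control.

Genotypes are held as an integer matrix coded by reference-allele count
(0/2 homozygous, 1 heterozygous, ``MISSING`` = -1 for no-calls).  The
reference allele of a marker is the lexicographically smaller of its
alleles: for text input the smaller *observed* allele, for binary input
the smaller of the two alleles listed in the .bim file.  Every statistic
computed downstream (homozygosity, F_ROH, the fixed-p G diagonal) is
invariant to this labelling.

Marker-level QC removes markers with a quality score below a threshold
or a call rate below a threshold (no minor-allele-frequency filter is
ever applied, so monomorphic markers survive — deliberately, because a
MAF filter would destroy homozygous runs).  Sample-level QC removes
samples whose call rate is not strictly greater than its threshold.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "MarkerMap",
    "GenotypeDataset",
    "QCReport",
    "chromosome_sort_key",
    "is_autosome",
    "read_plink_text",
    "write_plink_text",
    "read_plink_binary",
    "write_plink_binary",
    "read_quality_table",
    "attach_quality",
    "apply_marker_qc",
    "apply_sample_qc",
]

MISSING: int = -1

logger = logging.getLogger(__name__)

_BED_MAGIC = b"\x6c\x1b\x01"


def chromosome_sort_key(name: str) -> tuple:
    """Sort key placing autosomes in numeric order before named chromosomes ("X")."""
    try:
        return (0, int(name), "")
    except (TypeError, ValueError):
        return (1, 0, str(name))


def is_autosome(name: str) -> bool:
    """True for purely numeric chromosome names."""
    try:
        int(name)
    except (TypeError, ValueError):
        return False
    return True


@dataclass(frozen=True)
class MarkerMap:
    """Ordered marker coordinates: chromosome, marker id, 1-based bp position.

    Markers are stored sorted by (chromosome, position) with positions
    strictly increasing within a chromosome and globally unique ids.
    """

    chromosome: np.ndarray
    marker_id: np.ndarray
    position_bp: np.ndarray

    def __post_init__(self) -> None:
        chrom = np.asarray([str(c) for c in self.chromosome], dtype=object)
        mid = np.asarray([str(m) for m in self.marker_id], dtype=object)
        pos = np.asarray(self.position_bp, dtype=np.int64)
        if not (len(chrom) == len(mid) == len(pos)):
            raise ValueError("marker arrays differ in length")
        if len(pos) and pos.min() <= 0:
            raise ValueError("marker positions must be positive integers")
        if len(set(mid)) != len(mid):
            raise ValueError("duplicate marker ids")
        slices: dict[str, slice] = {}
        i = 0
        while i < len(chrom):
            c = chrom[i]
            if c in slices:
                raise ValueError("markers of one chromosome are not contiguous")
            j = i
            while j + 1 < len(chrom) and chrom[j + 1] == c:
                j += 1
            block = pos[i : j + 1]
            if len(block) > 1 and not np.all(np.diff(block) > 0):
                raise ValueError(
                    f"positions not strictly increasing on chromosome {c}"
                )
            slices[c] = slice(i, j + 1)
            i = j + 1
        if list(slices) != sorted(slices, key=chromosome_sort_key):
            raise ValueError("chromosomes are not in canonical order")
        object.__setattr__(self, "chromosome", chrom)
        object.__setattr__(self, "marker_id", mid)
        object.__setattr__(self, "position_bp", pos)
        object.__setattr__(self, "_slices", slices)

    @classmethod
    def from_arrays(
        cls,
        chromosome: Sequence,
        marker_id: Sequence,
        position_bp: Sequence,
        *,
        warn_on_sort: bool = True,
    ) -> "MarkerMap":
        """Build a map, re-sorting into canonical order if needed (with a warning)."""
        m, order = _canonical(chromosome, marker_id, position_bp, warn_on_sort)
        return m

    @property
    def n_markers(self) -> int:
        return len(self.position_bp)

    @property
    def chromosomes(self) -> list[str]:
        return list(self._slices)

    def chrom_slice(self, chrom: str) -> slice:
        return self._slices[str(chrom)]

    def positions_of(self, chrom: str) -> np.ndarray:
        return self.position_bp[self.chrom_slice(chrom)]

    def equals(self, other: "MarkerMap") -> bool:
        return (
            np.array_equal(self.chromosome, other.chromosome)
            and np.array_equal(self.marker_id, other.marker_id)
            and np.array_equal(self.position_bp, other.position_bp)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chromosome": self.chromosome,
                "marker_id": self.marker_id,
                "position_bp": self.position_bp,
            }
        )


def _canonical(chromosome, marker_id, position_bp, warn_on_sort: bool):
    chrom = [str(c) for c in chromosome]
    pos = np.asarray(position_bp, dtype=np.int64)
    order = sorted(
        range(len(chrom)), key=lambda k: (chromosome_sort_key(chrom[k]), pos[k])
    )
    if order != list(range(len(chrom))):
        if warn_on_sort:
            logger.warning("markers were not sorted by (chromosome, position); re-sorting")
        chrom = [chrom[k] for k in order]
        marker_id = [marker_id[k] for k in order]
        pos = pos[order]
    return (
        MarkerMap(np.asarray(chrom, dtype=object), np.asarray(marker_id, dtype=object), pos),
        np.asarray(order),
    )


@dataclass
class GenotypeDataset:
    """Samples x markers genotype matrix plus marker metadata.

    ``genotypes`` entries are reference-allele counts {0, 1, 2} or ``MISSING``.
    ``quality`` is an optional per-marker score in [0, 1] (NaN = score absent),
    kept as a side table because array-calling scores are not part of the
    PLINK formats.
    """

    markers: MarkerMap
    samples: list[str]
    genotypes: np.ndarray
    quality: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = [str(s) for s in self.samples]
        g = np.asarray(self.genotypes, dtype=np.int8)
        if g.ndim != 2 or g.shape != (len(self.samples), self.markers.n_markers):
            raise ValueError(
                f"genotype matrix shape {g.shape} does not match "
                f"{len(self.samples)} samples x {self.markers.n_markers} markers"
            )
        if g.size and not np.isin(g, (0, 1, 2, MISSING)).all():
            bad = g[~np.isin(g, (0, 1, 2, MISSING))][0]
            raise ValueError(f"invalid genotype state {bad}")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")
        self.genotypes = g
        if self.quality is not None:
            q = np.asarray(self.quality, dtype=float)
            if q.shape != (self.markers.n_markers,):
                raise ValueError("quality vector length does not match marker count")
            self.quality = q

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return self.markers.n_markers

    def marker_call_rate(self) -> np.ndarray:
        if self.n_samples == 0:
            return np.ones(self.n_markers)
        return (self.genotypes != MISSING).mean(axis=0)

    def sample_call_rate(self) -> np.ndarray:
        if self.n_markers == 0:
            return np.ones(self.n_samples)
        return (self.genotypes != MISSING).mean(axis=1)

    def equals(self, other: "GenotypeDataset") -> bool:
        qa, qb = self.quality, other.quality
        if (qa is None) != (qb is None):
            return False
        q_ok = qa is None or np.allclose(qa, qb, equal_nan=True)
        return (
            self.markers.equals(other.markers)
            and self.samples == other.samples
            and np.array_equal(self.genotypes, other.genotypes)
            and q_ok
        )


# ---------------------------------------------------------------------------
# text format (.map / .ped)


def _read_map_file(map_path) -> tuple[list[str], list[str], list[int]]:
    chroms, ids, pos = [], [], []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(
                    f"{map_path}: line {lineno}: expected 4 columns, got {len(parts)}"
                )
            try:
                bp = int(parts[3])
            except ValueError as exc:
                raise ValueError(
                    f"{map_path}: line {lineno}: position {parts[3]!r} is not an integer"
                ) from exc
            chroms.append(parts[0])
            ids.append(parts[1])
            pos.append(bp)
    if len(set(ids)) != len(ids):
        raise ValueError(f"{map_path}: duplicate marker id")
    return chroms, ids, pos


def read_plink_text(map_path, ped_path) -> GenotypeDataset:
    """Read a PLINK .map/.ped pair into a :class:`GenotypeDataset`.

    "0" alleles denote missing; a pair containing "0" becomes a missing
    genotype.  The reference allele per marker is the lexicographically
    smaller observed allele, so the coding is deterministic.
    """
    chroms, ids, pos = _read_map_file(map_path)
    m = len(ids)
    samples: list[str] = []
    rows_a: list[np.ndarray] = []
    rows_b: list[np.ndarray] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * m:
                raise ValueError(
                    f"{ped_path}: line {lineno}: expected {6 + 2 * m} fields, "
                    f"got {len(parts)}"
                )
            samples.append(parts[1])
            al = np.asarray(parts[6:], dtype=object)
            rows_a.append(al[0::2])
            rows_b.append(al[1::2])
    n = len(samples)
    a = np.vstack(rows_a) if n else np.empty((0, m), dtype=object)
    b = np.vstack(rows_b) if n else np.empty((0, m), dtype=object)
    geno = np.full((n, m), MISSING, dtype=np.int8)
    for l in range(m):
        al, bl = a[:, l], b[:, l]
        miss = (al == "0") | (bl == "0")
        observed = sorted(set(al[~miss]) | set(bl[~miss]))
        if len(observed) > 2:
            raise ValueError(
                f"{ped_path}: marker {ids[l]!r} has more than two alleles: {observed}"
            )
        if observed:
            ref = observed[0]
            geno[:, l] = (al == ref).astype(np.int8) + (bl == ref).astype(np.int8)
            geno[miss, l] = MISSING
    markers, order = _canonical(chroms, ids, pos, warn_on_sort=True)
    return GenotypeDataset(markers, samples, geno[:, order])


def write_plink_text(ds: GenotypeDataset, map_path, ped_path) -> None:
    """Write .map/.ped using 'A' for the reference allele and 'B' for the other."""
    with open(map_path, "w") as fh:
        for c, mid, bp in zip(ds.markers.chromosome, ds.markers.marker_id, ds.markers.position_bp):
            fh.write(f"{c}\t{mid}\t0\t{bp}\n")
    pair = {2: "A A", 1: "A B", 0: "B B", MISSING: "0 0"}
    with open(ped_path, "w") as fh:
        for s, row in zip(ds.samples, ds.genotypes):
            fields = [s, s, "0", "0", "0", "-9"]
            fields.extend(pair[int(g)] for g in row)
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# binary format (.bed / .bim / .fam), SNP-major

# 2-bit PLINK codes: 00 hom A1, 01 missing, 10 het, 11 hom A2


def read_plink_binary(bed_path, bim_path, fam_path) -> GenotypeDataset:
    """Read a SNP-major PLINK .bed/.bim/.fam trio.

    The reference allele is the lexicographically smaller of the two .bim
    alleles (ignoring "0" placeholders), which makes the binary round-trip
    an exact identity for any dataset.
    """
    bim_cols = ["chrom", "id", "cm", "bp", "a1", "a2"]
    try:
        bim = pd.read_csv(
            bim_path,
            sep=r"\s+",
            header=None,
            names=bim_cols,
            dtype={"chrom": str, "id": str, "a1": str, "a2": str},
        )
    except pd.errors.EmptyDataError:
        bim = pd.DataFrame(columns=bim_cols)
    if bim["id"].duplicated().any():
        raise ValueError(f"{bim_path}: duplicate marker id")
    try:
        fam = pd.read_csv(fam_path, sep=r"\s+", header=None, dtype=str)
        samples = [] if fam.empty else list(fam[1])
    except pd.errors.EmptyDataError:
        samples = []
    n, m = len(samples), len(bim)
    raw = Path(bed_path).read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise ValueError(f"{bed_path}: not a PLINK bed file (bad magic bytes)")
    bpm = (n + 3) // 4  # bytes per marker
    if len(raw) != 3 + bpm * m:
        raise ValueError(
            f"{bed_path}: expected {3 + bpm * m} bytes for {n} samples x {m} markers, "
            f"got {len(raw)}"
        )
    geno = np.full((n, m), MISSING, dtype=np.int8)
    if n and m:
        data = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, bpm)
        codes = (data[:, :, None] >> np.array([0, 2, 4, 6], dtype=np.uint8)) & 3
        codes = codes.reshape(m, bpm * 4)[:, :n]  # (markers, samples)
        a1 = bim["a1"].to_numpy()
        a2 = bim["a2"].to_numpy()
        ref_is_a2 = np.array(
            [
                (y != "0" and (x == "0" or y <= x))
                for x, y in zip(a1, a2)
            ]
        )
        # code -> ref count when ref == a2: 00->0, 10->1, 11->2, 01->missing
        lut_a2 = np.array([0, MISSING, 1, 2], dtype=np.int8)
        lut_a1 = np.array([2, MISSING, 1, 0], dtype=np.int8)
        vals = np.where(ref_is_a2[:, None], lut_a2[codes], lut_a1[codes])
        geno = vals.T.astype(np.int8)
    markers, order = _canonical(bim["chrom"], bim["id"], bim["bp"], warn_on_sort=True)
    return GenotypeDataset(markers, samples, geno[:, order])


def write_plink_binary(ds: GenotypeDataset, bed_path, bim_path, fam_path) -> None:
    """Write a SNP-major .bed/.bim/.fam trio (A1='B', A2='A' = reference)."""
    with open(bim_path, "w") as fh:
        for c, mid, bp in zip(ds.markers.chromosome, ds.markers.marker_id, ds.markers.position_bp):
            fh.write(f"{c}\t{mid}\t0\t{bp}\tB\tA\n")
    with open(fam_path, "w") as fh:
        for s in ds.samples:
            fh.write(f"{s} {s} 0 0 0 -9\n")
    n, m = ds.n_samples, ds.n_markers
    bpm = (n + 3) // 4
    out = bytearray(_BED_MAGIC)
    if n and m:
        # ref count -> 2-bit code with A2 = ref: 0->00, 1->10, 2->11, missing->01
        lut = np.array([0, 2, 3, 1], dtype=np.uint8)
        codes = lut[ds.genotypes.T & 3]  # (markers, samples); MISSING & 3 == 3
        padded = np.zeros((m, bpm * 4), dtype=np.uint8)
        padded[:, :n] = codes
        packed = (
            padded[:, 0::4]
            | (padded[:, 1::4] << 2)
            | (padded[:, 2::4] << 4)
            | (padded[:, 3::4] << 6)
        )
        out.extend(packed.astype(np.uint8).tobytes())
    else:
        out.extend(b"\x00" * (bpm * m))
    Path(bed_path).write_bytes(bytes(out))


# ---------------------------------------------------------------------------
# quality side table and QC filters


def read_quality_table(path) -> pd.Series:
    """Read a 2-column TSV (marker_id, score in [0,1]) into a Series."""
    tab = pd.read_csv(path, sep="\t", header=None, names=["marker_id", "score"], dtype={"marker_id": str})
    if ((tab["score"] < 0) | (tab["score"] > 1)).any():
        raise ValueError(f"{path}: quality scores must lie in [0, 1]")
    return tab.set_index("marker_id")["score"]


def attach_quality(ds: GenotypeDataset, scores: Mapping[str, float] | pd.Series) -> GenotypeDataset:
    """Return a copy of ``ds`` with per-marker quality scores aligned by marker id.

    Markers without a score get NaN (treated as "score absent" = pass).
    """
    s = pd.Series(scores, dtype=float)
    q = s.reindex(ds.markers.marker_id).to_numpy()
    return GenotypeDataset(ds.markers, list(ds.samples), ds.genotypes.copy(), q)


@dataclass
class QCReport:
    """Counts of markers/samples removed by the QC filters."""

    n_markers_in: int = 0
    n_markers_removed_quality: int = 0
    n_markers_removed_callrate: int = 0
    n_markers_out: int = 0
    n_samples_in: int = 0
    n_samples_removed: int = 0
    n_samples_out: int = 0

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2) + "\n")


def _subset_markers(ds: GenotypeDataset, keep: np.ndarray) -> GenotypeDataset:
    markers = MarkerMap(
        ds.markers.chromosome[keep],
        ds.markers.marker_id[keep],
        ds.markers.position_bp[keep],
    )
    q = ds.quality[keep] if ds.quality is not None else None
    return GenotypeDataset(markers, list(ds.samples), ds.genotypes[:, keep], q)


def apply_marker_qc(
    ds: GenotypeDataset,
    quality_min: float = 0.70,
    call_rate_min: float = 0.98,
) -> tuple[GenotypeDataset, QCReport]:
    """Remove markers with quality < ``quality_min`` or call rate < ``call_rate_min``.

    A marker with no quality score passes the quality check.  Quality is
    checked first for reporting; total removal is order-invariant.  No MAF
    filter is applied.
    """
    if not (0 <= quality_min <= 1 and 0 <= call_rate_min <= 1):
        raise ValueError("QC thresholds must lie in [0, 1]")
    if ds.quality is None:
        qual_fail = np.zeros(ds.n_markers, dtype=bool)
    else:
        qual_fail = ~np.isnan(ds.quality) & (ds.quality < quality_min)
    call_fail = ds.marker_call_rate() < call_rate_min
    keep = ~(qual_fail | call_fail)
    report = QCReport(
        n_markers_in=ds.n_markers,
        n_markers_removed_quality=int(qual_fail.sum()),
        n_markers_removed_callrate=int((call_fail & ~qual_fail).sum()),
        n_markers_out=int(keep.sum()),
        n_samples_in=ds.n_samples,
        n_samples_removed=0,
        n_samples_out=ds.n_samples,
    )
    return _subset_markers(ds, keep), report


def apply_sample_qc(
    ds: GenotypeDataset, call_rate_min: float = 0.90
) -> tuple[GenotypeDataset, QCReport]:
    """Keep samples whose call rate is strictly greater than ``call_rate_min``."""
    if not 0 <= call_rate_min <= 1:
        raise ValueError("QC thresholds must lie in [0, 1]")
    keep = ds.sample_call_rate() > call_rate_min
    kept = GenotypeDataset(
        ds.markers,
        [s for s, k in zip(ds.samples, keep) if k],
        ds.genotypes[keep],
        None if ds.quality is None else ds.quality.copy(),
    )
    report = QCReport(
        n_markers_in=ds.n_markers,
        n_markers_out=ds.n_markers,
        n_samples_in=ds.n_samples,
        n_samples_removed=int((~keep).sum()),
        n_samples_out=int(keep.sum()),
    )
    return kept, report
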