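"""Cohort-level summaries of ROH and autozygosity distributions.

Skewness is the adjusted Fisher–Pearson sample estimator; the
coefficient of variation is 100 x sd/mean with the n-1 sample standard
deviation; correlations are Pearson's r over pairwise-complete samples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .autozygosity import FrohProfile, GrmDiagonal, profiles_to_frame, tier_label
from .caller import ROHSet

__all__ = ["CohortSummary", "summarize_cohort", "plot_locus_autozygosity"]


@dataclass
class CohortSummary:
    """Length distribution, tiered F_ROH distributions, and correlations."""

    n_samples: int
    n_segments: int
    length_stats_mb: dict[str, float]
    tier_stats: pd.DataFrame
    long_threshold_mb: float
    n_long_exceed: int
    pct_long_exceed: float
    correlations: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "n_samples": self.n_samples,
            "n_segments": self.n_segments,
            "length_stats_mb": self.length_stats_mb,
            "tier_stats": self.tier_stats.to_dict(orient="records"),
            "long_threshold_mb": self.long_threshold_mb,
            "n_long_exceed": self.n_long_exceed,
            "pct_long_exceed": self.pct_long_exceed,
            "correlations": json.loads(self.correlations.to_json()),
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, allow_nan=True) + "\n")


def _dist_stats(x: np.ndarray) -> dict[str, float]:
    out = {
        "min": float(np.min(x)),
        "mean": float(np.mean(x)),
        "median": float(np.median(x)),
        "max": float(np.max(x)),
    }
    out["skewness"] = float(stats.skew(x, bias=False)) if len(x) >= 3 else float("nan")
    mean = np.mean(x)
    out["cv_pct"] = (
        float(100.0 * np.std(x, ddof=1) / mean) if len(x) >= 2 and mean != 0 else float("nan")
    )
    return out


def summarize_cohort(
    rohset: ROHSet,
    profiles: Sequence[FrohProfile],
    grm_diag: GrmDiagonal,
    long_threshold_mb: float = 10.0,
) -> CohortSummary:
    """Cohort statistics over segments, tiered F_ROH profiles and G_ii."""
    prof = profiles_to_frame(profiles).set_index("sample")
    if set(prof.index) != set(rohset.segments) or set(prof.index) != set(grm_diag.g_ii):
        raise ValueError("rohset, profiles and grm_diag cover different samples")
    n = len(prof)

    lengths_mb = np.array([s.length_bp / 1e6 for s in rohset.all_segments()])
    length_stats = (
        {k: float(v) for k, v in _dist_stats(lengths_mb).items() if k in ("min", "mean", "median", "max")}
        if len(lengths_mb)
        else {"min": float("nan"), "mean": float("nan"), "median": float("nan"), "max": float("nan")}
    )

    tier_cols = [c for c in prof.columns if c.startswith("froh_gt_")]
    rows = []
    for col in tier_cols:
        x = prof[col].to_numpy(dtype=float)
        st = _dist_stats(x)
        st["tier"] = col
        st["n_zero"] = int((x == 0).sum())
        st["pct_zero"] = round(100.0 * st["n_zero"] / n, 2) if n else float("nan")
        rows.append(st)
    tier_stats = pd.DataFrame(rows)[
        ["tier", "min", "mean", "median", "max", "skewness", "cv_pct", "n_zero", "pct_zero"]
    ]

    thr_bp = long_threshold_mb * 1e6
    n_exceed = sum(
        1
        for segs in rohset.segments.values()
        if any(s.length_bp > thr_bp for s in segs)
    )
    pct_exceed = round(100.0 * n_exceed / n, 1) if n else float("nan")

    corr_tab = prof[tier_cols].copy()
    corr_tab["g_ii"] = pd.Series(grm_diag.g_ii).reindex(prof.index)
    correlations = corr_tab.corr(method="pearson")

    return CohortSummary(
        n_samples=n,
        n_segments=rohset.n_segments,
        length_stats_mb=length_stats,
        tier_stats=tier_stats,
        long_threshold_mb=long_threshold_mb,
        n_long_exceed=n_exceed,
        pct_long_exceed=pct_exceed,
        correlations=correlations,
    )


def plot_locus_autozygosity(
    locus_frame: pd.DataFrame, out_path, threshold: float = 0.5
) -> None:
    """Manhattan-style plot of F_L along the genome with a line at the threshold."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 3))
    offset = 0
    ticks, labels = [], []
    for k, (chrom, sub) in enumerate(locus_frame.groupby("chrom", sort=False)):
        x = sub["position_bp"].to_numpy() + offset
        ax.scatter(x, sub["f_l"], s=2, color="C0" if k % 2 == 0 else "C1", rasterized=True)
        ticks.append(offset + sub["position_bp"].mean())
        labels.append(str(chrom))
        offset += sub["position_bp"].max()
    ax.axhline(threshold, linestyle="--", color="grey")
    ax.set_xticks(ticks, labels)
    ax.set_ylabel("$F_L$")
    ax.set_xlabel("chromosome")
    ax.set_ylim(0, 1)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
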