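"""End-to-end pipeline driven by a YAML/JSON config.

Stages: input (read PLINK files or simulate) -> QC -> ROH calling ->
F_ROH / G diagonal -> incidence, locus autozygosity and islands ->
cohort summary.  Every artifact is written as deterministic text (TSV,
BED, JSON) so a re-run with the same config is bit-identical.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .autozygosity import (
    chromosome_froh_frame,
    froh_profile,
    genome_coverage,
    grm_diagonal,
    profiles_to_frame,
)
from .caller import ROHParams, call_roh_population
from .io import (
    apply_marker_qc,
    apply_sample_qc,
    attach_quality,
    read_plink_binary,
    read_plink_text,
    read_quality_table,
)
from .islands import (
    find_islands,
    incidence,
    islands_to_frame,
    locus_autozygosity_frame,
    n_min_from_fraction,
)
from .report import plot_locus_autozygosity, summarize_cohort
from .simulate import SimulationConfig, simulate_map, simulate_population

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


class ConfigError(ValueError):
    """Raised before any computation when a config is invalid."""


def load_config(path) -> dict:
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return cfg


def _validate(cfg: dict) -> None:
    if ("inputs" in cfg) == ("simulate" in cfg):
        raise ConfigError("config must contain exactly one of 'inputs' or 'simulate'")
    if "output_dir" not in cfg:
        raise ConfigError("config must name an output_dir")
    if "inputs" in cfg:
        inp = cfg["inputs"]
        fmt = inp.get("format", "text")
        need = {"text": ("map", "ped"), "binary": ("bed", "bim", "fam")}.get(fmt)
        if need is None:
            raise ConfigError(f"unknown input format {fmt!r}")
        for key in need:
            if key not in inp:
                raise ConfigError(f"inputs.{key} is required for format {fmt!r}")
            if not Path(inp[key]).exists():
                raise ConfigError(f"input file not found: {inp[key]}")


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def run_pipeline(config_path, output_dir=None) -> Path:
    """Run the full analysis; returns the output directory.

    Raises :class:`ConfigError` (before computing anything) on a bad
    config; stage failures propagate with the stage named in the log.
    """
    cfg = load_config(config_path) if not isinstance(config_path, dict) else dict(config_path)
    _validate(cfg)
    out = Path(output_dir or cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [
        f"autozyg {__version__} on python {platform.python_version()}",
        f"config: {json.dumps(cfg, sort_keys=True, default=str)}",
    ]

    stage = "input"
    try:
        if "simulate" in cfg:
            sim = dict(cfg["simulate"])
            sim.setdefault("seed", cfg.get("seed", 0))
            chroms = {str(k): int(v) for k, v in sim.pop("chromosomes").items()}
            spec = [tuple(x) for x in sim.pop("segments", [])] or None
            sc = SimulationConfig(
                n_samples=int(sim.pop("n_samples")),
                chromosome_lengths_bp=chroms,
                **({"segment_spec": spec} if spec else {}),
                **sim,
            )
            markers = simulate_map(sc)
            ds, truth = simulate_population(sc, markers)
            truth.write_bed(out / "truth_segments.bed")
        else:
            inp = cfg["inputs"]
            if inp.get("format", "text") == "binary":
                ds = read_plink_binary(inp["bed"], inp["bim"], inp["fam"])
            else:
                ds = read_plink_text(inp["map"], inp["ped"])
            if "quality_table" in inp:
                ds = attach_quality(ds, read_quality_table(inp["quality_table"]))
        log_lines.append(f"input: {ds.n_samples} samples x {ds.n_markers} markers")

        stage = "qc"
        qc = cfg.get("qc", {})
        ds, marker_report = apply_marker_qc(
            ds,
            quality_min=qc.get("marker_quality_min", 0.70),
            call_rate_min=qc.get("marker_call_rate_min", 0.98),
        )
        ds, sample_report = apply_sample_qc(ds, call_rate_min=qc.get("sample_call_rate_min", 0.90))
        marker_report.n_samples_removed = sample_report.n_samples_removed
        marker_report.n_samples_out = sample_report.n_samples_out
        marker_report.to_json(out / "qc_report.json")
        log_lines.append(
            f"qc: kept {marker_report.n_markers_out}/{marker_report.n_markers_in} markers, "
            f"{sample_report.n_samples_out}/{sample_report.n_samples_in} samples"
        )

        stage = "roh"
        params = ROHParams(**cfg.get("roh", {}))
        rohset = call_roh_population(ds, params)
        rohset.write_tsv(out / "roh_segments.tsv")
        rohset.write_bed(out / "roh_segments.bed")
        log_lines.append(f"roh: {rohset.n_segments} segments in {rohset.n_samples} samples")

        stage = "autozygosity"
        coverage = genome_coverage(ds.markers)
        profiles = froh_profile(rohset, coverage)
        _write_tsv(profiles_to_frame(profiles), out / "froh.tsv")
        _write_tsv(chromosome_froh_frame(profiles), out / "froh_chromosome.tsv")
        gd = grm_diagonal(ds, mode=cfg.get("grm_mode", "fixed_half"))
        _write_tsv(gd.to_frame(), out / "grm_diagonal.tsv")

        stage = "islands"
        isl_cfg = cfg.get("islands", {})
        track = incidence(rohset, ds.markers)
        locus = locus_autozygosity_frame(track, ds.markers)
        _write_tsv(locus, out / "locus_autozygosity.tsv")
        n_min = n_min_from_fraction(isl_cfg.get("fraction", 0.5), ds.n_samples)
        found = find_islands(track, ds.markers, isl_cfg.get("s_min_bp", 500_000), n_min)
        _write_tsv(islands_to_frame(found), out / "islands.tsv")
        with open(out / "islands.bed", "w") as fh:
            for isl in found:
                fh.write(f"{isl.chromosome}\t{isl.start_bp - 1}\t{isl.end_bp}\n")
        log_lines.append(f"islands: {len(found)} at n_min={n_min}")
        if cfg.get("plot", {}).get("manhattan", False):
            plot_locus_autozygosity(locus, out / "locus_autozygosity.png")

        stage = "summary"
        summary = summarize_cohort(
            rohset, profiles, gd,
            long_threshold_mb=cfg.get("summary", {}).get("long_threshold_mb", 10.0),
        )
        summary.to_json(out / "summary.json")
    except Exception as exc:
        log_lines.append(f"FAILED at stage {stage}: {exc}")
        (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    log_lines.append("done")
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return out
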