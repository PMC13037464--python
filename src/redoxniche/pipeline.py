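"""End-to-end orchestration: snapshot -> landmarks -> niche -> budget.

One :class:`RunConfig` drives the whole analysis.  A run reads (or
generates) a water-column snapshot, detects the redox landmarks,
classifies the niche window, extrapolates filter counts, runs the
nitrate flux budget and an abundance-nitrate correlation test, and
writes delimited output tables plus a machine-readable manifest (input
hashes, parameters, package version).  Runs are deterministic for a
given seed; reruns produce byte-identical outputs.  On any stage
failure, partial outputs are removed and the error is re-raised with the
stage name.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import __version__
from .abundance import extrapolate_table, records_to_frame
from .budget import FluxModelParams, run_budget
from .errors import PipelineError, ValidationError
from .permstats import perm_cor_test
from .profiles import (
    classify_redox,
    population_in_window,
    read_snapshot,
    write_snapshot,
)
from .synthetic import SyntheticLakeParams, generate_snapshot, sample_filter_counts

logger = logging.getLogger("redoxniche")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Either ``snapshot_path`` (a delimited snapshot table) or
    ``synthetic`` (generator parameters) must be set.  CLI flags override
    config-file values; the config file wins over built-in defaults.
    """

    snapshot_path: Optional[str] = None
    synthetic: Optional[SyntheticLakeParams] = None
    o2_tolerance: float = 0.1
    no3_threshold: float = 0.1
    h2s_threshold: float = 1.0
    r_sp: float = 12.0
    diffusivity: float = 27e-6
    n_perm: int = 20000
    seed: int = 1
    outdir: str = "redoxniche_run"

    def __post_init__(self) -> None:
        for name in ("o2_tolerance", "no3_threshold", "h2s_threshold"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.snapshot_path is None and self.synthetic is None:
            raise ValidationError(
                "config needs either snapshot_path or synthetic parameters"
            )

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "synthetic" in d and d["synthetic"] is not None:
            d["synthetic"] = SyntheticLakeParams(**d["synthetic"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; return the run report (also written as
    ``manifest.json`` in the output directory)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    report: dict = {"config": config.to_dict(), "version": __version__}

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:
                for p in written:
                    p.unlink(missing_ok=True)
                raise PipelineError(f"stage '{name}': {exc}") from exc
        return wrap

    def emit(name: str, writer) -> Path:
        path = outdir / name
        writer(path)
        written.append(path)
        return path

    # --- snapshot -----------------------------------------------------
    def load():
        if config.snapshot_path is not None:
            report["input_sha256"] = _sha256(Path(config.snapshot_path))
            return read_snapshot(config.snapshot_path)
        params = dataclasses.replace(config.synthetic, seed=config.seed)
        return generate_snapshot(params)

    snapshot = stage("snapshot")(load)
    emit("snapshot.tsv", lambda p: write_snapshot(snapshot, p))

    # --- counts and abundance extrapolation ---------------------------
    def counts():
        if config.synthetic is None:
            return None
        params = dataclasses.replace(config.synthetic, seed=config.seed)
        recs = sample_filter_counts(snapshot, params)
        table = extrapolate_table(records_to_frame(recs))
        emit("counts.tsv", lambda p: table.to_csv(p, sep="\t", index=False))
        return table

    stage("abundance")(counts)

    # --- landmarks and classification ---------------------------------
    def classify():
        cls = classify_redox(
            snapshot,
            o2_tolerance=config.o2_tolerance,
            no3_threshold=config.no3_threshold,
            h2s_threshold=config.h2s_threshold,
        )
        emit(
            "classification.tsv",
            lambda p: cls.to_frame().to_csv(p, sep="\t", index=False),
        )
        report["landmarks"] = {
            "interface_depth_m": cls.interface_depth,
            "no3_depletion_depth_m": cls.no3_depletion_depth,
            "sulfide_onset_depth_m": cls.sulfide_onset_depth,
            "niche_window_m": cls.niche_window,
            "warnings": cls.warnings,
        }
        if "abundance" in snapshot:
            report["population_in_window"] = population_in_window(
                snapshot["abundance"], cls
            )
        return cls

    stage("classification")(classify)

    # --- flux budget ---------------------------------------------------
    def budget():
        params = FluxModelParams(r_sp=config.r_sp, diffusivity=config.diffusivity)
        fb = run_budget(snapshot, params)
        emit("budget.tsv", lambda p: fb.to_frame().to_csv(p, sep="\t", index=False))
        peak = fb.peak_layer()
        report["budget"] = {
            "peak_layer": None
            if peak is None
            else {
                "top_m": float(fb.depths[peak]),
                "bottom_m": float(fb.depths[peak + 1]),
                "contribution_pct": float(fb.contribution_pct[peak]),
            }
        }
        return fb

    stage("budget")(budget)

    # --- correlation test ---------------------------------------------
    def cortest():
        if "abundance" not in snapshot or "no3" not in snapshot:
            return None
        ab = snapshot["abundance"]
        no3 = snapshot["no3"].resample(ab.depths)
        res = perm_cor_test(
            ab.values, no3.values, n_perm=config.n_perm, seed=config.seed
        )
        report["cortest_abundance_vs_no3"] = {
            "r": res.r,
            "p_value": res.p_value,
            "n_obs": res.n_obs,
            "n_perm": res.n_perm,
            "exhaustive": res.exhaustive,
        }
        return res

    stage("cortest")(cortest)

    # --- manifest ------------------------------------------------------
    report["outputs"] = {p.name: _sha256(p) for p in written}
    manifest = outdir / "manifest.json"
    manifest.write_text(json.dumps(report, indent=2, sort_keys=True, default=str))
    logger.info("run complete: %d tables in %s", len(written), outdir)
    return report
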