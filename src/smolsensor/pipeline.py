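"""End-to-end reproducible pipeline runs.

A :class:`RunConfig` (YAML-serialisable) declares which stages to run and
their parameters; :func:`run_pipeline` executes them in order (simulate ->
detect -> deconvolve / kinetics / ifquant -> copy-number report), writing
TIFFs, CSV tables and JSON reports into a run directory.  Every stochastic
stage receives a seed derived deterministically from the run seed, so
stages can be re-run in isolation and whole runs are byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import copynumber, deconvolution, ifquant, kinetics, simulate, spots

__all__ = ["RunConfig", "PipelineError", "validate_config", "run_pipeline", "stage_seed"]

# documented seed-splitting rule: stage_seed = (run_seed * 10007 + offset) mod 2^31
STAGE_OFFSETS = {
    "simulate_mixture": 1,
    "simulate_movie": 2,
    "simulate_trace": 3,
    "simulate_iffield": 4,
    "deconvolve": 5,
    "kinetics": 6,
}


def stage_seed(run_seed: int, stage: str) -> int:
    return (int(run_seed) * 10007 + STAGE_OFFSETS[stage]) % (2**31)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, msg: str):
        super().__init__(f"stage '{stage}': {msg}")
        self.stage = stage


@dataclass
class RunConfig:
    """Declarative configuration of one pipeline run."""

    seed: int = 0
    stages: list = field(default_factory=lambda: ["simulate_mixture", "deconvolve"])
    # synthetic mixture / deconvolution
    n_spots: int = 5000
    n_calib: int = 50000
    fractions: list = field(default_factory=lambda: [0.981, 0.019, 0.0])
    mode: str = "scale"
    max_order: int = 3
    n_bins: int = 50
    # movie / detection
    n_frames: int = 10
    pixel_size: float = 0.0867
    psf_sigma: float = 0.09
    min_snr: float = 5.0
    roi_area: float = 100.0
    # kinetics
    kinetic_params: dict = field(default_factory=lambda: dict(
        F_max=1.0, n_syn=2.0, tau_syn=1 / 1.09, n_deg=2.0, tau_deg=1 / 0.13, F0=0.0))
    noise_sd: float = 0.05
    t_start: float = -2.0
    t_stop: float = 15.0
    t_step: float = 0.5
    n_boot: int = 0
    # IF field
    n_cells: int = 20
    frac_transfected: float = 0.5
    transfected_offset: float = 300.0
    # copy-number report
    density: float = 25.0
    surface_area: float = 1500.0
    ploidy: int = 3
    total_copies: int = 23000

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


def validate_config(config: RunConfig) -> list[str]:
    """Check ranges/units; returns a list of violations (empty = ok)."""
    v: list[str] = []
    fr = np.asarray(config.fractions, dtype=float)
    if np.any(fr < 0) or abs(fr.sum() - 1.0) > 1e-9:
        v.append("fractions must be non-negative and sum to 1")
    if config.pixel_size <= 0:
        v.append("pixel_size must be positive")
    if config.psf_sigma <= 0:
        v.append("psf_sigma must be positive")
    if config.roi_area <= 0:
        v.append("roi_area must be positive")
    if config.n_spots < 0 or config.n_calib < 0 or config.n_cells < 0:
        v.append("counts must be non-negative")
    if config.t_step <= 0 or config.t_stop <= config.t_start:
        v.append("time grid must be increasing")
    if config.noise_sd < 0:
        v.append("noise_sd must be non-negative")
    if not set(config.stages) <= set(STAGE_OFFSETS) | {"copy_number"}:
        v.append(f"unknown stages: {set(config.stages) - set(STAGE_OFFSETS) - {'copy_number'}}")
    try:
        kinetics.KineticParams(**config.kinetic_params)
    except (TypeError, ValueError) as e:
        v.append(f"kinetic_params invalid: {e}")
    return v


def run_pipeline(config: RunConfig, outdir) -> Path:
    """Execute the configured stages; returns the run directory."""
    violations = validate_config(config)
    if violations:
        raise PipelineError("config", "; ".join(violations))
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    tag = config.hash()
    report: dict = {"config_hash": tag, "seed": config.seed, "stages": {}}
    mixture_df = calib = None
    trace = None

    for stage in config.stages:
        try:
            if stage == "simulate_mixture":
                mixture_df = simulate.gen_multimer_mixture(
                    config.n_spots, config.fractions, mode=config.mode,
                    seed=stage_seed(config.seed, stage))
                calib = simulate.gen_monomer_intensities(
                    config.n_calib, seed=stage_seed(config.seed, stage) + 1)
                mixture_df.to_csv(out / "mixture.csv", index=False)
                pd.DataFrame({"intensity": calib}).to_csv(out / "calibration.csv", index=False)
                report["stages"][stage] = {"n_spots": config.n_spots}
            elif stage == "simulate_movie":
                spec = simulate.SceneSpec(pixel_size=config.pixel_size, psf_sigma=config.psf_sigma)
                stack, truth = simulate.render_movie(
                    spec, simulate.MonomerModel(), config.n_frames,
                    seed=stage_seed(config.seed, stage), min_separation=3 * config.psf_sigma)
                tifffile.imwrite(out / "movie.tif", stack.astype(np.float32))
                truth.to_csv(out / "movie_truth.csv", index=False)
                table = spots.detect_spots_stack(
                    stack, config.pixel_size, min_snr=config.min_snr, psf_sigma=config.psf_sigma)
                spots.write_spot_table(table, out / "spots.csv")
                dens = spots.spot_density(table, spec.area_um2, per_frame=True,
                                          n_frames=config.n_frames)
                dens.to_csv(out / "density.csv", index=False)
                report["stages"][stage] = {"n_detected": int(len(table))}
            elif stage == "simulate_trace":
                params = kinetics.KineticParams(**config.kinetic_params)
                t = np.arange(config.t_start, config.t_stop + config.t_step / 2, config.t_step)
                trace = simulate.gen_timecourse(params, t, noise_sd=config.noise_sd,
                                                seed=stage_seed(config.seed, stage))
                trace.to_csv(out / "trace.csv")
                report["stages"][stage] = {"n_points": int(t.size)}
            elif stage == "deconvolve":
                if mixture_df is None:
                    raise PipelineError(stage, "no mixture data; run simulate_mixture first")
                model = deconvolution.MultimerMixtureModel.from_samples(
                    mixture_df["intensity"].to_numpy(), calib,
                    M=config.max_order, mode=config.mode, n_bins=config.n_bins)
                res = model.fit(seed=stage_seed(config.seed, stage))
                (out / "deconvolution.json").write_text(json.dumps(res.to_dict(), indent=2))
                report["stages"][stage] = res.to_dict()
            elif stage == "kinetics":
                if trace is None:
                    raise PipelineError(stage, "no trace; run simulate_trace first")
                res = kinetics.fit_timecourse(trace)
                d = res.to_dict()
                if config.n_boot >= 100:
                    ci = res.bootstrap_ci(config.n_boot, seed=stage_seed(config.seed, stage))
                    d["ci"] = {k: [float(ci.loc[k, "lo"]), float(ci.loc[k, "hi"])]
                               for k in ci.index}
                (out / "kinetics.json").write_text(json.dumps(d, indent=2))
                report["stages"][stage] = d
            elif stage == "simulate_iffield":
                channels, truth = simulate.gen_if_field(
                    config.n_cells, frac_transfected=config.frac_transfected,
                    transfected_offset=config.transfected_offset,
                    seed=stage_seed(config.seed, stage))
                for name, img in channels.items():
                    tifffile.imwrite(out / f"if_{name}.tif", img.astype(np.uint16))
                truth.to_csv(out / "if_truth.csv", index=False)
                spec = simulate.IFFieldSpec()
                rois = ifquant.segment_cells(
                    channels["dapi"], channels["cellbody"], spec.pixel_size,
                    channels={"reporter": channels["reporter"], "stain": channels["stain"]})
                rois = ifquant.filter_rois(rois)
                rois.to_csv(out / "cells.csv", index=False)
                report["stages"][stage] = {"n_cells_true": config.n_cells,
                                           "n_rois": int(len(rois))}
            elif stage == "copy_number":
                rep = copynumber.copy_number_report(
                    config.density,
                    copynumber.CellGeometry(config.surface_area, config.ploidy,
                                            config.total_copies))
                (out / "copy_number.json").write_text(json.dumps(rep, indent=2))
                report["stages"][stage] = rep
        except PipelineError:
            raise
        except Exception as e:  # surface the failing stage
            raise PipelineError(stage, str(e)) from e

    (out / "report.json").write_text(json.dumps(report, indent=2))
    return out
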