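"""Configuration-driven orchestration of the full simulation chain:
population generation -> forward field maps -> bandwidth analysis ->
Wiener-deconvolution resolution metrics.

Configs are nested dictionaries (YAML on disk) with explicit unit suffixes
in the key names.  Presets expand to fully specified configs for the
standard scenarios: evoked activity of a hippocampal CA1 patch with
spiking or sub-threshold (EPSP-only) drive, an apical-only (S.R.)
activation variant, and the single planar-cell recording geometry.
All randomness is seeded and recorded, so a config reproduces its outputs
bit-exactly.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .activity import WaveformParams, calibrate_waveforms, compute_ecd, generate_cell_activity
from .forward import SensorGrid, VolumeCorrection, render_field_map
from .geometry import (
    REGION_APICAL,
    REGION_BASAL,
    PopulationLayout,
    build_template_cell,
    place_population,
    sample_event_times,
)
from .reconstruction import (
    NoiseSpec,
    SlabSource,
    calibrate_source_strength,
    noise_level_at_psnr,
    psf,
    psnr,
    resolution_scan,
)
from .spectral import cumulative_power

logger = logging.getLogger("magslice")

__all__ = ["ScenarioConfig", "PRESETS", "run_scenario", "make_fixtures", "load_config"]


_DEFAULT_CONFIG: dict = {
    "population": {
        "width_x_um": 500.0,
        "length_y_um": 500.0,
        "active_thickness_um": 300.0,
        "dead_layer_um": 50.0,
        "cells_per_layer": 1000,
        "layer_thickness_um": 50.0,
        "soma_band_width_um": 50.0,
        "density_subsample": 1.0,
        "apical_length_um": 300.0,
        "basal_length_um": 200.0,
        "n_compartments_per_branch": 10,
        "r_i_megaohm_per_um": 0.12,
        "placement_seed": 1,
    },
    "schedule": {
        "base_event_times_ms": [12.5, 37.5],
        "jitter_sigma_ms": 1.56,
        "region_weight_apical": 0.5,
        "region_weight_basal": 0.5,
        "strength_label": "spiking",
        "schedule_seed": 2,
    },
    "waveform": {
        "case": "spiking",
        "dt_ms": 0.025,
        "duration_ms": 60.0,
        "ap_width_ms": 1.5,
        "ap_latency_ms": 2.0,
        "target_peak_ecd_pam": 0.2,
    },
    "sensor": {
        "extent_um": 1000.0,
        "pixels_m": 20,
        "subsamples_per_pixel": 1,
        "conductivity_s_per_m": 0.3,
        "correction_a1": 1.0,
        "correction_a2_um": 0.0,
        "correction_c_um": 0.0,
        "frame_window_ms": [10.0, 25.0],
        "frame_step_ms": 0.25,
    },
    "analysis": {
        "bandwidth_threshold": 0.95,
        "recon_standoff_um": 50.0,
        "recon_depth_um": 300.0,
        "recon_peak_field_nt": 1.5,
        "recon_delta_um": 7.8125,
        "recon_eta_grid_nt_um": [1.0, 3.0, 10.0, 30.0],
        "recon_area_fov_um2": 1.0e6,
        "psnr_threshold": 10.0,
    },
    "run": {"scenario_name": "custom", "with_fields": True},
}

PRESETS: dict[str, dict] = {
    "slice_spiking": {"run": {"scenario_name": "slice_spiking"}},
    "slice_nonspiking": {
        "run": {"scenario_name": "slice_nonspiking"},
        "schedule": {"strength_label": "non_spiking"},
        "waveform": {"case": "non_spiking"},
    },
    "slice_SR_only": {
        "run": {"scenario_name": "slice_SR_only"},
        "schedule": {"region_weight_apical": 1.0, "region_weight_basal": 0.0},
    },
    "planar_cell": {
        "run": {"scenario_name": "planar_cell", "with_fields": False},
        "analysis": {
            "recon_standoff_um": 1.0,
            "recon_depth_um": 2.0,
            "recon_peak_field_nt": 2.5,
            "recon_delta_um": 1000.0 / 512.0,
        },
    },
}


@dataclass
class ScenarioConfig:
    """A validated, fully expanded scenario configuration."""

    data: dict = field(default_factory=lambda: copy.deepcopy(_DEFAULT_CONFIG))

    @classmethod
    def from_preset(cls, name: str, overrides: dict | None = None) -> "ScenarioConfig":
        if name not in PRESETS:
            raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
        cfg = copy.deepcopy(_DEFAULT_CONFIG)
        _deep_update(cfg, copy.deepcopy(PRESETS[name]))
        if overrides:
            _deep_update(cfg, overrides)
        obj = cls(cfg)
        obj.validate()
        return obj

    @classmethod
    def from_dict(cls, overrides: dict) -> "ScenarioConfig":
        cfg = copy.deepcopy(_DEFAULT_CONFIG)
        _deep_update(cfg, overrides)
        obj = cls(cfg)
        obj.validate()
        return obj

    def validate(self) -> None:
        errors = _unknown_keys(self.data, _DEFAULT_CONFIG)
        if errors:
            raise ValueError("unknown config keys: " + ", ".join(sorted(errors)))

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.data, sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _deep_update(base: dict, overrides: dict, path: str = "") -> None:
    for key, value in overrides.items():
        if isinstance(value, dict) and isinstance(base.get(key), dict):
            _deep_update(base[key], value, f"{path}{key}.")
        else:
            base[key] = value


def _unknown_keys(data: dict, reference: dict, path: str = "") -> list[str]:
    errors = []
    for key, value in data.items():
        if key not in reference:
            errors.append(f"{path}{key}")
        elif isinstance(value, dict) and isinstance(reference[key], dict):
            errors.extend(_unknown_keys(value, reference[key], f"{path}{key}."))
    return errors


def load_config(path: str | Path) -> ScenarioConfig:
    with open(path) as fh:
        overrides = yaml.safe_load(fh) or {}
    preset = overrides.pop("preset", None)
    if preset:
        return ScenarioConfig.from_preset(preset, overrides)
    return ScenarioConfig.from_dict(overrides)


def _build_population(config: ScenarioConfig):
    p = config.data["population"]
    s = config.data["schedule"]
    w = config.data["waveform"]
    subsample = float(p["density_subsample"])
    cells_per_layer = max(1, int(round(p["cells_per_layer"] * subsample)))
    layout = PopulationLayout(
        width_x=p["width_x_um"],
        length_y=p["length_y_um"],
        active_thickness_d=p["active_thickness_um"],
        dead_layer_z0=p["dead_layer_um"],
        cells_per_layer=cells_per_layer,
        layer_thickness=p["layer_thickness_um"],
        soma_band_width_y=p["soma_band_width_um"],
        rng_seed=int(p["placement_seed"]),
    )
    template = build_template_cell(
        apical_length=p["apical_length_um"],
        basal_length=p["basal_length_um"],
        n_compartments_per_branch=int(p["n_compartments_per_branch"]),
        r_i=p["r_i_megaohm_per_um"],
    )
    cells = place_population(layout, template)
    schedule = sample_event_times(
        s["base_event_times_ms"],
        s["jitter_sigma_ms"],
        n_cells=len(cells),
        rng_seed=int(s["schedule_seed"]),
        region_weights={
            REGION_APICAL: s["region_weight_apical"],
            REGION_BASAL: s["region_weight_basal"],
        },
        strength_label=s["strength_label"],
    )
    params = WaveformParams(
        dt=w["dt_ms"],
        duration=w["duration_ms"],
        ap_width=w["ap_width_ms"],
        ap_latency=w["ap_latency_ms"],
        case=w["case"],
    )
    params = calibrate_waveforms(params, w["target_peak_ecd_pam"], cell=template)
    field_rescale = 1.0 / subsample  # linear density rescaling back to full count
    return layout, template, cells, schedule, params, field_rescale


def run_scenario(config: ScenarioConfig, out_dir: str | Path | None = None) -> dict:
    """Execute generate -> forward -> bandwidth -> reconstruct -> report.

    Returns a result bundle; when ``out_dir`` is given, writes NPZ/CSV
    outputs with full provenance (config hash, seeds, package version).
    """
    config.validate()
    t_start = time.time()
    results: dict = {
        "meta": {
            "config": copy.deepcopy(config.data),
            "config_hash": config.config_hash,
            "version": __version__,
        }
    }
    sensor = config.data["sensor"]
    analysis = config.data["analysis"]

    if config.data["run"]["with_fields"]:
        layout, template, cells, schedule, params, rescale = _build_population(config)
        logger.info("population: %d cells in %d layers", len(cells), layout.n_layers)
        traces = [
            generate_cell_activity(cell, schedule.per_cell_event_times[i], params,
                                   region_weights=schedule.region_weights)
            for i, cell in enumerate(cells)
        ]
        grid = SensorGrid(
            extent=sensor["extent_um"],
            pixels_m=int(sensor["pixels_m"]),
            subsamples_per_pixel=int(sensor["subsamples_per_pixel"]),
        )
        correction = VolumeCorrection(
            a1=sensor["correction_a1"], a2=sensor["correction_a2_um"], c=sensor["correction_c_um"]
        )
        t0, t1 = sensor["frame_window_ms"]
        dt = params.dt
        step = max(1, int(round(sensor["frame_step_ms"] / dt)))
        frames = np.arange(int(round(t0 / dt)), int(round(t1 / dt)) + 1, step)
        fmap = render_field_map(
            cells, traces, grid, correction=correction,
            conductivity=sensor["conductivity_s_per_m"], frame_indices=frames,
        )
        for name in ("B_X", "B_Y", "B_Z"):
            arr = getattr(fmap, name)
            arr *= rescale
        fmap.phi *= rescale
        ecd_total = np.zeros((params.time_base.size, 3))
        for cell, trace in zip(cells, traces):
            ecd_total += compute_ecd(cell, trace.I_axial).Q
        ecd_total *= rescale
        peak_pixel = np.unravel_index(np.abs(fmap.B_X).argmax(), fmap.B_X.shape)[:2]
        logger.info("peak |B_X| = %.3g nT", np.abs(fmap.B_X).max())

        # bandwidth on the B_X time course at the spatial peak: re-render the
        # full time series at that single pixel
        bx_tc = _pixel_time_course(cells, traces, grid, peak_pixel, correction,
                                   sensor["conductivity_s_per_m"]) * rescale
        fs_hz = 1000.0 / params.dt
        spectrum = cumulative_power(bx_tc, fs_hz)
        threshold = analysis["bandwidth_threshold"]
        results["fields"] = fmap
        results["ecd_pam"] = ecd_total
        results["bandwidth"] = {
            "f_cutoff_hz": spectrum.f_cutoff_at(threshold),
            "recommended_fs_hz": spectrum.recommended_fs(threshold),
            "threshold": threshold,
        }
        results["peak_fields_nt"] = fmap.peak_B

    source = SlabSource(
        z0=analysis["recon_standoff_um"],
        d=analysis["recon_depth_um"],
        correction=VolumeCorrection(
            a1=sensor["correction_a1"], a2=sensor["correction_a2_um"], c=sensor["correction_c_um"]
        ),
    )
    sigma_j = calibrate_source_strength(
        source, analysis["recon_peak_field_nt"], area_fov=analysis["recon_area_fov_um2"]
    )
    source = SlabSource(z0=source.z0, d=source.d, sigma_j=sigma_j, correction=source.correction)
    delta = analysis["recon_delta_um"]
    scan = resolution_scan(
        source, [delta], analysis["recon_eta_grid_nt_um"], area_fov=analysis["recon_area_fov_um2"]
    )
    eta_threshold = noise_level_at_psnr(
        source, delta, target_psnr=analysis["psnr_threshold"],
        area_fov=analysis["recon_area_fov_um2"],
    )
    results["reconstruction"] = {
        "sigma_j_na": sigma_j,
        "scan": scan,
        "eta_at_psnr_threshold_nt_um": eta_threshold,
    }
    results["meta"]["runtime_s"] = time.time() - t_start

    if out_dir is not None:
        _write_bundle(results, Path(out_dir))
    return results


def _pixel_time_course(cells, traces, grid, pixel, correction, conductivity):
    """Full-resolution B_X time series at one pixel centre."""
    from .forward import MU0_OVER_4PI, _segment_geometry

    centers = grid.pixel_centers()
    point = np.array([[centers[pixel[0]], centers[pixel[1]], grid.plane_z]])
    nt = traces[0].time_base.size
    bx = np.zeros(nt)
    for cell, trace in zip(cells, traces):
        u, rho_vec, rho, l, h, _ = _segment_geometry(cell.starts, cell.ends, point)
        bracket = l / np.hypot(l, rho) - h / np.hypot(h, rho)
        phi_vec = np.cross(np.broadcast_to(u[:, None, :], rho_vec.shape), rho_vec)
        kernel = (MU0_OVER_4PI * bracket / rho**2)[:, 0] * phi_vec[:, 0, 0]
        if not correction.is_identity:
            depth = 0.5 * (cell.starts[:, 2] + cell.ends[:, 2]) - grid.plane_z
            kernel *= np.asarray(correction(depth))
        bx += kernel @ trace.I_axial
    return bx


def _write_bundle(results: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = {
        "config_hash": results["meta"]["config_hash"],
        "version": results["meta"]["version"],
    }
    arrays: dict[str, np.ndarray] = {}
    if "fields" in results:
        fmap = results["fields"]
        arrays.update(
            fields_BX=fmap.B_X, fields_BY=fmap.B_Y, fields_BZ=fmap.B_Z,
            fields_phi=fmap.phi, time_ms=fmap.time_base, ecd_pam=results["ecd_pam"],
        )
        pd.DataFrame(
            {"time_ms": np.arange(results["ecd_pam"].shape[0]),
             "Qx_pam": results["ecd_pam"][:, 0],
             "Qy_pam": results["ecd_pam"][:, 1],
             "Qz_pam": results["ecd_pam"][:, 2]}
        ).to_csv(out_dir / "ecd.csv", index=False)
    np.savez_compressed(out_dir / "results.npz", **arrays, meta=json.dumps(
        {**meta, "config": results["meta"]["config"]}, default=float))
    results["reconstruction"]["scan"].to_csv(out_dir / "resolution_scan.csv", index=False)
    summary = {
        **meta,
        "eta_at_psnr_threshold_nt_um": results["reconstruction"]["eta_at_psnr_threshold_nt_um"],
        "sigma_j_na": results["reconstruction"]["sigma_j_na"],
    }
    if "bandwidth" in results:
        summary["bandwidth"] = results["bandwidth"]
        summary["peak_fields_nt"] = results["peak_fields_nt"]
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)


def make_fixtures(kind: str, out_dir: str | Path) -> list[Path]:
    """Write small deterministic inputs used by the test suite."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if kind == "tiny_population":
        layout = PopulationLayout(cells_per_layer=10, active_thickness_d=50.0, rng_seed=7)
        cells = place_population(layout, build_template_cell())
        soma = np.array([c.soma_position for c in cells])
        path = out_dir / "tiny_population_soma.csv"
        pd.DataFrame(soma, columns=["x_um", "y_um", "z_um"]).to_csv(path, index=False)
        written.append(path)
    elif kind == "point_source_maps":
        from .reconstruction import render_point_source_map

        for name, (z0, d, peak, delta) in {
            "slice": (50.0, 300.0, 1.5, 7.8125),
            "planar": (1.0, 2.0, 2.5, 1000.0 / 512.0),
        }.items():
            src = SlabSource(z0=z0, d=d)
            sj = calibrate_source_strength(src, peak)
            src = SlabSource(z0=z0, d=d, sigma_j=sj)
            bmap = render_point_source_map(src, delta)
            path = out_dir / f"point_source_bx_{name}.npz"
            np.savez_compressed(path, B_X=bmap, delta_um=delta, sigma_j=sj)
            written.append(path)
    elif kind == "tone_signals":
        fs = 10000.0
        t = np.arange(0, 1.0, 1.0 / fs)
        sig = np.sin(2 * np.pi * 100 * t) + np.sin(2 * np.pi * 300 * t)
        path = out_dir / "tones_100_300.csv"
        pd.DataFrame({"t_s": t, "signal": sig}).to_csv(path, index=False)
        written.append(path)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return written
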