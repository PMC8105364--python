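"""End-to-end orchestration: fit half-life -> correct release -> fit power
law -> simulate well concentration -> dose table, driven by one validated
run configuration and writing every intermediate to disk.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Any

import numpy as np

from . import concentration, io, kinetics, release
from .errors import EluteError, SchemaError

log = logging.getLogger("gfelute")

_KNOWN_TOP_KEYS = {
    "output_dir", "seed", "logging_level",
    "degradation", "release", "simulation", "read_times_h",
}
_KNOWN_STAGE_KEYS = {
    "degradation": {"input", "window_h"},
    "release": {
        "input", "vial_volume_ml", "substrate_area_cm2", "wash_recovery_ng",
        "half_life_h", "midpoint_correction",
    },
    "simulation": {
        "system", "t_end_h", "dt_h", "doses", "source", "half_life_h",
    },
}


def validate_config(config: dict[str, Any]) -> None:
    """Reject unknown keys and check stage-level schemas before running."""
    unknown = set(config) - _KNOWN_TOP_KEYS
    if unknown:
        raise SchemaError(f"unknown config key(s): {sorted(unknown)}")
    for stage, allowed in _KNOWN_STAGE_KEYS.items():
        block = config.get(stage)
        if block is None:
            continue
        if not isinstance(block, dict):
            raise SchemaError(f"config block {stage!r} must be a mapping")
        extra = set(block) - allowed
        if extra:
            raise SchemaError(f"unknown key(s) in {stage!r}: {sorted(extra)}")
    sim = config.get("simulation")
    if sim is not None and "doses" not in sim and "source" not in sim:
        raise SchemaError("simulation block needs a 'doses' and/or 'source' entry")


def run_pipeline(config: dict[str, Any], output_dir: str | Path | None = None) -> dict[str, Any]:
    """Execute the configured stages in dependency order.

    Returns a dict of in-memory artifacts keyed by stage; every stage also
    writes its CSV (plus metadata sidecar) under ``output_dir``. A failing
    stage aborts with the stage name while earlier outputs stay on disk.
    """
    validate_config(config)
    out_dir = Path(output_dir or config.get("output_dir", "."))
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Any] = {}
    half_life = None

    if "degradation" in config:
        stage = "degradation"
        try:
            block = config[stage]
            window = tuple(block.get("window_h", kinetics.DEFAULT_WINDOW))
            tcs = io.read_timecourse_csv(block["input"])
            log.info("degradation: %d replicates, window %s h", len(tcs), window)
            fits = kinetics.fit_replicates(tcs, window=window)
            summary = kinetics.summarize_fits(fits)
            half_life = summary.mean_t_half
            io.write_results(
                io.fits_to_frame(fits, summary), out_dir / "halflife_fits.csv",
                metadata={"window_h": list(window), "input": str(block["input"])},
            )
            artifacts[stage] = {"fits": fits, "summary": summary}
            log.info("degradation: mean half-life %.2f ± %.2f h", summary.mean_t_half,
                     summary.sd_t_half)
        except EluteError as exc:
            raise EluteError(f"stage {stage!r} failed: {exc}") from exc

    if "release" in config:
        stage = "release"
        try:
            block = config[stage]
            studies = io.read_release_csv(block["input"], block)
            hl = block.get("half_life_h") or half_life or release.DEFAULT_CORRECTION_HALF_LIFE_H
            log.info("release: %d replicates, correction half-life %.2f h", len(studies), hl)
            corrected_frames, pl_fits = [], {}
            for study in studies:
                corr = release.correct_study(
                    study, half_life=hl,
                    midpoint=bool(block.get("midpoint_correction", False)),
                )
                m_inf = release.m_infinity(corr, study.wash_recovery)
                pl_fits[study.replicate_id] = release.fit_power_law(corr, m_inf)
                corrected_frames.append(
                    io.corrected_to_frame(corr, study.condition_label, study.replicate_id)
                )
            import pandas as pd

            io.write_results(
                pd.concat(corrected_frames, ignore_index=True),
                out_dir / "corrected_release.csv",
                metadata={"half_life_h": hl},
            )
            io.write_results(
                io.powerlaw_to_frame(pl_fits), out_dir / "powerlaw_fits.csv",
                metadata={"half_life_h": hl},
            )
            artifacts[stage] = {"fits": pl_fits, "half_life_h": hl}
            ks = [f.K for f in pl_fits.values()]
            ns = [f.n for f in pl_fits.values()]
            log.info("release: K = %.4g ± %.2g, n = %.3f ± %.3f",
                     np.mean(ks), np.std(ks), np.mean(ns), np.std(ns))
        except EluteError as exc:
            raise EluteError(f"stage {stage!r} failed: {exc}") from exc

    if "simulation" in config:
        stage = "simulation"
        try:
            block = config[stage]
            sys_block = block.get("system", {})
            system = concentration.CultureSystem(
                surface_area=float(sys_block.get("surface_area_cm2", 1.9)),
                media_volume=float(sys_block.get("media_volume_ml", 0.6)),
            )
            hl = block.get("half_life_h") or half_life or release.DEFAULT_CORRECTION_HALF_LIFE_H
            k = kinetics.rate_from_half_life(hl)
            profiles: dict[str, concentration.ConcentrationProfile] = {}
            cfg_kwargs = dict(
                k=k, t_end=float(block["t_end_h"]), dt=float(block.get("dt_h", 0.05))
            )
            if "source" in block:
                src = dict(block["source"])
                fit = release.PowerLawFit(
                    K=float(src["K"]), n=float(src["n"]),
                    M_infinity=float(src["M_infinity_ng_per_cm2"]),
                    r_squared=float(src.get("r_squared", float("nan"))),
                    fit_domain=(0.0, float(block["t_end_h"])),
                )
                cfg = concentration.SimulationConfig(
                    **cfg_kwargs, study_area=float(src.get("study_area_cm2", 1.0))
                )
                profiles["eluting"] = concentration.simulate_eluting(fit, system, cfg)
            for i, dose_block in enumerate(block.get("doses", [])):
                events = [
                    concentration.DoseEvent(
                        time=float(d["time_h"]),
                        concentration_increment=float(d["conc_ng_ml"]),
                    )
                    for d in dose_block["schedule"]
                ]
                cfg = concentration.SimulationConfig(**cfg_kwargs)
                label = dose_block.get("label", f"exogenous_{i + 1}")
                profiles[label] = concentration.simulate_exogenous(events, system, cfg)
            for label, profile in profiles.items():
                io.write_results(
                    io.profile_to_frame(profile), out_dir / f"profile_{label}.csv",
                    metadata={"half_life_h": hl, "system": system},
                )
            artifacts[stage] = {"profiles": profiles, "half_life_h": hl}
            if config.get("read_times_h"):
                table = concentration.condition_table(
                    profiles, list(config["read_times_h"])
                )
                io.write_results(
                    table.reset_index(), out_dir / "dose_table.csv",
                    metadata={"read_times_h": list(config["read_times_h"])},
                )
                artifacts["dose_table"] = table
        except EluteError as exc:
            raise EluteError(f"stage {stage!r} failed: {exc}") from exc

    return artifacts
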