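"""CSV/YAML readers and writers.

Canonical internal units are hours, ng/mL, mL and cm²; every public column
name carries its unit suffix (``time_h``, ``conc_ng_ml``) so unit drift is
visible at the boundary. A ``time_d`` column is accepted and converted to
hours on read. Writers emit a JSON metadata sidecar (parameters, software
version, config hash) next to each CSV so outputs are self-describing.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from pathlib import Path
from typing import Any, Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .concentration import ConcentrationProfile
from .errors import SchemaError
from .kinetics import FirstOrderFit, FitSummary, Timecourse
from .qcmd import LayerMassProfile, QcmdTrace
from .release import CorrectedRelease, PowerLawFit, ReleaseStudy

TIMECOURSE_COLUMNS = ("condition", "replicate", "time_h", "conc_ng_ml")
RELEASE_COLUMNS = ("condition", "replicate", "time_h", "aliquot_conc_ng_ml")


def _read_table(path: str | Path, required: Sequence[str], time_col: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file not found: {path}")
    df = pd.read_csv(path)
    cols = set(df.columns)
    day_col = time_col.replace("_h", "_d")
    if time_col not in cols and day_col in cols:
        df[time_col] = df[day_col] * 24.0
        df = df.drop(columns=[day_col])
        cols = set(df.columns)
    missing = [c for c in required if c not in cols]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    if df[list(required)].isna().any().any():
        bad = int(df[df[list(required)].isna().any(axis=1)].index[0])
        raise SchemaError(f"{path}: missing value at row {bad}")
    return df


def read_timecourse_csv(path: str | Path) -> list[Timecourse]:
    """Read a degradation-assay CSV into per-replicate timecourses.

    Expected columns: ``condition,replicate,time_h,conc_ng_ml`` (``time_d``
    accepted, converted to hours).
    """
    df = _read_table(path, TIMECOURSE_COLUMNS, "time_h")
    out = []
    for (cond, rep), grp in df.groupby(["condition", "replicate"], sort=False):
        grp = grp.sort_values("time_h")
        if grp["time_h"].duplicated().any():
            t = grp.loc[grp["time_h"].duplicated(), "time_h"].iloc[0]
            raise SchemaError(
                f"duplicated time {t} h in condition {cond!r} replicate {rep!r}"
            )
        out.append(
            Timecourse(
                condition_label=str(cond),
                replicate_id=str(rep),
                samples=tuple(zip(grp["time_h"], grp["conc_ng_ml"])),
            )
        )
    return out


def read_release_csv(path: str | Path, study_config: dict[str, Any]) -> list[ReleaseStudy]:
    """Read a release-study CSV plus its sidecar config.

    ``study_config`` supplies ``vial_volume_ml``, ``substrate_area_cm2`` and
    ``wash_recovery_ng`` (scalars, applied to every replicate).
    """
    for key in ("vial_volume_ml", "substrate_area_cm2", "wash_recovery_ng"):
        if key not in study_config:
            raise SchemaError(f"study config missing key {key!r}")
    df = _read_table(path, RELEASE_COLUMNS, "time_h")
    out = []
    for (cond, rep), grp in df.groupby(["condition", "replicate"], sort=False):
        grp = grp.sort_values("time_h")
        out.append(
            ReleaseStudy(
                condition_label=str(cond),
                replicate_id=str(rep),
                vial_volume=float(study_config["vial_volume_ml"]),
                substrate_area=float(study_config["substrate_area_cm2"]),
                samples=tuple(zip(grp["time_h"], grp["aliquot_conc_ng_ml"])),
                wash_recovery=float(study_config["wash_recovery_ng"]),
            )
        )
    return out


def read_qcmd_csv(trace_path: str | Path, steps_path: str | Path) -> QcmdTrace:
    """Read a long-format QCM-D trace plus step annotations.

    Trace columns: ``time_min,overtone,delta_f_hz,delta_d``; steps columns:
    ``label,start_min,end_min``.
    """
    trace = _read_table(trace_path, ("time_min", "overtone", "delta_f_hz", "delta_d"), "time_min")
    steps = pd.read_csv(steps_path)
    for c in ("label", "start_min", "end_min"):
        if c not in steps.columns:
            raise SchemaError(f"{steps_path}: missing column {c!r}")
    times = np.sort(trace["time_min"].unique())
    delta_f: dict[int, np.ndarray] = {}
    delta_d: dict[int, np.ndarray] = {}
    for n, grp in trace.groupby("overtone"):
        grp = grp.sort_values("time_min")
        if grp["time_min"].to_numpy().shape != times.shape or not np.allclose(
            grp["time_min"].to_numpy(), times
        ):
            raise SchemaError(f"overtone {n}: time grid differs from other overtones")
        delta_f[int(n)] = grp["delta_f_hz"].to_numpy(dtype=float)
        delta_d[int(n)] = grp["delta_d"].to_numpy(dtype=float)
    annotations = tuple(
        (str(r.label), float(r.start_min), float(r.end_min)) for r in steps.itertuples()
    )
    return QcmdTrace(times=times, delta_f=delta_f, delta_d=delta_d, steps=annotations)


def timecourses_to_frame(tcs: Iterable[Timecourse]) -> pd.DataFrame:
    rows = [
        {"condition": tc.condition_label, "replicate": tc.replicate_id,
         "time_h": t, "conc_ng_ml": c}
        for tc in tcs
        for t, c in tc.samples
    ]
    return pd.DataFrame(rows, columns=list(TIMECOURSE_COLUMNS))


def studies_to_frame(studies: Iterable[ReleaseStudy]) -> pd.DataFrame:
    rows = [
        {"condition": s.condition_label, "replicate": s.replicate_id,
         "time_h": t, "aliquot_conc_ng_ml": c}
        for s in studies
        for t, c in s.samples
    ]
    return pd.DataFrame(rows, columns=list(RELEASE_COLUMNS))


def qcmd_to_frames(trace: QcmdTrace) -> tuple[pd.DataFrame, pd.DataFrame]:
    rows = [
        {"time_min": t, "overtone": n, "delta_f_hz": trace.delta_f[n][i],
         "delta_d": trace.delta_d[n][i]}
        for n in trace.overtones
        for i, t in enumerate(trace.times)
    ]
    steps = [{"label": l, "start_min": s, "end_min": e} for l, s, e in trace.steps]
    return pd.DataFrame(rows), pd.DataFrame(steps)


def fits_to_frame(fits: Sequence[FirstOrderFit], summary: FitSummary | None = None) -> pd.DataFrame:
    """One row per replicate fit, plus an optional trailing summary row."""
    rows = [
        {
            "condition": f.condition_label,
            "replicate": f.replicate_id,
            "k_per_h": f.k,
            "t_half_h": f.t_half,
            "ln_n0": f.ln_n0,
            "r_squared": f.r_squared,
            "window_start_h": f.window[0],
            "window_end_h": f.window[1],
            "n_points": f.n_points,
            "positive_slope": f.positive_slope,
        }
        for f in fits
    ]
    df = pd.DataFrame(rows)
    if summary is not None:
        df = pd.concat(
            [
                df,
                pd.DataFrame(
                    [{
                        "condition": fits[0].condition_label if fits else "",
                        "replicate": "summary(mean±sd)",
                        "t_half_h": summary.mean_t_half,
                        "t_half_sd_h": summary.sd_t_half,
                        "r_squared": summary.mean_r_squared,
                        "n_points": summary.n_replicates,
                    }]
                ),
            ],
            ignore_index=True,
        )
    return df


def corrected_to_frame(
    corrected: CorrectedRelease, condition: str = "", replicate: str = ""
) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "condition": condition,
            "replicate": replicate,
            "time_h": corrected.times,
            "cumulative_ng": corrected.cumulative_ng,
            "interval_true_ng": list(corrected.interval_true_release),
            "correction_k_per_h": corrected.correction_k,
        }
    )


def powerlaw_to_frame(fits: dict[str, PowerLawFit]) -> pd.DataFrame:
    rows = [
        {"replicate": rep, "K_per_h_pow_n": f.K, "n": f.n,
         "M_infinity_ng": f.M_infinity, "r_squared": f.r_squared,
         "fit_start_h": f.fit_domain[0], "fit_end_h": f.fit_domain[1]}
        for rep, f in fits.items()
    ]
    return pd.DataFrame(rows)


def profile_to_frame(profile: ConcentrationProfile) -> pd.DataFrame:
    return pd.DataFrame({"time_h": profile.times, "conc_ng_ml": profile.concentrations})


def layer_profile_to_frame(profile: LayerMassProfile) -> pd.DataFrame:
    return pd.DataFrame(
        [{"step": s.label, "mass_ng_per_cm2": s.mass, "increment_ng_per_cm2": s.increment}
         for s in profile.steps]
    )


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and not math.isfinite(obj):
        return str(obj)
    return obj


def config_hash(config: dict[str, Any]) -> str:
    payload = json.dumps(_jsonable(config), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def write_results(
    df: pd.DataFrame,
    path: str | Path,
    metadata: dict[str, Any] | None = None,
) -> Path:
    """Write a CSV at full float precision plus a JSON metadata sidecar.

    The sidecar (``<name>.meta.json``) records the software version, the
    parameters supplied in ``metadata`` and a hash of them, so every output
    file documents how it was produced. Floats are written with 17
    significant digits, so values round-trip bit-exactly through
    ``pd.read_csv(..., float_precision="round_trip")``.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.17g")
    meta = {
        "software": "gfelute",
        "version": __version__,
        "parameters": _jsonable(metadata or {}),
        "config_hash": config_hash(metadata or {}),
    }
    sidecar = path.with_suffix(path.suffix + ".meta.json").with_name(
        path.stem + ".meta.json"
    )
    sidecar.write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path


def load_config(path: str | Path) -> dict[str, Any]:
    """Load a YAML (or JSON) run configuration."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"config file not found: {path}")
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: config must be a mapping")
    return cfg
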