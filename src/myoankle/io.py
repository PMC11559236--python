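"""CSV/JSON readers and writers for EMG traces, gait trials and configs."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .signal_chain import CONTROL_RATE_HZ, ChainConfig, EmgTrace
from .myo_controller import SchedulerConfig
from .plant_bench import PlantConfig
from .gait_pipeline import GaitTrial

__all__ = [
    "read_emg_csv",
    "write_emg_csv",
    "read_trial_csv",
    "write_trial_csv",
    "load_config",
]


def write_emg_csv(emg: EmgTrace, path: str | Path) -> None:
    """Write `time_s,emg_mv` CSV plus a metadata sidecar JSON."""
    path = Path(path)
    pd.DataFrame({"time_s": emg.time, "emg_mv": emg.samples}).to_csv(path, index=False)
    meta = {"rate_hz": emg.rate, "muscle": emg.muscle, "side": emg.side}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_emg_csv(path: str | Path) -> EmgTrace:
    """Read an EMG CSV; rate from the sidecar JSON or the time column."""
    path = Path(path)
    df = pd.read_csv(path)
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        rate = float(meta.get("rate_hz", CONTROL_RATE_HZ))
        muscle = meta.get("muscle", "gastrocnemius")
        side = meta.get("side", "residual")
    else:
        dt = np.median(np.diff(df["time_s"].to_numpy()))
        rate, muscle, side = 1.0 / dt, "gastrocnemius", "residual"
    return EmgTrace(df["emg_mv"].to_numpy(), rate, muscle, side)


def write_trial_csv(trial: GaitTrial, path: str | Path) -> None:
    """Write a gait trial CSV: time, angle, moment, GRF and EMG columns."""
    cols = {
        "time_s": trial.time,
        "theta_deg": trial.theta,
        "moment_nm_kg": trial.moment,
        "grf_n": trial.grf_z,
    }
    for m, ch in trial.emg.items():
        cols[f"emg_{m}"] = ch
    pd.DataFrame(cols).to_csv(path, index=False)


def read_trial_csv(path: str | Path, rate: float | None = None) -> GaitTrial:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    if rate is None:
        rate = 1.0 / float(np.median(np.diff(t)))
    emg = {
        c.removeprefix("emg_"): df[c].to_numpy()
        for c in df.columns
        if c.startswith("emg_")
    }
    return GaitTrial(
        time=t,
        theta=df["theta_deg"].to_numpy(),
        moment=df["moment_nm_kg"].to_numpy(),
        grf_z=df["grf_n"].to_numpy(),
        rate=rate,
        emg=emg,
    )


def load_config(path: str | Path) -> dict:
    """Load a JSON config with optional `control_chain`, `analysis_chain`,
    `controller` and `plant` sections, returning constructed objects."""
    raw = json.loads(Path(path).read_text())
    out: dict = {}
    if "control_chain" in raw:
        out["control_chain"] = ChainConfig(**raw["control_chain"])
    if "analysis_chain" in raw:
        out["analysis_chain"] = ChainConfig(**raw["analysis_chain"])
    if "controller" in raw:
        out["controller"] = SchedulerConfig(**raw["controller"])
    if "plant" in raw:
        out["plant"] = PlantConfig(**raw["plant"])
    return out
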