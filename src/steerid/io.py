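"""Serialization of trials, kernels, and spectra.

Trial records are written as one CSV per trial (columns t, T_world,
T_displayed, H_world, H_displayed, x, r) with a dataset-level JSON sidecar
holding the task/plant configuration, kernel provenance, and seed.  An
optional HDF5 container packs a whole dataset into one file.  Kernels are
two-column CSVs (lag_s, k) with a JSON header; spectra are CSVs
(freq_hz, power) with a JSON header.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .kernels import Kernel
from .noise import Spectrum
from .tasks import PlantConfig, TaskConfig, TrialRecord

__all__ = [
    "save_dataset",
    "load_dataset",
    "save_dataset_hdf5",
    "load_dataset_hdf5",
    "save_kernel",
    "load_kernel",
    "save_spectrum",
    "load_spectrum",
]

_TRIAL_COLUMNS = ["t", "T_world", "T_displayed", "H_world", "H_displayed", "x", "r"]


def trial_to_frame(trial: TrialRecord) -> pd.DataFrame:
    return pd.DataFrame({c: getattr(trial, c) for c in _TRIAL_COLUMNS})


def _meta_jsonable(meta: dict) -> dict:
    out = {}
    for k, v in meta.items():
        out[k] = v.tolist() if isinstance(v, np.ndarray) else v
    return out


def save_dataset(
    trials: list[TrialRecord],
    out_dir: str | Path,
    cfg: TaskConfig | None = None,
    plant: PlantConfig | None = None,
    seed: int | None = None,
    kernel_provenance: dict | None = None,
) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    trial_meta = []
    for i, tr in enumerate(trials):
        trial_to_frame(tr).to_csv(out_dir / f"trial_{i:04d}.csv", index=False)
        trial_meta.append(_meta_jsonable(tr.meta))
    sidecar = {
        "n_trials": len(trials),
        "task_config": dataclasses.asdict(cfg) if cfg else None,
        "plant_config": dataclasses.asdict(plant) if plant else None,
        "seed": seed,
        "kernel_provenance": kernel_provenance,
        "trial_meta": trial_meta,
    }
    (out_dir / "dataset.json").write_text(json.dumps(sidecar, indent=1))
    return out_dir


def load_dataset(
    in_dir: str | Path,
) -> tuple[list[TrialRecord], TaskConfig | None, PlantConfig | None]:
    in_dir = Path(in_dir)
    sidecar = json.loads((in_dir / "dataset.json").read_text())
    cfg = TaskConfig(**sidecar["task_config"]) if sidecar.get("task_config") else None
    if cfg is not None:
        # tuples arrive as lists from JSON
        for f in ("step_amplitudes", "step_amplitude_weights",
                  "step_duration_range", "drift_update_range"):
            setattr(cfg, f, tuple(getattr(cfg, f)))
    plant = (
        PlantConfig(**sidecar["plant_config"]) if sidecar.get("plant_config") else None
    )
    trials = []
    for i in range(sidecar["n_trials"]):
        df = pd.read_csv(in_dir / f"trial_{i:04d}.csv")
        meta = dict(sidecar["trial_meta"][i]) if sidecar.get("trial_meta") else {}
        for key in ("step_times", "step_amplitudes"):
            if key in meta and meta[key] is not None:
                meta[key] = np.asarray(meta[key], dtype=float)
        trials.append(
            TrialRecord(**{c: df[c].to_numpy() for c in _TRIAL_COLUMNS}, meta=meta)
        )
    return trials, cfg, plant


def save_dataset_hdf5(trials: list[TrialRecord], path: str | Path) -> Path:
    import h5py

    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["n_trials"] = len(trials)
        for i, tr in enumerate(trials):
            g = f.create_group(f"trial_{i:04d}")
            for c in _TRIAL_COLUMNS:
                g.create_dataset(c, data=getattr(tr, c))
            g.attrs["meta"] = json.dumps(_meta_jsonable(tr.meta))
    return path


def load_dataset_hdf5(path: str | Path) -> list[TrialRecord]:
    import h5py

    trials = []
    with h5py.File(path, "r") as f:
        for i in range(int(f.attrs["n_trials"])):
            g = f[f"trial_{i:04d}"]
            meta = json.loads(g.attrs["meta"])
            for key in ("step_times", "step_amplitudes"):
                if key in meta and meta[key] is not None:
                    meta[key] = np.asarray(meta[key], dtype=float)
            trials.append(
                TrialRecord(**{c: g[c][()] for c in _TRIAL_COLUMNS}, meta=meta)
            )
    return trials


def save_kernel(kernel: Kernel, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"lag_s": kernel.lag_grid, "k": kernel.k}).to_csv(path, index=False)
    header = {
        "truncation_lag": kernel.truncation_lag,
        "weights": kernel.weights.tolist() if kernel.weights is not None else None,
        **kernel.meta,
    }
    path.with_suffix(".json").write_text(json.dumps(header, indent=1))
    return path


def load_kernel(path: str | Path) -> Kernel:
    path = Path(path)
    df = pd.read_csv(path)
    header_path = path.with_suffix(".json")
    header = json.loads(header_path.read_text()) if header_path.exists() else {}
    weights = header.pop("weights", None)
    trunc = header.pop("truncation_lag", float(df["lag_s"].iloc[-1]))
    return Kernel(
        lag_grid=df["lag_s"].to_numpy(), k=df["k"].to_numpy(),
        weights=np.asarray(weights) if weights is not None else None,
        truncation_lag=trunc, meta=header,
    )


def save_spectrum(spec: Spectrum, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"freq_hz": spec.frequencies, "power": spec.power}).to_csv(
        path, index=False
    )
    header = {
        "normalization": spec.normalization,
        "n_trials": spec.n_trials,
        "trial_length": spec.trial_length,
    }
    path.with_suffix(".json").write_text(json.dumps(header, indent=1))
    return path


def load_spectrum(path: str | Path) -> Spectrum:
    path = Path(path)
    df = pd.read_csv(path)
    header_path = path.with_suffix(".json")
    header = json.loads(header_path.read_text()) if header_path.exists() else {}
    return Spectrum(
        frequencies=df["freq_hz"].to_numpy(), power=df["power"].to_numpy(),
        normalization=header.get("normalization", "none"),
        n_trials=header.get("n_trials", 0),
        trial_length=header.get("trial_length", 0),
    )
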