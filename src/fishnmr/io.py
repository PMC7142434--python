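"""Readers/writers and configuration for the analysis pipeline.

Decay curves travel as two-column CSV (time_ms, signal) with an optional
JSON sidecar (<stem>.meta.json) carrying sample mass, label and the
generating noise level; cohorts are described by a JSON manifest.  All
formats are plain text.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from fishnmr.relaxometry import T2Distribution, WaterPools
from fishnmr.synthetic import DecayCurve, SampleSet

__all__ = [
    "DecayFormatError",
    "PipelineConfig",
    "read_decay_csv",
    "write_decay_csv",
    "write_distribution_csv",
    "write_pools_csv",
    "write_manifest",
    "read_manifest",
    "load_config",
    "config_hash",
]


class DecayFormatError(ValueError):
    """Malformed decay file; carries the offending row where known."""


def read_decay_csv(path: str | Path) -> DecayCurve:
    """Read a decay curve from CSV with header ``time_ms,signal``.

    Mass, label and noise level are taken from a ``<stem>.meta.json``
    sidecar when present (mass defaults to 1 g).
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns[:2]) != ["time_ms", "signal"]:
        raise DecayFormatError(
            f"{path}: expected header 'time_ms,signal', got {list(df.columns)}"
        )
    times = df["time_ms"].to_numpy(dtype=float)
    signal = df["signal"].to_numpy(dtype=float)
    for name, col in (("time_ms", times), ("signal", signal)):
        bad = np.flatnonzero(~np.isfinite(col))
        if bad.size:
            raise DecayFormatError(
                f"{path}: non-finite {name} at data row {bad[0] + 1}"
            )
    non_mono = np.flatnonzero(np.diff(times) <= 0)
    if non_mono.size:
        raise DecayFormatError(
            f"{path}: time_ms not strictly increasing at data row {non_mono[0] + 2}"
        )
    meta_path = path.with_suffix(".meta.json")
    mass_g, label, noise_sd = 1.0, None, None
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        mass_g = float(meta.get("mass_g", 1.0))
        label = meta.get("label")
        noise_sd = meta.get("noise_sd")
    return DecayCurve(
        times_ms=times, signal=signal, mass_g=mass_g, noise_sd=noise_sd, label=label
    )


def write_decay_csv(decay: DecayCurve, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame({"time_ms": decay.times_ms, "signal": decay.signal}).to_csv(
        path, index=False, float_format="%.17g"
    )
    meta = {"mass_g": decay.mass_g, "label": decay.label, "noise_sd": decay.noise_sd}
    path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=1))


def write_distribution_csv(dist: T2Distribution, path: str | Path) -> None:
    pd.DataFrame(
        {"t2_ms": dist.grid.values_ms, "amplitude": dist.amplitudes}
    ).to_csv(path, index=False, float_format="%.10g")


def write_pools_csv(rows: dict[str, WaterPools], path: str | Path) -> None:
    """Write a pool table (one row per sample or group) mirroring the
    T21/T22/T23 + per-gram area layout."""
    records = []
    for name, pools in rows.items():
        row = {"sample": name}
        row.update(pools.as_row())
        records.append(row)
    pd.DataFrame(records).to_csv(path, index=False, float_format="%.6g")


def write_manifest(samples: SampleSet, path: str | Path, decay_files: list[str]) -> None:
    entries = []
    for i, (decay, texture, label) in enumerate(
        zip(samples.decays, samples.textures, samples.labels)
    ):
        entries.append(
            {
                "sample_id": i,
                "decay_file": decay_files[i],
                "label": label,
                "mass_g": decay.mass_g,
                "texture": dataclasses.asdict(texture),
            }
        )
    Path(path).write_text(
        json.dumps({"seed": samples.seed, "samples": entries}, indent=1)
    )


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


@dataclass(frozen=True)
class PipelineConfig:
    """Settings for the end-to-end simulate -> invert -> model pipeline."""

    out_dir: str = "results/pipeline"
    seed: int = 42
    tau_us: float = 200.0
    n_echoes: int = 8000
    n_per_group: int = 9
    n_validation_per_group: int = 4
    decay_noise_sd: float = 0.0
    texture_noise_frac: float = 0.05
    pool_scatter_frac: float = 0.1
    mass_g: float = 6.0
    grid_points: int = 128
    lam: float | str = "auto"
    max_factors: int = 10
    downsample: int = 8
    profiles: tuple[str, ...] = (
        "control",
        "boiling",
        "steaming",
        "roasting",
        "frying",
    )

    def __post_init__(self) -> None:
        from fishnmr.profiles import TREATMENT_PROFILES

        unknown = set(self.profiles) - set(TREATMENT_PROFILES)
        if unknown:
            raise ValueError(f"unknown profiles: {sorted(unknown)}")
        if not isinstance(self.seed, int):
            raise ValueError("seed must be an integer")


def load_config(path: str | Path) -> PipelineConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    if "profiles" in data:
        data["profiles"] = tuple(data["profiles"])
    return PipelineConfig(**data)


def config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
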