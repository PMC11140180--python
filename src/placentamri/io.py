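"""File formats and configuration.

NIfTI-1 for image volumes (via nibabel), CSV sidecars for acquisition
grids and T2-prep series, JSON for results, YAML for pipeline
configuration.  The configuration schema is strict: unknown keys are
rejected, and every output file carries a provenance header (package
version, seed, config hash).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .model import AcquisitionGrid
from .oximetry import T2PrepSeries

__all__ = [
    "read_image",
    "write_image",
    "read_grid_csv",
    "write_grid_csv",
    "read_t2prep_csv",
    "write_t2prep_csv",
    "PipelineConfig",
    "load_config",
    "provenance",
]


def read_image(path):
    """Load a NIfTI volume: returns (data, affine, header)."""
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine, img.header


def write_image(path, data, affine=None):
    """Write a NIfTI-1 volume (identity affine by default)."""
    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))


def read_mask(path):
    """Load a mask volume; any nonzero voxel is True."""
    data, _, _ = read_image(path)
    return data != 0


def read_grid_csv(path) -> AcquisitionGrid:
    """Acquisition grid sidecar: columns b_s_per_mm2, TE_ms, volume_index."""
    df = pd.read_csv(path, comment="#")
    required = {"b_s_per_mm2", "TE_ms", "volume_index"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"grid CSV missing columns: {sorted(missing)}")
    df = df.sort_values("volume_index")
    if not (df["volume_index"].to_numpy() == np.arange(len(df))).all():
        raise ValueError("volume_index must be 0..n-1 without gaps")
    return AcquisitionGrid(tuple(zip(df["b_s_per_mm2"], df["TE_ms"])))


def write_grid_csv(path, grid: AcquisitionGrid, header: str = ""):
    df = pd.DataFrame(
        {
            "b_s_per_mm2": grid.b,
            "TE_ms": grid.te,
            "volume_index": np.arange(len(grid)),
        }
    )
    _write_csv(path, df, header)


def read_t2prep_csv(path, vessel_label: str = "UV") -> T2PrepSeries:
    """Per-vessel T2-prep series: columns prep_time_ms, signal."""
    df = pd.read_csv(path, comment="#")
    missing = {"prep_time_ms", "signal"} - set(df.columns)
    if missing:
        raise ValueError(f"T2-prep CSV missing columns: {sorted(missing)}")
    df = df.sort_values("prep_time_ms")
    return T2PrepSeries(
        prep_times=tuple(df["prep_time_ms"]),
        signals=tuple(df["signal"]),
        vessel_label=vessel_label,
    )


def write_t2prep_csv(path, series: T2PrepSeries, header: str = ""):
    df = pd.DataFrame(
        {"prep_time_ms": series.prep_times, "signal": series.signals}
    )
    _write_csv(path, df, header)


def _write_csv(path, df: pd.DataFrame, header: str = ""):
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


class DesignConfig(BaseModel):
    """Cohort-design overrides (subset of CohortDesign fields)."""

    model_config = ConfigDict(extra="forbid")

    n_animals: int = 7
    v_increase_tad2: bool = True
    v_effect: float = 0.08
    uta_fraction_decrease: bool = True
    uta_flow_factor: float = 0.78
    map_decrease: bool = True
    map_effect: float = 12.0
    snr_placentome: float = 50.0
    snr_t2prep: float = 100.0
    phase_noise_sd: float = 0.01
    placentome_shape: tuple[int, int, int] = (4, 4, 2)
    n_phases: int = 15
    pixel_size_mm: float = 0.5


class FitConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    method: str = "trf"
    ftol: float = 1e-10
    max_iter: int = 400
    fv_penalty: float = 1e3
    t2mb_ms: float = 150.0
    t2ts_ms: float = 42.0


class PipelineConfig(BaseModel):
    """Schema-validated pipeline configuration (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    calibration: str = "sheep_default"
    b_values: list[float] = Field(
        default=[0.0, 50.0, 100.0, 200.0, 400.0, 600.0]
    )
    te_values: list[float] = Field(default=[72.0, 96.0, 120.0, 144.0, 192.0])
    prep_times: list[float] = Field(
        default=[32.0, 64.0, 96.0, 128.0, 160.0, 192.0]
    )
    design: DesignConfig = Field(default_factory=DesignConfig)
    fit: FitConfig = Field(default_factory=FitConfig)
    variables: list[str] = Field(
        default=[
            "f", "v", "d", "d_star", "t2fb", "so2_fetoplacental",
            "lvco", "q_uta", "q_uv", "q_uta_pct_lvco",
            "fetal_do2", "fetal_vo2", "oef", "uta_do2_pct_available",
        ]
    )
    alpha: float = 0.05


def load_config(path) -> PipelineConfig:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig(**raw)


def config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.model_dump(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def provenance(config: PipelineConfig | None = None, seed: int | None = None) -> str:
    """Provenance header line for output files."""
    parts = [f"placentamri v{__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if config is not None:
        parts.append(f"config_hash={config_hash(config)}")
    return " ".join(parts)
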