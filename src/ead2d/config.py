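"""Run configuration: YAML files, schema validation, provenance.

``RunConfig`` is the validated, serializable description of one piece of
work (a cell sweep, a 2D run, a tissue sweep, an analysis, or fixture
generation).  Every CLI run writes a config snapshot next to its outputs
so any artifact is regenerable from the snapshot alone.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, field_validator

from . import __version__

__all__ = ["RunConfig", "ModelMultipliers", "load_config", "save_snapshot",
           "apply_overrides", "config_schema"]


class ModelMultipliers(BaseModel):
    """Dimensionless scalings of the EAD-relevant maximal conductances."""

    mult_CaL: float = Field(1.0, ge=0)
    mult_Ks: float = Field(1.0, ge=0)
    mult_Kr: float = Field(1.0, ge=0)
    mult_NaCa: float = Field(1.0, ge=0)
    tau_f_scale: float = Field(0.5, gt=0)


class CellSweepConfig(BaseModel):
    x_mults: list[float] = Field(default=[1, 2, 3, 4, 5, 6, 7, 8])
    y_channel: Literal["Ks", "Kr", "NaCa"] = "Ks"
    y_mults: list[float] = Field(default=[0.0, 0.2, 0.4, 0.6, 0.8, 1.0])
    n_beats: int = Field(1, ge=1)
    cycle_length: float = Field(1000.0, ge=300.0)
    dt: float = Field(0.02, gt=0, le=0.1)


class TissueRunConfig(BaseModel):
    nx: int = Field(600, ge=10)
    ny: int = Field(600, ge=10)
    dx: float = Field(0.25, gt=0)
    dt: float = Field(0.02, gt=0, le=0.1)
    D: float = Field(0.00154, ge=0)
    duration: float = Field(1000.0, ge=0)
    frame_interval: float = Field(5.0, gt=0)
    protocol: Literal["p1", "p2", "paced", "none"] = "p1"
    stim_amplitude: float = 20.0
    stim_duration: float = 2.0
    strip_width: int = Field(6, ge=1)
    strip_height: Optional[int] = None
    pacing_period: float = Field(1000.0, ge=300.0)
    pacing_epoch: float = Field(3000.0, ge=0)
    barrier_block: Optional[int] = Field(None, ge=4)
    barrier_thickness: int = Field(1, ge=1)
    barrier_start: float = 0.0
    record_gates: bool = True


class AnalysisSection(BaseModel):
    v_thresh: float = -30.0
    na_floor: float = -60.0
    na_avail_min: float = 0.01
    sf_split: float = 0.2
    osc_amp_max: float = 40.0
    v_active: float = -70.0
    sustain_window_ms: float = 3000.0
    spectrum_points: int = 10000
    min_spectrum_ms: float = 4000.0


class FixtureSection(BaseModel):
    kind: str = "osc_ap"
    k_eads: int = 0
    seed: int = 0
    duration: float = 5000.0
    ny: int = 40
    nx: int = 40
    f_hz: float = 6.0
    na_led: bool = True


class RunConfig(BaseModel):
    """Top-level validated configuration."""

    task: Literal["cell-sweep", "run", "tissue-sweep", "analyze",
                  "fixtures"] = "run"
    model: ModelMultipliers = ModelMultipliers()
    cell_sweep: CellSweepConfig = CellSweepConfig()
    tissue: TissueRunConfig = TissueRunConfig()
    analysis: AnalysisSection = AnalysisSection()
    fixtures: FixtureSection = FixtureSection()
    # tissue-sweep grids (each point is one 2D run)
    sweep_x_mults: list[float] = Field(default=[1, 2, 4, 6, 8])
    sweep_y_mults: list[float] = Field(default=[0.2, 0.4, 0.6, 0.8, 1.0])
    sweep_y_channel: Literal["Ks", "Kr", "NaCa"] = "Ks"
    out_dir: str = "ead2d-out"
    seed: int = 0
    version: str = __version__

    @field_validator("version", mode="before")
    @classmethod
    def _any_version(cls, v):
        return str(v)

    def tissue_config(self):
        from .tissue2d import BarrierSpec, TissueConfig
        t = self.tissue
        barrier = None
        if t.barrier_block is not None:
            barrier = BarrierSpec(block=t.barrier_block,
                                  thickness=t.barrier_thickness,
                                  start_time=t.barrier_start)
        return TissueConfig(
            nx=t.nx, ny=t.ny, dx=t.dx, dt=t.dt, D=t.D, duration=t.duration,
            frame_interval=t.frame_interval, protocol=t.protocol,
            stim_amplitude=t.stim_amplitude, stim_duration=t.stim_duration,
            strip_width=t.strip_width, strip_height=t.strip_height,
            pacing_period=t.pacing_period, pacing_epoch=t.pacing_epoch,
            mult_CaL=self.model.mult_CaL, mult_Ks=self.model.mult_Ks,
            mult_Kr=self.model.mult_Kr, mult_NaCa=self.model.mult_NaCa,
            tau_f_scale=self.model.tau_f_scale, barrier=barrier,
            record_gates=t.record_gates)

    def analysis_config(self):
        from .pattern_analysis import AnalysisConfig
        a = self.analysis
        return AnalysisConfig(
            v_thresh=a.v_thresh, na_floor=a.na_floor,
            na_avail_min=a.na_avail_min, sf_split=a.sf_split,
            osc_amp_max=a.osc_amp_max, v_active=a.v_active,
            sustain_window_ms=a.sustain_window_ms,
            spectrum_points=a.spectrum_points,
            min_spectrum_ms=a.min_spectrum_ms)


def config_schema() -> dict:
    """The published JSON schema of the config format."""
    return RunConfig.model_json_schema()


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(data)


def apply_overrides(cfg: RunConfig, overrides: list[str]) -> RunConfig:
    """Apply ``section.key=value`` strings on top of a config."""
    data = cfg.model_dump()
    for ov in overrides:
        if "=" not in ov:
            raise ValueError(f"override {ov!r} is not of the form key=value")
        key, raw = ov.split("=", 1)
        try:
            val = json.loads(raw)
        except json.JSONDecodeError:
            val = raw
        node = data
        parts = key.split(".")
        for part in parts[:-1]:
            if part not in node or not isinstance(node[part], dict):
                raise KeyError(f"unknown config section {part!r} in {key!r}")
            node = node[part]
        if parts[-1] not in node:
            raise KeyError(f"unknown config key {key!r}")
        node[parts[-1]] = val
    return RunConfig.model_validate(data)


def save_snapshot(cfg: RunConfig, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "config_snapshot.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.model_dump(), fh, sort_keys=False)
    return path
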