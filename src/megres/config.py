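"""Study configuration: one flat record of every knob in the pipeline.

Defaults reproduce the simulated study's reference conditions: a 306-channel
helmet (102 magnetometers, 204 planar gradiometers), a 17-subject cohort,
noise covariances from 146 trials of 200 ms baseline, regularization from
SNR = 3, and a trial-averaging divisor of 100 for dSPM weighting.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .cohort import DEFAULT_GRADIOMETER_BASELINE, GeometryConfig


@dataclass
class StudyConfig:
    # geometry
    n_mag: int = 102
    n_grad: int = 204
    n_sources: int = 1000
    n_subjects: int = 17
    conductor_radius: float = 0.09
    helmet_radius: float = 0.12
    fold_depth: float = 0.03
    fold_frequency: float = 6.0
    jitter_scale: float = 0.002
    gradiometer_baseline: float = DEFAULT_GRADIOMETER_BASELINE
    # noise simulation
    n_trials: int = 146
    baseline_duration: float = 0.2
    sampling_rate: float = 250.0
    brain_noise_fraction: float = 0.5
    # inverse operators
    snr: float = 3.0
    n_averages: int = 100
    # analysis selection
    methods: tuple = ("MNE", "dSPM", "sLORETA")
    modes: tuple = ("PSF", "CTF")
    metrics: tuple = ("DLE", "SD", "OA")
    # bookkeeping
    output_dir: str = "megres_output"
    master_seed: int = 0
    max_dense_sources: int = 4000

    def __post_init__(self) -> None:
        self.methods = tuple(self.methods)
        self.modes = tuple(self.modes)
        self.metrics = tuple(self.metrics)
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.helmet_radius <= self.conductor_radius:
            raise ValueError("helmet_radius must exceed conductor_radius")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        bad = set(self.methods) - {"MNE", "dSPM", "sLORETA"}
        if bad:
            raise ValueError(f"unknown methods: {sorted(bad)}")
        if set(self.modes) - {"PSF", "CTF"}:
            raise ValueError(f"unknown modes: {sorted(set(self.modes) - {'PSF', 'CTF'})}")
        if set(self.metrics) - {"DLE", "SD", "OA"}:
            raise ValueError(
                f"unknown metrics: {sorted(set(self.metrics) - {'DLE', 'SD', 'OA'})}")
        if self.n_sources > self.max_dense_sources:
            raise ValueError(
                f"n_sources={self.n_sources} exceeds max_dense_sources="
                f"{self.max_dense_sources} (dense resolution matrices); "
                "raise max_dense_sources explicitly to override"
            )

    def geometry(self) -> GeometryConfig:
        return GeometryConfig(
            n_mag=self.n_mag,
            n_grad=self.n_grad,
            n_sources=self.n_sources,
            conductor_radius=self.conductor_radius,
            helmet_radius=self.helmet_radius,
            fold_depth=self.fold_depth,
            fold_frequency=self.fold_frequency,
            gradiometer_baseline=self.gradiometer_baseline,
        )


def load_config(path, **overrides) -> StudyConfig:
    """Load a flat YAML key-value config; unknown keys are errors, never ignored."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a flat mapping")
    raw.update(overrides)
    known = {f.name for f in fields(StudyConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return StudyConfig(**raw)


def save_config(config: StudyConfig, path) -> None:
    data = {f.name: getattr(config, f.name) for f in fields(StudyConfig)}
    for key in ("methods", "modes", "metrics"):
        data[key] = list(data[key])
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


__all__ = ["StudyConfig", "load_config", "save_config"]
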