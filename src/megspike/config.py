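"""Pipeline configuration.

All numeric knobs of the two-stage spike-detection pipeline live in a single
dataclass so a run is fully described by one YAML file.  Field names map
one-to-one onto the YAML schema.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Numeric parameters of the spike-detection pipeline.

    Defaults are the operating point of the published two-stage procedure:
    20 ICA components of which the first 10 (by explained variance) are
    screened by excess kurtosis in [1, 10] and dipolar goodness of fit
    (0.80 for magnetometers, 0.60 for gradiometers, 0.95 overriding the
    kurtosis gate), adaptive peak detection in the 20-90 Hz band until at
    least 300 peaks, a 0.5 s refractory interval, rank-1 convolutional
    sparse coding with 3 atoms of 0.5 s and lambda = 0.1 on 1 s epochs,
    MAD-threshold event assignment from 7 down to 1.5 MAD aiming at >= 15
    events, 4 runs (12 candidate atoms per sensor type), 50 % binarization,
    majority voting and 10 mm smoothing for the irritative-zone map, and a
    3 mm margin around the resection border.
    """

    n_ica: int = 20
    n_ica_ranked: int = 10
    kurtosis_range: tuple[float, float] = (1.0, 10.0)
    gof_threshold_mag: float = 0.80
    gof_threshold_grad: float = 0.60
    gof_override: float = 0.95
    peak_band: tuple[float, float] = (20.0, 90.0)
    min_peaks: int = 300
    music_window: tuple[float, float] = (-0.020, 0.030)
    refractory: float = 0.5
    csc_band: tuple[float, float] = (2.0, 90.0)
    n_atoms_per_run: int = 3
    atom_len: float = 0.5
    lambda_reg: float = 0.1
    epoch_len: float = 1.0
    mad_start: float = 7.0
    mad_floor: float = 1.5
    min_events: int = 15
    events_cap: int = 20
    n_runs: int = 4
    binarize_frac: float = 0.5
    smooth_mm: float = 10.0
    resection_margin_mm: float = 3.0

    # non-numeric plumbing
    peak_threshold_grid: tuple[float, ...] = (8, 7, 6, 5, 4, 3, 2.5, 2)
    mad_grid: tuple[float, ...] = (7, 6, 5, 4, 3, 2.5, 2, 1.5)
    csc_n_iter: int = 30
    csc_tol: float = 1e-5
    lambda2_inverse: float = 1.0 / 9.0
    excluded_atoms: tuple[str, ...] = ()
    seed: int = 0

    def gof_threshold(self, sensor_type: str) -> float:
        if sensor_type == "magnetometer":
            return self.gof_threshold_mag
        if sensor_type == "gradiometer":
            return self.gof_threshold_grad
        raise ValueError(f"no GOF threshold for sensor type {sensor_type!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        # YAML-friendly: tuples -> lists
        return {k: list(v) if isinstance(v, tuple) else v for k, v in d.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in d:
                v = d[f.name]
                if isinstance(v, list):
                    v = tuple(v)
                kwargs[f.name] = v
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
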