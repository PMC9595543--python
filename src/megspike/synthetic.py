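"""Synthetic MEG fixtures: forward models, spike recordings, ground truth.

The generator emulates the data regime the detection pipeline is designed
for: a 10-20 minute recording at 200 Hz in which a small number of focal
cortical sources emit brief (70-200 ms) biphasic interictal spikes a few
times per minute, seen at the sensors as repeating rank-1 spatiotemporal
patterns (a fixed dipolar topography times a stereotyped waveform)
superimposed on 1/f-shaped Gaussian background noise.

The forward geometry is a hemispheric shell: sources on a cortex-like shell
of ~80 mm radius, sensors on a helmet shell outside it, and leadfield columns
given by the field of a tangential current dipole -- smooth, dipolar and
mutually distinguishable patterns, without claiming BEM realism.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data_model import CorticalMap, ForwardModel, SensorRecording

MIN_EVENT_SEPARATION = 0.5  # s, matches the pipeline's refractory interval


@dataclass
class GroundTruth:
    """Planted sources and events of a simulated recording."""

    true_atoms: list[tuple[np.ndarray, np.ndarray]]  # (u_true, v_true)
    event_times: list[np.ndarray]  # seconds, per atom
    true_vertices: list[int]
    resection_center: np.ndarray | None = None
    resection_radius: float | None = None
    seed: int = 0

    @property
    def all_event_times(self) -> np.ndarray:
        if not self.event_times:
            return np.array([])
        return np.sort(np.concatenate(self.event_times))

    def save(self, path: str | Path) -> None:
        d = {
            "true_atoms": [[u.tolist(), v.tolist()] for u, v in self.true_atoms],
            "event_times": [t.tolist() for t in self.event_times],
            "true_vertices": list(map(int, self.true_vertices)),
            "resection_center": None if self.resection_center is None
            else np.asarray(self.resection_center).tolist(),
            "resection_radius": self.resection_radius,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(d))

    @classmethod
    def load(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            true_atoms=[(np.array(u), np.array(v)) for u, v in d["true_atoms"]],
            event_times=[np.array(t) for t in d["event_times"]],
            true_vertices=d["true_vertices"],
            resection_center=None if d["resection_center"] is None
            else np.array(d["resection_center"]),
            resection_radius=d["resection_radius"],
            seed=d["seed"],
        )


def _fibonacci_hemisphere(n: int, radius: float) -> np.ndarray:
    """Quasi-uniform points on the upper half of a sphere (z >= 0), mm."""
    i = np.arange(n)
    golden = (1 + 5 ** 0.5) / 2
    z = (i + 0.5) / n  # upper hemisphere only
    phi = 2 * np.pi * i / golden
    r_xy = np.sqrt(1 - z ** 2)
    pts = np.stack([r_xy * np.cos(phi), r_xy * np.sin(phi), z], axis=1)
    return radius * pts


def _tangent_basis(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two orthonormal tangential directions at each point of a sphere."""
    r_hat = points / np.linalg.norm(points, axis=1, keepdims=True)
    ref = np.tile(np.array([0.0, 0.0, 1.0]), (len(points), 1))
    near_pole = np.abs(r_hat[:, 2]) > 0.98
    ref[near_pole] = [1.0, 0.0, 0.0]
    t1 = np.cross(ref, r_hat)
    t1 /= np.linalg.norm(t1, axis=1, keepdims=True)
    t2 = np.cross(r_hat, t1)
    return t1, t2


def _dipole_pattern(src: np.ndarray, moment: np.ndarray, sensors: np.ndarray,
                    normals: np.ndarray) -> np.ndarray:
    """Field of a point current dipole, measured along sensor normals.

    B(r) ~ m x (r - p) / |r - p|^3 (Biot-Savart point dipole); constants are
    irrelevant since leadfield columns are only used up to scale.
    """
    d = sensors - src[None, :]
    dist = np.linalg.norm(d, axis=1)
    b = np.cross(np.broadcast_to(moment, d.shape), d) / dist[:, None] ** 3
    return np.einsum("ij,ij->i", b, normals)


def simulate_forward(n_channels: int, n_vertices: int, seed: int = 0,
                     n_orientations: int = 1,
                     shell_radius_mm: float = 80.0,
                     helmet_radius_mm: float = 110.0) -> ForwardModel:
    """Synthetic forward model on a hemispheric shell.

    Sources sit on a shell of ``shell_radius_mm`` (cortex-like), sensors on a
    helmet shell outside.  Each leadfield column is the dipolar field pattern
    of a tangential current dipole at the vertex; with fixed orientation the
    tangential direction is drawn once per vertex (seeded), with free
    orientations the three columns span radial + two tangential axes.
    """
    if n_vertices < 10:
        raise ValueError("need at least 10 vertices")
    if n_channels < 4:
        raise ValueError("degenerate sensor array")
    rng = np.random.default_rng(seed)
    vertices = _fibonacci_hemisphere(n_vertices, shell_radius_mm)
    sensors = _fibonacci_hemisphere(n_channels, helmet_radius_mm)
    normals = sensors / np.linalg.norm(sensors, axis=1, keepdims=True)
    t1, t2 = _tangent_basis(vertices)

    cols = []
    if n_orientations == 1:
        angles = rng.uniform(0, 2 * np.pi, n_vertices)
        for j in range(n_vertices):
            m = np.cos(angles[j]) * t1[j] + np.sin(angles[j]) * t2[j]
            cols.append(_dipole_pattern(vertices[j], m, sensors, normals))
    elif n_orientations == 3:
        r_hat = vertices / np.linalg.norm(vertices, axis=1, keepdims=True)
        for j in range(n_vertices):
            for m in (t1[j], t2[j], r_hat[j]):
                cols.append(_dipole_pattern(vertices[j], m, sensors, normals))
    else:
        raise ValueError("n_orientations must be 1 or 3")
    leadfield = np.stack(cols, axis=1)
    ch_names = [f"SYN{j:04d}" for j in range(n_channels)]
    return ForwardModel(leadfield, vertices, ch_names, n_orientations)


def spike_waveform(sfreq: float, width_s: float, length_s: float = 0.5) -> np.ndarray:
    """Spike-and-wave template of total duration ``width_s``, unit L2 norm.

    A sharp biphasic transient (derivative of a Gaussian with sigma =
    width/20, so the complex keeps energy in the 20-90 Hz band like real
    interictal spikes) is followed by a slower after-wave continuing the
    second phase; the whole complex spans roughly ``width_s`` (70-200 ms).
    The sharp positive peak sits at the center of the window.
    """
    n = int(round(length_s * sfreq))
    t = (np.arange(n) - n // 2) / sfreq
    s_sharp = width_s / 20.0
    sharp = -(t / s_sharp) * np.exp(-t ** 2 / (2 * s_sharp ** 2))
    s_wave = width_s / 5.0
    delay = width_s / 3.0
    wave = -0.5 * np.exp(-(t - delay) ** 2 / (2 * s_wave ** 2))
    w = sharp + wave
    # sharp positive peak (at t = -s_sharp) to the window center
    w = np.roll(w, int(round(s_sharp * sfreq)))
    return w / np.linalg.norm(w)


def _one_over_f_noise(n_channels: int, n_samples: int, sfreq: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with ~1/f power spectrum, unit variance per channel."""
    white = rng.standard_normal((n_channels, n_samples))
    freqs = np.fft.rfftfreq(n_samples, 1.0 / sfreq)
    shape = 1.0 / np.sqrt(np.maximum(freqs, 1.0))  # flat below 1 Hz
    spec = np.fft.rfft(white, axis=1) * shape[None, :]
    noise = np.fft.irfft(spec, n=n_samples, axis=1)
    noise /= noise.std(axis=1, keepdims=True)
    return noise


def _poisson_events(rate_per_s: float, duration_s: float, pad_s: float,
                    min_sep: float, rng: np.random.Generator) -> np.ndarray:
    n_expect = rate_per_s * duration_s
    n = rng.poisson(n_expect)
    t = np.sort(rng.uniform(pad_s, duration_s - pad_s, n))
    kept: list[float] = []
    for ti in t:
        if not kept or ti - kept[-1] >= min_sep:
            kept.append(ti)
    return np.array(kept)


def simulate_recording(fwd: ForwardModel, n_atoms: int, rate_per_min: float,
                       duration_s: float, snr: float, seed: int = 0,
                       spike_width_range: tuple[float, float] = (0.07, 0.2),
                       sensor_type: str = "gradiometer",
                       min_vertex_dist_mm: float = 40.0,
                       ) -> tuple[SensorRecording, GroundTruth]:
    """Plant repeating rank-1 spike patterns in 1/f background noise.

    Each atom is ``u_true * v_true(t)`` with ``u_true`` the unit-normalized
    leadfield pattern of a randomly chosen vertex and ``v_true`` a biphasic
    spike of 70-200 ms.  Events follow a Poisson process thinned to a global
    separation of >= 0.5 s.  ``snr`` is the ratio of the spike's peak
    amplitude to the background RMS at the atom's best channel; snr = 0
    plants nothing but still reports the ground-truth events.
    """
    if duration_s < 60:
        raise ValueError("duration must be at least 60 s")
    total_rate_per_s = n_atoms * rate_per_min / 60.0
    if total_rate_per_s * 2 * MIN_EVENT_SEPARATION >= 1.0:
        raise ValueError("event rate incompatible with 0.5 s separation")
    rng = np.random.default_rng(seed)
    sfreq = 200.0
    n_samples = int(round(duration_s * sfreq))
    n_ch = fwd.n_channels

    # well-separated source vertices
    vertices: list[int] = []
    order = rng.permutation(fwd.n_vertices)
    for j in order:
        if all(np.linalg.norm(fwd.vertex_coords[j] - fwd.vertex_coords[k])
               >= min_vertex_dist_mm for k in vertices):
            vertices.append(int(j))
        if len(vertices) == n_atoms:
            break
    if len(vertices) < n_atoms:
        raise ValueError("could not place requested atoms with separation")

    data = _one_over_f_noise(n_ch, n_samples, sfreq, rng)

    true_atoms: list[tuple[np.ndarray, np.ndarray]] = []
    event_times: list[np.ndarray] = []
    all_times = np.array([])
    for j in vertices:
        if fwd.n_orientations == 1:
            u = fwd.vertex_columns(j)[:, 0].copy()
        else:
            ori = rng.standard_normal(fwd.n_orientations)
            u = fwd.vertex_columns(j) @ (ori / np.linalg.norm(ori))
        u /= np.linalg.norm(u)
        width = rng.uniform(*spike_width_range)
        v = spike_waveform(sfreq, width)
        # Poisson times for this atom, thinned against all placed events
        t = _poisson_events(rate_per_min / 60.0, duration_s, 1.0,
                            MIN_EVENT_SEPARATION, rng)
        if all_times.size:
            dist = np.min(np.abs(t[:, None] - all_times[None, :]), axis=1)
            t = t[dist >= MIN_EVENT_SEPARATION]
        all_times = np.sort(np.concatenate([all_times, t]))
        true_atoms.append((u, v))
        event_times.append(t)

        if snr > 0 and t.size:
            best = int(np.argmax(np.abs(u)))
            amp = snr / (np.abs(u[best]) * np.abs(v).max())  # noise RMS is 1
            peak_off = int(np.argmax(np.abs(v)))
            pattern = amp * np.outer(u, v)
            for ti in t:
                s0 = int(round(ti * sfreq)) - peak_off
                if s0 < 0 or s0 + v.size > n_samples:
                    continue
                data[:, s0:s0 + v.size] += pattern

    ch_names = list(fwd.channel_names)
    rec = SensorRecording(data, sfreq, ch_names, [sensor_type] * n_ch)
    gt = GroundTruth(true_atoms, event_times, vertices, seed=seed)
    return rec, gt


def make_resection_mask(fwd: ForwardModel, center: np.ndarray, radius_mm: float,
                        margin_mm: float = 3.0) -> CorticalMap:
    """Binary mask of vertices inside the resection or within its margin."""
    if radius_mm <= 0:
        raise ValueError("radius must be positive")
    center = np.asarray(center, dtype=float)
    dist = np.linalg.norm(fwd.vertex_coords - center[None, :], axis=1)
    values = (dist <= radius_mm + margin_mm).astype(float)
    if not values.any():
        raise ValueError("resection mask selects no vertex")
    return CorticalMap(values, fwd.vertex_coords, kind="binary")
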