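"""Source reconstruction and irritative-zone mapping.

Cluster averages (and visually marked spikes) are localized with a
Tikhonov-regularized minimum-norm inverse built from the forward model and a
diagonal noise covariance.  Per-atom activation maps are computed at two
latencies of the averaged waveform -- PEAK (maximum global field power) and
SLOPE (first sample at 50 % of the peak on the ascending branch) --
binarized at 50 % of the maximum activation, combined by majority voting
across atoms and dilated by 10 mm to delineate the predicted irritative
zone.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .config import PipelineConfig
from .csc import Atom
from .data_model import CorticalMap, EventTable, ForwardModel, SensorRecording
from .music import music_scan  # noqa: F401  (re-exported convenience)

logger = logging.getLogger(__name__)


class EdgePeakError(RuntimeError):
    """Averaged waveform peaks at the window edge; atom unusable for mapping."""


@dataclass
class InverseOperator:
    """Minimum-norm inverse: W maps whitened sensor data to source amplitudes."""

    W: np.ndarray  # [(n_vertices * n_orientations) x n_channels]
    noise_diag: np.ndarray
    lambda2: float
    n_orientations: int
    vertex_coords: np.ndarray

    def apply(self, data: np.ndarray) -> np.ndarray:
        """Source amplitudes for sensor data [n_channels] or [C x T]."""
        data = np.asarray(data, dtype=float)
        white = (data.T / np.sqrt(self.noise_diag)).T
        return self.W @ white

    def vertex_magnitude(self, data: np.ndarray) -> np.ndarray:
        """Per-vertex source magnitude (norm over free orientations)."""
        amp = self.apply(data)
        if self.n_orientations == 1:
            return np.abs(amp)
        shaped = amp.reshape(-1, self.n_orientations, *amp.shape[1:])
        return np.linalg.norm(shaped, axis=1)


def make_inverse(fwd: ForwardModel, noise_diag: np.ndarray,
                 lambda2: float = 1.0 / 9.0) -> InverseOperator:
    """Build W = G_w^T (G_w G_w^T + lambda2 * mu I)^-1 in whitened coordinates.

    ``noise_diag`` are per-channel noise variances (the diagonal covariance);
    ``lambda2`` follows the usual 1/SNR^2 convention and is scaled by the
    mean sensor-space power ``mu = trace(G_w G_w^T) / n_channels`` so that it
    is dimensionless.
    """
    noise_diag = np.asarray(noise_diag, dtype=float)
    if np.any(noise_diag <= 0):
        raise ValueError("noise variances must be strictly positive")
    gw = fwd.leadfield / np.sqrt(noise_diag)[:, None]
    gram = gw @ gw.T
    mu = np.trace(gram) / fwd.n_channels
    reg = lambda2 * mu
    try:
        w = np.linalg.solve(gram + reg * np.eye(fwd.n_channels), gw).T
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(
            "singular sensor gram matrix; increase lambda2") from e
    return InverseOperator(w, noise_diag, lambda2, fwd.n_orientations,
                           fwd.vertex_coords)


@dataclass
class ClusterAverage:
    """Average of an atom's assigned events, re-cut at +-0.5 s around peaks."""

    avg: np.ndarray  # [n_channels x T_window]
    sfreq: float
    peak_latency: int
    slope_latency: int
    noise_diag: np.ndarray
    gfp: np.ndarray
    n_events: int


def global_field_power(data: np.ndarray) -> np.ndarray:
    """Instantaneous spatial RMS across sensors."""
    return np.sqrt(np.mean(np.asarray(data, dtype=float) ** 2, axis=0))


def slope_latency_from_gfp(gfp: np.ndarray, peak: int,
                           frac: float = 0.5) -> int:
    """First sample at >= frac of the peak GFP on the ascending branch."""
    level = frac * gfp[peak]
    below = np.flatnonzero(gfp[:peak] < level)
    return int(below[-1] + 1) if below.size else 0


def average_cluster(atom: Atom, rec: SensorRecording,
                    window_s: float = 0.5) -> ClusterAverage:
    """Average the atom's assigned events and locate PEAK and SLOPE.

    Events are re-cut at +-0.5 s around their assigned timestamps and
    averaged.  PEAK is the sample of maximum global field power; SLOPE the
    first sample of the ascending branch at or above 50 % of the peak GFP.
    The per-channel variance over the averaged window is the diagonal noise
    covariance used to build the inverse.  A peak on the window edge raises
    :class:`EdgePeakError` so the caller can skip the atom.
    """
    if atom.assigned_events is None or len(atom.assigned_events) == 0:
        raise ValueError("atom has no assigned events")
    half = int(round(window_s * rec.sfreq))
    segs = []
    for s in atom.assigned_events.samples:
        s0 = int(s) - half
        if s0 < 0 or s0 + 2 * half + 1 > rec.n_samples:
            continue
        segs.append(rec.data[:, s0:s0 + 2 * half + 1])
    if not segs:
        raise ValueError("no event window fits inside the recording")
    avg = np.mean(segs, axis=0)
    gfp = global_field_power(avg)
    peak = int(np.argmax(gfp))
    if peak in (0, gfp.size - 1):
        raise EdgePeakError("averaged GFP peaks at the window edge")
    slope = slope_latency_from_gfp(gfp, peak)
    noise_diag = avg.var(axis=1)
    noise_diag = np.maximum(noise_diag, np.finfo(float).tiny)
    return ClusterAverage(avg, rec.sfreq, peak, slope, noise_diag, gfp,
                          len(segs))


def binarize_activation(activation: np.ndarray, coords: np.ndarray,
                        frac: float = 0.5) -> CorticalMap:
    """Threshold an activation map at ``frac`` of its maximum (scale-free)."""
    activation = np.asarray(activation, dtype=float)
    m = activation.max()
    if m <= 0:
        raise ValueError("all-zero activation map")
    return CorticalMap((activation >= frac * m).astype(float), coords,
                       kind="binary")


def atom_iz_map(ca: ClusterAverage, inv: InverseOperator,
                latency: str = "peak",
                cfg: PipelineConfig | None = None) -> CorticalMap:
    """Binary activation map of a cluster average at SLOPE or PEAK."""
    cfg = cfg or PipelineConfig()
    latency = latency.lower()
    if latency == "peak":
        samp = ca.peak_latency
    elif latency == "slope":
        samp = ca.slope_latency
    else:
        raise ValueError("latency must be 'slope' or 'peak'")
    if not 0 <= samp < ca.avg.shape[1]:
        raise ValueError("latency sample outside the averaged window")
    activation = inv.vertex_magnitude(ca.avg[:, samp])
    return binarize_activation(activation, inv.vertex_coords,
                               cfg.binarize_frac)


def dilate_binary(values: np.ndarray, coords: np.ndarray,
                  radius_mm: float) -> np.ndarray:
    """Include every vertex within ``radius_mm`` of an active vertex."""
    active = coords[values > 0]
    if active.size == 0:
        return np.zeros_like(values)
    d = cdist(coords, active)
    return (d.min(axis=1) <= radius_mm).astype(float)


def combine_atom_maps(maps: list[CorticalMap], smooth_mm: float = 10.0,
                      ) -> CorticalMap:
    """Majority vote across per-atom binary maps, then 10 mm smoothing.

    A vertex enters the irritative zone when strictly more than half of the
    atom maps point at it; gradiometer- and magnetometer-derived maps are
    independent contributions in the same vote.
    """
    if not maps:
        raise ValueError("need at least one map")
    coords = maps[0].vertex_coords
    votes = np.sum([m.values for m in maps], axis=0)
    kept = (votes > len(maps) / 2).astype(float)
    if not kept.any():
        logger.warning("majority vote selected no vertex; empty IZ map")
        return CorticalMap(kept, coords, kind="binary")
    return CorticalMap(dilate_binary(kept, coords, smooth_mm), coords,
                       kind="binary")


def visual_spike_map(events: EventTable, rec: SensorRecording,
                     inv: InverseOperator, smooth_mm: float = 10.0,
                     cfg: PipelineConfig | None = None) -> CorticalMap:
    """Irritative zone from visually marked spikes.

    Each spike is reconstructed individually at its (marked) peak sample and
    binarized at 50 % of its maximum activation; vertices present in at
    least half of the single-spike maps are kept and dilated by 10 mm.
    """
    cfg = cfg or PipelineConfig()
    if len(events) < 2:
        raise ValueError("need at least two visually marked spikes")
    coords = inv.vertex_coords
    spike_maps = []
    for s in events.samples:
        if not 0 <= s < rec.n_samples:
            logger.warning("visual spike at sample %d outside recording", s)
            continue
        activation = inv.vertex_magnitude(rec.data[:, int(s)])
        spike_maps.append(binarize_activation(activation, coords,
                                              cfg.binarize_frac).values)
    if len(spike_maps) < 2:
        raise ValueError("fewer than two usable spikes")
    votes = np.sum(spike_maps, axis=0)
    kept = (votes >= len(spike_maps) / 2).astype(float)
    if not kept.any():
        logger.warning("visual-spike vote selected no vertex; empty map")
        return CorticalMap(kept, coords, kind="binary")
    return CorticalMap(dilate_binary(kept, coords, smooth_mm), coords,
                       kind="binary")
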