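"""Stage I: candidate spike detection on ICA components.

The recording (already resampled to 200 Hz and band-passed 2-90 Hz) is
decomposed with FastICA into 20 components.  Among the first 10 components
ranked by explained variance, those with a peaky time course (excess
kurtosis in [1, 10]) and a dipolar topography (MUSIC goodness of fit above a
sensor-type threshold, or above 0.95 regardless of kurtosis) are selected.
Peaks are detected on the 20-90 Hz filtered, robust-scaled component time
courses with a threshold lowered until at least 300 peaks are found; every
peak is then scored by MUSIC on a [-20, +30] ms sensor window and, within
any 0.5 s span, only the event with the largest goodness of fit survives.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks
from scipy.stats import kurtosis as excess_kurtosis
from sklearn.decomposition import FastICA

from .config import PipelineConfig
from .data_model import EventTable, ForwardModel, SensorRecording, bandpass_array
from .music import music_scan

logger = logging.getLogger(__name__)


class NoCandidatesError(RuntimeError):
    """Raised when a run produces no candidate components or peaks."""


@dataclass
class ComponentSet:
    """ICA decomposition with per-component quality measures."""

    topographies: np.ndarray  # [n_channels x n_components]
    sources: np.ndarray  # [n_components x n_samples]
    sfreq: float
    sensor_type: str
    explained_var: np.ndarray  # descending, fraction of total
    kurtosis: np.ndarray  # excess (Fisher) kurtosis per component
    gof: np.ndarray = field(default=None)  # dipolarity, nan until scored
    selected: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        k = self.topographies.shape[1]
        if self.sources.shape[0] != k:
            raise ValueError("topographies/sources component mismatch")
        if self.gof is None:
            self.gof = np.full(k, np.nan)
        if self.selected is None:
            self.selected = np.zeros(k, dtype=bool)

    @property
    def n_components(self) -> int:
        return self.topographies.shape[1]


@dataclass
class CandidatePeaks:
    """Per-component peak lists from the adaptive threshold sweep."""

    peaks: dict[int, np.ndarray]  # component index -> peak sample indices
    amplitudes: dict[int, np.ndarray]  # scaled |amplitude| at each peak
    threshold: float
    sfreq: float
    sensor_type: str

    @property
    def n_peaks(self) -> int:
        return sum(len(p) for p in self.peaks.values())

    def merged_samples(self) -> np.ndarray:
        """Unique peak samples pooled over components, sorted."""
        if not self.peaks:
            return np.array([], dtype=int)
        return np.unique(np.concatenate(list(self.peaks.values())))


def ica_decompose(rec: SensorRecording, n_components: int = 20,
                  seed: int = 0) -> ComponentSet:
    """FastICA of the sensor data, components ordered by explained variance.

    The sign indeterminacy is resolved by flipping each component so that the
    largest-magnitude entry of its topography is positive, which makes the
    decomposition reproducible given the seed.
    """
    if rec.n_channels < n_components:
        raise ValueError("fewer channels than requested components")
    ica = FastICA(n_components=n_components, random_state=int(seed),
                  whiten="unit-variance", max_iter=1000, tol=1e-4)
    sources = ica.fit_transform(rec.data.T).T  # [K x T]
    topo = ica.mixing_  # [C x K]

    # explained variance of each component's sensor-space contribution
    contrib_var = sources.var(axis=1) * (topo ** 2).sum(axis=0)
    order = np.argsort(contrib_var)[::-1]
    sources, topo = sources[order], topo[:, order]
    ev = contrib_var[order] / max(contrib_var.sum(), np.finfo(float).tiny)

    flip = np.sign(topo[np.argmax(np.abs(topo), axis=0), np.arange(topo.shape[1])])
    flip[flip == 0] = 1.0
    topo = topo * flip
    sources = sources * flip[:, None]

    kurt = excess_kurtosis(sources, axis=1, fisher=True, bias=True)
    return ComponentSet(topo, sources, rec.sfreq, rec.sensor_types[0],
                        explained_var=ev, kurtosis=kurt)


def score_components(cs: ComponentSet, fwd: ForwardModel,
                     cfg: PipelineConfig | None = None) -> ComponentSet:
    """Select peaky, dipolar components among the top-ranked ones.

    A component among the first ``n_ica_ranked`` by explained variance is
    selected iff its excess kurtosis lies in the closed ``kurtosis_range``
    and its MUSIC dipolarity GOF reaches the sensor-type threshold, or its
    GOF exceeds the 0.95 override irrespective of kurtosis.
    """
    cfg = cfg or PipelineConfig()
    if cs.n_components < cfg.n_ica_ranked:
        raise ValueError("fewer components than the ranked pool size")
    gof = np.full(cs.n_components, np.nan)
    selected = np.zeros(cs.n_components, dtype=bool)
    lo, hi = cfg.kurtosis_range
    thr = cfg.gof_threshold(cs.sensor_type)
    for i in range(cfg.n_ica_ranked):
        gof[i] = music_scan(cs.topographies[:, i], fwd).gof
        peaky = lo <= cs.kurtosis[i] <= hi
        selected[i] = (peaky and gof[i] >= thr) or gof[i] > cfg.gof_override
    cs.gof = gof
    cs.selected = selected
    if not selected.any():
        raise NoCandidatesError("no ICA component passed the selection criteria")
    return cs


def robust_scale(x: np.ndarray) -> np.ndarray:
    """Center by median, scale by IQR; a constant series maps to zeros."""
    med = np.median(x)
    q75, q25 = np.percentile(x, [75, 25])
    iqr = q75 - q25
    if iqr < np.finfo(float).eps:
        return np.zeros_like(x)
    return (x - med) / iqr


def detect_component_peaks(cs: ComponentSet, cfg: PipelineConfig | None = None,
                           component_indices: list[int] | None = None,
                           ) -> CandidatePeaks:
    """Adaptive-threshold peak detection on selected component time courses.

    Each component's time course is band-passed 20-90 Hz and robust-scaled;
    peaks are local maxima of the absolute scaled signal (ICA sign is
    arbitrary) above a threshold that is lowered along a fixed grid until the
    pooled peak count reaches ``min_peaks`` or the grid floor.
    """
    cfg = cfg or PipelineConfig()
    if component_indices is None:
        component_indices = [int(i) for i in np.flatnonzero(cs.selected)]
    if not component_indices:
        raise NoCandidatesError("no components to search for peaks")

    scaled: dict[int, np.ndarray] = {}
    for i in component_indices:
        x = bandpass_array(cs.sources[i], cs.sfreq, *cfg.peak_band)[0]
        scaled[i] = np.abs(robust_scale(x))

    grid = sorted(cfg.peak_threshold_grid, reverse=True)
    peaks: dict[int, np.ndarray] = {}
    amps: dict[int, np.ndarray] = {}
    used = grid[-1]
    for theta in grid:
        peaks = {}
        amps = {}
        for i, x in scaled.items():
            idx, _ = find_peaks(x, height=theta)
            peaks[i] = idx
            amps[i] = x[idx]
        used = theta
        if sum(len(p) for p in peaks.values()) >= cfg.min_peaks:
            break
    total = sum(len(p) for p in peaks.values())
    logger.info("peak detection: threshold %.2f, %d peaks", used, total)
    if total == 0:
        raise NoCandidatesError("threshold floor reached with zero peaks")
    return CandidatePeaks(peaks, amps, used, cs.sfreq, cs.sensor_type)


def refine_peaks(peaks: CandidatePeaks, rec: SensorRecording,
                 fwd: ForwardModel, cfg: PipelineConfig | None = None,
                 ) -> EventTable:
    """MUSIC-score candidate peaks and prune to one event per 0.5 s.

    Every pooled peak gets a dipolarity GOF from the [-20, +30] ms sensor
    window around it; a greedy sweep in descending GOF order suppresses any
    remaining event within the refractory interval of a kept one, so
    surviving events are separated by more than 0.5 s.
    """
    cfg = cfg or PipelineConfig()
    samples = peaks.merged_samples()
    if samples.size == 0:
        raise NoCandidatesError("no peaks to refine")
    w_lo = int(round(cfg.music_window[0] * rec.sfreq))
    w_hi = int(round(cfg.music_window[1] * rec.sfreq))

    kept_samples = []
    gofs = []
    for s in samples:
        if s + w_lo < 0 or s + w_hi >= rec.n_samples:
            logger.warning("peak at sample %d: MUSIC window out of bounds, "
                           "dropped", s)
            continue
        window = rec.data[:, s + w_lo:s + w_hi + 1]
        if not np.any(window):
            continue
        gofs.append(music_scan(window, fwd).gof)
        kept_samples.append(s)
    if not kept_samples:
        raise NoCandidatesError("all peaks dropped at refinement")
    samples = np.array(kept_samples)
    gofs = np.array(gofs)

    # greedy refractory pruning: best GOF first, ties broken by earlier time
    order = np.lexsort((samples, -gofs))
    keep_mask = np.zeros(samples.size, dtype=bool)
    kept_times: list[float] = []
    refractory_samples = cfg.refractory * rec.sfreq
    for idx in order:
        t = samples[idx]
        if all(abs(t - k) > refractory_samples for k in kept_times):
            keep_mask[idx] = True
            kept_times.append(t)
    samples, gofs = samples[keep_mask], gofs[keep_mask]
    order = np.argsort(samples)
    return EventTable.from_times(samples[order] / rec.sfreq, rec.sfreq,
                                 stage="stage1", gof=gofs[order],
                                 sensor_type=peaks.sensor_type)


def run_stage1(rec: SensorRecording, fwd: ForwardModel,
               cfg: PipelineConfig | None = None, seed: int = 0,
               component_indices: list[int] | None = None,
               cs: ComponentSet | None = None,
               ) -> tuple[ComponentSet, EventTable]:
    """Full Stage I on a preprocessed single-sensor-type recording.

    ``component_indices`` restricts peak detection to a component subset (used
    by the library-generation runs); an existing ``ComponentSet`` can be
    passed to reuse the decomposition across runs.
    """
    cfg = cfg or PipelineConfig()
    if cs is None:
        cs = ica_decompose(rec, cfg.n_ica, seed)
        cs = score_components(cs, fwd, cfg)
    peaks = detect_component_peaks(cs, cfg, component_indices)
    events = refine_peaks(peaks, rec, fwd, cfg)
    return cs, events
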