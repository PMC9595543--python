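"""Stage II: rank-1 multivariate convolutional sparse coding on spike epochs.

One-second epochs centered on the Stage-I timestamps are concatenated into a
tensor X [N x C x T] and decomposed into K rank-1 spatiotemporal atoms: a
spatial pattern u_k (||u_k||^2 <= 1), a temporal waveform v_k of 0.5 s
(||v_k||^2 <= 1) and non-negative sparse activations z_k^n per epoch,
minimizing

    sum_n 1/2 || X^n - sum_k z_k^n * (u_k v_k^T) ||_2^2 + lambda sum_k ||z_k^n||_1

by alternating minimization: coordinate descent on the non-negative
convolutional lasso for z, and exact block least squares with unit-ball
projection for u and v.  Because the rank-1 constraint ties one spatial
pattern to one waveform, each atom acts as the template of one spike
cluster; events are assigned to an atom by thresholding its activations at a
multiple of their median absolute deviation, lowered from 7 to 1.5 MAD until
at least 15 events are collected.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
from numba import njit
from scipy.signal import correlate, fftconvolve
from sklearn.cluster import KMeans

from .config import PipelineConfig
from .data_model import EventTable, ForwardModel, SensorRecording
from .music import music_scan
from .stage1 import ComponentSet, NoCandidatesError, detect_component_peaks, \
    ica_decompose, refine_peaks, score_components

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Epochs
# ---------------------------------------------------------------------------

@dataclass
class EpochTensor:
    """Concatenated 1 s epochs centered on Stage-I timestamps."""

    X: np.ndarray  # [N x C x T]
    sfreq: float
    start_samples: np.ndarray  # epoch start in recording samples, [N]
    event_samples: np.ndarray  # Stage-I timestamp sample of each epoch, [N]
    sensor_type: str

    @property
    def n_epochs(self) -> int:
        return self.X.shape[0]

    @property
    def n_samples(self) -> int:
        return self.X.shape[2]


def build_epochs(rec: SensorRecording, events: EventTable,
                 cfg: PipelineConfig | None = None) -> EpochTensor:
    """Cut 1 s windows centered on event timestamps; out-of-bounds dropped."""
    cfg = cfg or PipelineConfig()
    t_epoch = int(round(cfg.epoch_len * rec.sfreq))
    half = t_epoch // 2
    epochs, starts, ev_samples = [], [], []
    for s in events.samples:
        s0 = int(s) - half
        if s0 < 0 or s0 + t_epoch > rec.n_samples:
            logger.warning("epoch at sample %d out of bounds, dropped", s)
            continue
        epochs.append(rec.data[:, s0:s0 + t_epoch])
        starts.append(s0)
        ev_samples.append(int(s))
    if not epochs:
        raise NoCandidatesError("no epochs within recording bounds")
    return EpochTensor(np.stack(epochs), rec.sfreq, np.array(starts),
                       np.array(ev_samples), events.df["sensor_type"].iloc[0])


# ---------------------------------------------------------------------------
# Atoms
# ---------------------------------------------------------------------------

@dataclass
class Atom:
    """Rank-1 spatiotemporal template with its activations and events."""

    u: np.ndarray  # spatial pattern [C], ||u||2 <= 1
    v: np.ndarray  # temporal waveform [L], ||v||2 <= 1
    z: np.ndarray  # activations [N x (T - L + 1)], >= 0
    sensor_type: str = "other"
    run_index: int = 0
    name: str = ""
    assigned_events: EventTable | None = None
    event_epochs: np.ndarray = field(default_factory=lambda: np.array([], int))
    event_latencies: np.ndarray = field(default_factory=lambda: np.array([], int))
    score: float = np.nan
    selected: bool = False
    mad_threshold: float = np.nan

    @property
    def n_events(self) -> int:
        return len(self.event_epochs)


# ---------------------------------------------------------------------------
# Solver
# ---------------------------------------------------------------------------

@njit(cache=True)
def _cd_epoch(b, gram, lam, z, n_sweeps, tol):
    """Coordinate descent for one epoch's non-negative convolutional lasso.

    b: [K x S] correlations of the epoch with each atom; gram: [K x K x 2L-1]
    atom cross-correlations; z: [K x S], updated in place.
    """
    K, S = b.shape
    lm1 = (gram.shape[2] - 1) // 2
    c = np.zeros((K, S))
    for j in range(K):
        for s in range(S):
            zjs = z[j, s]
            if zjs != 0.0:
                lo = s - lm1 if s - lm1 > 0 else 0
                hi = s + lm1 + 1 if s + lm1 + 1 < S else S
                for k in range(K):
                    for t in range(lo, hi):
                        c[k, t] += zjs * gram[k, j, t - s + lm1]
    for _ in range(n_sweeps):
        max_delta = 0.0
        for k in range(K):
            gkk = gram[k, k, lm1]
            if gkk <= 0.0:
                continue
            for t in range(S):
                r = b[k, t] - c[k, t] + gkk * z[k, t]
                zn = (r - lam) / gkk
                if zn < 0.0:
                    zn = 0.0
                d = zn - z[k, t]
                if d != 0.0:
                    z[k, t] = zn
                    lo = t - lm1 if t - lm1 > 0 else 0
                    hi = t + lm1 + 1 if t + lm1 + 1 < S else S
                    for j in range(K):
                        for s in range(lo, hi):
                            c[j, s] += d * gram[j, k, s - t + lm1]
                    if abs(d) > max_delta:
                        max_delta = abs(d)
        if max_delta < tol:
            break
    return z


def _atom_gram(U: np.ndarray, V: np.ndarray) -> np.ndarray:
    """gram[k, j, l + L - 1] = (u_k . u_j) * sum_tau v_k[tau] v_j[tau + l]."""
    K, L = V.shape
    gram = np.zeros((K, K, 2 * L - 1))
    uu = U @ U.T
    for k in range(K):
        for j in range(K):
            cc = np.zeros(2 * L - 1)
            for lag in range(-(L - 1), L):
                if lag >= 0:
                    cc[lag + L - 1] = V[k, :L - lag] @ V[j, lag:]
                else:
                    cc[lag + L - 1] = V[k, -lag:] @ V[j, :L + lag]
            gram[k, j] = uu[k, j] * cc
    return gram


def _correlate_epochs(X: np.ndarray, U: np.ndarray, V: np.ndarray) -> np.ndarray:
    """b[n, k, t] = <X^n shifted window, u_k v_k^T> for every valid shift."""
    proj = np.einsum("kc,nct->nkt", U, X)
    N, K, T = proj.shape
    L = V.shape[1]
    b = np.empty((N, K, T - L + 1))
    for k in range(K):
        b[:, k, :] = correlate(proj[:, k, :], V[k][None, :], mode="valid")
    return b


def sparse_code(X: np.ndarray, U: np.ndarray, V: np.ndarray, lam: float,
                z: np.ndarray | None = None, n_sweeps: int = 30,
                tol: float = 1e-8) -> np.ndarray:
    """Non-negative convolutional lasso activations for fixed atoms.

    Solves, per epoch, min_z 1/2 ||X^n - sum_k z_k * (u_k v_k^T)||^2
    + lam ||z||_1 subject to z >= 0, by cyclic coordinate descent.
    """
    N, _, T = X.shape
    K, L = V.shape
    S = T - L + 1
    b = _correlate_epochs(X, U, V)
    gram = _atom_gram(U, V)
    if z is None:
        z = np.zeros((N, K, S))
    for n in range(N):
        _cd_epoch(b[n], gram, lam, z[n], n_sweeps, tol)
    return z


def _reconstruction(U: np.ndarray, V: np.ndarray, z: np.ndarray) -> np.ndarray:
    """sum_k u_k outer conv(z_k, v_k): [N x C x T]."""
    N, K, S = z.shape
    L = V.shape[1]
    recon = np.zeros((N, U.shape[1], S + L - 1))
    for k in range(K):
        w = fftconvolve(z[:, k, :], V[k][None, :], mode="full", axes=1)
        recon += U[k][None, :, None] * w[:, None, :]
    return recon


def csc_objective(X: np.ndarray, U: np.ndarray, V: np.ndarray,
                  z: np.ndarray, lam: float) -> float:
    resid = X - _reconstruction(U, V, z)
    return 0.5 * float(np.sum(resid ** 2)) + lam * float(np.sum(z))


def _solve_ball_constrained(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """argmin_v 1/2 v^T A v - b^T v  s.t. ||v||^2 <= 1 (A PSD)."""
    ridge = 1e-12 * max(np.trace(A) / len(A), 1.0)
    try:
        v = np.linalg.solve(A + ridge * np.eye(len(A)), b)
    except np.linalg.LinAlgError:
        v = np.linalg.lstsq(A, b, rcond=None)[0]
    nv = np.linalg.norm(v)
    if nv <= 1.0:
        return v
    # constrained optimum lies on the boundary: (A + mu I) v = b, ||v|| = 1
    w, Q = np.linalg.eigh(A)
    beta = Q.T @ b

    def norm_at(mu: float) -> float:
        return float(np.sqrt(np.sum((beta / (w + mu)) ** 2)))

    lo, hi = 0.0, max(1.0, np.linalg.norm(b))
    while norm_at(hi) > 1.0:
        hi *= 2.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if norm_at(mid) > 1.0:
            lo = mid
        else:
            hi = mid
    v = Q @ (beta / (w + hi))
    return v / max(np.linalg.norm(v), 1.0)


def _init_atoms(X: np.ndarray, K: int, L: int,
                rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Seed atoms by clustering the epochs' rank-1 spatial patterns.

    Each epoch is summarized by the rank-1 SVD of the L-sample window around
    its absolute peak.  The resulting spatial patterns are grouped by a
    sign-invariant k-means (epochs join the centroid with the largest
    absolute correlation; centroids are principal eigenvectors of their
    members), so each atom starts near one recurring source; its waveform is
    seeded from the strongest member epoch.  Randomness enters only through
    the initial assignment, which the restart loop varies.
    """
    N, C, T = X.shape
    us, vs, strengths = [], [], []
    for n in range(N):
        flat = np.argmax(np.abs(X[n]))
        _, t_peak = np.unravel_index(flat, X[n].shape)
        t0 = int(np.clip(int(t_peak) - L // 2, 0, T - L))
        w = X[n, :, t0:t0 + L]
        if not np.any(w):
            continue
        uu, ss, vv = np.linalg.svd(w, full_matrices=False)
        us.append(uu[:, 0])
        vs.append(vv[0])
        strengths.append(float(ss[0]))
    U = np.zeros((K, C))
    V = np.zeros((K, L))
    if not us:  # all-zero data: random unit atoms keep the solver defined
        for k in range(K):
            U[k] = rng.standard_normal(C)
            U[k] /= np.linalg.norm(U[k])
            V[k] = rng.standard_normal(L)
            V[k] /= np.linalg.norm(V[k])
        return U, V
    us = np.stack(us)
    vs = np.stack(vs)
    strengths = np.array(strengths)
    M = len(us)

    labels = rng.integers(0, K, M)
    cents = np.zeros((K, C))
    for _ in range(30):
        for k in range(K):
            members = labels == k
            if not members.any():
                cents[k] = us[int(rng.integers(M))]
                continue
            _, vecs = np.linalg.eigh(us[members].T @ us[members])
            cents[k] = vecs[:, -1]
        new = np.argmax(np.abs(us @ cents.T), axis=1)
        if np.array_equal(new, labels):
            break
        labels = new
    for k in range(K):
        members = np.flatnonzero(labels == k)
        if members.size == 0:
            j = int(rng.integers(M))
            U[k], V[k] = us[j], vs[j]
            continue
        U[k] = cents[k]
        strongest = members[np.argmax(strengths[members])]
        sign = 1.0 if us[strongest] @ U[k] >= 0 else -1.0
        V[k] = vs[strongest] * sign
    return U, V


def _fix_signs(U: np.ndarray, V: np.ndarray) -> None:
    """Flip (u, v) jointly so the extremal sample of v is positive."""
    for k in range(V.shape[0]):
        if V[k, np.argmax(np.abs(V[k]))] < 0:
            V[k] *= -1.0
            U[k] *= -1.0


def fit_rank1_csc(epochs: EpochTensor | np.ndarray, K: int = 3,
                  lam: float = 0.1, n_iter: int = 30, seed: int = 0,
                  atom_len: int | None = None, tol: float = 1e-5,
                  sensor_type: str | None = None, run_index: int = 0,
                  n_restarts: int = 3, return_history: bool = False):
    """Fit K rank-1 atoms to an epoch tensor by alternating minimization.

    Each outer iteration performs a z-step (coordinate descent on the
    non-negative convolutional lasso with atoms fixed) followed by exact
    block updates of u and v under their unit-ball constraints, so the
    objective is non-increasing.  Stops after ``n_iter`` iterations or when
    the relative objective decrease falls below ``tol``.  The alternating
    scheme has local minima, so ``n_restarts`` seeded initializations are
    fitted and the solution with the lowest objective is returned.
    """
    best_atoms = None
    best_obj = np.inf
    best_hist: list[float] = []
    for r in range(max(1, n_restarts)):
        sub_seed = int(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, r])
                       .generate_state(1)[0] & 0x7FFFFFFF)
        atoms, obj, hist = _fit_rank1_once(epochs, K, lam, n_iter, sub_seed,
                                           atom_len, tol, sensor_type,
                                           run_index)
        if obj < best_obj:
            best_obj = obj
            best_atoms = atoms
            best_hist = hist
    if return_history:
        return best_atoms, best_hist
    return best_atoms


def _fit_rank1_once(epochs, K, lam, n_iter, seed, atom_len, tol,
                    sensor_type, run_index
                    ) -> tuple[list[Atom], float, list[float]]:
    if isinstance(epochs, EpochTensor):
        X = epochs.X
        sfreq = epochs.sfreq
        if sensor_type is None:
            sensor_type = epochs.sensor_type
    else:
        X = np.asarray(epochs, dtype=float)
        sfreq = 200.0
    if sensor_type is None:
        sensor_type = "other"
    if K < 1:
        raise ValueError("K must be >= 1")
    N, C, T = X.shape
    L = atom_len if atom_len is not None else int(round(0.5 * sfreq))
    if L > T:
        raise ValueError("atom longer than epoch")
    rng = np.random.default_rng(seed)
    U, V = _init_atoms(X, K, L, rng)
    S = T - L + 1
    z = np.zeros((N, K, S))

    obj_prev = np.inf
    history: list[float] = []
    for it in range(n_iter):
        z = sparse_code(X, U, V, lam, z=z)
        # block updates of (u_k, v_k) with residual excluding the other atoms
        W = np.empty((K, N, T))
        for k in range(K):
            W[k] = fftconvolve(z[:, k, :], V[k][None, :], mode="full", axes=1)
        for k in range(K):
            Rk = X.copy()
            for j in range(K):
                if j != k:
                    Rk -= U[j][None, :, None] * W[j][:, None, :]
            den = float(np.sum(W[k] ** 2))
            if den <= 0:
                continue  # silent atom: keep current template
            # u-step: isotropic quadratic, projection is exact
            u = np.einsum("nct,nt->c", Rk, W[k]) / den
            nu = np.linalg.norm(u)
            if nu > 1.0:
                u /= nu
            U[k] = u
            # v-step: Toeplitz least squares with unit-ball constraint
            r = np.einsum("c,nct->nt", U[k], Rk)
            ac = np.zeros(L)
            for d in range(L):
                ac[d] = np.sum(z[:, k, :S - d] * z[:, k, d:]) if d else \
                    np.sum(z[:, k, :] ** 2)
            uu = float(U[k] @ U[k])
            if uu <= 0 or ac[0] <= 0:
                continue
            from scipy.linalg import toeplitz
            A = uu * toeplitz(ac)
            bvec = np.array([np.sum(r[:, tau:tau + S] * z[:, k, :])
                             for tau in range(L)])
            V[k] = _solve_ball_constrained(A, bvec)
            W[k] = fftconvolve(z[:, k, :], V[k][None, :], mode="full", axes=1)
        obj = csc_objective(X, U, V, z, lam)
        logger.debug("csc iter %d objective %.6g", it, obj)
        history.append(obj)
        if obj_prev - obj <= tol * max(abs(obj_prev), 1e-12):
            obj_prev = obj
            break
        obj_prev = obj

    _fix_signs(U, V)
    z = sparse_code(X, U, V, lam, z=z)
    atoms = [Atom(U[k].copy(), V[k].copy(), z[:, k, :].copy(),
                  sensor_type=sensor_type, run_index=run_index,
                  name=f"{sensor_type[:4]}_r{run_index}_a{k}")
             for k in range(K)]
    return atoms, csc_objective(X, U, V, z, lam), history


# ---------------------------------------------------------------------------
# Event assignment and atom scoring
# ---------------------------------------------------------------------------

def mad(values: np.ndarray) -> float:
    """Plain median absolute deviation (no consistency constant)."""
    values = np.asarray(values, dtype=float)
    return float(np.median(np.abs(values - np.median(values))))


def assign_events(atom: Atom, epochs: EpochTensor,
                  cfg: PipelineConfig | None = None) -> Atom:
    """Assign epochs to an atom by MAD-thresholding its activations.

    Per epoch only the maximal activation (and its latency) is considered.
    The threshold starts at 7 MAD of the pooled nonzero activations and is
    lowered along a fixed grid to 1.5 MAD until at least 15 events are
    selected.  When the activations are so sparse that their MAD degenerates
    to zero, every epoch with a strictly positive activation is an event.
    Assigned timestamps are re-aligned to the activation latency plus the
    waveform peak offset, i.e. to the spike's sharp peak.
    """
    cfg = cfg or PipelineConfig()
    zmax = atom.z.max(axis=1)
    lat = atom.z.argmax(axis=1)
    nonzero = atom.z[atom.z > 0]
    if nonzero.size == 0:
        atom.event_epochs = np.array([], dtype=int)
        atom.event_latencies = np.array([], dtype=int)
        atom.assigned_events = None
        atom.mad_threshold = np.nan
        return atom
    scale = mad(nonzero)
    if scale == 0.0:
        picked = np.flatnonzero(zmax > 0)
        used_theta = 0.0
    else:
        grid = sorted(cfg.mad_grid, reverse=True)
        picked = np.array([], dtype=int)
        used_theta = grid[-1]
        for theta in grid:
            picked = np.flatnonzero(zmax >= theta * scale)
            used_theta = theta
            if picked.size >= cfg.min_events:
                break
    logger.info("atom %s: %d events at %.1f MAD", atom.name or "?",
                picked.size, used_theta)
    atom.event_epochs = picked
    atom.event_latencies = lat[picked]
    atom.mad_threshold = used_theta
    if picked.size:
        peak_off = int(np.argmax(np.abs(atom.v)))
        samples = epochs.start_samples[picked] + lat[picked] + peak_off
        times = np.unique(samples) / epochs.sfreq
        atom.assigned_events = EventTable.from_times(
            times, epochs.sfreq, stage=f"cluster:{atom.name or 'atom'}",
            sensor_type=epochs.sensor_type)
    else:
        atom.assigned_events = None
    return atom


def score_atom(atom: Atom, epochs: EpochTensor, fwd: ForwardModel,
               cfg: PipelineConfig | None = None) -> float:
    """Quality of the cluster built around an atom, in [0, 1].

    Average of three features: dipolarity GOF of the spatial pattern; mean
    Pearson correlation of the waveform with the assigned epochs' time
    course at the atom's best channel, taken at the activation latency
    (negative correlations clipped at 0); and event count saturating at 20.
    """
    cfg = cfg or PipelineConfig()
    f1 = music_scan(atom.u, fwd).gof if np.linalg.norm(atom.u) > 0 else 0.0
    L = atom.v.size
    if atom.n_events == 0 or np.linalg.norm(atom.v) == 0:
        f2 = 0.0
    else:
        ch = int(np.argmax(np.abs(atom.u)))
        template = atom.u[ch] * atom.v  # expected trace at the best channel
        cors = []
        for n, t0 in zip(atom.event_epochs, atom.event_latencies):
            seg = epochs.X[n, ch, t0:t0 + L]
            if seg.std() == 0 or template.std() == 0:
                cors.append(0.0)
            else:
                cors.append(float(np.corrcoef(seg, template)[0, 1]))
        f2 = float(np.mean(np.clip(cors, 0.0, None)))
    f3 = min(atom.n_events / cfg.events_cap, 1.0)
    atom.score = (f1 + f2 + f3) / 3.0
    return atom.score


# ---------------------------------------------------------------------------
# Library generation
# ---------------------------------------------------------------------------

@dataclass
class AtomLibrary:
    """Candidate and selected atoms pooled over runs and sensor types."""

    atoms: list[Atom] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def candidates(self) -> list[Atom]:
        return self.atoms

    @property
    def selected(self) -> list[Atom]:
        return [a for a in self.atoms if a.selected]

    def of_sensor_type(self, sensor_type: str) -> list[Atom]:
        return [a for a in self.atoms if a.sensor_type == sensor_type]

    def merge(self, other: "AtomLibrary") -> "AtomLibrary":
        return AtomLibrary(self.atoms + other.atoms)

    def apply_selection(self, excluded: tuple[str, ...] = ()) -> None:
        """Select atoms scoring above mean + 1 SD of the candidate scores.

        An exclusion list of atom names emulates the visual review step that
        removes atoms with unclear patterns.
        """
        scores = np.array([a.score for a in self.atoms], dtype=float)
        if scores.size == 0:
            return
        cut = float(np.mean(scores) + np.std(scores))
        for a in self.atoms:
            a.selected = bool(a.score > cut) and a.name not in excluded

    def save(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            for i, a in enumerate(self.atoms):
                g = f.create_group(f"atom_{i:03d}")
                g.create_dataset("u", data=a.u)
                g.create_dataset("v", data=a.v)
                g.create_dataset("z", data=a.z)
                g.create_dataset("event_epochs", data=a.event_epochs)
                g.create_dataset("event_latencies", data=a.event_latencies)
                g.attrs["sensor_type"] = a.sensor_type
                g.attrs["run_index"] = a.run_index
                g.attrs["name"] = a.name
                g.attrs["score"] = a.score
                g.attrs["selected"] = a.selected
                g.attrs["mad_threshold"] = a.mad_threshold
                if a.assigned_events is not None:
                    g.create_dataset("event_times",
                                     data=a.assigned_events.times)

    @classmethod
    def load(cls, path: str | Path, sfreq: float = 200.0) -> "AtomLibrary":
        atoms = []
        with h5py.File(path, "r") as f:
            for key in sorted(f.keys()):
                g = f[key]
                a = Atom(g["u"][()], g["v"][()], g["z"][()],
                         sensor_type=g.attrs["sensor_type"],
                         run_index=int(g.attrs["run_index"]),
                         name=str(g.attrs["name"]),
                         score=float(g.attrs["score"]),
                         selected=bool(g.attrs["selected"]),
                         mad_threshold=float(g.attrs["mad_threshold"]))
                a.event_epochs = g["event_epochs"][()].astype(int)
                a.event_latencies = g["event_latencies"][()].astype(int)
                if "event_times" in g:
                    a.assigned_events = EventTable.from_times(
                        g["event_times"][()], sfreq,
                        stage=f"cluster:{a.name}", sensor_type=a.sensor_type)
                atoms.append(a)
        return cls(atoms)


def cluster_components(cs: ComponentSet, n_clusters: int = 3,
                       seed: int = 0) -> list[list[int]]:
    """K-means groups of the selected components' topographies.

    Clustering acts on unit-normalized absolute topographies so that only
    spatial shape (not sign or amplitude) drives the grouping.  With fewer
    selected components than clusters, each component forms its own group.
    """
    idx = [int(i) for i in np.flatnonzero(cs.selected)]
    if len(idx) <= n_clusters:
        return [[i] for i in idx]
    feats = np.abs(cs.topographies[:, idx]).T
    feats = feats / np.linalg.norm(feats, axis=1, keepdims=True)
    km = KMeans(n_clusters=n_clusters, random_state=int(seed), n_init=10)
    labels = km.fit_predict(feats)
    return [[idx[i] for i in np.flatnonzero(labels == c)]
            for c in range(n_clusters)]


def build_library(rec: SensorRecording, fwd: ForwardModel,
                  cfg: PipelineConfig | None = None, seed: int = 0,
                  cs: ComponentSet | None = None) -> AtomLibrary:
    """Four-run library generation for one sensor type.

    Run 1 detects peaks on all selected ICA components and fits 3 atoms on
    the resulting epochs.  The selected components' topographies are then
    k-means clustered into 3 groups and runs 2-4 repeat peak detection and
    the 3-atom fit restricted to one group each, yielding 12 candidate atoms
    when every group produces peaks.  Scores are computed for every
    candidate; selection (mean + 1 SD rule, exclusion list) is applied by
    the caller once candidates of both sensor types are pooled.
    """
    cfg = cfg or PipelineConfig()
    if cs is None:
        cs = ica_decompose(rec, cfg.n_ica, seed)
        cs = score_components(cs, fwd, cfg)
    groups = cluster_components(cs, cfg.n_runs - 1, seed)
    subsets: list[list[int] | None] = [None] + list(groups)

    library = AtomLibrary()
    for run, subset in enumerate(subsets[:cfg.n_runs], start=1):
        if subset is not None and len(subset) == 0:
            logger.warning("run %d: empty component group, skipped", run)
            continue
        try:
            peaks = detect_component_peaks(cs, cfg, subset)
            events = refine_peaks(peaks, rec, fwd, cfg)
        except NoCandidatesError as e:
            logger.warning("run %d skipped: %s", run, e)
            continue
        epochs = build_epochs(rec, events, cfg)
        atoms = fit_rank1_csc(epochs, K=cfg.n_atoms_per_run,
                              lam=cfg.lambda_reg, n_iter=cfg.csc_n_iter,
                              seed=seed + run, tol=cfg.csc_tol,
                              run_index=run)
        for a in atoms:
            assign_events(a, epochs, cfg)
            score_atom(a, epochs, fwd, cfg)
        library.atoms.extend(atoms)
    return library
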