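"""Single-dipole MUSIC scanning.

MUSIC localizes a dipolar source by comparing the signal subspace of a sensor
data window with the leadfield of each candidate vertex: the goodness of fit
at a vertex is the squared cosine of the principal angle between the vertex's
leadfield span and the signal subspace.  The same scan scores ICA topography
dipolarity (a topography is a one-column window) and candidate spike windows.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import ForwardModel


@dataclass
class DipoleFit:
    """Best-fitting vertex of a MUSIC scan with its subspace correlation."""

    vertex_index: int
    gof: float  # squared subspace correlation, in [0, 1]
    orientation: np.ndarray | None = None
    gof_per_vertex: np.ndarray | None = None


def signal_subspace(window: np.ndarray, n_signal_dims: int = 1) -> np.ndarray:
    """Top left singular vectors of a [n_channels x n_samples] window."""
    window = np.atleast_2d(np.asarray(window, dtype=float))
    if window.shape[0] < window.shape[1] and window.shape[1] == 1:
        pass
    if window.shape[1] < n_signal_dims:
        raise ValueError("window has fewer samples than signal dimensions")
    norm = np.linalg.norm(window)
    if norm == 0:
        raise ValueError("zero-norm window")
    u, _, _ = np.linalg.svd(window, full_matrices=False)
    return u[:, :n_signal_dims]


def music_scan(data_window: np.ndarray, fwd: ForwardModel,
               n_signal_dims: int = 1) -> DipoleFit:
    """Scan all vertices for the best subspace alignment.

    ``data_window`` is either a [n_channels x n_samples] matrix or a single
    topography vector (treated as a one-column window with one signal
    dimension).  GOF is invariant to rescaling and sign of the input.
    """
    data_window = np.asarray(data_window, dtype=float)
    if data_window.ndim == 1:
        data_window = data_window[:, None]
        n_signal_dims = 1
    us = signal_subspace(data_window, n_signal_dims)  # [C x p]

    G = fwd.leadfield
    if fwd.n_orientations == 1:
        col_norm = np.linalg.norm(G, axis=0)
        proj = np.linalg.norm(us.T @ G, axis=0)  # [n_vertices]
        with np.errstate(invalid="ignore", divide="ignore"):
            gof = np.where(col_norm > 0, (proj / col_norm) ** 2, 0.0)
        best = int(np.argmax(gof))
        ori = None
    else:
        n_v = fwd.n_vertices
        gof = np.zeros(n_v)
        oris = np.zeros((n_v, 3))
        for j in range(n_v):
            Gj = fwd.vertex_columns(j)
            q, r = np.linalg.qr(Gj)
            keep = np.abs(np.diag(r)) > 1e-12 * max(1.0, np.abs(r[0, 0]))
            if not np.any(keep):
                continue
            # largest principal-angle cosine between span(Gj) and span(us)
            m = us.T @ q[:, keep]
            w, s, vt = np.linalg.svd(m)
            gof[j] = s[0] ** 2
            # orientation achieving the maximal correlation, in source coords
            coef = np.zeros(Gj.shape[1])
            coef_keep = np.linalg.solve(r[np.ix_(keep, keep)], vt[0])
            coef[keep] = coef_keep
            n = np.linalg.norm(coef)
            oris[j] = coef / n if n > 0 else 0.0
        best = int(np.argmax(gof))
        ori = oris[best]
    gof = np.clip(gof, 0.0, 1.0)
    return DipoleFit(vertex_index=best, gof=float(gof[best]), orientation=ori,
                     gof_per_vertex=gof)
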