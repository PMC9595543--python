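"""Rank-1 convolutional sparse coding: solver, assignment, scoring, library."""
import numpy as np
import pytest
from scipy.optimize import minimize

from megspike import (EventTable, PipelineConfig, assign_events,
                      build_epochs, build_library, fit_rank1_csc, preprocess,
                      score_atom, simulate_recording, sparse_code)
from megspike.csc import (Atom, AtomLibrary, EpochTensor, csc_objective,
                          mad)


def aligned_pearson(a, b, max_lag=25):
    """|Pearson correlation| maximized over small relative shifts."""
    best, L = 0.0, len(a)
    for lag in range(-max_lag, max_lag + 1):
        x, y = (a[lag:], b[:L - lag]) if lag >= 0 else (a[:L + lag], b[-lag:])
        if len(x) >= 10:
            best = max(best, abs(np.corrcoef(x, y)[0, 1]))
    return best


def _planted_tensor(seed=0, N=20, C=8, T=120, L=40, noise=0.0):
    """Epochs containing one rank-1 atom with known activations."""
    rng = np.random.default_rng(seed)
    u = rng.standard_normal(C)
    u /= np.linalg.norm(u)
    v = np.sin(np.linspace(0, 3 * np.pi, L)) * np.hanning(L)
    v /= np.linalg.norm(v)
    z = np.zeros((N, T - L + 1))
    shifts = rng.integers(10, T - L - 10, N)
    amps = rng.uniform(5.0, 8.0, N)
    X = noise * rng.standard_normal((N, C, T))
    for n in range(N):
        z[n, shifts[n]] = amps[n]
        X[n, :, shifts[n]:shifts[n] + L] += amps[n] * np.outer(u, v)
    return X, u, v, z


class TestSolver:
    def test_noiseless_single_atom_recovery(self):
        X, u, v, z = _planted_tensor()
        atoms = fit_rank1_csc(X, K=1, lam=1e-4, n_iter=50, seed=0,
                              atom_len=40, tol=1e-10)
        a = atoms[0]
        assert abs(np.corrcoef(a.u, u)[0, 1]) > 0.99
        assert aligned_pearson(a.v, v, max_lag=5) > 0.99
        recon = np.zeros_like(X)
        from megspike.csc import _reconstruction
        recon = _reconstruction(a.u[None], a.v[None], a.z[:, None, :])
        assert np.sum((X - recon) ** 2) / np.sum(X ** 2) < 0.01

    def test_all_zero_input(self):
        X = np.zeros((4, 3, 60))
        atoms = fit_rank1_csc(X, K=2, lam=0.1, n_iter=5, seed=0, atom_len=20)
        for a in atoms:
            assert np.all(a.z == 0.0)
        U = np.stack([a.u for a in atoms])
        V = np.stack([a.v for a in atoms])
        z = np.stack([a.z for a in atoms], axis=1)
        assert csc_objective(X, U, V, z, 0.1) == 0.0

    def test_objective_monotone_nonincreasing(self):
        X, *_ = _planted_tensor(noise=0.5)
        _, hist = fit_rank1_csc(X, K=2, lam=0.1, n_iter=20, seed=0,
                                atom_len=40, tol=0.0, n_restarts=1,
                                return_history=True)
        assert len(hist) >= 2
        diffs = np.diff(hist)
        assert np.all(diffs <= 1e-9 * np.abs(hist[:-1]))

    def test_constraints_hold_after_fit(self):
        X, *_ = _planted_tensor(noise=1.0)
        atoms = fit_rank1_csc(X, K=3, lam=0.1, n_iter=10, seed=1, atom_len=40)
        for a in atoms:
            assert np.linalg.norm(a.u) <= 1.0 + 1e-9
            assert np.linalg.norm(a.v) <= 1.0 + 1e-9
            assert np.all(a.z >= 0.0)

    def test_deterministic_given_seed(self):
        X, *_ = _planted_tensor(noise=0.5)
        a1 = fit_rank1_csc(X, K=2, lam=0.1, n_iter=10, seed=4, atom_len=40)
        a2 = fit_rank1_csc(X, K=2, lam=0.1, n_iter=10, seed=4, atom_len=40)
        for x, y in zip(a1, a2):
            np.testing.assert_array_equal(x.u, y.u)
            np.testing.assert_array_equal(x.v, y.v)
            np.testing.assert_array_equal(x.z, y.z)

    def test_invalid_arguments(self):
        X = np.zeros((2, 3, 50))
        with pytest.raises(ValueError):
            fit_rank1_csc(X, K=0, atom_len=10)
        with pytest.raises(ValueError):
            fit_rank1_csc(X, K=1, atom_len=60)

    def test_zstep_matches_generic_nonnegative_lasso(self):
        """CD on the convolutional lasso equals a generic bounded solver."""
        rng = np.random.default_rng(0)
        N, C, T, L = 5, 4, 40, 8
        u = rng.standard_normal(C)
        u /= np.linalg.norm(u)
        v = rng.standard_normal(L)
        v /= np.linalg.norm(v)
        X = 0.3 * rng.standard_normal((N, C, T))
        lam = 0.1
        S = T - L + 1
        zhat = sparse_code(X, u[None], v[None], lam, n_sweeps=2000,
                           tol=1e-14)
        obj_cd = csc_objective(X, u[None], v[None], zhat, lam)
        # oracle: explicit convolutional design matrix, L-BFGS-B with bounds
        D = np.zeros((C * T, S))
        for s in range(S):
            M = np.zeros((C, T))
            M[:, s:s + L] = np.outer(u, v)
            D[:, s] = M.ravel()
        obj_oracle = 0.0
        for n in range(N):
            y = X[n].ravel()
            res = minimize(
                lambda zz: 0.5 * np.sum((y - D @ zz) ** 2) + lam * zz.sum(),
                np.zeros(S),
                jac=lambda zz: -(D.T @ (y - D @ zz)) + lam,
                bounds=[(0, None)] * S, method="L-BFGS-B",
                options=dict(maxiter=5000, ftol=1e-16, gtol=1e-14))
            obj_oracle += res.fun
        assert abs(obj_cd - obj_oracle) < 1e-6

    def test_two_planted_atoms_recovered_at_snr4(self, small_fwd):
        """Both planted sources recovered from their event epochs at SNR 4."""
        rec, gt = simulate_recording(small_fwd, 2, 3.0, 1200, snr=4, seed=1)
        assert min(len(t) for t in gt.event_times) >= 30
        rec = preprocess(rec)
        ev = EventTable.from_times(gt.all_event_times, rec.sfreq, "stage1",
                                   sensor_type="gradiometer")
        ep = build_epochs(rec, ev)
        atoms = fit_rank1_csc(ep, K=2, lam=0.1, n_iter=60, seed=0, tol=1e-8)
        for a in atoms:
            assign_events(a, ep)
        for (u_true, v_true), times in zip(gt.true_atoms, gt.event_times):
            cors = [abs(np.corrcoef(u_true, a.u)[0, 1]) for a in atoms]
            best = atoms[int(np.argmax(cors))]
            assert max(cors) > 0.95
            assert aligned_pearson(best.v, v_true) > 0.9
            hits = sum(np.min(np.abs(best.assigned_events.times - t)) <= 0.05
                       for t in times)
            assert hits / len(times) >= 0.8


def _epochs_stub(n_epochs, n_channels=4, t_epoch=200):
    return EpochTensor(np.zeros((n_epochs, n_channels, t_epoch)), 200.0,
                       np.arange(n_epochs) * t_epoch,
                       np.arange(n_epochs) * t_epoch + t_epoch // 2,
                       "gradiometer")


def _atom_with_z(z):
    c = 4
    return Atom(u=np.ones(c) / np.sqrt(c), v=np.ones(100) * 0.1, z=z,
                sensor_type="gradiometer", name="test")


class TestAssignEvents:
    def _z_with_background(self, n_epochs, rng):
        """Sparse activations with a small nonzero background (MAD > 0)."""
        z = np.zeros((n_epochs, 101))
        z[:, 10] = rng.uniform(0.01, 1.0, n_epochs)
        return z

    def test_large_activations_assigned_at_start_threshold(self):
        rng = np.random.default_rng(0)
        z = self._z_with_background(100, rng)
        scale = mad(z[z > 0])
        z[:30, 50] = 10.0 * scale
        # planting the large values barely moves the pooled MAD
        assert mad(z[z > 0]) == pytest.approx(scale, rel=0.3)
        atom = _atom_with_z(z)
        assign_events(atom, _epochs_stub(100))
        assert atom.mad_threshold == 7.0
        assert atom.n_events == 30
        assert set(atom.event_epochs) == set(range(30))

    def test_threshold_lowered_until_enough_events(self):
        rng = np.random.default_rng(1)
        z = self._z_with_background(100, rng)
        z[:, 10] *= 0.3  # keep the background below the floor threshold
        scale = mad(z[z > 0])
        z[:5, 50] = 10.0 * scale
        z[5:25, 50] = 3.0 * scale
        atom = _atom_with_z(z)
        assign_events(atom, _epochs_stub(100))
        assert atom.n_events >= 15
        assert atom.mad_threshold < 7.0

    def test_all_zero_activations(self):
        atom = _atom_with_z(np.zeros((50, 101)))
        assign_events(atom, _epochs_stub(50))
        assert atom.n_events == 0
        assert atom.assigned_events is None

    def test_degenerate_mad_assigns_every_active_epoch(self):
        """Identical sparse activations: MAD collapses, all actives kept."""
        z = np.zeros((100, 101))
        z[:25, 50] = 4.0
        atom = _atom_with_z(z)
        assign_events(atom, _epochs_stub(100))
        assert atom.n_events == 25

    def test_timestamps_at_waveform_peak(self):
        z = np.zeros((3, 101))
        z[:, 20] = 5.0
        atom = _atom_with_z(z)
        atom.v = np.zeros(100)
        atom.v[40] = 1.0
        ep = _epochs_stub(3)
        assign_events(atom, ep)
        expected = (ep.start_samples + 20 + 40) / ep.sfreq
        np.testing.assert_allclose(atom.assigned_events.times, expected)


class TestScoreAtom:
    def test_perfect_atom_scores_one(self, small_fwd):
        cfg = PipelineConfig()
        v = np.sin(np.linspace(0, 2 * np.pi, 100))
        v /= np.linalg.norm(v)
        u = small_fwd.leadfield[:, 12].copy()
        u /= np.linalg.norm(u)
        n, L = 20, 100
        X = np.zeros((n, small_fwd.n_channels, 200))
        for i in range(n):
            X[i, :, 50:150] = np.outer(u, v)
        ep = EpochTensor(X, 200.0, np.arange(n) * 200,
                         np.arange(n) * 200 + 100, "gradiometer")
        atom = Atom(u=u, v=v, z=np.zeros((n, 101)),
                    sensor_type="gradiometer")
        atom.event_epochs = np.arange(n)
        atom.event_latencies = np.full(n, 50)
        score = score_atom(atom, ep, small_fwd, cfg)
        assert score == pytest.approx(1.0, abs=1e-6)

    def test_score_formula_weights(self, small_fwd, monkeypatch):
        """score = (gof + waveform corr + saturating count) / 3."""
        from megspike import csc as csc_mod
        from megspike.music import DipoleFit
        monkeypatch.setattr(csc_mod, "music_scan",
                            lambda *a, **k: DipoleFit(0, 0.8))
        v = np.sin(np.linspace(0, 2 * np.pi, 100))
        v /= np.linalg.norm(v)
        n = 10  # below the cap of 20: f3 = 0.5
        X = np.zeros((n, small_fwd.n_channels, 200))
        u = np.zeros(small_fwd.n_channels)
        u[0] = 1.0
        for i in range(n):
            X[i, 0, 50:150] = v
        ep = EpochTensor(X, 200.0, np.arange(n) * 200,
                         np.arange(n) * 200 + 100, "gradiometer")
        atom = Atom(u=u, v=v, z=np.zeros((n, 101)))
        atom.event_epochs = np.arange(n)
        atom.event_latencies = np.full(n, 50)
        score = score_atom(atom, ep, small_fwd, PipelineConfig())
        assert score == pytest.approx((0.8 + 1.0 + 0.5) / 3, abs=1e-9)

    def test_planted_atom_outscores_noise_atom(self, small_fwd):
        rec, gt = simulate_recording(small_fwd, 1, 4.0, 300, snr=6, seed=7)
        rec = preprocess(rec)
        ev = EventTable.from_times(gt.all_event_times, rec.sfreq, "stage1",
                                   sensor_type="gradiometer")
        ep = build_epochs(rec, ev)
        atoms = fit_rank1_csc(ep, K=2, lam=0.1, n_iter=40, seed=0)
        scores = []
        for a in atoms:
            assign_events(a, ep)
            scores.append(score_atom(a, ep, small_fwd))
        cors = [abs(np.corrcoef(gt.true_atoms[0][0], a.u)[0, 1])
                for a in atoms]
        assert scores[int(np.argmax(cors))] == max(scores)


class TestLibrary:
    def test_mean_plus_sd_selection(self):
        scores = [0.2, 0.3, 0.9]
        lib = AtomLibrary([Atom(np.ones(2), np.ones(4), np.zeros((1, 3)),
                                name=f"a{i}", score=s)
                           for i, s in enumerate(scores)])
        lib.apply_selection()
        cut = np.mean(scores) + np.std(scores)
        assert [a.selected for a in lib.atoms] == [s > cut for s in scores]
        assert sum(a.selected for a in lib.atoms) == 1

    def test_exclusion_list(self):
        lib = AtomLibrary([Atom(np.ones(2), np.ones(4), np.zeros((1, 3)),
                                name=f"a{i}", score=s)
                           for i, s in enumerate([0.1, 0.1, 0.9])])
        lib.apply_selection(excluded=("a2",))
        assert not any(a.selected for a in lib.atoms)

    def test_library_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        atoms = [Atom(rng.standard_normal(4), rng.standard_normal(10),
                      rng.uniform(0, 1, (3, 5)), sensor_type="gradiometer",
                      run_index=1, name="grad_r1_a0", score=0.5)]
        lib = AtomLibrary(atoms)
        lib.save(tmp_path / "lib.h5")
        back = AtomLibrary.load(tmp_path / "lib.h5")
        assert len(back) == 1
        np.testing.assert_allclose(back.atoms[0].u, atoms[0].u)
        np.testing.assert_allclose(back.atoms[0].z, atoms[0].z)
        assert back.atoms[0].name == "grad_r1_a0"

    def test_four_runs_give_twelve_candidates(self, small_fwd):
        """4 runs x 3 atoms on a fixture with 3 usable components."""
        rec, _ = simulate_recording(small_fwd, 3, 3.0, 600, snr=5, seed=4)
        rec = preprocess(rec)
        cfg = PipelineConfig(min_peaks=60, csc_n_iter=15)
        lib = build_library(rec, small_fwd, cfg, seed=0)
        assert len(lib) == 12
        assert sorted(set(a.run_index for a in lib.atoms)) == [1, 2, 3, 4]
        for a in lib.atoms:
            assert 0.0 <= a.score <= 1.0
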