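"""RMSD/Rg, van Hove, SISF and relaxation-time fits."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation
from scipy.stats import linregress

from prosolv.md_io import Box, Frame, Topology, Trajectory
from prosolv.dynamics import (SISFCurve, fit_relaxation, gyration_series,
                              radius_of_gyration, rmsd_series, sisf,
                              superposed_rmsd, vanhove_self)
from prosolv.synthetic import WalkerSpec, gen_brownian, gen_confined_walkers


class TestSuperposedRMSD:
    def test_self_is_zero(self):
        rng = np.random.default_rng(0)
        P = rng.normal(size=(15, 3))
        assert superposed_rmsd(P, P) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(1)
        P = rng.normal(size=(25, 3))
        R = Rotation.from_euler("xyz", [0.3, 1.1, -0.7]).as_matrix()
        moved = P @ R.T + np.array([2.0, -1.0, 5.0])
        assert superposed_rmsd(moved, P) < 1e-10

    def test_beats_rotation_grid_search(self):
        """The closed-form optimum is <= every orientation on a coarse grid,
        and matches the grid minimum to grid resolution, on two printed
        4-point configurations."""
        P = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
        Q = np.array([[0.1, 0, 0], [1, 0.2, 0], [0, 0.9, 0.1], [0.1, 0, 1.1]])

        def grid_min(P, Q, n=36):
            angles = np.linspace(0, 2 * np.pi, n, endpoint=False)
            Pc = P - P.mean(0)
            Qc = Q - Q.mean(0)
            best = np.inf
            for a in angles:
                for b in angles[: n // 2]:
                    for c in angles:
                        R = Rotation.from_euler("zyz", [a, b, c]).as_matrix()
                        best = min(best, np.sqrt(
                            ((Pc @ R.T - Qc) ** 2).sum(1).mean()))
            return best

        opt = superposed_rmsd(P, Q)
        grid = grid_min(P, Q)            # 10-degree grid
        assert opt <= grid + 1e-12
        # the coarse grid can overshoot the optimum only by its resolution:
        # a 10-degree misorientation on ~unit-size clouds costs <~ 0.09 nm
        assert grid - opt <= 0.09

    def test_too_few_atoms_flagged(self):
        with pytest.raises(ValueError):
            superposed_rmsd(np.zeros((2, 3)), np.ones((2, 3)))


class TestRMSDSeries:
    def test_reference_frame_is_zero_and_rigid_translation_is_zero(self):
        traj, _ = _rigid_chain_traj()
        r = rmsd_series(traj, selection="backbone")
        assert r.chain_average[0] == pytest.approx(0.0, abs=1e-12)
        # rigid-body translation only: superposition removes everything
        assert np.all(r.chain_average < 1e-10)

    def test_chain_average_is_mean_of_chains(self):
        traj, _ = _rigid_chain_traj(n_chains=2)
        r = rmsd_series(traj, selection="backbone")
        assert np.allclose(r.chain_average,
                           r.per_chain.mean(axis=1).to_numpy())


def _rigid_chain_traj(n_chains=1, n_frames=6):
    """Chains of 4 backbone atoms translated rigidly frame to frame."""
    rng = np.random.default_rng(7)
    names, resi, resn, chains, cls, mols, elements = [], [], [], [], [], [], []
    base = []
    res = 0
    for c in range(n_chains):
        offs = np.array([4.0 * c, 0, 0])
        for r in range(2):
            for name in ("N", "CA", "C"):
                names.append(name)
                elements.append(name[0])
                resi.append(res)
                resn.append("ALA")
                chains.append(chr(65 + c))
                cls.append("protein")
                mols.append(c)
                base.append(rng.normal(size=3) + offs)
            res += 1
    base = np.asarray(base)
    pos = np.empty((n_frames, len(base), 3))
    for t in range(n_frames):
        pos[t] = base + t * np.array([0.05, 0.02, -0.01])
    topo = Topology(names=names, resindices=resi, resnames=resn,
                    chain_ids=chains, elements=elements, molecule_ids=mols,
                    molecule_classes=cls)
    traj = Trajectory(topo, pos, np.arange(n_frames, dtype=float),
                      Box(np.full(3, 50.0)), unwrapped=pos)
    return traj, topo


class TestRadiusOfGyration:
    def test_two_unit_masses(self):
        d = 0.8
        rg = radius_of_gyration(np.array([[0, 0, 0], [d, 0, 0]]))
        assert rg == pytest.approx(d / 2)

    def test_coincident_atoms(self):
        assert radius_of_gyration(np.ones((5, 3))) == 0.0

    def test_matches_direct_formula_random_cloud(self):
        rng = np.random.default_rng(3)
        pos = rng.normal(size=(20, 3))
        m = rng.uniform(1, 16, size=20)
        com = (m[:, None] * pos).sum(0) / m.sum()
        expected = np.sqrt((m * ((pos - com) ** 2).sum(1)).sum() / m.sum())
        assert radius_of_gyration(pos, m) == pytest.approx(expected, rel=1e-12)

    def test_zero_mass_rejected(self):
        with pytest.raises(ValueError):
            radius_of_gyration(np.ones((3, 3)), np.zeros(3))

    def test_series_positive(self):
        traj, _ = _rigid_chain_traj()
        g = gyration_series(traj, selection="protein")
        assert (g.to_numpy() > 0).all()


class TestVanHove:
    def test_static_system_delta_at_zero(self):
        traj = gen_brownian(WalkerSpec(n=20, diffusion=0.0, n_frames=30,
                                       seed=0), Box(np.full(3, 5.0)))
        r, g = vanhove_self(traj, lag=5, bins=40, r_max=1.0)
        assert g[0] > 0 and np.all(g[1:] == 0)

    def test_normalisation(self, free_diffusion_traj):
        r, g = vanhove_self(free_diffusion_traj, lag=40, bins=80,
                            origin_stride=25)
        widths = np.diff(np.linspace(0, r[-1] + (r[1] - r[0]) / 2, len(r) + 1))
        assert (g * widths).sum() == pytest.approx(1.0, abs=1e-9)

    def test_matches_gaussian_propagator(self, free_diffusion_traj):
        D, lag = 0.002, 50
        r, g = vanhove_self(free_diffusion_traj, lag=lag, bins=60,
                            origin_stride=10)
        s2 = 2 * D * lag
        ref = 4 * np.pi * r ** 2 * np.exp(-r ** 2 / (2 * s2)) \
            / (2 * np.pi * s2) ** 1.5
        assert np.max(np.abs(g - ref)) < 0.15 * ref.max()


class TestSISF:
    def test_static_system_is_one(self):
        traj = gen_brownian(WalkerSpec(n=10, diffusion=0.0, n_frames=50,
                                       seed=2), Box(np.full(3, 5.0)))
        c = sisf(traj, q=15.71, selection="all")
        assert np.allclose(c.F, 1.0)

    def test_f_at_zero_lag_is_exactly_one(self, free_diffusion_traj):
        c = sisf(free_diffusion_traj, q=10.0, selection="all",
                 lags=[0, 10, 50], origin_stride=20)
        assert c.F[0] == 1.0

    def test_free_diffusion_closed_form(self, free_diffusion_traj):
        D = 0.002
        for q in (5.0, 10.0, 15.71):
            c = sisf(free_diffusion_traj, q, selection="all", origin_stride=5)
            ref = np.exp(-q * q * D * c.lags)
            m = ref >= 0.1
            assert np.max(np.abs(c.F[m] - ref[m]) / ref[m]) < 0.05, q

    def test_invalid_q(self, free_diffusion_traj):
        with pytest.raises(ValueError):
            sisf(free_diffusion_traj, q=0.0)

    def test_lag_beyond_span(self):
        traj = gen_brownian(WalkerSpec(n=5, diffusion=0.01, n_frames=10,
                                       seed=3), Box(np.full(3, 5.0)))
        with pytest.raises(ValueError, match="lag"):
            sisf(traj, q=10.0, lags=[50])


class TestRelaxationFit:
    def test_exact_exponential_recovery(self):
        t = np.linspace(0, 60, 200)
        curve = SISFCurve(q=10.0, lags=t, F=np.exp(-t / 10.0),
                          selection="all", n_origins=1)
        fit = fit_relaxation(curve)
        assert fit.converged
        assert fit.tau == pytest.approx(10.0, rel=1e-6)
        assert fit.amplitude == pytest.approx(1.0, rel=1e-6)

    def test_free_diffusion_tau(self, free_diffusion_traj):
        D, q = 0.002, 15.71
        c = sisf(free_diffusion_traj, q, selection="all", origin_stride=5)
        fit = fit_relaxation(c)
        assert fit.tau == pytest.approx(1.0 / (q * q * D), rel=0.05)

    def test_noise_bias_small(self):
        """1% multiplicative Gaussian noise, 50 replicates: tau bias < 2%."""
        t = np.linspace(0, 60, 80)
        clean = np.exp(-t / 10.0)
        rng = np.random.default_rng(9)
        taus = []
        for _ in range(50):
            noisy = clean * (1 + 0.01 * rng.normal(size=len(t)))
            curve = SISFCurve(q=1.0, lags=t, F=noisy, selection="all",
                              n_origins=1)
            taus.append(fit_relaxation(curve).tau)
        assert abs(np.mean(taus) / 10.0 - 1) < 0.02

    def test_too_few_points_in_window(self):
        t = np.array([0.0, 1.0, 2.0, 3.0])
        curve = SISFCurve(q=1.0, lags=t, F=np.exp(-t / 0.3),
                          selection="all", n_origins=1)
        with pytest.raises(ValueError, match="window"):
            fit_relaxation(curve)


class TestScalingLaws:
    def test_tau_scales_as_inverse_q_squared(self, free_diffusion_traj):
        qs = np.array([5.0, 10.0, 15.71])
        taus = [fit_relaxation(sisf(free_diffusion_traj, q, selection="all",
                                    origin_stride=5)).tau for q in qs]
        slope = linregress(np.log(qs), np.log(taus)).slope
        assert slope == pytest.approx(-2.0, abs=0.1)

    def test_confinement_raises_tau_and_plateau(self):
        """Confined walkers relax slower and keep a plateau relative to free
        walkers of equal short-time step variance."""
        tau_c, sigma, dt = 4.0, 0.12, 1.0
        # free walker with the same one-step displacement variance
        step_var = sigma ** 2 * (1 - np.exp(-2 * dt / tau_c))
        D = step_var / (2 * dt)
        free = gen_brownian(WalkerSpec(n=300, diffusion=D, dt=dt,
                                       n_frames=600, seed=4),
                            Box(np.full(3, 10.0)))
        conf = gen_confined_walkers(WalkerSpec(n=300, tau_c=tau_c, sigma=sigma,
                                               dt=dt, n_frames=600, seed=4))
        q = 10.0
        c_free = sisf(free, q, selection="all", origin_stride=4)
        c_conf = sisf(conf, q, selection="all", origin_stride=4)
        assert c_conf.F[-20:].mean() > c_free.F[-20:].mean() + 0.05
        # effective relaxation: confined curve sits above the free one
        assert np.all(c_conf.F[5:] >= c_free.F[5:] - 0.02)
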