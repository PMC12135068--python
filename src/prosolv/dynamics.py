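"""Dynamic observables: superposition RMSD, radius of gyration, the self
part of the van Hove function, self-intermediate scattering functions and
single-exponential relaxation-time fits.

The SISF is the isotropic (spherically averaged) transform of the self
van Hove function,

    F_s(q, t) = < sin(q |dr(t)|) / (q |dr(t)|) >,

averaged over particles and time origins, so F_s(q, 0) = 1 exactly and the
free-diffusion closed form is exp(-q^2 D t).  Relaxation times come from a
least-squares fit of A exp(-t/tau) over a configurable window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .md_io import (Box, Frame, Topology, Trajectory, make_molecules_whole,
                    unwrap_heuristic)

BACKBONE_NAMES = ("N", "CA", "C")
#: default scattering vectors (1/nm); 15.71 = 2*pi / 0.4 nm
DEFAULT_Q_VALUES = (5.0, 10.0, 15.71, 25.0)


def select_atoms(topology: Topology, selection: str | Sequence[int]) -> np.ndarray:
    """Resolve a selection: 'backbone', 'protein', 'all', or explicit indices."""
    if isinstance(selection, str):
        if selection == "all":
            return np.arange(topology.n_atoms)
        if selection == "protein":
            return topology.atoms_of_class("protein")
        if selection == "backbone":
            prot = topology.molecule_classes == "protein"
            return np.flatnonzero(prot & np.isin(topology.names, BACKBONE_NAMES))
        raise ValueError(f"unknown selection {selection!r}")
    idx = np.asarray(selection, dtype=int)
    if len(idx) == 0:
        raise ValueError("empty selection")
    return idx


# ---------------------------------------------------------------------------
# superposition and RMSD
# ---------------------------------------------------------------------------

def kabsch_rotation(P: np.ndarray, Q: np.ndarray,
                    weights: np.ndarray | None = None) -> np.ndarray:
    """Optimal rotation aligning centred P onto centred Q (SVD, det-corrected)."""
    w = (np.ones(len(P)) if weights is None else np.asarray(weights, float))
    H = (P * w[:, None]).T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def superposed_rmsd(mobile: np.ndarray, reference: np.ndarray,
                    weights: np.ndarray | None = None) -> float:
    """RMSD after optimal rigid (rotation + translation) superposition."""
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if mobile.shape != reference.shape:
        raise ValueError("shape mismatch")
    if len(mobile) < 3:
        raise ValueError("need >=3 atoms for superposition")
    w = (np.ones(len(mobile)) if weights is None
         else np.asarray(weights, float))
    w = w / w.sum()
    mc = mobile - (w[:, None] * mobile).sum(0)
    rc = reference - (w[:, None] * reference).sum(0)
    R = kabsch_rotation(mc, rc, w)
    diff = mc @ R.T - rc
    return float(np.sqrt((w * np.einsum("ij,ij->i", diff, diff)).sum()))


@dataclass
class RMSDSeries:
    times: np.ndarray
    per_chain: pd.DataFrame      # frames x chains, nm
    reference_frame: int
    selection: str

    @property
    def chain_average(self) -> np.ndarray:
        return self.per_chain.mean(axis=1).to_numpy()


def rmsd_series(trajectory: Trajectory, selection: str = "backbone",
                reference_frame: int = 0,
                mass_weighted: bool = False) -> RMSDSeries:
    """Per-chain superposition RMSD versus a reference frame.

    Each chain is made whole across periodic boundaries, superposed on its
    own reference coordinates, and the RMSD time series is averaged over
    chains afterwards (per-chain first, then the arithmetic chain mean).
    """
    topo = trajectory.topology
    sel = select_atoms(topo, selection)
    chains = topo.chains()
    if not chains:
        raise ValueError("no protein chains in topology")
    chain_sels = [np.intersect1d(c, sel) for c in chains]
    chain_sels = [c for c in chain_sels if len(c) >= 3]
    if not chain_sels:
        raise ValueError("selection leaves <3 atoms per chain")
    weights = topo.masses if mass_weighted else None

    def whole(i):
        if trajectory.unwrapped is not None:
            return trajectory.unwrapped[i]
        return make_molecules_whole(trajectory.positions[i], topo, trajectory.box)

    ref = whole(reference_frame)
    cols = {}
    for k, cs in enumerate(chain_sels):
        w = weights[cs] if weights is not None else None
        refc = ref[cs]
        cols[k] = [superposed_rmsd(whole(i)[cs], refc, w)
                   for i in range(trajectory.n_frames)]
    return RMSDSeries(times=trajectory.times.copy(),
                      per_chain=pd.DataFrame(cols),
                      reference_frame=reference_frame,
                      selection=str(selection))


def radius_of_gyration(positions: np.ndarray,
                       masses: np.ndarray | None = None) -> float:
    """Rg = sqrt(sum m_i |r_i - r_com|^2 / sum m_i)."""
    pos = np.asarray(positions, float)
    if len(pos) == 0:
        raise ValueError("empty selection")
    m = np.ones(len(pos)) if masses is None else np.asarray(masses, float)
    if m.sum() <= 0:
        raise ValueError("zero total mass")
    com = (m[:, None] * pos).sum(0) / m.sum()
    return float(np.sqrt((m * ((pos - com) ** 2).sum(1)).sum() / m.sum()))


def gyration_series(trajectory: Trajectory, selection: str = "protein",
                    mass_weighted: bool = True) -> pd.DataFrame:
    """Per-chain radius of gyration versus time (nm)."""
    topo = trajectory.topology
    sel = select_atoms(topo, selection)
    chains = [np.intersect1d(c, sel) for c in topo.chains()]
    chains = [c for c in chains if len(c) >= 2]
    if not chains:
        raise ValueError("no usable chains")
    masses = topo.masses if mass_weighted else None
    cols = {}
    for k, cs in enumerate(chains):
        m = masses[cs] if masses is not None else None
        vals = []
        for i in range(trajectory.n_frames):
            pos = (trajectory.unwrapped[i] if trajectory.unwrapped is not None
                   else make_molecules_whole(trajectory.positions[i], topo,
                                             trajectory.box))
            vals.append(radius_of_gyration(pos[cs], m))
        cols[k] = vals
    return pd.DataFrame(cols, index=trajectory.times)


# ---------------------------------------------------------------------------
# displacements, van Hove, SISF
# ---------------------------------------------------------------------------

def _unwrapped(trajectory: Trajectory, sel: np.ndarray) -> np.ndarray:
    if trajectory.unwrapped is not None:
        return trajectory.unwrapped[:, sel]
    return unwrap_heuristic(trajectory.positions[:, sel], trajectory.box)


def _displacement_magnitudes(unw: np.ndarray, lag: int,
                             origin_stride: int = 1,
                             max_origin_fraction: float = 0.5) -> np.ndarray:
    n_frames = unw.shape[0]
    if lag >= n_frames:
        raise ValueError(f"lag {lag} exceeds trajectory span {n_frames - 1}")
    if lag == 0:
        n0 = max(1, int(n_frames * max_origin_fraction))
        return np.zeros(unw[0:n0:origin_stride].shape[:2]).ravel()
    last = min(n_frames - lag, max(1, int(n_frames * max_origin_fraction)))
    origins = np.arange(0, last, origin_stride)
    d = unw[origins + lag] - unw[origins]
    return np.linalg.norm(d, axis=-1).ravel()


def vanhove_self(trajectory: Trajectory, selection: str = "all",
                 lag: int = 1, bins: int = 100, r_max: float | None = None,
                 origin_stride: int = 1):
    """Self van Hove function G_s(r, t): distribution of displacement
    magnitudes at one lag, normalised so the integral over r is 1.

    Returns (bin_centres, G_s).
    """
    sel = select_atoms(trajectory.topology, selection)
    r = _displacement_magnitudes(_unwrapped(trajectory, sel), lag, origin_stride)
    if r_max is None:
        r_max = max(float(r.max()) * 1.05, 1e-6)
    hist, edges = np.histogram(r, bins=bins, range=(0.0, r_max))
    widths = np.diff(edges)
    total = hist.sum()
    if total == 0:
        raise ValueError("no displacement samples")
    gs = hist / (total * widths)
    return 0.5 * (edges[:-1] + edges[1:]), gs


@dataclass
class SISFCurve:
    q: float
    lags: np.ndarray            # ps
    F: np.ndarray
    selection: str
    n_origins: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lag_ps": self.lags, "F": self.F})


def sisf(trajectory: Trajectory, q: float, selection: str = "all",
         lags: Sequence[int] | None = None, origin_stride: int = 1,
         max_origin_fraction: float = 0.5) -> SISFCurve:
    """Self-intermediate scattering function at scattering vector q (1/nm).

    ``lags`` are frame offsets (default: ~60 log-spaced lags up to half the
    trajectory).  Multiple time origins up to ``max_origin_fraction`` of the
    run are averaged; the r -> 0 limit of the sinc kernel is taken as 1.
    """
    if q <= 0:
        raise ValueError("q must be positive")
    sel = select_atoms(trajectory.topology, selection)
    unw = _unwrapped(trajectory, sel)
    n_frames = unw.shape[0]
    if lags is None:
        max_lag = max(1, (n_frames - 1) // 2)
        lags = np.unique(np.concatenate(
            [[0], np.geomspace(1, max_lag, 60).astype(int)]))
    lags = np.asarray(sorted(set(int(l) for l in lags)))
    F = np.empty(len(lags))
    n_origins = 0
    for i, lag in enumerate(lags):
        r = _displacement_magnitudes(unw, int(lag), origin_stride,
                                     max_origin_fraction)
        x = q * r
        F[i] = float(np.mean(np.sinc(x / np.pi)))   # sinc(0) = 1 exactly
        n_origins = max(n_origins, len(r) // max(unw.shape[1], 1))
    times = trajectory.times
    dt = times[1] - times[0] if len(times) > 1 else 1.0
    return SISFCurve(q=float(q), lags=lags * dt, F=F,
                     selection=str(selection), n_origins=n_origins)


# ---------------------------------------------------------------------------
# relaxation-time fits
# ---------------------------------------------------------------------------

@dataclass
class RelaxationFit:
    tau: float                  # ps
    amplitude: float
    window: tuple[float, float]
    residual_norm: float
    converged: bool
    fixed_amplitude: bool = False


def fit_relaxation(curve: SISFCurve, upper_F: float = 0.95,
                   lower_F: float = 0.05, fix_amplitude: bool = False,
                   min_points: int = 5) -> RelaxationFit:
    """Least-squares fit of A exp(-t/tau) to a SISF decay.

    The window keeps lags with F < ``upper_F`` (dropping the trivial t=0
    plateau) down to the first point below ``lower_F``.  Non-convergence is
    reported via the flag, never silently replaced.
    """
    t, F = np.asarray(curve.lags, float), np.asarray(curve.F, float)
    mask = F < upper_F
    below = np.flatnonzero(F < lower_F)
    if len(below):
        mask &= np.arange(len(F)) <= below[0]
    t_fit, F_fit = t[mask], F[mask]
    if len(t_fit) < min_points:
        raise ValueError(
            f"only {len(t_fit)} lag points inside the fit window "
            f"(F < {upper_F}); need >= {min_points}")
    tau0 = max(t_fit[np.argmin(np.abs(F_fit - np.exp(-1)))], t_fit[0])
    tau = A = np.nan
    converged = False
    try:
        if fix_amplitude:
            popt, _ = curve_fit(lambda tt, tau: np.exp(-tt / tau),
                                t_fit, F_fit, p0=[tau0],
                                bounds=(1e-12, np.inf), maxfev=10000)
            tau, A = float(popt[0]), 1.0
        else:
            popt, _ = curve_fit(lambda tt, A, tau: A * np.exp(-tt / tau),
                                t_fit, F_fit, p0=[1.0, tau0],
                                bounds=([0.0, 1e-12], [1.5, np.inf]),
                                maxfev=10000)
            A, tau = float(popt[0]), float(popt[1])
        converged = True
    except RuntimeError:
        pass
    resid = (F_fit - A * np.exp(-t_fit / tau) if converged
             else np.full_like(F_fit, np.nan))
    return RelaxationFit(tau=tau, amplitude=A,
                         window=(float(t_fit[0]), float(t_fit[-1])),
                         residual_norm=float(np.sqrt(np.nanmean(resid ** 2))),
                         converged=converged, fixed_amplitude=fix_amplitude)


def relaxation_times(trajectory: Trajectory, q_values=DEFAULT_Q_VALUES,
                     selection: str = "backbone", **fit_kw) -> pd.DataFrame:
    """Fitted tau (ps) for each q: the per-system relaxation summary row."""
    rows = []
    for q in q_values:
        curve = sisf(trajectory, q, selection=selection)
        try:
            fit = fit_relaxation(curve, **fit_kw)
            rows.append({"q": q, "tau_ps": fit.tau, "amplitude": fit.amplitude,
                         "converged": fit.converged,
                         "window_lo": fit.window[0], "window_hi": fit.window[1]})
        except ValueError:
            # curve does not decay through the fit window at this q
            rows.append({"q": q, "tau_ps": np.nan, "amplitude": np.nan,
                         "converged": False, "window_lo": np.nan,
                         "window_hi": np.nan})
    return pd.DataFrame(rows)
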