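"""Emulation of the measurement layer of a trapped-ion transfer experiment.

Three ingredients let the analysis pipeline run end-to-end on generated
data: finite-shot sampling of the donor population (state-dependent
fluorescence is a per-shot binary outcome, so shot noise is binomial),
the blue-sideband (BSB) phonon-number readout, and the spin-dependent
displacement used to prepare the donor well.

The BSB signal for a phonon-number distribution p(n) under a resonant
sideband drive of Rabi scale eta*Omega with decoherence alpha_m is

    P_up(t) = 1/2 sum_n p(n) [1 - exp(-alpha_m t) cos(sqrt(n+1) eta Omega t)]

Inverting the signal (nonnegative least squares over p(n)) recovers the
distribution and its mean occupation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.optimize

from .dynamics import Trajectory

__all__ = [
    "MeasuredSeries",
    "PhononDistribution",
    "BSBSignal",
    "sample_pd",
    "bsb_signal",
    "fit_bsb",
    "spin_dependent_displacement",
]


@dataclass
class MeasuredSeries:
    """Shot-averaged donor-population measurements with standard errors."""

    times: np.ndarray
    means: np.ndarray
    sems: np.ndarray
    shots: int

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.sems = np.asarray(self.sems, dtype=float)
        if np.any(self.means < 0) or np.any(self.means > 1):
            raise ValueError("means must lie in [0, 1]")
        if np.any(self.sems < 0):
            raise ValueError("sems must be nonnegative")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "t": self.times,
                "pd_mean": self.means,
                "pd_sem": self.sems,
                "shots": self.shots,
            }
        )


@dataclass
class PhononDistribution:
    """Probabilities over phonon numbers n = 0..n_max."""

    p: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if np.any(self.p < -1e-12):
            raise ValueError("probabilities must be nonnegative")
        self.p = np.clip(self.p, 0.0, None)
        if abs(self.p.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1")

    def mean(self) -> float:
        return float(np.arange(self.p.size) @ self.p)


@dataclass
class BSBSignal:
    """Blue-sideband excitation probability versus drive time."""

    times: np.ndarray
    p_up: np.ndarray
    eta_omega: float
    alpha_m: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.p_up = np.asarray(self.p_up, dtype=float)
        if np.any(self.p_up < -1e-9) or np.any(self.p_up > 1 + 1e-9):
            raise ValueError("P_up must lie in [0, 1]")


def sample_pd(traj: Trajectory, shots: int, seed: int) -> MeasuredSeries:
    """Binomial finite-shot sampling of a donor-population trajectory.

    Per time point: mean = Binomial(shots, PD)/shots and
    sem = sqrt(mean(1-mean)/shots), the plug-in standard error the lab
    would quote.  Reproducible under ``seed``.
    """
    if shots < 1:
        raise ValueError("shots must be >= 1")
    rng = np.random.default_rng(seed)
    counts = rng.binomial(shots, np.clip(traj.pd, 0.0, 1.0))
    means = counts / shots
    sems = np.sqrt(means * (1.0 - means) / shots)
    return MeasuredSeries(times=traj.times.copy(), means=means, sems=sems, shots=shots)


def _bsb_basis(times: np.ndarray, n_max: int, eta_omega: float, alpha_m: float) -> np.ndarray:
    """Column k: the BSB flop of Fock level k, 1/2 [1 - e^{-am t} cos(sqrt(k+1) eO t)]."""
    n = np.arange(n_max + 1)
    phase = np.sqrt(n + 1.0)[None, :] * eta_omega * times[:, None]
    return 0.5 * (1.0 - np.exp(-alpha_m * times)[:, None] * np.cos(phase))


def bsb_signal(
    p: PhononDistribution,
    eta_omega: float,
    alpha_m: float,
    times: np.ndarray,
) -> BSBSignal:
    """Forward model of the blue-sideband readout for a known p(n)."""
    times = np.asarray(times, dtype=float)
    basis = _bsb_basis(times, p.p.size - 1, eta_omega, alpha_m)
    return BSBSignal(times=times, p_up=basis @ p.p, eta_omega=eta_omega, alpha_m=alpha_m)


def fit_bsb(
    signal: BSBSignal,
    n_max: int,
    *,
    fit_alpha_m: bool = False,
) -> tuple[PhononDistribution, float, float]:
    """Invert a BSB signal into a phonon-number distribution.

    Nonnegative least squares over {p(n)}, n = 0..n_max, with the
    normalization sum p = 1 enforced as a heavily weighted design row.
    With ``fit_alpha_m`` the shared decoherence rate is optimized by a
    scalar search wrapped around the NNLS.  Returns the distribution,
    its mean occupation and the rms residual.

    The drive must cover at least two periods of the slowest flop
    (Fock level 0), otherwise the design is ill-conditioned.
    """
    t = signal.times
    span_needed = 2.0 * 2.0 * math.pi / signal.eta_omega
    if t[-1] - t[0] < span_needed:
        raise ValueError(
            f"signal covers {t[-1] - t[0]:.3g} time units; need >= {span_needed:.3g} "
            "(two periods of the slowest flop)"
        )
    weight = 100.0

    def solve(alpha_m: float) -> tuple[np.ndarray, float]:
        basis = _bsb_basis(t, n_max, signal.eta_omega, alpha_m)
        a = np.vstack([basis, weight * np.ones(n_max + 1)])
        b = np.concatenate([signal.p_up, [weight]])
        p, _ = scipy.optimize.nnls(a, b)
        resid = float(np.sqrt(np.mean((basis @ p - signal.p_up) ** 2)))
        return p, resid

    if fit_alpha_m:
        res = scipy.optimize.minimize_scalar(
            lambda am: solve(am)[1],
            bounds=(0.0, 5.0 * signal.eta_omega),
            method="bounded",
        )
        alpha_m = float(res.x)
    else:
        alpha_m = signal.alpha_m
    p, resid = solve(alpha_m)
    total = p.sum()
    if total <= 0:
        raise RuntimeError("BSB fit produced an empty distribution")
    dist = PhononDistribution(p / total)
    return dist, dist.mean(), resid


def spin_dependent_displacement(g: float, delta: float, t: float | np.ndarray) -> complex | np.ndarray:
    """Displacement amplitude accumulated under a detuned spin-dependent force.

    alpha(t) = alpha0 (1 - exp(-i delta t)) with alpha0 = g/(4 delta):
    a circle of radius |alpha0| in phase space, closing every 2 pi/delta.
    At the half-period t = pi/delta the displacement is g/(2 delta),
    which for delta = -omega is the donor-well preparation -g/(2 omega).
    """
    if delta == 0:
        raise ValueError("delta must be nonzero (resonant limit grows unboundedly)")
    alpha0 = g / (4.0 * delta)
    return alpha0 * (1.0 - np.exp(-1j * delta * np.asarray(t, dtype=float)))
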