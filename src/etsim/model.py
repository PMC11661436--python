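"""Dimensionless spin-boson model of molecular electron transfer.

The electronic donor/acceptor pair is a two-level system (``|D>`` and
``|A>``) coupled to a single harmonic reaction coordinate (one bosonic
mode).  The system Hamiltonian is

    H = (dE/2) sz + Vx sx + (g/2) sz (a + a^dag) + w a^dag a

with ``sz``, ``sx`` Pauli matrices and ``a`` the mode annihilation
operator.  Relaxation of the reaction coordinate toward a thermal bath
enters through Lindblad cooling/heating channels ``a`` and ``a^dag``
with rates ``gamma*(nbar+1)`` and ``gamma*nbar``.

Conventions (fixed throughout the package):

* hbar = 1 and the mode quantum ``omega = 1``; every energy and rate is
  expressed in units of omega.
* Basis ordering is spin-major: ``|up,0>, |up,1>, ..., |up,N-1>,
  |down,0>, ..., |down,N-1>`` for a Fock cutoff ``N``.
* The donor state is ``|D> = |up>``, the +1 eigenstate of sz, and the
  donor potential well is centred at quadrature ``y = -g/(2 omega)``.
* ``Vx >= 0``: the dynamics generated by ``Vx sx`` is invariant under a
  spin rotation flipping the sign of ``Vx``, so a nonnegative
  convention removes an unobservable degree of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm
from scipy.special import eval_genlaguerre, gammaln

__all__ = [
    "ModelParams",
    "BathParams",
    "NoiseParams",
    "TruncationConfig",
    "OperatorSet",
    "MarcusQuantities",
    "build_hamiltonian",
    "build_dissipators",
    "build_operators",
    "franck_condon",
    "marcus_quantities",
    "bath_temperature",
    "nbar_from_temperature",
    "donor_acceptor_levels",
    "default_n_fock",
    "destroy",
    "displacement_operator",
]


def _require_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class ModelParams:
    """Hamiltonian parameters, all in units of the mode quantum omega.

    Parameters
    ----------
    delta_e:
        Donor-acceptor energy gap (exothermicity) dE.
    vx:
        Electronic donor-acceptor coupling Vx (>= 0 by convention).
    g:
        Spin-phonon (vibronic) coupling g (>= 0).
    omega:
        Mode quantum; fixed to 1 internally and kept as an explicit
        field only so formulas read like their dimensionful originals.
    """

    delta_e: float
    vx: float
    g: float
    omega: float = 1.0

    def __post_init__(self) -> None:
        for name in ("delta_e", "vx", "g", "omega"):
            object.__setattr__(self, name, _require_finite(name, getattr(self, name)))
        if self.omega <= 0:
            raise ValueError("omega must be positive")
        if self.g < 0:
            raise ValueError("g must be nonnegative")
        if self.vx < 0:
            raise ValueError("vx must be nonnegative (sign is unobservable)")


@dataclass(frozen=True)
class BathParams:
    """Motional relaxation rate gamma and bath occupation nbar.

    The Lindblad description of the bath assumes weak damping
    (gamma << omega) and bath thermal energy above the relaxation rate
    (gamma * beta << 1).  ``validity_flags`` reports which of these are
    violated; construction never fails on them.
    """

    gamma: float
    nbar: float

    def __post_init__(self) -> None:
        _require_finite("gamma", self.gamma)
        _require_finite("nbar", self.nbar)
        if self.gamma < 0:
            raise ValueError("gamma must be nonnegative")
        if self.nbar < 0:
            raise ValueError("nbar must be nonnegative")

    def validity_flags(self, omega: float = 1.0) -> dict[str, bool]:
        flags = {"weak_damping": self.gamma < 0.2 * omega, "markovian_bath": True}
        if self.nbar > 0:
            beta = 1.0 / bath_temperature(self.nbar, omega)
            flags["markovian_bath"] = self.gamma * beta < 1.0
        elif self.gamma > 0:
            # nbar = 0 means zero temperature: gamma*beta diverges.
            flags["markovian_bath"] = False
        return flags


@dataclass(frozen=True)
class NoiseParams:
    """Technical decoherence: spin dephasing gamma_z, motional dephasing gamma_m."""

    gamma_z: float = 0.0
    gamma_m: float = 0.0

    def __post_init__(self) -> None:
        _require_finite("gamma_z", self.gamma_z)
        _require_finite("gamma_m", self.gamma_m)
        if self.gamma_z < 0 or self.gamma_m < 0:
            raise ValueError("decoherence rates must be nonnegative")


@dataclass(frozen=True)
class TruncationConfig:
    """Fock-space cutoff N and the allowed population in the top two levels."""

    n_fock: int
    tail_tol: float = 1e-6

    def __post_init__(self) -> None:
        if int(self.n_fock) != self.n_fock or self.n_fock < 2:
            raise ValueError("n_fock must be an integer >= 2")
        object.__setattr__(self, "n_fock", int(self.n_fock))
        if not self.tail_tol > 0:
            raise ValueError("tail_tol must be positive")


@dataclass
class OperatorSet:
    """Matrices defining one concrete simulation on the 2N-dim product space."""

    n_fock: int
    hamiltonian: np.ndarray | None = None
    jump_ops: list[tuple[np.ndarray, float]] = field(default_factory=list)
    observables: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def dim(self) -> int:
        return 2 * self.n_fock

    def merged_with(self, other: "OperatorSet") -> "OperatorSet":
        if other.n_fock != self.n_fock:
            raise ValueError("cannot merge operator sets with different cutoffs")
        out = OperatorSet(self.n_fock, self.hamiltonian, list(self.jump_ops), dict(self.observables))
        if other.hamiltonian is not None:
            out.hamiltonian = other.hamiltonian
        out.jump_ops.extend(other.jump_ops)
        out.observables.update(other.observables)
        return out


@dataclass(frozen=True)
class MarcusQuantities:
    """Classical Marcus quantities derived from the quantum parameters.

    lam:
        Reorganization energy lambda = g^2/omega, the energy to displace
        the nuclear wave packet by the donor-acceptor well separation
        without electronic transfer.
    u_act:
        Activation energy (dE + lambda)^2 / (4 lambda); None when
        lambda = 0 with dE != 0 (no barrier is defined).
    barrier_sym:
        lambda/4, the activation energy of the symmetric (dE = 0) case.
    """

    lam: float
    u_act: float | None
    barrier_sym: float


# ---------------------------------------------------------------------------
# elementary operators

_SZ = np.diag([1.0, -1.0]).astype(complex)
_SX = np.array([[0.0, 1.0], [1.0, 0.0]], dtype=complex)
_ID2 = np.eye(2, dtype=complex)


def destroy(n_fock: int) -> np.ndarray:
    """Annihilation operator on an ``n_fock``-dimensional Fock space."""
    return np.diag(np.sqrt(np.arange(1, n_fock, dtype=float)), k=1).astype(complex)


def displacement_operator(alpha: complex, n_fock: int) -> np.ndarray:
    """D(alpha) = exp(alpha a^dag - alpha* a) by direct matrix exponential."""
    a = destroy(n_fock)
    return expm(alpha * a.conj().T - np.conj(alpha) * a)


def _lift_spin(op2: np.ndarray, n_fock: int) -> np.ndarray:
    return np.kron(op2, np.eye(n_fock, dtype=complex))


def _lift_mode(opn: np.ndarray) -> np.ndarray:
    return np.kron(_ID2, opn)


# ---------------------------------------------------------------------------
# builders


def build_hamiltonian(params: ModelParams, trunc: TruncationConfig) -> OperatorSet:
    """Assemble H = (dE/2) sz + Vx sx + (g/2) sz (a+a^dag) + w a^dag a.

    The returned :class:`OperatorSet` also carries the standard
    observables: the donor projector ``|D><D|`` (spin-up projector), the
    mode number operator, the dimensionless quadrature ``y = (a+a^dag)/2``
    and the projector on the top two Fock levels used for truncation
    diagnostics.
    """
    n = trunc.n_fock
    a = destroy(n)
    x = a + a.conj().T
    num = a.conj().T @ a
    h = (
        0.5 * params.delta_e * _lift_spin(_SZ, n)
        + params.vx * _lift_spin(_SX, n)
        + 0.5 * params.g * np.kron(_SZ, x)
        + params.omega * _lift_mode(num)
    )
    proj_d = _lift_spin(np.diag([1.0, 0.0]).astype(complex), n)
    tail = np.zeros((n, n), dtype=complex)
    tail[n - 1, n - 1] = 1.0
    tail[n - 2, n - 2] = 1.0
    obs = {
        "proj_donor": proj_d,
        "number": _lift_mode(num),
        "quadrature": 0.5 * _lift_mode(x),
        "tail": _lift_mode(tail),
    }
    return OperatorSet(n_fock=n, hamiltonian=h, observables=obs)


def build_dissipators(
    bath: BathParams,
    noise: NoiseParams | None = None,
    trunc: TruncationConfig | None = None,
    *,
    extra_channels: list[tuple[np.ndarray, float]] | None = None,
) -> OperatorSet:
    """Assemble the Lindblad jump operators with their rates.

    Channels: mode cooling ``(a, gamma*(nbar+1))`` and heating
    ``(a^dag, gamma*nbar)``; optionally pure spin dephasing realized as
    jump operator ``sz`` at rate ``gamma_z/2`` and motional dephasing as
    ``a^dag a`` at rate ``gamma_m``.  The two auxiliary channels model
    technical decoherence whose microscopic form is not pinned down by
    the physics here, so ``extra_channels`` lets callers swap in
    alternative operators without touching the solver.
    Channels with exactly zero rate are omitted.
    """
    if trunc is None:
        raise ValueError("a TruncationConfig is required to size the operators")
    noise = noise or NoiseParams()
    n = trunc.n_fock
    a = destroy(n)
    jumps: list[tuple[np.ndarray, float]] = []
    if bath.gamma * (bath.nbar + 1.0) > 0:
        jumps.append((_lift_mode(a), bath.gamma * (bath.nbar + 1.0)))
    if bath.gamma * bath.nbar > 0:
        jumps.append((_lift_mode(a.conj().T), bath.gamma * bath.nbar))
    if noise.gamma_z > 0:
        jumps.append((_lift_spin(_SZ, n), 0.5 * noise.gamma_z))
    if noise.gamma_m > 0:
        jumps.append((_lift_mode(a.conj().T @ a), noise.gamma_m))
    for op, rate in extra_channels or []:
        if rate < 0:
            raise ValueError("jump rates must be nonnegative")
        if rate > 0:
            jumps.append((np.asarray(op, dtype=complex), float(rate)))
    return OperatorSet(n_fock=n, jump_ops=jumps)


def build_operators(
    model: ModelParams,
    bath: BathParams,
    noise: NoiseParams | None = None,
    trunc: TruncationConfig | None = None,
) -> OperatorSet:
    """Hamiltonian plus dissipators in one :class:`OperatorSet`."""
    if trunc is None:
        trunc = TruncationConfig(default_n_fock(model, bath.nbar))
    ham = build_hamiltonian(model, trunc)
    return ham.merged_with(build_dissipators(bath, noise, trunc))


def default_n_fock(
    model: ModelParams, nbar: float = 0.0, delta_e_max: float | None = None
) -> int:
    """Heuristic Fock cutoff covering the displaced wells plus thermal tail.

    Sized from the well displacement (g/2w)^2, the thermal occupation
    and the largest gap that will be scanned; generous by construction
    so that the top-two-level population stays below ~1e-6 for the
    regimes treated here.  Trajectory code still verifies the tail and
    asks for doubling on breach.
    """
    de = abs(model.delta_e if delta_e_max is None else delta_e_max) / model.omega
    disp_sq = (model.g / (2.0 * model.omega)) ** 2
    return int(math.ceil(4.0 * disp_sq + 6.0 * nbar + de + 15.0))


# ---------------------------------------------------------------------------
# closed-form quantities


def franck_condon(n: int, m: int, d: float) -> float:
    """Squared overlap |<n|D(d)|m>|^2 of Fock states displaced by ``d``.

    ``d`` is the donor-acceptor well separation g/omega.  Evaluated via
    the associated-Laguerre closed form with log-factorials for
    stability; symmetric in (n, m) and even in d by construction.
    """
    if n < 0 or m < 0 or int(n) != n or int(m) != m:
        raise ValueError("occupations must be nonnegative integers")
    n, m = int(n), int(m)
    if n > m:
        n, m = m, n
    x = float(d) ** 2
    if x == 0.0:
        return 1.0 if n == m else 0.0
    lag = eval_genlaguerre(n, m - n, x)
    log_pref = gammaln(n + 1) - gammaln(m + 1) + (m - n) * math.log(x) - x
    fc = float(lag) ** 2 * math.exp(log_pref)
    return min(fc, 1.0)


def marcus_quantities(params: ModelParams) -> MarcusQuantities:
    """Reorganization energy lambda = g^2/w and barrier U = (dE+lambda)^2/(4 lambda)."""
    lam = params.g**2 / params.omega
    if lam > 0:
        u = (params.delta_e + lam) ** 2 / (4.0 * lam)
    elif params.delta_e == 0:
        u = 0.0
    else:
        u = None  # no nuclear displacement: no barrier is defined
    return MarcusQuantities(lam=lam, u_act=u, barrier_sym=lam / 4.0)


def bath_temperature(nbar: float, omega: float = 1.0) -> float:
    """kB*T = omega / log(1 + 1/nbar); zero at nbar = 0 by continuity."""
    if nbar < 0:
        raise ValueError("nbar must be nonnegative")
    if nbar == 0:
        return 0.0
    return omega / math.log1p(1.0 / nbar)


def nbar_from_temperature(kbt: float, omega: float = 1.0) -> float:
    """Bose occupation at temperature kbt: 1/(exp(omega/kbt) - 1)."""
    if kbt < 0:
        raise ValueError("temperature must be nonnegative")
    if kbt == 0:
        return 0.0
    return 1.0 / math.expm1(omega / kbt)


def donor_acceptor_levels(params: ModelParams, n_max: int) -> tuple[np.ndarray, np.ndarray]:
    """Unperturbed (Vx = 0) vibronic ladders of the two displaced wells.

    Returns ``(E_D, E_A)`` with ``E_{D,n} = +dE/2 + n w - g^2/(4w)`` and
    ``E_{A,n} = -dE/2 + n w - g^2/(4w)`` for n = 0..n_max.  The ladders
    cross pairwise (E_{D,n} = E_{A,n+l}) exactly when dE = l*w.
    """
    n = np.arange(n_max + 1, dtype=float)
    shift = n * params.omega - params.g**2 / (4.0 * params.omega)
    return 0.5 * params.delta_e + shift, -0.5 * params.delta_e + shift
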