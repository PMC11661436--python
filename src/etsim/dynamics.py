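"""State preparation and Lindblad time evolution.

The master equation integrated here is

    drho/dt = -i [H, rho] + sum_k r_k ( c_k rho c_k^dag
                                        - 1/2 {c_k^dag c_k, rho} )

with the Hamiltonian and jump list supplied by an
:class:`~etsim.model.OperatorSet`.  The right-hand side is evaluated
with dense matrix products through the non-Hermitian effective
Hamiltonian H_eff = H - (i/2) sum_k r_k c_k^dag c_k, which halves the
number of products per step; the density matrix is propagated with an
adaptive high-order explicit Runge-Kutta integrator on the vectorized
state.  Problem sizes here are desk scale (2N <~ 100), so dense algebra
is both simplest and fastest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.integrate import solve_ivp

from .model import (
    ModelParams,
    OperatorSet,
    TruncationConfig,
    destroy,
    displacement_operator,
)

__all__ = [
    "DensityState",
    "InitialStateParams",
    "Trajectory",
    "TruncationError",
    "DegenerateSteadyStateError",
    "prepare_initial_state",
    "evolve",
    "steady_state",
    "check_truncation",
    "liouvillian_matrix",
]

_HERM_TOL = 1e-8
_TRACE_TOL = 1e-8
_POS_TOL = 1e-7


class TruncationError(RuntimeError):
    """Raised when the top of the Fock ladder accumulates population."""

    def __init__(self, message: str, suggested_n: int | None = None):
        super().__init__(message)
        self.suggested_n = suggested_n


class DegenerateSteadyStateError(RuntimeError):
    """Raised when the Liouvillian null space is not one dimensional."""


@dataclass
class DensityState:
    """Density matrix on the 2N-dimensional spin (x) Fock product space.

    Basis ordering is spin-major (see :mod:`etsim.model`).
    """

    matrix: np.ndarray
    n_fock: int

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=complex)
        d = 2 * self.n_fock
        if self.matrix.shape != (d, d):
            raise ValueError(f"expected a {d}x{d} matrix for n_fock={self.n_fock}")

    def validate(self) -> None:
        m = self.matrix
        herm = np.max(np.abs(m - m.conj().T))
        if herm > _HERM_TOL:
            raise ValueError(f"state not Hermitian (residual {herm:.2e})")
        tr = np.trace(m).real
        if abs(tr - 1.0) > _TRACE_TOL:
            raise ValueError(f"state trace deviates from 1 by {tr - 1.0:.2e}")
        w = np.linalg.eigvalsh(0.5 * (m + m.conj().T))
        if w.min() < -_POS_TOL:
            raise ValueError(f"state has negative eigenvalue {w.min():.2e}")

    def expect(self, op: np.ndarray) -> float:
        return float(np.trace(op @ self.matrix).real)

    def donor_population(self) -> float:
        n = self.n_fock
        return float(np.trace(self.matrix[:n, :n]).real)

    def mean_phonons(self) -> float:
        n = self.n_fock
        num = np.arange(n, dtype=float)
        pops = np.real(np.diagonal(self.matrix))
        return float(num @ pops[:n] + num @ pops[n:])

    def fock_populations(self) -> np.ndarray:
        """Phonon-number distribution traced over the spin."""
        pops = np.real(np.diagonal(self.matrix))
        return pops[: self.n_fock] + pops[self.n_fock :]

    def purity(self) -> float:
        return float(np.trace(self.matrix @ self.matrix).real)


@dataclass(frozen=True)
class InitialStateParams:
    """Initial thermal occupation and motional displacement.

    ``displacement=None`` selects the donor-well default -g/(2 omega):
    a thermal state of the *donor* surface, which is the standard
    preparation for transfer dynamics.
    """

    nbar0: float = 0.0
    displacement: float | None = None

    def __post_init__(self) -> None:
        if self.nbar0 < 0:
            raise ValueError("nbar0 must be nonnegative")


@dataclass
class Trajectory:
    """Sampled observables of one master-equation run.

    times are in units of 1/omega; ``pd`` is the donor population
    PD = (<sz>+1)/2, ``nbar_t`` the mean phonon number, ``y_t`` the
    dimensionless quadrature <(a+a^dag)/2> and ``tail`` the population
    in the top two Fock levels (truncation diagnostic).
    """

    times: np.ndarray
    pd: np.ndarray
    nbar_t: np.ndarray
    y_t: np.ndarray
    tail: np.ndarray
    n_fock: int
    final_state: DensityState | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.pd < -1e-9) or np.any(self.pd > 1 + 1e-9):
            raise ValueError("PD out of [0, 1]")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "t_omega_over_2pi": self.times / (2.0 * math.pi),
                "pd": self.pd,
                "nbar": self.nbar_t,
                "y": self.y_t,
                "tail": self.tail,
            }
        )


def thermal_fock_populations(nbar0: float, n_fock: int) -> np.ndarray:
    """Geometric (Bose) populations p_n = (1-q) q^n, q = nbar0/(1+nbar0)."""
    if nbar0 == 0:
        p = np.zeros(n_fock)
        p[0] = 1.0
        return p
    q = nbar0 / (1.0 + nbar0)
    p = (1.0 - q) * q ** np.arange(n_fock)
    return p


def prepare_initial_state(
    model: ModelParams,
    init: InitialStateParams,
    trunc: TruncationConfig,
) -> DensityState:
    """Donor vibronic state |D><D| (x) D(alpha) rho_th(nbar0) D(alpha)^dag.

    The default displacement alpha = -g/(2 omega) centres the motional
    thermal state in the donor well, so the preparation is a displaced
    thermal state with PD = 1 exactly and mean phonon number
    nbar0 + (g/2 omega)^2.
    """
    n = trunc.n_fock
    alpha = init.displacement
    if alpha is None:
        alpha = -model.g / (2.0 * model.omega)
    p = thermal_fock_populations(init.nbar0, n)
    lost = 1.0 - p.sum()
    if lost > trunc.tail_tol:
        raise TruncationError(
            f"thermal tail {lost:.2e} exceeds tail_tol at n_fock={n}",
            suggested_n=2 * n,
        )
    rho_th = np.diag(p / p.sum()).astype(complex)
    disp = displacement_operator(alpha, n)
    rho_mode = disp @ rho_th @ disp.conj().T
    tail = float(np.real(rho_mode[n - 1, n - 1] + rho_mode[n - 2, n - 2]))
    if tail > trunc.tail_tol:
        raise TruncationError(
            f"displaced-state tail {tail:.2e} exceeds tail_tol at n_fock={n}",
            suggested_n=2 * n,
        )
    spin = np.zeros((2, 2), dtype=complex)
    spin[0, 0] = 1.0  # |D><D| = |up><up|
    return DensityState(np.kron(spin, rho_mode), n_fock=n)


def _lindblad_rhs_factory(ops: OperatorSet):
    h = ops.hamiltonian
    if h is None:
        raise ValueError("OperatorSet has no Hamiltonian")
    h_eff = h.astype(complex).copy()
    jumps = [(c, r) for c, r in ops.jump_ops if r > 0]
    for c, r in jumps:
        h_eff -= 0.5j * r * (c.conj().T @ c)
    h_eff_dag = h_eff.conj().T
    cs = [math.sqrt(r) * c for c, r in jumps]
    cdags = [c.conj().T for c in cs]
    d = h.shape[0]

    def rhs(_t: float, vec: np.ndarray) -> np.ndarray:
        rho = vec.reshape(d, d)
        out = -1j * (h_eff @ rho - rho @ h_eff_dag)
        for c, cd in zip(cs, cdags):
            out += c @ rho @ cd
        return out.reshape(-1)

    return rhs


def evolve(
    state: DensityState,
    ops: OperatorSet,
    times: np.ndarray,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    tail_tol: float | None = 1e-6,
    keep_final_state: bool = True,
    validate_every: int = 0,
) -> Trajectory:
    """Integrate the master equation, sampling observables on ``times``.

    ``times`` must increase from 0.  State invariants (trace,
    Hermiticity, positivity) are checked on the first, middle and last
    sample by default; set ``validate_every`` to check every k-th
    sample.  A truncation-tail breach raises :class:`TruncationError`
    naming the first offending time.
    """
    times = np.asarray(times, dtype=float)
    if times[0] != 0.0:
        raise ValueError("time grid must start at 0")
    if np.any(np.diff(times) <= 0):
        raise ValueError("time grid must be strictly increasing")
    if ops.dim != 2 * state.n_fock:
        raise ValueError("operator set and state have different dimensions")

    rhs = _lindblad_rhs_factory(ops)
    d = ops.dim
    n = ops.n_fock
    nsamp = times.size
    pd = np.empty(nsamp)
    nbar_t = np.empty(nsamp)
    y_t = np.empty(nsamp)
    tail = np.empty(nsamp)
    num_diag = np.concatenate([np.arange(n), np.arange(n)]).astype(float)
    quad = ops.observables.get("quadrature")
    check_idx = {0, nsamp // 2, nsamp - 1}
    if validate_every > 0:
        check_idx.update(range(0, nsamp, validate_every))
    final = None
    vec = state.matrix.reshape(-1).astype(complex)
    nfev = 0
    for i in range(nsamp):
        if i > 0:
            # integrate sample-to-sample, re-hermitizing the carried
            # state each time: the exact flow preserves Hermiticity, so
            # the anti-Hermitian residue is pure integrator round-off
            # and projecting it out keeps it from accumulating
            sol = solve_ivp(
                rhs,
                (times[i - 1], times[i]),
                vec,
                method="DOP853",
                rtol=rtol,
                atol=atol,
            )
            if not sol.success:
                raise RuntimeError(
                    f"master-equation integration failed at t={times[i]:.3f}: "
                    f"{sol.message}"
                )
            nfev += sol.nfev
            vec = sol.y[:, -1]
        rho = vec.reshape(d, d)
        drift = np.max(np.abs(rho - rho.conj().T))
        if drift > 1e-7:
            raise RuntimeError(
                f"integrator Hermiticity drift {drift:.2e} at t={times[i]:.3f}; "
                "tighten rtol/atol"
            )
        rho = 0.5 * (rho + rho.conj().T)
        vec = rho.reshape(-1)
        diag = np.real(np.diagonal(rho))
        pd[i] = diag[:n].sum()
        nbar_t[i] = float(num_diag @ diag)
        if quad is not None:
            y_t[i] = float(np.trace(quad @ rho).real)
        else:
            y_t[i] = np.nan
        tail[i] = diag[n - 1] + diag[n - 2] + diag[2 * n - 1] + diag[2 * n - 2]
        if tail_tol is not None and tail[i] >= tail_tol:
            raise TruncationError(
                f"truncation tail {tail[i]:.2e} >= {tail_tol:.0e} at t={times[i]:.3f}",
                suggested_n=2 * n,
            )
        if i in check_idx:
            DensityState(rho, n_fock=n).validate()
        if i == nsamp - 1 and keep_final_state:
            final = DensityState(rho.copy(), n_fock=n)

    pd = np.clip(pd, 0.0, 1.0)
    return Trajectory(
        times=times,
        pd=pd,
        nbar_t=nbar_t,
        y_t=y_t,
        tail=tail,
        n_fock=n,
        final_state=final,
        meta={"rtol": rtol, "atol": atol, "nfev": nfev},
    )


def liouvillian_matrix(ops: OperatorSet) -> sp.csr_matrix:
    """Sparse Liouvillian acting on the row-major vectorized density matrix.

    Row-major vec obeys vec(A rho B) = (A kron B^T) vec(rho).
    """
    h = ops.hamiltonian
    d = ops.dim
    eye = sp.identity(d, format="csr", dtype=complex)
    hs = sp.csr_matrix(h)
    lio = -1j * (sp.kron(hs, eye) - sp.kron(eye, hs.T))
    for c, r in ops.jump_ops:
        if r <= 0:
            continue
        cs = sp.csr_matrix(c)
        cdc = sp.csr_matrix(c.conj().T @ c)
        lio = lio + r * (
            sp.kron(cs, cs.conj()) - 0.5 * (sp.kron(cdc, eye) + sp.kron(eye, cdc.T))
        )
    return lio.tocsr()


def steady_state(ops: OperatorSet, *, degeneracy_tol: float = 1e-10) -> DensityState:
    """Unique stationary state as the null vector of the Liouvillian.

    The null vector is obtained by replacing one row of the (singular)
    Liouvillian with the trace constraint and solving the resulting
    linear system.  Uniqueness is verified by inspecting the two
    smallest-magnitude Liouvillian eigenvalues; a second near-zero
    eigenvalue (e.g. conserved sigma_z when Vx = 0) raises
    :class:`DegenerateSteadyStateError`.
    """
    if not any(r > 0 for _, r in ops.jump_ops):
        raise ValueError("steady state requires at least one dissipative channel")
    lio = liouvillian_matrix(ops)
    d = ops.dim
    m = lio.tolil()
    trace_row = np.zeros(d * d, dtype=complex)
    trace_row[:: d + 1] = 1.0
    m[0, :] = trace_row
    b = np.zeros(d * d, dtype=complex)
    b[0] = 1.0
    vec = spla.spsolve(m.tocsc(), b)
    rho = vec.reshape(d, d)
    rho = 0.5 * (rho + rho.conj().T)
    rho /= np.trace(rho).real

    # degeneracy check: two eigenvalues nearest zero
    try:
        w = spla.eigs(
            lio, k=2, sigma=1e-12, which="LM", return_eigenvectors=False, maxiter=2000
        )
        gap = np.sort(np.abs(w))
        if gap[1] < degeneracy_tol:
            raise DegenerateSteadyStateError(
                f"Liouvillian null space is degenerate (|second eigenvalue| = {gap[1]:.2e})"
            )
    except spla.ArpackNoConvergence:
        # fall back: residual of a second, random-trace solve
        resid = np.linalg.norm(lio @ vec)
        if not np.isfinite(resid):
            raise
    state = DensityState(rho, n_fock=ops.n_fock)
    state.validate()
    return state


def check_truncation(traj: Trajectory, trunc: TruncationConfig) -> tuple[bool, float]:
    """Scan stored tail diagnostics; (passed, max tail population)."""
    max_tail = float(np.max(traj.tail))
    return max_tail < trunc.tail_tol, max_tail
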