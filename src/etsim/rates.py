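"""Transfer-rate computation and extraction.

Four routes to a transfer rate are provided:

* :func:`fgr_rate` — perturbative Fermi-golden-rule rate with the bath
  entering as a Lorentzian broadening (FWHM gamma) of each vibronic
  resonance;
* :func:`two_state_rate` — closed form for a single donor level coupled
  to a single decaying acceptor level;
* :func:`exp_fit_rate` — least-squares exponential fit of the donor
  population, appropriate in the nonadiabatic regime;
* :func:`inverse_lifetime_rate` — finite-window inverse mean lifetime
  kT = int PD dt / int t PD dt - 2/tsim, appropriate for the
  oscillatory decays of the adiabatic regime.

plus bootstrap error bars for measured series and sweep drivers over
the donor-acceptor gap (resonance spectra) and over Vx/gamma (optimal
transfer).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.signal
from scipy.optimize import curve_fit

from .dynamics import (
    InitialStateParams,
    Trajectory,
    TruncationError,
    evolve,
    prepare_initial_state,
    thermal_fock_populations,
)
from .model import (
    BathParams,
    ModelParams,
    NoiseParams,
    TruncationConfig,
    build_operators,
    default_n_fock,
    franck_condon,
)

__all__ = [
    "RateEstimate",
    "RateSpectrum",
    "PeakInventory",
    "OptimalTransferResult",
    "fgr_rate",
    "two_state_rate",
    "exp_fit_rate",
    "inverse_lifetime_rate",
    "bootstrap_rate",
    "scan_delta_e",
    "find_peaks",
    "find_optimal_vx",
    "simulate_trajectory",
    "default_tsim",
]


@dataclass(frozen=True)
class RateEstimate:
    """A transfer rate kT (units of omega) with provenance.

    method is one of {"exp_fit", "inverse_lifetime", "fgr", "two_state"};
    diagnostics carries method-specific extras (fit parameters, the
    finite-window correction k0, the integration window tsim, flags).
    """

    value: float
    stderr: float = 0.0
    method: str = "unknown"
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.value < -1e-9:
            raise ValueError(f"negative rate {self.value!r}")
        if self.stderr < 0:
            raise ValueError("stderr must be nonnegative")


@dataclass
class RateSpectrum:
    """Transfer rate versus donor-acceptor gap."""

    delta_e: np.ndarray
    estimates: list[RateEstimate | None]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.delta_e = np.asarray(self.delta_e, dtype=float)
        if np.any(np.diff(self.delta_e) <= 0):
            raise ValueError("delta_e grid must be strictly increasing")

    @property
    def values(self) -> np.ndarray:
        return np.array(
            [np.nan if e is None else e.value for e in self.estimates], dtype=float
        )

    @property
    def stderrs(self) -> np.ndarray:
        return np.array(
            [np.nan if e is None else e.stderr for e in self.estimates], dtype=float
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "delta_e": self.delta_e,
                "kT": self.values,
                "kT_err": self.stderrs,
                "method": [None if e is None else e.method for e in self.estimates],
            }
        )


@dataclass(frozen=True)
class Peak:
    ell: int
    position: float
    height: float
    width: float


@dataclass
class PeakInventory:
    peaks: list[Peak]

    def __iter__(self):
        return iter(self.peaks)

    def __len__(self):
        return len(self.peaks)

    def max_ell(self) -> int:
        return max((p.ell for p in self.peaks), default=0)


@dataclass
class OptimalTransferResult:
    """kT(Vx/gamma) curve with the refined optimum."""

    vx_over_gamma: np.ndarray
    rates: np.ndarray
    optimum: float | None
    optimum_rate: float | None
    on_boundary: bool
    provenance: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# closed-form / perturbative rates


def fgr_rate(
    model: ModelParams,
    bath: BathParams,
    pop0: np.ndarray,
    n_max: int | None = None,
    *,
    fc_mass_tol: float = 1e-6,
) -> RateEstimate:
    """Golden-rule rate with Lorentzian-broadened vibronic resonances.

    kT = 2 pi Vx^2 sum_{n,m} p_n FC(n, m, g/w)
         * (gamma/2 pi) / [ (dE + (n-m) w)^2 + gamma^2/4 ]

    ``pop0`` is the initial phonon distribution in the donor well; the
    acceptor-level sum is extended until the neglected Franck-Condon
    mass per donor level falls below ``fc_mass_tol``.
    """
    pop0 = np.asarray(pop0, dtype=float)
    if abs(pop0.sum() - 1.0) > 1e-8 or np.any(pop0 < 0):
        raise ValueError("pop0 must be a normalized distribution")
    if model.vx == 0:
        return RateEstimate(0.0, method="fgr", diagnostics={"reason": "vx=0"})
    if bath.gamma <= 0:
        raise ValueError("FGR broadening requires gamma > 0")
    d = model.g / model.omega
    sig = np.nonzero(pop0 > 1e-14)[0]
    if n_max is None:
        n_max = int(sig.max()) + int(math.ceil(4 * d * d + 10))
    gam = bath.gamma
    total = 0.0
    for n in sig:
        fc_row = np.array([franck_condon(n, m, d) for m in range(n_max + 1)])
        while fc_row.sum() < 1.0 - fc_mass_tol:
            n_max = 2 * n_max + 4
            fc_row = np.array([franck_condon(n, m, d) for m in range(n_max + 1)])
        detune = model.delta_e + (n - np.arange(n_max + 1)) * model.omega
        lor = (gam / (2.0 * math.pi)) / (detune**2 + gam**2 / 4.0)
        total += pop0[n] * float(fc_row @ lor)
    kt = 2.0 * math.pi * model.vx**2 * total
    return RateEstimate(kt, method="fgr", diagnostics={"n_max": n_max})


def two_state_rate(
    vx: float, fc: float, nu: int, gamma: float
) -> RateEstimate:
    """Closed-form rate for one donor level and one decaying acceptor level.

    A donor vibronic state coupled with strength vx*sqrt(fc) to a
    single acceptor level that decays at nu*gamma has, with
    x = nu*gamma / (vx*fc),

        kT = nu*gamma * (1 + x^2) / (1 + x^4/2)

    which tends to nu*gamma in the strong-coupling limit x -> 0 (rate
    limited by relaxation) and to 2 (vx*fc)^2/(nu*gamma) in the weak-
    coupling limit (golden-rule-like quadratic dependence on vx).
    """
    if nu < 1 or int(nu) != nu:
        raise ValueError("nu must be a positive integer")
    if vx < 0 or fc < 0 or gamma < 0:
        raise ValueError("arguments must be nonnegative")
    if vx * fc == 0:
        return RateEstimate(
            0.0, method="two_state", diagnostics={"flag": "no transfer channel"}
        )
    x = nu * gamma / (vx * fc)
    kt = nu * gamma * (1.0 + x**2) / (1.0 + 0.5 * x**4)
    return RateEstimate(kt, method="two_state", diagnostics={"x": x})


# ---------------------------------------------------------------------------
# trajectory-based estimators


def _extract_series(traj_or_series) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Accept a Trajectory, a MeasuredSeries-like, or a (times, pd) pair."""
    if isinstance(traj_or_series, Trajectory):
        return traj_or_series.times, traj_or_series.pd, None
    if hasattr(traj_or_series, "means"):
        s = traj_or_series
        sems = np.asarray(s.sems, dtype=float) if s.sems is not None else None
        return np.asarray(s.times, float), np.asarray(s.means, float), sems
    times, pd = traj_or_series
    return np.asarray(times, float), np.asarray(pd, float), None


def exp_fit_rate(traj_or_series) -> RateEstimate:
    """Rate from a least-squares fit of PD(t) = Pinf + (1-Pinf) exp(-kT t).

    The final population is a free parameter because the finite bath
    temperature leaves the transfer incomplete.  Initial guesses: Pinf
    from the tail mean, kT from the log-slope over the first e-fold.
    """
    t, pd, sems = _extract_series(traj_or_series)
    if t.size < 8:
        raise ValueError("need at least 8 samples for an exponential fit")
    if np.ptp(pd) < 1e-10:
        # constant donor population: no transfer, rate identically zero
        return RateEstimate(
            0.0, method="exp_fit",
            diagnostics={"p_inf": float(pd[0]), "rms_residual": 0.0},
        )

    pinf0 = float(np.clip(np.mean(pd[-max(3, t.size // 10):]), 0.0, 1.0))
    drop = pd - pinf0
    pos = np.nonzero(drop > 0.37 * max(drop[0], 1e-12))[0]
    if drop[0] > 1e-6 and pos.size > 1 and t[pos[-1]] > 0:
        k0 = 1.0 / t[pos[-1]]
    else:
        k0 = 1.0 / t[-1]

    def f(tt, k, pinf):
        return pinf + (1.0 - pinf) * np.exp(-k * tt)

    sigma = None
    if sems is not None and np.all(sems > 0):
        sigma = sems
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = curve_fit(
                f,
                t,
                pd,
                p0=[k0, pinf0],
                bounds=([0.0, 0.0], [np.inf, 1.0]),
                sigma=sigma,
                maxfev=20000,
            )
    except RuntimeError as err:
        resid = float(np.sqrt(np.mean((pd - f(t, k0, pinf0)) ** 2)))
        raise RuntimeError(
            f"exponential fit did not converge (guess residual {resid:.3e})"
        ) from err
    k, pinf = popt
    stderr = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else 0.0
    resid = float(np.sqrt(np.mean((pd - f(t, *popt)) ** 2)))
    return RateEstimate(
        max(k, 0.0),
        stderr=stderr,
        method="exp_fit",
        diagnostics={"p_inf": float(pinf), "rms_residual": resid},
    )


def inverse_lifetime_rate(traj_or_series, tsim: float | None = None) -> RateEstimate:
    """Finite-window inverse-lifetime rate with the 2/tsim correction.

    kT = [int_0^tsim PD dt] / [int_0^tsim t PD dt] - k0,  k0 = 2/tsim.

    The correction makes the estimator exactly zero for a frozen donor
    (PD = 1 on the whole window).  Integrals use the composite
    trapezoid rule on the linearly interpolated samples; if ``tsim``
    falls between samples, the endpoint is interpolated.
    """
    t, pd, _ = _extract_series(traj_or_series)
    if t.size < 4:
        raise ValueError("need at least 4 samples")
    if tsim is None:
        tsim = float(t[-1])
    if tsim <= 0:
        raise ValueError("tsim must be positive")
    if tsim > t[-1] + 1e-12:
        raise ValueError("samples do not span [0, tsim]")
    mask = t <= tsim + 1e-12
    tt, yy = t[mask], pd[mask]
    if tt[-1] < tsim - 1e-12:
        y_end = float(np.interp(tsim, t, pd))
        tt = np.append(tt, tsim)
        yy = np.append(yy, y_end)
    i0 = float(np.trapezoid(yy, tt))
    i1 = float(np.trapezoid(tt * yy, tt))
    k0 = 2.0 / tsim
    kt = i0 / i1 - k0
    return RateEstimate(
        max(kt, 0.0),
        method="inverse_lifetime",
        diagnostics={"k0": k0, "tsim": tsim, "int_pd": i0, "int_t_pd": i1, "raw": kt},
    )


def bootstrap_rate(
    series,
    n_resamples: int = 200,
    seed: int | None = None,
    tsim: float | None = None,
) -> RateEstimate:
    """Bootstrap standard error of the inverse-lifetime rate.

    Each time point of the measured series is resampled from a normal
    law centred at its mean with the SEM as standard deviation, clipped
    to [0, 1]; the rate is recomputed per resample and the standard
    deviation over resamples is reported as the error.
    """
    if seed is None:
        raise ValueError("a seed is mandatory for bootstrap resampling")
    t = np.asarray(series.times, dtype=float)
    means = np.asarray(series.means, dtype=float)
    sems = np.asarray(series.sems, dtype=float)
    base = inverse_lifetime_rate((t, means), tsim=tsim)
    if np.all(sems == 0):
        return replace(
            base,
            stderr=0.0,
            diagnostics={**base.diagnostics, "flag": "all SEMs zero"},
        )
    rng = np.random.default_rng(seed)
    draws = np.empty(n_resamples)
    for i in range(n_resamples):
        resampled = np.clip(rng.normal(means, sems), 0.0, 1.0)
        est = inverse_lifetime_rate((t, resampled), tsim=tsim)
        draws[i] = est.diagnostics["raw"]
    return replace(
        base,
        stderr=float(np.std(draws, ddof=1)),
        diagnostics={**base.diagnostics, "n_resamples": n_resamples},
    )


# ---------------------------------------------------------------------------
# sweep drivers


def default_tsim(bath: BathParams, factor: float = 10.0, floor_periods: float = 50.0) -> float:
    """Simulation window: max(factor/gamma, floor_periods vibrational periods)."""
    floor = floor_periods * 2.0 * math.pi
    if bath.gamma <= 0:
        return floor
    return max(factor / bath.gamma, floor)


def simulate_trajectory(
    model: ModelParams,
    bath: BathParams,
    noise: NoiseParams | None = None,
    init: InitialStateParams | None = None,
    *,
    tsim: float | None = None,
    n_samples: int = 400,
    trunc: TruncationConfig | None = None,
    delta_e_max: float | None = None,
    max_doublings: int = 3,
) -> Trajectory:
    """Prepare the donor state and evolve it, auto-enlarging the cutoff.

    On a truncation-tail breach the Fock cutoff is doubled (up to
    ``max_doublings`` times) and the run repeated.
    """
    init = init or InitialStateParams()
    if trunc is None:
        trunc = TruncationConfig(
            default_n_fock(model, max(bath.nbar, init.nbar0), delta_e_max)
        )
    if tsim is None:
        tsim = default_tsim(bath)
    times = np.linspace(0.0, tsim, n_samples)
    last_err: TruncationError | None = None
    for _ in range(max_doublings + 1):
        try:
            state = prepare_initial_state(model, init, trunc)
            ops = build_operators(model, bath, noise, trunc)
            return evolve(state, ops, times, tail_tol=trunc.tail_tol)
        except TruncationError as err:
            last_err = err
            trunc = TruncationConfig(2 * trunc.n_fock, trunc.tail_tol)
    raise TruncationError(
        f"truncation still breached at n_fock={trunc.n_fock}: {last_err}"
    )


def scan_delta_e(
    model_template: ModelParams,
    bath: BathParams,
    noise: NoiseParams | None,
    delta_e_grid: np.ndarray,
    estimator: str = "fgr",
    *,
    init: InitialStateParams | None = None,
    tsim: float | None = None,
    n_samples: int = 400,
) -> RateSpectrum:
    """Transfer-rate spectrum kT(dE) with the chosen estimator.

    ``estimator='fgr'`` evaluates the broadened golden-rule sum with a
    thermal donor distribution at ``init.nbar0`` (fast, perturbative);
    ``'lifetime'`` and ``'exp'`` run the full master equation per grid
    point and extract the rate from the donor-population trajectory.
    Per-point failures are retained as ``None`` entries.
    """
    delta_e_grid = np.asarray(delta_e_grid, dtype=float)
    init = init or InitialStateParams()
    estimates: list[RateEstimate | None] = []
    errors: dict[float, str] = {}
    de_max = float(np.max(np.abs(delta_e_grid)))
    for de in delta_e_grid:
        model = replace(model_template, delta_e=float(de))
        try:
            if estimator == "fgr":
                n_fock = default_n_fock(model, init.nbar0)
                pop0 = thermal_fock_populations(init.nbar0, n_fock)
                est = fgr_rate(model, bath, pop0 / pop0.sum())
            elif estimator in ("lifetime", "exp"):
                traj = simulate_trajectory(
                    model, bath, noise, init,
                    tsim=tsim, n_samples=n_samples, delta_e_max=de_max,
                )
                est = (
                    inverse_lifetime_rate(traj)
                    if estimator == "lifetime"
                    else exp_fit_rate(traj)
                )
            else:
                raise ValueError(f"unknown estimator {estimator!r}")
            estimates.append(est)
        except (RuntimeError, ValueError) as err:  # keep partial results
            estimates.append(None)
            errors[float(de)] = str(err)
    return RateSpectrum(
        delta_e_grid,
        estimates,
        provenance={
            "estimator": estimator,
            "model": model_template,
            "bath": bath,
            "noise": noise,
            "init": init,
            "errors": errors,
        },
    )


def find_peaks(
    spectrum: RateSpectrum,
    threshold_fraction: float = 0.02,
    match_tol: float = 0.15,
    *,
    expected_width: float | None = None,
) -> PeakInventory:
    """Locate vibronic resonances and label them with integer indices.

    Local maxima above ``threshold_fraction`` of the global maximum are
    assigned to the nearest integer gap dE = l*w within ``match_tol``;
    unassignable maxima are dropped.  Heights are absolute, widths are
    full widths at half maximum in gap units.  If ``expected_width``
    (e.g. gamma) is given and the grid step exceeds half of it, a
    coarse-grid warning is emitted.
    """
    de = spectrum.delta_e
    kt = spectrum.values
    finite = np.isfinite(kt)
    if expected_width is not None and np.max(np.diff(de)) > 0.5 * expected_width:
        warnings.warn(
            "grid step exceeds half the expected resonance width; peaks may be missed",
            stacklevel=2,
        )
    if not np.any(finite) or np.nanmax(kt) <= 0:
        return PeakInventory([])
    y = np.where(finite, kt, 0.0)
    height = threshold_fraction * float(np.nanmax(kt))
    idx, _ = scipy.signal.find_peaks(y, height=height)
    widths, _, lips, rips = scipy.signal.peak_widths(y, idx, rel_height=0.5)
    step = float(np.mean(np.diff(de)))
    peaks = []
    for j, i in enumerate(idx):
        # parabolic sub-grid refinement of the maximum position
        if 0 < i < de.size - 1:
            denom = y[i - 1] - 2 * y[i] + y[i + 1]
            shift = 0.5 * (y[i - 1] - y[i + 1]) / denom if denom != 0 else 0.0
            pos = de[i] + shift * step
        else:
            pos = de[i]
        ell = int(round(pos))
        if ell < 1 or abs(pos - ell) > match_tol:
            continue
        peaks.append(Peak(ell=ell, position=float(pos), height=float(y[i]),
                          width=float(widths[j] * step)))
    return PeakInventory(peaks)


def find_optimal_vx(
    model_template: ModelParams,
    bath: BathParams,
    noise: NoiseParams | None,
    vx_over_gamma_grid: np.ndarray,
    *,
    init: InitialStateParams | None = None,
    tsim: float | None = None,
    n_samples: int = 400,
) -> OptimalTransferResult:
    """kT(Vx/gamma) curve and its parabolically refined maximum.

    Each grid point runs the full master equation from the donor state
    and extracts the rate with the inverse-lifetime estimator.  When
    the grid maximum sits on the boundary the optimum is flagged and
    not refined.
    """
    grid = np.asarray(vx_over_gamma_grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("vx_over_gamma grid must be strictly increasing")
    init = init or InitialStateParams()
    if tsim is None:
        tsim = default_tsim(bath)
    rates = np.empty(grid.size)
    for i, r in enumerate(grid):
        model = replace(model_template, vx=float(r) * bath.gamma)
        traj = simulate_trajectory(
            model, bath, noise, init, tsim=tsim, n_samples=n_samples
        )
        rates[i] = inverse_lifetime_rate(traj).value
    imax = int(np.argmax(rates))
    prov = {"tsim": tsim, "model": model_template, "bath": bath, "noise": noise}
    if imax == 0 or imax == grid.size - 1:
        return OptimalTransferResult(
            grid, rates, optimum=float(grid[imax]), optimum_rate=float(rates[imax]),
            on_boundary=True, provenance=prov,
        )
    x0, x1, x2 = grid[imax - 1 : imax + 2]
    y0, y1, y2 = rates[imax - 1 : imax + 2]
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    b = (x2**2 * (y0 - y1) + x1**2 * (y2 - y0) + x0**2 * (y1 - y2)) / denom
    xopt = float(-b / (2 * a)) if a < 0 else float(x1)
    kopt = float(y1 if a >= 0 else y1 - a * (x1 - xopt) ** 2 + 0.0)
    # evaluate the parabola at its vertex for the refined height
    if a < 0:
        c = y1 - a * x1**2 - b * x1
        kopt = float(a * xopt**2 + b * xopt + c)
    return OptimalTransferResult(
        grid, rates, optimum=xopt, optimum_rate=kopt, on_boundary=False,
        provenance=prov,
    )
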