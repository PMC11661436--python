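# Methods

## Model and conventions

`etsim` simulates a single electronic two-level system (donor `|D⟩`,
acceptor `|A⟩`) coupled to one harmonic reaction coordinate, evolving
under a Markovian (Lindblad) master equation.  Everything is
dimensionless: ħ = 1 and the mode quantum ω = 1, so all energies and
rates are "in units of ω" and times in units of 1/ω.

Fixed conventions (chosen once so that signs are testable):

* basis ordering is spin-major, `|↑,0⟩ … |↑,N−1⟩, |↓,0⟩ … |↓,N−1⟩`;
* `|D⟩ = |↑⟩`, the +1 eigenstate of σz; with the coupling term
  (g/2)σz(a+a†) this puts the donor well at quadrature −g/2ω and the
  acceptor well at +g/2ω, and a positive gap ΔE > 0 makes transfer
  D → A exothermic;
* Vx ≥ 0: the sign of the σx coupling is unobservable (it can be
  absorbed by a spin rotation), so the API rejects negative values
  rather than silently carrying a convention.

The bath enters as cooling/heating channels `(a, γ(n̄+1))` and
`(a†, γn̄)`.  This Lindblad description stands in for an ohmic
environment and is valid for weak damping (γ ≪ ω) and γβ ≪ 1;
`BathParams.validity_flags` reports violations but construction never
fails, since exploring the breakdown is itself informative.  Two
technical-noise channels are available: spin dephasing as jump operator
σz with rate γz/2 (so that spin coherences decay at γz) and motional
dephasing as a†a with rate γm.  The microscopic form of these two
channels is a modeling choice — only their rates are physically
specified — so `build_dissipators` accepts injected alternatives
without touching the solver.

## Parameters that matter

| parameter | meaning | typical default |
|---|---|---|
| ΔE | donor-acceptor gap [ω] | swept, 0.5–4.6 |
| Vx | electronic coupling [ω] | 0.05–0.4 per regime |
| g  | vibronic coupling [ω] | 0.5–1.4 per regime |
| γ  | mode relaxation rate [ω] | 0.014–0.11 per regime |
| n̄  | bath occupation | 0–0.2 |
| n̄0 | initial thermal occupation | 0.15–0.2 |
| γz, γm | technical dephasing [ω] | 0.0005–0.0025 |
| N | Fock cutoff | adaptive, see below |
| tsim | analysis window [1/ω] | max(10/γ, 50 periods) |

The named presets encode the parameter sets of the characteristic
regimes (nonadiabatic with strong/weak vibronic coupling, adiabatic
with slow/fast relaxation, optimal-transfer sweep, crossover
dynamics).  Where a preset's bath occupation is not pinned by the
regime definition itself, a representative sideband-cooled value in
the 0.1–0.3 range was fixed once (n̄ = n̄0 = 0.2 for the adiabatic and
optimal-transfer presets; n̄ = 0 with n̄0 = 0.15 for the nonadiabatic
spectra, whose resonance structure is insensitive to the residual
thermal population).

## Numerics

**Truncation.**  The Fock cutoff defaults to
N = ⌈4(g/2ω)² + 6n̄ + ΔE/ω + 15⌉, generous for every shipped regime.
Trajectories track the population of the top two Fock levels at every
sample; if it reaches `tail_tol` (default 1e-6) the run aborts naming
the breach time, and the sweep drivers retry with a doubled cutoff.
Doubling N changes PD(t) by < 1e-4 sup-norm on the shipped presets.

**Integration.**  The density matrix is vectorized and propagated with
an adaptive 8th-order explicit Runge-Kutta scheme (rtol 1e-8,
atol 1e-10), evaluated through the non-Hermitian effective Hamiltonian
plus jump terms (dense algebra: the problem sizes are 2N ≲ 100, where
dense matrix products beat sparse machinery).  Integration proceeds
sample-to-sample; at each sample the numerically accumulated
anti-Hermitian residue (pure integrator round-off, since the exact flow
preserves Hermiticity) is checked against 1e-7 and projected out, which
prevents drift over long windows.  The solver was validated against
direct matrix exponentials of the Liouvillian to ~1e-9 in PD.

**Steady states.**  The stationary state is obtained by replacing one
row of the (singular) sparse Liouvillian with the trace constraint and
solving the linear system; uniqueness is verified via the two
smallest-magnitude Liouvillian eigenvalues (shift-invert Arnoldi).
Whenever Vx = 0, σz is conserved, the null space is two-dimensional
and `steady_state` raises instead of silently picking a mixture — the
thermal fixed point of the bare mode is therefore asserted through
long-time evolution rather than through the null-space solver.

**Franck-Condon factors** use the associated-Laguerre closed form with
log-gamma prefactors; they are exact for the symmetries FC(n,m,d) =
FC(m,n,d) = FC(n,m,−d), sum to one over either index, and match the
matrix-exponential displacement operator to 1e-12.

**Golden-rule spectra** replace the energy delta functions by
normalized Lorentzians of FWHM γ; the acceptor-level sum is extended
until the neglected Franck-Condon mass per donor level is below 1e-6.

## Rate extraction

Two estimators act on donor-population trajectories or measured series:

* **Exponential fit** PD(t) = P∞ + (1−P∞)e^{−kT t} (free final
  population, because finite bath temperature leaves transfer
  incomplete).  Initial guesses: P∞ from the tail mean, kT from the
  first e-fold; bounds P∞ ∈ [0,1], kT ≥ 0.  Appropriate for the
  monotone decays of the nonadiabatic regime.
* **Finite-window inverse lifetime** kT = ∫₀^tsim PD dt / ∫₀^tsim t·PD dt
  − k0 with k0 = 2/tsim, integrals by composite trapezoid on the
  linearly interpolated samples.  The correction is fixed by the
  requirement that a frozen donor (PD ≡ 1, the Vx = 0 case) yields
  exactly zero for every window.  Note the estimator is intentionally
  window-anchored: on a pure exponential with k·tsim = 20 it reads
  0.9k, and when PD settles on a plateau the value decreases with
  growing tsim as the plateau dilutes the integrals.  Sweeps therefore
  fix tsim (default 10/γ) as part of the study conditions.
* **Bootstrap errors** for measured series: each time point is redrawn
  from a normal law centred at its mean with the SEM as width, clipped
  to [0,1] (unclipped values would be unphysical probabilities), the
  rate recomputed per resample (default 200, seed mandatory), and the
  spread reported.

The two-vibronic-state closed form kT = νγ(1+x²)/(1+x⁴/2) with
x = νγ/(Vx·FC) is provided for intuition in the strongly adiabatic
regime; its relaxation-limited limit kT → νγ is exact, but its
absolute prefactor in the weak-coupling branch is approximate (tests
log, and do not assert, the prefactor against a three-level
donor/acceptor/sink oracle).

**Peak detection** on rate spectra marks local maxima above 2% of the
spectrum maximum (a proxy for an experimental resolution floor),
refines positions sub-grid by a local parabola, and assigns each to the
nearest integer gap within 0.15 ω.  **Optimal-coupling sweeps** locate
the grid maximum of kT(Vx/γ) and refine it with a three-point parabola
unless the maximum sits on the grid boundary, which is flagged instead.

## Measurement emulation

The synthetic-experiment layer emulates what a trapped-ion realization
of this model would actually record.  Donor populations are sampled per
time point as Binomial(shots, PD)/shots with the plug-in SEM
√(p̂(1−p̂)/shots); the default of 300 shots per point gives SEMs of a
few percent, typical of fluorescence-readout experiments.  Detection
infidelity (~0.5% in such setups) is far below every effect tested here
and is deliberately not modeled.  The blue-sideband phonon readout
forward-evaluates P↑(t) = ½Σₙ p(n)[1 − e^{−αm t}cos(√(n+1) ηΩ t)] and
inverts it by nonnegative least squares over {p(n)} with normalization
enforced as a weighted design row; the shared decoherence rate αm can
be held fixed or optimized by a bounded scalar search.  The emulation
covers shot noise and readout decoherence only — slow drifts,
calibration errors and state-preparation imperfections of real
hardware are out of scope, so passing end-to-end recovery tests bounds
statistical, not systematic, errors of real data.

The spin-dependent displacement α(t) = (g/4δ)(1 − e^{−iδt}) documents
how the donor-well preparation arises physically: a half-period pulse
(t = π/δ at δ = −ω) lands the packet at −g/2ω, exactly the
displacement `prepare_initial_state` applies.

## Problem sizes and runtime

All shipped analyses are desk scale: Fock cutoffs N ≈ 16–32
(Hilbert-space dimension ≲ 64), trajectory windows 10–20/γ with
300–600 samples, 16-point coupling sweeps and ~200-point gap grids.
The full test suite runs in ~2 minutes and the headline-results script
in under a minute on a single CPU.

## Known limitations

* Single mode, Markovian bath: no structured spectral densities,
  multi-mode baths or non-Markovian memory.
* Time-independent Hamiltonian only; no drive engineering, quantum
  trajectories or unravelings.
* The inverse-lifetime estimator is only meaningful together with its
  window; cross-study comparisons must match tsim.
* The two-state closed form is heuristic away from its
  relaxation-limited limit.
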