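"""Named parameter sets covering the characteristic transfer regimes.

Each preset bundles Hamiltonian, bath, technical-noise and
initial-state parameters (all in units of the mode quantum omega) for
one physical regime:

* ``crossover-dynamics`` — moderate electronic coupling at resonance,
  showing transient donor-acceptor oscillations before equilibration;
* ``nonadiabatic-a``/``nonadiabatic-b`` — perturbative electronic
  coupling (Vx << lambda/4, Vx <~ gamma), where the rate spectrum shows
  isolated vibronic resonances at integer gaps; ``-a`` has strong
  vibronic coupling (many resonances), ``-b`` weak (few, sharper);
* ``adiabatic-a``/``adiabatic-b`` — electronic coupling comparable to
  the barrier and larger than the relaxation rate, where kT scales
  with gamma; the two differ mainly in gamma, for the scaling collapse;
* ``optimal-transfer`` — resonant gap dE = 2 omega, used to sweep
  Vx/gamma through the optimal-transfer maximum.

For presets whose bath occupation is not pinned by the regime itself a
representative sideband-cooled value (nbar, nbar0 in the 0.1-0.3
range) is chosen; see the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .dynamics import InitialStateParams
from .model import BathParams, ModelParams, NoiseParams

__all__ = ["Preset", "PRESETS", "get_preset", "list_presets"]


@dataclass(frozen=True)
class Preset:
    name: str
    model: ModelParams
    bath: BathParams
    noise: NoiseParams
    init: InitialStateParams
    provenance: str
    scan: dict = field(default_factory=dict)


PRESETS: dict[str, Preset] = {
    p.name: p
    for p in [
        Preset(
            name="crossover-dynamics",
            model=ModelParams(delta_e=1.0, vx=0.18, g=1.0),
            bath=BathParams(gamma=0.014, nbar=0.2),
            noise=NoiseParams(gamma_z=0.0013, gamma_m=0.0013),
            init=InitialStateParams(nbar0=0.2),
            provenance=(
                "resonant transfer with transient coherent oscillations: "
                "(dE, Vx, g) = (1, 0.18, 1) w, gamma = 0.014 w, "
                "gamma_z = gamma_m = 0.0013 w"
            ),
        ),
        Preset(
            name="nonadiabatic-a",
            model=ModelParams(delta_e=1.0, vx=0.056, g=1.4),
            bath=BathParams(gamma=0.06, nbar=0.0),
            noise=NoiseParams(gamma_z=0.0, gamma_m=0.001),
            init=InitialStateParams(nbar0=0.15),
            provenance=(
                "nonadiabatic spectrum, strong vibronic coupling: "
                "(Vx, g, gamma) = (0.056, 1.4, 0.06) w, gamma_m = 0.001 w, "
                "thermal donor distribution nbar0 = 0.15"
            ),
            scan={"delta_e": (0.5, 4.6, 0.02)},
        ),
        Preset(
            name="nonadiabatic-b",
            model=ModelParams(delta_e=1.0, vx=0.046, g=0.521),
            bath=BathParams(gamma=0.025, nbar=0.0),
            noise=NoiseParams(gamma_z=0.0, gamma_m=0.0005),
            init=InitialStateParams(nbar0=0.15),
            provenance=(
                "nonadiabatic spectrum, weak vibronic coupling: "
                "(Vx, g, gamma) = (0.046, 0.521, 0.025) w, gamma_m = 0.0005 w"
            ),
            scan={"delta_e": (0.5, 4.6, 0.02)},
        ),
        Preset(
            name="adiabatic-a",
            model=ModelParams(delta_e=1.0, vx=0.18, g=0.95),
            bath=BathParams(gamma=0.020, nbar=0.2),
            noise=NoiseParams(gamma_z=0.0025, gamma_m=0.0013),
            init=InitialStateParams(nbar0=0.2),
            provenance=(
                "adiabatic regime, slow relaxation: "
                "(Vx, g, gamma) = (0.18, 0.95, 0.020) w, "
                "gamma_z = 0.0025 w, gamma_m = 0.0013 w"
            ),
            scan={"delta_e": (0.5, 3.0, 0.1)},
        ),
        Preset(
            name="adiabatic-b",
            model=ModelParams(delta_e=1.0, vx=0.21, g=1.08),
            bath=BathParams(gamma=0.038, nbar=0.2),
            noise=NoiseParams(gamma_z=0.0025, gamma_m=0.0013),
            init=InitialStateParams(nbar0=0.2),
            provenance=(
                "adiabatic regime, faster relaxation: "
                "(Vx, g, gamma) = (0.21, 1.08, 0.038) w, "
                "gamma_z = 0.0025 w, gamma_m = 0.0013 w"
            ),
            scan={"delta_e": (0.5, 3.0, 0.1)},
        ),
        Preset(
            name="optimal-transfer",
            model=ModelParams(delta_e=2.0, vx=3.3 * 0.11, g=0.80),
            bath=BathParams(gamma=0.11, nbar=0.2),
            noise=NoiseParams(gamma_z=0.0013, gamma_m=0.0013),
            init=InitialStateParams(nbar0=0.2),
            provenance=(
                "optimal-transfer sweep at the dE = 2 w resonance: "
                "(dE, g, gamma) = (2, 0.80, 0.11) w, "
                "gamma_z = gamma_m = 0.0013 w; Vx swept over Vx/gamma in [0.5, 10]"
            ),
            scan={"vx_over_gamma": (0.5, 10.0, 0.5)},
        ),
    ]
}


def get_preset(name: str) -> Preset:
    try:
        return PRESETS[name]
    except KeyError:
        known = ", ".join(sorted(PRESETS))
        raise KeyError(f"unknown preset {name!r}; known presets: {known}") from None


def list_presets() -> list[Preset]:
    return list(PRESETS.values())
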