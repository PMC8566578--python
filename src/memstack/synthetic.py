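"""Synthetic data generation: the stand-in for beamline and trough.

Produces every input the analysis chain consumes — noisy multi-contrast
reflectivity curves from slab models, compression isotherms with a
tunable condensation effect, and random lattice configurations come from
:mod:`memstack.lattice` directly — so the whole pipeline is exercisable
without experimental data.

The canonical fixtures encode the two supported-membrane systems this
package was built around:

* ``ternary`` — PLPC/sitosterol/glucosylceramide 60/20/20 on silicon:
  ~10 Å native oxide, 4 Å interstitial water, 10 Å head slabs, two 15 Å
  chain slabs with *asymmetric* SLD (−0.28 inner vs −0.41 outer,
  ×10⁻⁶ Å⁻²: all the sterol sits in the substrate-proximal leaflet) and
  a modest extra hydration of the inner leaflet, interlayer roughness
  2.5 Å, near-complete coverage.
* ``binary`` — PLPC/sitosterol 80/20: fully symmetric leaflets (both
  chain slabs at the sterol-loaded −0.28), a 6 Å water layer, roughness
  3.5 Å, 97% coverage.

Measured in H₂O, D₂O and a 4×10⁻⁶ Å⁻² match water on a two-wavelength
time-of-flight reflectometer reaching q = 0.25 Å⁻¹ at 10% ΔQ/Q.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io import ContrastSet
from .membrane_model import SlabStack, build_stack
from .monolayer import Isotherm, additivity_area
from .reflectivity import Instrument, ReflectivityCurve, reflectivity
from .sld_core import MATERIALS, Material

__all__ = [
    "NoiseModel",
    "synth_reflectivity",
    "canonical_fixtures",
    "Fixture",
    "default_q_grid",
    "synth_isotherm",
]

#: Default solvent set for a three-contrast experiment.
DEFAULT_SOLVENTS = ("h2o", "d2o", "4mw")


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative Gaussian noise with a counting-statistics term.

    σ_rel = max(floor, counting_scale/√(R·I₀-equivalent)); by default the
    counting term is off and a flat 3% relative error applies, matching
    the quality of a well-measured solid/liquid cell curve.
    """

    floor: float = 0.03
    counting_scale: float = 0.0
    seed: int = 0

    def relative_sigma(self, r: np.ndarray) -> np.ndarray:
        rel = np.full_like(r, self.floor, dtype=float)
        if self.counting_scale > 0:
            rel = np.maximum(
                rel, self.counting_scale / np.sqrt(np.clip(r, 1e-12, None))
            )
        return rel


def default_q_grid(
    q_min: float = 0.005, q_max: float = 0.25, n: int = 120
) -> np.ndarray:
    """Logarithmic q grid emulating two-wavelength time-of-flight binning."""
    return np.geomspace(q_min, q_max, n)


def synth_reflectivity(
    stack: SlabStack,
    solvents: Sequence[Material | str] = DEFAULT_SOLVENTS,
    instrument: Instrument | None = None,
    noise: NoiseModel | None = None,
    q: np.ndarray | None = None,
    name: str = "",
) -> ContrastSet:
    """Noisy smeared reflectivity of one structure in several contrasts.

    The dR column carries the generating σ, so a subsequent fit with the
    true model has E[χ²/N] = 1.  ``noise.floor = 0`` returns the exact
    smeared engine output.  Reproducible for a given ``noise.seed``.
    """
    instrument = instrument or Instrument()
    noise = noise or NoiseModel()
    if q is None:
        q = default_q_grid(q_max=instrument.q_max)
    rng = np.random.default_rng(noise.seed)
    curves, sols = [], []
    for solv in solvents:
        solvent = MATERIALS[solv] if isinstance(solv, str) else solv
        r = reflectivity(stack, solvent, q, resolution=instrument.resolution)
        sigma = noise.relative_sigma(r) * r
        r_noisy = r + sigma * rng.standard_normal(len(q))
        r_noisy = np.clip(r_noisy, 1e-12, None)
        curves.append(
            ReflectivityCurve(q, r_noisy, dr=np.maximum(sigma, 1e-12))
        )
        sols.append(solvent)
    return ContrastSet(tuple(curves), tuple(sols), name=name)


@dataclass(frozen=True)
class Fixture:
    """A named generating structure plus its reference values."""

    name: str
    params: Mapping[str, float]
    stack: SlabStack
    reference: Mapping[str, float]
    notes: Mapping[str, str]


def canonical_fixtures() -> dict[str, Fixture]:
    """The two reference membranes used throughout tests and demos."""
    ternary_params = {
        "oxide_thickness": 10.0,
        "water_thickness": 4.0,
        "head_thickness": 10.0,
        "chain_thickness_inner": 15.0,
        "chain_thickness_outer": 15.0,
        "chain_sld_inner": -0.28,  # sterol-loaded inner leaflet
        "chain_sld_outer": -0.41,  # bare-chain outer leaflet
        "chain_solvent_fraction_inner": 0.10,
        "chain_solvent_fraction_outer": 0.02,
        "head_solvent_fraction": 0.25,
        "coverage": 0.99,
        "roughness": 2.5,
    }
    binary_params = {
        "oxide_thickness": 10.0,
        "water_thickness": 6.0,
        "head_thickness": 10.0,
        "chain_thickness_inner": 15.0,
        "chain_thickness_outer": 15.0,
        "chain_sld_inner": -0.28,  # sterol shared evenly by both leaflets
        "chain_sld_outer": -0.28,
        "chain_solvent_fraction_inner": 0.02,
        "chain_solvent_fraction_outer": 0.02,
        "head_solvent_fraction": 0.25,
        "coverage": 0.97,
        "roughness": 3.5,
    }
    fixtures = {
        "ternary": Fixture(
            name="ternary",
            params=ternary_params,
            stack=build_stack(ternary_params),
            reference={
                "d_max": 65.0,
                "water_thickness": 4.0,
                "chain_sld_inner": -0.28,
                "chain_sld_outer": -0.41,
                "inner_sterol_fraction": 0.191,
                "roughness_max": 3.0,
            },
            notes={
                "d_max": "overall interfacial extent incl. native oxide",
                "water_thickness": "membrane-substrate interstitial water",
                "chain_sld_inner": "sterol-enriched substrate-proximal leaflet",
                "chain_sld_outer": "bare acyl chains, solvent-facing leaflet",
                "inner_sterol_fraction": "volume fraction from SLD inversion",
                "roughness_max": "upper end of the fitted interlayer roughness",
            },
        ),
        "binary": Fixture(
            name="binary",
            params=binary_params,
            stack=build_stack(binary_params),
            reference={
                "d_max": 65.0,
                "water_thickness": 6.0,
                "coverage": 0.97,
                "roughness_range": 3.5,
            },
            notes={
                "coverage": "fraction of the substrate carrying membrane",
                "water_thickness": "membrane-substrate interstitial water",
                "roughness_range": "interlayer roughness, middle of 3-4 Å",
            },
        ),
    }
    return fixtures


def synth_isotherm(
    pure_areas: Mapping[str, float],
    fractions: Mapping[str, float],
    delta: float = 0.0,
    noise: float = 0.05,
    seed: int = 0,
    n_replicates: int = 2,
    reference_pressure: float = 30.0,
    lift_off_factor: float = 1.6,
    max_pressure: float = 45.0,
) -> dict:
    """Smooth synthetic Π–A curves for pure components and their mixture.

    ``pure_areas`` gives each component's area at ``reference_pressure``;
    the mixture's noiseless area there equals the additivity prediction
    minus ``delta`` (Å²/molecule), so ``delta`` *is* the condensation
    effect.  Replicate curves get a multiplicative area scatter with
    coefficient of variation ``noise`` (replicate-to-replicate, the
    scale typical of independent monolayer spreadings).

    The functional form Π(A) = c·(exp((A₀−A)/w) − 1) is a convenient
    monotone compression curve; c = 5 mN/m and the lift-off area
    A₀ = ``lift_off_factor``·A(Π_ref) set a realistic steepness, and w
    is solved so the curve passes through the requested area exactly.

    Returns ``{"pure": {name: Isotherm}, "mixture": [replicates],
    "theoretical_area": float, "target_area": float}``.
    """
    if delta < 0:
        raise ValueError("condensation delta must be >= 0")
    rng = np.random.default_rng(seed)
    c = 5.0

    def curve(a_ref: float, scale: float, composition, label) -> Isotherm:
        a0 = lift_off_factor * a_ref
        w = (a0 - a_ref) / np.log(1.0 + reference_pressure / c)
        a_min = a0 - w * np.log(1.0 + max_pressure / c)
        area = np.linspace(a0 * 1.05, a_min, 160)
        pi = np.where(area < a0, c * (np.exp((a0 - area) / w) - 1.0), 0.0)
        return Isotherm(area * scale, pi, composition, label=label)

    names = list(fractions)
    pure = {
        n: curve(pure_areas[n], 1.0, {n: 1.0}, label=n) for n in names
    }
    a_theo = additivity_area(
        [pure_areas[n] for n in names], [fractions[n] for n in names]
    )
    a_mix = a_theo - delta
    mixture = []
    for k in range(n_replicates):
        scale = 1.0 + noise * rng.standard_normal()
        mixture.append(
            curve(a_mix, scale, dict(fractions), label=f"mixture_rep{k + 1}")
        )
    return {
        "pure": pure,
        "mixture": mixture,
        "theoretical_area": a_theo,
        "target_area": a_mix,
    }
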