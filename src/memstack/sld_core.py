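"""Scattering-length-density (SLD) arithmetic.

All SLDs in this package are carried in units of 10⁻⁶ Å⁻² (the scale on
which reflectometry results are conventionally printed); conversion to
absolute Å⁻² happens only inside the reflectivity engine.  Only real,
coherent SLDs are modelled: incoherent scattering and absorption are
negligible for the cold-neutron experiments this package targets.

The central inverse problem handled here is linear volume-fraction mixing
and its inversion: a measured layer SLD that lies between the SLDs of two
candidate components determines the volume fraction of each, which is how
per-leaflet sterol content — and hence membrane compositional asymmetry —
is quantified.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "Material",
    "SolventMixture",
    "MATERIALS",
    "InvalidCompositionError",
    "UnreachableContrastError",
    "IllConditionedInversionError",
    "CompositionEstimate",
    "mix_sld",
    "solvent_match",
    "infer_binary_composition",
    "load_materials",
]

_FRACTION_SUM_TOL = 1e-9

#: Default SLD gap (10⁻⁶ Å⁻²) below which a two-component inversion is
#: considered ill-conditioned.  A 0.68 gap (sterol vs. bare chains) is
#: comfortably quantifiable; the 0.27 gap between glucosylceramide and
#: phosphocholine head groups is not.
DEFAULT_EPSILON = 0.5


class InvalidCompositionError(ValueError):
    """Volume fractions are negative or do not sum to one."""


class UnreachableContrastError(ValueError):
    """Requested solvent SLD lies outside the two-solvent mixing range."""


class IllConditionedInversionError(ValueError):
    """Component SLDs are too close for a meaningful composition inversion."""


@dataclass(frozen=True)
class Material:
    """A homogeneous scattering medium.

    Parameters
    ----------
    name : str
        Non-empty identifier.
    sld : float
        Real coherent scattering length density, 10⁻⁶ Å⁻².
    """

    name: str
    sld: float

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("material name must be non-empty")
        if not math.isfinite(self.sld):
            raise ValueError(f"material {self.name!r}: SLD must be finite")


@dataclass(frozen=True)
class SolventMixture:
    """A two-solvent mixture (typically H₂O/D₂O) with a derived SLD."""

    component_a: Material
    component_b: Material
    fraction_b: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_b <= 1.0:
            raise InvalidCompositionError(
                f"fraction_b must be in [0, 1], got {self.fraction_b}"
            )

    @property
    def sld(self) -> float:
        return mix_sld(
            [
                (self.component_a.sld, 1.0 - self.fraction_b),
                (self.component_b.sld, self.fraction_b),
            ]
        )

    def as_material(self, name: str | None = None) -> Material:
        if name is None:
            name = (
                f"{self.component_a.name}/{self.component_b.name}"
                f"({self.fraction_b:.3f})"
            )
        return Material(name, self.sld)


# Component registry.  Substrate/solvent entries are standard coherent-
# scattering-length values; the membrane components are the values used
# throughout the leaflet-composition analysis.
MATERIALS: dict[str, Material] = {
    m.name: m
    for m in [
        Material("silicon", 2.07),
        Material("silicon_oxide", 3.47),
        Material("h2o", -0.56),
        Material("d2o", 6.36),
        Material("4mw", 4.00),  # H2O/D2O mix matched to 4e-6 Å⁻²
        Material("sitosterol", 0.27),
        Material("lipid_chains", -0.41),  # bare (sterol-free) acyl chains
        Material("plpc_heads", 1.93),
        Material("glucer_heads", 2.2),
    ]
}


def mix_sld(components: Iterable[tuple[float, float]]) -> float:
    """Volume-weighted mean SLD of a mixture.

    Parameters
    ----------
    components : iterable of (sld, volume_fraction)
        Fractions must be non-negative and sum to 1 within 1e-9.

    Returns
    -------
    float
        Mixture SLD, 10⁻⁶ Å⁻².
    """
    comps = list(components)
    if not comps:
        raise InvalidCompositionError("empty component list")
    fracs = [f for _, f in comps]
    if any(f < 0 for f in fracs):
        raise InvalidCompositionError(f"negative volume fraction in {fracs}")
    total = sum(fracs)
    if abs(total - 1.0) > _FRACTION_SUM_TOL:
        raise InvalidCompositionError(
            f"volume fractions sum to {total!r}, expected 1"
        )
    return sum(s * f for s, f in comps)


def solvent_match(
    target_sld: float, solvent_a: Material, solvent_b: Material
) -> float:
    """Fraction of ``solvent_b`` needed to hit ``target_sld``.

    The classical contrast-matching calculation: e.g. a 4×10⁻⁶ Å⁻² match
    water requires ~66% D₂O in H₂O.
    """
    lo, hi = sorted((solvent_a.sld, solvent_b.sld))
    if not lo <= target_sld <= hi:
        raise UnreachableContrastError(
            f"target {target_sld} outside solvent range [{lo}, {hi}]"
        )
    return (target_sld - solvent_a.sld) / (solvent_b.sld - solvent_a.sld)


@dataclass(frozen=True)
class CompositionEstimate:
    """Result of a two-component SLD inversion.

    ``fraction_b`` is the inferred volume fraction of component b; it is
    *not* clamped to [0, 1] — ``in_range`` flags physically admissible
    results.  ``ill_conditioned`` marks inversions across an SLD gap too
    small to resolve (the estimate is then reported but untrustworthy).
    """

    fraction_b: float
    sigma: float | None = None
    in_range: bool = True
    ill_conditioned: bool = False
    component_a: str = ""
    component_b: str = ""


def infer_binary_composition(
    measured_sld: float,
    component_a: Material,
    component_b: Material,
    *,
    measured_sigma: float | None = None,
    epsilon: float = DEFAULT_EPSILON,
    strict: bool = False,
) -> CompositionEstimate:
    """Invert a measured layer SLD into a binary volume fraction.

    f_b = (measured − sld_a) / (sld_b − sld_a), with linear error
    propagation of ``measured_sigma`` when given.

    When ``|sld_b − sld_a| < epsilon`` the inversion is ill-conditioned
    (this is why a glucosylceramide/phosphocholine head-group contrast of
    2.2 vs 1.93 cannot be quantified); the estimate is flagged, or an
    :class:`IllConditionedInversionError` raised if ``strict``.
    """
    gap = component_b.sld - component_a.sld
    ill = abs(gap) < epsilon
    if ill and strict:
        raise IllConditionedInversionError(
            f"|SLD({component_b.name}) - SLD({component_a.name})| = "
            f"{abs(gap):.3g} < epsilon = {epsilon}"
        )
    if gap == 0:
        raise IllConditionedInversionError(
            f"components {component_a.name!r} and {component_b.name!r} "
            "have identical SLDs"
        )
    f_b = (measured_sld - component_a.sld) / gap
    sigma = None if measured_sigma is None else abs(measured_sigma / gap)
    return CompositionEstimate(
        fraction_b=f_b,
        sigma=sigma,
        in_range=0.0 <= f_b <= 1.0,
        ill_conditioned=ill,
        component_a=component_a.name,
        component_b=component_b.name,
    )


def load_materials(path: str | Path) -> dict[str, Material]:
    """Read a plain-text materials table: ``name sld`` per line, '#' comments.

    Returns the built-in registry extended/overridden by the file entries.
    """
    registry = dict(MATERIALS)
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.replace(",", " ").split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'name sld', got {raw!r}")
        name, sld = parts[0], float(parts[1])
        registry[name] = Material(name, sld)
    return registry
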