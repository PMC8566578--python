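"""Langmuir compression-isotherm analysis.

A compressed monolayer of an ideally mixed (or fully immiscible) film
obeys the additivity rule A_mix = Σ X_i·A_i at fixed surface pressure,
where X_i are mole fractions and A_i the pure-component mean molecular
areas.  A measured mixture area significantly *below* the additivity
prediction (a negative excess area) indicates a condensing, attractive
interaction between components; an area above it, an expanding one.  The
reference pressure for bilayer-relevant packing is 30 mN/m.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "Isotherm",
    "ExcessAreaResult",
    "OutOfRangeError",
    "area_at_pressure",
    "additivity_area",
    "excess_area",
    "condensation_analysis",
    "BILAYER_PRESSURE",
]

#: Surface pressure (mN/m) conventionally taken to match the lateral
#: packing prevailing in a bilayer.
BILAYER_PRESSURE = 30.0

#: Replicate variation coefficient used when no per-curve errors exist.
DEFAULT_VARIATION = 0.05


class OutOfRangeError(ValueError):
    """Requested pressure outside the recorded compression range."""


@dataclass(frozen=True)
class Isotherm:
    """A surface pressure–area (Π–A) compression curve.

    Stored in compression order (area decreasing).  ``composition`` maps
    component names to mole fractions summing to 1.
    """

    area: np.ndarray
    pressure: np.ndarray
    composition: Mapping[str, float] = field(default_factory=dict)
    label: str = ""

    def __post_init__(self) -> None:
        a = np.asarray(self.area, dtype=float)
        p = np.asarray(self.pressure, dtype=float)
        if a.shape != p.shape or a.ndim != 1 or len(a) < 2:
            raise ValueError("area and pressure must be equal-length 1-d arrays")
        order = np.argsort(a)[::-1]  # large area (dilute) first
        object.__setattr__(self, "area", a[order])
        object.__setattr__(self, "pressure", p[order])
        if self.composition:
            total = sum(self.composition.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"mole fractions sum to {total}, expected 1")

    def compression_branch(self) -> tuple[np.ndarray, np.ndarray]:
        """Curve up to the pressure maximum (collapse region excluded),
        cleaned to be pressure-monotone as area decreases."""
        i_max = int(np.argmax(self.pressure))
        a = self.area[: i_max + 1]
        p = self.pressure[: i_max + 1]
        # enforce monotonicity against small instrumental jitter
        p = np.maximum.accumulate(p)
        return a, p


def area_at_pressure(iso: Isotherm, target_pi: float) -> float:
    """Mean molecular area at a target pressure, Å²/molecule.

    Linear interpolation on the compression branch; exact recorded points
    are returned as stored.
    """
    a, p = iso.compression_branch()
    if not p.min() <= target_pi <= p.max():
        raise OutOfRangeError(
            f"pressure {target_pi} mN/m outside recorded range "
            f"[{p.min():.3g}, {p.max():.3g}]"
        )
    # p increases along the branch (area decreasing)
    return float(np.interp(target_pi, p, a))


def additivity_area(
    pure_areas: Sequence[float], fractions: Sequence[float]
) -> float:
    """Ideal-mixing (additivity-rule) area: A_mix = Σ X_i·A_i."""
    areas = np.asarray(pure_areas, dtype=float)
    x = np.asarray(fractions, dtype=float)
    if areas.shape != x.shape:
        raise ValueError("pure_areas and fractions length mismatch")
    if np.any(x < 0) or abs(x.sum() - 1.0) > 1e-9:
        raise ValueError("mole fractions must be >= 0 and sum to 1")
    return float(np.dot(areas, x))


@dataclass(frozen=True)
class ExcessAreaResult:
    delta: float  # theoretical - measured, Å²/molecule
    verdict: str  # "condensing" | "ideal/immiscible" | "expanding"
    threshold: float  # significance threshold applied, Å²


def excess_area(
    measured: float,
    theoretical: float,
    sigma_measured: float | None = None,
    sigma_theoretical: float | None = None,
    variation: float = DEFAULT_VARIATION,
) -> ExcessAreaResult:
    """Deviation from the additivity rule and its interpretation.

    delta = theoretical − measured.  The verdict requires |delta| to
    exceed 2·√(σ_m² + σ_t²); when a σ is not supplied it is taken as
    ``variation``·area (replicate scatter).
    """
    if measured <= 0 or theoretical <= 0:
        raise ValueError("areas must be positive")
    s_m = variation * measured if sigma_measured is None else sigma_measured
    s_t = (
        variation * theoretical
        if sigma_theoretical is None
        else sigma_theoretical
    )
    threshold = 2.0 * float(np.hypot(s_m, s_t))
    delta = theoretical - measured
    if delta > threshold:
        verdict = "condensing"
    elif delta < -threshold:
        verdict = "expanding"
    else:
        verdict = "ideal/immiscible"
    return ExcessAreaResult(delta=delta, verdict=verdict, threshold=threshold)


def condensation_analysis(
    pure: Mapping[str, Isotherm],
    mixture_replicates: Sequence[Isotherm],
    fractions: Mapping[str, float],
    pressure: float = BILAYER_PRESSURE,
) -> dict:
    """Full additivity-rule analysis at one pressure.

    Looks up each pure-component area and the replicate mixture areas at
    ``pressure``, forms the additivity prediction from ``fractions`` and
    returns measured/theoretical areas, replicate scatter and the
    :func:`excess_area` verdict.
    """
    names = list(fractions)
    pure_areas = [area_at_pressure(pure[n], pressure) for n in names]
    a_theo = additivity_area(pure_areas, [fractions[n] for n in names])
    reps = np.array(
        [area_at_pressure(m, pressure) for m in mixture_replicates]
    )
    a_meas = float(reps.mean())
    sigma_m = float(reps.std(ddof=1)) if len(reps) > 1 else None
    result = excess_area(a_meas, a_theo, sigma_measured=sigma_m)
    return {
        "pressure": pressure,
        "pure_areas": dict(zip(names, pure_areas)),
        "measured_area": a_meas,
        "measured_sigma": sigma_m,
        "theoretical_area": a_theo,
        "excess": result,
    }
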