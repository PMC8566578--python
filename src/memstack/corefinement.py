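"""Simultaneous (co-)refinement of multi-contrast reflectivity data.

All curves of a contrast set are fitted with one set of structural
parameters — thicknesses, SLDs, hydrations, coverage, roughness — while
only the backing solvent differs between curves.  Sharing the structure
across contrasts is what breaks the phase ambiguity of single-curve
reflectometry and is the reason contrast variation resolves sub-nanometre
compositional detail such as leaflet asymmetry.

The fit minimizes χ² = Σ_curves Σ_points ((R_model − R_data)/dR)² with a
seeded differential-evolution global search (the fringe-matching
landscape is multimodal) followed by a Nelder–Mead polish.  Per-parameter
uncertainties come from a Δχ² = 1 profile scan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import optimize

from .io import ContrastSet
from .membrane_model import SlabStack, build_stack
from .reflectivity import reflectivity
from .sld_core import Material

__all__ = [
    "Parameter",
    "FitProblem",
    "FitResult",
    "chi2",
    "corefine",
    "uncertainties",
    "DEFAULT_BOUNDS",
]

log = logging.getLogger("memstack")

#: Default box constraints for commonly fitted structural parameters.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "oxide_thickness": (0.0, 40.0),
    "water_thickness": (0.0, 40.0),
    "head_thickness": (0.0, 40.0),
    "chain_thickness_inner": (0.0, 40.0),
    "chain_thickness_outer": (0.0, 40.0),
    "roughness": (0.0, 10.0),
    "coverage": (0.5, 1.0),
    "chain_sld_inner": (-0.6, 0.6),
    "chain_sld_outer": (-0.6, 0.6),
}


@dataclass(frozen=True)
class Parameter:
    """One named model parameter with bounds and a free/fixed flag."""

    name: str
    value: float
    bounds: tuple[float, float] | None = None
    free: bool = False

    def __post_init__(self) -> None:
        if self.free:
            b = self.bounds
            if b is None or not (np.isfinite(b[0]) and np.isfinite(b[1])):
                raise ValueError(
                    f"free parameter {self.name!r} needs finite bounds"
                )
            if not b[0] <= self.value <= b[1]:
                raise ValueError(
                    f"parameter {self.name!r} value {self.value} outside "
                    f"bounds {b}"
                )


@dataclass
class FitProblem:
    """A contrast set plus the parametric stack that should explain it.

    ``builder`` maps a full parameter dict to a :class:`SlabStack`; the
    default is the six-slab supported-membrane builder.  All structural
    parameters are shared across contrasts; each curve keeps its own
    solvent (registered in the contrast set).

    ``error_floor`` supplies relative errors where a curve has no dR
    column; ``use_log`` switches the residual to log₁₀R (unweighted by
    dR), an alternative convention some refinement programs use.
    """

    parameters: list[Parameter]
    data: ContrastSet
    builder: Callable[[dict], SlabStack] = build_stack
    resolution: float = 0.10
    use_log: bool = False
    error_floor: float = 0.03

    def __post_init__(self) -> None:
        if len(self.data) == 0:
            raise ValueError("at least one curve required")
        names = [p.name for p in self.parameters]
        if len(set(names)) != len(names):
            raise ValueError("duplicate parameter names")

    @property
    def free_names(self) -> list[str]:
        return [p.name for p in self.parameters if p.free]

    @property
    def free_bounds(self) -> list[tuple[float, float]]:
        return [p.bounds for p in self.parameters if p.free]

    def param_dict(self, free_values: Sequence[float] | None = None) -> dict:
        values = {p.name: p.value for p in self.parameters}
        if free_values is not None:
            values.update(zip(self.free_names, free_values))
        return values

    def stack(self, free_values: Sequence[float] | None = None) -> SlabStack:
        return self.builder(self.param_dict(free_values))


def chi2(
    problem: FitProblem, free_values: Sequence[float] | None = None
) -> float:
    """Total χ² of the model over every curve and point, equal weights."""
    stack = problem.stack(free_values)
    total = 0.0
    for curve, solvent in problem.data:
        r_model = reflectivity(
            stack, solvent, curve.q,
            resolution=None if curve.dq is not None else problem.resolution,
            dq=curve.dq,
        )
        if problem.use_log:
            eps = 1e-12
            res = np.log10(np.clip(r_model, eps, None)) - np.log10(
                np.clip(curve.r, eps, None)
            )
        else:
            if curve.dr is not None:
                dr = curve.dr
            else:
                log.warning(
                    "curve without dR: using %.0f%% relative error floor",
                    100 * problem.error_floor,
                )
                dr = problem.error_floor * np.abs(curve.r)
            res = (r_model - curve.r) / dr
        total += float(np.sum(res**2))
    return total


def chi2_per_curve(
    problem: FitProblem, free_values: Sequence[float] | None = None
) -> list[float]:
    out = []
    for curve, solvent in problem.data:
        sub = replace(problem, data=ContrastSet((curve,), (solvent,)))
        out.append(chi2(sub, free_values))
    return out


@dataclass(frozen=True)
class FitResult:
    """Best-fit values, χ² bookkeeping and convergence metadata."""

    params: dict[str, float]
    free_names: tuple[str, ...]
    chi2: float
    chi2_per_curve: tuple[float, ...]
    n_points: int
    errors: dict[str, float] = field(default_factory=dict)
    converged: bool = True
    message: str = ""
    nfev: int = 0
    seed: int | None = None

    @property
    def reduced_chi2(self) -> float:
        dof = max(1, self.n_points - len(self.free_names))
        return self.chi2 / dof


def corefine(
    problem: FitProblem,
    seed: int = 0,
    maxiter: int = 150,
    popsize: int = 15,
    tol: float = 1e-8,
    polish: bool = True,
) -> FitResult:
    """Global seeded fit of all free parameters.

    Differential evolution (population ``popsize``×n_free) over the free
    parameter box, then a Nelder–Mead polish from the best point.
    Deterministic for a given seed.  Non-convergence within the iteration
    budget flags the result rather than raising.
    """
    n_points = sum(len(c) for c in problem.data.curves)
    free = problem.free_names
    if not free:
        return FitResult(
            params=problem.param_dict(),
            free_names=(),
            chi2=chi2(problem),
            chi2_per_curve=tuple(chi2_per_curve(problem)),
            n_points=n_points,
            message="all parameters fixed",
            seed=seed,
        )

    objective = lambda x: chi2(problem, x)  # noqa: E731
    bounds = problem.free_bounds
    de = optimize.differential_evolution(
        objective,
        bounds=bounds,
        seed=seed,
        maxiter=maxiter,
        popsize=popsize,
        tol=tol,
        init="latinhypercube",
        updating="deferred",
        polish=False,
    )
    x_best, f_best, nfev = de.x, de.fun, de.nfev
    if polish:
        nm = optimize.minimize(
            objective,
            x_best,
            method="Nelder-Mead",
            bounds=bounds,
            options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 4000},
        )
        if nm.fun <= f_best:
            x_best, f_best = nm.x, nm.fun
        nfev += nm.nfev
        x_best = np.clip(x_best, [b[0] for b in bounds], [b[1] for b in bounds])
        f_best = objective(x_best)

    converged = bool(de.success or polish)
    if not de.success:
        log.warning("differential evolution budget exhausted: %s", de.message)
    return FitResult(
        params=problem.param_dict(x_best),
        free_names=tuple(free),
        chi2=float(f_best),
        chi2_per_curve=tuple(chi2_per_curve(problem, x_best)),
        n_points=n_points,
        converged=converged,
        message=str(de.message),
        nfev=int(nfev),
        seed=seed,
    )


def log_probability(problem: FitProblem):
    """Hook for Bayesian posterior sampling of the free parameters.

    Returns ``f(x) -> log P`` (flat priors inside the bounds, −χ²/2
    inside, −inf outside), directly usable as the log-probability of an
    affine-invariant ensemble sampler.  Sampling itself is out of scope
    here; this is the integration point.
    """
    bounds = problem.free_bounds

    def logp(x: Sequence[float]) -> float:
        for v, (lo, hi) in zip(x, bounds):
            if not lo <= v <= hi:
                return -np.inf
        return -0.5 * chi2(problem, x)

    return logp


def uncertainties(
    result: FitResult,
    problem: FitProblem,
    delta_chi2: float = 1.0,
    max_step_frac: float = 0.5,
) -> dict[str, float]:
    """Per-parameter errors from a Δχ² = 1 profile scan.

    Each free parameter is scanned away from its best value (others held
    fixed) until χ² rises by ``delta_chi2``; the half-width is the
    averaged two-sided interval.  A parameter pinned at a bound gets a
    one-sided interval (logged).
    """
    x0 = np.array([result.params[n] for n in result.free_names])
    f0 = chi2(problem, x0)
    errors: dict[str, float] = {}
    for i, name in enumerate(result.free_names):
        lo, hi = problem.free_bounds[i]
        span = (hi - lo) * max_step_frac
        sides = []
        for direction in (+1.0, -1.0):
            limit = hi if direction > 0 else lo
            room = abs(limit - x0[i])
            if room <= 0:
                continue

            def excess(t: float) -> float:
                x = x0.copy()
                x[i] = x0[i] + direction * t
                return chi2(problem, x) - f0 - delta_chi2

            t_hi = min(room, span)
            if excess(t_hi) < 0:
                sides.append(t_hi)  # bound reached first
                continue
            t = optimize.brentq(excess, 0.0, t_hi, xtol=1e-8)
            sides.append(t)
        if not sides:
            log.warning("parameter %s pinned at both bounds", name)
            errors[name] = float("nan")
        else:
            if len(sides) == 1:
                log.warning("parameter %s: one-sided interval", name)
            errors[name] = float(np.mean(sides))
    return errors
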