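"""Parametric slab description of a silicon-supported lipid membrane.

The supported-membrane geometry is the standard solid/liquid cell stack:

    silicon | native oxide | interstitial water | inner heads |
    inner chains | outer chains | outer heads | bulk solvent

z = 0 sits at the silicon/oxide interface and increases toward the bulk
solvent.  The hydrocarbon core is split into two chain slabs so that the
two leaflets may carry different SLDs — the handle through which sterol
asymmetry between the substrate-proximal (inner) and solvent-facing
(outer) leaflets is expressed and later inferred.

Incomplete surface coverage is modelled as additional uniform solvent
admixture in the membrane slabs (single-structure model): a coverage c and
intrinsic solvent fraction φ give an effective solvent fraction
φ_eff = 1 − c·(1 − φ).  The substrate slabs (oxide, interstitial water)
are exempt from coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

from .sld_core import (
    MATERIALS,
    CompositionEstimate,
    Material,
    infer_binary_composition,
    mix_sld,
)

__all__ = [
    "Slab",
    "SlabStack",
    "LeafletReport",
    "ResolvedSlab",
    "build_stack",
    "effective_slabs",
    "leaflet_report",
    "stack_to_config",
    "stack_from_config",
    "sld_profile",
]


class ConfigurationError(ValueError):
    """A required structural parameter is missing or inconsistent."""


@dataclass(frozen=True)
class Slab:
    """One homogeneous layer.

    ``roughness`` is the Gaussian width (Å) of the interface between this
    slab and its *predecessor*.  ``apply_coverage`` marks membrane slabs
    that dilute with solvent when the film is incomplete.
    """

    name: str
    thickness: float
    sld: float  # solvent-free material SLD, 1e-6 Å⁻²
    solvent_fraction: float = 0.0
    roughness: float = 0.0
    apply_coverage: bool = True

    def __post_init__(self) -> None:
        if self.thickness < 0:
            raise ValueError(f"slab {self.name!r}: negative thickness")
        if self.roughness < 0:
            raise ValueError(f"slab {self.name!r}: negative roughness")
        if not 0.0 <= self.solvent_fraction <= 1.0:
            raise ValueError(
                f"slab {self.name!r}: solvent_fraction outside [0, 1]"
            )


@dataclass(frozen=True)
class ResolvedSlab:
    """A slab with its per-contrast effective SLD already mixed in."""

    name: str
    thickness: float
    sld: float
    roughness: float


@dataclass(frozen=True)
class SlabStack:
    """Ordered layer stack between a fronting and a backing medium.

    The beam travels through the silicon block, so ``fronting`` is silicon
    and ``backing`` is the solvent; the backing can be swapped per
    measurement contrast without touching any structural parameter.
    """

    fronting: Material
    slabs: tuple[Slab, ...]
    backing: Material
    coverage: float = 1.0
    fronting_roughness: float = 0.0  # fronting/first-slab interface
    backing_roughness: float = 0.0  # last-slab/backing interface

    def __post_init__(self) -> None:
        if not 0.0 <= self.coverage <= 1.0:
            raise ValueError("coverage must lie in [0, 1]")
        if self.fronting_roughness < 0 or self.backing_roughness < 0:
            raise ValueError("negative fronting/backing roughness")

    @property
    def d_max(self) -> float:
        """Total interfacial layer extent (Σ thickness, oxide included)."""
        return sum(s.thickness for s in self.slabs)

    def with_backing(self, solvent: Material) -> "SlabStack":
        return replace(self, backing=solvent)

    def slab(self, name: str) -> Slab:
        for s in self.slabs:
            if s.name == name:
                return s
        raise KeyError(name)


@dataclass(frozen=True)
class LeafletReport:
    """Per-leaflet chain composition and the asymmetry verdict.

    The asymmetry flag is true iff the inferred sterol volume fractions of
    the two leaflets differ beyond their propagated (or minimum) joint
    uncertainty.
    """

    inner_chain_sld: float
    outer_chain_sld: float
    inner_sterol_fraction: CompositionEstimate
    outer_sterol_fraction: CompositionEstimate
    inner_head_hydration: float | None
    outer_head_hydration: float | None
    asymmetric: bool


# Parameter names accepted by build_stack; SLD defaults come from the
# shared materials registry.
_DEFAULTS = {
    "oxide_sld": MATERIALS["silicon_oxide"].sld,
    "oxide_solvent_fraction": 0.0,
    "head_sld": MATERIALS["plpc_heads"].sld,
    "head_solvent_fraction": 0.0,
    "chain_solvent_fraction_inner": 0.0,
    "chain_solvent_fraction_outer": 0.0,
    "coverage": 1.0,
    "roughness": 0.0,
}

_REQUIRED = (
    "oxide_thickness",
    "water_thickness",
    "head_thickness",
    "chain_thickness_inner",
    "chain_thickness_outer",
    "chain_sld_inner",
    "chain_sld_outer",
)


def build_stack(
    params: Mapping[str, float],
    *,
    fronting: Material | None = None,
    backing: Material | None = None,
) -> SlabStack:
    """Assemble the six-slab supported-membrane stack from named parameters.

    Required keys: ``oxide_thickness, water_thickness, head_thickness,
    chain_thickness_inner, chain_thickness_outer, chain_sld_inner,
    chain_sld_outer``.  Optional keys (with defaults): ``oxide_sld,
    oxide_solvent_fraction, head_sld, head_solvent_fraction,
    chain_solvent_fraction_inner, chain_solvent_fraction_outer, coverage,
    roughness`` and per-slab roughness overrides ``roughness_<slab>``.

    A single ``roughness`` value is applied to every interface unless
    overridden — the analyses this package reproduces fitted one shared
    interlayer roughness.
    """
    missing = [k for k in _REQUIRED if k not in params]
    if missing:
        raise ConfigurationError(f"missing structural parameters: {missing}")
    p = {**_DEFAULTS, **params}

    def rough(slab_name: str) -> float:
        return float(p.get(f"roughness_{slab_name}", p["roughness"]))

    slabs = (
        Slab(
            "oxide",
            p["oxide_thickness"],
            p["oxide_sld"],
            p["oxide_solvent_fraction"],
            rough("oxide"),
            apply_coverage=False,
        ),
        # Interstitial water: pure solvent, so its material SLD is moot.
        Slab("water", p["water_thickness"], 0.0, 1.0, rough("water"),
             apply_coverage=False),
        Slab("heads_inner", p["head_thickness"], p["head_sld"],
             p["head_solvent_fraction"], rough("heads_inner")),
        Slab("chains_inner", p["chain_thickness_inner"], p["chain_sld_inner"],
             p["chain_solvent_fraction_inner"], rough("chains_inner")),
        Slab("chains_outer", p["chain_thickness_outer"], p["chain_sld_outer"],
             p["chain_solvent_fraction_outer"], rough("chains_outer")),
        Slab("heads_outer", p["head_thickness"], p["head_sld"],
             p["head_solvent_fraction"], rough("heads_outer")),
    )
    # Drop zero-thickness lipid slabs so a degenerate "empty membrane"
    # reduces cleanly to silicon/oxide/water/solvent.
    slabs = tuple(
        s for s in slabs if s.thickness > 0 or not s.apply_coverage
    )
    return SlabStack(
        fronting=fronting or MATERIALS["silicon"],
        slabs=slabs,
        backing=backing or MATERIALS["d2o"],
        coverage=float(p["coverage"]),
        fronting_roughness=float(p.get("roughness_fronting", p["roughness"])),
        backing_roughness=float(p.get("roughness_backing", p["roughness"])),
    )


def effective_slabs(stack: SlabStack, solvent: Material) -> list[ResolvedSlab]:
    """Resolve per-contrast effective SLDs (solvent mixing + coverage).

    Each slab's effective SLD is the volume-weighted mix of its dry
    material and the solvent at φ_eff = 1 − coverage·(1 − φ); substrate
    slabs use φ_eff = φ.
    """
    out = []
    for s in stack.slabs:
        if s.apply_coverage:
            phi = 1.0 - stack.coverage * (1.0 - s.solvent_fraction)
        else:
            phi = s.solvent_fraction
        sld = mix_sld([(s.sld, 1.0 - phi), (solvent.sld, phi)])
        out.append(ResolvedSlab(s.name, s.thickness, sld, s.roughness))
    return out


def leaflet_report(
    stack: SlabStack,
    *,
    chains: Material | None = None,
    sterol: Material | None = None,
    sld_sigma: float = 0.02,
    min_significant: float = 0.05,
) -> LeafletReport:
    """Quantify per-leaflet sterol content and flag asymmetry.

    Inverts each chain slab's dry SLD against the bare-chain and sterol
    end members.  ``sld_sigma`` (1e-6 Å⁻²) is the assumed uncertainty of a
    fitted chain SLD; the asymmetry test requires the leaflet fractions to
    differ by more than 2× their propagated joint uncertainty (and by at
    least ``min_significant`` in absolute volume fraction).
    """
    chains = chains or MATERIALS["lipid_chains"]
    sterol = sterol or MATERIALS["sitosterol"]
    try:
        inner = stack.slab("chains_inner")
        outer = stack.slab("chains_outer")
    except KeyError as exc:
        raise ConfigurationError("stack has no chain slabs") from exc

    est_in = infer_binary_composition(
        inner.sld, chains, sterol, measured_sigma=sld_sigma
    )
    est_out = infer_binary_composition(
        outer.sld, chains, sterol, measured_sigma=sld_sigma
    )
    diff = abs(est_in.fraction_b - est_out.fraction_b)
    joint = ((est_in.sigma or 0.0) ** 2 + (est_out.sigma or 0.0) ** 2) ** 0.5
    asymmetric = bool(diff > max(2.0 * joint, min_significant))

    def hydration(name: str) -> float | None:
        try:
            return stack.slab(name).solvent_fraction
        except KeyError:
            return None

    return LeafletReport(
        inner_chain_sld=inner.sld,
        outer_chain_sld=outer.sld,
        inner_sterol_fraction=est_in,
        outer_sterol_fraction=est_out,
        inner_head_hydration=hydration("heads_inner"),
        outer_head_hydration=hydration("heads_outer"),
        asymmetric=asymmetric,
    )


def interface_roughnesses(stack: SlabStack) -> list[float]:
    """Gaussian widths for the N+1 interfaces of an N-slab stack.

    Interface i sits at the top of slab i−1: the fronting/first-slab and
    last-slab/backing widths are stack-level parameters, the interior ones
    belong to the upper slab of each pair (its "interface to the
    predecessor").  The first slab's own ``roughness`` field is therefore
    unused; :func:`build_stack` keeps all of them in sync with the shared
    ``roughness`` parameter.
    """
    if not stack.slabs:
        return [max(stack.fronting_roughness, stack.backing_roughness)]
    interior = [s.roughness for s in stack.slabs[1:]]
    return [stack.fronting_roughness, *interior, stack.backing_roughness]


# ---------------------------------------------------------------------------
# Serialization and profile export


def stack_to_config(stack: SlabStack) -> dict[str, float | str]:
    """Flatten a stack to a key-value mapping (round-trips with
    :func:`stack_from_config`)."""
    cfg: dict[str, float | str] = {
        "fronting_name": stack.fronting.name,
        "fronting_sld": stack.fronting.sld,
        "backing_name": stack.backing.name,
        "backing_sld": stack.backing.sld,
        "coverage": stack.coverage,
        "roughness_fronting": stack.fronting_roughness,
        "roughness_backing": stack.backing_roughness,
    }
    for s in stack.slabs:
        cfg[f"{s.name}_thickness"] = s.thickness
        cfg[f"{s.name}_sld"] = s.sld
        cfg[f"{s.name}_solvent_fraction"] = s.solvent_fraction
        cfg[f"{s.name}_roughness"] = s.roughness
        cfg[f"{s.name}_apply_coverage"] = float(s.apply_coverage)
    cfg["slab_order"] = ",".join(s.name for s in stack.slabs)
    return cfg


def stack_from_config(cfg: Mapping[str, float | str]) -> SlabStack:
    order = str(cfg["slab_order"]).split(",") if cfg.get("slab_order") else []
    slabs = tuple(
        Slab(
            name,
            float(cfg[f"{name}_thickness"]),
            float(cfg[f"{name}_sld"]),
            float(cfg[f"{name}_solvent_fraction"]),
            float(cfg[f"{name}_roughness"]),
            bool(float(cfg.get(f"{name}_apply_coverage", 1.0))),
        )
        for name in order
        if name
    )
    return SlabStack(
        fronting=Material(str(cfg["fronting_name"]), float(cfg["fronting_sld"])),
        slabs=slabs,
        backing=Material(str(cfg["backing_name"]), float(cfg["backing_sld"])),
        coverage=float(cfg.get("coverage", 1.0)),
        fronting_roughness=float(cfg.get("roughness_fronting", 0.0)),
        backing_roughness=float(cfg.get("roughness_backing", 0.0)),
    )


def sld_profile(
    stack: SlabStack,
    solvent: Material,
    dz: float = 0.5,
    pad: float = 20.0,
):
    """Real-space SLD profile ρ(z) with error-function interfaces.

    Returns ``(z, rho)`` arrays on the z = 0 at silicon/oxide convention,
    extended ``pad`` Å into the fronting and backing.  Intended for
    plotting and for two-column text export.
    """
    import numpy as np
    from scipy.special import erf

    resolved = effective_slabs(stack, solvent)
    edges = np.concatenate([[0.0], np.cumsum([s.thickness for s in resolved])])
    slds = [stack.fronting.sld] + [s.sld for s in resolved] + [solvent.sld]
    sigmas = [max(s, 1e-3) for s in interface_roughnesses(stack)]
    # interface i sits at edges[i] with width sigmas[i]
    iface_z = list(edges)
    z = np.arange(-pad, edges[-1] + pad + dz, dz)
    rho = np.full_like(z, slds[0], dtype=float)
    for i, zi in enumerate(iface_z):
        step = 0.5 * (1.0 + erf((z - zi) / (np.sqrt(2.0) * sigmas[i])))
        rho = rho + (slds[i + 1] - slds[i]) * step
    return z, rho
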