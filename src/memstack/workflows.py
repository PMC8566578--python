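"""End-to-end workflows tying the analysis stages together.

A workflow takes a :class:`RunConfig` (loadable from a YAML file),
generates or reads its inputs, runs the relevant stages — model-free
profiling then model-based co-refinement for the reflectometry
workflows, or the monolayer / lattice analyses — and writes a report
bundle: a parameter table, profile exports, the leaflet report and a log
recording seeds and tolerances.  Every numeric artifact of a run is
reconstructible from config + seed alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .corefinement import FitProblem, Parameter, corefine, uncertainties
from .io import ContrastSet, write_curve
from .lattice import (
    contact_fractions,
    lattice_to_text,
    radial_distribution,
    random_lattice,
    run_mc,
)
from .membrane_model import build_stack, leaflet_report, sld_profile
from .model_free import anneal_profiles, estimate_dmax
from .monolayer import condensation_analysis
from .sld_core import MATERIALS
from .synthetic import (
    NoiseModel,
    canonical_fixtures,
    synth_isotherm,
    synth_reflectivity,
)

__all__ = ["RunConfig", "run_workflow", "load_config"]

log = logging.getLogger("memstack")

WORKFLOWS = ("ternary-demo", "binary-demo", "monolayer-demo", "lattice-demo")


@dataclass
class RunConfig:
    """Declarative description of one run."""

    workflow: str
    outdir: str = "memstack_out"
    seed: int = 1
    noise_floor: float = 0.03
    run_model_free: bool = True
    run_anneal: bool = False  # annealing stage is the slow one
    run_corefine: bool = True
    fit_maxiter: int = 80
    lattice_size: int = 24
    lattice_sweeps: int = 400
    #: optional measured input: {solvent name: curve file path}; when set,
    #: these curves are fitted instead of generating synthetic data
    curve_files: dict = field(default_factory=dict)
    condensation_delta: float = 9.8
    pure_areas: dict = field(
        default_factory=lambda: {"PLPC": 63.0, "SITO": 38.0, "GLUCER": 39.0}
    )
    fractions: dict = field(
        default_factory=lambda: {"PLPC": 0.6, "SITO": 0.2, "GLUCER": 0.2}
    )

    def __post_init__(self) -> None:
        if self.workflow not in WORKFLOWS:
            raise ValueError(
                f"unknown workflow {self.workflow!r}; choose from {WORKFLOWS}"
            )


def load_config(path: str | Path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig(**data)


def _setup_logging(outdir: Path) -> logging.Handler:
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    return handler


def _fmt(value) -> str:
    if isinstance(value, float):
        return f"{value:.6g}"
    return str(value)


def run_workflow(config: RunConfig) -> dict:
    """Execute one workflow; returns the report dict written to disk."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = _setup_logging(outdir)
    report: dict = {
        "workflow": config.workflow,
        "seed": config.seed,
        "version": __version__,
        "status": "complete",
    }
    try:
        if config.workflow in ("ternary-demo", "binary-demo"):
            report.update(_reflectometry_workflow(config, outdir))
        elif config.workflow == "monolayer-demo":
            report.update(_monolayer_workflow(config, outdir))
        else:
            report.update(_lattice_workflow(config, outdir))
    except Exception as exc:  # noqa: BLE001 - bundle marked partial
        log.exception("stage failed")
        report["status"] = "partial"
        report["error"] = f"{type(exc).__name__}: {exc}"
    finally:
        log.removeHandler(handler)
        handler.close()
    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=_fmt) + "\n"
    )
    return report


def _reflectometry_workflow(config: RunConfig, outdir: Path) -> dict:
    fixture_name = "ternary" if config.workflow == "ternary-demo" else "binary"
    fixture = canonical_fixtures()[fixture_name]
    solvents = ("h2o", "d2o", "4mw") if fixture_name == "ternary" else (
        "h2o",
        "d2o",
    )
    if config.curve_files:
        from .io import read_curve

        log.info("reading measured curves: %s", sorted(config.curve_files))
        for path in config.curve_files.values():
            if not Path(path).exists():
                raise FileNotFoundError(path)
        solvent_objs = tuple(
            MATERIALS[name] for name in config.curve_files
        )
        data = ContrastSet(
            tuple(read_curve(p) for p in config.curve_files.values()),
            solvent_objs,
            name=fixture_name,
        )
    else:
        log.info(
            "generating %s synthetic data, seed %d", fixture_name, config.seed
        )
        data = synth_reflectivity(
            fixture.stack,
            solvents,
            noise=NoiseModel(floor=config.noise_floor, seed=config.seed),
            name=fixture_name,
        )
        for curve, solvent in data:
            write_curve(
                outdir / f"{fixture_name}_{solvent.name}.dat",
                curve,
                header=[
                    f"memstack {__version__} synthetic curve",
                    f"fixture={fixture_name} solvent={solvent.name} "
                    f"seed={config.seed} noise_floor={config.noise_floor}",
                ],
            )
    out: dict = {"fixture": fixture_name, "solvents": [s.name for s in data.solvents]}

    if config.run_model_free:
        scan = estimate_dmax(data)
        out["d_max"] = scan.d_max
        out["d_max_plateau_found"] = scan.plateau_found
        log.info("model-free D_max = %.1f Å", scan.d_max)
        if config.run_anneal:
            prof = anneal_profiles(data, scan.d_max, seed=config.seed)
            np.savetxt(
                outdir / f"{fixture_name}_modelfree_profile.dat",
                np.column_stack(
                    [prof.z_centers, prof.sld_bins, prof.solvent_bins]
                ),
                header="z(A)  SLD(1e-6/A^2)  solvent_fraction",
                fmt="%.6g",
            )
            out["model_free_chi2"] = prof.chi2

    if config.run_corefine:
        free = [
            "water_thickness",
            "coverage",
            "roughness",
            "chain_sld_inner",
            "chain_sld_outer",
        ]
        params = [
            Parameter(
                k,
                float(v),
                bounds=_fit_bounds(k),
                free=k in free,
            )
            for k, v in fixture.params.items()
        ]
        problem = FitProblem(parameters=params, data=data)
        result = corefine(problem, seed=config.seed, maxiter=config.fit_maxiter)
        errs = uncertainties(result, problem)
        table_path = outdir / f"{fixture_name}_fit_parameters.txt"
        lines = ["# parameter  value  error(dchi2=1)"]
        for name in result.free_names:
            lines.append(
                f"{name}  {result.params[name]:.6g}  {errs[name]:.3g}"
            )
        for p in params:
            if not p.free:
                lines.append(f"{p.name}  {p.value:.6g}  (fixed)")
        lines.append(f"# chi2 = {result.chi2:.6g}  n = {result.n_points}")
        table_path.write_text("\n".join(lines) + "\n")

        best = build_stack(result.params)
        rep = leaflet_report(best)
        out["fit"] = {k: result.params[k] for k in result.free_names}
        out["fit_errors"] = errs
        out["chi2"] = result.chi2
        out["reduced_chi2"] = result.reduced_chi2
        out["leaflet_report"] = {
            "inner_sterol_fraction": rep.inner_sterol_fraction.fraction_b,
            "outer_sterol_fraction": rep.outer_sterol_fraction.fraction_b,
            "asymmetric": rep.asymmetric,
        }
        for solvent in data.solvents:
            z, rho = sld_profile(best, solvent)
            np.savetxt(
                outdir / f"{fixture_name}_sld_profile_{solvent.name}.dat",
                np.column_stack([z, rho]),
                header="z(A)  SLD(1e-6/A^2)",
                fmt="%.6g",
            )
        log.info(
            "co-refinement chi2/N = %.3g; asymmetric = %s",
            result.reduced_chi2,
            rep.asymmetric,
        )
    return out


def _fit_bounds(name: str) -> tuple[float, float] | None:
    from .corefinement import DEFAULT_BOUNDS

    if name in DEFAULT_BOUNDS:
        return DEFAULT_BOUNDS[name]
    if name.endswith("_fraction") or name.startswith("chain_solvent"):
        return (0.0, 1.0)
    return (0.0, 50.0)


def _monolayer_workflow(config: RunConfig, outdir: Path) -> dict:
    data = synth_isotherm(
        config.pure_areas,
        config.fractions,
        delta=config.condensation_delta,
        seed=config.seed,
    )
    analysis = condensation_analysis(
        data["pure"], data["mixture"], config.fractions
    )
    from .io import write_isotherm_table

    for name, iso in data["pure"].items():
        write_isotherm_table(
            outdir / f"isotherm_{name}.dat", iso.area, iso.pressure,
            header=[f"pure {name}, seed={config.seed}"],
        )
    for k, iso in enumerate(data["mixture"]):
        write_isotherm_table(
            outdir / f"isotherm_mixture_rep{k + 1}.dat",
            iso.area,
            iso.pressure,
            header=[f"mixture replicate {k + 1}, seed={config.seed}"],
        )
    ex = analysis["excess"]
    log.info(
        "excess area %.2f Å² (threshold %.2f): %s",
        ex.delta,
        ex.threshold,
        ex.verdict,
    )
    return {
        "pure_areas": analysis["pure_areas"],
        "measured_area": analysis["measured_area"],
        "theoretical_area": analysis["theoretical_area"],
        "excess_area": ex.delta,
        "verdict": ex.verdict,
    }


def _lattice_workflow(config: RunConfig, outdir: Path) -> dict:
    state = random_lattice(config.lattice_size, seed=config.seed)
    final, energy, meta = run_mc(state, config.lattice_sweeps, seed=config.seed)
    (outdir / "lattice_final.txt").write_text(lattice_to_text(final) + "\n")
    np.savetxt(
        outdir / "lattice_energy.dat",
        np.column_stack([np.arange(1, len(energy) + 1), energy]),
        header="sweep  energy(kcal/mol)",
        fmt="%.6g",
    )
    fractions = contact_fractions(final)
    rdf = radial_distribution(final, ("GLUCER", "GLUCER"))
    np.savetxt(
        outdir / "lattice_rdf_glucer.dat",
        np.column_stack([rdf.r, rdf.g]),
        header="r(lattice units)  g(r)",
        fmt="%.6g",
    )
    key = {f"{a}-{b}": v for (a, b), v in fractions.items()}
    log.info("final energy %.1f, acceptance %.2f", energy[-1], meta["acceptance"])
    return {
        "contact_fractions": key,
        "final_energy": float(energy[-1]),
        "acceptance": meta["acceptance"],
        "g_glucer_glucer_r1": float(rdf.g[0]),
    }
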