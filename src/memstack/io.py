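"""Plain-text I/O for reflectivity curves and compression isotherms.

Curve files are whitespace- or comma-separated columns ``q R [dR [dq]]``;
isotherm files are two columns ``area pressure``.  Lines starting with
'#' are comments and are preserved on round-trip where noted.  Writers
emit 6 significant digits, which the readers reproduce losslessly at that
precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .reflectivity import ReflectivityCurve
from .sld_core import Material

__all__ = [
    "ContrastSet",
    "CurveParseError",
    "read_curve",
    "write_curve",
    "read_isotherm",
    "write_isotherm",
    "read_isotherm_table",
    "write_isotherm_table",
]

log = logging.getLogger("memstack")

#: Relative error imputed when a data file carries no dR column.
DEFAULT_ERROR_FLOOR = 0.03


class CurveParseError(ValueError):
    """Malformed data file; the message names the offending line."""


@dataclass(frozen=True)
class ContrastSet:
    """Several curves measured on one physical structure.

    The curves share every structural parameter and differ only in the
    solvent filling the cell — the unit of multi-contrast co-refinement.
    """

    curves: tuple[ReflectivityCurve, ...]
    solvents: tuple[Material, ...]
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.curves) != len(self.solvents):
            raise ValueError("one solvent per curve required")

    def __len__(self) -> int:
        return len(self.curves)

    def __iter__(self):
        return iter(zip(self.curves, self.solvents))


def _parse_columns(path: Path, n_min: int, n_max: int):
    rows, comments = [], []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            comments.append(line)
            continue
        parts = line.replace(",", " ").split()
        if not n_min <= len(parts) <= n_max:
            raise CurveParseError(
                f"{path}:{lineno}: expected {n_min}-{n_max} columns, "
                f"got {len(parts)}: {raw!r}"
            )
        try:
            rows.append([float(p) for p in parts])
        except ValueError as exc:
            raise CurveParseError(f"{path}:{lineno}: {exc}") from exc
    if not rows:
        raise CurveParseError(f"{path}: no data lines")
    ncol = min(len(r) for r in rows)
    data = np.array([r[:ncol] for r in rows], dtype=float)
    return data, comments


def read_curve(
    path: str | Path, error_floor: float = DEFAULT_ERROR_FLOOR
) -> ReflectivityCurve:
    """Read a reflectivity curve; impute dR = floor·R when absent."""
    path = Path(path)
    data, _ = _parse_columns(path, 2, 4)
    q, r = data[:, 0], data[:, 1]
    if data.shape[1] >= 3:
        dr = data[:, 2]
    else:
        log.warning(
            "%s has no dR column; imputing %.0f%% relative errors",
            path,
            100 * error_floor,
        )
        dr = error_floor * np.abs(r)
    dq = data[:, 3] if data.shape[1] >= 4 else None
    order = np.argsort(q)
    return ReflectivityCurve(
        q[order], r[order], dr[order], None if dq is None else dq[order]
    )


def write_curve(
    path: str | Path,
    curve: ReflectivityCurve,
    header: Sequence[str] = (),
) -> None:
    """Write ``q R dR [dq]`` columns at 6 significant digits."""
    path = Path(path)
    cols = [curve.q, curve.r]
    names = ["q(1/A)", "R"]
    if curve.dr is not None:
        cols.append(curve.dr)
        names.append("dR")
    if curve.dq is not None:
        cols.append(curve.dq)
        names.append("dq(FWHM)")
    lines = [f"# {h}" for h in header]
    lines.append("# " + "  ".join(names))
    for row in zip(*cols):
        lines.append("  ".join(f"{v:.6g}" for v in row))
    path.write_text("\n".join(lines) + "\n")


def read_isotherm_table(path: str | Path):
    """Read ``area pressure`` columns; returns (area, pressure) arrays."""
    data, _ = _parse_columns(Path(path), 2, 2)
    return data[:, 0], data[:, 1]


def write_isotherm_table(
    path: str | Path,
    area: np.ndarray,
    pressure: np.ndarray,
    header: Sequence[str] = (),
) -> None:
    lines = [f"# {h}" for h in header]
    lines.append("# area(A^2/molecule)  pressure(mN/m)")
    for a, p in zip(area, pressure):
        lines.append(f"{a:.6g}  {p:.6g}")
    Path(path).write_text("\n".join(lines) + "\n")


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml")


def read_isotherm(path: str | Path):
    """Read an :class:`~memstack.monolayer.Isotherm`.

    The composition, if any, lives in a YAML sidecar ``<file>.yaml`` with
    a ``composition:`` mapping of mole fractions.
    """
    import yaml

    from .monolayer import Isotherm

    path = Path(path)
    area, pressure = read_isotherm_table(path)
    composition = {}
    side = _sidecar(path)
    if side.exists():
        meta = yaml.safe_load(side.read_text()) or {}
        composition = meta.get("composition", {}) or {}
    return Isotherm(area, pressure, composition, label=path.stem)


def write_isotherm(
    path: str | Path, isotherm, header: Sequence[str] = ()
) -> None:
    """Write an Isotherm plus a YAML sidecar carrying its composition."""
    import yaml

    path = Path(path)
    write_isotherm_table(path, isotherm.area, isotherm.pressure, header)
    if isotherm.composition:
        _sidecar(path).write_text(
            yaml.safe_dump({"composition": dict(isotherm.composition)})
        )
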