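"""Exact specular reflectivity of a slab stack.

Implements the Parratt recursion for a stack of homogeneous layers with
Gaussian (Nevot–Croce) interfacial roughness, plus constant-ΔQ/Q Gaussian
resolution smearing.  The geometry is the solid/liquid cell: the beam
arrives through the silicon block (fronting) and reflects off the
membrane/solvent structure, so total reflection occurs below the critical
edge of the silicon→solvent SLD step when the solvent is D₂O-rich.

Momentum transfer q = (4π/λ)·sin α, with α the grazing incidence angle.
SLDs enter in 10⁻⁶ Å⁻² and are converted to absolute Å⁻² internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .sld_core import Material
from .membrane_model import SlabStack, effective_slabs, interface_roughnesses

__all__ = [
    "ReflectivityCurve",
    "Instrument",
    "InvalidModelError",
    "qz",
    "fresnel",
    "abeles",
    "reflectivity",
    "smear",
    "critical_q",
]

SLD_SCALE = 1e-6  # conventional 1e-6 units -> absolute Å⁻²

#: Gauss-Legendre quadrature order for resolution smearing.
_N_GAUSS = 17
#: Half-width of the smearing kernel support, in σ.
_GAUSS_EXTENT = 3.5


class InvalidModelError(ValueError):
    """Structural parameters outside their physical domain."""


@dataclass(frozen=True)
class Instrument:
    """Time-of-flight-style instrument summary.

    Two incident wavelengths cover the low- and high-q regions; the
    relative resolution ΔQ/Q (FWHM) is dominated by the wavelength spread.
    """

    wavelengths: tuple[float, ...] = (10.0, 5.0)
    resolution: float = 0.10
    q_max: float = 0.25

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")


@dataclass(frozen=True)
class ReflectivityCurve:
    """One measured or synthetic specular curve (single solvent contrast)."""

    q: np.ndarray
    r: np.ndarray
    dr: np.ndarray | None = None
    dq: np.ndarray | None = None

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        r = np.asarray(self.r, dtype=float)
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "r", r)
        for name in ("dr", "dq"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                object.__setattr__(self, name, v)
                if v.shape != q.shape:
                    raise ValueError(f"{name} length mismatch")
        if q.shape != r.shape:
            raise ValueError("q and R length mismatch")
        if q.ndim != 1 or len(q) == 0:
            raise ValueError("q must be a non-empty 1-d array")
        if np.any(q <= 0) or np.any(np.diff(q) <= 0):
            raise ValueError("q must be strictly increasing and positive")

    def __len__(self) -> int:
        return len(self.q)


def qz(alpha_deg: float, wavelength: float) -> float:
    """Momentum transfer q = (4π/λ)·sin α for grazing angle α in degrees."""
    if not 0.0 < alpha_deg < 90.0:
        raise ValueError("incidence angle must lie in (0, 90) degrees")
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    return 4.0 * math.pi / wavelength * math.sin(math.radians(alpha_deg))


def critical_q(fronting_sld: float, backing_sld: float) -> float:
    """Critical edge q_c = √(16π·Δρ) of a positive fronting→backing step.

    Returns 0 when the backing SLD does not exceed the fronting SLD (no
    total reflection).
    """
    drho = (backing_sld - fronting_sld) * SLD_SCALE
    return math.sqrt(16.0 * math.pi * drho) if drho > 0 else 0.0


def abeles(
    q: np.ndarray,
    thickness: np.ndarray,
    sld: np.ndarray,
    roughness: np.ndarray,
    fronting_sld: float,
    backing_sld: float,
) -> np.ndarray:
    """Parratt recursion over resolved layers, vectorized over q.

    Parameters
    ----------
    q : array
        Momentum transfer grid, Å⁻¹ (positive).
    thickness, sld, roughness : arrays
        Per-slab thickness (Å), effective SLD (10⁻⁶ Å⁻²) and the N+1
        interface Gaussian widths (Å): ``roughness[i]`` belongs to the
        interface below layer i (fronting side first).
    fronting_sld, backing_sld : float
        Semi-infinite media SLDs, 10⁻⁶ Å⁻².
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    d = np.asarray(thickness, dtype=float)
    rho = np.concatenate(([fronting_sld], np.asarray(sld, float), [backing_sld]))
    sig = np.asarray(roughness, dtype=float)
    n_slab = len(d)
    if len(sig) != n_slab + 1:
        raise InvalidModelError(
            f"need {n_slab + 1} interface roughnesses, got {len(sig)}"
        )
    if np.any(d < 0) or np.any(sig < 0):
        raise InvalidModelError("negative thickness or roughness")

    # kz in each medium, referenced to the fronting
    k0sq = (q / 2.0) ** 2
    kz = np.sqrt(
        k0sq[:, None].astype(complex)
        - 4.0 * np.pi * (rho[None, :] - rho[0]) * SLD_SCALE
    )  # (nq, n_slab + 2)

    # recursion from the backing upward
    r_tot = np.zeros(len(q), dtype=complex)
    for j in range(n_slab, -1, -1):
        kj, kj1 = kz[:, j], kz[:, j + 1]
        rj = (kj - kj1) / (kj + kj1) * np.exp(-2.0 * kj * kj1 * sig[j] ** 2)
        if j == n_slab:
            r_tot = rj
        else:
            phase = np.exp(2j * kz[:, j + 1] * d[j])
            r_tot = (rj + r_tot * phase) / (1.0 + rj * r_tot * phase)
    # non-absorbing media: unitarity caps R at 1 (trim rounding excess)
    return np.minimum(np.abs(r_tot) ** 2, 1.0)


def fresnel(
    fronting: Material | float,
    backing: Material | float,
    q: np.ndarray,
    roughness: float = 0.0,
) -> np.ndarray:
    """Closed-form two-medium Fresnel reflectivity.

    Serves as the zero-slab limit of the recursion; with identical media
    it returns 0, and at large q it decays as (4π Δρ)²/q⁴.
    """
    rho_f = fronting.sld if isinstance(fronting, Material) else float(fronting)
    rho_b = backing.sld if isinstance(backing, Material) else float(backing)
    q = np.atleast_1d(np.asarray(q, dtype=float))
    k0 = (q / 2.0).astype(complex)
    k1 = np.sqrt(k0**2 - 4.0 * np.pi * (rho_b - rho_f) * SLD_SCALE)
    r = (k0 - k1) / (k0 + k1) * np.exp(-2.0 * k0 * k1 * roughness**2)
    return np.abs(r) ** 2


def _stack_arrays(stack: SlabStack, solvent: Material):
    resolved = effective_slabs(stack, solvent)
    d = np.array([s.thickness for s in resolved])
    rho = np.array([s.sld for s in resolved])
    sig = np.array(interface_roughnesses(stack))
    return d, rho, sig


def reflectivity(
    stack: SlabStack,
    solvent: Material,
    q: np.ndarray,
    resolution: float | None = None,
    dq: np.ndarray | None = None,
    micro_slice: bool = False,
    slice_width: float = 0.5,
) -> np.ndarray:
    """R(q) of a slab stack in a given solvent contrast.

    ``resolution`` is a constant ΔQ/Q (FWHM); ``dq`` gives per-point FWHM
    widths instead and takes precedence.  Either triggers Gaussian
    resolution smearing by fixed-order quadrature; with neither, the
    unsmeared curve is returned.

    ``micro_slice`` replaces the Nevot–Croce roughness factors by an
    explicit rendering of the error-function-blended profile into thin
    zero-roughness slices (``slice_width`` Å) — a sanity check for
    roughnesses approaching the slab thicknesses, where the Nevot–Croce
    approximation degrades.
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    if np.any(q <= 0):
        raise InvalidModelError("q must be positive")
    if micro_slice:
        from .membrane_model import sld_profile

        z, rho_z = sld_profile(stack, solvent, dz=slice_width, pad=25.0)
        d = np.full(len(z) - 2, slice_width)
        rho = 0.5 * (rho_z[1:-1] + rho_z[2:])
        sig = np.zeros(len(d) + 1)

        def model(qq: np.ndarray) -> np.ndarray:
            return abeles(qq, d, rho, sig, stack.fronting.sld, solvent.sld)

    else:
        d, rho, sig = _stack_arrays(stack, solvent)

        def model(qq: np.ndarray) -> np.ndarray:
            return abeles(qq, d, rho, sig, stack.fronting.sld, solvent.sld)

    if dq is not None:
        width = np.asarray(dq, dtype=float)
    elif resolution:
        width = resolution * q
    else:
        return model(q)
    return _smear_model(model, q, width)


def _gauss_nodes():
    x, w = np.polynomial.legendre.leggauss(_N_GAUSS)
    x = x * _GAUSS_EXTENT  # nodes in units of σ
    g = np.exp(-0.5 * x**2)
    w = w * g
    w = w / w.sum()  # exact for constants
    return x, w


_GX, _GW = _gauss_nodes()


def _smear_model(model, q: np.ndarray, fwhm: np.ndarray) -> np.ndarray:
    """Constant-kernel Gaussian smearing by quadrature on the model."""
    sigma = np.asarray(fwhm, dtype=float) / 2.35482
    nodes = q[:, None] + sigma[:, None] * _GX[None, :]
    nodes = np.clip(nodes, 1e-6, None)  # model undefined at q <= 0
    r = model(nodes.ravel()).reshape(nodes.shape)
    return r @ _GW


def smear(
    curve: ReflectivityCurve, resolution: float
) -> ReflectivityCurve:
    """Smear a tabulated curve with a constant ΔQ/Q Gaussian kernel.

    σ_q = (ΔQ/Q)·q/2.355.  The curve is linearly interpolated and held
    constant beyond its endpoints (local grid extension), so a constant
    curve is returned unchanged and ``resolution = 0`` is the identity.
    """
    if resolution < 0:
        raise ValueError("resolution must be >= 0")
    if resolution == 0:
        return curve

    def interp(qq: np.ndarray) -> np.ndarray:
        return np.interp(qq, curve.q, curve.r)

    r_sm = _smear_model(interp, curve.q, resolution * curve.q)
    return ReflectivityCurve(curve.q, r_sm, curve.dr, curve.dq)
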