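"""Assumption-light ("model-free") analysis of reflectivity data.

Two stages, run before any parametric slab fitting:

1. **Overall layer extent D_max.**  In the kinematic regime,
   q⁴R(q)/16π² = |∫ ρ′(z) e^{iqz} dz|², which equals the cosine
   transform of the autocorrelation Γ(u) of the SLD gradient — a
   function supported on |u| ≤ D_max.  For each candidate D the data are
   fitted with a ridge-regularized linear expansion of Γ on [0, D]
   (an indirect transform), and D_max is taken at the onset of the
   fit-quality plateau: the smallest D beyond which the misfit improves
   by less than 1% per Å.  D_max includes the native oxide layer.

2. **Free-form profiles.**  The interfacial region [0, D_max] is divided
   into bins, each carrying a material SLD and a solvent volume
   fraction.  Simulated annealing minimizes the summed χ² of all
   contrasts (each bin rendered as a slab whose effective SLD mixes the
   bin material with that contrast's solvent) plus a smoothness penalty.
   Because the material/solvent split must explain every contrast at
   once, two or more contrasts largely lift the degeneracy of the split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .io import ContrastSet
from .reflectivity import abeles, critical_q, _smear_model

__all__ = [
    "FreeFormProfile",
    "DmaxScan",
    "estimate_dmax",
    "anneal_profiles",
    "profile_reflectivity",
]

log = logging.getLogger("memstack")

#: SLD (1e-6 Å⁻²) of the silicon fronting used to render free-form bins.
_SI_SLD = 2.07


@dataclass(frozen=True)
class FreeFormProfile:
    """Binned model-free profile over [0, d_max]."""

    d_max: float
    sld_bins: np.ndarray  # material SLD per bin, 1e-6 Å⁻²
    solvent_bins: np.ndarray  # solvent volume fraction per bin, [0, 1]
    chi2: float = np.nan
    seed: int | None = None

    def __post_init__(self) -> None:
        s = np.asarray(self.sld_bins, float)
        phi = np.asarray(self.solvent_bins, float)
        object.__setattr__(self, "sld_bins", s)
        object.__setattr__(self, "solvent_bins", phi)
        if len(s) != len(phi) or len(s) < 5:
            raise ValueError("need >= 5 equal-length bins")
        if np.any((phi < 0) | (phi > 1)):
            raise ValueError("solvent fractions outside [0, 1]")

    @property
    def n_bins(self) -> int:
        return len(self.sld_bins)

    @property
    def z_centers(self) -> np.ndarray:
        w = self.d_max / self.n_bins
        return (np.arange(self.n_bins) + 0.5) * w

    def effective_sld(self, solvent_sld: float) -> np.ndarray:
        phi = self.solvent_bins
        return (1.0 - phi) * self.sld_bins + phi * solvent_sld


@dataclass(frozen=True)
class DmaxScan:
    """Result of the D_max scan: the estimate plus the score curve."""

    d_max: float
    candidates: np.ndarray
    scores: np.ndarray
    plateau_found: bool
    #: the smallest candidate already fits: no resolvable layer structure
    degenerate: bool = False


def _gamma_basis(q: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Cosine transforms of Γ-histogram bins: |F(q)|² = Σ_k c_k B_k(q).

    B[i, k] = 2·(sin(q·u_hi) − sin(q·u_lo))/q for the bin [u_lo, u_hi]
    (Γ is even, so bins cover u ≥ 0 only).
    """
    lo, hi = edges[:-1], edges[1:]
    return 2.0 * (np.sin(q[:, None] * hi) - np.sin(q[:, None] * lo)) / q[:, None]


def _ift_misfit(
    curves: ContrastSet,
    d: float,
    du: float = 2.0,
    q_min: float = 0.04,
    ridge: float = 0.05,
    resolution: float = 0.10,
) -> float:
    """Misfit of the regularized indirect-transform fit at support D.

    Per contrast, the data are fitted with the Fresnel-normalized
    ("master formula") kinematic model
    R(q) ≈ R_F(q)·|Φ(q′)|² = R_F(q)·Σ c_k B_k(q′)/Δρ², where
    q′ = √(q² − q_c²) corrects for refraction and R_F is the exact
    two-medium Fresnel curve of the fronting/backing pair.  The model —
    resolution-smeared with the same quadrature the engine uses — is
    linear in the Γ-histogram coefficients c_k, so the fit is a
    deterministic ridge-regularized least squares.
    """
    total, n_total = 0.0, 0
    n_bins = max(3, int(np.ceil(d / du)))
    edges = np.linspace(0.0, d, n_bins + 1)
    from .reflectivity import _GW, _GX, fresnel  # smearing quadrature

    for curve, solvent in curves:
        qc = critical_q(_SI_SLD, solvent.sld)
        sel = curve.q >= max(q_min, 1.5 * qc)
        q = curve.q[sel]
        r = curve.r[sel]
        dr = curve.dr[sel] if curve.dr is not None else 0.03 * r
        # 1% relative floor: the master-formula model is itself only
        # accurate to about that level, so tighter errors would score
        # model inadequacy instead of support mismatch
        sigma = np.maximum(dr, 0.01 * np.abs(r))
        qc_sq = 16.0 * np.pi * (solvent.sld - _SI_SLD) * 1e-6
        drho_sq = (solvent.sld - _SI_SLD) ** 2  # (1e-6 Å⁻²)² units

        def basis_at(qq: np.ndarray) -> np.ndarray:
            qp = np.sqrt(np.maximum(qq**2 - qc_sq, 1e-10))
            rf = fresnel(_SI_SLD, solvent.sld, qq)
            return _gamma_basis(qp, edges) * (rf / drho_sq)[:, None]

        if resolution:
            sig_q = resolution * q / 2.35482
            nodes = q[:, None] + sig_q[:, None] * _GX[None, :]
            nodes = np.clip(nodes, 1e-6, None)
            bn = basis_at(nodes.ravel())  # (nq*ng, K)
            b = np.einsum(
                "g,qgk->qk", _GW, bn.reshape(len(q), len(_GX), n_bins)
            )
        else:
            b = basis_at(q)
        a = b / sigma[:, None]
        rhs = r / sigma
        # ridge on second differences keeps Γ smooth without biasing D
        d2 = np.diff(np.eye(n_bins), n=2, axis=0)
        lam = ridge * np.sqrt(len(q))
        a_full = np.vstack([a, lam * d2])
        rhs_full = np.concatenate([rhs, np.zeros(d2.shape[0])])
        coef, *_ = np.linalg.lstsq(a_full, rhs_full, rcond=None)
        total += float(np.sum((a @ coef - rhs) ** 2))
        n_total += len(q)
    return total, n_total


def estimate_dmax(
    curves: ContrastSet,
    search: tuple[float, float] = (30.0, 100.0),
    step: float = 1.0,
    plateau_tol: float = 0.01,
) -> DmaxScan:
    """Overall interfacial layer thickness from an indirect-transform scan.

    Scans candidate supports D over ``search`` and returns the plateau
    onset: the smallest D where either the relative misfit improvement
    drops below ``plateau_tol`` per Å and stays there, or the fit is
    already essentially perfect (χ²/N < 0.05, the noiseless-data limit
    where relative improvements stop being meaningful).  If no plateau
    exists in range, the range maximum is returned with
    ``plateau_found = False``.
    """
    q_max = max(c.q.max() for c in curves.curves)
    if q_max < 0.15:
        log.warning("q_max = %.3g < ~0.2: D_max resolution is poor", q_max)
    cand = np.arange(search[0], search[1] + 0.5 * step, step)
    pairs = [_ift_misfit(curves, d) for d in cand]
    scores = np.array([p[0] for p in pairs])
    n_points = pairs[0][1]
    # relative improvement per Å between consecutive candidates
    with np.errstate(divide="ignore", invalid="ignore"):
        impr = -np.diff(scores) / scores[:-1] / step
    plateau = impr < plateau_tol
    solved = scores < 0.05 * n_points
    for i in range(len(plateau)):
        if solved[i]:
            if i == 0:
                log.warning(
                    "data fitted with no layer support: no resolvable "
                    "interfacial structure"
                )
            return DmaxScan(float(cand[i]), cand, scores, True, i == 0)
        # the improvement plateau must persist over the rest of the scan
        # (tolerating isolated noise-driven dips)
        if plateau[i] and plateau[i:].mean() > 0.8:
            return DmaxScan(float(cand[i]), cand, scores, True)
    log.warning("no fit-quality plateau in range %s", search)
    return DmaxScan(float(cand[-1]), cand, scores, False)


def profile_reflectivity(
    profile: FreeFormProfile,
    solvent_sld: float,
    q: np.ndarray,
    resolution: float = 0.10,
    fronting_sld: float = _SI_SLD,
) -> np.ndarray:
    """Render the binned profile as slabs and compute smeared R(q)."""
    w = profile.d_max / profile.n_bins
    d = np.full(profile.n_bins, w)
    sld = profile.effective_sld(solvent_sld)
    sig = np.full(profile.n_bins + 1, w / 4.0)  # mild inter-bin blending

    def model(qq):
        return abeles(qq, d, sld, sig, fronting_sld, solvent_sld)

    if resolution:
        return _smear_model(model, np.asarray(q, float), resolution * q)
    return model(np.asarray(q, float))


_SLD_RANGE = (-0.7, 7.0)


class _ProfileObjective:
    """Fast summed-χ² evaluator for a binned profile over a contrast set.

    Pre-computes the smearing quadrature node grids per curve so that one
    evaluation is three recursion calls plus dot products.
    """

    def __init__(
        self,
        curves: ContrastSet,
        d_max: float,
        n_bins: int,
        resolution: float,
        lambda_s: float,
    ) -> None:
        from .reflectivity import _GW, _GX

        self.d = np.full(n_bins, d_max / n_bins)
        self.sig = np.full(n_bins + 1, (d_max / n_bins) / 4.0)
        self.lambda_s = lambda_s
        self.n_bins = n_bins
        self.gw = _GW
        self.terms = []
        for curve, solvent in curves:
            q = curve.q
            if resolution:
                sq = resolution * q / 2.35482
                nodes = np.clip(
                    q[:, None] + sq[:, None] * _GX[None, :], 1e-6, None
                )
            else:
                nodes = q[:, None]
            dr = curve.dr if curve.dr is not None else 0.03 * curve.r
            self.terms.append((nodes, curve.r, dr, solvent.sld))

    def residuals(self, rho: np.ndarray, phi: np.ndarray) -> np.ndarray:
        out = []
        for nodes, r_data, dr, solvent_sld in self.terms:
            eff = (1.0 - phi) * rho + phi * solvent_sld
            r = abeles(
                nodes.ravel(), self.d, eff, self.sig, _SI_SLD, solvent_sld
            ).reshape(nodes.shape)
            r_sm = r @ self.gw if nodes.shape[1] > 1 else r[:, 0]
            out.append((r_sm - r_data) / dr)
        # smoothness as pseudo-residuals so the polish sees one system
        lam = np.sqrt(self.lambda_s)
        out.append(lam * np.diff(rho))
        out.append(lam * 5.0 * np.diff(phi))
        return np.concatenate(out)

    def __call__(self, rho: np.ndarray, phi: np.ndarray) -> float:
        return float(np.sum(self.residuals(rho, phi) ** 2))


def anneal_profiles(
    curves: ContrastSet,
    d_max: float,
    n_bins: int = 13,
    seed: int = 0,
    sweeps: int = 200,
    t_start: float | None = None,
    cooling: float = 0.95,
    lambda_s: float = 2.0,
    resolution: float = 0.10,
    polish: bool = True,
    max_restarts: int = 3,
    accept_reduced_chi2: float = 5.0,
) -> FreeFormProfile:
    """Free-form (SLD, solvent-fraction) profile by simulated annealing.

    Geometric cooling (T ← T·``cooling`` per sweep); each sweep proposes
    one Gaussian perturbation of (ρ, φ) per bin.  ``lambda_s`` weights a
    first-difference smoothness penalty (φ differences weighted ×5 since
    φ spans only [0, 1]).  A deterministic trust-region least-squares
    polish of the annealed state (on by default) removes residual
    annealing scatter.  A run stranded in a poor local minimum
    (χ²/N > ``accept_reduced_chi2``) is restarted with a derived seed,
    up to ``max_restarts`` attempts; the best attempt is returned.
    Seeded and reproducible.

    With a single contrast the material/solvent split is degenerate (a
    warning is logged); two or three contrasts are recommended.
    """
    if d_max <= 0:
        raise ValueError("d_max must be positive")
    if len(curves) < 2:
        log.warning(
            "single-contrast model-free fit: SLD/solvent split is degenerate"
        )
    cost = _ProfileObjective(curves, d_max, n_bins, resolution, lambda_s)
    n_data = sum(len(c) for c in curves.curves)
    best_prof: FreeFormProfile | None = None
    for attempt in range(max(1, max_restarts)):
        prof = _anneal_once(
            curves, cost, d_max, n_bins, seed + 7919 * attempt, sweeps,
            t_start, cooling, polish,
        )
        if best_prof is None or prof.chi2 < best_prof.chi2:
            best_prof = prof
        if best_prof.chi2 / n_data <= accept_reduced_chi2:
            break
        log.info(
            "annealing attempt %d stranded (chi2/N = %.1f); restarting",
            attempt + 1,
            prof.chi2 / n_data,
        )
    return FreeFormProfile(
        best_prof.d_max,
        best_prof.sld_bins,
        best_prof.solvent_bins,
        chi2=best_prof.chi2,
        seed=seed,
    )


def _anneal_once(
    curves: ContrastSet,
    cost: "_ProfileObjective",
    d_max: float,
    n_bins: int,
    seed: int,
    sweeps: int,
    t_start: float | None,
    cooling: float,
    polish: bool,
) -> FreeFormProfile:
    rng = np.random.default_rng(seed)
    solvent_mean = float(np.mean([s.sld for s in curves.solvents]))
    # neutral start: silicon-like near the substrate blending to solvent
    rho = np.linspace(_SI_SLD, solvent_mean, n_bins)
    phi = np.full(n_bins, 0.3)

    current = cost(rho, phi)
    n_data = sum(len(c) for c in curves.curves)
    temp = 2.0 * n_data if t_start is None else t_start
    sigma_rho, sigma_phi = 0.5, 0.10
    best = (rho.copy(), phi.copy(), current)
    for _ in range(sweeps):
        for k in range(n_bins):
            rho_new, phi_new = rho.copy(), phi.copy()
            rho_new[k] = np.clip(rho[k] + rng.normal(0, sigma_rho), *_SLD_RANGE)
            phi_new[k] = np.clip(phi[k] + rng.normal(0, sigma_phi), 0, 1)
            trial = cost(rho_new, phi_new)
            if trial < current or rng.random() < np.exp(
                -(trial - current) / temp
            ):
                rho, phi, current = rho_new, phi_new, trial
                if current < best[2]:
                    best = (rho.copy(), phi.copy(), current)
        temp *= cooling
    rho, phi, current = best

    if polish:
        x0 = np.concatenate([rho, phi])
        lower = [_SLD_RANGE[0]] * n_bins + [0.0] * n_bins
        upper = [_SLD_RANGE[1]] * n_bins + [1.0] * n_bins
        res = optimize.least_squares(
            lambda x: cost.residuals(x[:n_bins], x[n_bins:]),
            x0,
            bounds=(lower, upper),
            method="trf",
            max_nfev=150 * 2 * n_bins,
        )
        f = float(np.sum(res.fun**2))
        if f < current:
            rho, phi, current = res.x[:n_bins], res.x[n_bins:], f

    return FreeFormProfile(
        d_max, rho, np.clip(phi, 0, 1), chi2=current, seed=seed
    )
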