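"""Engine checks, including two independent oracles:

* the closed-form Fresnel curve (zero-slab limit), and
* a transfer-matrix (Abeles 2x2 matrix product) implementation written
  here from scratch, against which the recursion must agree to 1e-8
  relative.
"""

import numpy as np
import pytest

from memstack.membrane_model import Slab, SlabStack, build_stack, effective_slabs, interface_roughnesses
from memstack.reflectivity import (
    Instrument,
    InvalidModelError,
    ReflectivityCurve,
    abeles,
    critical_q,
    fresnel,
    qz,
    reflectivity,
    smear,
)
from memstack.sld_core import MATERIALS, Material


def transfer_matrix_reflectivity(q, thickness, sld, roughness, rho_f, rho_b):
    """Independent 2x2 matrix-product oracle (scalar, per q point)."""
    out = np.empty(len(q))
    rho = np.concatenate(([rho_f], sld, [rho_b])) * 1e-6
    d = np.concatenate(([0.0], thickness))
    for iq, qi in enumerate(q):
        k = np.sqrt(
            (qi / 2.0) ** 2 - 4.0 * np.pi * (rho - rho[0]) + 0j
        )
        m = np.eye(2, dtype=complex)
        for j in range(len(rho) - 1):
            r = (k[j] - k[j + 1]) / (k[j] + k[j + 1]) * np.exp(
                -2.0 * k[j] * k[j + 1] * roughness[j] ** 2
            )
            beta = 1j * k[j] * d[j]
            layer = np.array(
                [
                    [np.exp(beta), r * np.exp(beta)],
                    [r * np.exp(-beta), np.exp(-beta)],
                ]
            )
            m = m @ layer
        out[iq] = abs(m[1, 0] / m[0, 0]) ** 2
    return np.minimum(out, 1.0)


class TestQz:
    def test_direct_formula(self):
        alpha = np.degrees(np.arcsin(0.01))
        assert qz(alpha, 10.0) == pytest.approx(0.012566, abs=1e-6)

    def test_small_angle_limit(self):
        assert qz(1e-6, 10.0) == pytest.approx(0.0, abs=1e-6)

    def test_high_q_wavelength(self):
        """The short 5 A wavelength reaches the 0.25 A^-1 upper limit at
        sin(alpha) ~ 0.0995."""
        alpha = np.degrees(np.arcsin(0.0995))
        assert qz(alpha, 5.0) == pytest.approx(0.2500, abs=2e-4)

    def test_domain(self):
        with pytest.raises(ValueError):
            qz(-1.0, 10.0)
        with pytest.raises(ValueError):
            qz(1.0, 0.0)


class TestFresnel:
    def test_zero_contrast(self, q_grid):
        assert fresnel(2.07, 2.07, q_grid) == pytest.approx(0.0)

    def test_critical_edge_si_d2o(self, q_grid):
        qc = critical_q(2.07, 6.36)
        assert qc == pytest.approx(0.0147, abs=2e-4)
        r = fresnel(2.07, 6.36, np.linspace(0.002, qc * 0.98, 20))
        assert np.all(r >= 1.0 - 1e-9)

    def test_asymptotic_q4_law(self):
        """At large q, R ~ (4 pi drho / q^2)^2."""
        q = np.array([0.5])
        drho = (6.36 - 2.07) * 1e-6
        expected = (4 * np.pi * drho) ** 2 / q[0] ** 4
        assert fresnel(2.07, 6.36, q)[0] == pytest.approx(expected, rel=1e-3)

    def test_matches_zero_slab_recursion(self, q_grid, si, d2o):
        stack = SlabStack(si, (), d2o)
        r_rec = reflectivity(stack, d2o, q_grid)
        r_fr = fresnel(si, d2o, q_grid)
        assert np.max(np.abs(r_rec - r_fr)) < 1e-10


class TestRecursion:
    def test_no_contrast_no_reflection(self, q_grid, d2o):
        stack = SlabStack(d2o, (), d2o)
        assert np.max(reflectivity(stack, d2o, q_grid)) == pytest.approx(0.0)

    def test_energy_bound(self, ternary, q_grid):
        for name in ("h2o", "d2o", "4mw"):
            r = reflectivity(ternary.stack, MATERIALS[name], q_grid)
            assert np.all((r >= 0.0) & (r <= 1.0))

    def test_total_reflection_below_critical_edge(self, ternary, d2o):
        q = np.linspace(0.002, 0.0135, 30)
        r = reflectivity(ternary.stack, d2o, q)
        assert np.all(r >= 1.0 - 1e-9)

    def test_null_slab_is_invisible(self, q_grid, si, d2o):
        base = SlabStack(si, (Slab("a", 20.0, 3.0, 0.0, 0.0),), d2o)
        padded = SlabStack(
            si,
            (Slab("z", 0.0, 1.0, 0.0, 0.0), Slab("a", 20.0, 3.0, 0.0, 0.0)),
            d2o,
        )
        r1 = reflectivity(base, d2o, q_grid)
        r2 = reflectivity(padded, d2o, q_grid)
        assert np.max(np.abs(r1 - r2)) < 1e-12

    def test_slab_matching_neighbours_is_invisible(self, q_grid, si, d2o):
        matched = SlabStack(si, (Slab("ghost", 25.0, d2o.sld, 0.0, 0.0),), d2o)
        r = reflectivity(matched, d2o, q_grid)
        r_fresnel = fresnel(si, d2o, q_grid)
        assert np.max(np.abs(r - r_fresnel)) < 1e-12

    def test_roughness_zero_limit_and_damping(self, q_grid, si, d2o):
        sharp = SlabStack(si, (Slab("f", 30.0, 0.0, 0.0, 0.0),), d2o)
        vanishing = SlabStack(si, (Slab("f", 30.0, 0.0, 0.0, 1e-9),), d2o)
        r0 = reflectivity(sharp, d2o, q_grid)
        r1 = reflectivity(vanishing, d2o, q_grid)
        assert np.max(np.abs(r0 - r1)) < 1e-10
        # increasing roughness damps the high-q tail monotonically
        high_q = q_grid[q_grid > 0.1]
        tails = []
        for sigma in (0.0, 2.0, 4.0):
            s = SlabStack(
                si,
                (Slab("f", 30.0, 0.0, 0.0, sigma),),
                d2o,
                fronting_roughness=sigma,
                backing_roughness=sigma,
            )
            tails.append(reflectivity(s, d2o, high_q).sum())
        assert tails[0] > tails[1] > tails[2]

    def test_kiessig_fringes_of_65A_film(self, si, h2o):
        """Fringe minima of a 65 A film are spaced ~2 pi / 65."""
        from scipy.signal import argrelmin

        stack = SlabStack(
            si, (Slab("film", 65.0, 4.0, 0.0, 0.0, apply_coverage=False),), h2o
        )
        q = np.linspace(0.02, 0.25, 6000)
        r = reflectivity(stack, h2o, q)
        minima = q[argrelmin(r)[0]]
        spacing = np.diff(minima)
        assert np.all(np.abs(spacing - 2 * np.pi / 65.0) < 0.004)

    def test_transfer_matrix_oracle_on_ternary(self, ternary, d2o):
        """Parratt recursion vs independent matrix-product formulation."""
        q = np.geomspace(0.01, 0.25, 60)
        resolved = effective_slabs(ternary.stack, d2o)
        d = np.array([s.thickness for s in resolved])
        sld = np.array([s.sld for s in resolved])
        sig = np.array(interface_roughnesses(ternary.stack))
        r_rec = abeles(q, d, sld, sig, 2.07, d2o.sld)
        r_tm = transfer_matrix_reflectivity(q, d, sld, sig, 2.07, d2o.sld)
        assert np.max(np.abs(r_rec - r_tm) / np.maximum(r_tm, 1e-12)) < 1e-8

    def test_micro_slicing_agrees_with_nevot_croce(self, ternary, d2o):
        """For roughness well below the slab thicknesses the explicit
        sliced-profile rendering matches the Nevot-Croce factors."""
        q = np.geomspace(0.01, 0.25, 60)
        r_nc = reflectivity(ternary.stack, d2o, q)
        r_ms = reflectivity(ternary.stack, d2o, q, micro_slice=True)
        rel = np.abs(r_ms - r_nc) / np.maximum(r_nc, 1e-12)
        assert rel.max() < 0.02

    def test_invalid_model(self, q_grid):
        with pytest.raises(InvalidModelError):
            abeles(q_grid, [-1.0], [1.0], [0.0, 0.0], 2.07, 6.36)
        with pytest.raises(ValueError):
            Slab("bad", 10.0, 1.0, 0.0, -1.0)


class TestSmearing:
    def test_zero_resolution_identity(self, q_grid):
        curve = ReflectivityCurve(q_grid, np.exp(-q_grid * 10))
        assert smear(curve, 0.0) is curve

    def test_constant_curve_unchanged(self, q_grid):
        curve = ReflectivityCurve(q_grid, np.full_like(q_grid, 0.37))
        smeared = smear(curve, 0.1)
        assert np.max(np.abs(smeared.r - 0.37)) < 1e-12

    def test_fringe_positions_stable_contrast_reduced(self, si, h2o):
        from scipy.signal import argrelmin

        stack = SlabStack(
            si, (Slab("film", 65.0, 4.0, 0.0, 0.0, apply_coverage=False),), h2o
        )
        q = np.linspace(0.03, 0.25, 4000)
        r_sharp = reflectivity(stack, h2o, q)
        r_sm = reflectivity(stack, h2o, q, resolution=0.10)
        m_sharp = q[argrelmin(r_sharp)[0]]
        m_sm = q[argrelmin(r_sm)[0]]
        # minima positions shift by < 2%
        for ms in m_sm:
            assert np.min(np.abs(m_sharp - ms)) / ms < 0.02
        # fringe contrast is reduced
        assert r_sm.min() > r_sharp.min()

    def test_per_point_dq_column_honoured(self, ternary, d2o, q_grid):
        dq = 0.10 * q_grid
        r_dq = reflectivity(ternary.stack, d2o, q_grid, dq=dq)
        r_const = reflectivity(ternary.stack, d2o, q_grid, resolution=0.10)
        assert np.allclose(r_dq, r_const, rtol=1e-12)


class TestInstrument:
    def test_invariants(self):
        with pytest.raises(ValueError):
            Instrument(resolution=0.0)
        inst = Instrument()
        assert inst.q_max == 0.25
        assert inst.wavelengths == (10.0, 5.0)


class TestCurveInvariants:
    def test_shape_checks(self, q_grid):
        with pytest.raises(ValueError):
            ReflectivityCurve(q_grid, q_grid[:-1])
        with pytest.raises(ValueError):
            ReflectivityCurve(q_grid[::-1], np.ones_like(q_grid))
        with pytest.raises(ValueError):
            ReflectivityCurve(
                q_grid, np.ones_like(q_grid), dr=np.ones(3)
            )
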