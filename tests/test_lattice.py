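"""Lattice Monte Carlo: conservation, detailed balance against an
exhaustive Boltzmann oracle, contact fractions and g(r) against
brute-force pair enumeration."""

import itertools
from collections import Counter

import numpy as np
import pytest

from memstack.lattice import (
    SPECIES,
    LatticeState,
    contact_fractions,
    default_energies,
    lattice_to_text,
    radial_distribution,
    random_lattice,
    random_mixing_contact,
    run_mc,
)

_IDX = {name: i for i, name in enumerate(SPECIES)}


def grid_from_string(rows):
    lookup = {"P": 0, "S": 1, "G": 2}
    return np.array([[lookup[c] for c in row] for row in rows], dtype=np.int8)


def brute_force_pair_counts(grid, a, b):
    """O(N^2) ordered pair counts per squared periodic distance."""
    size = grid.shape[0]
    counts = Counter()
    sites = [(i, j) for i in range(size) for j in range(size)]
    for (i1, j1) in sites:
        for (i2, j2) in sites:
            if (i1, j1) == (i2, j2):
                continue
            if grid[i1, j1] == a and grid[i2, j2] == b:
                di = min(abs(i1 - i2), size - abs(i1 - i2))
                dj = min(abs(j1 - j2), size - abs(j1 - j2))
                counts[di * di + dj * dj] += 1
    return counts


def lattice_energy(grid, energies):
    size = grid.shape[0]
    e = 0.0
    for i in range(size):
        for j in range(size):
            e += energies[grid[i, j], grid[(i + 1) % size, j]]
            e += energies[grid[i, j], grid[i, (j + 1) % size]]
    return e


def sg_bond_count(grid):
    size = grid.shape[0]
    n = 0
    for i in range(size):
        for j in range(size):
            a = grid[i, j]
            for b in (grid[(i + 1) % size, j], grid[i, (j + 1) % size]):
                if {int(a), int(b)} == {1, 2}:
                    n += 1
    return n


class TestRunMc:
    def test_composition_conserved(self):
        state = random_lattice(16, seed=3)
        before = state.counts()
        final, energy, _ = run_mc(state, 30, seed=3)
        assert final.counts() == before
        assert len(energy) == 30

    def test_zero_energies_full_acceptance_random_mixing(self):
        state = random_lattice(24, seed=1, energies=np.zeros((3, 3)))
        final, _, meta = run_mc(state, 60, seed=1)
        assert meta["acceptance"] == pytest.approx(1.0)
        # random-mixing contact statistics: closed form 1 - 0.8^4
        frac = contact_fractions(final)
        assert frac[("SITO", "GLUCER")] == pytest.approx(
            random_mixing_contact(0.2), abs=0.06
        )

    def test_seeded_reproducibility(self):
        state = random_lattice(12, seed=9)
        f1, e1, _ = run_mc(state, 20, seed=9)
        f2, e2, _ = run_mc(state, 20, seed=9)
        assert np.array_equal(f1.grid, f2.grid)
        assert np.array_equal(e1, e2)

    def test_energy_decreases_with_attraction(self):
        state = random_lattice(20, seed=4)
        _, energy, _ = run_mc(state, 150, seed=4)
        assert energy[-1] < energy[0]

    def test_boltzmann_distribution_on_3x3_oracle(self):
        """Long-run sampled sterol-glycolipid bond counts on a 3x3 grid
        match the exhaustive Boltzmann enumeration (chi^2 GOF p > 0.01)."""
        from scipy.stats import chisquare

        e = np.zeros((3, 3))
        e[1, 2] = e[2, 1] = -1.0
        labels = [0] * 5 + [1] * 2 + [2] * 2
        temp = 1.0
        # exhaustive enumeration over all distinguishable configurations
        weights = Counter()
        seen = set()
        for perm in itertools.permutations(labels):
            if perm in seen:
                continue
            seen.add(perm)
            grid = np.array(perm, dtype=np.int8).reshape(3, 3)
            w = np.exp(-lattice_energy(grid, e) / temp)
            weights[sg_bond_count(grid)] += w
        total = sum(weights.values())
        probs = {k: v / total for k, v in weights.items()}

        state = LatticeState(
            grid=np.array(labels, dtype=np.int8).reshape(3, 3),
            energies=e,
            temperature=temp,
        )
        final, _, meta = run_mc(state, 2000, seed=11, record_every=1)
        observed = Counter()
        for snap in meta["snapshots"][200:]:
            observed[sg_bond_count(snap)] += 1
        n = sum(observed.values())
        classes = [k for k, p in probs.items() if p * n >= 5]
        obs = np.array([observed.get(k, 0) for k in classes], dtype=float)
        exp = np.array([probs[k] * n for k in classes])
        # renormalize over the retained classes for the GOF test
        exp *= obs.sum() / exp.sum()
        stat, p = chisquare(obs, exp)
        assert p > 0.01

    def test_contact_fraction_monotone_in_coupling(self):
        """Stronger sterol-glycolipid attraction yields more S-G contacts
        at fixed sweeps."""
        fracs = []
        for strength in (0.0, -1.5, -3.0):
            e = np.zeros((3, 3))
            e[1, 2] = e[2, 1] = strength
            state = random_lattice(20, seed=6, energies=e)
            final, _, _ = run_mc(state, 120, seed=6)
            fracs.append(contact_fractions(final)[("SITO", "GLUCER")])
        assert fracs[0] < fracs[1] < fracs[2]


class TestContactFractions:
    def test_single_species(self):
        state = LatticeState(np.zeros((6, 6), dtype=np.int8), np.zeros((3, 3)))
        frac = contact_fractions(state)
        assert frac[("PLPC", "PLPC")] == 1.0
        assert frac[("SITO", "PLPC")] is None  # species absent

    def test_checkerboard(self):
        grid = np.indices((6, 6)).sum(axis=0) % 2
        state = LatticeState(grid.astype(np.int8), np.zeros((3, 3)))
        frac = contact_fractions(state)
        assert frac[("PLPC", "SITO")] == 1.0
        assert frac[("PLPC", "PLPC")] == 0.0
        assert frac[("SITO", "SITO")] == 0.0

    def test_random_mixing_closed_form(self):
        """P(>=1 glycolipid among 4 neighbours) = 1 - 0.8^4 = 0.5904 for a
        random 60/20/20 lattice, within sampling error."""
        state = random_lattice(60, seed=123)
        frac = contact_fractions(state)
        assert frac[("SITO", "GLUCER")] == pytest.approx(0.5904, abs=0.04)


class TestRadialDistribution:
    def test_random_mixture_is_uniform(self):
        state = random_lattice(48, seed=7)
        for pair in [("PLPC", "PLPC"), ("SITO", "GLUCER"), ("GLUCER", "GLUCER")]:
            rdf = radial_distribution(state, pair, r_max=10.0)
            assert np.all(np.abs(rdf.g - 1.0) < 0.35)
            # large-r normalization is tight
            assert abs(rdf.g[rdf.r > 4].mean() - 1.0) < 0.05

    def test_two_block_demixed_configuration(self):
        rows_top = ["S" * 12] * 6
        rows_bottom = ["G" * 12] * 6
        state = LatticeState(
            grid_from_string(rows_top + rows_bottom), np.zeros((3, 3))
        )
        g_self = radial_distribution(state, ("SITO", "SITO"))
        g_cross = radial_distribution(state, ("SITO", "GLUCER"))
        assert g_self.g[0] > 1.0
        assert g_cross.g[0] < 1.0

    def test_counts_match_brute_force_enumeration(self):
        state = random_lattice(10, seed=2)
        for pair in [("PLPC", "SITO"), ("GLUCER", "GLUCER")]:
            a, b = _IDX[pair[0]], _IDX[pair[1]]
            brute = brute_force_pair_counts(state.grid, a, b)
            rdf = radial_distribution(state, pair)
            n = state.size**2
            counts = {
                name: int(np.sum(state.grid == i)) for name, i in _IDX.items()
            }
            na, nb = counts[pair[0]], counts[pair[1]]
            exp_pair = (
                na * (na - 1) if a == b else na * nb
            ) / (n * (n - 1))
            # reconstruct observed counts from g and compare exactly
            dx = np.arange(10)
            dx = np.minimum(dx, 10 - dx)
            d2 = dx[:, None] ** 2 + dx[None, :] ** 2
            for r, g in zip(rdf.r, rdf.g):
                u = int(round(r * r))
                m_r = int((d2 == u).sum()) * n
                observed = g * m_r * exp_pair
                assert observed == pytest.approx(brute.get(u, 0), abs=1e-6)

    def test_r_max_clipped_to_half_box(self):
        state = random_lattice(12, seed=0)
        rdf = radial_distribution(state, ("PLPC", "PLPC"), r_max=100.0)
        assert rdf.r.max() <= 6.0


class TestLatticeHousekeeping:
    def test_energy_matrix_validation(self):
        with pytest.raises(ValueError):
            LatticeState(
                np.zeros((4, 4), dtype=np.int8),
                np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 0.0], [0.0, 0.0, 0.0]]),
            )

    def test_default_energy_ordering(self):
        e = default_energies()
        assert e[1, 2] < e[1, 1] < e[1, 0] <= 0.0
        assert np.allclose(e, e.T)

    def test_text_rendering(self):
        state = LatticeState(
            grid_from_string(["PS", "GP"]), np.zeros((3, 3))
        )
        assert lattice_to_text(state) == "PS\nGP"

    def test_composition_fractions_validated(self):
        with pytest.raises(ValueError):
            random_lattice(10, {"PLPC": 0.5, "SITO": 0.2})
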