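"""Lattice Monte Carlo model of lateral lipid demixing.

A minimal, property-level model of in-plane lipid organization: each site
of an L×L periodic square lattice holds one molecule of one species
(PLPC matrix lipid, sitosterol, glucosylceramide), and a symmetric
pairwise contact-energy matrix E_ij (kcal/mol, nearest neighbours only)
drives demixing through composition-conserving Kawasaki dynamics —
Metropolis-accepted swaps of two randomly chosen sites.  Temperature is
absorbed into the energy scale: the acceptance rule uses exp(−ΔE/T) with
a single dimensionless coupling T, because only the *ordering* of the
contact energies (sterol–glycolipid strongest, then sterol–sterol, then
sterol–matrix) is defensible input; absolute docking energies are not.

Observables are the ones used to characterize lateral organization:
nearest-neighbour contact fractions (the probability that a molecule of
species i touches at least one j) and the two-dimensional radial
distribution function g_ij(r), normalized so that random mixing gives
g = 1 at every distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

__all__ = [
    "SPECIES",
    "LatticeState",
    "RDF",
    "default_energies",
    "random_lattice",
    "run_mc",
    "contact_fractions",
    "random_mixing_contact",
    "radial_distribution",
    "lattice_to_text",
]

#: Species labels in grid-encoding order.
SPECIES = ("PLPC", "SITO", "GLUCER")
_INDEX = {name: i for i, name in enumerate(SPECIES)}


def default_energies(
    e_sito_glucer: float = -4.0,
    e_sito_sito: float = -3.0,
    e_sito_plpc: float = -2.0,
    e_glucer_glucer: float = -2.5,
) -> np.ndarray:
    """Illustrative contact-energy matrix (kcal/mol).

    Only the ordering E(SITO,GLUCER) < E(SITO,SITO) < E(SITO,PLPC) ≤ 0 is
    meaningful: it encodes the docking-derived preference of sitosterol
    for glucosylceramide over itself over the matrix lipid.  A moderate
    glycolipid self-attraction is included so that glucosylceramide both
    co-clusters with the sterol and self-associates (without it a pure
    sterol-glycolipid attraction produces alternating, checkerboard-like
    contacts instead of mixed clusters).  The default magnitudes are
    illustrative placeholders, not measured values; users supply their
    own matrix for anything quantitative.
    """
    e = np.zeros((3, 3))
    e[_INDEX["SITO"], _INDEX["GLUCER"]] = e_sito_glucer
    e[_INDEX["SITO"], _INDEX["SITO"]] = e_sito_sito
    e[_INDEX["SITO"], _INDEX["PLPC"]] = e_sito_plpc
    e[_INDEX["GLUCER"], _INDEX["GLUCER"]] = e_glucer_glucer
    return np.minimum(e, e.T)  # symmetrize (entries are <= 0)


@dataclass(frozen=True)
class LatticeState:
    """Occupancy grid + contact energies + temperature factor."""

    grid: np.ndarray  # (L, L) int8 species indices
    energies: np.ndarray  # (3, 3) symmetric, kcal/mol
    temperature: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        g = np.ascontiguousarray(self.grid, dtype=np.int8)
        object.__setattr__(self, "grid", g)
        e = np.asarray(self.energies, dtype=float)
        if e.shape != (3, 3) or not np.allclose(e, e.T):
            raise ValueError("energy matrix must be 3x3 symmetric")
        object.__setattr__(self, "energies", e)
        if g.ndim != 2 or g.shape[0] != g.shape[1]:
            raise ValueError("grid must be square")
        if self.temperature <= 0:
            raise ValueError("temperature factor must be positive")

    @property
    def size(self) -> int:
        return self.grid.shape[0]

    def counts(self) -> dict[str, int]:
        return {
            name: int(np.sum(self.grid == i)) for name, i in _INDEX.items()
        }

    def total_energy(self) -> float:
        return float(_total_energy(self.grid, self.energies))


@dataclass(frozen=True)
class RDF:
    """Radial distribution of species ``pair`` on the lattice."""

    r: np.ndarray  # bin centers, lattice units (r > 0)
    g: np.ndarray
    pair: tuple[str, str]


def random_lattice(
    size: int,
    fractions: dict[str, float] | None = None,
    seed: int = 0,
    energies: np.ndarray | None = None,
    temperature: float = 1.0,
) -> LatticeState:
    """Random initial configuration at fixed composition.

    Default composition is the plant-membrane mimic 60/20/20
    PLPC/sitosterol/glucosylceramide; counts are rounded to fill the grid
    exactly, largest component absorbing the remainder.
    """
    fractions = fractions or {"PLPC": 0.6, "SITO": 0.2, "GLUCER": 0.2}
    if abs(sum(fractions.values()) - 1.0) > 1e-9:
        raise ValueError("composition fractions must sum to 1")
    n = size * size
    counts = {k: int(round(v * n)) for k, v in fractions.items()}
    # absorb rounding remainder into the most abundant species
    rem = n - sum(counts.values())
    counts[max(counts, key=counts.get)] += rem
    labels = np.concatenate(
        [np.full(c, _INDEX[k], dtype=np.int8) for k, c in counts.items()]
    )
    rng = np.random.default_rng(seed)
    rng.shuffle(labels)
    return LatticeState(
        grid=labels.reshape(size, size),
        energies=default_energies() if energies is None else energies,
        temperature=temperature,
        seed=seed,
    )


@njit
def _total_energy(grid, energies):
    size = grid.shape[0]
    e = 0.0
    for i in range(size):
        for j in range(size):
            a = grid[i, j]
            e += energies[a, grid[(i + 1) % size, j]]
            e += energies[a, grid[i, (j + 1) % size]]
    return e


@njit
def _site_energy(grid, energies, i, j, species):
    size = grid.shape[0]
    return (
        energies[species, grid[(i + 1) % size, j]]
        + energies[species, grid[(i - 1) % size, j]]
        + energies[species, grid[i, (j + 1) % size]]
        + energies[species, grid[i, (j - 1) % size]]
    )


@njit
def _kawasaki_kernel(grid, energies, beta_inv, n_steps, rand_sites, rand_u):
    """In-place Kawasaki swap dynamics; returns accepted-move count."""
    size = grid.shape[0]
    accepted = 0
    for step in range(n_steps):
        i1 = rand_sites[step, 0]
        j1 = rand_sites[step, 1]
        i2 = rand_sites[step, 2]
        j2 = rand_sites[step, 3]
        a = grid[i1, j1]
        b = grid[i2, j2]
        if a == b:
            accepted += 1  # null swap, trivially accepted
            continue
        e_old = _site_energy(grid, energies, i1, j1, a) + _site_energy(
            grid, energies, i2, j2, b
        )
        grid[i1, j1] = b
        grid[i2, j2] = a
        e_new = _site_energy(grid, energies, i1, j1, b) + _site_energy(
            grid, energies, i2, j2, a
        )
        de = e_new - e_old
        # exact also for adjacent sites: the mutual a-b bond enters both
        # local sums before and after the swap and cancels (E symmetric)
        if de <= 0.0 or rand_u[step] < np.exp(-de / beta_inv):
            accepted += 1
        else:
            grid[i1, j1] = a
            grid[i2, j2] = b
    return accepted


def run_mc(
    state: LatticeState,
    sweeps: int,
    seed: int | None = None,
    record_every: int = 0,
):
    """Run Kawasaki (composition-conserving) Metropolis dynamics.

    One sweep = L² attempted swaps of two uniformly chosen sites.
    Returns ``(final_state, energies_per_sweep, snapshots)``; snapshots
    are grid copies taken every ``record_every`` sweeps (0 = none).
    Deterministic for a given seed.
    """
    rng = np.random.default_rng(state.seed if seed is None else seed)
    grid = state.grid.copy()
    size = state.size
    per_sweep = size * size
    energy_trace = np.empty(sweeps)
    snapshots: list[np.ndarray] = []
    acc_total = 0
    for sweep in range(sweeps):
        sites = rng.integers(0, size, size=(per_sweep, 4)).astype(np.int64)
        u = rng.random(per_sweep)
        acc_total += _kawasaki_kernel(
            grid, state.energies, state.temperature, per_sweep, sites, u
        )
        energy_trace[sweep] = _total_energy(grid, state.energies)
        if record_every and (sweep + 1) % record_every == 0:
            snapshots.append(grid.copy())
    final = replace(state, grid=grid)
    acceptance = acc_total / max(1, sweeps * per_sweep)
    return final, energy_trace, {"snapshots": snapshots, "acceptance": acceptance}


def contact_fractions(state: LatticeState) -> dict[tuple[str, str], float | None]:
    """P(molecule of species i has ≥ 1 nearest neighbour of species j).

    4-neighbour connectivity on the periodic grid.  Pairs whose first
    species is absent are reported as None.
    """
    g = state.grid
    neighbours = [
        np.roll(g, 1, axis=0),
        np.roll(g, -1, axis=0),
        np.roll(g, 1, axis=1),
        np.roll(g, -1, axis=1),
    ]
    out: dict[tuple[str, str], float | None] = {}
    for a_name, a in _INDEX.items():
        mask_a = g == a
        n_a = int(mask_a.sum())
        for b_name, b in _INDEX.items():
            if n_a == 0:
                out[(a_name, b_name)] = None
                continue
            has_b = np.zeros_like(mask_a)
            for nb in neighbours:
                has_b |= nb == b
            out[(a_name, b_name)] = float((mask_a & has_b).sum() / n_a)
    return out


def random_mixing_contact(fraction_j: float, z: int = 4) -> float:
    """Closed-form random-mixing expectation P(≥1 of j among z neighbours).

    1 − (1 − x_j)^z; e.g. x = 0.2 on a square lattice gives 0.5904.
    """
    return 1.0 - (1.0 - fraction_j) ** z


def radial_distribution(
    state: LatticeState,
    pair: tuple[str, str],
    r_max: float | None = None,
) -> RDF:
    """Lattice g_ij(r), normalized by the conserved-composition ideal.

    Counts ordered site pairs of species (i, j) at each distinct periodic
    minimum-image distance 0 < r ≤ r_max (default L/2) and divides by the
    random-permutation expectation M_r·N_i·N_j/(N(N−1)) (with N_i(N_i−1)
    for the self pair), so g → 1 for a random mixture at every r.
    """
    g = state.grid
    size = state.size
    r_max = size / 2.0 if r_max is None else min(r_max, size / 2.0)
    a, b = (_INDEX[pair[0]], _INDEX[pair[1]])
    n = size * size
    counts_a = int(np.sum(g == a))
    counts_b = int(np.sum(g == b))

    # displacement classes on the periodic lattice
    dx = np.arange(size)
    dx = np.minimum(dx, size - dx)
    d2 = dx[:, None] ** 2 + dx[None, :] ** 2  # (size, size) squared dist
    flat_d2 = d2.ravel()

    # pair counts per displacement via 2-d correlation of indicators
    ind_a = (g == a).astype(float)
    ind_b = (g == b).astype(float)
    fa = np.fft.rfft2(ind_a)
    fb = np.fft.rfft2(ind_b)
    corr = np.fft.irfft2(np.conj(fa) * fb, s=g.shape)  # counts per shift
    corr = np.rint(corr).astype(np.int64)

    # multiplicity of each shift class (every shift counts each ordered
    # site pair once)
    uniq = np.unique(flat_d2)
    uniq = uniq[(uniq > 0) & (uniq <= r_max**2 + 1e-9)]
    r_vals, g_vals = [], []
    exp_pairs = (
        counts_a * (counts_a - 1) if a == b else counts_a * counts_b
    ) / (n * (n - 1))
    for u in uniq:
        mask = d2 == u
        n_shifts = int(mask.sum())
        observed = int(corr[mask].sum())
        m_r = n_shifts * n  # ordered site pairs at this distance
        expected = m_r * exp_pairs
        r_vals.append(np.sqrt(u))
        g_vals.append(observed / expected if expected > 0 else np.nan)
    return RDF(np.array(r_vals), np.array(g_vals), (pair[0], pair[1]))


def lattice_to_text(state: LatticeState) -> str:
    """Character-grid rendering (P/S/G) for quick inspection."""
    chars = np.array(["P", "S", "G"])
    return "\n".join("".join(row) for row in chars[state.grid])
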