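# Methods

This note documents the models, numerical choices and known limits of
the analysis chain; it is the place to look before trusting a number
the package produces.

## Units and conventions

All SLDs are carried in 10⁻⁶ Å⁻² (conversion to absolute Å⁻² happens
once, inside the reflectivity engine); thicknesses and roughnesses in
Å; momentum transfer q in Å⁻¹ with q = (4π/λ)·sin α; surface pressure
in mN/m; molecular areas in Å²/molecule; contact energies in kcal/mol.
Only real, coherent SLDs are modelled — incoherent scattering and
absorption are negligible for cold neutrons on these systems.  The
depth axis has z = 0 at the silicon/oxide interface, increasing toward
the bulk solvent.

## Reflectivity engine

R(q) is computed by the Parratt recursion over the resolved slabs, with
the beam entering through the silicon block (fronting) — the standard
solid/liquid-cell geometry, which places the total-reflection edge at
q_c = √(16π·Δρ) of the silicon→solvent step (0.0147 Å⁻¹ for Si/D₂O).
Interfacial roughness enters as the Nevot–Croce factor
exp(−2·k_j·k_{j+1}·σ²) per interface; this is accurate for σ much
smaller than the adjoining thicknesses, which holds for the 2–4 Å
roughnesses relevant here (for σ approaching a third of a slab
thickness the slab description itself stops being meaningful and the
engine should be fed a finer stack instead).  Each slab's roughness
field refers to its interface with the preceding slab; the outermost
two interfaces (fronting/first slab, last slab/backing) are stack-level
parameters.  Unitarity (0 ≤ R ≤ 1) is enforced exactly; the recursion
agrees with an independently written transfer-matrix implementation to
10⁻⁸ relative and with the closed-form Fresnel curve to 10⁻¹⁰ in the
zero-slab limit (test suite).

Resolution smearing uses a constant ΔQ/Q Gaussian kernel
(σ_q = ΔQ/Q·q/2.355, default 10% FWHM from the two-wavelength
time-of-flight configuration), evaluated by 17-point Gauss–Legendre
quadrature over ±3.5σ with weights normalized so constants are
preserved exactly.  A per-point dq column, when present in a data file,
takes precedence over the constant kernel.

## Membrane model and coverage

The supported membrane is six slabs: native oxide (~10 Å), interstitial
water, inner head groups, inner chains, outer chains, outer head
groups.  The ~30 Å hydrocarbon core is split into two 15 Å leaflet
slabs so that each leaflet carries its own chain SLD; the split
position is a modelling choice, not a measurement, and both chain
thicknesses remain independently fittable.  Incomplete coverage c is
modelled as extra uniform solvent admixture in the membrane slabs,
φ_eff = 1 − c·(1 − φ) (single-structure model, the convention of the
co-refinement software this package's table layout mirrors); the
substrate slabs are exempt.  Incoherent patch averaging of covered and
bare regions is deliberately out of scope.

Leaflet composition is the linear inversion
f_b = (ρ_meas − ρ_a)/(ρ_b − ρ_a) with 1σ error |σ_meas/(ρ_b − ρ_a)|.
Inversions across an SLD gap below 0.5×10⁻⁶ Å⁻² are flagged
ill-conditioned: a 0.68 gap (bare chains −0.41 vs sitosterol 0.27)
is quantifiable, the 0.27 head-group gap (PLPC 1.93 vs
glucosylceramide 2.2) is not — which is exactly why the glycolipid's
transverse distribution can only be inferred indirectly (via the
excess hydration of the leaflet it occupies), not fitted.  Out-of-range
fractions are reported with a flag, never clamped.  The asymmetry
verdict requires the two leaflet fractions to differ by more than
twice their joint propagated uncertainty and by at least 0.05 in
volume fraction.

The bare-chain value −0.41×10⁻⁶ Å⁻² is stored as a single opaque
registry entry; whether it averages over the glycolipid's acyl chains
is not resolvable from the analysis and the registry does not pretend
otherwise.

## Model-free stage

**D_max.**  Above the critical region the data are fitted with the
Fresnel-normalized kinematic ("master") formula
R(q) ≈ R_F(q)·|Φ(q′)|², q′ = √(q² − q_c²), where |Φ|² is the cosine
transform of the autocorrelation Γ(u) of the SLD derivative — a
function supported on |u| ≤ D.  For each candidate D, Γ is expanded in
2 Å histogram bins and fitted by ridge-regularized linear least squares
(second-difference penalty, weight 0.05·√N), with the basis smeared by
the same resolution quadrature as the engine; only q ≥ max(0.04,
1.5·q_c) enters, and the effective error bars are floored at 1% of R
because the master formula is itself only accurate to about that level.
D_max is the plateau onset of the misfit-vs-D curve: the smallest D
whose relative improvement falls below 1% per Å and stays there, or at
which the fit is already essentially perfect (χ²/N < 0.05 — needed for
noiseless inputs, where relative improvements of a near-zero score are
meaningless).  A scan whose smallest candidate already fits is flagged
degenerate (no resolvable layer); one with no plateau in range returns
the range maximum with a flag.  On the canonical fixtures the estimate
lands within ±3 Å of the generating total thickness.  D_max includes
the native oxide layer.

**Free-form profiles.**  The region [0, D_max] is divided into equal
bins (default 13, ~5 Å), each carrying a material SLD ρ ∈ [−0.7, 7.0]
and a solvent fraction φ ∈ [0, 1]; per contrast the bin is rendered as
a slab with effective SLD (1−φ)ρ + φρ_solvent, mild inter-bin blending
(σ = bin width/4) and the standard smearing.  The summed χ² over all
contrasts plus a first-difference smoothness penalty (weight λ_s = 2
by default, φ-differences weighted ×5 since φ spans only [0, 1]) is
minimized by simulated annealing — geometric cooling T ← 0.95·T per
sweep from T₀ = 2N, one Gaussian proposal per bin per sweep (σ_ρ = 0.5,
σ_φ = 0.10), 200 sweeps by default — followed by a deterministic
bounded trust-region least-squares polish.  Runs stranded in a poor
local minimum (χ²/N > 5) are restarted with a derived seed, up to three
attempts; everything is reproducible from the seed.

**What the solution does and does not determine.**  With two or three
contrasts the (ρ, φ) split per bin is formally identifiable, and the
solvent-fraction profile round-trips on noiseless synthetic data to a
mean absolute error of about 0.03.  The material-SLD profile, however,
inherits the reflectometry phase ambiguity: at q_max = 0.25 Å⁻¹ and
~5 Å bins, visibly different SLD profiles reproduce all three curves to
χ² ≈ 0, and the residual profile ambiguity is of order 0.2×10⁻⁶ Å⁻²,
concentrated in bins straddling interfaces.  Conclusions drawn from
this stage should therefore be qualitative (sign and location of
asymmetry, hydration contrast between leaflets) — which is how it is
used; the quantitative numbers come from the model-based co-refinement.

## Co-refinement

All curves of a contrast set share one structure; only the backing
solvent SLD differs per curve.  χ² = Σ_curves Σ_points
((R_model − R)/dR)², curves equally weighted; curves without a dR
column fall back to a configurable relative floor (logged), and a
log₁₀R residual mode is available behind a flag (default is linear R
weighted by dR — which of the two the original analyses used is
generally unstated, so both are supported and the default documented).
The global search is seeded differential evolution (population
15×n_free, Latin hypercube init, tol 10⁻⁸) with a Nelder–Mead polish;
given a seed the result is deterministic.  Default bounds: slab
thicknesses [0, 40] Å, roughness [0, 10] Å, coverage [0.5, 1], chain
SLDs [−0.6, 0.6]×10⁻⁶ Å⁻².  Uncertainties come from a Δχ² = 1 profile
scan per parameter with the others held at their best values
(re-optimization of nuisance parameters is intentionally not the
default; correlated parameters therefore get lower bounds on their
errors); parameters pinned at a bound get one-sided intervals with a
log warning.  On the synthetic fixtures (3% noise, 120 points per
curve) these intervals are far tighter than the integer-Å granularity
at which such parameters are conventionally reported — real beamline
data are noisier and sparser, so intervals on real data will be wider.

Recovery performance under the study conditions (3% relative noise,
q ∈ [0.005, 0.25], seeded): median absolute errors ≤ 1 Å on the
interstitial water thickness, ≤ 2 points on coverage, ≤ 0.05×10⁻⁶ Å⁻²
on leaflet chain SLDs; adding contrasts narrows the Δχ² = 1 intervals
of the chain SLDs (the ambiguity-reduction that motivates contrast
variation in the first place).

## Monolayer analysis

Isotherms are stored in compression order; the lookup interpolates
linearly on the compression branch only (points past the pressure
maximum — the collapse region — are excluded, and small instrumental
jitter is removed by a running maximum).  The additivity rule
A_mix = Σ Xᵢ·Aᵢ is evaluated at the same pressure as the measured
mixture area, by default 30 mN/m (the packing conventionally equated
with the bilayer state).  The excess area Δ = A_theoretical − A_measured
is called condensing (or expanding, by sign) only when it exceeds
2·√(σ_m² + σ_t²); absent per-curve errors, σ defaults to a 5% variation
coefficient, the replicate-scatter scale of independent monolayer
spreadings.  Pure-component areas are inputs (read from user curves or
the generator); they are not bundled as constants.

## Lattice simulator

The lateral-organization stage is deliberately a property-level model:
an L×L periodic grid of species labels (matrix lipid / sterol /
glycolipid, default composition 60/20/20) evolving under Kawasaki
composition-conserving Metropolis dynamics — per step two uniformly
chosen sites swap with probability min(1, exp(−ΔE/T)).  ΔE is computed
from the 4-neighbour contact energies and is exact also for adjacent
pairs (the mutual bond cancels, E being symmetric).  Temperature is a
single dimensionless factor absorbed into the energy scale, because
only the *ordering* of the pairwise energies — sterol–glycolipid
strongest, then sterol–sterol, then sterol–matrix — is defensible
input; absolute docking energies are not transferable to a lattice
Hamiltonian.  The shipped default matrix (−4/−3/−2 kcal/mol on the
sterol row, −2.5 for glycolipid–glycolipid, 0 elsewhere) is explicitly
illustrative: the glycolipid self-attraction is included because a pure
sterol–glycolipid attraction produces alternating checkerboard contacts
rather than the mixed sterol/glycolipid clusters the simulator is meant
to emulate.

Observables: contact fractions (probability that a molecule of species
i has ≥ 1 nearest neighbour of species j; 1 − (1−x_j)⁴ = 0.5904 for
x_j = 0.2 under random mixing) and the lattice radial distribution
g_ij(r), normalized by the conserved-composition random-permutation
expectation so g ≡ 1 for an ideal mixture at every distance.  The
dynamics satisfy detailed balance — verified against exhaustive
Boltzmann enumeration on a 3×3 grid — and conserve composition
exactly.  Quantitative molecular-dynamics contact statistics (e.g.
"half of the glycolipids touch another glycolipid") are *not* claims
this model can reproduce; it is used only for direction-of-effect
checks (clustering exceeds random mixing under attractive ordering).

## Synthetic data

The generator replaces the beamline and the trough.  Reflectivity:
logarithmic q grid, 0.005–0.25 Å⁻¹, 120 points, smeared model curve
per solvent, multiplicative Gaussian noise with relative σ =
max(floor, counting term) (default: flat 3% floor, counting term off),
dR column carrying the generating σ — so a fit with the true model has
E[χ²/N] = 1.  Isotherms: Π(A) = c·(exp((A₀−A)/w) − 1) with c = 5 mN/m
and lift-off at 1.6× the reference area, solved to pass exactly through
each component's requested area at the reference pressure; the mixture
curve's noiseless area equals the additivity prediction minus the
condensation parameter δ, and replicates carry a multiplicative area
scatter (5% CoV default).  These functional forms and noise defaults
are package choices (instrument q-binning and counting statistics are
not public inputs); all are overridable and recorded in dataset
headers.

Canonical fixtures encode the two reference membranes: the *ternary*
(asymmetric) one — oxide 10 Å, water gap 4 Å, heads 10 Å at 25%
hydration, chains 15+15 Å with SLD −0.28 (inner) / −0.41 (outer) and
hydration 10%/2%, roughness 2.5 Å, coverage 0.99 — and the *binary*
(symmetric) one — water gap 6 Å, both chain slabs −0.28, 2% hydration,
roughness 3.5 Å, coverage 0.97.  The inner-leaflet hydration excess of
the ternary fixture encodes the qualitative model-free observation that
the substrate-proximal leaflet is the wetter one; its size (8 points)
is a generator choice, as no quantitative value is available.  What
synthetic data do not emulate: instrument backgrounds, off-specular
scattering, q-dependent resolution beyond constant ΔQ/Q, detector
nonlinearity, and sample ageing — so passing recovery tests demonstrate
the correctness of the analysis chain under its own assumptions, not
robustness to every real-data pathology.

## Problem sizes used in the shipped tests and acceptance script

Co-refinements free five parameters (water gap, coverage, shared
roughness, two chain SLDs) over 2–3 contrasts × 120 points with an
80-iteration evolution budget; the recovery-statistics tests use eight
noise realizations with three free parameters and a 40-iteration
budget; annealing tests run 120 sweeps plus polish; the lattice
equilibrium checks use 24²–60² grids and a 2500-sweep 3×3 oracle run.
These sizes were chosen so the full chain demonstrates its statistical
claims at desk scale; all are parameters, not limits.
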