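# Methods

`saxskit` implements the standard small-angle X-ray scattering (SAXS)
analysis chain for dilute protein solutions — forward scattering from
coordinates, goodness-of-fit, model-free inversion, mass estimation — plus
a seeded Monte-Carlo rigid-body refinement engine for oligomer models, and
a synthetic-data generator that makes the whole chain testable without
instrument data.

## Scattering model

A particle is a set of point scattering centres with coordinates `x_j`
(Å) and excess scattering weights `w_j` (effective electrons). The
orientationally averaged intensity is the Debye equation

    I(q) = Σ_j Σ_k w_j w_k sin(q d_jk) / (q d_jk),

with `d_jk` the pairwise distances, `sinc(0) = 1` and therefore
`I(0) = (Σ w_j)²`. The momentum transfer is `q = 4π sin θ / λ` (Å⁻¹).

Two evaluation paths exist:

* **exact** — the double sum, evaluated one `q` at a time (memory stays
  `O(n²)`); used below 2000 centres.
* **binned** — a pair-distance histogram with 0.1 Å bins, where each bin
  contributes at its weighted mean distance plus a curvature correction
  `½ sinc''(q d̄) q² Var(d | bin)`. The moment corrections matter: without
  them the error near form-factor minima reaches ~4×10⁻³ relative; with
  them the two paths agree to better than 10⁻⁶ on the instrument q-range
  (0.008–0.34 Å⁻¹), and the unit suite enforces 10⁻³.

Weights are unit (bead mode, the default for algorithmic work) or atomic:
element electron count minus the displaced-solvent term `ρ_s·V` with
`ρ_s = 0.334 e/Å³` and Fraser–MacRae–Suzuki average atomic volumes.
Hydrogens are skipped on reading; no hydration-shell term is modelled, so
atomic-mode profiles approximate, but do not reproduce, shell-aware
calculators.

## Goodness of fit

    χ = sqrt( (1/N) Σ_j [ (I_exp(q_j) − (c·I(q_j) + b)) / σ(q_j) ]² )

with `N` the number of points; the scale `c` (applied to the model) and
optional constant background `b` minimise χ by weighted linear least
squares. A `1/(N−1)` normalisation is available by option; the default
divides by `N`. Mixtures of component curves are decomposed with
non-negative weights (bounded-variable least squares) plus an
unconstrained background — weights are physical fractions, the background
absorbs flexibility and buffer mismatch.

## Guinier analysis

`ln I` versus `q²` is fitted by σ-weighted least squares on a low-q
window that the iteration grows or shrinks until `q_max·Rg ≤ 1.3` (the
community-standard validity limit; configurable). A non-negative slope
flags repulsion/aggregation and leaves Rg undefined. On a noiseless
5000-bead sphere curve the recovered Rg sits ~1.9 % above `√(3/5)·R`,
which is the combined Guinier-approximation and bead-sampling bias at the
1.3 window — inside the 2 % band the tests enforce, but close to it.

## Indirect Fourier transformation

p(r) is expanded in 30 cubic B-splines on `[0, Dmax]` (clamped knots, the
two end splines dropped so `p(0) = p(Dmax) = 0`). Coefficients minimise

    Σ_j [(I_exp − I_model)/σ]² + α ∫ p''(r)² dr,
    I_model(q) = 4π ∫₀^Dmax p(r) sinc(qr) dr,

with the r-integrals on a 601-point trapezoid grid. Derived quantities:
`Rg² = ∫ r² p dr / (2 ∫ p dr)`, `I(0) = 4π ∫ p dr`.

* **α selection** (per Dmax): α is scanned over eleven decades scaled by
  `tr(AᵀΣ⁻¹A)/tr(P)`; the largest α whose χ stays within 5 % of the best
  is kept — the smoothest solution the data allow. `α = 0` requests the
  raw (ill-conditioned) least-squares solution and is only useful for
  diagnostics.
* **Dmax selection** (`ift_auto`): Dmax is scanned geometrically over
  `[1.4, 6.5]·Rg_Guinier` (28 candidates). χ falls steeply while Dmax is
  too small and plateaus once the particle fits; the selected value is
  the smallest candidate whose χ is within 50 % of the plateau level
  (median of the five largest-Dmax candidates — a robust estimate,
  because per-candidate α quantisation makes the plateau noisy at the
  10⁻⁵ level). Candidates whose p(r) dips below −1 % of its maximum are
  excluded, unless no candidate passes that screen (a p(r) made of
  near-delta spikes, e.g. an ideal point pair, cannot avoid Gibbs lobes).

## Molecular mass and bookkeeping

On absolute scale (curve in cm⁻¹, calibrated against water — accepted as
metadata, not computed), the mass follows from forward scattering:

    M = I(0) · N_A / (c · Δρ_m²),

with `c` the mass concentration (g/cm³) and `Δρ_m` the excess scattering
length per unit mass (default 2.0×10¹⁰ cm/g, a typical protein value,
overridable). Reported masses are quoted at 0.01 kDa precision and molar
concentrations `c = ρ/M·10⁶` µM at the nearest integer (half-up) — with
the monomer at 22.14 kDa this reproduces the reported 542/271/136 µM for
12/6/3 mg/mL exactly; note that 3 mg/mL sits within 0.01 µM of the
rounding boundary, which is why the reporting precision of the mass is
stated explicitly. SEC masses come from a least-squares line of
`log10 M` versus elution volume over the calibration standards, with a
warning outside the calibrated range.

## Monte-Carlo rigid-body refinement

One component of the assembly stays fixed (χ is invariant to global
rigid motion); each step rotates one randomly chosen movable component
about its own centroid (uniform random axis, angle uniform in
`[0, max_rotation]`) and translates it (per-axis uniform in
`±max_translation`). Proposals with any inter-component centre pair
closer than the clash threshold (2.5 Å between heavy-atom/bead centres —
below any bonded contact; the boundary is strict, `distance < threshold`)
are rejected before any scattering work. Otherwise χ is evaluated with
the scale refit (background optional) and the move is accepted greedily
(Δχ ≤ 0; optionally Metropolis with fixed or geometrically annealed
temperature). Runs are bit-reproducible from the seed; the best state
ever accepted is returned along with a full per-step trace.

In the loop, intra-component Debye terms are computed once (they are
invariant under rigid moves) and only the moved component's cross terms
are rebuilt, via a fixed-centre histogram with 0.005 Å bins against a
precomputed sinc table. The narrow bins are deliberate: the late phase of
a greedy descent has to resolve intensity differences of ~10⁻⁴ relative,
below the evaluation error of coarser bins.

### Step schedule and pose identifiability

The default schedule is `max_rotation` 5°, `max_translation` 0.12 Å,
geometric decay 0.998 per step with a 0.1 amplitude floor, and a
restart-from-best every 1000 steps that re-expands the schedule. These
defaults were calibrated on the planted two-lobe recovery problem, and
the translation step is small for a reason worth recording: the
orientationally averaged intensity is nearly blind to (i) the direction
of one component relative to the other and (ii) rotation of a
quasi-spherical component about the inter-component axis. Poses several
Å RMSD from a planted truth can fit noiseless data to χ ≈ 0.02 at a 1 %
uncertainty band — the residual pose signal is only the finite-bead
"speckle" of the lobes. Large translation steps let the pose drift along
these weakly constrained directions while the strong modes (separation,
in-plane rotation) are being fixed, and greedy descent cannot climb back
out; small steps keep the drift-to-travel ratio low and the fine tail of
the schedule then follows the weak residual gradient into the planted
basin. Under the default schedule, 9 of 10 refinement seeds recover a
30°/10 Å perturbation of the default fixture to better than 2 Å RMSD
within 3000 greedy steps (the tenth stalls in a speckle-level local
minimum ~3 Å away). Log-uniform multiscale amplitudes and "orbit" moves
(rotation about the partner centroid) are available as options but
degrade recovery — they diffuse along the degenerate manifold — and are
off by default. On real data, where noise exceeds the speckle signal,
pose uncertainty of a few Å along these directions is a property of the
experiment, not of the optimizer.

## Synthetic data

Generators are pure functions of their arguments including the seed.
`make_bead_sphere` rejection-samples unit-weight beads uniformly in a
ball; `make_two_lobe_dimer` builds a prolate two-sphere assembly
(defaults: lobe radius 15 Å, separation 32 Å, 800 beads per lobe —
dimer-envelope-like and fast to evaluate). `simulate_curve` sums weighted
Debye profiles plus a flat background on the instrument-like grid
(0.008–0.34 Å⁻¹, 200 points) and adds Gaussian noise with recorded
`σ(q) = rel·I(q) + abs` (default rel = 1 %, a typical counting-statistics
scale). Gaussian rather than Poisson noise is deliberate: χ is computed
against the recorded σ, so the calibration `E[χ] = 1` against the truth
is exact by construction — and verified (mean χ over 200 seeds within
±0.05 of 1). `attach_uncertainties` records a σ band on a noiseless
curve for planted-truth tests.

What the generator does **not** emulate: Poisson statistics at very low
counts, instrumental smearing, inter-particle structure factors at high
concentration, buffer-subtraction artefacts, and residue-level detail.
Passing tests therefore demonstrate the correctness of the computational
machinery on data whose generative model is known exactly, not
performance on real instrument data.

## Verification problem sizes

The shipped checks run bead models of 50–5000 centres, 200-point curves,
200-seed χ calibrations, 100-seed mixture recoveries and ten 3000-step
refinement runs; these sizes keep every oracle (O(n²) double sums,
brute-force pair scans, grid searches) exactly computable while the full
suite stays desk-scale.

## Known limitations

* No hydration shell or explicit solvent; atomic-mode intensities differ
  from shell-aware calculators, increasingly so beyond q ≈ 0.2 Å⁻¹.
* The IFT Dmax criterion assumes a single well-defined particle size; for
  polydisperse or aggregated samples the "plateau" is ill-defined and the
  selected Dmax reflects the largest abundant species.
* Rigid-body refinement treats components as rigid and the experiment's σ
  as exact; flexible linkers, symmetry constraints and ensemble models
  are out of scope.
* PDB output stores bead weights in the B-factor column; files are valid
  PDB but the convention is local to this package.
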