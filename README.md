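# saxskit

Small-angle X-ray scattering (SAXS) analysis for dilute protein
solutions, built around the computational chain used to characterise
monomer/dimer equilibria of globular proteins in solution:

* **Forward scattering** from coordinates (PDB atoms or bead models) via
  the Debye equation, `I(q) = ΣΣ w_j w_k sin(q d_jk)/(q d_jk)`, with an
  oracle-tested histogram acceleration for large models.
* **Goodness of fit** `χ = sqrt((1/N) Σ [(I_exp − (c·I + b))/σ]²)` with
  analytic scale/background, and non-negative **mixture decomposition**
  (e.g. monomer + dimer + flat background) of experimental curves.
* **Model-free inversion**: Guinier analysis (`I ≈ I(0)·e^{−q²Rg²/3}`,
  window `q·Rg ≤ 1.3`), and regularised indirect Fourier transformation
  to the pair-distance distribution p(r) with Rg, I(0) and automatic
  Dmax selection.
* **Molecular mass from forward scattering** on absolute scale,
  `M = I(0)·N_A/(c·Δρ_m²)`, plus concentration and size-exclusion
  calibration bookkeeping.
* **Monte-Carlo rigid-body refinement** of oligomer assemblies against a
  scattering curve: seeded, clash-checked, greedy or Metropolis, with a
  full per-step trace.
* A **synthetic-data generator** (bead spheres, planted two-lobe dimers,
  counting-statistics-like noise on the 0.008–0.34 Å⁻¹ instrument range)
  so every stage is testable end to end without instrument data.

The fitting stages follow a Model/Results convention: `Guinier(curve)`,
`PairDistanceModel(curve)`, `MixtureModel(experiment, components)` and
`RigidBodyModel(assembly, curve)` expose `.fit()` returning a results
object with the estimates and a `summary()`; module-level functions
(`guinier_fit`, `ift`, `mixture_fit`, `mc_refine`, ...) wrap them.

See `docs/methods.md` for the models, numerical choices and limitations.

## Worked example

```python
import saxskit as sk

# 1. simulate a noisy curve for a 30 A sphere
sphere = sk.make_bead_sphere(radius=30.0, n_beads=3000, seed=1)
curve = sk.simulate_curve(sphere, noise=sk.NoiseModel(relative_floor=0.01, seed=1))

# 2. model-free analysis
print(sk.guinier_fit(curve).summary())
print(sk.ift_auto(curve).summary())

# 3. mass from forward scattering (absolute-scale inputs)
est = sk.mass_from_i0(i0_abs=0.1765, c_mass=0.012, delta_rho_m=2.0e10)
print(est.summary())
print("at 12 mg/mL:", sk.mgml_to_micromolar(12.0, round(est.kda, 2) * 1000), "uM")
```

prints

```
Guinier: Rg = 23.89 A, I(0) = 9.0515e+06
  window q in [0.008, 0.05305] (28 points), R^2 = 0.99734
IFT p(r): Dmax = 55.81 A, alpha = 1.49e-06
  Rg = 23.23 A, I(0) = 8.97465e+06, fit chi = 0.9392
M = 22.14 kDa from I(0) = 0.1765 1/cm at c = 12 mg/mL (drho_m = 2e+10 cm/g)
at 12 mg/mL: 542 uM
```

A uniform 30 Å sphere has `Rg = √(3/5)·30 = 23.24 Å` and `Dmax = 60 Å`:
the Guinier window recovers Rg to ~3 % on this noisy curve and the p(r)
moments to 0.1 %; the IFT fit χ ≈ 0.94 says the inversion matches the
data to within the recorded uncertainties. The mass example turns an
absolute-scale forward intensity measured at 12 mg/mL into 22.14 kDa —
a calcium-sensor-protein-sized monomer — and back into its molar
concentration.

The same operations are available from the shell:

```sh
saxskit simulate --radius 30 --n-beads 3000 --seed 1 --out sphere.dat
saxskit ift sphere.dat --out pr.dat
saxskit refine dimer.pdb curve.dat --out-pdb best.pdb --out-trace trace.tsv
saxskit mass --i0 0.1765 --conc 0.012
```

Every stochastic command takes `--seed` and echoes its full
configuration, so runs are reproducible from their logs.

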