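# kbsolv

Kirkwood–Buff solvation analysis for cyclodextrin–amino-acid systems:
radial distribution functions with a closed-system finite-size correction,
Kirkwood–Buff integrals with uncertainty, inversion of binary-solution
thermodynamics, preferential-interaction decomposition, host–guest
structural metrics, and the ADD hydroxyl parameter patch for
hydroxypropyl-β-cyclodextrin (HPβCD) topologies.

## The scientific problem

Cyclodextrins such as HPβCD are amphiphilic excipients used to solubilize
hydrophobic drugs and to stabilize protein formulations. Whether a
cosolvent like HPβCD stabilizes or denatures a protein is governed by its
*preferential interaction* with the protein surface, which Kirkwood–Buff
(KB) theory expresses through integrals of pair correlation functions.
For species *i*, *j*,

```
G_ij = 4π ∫₀^∞ [g_ij(r) − 1] r² dr        (nm³ per molecule)
```

measures the net excess (G > 0) or depletion (G < 0) of *j* around *i*.
In a water(1)–solute(2)–cosolvent(3) mixture the difference
γ = G₂₃ − G₁₂ quantifies preferential interaction (γ > 0) or exclusion
(γ < 0). A positive per-residue backbone contribution γ^bb is the KB
signature of a denaturant.

Three practical obstacles stand between a simulation (or an experimental
data table) and those numbers, and this package implements the machinery
for each:

1. **Finite-size bias.** RDFs from closed (NVT/NpT) simulations carry an
   O(1/N) bias that shifts KB integrals systematically. `kbsolv.rdf`
   applies the Ganguly–van der Vegt rescaling

   ```
   g∞(r) = g(r) · N_j (1 − V_s/V) / [N_j (1 − V_s/V) − ΔN_ij(r) − δ_ij]
   ```

   with V_s = (4/3)πr³ and ΔN_ij(r) the excess count of *j* within *r*,
   then integrates to running KBIs G(R) and averages over a convergence
   window with block-averaged uncertainty.

2. **Experiment → KBIs.** For a binary water–cosolvent solution the KBIs
   follow from measurable quantities via the Ben-Naim inversion. With the
   thermodynamic factor η = x₃(∂μ₃/∂x₃)_{p,T}/(RT), ξ = RTβ_T and molar
   volume V_m = 1/ρ:

   ```
   G13 = ξ − V1·V3 / (V_m·η)
   G33 = G13 + (V1/η − V_m)/x3
   G11 = G13 + (V3/η − V_m)/x1
   ```

   and, in the reverse direction, the activity-coefficient derivative
   f₃₃ = (∂ln f₃/∂ln x₃)_{p,T} = −x₁ρ₃Δ/(1 + x₁ρ₃Δ) with
   Δ = G₁₁ + G₃₃ − 2G₁₃. `kbsolv.thermo` implements both routes; they
   close algebraically, which the test suite verifies to 1e−6.

3. **Where the interaction happens.** `kbsolv.preferential` decomposes γ
   into side-chain terms (γ_i^sc = γ_i − γ_gly) and a backbone slope via
   the constant-increment fit γ(x) = γ^eg + γ^bb·x over a glycine-repeat
   peptide series; `kbsolv.structure` counts geometric hydrogen bonds
   (donor–acceptor < 0.35 nm, proton deviation < 30°, strict), cavity
   inclusions (guest COM < 0.5 nm from host COM), and rim-orientation RDF
   maxima.

`kbsolv.forcefield` holds the parameter side: it represents HPβCD-like
topologies in a strict itp subset and applies the ADD patch — hydroxyl H
charge 0.42 → 0.33 e with neutrality-preserving redistribution, and a
single hydroxyl Lennard-Jones set ε(O) = 0.450, ε(H) = 0.120 kJ/mol
replacing the CHARMM36 values (0.804/0.192 glucopyranose, 0.636/0.192
hydroxypropyl). σ and all bonded terms are untouched.

Because MD trajectories are expensive and no public dataset accompanies
the method, `kbsolv.synthetic` generates every input with known ground
truth: pair fluids whose KBI is exactly 8πAλ³, binary thermodynamic
datasets forward-generated from a chosen KBI profile, planted
hydrogen-bond/inclusion geometries, and noisy linear γ series.

## Worked example

```python
import kbsolv as kb

spec = kb.SyntheticFluidSpec(n_centers=40, n_partners=1000, box_edge=8.0,
                             rdf_form="exponential_excess", amplitude=0.5,
                             decay_length=0.3, n_frames=100, seed=1)
traj = kb.gen_structured_fluid(spec)
est = kb.kbi_from_trajectory(traj, "center", "partner", dr=0.02,
                             r_max=3.5, window=(2.0, 3.0), blocks=20)
print(f"analytic G = {traj.metadata['G_analytic']:.4f} nm^3")
print(f"estimated G = {est.G:.4f} +/- {est.stderr:.4f} nm^3")
```

prints

```
analytic G = 0.3393 nm^3
estimated G = 0.3003 +/- 0.0746 nm^3
```

i.e. the finite-size-corrected estimate reproduces the closed-form KBI
8π·0.5·0.3³ = 0.3393 nm³ within one standard error. Continuing with the
thermodynamic and decomposition layers:

```python
profile = lambda x3: kb.KBITriple(G11=-10.0, G13=-40.0, G33=300.0)
states = kb.gen_binary_thermo_dataset(profile, [0.01, 0.03, 0.05])
k = kb.invert_thermo_to_kbi(states[1])
print(kb.f33_from_kbi(k, states[1]).f33, kb.f33_from_state(states[1]).f33)
# -0.368797...  -0.368797...   (two independent routes agree)

fit = kb.backbone_fit(kb.gen_gamma_series(kb.GammaSeriesSpec(
    gamma_eg_true=0.5, gamma_bb_true=1.20, noise_sd=0.3, seed=8)))
print(fit.gamma_bb, fit.r_squared)   # 1.250 nm^3, R^2 = 0.991
```

The inverted G₃₃ equals the generator's 300 cm³/mol to 13 significant
digits, and the noisy six-point glycine series recovers the planted
backbone slope of 1.20 nm³ within its sampling scatter.

A `kbsolv` console command exposes the same operations
(`kbsolv synth`, `rdf`, `kbi`, `invert`, `f33`, `gamma`, `fit-backbone`,
`hbonds`, `chi`, `inclusion`, `orientation`, `patch-ff`); see
`kbsolv --help`.

## Documentation

`docs/methods.md` describes the models, the numerical choices (binning,
quadrature, window placement, spline differentiation), what the synthetic
generators do and do not emulate, and known limitations.
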