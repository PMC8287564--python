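# Methods

This note documents the models and estimators implemented in `kbsolv`,
the conventions that make its tests exact, the synthetic data it is
validated on, and the limits of what that validation shows.

## Units and conventions

Coordinates in nm, times in ps, masses in amu, charges in elementary
charge units, Lennard-Jones ε in kJ/mol and σ in nm. Per-molecule KB
integrals are in nm³; the molar (experimental) scale is cm³/mol, with
1 nm³ = N_A·10⁻²¹ cm³/mol = 602.214076 cm³/mol. Boxes are orthorhombic;
all distances use the minimum-image convention and are valid only below
half the smallest box edge, which the code enforces.

## Radial distribution functions and KB integrals

`compute_rdf` histograms pair distances into uniform half-open bins
[r, r+dr), reports bin centers, and normalizes by the ideal-gas count
N_i·N_j·V_shell/V from the instantaneous box volume. When the two
selections coincide, self pairs are excluded from the counting but *not*
from the normalization: this is the closed-system convention under which
a fixed-N ideal gas shows g = (N−1)/N rather than 1, which is exactly the
depletion the finite-size correction is designed to remove. Selections
may be species labels, index arrays, or lists of index groups; groups are
reduced to mass-weighted centers of mass (unwrapped relative to the first
atom, so groups must be compact on the half-box scale).

`excess_counts` measures ΔN_ij(r) — the mean number of j particles within
r of an i particle minus the ideal expectation (N_j/V)·(4/3)πr³ — by
direct counting on the same grid, with the same self-exclusion rule.

`correct_rdf_finite_size` applies the Ganguly–van der Vegt rescaling

    g∞(r) = g(r) · N_j(1 − V_s/V) / (N_j(1 − V_s/V) − ΔN_ij(r) − δ_ij),

which restores open-system behaviour to first order in 1/N_j and in
G/V. Two exact properties anchor the tests: for an unlike pair with zero
excess the factor is identically 1, and for a fixed-N ideal gas
(ΔN = −V_s/V, δ = 1) it is N_j/(N_j−1), recovering g∞ = 1 exactly.
The operation refuses already-corrected input; applying it twice is
never meaningful.

`running_kbi` integrates 4π(g−1)r² cumulatively by the trapezoid rule,
prepending the exact point G(0) = 0 (the integrand vanishes at r = 0
regardless of g). `estimate_kbi` averages G(R) over a convergence window
and, given per-block curves, reports the block mean and standard error;
`kbi_from_trajectory` wires the chain together, splitting frames into
blocks (default 5; the oracle studies below use more because their frames
are independent), correcting each block's RDF, and attaching a flatness
warning when mean |dG/dR| on the window exceeds a configurable threshold
(default 0.5 nm²). The warning never fails an analysis — convergence
judgment is left visible to the user rather than automated silently.

### Window placement

The default window [1.5, 2.5] nm is a reasonable choice for ~8 nm boxes
of molecular liquids. It is *not* appropriate when the pair excess decays
exponentially with λ = 0.3 nm and the target is the full integral
8πAλ³: the closed-form partial integral carries 12.5% of its mass beyond
R = 5λ = 1.5 nm, and only <3.5% beyond 2 nm. Plugging the exact ensemble
curves through the estimator shows a deterministic residual of −0.02 nm³
for the early window and −0.009 nm³ for a [2.0, 3.0] nm window (with
r_max = 3.5 nm). The oracle tests and the acceptance script therefore use
[2.0, 3.0]; the rule of thumb is R_lo ≳ 7 decay lengths. A 100-seed
Monte-Carlo check of the full pipeline at these settings gives a mean of
0.3337 ± 0.0088 nm³ against the analytic 0.3393 nm³.

## Thermodynamic inversion

For a binary water(1)–cosolvent(3) solution the Ben-Naim inversion maps
(ρ, V̄1, V̄3, β_T, ∂μ₃/∂x₃) to (G11, G13, G33); the intermediates are the
thermodynamic factor η = x₃(∂μ₃/∂x₃)/(RT), the compressibility term
ξ = RTβ_T, and the molar volume V_m = 1/ρ. The same algebra run forward
defines `gen_binary_thermo_dataset`: given a KBI profile and a dilute
grid (x₃ ≤ 0.05, mirroring the tens-of-mM regime where V̄1 and β_T may be
treated as constants), the generator solves a quadratic for the density
consistent with constant V̄1 = 18.07 cm³/mol, obtains V̄3 from the volume
identity and the chemical-potential derivative from
D = 1/(1 + ρx₁x₃Δ), and integrates ln f₃ = ∫(D−1)/s ds for the activity
coefficient (f₃,m = x₃f₃ on the molal scale).

Two consequences of exact closure are worth stating. First, prescribing
all three KBIs together with a constant V̄1 leaves no freedom for an
independent compressibility: the generator computes the state-consistent
β_T per composition and stores it in the state (the nominal
4.52×10⁻¹⁰ Pa⁻¹ is retained as reference metadata). Second, not every
KBI profile is realizable — profiles implying a non-positive density
root, thermodynamic factor, or compressibility are rejected with a
diagnostic naming the offending composition. This is material stability,
not a numerical tolerance; test profiles live inside the stable region.

Differentiation of tabulated activity data uses a cubic smoothing spline
of ln f₃ vs x₃ (scipy's `make_smoothing_spline`; generalized
cross-validation by default, a fixed penalty or `lam=0` for noiseless
tables, and an exact cubic interpolant below five points where GCV is
ill-posed). Curve comparison (`compare_curves`) interpolates the
simulated curve linearly onto the experimental compositions and reports
the RMSE. No experimental tables ship with the package; the module
consumes any CSV in the documented schema.

## Preferential interaction and decomposition

γ = G₂₃ − G₁₂, with negative values labelled preferential exclusion.
Standard errors propagate in quadrature only when the caller supplies
them — the package does not invent error bars. Side-chain contributions
subtract the glycine reference measured under the same capping
conditions (a metadata mismatch warns). The backbone contribution comes
from ordinary least squares of γ against the number of internal glycine
units; R² is the conventional 1 − SS_res/SS_tot, and a two-point series
warns that its perfect fit is vacuous. No weighting is applied. The
claim that side-chain terms are insensitive to capping is a property of
simulation data, not of this arithmetic, and is deliberately not
asserted anywhere.

## Structural metrics

Hydrogen bonds use the strict geometric criterion d(D,A) < 0.35 nm and
angle < 30°. The angle is measured at the donor between the donor→H
vector and the donor→acceptor line (the standard proton-deviation
criterion); the vertex is configurable (`angle_vertex="hydrogen"` gives
the deviation of D–H···A from linearity) because the phrase "the angle
formed between the hydrogen atom and the line joining donor and
acceptor" admits both readings. Donor/acceptor chemistry is supplied by
the user's selections — one hydrogen maps to exactly one donor — rather
than inferred from element types. Exact-cutoff geometries are excluded
by strictness; since an exactly-30° angle is not representable in binary
floating point, planted fixtures keep ≥ 0.005 nm and ≥ 2° margins so no
binning or rounding can flip a planted label.

χ is the percentage of the guests' hydrogen bonds that involve the host,
χ = 100·Σn_host-guest/Σn_total over equilibrated frames: monotone in the
host–guest count at fixed normalization, 100% when every guest bond is a
host bond, and defined as 0 (with a warning) when no bonds exist at all.

A host "includes" a guest in a frame when at least one guest center of
mass lies strictly within 0.5 nm of the host center of mass; several
guests in one cavity count the host once. The result is the mean
per-frame count over the host total, ×100, which makes the percentage of
a concatenated trajectory the frame-weighted mean of its parts.

Rim orientation takes the maximum of the RDF between each rim's atoms
(primary = C6 side, secondary = C2/C3 side, as disjoint selections) and
the guest centers of mass; the backbone/side-chain variant swaps roles,
using the secondary-rim center of mass as reference. A residue with no
side-chain atoms (glycine) yields a result flagged absent, not a zero.

## Synthetic data: what it emulates and what it does not

The generators provide statistical stand-ins, not chemistry:

- *Ideal gas*: uniform i.i.d. placement; the null model (G = 0).
- *Exponential-excess fluid*: partners drawn i.i.d. from a density
  proportional to 1 + A′Σ_c exp(−r_c/λ), with A′ = A/(1 − n_c·A·w̄),
  w̄ = 8πλ³/V, so the ensemble pair excess around any center has
  amplitude exactly A after bulk renormalization. Positive A uses exact
  mixture sampling (uniform component plus per-center radial bumps with
  pdf ∝ r²e^{−r/λ}); negative A uses thinning with weight clamped at
  zero, a distortion that only activates for near-coincident centers.
  The construction reproduces the closed-system depletion (a −G/V
  background offset) that a real canonical simulation would show, which
  is precisely what the finite-size correction removes; the recorded
  ground truth 8πAλ³ is the open-system value.
- *Planted H-bond/inclusion fixtures*: lattice-separated geometries with
  margins (above) so counts are exact integers by construction.
- *γ series*: γ(x) = γ^eg + γ^bb·x + N(0, σ) with defaults matching the
  six-member glycine-repeat design (x = 1…6) and reference slopes 1.20
  and 2.33 nm³ used as generator truths in the tests.
- *Binary thermodynamic datasets*: exact algebraic inverses of the
  KB inversion (above).

Every generator draws from a single `numpy` Generator seeded from its
spec; equal specs give bit-identical output.

Passing tests on these fluids demonstrates that the estimators are
correct and unbiased *under their own assumptions* — uncorrelated
frames, compact groups, orthorhombic boxes, pair structure of the
assumed form. They do not demonstrate anything about real HPβCD
thermodynamics, which would require long molecular-dynamics trajectories
and digitized experimental activity data that are outside this package's
scope.

## Study sizes

The oracle studies are desk-scale by design: the exponential-excess
pipeline uses 40 centers and 1000 partners in an 8 nm box over 100
independent frames (10⁵ partner·frames, ~20 s); the closed-system
ideal-gas comparison uses 300 particles in a 6 nm box over 80 frames;
thermodynamic closure runs a 20-point dilute grid; the decomposition
study uses 500 replicate series. Block counts (16–20) are chosen large
because frames are independent, making the standard-error estimate
itself well-conditioned.

## Force-field patch

Topologies live in a strict itp subset — `[ moleculetype ]`,
`[ atomtypes ]` (ε, σ per type), `[ atoms ]` (index, name, type, charge,
hydroxyl group tag, bonded-O index), `[ variant ]` — with ε denormalized
per atom at load so the two CHARMM36 hydroxyl classes can coexist.
Neutrality is validated to 1e−6 e at load, after patching, and at write;
serialization uses fixed precision (charges 4 decimals, ε 3, σ 4) so
golden-file comparisons are byte-stable.

`apply_add_patch` sets every hydroxyl H to 0.33 e and, absent an explicit
per-atom charge map, moves the deficit (+0.09 e per CHARMM36 hydroxyl)
to the bonded oxygen — the minimal neutrality-preserving redistribution.
A user-supplied charge map (YAML name → charge) overrides the
redistribution atom-by-atom for workflows that have a published per-atom
charge set. ε values of the four hydroxyl classes switch to the single
ADD set; a diff operation verifies the patch touches nothing else, and
re-patching an ADD topology is an error rather than a silent double
shift. The bundled topology (`data/hpbcd_synthetic_charmm36.itp`) is a
*synthetic* HPβCD-like molecule — seven glucopyranose units, four
carrying a 2-hydroxypropyl substitution, with plausible CHARMM36-style
group charges summing to zero — intended for tests and demonstrations,
not for simulation of real HPβCD.

## Known limitations

- Orthorhombic boxes and O(N²) pair loops only; adequate for desk-scale
  validation, not for large production trajectories.
- The finite-size correction is first-order; a residual of order G²/V
  and window-truncation effects remain (quantified above).
- Group centers of mass assume compact groups; molecules spanning half
  the box would need proper unwrapping.
- The thermodynamic generator's constant-V̄1 convention makes the implied
  compressibility a model output, larger than real water's; it is
  exactly self-consistent but not a fit to any measured β_T.
- Equilibration handling is a frame-skip option, not automatic
  detection.
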