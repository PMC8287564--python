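"""Synthetic inputs with known ground truth for the full analysis pipeline.

Every downstream operation -- RDF/KBI estimation, thermodynamic inversion,
preferential-interaction decomposition, hydrogen-bond / inclusion counting
-- can be exercised without molecular-dynamics trajectories:

- ideal and exponential-excess pair fluids whose KB integral is known in
  closed form (G = 8 pi A lambda^3 for g(r) = 1 + A exp(-r/lambda));
- binary-solution thermodynamic datasets generated *forward* from a chosen
  KBI profile, so the inversion can be round-tripped exactly;
- configurations with planted hydrogen-bond geometries and planted
  guest-inclusion events, at a safe margin from the decision boundaries;
- noisy linear gamma-vs-chain-length series emulating a glycine-repeat
  (NAG_xA-style) peptide experiment.

All generators draw from one numpy Generator seeded from the spec; equal
specs give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import quad

from .thermo import GAS_CONSTANT, BinaryThermoState, KBITriple
from .trajectory import Trajectory, minimum_image_distance_matrix

__all__ = [
    "SyntheticFluidSpec",
    "PlantedHBondFixture",
    "PlantedInclusionFixture",
    "GammaSeriesSpec",
    "ThermoConstants",
    "analytic_kbi",
    "gen_ideal_gas",
    "gen_structured_fluid",
    "gen_hbond_fixture",
    "gen_inclusion_fixture",
    "gen_gamma_series",
    "gen_binary_thermo_dataset",
]


@dataclass
class SyntheticFluidSpec:
    """Parameters of a synthetic pair fluid.

    ``n_centers`` reference particles (species "center") and ``n_partners``
    observed particles (species "partner") in a cubic periodic box of edge
    ``box_edge`` nm.  For ``rdf_form="exponential_excess"`` the partner pair
    density around centers follows g(r) = 1 + A exp(-r/lambda).
    """

    n_centers: int
    n_partners: int
    box_edge: float
    rdf_form: str = "ideal"
    amplitude: float = 0.0
    decay_length: float | None = None
    n_frames: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_centers < 1 or self.n_partners < 1:
            raise ValueError("particle counts must be >= 1")
        if self.box_edge <= 0:
            raise ValueError("box edge must be positive")
        if self.n_frames < 1:
            raise ValueError("need at least one frame")
        if self.rdf_form not in ("ideal", "exponential_excess"):
            raise ValueError(f"unknown rdf_form {self.rdf_form!r}")
        if self.rdf_form == "exponential_excess":
            if self.decay_length is None or self.decay_length <= 0:
                raise ValueError("exponential_excess requires decay_length > 0")
            if self.amplitude <= -1.0:
                raise ValueError("amplitude must exceed -1 (pair density >= 0)")
            if self.decay_length >= self.box_edge / 4.0:
                raise ValueError(
                    "decay_length must be below box_edge/4 for a minimum-image-"
                    "realizable target"
                )


def analytic_kbi(amplitude: float, decay_length: float) -> float:
    """Closed-form KBI of g(r) = 1 + A exp(-r/lambda):
    4 pi A int_0^inf r^2 exp(-r/lambda) dr = 8 pi A lambda^3, nm^3."""
    return 8.0 * np.pi * amplitude * decay_length**3


def _species(spec: SyntheticFluidSpec) -> np.ndarray:
    return np.array(["center"] * spec.n_centers + ["partner"] * spec.n_partners)


def gen_ideal_gas(spec: SyntheticFluidSpec) -> Trajectory:
    """Uniform i.i.d. placement of centers and partners: the null model with
    g(r) = 1 and G = 0 in the open-system sense."""
    if spec.rdf_form != "ideal":
        raise ValueError("gen_ideal_gas requires rdf_form='ideal'")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_centers + spec.n_partners
    pos = rng.random((spec.n_frames, n, 3)) * spec.box_edge
    return Trajectory(
        positions=pos,
        species=_species(spec),
        box=np.full(3, spec.box_edge),
        metadata={"rdf_form": "ideal", "G_analytic": 0.0, "spec": spec},
    )


def _sample_excess_radii(rng, lam, r_cut, size):
    """Radii with pdf proportional to r^2 exp(-r/lambda), truncated at r_cut."""
    out = np.empty(0)
    while out.size < size:
        r = rng.gamma(3.0, lam, size=2 * size)
        out = np.concatenate([out, r[r < r_cut]])
    return out[:size]


def gen_structured_fluid(spec: SyntheticFluidSpec) -> Trajectory:
    """Partner placement realizing g(r) = 1 + A exp(-r/lambda) around centers.

    Partners are drawn i.i.d. from the normalized density proportional to
    1 + A' sum_c exp(-|x - c|/lambda), with A' = A / (1 - n_c A wbar),
    wbar = 8 pi lambda^3 / V, so that after bulk renormalization the pair
    density around any one center has excess amplitude exactly A.  Positive
    A uses exact mixture sampling (uniform + per-center radial bumps);
    negative A uses thinning of uniform candidates with acceptance weight
    1 + A' sum_c exp(-r_c/lambda), clamped at zero (the clamp triggers only
    for near-coincident centers and is negligible at the default dilutions).

    The trajectory records the analytic open-system KBI 8 pi A lambda^3 in
    ``metadata["G_analytic"]``; the residual closed-system depletion of
    order G/V is first-order removed by the finite-size correction.
    """
    if spec.rdf_form != "exponential_excess":
        raise ValueError("gen_structured_fluid requires rdf_form='exponential_excess'")
    rng = np.random.default_rng(spec.seed)
    A, lam, L = spec.amplitude, spec.decay_length, spec.box_edge
    V = L**3
    wbar = 8.0 * np.pi * lam**3 / V
    denom = 1.0 - spec.n_centers * A * wbar
    if denom <= 0:
        raise ValueError("target amplitude not realizable: too many centers per volume")
    A_eff = A / denom
    box = np.full(3, L)
    r_cut = L / 2.0

    frames = np.empty((spec.n_frames, spec.n_centers + spec.n_partners, 3))
    for f in range(spec.n_frames):
        centers = rng.random((spec.n_centers, 3)) * L
        if A == 0.0:
            partners = rng.random((spec.n_partners, 3)) * L
        elif A > 0.0:
            # mixture: uniform with weight V, one bump of weight A' * 8 pi
            # lambda^3 per center
            bump_w = A_eff * 8.0 * np.pi * lam**3
            p_uniform = V / (V + spec.n_centers * bump_w)
            u = rng.random(spec.n_partners)
            n_unif = int(np.sum(u < p_uniform))
            n_bump = spec.n_partners - n_unif
            partners = np.empty((spec.n_partners, 3))
            partners[:n_unif] = rng.random((n_unif, 3)) * L
            if n_bump:
                which = rng.integers(0, spec.n_centers, size=n_bump)
                radii = _sample_excess_radii(rng, lam, r_cut, n_bump)
                vec = rng.normal(size=(n_bump, 3))
                vec /= np.linalg.norm(vec, axis=1, keepdims=True)
                partners[n_unif:] = np.mod(centers[which] + radii[:, None] * vec, L)
            partners = partners[rng.permutation(spec.n_partners)]
        else:
            # thinning: weight <= 1 everywhere for A' < 0
            accepted = []
            need = spec.n_partners
            while need > 0:
                cand = rng.random((max(2 * need, 256), 3)) * L
                d = minimum_image_distance_matrix(cand, centers, box)
                w = np.clip(1.0 + A_eff * np.exp(-d / lam).sum(axis=1), 0.0, None)
                keep = cand[rng.random(len(cand)) < w]
                accepted.append(keep[:need])
                need -= len(keep[:need])
            partners = np.concatenate(accepted)
        frames[f, : spec.n_centers] = centers
        frames[f, spec.n_centers :] = partners

    return Trajectory(
        positions=frames,
        species=_species(spec),
        box=box,
        metadata={
            "rdf_form": "exponential_excess",
            "amplitude": A,
            "decay_length": lam,
            "G_analytic": analytic_kbi(A, lam),
            "spec": spec,
        },
    )


# ---------------------------------------------------------------------------
# planted geometric fixtures


@dataclass
class PlantedHBondFixture:
    """Donor/hydrogen/acceptor triples with a known number of true hydrogen
    bonds; every planted geometry keeps >= 0.005 nm / >= 2 deg margin from
    the 0.35 nm / 30 deg criterion so binning can never flip it."""

    donor_positions: np.ndarray
    hydrogen_positions: np.ndarray
    acceptor_positions: np.ndarray
    planted_true_count: int
    box: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.donor_positions)
        if self.planted_true_count > n:
            raise ValueError("planted_true_count exceeds number of triples")


def _triple_geometry(rng, d, theta_deg, origin):
    """Donor at origin, acceptor at distance d, hydrogen at 0.1 nm from the
    donor making angle theta with the donor->acceptor line."""
    u = rng.normal(size=3)
    u /= np.linalg.norm(u)
    v = rng.normal(size=3)
    v -= v.dot(u) * u
    v /= np.linalg.norm(v)
    theta = np.deg2rad(theta_deg)
    h_dir = np.cos(theta) * u + np.sin(theta) * v
    return origin, origin + 0.1 * h_dir, origin + d * u


def gen_hbond_fixture(n_true: int, n_false: int, seed: int = 0) -> PlantedHBondFixture:
    """Plant ``n_true`` genuine and ``n_false`` spoiled donor-H-acceptor
    triples on a lattice (spacing 1.2 nm, so no cross-triple pair can come
    within the distance cutoff)."""
    if n_true < 0 or n_false < 0:
        raise ValueError("counts must be non-negative")
    rng = np.random.default_rng(seed)
    n = n_true + n_false
    side = max(int(np.ceil(n ** (1.0 / 3.0))), 1)
    spacing = 1.2
    sites = spacing * (
        np.stack(
            np.meshgrid(*[np.arange(side)] * 3, indexing="ij"), axis=-1
        ).reshape(-1, 3)
        + 0.5
    )
    box = np.full(3, max(side * spacing, 2.0))

    donors = np.zeros((n, 3))
    hydrogens = np.zeros((n, 3))
    acceptors = np.zeros((n, 3))
    for k in range(n):
        if k < n_true:
            d = rng.uniform(0.26, 0.345)
            theta = rng.uniform(0.0, 28.0)
        else:
            mode = rng.integers(0, 3)
            d = rng.uniform(0.355, 0.50) if mode in (0, 2) else rng.uniform(0.26, 0.345)
            theta = rng.uniform(32.0, 80.0) if mode in (1, 2) else rng.uniform(0.0, 28.0)
        donors[k], hydrogens[k], acceptors[k] = _triple_geometry(rng, d, theta, sites[k])
    return PlantedHBondFixture(
        donor_positions=donors,
        hydrogen_positions=hydrogens,
        acceptor_positions=acceptors,
        planted_true_count=n_true,
        box=box,
    )


@dataclass
class PlantedInclusionFixture:
    """Host (cyclodextrin) and guest centers of mass with a known number of
    inclusion events; planted distances keep >= 0.02 nm margin from the
    0.5 nm center-of-mass cutoff."""

    cd_com_positions: np.ndarray
    guest_com_positions: np.ndarray
    planted_included_count: int
    box: np.ndarray

    def to_trajectory(self) -> Trajectory:
        pos = np.concatenate([self.cd_com_positions, self.guest_com_positions])
        species = np.array(
            ["CD"] * len(self.cd_com_positions) + ["GUEST"] * len(self.guest_com_positions)
        )
        return Trajectory(positions=pos[None], species=species, box=self.box)


def gen_inclusion_fixture(
    n_in: int, n_out: int, n_cds: int, seed: int = 0
) -> PlantedInclusionFixture:
    """Plant ``n_in`` guests inside (< 0.48 nm) distinct hosts and ``n_out``
    guests outside every host (> 0.52 nm from all).  Hosts sit on a 3 nm
    lattice so assignments are unambiguous."""
    if n_in < 0 or n_out < 0:
        raise ValueError("counts must be non-negative")
    if n_cds < 1:
        raise ValueError("need at least one host")
    if n_in > n_cds:
        raise ValueError("cannot plant more included hosts than hosts")
    rng = np.random.default_rng(seed)
    side = max(int(np.ceil(n_cds ** (1.0 / 3.0))), 1)
    spacing = 3.0
    sites = spacing * (
        np.stack(
            np.meshgrid(*[np.arange(side)] * 3, indexing="ij"), axis=-1
        ).reshape(-1, 3)
        + 0.5
    )
    cds = sites[:n_cds]
    box = np.full(3, side * spacing)

    guests = []
    for k in range(n_in):
        r = rng.uniform(0.15, 0.48)
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        guests.append(cds[k] + r * u)
    for k in range(n_out):
        host = cds[rng.integers(0, n_cds)]
        r = rng.uniform(0.60, 1.20)
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        guests.append(host + r * u)
    guests = np.asarray(guests).reshape(-1, 3) if guests else np.empty((0, 3))
    return PlantedInclusionFixture(
        cd_com_positions=np.mod(cds, box),
        guest_com_positions=np.mod(guests, box) if len(guests) else guests,
        planted_included_count=n_in,
        box=box,
    )


# ---------------------------------------------------------------------------
# gamma series (glycine-repeat peptide emulation)


@dataclass
class GammaSeriesSpec:
    """Ground truth for a preferential-interaction series gamma(x) =
    gamma_eg + gamma_bb * x + noise, x = number of internal glycine units."""

    gamma_eg_true: float
    gamma_bb_true: float
    x_values: Sequence[int] = field(default_factory=lambda: (1, 2, 3, 4, 5, 6))
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        xs = np.asarray(self.x_values)
        if xs.size == 0:
            raise ValueError("x_values must be non-empty")
        if np.any(np.diff(xs) <= 0) or np.any(xs < 1):
            raise ValueError("x_values must be strictly increasing integers >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def gen_gamma_series(spec: GammaSeriesSpec) -> list[tuple[int, float]]:
    """One realization of the series: (x, gamma) pairs with i.i.d. Gaussian
    noise of the spec's standard deviation, reproducible under the seed."""
    rng = np.random.default_rng(spec.seed)
    xs = np.asarray(spec.x_values, dtype=float)
    gam = spec.gamma_eg_true + spec.gamma_bb_true * xs
    if spec.noise_sd > 0:
        gam = gam + rng.normal(0.0, spec.noise_sd, size=xs.size)
    else:
        gam = gam + 0.0 * rng.normal(size=xs.size)  # keep stream position deterministic
    return [(int(x), float(g)) for x, g in zip(xs, gam)]


# ---------------------------------------------------------------------------
# forward-generated binary thermodynamic datasets


@dataclass
class ThermoConstants:
    """Dilute-limit constants of the binary mixture: temperature (K), water
    partial molar volume (cm^3/mol) and a reference isothermal
    compressibility (1/Pa) kept as metadata."""

    T: float = 298.0
    V1: float = 18.07
    betaT: float = 4.52e-10


def _forward_point(x3: float, kbi: KBITriple, const: ThermoConstants):
    """Solve the binary KB system at one composition for (rho, V3, D).

    Unknowns follow from the inversion algebra run forward with constant V1:
    rho (mol/cm^3) is the positive root of
        V1 x1 x3 Delta rho^2 + (V1 - x3 (G33 - G13)) rho - 1 = 0,
    then V3 from the volume identity x1 V1 + x3 V3 = 1/rho and the
    thermodynamic factor D = 1 / (1 + rho x1 x3 Delta).
    """
    kbi = kbi.in_cm3_per_mol()
    x1 = 1.0 - x3
    delta = kbi.G11 + kbi.G33 - 2.0 * kbi.G13
    a = const.V1 * x1 * x3 * delta
    b = const.V1 - x3 * (kbi.G33 - kbi.G13)
    disc = b * b + 4.0 * a
    if disc <= 0:
        raise ValueError(f"KBI profile unrealizable at x3 = {x3}: density root vanishes")
    rho = 2.0 / (b + np.sqrt(disc))  # stable positive root, -> 1/b as a -> 0
    if rho <= 0:
        raise ValueError(f"KBI profile gives non-positive density at x3 = {x3}")
    denomD = 1.0 + rho * x1 * x3 * delta
    if denomD <= 0:
        raise ValueError(
            f"thermodynamic factor denominator vanishes at x3 = {x3} "
            "(KBI profile thermodynamically unstable)"
        )
    V3 = (1.0 / rho - x1 * const.V1) / x3
    D = 1.0 / denomD
    return rho, V3, D, delta, kbi


def gen_binary_thermo_dataset(
    kbi_profile: Callable[[float], KBITriple],
    x3_grid: Sequence[float],
    constants: ThermoConstants | None = None,
) -> list[BinaryThermoState]:
    """Forward-generate binary thermodynamic states from a KBI profile.

    For each dilute composition (0 < x3 <= 0.05) the density, cosolvent
    partial molar volume, chemical-potential derivative and activity
    coefficients are constructed so that :func:`kbsolv.thermo.
    invert_thermo_to_kbi` returns exactly the profile's KBIs.  The
    state-consistent compressibility betaT = (G13 + rho V1 V3 / D)/(RT) is
    stored per state: prescribing all three KBIs together with constant V1
    leaves no freedom for an independent betaT, so the constants' value is
    dilute-limit metadata only.  The activity coefficient follows from
    ln f3(x3) = int_0^x3 (D(s) - 1)/s ds and f3m = x3 f3.
    """
    const = constants or ThermoConstants()
    x3_grid = np.asarray(x3_grid, dtype=float)
    if np.any(x3_grid <= 0) or np.any(x3_grid > 0.05):
        raise ValueError("x3 grid must lie in (0, 0.05] (dilute regime)")

    def dlnf3_dx3(s: float) -> float:
        _, _, D, _, _ = _forward_point(s, kbi_profile(s), const)
        return (D - 1.0) / s

    states = []
    for x3 in x3_grid:
        rho, V3, D, delta, kbi = _forward_point(float(x3), kbi_profile(float(x3)), const)
        x1 = 1.0 - x3
        dmu3 = GAS_CONSTANT * const.T * D / x3
        # betaT consistent with the inversion identity G13 = RT betaT - rho V1 V3 / D
        betaT = (kbi.G13 + rho * const.V1 * V3 / D) * 1e-6 / (GAS_CONSTANT * const.T)
        if betaT <= 0:
            raise ValueError(f"KBI profile implies non-positive compressibility at x3 = {x3}")
        lnf3, _ = quad(dlnf3_dx3, 0.0, float(x3), limit=200)
        f3 = float(np.exp(lnf3))
        states.append(
            BinaryThermoState(
                T=const.T,
                x3=float(x3),
                rho=rho * 1000.0,  # mol/cm^3 -> mol/L
                V1=const.V1,
                V3=V3,
                betaT=float(betaT),
                dmu3_dx3=float(dmu3),
                f3=f3,
                f3m=float(x3 * f3),
            )
        )
    return states
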