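"""Radial distribution functions and Kirkwood-Buff integrals.

The pipeline is g_ij(r) -> finite-size-corrected g_ij(r) -> running integral
G_ij(R) -> converged estimate with uncertainty.  The Kirkwood-Buff integral

    G_ij = 4 pi * integral_0^inf (g_ij(r) - 1) r^2 dr      [nm^3]

measures the net excess (+) or depletion (-) of species j around species i
relative to an ideal solution.  Closed-system (NVT/NpT) radial distribution
functions carry an O(1/N) finite-size bias that shifts G_ij systematically;
the Ganguly-van der Vegt rescaling applied here removes it to first order.

Conventions (fixed so that brute-force oracles are exact):
- uniform half-open distance bins [r, r + dr), reported at bin centers;
- minimum-image distances, orthorhombic boxes only;
- ideal-gas normalization uses the instantaneous box volume and the *total*
  count N_j of the observed species (self pairs excluded from counting when
  the two selections coincide, but not from the normalization -- this is the
  closed-system convention the finite-size correction expects).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .trajectory import (
    Trajectory,
    group_centers_of_mass,
    minimum_image_distance_matrix,
    resolve_selection,
)

__all__ = [
    "RDFCurve",
    "RunningKBI",
    "KBIEstimate",
    "compute_rdf",
    "excess_counts",
    "correct_rdf_finite_size",
    "running_kbi",
    "estimate_kbi",
    "kbi_from_trajectory",
    "nm3_to_cm3_per_mol",
    "cm3_per_mol_to_nm3",
]

AVOGADRO = 6.02214076e23
#: 1 nm^3 per molecule expressed in cm^3/mol
NM3_TO_CM3_MOL = AVOGADRO * 1e-21


def nm3_to_cm3_per_mol(value):
    """Convert a per-molecule KBI in nm^3 to the molar scale in cm^3/mol."""
    value = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(value)):
        raise ValueError("KBI value must be finite")
    out = value * NM3_TO_CM3_MOL
    return float(out) if out.ndim == 0 else out


def cm3_per_mol_to_nm3(value):
    """Inverse of :func:`nm3_to_cm3_per_mol`."""
    value = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(value)):
        raise ValueError("KBI value must be finite")
    out = value / NM3_TO_CM3_MOL
    return float(out) if out.ndim == 0 else out


@dataclass
class RDFCurve:
    """g_ij(r) on uniform bin centers, plus the bookkeeping the finite-size
    correction needs (particle counts, mean volume, like-species flag)."""

    r: np.ndarray
    g: np.ndarray
    pair: tuple
    n_i: int
    n_j: int
    volume: float
    frame_count: int
    dr: float
    like_species: bool = False
    corrected: bool = False

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if self.r.ndim != 1 or self.r.shape != self.g.shape:
            raise ValueError("r and g must be 1-D arrays of equal length")
        if np.any(np.diff(self.r) <= 0):
            raise ValueError("r must be strictly increasing")
        if np.any(self.g < 0):
            raise ValueError("g(r) must be non-negative")
        if self.n_i < 1 or self.n_j < 1:
            raise ValueError("particle counts must be >= 1")


@dataclass
class RunningKBI:
    """Cumulative KB integral G(R) = 4 pi int_0^R (g-1) r^2 dr, nm^3.

    The grid starts at R = 0 where G is identically zero; quadrature is
    trapezoidal on the RDF bin centers.
    """

    R: np.ndarray
    G_of_R: np.ndarray
    quadrature: str = "trapezoid"

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        self.G_of_R = np.asarray(self.G_of_R, dtype=float)
        if self.R.shape != self.G_of_R.shape:
            raise ValueError("R and G_of_R must have equal length")
        if self.G_of_R[0] != 0.0:
            raise ValueError("running KBI must start at G(0) = 0")


@dataclass
class KBIEstimate:
    """Converged KBI: window average of G(R) with a block-averaging stderr."""

    G: float
    stderr: float
    window: tuple
    corrected: bool
    blocks: int = 1
    flat: bool = True
    unit: str = "nm^3"

    def __post_init__(self) -> None:
        if self.stderr < 0:
            raise ValueError("stderr must be non-negative")
        lo, hi = self.window
        if not lo < hi:
            raise ValueError("window must satisfy R_lo < R_hi")


def _selection_positions(traj: Trajectory, frame: int, sel):
    """Positions for a selection: atom indices, a species label, or a list of
    index groups (interpreted as mass-weighted centers of mass)."""
    pos = traj.positions[frame]
    if isinstance(sel, (list, tuple)) and len(sel) and not np.isscalar(sel[0]):
        return group_centers_of_mass(pos, traj.masses, traj.box[frame], sel)
    idx = resolve_selection(traj.species, sel)
    return pos[idx]


def _same_selection(traj: Trajectory, sel_i, sel_j) -> bool:
    grouped_i = isinstance(sel_i, (list, tuple)) and len(sel_i) and not np.isscalar(sel_i[0])
    grouped_j = isinstance(sel_j, (list, tuple)) and len(sel_j) and not np.isscalar(sel_j[0])
    if grouped_i != grouped_j:
        return False
    if grouped_i:
        return len(sel_i) == len(sel_j) and all(
            np.array_equal(a, b) for a, b in zip(sel_i, sel_j)
        )
    return np.array_equal(
        resolve_selection(traj.species, sel_i), resolve_selection(traj.species, sel_j)
    )


def _check_rmax(traj: Trajectory, r_max: float) -> None:
    half_min_edge = float(traj.box.min()) / 2.0
    if r_max > half_min_edge + 1e-12:
        raise ValueError(
            f"r_max = {r_max} nm exceeds half the smallest box edge "
            f"({half_min_edge} nm); minimum-image distances are invalid there"
        )


def compute_rdf(traj: Trajectory, sel_i, sel_j, dr: float, r_max: float) -> RDFCurve:
    """Radial distribution function of selection j around selection i.

    Selections may be species labels, index arrays, or lists of index groups
    (centers of mass).  Distances use the minimum-image convention; bins are
    half-open [r, r + dr); normalization divides the observed pair count by
    the ideal-gas expectation N_i * N_j * V_shell / V from the instantaneous
    box volume.  Self pairs are excluded when the selections coincide.
    """
    if dr <= 0:
        raise ValueError("dr must be positive")
    _check_rmax(traj, r_max)
    n_bins = int(np.floor(r_max / dr + 1e-9))
    if n_bins < 1:
        raise ValueError("r_max must allow at least one bin")
    edges = dr * np.arange(n_bins + 1)
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    like = _same_selection(traj, sel_i, sel_j)

    g_sum = np.zeros(n_bins)
    vol_sum = 0.0
    n_i = n_j = 0
    for f in range(traj.n_frames):
        pos_i = _selection_positions(traj, f, sel_i)
        pos_j = _selection_positions(traj, f, sel_j)
        n_i, n_j = len(pos_i), len(pos_j)
        box = traj.box[f]
        vol = float(np.prod(box))
        d = minimum_image_distance_matrix(pos_i, pos_j, box)
        if like:
            np.fill_diagonal(d, np.inf)
        counts, _ = np.histogram(d[d < r_max], bins=edges)
        ideal = n_i * n_j / vol * shell_vol
        g_sum += counts / ideal
        vol_sum += vol

    return RDFCurve(
        r=edges[:-1] + dr / 2.0,
        g=g_sum / traj.n_frames,
        pair=(str(sel_i), str(sel_j)),
        n_i=n_i,
        n_j=n_j,
        volume=vol_sum / traj.n_frames,
        frame_count=traj.n_frames,
        dr=dr,
        like_species=like,
    )


def excess_counts(traj: Trajectory, sel_i, sel_j, r_grid: np.ndarray) -> np.ndarray:
    """Mean excess number of j particles within radius r of an i particle.

        Delta N_ij(r) = <n_j(< r)> - (N_j / V) * (4/3) pi r^3

    averaged over frames and reference particles, with the self pair
    excluded when the selections coincide (consistent with compute_rdf).
    """
    r_grid = np.asarray(r_grid, dtype=float)
    _check_rmax(traj, float(r_grid.max()))
    like = _same_selection(traj, sel_i, sel_j)
    sphere = 4.0 / 3.0 * np.pi * r_grid**3

    dn = np.zeros_like(r_grid)
    for f in range(traj.n_frames):
        pos_i = _selection_positions(traj, f, sel_i)
        pos_j = _selection_positions(traj, f, sel_j)
        box = traj.box[f]
        vol = float(np.prod(box))
        d = minimum_image_distance_matrix(pos_i, pos_j, box)
        if like:
            np.fill_diagonal(d, np.inf)
        flat = np.sort(d, axis=None)
        counts = np.searchsorted(flat, r_grid, side="left") / len(pos_i)
        dn += counts - len(pos_j) / vol * sphere
    return dn / traj.n_frames


def correct_rdf_finite_size(rdf: RDFCurve, excess: np.ndarray) -> RDFCurve:
    """Ganguly-van der Vegt finite-size rescaling of a closed-system RDF.

        g_corr(r) = g(r) * N_j (1 - Vs/V) / (N_j (1 - Vs/V) - DN_ij(r) - d_ij)

    with Vs = (4/3) pi r^3, DN_ij the excess count of j within r, and d_ij
    the Kronecker delta on the species pair.  The factor tends to 1 at small
    r for unlike pairs and restores open-system behaviour to first order in
    1/N_j.  Refuses already-corrected input.
    """
    if rdf.corrected:
        raise ValueError("RDF is already finite-size corrected; refusing to re-apply")
    excess = np.asarray(excess, dtype=float)
    if excess.shape != rdf.r.shape:
        raise ValueError("excess-count curve must share the RDF grid")
    delta = 1.0 if rdf.like_species else 0.0
    vs = 4.0 / 3.0 * np.pi * rdf.r**3
    closed = rdf.n_j * (1.0 - vs / rdf.volume)
    denom = closed - excess - delta
    if np.any(denom <= 0):
        raise ValueError("finite-size correction denominator vanished; system too small")
    return RDFCurve(
        r=rdf.r.copy(),
        g=rdf.g * closed / denom,
        pair=rdf.pair,
        n_i=rdf.n_i,
        n_j=rdf.n_j,
        volume=rdf.volume,
        frame_count=rdf.frame_count,
        dr=rdf.dr,
        like_species=rdf.like_species,
        corrected=True,
    )


def running_kbi(rdf: RDFCurve) -> RunningKBI:
    """Cumulative trapezoidal KB integral on the RDF grid (prepending the
    exact point G(0) = 0; the integrand 4 pi (g-1) r^2 vanishes at r = 0)."""
    integrand = 4.0 * np.pi * (rdf.g - 1.0) * rdf.r**2
    R = np.concatenate([[0.0], rdf.r])
    f = np.concatenate([[0.0], integrand])
    G = np.concatenate([[0.0], np.cumsum(np.diff(R) * (f[1:] + f[:-1]) / 2.0)])
    return RunningKBI(R=R, G_of_R=G)


def estimate_kbi(
    running,
    window: tuple = (1.5, 2.5),
    flatness_threshold: float = 0.5,
    corrected: bool | None = None,
) -> KBIEstimate:
    """Average G(R) over a convergence window.

    ``running`` may be a single :class:`RunningKBI` (stderr = 0, one block)
    or a sequence of per-block curves, in which case the estimate is the
    block mean and stderr the standard error over blocks.  A window where
    the mean |dG/dR| exceeds ``flatness_threshold`` (nm^3 per nm) draws a
    convergence warning but not a failure.
    """
    curves = [running] if isinstance(running, RunningKBI) else list(running)
    if not curves:
        raise ValueError("need at least one running-KBI curve")
    lo, hi = window
    R = curves[0].R
    if lo < R.min() - 1e-12 or hi > R.max() + 1e-12:
        raise ValueError(f"window {window} lies outside the R grid [{R.min()}, {R.max()}]")
    mask = (R >= lo) & (R <= hi)
    if mask.sum() < 2:
        raise ValueError("window contains fewer than two grid points")

    per_block = []
    for c in curves:
        if c.R.shape != R.shape or not np.allclose(c.R, R):
            raise ValueError("block curves must share one R grid")
        per_block.append(float(c.G_of_R[mask].mean()))
    per_block = np.asarray(per_block)
    G = float(per_block.mean())
    stderr = (
        float(per_block.std(ddof=1) / np.sqrt(len(per_block))) if len(per_block) > 1 else 0.0
    )

    mean_curve = np.mean([c.G_of_R for c in curves], axis=0)
    slope = np.abs(np.gradient(mean_curve, R))[mask].mean()
    flat = bool(slope <= flatness_threshold)
    if not flat:
        warnings.warn(
            f"running KBI is not flat on window {window}: mean |dG/dR| = {slope:.3g} nm^2",
            stacklevel=2,
        )
    return KBIEstimate(
        G=G,
        stderr=stderr,
        window=(float(lo), float(hi)),
        corrected=bool(corrected) if corrected is not None else False,
        blocks=len(per_block),
        flat=flat,
    )


def kbi_from_trajectory(
    traj: Trajectory,
    sel_i,
    sel_j,
    dr: float = 0.02,
    r_max: float | None = None,
    window: tuple = (1.5, 2.5),
    blocks: int = 5,
    correct: bool = True,
) -> KBIEstimate:
    """End-to-end KBI estimate: per-block RDF (optionally finite-size
    corrected), running integral, window average, block-averaging stderr."""
    if blocks < 1:
        raise ValueError("blocks must be >= 1")
    if traj.n_frames < blocks:
        raise ValueError("fewer frames than blocks")
    if r_max is None:
        r_max = float(traj.box.min()) / 2.0
    bounds = np.linspace(0, traj.n_frames, blocks + 1).astype(int)
    curves = []
    for b in range(blocks):
        part = traj.slice_frames(bounds[b], bounds[b + 1])
        rdf = compute_rdf(part, sel_i, sel_j, dr=dr, r_max=r_max)
        if correct:
            dn = excess_counts(part, sel_i, sel_j, rdf.r)
            rdf = correct_rdf_finite_size(rdf, dn)
        curves.append(running_kbi(rdf))
    est = estimate_kbi(curves, window=window)
    est.corrected = correct
    return est
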