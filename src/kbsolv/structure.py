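"""Per-trajectory structural metrics for host-guest solvation analysis.

Three families of metrics characterize how a cyclodextrin-like host meets
an amino-acid guest:

- geometric hydrogen bonds: donor-acceptor distance < 0.35 nm and proton
  deviation angle < 30 deg (strict inequalities), plus the chi percentage
  of a guest's hydrogen bonds that involve the host;
- cavity inclusion: a host counts as including when any guest center of
  mass lies strictly closer than 0.5 nm to the host center of mass,
  frame-averaged and normalized by the host count;
- orientation: maxima of radial distribution functions between the host's
  primary (C6-side) or secondary (C2/C3-side) rim atoms and guest centers
  of mass, and between guest backbone/side-chain atoms and the secondary
  rim center of mass.

The hydrogen-bond angle phrase in the underlying criterion is ambiguous;
this module uses the standard proton-deviation reading -- the angle at the
donor between the donor->hydrogen vector and the donor->acceptor line --
with the vertex configurable (``angle_vertex="hydrogen"`` measures the
D-H...A angle deviation from linearity instead).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .rdf import compute_rdf
from .trajectory import (
    ParticleConfiguration,
    Trajectory,
    group_centers_of_mass,
    minimum_image_displacements,
    minimum_image_distance_matrix,
)

__all__ = [
    "HBondCriterion",
    "InclusionCriterion",
    "InclusionResult",
    "ChiResult",
    "RimDefinition",
    "RdfMaximum",
    "detect_hbonds",
    "chi_parameter",
    "inclusion_fraction",
    "rim_orientation_rdf_max",
    "backbone_sidechain_rdf_max",
]


@dataclass
class HBondCriterion:
    """Geometric hydrogen-bond criterion: donor-acceptor distance below
    ``d_max`` nm and angle below ``angle_max`` degrees, both strict."""

    d_max: float = 0.35
    angle_max: float = 30.0

    def __post_init__(self) -> None:
        if self.d_max <= 0:
            raise ValueError("d_max must be positive")
        if not 0.0 < self.angle_max < 90.0:
            raise ValueError("angle_max must lie in (0, 90) degrees")


@dataclass
class InclusionCriterion:
    """Center-of-mass inclusion cutoff (nm, strict)."""

    com_cutoff: float = 0.5

    def __post_init__(self) -> None:
        if self.com_cutoff <= 0:
            raise ValueError("com_cutoff must be positive")


@dataclass
class InclusionResult:
    percent_cds_including: float
    per_frame_counts: np.ndarray
    n_cds: int

    def __post_init__(self) -> None:
        self.per_frame_counts = np.asarray(self.per_frame_counts)
        if not 0.0 <= self.percent_cds_including <= 100.0:
            raise ValueError("percentage must lie in [0, 100]")


@dataclass
class ChiResult:
    """chi: percentage of the guests' hydrogen bonds that involve the host."""

    chi: float
    host_guest_bonds: float
    total_guest_bonds: float
    per_frame_counts: np.ndarray | None = None


@dataclass
class RimDefinition:
    """Disjoint atom selections for the host's two rims."""

    primary_rim_atoms: np.ndarray
    secondary_rim_atoms: np.ndarray

    def __post_init__(self) -> None:
        self.primary_rim_atoms = np.asarray(self.primary_rim_atoms, dtype=int)
        self.secondary_rim_atoms = np.asarray(self.secondary_rim_atoms, dtype=int)
        if self.primary_rim_atoms.size == 0 or self.secondary_rim_atoms.size == 0:
            raise ValueError("rim selections must be non-empty")
        if np.intersect1d(self.primary_rim_atoms, self.secondary_rim_atoms).size:
            raise ValueError("rim selections must be disjoint")


@dataclass
class RdfMaximum:
    max_g: float
    r_at_max: float
    absent: bool = False


def detect_hbonds(
    config: ParticleConfiguration,
    donors: Sequence[int],
    hydrogens: Sequence[int],
    acceptors: Sequence[int],
    crit: HBondCriterion | None = None,
    angle_vertex: str = "donor",
) -> int:
    """Count hydrogen bonds in one frame under the strict geometric criterion.

    ``donors`` and ``hydrogens`` are index arrays of equal length mapping
    each hydrogen to exactly one donor; ``acceptors`` is independent.  A
    (hydrogen, acceptor) pair is bonded when the donor-acceptor distance is
    strictly below ``crit.d_max`` and the deviation angle strictly below
    ``crit.angle_max``.  An acceptor identical to the donor atom is skipped.
    """
    crit = crit or HBondCriterion()
    donors = np.asarray(donors, dtype=int)
    hydrogens = np.asarray(hydrogens, dtype=int)
    acceptors = np.asarray(acceptors, dtype=int)
    if donors.size == 0 or acceptors.size == 0:
        raise ValueError("donor and acceptor selections must be non-empty")
    if donors.shape != hydrogens.shape:
        raise ValueError("each hydrogen must map to exactly one donor (equal-length arrays)")
    if angle_vertex not in ("donor", "hydrogen"):
        raise ValueError("angle_vertex must be 'donor' or 'hydrogen'")

    pos, box = config.positions, config.box
    d_da = minimum_image_distance_matrix(pos[donors], pos[acceptors], box)
    self_pair = donors[:, None] == acceptors[None, :]

    if angle_vertex == "donor":
        ref = minimum_image_displacements(pos[donors], pos[hydrogens], box)
        to_acc = minimum_image_displacements(
            pos[donors][:, None, :], pos[acceptors][None, :, :], box
        )
    else:
        ref = minimum_image_displacements(pos[hydrogens], pos[donors], box)
        to_acc = minimum_image_displacements(
            pos[hydrogens][:, None, :], pos[acceptors][None, :, :], box
        )
    ref_n = ref / np.linalg.norm(ref, axis=1, keepdims=True)
    acc_n = to_acc / np.linalg.norm(to_acc, axis=2, keepdims=True)
    cosang = np.clip(np.einsum("ik,ijk->ij", ref_n, acc_n), -1.0, 1.0)
    ang = np.degrees(np.arccos(cosang))
    if angle_vertex == "hydrogen":
        # deviation of D-H...A from linearity: angle between H->A and the
        # extension of D->H, i.e. 180 deg minus the H-vertex angle
        ang = 180.0 - ang

    bonded = (d_da < crit.d_max) & (ang < crit.angle_max) & ~self_pair
    return int(bonded.sum())


def chi_parameter(
    host_guest_counts: Sequence[float],
    total_guest_counts: Sequence[float],
) -> ChiResult:
    """Percentage of guest hydrogen bonds formed with the host.

        chi = 100 * sum_f n_host-guest(f) / sum_f n_total(f)

    over equilibrated frames.  chi is monotone nondecreasing in the
    host-guest count at fixed normalization; a zero denominator yields
    chi = 0 with a warning.
    """
    hg = np.asarray(host_guest_counts, dtype=float)
    tot = np.asarray(total_guest_counts, dtype=float)
    if hg.shape != tot.shape:
        raise ValueError("count series must have equal length")
    if np.any(hg < 0) or np.any(tot < 0):
        raise ValueError("counts must be non-negative")
    if np.any(hg > tot):
        raise ValueError("host-guest bonds cannot exceed the total guest bonds")
    denom = tot.sum()
    if denom == 0:
        warnings.warn("no guest hydrogen bonds at all; chi defined as 0", stacklevel=2)
        return ChiResult(chi=0.0, host_guest_bonds=0.0, total_guest_bonds=0.0,
                         per_frame_counts=hg)
    return ChiResult(
        chi=float(100.0 * hg.sum() / denom),
        host_guest_bonds=float(hg.sum()),
        total_guest_bonds=float(denom),
        per_frame_counts=hg,
    )


def inclusion_fraction(
    traj: Trajectory,
    cd_groups: Sequence[Sequence[int]],
    guest_groups: Sequence[Sequence[int]],
    crit: InclusionCriterion | None = None,
) -> InclusionResult:
    """Percentage of hosts including at least one guest, frame-averaged.

    A host counts as including in a frame when >= 1 guest center of mass
    lies strictly closer than the cutoff to the host center of mass
    (multiple guests in one cavity still count the host once).  The result
    is the mean per-frame count divided by the host count, times 100.
    """
    crit = crit or InclusionCriterion()
    if len(cd_groups) == 0 or len(guest_groups) == 0:
        raise ValueError("need at least one host group and one guest group")
    counts = np.zeros(traj.n_frames)
    for f in range(traj.n_frames):
        box = traj.box[f]
        cd_com = group_centers_of_mass(traj.positions[f], traj.masses, box, cd_groups)
        guest_com = group_centers_of_mass(traj.positions[f], traj.masses, box, guest_groups)
        d = minimum_image_distance_matrix(cd_com, guest_com, box)
        counts[f] = int(np.sum((d < crit.com_cutoff).any(axis=1)))
    percent = float(counts.mean() / len(cd_groups) * 100.0)
    return InclusionResult(
        percent_cds_including=percent, per_frame_counts=counts, n_cds=len(cd_groups)
    )


def _rdf_max(traj, sel_i, sel_j, dr, r_max) -> RdfMaximum:
    rdf = compute_rdf(traj, sel_i, sel_j, dr=dr, r_max=r_max)
    k = int(np.argmax(rdf.g))
    return RdfMaximum(max_g=float(rdf.g[k]), r_at_max=float(rdf.r[k]))


def rim_orientation_rdf_max(
    traj: Trajectory,
    rim: RimDefinition,
    target_groups: Sequence[Sequence[int]],
    dr: float = 0.02,
    r_max: float = 2.0,
) -> tuple[RdfMaximum, RdfMaximum]:
    """Maximum of the RDF between each rim's atoms and the guest centers of
    mass; a larger secondary-rim maximum signals orientation of the host's
    open (secondary) face toward the guest."""
    primary = _rdf_max(traj, list(target_groups), rim.primary_rim_atoms, dr, r_max)
    secondary = _rdf_max(traj, list(target_groups), rim.secondary_rim_atoms, dr, r_max)
    return primary, secondary


def backbone_sidechain_rdf_max(
    traj: Trajectory,
    backbone_sel,
    sidechain_sel,
    secondary_rim_groups: Sequence[Sequence[int]],
    dr: float = 0.02,
    r_max: float = 2.0,
) -> tuple[RdfMaximum, RdfMaximum]:
    """Maximum of the RDF between guest backbone or side-chain atoms and the
    center of mass of the host's secondary rim.  An empty side-chain
    selection (glycine) yields a result flagged absent rather than zero."""
    backbone = _rdf_max(traj, list(secondary_rim_groups), backbone_sel, dr, r_max)
    sidechain_sel = np.asarray(sidechain_sel, dtype=int)
    if sidechain_sel.size == 0:
        return backbone, RdfMaximum(max_g=np.nan, r_at_max=np.nan, absent=True)
    sidechain = _rdf_max(traj, list(secondary_rim_groups), sidechain_sel, dr, r_max)
    return backbone, sidechain
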