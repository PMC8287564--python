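"""Particle configurations and trajectories with orthorhombic periodic boxes.

Coordinates are in nm, times in ps, masses in amu throughout the package.
These containers are the substrate of every structural metric: radial
distribution functions, Kirkwood-Buff integrals, hydrogen-bond counts and
cavity-inclusion statistics all operate on them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ParticleConfiguration",
    "Trajectory",
    "minimum_image_displacements",
    "minimum_image_distance_matrix",
    "resolve_selection",
    "group_centers_of_mass",
]


def minimum_image_displacements(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Pairwise displacement vectors b - a under the minimum-image convention.

    Parameters
    ----------
    a, b : arrays of shape (..., 3), nm
    box : array of shape (3,), orthorhombic box edges, nm
    """
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    box = np.asarray(box, dtype=float)
    return d - box * np.round(d / box)


def minimum_image_distance_matrix(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """All-pairs minimum-image distances, shape (len(a), len(b))."""
    d = minimum_image_displacements(a[:, None, :], b[None, :, :], box)
    return np.sqrt(np.einsum("ijk,ijk->ij", d, d))


@dataclass
class ParticleConfiguration:
    """A single frame: positions (N, 3) nm, species labels, box edges (3,) nm."""

    positions: np.ndarray
    species: np.ndarray
    box: np.ndarray
    masses: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.species = np.asarray(self.species)
        self.box = np.asarray(self.box, dtype=float).reshape(3)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (N, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if np.any(self.box <= 0):
            raise ValueError("box edges must be positive")
        if len(self.species) != len(self.positions):
            raise ValueError("species labels must match particle count")
        if self.masses is None:
            self.masses = np.ones(len(self.positions))
        else:
            self.masses = np.asarray(self.masses, dtype=float)
            if len(self.masses) != len(self.positions):
                raise ValueError("masses must match particle count")

    @property
    def n_particles(self) -> int:
        return len(self.positions)

    @property
    def volume(self) -> float:
        return float(np.prod(self.box))


@dataclass
class Trajectory:
    """An ordered set of frames with constant particle identities.

    positions : (n_frames, N, 3) nm
    species   : (N,) labels, constant across frames
    box       : (n_frames, 3) nm, orthorhombic
    times     : (n_frames,) ps
    """

    positions: np.ndarray
    species: np.ndarray
    box: np.ndarray
    times: np.ndarray | None = None
    masses: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim == 2:
            self.positions = self.positions[None]
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must have shape (n_frames, N, 3)")
        if self.positions.shape[0] < 1:
            raise ValueError("a trajectory needs at least one frame")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        self.species = np.asarray(self.species)
        if len(self.species) != self.positions.shape[1]:
            raise ValueError("species labels must match particle count")
        self.box = np.asarray(self.box, dtype=float)
        if self.box.ndim == 1:
            self.box = np.tile(self.box.reshape(1, 3), (self.n_frames, 1))
        if self.box.shape != (self.n_frames, 3):
            raise ValueError("box must have shape (n_frames, 3)")
        if np.any(self.box <= 0):
            raise ValueError("box edges must be positive")
        if self.times is None:
            self.times = np.arange(self.n_frames, dtype=float)
        else:
            self.times = np.asarray(self.times, dtype=float)
        if self.masses is None:
            self.masses = np.ones(self.positions.shape[1])
        else:
            self.masses = np.asarray(self.masses, dtype=float)

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_particles(self) -> int:
        return self.positions.shape[1]

    def frame(self, i: int) -> ParticleConfiguration:
        return ParticleConfiguration(
            positions=self.positions[i],
            species=self.species,
            box=self.box[i],
            masses=self.masses,
        )

    def slice_frames(self, start: int, stop: int) -> "Trajectory":
        return Trajectory(
            positions=self.positions[start:stop],
            species=self.species,
            box=self.box[start:stop],
            times=self.times[start:stop],
            masses=self.masses,
            metadata=dict(self.metadata),
        )

    @classmethod
    def concatenate(cls, parts: Sequence["Trajectory"]) -> "Trajectory":
        first = parts[0]
        for p in parts[1:]:
            if not np.array_equal(p.species, first.species):
                raise ValueError("cannot concatenate trajectories with different particles")
        return cls(
            positions=np.concatenate([p.positions for p in parts]),
            species=first.species,
            box=np.concatenate([p.box for p in parts]),
            times=np.concatenate([p.times for p in parts]),
            masses=first.masses,
            metadata=dict(first.metadata),
        )


def resolve_selection(species: np.ndarray, sel) -> np.ndarray:
    """Resolve a selection to an integer index array.

    Accepts a species label (str), an integer index sequence, or a boolean
    mask. Raises on an empty result.
    """
    species = np.asarray(species)
    if isinstance(sel, str):
        idx = np.flatnonzero(species == sel)
    else:
        arr = np.asarray(sel)
        if arr.dtype == bool:
            if len(arr) != len(species):
                raise ValueError("boolean selection mask has wrong length")
            idx = np.flatnonzero(arr)
        else:
            idx = arr.astype(int)
            if idx.size and (idx.min() < 0 or idx.max() >= len(species)):
                raise ValueError("selection index out of range")
    if idx.size == 0:
        raise ValueError(f"selection {sel!r} matched no particles")
    return idx


def group_centers_of_mass(
    positions: np.ndarray,
    masses: np.ndarray,
    box: np.ndarray,
    groups: Sequence[np.ndarray],
) -> np.ndarray:
    """Mass-weighted centers of mass for compact atom groups under PBC.

    Each group is unwrapped relative to its first atom via minimum image
    before averaging, then wrapped back into the primary box. Valid for
    groups whose extent is below half the smallest box edge.
    """
    coms = np.empty((len(groups), 3))
    for k, g in enumerate(groups):
        g = np.asarray(g, dtype=int)
        if g.size == 0:
            raise ValueError("empty group in center-of-mass computation")
        ref = positions[g[0]]
        disp = minimum_image_displacements(ref, positions[g], box)
        m = masses[g]
        coms[k] = ref + (m[:, None] * disp).sum(axis=0) / m.sum()
    return np.mod(coms, box)
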