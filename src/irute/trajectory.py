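"""Center-out radial trajectories, view ordering, and segment assignment.

Spokes are half-projections starting at the k-space center ("center-out").
Geometric spoke ``i`` of ``n`` has azimuth ``2*pi*i/n`` (2D) or sits on a
quasi-uniform Fibonacci lattice (3D, used for coverage visualization only).
A *view ordering* is a permutation mapping acquisition index to geometric
spoke index; sequential ordering is the identity, bit-reversed ordering
reverses the binary digits of the index, dispersing any temporally
contiguous data loss (e.g. motion gating) pseudo-randomly over k-space.

k-space coordinates are expressed in cycles per field of view, so one grid
cell of the image matrix corresponds to unit spacing and spokes extend from
``|k| = 0`` to ``|k| = matrix / 2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RadialTrajectory",
    "nyquist_spoke_count",
    "radial_angles_2d",
    "bit_reversed_permutation",
    "sequential_permutation",
    "sphere_directions_3d",
    "assign_segments",
    "coverage_gap_after_rejection",
    "radial_trajectory_2d",
]


def nyquist_spoke_count(matrix: int) -> int:
    """Minimum center-out spoke count meeting the angular Nyquist criterion.

    Full-circle half-spokes require ``ceil(pi * matrix)`` views so that the
    azimuthal sample spacing at the k-space edge does not exceed the radial
    spacing (220 -> 692).
    """
    if matrix < 1:
        raise ValueError("matrix must be >= 1")
    return math.ceil(math.pi * matrix)


def radial_angles_2d(n_spokes: int) -> np.ndarray:
    """Azimuths of the geometric spokes, uniform over the full circle."""
    if n_spokes < 1:
        raise ValueError("n_spokes must be >= 1")
    return 2.0 * np.pi * np.arange(n_spokes) / n_spokes


def bit_reversed_permutation(n_spokes: int) -> np.ndarray:
    """Bit-reversed view ordering as an acquisition -> geometric permutation.

    With ``B = ceil(log2 n)``, every index ``j < 2**B`` is reversed over B
    bits and the reversed values ``< n`` are kept in order of reversed rank.
    For ``n`` a power of two this is the classical (self-inverse)
    bit-reversal permutation; for other ``n`` the enumerate-and-filter
    construction preserves bijectivity and the pseudo-random dispersion.
    """
    if n_spokes < 1:
        raise ValueError("n_spokes must be >= 1")
    if n_spokes == 1:
        return np.zeros(1, dtype=np.int64)
    b = int(math.ceil(math.log2(n_spokes)))
    j = np.arange(1 << b, dtype=np.int64)
    rev = np.zeros_like(j)
    for _ in range(b):
        rev = (rev << 1) | (j & 1)
        j >>= 1
    return rev[rev < n_spokes]


def sequential_permutation(n_spokes: int) -> np.ndarray:
    """Identity ordering: spokes acquired in geometric order."""
    if n_spokes < 1:
        raise ValueError("n_spokes must be >= 1")
    return np.arange(n_spokes, dtype=np.int64)


_ORDERINGS = {
    "sequential": sequential_permutation,
    "bit_reversed": bit_reversed_permutation,
}


def sphere_directions_3d(n_spokes: int) -> np.ndarray:
    """Quasi-uniform unit vectors over the sphere (Fibonacci lattice).

    Used for 3D spoke-endpoint coverage plots; deterministic.
    """
    if n_spokes < 1:
        raise ValueError("n_spokes must be >= 1")
    i = np.arange(n_spokes, dtype=float)
    z = 1.0 - 2.0 * (i + 0.5) / n_spokes
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = golden * i
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def assign_segments(ordering: np.ndarray | int, segment_size: int) -> np.ndarray:
    """Segment id per acquisition-order spoke (last segment may be partial)."""
    if segment_size < 1:
        raise ValueError("segment_size must be >= 1")
    n = int(ordering) if np.isscalar(ordering) else len(ordering)
    return np.arange(n, dtype=np.int64) // segment_size


@dataclass
class RadialTrajectory:
    """Ordered center-out radial sampling pattern.

    ``ordering`` maps acquisition index to geometric spoke index;
    ``directions`` are the unit vectors in acquisition order; ``k_radii``
    the common center-out radial sample positions in cycles/FOV.
    """

    directions: np.ndarray      # (n_spokes, dim), acquisition order
    ordering: np.ndarray        # (n_spokes,)
    segment_id: np.ndarray      # (n_spokes,)
    k_radii: np.ndarray         # (samples_per_spoke,)
    matrix: int
    fov: float = 220.0
    ordering_name: str = "sequential"

    @property
    def n_spokes(self) -> int:
        return int(self.directions.shape[0])

    @property
    def dimension(self) -> int:
        return int(self.directions.shape[1])

    @property
    def samples_per_spoke(self) -> int:
        return int(self.k_radii.shape[0])

    def k_coords(self) -> np.ndarray:
        """Per-sample k-space coordinates, ``(n_spokes, samples, dim)``."""
        return self.directions[:, None, :] * self.k_radii[None, :, None]

    def segment_position(self, segment_size: int) -> np.ndarray:
        """Position of each acquisition-order spoke within its segment."""
        return np.arange(self.n_spokes, dtype=np.int64) % segment_size

    def to_frame(self) -> pd.DataFrame:
        cols = {
            "acquisition_index": np.arange(self.n_spokes),
            "geometric_index": self.ordering,
            "segment": self.segment_id,
        }
        for d in range(self.dimension):
            cols[f"dir_{'xyz'[d]}"] = self.directions[:, d]
        return pd.DataFrame(cols)


def radial_trajectory_2d(
    matrix: int,
    n_spokes: int | None = None,
    ordering: str = "sequential",
    segment_size: int = 21,
    fov: float = 220.0,
    readout_oversampling: int = 2,
) -> RadialTrajectory:
    """Build a 2D center-out radial trajectory.

    ``n_spokes`` defaults to the Nyquist count ``ceil(pi * matrix)``.
    Spokes are sampled uniformly over ``|k| in [0, matrix / 2]`` cycles/FOV
    with radial spacing ``1 / readout_oversampling``; the default two-fold
    readout oversampling (standard for UTE readouts) keeps the radial
    sample spacing at one oversampled-grid cell, which the iterative
    density-compensation relies on for accurate k-space weighting.
    """
    if ordering not in _ORDERINGS:
        raise ValueError(f"unknown ordering {ordering!r}; use one of {sorted(_ORDERINGS)}")
    if readout_oversampling < 1:
        raise ValueError("readout_oversampling must be >= 1")
    if n_spokes is None:
        n_spokes = nyquist_spoke_count(matrix)
    perm = _ORDERINGS[ordering](n_spokes)
    angles = radial_angles_2d(n_spokes)[perm]
    directions = np.stack([np.cos(angles), np.sin(angles)], axis=1)
    k_radii = np.arange(readout_oversampling * (matrix // 2) + 1, dtype=float) \
        / readout_oversampling
    return RadialTrajectory(
        directions=directions,
        ordering=perm,
        segment_id=assign_segments(perm, segment_size),
        k_radii=k_radii,
        matrix=matrix,
        fov=fov,
        ordering_name=ordering,
    )


def coverage_gap_after_rejection(
    trajectory: RadialTrajectory, accept_mask: np.ndarray
) -> float:
    """Largest angular coverage hole left by rejected spokes.

    2D: the maximum circular gap (radians) between consecutive accepted
    spoke azimuths.  3D: the largest spherical-cap hole radius, estimated as
    the maximum over a dense probe lattice of the angle to the nearest
    accepted direction.
    """
    accept_mask = np.asarray(accept_mask, dtype=bool)
    if accept_mask.shape != (trajectory.n_spokes,):
        raise ValueError("accept_mask must have one entry per spoke")
    if not accept_mask.any():
        raise ValueError("at least one spoke must be accepted")
    dirs = trajectory.directions[accept_mask]
    if trajectory.dimension == 2:
        ang = np.sort(np.mod(np.arctan2(dirs[:, 1], dirs[:, 0]), 2 * np.pi))
        if len(ang) == 1:
            return 2 * np.pi
        gaps = np.diff(ang)
        wrap = 2 * np.pi - (ang[-1] - ang[0])
        return float(max(gaps.max(), wrap))
    probes = sphere_directions_3d(4096)
    cos = np.clip(probes @ dirs.T, -1.0, 1.0)
    return float(np.arccos(cos.max(axis=1)).max())
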