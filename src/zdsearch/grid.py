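"""Voxel-grid container and unit-ball normalization.

Molecular surfaces (or any shape function) are represented as a real scalar
field sampled on a regular lattice.  Moment integration in
:mod:`zdsearch.zernike` is defined on the unit ball, so before moments are
taken a grid is translated to the center of mass of its support and rescaled
uniformly so that every nonzero voxel lies well inside radius 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import EmptySupportError, ParameterError

#: Fraction of the unit-ball radius the support is scaled to.  Leaving a
#: margin avoids truncating boundary voxels whose centers fall just outside
#: the integration domain, a standard precaution for grid-sampled moments.
DEFAULT_MARGIN = 0.7


@dataclass
class VoxelGrid:
    """A real scalar field on an ``Nx x Ny x Nz`` lattice.

    Parameters
    ----------
    values
        3-D array of finite voxel values (surface indicator or density).
    spacing
        Lattice step per axis; a scalar is broadcast to all three axes.
    origin
        Continuous coordinate of voxel ``(0, 0, 0)``.

    The continuous coordinate of voxel ``(i, j, k)`` is
    ``origin + (i, j, k) * spacing``.
    """

    values: np.ndarray
    spacing: np.ndarray = field(default=None)  # type: ignore[assignment]
    origin: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ParameterError("voxel grid must be a 3-D array")
        if min(self.values.shape) < 2:
            raise ParameterError("voxel grid needs at least 2 voxels per axis")
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("voxel grid contains non-finite values")
        self.spacing = (
            np.ones(3) if self.spacing is None else np.broadcast_to(np.asarray(self.spacing, dtype=float), (3,)).copy()
        )
        self.origin = (
            np.zeros(3) if self.origin is None else np.broadcast_to(np.asarray(self.origin, dtype=float), (3,)).copy()
        )
        if np.any(self.spacing <= 0):
            raise ParameterError("voxel spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def support_points(self) -> tuple[np.ndarray, np.ndarray]:
        """Continuous coordinates and values of all nonzero voxels.

        Returns ``(points, weights)`` with ``points`` of shape ``(P, 3)``.
        """
        idx = np.argwhere(self.values != 0)
        weights = self.values[self.values != 0]
        points = self.origin + idx * self.spacing
        return points, weights


def normalize_grid(grid: VoxelGrid, margin: float = DEFAULT_MARGIN) -> VoxelGrid:
    """Map the support of ``grid`` into the unit ball.

    The continuous coordinate frame is translated to the support's center of
    mass (voxel values as weights) and scaled uniformly so the farthest
    nonzero voxel sits at radius ``margin``.  Voxel values are unchanged;
    only ``origin`` and ``spacing`` move.

    Raises
    ------
    EmptySupportError
        If every voxel is zero.
    """
    if not 0 < margin <= 1:
        raise ParameterError(f"margin must be in (0, 1], got {margin}")
    points, weights = grid.support_points()
    if points.shape[0] == 0:
        raise EmptySupportError("cannot normalize an all-zero grid")
    com = (weights[:, None] * points).sum(axis=0) / weights.sum()
    rmax = float(np.linalg.norm(points - com, axis=1).max())
    scale = margin / rmax if rmax > 0 else 1.0
    return VoxelGrid(
        values=grid.values.copy(),
        spacing=grid.spacing * scale,
        origin=(grid.origin - com) * scale,
    )
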