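"""Rotation-invariant 3D Zernike descriptors (3DZD).

A shape function ``f(x)`` supported on the unit ball is expanded in the
Zernike-Canterakis basis

    Z_nlm(r, theta, phi) = R_nl(r) * Y_lm(theta, phi),

with ``0 <= l <= n``, ``n - l`` even and ``|m| <= l``, where ``Y_lm`` are
orthonormal complex spherical harmonics and ``R_nl`` the Canterakis radial
polynomials.  With the additional factor ``sqrt(3)`` used here the basis is
orthonormal in plain L2 over the unit ball.  Moments are

    Omega_nlm = 3/(4 pi) * Integral_{|x|<=1} f(x) conj(Z_nlm)(x) dx,

approximated by a midpoint Riemann sum over voxel centers, and the
descriptor collects the rotation-invariant norms

    F_nl = sqrt( sum_m |Omega_nlm|^2 ),

ordered lexicographically by ``(n, l)``.  At the default order 20 the
descriptor has 121 components.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.special import sph_harm_y

from .exceptions import IndexConstraintError, ParameterError
from .grid import DEFAULT_MARGIN, VoxelGrid, normalize_grid

DEFAULT_ORDER = 20


def _check_triple(n: int, l: int, m: int) -> None:
    if n < 0 or l < 0 or l > n or (n - l) % 2 != 0 or abs(m) > l:
        raise IndexConstraintError(
            f"invalid Zernike index (n={n}, l={l}, m={m}): need 0 <= l <= n, n-l even, |m| <= l"
        )


def nl_pairs(order: int) -> list[tuple[int, int]]:
    """Valid ``(n, l)`` pairs up to ``order``, lexicographically ordered."""
    if order < 0:
        raise ParameterError(f"order must be >= 0, got {order}")
    return [(n, l) for n in range(order + 1) for l in range(n % 2, n + 1, 2)]


def descriptor_length(order: int) -> int:
    """Number of invariants at a given maximum order (121 at order 20)."""
    return len(nl_pairs(order))


@lru_cache(maxsize=None)
def _radial_coefficients(n: int, l: int) -> tuple[tuple[int, float], ...]:
    """Canterakis radial polynomial R_nl as ``(power, coefficient)`` pairs."""
    k = (n - l) // 2
    pref = (-1) ** k / 4.0**k * math.sqrt((2 * l + 4 * k + 3) / 3.0) * math.comb(2 * k, k)
    out = []
    for nu in range(k + 1):
        c = (
            pref
            * (-1) ** nu
            * math.comb(k, nu)
            * math.comb(2 * (k + l + nu) + 1, 2 * k)
            / math.comb(k + l + nu, k)
        )
        out.append((2 * nu + l, c))
    return tuple(out)


def _radial_eval(n: int, l: int, r_pows: dict[int, np.ndarray]) -> np.ndarray:
    acc = None
    for power, coeff in _radial_coefficients(n, l):
        term = coeff * r_pows[power]
        acc = term if acc is None else acc + term
    return acc


def zernike_basis(n: int, l: int, m: int, x) -> complex | np.ndarray:
    """Evaluate ``Z_nlm`` at point(s) ``x`` inside the unit ball.

    ``x`` may be a single 3-vector or an ``(P, 3)`` array.  The basis is
    L2-orthonormal over the unit ball.
    """
    _check_triple(n, l, m)
    pts = np.atleast_2d(np.asarray(x, dtype=float))
    r = np.linalg.norm(pts, axis=1)
    if np.any(r > 1 + 1e-12):
        raise ParameterError("zernike_basis requires |x| <= 1")
    theta = np.arccos(np.clip(np.divide(pts[:, 2], r, out=np.zeros_like(r), where=r > 0), -1, 1))
    theta[r == 0] = 0.0
    phi = np.arctan2(pts[:, 1], pts[:, 0])
    r_pows = {p: r**p for p, _ in _radial_coefficients(n, l)}
    radial = math.sqrt(3.0) * _radial_eval(n, l, r_pows)
    val = radial * sph_harm_y(l, m, theta, phi)
    return val[0] if np.asarray(x).ndim == 1 else val


@dataclass
class ZernikeMoments:
    """Complex moments ``Omega_nlm`` for all valid triples up to ``order``."""

    order: int
    entries: dict[tuple[int, int, int], complex] = field(default_factory=dict)

    def __getitem__(self, key: tuple[int, int, int]) -> complex:
        _check_triple(*key)
        return self.entries[key]


@dataclass
class InvariantVector:
    """A labeled 3DZD: non-negative norms ``F_nl`` in (n, l) order."""

    id: str
    order: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) != descriptor_length(self.order):
            raise ParameterError(
                f"invariant vector at order {self.order} must have "
                f"{descriptor_length(self.order)} entries, got {self.values.shape}"
            )
        if np.any(self.values < 0):
            raise ParameterError("invariants must be non-negative")


def compute_moments(grid: VoxelGrid, order: int = DEFAULT_ORDER) -> ZernikeMoments:
    """Riemann-sum approximation of the Zernike moments of a normalized grid.

    Only voxel centers at radius <= 1 contribute.  The grid should already be
    normalized into the unit ball (see :func:`zdsearch.grid.normalize_grid`);
    voxels outside are silently dropped, matching the integration domain.
    """
    if order < 0:
        raise ParameterError(f"order must be >= 0, got {order}")
    points, weights = grid.support_points()
    moments = ZernikeMoments(order=order)
    if points.shape[0] == 0:
        for n, l in nl_pairs(order):
            for m in range(-l, l + 1):
                moments.entries[(n, l, m)] = 0j
        return moments
    r = np.linalg.norm(points, axis=1)
    inside = r <= 1.0
    points, weights, r = points[inside], weights[inside], r[inside]
    w = weights * grid.voxel_volume * (3.0 / (4.0 * math.pi)) * math.sqrt(3.0)
    theta = np.arccos(np.clip(np.divide(points[:, 2], r, out=np.zeros_like(r), where=r > 0), -1, 1))
    theta[r == 0] = 0.0
    phi = np.arctan2(points[:, 1], points[:, 0])
    r_pows = {p: r**p for p in range(order + 1)}
    for l in range(order + 1):
        for m in range(l + 1):
            ybar_w = w * np.conj(sph_harm_y(l, m, theta, phi))
            for n in range(l, order + 1, 2):
                om = complex(np.dot(_radial_eval(n, l, r_pows), ybar_w))
                moments.entries[(n, l, m)] = om
                if m > 0:
                    # conjugate symmetry of Y_lm for real-valued f
                    moments.entries[(n, l, -m)] = (-1) ** m * om.conjugate()
    return moments


def invariants(moments: ZernikeMoments, id: str = "") -> InvariantVector:
    """Collapse moments to the rotation-invariant descriptor.

    ``F_nl = sqrt(sum_m |Omega_nlm|^2)``; the per-(n, l) Euclidean norm over
    ``m`` is what makes the descriptor independent of the orientation of the
    input shape.
    """
    vals = np.empty(descriptor_length(moments.order))
    for pos, (n, l) in enumerate(nl_pairs(moments.order)):
        acc = 0.0
        for m in range(-l, l + 1):
            acc += abs(moments.entries[(n, l, m)]) ** 2
        vals[pos] = math.sqrt(acc)
    return InvariantVector(id=id, order=moments.order, values=vals)


def compute_descriptor(
    grid: VoxelGrid,
    order: int = DEFAULT_ORDER,
    margin: float = DEFAULT_MARGIN,
    id: str = "",
) -> InvariantVector:
    """Normalize a grid, take moments, and return the invariant vector."""
    return invariants(compute_moments(normalize_grid(grid, margin=margin), order=order), id=id)
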