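"""Cell and lattice algebra shared by all modules.

The two central containers are :class:`UnitCell` (direct space, lengths in
Å, angles in degrees) and :class:`ReciprocalCell` (lengths in Å⁻¹).  All
angles cross the API in degrees; radians are used internally.  The basis
realization convention is: **a** along *x*, **b** in the *x–y* plane,
right-handed.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "UnitCell",
    "ReciprocalCell",
    "cell_volume",
    "reciprocal_of",
    "direct_of",
    "d_spacing",
    "transform_cell",
    "cells_equivalent",
    "metric_tensor",
    "basis_matrix",
    "cell_from_metric",
]


def _deg_cos(x: float) -> float:
    return float(np.cos(np.radians(x)))


def _validate_params(a, b, c, alpha, beta, gamma) -> None:
    if not (a > 0 and b > 0 and c > 0):
        raise ValueError(f"cell lengths must be positive, got {(a, b, c)}")
    for name, ang in (("alpha", alpha), ("beta", beta), ("gamma", gamma)):
        if not (0.0 < ang < 180.0):
            raise ValueError(f"cell angle {name}={ang} outside (0, 180)")
    g = _metric_from_params(a, b, c, alpha, beta, gamma)
    if np.linalg.det(g) <= 0.0:
        raise ValueError(
            "cell parameters do not define a positive-definite metric "
            f"(a={a}, b={b}, c={c}, alpha={alpha}, beta={beta}, gamma={gamma})"
        )


def _metric_from_params(a, b, c, alpha, beta, gamma) -> np.ndarray:
    ca, cb, cg = _deg_cos(alpha), _deg_cos(beta), _deg_cos(gamma)
    return np.array(
        [
            [a * a, a * b * cg, a * c * cb],
            [a * b * cg, b * b, b * c * ca],
            [a * c * cb, b * c * ca, c * c],
        ]
    )


def _params_from_metric(g: np.ndarray) -> tuple[float, float, float, float, float, float]:
    a, b, c = np.sqrt(np.diag(g))
    alpha = np.degrees(np.arccos(np.clip(g[1, 2] / (b * c), -1.0, 1.0)))
    beta = np.degrees(np.arccos(np.clip(g[0, 2] / (a * c), -1.0, 1.0)))
    gamma = np.degrees(np.arccos(np.clip(g[0, 1] / (a * b), -1.0, 1.0)))
    return float(a), float(b), float(c), float(alpha), float(beta), float(gamma)


@dataclass(frozen=True)
class UnitCell:
    """A direct-space unit cell: lengths in Å, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        _validate_params(self.a, self.b, self.c, self.alpha, self.beta, self.gamma)

    @property
    def lengths(self) -> tuple[float, float, float]:
        return (self.a, self.b, self.c)

    @property
    def angles(self) -> tuple[float, float, float]:
        return (self.alpha, self.beta, self.gamma)

    @property
    def parameters(self) -> tuple[float, ...]:
        return (self.a, self.b, self.c, self.alpha, self.beta, self.gamma)

    @property
    def volume(self) -> float:
        return cell_volume(self)

    def to_dict(self) -> dict[str, float]:
        return dict(zip(("a", "b", "c", "alpha", "beta", "gamma"), self.parameters))

    @classmethod
    def from_dict(cls, record: dict) -> "UnitCell":
        return cls(*(float(record[k]) for k in ("a", "b", "c", "alpha", "beta", "gamma")))

    def to_cif(self) -> str:
        """A minimal cell-only CIF fragment."""
        a, b, c, al, be, ga = self.parameters
        return (
            "data_cell\n"
            f"_cell_length_a {a:.4f}\n_cell_length_b {b:.4f}\n_cell_length_c {c:.4f}\n"
            f"_cell_angle_alpha {al:.3f}\n_cell_angle_beta {be:.3f}\n_cell_angle_gamma {ga:.3f}\n"
            f"_cell_volume {self.volume:.2f}\n"
        )


@dataclass(frozen=True)
class ReciprocalCell:
    """A reciprocal-space cell: lengths in Å⁻¹, angles in degrees."""

    a_star: float
    b_star: float
    c_star: float
    alpha_star: float = 90.0
    beta_star: float = 90.0
    gamma_star: float = 90.0

    def __post_init__(self) -> None:
        _validate_params(
            self.a_star, self.b_star, self.c_star,
            self.alpha_star, self.beta_star, self.gamma_star,
        )

    @property
    def lengths(self) -> tuple[float, float, float]:
        return (self.a_star, self.b_star, self.c_star)

    @property
    def angles(self) -> tuple[float, float, float]:
        return (self.alpha_star, self.beta_star, self.gamma_star)

    @property
    def parameters(self) -> tuple[float, ...]:
        return self.lengths + self.angles

    @property
    def volume(self) -> float:
        """Reciprocal-cell volume in Å⁻³ (equals 1/V of the direct cell)."""
        g = _metric_from_params(*self.parameters)
        return float(np.sqrt(np.linalg.det(g)))


def metric_tensor(cell: UnitCell | ReciprocalCell) -> np.ndarray:
    """3×3 metric tensor (Å² for a direct cell, Å⁻² for a reciprocal one)."""
    return _metric_from_params(*cell.parameters)


def cell_from_metric(g: np.ndarray) -> UnitCell:
    """Build a direct cell from a 3×3 metric tensor."""
    g = np.asarray(g, dtype=float)
    if g.shape != (3, 3) or not np.allclose(g, g.T, rtol=1e-8, atol=1e-10):
        raise ValueError("metric tensor must be symmetric 3x3")
    return UnitCell(*_params_from_metric(g))


def basis_matrix(cell: UnitCell | ReciprocalCell) -> np.ndarray:
    """Row-vector basis realization (rows are the three cell vectors).

    Convention: first vector along *x*, second in the *x–y* plane,
    right-handed (positive determinant).
    """
    a, b, c, alpha, beta, gamma = cell.parameters
    ca, cb, cg = (_deg_cos(x) for x in (alpha, beta, gamma))
    sg = float(np.sin(np.radians(gamma)))
    v1 = np.array([a, 0.0, 0.0])
    v2 = np.array([b * cg, b * sg, 0.0])
    cy = (ca - cb * cg) / sg
    cz_sq = 1.0 - cb * cb - cy * cy
    if cz_sq <= 0.0:
        raise ValueError("cell parameters do not define a positive-definite metric")
    v3 = c * np.array([cb, cy, np.sqrt(cz_sq)])
    return np.array([v1, v2, v3])


def cell_volume(cell: UnitCell) -> float:
    """Unit-cell volume in Å³ (square root of the metric determinant)."""
    g = metric_tensor(cell)
    det = np.linalg.det(g)
    if det <= 0.0:
        raise ValueError("non-positive-definite metric")
    return float(np.sqrt(det))


def reciprocal_of(cell: UnitCell) -> ReciprocalCell:
    """Reciprocal cell of a direct cell (V·V* = 1)."""
    gstar = np.linalg.inv(metric_tensor(cell))
    return ReciprocalCell(*_params_from_metric(gstar))


def direct_of(rcell: ReciprocalCell) -> UnitCell:
    """Direct cell of a reciprocal cell (inverse of :func:`reciprocal_of`)."""
    g = np.linalg.inv(_metric_from_params(*rcell.parameters))
    return UnitCell(*_params_from_metric(g))


def d_spacing(cell: UnitCell, hkl: Sequence[int]) -> float:
    """Interplanar spacing d(hkl) in Å; invariant under hkl → −hkl."""
    h = np.asarray(hkl, dtype=float)
    if h.shape != (3,) or not np.any(h):
        raise ValueError(f"hkl must be a non-zero integer triple, got {hkl!r}")
    gstar = np.linalg.inv(metric_tensor(cell))
    return float(1.0 / np.sqrt(h @ gstar @ h))


def _as_matrix(M: Iterable) -> np.ndarray:
    arr = np.array([[float(Fraction(x)) if isinstance(x, str) else float(x) for x in row] for row in M])
    if arr.shape != (3, 3):
        raise ValueError("transformation matrix must be 3x3")
    return arr


def transform_cell(cell: UnitCell, M: Iterable) -> UnitCell:
    """Re-express a cell on a new basis given by the rows of ``M``.

    Row *i* of ``M`` holds the components of the new basis vector *i* on the
    old basis; rational entries (e.g. ``"1/2"``) are accepted for
    centred↔primitive conversions.  The volume scales by ``|det M|``.
    """
    m = _as_matrix(M)
    det = np.linalg.det(m)
    if abs(det) < 1e-12:
        raise ValueError("singular transformation matrix")
    g_new = m @ metric_tensor(cell) @ m.T
    return UnitCell(*_params_from_metric(g_new))


def _reduced_signature(cell: UnitCell) -> tuple[np.ndarray, np.ndarray]:
    from .reduction import delaunay_reduce  # local import to avoid a cycle

    red = delaunay_reduce(cell).cell
    return np.array(red.lengths), np.array(red.angles)


_PERMS = [(0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0)]


def cells_equivalent(
    cell_a: UnitCell,
    cell_b: UnitCell,
    tol_len: float = 0.02,
    tol_ang: float = 2.0,
) -> tuple[bool, float, float]:
    """Compare two lattices after Delaunay reduction.

    Lengths are compared as ratios, so a common scale error contributes only
    through the returned ``scale`` factor (best-fit length ratio A/B).
    Returns ``(equivalent, mismatch, scale)`` where ``mismatch`` is the
    largest relative length deviation plus angle deviation (deg) divided by
    its tolerance, minimized over axis permutations: ≤ 1 means equivalent.
    """
    len_a, ang_a = _reduced_signature(cell_a)
    len_b, ang_b = _reduced_signature(cell_b)
    # fold angles so that 80° and 100° (sign-flipped axes) compare equal
    ang_a = np.minimum(ang_a, 180.0 - ang_a)
    ang_b = np.minimum(ang_b, 180.0 - ang_b)
    best = np.inf
    best_scale = 1.0
    for p in _PERMS:
        lb, ab = len_b[list(p)], ang_b[list(p)]
        scale = float(np.sum(len_a * lb) / np.sum(lb * lb))
        if scale <= 0:
            continue
        rel = np.max(np.abs(len_a / (scale * lb) - 1.0))
        dang = np.max(np.abs(ang_a - ab))
        score = max(rel / tol_len, dang / tol_ang)
        if score < best:
            best = score
            best_scale = scale
    return bool(best <= 1.0), float(best), best_scale
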