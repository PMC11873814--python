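"""Reduction of zonal diffraction patterns to basis-vector descriptors.

A zonal pattern — a flat 2D net of reflections recorded along a zone axis —
is reduced to two reciprocal basis-vector lengths and the angle between
them.  This module extracts that basis from peak lists (difference-vector
clustering followed by least-squares refinement), corrects known elliptical
detector distortion, canonicalizes descriptors for comparison, classifies
the metric plane symmetry (intensities are never used) and scores how
lattice-like a peak list is.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "PeakList",
    "ZonePattern",
    "correct_elliptical_distortion",
    "extract_basis_autocorrelation",
    "refine_basis_lsq",
    "lattice_score",
    "canonicalize",
    "classify_metric_symmetry",
    "SYMMETRY_LABELS",
]

SYMMETRY_LABELS = ("p1", "pmm", "cmm", "p4", "p6")

# ranking used when choosing the initial zone: higher symmetry first
SYMMETRY_RANK = {"p6": 4, "p4": 3, "cmm": 2, "pmm": 1, "p1": 0}


@dataclass(frozen=True)
class PeakList:
    """2D peak coordinates of one pattern, in reciprocal Å⁻¹."""

    pattern_id: str
    coords: np.ndarray  # (n, 2)

    def __post_init__(self) -> None:
        coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ValueError("peak coordinates must be an (n, 2) array")
        if not np.all(np.isfinite(coords)):
            raise ValueError("peak coordinates must be finite")
        object.__setattr__(self, "coords", coords)

    def __len__(self) -> int:
        return len(self.coords)


@dataclass(frozen=True)
class ZonePattern:
    """One zonal pattern reduced to (d1, d2, φ).

    ``d1``/``d2`` are d-spacings (Å) of the two basis reflections,
    ``phi`` the angle between the basis vectors in degrees.  The symmetry
    label is either user-supplied (trusted) or ``"auto"``; ``scale`` is a
    camera-constant multiplier applied to both g-lengths.
    """

    pattern_id: str
    d1: float
    d2: float
    phi: float
    symmetry: str = "auto"
    scale: float = 1.0
    peaks: Optional[PeakList] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not (self.d1 > 0 and self.d2 > 0):
            raise ValueError(f"pattern {self.pattern_id}: d-spacings must be positive")
        if not (0.0 < self.phi < 180.0):
            raise ValueError(f"pattern {self.pattern_id}: phi={self.phi} outside (0, 180)")
        if self.symmetry not in SYMMETRY_LABELS + ("auto",):
            raise ValueError(f"pattern {self.pattern_id}: unknown symmetry {self.symmetry!r}")
        if self.scale <= 0:
            raise ValueError(f"pattern {self.pattern_id}: scale must be positive")

    @property
    def canonical(self) -> tuple[float, float, float]:
        """(g_short, g_long, φ) in canonical form, scale applied."""
        gs, gl, phi = canonicalize(self.d1, self.d2, self.phi)
        return gs * self.scale, gl * self.scale, phi

    @property
    def ratio(self) -> float:
        """g_long / g_short ≥ 1 of the canonical basis."""
        gs, gl, _ = self.canonical
        return gl / gs

    def effective_symmetry(self, tol_len: float = 0.01, tol_ang: float = 0.5) -> str:
        """User label when given, metric auto-classification otherwise."""
        if self.symmetry != "auto":
            return self.symmetry
        return classify_metric_symmetry(self, tol_len=tol_len, tol_ang=tol_ang)

    def with_symmetry(self, label: str) -> "ZonePattern":
        return replace(self, symmetry=label)


def correct_elliptical_distortion(
    peaks: PeakList, ratio: float, axis_angle: float
) -> PeakList:
    """Undo an elliptical detector distortion.

    ``ratio`` is the long/short axis ratio of the distortion (1 = none) and
    ``axis_angle`` the direction of the long axis in degrees from +x.  The
    correction rotates by −axis_angle, divides the x component by ``ratio``
    and rotates back.
    """
    if ratio <= 0:
        raise ValueError("distortion ratio must be positive")
    t = np.radians(axis_angle)
    rot = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
    scale = np.diag([1.0 / ratio, 1.0])
    m = rot @ scale @ rot.T
    return PeakList(peaks.pattern_id, peaks.coords @ m.T)


def _gauss_reduce_2d(v1: np.ndarray, v2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Lagrange/Gauss reduction: shortest basis of a 2D lattice."""
    v1, v2 = v1.copy(), v2.copy()
    for _ in range(100):
        if v1 @ v1 > v2 @ v2:
            v1, v2 = v2, v1
        t = round(float(v1 @ v2) / float(v1 @ v1))
        if t == 0:
            break
        w = v2 - t * v1
        if w @ w >= v2 @ v2:
            break
        v2 = w
    return v1, v2


def canonicalize(d1: float, d2: float, phi: float) -> tuple[float, float, float]:
    """Canonical (g_short, g_long, φ) descriptor of a pattern basis.

    g = 1/d; the basis is first Gauss-reduced (a difference vector shorter
    than either input replaces the longer one), vectors are ordered
    g_short ≤ g_long, and φ is folded into (0, 90] via φ → 180 − φ, allowed
    because g and −g are indistinguishable in a diffraction pattern.
    Idempotent.
    """
    if not (d1 > 0 and d2 > 0 and 0.0 < phi < 180.0):
        raise ValueError("invalid pattern descriptor")
    g1, g2 = 1.0 / d1, 1.0 / d2
    p = np.radians(phi)
    v1 = np.array([g1, 0.0])
    v2 = np.array([g2 * np.cos(p), g2 * np.sin(p)])
    v1, v2 = _gauss_reduce_2d(v1, v2)
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 > n2:
        v1, v2, n1, n2 = v2, v1, n2, n1
    cosang = np.clip((v1 @ v2) / (n1 * n2), -1.0, 1.0)
    ang = float(np.degrees(np.arccos(cosang)))
    if ang > 90.0:
        ang = 180.0 - ang
    return float(n1), float(n2), ang


def classify_metric_symmetry(
    pattern: "ZonePattern | tuple", tol_len: float = 0.01, tol_ang: float = 0.5
) -> str:
    """Metric plane-group label of a pattern: p4, p6, cmm, pmm or p1.

    Checked in order of decreasing symmetry on the canonical basis:

    * ``p4``  — equal lengths and φ ≈ 90°
    * ``p6``  — equal lengths and φ ≈ 60° (the canonical form maps 120° → 60°)
    * ``cmm`` — equal lengths (diagonal setting) or 2·g_long·cos φ ≈ g_short
      (centred-rectangular setting, double length tolerance)
    * ``pmm`` — φ ≈ 90°
    * ``p1``  — otherwise

    Lengths compare as relative differences against ``tol_len``; angles in
    degrees against ``tol_ang``.
    """
    if isinstance(pattern, ZonePattern):
        gs, gl, phi = pattern.canonical
    else:
        gs, gl, phi = canonicalize(*pattern)
    equal_len = abs(gs - gl) / gl <= tol_len
    if equal_len and abs(phi - 90.0) <= tol_ang:
        return "p4"
    if equal_len and abs(phi - 60.0) <= tol_ang:
        return "p6"
    centred_rect = abs(2.0 * gl * np.cos(np.radians(phi)) - gs) / gs <= 2.0 * tol_len
    if equal_len or centred_rect:
        return "cmm"
    if abs(phi - 90.0) <= tol_ang:
        return "pmm"
    return "p1"


def refine_basis_lsq(
    peaks: PeakList,
    v1: Sequence[float],
    v2: Sequence[float],
    max_iter: int = 20,
    frac_tol: float = 0.25,
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Least-squares refinement of a 2D pattern basis against a peak list.

    Each peak is assigned its nearest integer index pair under the current
    basis; peaks whose fractional residual exceeds ``frac_tol`` are left out
    of the solve.  Iterates to convergence (basis change < 1e-8 or
    ``max_iter``).  Returns (v1, v2, rms positional residual,
    matched_fraction).
    """
    basis = np.array([v1, v2], dtype=float)
    if abs(np.linalg.det(basis)) < 1e-14:
        raise ValueError("initial basis vectors are collinear")
    pts = peaks.coords
    for _ in range(max_iter):
        frac = pts @ np.linalg.inv(basis)
        idx = np.round(frac)
        resid = frac - idx
        keep = np.max(np.abs(resid), axis=1) < frac_tol
        if np.count_nonzero(keep) < 3 or np.linalg.matrix_rank(idx[keep]) < 2:
            raise ValueError("refinement failed: degenerate peak assignment")
        new_basis, *_ = np.linalg.lstsq(idx[keep], pts[keep], rcond=None)
        if np.max(np.abs(new_basis - basis)) < 1e-8:
            basis = new_basis
            break
        basis = new_basis
    frac = pts @ np.linalg.inv(basis)
    idx = np.round(frac)
    pos_resid = (frac - idx) @ basis
    dist = np.linalg.norm(pos_resid, axis=1)
    matched = np.max(np.abs(frac - idx), axis=1) < frac_tol
    rms = float(np.sqrt(np.mean(dist[matched] ** 2))) if matched.any() else float("inf")
    return basis[0], basis[1], rms, float(np.mean(matched))


def extract_basis_autocorrelation(
    peaks: PeakList,
    cluster_tol: float | None = None,
    min_sin: float = 0.05,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Pattern basis from clustered peak-to-peak difference vectors.

    All pairwise differences are folded into a half plane and clustered
    greedily within ``cluster_tol`` (default: 5% of the shortest difference
    length).  The two shortest well-populated, non-collinear cluster
    centroids seed :func:`refine_basis_lsq`; the refined basis and rms
    residual are returned.
    """
    if len(peaks) < 5:
        raise ValueError("basis extraction needs at least 5 peaks")
    pts = peaks.coords
    n = len(pts)
    diffs = (pts[:, None, :] - pts[None, :, :]).reshape(-1, 2)
    norms = np.linalg.norm(diffs, axis=1)
    diffs = diffs[norms > 1e-12]
    # fold v / −v together
    flip = (diffs[:, 0] < 0) | ((diffs[:, 0] == 0) & (diffs[:, 1] < 0))
    diffs[flip] *= -1
    norms = np.linalg.norm(diffs, axis=1)
    order = np.argsort(norms, kind="stable")
    diffs = diffs[order]
    if cluster_tol is None:
        cluster_tol = 0.05 * float(np.linalg.norm(diffs[0]))

    centroids: list[np.ndarray] = []
    sums: list[np.ndarray] = []
    counts: list[int] = []
    for d in diffs:
        placed = False
        for i, c in enumerate(centroids):
            if np.linalg.norm(d - c) <= cluster_tol:
                sums[i] += d
                counts[i] += 1
                centroids[i] = sums[i] / counts[i]
                placed = True
                break
        if not placed:
            centroids.append(d.copy())
            sums.append(d.copy())
            counts.append(1)

    counts_arr = np.array(counts)
    support = max(3, int(0.3 * counts_arr.max()))
    good = [c for c, k in zip(centroids, counts) if k >= support]
    good.sort(key=lambda c: float(np.linalg.norm(c)))
    if not good:
        raise ValueError("no 2D lattice found in peak differences")
    v1 = good[0]
    v2 = None
    for c in good[1:]:
        sin = abs(v1[0] * c[1] - v1[1] * c[0]) / (np.linalg.norm(v1) * np.linalg.norm(c))
        if sin > min_sin:
            v2 = c
            break
    if v2 is None:
        raise ValueError("no 2D lattice found: fewer than two non-collinear clusters")
    r1, r2, rms, _ = refine_basis_lsq(peaks, v1, v2)
    return r1, r2, rms


def lattice_score(peaks: PeakList, basis: Sequence[Sequence[float]], tol: float = 0.15) -> float:
    """Fraction of peaks lying on the net predicted by ``basis``.

    A peak counts as matched when it is within ``tol`` × (shorter basis
    length) of the nearest lattice node.  A high score marks a pattern as a
    prominent zonal section; interleaved or off-lattice peaks (high-index
    sections) pull the score down.
    """
    b = np.array(basis, dtype=float)
    if abs(np.linalg.det(b)) < 1e-14:
        raise ValueError("basis vectors are collinear")
    frac = peaks.coords @ np.linalg.inv(b)
    resid = (frac - np.round(frac)) @ b
    dist = np.linalg.norm(resid, axis=1)
    limit = tol * min(np.linalg.norm(b[0]), np.linalg.norm(b[1]))
    return float(np.mean(dist <= limit))
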