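"""Zone enumeration, zone nets and pattern indexing against a candidate cell.

A zone [uvw] of a cell cuts the reciprocal lattice in a 2D net; its
Gauss-reduced basis (the two shortest independent in-zone vectors) is what
a zonal pattern records.  A pattern is indexed by finding the zone whose
net best matches the pattern's canonical (g_short, g_long, φ) descriptor
under three weighted relative mismatches: basis-vector ratio, angle and
overall pattern scale.  The per-pattern score T_p averages the three
weight-normalized mismatches; the reliability index R of a candidate cell
is the mean T_p over its indexed patterns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np

from .lattice import ReciprocalCell, UnitCell, basis_matrix, reciprocal_of
from .patterns import ZonePattern

__all__ = [
    "MatchWeights",
    "ZoneNet",
    "IndexingResult",
    "enumerate_zones",
    "zone_net",
    "pattern_mismatch",
    "index_pattern",
    "reliability_index",
    "rescore_with_mean_scale",
    "CENTRING_CONDITIONS",
]

# systematic-absence rules: a reflection exists iff the condition holds
CENTRING_CONDITIONS = {
    "P": lambda h, k, l: np.ones_like(h, dtype=bool),
    "A": lambda h, k, l: (k + l) % 2 == 0,
    "B": lambda h, k, l: (h + l) % 2 == 0,
    "C": lambda h, k, l: (h + k) % 2 == 0,
    "I": lambda h, k, l: (h + k + l) % 2 == 0,
    "F": lambda h, k, l: ((h + k) % 2 == 0) & ((k + l) % 2 == 0),
}


@dataclass(frozen=True)
class MatchWeights:
    """Mismatch tolerances and the acceptance multiplier.

    ``w1``/``w2``/``w3`` normalize the relative mismatches of the basis
    ratio, angle and pattern scale (a weight of 0.008 means a 0.8% mismatch
    contributes 1 to that term).  A pattern is accepted when every mismatch
    stays below ``k`` times its weight.
    """

    w1: float = 0.008
    w2: float = 0.006
    w3: float = 0.003
    k: float = 5.0

    def __post_init__(self) -> None:
        if min(self.w1, self.w2, self.w3, self.k) <= 0:
            raise ValueError("weights and acceptance multiplier must be positive")


@dataclass(frozen=True)
class ZoneNet:
    """Gauss-reduced 2D net of zone [uvw]: shortest pair with their hkl."""

    uvw: tuple[int, int, int]
    hkl_short: tuple[int, int, int]
    hkl_long: tuple[int, int, int]
    g_short: float  # Å⁻¹
    g_long: float  # Å⁻¹
    phi: float  # deg, in (0, 90]

    @property
    def ratio(self) -> float:
        return self.g_long / self.g_short


@dataclass(frozen=True)
class IndexingResult:
    """Best zone assignment of one pattern against one cell."""

    pattern_id: str
    uvw: tuple[int, int, int]
    hkl_short: tuple[int, int, int]
    hkl_long: tuple[int, int, int]
    eps_ratio: float
    eps_angle: float
    eps_scale: float
    s_p: float  # per-pattern scale: mean observed/net length ratio
    t_p: float
    accepted: bool
    net_g_short: float = 0.0
    net_g_long: float = 0.0


def _coprime(u: int, v: int, w: int) -> bool:
    return math.gcd(math.gcd(abs(u), abs(v)), abs(w)) == 1


@lru_cache(maxsize=32)
def enumerate_zones(max_index: int) -> tuple[tuple[int, int, int], ...]:
    """All coprime zone triples with components in ±``max_index``.

    One representative per ± pair (first non-zero component positive),
    sorted by |u|+|v|+|w| then lexicographically — a deterministic order
    used for tie-breaking everywhere.
    """
    if max_index < 1:
        raise ValueError("max_index must be >= 1")
    zones = []
    rng = range(-max_index, max_index + 1)
    for u in rng:
        for v in rng:
            for w in rng:
                if (u, v, w) == (0, 0, 0) or not _coprime(u, v, w):
                    continue
                nz = next(x for x in (u, v, w) if x != 0)
                if nz < 0:
                    continue
                zones.append((u, v, w))
    zones.sort(key=lambda z: (abs(z[0]) + abs(z[1]) + abs(z[2]), z))
    return tuple(zones)


@lru_cache(maxsize=16)
def _hkl_table(hkl_max: int, centring: str) -> np.ndarray:
    """Reflection triples within ±``hkl_max`` passing the centring condition,
    one representative per Friedel pair."""
    rng = np.arange(-hkl_max, hkl_max + 1)
    h, k, l = np.meshgrid(rng, rng, rng, indexing="ij")
    H = np.stack([h.ravel(), k.ravel(), l.ravel()], axis=1)
    H = H[np.any(H != 0, axis=1)]
    # one per ± pair: first non-zero component positive
    first_nz = np.where(H[:, 0] != 0, H[:, 0], np.where(H[:, 1] != 0, H[:, 1], H[:, 2]))
    H = H[first_nz > 0]
    cond = CENTRING_CONDITIONS[centring]
    return H[cond(H[:, 0], H[:, 1], H[:, 2])]


@lru_cache(maxsize=16)
def _zone_index_lists(max_index: int, hkl_max: int, centring: str):
    """For each enumerated zone, the row indices of its in-zone reflections."""
    H = _hkl_table(hkl_max, centring)
    zones = enumerate_zones(max_index)
    Z = np.array(zones, dtype=np.int64)
    dots = H @ Z.T
    return zones, [np.flatnonzero(dots[:, j] == 0) for j in range(len(zones))]


def _net_from_subset(H, gvecs, lengths, idx, uvw) -> ZoneNet | None:
    if len(idx) < 2:
        return None
    sub_len = lengths[idx]
    order = np.argsort(sub_len, kind="stable")
    i1 = idx[order[0]]
    hkl1 = H[i1]
    for o in order[1:]:
        i2 = idx[o]
        if np.any(np.cross(hkl1, H[i2])):
            return _canonical_net(uvw, H[i1], H[i2], gvecs[i1], gvecs[i2])
    return None


def _canonical_net(uvw, hkl1, hkl2, v1, v2) -> ZoneNet:
    n1, n2 = float(np.linalg.norm(v1)), float(np.linalg.norm(v2))
    if n1 > n2:
        hkl1, hkl2, v1, v2, n1, n2 = hkl2, hkl1, v2, v1, n2, n1
    cosang = float(np.clip((v1 @ v2) / (n1 * n2), -1.0, 1.0))
    ang = math.degrees(math.acos(cosang))
    if ang > 90.0:
        ang = 180.0 - ang
        hkl2 = -np.asarray(hkl2)
    return ZoneNet(
        uvw=tuple(int(x) for x in uvw),
        hkl_short=tuple(int(x) for x in hkl1),
        hkl_long=tuple(int(x) for x in hkl2),
        g_short=n1,
        g_long=n2,
        phi=ang,
    )


def zone_net(
    cell: ReciprocalCell | UnitCell,
    uvw: Sequence[int],
    centring: str = "P",
    hkl_max: int = 12,
) -> ZoneNet:
    """Reduced 2D net of zone [uvw]: the two shortest independent reciprocal
    vectors satisfying hu + kv + lw = 0 and the centring condition."""
    u, v, w = (int(x) for x in uvw)
    if not _coprime(u, v, w):
        raise ValueError(f"zone index must be coprime, got {uvw!r}")
    rcell = reciprocal_of(cell) if isinstance(cell, UnitCell) else cell
    H = _hkl_table(hkl_max, centring)
    in_zone = np.flatnonzero(H @ np.array([u, v, w]) == 0)
    bstar = basis_matrix(rcell)
    gvecs = H @ bstar
    lengths = np.linalg.norm(gvecs, axis=1)
    net = _net_from_subset(H, gvecs, lengths, in_zone, (u, v, w))
    if net is None:
        raise ValueError(f"zone net not constructible for {uvw!r} within hkl_max={hkl_max}")
    return net


def pattern_mismatch(
    pattern: ZonePattern,
    net: ZoneNet,
    weights: MatchWeights = MatchWeights(),
    mean_scale: float | None = None,
) -> tuple[float, float, float, float]:
    """Weighted mismatch components of a pattern against a zone net.

    Returns (eps_ratio, eps_angle, eps_scale, T_p).  All components are
    dimensionless relative deviations; with ``mean_scale`` None the scale
    term is zero (single-pattern comparison).  T_p sums the two
    weight-normalized *shape* mismatches (ratio, angle); the camera-constant
    mismatch is kept separate — it gates acceptance but does not score,
    because absolute lengths carry calibration error rather than lattice
    misfit.
    """
    gs, gl, phi = pattern.canonical
    eps_ratio = abs((gl / gs) - net.ratio) / net.ratio
    eps_angle = abs(phi - net.phi) / net.phi
    s_p = 0.5 * (gs / net.g_short + gl / net.g_long)
    eps_scale = 0.0 if mean_scale is None else abs(s_p - mean_scale) / mean_scale
    t_p = eps_ratio / weights.w1 + eps_angle / weights.w2
    return eps_ratio, eps_angle, eps_scale, t_p


def _result_for_net(pattern, net, weights, mean_scale) -> IndexingResult:
    eps_ratio, eps_angle, eps_scale, t_p = pattern_mismatch(pattern, net, weights, mean_scale)
    gs, gl, _ = pattern.canonical
    s_p = 0.5 * (gs / net.g_short + gl / net.g_long)
    accepted = (
        eps_ratio <= weights.k * weights.w1
        and eps_angle <= weights.k * weights.w2
        and eps_scale <= weights.k * weights.w3
    )
    return IndexingResult(
        pattern_id=pattern.pattern_id,
        uvw=net.uvw,
        hkl_short=net.hkl_short,
        hkl_long=net.hkl_long,
        eps_ratio=eps_ratio,
        eps_angle=eps_angle,
        eps_scale=eps_scale,
        s_p=s_p,
        t_p=t_p,
        accepted=accepted,
        net_g_short=net.g_short,
        net_g_long=net.g_long,
    )


def index_pattern(
    pattern: ZonePattern,
    cell: UnitCell | ReciprocalCell,
    centring: str = "P",
    weights: MatchWeights = MatchWeights(),
    max_index: int = 10,
    hkl_max: int = 12,
    mean_scale: float | None = None,
) -> IndexingResult:
    """Best zone assignment for one pattern against one cell.

    Scans every enumerated zone, scores its net with
    :func:`pattern_mismatch` and keeps the lowest T_p; ties break on
    smaller |u|+|v|+|w|, then lexicographically (inherited from the zone
    enumeration order).  ``accepted`` is False when no zone stays within
    the ``k``-fold tolerance windows.
    """
    rcell = reciprocal_of(cell) if isinstance(cell, UnitCell) else cell
    zones, idx_lists = _zone_index_lists(max_index, hkl_max, centring)
    H = _hkl_table(hkl_max, centring)
    bstar = basis_matrix(rcell)
    gvecs = H @ bstar
    lengths = np.linalg.norm(gvecs, axis=1)
    best: IndexingResult | None = None
    for zone, idx in zip(zones, idx_lists):
        net = _net_from_subset(H, gvecs, lengths, idx, zone)
        if net is None:
            continue
        res = _result_for_net(pattern, net, weights, mean_scale)
        if best is None or res.t_p < best.t_p:
            best = res
    if best is None:
        raise ValueError("no zone net constructible for this cell")
    return best


def rescore_with_mean_scale(
    results: Iterable[IndexingResult], weights: MatchWeights = MatchWeights()
) -> tuple[float, list[IndexingResult]]:
    """Second scoring pass: set the dataset scale to the mean per-pattern
    scale and re-evaluate the scale mismatches and T_p once.

    Returns (R, updated results) with R the mean T_p.  Because the scale
    term only measures deviation from the common mean, R is invariant under
    a global camera-constant error.
    """
    results = list(results)
    if not results:
        raise ValueError("no indexing results to aggregate")
    mean_scale = float(np.mean([r.s_p for r in results]))
    out = []
    for r in results:
        eps_scale = abs(r.s_p - mean_scale) / mean_scale
        t_p = r.eps_ratio / weights.w1 + r.eps_angle / weights.w2
        accepted = (
            r.eps_ratio <= weights.k * weights.w1
            and r.eps_angle <= weights.k * weights.w2
            and eps_scale <= weights.k * weights.w3
        )
        out.append(replace(r, eps_scale=eps_scale, t_p=t_p, accepted=accepted))
    return float(np.mean([r.t_p for r in out])), out


def reliability_index(
    results: Iterable[IndexingResult], weights: MatchWeights = MatchWeights()
) -> float:
    """Reliability index R: mean weight-normalized mismatch over patterns.

    All results must be accepted; the dataset scale is re-estimated from
    the results (two-pass) before averaging.
    """
    results = list(results)
    if not all(r.accepted for r in results):
        raise ValueError("reliability index is undefined with rejected patterns")
    r_value, rescored = rescore_with_mean_scale(results, weights)
    if not all(r.accepted for r in rescored):
        raise ValueError("reliability index is undefined with rejected patterns")
    return r_value
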