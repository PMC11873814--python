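"""Grid search for the unit cell consistent with a set of zonal patterns.

One pattern is chosen to define the [001] zone of the unknown cell, fixing
three reciprocal parameters (a*, b*, γ*).  The missing vector **c*** is
scanned on a grid parametrized by its fractional in-plane components
(ξ, η) and the direct-cell volume V, with V stepped in geometric layers
V_{i+1} = V_i·(1+f).  The metric plane symmetry of the initial pattern
restricts the in-plane scan: p1 → full 2D grid per layer (3D search),
pmm → four mirror lines, cmm → three mirror planes, p4/p6 → two points
(1D search).  Every candidate cell must index all remaining patterns
within tolerance; survivors are ranked by the reliability index R,
locally refined, Delaunay-reduced and deduplicated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize

from .lattice import ReciprocalCell, UnitCell, cells_equivalent, direct_of
from .patterns import SYMMETRY_RANK, ZonePattern
from .reduction import ConventionalCell, ReducedCellResult, conventional_setting, delaunay_reduce
from .zones import (
    IndexingResult,
    MatchWeights,
    _hkl_table,
    _zone_index_lists,
)

__all__ = [
    "ScanFrame",
    "ScanConfig",
    "CandidateSolution",
    "SearchResult",
    "select_initial_zone",
    "volume_layers",
    "vmin_default",
    "candidate_grid",
    "build_candidate_cell",
    "search",
    "refine_candidate",
    "conventional_assignments",
    "fom_surface",
]


@dataclass(frozen=True)
class ScanFrame:
    """The fixed part of the scan: the initial pattern's reciprocal net.

    ``a_star``/``b_star`` (Å⁻¹) and ``gamma_star`` (deg) are taken from the
    initial pattern, after any regularization its symmetry label implies
    (pmm/p4 snap the angle to 90°, p4/p6/cmm equalize the lengths; a
    centred-rectangular cmm pattern is first re-expressed on its
    equal-length diagonal basis).  ``symmetry`` is the label that drives
    the scan dimensionality.
    """

    pattern_id: str
    a_star: float
    b_star: float
    gamma_star: float
    symmetry: str

    @property
    def vectors(self) -> np.ndarray:
        """2×2 rows: in-plane realization of a* and b*."""
        g = math.radians(self.gamma_star)
        return np.array(
            [
                [self.a_star, 0.0],
                [self.b_star * math.cos(g), self.b_star * math.sin(g)],
            ]
        )

    @property
    def area_star(self) -> float:
        """Reciprocal mesh area A* (Å⁻²)."""
        return self.a_star * self.b_star * math.sin(math.radians(self.gamma_star))

    @property
    def area(self) -> float:
        """Direct mesh area A = 1/A* (Å²): base area of the searched cell."""
        return 1.0 / self.area_star

    @classmethod
    def from_pattern(
        cls,
        pattern: ZonePattern,
        symmetry: str | None = None,
        tol_len: float = 0.01,
        tol_ang: float = 0.5,
    ) -> "ScanFrame":
        label = symmetry or pattern.effective_symmetry(tol_len, tol_ang)
        gs, gl, phi = pattern.canonical
        if label == "p4":
            g = 0.5 * (gs + gl)
            return cls(pattern.pattern_id, g, g, 90.0, label)
        if label == "p6":
            g = 0.5 * (gs + gl)
            return cls(pattern.pattern_id, g, g, 60.0, label)
        if label == "cmm":
            if abs(gs - gl) / gl <= 2.0 * tol_len:
                g = 0.5 * (gs + gl)
                return cls(pattern.pattern_id, g, g, phi, label)
            # centred-rectangular setting: the equal-length primitive pair
            # is {g_long, g_long − g_short}
            c = math.cos(math.radians(phi))
            l2 = math.sqrt(gl * gl + gs * gs - 2.0 * gs * gl * c)
            cosd = (gl * gl - gs * gl * c) / (gl * l2)
            phi_d = math.degrees(math.acos(max(-1.0, min(1.0, cosd))))
            g = 0.5 * (gl + l2)
            return cls(pattern.pattern_id, g, g, phi_d, label)
        if label == "pmm":
            return cls(pattern.pattern_id, gs, gl, 90.0, label)
        return cls(pattern.pattern_id, gs, gl, phi, "p1")


@dataclass(frozen=True)
class ScanConfig:
    """Search parameters.

    ``v_min``/``v_max`` bound the direct-cell volume (Å³); ``v_min`` left
    None defaults to base area × ``h_min``.  ``f`` is the fractional volume
    increment between layers, ``step`` the in-plane fractional grid step.
    ``mode`` forces the scan dimensionality ("auto" follows the initial
    pattern's symmetry; "3d" ignores it).  ``scale_window`` is the relative
    half-width of the reflection-length window used when collecting
    candidate basis pairs for a pattern.
    """

    v_max: float
    v_min: Optional[float] = None
    f: float = 0.025
    step: float = 1.0 / 24.0
    mode: str = "auto"
    weights: MatchWeights = field(default_factory=MatchWeights)
    max_index: int = 10
    hkl_max: int = 12
    h_min: float = 3.4
    refine: bool = True
    initial: Optional[str] = None
    exclude: tuple[str, ...] = ()
    scale_window: float = 0.06
    max_refine: int = 40
    keep_trace: bool = False
    merge_tol_len: float = 0.02
    merge_tol_ang: float = 2.0
    sym_tol_len: float = 0.01
    sym_tol_ang: float = 0.5
    n_conventional: int = 10

    def __post_init__(self) -> None:
        if self.v_max <= 0 or self.f <= 0:
            raise ValueError("v_max and f must be positive")
        if not (0 < self.step <= 0.5):
            raise ValueError("step must be in (0, 0.5]")
        if self.v_min is not None and not (0 < self.v_min < self.v_max):
            raise ValueError("need 0 < v_min < v_max")
        if self.mode not in ("auto", "1d", "2d", "3d"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class CandidateSolution:
    """One surviving candidate cell with its indexing evidence."""

    xi: float
    eta: float
    volume: float
    plane: str
    t: float
    rcell: ReciprocalCell
    cell: UnitCell
    r: float
    results: list[IndexingResult]
    reduced: Optional[ReducedCellResult] = None
    conventional: Optional[ConventionalCell] = None

    @property
    def reduced_cell(self) -> UnitCell:
        return self.reduced.cell if self.reduced else self.cell


@dataclass
class SearchResult:
    solutions: list[CandidateSolution]
    frame: ScanFrame
    layers: list[float]
    n_candidates: int
    n_survivors: int
    trace: list[tuple]  # (plane, t, xi, eta, V, R-or-None)


def select_initial_zone(
    patterns: Sequence[ZonePattern], tol_len: float = 0.01, tol_ang: float = 0.5
) -> str:
    """Choose the pattern defining the [001] zone: highest metric symmetry
    first (p6 ≻ p4 ≻ cmm ≻ pmm ≻ p1), ties broken by the longest basis
    vectors (largest d1 + d2)."""
    if not patterns:
        raise ValueError("no patterns to choose from")
    best = max(
        patterns,
        key=lambda p: (SYMMETRY_RANK[p.effective_symmetry(tol_len, tol_ang)], p.d1 + p.d2),
    )
    return best.pattern_id


def volume_layers(v_min: float, v_max: float, f: float) -> list[float]:
    """Geometric volume ladder V, V(1+f), …; the first value above
    ``v_max`` terminates (and is included in) the list."""
    if not (0 < v_min <= v_max) or f <= 0:
        raise ValueError("need 0 < v_min <= v_max and f > 0")
    layers = [v_min]
    while layers[-1] < v_max:
        layers.append(layers[-1] * (1.0 + f))
    return layers


def vmin_default(frame: ScanFrame, h_min: float = 3.4) -> float:
    """Smallest plausible cell volume for the frame: base area × ``h_min``."""
    if h_min <= 0:
        raise ValueError("h_min must be positive")
    return frame.area * h_min


def _plane_points(
    symmetry: str, step: float, aspect: tuple[float, float] = (1.0, 1.0)
) -> list[tuple[str, float, float, float]]:
    """(plane tag, scan parameter t, ξ, η) tuples for one volume layer.

    ``aspect`` rescales the fractional step per axis so that the physical
    c* displacement per grid step is uniform when the frame vectors have
    very different lengths (step·aspect along ξ and η respectively).
    """
    step_xi = step * aspect[0]
    step_eta = step * aspect[1]
    ts_eta = np.arange(0.0, 0.5 + 1e-9, step_eta)
    ts_xi = np.arange(0.0, 0.5 + 1e-9, step_xi)
    pts: list[tuple[str, float, float, float]] = []
    if symmetry == "p1":
        xs = np.arange(-0.5, 0.5 - 1e-9, step_xi)
        for eta in ts_eta:
            for xi in xs:
                pts.append(("grid", float(xi), float(xi), float(eta)))
        return pts
    if symmetry == "pmm":
        for t in ts_eta:
            pts.append(("x=0", float(t), 0.0, float(t)))
            pts.append(("x=1/2", float(t), 0.5, float(t)))
        for t in ts_xi:
            pts.append(("y=0", float(t), float(t), 0.0))
            pts.append(("y=1/2", float(t), float(t), 0.5))
    elif symmetry == "cmm":
        for t in ts_xi:
            pts.append(("xi=eta", float(t), float(t), float(t)))
            pts.append(("xi=-eta", float(t), float(t), -float(t)))
            pts.append(("xi+eta=1", float(t), float(t), 1.0 - float(t)))
    elif symmetry == "p4":
        pts = [("origin", 0.0, 0.0, 0.0), ("centre", 0.5, 0.5, 0.5)]
    elif symmetry == "p6":
        pts = [("origin", 0.0, 0.0, 0.0), ("centre", 1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0)]
    else:
        raise ValueError(f"unknown symmetry label {symmetry!r}")
    seen: set[tuple[int, int]] = set()
    out = []
    for tag, t, xi, eta in pts:
        key = (round(xi * 1e9), round(eta * 1e9))
        if key in seen:
            continue
        seen.add(key)
        out.append((tag, t, xi, eta))
    return out


def candidate_grid(
    symmetry: str,
    layers: Sequence[float],
    step: float,
    aspect: tuple[float, float] = (1.0, 1.0),
) -> list[tuple[float, float, float]]:
    """All (ξ, η, V) scan candidates for a symmetry label."""
    pts = _plane_points(symmetry, step, aspect)
    return [(xi, eta, float(V)) for V in layers for (_, _, xi, eta) in pts]


def _cstar_vector(frame: ScanFrame, xi: float, eta: float, volume: float) -> np.ndarray:
    vecs = frame.vectors
    zeta = 1.0 / (frame.area_star * volume)
    xy = xi * vecs[0] + eta * vecs[1]
    return np.array([xy[0], xy[1], zeta])


def build_candidate_cell(frame: ScanFrame, xi: float, eta: float, volume: float) -> ReciprocalCell:
    """Reciprocal cell with c* = ξ·a* + η·b* + ζ·ĉ₀, ζ fixed so the direct
    cell volume equals ``volume`` (Å³)."""
    if volume <= 0:
        raise ValueError("volume must be positive")
    cvec = _cstar_vector(frame, xi, eta, volume)
    vecs = frame.vectors
    a = np.array([vecs[0][0], vecs[0][1], 0.0])
    b = np.array([vecs[1][0], vecs[1][1], 0.0])
    na, nb, nc = (float(np.linalg.norm(v)) for v in (a, b, cvec))

    def ang(u, v, nu, nv):
        return math.degrees(math.acos(max(-1.0, min(1.0, float(u @ v) / (nu * nv)))))

    return ReciprocalCell(
        a_star=na,
        b_star=nb,
        c_star=nc,
        alpha_star=ang(b, cvec, nb, nc),
        beta_star=ang(a, cvec, na, nc),
        gamma_star=ang(a, b, na, nb),
    )


class _FastMatcher:
    """Vectorized indexing of a pattern set against candidate c* vectors.

    Works on a fixed frame: reflection triples are enumerated once, their
    in-plane components precomputed, and for each candidate only the
    c*-dependent part of every g vector is rebuilt.  A pattern is matched
    by collecting reflections whose lengths fall in a window around its
    two observed g-lengths, scoring all cross pairs, and validating that
    the winning pair is the Gauss-reduced basis of its own zone (a pair
    spanning a sub-net of a zone is not what the pattern would show).
    """

    def __init__(
        self,
        frame: ScanFrame,
        patterns: Sequence[ZonePattern],
        weights: MatchWeights,
        max_index: int,
        hkl_max: int,
        scale_window: float,
    ):
        self.frame = frame
        self.weights = weights
        self.max_index = max_index
        H = _hkl_table(hkl_max, "P")
        self.H = H
        self.M = H[:, :2].astype(float) @ frame.vectors
        self.l = H[:, 2].astype(float)
        self.norm_m = np.linalg.norm(self.M, axis=1)
        self.abs_l = np.abs(self.l)
        zones, idx_lists = _zone_index_lists(max_index, hkl_max, "P")
        self.zone_lookup = {z: idx for z, idx in zip(zones, idx_lists)}
        self.patterns = list(patterns)
        self.windows = []
        w = scale_window
        for p in self.patterns:
            gs, gl, phi = p.canonical
            self.windows.append(
                (
                    gs,
                    gl,
                    phi,
                    gl / gs,
                    (gs / (1 + w)) ** 2,
                    (gs * (1 + w)) ** 2,
                    (gl / (1 + w)) ** 2,
                    (gl * (1 + w)) ** 2,
                )
            )
        self.g_max_sq = max(hi2 for *_, hi2 in self.windows)
        # widest in-plane excursion of c* over the scan region, with margin
        na = float(np.linalg.norm(frame.vectors[0]))
        nb = float(np.linalg.norm(frame.vectors[1]))
        self.cxy_max = 0.6 * na + 1.1 * nb

    def feasible_rows(self, zeta_min: float) -> np.ndarray:
        """Rows whose g length can fall inside some pattern window anywhere
        in the scan region at interlayer spacing ≥ ``zeta_min`` (a
        conservative lower bound on each row's g)."""
        deficit = np.clip(self.norm_m - self.abs_l * self.cxy_max, 0.0, None)
        lower_sq = deficit**2 + (self.abs_l * zeta_min) ** 2
        return np.flatnonzero(lower_sq <= self.g_max_sq * 1.02)

    def _zone_reduced_lengths(self, zone, cvec) -> tuple[float, float] | None:
        idx = self.zone_lookup.get(zone)
        if idx is None or len(idx) < 2:
            return None
        xy = self.M[idx] + self.l[idx, None] * cvec[:2]
        g2 = xy[:, 0] ** 2 + xy[:, 1] ** 2 + (self.l[idx] * cvec[2]) ** 2
        order = np.argsort(g2, kind="stable")
        h1 = self.H[idx[order[0]]]
        for o in order[1:]:
            h2 = self.H[idx[o]]
            if (
                h1[1] * h2[2] - h1[2] * h2[1]
                or h1[2] * h2[0] - h1[0] * h2[2]
                or h1[0] * h2[1] - h1[1] * h2[0]
            ):
                pair = sorted((math.sqrt(g2[order[0]]), math.sqrt(g2[o])))
                return pair[0], pair[1]
        return None

    def index_one(
        self,
        ip: int,
        cvec: np.ndarray,
        rows: np.ndarray,
        xy: np.ndarray,
        z: np.ndarray,
        g2: np.ndarray,
    ) -> IndexingResult | None:
        """Best accepted zone for pattern ``ip``, or None (scale term left 0)."""
        wts = self.weights
        gs, gl, phi_obs, rho_obs, lo1, hi1, lo2, hi2 = self.windows[ip]
        sel1 = np.flatnonzero((g2 >= lo1) & (g2 <= hi1))
        sel2 = np.flatnonzero((g2 >= lo2) & (g2 <= hi2))
        if len(sel1) == 0 or len(sel2) == 0:
            return None
        idx1 = rows[sel1]
        idx2 = rows[sel2]
        v1 = np.column_stack([xy[sel1], z[sel1]])
        v2 = np.column_stack([xy[sel2], z[sel2]])
        L1 = np.sqrt(g2[sel1])
        L2 = np.sqrt(g2[sel2])
        dots = np.abs(v1 @ v2.T)
        denom = L1[:, None] * L2[None, :]
        cosang = np.clip(dots / denom, 0.0, 1.0)
        phi_net = np.degrees(np.arccos(cosang))
        ls = np.minimum(L1[:, None], L2[None, :])
        ll = np.maximum(L1[:, None], L2[None, :])
        with np.errstate(divide="ignore", invalid="ignore"):
            rho_net = ll / ls
        eps_ratio = np.abs(rho_obs - rho_net) / rho_net
        eps_angle = np.where(
            phi_net > 1e-9, np.abs(phi_obs - phi_net) / np.maximum(phi_net, 1e-12), np.inf
        )
        valid = (eps_ratio <= wts.k * wts.w1) & (eps_angle <= wts.k * wts.w2)
        if not valid.any():
            return None
        t_partial = eps_ratio / wts.w1 + eps_angle / wts.w2
        flat = np.flatnonzero(valid.ravel())
        order = flat[np.argsort(t_partial.ravel()[flat], kind="stable")]
        n2 = len(idx2)
        tried: list[tuple[float, int, tuple, int, int]] = []
        best_t = None
        for f_idx in order:
            i, j = divmod(int(f_idx), n2)
            t_here = float(t_partial[i, j])
            if best_t is not None and t_here > best_t + 1e-9:
                break
            h1, h2 = self.H[idx1[i]], self.H[idx2[j]]
            zv = np.cross(h1, h2)
            if not np.any(zv):
                continue
            g = math.gcd(math.gcd(abs(int(zv[0])), abs(int(zv[1]))), abs(int(zv[2])))
            zv = zv // g
            nzv = next((x for x in zv if x != 0), 0)
            if nzv < 0:
                zv = -zv
            zone = (int(zv[0]), int(zv[1]), int(zv[2]))
            if max(abs(c) for c in zone) > self.max_index:
                continue
            red = self._zone_reduced_lengths(zone, cvec)
            if red is None:
                continue
            pair = sorted((float(L1[i]), float(L2[j])))
            if abs(pair[0] - red[0]) > 1e-7 * red[0] or abs(pair[1] - red[1]) > 1e-7 * red[1]:
                continue  # pair spans a sub-net of this zone
            if best_t is None:
                best_t = t_here
            tried.append((t_here, sum(abs(c) for c in zone), zone, i, j))
        if not tried:
            return None
        tried.sort(key=lambda x: (x[1], x[2]))
        _, _, zone, i, j = tried[0]
        i1, i2 = idx1[i], idx2[j]
        pair_ls, pair_ll = sorted((float(L1[i]), float(L2[j])))
        hkl_s, hkl_l = (self.H[i1], self.H[i2]) if L1[i] <= L2[j] else (self.H[i2], self.H[i1])
        er = float(eps_ratio[i, j])
        ea = float(eps_angle[i, j])
        s_p = 0.5 * (gs / pair_ls + gl / pair_ll)
        t_p = er / wts.w1 + ea / wts.w2
        return IndexingResult(
            pattern_id=self.patterns[ip].pattern_id,
            uvw=zone,
            hkl_short=tuple(int(x) for x in hkl_s),
            hkl_long=tuple(int(x) for x in hkl_l),
            eps_ratio=er,
            eps_angle=ea,
            eps_scale=0.0,
            s_p=float(s_p),
            t_p=float(t_p),
            accepted=True,
            net_g_short=pair_ls,
            net_g_long=pair_ll,
        )

    def evaluate(
        self, cvec: np.ndarray, rows: np.ndarray | None = None
    ) -> tuple[float, list[IndexingResult]] | None:
        """Index every pattern against the candidate; two-pass scale scoring.

        Returns (R, results) or None if any pattern fails its tolerance
        windows (early abort on the first failure).  ``rows`` restricts the
        reflection table to a precomputed feasible subset (see
        :meth:`feasible_rows`)."""
        wts = self.weights
        if rows is None:
            rows = self.feasible_rows(cvec[2])
        xy = self.M[rows] + self.l[rows, None] * cvec[:2]
        z = self.l[rows] * cvec[2]
        g2 = xy[:, 0] ** 2 + xy[:, 1] ** 2 + z**2
        results = []
        for ip in range(len(self.patterns)):
            res = self.index_one(ip, cvec, rows, xy, z, g2)
            if res is None:
                return None
            results.append(res)
        mean_scale = float(np.mean([r.s_p for r in results]))
        final = []
        for r in results:
            eps_scale = abs(r.s_p - mean_scale) / mean_scale
            if eps_scale > wts.k * wts.w3:
                return None
            t_p = r.eps_ratio / wts.w1 + r.eps_angle / wts.w2
            final.append(replace(r, eps_scale=eps_scale, t_p=t_p))
        return float(np.mean([r.t_p for r in final])), final


def _effective_symmetry(pattern: ZonePattern, config: ScanConfig) -> str:
    label = pattern.effective_symmetry(config.sym_tol_len, config.sym_tol_ang)
    if config.mode == "3d":
        return "p1"
    if config.mode == "2d":
        if label in ("p4", "p6"):
            return "cmm" if label == "p6" else "pmm"
        if label == "p1":
            raise ValueError("2D scan requested but the initial pattern has no mirror symmetry")
        return label
    if config.mode == "1d":
        if label not in ("p4", "p6"):
            raise ValueError("1D scan requires a fourfold or sixfold initial pattern")
        return label
    return label


def search(patterns: Sequence[ZonePattern], config: ScanConfig) -> SearchResult:
    """Run the full grid search and return ranked candidate solutions."""
    pats = [p for p in patterns if p.pattern_id not in config.exclude]
    if len(pats) < 2:
        raise ValueError("search needs at least 2 patterns")
    ids = [p.pattern_id for p in pats]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate pattern ids")

    initial_id = config.initial or select_initial_zone(pats, config.sym_tol_len, config.sym_tol_ang)
    initial = next((p for p in pats if p.pattern_id == initial_id), None)
    if initial is None:
        raise ValueError(f"initial pattern {initial_id!r} not in the dataset")
    scan_sym = _effective_symmetry(initial, config)
    frame = ScanFrame.from_pattern(
        initial, symmetry=scan_sym, tol_len=config.sym_tol_len, tol_ang=config.sym_tol_ang
    )

    others = [p for p in pats if p.pattern_id != initial_id]
    others.sort(key=lambda p: -p.d1)  # most constraining (longest axis) first

    v_min = config.v_min if config.v_min is not None else vmin_default(frame, config.h_min)
    if v_min >= config.v_max:
        raise ValueError("v_min is above v_max; lower h_min or raise v_max")
    layers = volume_layers(v_min, config.v_max, config.f)
    # uniform physical step: the fractional step shrinks along a long axis
    g_min = min(frame.a_star, frame.b_star)
    aspect = (g_min / frame.a_star, g_min / frame.b_star)
    points = _plane_points(frame.symmetry, config.step, aspect)

    matcher = _FastMatcher(
        frame, others, config.weights, config.max_index, config.hkl_max, config.scale_window
    )

    survivors: list[CandidateSolution] = []
    trace: list[tuple] = []
    n_candidates = 0
    for volume in layers:
        layer_rows = matcher.feasible_rows(1.0 / (frame.area_star * volume))
        for tag, t, xi, eta in points:
            n_candidates += 1
            cvec = _cstar_vector(frame, xi, eta, volume)
            out = matcher.evaluate(cvec, layer_rows)
            if config.keep_trace:
                trace.append((tag, t, xi, eta, volume, out[0] if out else None))
            if out is None:
                continue
            r_value, results = out
            rcell = build_candidate_cell(frame, xi, eta, volume)
            survivors.append(
                CandidateSolution(
                    xi=xi, eta=eta, volume=volume, plane=tag, t=t,
                    rcell=rcell, cell=direct_of(rcell), r=r_value, results=results,
                )
            )

    survivors.sort(key=lambda s: s.r)
    if config.refine:
        refined = [
            refine_candidate(c, frame, matcher, config) for c in survivors[: config.max_refine]
        ]
        survivors = refined + survivors[config.max_refine:]
        survivors.sort(key=lambda s: s.r)

    for s in survivors:
        s.reduced = delaunay_reduce(s.cell)

    merged: list[CandidateSolution] = []
    for s in survivors:  # ascending R: first representative kept
        if any(
            cells_equivalent(
                s.reduced_cell, m.reduced_cell, config.merge_tol_len, config.merge_tol_ang
            )[0]
            for m in merged
        ):
            continue
        merged.append(s)

    for s in merged[: config.n_conventional]:
        s.conventional = conventional_setting(s.reduced)

    return SearchResult(
        solutions=merged,
        frame=frame,
        layers=layers,
        n_candidates=n_candidates,
        n_survivors=len(survivors),
        trace=trace,
    )


def _free_params(plane: str, sol: CandidateSolution) -> tuple[list[float], callable]:
    """Refinement parametrization restricted to the candidate's scan locus."""
    lnv = math.log(sol.volume)
    if plane == "grid":
        def to_point(p):
            return p[0], p[1], math.exp(p[2])
        return [sol.xi, sol.eta, lnv], to_point
    if plane in ("origin", "centre"):
        xi, eta = sol.xi, sol.eta
        def to_point(p):
            return xi, eta, math.exp(p[0])
        return [lnv], to_point
    mapping = {
        "x=0": lambda t: (0.0, t),
        "x=1/2": lambda t: (0.5, t),
        "y=0": lambda t: (t, 0.0),
        "y=1/2": lambda t: (t, 0.5),
        "xi=eta": lambda t: (t, t),
        "xi=-eta": lambda t: (t, -t),
        "xi+eta=1": lambda t: (t, 1.0 - t),
    }
    fn = mapping[plane]
    def to_point(p):
        xi, eta = fn(p[0])
        return xi, eta, math.exp(p[1])
    return [sol.t, lnv], to_point


def refine_candidate(
    sol: CandidateSolution,
    frame: ScanFrame,
    matcher: _FastMatcher,
    config: ScanConfig,
) -> CandidateSolution:
    """Derivative-free local refinement of a candidate along its scan locus.

    Minimizes R over the free coordinates (V only for 1D loci, the in-plane
    parameter and V for mirror planes, ξ, η and V for the general grid).
    Steps that lose any pattern are penalized, so acceptance is preserved;
    R never increases (the grid solution is kept if no improvement)."""
    x0, to_point = _free_params(sol.plane, sol)
    # feasible-row set wide enough for the local neighbourhood (V up to ~40% above start)
    rows = matcher.feasible_rows(0.7 / (frame.area_star * sol.volume))

    def objective(p):
        xi, eta, volume = to_point(p)
        out = matcher.evaluate(_cstar_vector(frame, xi, eta, volume), rows)
        return 1e3 if out is None else out[0]

    res = minimize(
        objective,
        np.array(x0),
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-6, "maxiter": 400},
    )
    xi, eta, volume = to_point(res.x)
    out = matcher.evaluate(_cstar_vector(frame, xi, eta, volume))
    if out is None or out[0] > sol.r:
        return sol
    r_value, results = out
    rcell = build_candidate_cell(frame, xi, eta, volume)
    t_new = {"grid": sol.t, "origin": sol.t, "centre": sol.t}.get(sol.plane, float(res.x[0]))
    return CandidateSolution(
        xi=xi, eta=eta, volume=volume, plane=sol.plane, t=t_new,
        rcell=rcell, cell=direct_of(rcell), r=r_value, results=results,
    )


def conventional_assignments(sol: CandidateSolution) -> list[tuple[str, tuple, tuple, tuple]]:
    """Per-pattern (id, hkl_short, hkl_long, uvw) of a solution, re-indexed
    from the search's primitive frame into its conventional setting.

    Reflections transform with the row-transform M (conventional basis on
    the frame basis) as h_conv = h_frame·Mᵀ; zone indices transform
    contravariantly and are rescaled to coprime integers.
    """
    from fractions import Fraction

    if sol.reduced is None or sol.conventional is None:
        raise ValueError("solution lacks reduced/conventional settings")
    m = sol.conventional.transform.astype(float) @ sol.reduced.transform.astype(float)
    m_inv = np.linalg.inv(m)
    out = []
    for r in sol.results:
        h1 = tuple(int(x) for x in np.rint(np.array(r.hkl_short, float) @ m.T))
        h2 = tuple(int(x) for x in np.rint(np.array(r.hkl_long, float) @ m.T))
        u = np.array(r.uvw, float) @ m_inv
        fr = [Fraction(x).limit_denominator(24) for x in u]
        den = int(np.lcm.reduce([f.denominator for f in fr]))
        ui = np.array([int(f * den) for f in fr])
        if np.any(ui):
            ui = ui // int(np.gcd.reduce(np.abs(ui[ui != 0])))
        out.append((r.pattern_id, h1, h2, tuple(int(x) for x in ui)))
    return out


def fom_surface(
    trace: Sequence[tuple], plane: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Inverse figure-of-merit surface F_inv = 1/R over one scan plane.

    Returns (t values, volumes, grid) where ``grid[i, j]`` is 1/R at scan
    parameter ``t[i]`` and volume ``V[j]``; rejected candidates enter as 0.
    Requires a search run with ``keep_trace=True``.
    """
    rows = [r for r in trace if r[0] == plane]
    if not rows:
        raise ValueError(f"no trace entries for plane {plane!r} (was the trace retained?)")
    ts = np.array(sorted({round(r[1], 12) for r in rows}))
    vs = np.array(sorted({round(r[4], 9) for r in rows}))
    grid = np.zeros((len(ts), len(vs)))
    t_index = {t: i for i, t in enumerate(ts)}
    v_index = {v: j for j, v in enumerate(vs)}
    for _, t, _, _, v, r in rows:
        i, j = t_index[round(t, 12)], v_index[round(v, 9)]
        grid[i, j] = 0.0 if (r is None or r <= 0) else 1.0 / r
    return ts, vs, grid
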