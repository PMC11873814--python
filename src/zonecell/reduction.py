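"""Delaunay cell reduction and conventional-setting proposal.

The reduction iterates the classical transformation on the four vectors
{a, b, c, d = −(a+b+c)} until all six pairwise scalar products are
non-positive, then picks the three shortest of the seven derived vectors
{a, b, c, d, a+b, b+c, a+c} forming a |det| = 1 basis.  The conventional
setting is found by enumerating small integer supercell bases (|det| ≤ 4)
of the reduced cell and scoring them against the lattice systems; angles
are reported as computed, never snapped to special values.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .lattice import UnitCell, basis_matrix, cell_from_metric

__all__ = [
    "ReducedCellResult",
    "ConventionalCell",
    "delaunay_reduce",
    "conventional_setting",
]


@dataclass(frozen=True)
class ReducedCellResult:
    """Delaunay-reduced cell, the integer transform that produced it and the
    six pairwise scalar products (Å²) of the terminal Delaunay vectors."""

    cell: UnitCell
    transform: np.ndarray  # rows: reduced basis on the input basis
    scalar_products: np.ndarray  # six values, all ≤ tolerance

    @property
    def volume(self) -> float:
        return self.cell.volume


@dataclass(frozen=True)
class ConventionalCell:
    """A proposed conventional setting of a reduced cell."""

    cell: UnitCell
    centring: str  # P, A, B, C, I, F or R
    system: str  # lattice-system guess from the metric
    transform: np.ndarray  # rows: conventional basis on the reduced basis
    deviation: float  # worst tolerance-normalized metric deviation

    @property
    def volume(self) -> float:
        return self.cell.volume


_MAX_ITER = 10_000


def delaunay_reduce(cell: UnitCell, tol: float | None = None) -> ReducedCellResult:
    """Delaunay-reduce a cell (volume-preserving, |det| = 1 transform)."""
    basis = basis_matrix(cell)
    # rows: the four Delaunay vectors expressed on the input basis
    coeff = np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1], [-1, -1, -1]], dtype=np.int64)
    vecs = coeff @ basis
    if tol is None:
        tol = 1e-8 * float(np.max(np.sum(vecs * vecs, axis=1)))

    pairs = list(itertools.combinations(range(4), 2))
    for _ in range(_MAX_ITER):
        dots = np.array([vecs[i] @ vecs[j] for i, j in pairs])
        worst = int(np.argmax(dots))
        if dots[worst] <= tol:
            break
        i, j = pairs[worst]
        # classic step: flip v_i, add the old v_i to the two vectors not in
        # the offending pair; the four vectors keep summing to zero
        for k in range(4):
            if k != i and k != j:
                vecs[k] += vecs[i]
                coeff[k] += coeff[i]
        vecs[i] = -vecs[i]
        coeff[i] = -coeff[i]
    else:
        raise RuntimeError("Delaunay reduction did not converge")

    final_dots = np.array([vecs[i] @ vecs[j] for i, j in pairs])

    # seven derived vectors: the four plus the three pairwise sums of a,b,c
    seven_c = list(coeff) + [coeff[0] + coeff[1], coeff[1] + coeff[2], coeff[0] + coeff[2]]
    seven_v = [c @ basis for c in seven_c]
    order = np.argsort([v @ v for v in seven_v], kind="stable")

    chosen: list[int] = []
    for idx in order:
        trial = chosen + [int(idx)]
        if len(trial) >= 2:
            m = np.array([seven_c[t] for t in trial])
            if np.linalg.matrix_rank(m) < len(trial):
                continue
        chosen = trial
        if len(chosen) == 3:
            m = np.array([seven_c[t] for t in chosen])
            if round(abs(np.linalg.det(m))) == 1:
                break
            chosen = chosen[:2]  # rare: shortest triple spans a sublattice
    red_c = np.array([seven_c[t] for t in chosen], dtype=np.int64)
    red_v = red_c @ basis

    # fix signs so all three mutual scalar products are non-positive
    best_signs, best_score = (1, 1, 1), np.inf
    for s in itertools.product((1, -1), repeat=3):
        if s[0] < 0:
            continue
        sv = red_v * np.array(s)[:, None]
        score = max(sv[0] @ sv[1], sv[1] @ sv[2], sv[0] @ sv[2])
        if score < best_score:
            best_score, best_signs = score, s
    red_c = red_c * np.array(best_signs)[:, None]
    red_v = red_c @ basis

    order3 = np.argsort(np.sum(red_v * red_v, axis=1), kind="stable")
    red_c = red_c[order3]
    red_v = red_v[order3]
    if np.linalg.det(red_v) < 0:
        red_c, red_v = -red_c, -red_v

    reduced = cell_from_metric(red_v @ red_v.T)
    return ReducedCellResult(cell=reduced, transform=red_c, scalar_products=final_dots)


# lattice systems ranked so the most symmetric qualifying metric wins
_SYSTEM_RANK = {
    "cubic": 6,
    "hexagonal": 5,
    "tetragonal": 4,
    "rhombohedral": 3,
    "orthorhombic": 2,
    "monoclinic": 1,
    "triclinic": 0,
}

_CENTRING_BY_TRANSLATIONS = {
    frozenset(): "P",
    frozenset({(0, 6, 6)}): "A",
    frozenset({(6, 0, 6)}): "B",
    frozenset({(6, 6, 0)}): "C",
    frozenset({(6, 6, 6)}): "I",
    frozenset({(0, 6, 6), (6, 0, 6), (6, 6, 0)}): "F",
}


_N_GRID = np.array(list(itertools.product(range(-2, 3), repeat=3)), dtype=float)


def _centring_symbol(coeff: np.ndarray) -> str | None:
    """Centring letter from the sublattice translations of a supercell basis."""
    det = int(round(abs(np.linalg.det(coeff))))
    inv = np.linalg.inv(coeff)
    frac = (_N_GRID @ inv) % 1.0
    twelfths = np.rint(frac * 12.0)
    if np.max(np.abs(frac * 12.0 - twelfths)) > 0.02:
        return None  # translations not on a 12th grid: not a standard centring
    keys = np.unique(twelfths.astype(np.int64) % 12, axis=0)
    pts = {tuple(int(x) for x in row) for row in keys}
    pts.discard((0, 0, 0))
    if len(pts) != det - 1:
        return None
    if det == 3:
        # third-integer translations: rhombohedral-style centring
        if all(all(x in (0, 4, 8) for x in p) for p in pts):
            return "R"
        return None
    return _CENTRING_BY_TRANSLATIONS.get(frozenset(pts))


_CENTRING_RANK = {"C": 3, "P": 3, "I": 2, "A": 1, "B": 0}


def _monoclinic_standardize(coeff: np.ndarray, basis: np.ndarray) -> np.ndarray:
    """Normalize a b-unique monoclinic setting.

    Recombines the in-plane pair (a, c) over small unimodular mixes to reach
    the standard setting: centring C (or P) preferred over I/A, shortest
    axes, β ≥ 90 and a ≥ c.
    """
    b_row = coeff[1]
    a0, c0 = coeff[0], coeff[2]
    best_key, best = None, coeff
    for p, q, r, s in itertools.product(range(-2, 3), repeat=4):
        if abs(p * s - q * r) != 1:
            continue
        new = np.array([p * a0 + q * c0, b_row, r * a0 + s * c0])
        v = new @ basis
        la, lc = np.linalg.norm(v[0]), np.linalg.norm(v[2])
        beta = np.degrees(np.arccos(np.clip((v[0] @ v[2]) / (la * lc), -1, 1)))
        symbol = _centring_symbol(new)
        if symbol is None:
            continue
        key = (
            _CENTRING_RANK.get(symbol, -1),
            -round(la * la + lc * lc, 6),
            beta >= 90.0,
            round(la, 6) >= round(lc, 6),
        )
        if best_key is None or key > best_key:
            best_key, best = key, new
    return best


def conventional_setting(
    reduced: ReducedCellResult | UnitCell,
    tol_ang: float = 2.0,
    tol_len: float = 0.02,
    max_coeff: int = 2,
    n_shortest: int = 40,
) -> ConventionalCell:
    """Propose a conventional centred setting for a reduced cell.

    Enumerates integer bases (coefficients in ±``max_coeff``, |det| ∈ 1…4)
    built from the ``n_shortest`` shortest candidate lattice vectors, keeps
    those whose sublattice translations form a standard centring, and
    returns the highest-symmetry qualifying setting; ties prefer a smaller
    conventional volume, then a smaller metric deviation.  P triclinic is
    always available as a fallback.
    """
    red_cell = reduced.cell if isinstance(reduced, ReducedCellResult) else reduced
    basis = basis_matrix(red_cell)

    coeffs = []
    for m in itertools.product(range(-max_coeff, max_coeff + 1), repeat=3):
        if m == (0, 0, 0):
            continue
        nz = next(x for x in m if x != 0)
        if nz < 0:
            continue  # one representative per ± pair
        coeffs.append(m)
    coeffs = np.array(coeffs, dtype=np.int64)
    vecs = coeffs @ basis
    norms = np.linalg.norm(vecs, axis=1)
    order = np.argsort(norms, kind="stable")[:n_shortest]
    coeffs, vecs, norms = coeffs[order], vecs[order], norms[order]

    n = len(coeffs)
    # all i<j<k triples with integer sublattice index |det| in 1…4,
    # assembled with vectorized pair cross products
    ii, jj = np.triu_indices(n, k=1)
    ccross = np.cross(coeffs[ii], coeffs[jj])
    cdets = ccross @ coeffs.T  # (n_pairs, n) integer determinants
    k_ok = np.arange(n)[None, :] > jj[:, None]
    absd = np.abs(cdets)
    qual = k_ok & (absd >= 1) & (absd <= 4)
    p_idx, k_idx = np.nonzero(qual)
    ti, tj, tk = ii[p_idx], jj[p_idx], k_idx
    tdet = absd[p_idx, k_idx].astype(np.int64)

    dots = vecs @ vecs.T
    L = norms
    lens3 = np.stack([L[ti], L[tj], L[tk]], axis=1)
    cos3 = np.stack(
        [
            dots[tj, tk] / (L[tj] * L[tk]),  # alpha: between axes 2 and 3
            dots[ti, tk] / (L[ti] * L[tk]),  # beta
            dots[ti, tj] / (L[ti] * L[tj]),  # gamma
        ],
        axis=1,
    )
    ang3 = np.degrees(np.arccos(np.clip(cos3, -1.0, 1.0)))

    perms = list(itertools.permutations(range(3)))
    best_rank = np.full(len(ti), -1)
    best_dev = np.full(len(ti), np.inf)
    best_perm = np.zeros(len(ti), dtype=np.int64)
    for ip, perm in enumerate(perms):
        Lp = lens3[:, perm]
        Ap = ang3[:, perm]
        d_ab = np.abs(Lp[:, 0] / Lp[:, 1] - 1.0)
        d_bc = np.abs(Lp[:, 1] / Lp[:, 2] - 1.0)
        d90 = np.abs(Ap - 90.0)
        d90max = d90.max(axis=1)
        d120 = np.minimum(np.abs(Ap[:, 2] - 120.0), np.abs(Ap[:, 2] - 60.0))
        d_eq1 = np.abs(Ap[:, 0] - Ap[:, 1])
        d_eq2 = np.abs(Ap[:, 1] - Ap[:, 2])
        eq_len2 = (d_ab <= tol_len) & (d_bc <= tol_len)
        conds = [
            (eq_len2 & (d90max <= tol_ang),
             np.maximum(np.maximum(d_ab, d_bc) / tol_len, d90max / tol_ang)),  # cubic
            ((d_ab <= tol_len) & (d90[:, 0] <= tol_ang) & (d90[:, 1] <= tol_ang) & (d120 <= tol_ang),
             np.maximum(d_ab / tol_len, np.maximum(np.maximum(d90[:, 0], d90[:, 1]), d120) / tol_ang)),  # hexagonal
            ((d_ab <= tol_len) & (d90max <= tol_ang),
             np.maximum(d_ab / tol_len, d90max / tol_ang)),  # tetragonal
            (eq_len2 & (d_eq1 <= tol_ang) & (d_eq2 <= tol_ang),
             np.maximum(np.maximum(d_ab, d_bc) / tol_len, np.maximum(d_eq1, d_eq2) / tol_ang)),  # rhombohedral
            (d90max <= tol_ang, d90max / tol_ang),  # orthorhombic
            ((d90[:, 0] <= tol_ang) & (d90[:, 2] <= tol_ang),
             np.maximum(d90[:, 0], d90[:, 2]) / tol_ang),  # monoclinic (b-unique)
        ]
        rank = np.select([c for c, _ in conds], [6, 5, 4, 3, 2, 1], default=0)
        dev = np.select([c for c, _ in conds], [d for _, d in conds], default=0.0)
        better = (rank > best_rank) | ((rank == best_rank) & (dev < best_dev))
        best_rank = np.where(better, rank, best_rank)
        best_dev = np.where(better, dev, best_dev)
        best_perm = np.where(better, ip, best_perm)

    sumlen2 = np.sum(lens3**2, axis=1)
    order = np.lexsort((best_dev, sumlen2, tdet, -best_rank))

    system_names = {6: "cubic", 5: "hexagonal", 4: "tetragonal", 3: "rhombohedral",
                    2: "orthorhombic", 1: "monoclinic", 0: "triclinic"}
    system, dev, coeff, symbol = "triclinic", 0.0, np.eye(3, dtype=np.int64), "P"
    for t in order:
        triple = np.array([coeffs[ti[t]], coeffs[tj[t]], coeffs[tk[t]]])
        sym = _centring_symbol(triple)
        if sym is None:
            continue
        det = int(tdet[t])
        if (sym == "P") != (det == 1) or (sym == "R") != (det == 3) or (sym == "F") != (det == 4):
            continue
        system = system_names[int(best_rank[t])]
        dev = float(best_dev[t])
        coeff = triple[list(perms[int(best_perm[t])])]
        symbol = sym
        break
    if system == "monoclinic":
        coeff = _monoclinic_standardize(coeff, basis)
        v = coeff @ basis
        gamma = np.degrees(
            np.arccos(np.clip((v[0] @ v[1]) / np.linalg.norm(v[0]) / np.linalg.norm(v[1]), -1, 1))
        )
        if gamma < 90.0:  # sign of b is free; report the γ ≥ 90 choice
            coeff = coeff * np.array([[1], [-1], [1]])
        symbol = _centring_symbol(coeff)
    v = coeff @ basis
    if np.linalg.det(v) < 0:
        coeff = -coeff
        v = -v
    cell = cell_from_metric(v @ v.T)
    return ConventionalCell(cell=cell, centring=symbol or "P", system=system, transform=coeff, deviation=dev)
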