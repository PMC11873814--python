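"""Synthetic zonal-pattern datasets from a known cell.

Generates the (d1, d2, φ) descriptors a perfect experiment would measure
for chosen zones of a generating cell, with optional Gaussian noise:
multiplicative ``(1 + σ·ε)`` on each d-spacing and additive (degrees) on
the angle.  Used for round-trip validation of the search and for
demonstrating the coplanar-zone (tilt-series) degeneracy.  Intensities,
excitation errors and off-zone tilts are not simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .lattice import UnitCell
from .patterns import ZonePattern
from .zones import enumerate_zones, zone_net

__all__ = [
    "SimulationSpec",
    "simulate_zone_pattern",
    "simulate_dataset",
    "zones_coplanar",
]


def zones_coplanar(zones: Sequence[Sequence[int]]) -> bool:
    """True iff all zone-index vectors lie in a common plane (every 3×3
    determinant vanishes) — the tilt-series degeneracy condition."""
    z = np.asarray(list(zones), dtype=float)
    if len(z) < 2:
        raise ValueError("need at least 2 zones")
    return bool(np.linalg.matrix_rank(z, tol=1e-9) < 3)


def simulate_zone_pattern(
    cell: UnitCell,
    uvw: Sequence[int],
    centring: str = "P",
    noise_len: float = 0.0,
    noise_ang: float = 0.0,
    seed: int | np.random.Generator | None = None,
    pattern_id: str | None = None,
    hkl_max: int = 12,
) -> ZonePattern:
    """Descriptor of the zone [uvw] pattern of ``cell``, optionally noisy.

    ``noise_len`` is the relative σ on each d-spacing, ``noise_ang`` the
    absolute σ on φ in degrees.
    """
    if min(noise_len, noise_ang) < 0:
        raise ValueError("noise levels must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    net = zone_net(cell, uvw, centring=centring, hkl_max=hkl_max)
    d1 = (1.0 / net.g_short) * (1.0 + noise_len * rng.standard_normal())
    d2 = (1.0 / net.g_long) * (1.0 + noise_len * rng.standard_normal())
    phi = net.phi + noise_ang * rng.standard_normal()
    phi = min(max(phi, 1e-3), 180.0 - 1e-3)
    pid = pattern_id if pattern_id is not None else "".join(str(abs(x)) for x in uvw)
    return ZonePattern(pid, d1=float(d1), d2=float(d2), phi=float(phi))


@dataclass(frozen=True)
class SimulationSpec:
    """Recipe for a synthetic dataset: generating cell, zone selection and
    noise levels.  ``zones`` is either an explicit list of coprime triples
    or an integer count drawn from the enumeration, preferring low-index
    zones.  ``seed`` fixes all randomness."""

    cell: UnitCell
    centring: str = "P"
    zones: Sequence[Sequence[int]] | int = 5
    max_index: int = 3
    noise_len: float = 0.0
    noise_ang: float = 0.0
    seed: int = 0
    ensure_noncoplanar: bool = True
    hkl_max: int = 12

    def __post_init__(self) -> None:
        if min(self.noise_len, self.noise_ang) < 0:
            raise ValueError("noise levels must be non-negative")


def _draw_zones(spec: SimulationSpec, rng: np.random.Generator) -> list[tuple[int, int, int]]:
    pool = list(enumerate_zones(spec.max_index))
    n = int(spec.zones)
    if n > len(pool):
        raise ValueError("not enough enumerable zones for the requested count")
    if spec.ensure_noncoplanar and n < 3:
        raise ValueError("non-coplanarity needs at least 3 zones")
    # low |u|+|v|+|w| preferred: weight falls off with the index sum
    sums = np.array([sum(abs(c) for c in z) for z in pool], dtype=float)
    weights = 1.0 / (sums**2)
    weights /= weights.sum()
    for _ in range(200):
        pick = rng.choice(len(pool), size=n, replace=False, p=weights)
        zones = [pool[i] for i in sorted(pick)]
        if not spec.ensure_noncoplanar or not zones_coplanar(zones):
            return zones
    raise RuntimeError("could not draw a non-coplanar zone set")


def simulate_dataset(spec: SimulationSpec) -> tuple[list[ZonePattern], dict]:
    """Simulate a zonal-pattern dataset; returns (patterns, ground_truth).

    The ground-truth record carries the generating cell, centring and zone
    list so downstream tests never re-derive them.
    """
    rng = np.random.default_rng(spec.seed)
    if isinstance(spec.zones, int):
        zones = _draw_zones(spec, rng)
    else:
        zones = [tuple(int(x) for x in z) for z in spec.zones]
        if len(zones) < 2:
            raise ValueError("need at least 2 zones")
    patterns = [
        simulate_zone_pattern(
            spec.cell,
            z,
            centring=spec.centring,
            noise_len=spec.noise_len,
            noise_ang=spec.noise_ang,
            seed=rng,
            pattern_id=str(i + 1),
            hkl_max=spec.hkl_max,
        )
        for i, z in enumerate(zones)
    ]
    truth = {
        "cell": spec.cell.to_dict(),
        "centring": spec.centring,
        "zones": [list(z) for z in zones],
        "noise_len": spec.noise_len,
        "noise_ang": spec.noise_ang,
        "seed": spec.seed,
    }
    return patterns, truth
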