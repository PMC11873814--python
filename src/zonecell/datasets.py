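"""Bundled measured zonal-pattern descriptors for three reference samples.

Each dataset is a list of :class:`~zonecell.patterns.ZonePattern` rows
(d-spacings in Å, angles in degrees) measured on electron-diffraction
zonal patterns of:

* copper perchlorophthalocyanine (CuPcCl₁₆) — C-centred monoclinic small
  molecule, seven patterns including the long-axis [001] zone;
* tetragonal hen egg-white lysozyme microcrystals — six patterns with
  mirror symmetry, angles fixed to 90° as the symmetry dictates;
* the pentapeptide GRGDS — five patterns, one with cmm symmetry.

Symmetry labels are the ones assigned when the data were recorded; pass
``labelled=False`` to strip them and rely on metric auto-classification.
"""

from __future__ import annotations

from dataclasses import replace

from .patterns import ZonePattern

__all__ = ["cupc_patterns", "lysozyme_patterns", "grgds_patterns"]

_CUPC = [
    ("1", 7.59, 3.75, 93.3, "auto"),
    ("2", 7.59, 3.55, 74.5, "auto"),
    ("3", 8.51, 2.62, 95.6, "auto"),
    ("4", 12.76, 2.97, 89.4, "pmm"),
    ("5", 12.75, 2.65, 96.5, "auto"),
    ("6", 12.75, 2.15, 85.9, "auto"),
    ("7", 14.15, 14.45, 68.0, "cmm"),
]

_LYSOZYME = [
    ("1", 79.06, 79.06, 90.0, "p4"),
    ("2", 77.48, 6.46, 90.0, "pmm"),
    ("3", 78.99, 14.68, 90.0, "pmm"),
    ("4", 77.12, 9.53, 90.0, "pmm"),
    ("5", 78.20, 8.52, 90.0, "pmm"),
    ("6", 79.64, 12.09, 90.0, "pmm"),
]

_GRGDS = [
    ("1", 13.82, 4.39, 80.9, "cmm"),
    ("2", 12.94, 3.91, 85.6, "auto"),
    ("3", 7.10, 4.42, 80.8, "auto"),
    ("4", 4.76, 4.40, 80.5, "auto"),
    ("5", 12.99, 1.47, 89.1, "auto"),
]


def _build(rows, labelled: bool) -> list[ZonePattern]:
    pats = [ZonePattern(pid, d1, d2, phi, sym) for pid, d1, d2, phi, sym in rows]
    if not labelled:
        pats = [replace(p, symmetry="auto") for p in pats]
    return pats


def cupc_patterns(labelled: bool = True) -> list[ZonePattern]:
    """Seven zonal patterns of copper perchlorophthalocyanine."""
    return _build(_CUPC, labelled)


def lysozyme_patterns(labelled: bool = True) -> list[ZonePattern]:
    """Six zonal patterns of tetragonal lysozyme (angles fixed to 90°)."""
    return _build(_LYSOZYME, labelled)


def grgds_patterns(labelled: bool = True) -> list[ZonePattern]:
    """Five zonal patterns of the GRGDS peptide."""
    return _build(_GRGDS, labelled)
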