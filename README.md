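# zonecell

Unit-cell determination from independent electron-diffraction zonal
patterns.

In serial electron crystallography, each crystal contributes a single
still diffraction pattern in a random, unknown orientation. When the beam
happens to lie along a zone axis [uvw], the pattern is a flat 2D net of
reflections — a central section of the reciprocal lattice — and can be
reduced to just three numbers: two basis d-spacings d₁, d₂ (Å) and the
angle φ between the basis vectors. Such zonal patterns carry no 3D
information individually, so standard serial-crystallography indexing
cannot use them. `zonecell` determines the 3D unit cell from a handful of
these reduced patterns, for electron crystallographers working with
microED / serial ED data on small molecules, peptides or proteins.

## Method

One pattern is chosen to represent the [001] zone of the unknown cell,
which fixes three of the six reciprocal parameters: a\*, b\* and γ\*. The
remaining unknown is the vector **c\***, scanned over a grid parametrized
by its fractional in-plane components (ξ, η) and the direct-cell volume
V, with V stepped in geometric layers Vᵢ₊₁ = Vᵢ(1 + f) (default
f = 0.025). The metric plane symmetry of the initial pattern — judged
from lengths and angle only, never intensities — reduces the scan
dimensionality:

| initial pattern symmetry | scan |
| --- | --- |
| p1 | full (ξ, η, V) grid — 3D |
| pmm | four mirror lines {ξ=0}, {ξ=½}, {η=0}, {η=½} — 2D |
| cmm | three mirror planes {ξ=η}, {ξ=−η}, {ξ+η=1} — 2D |
| p4 / p6 | two points (0,0) and (½,½) / (⅓,⅓) — 1D |

Every candidate cell must index all remaining patterns: for each pattern
the candidate's zone nets are matched against the canonical descriptor
(g_short, g_long, φ) with three relative mismatches — basis-vector ratio
(weight w₁ = 0.008), angle (w₂ = 0.006) and per-pattern scale against the
dataset mean (w₃ = 0.003). A pattern is accepted when each mismatch stays
below k·wᵢ (default k = 5). Surviving candidates are ranked by the
reliability index

    R = ⟨ ε_ratio/w₁ + ε_angle/w₂ ⟩ over patterns,

locally refined along their scan locus, Delaunay-reduced, deduplicated
and reported together with a proposed conventional centred setting. The
camera-constant (scale) mismatch gates acceptance but deliberately does
not enter R: absolute lengths carry calibration error, not lattice
misfit. An inverse figure of merit F_inv = 1/R can be exported as a
surface over any scan plane.

## Worked example

The package bundles the measured descriptors of seven zonal patterns of
copper perchlorophthalocyanine (CuPcCl₁₆). A full 3D search over
763–1000 Å³:

```
>>> from zonecell.datasets import cupc_patterns
>>> from zonecell.search import ScanConfig, search
>>> res = search(cupc_patterns(labelled=False),
...              ScanConfig(v_max=1000.0, v_min=763.0, initial="7", mode="3d"))
>>> top = res.solutions[0]
>>> print(f"R={top.r:.2f}", top.reduced_cell.parameters, f"V={top.reduced_cell.volume:.1f}")
R=0.52 (3.76, 15.29, 15.60, 111.73, 92.77, 93.71) V=829.3
>>> conv = top.conventional
>>> print(conv.centring, conv.system, conv.cell.parameters, f"V={conv.volume:.1f}")
C monoclinic (17.34, 25.57, 3.76, 90.53, 95.77, 91.24) V=1658.7
```

The best solution is the primitive reduced cell of the known C-centred
monoclinic structure (a = 17.69, b = 25.92, c = 3.83 Å, β = 95.1°,
V = 1750 Å³, here found ~1.5% smaller because the measured d-spacings
carry a small common camera-constant error); the conventional-setting
step recovers the C-centring and the monoclinic axes directly from the
reduced cell.

The same pipeline is exposed on the command line:

```
zonecell search patterns.tsv --vmax 1000 --vmin 763 --initial 7 --mode 3d --out solutions.tsv
zonecell index patterns.tsv --cell 17.34,25.57,3.76,90.5,95.8,91.2 --centring C
zonecell reduce 3.82 15.28 15.60 111.7 93.1 92.9
zonecell simulate --cell 8,11,13,80,95,99 --zones 5 --seed 1 --out sim.tsv
```

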