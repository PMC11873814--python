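# Methods

## Problem and model

A zonal electron-diffraction pattern records a central planar section of
a crystal's reciprocal lattice. Reduced to scalars, it is the triple
(d₁, d₂, φ): the d-spacings of the two shortest independent in-plane
reflections and the angle between them. Orientation information is lost;
the sign of every vector is ambiguous (Friedel symmetry), so all
comparisons happen on a canonical form: g = 1/d, the 2D basis
Gauss-reduced, g_short ≤ g_long, and φ folded into (0, 90].

Given N such patterns from the same lattice, the search treats one of
them as the [001] zone of an unknown cell. Its net fixes a\*, b\*, γ\*;
the remaining vector c\* = ξ·**a\*** + η·**b\*** + ζ·**ĉ₀** is scanned
with (ξ, η) fractional in-plane coordinates and ζ determined by the
direct-cell volume V through ζ = A/V, where A = 1/(a\* b\* sin γ\*) is
the direct base-mesh area. V runs over a geometric ladder
Vᵢ₊₁ = Vᵢ(1+f); V within a layer is constant, so the grid is a stack of
in-plane scans. V is the direct-cell volume in Å³ throughout — the
printed layer values of the reference runs fix this reading.

A candidate cell survives only if every other pattern matches one of its
zone nets. The net of zone [uvw] is the Gauss-reduced shortest pair of
reciprocal-lattice vectors satisfying hu + kv + lw = 0 (and, when a
centring is imposed, its reflection condition). Mismatches are relative:

* ε_ratio = |ρ_obs − ρ_net| / ρ_net with ρ = g_long/g_short,
* ε_angle = |φ_obs − φ_net| / φ_net,
* ε_scale = |s_p − ⟨s⟩| / ⟨s⟩ with s_p the mean observed/net length
  ratio of the pattern and ⟨s⟩ the dataset mean (two-pass).

Acceptance requires ε ≤ k·wᵢ for all three, with w = (0.008, 0.006,
0.003) and k = 5 by default. The reliability index ranks survivors:

    T_p = ε_ratio/w₁ + ε_angle/w₂,    R = mean(T_p).

The scale term is excluded from R by design: the absolute pattern scale
is dominated by per-pattern camera-constant error, and letting it score
candidates systematically favours cells that "average out" calibration
noise rather than fit the lattice shape. On the bundled lysozyme data
(per-pattern scale spread ~1.5%) a scale-in-R variant ranks a wrong cell
first, while the shape-only R reproduces both the ordering and the
magnitudes of the original solution tables. The acceptance gate still
bounds the scale spread (k·w₃ = 1.5% by default), so R = 0 occurs only
for exact shape matches with scales equal within that window, and R is
exactly invariant under a common scale factor on all patterns.

## Symmetry-adapted scan

The metric plane symmetry of the initial pattern is classified from the
canonical descriptor only (intensities are never used), with rules
checked from most to least symmetric at tolerances 1% / 0.5°:

* p4 — equal lengths, φ ≈ 90°;
* p6 — equal lengths, φ ≈ 60° (120° folds to 60°);
* cmm — equal lengths (diagonal setting), or 2·g_long·cos φ ≈ g_short
  (centred-rectangular setting, double length tolerance);
* pmm — φ ≈ 90°;
* p1 — otherwise.

A user-supplied label always overrides the metric classification; the
tolerances are deliberately tight so that a pattern with a 2% length
difference is *not* promoted to cmm — over-assigned symmetry prunes the
true solution, and the documented recovery is to force a 3D scan.

The label sets the scan: p1 → full (ξ, η) grid (ξ ∈ [−½, ½), η ∈ [0, ½];
η ≥ 0 suffices because the mirrored lattice has identical cell
parameters); pmm → the four mirror lines ξ = 0, ξ = ½, η = 0, η = ½;
cmm → three planes {ξ=η}, {ξ=−η}, {ξ+η=1}; p4/p6 → the two points (0,0)
and (½,½) / (⅓,⅓). For a cmm pattern in the centred-rectangular setting
the frame is first re-expressed on its equal-length diagonal basis
{g_long, g_long − g_short}, which is the primitive basis of the centred
net; for imposed pmm/p4/p6 the angle is snapped to the symmetry value
and lengths are equalized to their mean, as the symmetry dictates.

The initial zone is chosen automatically as the pattern with the highest
symmetry rank (p6 ≻ p4 ≻ cmm ≻ pmm ≻ p1), ties broken by the longest
basis vectors (largest d₁ + d₂) — prominent low-index zones constrain
the search best.

## Numerical choices

* **Grid step.** The in-plane step is expressed as a fraction of the
  *shorter* frame vector and scaled per axis by g_min/g_axis, so each
  grid step displaces c\* by the same physical amount (~0.003 Å⁻¹ at the
  default 1/24 for the bundled data). A purely fractional step fails
  when one frame vector is long (a short d-spacing): the acceptance
  basin around a true solution is a few 10⁻³ Å⁻¹ wide, set by the
  absolute match tolerances, and an isotropic fractional grid steps
  clean over it.
* **Matching.** For each pattern, reflections whose lengths fall within
  a ±6% window of the two observed g-lengths are collected; all cross
  pairs are scored, and the best pair is validated by requiring that it
  is the Gauss-reduced basis of its own zone (a pair spanning a sparser
  sub-net of the zone is not what the pattern would show). Ties in T_p
  resolve to the lowest zone index (by |u|+|v|+|w|, then
  lexicographically).
* **Early abort.** Candidates are rejected at the first pattern that
  finds no acceptable pair; patterns are tried in order of decreasing d₁
  (most constraining first). This changes nothing in the result set.
* **Refinement.** The top candidates (40 by default) are polished by
  Nelder–Mead over their free scan coordinates only — V for 1D points,
  the line parameter and V for mirror planes, (ξ, η, V) for the 3D grid
  — with a convergence tolerance of 10⁻⁶ on R. Steps that lose a
  pattern are penalized, so acceptance is preserved and R never
  increases. The frame parameters (a\*, b\*, γ\*) are never refined: the
  reference runs keep the initial pattern's values exactly, and so do
  we.
* **Deduplication.** Solutions whose Delaunay-reduced cells agree within
  2% / 2° are merged, keeping the lowest R.
* **V_min.** Defaults to A·h_min with h_min = 3.4 Å (no crystal packs
  shorter axes); an explicit V_min overrides.

## Delaunay reduction and conventional settings

The reduction iterates the classical transformation on the four vectors
{a, b, c, −(a+b+c)} until all six pairwise scalar products are
non-positive, then takes the three shortest of the seven derived vectors
{a, b, c, d, a+b, b+c, a+c} that form a |det| = 1 basis, signs fixed to
the all-obtuse representation and axes sorted ascending. Volume is
preserved exactly; the reduced basis lengths agree with an independent
Niggli reduction on random cells (cross-checked in the tests).

Conventional settings are proposed by enumerating integer supercell
bases (coefficients within ±2, sublattice index 1–4) of the reduced
cell, keeping those whose lattice translations form a standard centring
(P, A, B, C, I, F, R), and scoring the metric against the lattice
systems at 2% / 2°. The most symmetric qualifying setting wins; ties
prefer a smaller conventional cell, then shorter axes. Monoclinic cells
are normalized to b-unique, C-centring (over A/I, via in-plane basis
recombination), β ≥ 90 and a ≥ c. Angles are reported as computed —
an 89.8° stays 89.8° — because snapping would hide the measurement
error that the centring classification already tolerates.

## Synthetic data

The generator emulates exactly what the search consumes: for chosen
zones of a known cell it computes the zone-net descriptors and applies
independent Gaussian noise — multiplicative (1 + σ·ε) on each d-spacing,
additive (degrees) on φ — under a fixed seed. Zones are drawn preferring
low indices, optionally rejected until non-coplanar. It does *not*
emulate intensities, excitation errors, off-zone tilt, detector
point-spread or peak-position noise, so passing round trips demonstrate
the correctness and conditioning of the search, not robustness to every
experimental artefact. Two properties anchor the test suite: noise-free
patterns from ≥ 4 non-coplanar zones let the search recover the
generating cell to 1% / 1°, and patterns whose zone axes are coplanar (a
tilt series about a common row) admit many inequivalent cells with
comparable R — such a series cannot fix a lattice, which is why input
patterns with a shared basis vector should be avoided.

## Known limitations

* Zone assignment of noisy high-index patterns is not always unique: two
  different zones can fit a descriptor within tolerance, and which one
  scores best can flip within the solution's own error bar. One row of
  the bundled phthalocyanine reference indexing resolves to such an
  alternative assignment (d₂ = 3.75 Å matches both the 3.76 Å and the
  3.80 Å candidate spacings).
* The acceptance multiplier k trades recall against solution-list noise;
  k = 5 admits the bundled measured datasets, but cleaner data support
  smaller k (tighter gates, fewer spurious survivors).
* Patterns enter only through (d₁, d₂, φ); elliptical-distortion
  correction and basis extraction from peak lists are provided, but raw
  frame processing (peak finding) is out of scope.
* The volume range must bracket the true cell; if no solution survives,
  raising V_max is the documented first resort.
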