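# Model and methods

## The physical model

A magnetosome chain is represented as `N` hard magnetic spheres in a
cylindrical cell, elastically tethered to a rigid cytoskeletal filament
(the MamK bundle) that runs along the cylinder axis.  Each particle is
a single-domain magnetite crystal of radius `R` carrying a permanent
dipole moment

    m = Msat · (4/3) π R³,

with `Msat = 0.48 × 10⁶ J m⁻³ T⁻¹`; for the reference radius
`R = 20 nm` this gives `m = 1.61 × 10⁻¹⁷ J/T`.  The configurational
energy has four finite terms (all energies below are quoted in units of
kBT at the 300 K reference temperature):

* **Dipole–dipole.**  The point-dipole interaction
  `E_dd = −μ₀/(4π r³) [3 (m̂ᵢ·r̂)(m̂ⱼ·r̂) − m̂ᵢ·m̂ⱼ] mᵢmⱼ`.
  At the contact separation `d_n = 2R + d = 50 nm` a head-to-tail pair
  is bound by ≈100 kBT — two orders of magnitude above thermal energy,
  which is why assembled structures freeze at room temperature.
* **Hard core.**  Centres may not approach closer than
  `Rᵢ + Rⱼ + d`, where `d = 10 nm` is a gap representing the two
  intervening membranes (`d/2` per particle, independent of crystal
  size).  The same membrane surface at radius `R + d/2` cannot
  interpenetrate the filament rod, so centres keep a transverse
  distance `ρ ≥ R + d/2` from the axis.  Both constraints are enforced
  by move rejection, never by infinite-energy arithmetic.
* **Elastic linker.**  A bound particle is connected to the filament by
  a cable-like, semi-linear spring: zero energy while the linker is
  shorter than its rest length `l₀ = 5 nm`, and `½ k_l (l − l₀)²`
  beyond it, with `k_l = 0.106 kBT/nm²` (≈0.44 pN/nm, in the range of
  kinesin-tether stiffnesses).  The linker attaches anywhere on the
  membrane and anywhere on the filament, so its length is the minimal
  one, `l = max(0, ρ − R − d/2)`.
* **Binding.**  A discrete per-particle flag; switching it on
  contributes `−|E_b|` (default 2 kBT) plus the elastic energy above.
* **Zeeman.**  `E_B = −Σ mᵢ·B`, with the field in the x–y plane at
  angle θ_B from the filament.  At 50 mT, `mB ≈ 194 kBT`.

### The filament as a hard rod

Treating the filament as a rod the membrane cannot interpenetrate —
rather than a zero-width line that particles may straddle — is a
deliberate geometric choice.  It makes bound chains lie *alongside* the
filament with their membranes resting against it (`ρ = R + d/2`,
linkers slack), which is the geometry the closed-form unbinding
criterion is built on: its lever arms are exactly the membrane radius
`a = R + d/2` and the anchor distance `b = a + l₀`.  It is also what
produces the rupture phenomenology: a chain end that tilts toward a
rotated field swings away from the rod, stretches its linker past
`l₀ + sqrt(2|E_b|/k_l)` and detaches.  A chain sitting *on* the axis
(the line-filament reading) can swing its ends toward the field at zero
elastic cost and shows no end-detachment transition below ~60°.

Because the moment direction is the only orientational degree of
freedom tracked, particle rotation has no elastic consequence in
itself; all elastic coupling goes through the centre position.

## Monte Carlo sampling

Each step draws one particle uniformly and one of three moves
uniformly: a translation with components uniform on `[−d_n, +d_n]`, a
moment rotation perturbing the lab-frame polar and azimuthal angles by
independent uniform draws from `[−5°, +5°]`, or a binding flip.
Geometric violations (overlap, box, rod) are rejected outright; the
rest pass a Metropolis test `min(1, exp(−ΔE/kBT))`.  Energies are
accumulated incrementally (O(N) per move) and verified against a full
recomputation to 10⁻⁶ kBT in the tests; the inner loop is compiled
with numba, at roughly 4×10⁶ attempts per second for N = 20.  One seed
drives each run; equal seeds give bit-identical trajectories.

With `|E_b| = 2 kBT` and a slack linker, binding is a two-state system
with equilibrium bound probability `p_eq = 1/(1+e^{−|E_b|/kBT}) ≈ 0.88`.
The time-averaged bound count of an intact 20-chain is therefore ≈17.6,
not 20, and a permanently detached particle lowers the average by
`p_eq`, not 1 — the event detectors account for this.

### Simulated annealing

Self-assembled structures freeze far from equilibrium unless cooled
through the window where bonds still open.  The default schedule is a
geometric ladder of 60 stages from `T_start = 3×10⁴ K` — where kBT
equals one contact bond, so any structure melts — down to 300 K
(per-stage factor ≈0.925), with 10⁵ attempts per stage.  Starting a
decade higher only simulates an ideal gas; the productive range is
roughly 3×10⁴–3×10³ K, where clusters grow, rings open, and fragments
merge.

## Scripted experiments

**Structure census.**  `n_runs` independent anneals from random
non-overlapping states, classified via a contact graph (edge when
`r ≤ 1.2 ×` contact distance; 1.2 tolerates thermal rattle and excludes
second neighbours at 2×).  Connected components are labelled chain
(simple path), ring (single cycle), handle (cycle plus pendant path
sharing one node) or other; a configuration is labelled by its unique
non-singleton cluster, else "other".

At desk scale, coalescence is the bottleneck: in the cell-sized default
box (radius 250 nm, length 2000 nm) twenty particles reliably form 2–3
chains/rings rather than one 20-particle structure, because rings are
terminal (no free ends to merge through) and cluster diffusion freezes
below the coalescence window.  Census-quality runs therefore use a denser
assembly box (radius 120 nm, length 1200 nm — the 19-bond chain still
fits) and report both configuration labels and the cluster-level
taxonomy, in which chains and rings dominate and handles are a
few-percent minority.

**Binding × field grid.**  Annealing in a fixed 90° field over a grid
of `|E_b|` and `B`, reporting the number of multi-particle clusters and
the bound count, averaged over seeds and rounded to integers.

**Rupture sweep.**  From a pre-assembled bound chain (moments along
+x, membranes against the rod on the +y side, the side toward which
the field tilts), the field angle advances 1° every
`steps_per_increment` attempts from 0° to 90°.  Per increment the
time-averaged bound count and net-moment angle θ_m (400 samples), a
snapshot energy decomposition and the cluster counts are recorded.

The default rate is 10⁶ attempts/degree (the quasi-static reference is
10⁷).  Rupture events are thermally activated escapes, so faster
rotation finds them at larger angles and slower rotation at smaller
ones; the default is the largest rate whose 30-sweep campaign stays
within a desk-scale compute budget, and `steps_scale` exposes slower,
more quasi-static rotation.

Event detection scales the nominal thresholds by `p_eq` (see above).
The first critical angle fires on a *single* permanently detached end
(threshold 0.75 p_eq within a 4° window): with the chain on one side of
the rod the in-plane escape path is open to one end at a time — the
other end's swing is blocked by the rod — so ends detach sequentially.
The second fires on a bound-count drop of `N/4 · p_eq` or a 15° jump
in θ_m (fragmentation).  The generic detector
(`detect_critical_angles`) keeps the nominal raw-count thresholds and
2° window for constructed traces.

**Recovery.**  From a post-rupture state, either the field is removed
or it is restored along the filament; the run reports first-passage
attempt counts until θ_m enters a 10° band around the axis and until
the bound count reaches 90% of its pre-rupture equilibrium value
(`N·p_eq`), with censoring if the duration elapses.  Aligned-field
recovery of θ_m is much faster than field-off recovery, because the
field pre-aligns the fragments' moments and removes the dipolar
barrier to re-merging; the bound count recovers on a much longer scale
in both modes.  The speed-up ratios are rate- and scale-dependent, so
the suite asserts only the ordering.

**Bulk averaging.**  Replica sweeps under cell-to-cell variability:
per-replica particle radii from a truncated Gaussian (mean 20.3 nm,
sd 6.8 nm, resampled into [5, 40] nm, moments ∝ R³), or initial
chain–field misalignments on a uniform grid weighted by a Fisher
density (default concentration κ = 10, grid half-width 30°).  The
averaged θ_m(θ_B) curve loses the abrupt single-chain jumps.

## Closed-form oracles

The analytic module provides the contact-bond energy and the
two-particle unbinding criterion: a tethered particle, moments aligned
with the field, unbinds beyond the angle where

    cos θ = a/(2b) + b/(2a) − (sqrt(2|E_b|/k_l) + l₀)² / (2ab),

with `a = R + d/2`, `b = a + l₀`.  For `|E_b| = 4 kBT` this is ≈27°.
Two algebraic routes are implemented: the published cosine expression
and a law-of-cosines rederivation `l² = a² + b² − 2ab cos θ` (which
satisfies `l(0) = l₀`); they give the same threshold, and the
rederived `l(θ)` is used where an explicit length is needed.  (The
published intermediate `l²` expression with `+2l₀(R+d/2)cosθ` is
inconsistent with its own final inequality — `l(0) ≠ l₀` — so it is
not used for lengths.)

## Known limitations

* **First critical angles.**  The simulated end-detachment onset is
  nearly field-independent (~17–25° across 20–150 mT at the default
  rate), because escape is gated by the geometric swing threshold
  `ρ > R + d/2 + l₀ + sqrt(2|E_b|/k_l)` (≈13° of swing about the
  neighbour) plus a kinetic delay.  Experimentally motivated reference
  values for the same probe are strongly field-dependent (≈20°/10°/3°
  at 20/50/150 mT, consistent with a constant-torque threshold
  `mB sin θ_c ≈ const`).  No variant of the stated Hamiltonian that we
  tested (line filament, membrane-rod geometry, with and without the
  published elastic form) reproduces that scaling in equilibrium
  analysis or simulation; the discrepancy is reported, not hidden, and
  the weak-field (20 mT) value happens to agree.
* **Two-particle cross-check.**  The Monte Carlo unbinding angle of a
  single tethered particle is ≈20° at `|E_b| = 4 kBT`, below the
  closed form's 27°, because the simulated particle swings about its
  neighbour with lever `d_n = 50 nm` while the closed form's schematic
  uses the shorter lever pair (a, b) = (25, 30) nm.  The equivalent
  swing-geometry threshold `asin((l₀ + sqrt(2|E_b|/k_l))/d_n) ≈ 16°`
  brackets the simulation from below.
* **Sequential, not pairwise, end detachment** (rod-side asymmetry; see
  above).  A chain assembled on the far side of the rod relative to
  the field rotation shows the mirror-image behaviour.
* Monte Carlo "time" has no hydrodynamics; recovery and rupture
  kinetics are meaningful only as relative comparisons at a fixed
  attempt rate.
* No magnetic anisotropy energy, no induced moments, no short-range
  membrane adhesion, no filament dynamics.
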