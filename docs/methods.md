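# Methods

## Model

The tibia is idealised as a square column whose top surface (the
"plateau") is inclined posteriorly by the initial posterior slope α₀
(default 10°, a representative population mean). All geometry lives in
a fixed right-handed frame: x medial+, y anterior+, z superior+. Angles
carry the radiological sign convention that a positive slope or
osteotomy inclination descends posteriorly; under the frame above that
means the slope-line direction is (0, cos α₀, sin α₀).

The osteotomy is a complete planar cut through the column, inclined at
the sagittal plane osteotomy inclination (SPOI) φ and terminating in a
*true lateral hinge*: a hinge line lying in the cut plane along the
lateral face, parallel to the osteotomy line in the axial view, hence
with direction (0, cos φ, sin φ). Opening the medial wedge is a rigid
rotation of the proximal fragment about this line by the correction
angle θ, with the sign that elevates the medial side.

The posterior slope is measured as the inclination of the **sagittal
projection** of the plateau line, atan(d_z/d_y) — not the 3-D elevation
angle asin(d_z) and not the intersection of the rotated plateau plane
with the sagittal plane. Only the projection reproduces the virtual
reference grid (at SPOI 0°, θ = 30° the three definitions give 8.7°,
8.6° and 11.5° respectively), and it is also what a lateral radiograph
or a sagittal-view measurement in a CAD package sees.

Composing rotation and projection gives the closed form

α'(θ) = atan[(sin α₀ cos θ + sin φ cos(α₀−φ)(1−cos θ)) /
(cos α₀ cos θ + cos φ cos(α₀−φ)(1−cos θ))].

Three consequences, each verified in the test suite:

* **Parallel invariance.** For φ = α₀ numerator and denominator reduce
  to sin α₀ and cos α₀: the slope never changes, exactly, at any θ.
* **Direction.** Over θ ∈ [0°, 30°] the slope strictly increases when
  φ > α₀ and strictly decreases when φ < α₀.
* **Small-angle law.** Second-order Taylor expansion in θ gives
  α'(θ) − α₀ = (θ²/4)·sin 2(φ−α₀) + O(θ⁴) (radians): the distortion is
  quadratic in the correction and grows with the mismatch between cut
  and plateau.

The measured slope is independent of the column's dimensions and of the
hinge-line position; both facts are property-tested, which is why the
default 50×50×100 mm block is purely a convenience.

### Planar end-point model

A complementary 2-D construction assigns each plateau end-point
(P1 anterior, P2 posterior) polar coordinates (rᵢ, θᵢ) about the
corresponding hinge end-point (H1, H2), taken in the plane
perpendicular to the hinge axis, with the osteotomy-plane trace as the
angular reference. The offset of an end-point from the cut plane is
rᵢ·sin θᵢ before and rᵢ·sin(θᵢ+θ) after correction. θ1 = θ2 holds
exactly when the cut parallels the plateau, and the package checks that
this planar criterion agrees with the 3-D closed form across the whole
SPOI range rather than relying on the verbal argument alone.

## Virtual simulation

`run_grid` sweeps SPOI ∈ {20°, 10°, 0°, −10°} × θ ∈ {0°, 5°, …, 30°}
at α₀ = 10° through either backend (closed form or explicit Rodrigues
pipeline; both are asserted identical to 1e−10) and rounds cells
half-away-from-zero to 0.1°, the print resolution of the reference
grid packaged in `owhto/data/table1_reference.csv`. No grid value falls
within 0.005° of a rounding tie, so the tie rule is unobservable here.
The θ = 0° row is included as the identity check even though the
reference table tabulates 5°–30°.

## Physical-experiment emulation

The generator reproduces the bench protocol: a printed column is
mounted in an angled jig (the jig angle realises the SPOI), corrected
by a testing machine, and the two slope end-points A and B — pre-made
holes, placed here on the top-surface midline a full anteroposterior
depth apart — are digitized with a coordinate-measuring arm, n = 10
times per condition. Two noise sources, independent across replicates:

* **σ_point = 0.025 mm** per coordinate of each digitized point. The
  arm's stated ±0.05 mm accuracy is read as a ~2-SD bound of Gaussian
  error; configurable.
* **σ_mount = 0.25°** of per-replicate mounting error, applied as a
  rigid sagittal tilt of the corrected assembly, plus an independent
  equal-magnitude error in the applied correction angle. The tilt term
  is the calibration choice that matters: point noise over a 50 mm
  baseline contributes only ~0.04° of slope SD, and with a true-lateral
  hinge the slope is nearly (for the parallel cut, exactly) insensitive
  to correction-angle error, yet the bench data show 0.1–0.7° replicate
  SDs *in every column, including the parallel one*. A per-replicate
  seating tilt is the simplest mechanism consistent with that pattern;
  at these defaults simulated per-cell SDs land in the observed band
  essentially always. It is a modelling choice, not a measured quantity
  — the true split between jig seating, digitizer and machine error is
  not identifiable from the published summary statistics.

RNG streams derive from `(seed, spoi, correction, replicate)` via
`numpy` `SeedSequence`, so any single cell is bit-reproducible in
isolation and tables are byte-identical across runs with the same seed.
Measured slopes are quantized at 1e−9° — far below any physical
resolution — so that physically identical conditions produce exact rank
ties downstream instead of floating-point jitter.

What the generator does **not** emulate: printer tolerance and material
compliance, machine load control, systematic (bias) jig error, or the
per-cell systematic deviations visible in the bench means (which are a
single physical realization, not population parameters). Passing the
stochastic tests therefore shows that the model's *scatter and trend
structure* matches the bench experiment, not that any individual bench
mean is reproduced.

## Statistical analysis

Replicates are screened per cell with Shapiro-Wilk (flag at p < 0.05;
reported, never gating). Group comparisons use the Kruskal-Wallis test
with the standard tie-corrected H and the chi-square upper-tail
p-value (df = k−1), the default in mainstream statistics software:
across the six correction angles 5°–30° within each SPOI, and across
the four SPOI groups within each correction angle, mirroring the two
margins of the bench table. θ = 0° is excluded as the uncorrected
state. Raw p-values are reported per margin without multiplicity
adjustment, and values below 0.001 print as "< 0.001". A fully tied
sample returns H = 0, p = 1 by convention rather than erroring.

For small designs `kruskal_wallis_exact` enumerates every assignment of
the pooled observations to the group sizes and reports the exact
permutation p. Complete enumeration of the balanced 3×3 design shows
the chi-square approximation tracks the exact p within 0.05 throughout
the rejection-relevant tail (exact p ≤ 0.25) but drifts by up to ~0.096
in the middle of the distribution — an intrinsic property of the
approximation at n = 9, which is why the correctness tests compare the
two over the enumerated tail rather than on arbitrary datasets, and why
the exact option exists at all.

## Numerical and design choices

* Rotation sign: the proximal fragment rotates so the medial side
  elevates. The slope measurement is provably invariant to this sign
  (only the medial-lateral component of the rotated direction flips),
  so the reference grid does not constrain it.
* Degenerate inputs are rejected at construction: |φ| ≥ 90°, θ < 0,
  non-unit hinge overrides, directions with no anteroposterior
  component.
* Mesh export computes fragment vertices analytically (both fragments
  are convex polyhedra) and meshes them as convex hulls; watertightness
  and the exact analytic volume are asserted in tests. STL is binary,
  in millimetres. Plans whose cut plane leaves the column between its
  bottom and top surfaces are rejected.
* Angle-equality tolerance in the end-point model: 1e−9°
  (exact-arithmetic intent).

## Problem sizes

The stochastic calibration checks run 200 independent seeds of the full
bench emulation (4 SPOI × 6 corrections × 10 replicates) for the
Kruskal-Wallis margins and SD band, 2000 null simulations for the
type-I calibration, and 1000 random parameter triples for the
three-backend agreement; the whole suite completes in well under a
minute on a single core.

## Known limitations

The square column isolates the SPOI–slope mechanism; a real proximal
tibia's geometry may scale the magnitude of the slope change, and
posterolateral (rather than true lateral) hinge positions — which
clinical studies implicate in slope *increase* after anterior-inclined
cuts — are parameterized via the hinge-axis override but not studied
here. Soft tissue is ignored. The noise model is calibrated to summary
statistics only.
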