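# Methods

This note documents the measurement model, the synthetic phantoms used
for validation, and the numerical and design choices the package makes
where the underlying semi-automated workflow left them open.

## Measurement model

### Geometry pipeline

A raw axial CBCT stack is reduced to an aligned vestibulo-oral slice
series in six deterministic steps: 8-bit homogenization, apical/coronal
slice removal, rectangular cropping, in-plane rotation, orthogonal
reslicing (vestibular → oral), and thinning to every k-th slice
(default k = 2). All steps except bilinear rotation are exact index
manipulations: gray values are moved, never resampled, so the gray
multiset of any crop/keep/thin output is a sub-multiset of its input
and reslicing is invertible bit-exactly. Reslicing is a pure axis
transpose; anisotropic spacing is carried in metadata rather than
resampled, and all in-plane area math uses the spacing of the current
orientation.

Thinning multiplies the recorded slice-depth spacing by the increment.
Because the Cavalieri estimator always reads its section thickness from
the volume's post-thinning slice depth, the classic mistake of
forgetting to double the thickness after removing every other slice
cannot occur.

### 8-bit homogenization

Gray values are mapped from `[0, max]` onto `[0, 255]` with
round-half-up — a zero-preserving pure rescale, not a min–max stretch.
The choice matters: all densitometry downstream works on gray-value
quotients (socket / reference bone), which a pure rescale leaves
exactly invariant under per-scan gain. Subtracting the global minimum
would inject an offset driven by the extreme order statistic of the
noise — which varies with scan gain — into every quotient, degrading
gain robustness by about two density points at realistic noise. A
constant (contrast-free) volume maps to all zeros. The map is monotone,
so gray ordering is preserved.

### ROI semantics

ROIs are per-slice polygons (alveolus outline) and axis-aligned
ellipses (reference spongy bone) in pixel units, 0-based, with pixel
(r, c) occupying `[c, c+1) × [r, r+1)`. Rasterization uses pixel-center
containment: even–odd rule for polygons, the quadratic form for
ellipses, with points exactly on a polygon edge counted inside (a
deterministic tie-break). Area is pixel-count × in-plane pixel area —
raster "measure" semantics — which differs from the shoelace area of
the vertex chain by boundary pixels (a perimeter-order effect,
sub-percent for socket-sized ROIs at 0.2 mm pixels). ROI transfer from
t1 to t2 is a rigid translation by the difference of landmark
centroids (vertex means); residual rotation is assumed removed during
geometric alignment. Alignment angles and offsets come from
configuration — there is no automatic registration.

### Mineralized-tissue segmentation

The delimitation of mineralized tissue inside the t2 alveolar outline
(drawn by eye in the original interactive workflow) is replaced by a
threshold rule, recorded in provenance:

- `fraction_of_reference` (default, fraction 0.5): gray ≥ 0.5 × the
  slice's reference spongy-bone gray. Anchored to endogenous bone,
  hence gain-robust. Appropriate when regenerate is expected to reach
  at least half of reference density; it is the package default.
- `otsu_within_roi`: Otsu's threshold on the within-ROI histogram.
  Appropriate when the regenerate's gray level is itself the unknown
  under study (it adapts to any bimodal empty/filled mixture); used in
  the density-recovery validation, where the new-bone radiodensity is
  swept from 0.3 to 0.8 of spongy and a fixed fraction would sit at
  its own breakeven.
- `fixed_gray`: an absolute threshold, for calibrated special cases.

A threshold above the slice maximum yields zero mineralized area (not
an error).

### Endpoints

V_alv sums t1 alveolar areas × section thickness over the slice
indices present at both time points (unmatched slices are flagged);
V_min does the same with t2 mineralized areas. Per-socket mean grays
are pooled across slices weighted by measured area (equal to the
pixel-pooled mean of one big measurement); the reference gray is the
unweighted mean across the uniform-size ellipses. The density formula

    D = 100 · (q₂ − q₁) / (1 − q₁),  qᵢ = socket gray / reference gray

realizes the baseline-corrected, reference-normalized comparison as an
arithmetic rule: the empty-socket baseline q₁ (artifacts, soft-tissue
projections) maps to 0 %, reference-density regenerate to 100 %, and
per-scan gain cancels inside each quotient. The t2 numerator is the
gray of the *newly formed bone* — the mineralized segmentation mask —
not of the whole socket; this makes D estimate the regenerate's
radiodensity independently of how much of the socket is filled. The
underlying workflow describes this correction as a flow chart without
printing its arithmetic, so the formula is an interpretation; it is
versioned (`relative-density/q-ratio-v1`) in every output row.

Degenerate cases: if the baseline quotient is within ε = 0.05 of 1 the
denominator is meaningless and density is reported undefined (flagged);
if the total mineralized area is below 1 % of the alveolar area there
is no regenerate to measure and density is reported as 0 with a
`no_detectable_mineralization` flag rather than estimated from a few
noise pixels.

Group summaries report n, arithmetic mean and sample SD (n−1
denominator) per stratum of {all, type 1, type 2} × {all, premolar,
molar}. Socket type (both bony lamellae preserved vs. not) is human
annotation metadata and is never computed. No significance testing is
performed.

## Phantoms

The generator emulates what the pipeline actually sees, not CBCT
physics. A phantom pair consists of: spongy background with Gaussian
texture (mean 140, SD 8 on the 8-bit scale), a 3-voxel cortical shell
(gray 230), and a socket cavity (gray 40 — the non-zero artifact
baseline) that is empty at t1 and refilled from the apical end at t2.
The refilled fraction f_v of the socket *volume* is mineralized at gray
`40 + f_d · (140 − 40)`, where f_d is the new-bone radiodensity
relative to spongy bone. Each scan is scaled by its own gain (defaults
1.0 and 1.1, emulating between-visit drift), perturbed with additive
Gaussian noise (SD 5), rounded half-up and clipped to 8 bits. Both time
points share one texture realization (the bone did not change; the
scans did). All randomness flows from a single seed; identical specs
give bit-identical volumes.

The default socket is a 3 mm × 10 mm cylinder at 0.2 mm isotropic
voxels in a 64 × 48 × 64 grid (12.8 × 9.6 × 12.8 mm block) — a
molar-scale socket that yields ~30 vestibulo-oral slices, ~15 after
thinning, matching the slice counts a real measured stack produces. An
elliptic frustum geometry is available for tapered sockets; its volume
uses the prismatoid rule (exact, as the section area is quadratic in
depth), and bottom-up fill solves for the depth that holds f_v of the
volume. Ground-truth annotations are generated analytically: per
vestibulo-oral slice an n-gon (default 64 vertices) whose vertices lie
exactly on the section boundary (exact for the cylinder's rectangular
sections), plus a reference ellipse (semi-axes 3 px) placed lateral of
the socket in guaranteed-spongy territory, verified non-overlapping.

What the phantoms do **not** model — and hence what passing tests do
not demonstrate about clinical data: beam hardening, scatter and other
ray physics; wall collapse or any change of socket morphology during
healing; annotation error (ground-truth ROIs are exact, so validation
isolates the estimators from observer variability); and
partial-volume gradation at tissue boundaries (voxels are classified
by center). Accuracy on real scans is additionally limited by manual
ROI placement and landmark transfer.

## Validation experiments and sizes

All validation runs use the default phantom above. The volume-recovery
experiment estimates the cylinder socket within 5 % of π·9·10 =
282.743 mm³ (measured ≈ 1.3 % error, dominated by boundary-pixel
inclusion of the raster area convention). Thinning consistency
compares increment-1 and increment-2 estimates (< 3 %; exactly 0 for
the symmetric cylinder). Mineralized recovery runs f_v ∈ {0.3, 0.6,
0.9} over 20 seeds (mean absolute error well under 1 point). Density
recovery runs f_d ∈ {0.3, 0.5, 0.8} with the Otsu rule (errors ≈ 0.1–
0.3 points); gain robustness swaps the t2 gain between 0.8 and 1.2
(shift < 0.5 points; in the noiseless case the only residual is 8-bit
rounding). The rasterizer is checked pixel-for-pixel against an
independent scalar inside-test on 100 random star-shaped polygons and
100 random ellipses (zero mismatches). These sizes keep the whole
suite around half a minute while leaving every estimator's error an
order of magnitude inside its bound.

## Numerical choices

- Round-half-up (`floor(x + 0.5)`) everywhere an integer gray is
  produced (8-bit conversion, rotation output, phantom generation), so
  results are bit-reproducible across platforms.
- Rotation center is `((rows−1)/2, (cols−1)/2)`; bilinear
  interpolation by default, zero fill outside the frame; 0° is an
  exact identity and ±90° nearest-neighbour is an exact index
  permutation on square slices.
- Thinning keeps indices 0, k, 2k, … (the even half for k = 2); the
  choice is recorded in provenance.
- Spacing agreement between paired scans uses a 1e-3 mm tolerance
  (scanner metadata rounding); within one series, 1e-6 mm.
- Slice ordering comes from spatial position metadata, falling back to
  filename order with a warning.
- Polygon simplicity is validated exactly (orientation predicates);
  degenerate zero-area chains rasterize to empty masks.

## Known limitations

- Translation-only ROI transfer cannot compensate rotational
  misalignment between visits; the geometry step must remove it first.
- The density formula is an interpretation of a narratively described
  correction (see above); alternative arithmetics would need a new
  formula version.
- Cavalieri accuracy degrades for sockets spanning only a few slices;
  the thinning increment should be 1 for very narrow (< ~4 mm) sockets.
- DICOM support covers plain series and multiframe files with standard
  pixel-spacing tags; exotic encodings are out of scope.
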