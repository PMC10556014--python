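# Methods

This note documents the models, conventions and numerical choices behind
`pedobar`, and what the synthetic test bed does and does not demonstrate
about real data.

## Units and coordinate conventions

All geometry is in **mm**, sensor areas in **cm²**, pressures in **kPa**,
forces in **N** (1 kPa × 1 cm² = 0.1 N). In grid coordinates, x is the
column direction and y the row direction, with the origin at the
bottom-left cell center. Frames are 0-indexed; step-event intervals are
inclusive on both ends. One fixed convention, stated once, prevents silent
mirror and off-by-one bugs across hardware families.

After footprint alignment, the longitudinal axis `v` points from heel to
toes and `m = rot90_ccw(v)`. For a subject walking toward +y seen from
above, `m` points toward the medial border of a **right** foot — this single
chirality convention is what makes side detection, the automask's
medial/lateral splits and CPEI's sign mutually consistent, and makes every
one of those mirror-antisymmetric by construction.

## The standardized recording and canonical file

A `PressureRecording` holds the frame series (T × rows × cols, kPa, with a
sampling rate), the sensor geometry (per-cell centers, quadrilateral
vertices, areas, an active map for trimmed insole layouts), the source
system, the foot side, step events and named regional masks.
`validate_recording` checks every invariant (finite non-negative pressures,
positive active areas, centers inside their sensor polygons, silent
inactive cells, sorted non-overlapping in-range events, in-grid masks) and
reports all violations without mutating anything.

The canonical interchange file is versioned plain text. Floats are written
with `repr` (shortest round-tripping decimal), so write→read is
bit-faithful and repeated writes are byte-identical — archived trials can
be diffed and hashed. Vendor dialects, by contrast, are *documented
simplified dialects*, one per hardware family, parsed strictly: real
exports vary by software version, and failing loudly beats silently
mis-parsing pressure data. In-shoe (pedar) exports carry no geometry, so a
bundled 99-sensor insole layout (16 × 7 grid trimmed to 99 active cells,
13 × 15.3 mm sensors) supplies positions and areas; custom layouts can be
registered at run time. Declared `N/cm²` inputs are scaled by exactly 10;
uncalibrated (RAW) Tekscan exports are rejected rather than guessed at.

## Processing

* **Whole-foot curves.** force_t = 0.1·Σ p·a; peak pressure = spatial max;
  contact area = Σ a over cells with p above a threshold (default 5 kPa).
* **Interpolation** is linear per sensor on a uniform [0, 1] parameter
  (percent-of-stance convention; 101 frames by default). Linear
  interpolation is shape-preserving and cannot overshoot non-negative
  pressures; endpoints are copied verbatim, and the sampling rate is
  rescaled so the trial duration is preserved. Tiny negative float residue
  between non-negative knots is clipped at 0.
* **Step detection** takes maximal runs of frames with force ≥ threshold
  (default 10 N), drops runs shorter than 0.15 s, then drops a configurable
  number of initial steps; an explicit keep-list replaces interactive
  prompting. Both defaults are overridable; they are documented choices,
  not calibrated constants.
* **Footprint detection** uses max-over-time pressure > 5 kPa and keeps all
  8-connected components of ≥ 3 cells: toes routinely print as islands
  detached from the forefoot pad, while 1–2-cell specks are sensor noise.
* **Orientation** (which end is the toes) comes from COP travel between the
  first and last frames carrying ≥ 10 % of peak force — at literal contact
  and lift-off the load is near zero and the COP is noise. If the COP
  travels less than 0.5 mm along the axis the orientation is refused rather
  than guessed.
* **Side detection** classifies the pressure-weighted centroid of the
  anterior third of the aligned footprint: the hallux and first metatarsal
  head carry most forefoot load and sit medially. Offsets smaller than 5 %
  of footprint width return `unknown`, never a silent guess.
* **COP** is the force-weighted centroid of sensor centers per frame;
  frames below a force threshold are marked invalid (NaN). A valid COP is
  a convex combination of loaded cell centers, hence always inside their
  convex hull.

## Regional masking

Masks are polygons (in mm) or explicit sensor sets. Polygon masks resolve
to cells by either rule: `center_in` (cell center inside the polygon,
boundary inclusive) or `fraction_ge(f)` (covered fraction of the cell's own
polygon ≥ f, compared with a 1e-9 slack so exact tiling passes f = 1).
Shapely performs the point-in-polygon and intersection-area computations;
tests check them against independent analytic oracles.

The barefoot **automask** aligns the footprint, then splits foot length
into heel / midfoot / forefoot / toes at 30 / 25 / 27 / 18 % of footprint
length; the forefoot band splits mediolaterally into MTH1…MTH5 at
30 / 20 / 17.5 / 17.5 / 15 % of that band's width (medial first), and the
toe band into hallux / toe2 / toes3–5 at 35 / 20 / 45 %. These are
literature-typical proportions and every fraction is overridable through
`MaskingScheme`. Cells landing exactly on a split go to the more posterior
or more medial region — a deterministic tie-break that guarantees the ten
regions partition the active footprint. The three bundled insole template
schemes (3, 9 and 10 regions) are shipped as an editable JSON table and are
explicitly labelled approximations: the exact published schemes they stand
in for are defined on proprietary layouts.

## Metrics

* `press_peak_sensor` — max over the region's cells and frames.
* `press_peak_mean` — *temporal* mean of the *spatial* peak over contact
  frames, named unambiguously because "mean peak pressure" without a
  qualifier is ambiguous.
* `fti` = ∫ F dt by the trapezoidal rule with Δt = 1/rate — exact for
  piecewise-linear force with knots on frames.
* Two pressure–time integrals under distinct names, never a bare "PTI":
  `pti_melai` = FTI / A and `pti_peak` = ∫ (regional spatial peak) dt.
  A is the region's **peak contact area** over the trial (cells above the
  5 kPa activity threshold), a deterministic reading of "the contact area
  of the region"; with that choice `pti_melai · A ≡ FTI` holds to machine
  precision by construction.
* Metrics run over the full frame range of the recording; crop to a
  detected step first (`crop_to_event`) for per-step values.

**CPEI.** The footprint is aligned, foot length trisected, and a
construction line drawn from the first COP point to the most medial COP
point of the anterior third (the "medial border" tangent; a first-to-last
chord variant is exposed as `method="chord"` since the literature admits
both constructions). CPEI is the perpendicular deviation of the COP path
from that line at the anterior trisection boundary (first path crossing,
linearly interpolated), normalized by forefoot width — the mediolateral
footprint extent between 55 % and 82 % of foot length — with lateral
deviation positive. The construction is invariant under rigid rotation and
uniform scaling, and mirror-consistent in sign.

**DPLI.** The dynamic plantar loading index measures how far a
peak-pressure-versus-time curve departs from a bell shape: a scaled
Gaussian a·exp(−(t−μ)²/2σ²) is least-squares fitted (moment-based start:
a = max, μ = argmax, σ from the half-width at half-maximum; bounded
Levenberg–Marquardt refinement, falling back to the moment fit if the
optimizer fails) and DPLI = 1 − R², clipped to [0, 1]. A constant series is
the σ→∞ limit of a Gaussian and returns 0 by convention. Tests compare the
fit against a brute-force parameter-grid oracle.

## The synthetic gait generator

Each anatomical site (heel, midfoot, MTH1–5, hallux, toe2, toes3–5) is a
compact quartic pad p(d) = peak·(1 − (d/R)²)² for d < R — unlike a
Gaussian, this has the steep falloff of a real skin-contact boundary, so
footprint edges are sharp and proportional masking behaves as it does on
real prints. Temporal activation is a raised cosine from onset to offset
(stance fractions), heel early and forefoot late, which yields the classic
two-peak vertical force curve. Noise is additive truncated-at-zero Gaussian
per cell per frame (1 kPa platform, 0.5 kPa in-shoe) followed by a
hardware-style noise floor (readings below 4 kPa platform / 2 kPa in-shoe
are zeroed, as acquisition software does to suppress unloaded-sensor
chatter; without it, rectified noise over thousands of unloaded cells
biases force and COP). All randomness flows through explicit seeds.

The default foot is a 250 × 95 mm right foot with heel / MTH1 / hallux
peaks of 400 / 450 / 350 kPa — typical adult barefoot magnitudes used as
fixture conventions. Site positions follow standard anatomical proportions
and were chosen, together with the automask split fractions, by forward
geometric design so that each pad's core sits inside the region that bears
its name: this is the "textbook foot" a proportional masking scheme is
meant for. Ground truth per trial: per-site cell sets (cells where the site
is the dominant noise-free contributor at ≥ 30 % of its peak), the side,
contact windows (frames where the noise-free force is ≥ 10 N — contact
below the detection threshold is unmeasurable by construction), and the
noise-free COP. The resolution guard rejects grids whose pitch exceeds the
smallest pad diameter.

What passing on this test bed shows — and does not. It shows the geometry,
bookkeeping and numerics are right: conservation identities, partitions,
round trips, mirror antisymmetry, recovery of planted structure. It does
not show the automask proportions fit a given clinical population
(deformed, pediatric or high-arch feet can violate them — the proportional
approach is known to fail for atypical pressure patterns), nor that real
vendor exports parse (only the documented dialects do), nor anything about
inter-trial subject variability, which the generator does not model.

## Problem sizes

Default test-bed sizes: platform 56 × 36 cells at 5 mm pitch, 0.6 s stance
at 100 Hz (61 frames); in-shoe trials of 3 steps at 0.9 Hz cadence, 38 %
swing, 50 Hz on the 99-sensor layout (~190 frames). Batch checks use 20–50
seeded trials. These sizes are representative of single clinical trials
while keeping the full suite and the acceptance script in the seconds
range.

## Known limitations

* Vendor compatibility is limited to the documented simplified dialects;
  real-file support is best-effort future work.
* The automask is purely geometric (no anatomical landmark registration)
  and single-foot, single-step; large multi-step platforms are out of
  scope.
* CPEI's construction-line convention has published variants; both the
  tangent and chord forms are provided without claiming either matches any
  specific proprietary implementation, and numeric DPLI agreement with
  prior literature is likewise not claimed.
* GIF timing is quantized to 10 ms, so fps values that divide 100 round-trip
  exactly.
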