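# Methods

This note records the models, conventions and design choices behind
`olfnav`, in the spirit of a package methods appendix: what is computed,
under which assumptions, and what the synthetic tests do and do not show.

## Geodesy and circular statistics

All positions live on a sphere of radius 6371.0 km. At the ≤ 100 km scales
of regional homing flights the ellipsoidal correction is below 0.5 %,
smaller than GPS fix noise, so no datum or projection machinery is used.
Bearings are degrees clockwise from true north; "west" is 270°. The
circular mean returns the resultant length `r ∈ [0, 1]`; a fully symmetric
sample (`r = 0`) has no mean direction and is flagged undefined rather
than assigned an arbitrary angle. Angular differences wrap the signed
variant into `(−180°, 180°]` and the absolute variant into `[0°, 180°]`.

## Homing indices

*Initial orientation* averages the headings of track steps whose starting
fix lies within 10 km (configurable) of the release site. Step headings
were chosen over bearings-from-release because they describe what the
bird is doing rather than where it has accumulated; the
bearing-from-release mode is available as an option and the two agree for
nearly straight flights. Zero-length steps (duplicate fixes) carry no
heading and are excluded from heading statistics. Birds with `r < 0.1`
keep their indices but are flagged inconsistent and excluded from
association analyses.

*Deviation from west* defaults to the signed difference in
`(−180°, 180°]`; the absolute variant is always emitted alongside it
(`deviation_from_west_abs`). The association analyses in this package use
the absolute variant because the release sites sit on both sides of west
(home azimuths 241°, 309° and 270°), so the behaviourally meaningful
quantity — "how far from west did the bird orient?" — is a magnitude.

*HEI* truncates the track where the cumulative *active-flight* time
(steps with speed above 10 km/h; logger speed when recorded, displacement
speed otherwise) reaches 50 min, or at home arrival if earlier. "Home
arrival" means first fix within 0.5 km of the loft (configurable; the
field definition is operational, not stated). The path length `l` sums
*all* step lengths up to the truncation fix: the activity threshold gates
the clock, not the path. Consequences worth knowing: a perfectly straight
flight that does not reach home within the active window has `a/l = 1`
but `c > 0`, so its HEI is below 1; HEI = 1 is attained exactly when the
truncation fix coincides with home.

*MAAP* samples the nearest fix within ±5 min of each hourly boundary from
release; boundaries with no fix (signal loss) are skipped, so gaps are not
penalised. The observed azimuth is the displacement bearing between
consecutive retained samples — robust to GPS jitter, unlike instantaneous
logger headings. Intervals with zero displacement contribute nothing.
MAAP needs a flight spanning at least two retained samples (> 1 h); for
shorter tracks the index is reported as NaN.

## Air-mass classification

HYSPLIT endpoint ("tdump") files are parsed in the standard dialect; the
MIXDEPTH diagnostic is mandatory and its absence is a hard, named error.
For a backward trajectory the analysis window is the 24 hourly points
before release (offsets −24…−1); the origin point is excluded. Precedence:
a parcel above the local mixing depth is *above-BL* regardless of what is
underneath; below it, the land/sea mask decides. Residence ratios use
`x/0 = +∞` and `0/0 = NaN`; infinities are deliberately propagated —
downstream statistics are rank-based and handle them without capping.

Masks are either real GeoJSON polygon sets (`surface: sea|land`
properties) or the idealised half-plane coastline `sea ⇔ lon <
coast_lon`, which makes residence hours analytically checkable.

## West wind component

Wind occupancy is a 16 × 6 matrix `P` (direction sector × speed class,
fractions summing to 1) with encoded angles `θᵢ = i·π/8`, θ = 0 aligned
with west. Speed classes default to the edges 0–1–2–4–6–8–∞ m/s (the
binning NOAA-style wind summaries commonly use) and the speed weight
vector `S` defaults to the ordinal ranks 1…6; physical class midpoints are
available by option. `WWC = Σ cosθ·S·P` is linear in `P`, bounded by
±max(S), zero for direction-uniform profiles, and negated by reflecting
the profile about the north–south axis — these algebraic properties are
tested directly.

## VOC processing

Background subtraction anchors each background run at its midpoint,
interpolates linearly between midpoints and holds the level constant
outside; post-subtraction negatives are clipped to zero *and counted*, so
data loss is visible rather than silent.

Diel cycles compute within-day hourly means first and take statistics
across days, matching the campaign convention of quoting a "maximum
hourly average ± 1σ"; pooling all records first would weight days by
sampling density.

Bivariate polar maps join VOC and meteorology records by nearest
timestamp within 60 s, then average mixing ratios in 10° × 1 m/s cells;
cells observed fewer than 3 times are masked. No kernel or GAM smoothing
is applied: plain binned means keep the operation exactly testable against
a brute-force group-by, at the cost of blockier maps than the smoothed
plots common in the source-apportionment literature.

Lifetimes are OH-only: `τ = 1/(k_OH·[OH])` at a fixed `[OH] = 2×10⁶
molecules cm⁻³`, and e-folding range `u·τ` at `u = 2.2 m/s`. This
deliberately ignores O₃/NO₃/Cl loss, deposition and nighttime chemistry.
A known consequence: published e-folding distances for some species
(e.g. limonene ~2 km, DMS ~88 km) are *not* reproducible from OH-only
lifetimes at 2.2 m/s — limonene's 49 min × 2.2 m/s gives ≈ 6.5 km —
indicating additional loss terms or different transport assumptions in
those figures. The packaged rate-constant table carries the standard
298 K recommendations (IUPAC / Atkinson & Arey).

## Spearman association

Ranks are computed from first principles with tie averaging so that +∞
covariate values participate naturally (they tie above all finite
values). The p-value uses the t-approximation
`t = ρ√((n−2)/(1−ρ²))` on `n − 2` degrees of freedom, adequate at cohort
sizes near 100; a seeded permutation mode exists for small n. Degenerate
inputs (zero rank variance, NaNs, n < 3) raise explicit errors.

## Synthetic scenario

The generator reproduces the statistical structure of a coastal
sea-breeze release campaign:

- **Meteorology**: 1-min records; wind direction von Mises (κ = 8) around
  150° (offshore) outside the 12:00–20:00 onshore window and around 270°
  within it; temperature and RH anti-phased sinusoids clipped to 12–25 °C
  and 60–85 %; dry days.
- **VOC sources**: each species is `baseline + gain · vonMises kernel
  (wind direction; source direction) · diel factor + lognormal noise` —
  marine DMS peaked at 270°, isoprene (daytime) and monoterpenes
  (nocturnal) inland, aromatics to the south-east.
- **Tracks**: correlated random walks, 10 s steps, lognormal speeds
  (median 60 km/h, σ = 0.35), von Mises headings (κ = 4) around a vector
  blend of the current home azimuth and due west with weight
  `w = c·(1 − sea fraction)`, `c = 0.9` by default. Cohort tracks run
  15 min — enough to traverse the 10 km initial-orientation window at the
  study's typical speeds — which keeps replicate experiments cheap.
- **Back-trajectories**: hourly upwind steps at 4 m/s with 10° direction
  jitter, transport altitude 150 ± 20 m, mixing depth cycling 250 m
  (night) to 900 m (day). The night floor sits above the 150 m transport
  level, so cohort sea fractions are driven purely by coastline geometry;
  above-BL classification is exercised by dedicated tests instead.
- **Release days**: day-level synoptic directions are von Mises around
  270° (κ = 1) — release campaigns in this design happen under prevailing
  westerlies — with per-bird jitter from staggered release times.

The coupling `w = c·(1 − sea fraction)` encodes the hypothesis under
test: birds released into land-influenced air (low predicted marine-gas
levels) orient toward the marine source direction, so the absolute
deviation from west *increases* with the sea/land ratio, a positive rank
correlation by construction.

**What the synthetic tests show and do not show.** Passing recovery tests
demonstrate that the pipeline's indices and statistics faithfully extract
a coupling of this form at realistic sample sizes and noise levels. They
do not validate the behavioural hypothesis on real birds, nor do they
emulate GPS dropouts, wind drift of flight paths, landscape channelling,
or real coastline geometry.

**Multi-site confounding (known limitation).** The three release sites
differ systematically both in their home-azimuth offset from west (29°,
39°, 0°) and in their upwind distance to the coast. Pooling sites
therefore correlates deviation-from-west with the sea/land ratio even
when birds ignore air masses entirely — a genuine design confound, not a
code artifact. Calibration and sign-recovery experiments consequently use
single-site cohorts (`recovery_config()`), where the null is
exchangeable; site-stratified or mixed-effects modelling is out of scope.

## Numerical choices

- Truncation/arrival ties: home arrival and the active-time limit are both
  computed as *first fix indices*; the earlier wins.
- `destination_point` with zero distance returns its input exactly;
  bearings guard the `% 360 → 360.0` float wraparound.
- Replicate experiments derive replicate k's seed as `base_seed + k`;
  every generator is a pure function of (config, seed).
- Problem sizes: replicate suites run 100 cohorts × 100 birds × 15-min
  tracks (≈ 90 fixes each) per arm; unit oracles use ≥ 100 seeded random
  instances per kernel.
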