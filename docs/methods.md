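# Methods

This note documents the models, parameters and numerical choices behind
`soarharness`, and what its synthetic-data experiments do and do not show
about real field data.

## Behavioural segmentation

**Static/dynamic decomposition.** Static acceleration is the centred
running mean of each raw axis over 0.5 s — at 25 Hz that is 12.5 samples,
forced odd to 13 so the window is symmetric and introduces no phase shift;
at a 4 Hz wingbeat, 0.5 s spans two complete flapping cycles, so flapping
averages out of the static estimate. Near the stream boundaries the window
truncates to the available samples. Dynamic = raw − static, so the raw
signal is reconstructed exactly as their sum (an invariant the tests
enforce). VeDBA is the per-sample Euclidean norm of the three dynamic
axes, averaged over whole seconds (timestamps floored to the second;
seconds with no sample yield no summary, and their GPS fixes carry missing
VeDBA).

**Exact 1-D k-means.** Both classification steps use k-means with k = 2 on
a one-dimensional variable. In one dimension the k-means optimum is a
threshold split of the sorted values, so we enumerate all n − 1 splits
between distinct adjacent values and take the global within-cluster
sum-of-squares minimum. This removes the seed sensitivity and local optima
of Lloyd iterations while optimising the identical objective; a `seed`
argument is accepted for interface stability and ignored. Clustering runs
per flight session, since recording is continuous within a session but
conditions differ between sessions; this is a configuration choice
(`kmeans_scope`), not a claim about any particular field protocol.

**Degenerate and no-signal inputs.** All-identical VeDBA raises the
degenerate path (all seconds passive, with a warning). Additionally, when
the two VeDBA cluster centres are separated by less than 0.1 g the stream
is treated as containing no flapping and labelled all-passive: per-second
VeDBA of genuine flapping sits several tenths of a g above passive flight,
whereas k-means applied to pure sensor noise would otherwise split the
noise in half and label half of a flapless session active. The 0.1 g guard
is an order of magnitude below a flapping signal and an order above
passive noise. The soaring/gliding split has only the degenerate path
(all fixes unclassified with a warning): a session always contains both
climbing and sinking if the bird returned.

**GPS kinematics.** Tracks are subsampled to 1 Hz by keeping the first fix
within each whole second. Step length is the haversine distance on a
sphere of radius 6 371 km — the difference from an ellipsoid is far below
GPS error at these scales. Speeds are forward differences attached to the
leading fix (configurable in principle; centred differences would shift
phase at thermal entries/exits); the last fix carries missing values.
Vertical speed is smoothed with a centred 15 s running mean before
clustering; missing values inside a window are ignored rather than
propagated.

**Segments.** Consecutive fixes sharing a behaviour class form a segment;
runs shorter than 5 fixes are dropped (their fix count is logged so the
partition of classified fixes into kept + dropped is auditable). Step
aggregates (mean speeds, distance, glide ratio) use the n − 1 steps
internal to the segment, which makes the glide ratio of a noise-free
constant-rate glide exactly |horizontal rate / vertical rate|. The segment
centroid is the mean fix position at the midpoint time; the centred hour
covariate is the centroid's UTC hour minus 12. Travel direction for the
wind triangle is the initial great-circle bearing from the first to the
last fix of the segment — stable for straight glides, and for circling
segments any convention is arbitrary. Wind is attached per centroid by
minimal absolute time difference, with 3-D distance (horizontal haversine
and height difference in quadrature) breaking ties, then the earlier
record.

**Filters.** Mean horizontal speed must exceed 4 m/s (the observed speed
distribution of segment means is bimodal; the low mode is perched or
near-stationary time that cannot be assigned a flight behaviour). Glide
ratio is analysed only for segments with mean vertical speed below
−0.2 m/s: near-level "glides" divide by a tiny height drop and produce
glide ratios in the hundreds. Excluded counts are logged at each filter.

## Session-level ΔP test

For each species and parameter, the two harness groups are first equalised
in size by a seeded subsample without replacement of the larger group (one
draw by default; the seed is recorded in the result for exact
reproducibility). The statistic is the full n × n set of between-group
absolute differences, tested one-sidedly against the pooled mean of
within-group absolute differences B, treated as a fixed constant. The
Wilcoxon signed-rank test is applied to ΔP − B with alternative "greater";
all-zero differences return p = 1 without error.

Calibration, measured by simulation (and re-measured by the test suite):
with two null groups of 10 drawn from one normal distribution, the
rejection rate at nominal α = 0.05 is ≈ 0.043 over 2 000 replicates — the
right-skew of absolute differences (median < mean) pushes the test
conservative while the dependence among the n² cross-pairs pushes it
anticonservative, and the two nearly cancel at this group size. Power at
n = 20 per group is ≈ 0.66 for a 1 SD between-group location shift,
≈ 0.89 at 1.25 SD and ≈ 0.98 at 1.5 SD; the property test asserts the
high-power regime at 1.5 SD.

For validation data from a bird carrying both harnesses simultaneously,
`validation_compare` uses a two-sided signed-rank test on paired per-flight
values when the two lists pair up, and falls back to a two-sided rank-sum
test for unequal lengths, reporting which test was used — rank statistics
reported for such designs are sometimes consistent with unpaired tests
even when described as signed-rank, so both routes are provided.

## Mixed-model battery

Seven Gaussian models: mean vertical speed (soaring; gliding), airspeed
(soaring; gliding), √glide-ratio (gliding, vertical-speed filtered), log
maximum height (soaring), log mean VeDBA (passive segments only — active
segments are excluded from the VeDBA model). Fixed effects: harness ×
species (reference levels backpack and black kite, the species baseline),
centred hour, and segment length (fix count). Random intercepts for
individual and date are crossed, implemented in statsmodels `MixedLM` as
variance components within a single all-encompassing group. Temporal
autocorrelation is reduced by keeping every 2nd (airspeed), 4th (height)
or 3rd (VeDBA) segment within each session, ordered by segment start.

The interaction is assessed by a likelihood-ratio test comparing ML refits
of the full and no-interaction models; when non-significant at α = 0.05
the reported model excludes it. A second LRT drops harness entirely from
the retained structure. Reported coefficients and variance components come
from the REML fit (REML for estimates, ML for fixed-effect comparisons is
the standard division of labour). R² follows the variance-partition
(Nakagawa) definitions: marginal = Var(fixed predictions) / (Var(fixed) +
Σ variance components + residual), conditional adds the variance
components to the numerator; conditional ≥ marginal by construction.

Derived quantities: a log-scale coefficient β maps to a percent change
100·(e^β − 1); a species-specific net effect is the harness main effect
plus that species' interaction coefficient; a √-scale coefficient maps to
a response-scale gain (intercept + β)² − intercept².

## Synthetic data

`simulate_session` generates: alternating thermal phases (heading rotating
at v/r rad/s around a 40 m-radius circle, altitude rising at
1.1 m/s + harness offset + N(0, 0.3) per second) and glide phases
(straight heading, −1.2 m/s + offset + noise), horizontal speeds of
9 m/s (circling) and 13 m/s (gliding) so segments clear the 4 m/s filter;
a constant wind added to ground velocity; positions integrated on a local
flat-earth plane around the release point (44.801962° N, 1.612855° E) and
converted to lon/lat (error negligible within the ≤ 13 km flight range).
The accelerometer signal is a unit-gravity static vector slowly rotating
with a 25° bank during circling, white dynamic noise of 0.05 g per axis,
and a 0.8 g, 4 Hz sinusoid on the heave axis during flapping bouts (each
phase starts with a 3–8 s bout with probability 0.15). Defaults emulate
the target study's scale: 10 individuals from 5 species, 3 sessions/day
over 7 days with 55 % of scheduled sessions skipped (~96 flown), 41 min
per session, harness randomised per session by a fair coin.

Injectable effects: +0.3 m/s on leg-loop climb rate and +0.15 m/s on
leg-loop glide vertical speed (reduced sink) by default, magnitudes in the
range reported for large raptors; and a 1.1× multiplier on the *whole*
dynamic-acceleration amplitude (flapping sinusoid and passive noise) for
backpack sessions. Scaling only the flapping amplitude was considered and
rejected: the VeDBA model runs on passive segments, so a flap-only effect
would be invisible to the very analysis it is meant to exercise; scaling
the full dynamic signal yields the intended ≈ −9.5 % log-VeDBA contrast
for leg-loops on passive flight.

`simulate_segment_table` draws soaring-segment tables directly from the
mixed-model data-generating process (fixed effects + individual and date
random intercepts + residual noise) for recovery and error-rate
experiments where thousands of tables are needed and the trajectory layer
adds cost but no information.

**What passing tests show — and don't.** The simulator produces
well-separated behavioural phases, stationary noise, a constant wind and
perfectly regular sampling. Passing the ≥ 95 % label-recovery and
parameter-recovery tests therefore demonstrates the pipeline's
correctness, not its robustness to GPS multipath, baro/GPS height drift,
irregular duty cycles, weak thermals with ambiguous vertical speed, or
non-sinusoidal wingbeat signatures. Real-data performance depends on those
factors and must be judged on real data.

## Problem sizes in the test suite

Statistical checks run at sizes chosen to give decisive Monte-Carlo
evidence quickly: 100 replicate studies of ~600 segments for confidence-
interval coverage of the injected 0.3 m/s effect (≥ 90/100 required,
~95 expected), 2 000 null replicates for the ΔP type-I error (accepted
band 0.03–0.07), three 15-min sessions for segmentation recovery, and
50–100 random small instances per numeric kernel for exact-oracle
equivalence. The full suite runs in well under a minute on one CPU apart
from the coverage experiment (~25 s).

## Known limitations

- Only k = 2 clustering; no finer behavioural repertoire, no
  wingbeat-frequency estimation, no ODBA variant.
- No GPS error model or filtering; heights are used as reported.
- The LMM battery assumes Gaussian errors after the fixed transforms and
  handles autocorrelation only by subsampling.
- The ΔP test's calibration was verified for group sizes around 10; very
  small groups (n ≤ 3) make the signed-rank discrete enough that the
  nominal level is unattainable.
- Reproducing the original field study's counts and test statistics
  requires its separately deposited raw data; the corresponding test fails
  (by design, with an explanatory message) when that archive is absent.
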