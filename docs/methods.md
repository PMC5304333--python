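# Methods

This note records the models, conventions and numerical choices behind
`cellmig`, in the spirit of the methods documentation of mature scientific
packages: what is computed, under which assumptions, which knobs matter,
and what the synthetic-data tests do and do not demonstrate.

## Data model and input conventions

The atomic unit is a trajectory: a time-ordered list of 2D positions of
one tracked cell, identified by an id unique within its well. Input files
are four delimited columns (`track_id, time_index, x, y`); tab, comma and
semicolon delimiters and an optional single header line are auto-detected
(decimal points only). The time column is an integer frame index; minutes
are derived from the experiment's frame interval, which is metadata rather
than file content because acquisition intervals (e.g. 1.5 min for fast
immune-like cells, 20 min for slow mesenchymal cells) belong to the
experiment, not to each row.

Coordinates may be pixels or micrometres; pixel data are converted once
via the pixel size, and unit conversion commutes with all downstream
computations (lengths scale linearly; angles and the directionality ratio
are dimensionless). Coordinates are kept in the image convention (y
typically pointing down) with no axis flip: every reported parameter is
invariant under reflection except the *sign* of turning angles, whose
distributions are symmetric under the models considered; users overlaying
tracks on images will find them where the tracker put them.

Tracking gaps (missing frames inside a track) are allowed. Steps are
computed between consecutive *recorded* points using the true elapsed
time, so speeds remain correct across gaps; an optional split-at-gaps
helper produces contiguous fragments for users who prefer that, but the
default is no splitting since a gap does not invalidate the surrounding
motion. Single-point tracks are counted but excluded from all step
statistics, and are flagged degenerate in per-track tables.

## Migration parameters

Turning angle is defined as the signed direction *change* between
consecutive step vectors, computed as `atan2(cross, dot)` and mapped to
(−180°, 180°] (a pure reversal is +180°, not −180°). Steps of zero length
leave both adjacent angles undefined (NaN, excluded from distributions)
since a direction change through a zero-length step has no geometric
meaning. Step orientation relative to the x-axis was considered as an
alternative reading of "turning angle" but the step-to-step change is the
speed-independent persistence indicator, and is what the signed-angle
histograms show.

Track speed is cumulative path length over elapsed time — under uniform
sampling, exactly the mean per-step speed. The trajectory-centric value of
the "turning angle" parameter is the per-track mean of |α|, a scalar
directional-persistence proxy (the sign carries no information for
chemokinesis data and cancels in means).

Aggregation defaults: condition-level distributions pool tracks across
replicate wells, with per-well provenance retained in every distribution
object so replicate-level views cost nothing. Step-centric pooling of the
end-point directionality ratio is rejected with an error: it is a
whole-track quantity.

Quantiles use linear interpolation (numpy's default) everywhere —
boxplots, reference percentiles, summaries — so all tables are mutually
consistent. Boxplots default to Tukey fences (outliers beyond 1.5×IQR,
far outliers beyond 3×IQR, whiskers at the most extreme non-outliers);
a min/max whisker mode is available, because both conventions circulate
in the field's figures and the choice is cosmetic, not statistical.

KDE uses a Gaussian kernel with Silverman's rule-of-thumb bandwidth
(0.9·min(sd, IQR/1.34)·n^(−1/5)), user-overridable in data units; the
evaluation grid spans the data range ± 3 bandwidths, so the returned curve
integrates to 1 within ~10⁻³. Mode counting for subpopulation detection
uses peak *prominence* (≥ 5% of the density maximum) rather than raw local
maxima: sampling wiggles on a unimodal density have near-zero prominence,
while genuine subpopulation modes are separated by deep valleys. Angular
histograms bin (−180°, 180°] into half-open 10° bins by default (the top
bin closed so +180° is counted); the bin width must divide 360.

## Quality control

The two-step filter labels each step motile if its displacement is at
least the minimal translocation threshold, then retains tracks whose
motile fraction is at least the chosen percentage. Both comparisons are
inclusive (≥) so "30% motile steps" retains a track at exactly 30% — the
natural reading of "at least". Practical starting ranges are exposed as
presets (0.1–0.5 µm for immune-like cells, 1.6–2 µm for cancer-like
cells, motile fraction 0.2–0.3) but never auto-applied: threshold choice
is a judgment call the toolkit supports with a threshold-scan table
(track × threshold retain matrix plus retention curve) and pooled
median / 5th-percentile reference displacements per condition and
experiment. Zero-step tracks count toward the initial total and are
always rejected (they carry no motility evidence). Filters never mutate
the experiment — they return reports naming retained tracks — so raw
data remain analysable alongside filtered data, and per-condition filter
settings are applied independently of one another.

The single-cutoff filter (median step displacement ≥ threshold, applied
globally) is provided as the stricter alternative: a cell pausing more
than half its frames has a sub-threshold median and is discarded, which
is exactly the behaviour the two-step filter exists to avoid.

## Statistics

Migration parameter distributions are right-skewed, so pairwise condition
comparison uses the two-sided Mann-Whitney U test. The exact null
distribution is used when the smaller sample has ≤ 8 observations and the
pooled data are tie-free; otherwise the normal approximation with
continuity and tie correction. Tests run on trajectory-centric values (one
per cell) by default: pooled steps within a cell are strongly
autocorrelated, and treating them as independent would inflate the
effective sample size (pseudo-replication). Step-centric testing exists
behind a flag for exploration, with this caveat documented. Corrections
(Bonferroni, Benjamini-Hochberg step-up; BH the default) are applied over
the full set of condition pairs; untestable pairs (an empty side) are
flagged and excluded from the correction family. Default α = 0.05.

Plate-level screening scores each well's summary metric (track count,
mean/median speed, mean/median directionality) or its robust z*-score,
(x − median)/(1.4826·MAD) over all data-bearing wells — the screening
convention whose 1.4826 factor makes MAD a consistent normal-σ estimator.
A plate whose MAD is zero (more than half the wells identical) raises an
explicit error steering the user to a mean/median metric, rather than
returning infinities.

## Synthetic data: what it emulates, and what it does not

Motile cells are modelled as persistent random walks — heading a Gaussian
random walk (turn SD in degrees controls persistence), step lengths
truncated-normal, optional between-track spread of the mean step length
(cell-to-cell heterogeneity), optional per-frame pause probability under
which a frame contributes only localisation jitter. Stationary artifacts
are a fixed point plus isotropic Gaussian centroid jitter, the mechanism
by which trackers assign non-zero displacement to dead cells and debris;
their step displacements are Rayleigh(σ√2) and their net displacement is
bounded in probability, unlike any walker's. Default scales (step ~2 µm,
jitter SD 0.05 µm, 31–61 frames, tens of tracks per well) reflect
cancer-cell imaging at screen throughput. Simulation is hierarchically
seeded per well (numpy `SeedSequence.spawn`), so replicate wells are
independent draws while the whole experiment is bit-reproducible; the
vectorised track-speed sampler used in large calibration studies draws
from the identical step-length law (track speed depends only on step
lengths, not headings).

The generator deliberately omits: track splitting/switching and other
tracking errors beyond jitter, cell division and collisions, spatial
drift, field-of-view edge effects, and 3D motion. Passing tests therefore
demonstrate correctness of the *computations* and recoverability of
planted effects under a clean generative model — not robustness to every
real-data pathology.

## Calibration studies and problem sizes

The test suite and the acceptance script size their simulations to what
the statistics need rather than what a full screen would produce:
1,000 random tracks for oracle agreement (tolerance 10⁻⁹ relative),
10,000 for geometric invariants, 200-track mixtures for filter recovery,
10,000 simulated null experiment pairs (50 tracks per side, 30 steps per
track) for the type-I error of the speed comparison, 400 repeats for
power against a ×0.5 speed effect, 300 repeats for spiked-plate
detection, and a 2-condition × 3-replicate plate for the end-to-end
pipeline run. These sizes give Monte-Carlo standard errors comfortably
inside the asserted bands (e.g. ±0.002 on a 0.05 rejection rate at
10,000 repeats).

## Known limitations

- 2D trajectories only; no z coordinate.
- No mean-squared-displacement, velocity autocorrelation or
  persistence-time model fitting; the parameter set is the
  displacement/speed/turning-angle/directionality family.
- No automatic threshold selection for the motility filters; the scan
  tables support a human decision by design.
- No directional (chemotaxis) statistics such as the Rayleigh test.
- Exact Mann-Whitney requires tie-free data; tied data always use the
  tie-corrected normal approximation, which is inaccurate for very small
  samples with heavy ties.
- The CLI's figure output is deterministic in content, but PNG/SVG bytes
  may differ across matplotlib versions; the companion TSV tables are the
  stable artifact.
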