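# Methods

## Image quantification

A plate photograph is reduced to per-colony pixel counts in five
stages.

**Channel selection.** On RGB images the channel with the highest
intensity standard deviation is used (ties break to the lower index);
grayscale images use their single channel.  Contrast, not hue, is what
the downstream thresholding needs.

**Rotation.** Pinned plates are nearly axis-aligned; a skew of even 1°
smears the row profiles.  The correction angle is searched on a 0.1°
lattice in ±5° (configurable), scoring each candidate by the variance
of the horizontal projection profile of the foreground mask — aligned
rows give sharp peaks and maximal variance.  Only foreground pixel
coordinates are rotated during the search, so the scan is cheap; the
image itself is rotated once, bilinearly, by the winning angle.  The
recovered angle is accurate to ~0.1° on rendered plates skewed up to
±3°.

**Cropping.** `auto` separates the dark plastic rim from the agar with
a three-class Otsu split and crops to the bounding box of the largest
connected non-rim region.  If the image is effectively bimodal (no rim
present) the whole frame is interior and the crop is a no-op; if no
region covers at least half the image the method falls back to fixed
5% margins with a warning.  `fixed_margin` and `none` are available
for unusual images.

**Grid fit.** Foreground is defined by a global Otsu threshold on the
selected channel (colonies brighter than agar by default;
`dark_colonies` inverts).  Peaks of the column-sum and row-sum
profiles are detected (minimum separation 0.6 × the expected spacing)
and least-squares fitted to an arithmetic progression `a + k·s`,
tolerating missing peaks down to half the expected count per axis;
the integer grid offset is chosen to maximize profile mass under the
nodes.  Fewer than 50% of expected peaks on an axis is a hard failure
naming the axis.

**Quantification.** Each foreground pixel is assigned to the nearest
grid node when within half the spacing on both axes, so no pixel is
counted twice.  Colony size is the assigned count; circularity is
4πA/P² of the largest connected component of the blob, with the
perimeter from the standard weighted boundary-crossing estimate
(4-connectivity), clamped to [0, 1] — a rasterized disc of radius
10 px scores ≈ 1.0, single-pixel blobs are defined as 1.  The
8-neighbourhood perimeter variant over-counts boundary steps and was
rejected (it scores the same disc at ≈ 0.74).

The interleaved 768 format is analyzed on its physical 32 × 48 grid;
the two 384 sub-arrays occupy the odd/odd and even/even parity classes
and are recorded per colony as `subarray=A|B`.

## Normalization

All three corrections are ratios of medians, hence scale-equivariant
and robust to the rare true interactions.  Zero-size (dead) colonies
and pre-flagged colonies are excluded from every median estimate but
transformed like any other colony, so synthetic-lethal zeros stay
zero.  (Published example tables for this type of pipeline sometimes
show zero raw sizes with nonzero normalized values; we deliberately
keep 0 → 0 rather than impute.)

* **Plate scale.** Sizes are multiplied by `target/median(plate)`.
  The default target is the *batch* median — the median of the
  per-plate medians of the submitted set — which puts control and
  experiment plates on one common scale without privileging either.
* **Row/column.** Row effect `r_i = median(row i)/median(plate)`,
  column effect analogously; sizes are divided by `r_i·c_j`.  Effects
  are floored at 0.1 so sparse rows cannot blow up the correction;
  all-NA rows get effect 1 with a warning.
* **Spatial.** The local surface is a 7 × 7 NaN-ignoring running
  median, with the grid reflected across the plate edges.  Reflection
  (rather than shrinking the window at the borders) keeps the
  correction idempotent: on bias-only plates a second pass changes no
  colony by more than ~0.6%, while shrunk corner windows leave ~1.2%
  residuals.  The surface is floored at 0.1 × the plate median, and
  sizes are multiplied by `median(plate)/L`.

A window of 7 spans about a fifth of a 32-row plate: wide enough to
be insensitive to individual interactions, narrow enough to track
agar-thickness gradients.  The median (not mean) smoother is chosen so
a single giant colony shifts its neighbourhood surface by nothing.

Two intrinsic limitations are worth knowing.  First, on finite plates
the median estimates re-fit a few percent of *true* strain-to-strain
variation, so even a bias-free, noise-free screen normalizes to a
truth correlation of ~0.94–0.95 rather than 1.0; this is the price of
estimating corrections from the data being corrected.  Second, exact
idempotence holds only on the bias model family — with per-colony
noise, each pass re-estimates the noise realization under the smoother
(~2% per pass at the default noise).

A whole-plate query-fitness defect is mathematically confounded with
the plate effect: normalizing the experiment plate to the batch median
absorbs it.  W_i is therefore ≈ 1 under default settings; to estimate
the query's own defect, disable the plate stage (or anchor the target
to control plates only).

## Filters

* **Jackknife (JK).** With ≥ 3 technical replicates, replicate *k* is
  an outlier when `std(group \ k) < (1 − f)·std(group)` with
  `f = 0.9`, i.e. removing it collapses the spread by more than 90%.
  At most one replicate per group is flagged (largest collapse, ties
  to the lower index) to prevent cascade removal.  The criterion is a
  concrete instantiation of "differs from its technical replicates";
  the spread-collapse form makes the test scale-free.
* **Linkage (LK).** Positions whose array gene lies on the query's
  chromosome within a user-set distance (default 200 kb, inclusive —
  the conventional window for crossover suppression in SGA-style
  crosses) are masked before scoring: their small colonies reflect
  crossover frequency, not fitness.  Entries without locus information
  are never flagged; an unknown query locus skips the filter with a
  warning.
* **Big colony (BG).** Strictly larger than 1.5 × the plate median
  (over nonzero colonies) suggests contamination or an escaped
  diploid.
* **Competition (CF).** A score above +0.1 with any 8-neighbour below
  −0.1 (replicate blocks collapsed first under the quad layout) marks
  a potential false positive fed by its dying neighbours.  The +0.1
  bound is the lower edge of the caution band for positive scores; CF
  annotates the record but keeps the score, since the flag itself is
  computed from the score.

BG and JK are applied to raw sizes *before* normalization, because
oversized or discordant colonies corrupt the median estimates; LK is
applied before scoring and CF on the finished score grid.  Filters
only add flags or NA — they never alter a surviving colony's value.

## Scoring

The reference scale `C` is the median unflagged normalized size of the
matched control plate (several controls for one query are
median-pooled).  `W_ij = size/C`, `W_i = median(experiment)/C`, `W_j =
median(strain replicates on control)/C`, `score = W_ij − W_i·W_j`.
Scores are exactly linear in `W_ij` (unit slope), and a screen scored
against itself yields identically zero.  BLANK and control-gene
positions report their normalized size but score NA, as does any
filtered colony.  Replicates are averaged per (query, array gene) with
NA-ignoring means; the combined record reports `n=` in its annotation
column.  Scores and normalized sizes are written with three decimals.

## Synthetic screens

The generator draws from the explicit multiplicative model

    observed = true × plate × rowcol × spatial × noise

with array-strain fitness lognormal around 1 (σ = 0.1), interaction
effects at 5% of positions drawn from point masses at −1 / −0.4 / +0.3
(weights 0.2 / 0.6 / 0.2), a uniform plate scale in [0.8, 1.25], an
edge effect of 1.5 decaying to 1 over two positions (rows × columns),
a smooth random spatial surface (quadratic polynomial plus one
off-center Gaussian bump) bounded at 1 ± 0.45, and unit-mean lognormal
noise with CV 0.13.  Base colony size is 500 px.  All draws descend
from a single seed, so every output is a pure function of
(config, seed).

The bias magnitudes and noise level are the package's calibration of
"realistic screen conditions": they were chosen once so that the raw
sizes of a 1536-colony control/experiment pair correlate with the
bias-free truth at r ≈ 0.42 — the degradation level reported for
real screens of this kind — and then frozen.  Under these conditions
the full correction lifts the mean correlation to ≈ 0.69 over 1000
screens (`scripts/acceptance.py`; a 100-screen run lands within 0.01
of the 1000-screen values).  Correlations are computed over the pooled
control + experiment colonies of each screen, which keeps the plate
effect visible in the raw correlation.

What the generator does *not* emulate: pin-to-pin carryover,
batch effects across many screens, actual nutrient competition
(flagged, never simulated or corrected), agar texture/reflections in
renders, and technical-replicate structure (each position is an
independent strain).  Passing tests therefore demonstrate correctness
of the corrections under the multiplicative model, not performance on
any particular laboratory's imaging setup.

The plate renderer draws each colony as a disc of area equal to its
size at exact grid centers (radius clipped to 0.48 × spacing with a
warning), on uniform agar, optionally framed by a plastic rim and
rotated; it returns pixel-exact drawn areas and centers, which is what
makes the image stage testable to ±5% without any external data.

## Numerical choices and degenerate inputs

* Medians are NaN-ignoring throughout; all-NaN slices produce warnings
  and neutral effects rather than failures.
* A plate whose usable median is zero (dead plate) is a hard error; a
  plate with under 50% nonzero colonies warns that the wild-type
  assumption is shaky.
* Jackknife uses population standard deviations (ddof 0); the
  criterion compares like with like, so the normalization is
  irrelevant.
* Boundary conventions: linkage distance inclusive (≤ threshold), big
  colony strict (> multiplier × median).
* Rounding of simulated sizes to integer pixel counts happens after
  bias application; the stored truth keeps the exact floats.

## Problem sizes

Tests run on one plate pair per case (96–1536 colonies) with 50–100
screen replicates for distributional checks; the validation experiment
uses 1000 screens of 1536 colonies each and completes in well under a
minute on one CPU.
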