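# Methods

## Problem and data model

A diving seabird (the motivating case is a krill-eating penguin) carries
two loggers: a tri-axial accelerometer sampling surge (X), sway (Y) and
heave (Z) at 25 Hz in units of g, and a time-depth recorder sampling depth
at 1 Hz.  A prey-capture event (PCE) is the ingestion of a single prey
item; on the acceleration stream it is annotated as a window of eight
samples — three before and four after the capture moment — because nearly
all captures are more than 0.32 s apart, so 8-sample windows never merge
consecutive events.  The analysis unit is the *dive*, and the quantity of
interest is the number of captures per dive.

All analysis runs on a single merged 25 Hz series: depth is linearly
interpolated onto the accelerometer time base, the accelerometer clock
being authoritative.  Indices are 0-based and intervals half-open
throughout.

## Dive segmentation

A dive is a maximal run of samples with depth > 0.4 m.  Dives with maximum
depth ≤ 2 m or duration ≤ 10 s are *surface dives* and are not phase-split;
the remaining *regular* dives are partitioned into descent, bottom and
ascent.

The phase rule uses the **normalized depth rate of change**, which the
source description leaves without a formula; our reading, recorded here as
the package's interpretation: within each dive, depth differences are taken
on the 1 Hz grid anchored at the dive's first sample (the native TDR
resolution), smoothed with a 3-point moving average to suppress sensor
jitter, and divided by the dive's maximum absolute smoothed difference, so
the 0.5 threshold is scale-free.  The descent ends at the first grid point
where this normalized rate is < 0.5 *and* depth is > 50% of the dive
maximum (both strictly: boundary equality does not satisfy the printed
inequalities); the ascent start applies the same criterion to the
time-reversed dive, mirrored so that the ascent comprises the last
`k` grid points when the reversed scan finds its boundary after `k` steps.
On a symmetric trapezoid dive both boundaries land within one 1 Hz step of
the geometric corners; the smoothing contributes that one-step lag.  If
either criterion is never met, or the boundaries cross (e.g. a narrow depth
spike above 50% of the maximum), the dive is split at its deepest sample
and flagged `degenerate_bottom`.

A dive is a *foraging dive* iff at least one labelled sample overlaps it.

## Motion features and CNN data balancing

Static (gravity) acceleration is a centered 2 s running mean per axis
(51 samples at 25 Hz; edge windows shrink).  Whether the original
procedure's mean was centered or trailing is unstated; centered was chosen
as it is phase-neutral.  Pitch is `atan2(Xs, sqrt(Ys^2 + Zs^2))` in
degrees, positive head-up; an all-zero static vector maps to 0° by
convention.  Pitch is gain-invariant, so logger calibration errors scale
out.

Capture labels are ~2% of raw samples.  The CNN's training data are
balanced by a dive-threshold filter: keep only samples inside dives with
max depth > 2 m, duration > 10 s and pitch standard deviation > 15°
(sample s.d. over the dive), excluding each passing dive's descent phase.
Surface dives fail the depth/duration thresholds by construction.  The
filter applies to training data only; at prediction time both detectors
run on whole dives, since test individuals carry no labels and evaluation
covers every dive.

Network inputs are per-individual, per-axis z-scores over the individual's
full series (the normalization used by the detectors is otherwise
unspecified); this removes mounting offsets without leaking statistics
across individuals.

## Window construction

*CNN*: 8-sample windows at step 4 (50% overlap), cut within each dive's
masked region separately so windows never cross dive boundaries.  A window
is labelled positive iff ≥ 6 of its 8 samples are labelled.  The label
threshold was an open design point: a majority rule (≥ 4/8) makes an ideal
step-4 classifier fire on 2–3 windows per event, whose union (~13 samples)
inflates the divide-by-eight count conversion by ~60%; with ≥ 6/8 only 1–2
windows fire per event (expected union ≈ 9 samples ≈ 1.1 events), keeping
per-dive counts near-unbiased, and every 8-sample annotation still yields
at least one positive window (5 consecutive valid placements always
intersect the step-4 grid).

*V-Net*: the *global generator* draws 128-sample windows (5.12 s) from the
pooled training individuals: with probability 0.1 a uniformly random window
of a uniformly random individual, with probability 0.9 a window positioned
uniformly at random among the placements containing a uniformly chosen
labelled sample.  The biased-placement scheme is one consistent reading of
"drawn with a higher probability of encompassing" captures; it guarantees
the positive class a ~90% window share regardless of prevalence.  Windows
may include surface and descent samples.  Draws are reproducible under a
seeded generator; a pool without any labelled sample falls back to uniform
draws with a warning.

*Splits*: individuals (never windows) are assigned to train / validation /
test so that each group holds 50/20/30% (±5 points by default) of the
annotated events, by rejection sampling up to 10 000 attempts (best-found
split returned with a warning otherwise).  Individuals with zero events are
excluded from assignment and carried as a side list for test-time
prediction.

## Detectors

Both are small, self-contained numpy networks with hand-written
backpropagation (finite-difference-verified) and the Adam optimizer; with
single-threaded numpy, training is bit-reproducible for a fixed seed.

*CNN* (8×3 input): conv1d(128 filters, kernel 2, ReLU) ×2 → dropout 0.2 →
max-pool 2 → flatten → dense(100, ReLU) → dense(2, softmax); categorical
cross-entropy; batches of 6; 10 epochs (~72k parameters).

*V-Net* (128×3 input, per-sample output): a 1D transcription of the
volumetric segmentation architecture at three encoder levels with filters
(16, 32, 64), kernel 5 and PReLU: each level is a residual block (two convs
at the bottom), levels are joined by stride-2 down-convolutions; the
decoder upsamples with kernel-2/stride-2 transposed convolutions, concatenates
the encoder skip, mixes with one conv and adds the upsampled signal
residually; a kernel-1 conv produces per-sample 2-class logits (~94k
parameters).  The loss is the generalized dice loss with inverse-squared
class-frequency weights (ε = 1e-5 guards empty classes), which weights the
~2%-positive class equally with the background.

For both models the validation loss is evaluated after every epoch and the
weights of the best epoch are retained; whether the original CNN kept best
or last weights is unstated, and best-epoch was chosen for parity with the
V-Net.  Dice-loss training can sit on an all-background plateau for several
epochs before collapsing to a good segmentation; the best-epoch rule makes
the outcome robust to where within the schedule the collapse happens.

*Prediction* is restricted to dives: the CNN slides 8-sample windows at
step 4 over each dive (a final window is anchored at the dive end to cover
the tail) and marks every sample of positively classified windows (union
over overlaps); the V-Net tiles each dive with non-overlapping 128-sample
windows, edge-padding the final partial window and discarding outputs on
the padding, then takes the per-sample argmax (equivalent to a 0.5
probability threshold).  All samples at depth ≤ 0.4 m are forced to 0,
excluding spurious surface predictions.

## Evaluation

Counts: (positive samples in the dive)/8, kept as real numbers for the
regression and rounded to integers for dive-level classification; samples
at depth ≤ 0.4 m count for neither observed nor predicted (surface captures
are excluded from the analysis).  Predicted counts are regressed on
observed counts by OLS; R² is the squared correlation.

Metric naming follows the penguin-capture validation literature:
*accuracy* is the proportion of correct predictions, *sensitivity* is
TP/(TP+FP) — what is conventionally called precision — and the
*false-positive rate* is FP divided by the total observed positives.  They
are implemented as printed, and conventional recall TP/(TP+FN) is reported
additionally as `recall_conventional`.  0/0 cases are reported as None
rather than NaN.  Dive-level metrics classify dives as foraging (observed:
≥ 1 labelled sample; predicted: rounded count ≥ 1); point-wise metrics
first collapse both vectors to 1 s any-positive bins anchored at each dive
start, since sub-second alignment between annotation and prediction cannot
be guaranteed.

Phase attribution assigns each event the phase containing its centre
sample; samples in surface dives (not phase-split) and outside dives count
as `surface`.

The split/train/evaluate cycle is repeated (default 10×) with fresh random
splits; the retained split minimizes |slope − 1| summed over both
detectors, ties broken by higher mean R².  A failed repeat is recorded and
the remaining repeats continue.

## Synthetic data generator

The generator emulates the statistical structure the detectors rely on; it
is first-class, tested code, not a fixture.

*Trip structure*: alternating surface intervals (truncated normal,
40 ± 10 s) and dives.  Regular dives descend at 1.2 m/s to a truncated-
normal depth (30 ± 8 m), hold a bottom phase (total duration 90 ± 15 s,
bottom ≥ 16 s) with small sinusoidal wiggles, and ascend at 1.2 m/s; 8% of
dives are shallow, short "surface dives" (1–2 m, 4–8 s).  Depth is
generated at 1 Hz first, with surface blocks exactly 0 m, and the 25 Hz
truth depth is its linear interpolation — the same operation the pipeline
applies, keeping generator and analysis consistent.

*Events*: each regular dive forages with probability 0.5; foraging dives
draw Poisson(19) events, each assigned bottom / ascent / other with
probabilities (0.83, 0.12, 0.05) — within "other", 96% descent and 4%
genuinely at the surface — and placed uniformly within the phase interval
(the ascent interval stops one 1 Hz step short of the dive end so planted
events sit strictly below the 0.4 m threshold), subject to a minimum
separation of 8 samples; infeasible placements are reallocated
bottom → ascent → descent and logged.  With these defaults the pooled label
prevalence of a cohort is ~2% of all samples (the Poisson mean was
calibrated once against that target, with 10% of individuals foraging
nowhere, and then frozen).  Labels set exactly the 8-sample window of each
event, so label mass = 8 × events and windows never overlap.

*Acceleration*: gravity rotated by the instantaneous pitch — −70° during
descent, a smoothed wander of s.d. 20° around 0° at the bottom, +70° during
ascent, 0° at the surface, all smoothed over 1 s — plus a flapping
sinusoid (2.6 Hz, 0.25 g on heave, 0.1 g on surge) during dives, Gaussian
sensor noise (0.05 g), and one fixed 8-sample strike template (3 rising
samples, peak, 4 decaying) scaled by 1.2 g on surge and 0.72 g on heave per
event.  The steep descent/ascent pitch makes the pitch-s.d. filter
discriminative by construction.  The strike amplitude is a free
signal-to-noise knob of the simulation — the real capture waveform is not
visually identifiable in field data, so no claim is made about its shape;
at the default SNR the task is learnable by both detectors in a few
epochs, which is the regime the pipeline's validation logic is tested in.

*Seeding*: one master seed; per-individual substreams derived by stable
hashing of (seed, individual id), so cohorts are reproducible bit-exactly
and independent of cohort size or order.

*What the generator does not emulate* — and hence what passing tests do not
show about real data: hydrodynamic noise, prey-type variety, logger clock
drift, annotation error, between-individual variation in strike shape, and
any capture signal weaker than the configured SNR.  Results on the
synthetic cohort validate the pipeline's logic and calibration, not field
performance.

## Reference problem size

The reference experiment (shared by `scripts/acceptance.py` and the
end-to-end tests) uses 24 individuals with 20-minute trips — roughly 11
train / 4 validation / 7 test after the event-share split, plus
non-foragers — and V-Net epochs of 8000 training / 2400 validation windows
(the sampler's defaults of 20 000/16 000 windows per epoch remain available
for larger runs).  This is the package's own choice of a problem size that
trains both detectors end-to-end in a few minutes on one CPU while leaving
dozens of held-out test dives for the count regression.

## Numerical choices and degenerate inputs

- Running means use shrinking edge windows (no padding bias).
- `atan2(0, 0) = 0` for all-zero static vectors, logged.
- Dropout is inverted (scaling at train time); evaluation is deterministic.
- Adam: lr 1e-3, β = (0.9, 0.999), ε = 1e-8.  A higher V-Net rate (3e-3)
  was observed to destabilize dice training and is not used.
- Training with zero epochs returns the initialized weights with an empty
  history; a single-class training pool is an error (both losses are
  degenerate).
- Zero temporal overlap between streams, non-monotone timestamps, and
  non-binary labels are errors; accelerometer samples outside the TDR span
  are clamped to the nearest depth and counted in the log.
- Dives shorter than one window produce no windows (counted in the log);
  an empty event list yields an all-zero phase distribution flagged
  `empty`.
- Regression requires ≥ 2 dives and nonzero variance of observed counts and
  names the violated condition otherwise.

## Known limitations

- The normalized-depth-rate phase rule is an interpretation (formula not
  given at source); boundaries carry a one-grid-step smoothing lag.
- The CNN's segment-union counting is inherently quantized in units of 4
  samples; its count regression is slightly biased upward (slope ~1.05–1.1
  at high SNR) even with the ≥ 6/8 label rule.
- The V-Net architecture beyond "encoder/decoder with residuals and skips"
  is a transcription choice; other level/filter configurations are
  supported through `VnetConfig` but untested at scale.
- Metrics follow the field's naming (its "sensitivity" is precision); use
  `recall_conventional` for the standard quantity.
- Training runtime scales linearly with windows per epoch; the numpy
  implementation is single-threaded and has no GPU path.
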