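# Methods

## Gating model and theoretical dwell structure

Channels are aggregated continuous-time Markov chains: a rate matrix
**Q** (s⁻¹, rows summing to zero) over named states, each state
assigned to a conductance class (`closed` → 0 pA; open classes with
positive unitary amplitudes). The theoretical dwell-time distribution
of an aggregate is the spectral expansion of the sub-generator
**Q**<sub>AA</sub>: time constants are −1/eigenvalue (reported in ms —
model files keep rates in s⁻¹ and every downstream quantity is in ms,
with the conversion centralised in the gating module), and component
areas are entry-probability-weighted spectral weights at stationarity.
No missed-event correction is applied at this layer: the theoretical
mixture describes the ideal record, and finite resolution is handled at
idealization (dead time) and fitting (left truncation plus the
concatenation correction below). Degenerate sub-generator eigenvalues
are treated as an error rather than silently merged; the bundled
fixture models avoid them by construction.

Two preset constructors encode the study regimes the synthetic data
emulate. `hs_like_model()` is an uncoupled hyperexponential scheme
whose closed aggregate is exactly (0.8 ms, 30 %; 250 ms, 70 %) and open
aggregate (0.6 ms, 64 %; 2.1 ms, 36 %) at 1.35 pA — the
high-sensitivity-isoform single-amplitude regime. `ls_like_model()` has
two open classes (≈1.05 and ≈2.06 pA) with class-private within-burst
closed states (0.55 and 0.70 ms — distinct so the closed sub-generator
is non-degenerate), connected only through long-lived interburst closed
states (170 ms, 2 s); bursts are therefore class-pure by construction,
which is the property the burst-classification stage must recover. The
uncoupled construction makes every aggregate sojourn an exact draw from
the stated mixture with history-independent component choice — the
strongest possible ground truth for the fitters.

## Synthetic records

`sample_trajectory` is plain Gillespie sampling. `render_trace` holds
the summed class amplitude per sample (openings as positive deflections
from a 0 pA baseline; all amplitudes are magnitudes, matching reporting
convention for inward unitary currents), applies optional run-down (a
linear amplitude ramp after a start time) and multi-channel summation
(independent trajectories of the same model), adds white Gaussian
baseline noise, then low-pass filters. Acquisition defaults are the
study conditions: 50 kHz sampling, 5 kHz on-line corner, 1 kHz off-line
corner, 0.15 pA baseline noise (SNR 9 against a 1.35 pA opening at
acquisition bandwidth). The filter is a Gaussian FIR with matched −3 dB
corner (σ_t = √(ln 2)/(2π f_c) ≈ 0.1325/f_c), the standard stand-in for
a 4-pole Bessel in single-channel simulation; its unit DC gain and
closed-form white-noise variance reduction (Σh² = 1/(2√π σ)) are
asserted by tests.

What the generator does **not** emulate: baseline drift and 1/f or
line-frequency noise, capacitive transients, mechanosensitive-channel
contamination, seal-resistance variation, and genuinely correlated
gating (adjacent-dwell correlations beyond what the uncoupled schemes
produce). Passing tests therefore demonstrate correctness of the
analysis chain under ideal-amplifier assumptions, not robustness to
every artefact of real oocyte recordings.

## Idealization

`SegmentalKMeans` alternates (a) re-estimation of per-class amplitude
means from currently assigned samples and (b) Viterbi restoration under
a discrete-time transition model with a uniform switching probability
(0.01 per sample — the scheme is deliberately generic since no
particular gating topology should be assumed during idealization;
sensitivity to this choice is part of the test suite via the
threshold-oracle comparisons). Convergence is declared when the
fraction of reassigned samples falls below `tol`; the joint
log-likelihood is non-decreasing across iterations (asserted).

Two estimation choices matter on heavily filtered data and are
deliberate:

- **Shared emission variance** (default). Samples on filter ramps
  inflate a per-class open variance, which drags the Viterbi decision
  boundary toward the baseline and systematically widens open events.
  A pooled variance keeps the boundary at the class midpoint, matching
  the half-amplitude convention; on noiseless traces SKM and the
  threshold idealizer then agree exactly (asserted).
- **Plateau amplitude estimation.** Class amplitudes are re-estimated
  after convergence from samples at least three filter time-constants
  away from any level change; event amplitudes use the same interior
  rule per event where the event is long enough, falling back to the
  class amplitude for brief (attenuation-biased) events. Per-event
  amplitudes are what stability profiling needs to detect run-down;
  class amplitudes are what burst-class assignment needs.

Idealization runs at the full sampling rate by default; a decimation
option exists for speed at the cost of coarser duration quantisation.
First and last events of a record are flagged censored and excluded
from dwell fitting.

`apply_dead_time` merges events shorter than the dead time into their
flanking opposite-kind events (shortest first, so cascades resolve
deterministically; edge events merge into their single neighbour and
are flagged censored). Total duration and alternation are preserved
exactly. The default dead time is 0.3 ms ≈ the rise time of the 1 kHz
Gaussian analysis filter, the imposed resolution a 1 kHz off-line
bandwidth implies.

## Dwell-time mixtures

`ExponentialMixture` fits k-component exponential mixtures by
maximum likelihood with multi-start EM (10 k-means++-style seedings on
log dwell times; ties broken by best LL, then smallest k and lowest τ₁
at the selection stage). Left truncation at the dead time is exact: on
[t_min, ∞) the renormalised mixture equals a mixture of shifted
exponentials, so EM runs on t − t_min and areas are mapped back with
aᵢ ∝ wᵢ e^(t_min/τᵢ). For k = 1 the MLE is the sample mean (closed
form). Censored dwells are excluded rather than survival-corrected.

Two refinements:

- **Interval censoring** (`dt_ms`): idealized durations are multiples
  of the sample period; the atom at t = t_min makes plain density MLE
  collapse (τ → 0). With `dt_ms` set, each observation is the interval
  [d − dt/2, d + dt/2] and the M-step uses the conditional mean of an
  exponential within the bin — a valid EM on the latent exact
  durations. ΔLL comparisons remain consistent because all k use the
  same likelihood type.
- **Missed-event (concatenation) correction.** A gap (opposite-kind
  event) below the dead time concatenates its flanking dwells. For
  mixtures with history-independent component choice, an apparent
  dwell is a geometric sum of true dwells plus the missed gaps, which
  is phase-type: k dwell phases entered with the mixture areas, a gap
  phase with the mean missed-gap length, continuation probability q.
  Without the gap phase the apparent density is again exactly a
  k-exponential mixture whose parameters are an invertible transform of
  the true ones (`missed_gap_transform`; the inverse is the same map at
  −q/(1−q)). The pipeline goes one step further and maximises the
  phase-type likelihood directly over the true parameters
  (`fit_compound_mixture`), seeded at the plain truncated fit, because
  for sub-ms open components the missed closed gaps (~0.14 ms) are not
  negligible. q and the gap mean are estimated from the complementary
  fit's mass below the dead time and iterated twice to a fixed point.
  Without this correction the long closed time constant of the
  HS-regime fixture is overestimated by ~30 % (the fraction of openings
  below the 0.3 ms dead time is ~0.30); with it, 40-seed medians of all
  eight closed/open parameters are within 4 % of the generating values.
  This is a first-order correction: the exact missed-event treatment
  for general correlated schemes is out of scope, and the geometric-sum
  assumption is exact only for history-independent mixtures like the
  fixtures.

Component-count selection implements the log-likelihood rule exactly as
stated in single-channel practice — the selected k is the largest whose
fit improves the LL by more than 10 nats over k−1 (k = 1 always
admissible) — not AIC/BIC. A component that collapses (τ below the data
support, vanished weight, or indistinguishable τ pair) records a
convergence warning in the result rather than raising.

A minor interface note: the minimum-data precondition (≥ 5k dwells)
applies for k ≥ 2; a single-component fit is the sample mean and is
accepted for any non-empty dwell list.

## Bursts

T_crit between adjacent closed components i, i+1 solves
aᵢ e^(−t/τᵢ) = aᵢ₊₁ (1 − e^(−t/τᵢ₊₁)) (equal **numbers** of
misclassified closed events, bracketed root-finding to 1e-9 ms). The
equal-proportions and pdf-crossing variants are available behind a
flag for sensitivity analysis; equal-counts is the default because the
criterion is stated as minimising the number of misclassified closed
events. The default boundary is between the first and second closed
components (τ₁ is the within-burst closure); T_crit is computed per
patch from that patch's own closed-dwell fit.

Burst segmentation takes maximal runs of ≥ 2 openings whose internal
closures are all < T_crit; single openings are isolated events;
censored events never start or end a burst. Bursts whose openings span
more than one amplitude class (nearest-class assignment disagrees, or
any opening sits further than a tolerance — default 0.3 pA — from every
class, e.g. a summed double opening) are moved to a discard list, since
they indicate simultaneously active channels. Remaining bursts are
classified on their **per-burst mean open amplitude** (bursts contain
repeated openings of one class, so the burst mean is the natural
feature) by k-means over k = 1…max_classes with BIC under a
shared-variance spherical Gaussian — the X-means criterion; with k = 2
the lower cluster is O_S and the higher O_L. Burst statistics per class:
proportion of bursts among all events (bursts + isolated openings),
mean openings per burst, burst duration (single-exponential MLE = mean),
and mean within-burst P_open (open time / burst span).

## Quality control

Stability profiles compute per-10-s-window mean open amplitude, mean
open/closed durations and event rate, with OLS trend slopes and
p-values against the window midpoint; a planted run-down ramp yields a
significant negative amplitude slope (asserted over seeded replicates),
while stationary records stay clean at the α = 0.05 false-positive
rate. Analysis windows are configured per group (60 s for HS-like
groups, 120 s for LS-like groups); truncation cuts a straddling event
at the window edge and flags it censored, conserving pre-cutoff time
exactly. The event-rate outlier rule is a single pass: group mean ± 2
sample SD with the candidate included, no iteration — the simplest
reading of a 2-SD outlier test, documented as such; groups smaller than
three patches are left unfiltered with a warning.

## Statistics

Fold change divides each patch's property value by the wildtype
reference mean for that property — reference means are configuration
inputs, not embedded constants — and tests the per-patch folds against
1.0 with a two-tailed one-sample t (df = n − 1; zero-variance folds are
flagged degenerate and no p-value is reported). Group comparisons
produce one table row per property with mean ± SEM, fold ± SEM, t, df
and the conventional star codes (*, **, ***, **** at 0.05, 0.01, 0.001,
0.0001). Unpaired comparisons use the classical pooled-variance t.
Two-way ANOVA uses Type II sums of squares (the conventional choice for
main-effect reporting in unbalanced designs such as 5-vs-8 patches)
with Tukey HSD over the crossed cells; on balanced data Type II reduces
to the textbook sums of squares (asserted to 1e-9). No multiple-testing
correction is applied across table rows. Percentages per τ component
are averaged per patch, not pooled across patches, matching the
mean ± SEM-over-patches reporting convention; a class observed in a
single patch is reported with its count and no test.

## Problem sizes and determinism

Simulation-backed tests use 20–600 s records and 10–40 seeded
replicates; the end-to-end recovery check uses 120 s of simulated
recording per seed with medians over 10 seeds, and the
component-count checks use 5 000 simulated closed dwells — sizes at
which the seed-median estimators are well inside their tolerance bands
while the whole suite stays fast. All randomness flows through
explicit integer seeds (`numpy.random.default_rng`); identical seeds
give identical trajectories, traces, fits and CSV outputs.

## Known limitations

- The missed-event correction assumes history-independent component
  choice; for strongly correlated gating schemes it is approximate.
- Apparent durations of events within ~2 filter rise times of the dead
  time carry residual distortion the correction does not model; the
  short closed τ of the HS fixture shows a ~10 % downward median bias
  end-to-end (well inside the 15 % acceptance band, but real).
- Exact missed-event-corrected theoretical distributions and direct
  rate-matrix estimation from event sequences are out of scope: the
  package fits dwell-time mixtures, the form in which such analyses are
  reported.
- ABF reading requires the optional `pyabf` dependency; raw-f32+JSON
  and CSV traces are first-class.
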