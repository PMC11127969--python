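# Methods

`nascode` analyzes neuronal activation sequences (NAS) — trial-spanning,
temporally ordered patterns of transient single-unit firing peaks — in
simultaneously recorded prefrontal populations during a cued virtual-navigation
working-memory task, and asks whether those sequences encode the remembered
target. This note documents the model assumptions, the synthetic-data
generator that stands in for the unreleased recordings, the numerical choices,
and the limits of what the test suite shows.

## Task and data model

A trial is a fixed timeline from cue onset: a 3 s cue epoch, a 2 s memory
delay, and a navigation epoch of which 1.5 s are analyzed, followed by a short
(~0.5 s) inter-trial interval used only for baseline firing rates. Targets lie
on a 3×3 grid in the virtual arena, 290 world units apart; movement speed is
fixed at 580 units/s, so adjacent targets are ~0.5 s apart. All times are
seconds from cue onset; windows are half-open `[start, end)`; rows/columns are
0-based.

A session is four tables: spikes `(unit_id, trial_id, t_s)`, trial metadata
(target row/column, epoch onsets, correct flag, ITI bounds), 3-D movement
trajectories `(trial_id, t_s, x, y, z)`, and a unit roster. Synthetic sessions
carry a ground-truth sidecar with every planted parameter.

## Analysis pipeline

1. **Spike-density functions.** Each unit × trial spike train is convolved
   with a Gaussian kernel (SD 100 ms, truncated at ±5 SD, no boundary
   renormalization) on a 1 ms grid. The grid time of the global maximum is the
   unit's peak firing time t_n; ties break to the earliest grid point; a
   spikeless trial yields a missing entry. Units must fire above 0.5 Hz over
   the whole session (total spikes / total recorded time) to enter the
   analysis. Densities are computed over the whole trial and epoch-restricted
   afterwards by masking (`mask_epoch`); the same-trial replay control instead
   recomputes peaks inside each epoch window, since whole-trial peaks give
   each unit a single epoch and disjoint support across epochs.

2. **Temporal consistency.** Per (unit, condition) with ≥ 5 trials, the sample
   SD (n−1) of t_n across trials. The null permutes, within each trial, the
   assignment of peak times to units (missing stays missing), preserving each
   trial's time marginal while destroying unit identity; 100 repeats are
   pooled (an across-trial per-unit permutation is available behind
   `scheme="across_trial"`). The session statistic is the shuffled-minus-real
   difference of distribution means, in ms; positive means more consistent
   than chance.

3. **Time-boundary cells.** Per unit, the FWHM of a fixed-bandwidth (0.1 s)
   Gaussian KDE of its peak times pooled over all trials: the width of the
   contiguous region around the global mode above half its height. Units below
   a width threshold are time-selective; the two neural epoch boundaries are
   the highest bins (0.1 s) of their pooled peak histogram, one before delay
   onset and one between delay and navigation onset. The threshold defaults to
   1 s but is meant to be calibrated per session so that the selective set
   isolates the narrow anticipatory cluster — the tallest-lobe estimator has
   substantial sampling noise at ~10² peak samples per unit, so at realistic
   jitter a 0.5 s threshold separates the planted boundary cluster essentially
   without error while 1 s admits a noise-driven tail of target-coding units.
   Boundary *locations* are insensitive to that tail: false positives spread
   their peaks across the trial while true boundary cells stack in one bin.

4. **Spectral embedding.** Pearson correlations between every pair of trial
   sequence vectors over pairwise-complete units (pairs with < 10 shared units
   or zero variance → 0; diagonal 1) give a symmetric T×T matrix X. With
   eigenpairs ordered by |λ| (ties by ascending index, eigenvector sign fixed
   by the largest-magnitude entry), Q holds the first k = 3 eigenvectors and
   trials embed as P = XQ. Condition centroids are per-target coordinate
   means; their Euclidean distance matrix is normalized by its maximum.

5. **Behavioral linkage.** 3-D paths are perspective-projected to the
   subject's screen view (pinhole camera: eye slightly behind the start
   position at avatar height 100, forward-facing, 90° horizontal FOV,
   1024×768; points behind the near plane dropped). Per target, correct-trial
   paths are arc-length-resampled to 50 points, outliers removed by the
   z > 1 rule on mean Fréchet distance to group mates, and averaged pointwise.
   The 9×9 discrete Fréchet matrix (dynamic programming, Euclidean ground
   metric) is normalized by its max and rank-correlated (Spearman, strict
   upper triangle, 36 entries) with the centroid matrix. The null permutes
   target labels across trials and recomputes centroids. Alternative distance
   bases (bird's-eye world paths, straight-line optimal paths, raw target
   locations) plug into the same correlation. The ablation curve masks a
   fraction of units, re-runs correlation → projection → centroids → link, and
   averages 100 iterations per fraction.

6. **Decoding.** An unsupervised nearest-centroid classifier on the embedding
   coordinates, stratified 5-fold CV, distance ties to the lowest class index.
   Epoch decoding stacks three epoch-masked copies of each trial (neural
   boundaries when found, task boundaries otherwise; chance 1/3). Target
   decoding runs on all cells (chance 1/9) and, separately, per axis: units
   are scored by the maximum pairwise |Cohen's d| (pooled SD) between their
   spike-time distributions across rows (or columns); the selectivity
   percentile is tuned by cross-validated decoding of that axis over a coarse
   grid (50–95th); row and column predictions combine to a unique target.
   Persistent cells must pass (1) a one-way ANOVA of delay rate across the
   nine targets and (2) a one-sided Welch t-test of preferred-target delay
   rate above the ITI baseline, both at p < 0.05 (relaxing the threshold grows
   the set monotonically). Matched linear SVMs (10-fold, standardized inputs)
   compare the persistent code (delay rates of persistent cells) with the
   sequence code (delay-sequence projection coordinates).

## The synthetic generator

The generator emulates the recorded preparation: ~200 units per session, 9
targets × 20 trials, ~15% error trials, background Poisson firing at 2 Hz, and
transient Gaussian firing bumps whose width at 80% of maximum is 220 ms
(σ ≈ 165 ms). Spikes are drawn by thinning an inhomogeneous Poisson process;
all draws derive from one seed in a fixed order, so sessions are byte-identical
across runs.

Planted structure, per mode:

- **sequence** — each non-boundary unit gets a base peak time tiling the
  trial plus a target-dependent offset. Generic units' offsets are linear in
  the target's screen coordinates (per-axis standardized; lateral loading
  U(1.0, 1.5) s, depth loading U(0.25, 0.5) s — the perspective view expands
  the lateral axis relative to depth, and the planted code follows the view,
  not the arena), plus an idiosyncratic per-(unit,target) N(0, 0.25 s) term,
  then rank-respaced onto an even grid with span U(1.2, 1.6) s. The respacing
  resolves an estimator-level tension: the tallest-lobe FWHM rule needs each
  unit's nine peak modes to merge into one band wider than the selectivity
  threshold (no two targets may stack), while the rank statistics only need
  the target ordering, which respacing preserves. The span is capped near the
  epoch width so units keep a stable epoch identity across targets, and base
  times are rescaled so base + offset stays inside the trial (clipping would
  stack targets; wrapping would let one unit peak both early and late).
  Row-/column-selective subsets (15% each) instead shift 0.6 s per grid step
  along their axis with a small cross-axis term, untouched block structure.
- **boundary cells** (5%) peak 750 ms before delay onset or 500 ms before
  navigation onset on every trial, target-independent, 50 ms jitter.
- **persistent** — tuned units (50%) hold an elevated delay rate (10 Hz vs
  2 Hz baseline) for one preferred target; no timing structure.
- **unstructured** — peak times drawn independently per trial; the null model.
- **perception_control** — sequence mode without boundary cells (nothing to
  anticipate when the target never disappears).

Trial-to-trial realism: realized peaks jitter around planted times with SD
0.3 s by default (error trials ×2) — chosen to match the scale of real
per-condition peak-time SDs, which are many hundreds of ms; and every
(unit, trial) bump amplitude carries a lognormal gain (σ = 0.8). The gain
implements the premise that the timing code is robust to rate fluctuations
while a windowed rate code is not: without it, bump-position-dependent delay
spike counts hand the rate decoder the timing structure for free. Trajectories
run straight to the target at fixed speed with tapered lateral noise; error
trials aim at a displaced endpoint.

## What the synthetic tests do and do not show

Passing recovery tests show the pipeline correctly extracts structure *of the
planted kind*: tiled transient bumps with view-aligned target timing, discrete
anticipatory boundary cells, rate-vs-timing codes as configured. Real
recordings differ in ways the generator does not emulate — non-Poisson
spiking, correlated noise across units, eye-movement covariates, drift,
heterogeneous bump widths and multi-peak units, behaviorally variable epoch
lengths. Consequently the suite validates the machinery and its
calibration (nulls, chance levels, orderings), not the empirical claims about
cortex; printed real-data percentages are not reproduction targets.

## Numerical choices and problem sizes

Grid step 1 ms; kernel truncation ±5 SD; KDE bandwidth 0.1 s; histogram bins
0.1 s; minimum pairwise overlap 10 units (5 in small-session tests); Spearman
over the 36 upper-triangle entries; stratified folds seeded per run; SVM:
linear kernel, C = 1, standardized features. Degenerate cases are defined, not
errors: empty density → missing peak; < 2 peaks → missing SD/FWHM; constant
distance matrix → link 0 with a warning; all-outlier trajectory groups fall
back to no exclusion.

Test and acceptance runs use deliberately scaled sessions: chance levels on
~1000 trials/samples, planted recovery at the full 200 × 180 session, null
calibration and ordering properties on 50–100-unit sessions over 20 seeds,
ablation at 100 iterations per fraction on a 50-unit session. These sizes give
standard errors comfortably inside the asserted margins while keeping a full
run in minutes on one core.

## Known limitations

- The epoch decoder with k = 3 spends most of its capacity on the
  delay-vs-rest contrast plus within-delay target structure, so cue/navigation
  separation can land in the 4th–5th eigenvector; accuracy varies 0.74–0.99
  across sessions (k = 5 is uniformly ≈ 0.99). This matches the scale of
  epoch-decoding accuracies observed in comparable recordings.
- The tallest-lobe FWHM is noisy at realistic sample sizes; the selective
  *fraction* is threshold-calibration-dependent, though boundary locations are
  not.
- The discrete Fréchet distance is exact only on the sampled points;
  trajectories are resampled to 50 points before comparison.
- `min_overlap` interacts with epoch masking: very small populations (< ~30
  units) need a lower floor or correlations zero out.
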