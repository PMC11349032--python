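# Methods

`mindwander` implements an idiographic (fully within-subject) analysis chain
for experience-sampling fMRI: behavioral recoding of thought-probe responses,
event-locked activation statistics, trial-wise windowed functional
connectivity, connectome-based predictive modeling (CPM) with permutation
inference, network-level interpretation by computational lesioning, and
cross-subject model transfer. Because dense-sampling datasets of this kind
are rarely public, the package ships a synthetic data generator that plants
known activation and connectivity signal, so every downstream stage can be
validated by parameter recovery and null calibration rather than by fixture
comparison.

## Behavioral model

Thought probes interrupt a fixation task every 45–90 s. The raw response is
task focus on a 1–8 Likert scale, with "9" meaning distracted-but-not-
mind-wandering. All analyses use the reverse-coded rating `9 − raw`, so
higher ratings mean more mind-wandering, and a trial is a *mind-wandering
trial* when the reverse-coded rating is ≥ 5. Distracted trials are kept in
the stored table with a flag (for auditable partition counts) and filtered
from every analysis view. Runs whose non-distracted ratings show no
variation are flagged and excluded from GLM fitting.

Content questions are summarized as per-option count vectors over
mind-wandering trials; between-subject dissimilarity is the Euclidean
distance between count vectors. Nuisance association of ratings with head
motion (mean framewise displacement over the 28 pre-probe TRs), onset within
run, and trial order within session uses Spearman correlation, pooled within
subject across sessions (per-session output is available but the pooled
estimate is the headline number, since the per-covariate trial counts per
session are small).

## Event-locked activation

* **%SC**: per region, `100·(x − mean)/mean` with the mean taken over the
  run. Regions with an exactly zero run mean are rejected by name.
* **Network time series**: per-frame median %SC over the atlas regions of
  each network.
* **Pre-probe window**: the "~10-s pre-probe period" is operationalized as
  exactly 9 TRs (9.54 s at TR = 1.06 s) immediately preceding the probe
  frame. The probe frame is the first frame acquired at or after probe
  onset and is excluded from the averaging window — the rating describes
  experience *before* the probe.
* **Correlation tests**: Spearman and partial Spearman (average-rank
  transform, then plain or partial Pearson on the ranks). P-values use the
  large-sample t approximation, switching to exact enumeration of rank
  permutations below n = 10 (trial counts in practice are in the hundreds,
  so the exact branch exists for degenerate inputs and testing).
* **TR-by-TR tests**: trials split into high (rating 6–8) and low (1–3)
  sets, intermediate ratings discarded. At each of the 20 TRs spanning
  −20.14 s to 0 s (this span, stated inclusively of the probe frame, is the
  one analysis window that contains frame 0; the lag of the haemodynamic
  response makes the probe-frame sample still reflect pre-probe experience),
  a two-sided Wilcoxon rank-sum test compares groups, exact for small
  tie-free samples and tie-corrected normal otherwise, with
  Benjamini–Hochberg adjustment across the 20 offsets.
* **Region-level GLM**: per run, a boxcar of 10 s ending at probe onset
  with height equal to the within-subject z-scored rating, convolved with a
  single-gamma HRF (mean lag 6 s, SD 3 s — a common convention), regressed
  per region by OLS; runs combined by fixed-effects inverse-variance
  averaging of betas into per-region z statistics (deterministic and
  desk-scale, in place of a full mixed-effects voxel analysis, which is out
  of scope along with all image preprocessing). z values from zero-residual
  fits are reported capped at ±100. Networks are summarized by the median z
  of their regions and rank-ordered (ties broken by atlas label order).

## Trial-wise connectivity and CPM

Each analyzable trial yields the Fisher-z transformed Pearson correlations
of all region pairs within the 28 frames (29.68 s at TR 1.06 — the frame
count, not the rounded "30 s", is authoritative) immediately preceding the
probe frame. Edges are enumerated row-major over the upper triangle
(i < j), a fixed order shared by every mask and serialized model.
Correlations are clamped to ±(1 − 1e−7) before `atanh`; a region constant
within a window zeroes its edges and raises a QC flag rather than dropping
the trial.

CPM follows the standard thresholded-selection recipe:

1. Within training trials only, Pearson-correlate every edge with the
   rating; edges with two-tailed p < 0.01 form the positive (r > 0) and
   negative (r < 0) masks. Pearson (not Spearman) selection follows the
   method's lineage.
2. Network strength per trial = sum of positive-mask edges − sum of
   negative-mask edges. The opposite convention is accepted and provably
   yields identical predictions (the fitted slope absorbs the sign); the
   invariance is enforced by a test rather than resolved by fiat.
3. A least-squares line maps training strength to rating; held-out trials
   are predicted through it. Folds whose strength has zero variance (e.g.
   empty masks) fall back to the train-mean constant predictor, flagged.

Validation is leave-one-trial-out or 5-fold repeated over 120 random
unstratified partitions (mean r reported with its per-iteration spread).
Permutation significance re-runs the *entire* pipeline — selection inside
folds — on each of 1,000 shuffled outcome vectors;
`p = (1 + #{null ≥ observed}) / (1 + N)`, one-tailed in r, giving the
familiar floor of 0.001 at 1,000 permutations. The confound-controlled
variant scores predicted-vs-observed by partial Pearson correlation given
motion, within-run onset and within-session trial order, with outcome and
confound rows shuffled jointly so their coupling survives under the null.
A brain-basis-set alternative (PCA to 75 components on training edges, then
linear regression) is provided with the same fold schemes.

Note a known small-sample artifact: under the null, leave-one-out
predictions anti-correlate slightly with observed values (held-out
predictions track the training-fold mean), so null LOO r is centred a few
hundredths below zero; k-fold averaging dilutes the effect. Permutation
inference is immune because observed and null statistics share the scheme.

### Interpretation and transfer

"Edges assigned to a network" means edges with **at least one** endpoint in
it. This one-endpoint convention is required for single-network retention to
include between-network edges, which demonstrably carry predictive signal;
it also makes lesion and retention of the same network an exact partition of
the candidate edge space (a tested invariant). Pair tallies count mask edges
per unordered network pair (28 pairs for 7 networks); node degree counts
incident mask edges per region and sign. Interpretation masks are computed
on a single fold containing all trials.

Exported models carry masks, line coefficients, the strength convention and
an atlas hash; applying a model to another subject computes strength from
the training subject's masks, predicts through the training subject's line,
and reports Spearman rho (rank correlation is the right scale-free choice
across subjects). Fixed external masks (population-derived models) are
scored without any line — Spearman is invariant to positive affine maps of
strength.

## Synthetic data generator

The generator emulates the paradigm it is meant to stress: ~46 runs of
8 min at TR 1.06 s across 5 sessions, probes at uniform 45–90 s intervals
(the first probe also 45–90 s from run start, so probes never fall within
30 s of the start), ratings on the reverse-coded 1–8 scale plus "9 =
distracted" with configurable probability, and optional motion/time-on-task
confound contamination of the ratings. Adaptive probe scheduling (interval
lengths adjusted to the participant's recent reports) is not modeled; the
intervals stay uniform.

* **Latent state** — a stationary unit-variance Ornstein–Uhlenbeck process
  (discrete AR(1) with lag-1 autocorrelation `exp(−TR/τ)`, τ = 30 s by
  default): the simplest stationary autocorrelated stand-in for slow
  attention fluctuations, with a single time-constant knob.
* **Activation** — per-region gains multiply the latent state and are added
  to white region noise; the sum is convolved with a canonical double-gamma
  HRF (peak 6 s, undershoot 16 s, ratio 1/6). The kernel is L2-normalized
  inside the generator, so convolution shapes the autocorrelation without
  inflating variance and all gains are in units of baseline BOLD SD.
* **Edge coupling** — each planted edge has its own white shared source
  whose loading is a logistic function of the latent state (slope 2;
  increasing for positive edges, decreasing for negative ones), injected at
  the BOLD level after the HRF stage. The planted quantity is the
  within-window correlation contrast itself; passing the shared sources
  through the HRF would merely autocorrelate them, leaving ~4 effective
  samples per 28-frame window and destroying the contrast the feature model
  is supposed to see. The slope-2 logistic gives a ~7× loading ratio
  between latent states ±1 SD, i.e. clearly separable window correlations
  at unit gain.
* **Ratings** — raw response = `clip(round(4.5 − scale·m − ε), 1, 8)` where
  `m` is the latent-state mean over the 28 pre-probe frames, `scale` = 2.5
  and ε is Gaussian rating noise; the *negative* sign makes the raw
  (task-focus) response fall, and hence the reverse-coded rating rise, with
  the latent state. The response is replaced by 9 with probability
  `p_distracted` (default 0.1). Rounding to integers emulates Likert
  semantics; ties are expected and all rank statistics use average ranks.
* **BOLD scale** — signal rides on a baseline of 1000 as a ~1% fluctuation,
  plus white measurement noise, giving realistic %SC magnitudes.

Everything is a pure function of (config, seed): per-run generators are
spawned from a single `SeedSequence`, and written datasets are
byte-identical across reruns (gzip members are written with a pinned
mtime).

What the generator does *not* emulate: voxel-level spatial structure,
physiological noise spectra, scanner drift, motion artifacts coupled to the
BOLD signal, or adaptive probe scheduling. Passing recovery tests therefore
shows the estimators are correct and calibrated under the stated generative
assumptions — not that real acquisitions satisfy those assumptions.

## Validation studies and their sizes

The `validation` module runs each study end to end at a standard desk scale
chosen once: 50 regions (1,225 edges), 18 runs ≈ 120 analyzable trials per
synthetic subject — large enough for the asymptotics the selection
threshold relies on, small enough that the full battery runs in minutes on
one CPU.

* **Null calibration**: 200 datasets with no brain–behavior coupling;
  permutation p-values (200 permutations, 5-fold CV with one partition —
  calibration is invariant to the iteration count since observed and null
  statistics share the scheme) should be uniform: the fraction below 0.05
  and a Kolmogorov–Smirnov test are reported.
* **Signal recovery**: planted 40 positive + 40 negative edges at gain 1.5
  with 0.25-SD rating noise ("high gain, low noise"); reports mean LOO r,
  planted-edge recall, and Jaccard overlap of selected vs planted sets over
  20 seeds.
* **Event-locked detection**: activation gain 1.0 confined to the
  default-network block (12 runs, 0.5-SD rating noise); reports the rate of
  seeds with ≥1 FDR-significant pre-probe TR in the coupled network, and the
  same rate for an uncoupled network as a false-positive control.
* **Lesion specificity**: planted edges confined within an enlarged
  (14-region) default-network block, so that lesioning that network removes
  all signal while lesioning any other removes none; 5-fold CV at 20
  iterations (the reduced count keeps the study desk-scale; the statistic
  is the same mean-r) and 100 permutations for retention significance.
* **Transfer**: pairs of subjects share planted edges (same edge seed,
  different noise seeds) or have strictly disjoint planted sets; reports the
  rates of significant Spearman transfer in each case.
* **Moderate-SNR regime**: edge gain 0.7 with 2.0-SD rating noise, the
  calibrated setting in which ground-truth trial-level signal-to-noise is
  moderate; reports mean LOO r over 24 seeds. This sits in the band
  reported for real densely sampled individuals and is a qualitative
  plausibility check, not a recovery target.

## Numerical choices and degenerate inputs

* Probe frame = first frame with acquisition time ≥ onset (half-open
  windows `[start, probe_frame)` for averaging and connectivity).
* Constant covariates/outcomes: rank correlations are reported as NaN with
  the condition flagged; constant confounds are dropped with a warning;
  constant fold outcomes trigger the train-mean fallback rather than an
  error, so permutation columns never abort a run.
* BH adjustment is the standard monotone step-up; adjusted p ≥ raw p
  always.
* Fisher clamp at |r| = 1 − 1e−7 keeps edges finite; `tanh∘atanh` round
  trips to 1e−9 away from the clamp.
* All random draws flow from a single seed through named `SeedSequence`
  substreams (simulation, folds, permutations), recorded in pipeline
  reports.

## Known limitations

* The generator's rating read-out uses the latent state at neural time; the
  BOLD window lags it by the HRF delay. With 28-frame windows and τ = 30 s
  the overlap is large, but recovery numbers would degrade for much shorter
  windows or faster latent dynamics.
* The region-level GLM assumes white residuals within runs; convolved noise
  is autocorrelated, so its z statistics are calibrated only for white
  region noise (as tested) and should be read as descriptive for simulated
  BOLD with strong autocorrelation.
* Leave-one-out CPM r has the negative null bias discussed above; compare
  LOO r values only against nulls produced by the same scheme.
* Cross-subject transfer assumes an identical atlas and edge enumeration on
  both sides; there is no re-registration of masks between parcellations.
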