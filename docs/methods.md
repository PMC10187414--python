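# Methods

`ernstates` implements a complete EEG microstate analysis linking
resting-state microstates to error-related brain activity, exercised
end-to-end on synthetic multichannel EEG with known ground truth.  This
note documents the models, the parameters that matter, the synthetic
generator's assumptions, and the design choices made where the design was
genuinely open.

## Topographic model

A *topography* u(t) is the instantaneous average-referenced scalp
potential vector.  Average referencing is the projection u → u − ū; all
downstream quantities live in that (N−1)-dimensional subspace.

* **GFP** (global field power) is the spatial standard deviation,
  GFP(t) = sqrt((1/N) Σᵢ (uᵢ − ū)²), using the population (1/N) variance
  — the standard convention in the microstate literature.
* **Spatial correlation** between two maps is the Pearson correlation of
  their channel values; on zero-mean vectors it equals the cosine of the
  angle between them.  *Polarity-invariant* mode takes the absolute value
  (spontaneous EEG oscillates, so a map and its mirror are the same
  state); *polarity-variant* mode keeps the sign (used for ERPs, where
  polarity is meaningful).
* **Median-GFP normalization** divides a recording by the scalar median
  of its GFP series, removing between-subject scale differences (skull
  conductivity) without changing any spatial correlation — and therefore
  without changing any backfitting label.
* The **instantaneous spatial filter** replaces each channel's value by
  the mean of {itself ∪ its g nearest neighbours} after discarding that
  pool's single minimum and maximum (g = 6 by default).  The exact kernel
  of the filter this emulates is not published; the min/max-trimmed
  neighbourhood mean is this package's documented stand-in with the same
  purpose (single-channel outlier rejection plus topographic smoothing)
  and a testable closed form.

## Modified k-means and GEV

Clustering maximizes **global explained variance**

    GEV = Σₜ (GFP(t)·corr(u(t), T_{L(t)}))² / Σₜ GFP(t)²,

the fraction of GFP-weighted variance captured by assigning each map to
its template.  Assignment goes to the template with the highest |corr|
(invariant) or signed corr (variant).  For a fixed assignment the
GEV-optimal invariant-mode template is the dominant eigenvector of the
assigned maps' outer-product sum (computed by warm-started power
iteration with a dense fallback; tolerance 1e-12); variant mode uses the
normalized mean map.  Iteration stops when the GEV gain falls below 1e-6
(max 100 sweeps), and the best of `restarts` seeded initializations
(templates drawn from the data without replacement) is kept.  Empty
clusters are re-seeded from the worst-fit map.  On 20 maps × 4 channels
the best-of-100-restarts GEV equals the exhaustive-assignment optimum to
1e-15 (tested).

## Choosing the model order: the meta-criterion

Seven cluster-validity indices are evaluated on the polarity-respecting
correlation distance d(u,v) = 1 − |corr| (or 1 − corr): Krzanowski–Lai,
silhouette, Davies–Bouldin, point-biserial, Dunn, Calinski–Harabasz, and
a predictive-residual (cross-validation) criterion with penalty
((m−1)/(m−1−k))², m = channels − 1.  Each index votes for its optimal k;
the meta-criterion takes the lower-median vote, snapping ties toward
smaller k (parsimony).  Two guards make the aggregate robust:

* **Rank-one degeneracy**: if one template explains the data to within
  1e-9 (all maps equal up to polarity and scale), the data are flagged
  unclusterable and every criterion votes for the grid minimum.
* **Boundary guard**: an index whose optimum lands in the top fifth of
  the grid span has found no parsimonious structure (the signature of a
  dispersion measure with no noise floor, e.g. Calinski–Harabasz on
  noise-free pooled templates); its vote falls back to the grid minimum
  so it cannot drag the median upward.

## Two-level resampled clustering

Resting analysis follows a two-level resampling scheme.  Subject level:
topographies at strict GFP local maxima are extracted; each of E epochs
draws S of them without replacement, fits the polarity-invariant k-means
over the k grid, and keeps the meta-criterion's winner (full-scale
defaults E=50, S=833, k=1..12, 50 restarts).  Group level, stage 1: each
epoch pools the template maps of randomly sampled subject sets (after a
canonical sign/lexicographic sort, making the result independent of
subject order) and clusters them, the meta-criterion choosing k per
epoch (defaults 100 epochs × 1000 sets, k=1..15, 100 restarts).  Stage
2: the final model order is the lower-median consensus of the stage-1
winners' orders, and the winners agreeing with that order contribute
their maps to a single final k-means fit.

The stage-2 consensus rule is a deliberate design choice.  At reduced
(desk-scale) resampling the stage-1 epochs see nearly the same pool, so
the occasional off-cluster template contributed by a stage-1
over-selection recurs identically across epochs and forms a genuine
small clump in the stage-2 pool; every validity index then votes for an
inflated k.  Basing the final order on the resampled epochs' own
meta-criterion votes — each of which already aggregated seven indices —
is robust to those recurring stragglers, and at full scale it coincides
with what a final index evaluation would choose.

## Backfitting and temporal parameters

Group templates are backfit to median-GFP-normalized, spatially filtered
data at every sample (not only GFP peaks): winner by |corr| (rest,
threshold .50, polarity ignored) or signed corr (task, threshold .25 on
the winner's magnitude, restricted to the error-microstate window);
sub-threshold or zero-GFP samples are UNASSIGNED.  Temporal smoothing
re-chooses each label to maximize corr² + λ·n_k(t)/(2w), where n_k
counts same-label samples within ±w (w from the 32 ms window half-size)
and λ = besag_factor × mean winning corr² / 10 — calibrated so the
documented smoothing strength of 10 weighs temporal agreement about as
strongly as topographic fit.  A factor of 0 is an exact no-op; sweeps
run to a fixed point (max 20).  Segments shorter than 32 ms are split in
half, the first ⌈n/2⌉ samples joining the preceding segment (the odd
sample goes backward — a deterministic tie-break), the rest the
following; boundary segments merge wholly into their single neighbour;
the rule repeats until no short segment remains (single-pass behaviour
available by flag).

Per microstate the package reports GEV (denominator over all eligible
samples by default; labelled-only behind a flag), mean duration (ms),
coverage (% of eligible time) and occurrence (segments/s).  Coverage,
occurrence and duration are all computed over the same eligible span, so
coverage/100 = occurrence × duration/1000 holds to 1e-9 by construction.

## ERN quantification

Response-locked epochs (−500..800 ms, baseline −500..−300 ms; minima 21
correct go / 6 erroneous no-go trials) are baseline-corrected per epoch
and averaged; error-related activity is the no-go minus go difference.
The grand-averaged difference wave is segmented sequentially
(polarity-variant, all non-baseline timepoints, k up to 20); the
*error-related microstate* is the longest contiguous segment spanning
the button-press — a programmatic stand-in for visual inspection.  Its
time span defines the measurement window; the channel holding its
template minimum plus the 4 nearest neighbours define the region of
interest (ROI size 5 by default, configurable).  Mean amplitudes over
window × ROI are measured on the *unfiltered* per-subject averages — the
spatial filter is a topographic outlier remover that demonstrably clips
sharp extrema (its trimmed mean discards the peak channel's own value),
so it feeds only the segmentation path, not amplitude measurement.
Per-subject erroneous no-go amplitudes are regressed on correct go
amplitudes (OLS with intercept) and the unstandardized residuals carry
forward; they are exactly orthogonal to the go amplitudes, removing the
shared response-locked component.

## Association battery

Resting microstates of interest are ranked by polarity-invariant spatial
correlation with the error-related template (flag threshold 0.5).  Each
model in the battery: complete cases on its variables → Minimum
Covariance Determinant outlier screening (FAST-MCD, support fraction
0.75) → hierarchical OLS (age and sex in step 1, the predictor in step
2; some models use sex only, or no covariates), reporting the adjusted-R²
change, its F test with (1, n−k−1) df, the full model's omnibus F, and
the standardized β (outcome and predictor z-scored, covariates raw).
Omnibus p-values are Benjamini–Hochberg corrected across the battery.

The MCD flag cutoff is the chi-square quantile of the squared robust
Mahalanobis distance, **0.999 by default**.  This targets gross outliers
only: at moderate cutoffs (0.975) the screening removes 3–5 % of
perfectly clean rows at n = 90 (FAST-MCD distances run hot in small
samples), and classical F tests refit on tail-trimmed data become
markedly anti-conservative (measured family-wise error ≈ 0.19 for an
8-model null battery versus ≈ 0.05 at the 0.999 cutoff, 300–400
Monte-Carlo reps).  At 0.999 the clean-data removal rate is < 1 % while
planted 10σ outliers are still flagged without fail.

## The synthetic generator

The generator *defines* the study conditions every test runs under:

* **Montage**: quasi-uniform Fibonacci lattice on the upper unit
  hemisphere (default 30 channels), vertex channel labelled Cz.
* **Resting maps**: seeded smooth Gaussian-process fields on the
  montage, iterated through the spatial filter to near-fixed-points
  (otherwise the pipeline's own filtering would bias recovered templates
  to ~0.85–0.90 correlation with the raw planted maps, and no correct
  implementation could score recovery above that), then accepted by
  rejection sampling against a pairwise |corr| ceiling (default 0.5).
  The filter-stable smooth space is only ~5–6 dimensional, so acceptance
  can take a few thousand draws for k = 5 — still about a second.  A
  ceiling of 0 instead returns a symmetrically (Löwdin) orthogonalized
  set, exactly orthogonal at a small cost in filter stability.
* **Resting dynamics**: a Markov state sequence with no self-transitions
  and geometric dwell times (mean 80 ms by default — mid-range for the
  30–150 ms quasi-stability the segmentation model assumes), each sample
  being the active map times a rectified-sinusoid GFP envelope (period
  100 ms, peak 10 µV) plus spatially smooth Gaussian noise scaled to a
  target signal-to-noise ratio of GFP RMS values (default 5).  Default
  recording length 157 s at 250 Hz.
* **Task epochs** (−500..800 ms at 250 Hz; 120 go / 80 no-go trials by
  default): background microstate dynamics in both conditions, plus a
  response-locked fronto-central negative Gaussian deflection (peak −8
  µV at the vertex, latency +20 ms, width σ = 60 ms).  Error trials
  carry it scaled by the subject's latent effect; correct trials carry
  the *common* response component (0.30 × nominal amplitude, no subject
  scaling), so residualization removes the shared part while the
  error-specific between-subject variance survives — if correct trials
  scaled with the subject effect too, residualization would remove all
  subject variance and no residualized score could track anything.
  Error trials also carry the flanking components of real error data — a
  frontal pre-response negativity (the no-go stimulus response, absent
  on go trials because the stimuli differ) and a centro-parietal error
  positivity afterward, both at 0.6 × nominal amplitude — which bound
  the error-related microstate in time the way flanking microstates do
  in real sequential segmentations.
* **Cohorts**: a per-subject latent pair with population correlation
  `coupling_rho` (shared-factor construction) drives the ERN scaling
  (1 + 0.3·e) and the designated resting map's dwell-time multiplier
  (1 + 0.35·e), linking a subject's error response to that map's
  long-run GEV.  Age is uniform on 4–8 years; sex Bernoulli(0.5).
  `simulate_association_table` draws the analysis table directly from
  the latent model (no EEG synthesis) for power and error-rate studies
  of the battery.

All randomness descends from one integer seed via
`numpy.random.SeedSequence` spawning; identical seeds give bit-identical
cohorts.

What the generator does **not** emulate: forward-modelled cortical
sources, eye/muscle artifacts, 1/f spectral shape, channel-specific
noise, or real electrode geometry.  Passing tests therefore demonstrate
the correctness and statistical behaviour of the *analysis*, not
field-realistic effect sizes.

## Problem sizes used in tests and the acceptance script

Desk-scale conditions, chosen as this package's own reduced study
design: recovery runs use 10-subject cohorts (30 channels, 120 s rest at
250 Hz, snr 5, dwell 80 ms) with reduced resampling (10 epochs × 200
subsamples at the subject level, 20 × 200 at the group level, 4/8
k-means restarts); the ERN pipeline runs a 20-subject cohort with 80/40
trials; battery power uses 100 seeds at n = 90 and the null battery
200–250 Monte-Carlo replicates.  The acceptance script
(`scripts/acceptance.py`) re-runs all of these from scratch and reports
the measured quantities as JSON.

## Known limitations

* The seven-index composition of the model-order criterion and the
  spatial filter kernel are documented stand-ins for incompletely
  published procedures; their guards (boundary, degeneracy) matter at
  desk scale.
* Variant-mode (ERP) k-means uses the normalized mean-map update; its
  monotonicity is enforced by early stopping rather than guaranteed by
  the update itself.
* Outlier screening at cutoffs that trim distribution tails (rather than
  gross outliers) invalidates the battery's classical F tests; the
  package defaults guard against this but the quantile is configurable.
* With ~100 subject-level sets, the group-stage resampling epochs
  overlap almost completely; the stage-2 consensus rule compensates (see
  above), which matters less as cohort size grows.
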