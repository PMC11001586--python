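# Methods

This note documents the measurement models implemented in `drosoquant`,
the defaults and why they were chosen, what the synthetic generators do
and do not emulate, and the numerical conventions that make results
exactly reproducible.

## Sleep architecture (`drosoquant.dam`)

**Model.** Activity is a per-minute beam-break count on a Zeitgeber-time
grid (ZT0 = lights-on, 12 h light : 12 h dark). Sleep is the standard fly
definition: a maximal run of zero-count minutes of length ≥ `min_bout`
(default 5 min). Everything else derives from the resulting minute-level
sleep flags.

**Conventions.**
- *Day boundary*: days are ZT0-aligned. A bout spanning ZT0 is split at
  the boundary for per-day minute totals (keeping totals additive across
  days) but is assigned whole to the day containing its start for bout
  counts and mean duration; hence `mean_bout × n_bouts` recovers the
  unclipped bout minutes of a day, while `total_sleep` is the clipped
  minute count. The two bookkeepings coincide except at boundaries.
- *Multi-day summaries* drop the first day (acclimation) when more than
  one day is available.
- *Waking activity* = total counts / awake minutes within the day
  (undefined for a fully sleeping day). This is the usual activity
  index; no alternative definition is computed.
- *Dead-fly exclusion*: a fly is excluded when its counts are zero from
  some minute through the end of the recording and that terminal span is
  ≥ `death_window` (default 1440 min, one full day). The rule is
  deliberately conservative — an immobile-but-alive fly asleep for its
  final day would be excluded, which is the safe direction for sleep
  phenotypes.
- *Control subtraction*: per-fly loss is `x_i − mean(control)`; the SEM
  of the difference combines group SEMs in quadrature,
  `√(SEM_e² + SEM_c²)`, the variance of `x_i − mean(ctrl)` for
  independent groups. Hypothesis tests always run on the raw groups,
  never on subtracted values.
- *Monitor dialect*: standard TriKinetics text rows — record index,
  date, time, status, six device fields, 32 channel counts,
  tab-separated, 1-min cadence. Only status-1 rows are data; non-OK rows
  are tolerated at the edges (trimmed) but an interior one, like any
  timestamp gap, is a hard format error rather than a silent
  interpolation.

## Ratiometric redox scoring (`drosoquant.redox`)

**Model.** For a two-channel stack the per-brain statistic is the mean
of per-pixel intensity ratios after two exclusion passes, in this order:

1. ratio gate — pixels with numerator/denominator outside
   `[ratio_low, ratio_high]` are excluded (debris and autofluorescent
   structures produce extreme ratios). Zero-denominator pixels count as
   ratio-excluded (their ratio is out of bounds by definition).
2. background cut — among gate survivors, pixels dimmer than
   `bg_factor ×` that channel's mean *over survivors* in either channel
   are excluded.

Presets: roGFP2-Grx1 gate 0.25–4.0 with `bg_factor` 0.5; MitoTimer sets
use 1/2.5–2.5 with 0.4 (glial driver) and 0.25–4.0 with 0.25 (neuronal
driver), reflecting that gating constants are tuned per experimental set
when signal and background levels differ.

**Open choices, resolved.** Whether the background-cut channel mean is
taken over all pixels or over gate survivors is ambiguous; the survivor
mean was chosen because it is robust to the very debris the gate just
removed, and the choice is recorded here because reimplementations may
differ. Likewise the per-brain statistic is the mean of per-pixel ratios
(matching pixel-by-pixel division), not the ratio of channel sums; both
interpretations agree on uniform scenes but diverge on heterogeneous
ones. Pixel accounting (`n_included + n_excluded_ratio + n_excluded_bg`
= unmasked pixels) is preserved for every input so exclusions are
auditable.

**Calibration.** Percent oxidized maps a control-normalized score `x`
onto the sensor's dynamic range: `(x − DTT)/(DA − DTT)`, 0 at the fully
reduced (DTT) reference and 1 at the fully oxidized (DA) reference.
Values outside [0, 1] are returned unchanged with a warning rather than
clipped — they are information about calibration drift. The map is
invariant to any common rescaling of `x`, DA and DTT, which is why
control normalization upstream is safe.

**CaLexA** uses a sum projection, making the index the ratio of
whole-stack totals (a maximum projection is available but changes the
meaning from total to peak signal). **MDA** scoring sums all z-slices
and averages projected pixels strictly above a user-held background
threshold, which must be held constant within an experiment.

## Droplet morphometry (`drosoquant.droplets`)

**Thresholds.** Both auto-thresholds operate on a 256-bin histogram of
the analyzed (unmasked) pixels, binned over the data range.

- *Triangle*: chord from the histogram peak (lowest bin attaining the
  maximum) to the farthest nonzero bin on the longer-tail side; the
  threshold is the bin maximizing perpendicular point-to-chord distance,
  lowest bin on ties. The distance is computed as an unnormalized cross
  product, so the argmax is invariant to scaling the counts.
- *Rényi entropy*: for orders α ∈ {0.5, 1, 2} the bin maximizing the
  summed background+foreground Rényi entropy is found exhaustively
  (α = 1 is the Shannon / maximum-entropy limit); the three sorted
  maximizers are combined with spacing-dependent weights β — (1,2,1)
  when all three lie within 5 bins, shifting weight to the distant pair
  when one maximizer is outlying — via
  `t = t₁(P(t₁) + wβ₁/4) + t₂wβ₂/4 + t₃(1 − P(t₃) + wβ₃/4)`,
  `w = P(t₃) − P(t₁)`.
- *Numerical tie rule*: runs of empty bins create split candidates whose
  entropies are mathematically identical but differ by float rounding;
  candidates within 1e-10 relative tolerance of the maximum count as
  tied and the lowest bin wins. Without this rule, independent
  implementations disagree on ~5 % of sparse histograms for no
  substantive reason.

Foreground is strictly above the threshold bin. A constant
(single-nonzero-bin) plane has nothing separable: the threshold
functions raise a degenerate-histogram error, and slice-wise
segmentation treats such a slice as all background.

**Particle metrics.** Connected components are labeled in 2-D per slice
(8-connectivity default), counts summed across slices with no 3-D
linking — droplets spanning slices are counted once per slice, matching
slice-wise particle analysis; a 3-D merge would change the meaning of
"count" and is deliberately not the default. `mean_size = total area /
count` by definition, so the size–count–area identity is exact by
construction. `min_area_px` defaults to 0 (no size filter). For recovery
experiments on white-noise synthetic scenes the analysis configuration
uses `min_area_px = 4`: isolated suprathreshold noise pixels are a
segmentation artifact of uncorrelated noise (real confocal images are
PSF-smoothed), and 4 px is an order of magnitude below the ~50 px disks
being counted.

## Mitophagy index (`drosoquant.mitophagy`)

Per slice z in a window of `n_slices` (default 30):
`ratio_z = |mito_z ∧ atg_z| / |mito_z|`, and the index is Σ ratio_z.
Slices with no mitochondrial foreground contribute 0 — not NaN and not
exclusion — which keeps the index bounded by the window length and
windows comparable across brains. The window starts at the slice with
the greatest mitochondrial area (ties → lowest index) so every brain is
analyzed from the same relative depth; `first_slice` mode covers
full-stack analyses. A window extending past the stack is clipped with a
warning rather than failing. Binarization of intensity stacks defaults
to the per-slice Rényi-entropy threshold for both channels; any
upstream binarization can be supplied instead.

## OCR quality control (`drosoquant.ocr`)

Traces are one value per 4.5-min mix/wait/measure cycle with a 6-cycle
baseline. Normalization divides by the mean of the last 3 baseline
cycles ("end of the baseline period"; the count is configurable), making
normalization scale-invariant. Stability: a well is excluded iff any
consecutive pair changes by strictly more than `max_rel_step` (default
0.30) of the earlier value — rises and falls count equally, and exactly
30 % is kept (the rule is a strict inequality). The check runs on raw
values, so it commutes with normalization. Injection failure is a manual
flag carried in the input table (it is diagnosed physically, from the
cartridge), never inferred from the trace.

## Gated statistics (`drosoquant.stats`)

Branch selection: parametric iff every group passes Shapiro–Wilk at the
gate α (0.05) *and* median-centered Levene finds no variance
heterogeneity. Levene with median centering was chosen as a robust
default since the variance test is otherwise unspecified. Zero-variance
groups cannot be tested for normality and route to the nonparametric
branch with a warning. Groups need n ≥ 3 to be gated at all.

Parametric branch: pooled-variance t-test (the gate has already vetted
variance homogeneity) or one-way ANOVA with per-group t-tests against
the reference, Holm–Šídák adjusted. Nonparametric: two-sided
Mann–Whitney (exact enumeration when both groups are ≤ 25 and tie-free,
asymptotic otherwise) or Kruskal–Wallis with Dunn's rank comparisons
against the reference (z on mean ranks with the Σ(t³−t)/(12(N−1)) tie
correction), Holm–Šídák adjusted by default with Bonferroni and
uncorrected available. Dunn's test is implemented here because no
installed library provides it. Sleep-deprivation contrasts are treated
as independent two-group experiments, uncorrected with any circadian
panel.

The dual-control rule is a policy, not a test: with both a driver and a
responder control, the reported p is max(p₁, p₂) and significance
requires both individual comparisons to pass α (boundary exclusive).
Per-experiment normalization divides every value by its own experiment's
control mean before pooling, so pooled controls center at exactly 1 and
within-experiment ratios are untouched.

ΔΔCt: per sample ΔCt = Ct(target) − Ct(reference gene); ΔΔCt subtracts
the control-condition mean ΔCt; expression = 2^(−ΔΔCt). The control
*geometric* mean expression is always 1; the arithmetic mean is 1
exactly when control ΔCts coincide.

## Synthetic data (`drosoquant.synthetic`)

Every generator is a pure function of (parameters, seed) and emits
ground truth beside the data. What they emulate, and what they don't:

- *Droplet scenes*: hard disks (pixel centers within radius r) of known
  count/radius at ≥ min-separation over Gaussian or Poisson white noise;
  defaults 256×256, 50 disks, r = 4 px, fg 160 / bg 40, σ = 12
  (SNR 10). No PSF, no intensity falloff, no overlapping or out-of-focus
  droplets — so passing recovery tests demonstrates correct
  thresholding/counting, not robustness to real optics.
- *Redox scenes*: a fixed true ratio ρ* on a random 30 % of pixels
  (denominator base 100, per-channel noise σ = level/SNR), background
  dim in both channels so it falls below the background cut by
  construction. At SNR 10 the expected mean-of-ratios bias is
  ≈ ρ*(1 + 1/SNR²) ≈ 1 %, within the 2 % recovery band; there is no
  spatial structure, bleed-through, or depth attenuation.
- *Colocalization masks*: per-slice overlap fractions realized exactly
  by integer pixel budgets (default 100 mito pixels per slice, so any
  two-decimal fraction is representable; others raise with a suggested
  size), plus autophagosome-only pixels so the atg mask is not a subset.
- *Sleep traces*: alternating wake/sleep bouts with geometric
  (memoryless, integer-minute) durations, means switchable by
  light phase (defaults: sleep 20 min day / 60 min night, wake 30/10,
  i.e. a night-consolidated sleeper); wake minutes draw
  Poisson(λ = 2) counts clipped to ≥ 1 so wake is never misread as
  sleep — a fixture convention, not a biological claim. Mechanical
  deprivation (shaking at sub-minute cadence) is modeled at the DAM's
  1-min resolution: every minute in the window registers activity.
  Ground-truth bout lists are derived by run-length analysis of the
  emitted counts, so generator and detector share one sleep definition
  by construction; the closure test then verifies the write → parse →
  detect loop, not the generator against itself. No circadian waveform
  beyond the day/night bout-mean split, no rebound dynamics.
- *OCR cohorts*: multiplicative well-level variation, slow linear drift,
  a rotenone-like exponential decline to 35 % of baseline (slow enough
  never to trip the 30 % rule by itself), 2 % CV measurement noise, and
  injected step artifacts constructed so the noise-free consecutive
  ratio at the step cycle equals exactly 1 + step size.

## Pipeline and reproducibility (`drosoquant.config`, CLI)

A YAML run config is validated before anything executes: unknown keys,
bad ranges and missing input files are aggregated into one error report,
and every applied default is logged. Outputs are write-once per run
directory; the manifest records the package version, a canonical config
hash, the seed, per-stage status and SHA-256 of every output, which is
sufficient to verify a rerun bit-for-bit. All randomness flows from the
single config seed through `numpy.random.default_rng`.

## Validation scales

The test suite and `scripts/acceptance.py` use: 1,000 random 2-day
traces for the bout oracle; 100 simulated flies (including deprivation
windows) for generator/detector closure; 500 random histograms for both
threshold oracles; 20 scenes × 50 disks for droplet recovery; 5 scenes
each for noisy redox recovery; 200 random mask stacks for
colocalization; 48 boundary wells for OCR; and 5,000 Monte-Carlo
replicates per null (Gaussian, lognormal; n = 20/group) for the type-I
calibration of the gated procedure. These sizes make the full
validation run in well under a minute for the suite's unit portion and
about half a minute for the acceptance script on one CPU.

## Known limitations

- The redox gating constants are presets, not fitted; real MitoTimer
  experiments may need per-set retuning exactly as the presets suggest.
- Per-slice droplet counts double-count droplets spanning slices, by
  design (matching slice-wise particle analysis); absolute counts are
  comparable only within a fixed slicing scheme.
- The mitophagy index is an area-overlap proxy; it is not an
  object-level mitophagy event count and does not compute
  intensity-based colocalization coefficients (Manders/Pearson).
- The statistics module implements the gate as a hard decision;
  pre-testing affects downstream error rates in ways the Monte-Carlo
  calibration quantifies empirically (it holds 0.05 ± 0.01 under the two
  nulls tested) but does not correct analytically.
- Synthetic scenes validate algorithmic correctness against ground
  truth; they do not certify performance on real microscopy, where PSF,
  depth attenuation and debris dominate error.
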