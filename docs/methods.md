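# Methods

This note documents the models, estimators and numerical choices behind
`sleeptopo`, and what the synthetic-data tests do and do not establish.

## Spectral estimation

Per 30-s scoring epoch, each channel's power density spectrum is the mean of
six non-overlapping 5-s segments taken from epoch start. Each segment is
multiplied by a *periodic* Hann window and its one-sided periodogram is
scaled as `2 |X(f)|² / (fs · Σw²)` (units µV²/Hz). A 5-s window gives the
0.2-Hz bin grid; the DC bin is discarded and analysis retained to 44 Hz
(220 bins). Segments are not detrended: slow drifts land in the lowest bins,
which the artifact screen monitors anyway, and detrending would break the
direct-DFT oracle equivalence the tests assert (relative error ≤ 1e-10).
Float32 recordings (the synthetic path) are transformed in single precision
for speed; float64 input keeps full precision.

Periodogram scaling is irrelevant downstream — the topographic normalization
divides it out — but is fixed so the estimator is testable against Parseval
and a flat-spectrum oracle.

Decimation (e.g. 1000 Hz → 250 Hz) uses a Kaiser-window FIR low-pass with
pass edge at 0.8× and stop edge at 1.0× the new Nyquist, ≥ 60 dB stopband,
applied forward-backward (zero phase) before taking every q-th sample. Only
integer factors are supported.

Epoch k covers samples [k·30·fs, (k+1)·30·fs), 0-based, half-open; a
trailing partial epoch is dropped.

## Artifact screening

Channel-epochs are flagged when summed power in the low (0.8–4.6 Hz) or
high (20–40 Hz) range exceeds k× a centered moving median (half-width 10
epochs) of that channel's band-power series, computed within the same sleep
state class (NREM vs REM vs other). Defaults k_low = 4, k_high = 3. The
reference is the subject's own moving median, so flagging is invariant to
global gain and adapts to slow drifts; computing it within state classes
prevents REM's lower slow-wave power from inflating NREM flags. The
constants are not taken from any published procedure; they are calibrated
only against the injection/recovery simulations in the test suite
(sensitivity ≥ 0.95, false positives ≤ 0.05 for gain-10 artifacts on 5% of
epochs).

A channel flagged in > 20% of epochs is excluded ("bad"); an epoch whose
flagged fraction among good channels exceeds 10% is dropped. Isolated
flagged channel-epochs below both thresholds are masked out of that
channel's state average rather than ignored — without this, rare
high-gain artifacts on a few channels would survive both screens and
dominate the channel mean. Bad channels are repaired at the normalized-map
level (inverse-distance-weighted mean of the 3 nearest good channels,
then per-band renormalization); repairing maps rather than signals is
cheaper and sufficient because all downstream statistics consume maps.
The interactive visual-inspection step of a real workflow is replaced by an
optional user-supplied epoch drop list, never guessed automatically.

Processing order: flagging and channel screening run on *unreferenced*
spectra, so a single noisy channel cannot leak into the reference; the
average reference is then the mean of good channels only, and spectra are
recomputed on the re-referenced signal for all later stages.

## Topography

State averages (NREM = stages S2 + SWS; stage 1 is excluded, the
conventional choice for NREM spectral analysis) are normalized per 0.2-Hz
bin: q(ch, f) = P(ch, f) / Σ_ch' P(ch', f). Band values are the *mean* (not
sum) of member bins, which preserves the per-band channel sum of 1. Band
membership is by bin center, inclusive of both printed edges; adjacent
bands are separated by one bin step so no bin is double-counted. Within a
twin pair, both siblings use the maximal common number of clean epochs per
state, taken chronologically (first n); the resulting single map per
subject × state × time is reused for Self and non-related comparisons.

## Similarity and heritability

Topographic similarity is the Pearson correlation of two subjects' 58-value
normalized band maps across derivations. Groups: MZ co-twins, DZ co-twins,
NR = all unordered cross-family pairs at one time point (both zygosity
groups pooled; a subject-exclusion list can shrink this set), Self = the
same subject at the two assessments. Per-pair r values are Fisher
z-transformed before averaging and the mean is back-transformed for
reporting; per-pair values are exported for external ANOVA tooling.
Correlations undefined because a map has zero variance are excluded from
their cell with a logged warning, not imputed.

Falconer's estimate h² = 2(r_MZ − r_DZ) and c² = r_MZ − h² are applied to
the back-transformed group means by default (the z-domain alternative is an
option; which domain the classical analysis used is ambiguous in the
literature). Estimates are reported raw with an out-of-range flag —
Falconer estimates can leave [0, 1] by construction — and clipping is
opt-in and always flagged.

Cross-state (NREM vs REM) correlations of grand-average maps carry
two-sided p-values from the ordinary correlation t-test with
df = channels − 2. Neighbouring derivations are spatially correlated, so
for smooth real maps these p-values are anticonservative; they are
calibrated (uniform under the null) only for spatially independent maps,
which is exactly what the null-calibration test checks.

## Synthetic cohorts

Per band, a subject's map deviation is d = √a2·A + √c2·C + √e2·E with unit
total variance: A is shared by MZ co-twins and correlated 0.5 in DZ pairs
(constructed as A₂ = 0.5·A₁ + √0.75·A′, which has the same law as a joint
draw), C is shared within every pair, E is unique. A population template
with spatial variance `template_var` is added. Fields are unit-variance
white noise over a circular channel layout, smoothed by a circular moving
average of width `smoothness` (real electrode geometry is not needed for
testing). Two modes:

- **linear**: map = template + d. Negative values possible; the expected
  pair correlation has the closed form
  E[r] ≈ (template_var + a2·ρ_A + c2·ρ_C)/(template_var + 1), the oracle
  for the parameter-recovery tests. It also yields the attenuation law
  ĥ² → a2/(1 + template_var): a shared template inflates all group
  correlations equally and compresses their difference.
- **compositional**: map = exp(template)·exp(d), renormalized per band —
  positive, sum-1, realistic; verified against the linear oracle only by
  Monte Carlo.

Across the two assessments A and C persist and E is partially re-drawn:
E₂ = ρ·E₁ + √(1−ρ²)·E′ with ρ = `retest_stability` (default 0.85, echoing
high within-person stability over months; no quantitative retest model
exists to estimate it from). Note ρ is the correlation of the *unique*
component; the full deviation correlates a2 + c2 + e2·ρ between
assessments, which is necessarily ≥ a2 + c2.

Signal rendering draws each epoch's channels as Gaussian processes in the
frequency domain: within band b, power density is flat at
(√(map·n_channels)·amplitude[stage][b])², so a uniform map gives equal
channel gains and the generated normalized topography equals the input map
in expectation; a common 1/f background is added (it shifts every channel
equally and cancels in the correlation of normalized maps). Stage-dependent
amplitudes mimic slow-wave-dominant SWS, spindle-band S2 and flatter REM.
Hypnograms are first-order Markov chains over Wake/S1/S2/SWS/REM. Artifact
epochs (fraction `artifact_rate`) have 1–4 randomly chosen channels
multiplied by `artifact_gain`, and every injected (subject, epoch, channel)
is logged as ground truth.

Default cohort parameters mirror the stated world of an adolescent twin
study: 14 MZ + 11 DZ same-sex pairs, 58 EEG derivations, two assessments,
30-s epochs; default per-band (a2, c2) echo the reported pattern (shared
environment dominating delta–sigma, strongest genetic contribution in the
beta bands) and template_var = 1 reflects the substantial topography shared
by unrelated individuals.

What the generator does *not* emulate: discrete sleep microstructure
(spindles as events, slow-wave morphology, sleep cycles), volume-conduction
correlations between channels within an epoch, ocular/muscle artifact
spectra, or real electrode geometry. A green end-to-end test therefore
establishes that the pipeline recovers known band topographies and ACE
structure from stationary band-limited noise — not that the artifact
thresholds or interpolation match any particular laboratory's data.

## Randomness and determinism

A master seed spawns independent named substreams (maps per state,
hypnogram/signal/artifacts per subject-night), so adding a stage or subject
never perturbs another's draws. All tables are written with a fixed float
format; identical config + seed reproduces byte-identical outputs, which
the determinism test asserts.

## Known limitations

- Falconer's method only: no SEM-based ACE fitting, no confidence
  intervals (a bootstrap over pairs would be straightforward plumbing but
  is not provided).
- Cross-state p-values ignore spatial autocorrelation (see above).
- The EDF layer implements plain EDF (1-s records, 16-bit), not EDF+;
  amplitudes round-trip only to 16-bit quantization of the per-channel
  range.
- Epoch matching uses the first n clean epochs chronologically; whether a
  random-n choice would alter similarity slightly is untested.
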