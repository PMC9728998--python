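# Methods

## Signal model and processing chain

The unit of analysis is the 8-s artifact-free epoch (8,192 samples at the
1,024-Hz acquisition default). Epochs are processed in a fixed order:

1. **Common-average reference.** Each sample is re-expressed relative to the
   mean of all 61 scalp channels; auxiliary polygraphy channels (ECG/EMG)
   are excluded from the average and untouched. The operation is idempotent
   and leaves a per-sample channel mean of exactly zero.
2. **Band decomposition.** Five bandpass filters are applied in the
   frequency domain: each epoch/channel is demeaned, its real FFT
   multiplied by a real (hence zero-phase) magnitude response, and inverted
   at the original length. The response is 1 over the passband, 0 beyond
   the transition bands, with a raised-cosine taper across each transition
   (midpoint = 0.5). Passbands and transition widths (low/high, Hz):
   delta 0.5–3 (1/2), theta 3–8 (2/3), alpha 8–12 (3/4), beta 12–30 (4/5),
   gamma 30–50 (3/3). The delta low-side taper would extend below 0 Hz; it
   is truncated at 0 and the DC bin is always zeroed. Epochs are filtered
   independently (they are non-contiguous selections), without additional
   edge tapering — at 8 s the transient support of these responses is a
   small fraction of the epoch.
3. **PLI.** Instantaneous phases come from the analytic signal (Hilbert
   transform) of each band output, per epoch. For a pair,
   `PLI = |mean_t sign(wrap(φ_a − φ_b))|` with the difference wrapped to
   (−π, π] and `sign(0) = 0`, so exact zero-lag (volume-conduction-like)
   differences contribute nothing. No edge-sample trimming is applied by
   default. Aggregation: per-epoch mean over all unordered pairs (global),
   over within-region pairs only (regional; a region with fewer than two
   channels is flagged undefined, never silently averaged), and the mean of
   the 60 pairs containing each channel (channel scale). The channel values
   average back to the global value exactly — this identity is tested.
4. **Aperiodic parameters.** Spectra are Welch averages of Hamming-windowed
   2-s segments with 50 % overlap (seven segments per 8-s epoch, 0.5-Hz
   resolution), fitted over 1–40 Hz by default — above the 0.5-Hz
   acquisition high-pass shoulder and below the mains region. The fit is a
   robust iterative regression in log–log coordinates: ordinary least
   squares, exclusion of points whose residual exceeds 2.5 residual
   standard deviations (positive residuals only, i.e. oscillatory peaks),
   refit until the excluded set stabilizes (≤ 10 rounds; error if < 10
   points enter or < 5 survive). Offset is the intercept at log10 f = 0
   (1 Hz); exponent is minus the slope. Parameters are fitted per channel
   *and* per epoch — the epoch-level distributions are what the group
   statistics consume — then averaged over channels (global) and region
   members (regional). A noiseless power law is recovered to machine
   precision; ×10 amplitude scaling adds exactly 2 to the offset and leaves
   the exponent unchanged.

## Statistics

Pre- vs post-implantation comparisons run separately per group (responders
R, non-responders NR). The default statistical unit is the **epoch-level
feature value pooled across a group's subjects** (5 × 20 = 100 values per
condition); per-subject medians are available via `unit_mode="subject"`.
This pooling is the key ambiguity of the design: subject-level tests at
n = 5 cannot produce the small p-values the pooled analysis yields, while
pooling treats within-subject epochs as exchangeable units and therefore
overstates independent evidence. Both modes are implemented; the pooled
default should be read as "epochs as units", not as subject-level
inference.

* **Mann–Whitney U**, two-sided: exact null distribution when
  min(n) ≤ 8 and the pooled sample is tie-free, tie-corrected normal
  approximation with continuity correction otherwise (verified against
  full enumeration of rank assignments).
* **BH-FDR** within families defined by the spatial subdivision: for PLI,
  each (group, subdivision) family spans the five bands; for aperiodic
  parameters it spans offset and exponent. At the global and regional
  scales the subdivision is the scalp or the single region; at the channel
  scale the default family pools all channel × band (or channel ×
  parameter) tests, with a per-region alternative
  (`channel_family_per_region=True`). Verified against a brute-force
  step-up oracle.
* **Trend** (up/down, sign of the median difference) is reported only for
  FDR-significant tests. **Cohen's d** uses the pooled-SD formula and is
  reported descriptively.
* **Labar index** `−100·(post − pre)/pre` (percent; both rates zero
  defined as 0, zero pre with seizures after flagged undefined).
  Responder iff ≥ 50; frequency-computable outcome buckets are ≥ 80 (I)
  and 50–79 (II); lower classes need non-frequency clinical input and are
  bucketed "other".
* **Outcome correlation**: per feature, the per-subject relative variation
  `(median_post − median_pre)/median_pre` of the global series against the
  Labar index, Spearman's ρ. The p-value is an exact permutation value for
  n ≤ 9 and a t-approximation above (the exact branch is capped at 9
  because enumerating 10! permutations is disproportionate for a single
  p-value; at the cohort's n = 10 the t-approximation is used).

## The synthetic cohort

The generator emulates the study conditions — 61 channels, 1,024 Hz, 8-s
epochs, 20 per session, 5 responders + 5 non-responders — with known truth:

* **Aperiodic background** by inverse spectral shaping: amplitude spectrum
  = square root of the target `10^offset / f^χ` one-sided density over the
  0.5–70 Hz synthesis band (mirroring the acquisition bandpass), with
  independently uniform phases. The target density is exact in
  expectation; mean Welch spectra over ≥ 100 epochs recover (offset, χ)
  within ±0.05. Group baselines default to offset 1.4 / exponent 2.0 (R)
  and 1.7 / 2.2 (NR), with between-subject SDs of 0.35 / 0.2 and a 0.1
  per-channel spread.
* **Pairwise couplings** (`CouplingSpec`): two series on a common carrier
  at the band's passband midpoint whose phase difference is i.i.d.
  von Mises(δ, κ) across samples. `expected_pli(δ, κ)` integrates the
  wrapped density numerically and is cross-checked against 10⁶ Monte-Carlo
  draws; empirical PLI matches it within 3 SE at 200 epochs across a
  (δ, κ) grid.
* **Diffuse couplings** (`DiffuseCoupling`): every channel carries a
  band's common carrier at a fixed channel-specific lag (uniform in
  ±π/2, fixed per subject). The measured PLI level is set by the
  oscillation-to-background SNR within the band: the band-limited
  background acts as phase noise, approximately von Mises with pair
  concentration ≈ snr². Target global PLI levels (pre defaults: delta
  0.18, theta 0.16, alpha 0.15, beta 0.12, gamma 0.08) are inverted
  through this approximation. The mapping is approximate — narrowband
  phase noise is autocorrelated, and the small-sample bias of |mean sign|
  depends on the effective number of independent phase samples — so
  measured levels and shifts are compressed relative to their targets, but
  the mapping is monotone, which is what the signed group effects require.
* **Volume conduction**: zero-lag convex mixing of each channel with the
  mean of the others (default leakage 0.2). It changes spectra but cannot
  create phase lags; mixed independent sources keep mean PLI below 0.05.
* **Cohort layer**: pre-implantation seizure rates are log-normal
  (log-mean 1.5, log-SD 1.2 — spanning the reference cohort's 0.13–44
  seizures/month); responders draw a reduction in [0.5, 1.0] (Labar
  ≥ 50), non-responders in [−0.3, 0.5). Feature shifts default to the
  group-level pre→post differences of the reference analysis: responders
  PLI delta −0.01, alpha +0.03, gamma −0.01 and offset/exponent −0.1;
  non-responders offset/exponent +0.2. With `outcome_coupling` on
  (default), each subject's aperiodic shift is linear in their Labar
  index, anchored so the group means equal the per-group shifts — this
  produces both the opposite group signs and the negative
  variation-vs-Labar correlation in one mechanism, with 0.05 SD
  subject-level noise.

### What the generator does not emulate

Real artifacts (muscle, ocular, electrode), non-stationarity and state
changes within a session, realistic head geometry (leakage is uniform
all-to-all rather than distance-dependent), oscillatory peak structure
beyond single band carriers, and epileptiform transients. Passing tests
therefore demonstrate that the estimators recover known truth under the
stated model, not that the clinical effects would replicate in new
patients.

Two interactions of the simulator are worth knowing. First, per-epoch PLI
of *narrowband* independent noise is biased upward (an 8-s alpha-band
epoch has ≈ 60 independent phase samples, so the null PLI sits near 0.1,
as it does for real EEG at these epoch lengths); null levels are therefore
band-dependent. Second, changing the background exponent changes the
in-band noise bandwidth and hence this bias, so large aperiodic shifts
leak slightly into measured PLI levels — visible as small significant
delta/theta PLI increases in simulated non-responders. Both are
properties of the PLI estimator itself, not bugs in the generator, and
both vanish for wideband signals.

## Desk-scale problem sizes

Full-scale defaults (61 channels, 1,024 Hz) are used for geometry and
determinism tests. The replicated end-to-end study runs on a reduced but
region-complete configuration chosen as the package's desk-scale standard:
10 channels (2 per region: F3 F4 T7 T8 C3 C4 P3 P4 O1 O2), 256 Hz, 20 ×
8-s epochs, 5 + 5 subjects, 20 seeded replicates. Recovery grids use
512 Hz / 8-s single channels. All generators take explicit seeds; there is
no global random state, and identical configs reproduce identical outputs
bit-for-bit (checksummed in the run manifest).

## Known limitations

* The PLI-level calibration (SNR inversion) targets expected levels only
  approximately; absolute simulated PLI values should not be read as
  calibrated, only their ordering and shift signs.
* EDF export is 16-bit; round-trips are exact only to the quantization
  step. The internal `.npz` store is the lossless path.
* The exact Micromed 61-electrode set is not published; the default
  montage is a standard 61-name 10–10 subset and both the labels and the
  prefix-based region rule are overridable.
* McHugh subclasses and classes III–V are not computable from seizure
  frequency alone and are out of scope; classification stops at R/NR plus
  the I/II frequency buckets.
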