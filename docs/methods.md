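# Methods notes

This note documents the models and procedures `somnostat` implements,
the parameter choices that matter, what the synthetic-data generator does
and does not emulate, and the numerical decisions taken where the design
was genuinely open.  It states no empirical result that the test suite
does not itself compute.

## Slow-wave detection

**Pipeline.** Each channel is demeaned, resampled to 100 Hz
(`scipy.signal.resample_poly`, whose polyphase FIR provides anti-alias
low-passing) and band-passed 0.5–2 Hz with a 4th-order Butterworth
applied forward and backward (`sosfiltfilt`).  Zero-phase filtering
means event times are not shifted by group delay; demeaning first makes
detection exactly invariant to DC offsets (the band-pass removes DC
asymptotically but `filtfilt` edge transients would otherwise depend on
the offset).

**Wave delimitation.** A candidate is a maximal negative excursion of
the filtered trace followed by the next positive excursion — the span
between consecutive descending zero crossings, negative half-wave first.
This ordering matters: slow oscillations begin with the down-state, and
delimiting the other way round would split a wave's trough and peak
across two candidates.  On synthetic flat-zero background (where "zero
crossing" is degenerate) the run-based formulation remains well defined.

**Criteria.** Trough ≤ −32 μV, peak-to-peak ≥ 60 μV, duration within
[0.5, 2.5] s (0.5 s is the period of the 2 Hz band edge; only the upper
bound is an age-adapted choice), trough sample inside an N2 or N3 epoch.
Amplitudes are measured on the filtered trace, the convention the
thresholds were tuned under in the detector lineage.

**SWA summary.** Per subject, the detection counts of C3, C4 and Cz are
summed and log10-transformed (`central_log_sum`); the inclusion rule
requires ≥ 120 detections in Fz *or* Cz (either channel suffices), and a
zero central sum leaves the summary undefined (NaN) with the subject
excluded.

**Filter-choice analysis.** For an *isolated* single-cycle 1 Hz pulse,
any filter genuinely confined to 0.5–2 Hz retains only ~89% of the
trough depth (the ideal brick-wall bound; the Butterworth is within 2%
of it — cascaded high-/low-pass pairs and windowed FIR designs were
measured and are all worse).  This attenuation is a property of
band-limiting a transient, not of the filter order, and it shapes the
synthetic-template decision below.

## Spindle detection

Candidates are maximal runs of the sigma (12–15 Hz) RMS envelope above
mean + 2·SD, both statistics computed per channel over N2+N3 samples
only; runs must last 0.4–2 s and lie in NREM.  The RMS window is 200 ms
with a 1-sample step — the standard choice for sigma envelopes; it
(together with the sigma filter's ~0.3 s ring-down) smears run durations
by roughly 0.1–0.3 s relative to the underlying burst, which is why
duration thresholds apply to envelope runs, not to any notion of "true"
burst length.

Validation applies three conjunctive criteria per candidate:

1. **correlation** — Pearson r ≥ 0.5 between the 1–30 Hz and
   sigma-filtered traces over the event window;
2. **neighbor** — at least one *candidate* (not validated — this keeps
   validation order-independent and the relation symmetric) on an
   adjacent 10-20 channel with nonzero temporal overlap, using a shipped
   symmetric adjacency table;
3. **sigma power** — ≥ 5% of the 1–30 Hz periodogram power of the
   window inside 12–15 Hz.

Criterion 3 is not redundant with criterion 1: a strong narrowband
artifact just below the band edge (e.g. 11.5 Hz) leaks through the sigma
filter's skirt and *correlates* well with the broadband trace while
carrying no true sigma power — exactly the global-power artifact class
the criterion exists to reject.  Conversely, for additive independent
components the correlation is approximately the square root of the
relative power, so the two criteria bind in different regimes.

The 2-SD threshold is read as mean + 2·SD of the envelope (the phrasing
"2 standard deviations of the RMS" is ambiguous; mean-anchored
thresholds are the norm and an absolute 2·SD threshold would sit *below*
the mean for heavy-tailed envelopes).

## Event QC

Every event is scored on (frequency, p2p amplitude, duration) by an
isolation forest (100 trees, features standardized to unit variance);
exactly `ceil(contamination · n)` events with the lowest
`score_samples` values are flagged and excluded from all counts.  The
contamination default is 0.025 — the removed fraction is not an
externally fixed quantity, so it is configurable and recorded in the run
manifest.  Rows are canonically sorted by their feature triple before
scoring so flags are invariant to arrival order; a fixed seed makes the
procedure fully deterministic.

## Atrophy scoring

Normalized ROI value = 100 × raw volume / TIV; the ×100 scale puts
values on the conventional percent-of-TIV magnitude (bilateral amygdala
≈ 0.19).  "Bilateral" columns are left+right *sums* (declared in the
column spec).  The composite anxiety-sensitive score is the sum over
bilateral amygdala, left insula, bilateral putamen, posterior cingulate
and left parahippocampal cortex; higher = more preserved volume.
Network-level scores accept any user-supplied parcellation mapping and
use identical arithmetic.

Exclusion is a single pass: mean and sample SD (ddof = 1) are computed
once over the full submitted sample and subjects strictly below
mean − 2.5·SD are dropped.  A consequence worth knowing: because the
outlier inflates the full-sample SD, an outlier must sit well below
mean − 3 SD *of the remaining subjects* before the rule fires (a 3-SD
construction only reaches z ≈ −2.0 on the full sample).

## Statistics

* **Overnight anxiety change** = post-sleep STAI state score − mean of
  the two pre-sleep scores.  Positive change = anxiety rose overnight.
  This convention is stated everywhere it appears because the reverse
  reading ("pre − post") is equally natural linguistically; all signs in
  the package follow the declared convention.
* **Correlations** (Pearson or Spearman) carry Fisher-z 95% CIs
  (`tanh(arctanh r ± 1.96/√(n−3))`).
* **OLS** via statsmodels with t-based per-coefficient CIs and p-values;
  the default covariate set is (age, gender, trait anxiety), extensible
  with macro sleep features.  Rank deficiency raises with the collinear
  columns named.
* **BH-FDR** via statsmodels `fdr_bh`; a brute-force step-up
  enumeration serves as the independent oracle in tests.
* **Mediation** is the product-of-coefficients form: fit
  `M ~ X + covariates` and `Y ~ X + M + covariates` by least squares;
  indirect = a·b.  For linear models this equals the average causal
  mediation effect, so a quasi-Bayesian engine is deliberately not
  reimplemented.  The nonparametric subject-level bootstrap (default
  1000 resamples) yields the 2.5th/97.5th-percentile CI; significance =
  CI entirely above or below zero; the bootstrap p-value is
  2·min(frac ≤ 0, frac ≥ 0).  Bootstrap fits are batched (normal
  equations solved per resample in one einsum/solve), with a pseudoinverse
  fallback for singular resamples.  The identity total = c′ + a·b holds
  exactly on the fitted sample and is asserted in tests at 1e-8.
* **Degenerate mediation inputs**: a mediator exactly linear in the
  exposure makes the outcome design rank-deficient and is rejected — a
  "noise-free" mediation dataset is only well-posed if the mediator
  carries some variation independent of the exposure.
* Skewed variables are log-transformed only through an explicit
  `log_transform` call that records what it touched.

## Synthetic data: what it emulates, what it does not

**Hypnogram.** Per-stage totals are the stated quantities (they match
requests within ±1 epoch, i.e. rounding of minutes×2); sequencing is an
alternating W→N1→N2→N3→N2→REM bout model with seeded bout lengths —
cosmetic realism only, no circadian or ultradian fidelity is claimed.

**EEG.** 19-channel 10-20 montage at 400 Hz, pink (1/f) background at
σ = 10 μV by default (matching the EEG spectral shape so detector
thresholds are stressed realistically), with planted events and an exact
ground-truth ledger.  The canonical slow-wave template is an
*asymmetric* biphasic wave: down-state trough of 2/3 p2p followed by an
up-state peak of 1/3 p2p (half-sine lobes; trough exactly at a quarter
period).  The asymmetry is forced by the detector's own threshold pair —
at p2p = 60 μV a symmetric wave has a 30 μV trough and could never meet
the 32 μV trough criterion — and matches the down-state dominance of
real slow oscillations.  It also interacts with the filter analysis
above: a symmetric template loses enough trough depth under any faithful
0.5–2 Hz filter that planted-wave recall is capped near 0.89, whereas
the physiological template leaves a comfortable margin.  Spindles are
Hann-windowed sigma sinusoids.  Not emulated: K-complexes, artifacts,
ECG bleed, channel-specific spectra, topographic gradients — so green
detector tests establish threshold logic and robustness to 1/f noise,
not performance on clinical recordings.

**Cohort.** Linear-Gaussian mediation with atrophy as exposure, log SWA
as mediator, anxiety change as outcome, plus age/gender/trait-anxiety
covariate effects.  Marginals default to the magnitudes a cohort of
cognitively healthy adults over 65 shows (age 74.57 ± 5.6 y, trait
anxiety 28.61 ± 5.7, composite atrophy 1.67 ± 0.15, log SWA centred on
2.3); the path defaults are the full-mediation configuration
(a = 0.75, b = −9.12, c′ = 0) with covariate effects of the magnitude
multiple-regression covariate tables report for such cohorts.  Residual
SDs default to 0.2 (mediator, log10 units) and 4.0 (outcome, STAI
points) — chosen so that bivariate correlations land in the
|r| ≈ 0.3–0.5 range typical of this literature.  At that realistic noise
level a single n ≈ 60 study detects the mediation in only ~80% of
seeds; the end-to-end replication test therefore uses a deliberately
well-powered variant (residual SDs 0.15/1.5, fixed a priori by power
analysis) because it asserts a ≥ 90%-of-replicates property, not a
claim about typical field power.  Pre/post STAI scores are
reconstructed from a trait-anchored evening level so that
post − mean(pre) reproduces the generated change exactly; evening
levels are clipped to keep all scores inside the 20–80 instrument range.

**Volume tables.** Per-subject raw ROI volumes and TIVs are generated
so that re-scoring reproduces the composite exactly (composite split by
the canonical ROI magnitude profile); they exercise the scoring
arithmetic, not anatomical covariance between regions.

## Pipeline execution modes

`run_pipeline` defaults to *summary mode*: the cohort mediator comes
from the generative model, which keeps a full study (simulate → score →
exclude → correlate → regress → mediate) under a second and makes
many-replicate properties testable.  Setting `eeg_subjects > 0` adds a
*signal mode* demo: short staged recordings with a planted slow-wave
load proportional to each subject's mediator are synthesized, detected,
QC'd and summarised, exercising the entire signal path end to end.
Signal-level simulation of a full 61-subject × 8-h cohort is
deliberately out of budget.  Re-running an identical config reproduces
every output byte-identically; the manifest records the package
version, all parameters and all seeds.

## Known limitations

* The EDF codec handles the plain 16-bit EDF subset this pipeline
  writes (equal rates, one-second records); EDF+ annotations and
  vendor formats are out of scope.
* Spindle frequency is estimated from zero crossings of the sigma trace
  over the event window — adequate for QC features, not for slow/fast
  spindle subclassification (out of scope).
* The mediation bootstrap resamples subjects i.i.d.; no sensitivity
  analysis for sequential ignorability is provided, and the computed
  quantities are associations under the stated model, not causal
  claims.
* The exclusion and inclusion rules are single-pass by design;
  iterating them would change the operating characteristics.
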