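# Methods

This note documents the models, conventions and numerical choices behind
flyclock, in the spirit of a statistics package's methods appendix. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Activity records and time conventions

A DAM monitor file holds per-minute beam-break counts for up to 32 flies
(tab-delimited: reading index, `dd mmm yy` date, `HH:MM:SS` time, a status
code, six metadata columns, 32 counts). Only this dialect is parsed; other
layouts are rejected with a line-numbered error rather than guessed at.
Bins are half-open `[t, t + width)` and timestamped by their start. ZT0 is
lights-on; in constant darkness CT0 is the projection of the prior lights-on
time, the only convention supported, and day boundaries sit at phase 0.
Rows with a non-1 status code are treated as monitor dropouts: counts are
zeroed and the bin flagged rather than dropped, because the periodograms
assume evenly spaced samples. Re-binning (1 → 15 → 60 min) sums counts and
conserves totals exactly over complete bins; a trailing partial bin is
dropped and logged.

## Synthetic cohorts

The generator emulates the features of a fly activity record the analyses
rely on, not fly physiology. Expected rate per minute:

    lambda(t) = baseline * [1 + A * template(phi) + ramp(phi)] * (1 - d)^day

where `phi` is the fly's internal circadian hour — the entrained 24 h clock
on LD days, advancing at `24/tau` per hour after release into DD. The
template is two raised-cosine bumps (default half-width 4 h) at the morning
(CT 0) and evening (CT 12) peaks. The morning bump is down-weighted
(default 0.5) to give the evening-dominant profile typical of free-running
flies; a perfectly symmetric bimodal profile has no 24 h Fourier component
at all (the two peaks cancel), which would make the Lomb–Scargle statistic
blind to it in the 18–30 h band — an instructive degeneracy, not a realistic
one. Anticipation ramps rise linearly from 0 to `ramp_gain` over the 3 h
before the projected transition (internal hours 21–24 morning, 9–12
evening), which makes ramped cohorts exceed MAI/EAI 0.5 by construction.
Counts are Poisson per minute (beam breaks are sparse counts); a
negative-binomial dispersion knob exists but defaults off. Damping
multiplies the whole rate, baseline included. `baseline_rate` defaults to
0.6 counts/min (~900–2000 beam breaks/day after modulation, a realistic
magnitude for a healthy fly); no per-fly activity magnitudes are published
for the motivating experiments, so this is a free calibration constant.
Per-fly seeds are spawned from `(master_seed, fly_index)`, so a fly's record
does not depend on cohort size, and every generator is a pure function of
its seed.

What the generator does *not* emulate: sleep-bout structure, startle
responses at transitions, inter-fly activity-level heterogeneity beyond
period/phase jitter, and death during the recording. Passing tests
therefore demonstrate correctness of the analysis chain under the stated
count model, not robustness to every pathology of real recordings.

## Periodograms

Candidate periods are integer multiples of the bin width in 18–30 h (0.25 h
steps at 15-min bins); Lomb–Scargle is evaluated on the same grid for
comparability. The Lomb–Scargle statistic is the classical Scargle
normalized periodogram with the time-offset `tau`; normalization is by the
sample variance (ddof = 1), so the power at a period equals the
least-squares sine+cosine fit's reduction in sum of squares divided by
`2 * variance` — an identity the tests verify to 1e-8 against an
independent least-squares oracle. The significance line uses the
independent-frequency approximation `-ln(1 - (1 - alpha)^(1/M))`, constant
across periods. The chi-square periodogram follows Sokolove–Bushell with
`K = floor(N/P)` complete cycles retained (the trailing partial cycle is
discarded; the original formulation is ambiguous on this), the grand mean
and variance computed over the retained bins, and a `chi2(P-1)` threshold.
No detrending is applied by default (DD counts are treated as stationary).
Both statistics are scale-invariant; constant series raise an error rather
than returning 0/0.

## Rhythmicity classification

The gate is Lomb–Scargle peak minus its threshold line, compared to a delta
threshold; the reported period comes from the chi-square peak (the
conventional period readout), and rhythm power is the chi-square peak minus
its threshold, floored at zero for reporting with the raw value retained.
The classic fixed delta cutoff of 150 belongs to a commercial
implementation's unnormalized statistic scale; under this package's
normalization the meaningful analogue is the 99.9th percentile of the null
distribution, which `calibrate_delta_threshold` estimates from a seeded
arrhythmic cohort (default 300–500 flies). 150 is retained as the
documented historical default, not as a claim of numeric identity with the
commercial output. "Weakly rhythmic" was originally a blinded human
judgment of actograms; the automated proxy here — deltas within
`(threshold, threshold + 2*threshold]` — is explicitly labeled as such,
and the reporting rule folds a weak class under 10% of the cohort into
"rhythmic". Sustained rhythmicity over a ≥8-day DD window splits the
window in half and requires both halves to classify rhythmic with periods
agreeing within 1 h; the halves are classified with the minimum-duration
guard relaxed to the half length.

## Anticipation indices

Sums of beam breaks over whole hourly bins: MAI = hours 21–23 over 18–23
before lights-on, EAI = hours 9–11 over 6–11 before lights-off (the
"average hourly activity" and "summed beam breaks" formulations are
identical for equal window sizes; sums are implemented). Multi-day spans
(e.g. DD days 3–9) sum counts across days before dividing, which is robust
to a near-empty day; mean-of-daily-indices is available by flag. A span
whose 6-h denominator is zero leaves the index undefined — the fly is
flagged, logged and excluded listwise from group statistics, a policy choice
(the motivating protocol does not state one).

## JTK

Reference patterns are dense rank vectors of `cos(2*pi*(t - lag)/period)`
over the sample times (rounded to 9 decimals before ranking so analytic
ties are tied), deduplicated across the default grid of periods
{20, 24, 28} h and 4-h lags. Sample times one full cycle apart (CT 1 and
CT 25) are retained as distinct samples whose phases tie at period 24 —
this deliberately shapes the reference tie structure. Kendall's S uses
standard tie handling (tied pairs contribute zero); tau uses the tau-b
denominator `sqrt((n0 - Tx)(n0 - Ty))`, the maximal attainable |S| given
both tie structures. The exact null of S against a tied reference is
computed by dynamic programming: S = 2J − (number of untied reference
pairs), where J's generating function is the Gaussian multinomial over the
reference tie-group sizes, evaluated with exact integer convolution (the
28-value design yields polynomial degrees of a few hundred). Data ties are
assumed absent under the null, as in the published procedure. The best
alternative maximizes |tau|, breaking ties by smaller exact p, then the
positively-correlated member of an antiphase pair, then the earlier lag;
p is two-sided on |S| and Bonferroni-adjusted over the distinct patterns.

## qPCR

Ordinary least squares of Ct on log10(relative template); efficiency
`10^(-1/slope) - 1` reported as a fraction (1.0 = 100%), with the per-cycle
amplification factor also exposed. Replicate Cts at a dilution are averaged
before regression by default (per-replicate mode by flag). Slopes ≥ 0 are
rejected as non-amplifying. Quantification inverts the fitted line;
normalization is a plain ratio to the reference gene, so global rescaling of
both cancels.

## Image quantification

Segmentation is out of scope: masks are inputs. Net intensity is the mask's
pixel mean minus the background ROI mean; adding a constant to every pixel
cancels exactly. The default background ROI is the complement of the masks
dilated by 3 px — chosen over a "largest empty rectangle" because it uses
far more pixels (smaller background standard error) while the dilation
keeps nucleus edges out. Negative net intensities are retained in raw
output and floored only in display tables, mirroring the rhythm-power
philosophy. Brains, not nuclei, are the unit passed to group statistics.

## Group statistics

Kruskal–Wallis (scipy, tie-corrected) with Dunn's post-hoc implemented
directly: z-tests on mean ranks with pooled variance
`N(N+1)/12 - sum(t^3 - t)/(12(N-1))`, two-sided normal p-values,
Bonferroni-adjusted over all pairs (Holm available). One-way ANOVA uses
scipy's F test and Tukey HSD. The normality screen (Shapiro–Wilk per
group) is advisory only; configured per-figure choices win.

## Problem sizes and determinism

The acceptance script and tests use the design sizes of the motivating
protocol where they are stated — cohorts of 32 flies, 9 DD days at 15-min
bins, 1000-fly null cohorts, 1000-replicate type-I simulations, the
7-timepoint × 4-replicate expression design — and smaller cohorts (6–16
flies) in unit tests where only structure is being checked. Every stochastic
stage takes an explicit seed; the pipeline's outputs are byte-identical
across reruns with the same master seed (fixed float formatting, sorted JSON
keys).

## Known limitations

- The chi-square peak is taken as the maximum of `Q_P`, not of
  `Q_P - threshold`; under the null this biases the nominal "period" toward
  the long end of the grid, which is why periods are only reported for
  rhythmic flies.
- The Lomb–Scargle significance line uses the independent-frequency
  approximation; neighboring candidate periods are correlated, so the line
  is conservative at fine grids.
- The exact-null DP scales with the product of reference tie-group sizes
  and is intended for designs of tens of samples, not hundreds.
- LD-day rhythmicity is deliberately not scored (light-driven activity masks
  the endogenous rhythm); anticipation indices are the LD-day readout.
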