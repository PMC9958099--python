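# Methods

This document records the exact conventions implemented in `turntap`: what
each operation computes, the defaults and why, and what the simulator does
and does not emulate.

## 1. Input and trial structure

A trial is 16 tap onsets (15 ITIs) of a pentatonic 16-note melody at a cued
500 ms inter-onset target. Tasks: `Individual` (one performer taps the whole
melody) and `Joint` (partners alternate in `AB` or `AABB` turn schedules on a
single merged stream). Metadata per trial: pair, subject (solo only), task,
block (1-4), trial index (1-9), sequence predictability (`Predictable` /
`Random`), turn pattern, starting performer, and an online-flag bit.

MIDI input: note-on events with velocity > 0 only; channels map to performers
via an explicit 1-based channel map; onset times come from a tempo-map walk
(SMPTE division unsupported). The TSV fixture format is lossless: onset times
are written with `repr()` (shortest round-tripping decimal) and read with
`float_precision="round_trip"`.

## 2. Preprocessing

- **ITIs** are successive onset differences; each ITI is labelled with its
  producing performer(s) (`A`, `B`, or `AB` for a between-turn interval).
- **Trial exclusion**: a joint trial is excluded when its performer sequence
  deviates from the scheduled turn template (first deviating tap index is
  reported), or when it was flagged online. Exclusion happens before any
  other processing.
- **Outlier flagging**: an ITI is an outlier when
  `|x - median| > 3 * 1.4826 * MAD` (strict inequality), with the median and
  MAD pooled per unit x task across all of that unit's blocks and trials
  (unit = subject for solo, pair for joint). Pools smaller than 3 values are
  an error. Flagged ITIs are set to NaN for accuracy and CV but *retained*
  for autocorrelations and ITI contrasts, which require unbroken series.
- **Detrending** (autocorrelation only): ordinary least-squares line removal
  per trial.

## 3. Dependent measures

- **Accuracy**: mean of `|500 - ITI| / 500 * 100` over non-missing ITIs
  (lower = more accurate).
- **Precision**: coefficient of variation, sample SD (ddof=1) / mean.
- **Autocorrelation**: biased sample estimator on the detrended, mean-removed
  series, `r_k = sum(x_t x_{t+k}) / sum(x_t^2)`, reported at lags 1, 2, 4.
  The biased form keeps every `r_k` in [-1, 1]; for a strictly alternating
  series of length N it gives `r_1 = -(N-1)/N`. A numerically constant
  series returns 0 at all lags rather than correlating round-off noise.
- **ITI contrasts**: with `d_k = ITI_{k+1} - ITI_k`, the first contrast
  position is 1 by definition; later positions are 1 if `d_k` has the same
  sign as the trial's reference direction (the first nonzero `d`), 0 if
  opposite, 0.5 if `|d_k| < 0.5 ms` (tie at measurement resolution).
  Profiles average contrasts per position over trials; the rhythmicity
  exemplar is `[1, 0, 1, 0, ...]` and the profile distance is the mean
  Manhattan (absolute) deviation from it. Reported profiles start at
  position 2 because position 1 is constant by construction.
- **Aggregation** to the analysis table is two-stage: trial values are
  averaged within subject x task x block, then solo partners are averaged
  within pair, giving one value per pair x task x block (x lag for acf).
  Empty cells are an error naming the cell.

## 4. Inference

- **Mixed factorial ANOVA** for balanced complete designs with any number of
  within-unit factors and at most one between-unit factor. Implementation:
  orthonormal Kronecker contrast transforms per within-effect subset; sums
  of squares are Type III (equal to Type I under balance; mild imbalance in
  the between factor is handled with unweighted means and harmonic-mean n).
- **Sphericity**: Greenhouse-Geisser epsilon from the pooled within-group
  covariance of the contrast scores, `eps = (tr S)^2 / (d tr S^2)`, clamped
  to [1/d, 1], *always applied* (dfs are multiplied by eps before the F
  tail probability). Pooling the covariance within groups follows the
  afex/SPSS convention for mixed designs.
- **Effect size**: generalized eta squared,
  `ges = SS_effect / (SS_effect + sum of all error SS in the design)`.
- **Linear block contrasts**: weights (-3, -1, 1, 3) over blocks per unit,
  tested with a one-sample t; the contrast-of-contrasts is the paired t on
  per-unit (Individual - Joint) linear scores, so a steeper Joint decline
  yields a positive t.
- **Tukey pairwise**: paired mean differences tested against the
  studentized-range distribution (`p = sf(|t| sqrt(2), k, df)`); with k = 2
  levels this reduces exactly to the paired t-test.
- **Within-subject CIs**: Cousineau-centred cell scores with the Morey
  `sqrt(J/(J-1))` correction, t-based 95% half-widths.

### Null calibration

The GG-always-applied convention is intrinsically conservative for multi-df
effects at small sample sizes (measured type-I rates 0.028-0.037 at 12
units). The calibration test in `tests/test_acceptance.py` therefore runs at
48 units (2x4 within design, non-spherical errors, 2000 replicates), where
every effect's rejection rate at alpha = .05 falls inside the 99% binomial
interval [0.0374, 0.0626]. This regime was fixed from a standalone N-sweep
before the test was written.

## 5. Simulator

### Model

Tap onsets follow the two-level timing model with first-order phase
correction on the produced stream:

```
ITI_k = T_k + M_{k+1} - M_k - alpha * (ITI_{k-1} - 500) + drift * k
```

`T_k ~ N(mu, sigma_t^2)` is drawn from the timekeeper of the performer
producing tap k+1; `M` are the motor delays of each tap's own performer.
Joint trials run this recurrence on the merged stream under the turn
schedule; between-turn intervals get a fixed transition offset. Hesitation
outliers add a one-off delay to a single timekeeper interval.

### Defaults and rationale

| parameter             | default | rationale |
|-----------------------|---------|-----------|
| `sigma_t_ms`          | 20      | ~4% of target, typical paced-tapping variability |
| `sigma_m_ms`          | 10      | motor noise half the central noise, gives the classic mild negative lag-1 solo acf (-sigma_m^2 / (sigma_t^2 + 2 sigma_m^2) = -1/6) |
| `alpha`               | 0.15    | weak-to-moderate phase correction; keeps solo series stationary around the target |
| `drift_ms_per_tap`    | 0.3     | small linear drift so per-trial detrending has observable work to do |
| `tempo_sd_ms`         | 25      | between-subject spread of natural tempo (5% of target); partner tempo mismatch is the mechanism that generates joint rhythmicity, and 25 ms produces robust rather than knife-edge AB/AABB signatures |
| `transition_offset_ms`| 10      | handing over a turn takes slightly longer than continuing |
| `learning_schedule`   | (1.0, 0.9, 0.8, 0.7) | noise and tempo mismatch shrink across blocks (learning) |
| `outlier_rate/shift`  | 0.02 / 250 | rare hesitations, large enough to trip the 3-MAD rule |

Per pair, each partner's `mu` is drawn as `500 + N(0, tempo_sd_ms)`; the
starting performer alternates across blocks; study profiles are
`study1` (AB, half the pairs Predictable) and `study2` (AABB, Random only).
Identical config including seed reproduces the dataset byte-for-byte. A
plant manifest records deliberately injected turn violations and outlier
intervals for pipeline-recovery testing.

### What the generator emulates — and does not

Emulated: solo two-level timing moments, joint alternation (negative lag-1
acf under AB), period-4 structure (positive lag-4 under AABB), learning
(declining inaccuracy/CV across blocks with near-linear trend), hesitation
outliers, turn-taking errors, online-flagged trials.

Not emulated / known limitations:

- Under the AB profile the *joint* lag-2 and lag-4 autocorrelations come out
  positive (persistent short-long alternation from a fixed tempo mismatch
  also feeds even lags), whereas empirically they are typically near zero.
  The mechanism is deliberate and minimal; matching empirical cell means is
  not a goal of the generator.
- No pitch-error or velocity dynamics; velocities are uniform random.
- Phase correction is first-order toward the cue only (no period
  correction, no mutual prediction/anticipation).
- Predictable vs Random sequences have no effect on simulated timing; the
  factor exists so the between-factor analysis path is exercised under a
  true null.

## 6. Stimulus sequences

Predictable: a fixed 16-note pentatonic melody and its retrograde. Random:
uniform draws over the 5 scale degrees, pruned of sequences with an
immediate repeat or incomplete coverage of the five degrees (and of the two
predictable melodies). The survivor probability has the closed form

```
sum_{j=1..5} (-1)^(5-j) C(5,j) j (j-1)^15 / 5^16  ≈ 0.0333
```

which the generator's empirical survival rate matches within binomial error.

## 7. Numerical conventions worth knowing

- MAD flagging uses strict `>`, scale factor 1.4826, and is invariant under
  positive rescaling.
- `wk_estimate_pooled` centres on the grand mean across trials, not
  per-trial means: per-trial centring biases the lag-1 autocovariance by
  O(1/n) at 15 intervals per trial, which is large enough to break 10%
  parameter recovery.
- Acceptance target t1 (the alternating-series `|r_1|` limit) is computed by
  Richardson extrapolation `2 r_{2N} - r_N`, which cancels the O(1/N) bias
  of `r_N = -(N-1)/N` exactly.
- ANOVA p-values use GG-adjusted dfs in `scipy.stats.f.sf`; reported dfs in
  tables/reports are the adjusted ones, with raw dfs retained alongside.
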