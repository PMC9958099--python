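# turntap

Analysis pipeline for dyadic turn-taking finger tapping.

Two people alternate producing a 16-note melody at a cued 500 ms pace, either
note-by-note (A-B) or in two-note turns (A-A-B-B), and each partner also taps
the whole melody alone. The scientific questions are how accurate, stable, and
*rhythmic* the merged tap stream is: does handing the melody back and forth
leave a periodic fingerprint in the inter-tap intervals (ITIs)? This package
implements the full analysis chain for that design plus a generative model of
the task for validation:

- **io** — keystroke input from standard MIDI files (hand-rolled SMF reader,
  tempo-map aware) or a lossless TSV fixture format.
- **preprocess** — ITI computation with performer resolution, turn-pattern
  trial exclusion, pooled 3-scaled-MAD outlier flagging, linear detrending.
- **metrics** — ITI accuracy (% deviation from 500 ms), precision (CV),
  lag-1/2/4 autocorrelations of detrended ITIs, and ITI-contrast profiles
  with Manhattan distance to the perfect-alternation exemplar.
- **stats** — balanced mixed factorial ANOVA (Type-III SS, Greenhouse-Geisser
  correction, generalized eta squared), linear block contrasts and their
  task difference, Tukey-corrected pairwise comparisons, within-subject CIs.
- **simulate** — a two-level timekeeper-plus-motor dyad model with phase
  correction, partner tempo mismatch, learning across blocks, hesitation
  outliers, and the pentatonic stimulus-sequence generator.
- **cli** — `turntap simulate | analyze | report`.

## Model in one paragraph

Each performer has a central timekeeper (intervals `N(mu, sigma_t^2)`) and a
peripheral motor delay (`N(0, sigma_m^2)`) with first-order phase correction
toward the cued 500 ms target. Solo, this predicts ITI variance
`sigma_t^2 + 2 sigma_m^2` and lag-1 autocovariance `-sigma_m^2` (mildly
negative lag-1 autocorrelation). Jointly, the same recurrence runs on the
merged tap stream, so a tempo mismatch between partners (`mu_A != mu_B`)
produces short-long alternation under A-B turn taking (strongly negative lag-1
autocorrelation) and a period-4 pattern under A-A-B-B (positive lag-4) — the
rhythmicity signatures of turn taking.

## Worked example

```bash
turntap simulate --study study1 --seed 0 --out results/study1
turntap analyze  --in results/study1 --out results/study1
turntap report   --in results/study1
```

or equivalently via the numbered drivers:

```bash
python analysis/01_simulate.py --seed 0   # both study profiles
python analysis/02_preprocess.py
python analysis/03_measures.py
python analysis/04_inference.py
```

With seed 0 the study-1 profile (12 pairs, A-B turns) gives grand means of

| measure        | Individual | Joint   |
|----------------|-----------:|--------:|
| accuracy (%)   |     4.879  |  5.423  |
| CV             |     0.044  |  0.055  |
| lag-1 acf      |    -0.322  | -0.448  |
| lag-4 acf      |    -0.042  |  0.139  |

and the inference layer reports, e.g., a task difference in CV
(`F(1, 10) = 11.10, p = .0076, ges = .29`), a strong block (learning) effect
on accuracy (`F(1.57, 15.70) = 57.90, p < .0001` after Greenhouse-Geisser
correction), a task-by-lag interaction in the autocorrelation ANOVA
(`F(1.02, 10.25) = 15.42, p = .0026`), and significant linear declines in
both accuracy and CV across blocks. The study-2 profile (A-A-B-B) moves the
joint rhythmicity from lag 1 to lag 4 (joint lag-4 acf `+0.122` vs individual
`-0.040` at seed 0).

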