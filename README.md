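# critsort

Tools for studying how response-criterion placement confounds post-hoc-sorted
neural measures. The package combines:

- **`critsort.sdt`** — closed-form equal-variance signal-detection
  primitives: d′/criterion estimation from hit and false-alarm rates
  (with a log-linear correction for extreme rates), the analytic
  AUC = Φ(d/√2) transform, tail-stable truncated-normal means, paired
  Hedges g, and analytic expectations for post-hoc-sorted AUC.
- **`critsort.simulator`** — Monte-Carlo criterion-shift scenarios:
  draw noise/signal internal-signal strengths, apply liberal vs
  conservative criteria, sort trials post hoc by response, and tabulate
  the sorted mean differences as AUC. Ships scenario presets
  (`fig1b`, `fig4c_low_sens`, `fig4d_high_sens`,
  `fig4e_conservative_overall`, `fig4f_liberal_overall`) that reproduce
  the qualitative orderings of the corresponding published panels; the
  preset parameters are documented reconstructions, not the original
  settings.
- **`critsort.synth`** — synthetic epoched-EEG cohorts. Each trial's
  latent SDT strength drives both the observer's response (criterion
  binning; yes/no or 4-level ratings) and, via per-component coupling
  coefficients, the amplitude of Gaussian-kernel components (defaults at
  137/266/430 ms) mixed through subject-jittered spatial patterns plus
  spatially correlated noise. HDF5 round-trip I/O included.
- **`critsort.decoding`** — per-timepoint shrinkage LDA with
  leave-one-subject-out transfer (train on every subject, test on every
  other, average AUC series per test subject), stimulus–response trial
  balancing between conditions, post-hoc sorting into response cells,
  rank-based AUC, peak finding, Haufe-style forward-transformed
  activation patterns, and conservative-vs-liberal contrasts with
  one-sided paired t-tests.
- **`critsort.behavior`** — behavioural summaries from canonical trial
  tables (subject, condition, stimulus, response): hit/FA rates,
  per-rating-level distributions, per-subject c and d′, group
  aggregates, and paired effect sizes.

## A note on the sorted-AUC construct

The post-hoc-sorted contrast can be referenced three ways, selected by
the `baseline` argument: `cell` (signal minus noise trials *within* the
response cell), `signal_vs_noise` (sorted signal trials against the full
noise distribution), and `pooled_vs_noise` (the sorted cell's pooled
mean against the noise mean). The within-cell contrast *decreases* in
the seen cell as the criterion moves rightward; only the `*_vs_noise`
constructs produce the joint seen-and-unseen inflation under a
conservative criterion, so scenario presets default to
`pooled_vs_noise`. Analogously, the decoding pipeline's sorted cells
pair response-sorted target trials with the condition's pooled no-target
trials by default (`reference="pooled_noise"`).

## CLI

```bash
# Monte-Carlo scenario -> sorted-AUC table + direction verdict
critsort simulate --scenario fig1b --n 10000 --seed 1 --out table.csv

# synthetic cohort -> per-subject HDF5 + trials.csv
critsort generate --subjects 12 --trials 500 --seed 1 --out cohort/

# leave-one-subject-out decoding with post-hoc sorting and balancing
critsort decode --cohort cohort/ --cells sorted --balance-seed 7 \
    --channels occipitoparietal --out result.h5 --summary-csv peaks.csv

# behavioural SDT summary of a trial table
critsort behavior --table cohort/trials.csv --mode yes_no \
    --correction loglinear --out sdt.csv
```

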