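# tripletseg

Frequency-tagged EEG analysis of statistical word segmentation, exercised
end-to-end on synthetic recordings.

An artificial language of four trisyllabic pseudo-words (syllables at 4 Hz,
words at 1.33 Hz) is concatenated into constrained continuous streams whose
only word-boundary cue is the drop in transitional probability between words.
The package provides:

- **stimuli** — lexicons (three counterbalanced lists), constrained
  structured/random stream generation (no immediate repetition, no repeated
  pairwise alternation, exact word balance, near-uniform transition usage),
  the 16 test triplets (Words / Edge-words / Part-words / Non-words), full
  session schedules (resting state, random streams, one long + eight short
  learning streams, 8 × 16 isolated test words), and transitional-probability
  audits.
- **simulate** — a synthetic 250 Hz multichannel EEG generator: syllable-rate
  steady-state response, a word-rate component that ramps in after a
  configurable amount of structured exposure, condition-dependent ERPs to
  isolated triplets, spatially mixed 1/f background, white sensor noise, and
  high-amplitude artifacts. Deterministic per seed; cohort-level topography
  seed for group analyses.
- **edfio** — EDF signal files with TSV event/montage sidecars (round-trip to
  16-bit quantization; byte-stable events sidecar).
- **preprocess** — zero-phase filtering, polyphase resampling (0.75 s triplet
  = 225 samples at 300 Hz), epoching, peak-to-peak artifact rejection,
  average reference, per-epoch normalization, baseline correction; canonical
  entrainment and ERP pipelines.
- **entrainment** — reshaping into 7.5 s epochs (word and syllable rates on
  exact FFT bins 10 and 30), DSS denoising (30 PCA / 6 DSS components),
  evoked power, inter-trial coherence, SNR scores against a power-law noise
  floor fit on the 12 adjacent bins, per-condition analysis, and the 2 min /
  1.5 s-step sliding learning curve.
- **erp_cluster** — ERP contrasts (ABx vs BCx, heard vs unheard, pairwise)
  and spatio-temporal cluster-based permutation statistics (3 cm electrode
  neighborhoods, alpha 0.05, minimum cluster size 2, 5000 sign-flip
  permutations, exact enumeration option), plus the per-block effect time
  course with the 3-of-8-trial inclusion rule.
- **group_stats** — electrode-wise one-sided t-tests with Benjamini–Hochberg
  FDR, one-way repeated-measures ANOVA with Bonferroni post-hocs.
- **orchestrate / cli** — a reproducible demo-cohort pipeline gluing all of
  the above together.

## CLI

All functionality is reachable through one entry point:

```sh
tripletseg audit --list-id A --duration 180 --seed 0     # stream statistics
tripletseg audit --duration 30 --series 8                # pooled short streams
tripletseg schedule --list-id A --out events.tsv         # full session events
tripletseg simulate --channels 32 --out sub01.edf        # synthetic session
tripletseg preprocess --mode entrainment --in sub01.edf --out epochs.h5
tripletseg entrain --in sub01.edf --condition Structured --out snr.tsv
tripletseg entrain --in sub01.edf --sliding --out curve.tsv
tripletseg erp --in sub01.edf --in sub02.edf --contrast abx-bcx --out clusters.tsv
tripletseg demo --subjects 20 --seed 1 --out report/     # full cohort demo
```

The demo simulates a cohort, runs both analysis arms and writes TSV reports
(per-electrode SNR, FDR-corrected significance tables, condition ANOVA, ERP
clusters, per-block effect time course) plus advisory figures; every table
carries the run's config hash.

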