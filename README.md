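# betarebound

An analysis pipeline for EEG experiments that probe the somatosensory
mapping of speech sounds through the **beta rebound**.  When a body part is
stimulated (here: the lower lip, electrically), central EEG shows a
stereotyped sequence in the sensorimotor rhythms — an event-related
desynchronization (ERD) of the mu (8–12 Hz) and beta (13–30 Hz) bands at
about 200–400 ms, followed by an event-related synchronization (ERS, the
"rebound") from about 500 ms.  If hearing a lip-articulated syllable
(bilabial, e.g. /bi/) recruits the same lip somatosensory cortex, the beta
rebound after lip stimulation should be attenuated for bilabial syllables
but not for tongue-articulated ones (dental, e.g. /di/), specifically over
left central electrodes.  The pipeline quantifies this as the
syllable × stimulation × time-window interaction of a fully within-subject
2 × 2 × 2 ANOVA on band-averaged ERSP values.

The package is aimed at cognitive neurophysiologists who want a tested,
reproducible implementation of this analysis — and at methodologists who
want its statistics (sign-flip permutation maps with FDR, baseline
bootstrap, contrast-based repeated-measures ANOVA) with calibrated error
rates.  Because no public data exist for this paradigm, a synthetic-data
generator is a first-class module: it produces continuous EDF+ recordings
with 1/f background, narrowband mu/beta oscillators carrying the ERD/ERS
dynamics, a left-lateralized condition-specific rebound attenuation, and
EOG saccade responses, so the whole chain is testable end to end.

## The quantities at the core

* **ERSP** (event-related spectral perturbation), from Morlet wavelets with
  cycles rising linearly from 3 at 4 Hz to 20 at 40 Hz (0.5 Hz grid):

  `ERSP(f, t) = 10 log10( mean_k |W_k(f, t)|² / P₀(f) )`,

  with `P₀(f)` the trial- and baseline-averaged power (−1000…−150 ms).
* **Map statistics**: per-point paired t across subjects, null by
  sign-flipping subject difference maps (exact enumeration when feasible),
  Benjamini–Hochberg FDR across the time–frequency grid.
* **Band/window ANOVA**: ERSP averaged over mu/beta × ERD/ERS regions; each
  effect's F is the squared paired t of its ±1 contrast, df (1, n−1);
  Bonferroni-corrected paired-t post-hocs.
* **Behaviour**: saccade detection on the bipolar EOG difference (20 Hz
  low-pass, 1.5 SD threshold, 150 ms anticipation rule) yields response
  side, correctness and reaction time; incorrect/invalid trials are
  discarded before the spectral analysis.

See `docs/methods.md` for the full model, parameter defaults and numerical
choices.

## Worked example

Simulate a 12-subject study at a reduced session size (64 trials per
subject), run the full chain, and read off the beta-band ANOVA:

```python
from betarebound.pipeline import PipelineConfig, run_pipeline
from betarebound.validation import scaled_design_config

cfg = PipelineConfig(design=scaled_design_config(), map_stats=False, seed=7)
res = run_pipeline(cfg, out_dir="results/demo")
print(res["anovas"]["beta"].effects.round(4).to_string(index=False))
print(res["posthocs"]["beta"].round(4).to_string(index=False))
```

```
                     effect        F  df1  df2      p
                   syllable  34.2322    1   11 0.0001
                stimulation   1.0180    1   11 0.3347
                     window 203.8388    1   11 0.0000
       syllable*stimulation  19.4520    1   11 0.0010
            syllable*window  23.3900    1   11 0.0005
         stimulation*window 258.6352    1   11 0.0000
syllable*stimulation*window  42.3144    1   11 0.0000

               comparison      t  df     p  alpha_adj  significant
  dental_vs_bilabial_stim 7.1152  11 0.000      0.025         True
dental_vs_bilabial_nostim 0.1844  11 0.857      0.025        False
```

Reading the output: the strong `window` and `stimulation*window` effects
are the ERD/ERS time course and its amplification by stimulation; the
significant three-way interaction `syllable*stimulation*window`
(F(1, 11) = 42.3) is the headline effect — the syllable difference exists
only in the rebound window and only with lip stimulation — and the
post-hocs confirm that dental and bilabial syllables differ on stimulation
trials (t(11) = 7.12, p < .001) but not without stimulation (p = .857),
exactly the injected structure.  13.5 % of trials were discarded for
incorrect or undetectable saccade responses.  `run_pipeline` also writes
group ERSP maps (TSV), FDR-corrected significance masks, the band/window
table, the reaction-time ANOVA and a manifest that makes the run
bit-for-bit reproducible.

A command-line interface mirrors the stages
(`betarebound simulate | preprocess | score-behavior | ersp | stats |
run-all`, each with `--config`, `--seed`, `--out-dir`), reading and
writing EDF+/BrainVision recordings, FIF epochs and CSV/TSV/JSON tables.

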