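# pupilsync

Does synchronizing to a simple beat and synchronizing with another mind
reflect one underlying tendency?  `pupilsync` implements the full analysis
chain for testing that question with pupillometry: a rhythmic auditory
oddball task in which the pupil entrains to the stimulus train, and a
story-listening task in which a listener's pupil synchronizes with a
storyteller's.  Because no raw data ship with the package, a first-class
synthetic-data module simulates every input — tone schedules, blinky pupil
traces with known entrained oscillations, signal-detection button presses,
and speaker–listener dyads with a controllable latent-attention coupling —
so each stage is verifiable against ground truth.

The package is aimed at psychophysiologists who want a tested, scriptable
pipeline for pupillary entrainment and interpersonal synchrony analyses,
and at methodologists who want calibrated resampling inference for them.

## What it computes

**Entrainment synchrony.** Tones arrive every 1200 ms (0.83 Hz) and every
fourth beat (4800 ms, 0.21 Hz) carries a quiet target or a silent omission.
Each task block's pupil trace is blink-interpolated, demeaned,
Hamming-windowed and periodogram-transformed; power is z-scored across
frequency bins and averaged within the beat band (0.8–0.9 Hz) and the
fourth-beat band (0.2–0.3 Hz):

    score = mean over blocks of (z_ISI + z_TSI)

**Task performance.** Sensitivity is `d' = Z(H/n_targets) − Z(FA/n_distractors)`
with the log-linear correction for extreme rates.

**Dyadic pupillary synchrony.** The 120 Hz speaker trace is decimated to the
listener's 30 Hz; 3 s windows with 1.5 s overlap are compared by a
segment-level dynamic-time-warping cost (minimal accumulated cosine distance
over an alignment path, verified against exhaustive path enumeration),
averaged into 6 s bins and log-transformed; a story's synchrony is
`−mean(log(cost + ε))`, so larger means more synchronous.

**Inference.** OLS links d′ to the entrainment score; a linear mixed model
with crossed random intercepts for participant and story links story-level
synchrony to entrainment; and a participant-level permutation test
(scores shuffled across participants, model refit per shuffle,
`p = (1 + #{|β*| ≥ |β|}) / (n_perm + 1)`) provides a distribution-free check.

## Worked example

The numbered scripts under `analysis/` run a 12-participant demo cohort in
which one latent "tendency to synchronize" drives each subject's
entrainment gain, oddball sensitivity and coupling to the storyteller.
Running them in order (`python analysis/01_simulate_cohort.py` … `07_inference.py`)
writes tables under `results/` and prints, among others:

```
Spearman(true gain, session score) = 0.951 over 12 participants
mean |recovered d' - true d'| = 0.090
           measure      statistic      U        p         d
     target_curves      pearson_r 2191.0 0.024910  0.664511
entrainment_scores abs_difference  789.0 0.003303 -0.864787
                   model   beta     se      t   df      p  adj_r2  p_perm
   dprime_on_entrainment 0.9212 0.1230 7.4883 10.0 0.0000  0.8335     NaN
synchrony_on_entrainment 0.3989 0.0932 4.2820 10.0 0.0016     NaN     NaN
   synchrony_permutation 0.3989 0.1039 3.8384 10.0 0.0010     NaN   0.001
```

Reading those numbers: the periodogram score ranks the cohort's true
entrainment gains almost perfectly; d′ comes back within ±0.1 of its
generative value; target-tone response curves and entrainment scores are
both more similar within a participant than between participants (positive
d for correlations, negative d for difference scores); and the mixed-model
effect of entrainment on dyadic synchrony (β = 0.40) lands outside all 1000
permutations (p = 1/1001).

A YAML-configured end-to-end run of the same stages is available as a CLI:

```
pupilsync all --config config.yaml --seed 1 --out run1
```

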