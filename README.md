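# rutvox

Tools for studying the rutting behaviour of male reindeer (*Rangifer
tarandus*) from collar-mounted acoustic recorders. During the autumn rut,
males produce low-frequency grunts (fundamental below 100 Hz, in series
from a fraction of a second to over 30 s) whose hourly rhythm tracks
dominance status, time of day, and distance to the peak of the rut. The
package re-creates the full analysis chain as a tested, desk-scale
library for bioacousticians and behavioural ecologists:

1. **Synthetic annotated soundscapes** — grunt series with realistic
   spectral structure embedded in wind/biophony backgrounds, with
   ground-truth time-frequency boxes, so every downstream stage is
   testable without field recordings.
2. **Spectrogram preprocessing** — 1 kHz low-pass, downsampling to
   8 kHz, 4-s windows anchored at annotation boxes, 128-bin mel
   spectrograms (Hann 1024, hop 256, 0–4000 Hz), and S¹/S³/S⁵ exponent
   channels.
3. **CNN grunt detection** — a compact convolutional classifier with two
   softmax outputs, trained with Adam (batch 32), applied to whole
   recordings with a 4-s sliding window at a 1-s hop and a 0.5 decision
   threshold.
4. **Segment-based evaluation** — recall, precision, accuracy and F1 on
   1-s frames against ground-truth boxes, per file and pooled.
5. **Behavioural modelling** — hourly grunt proportions
   g ∈ [0, 1] fitted with a hierarchical beta GAM:

   ```
   g_it ~ Beta(μ_it, θ)
   logit(μ_it) = β₀ + Status_it + f_i(Day) + g_i(Hour) + b_i
   ```

   with g_i a per-individual cyclic cubic regression spline on the 24-h
   clock (10 basis functions), f_i a per-individual penalized spline over
   days relative to the rut peak (22 basis functions), b_i random
   intercepts, and exact zeros moved to 2.2 × 10⁻¹⁴ before fitting.
   Smoothing parameters are selected by a Fellner–Schall (REML-type)
   update; a Wilcoxon rank-sum test compares dominant and subdominant
   hours directly.

## Worked example

```sh
python examples/04_behaviour_hgam.py
```

generates 2,000 synthetic individual-hours with a known dominance effect
of +1.5 on the logit scale and fits the model:

```
status contrast (dominant - subdominant, logit): +1.578 +- 0.099  (truth +1.5)
beta precision theta: 8.09   deviance explained: 75.7%   adjusted r2: 0.680
diel smooth: minimum at 4.8 h, maximum at 11.2 h
Wilcoxon rank sum: W = 769698, p = 1.14e-108; mean proportion dominant 0.424 vs subdominant 0.178
```

The recovered contrast brackets the truth, the diel smooth bottoms out in
the pre-dawn hours the generator encodes, and the rank-sum test confirms
dominant males grunt far more per hour. The other scripts in `examples/`
walk through soundscape synthesis, detector training/evaluation and
hourly aggregation; the `rutvox` CLI (`synth`, `train`, `detect`,
`evaluate`, `analyze`, `run-all`) wraps the same functions for shell use.

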