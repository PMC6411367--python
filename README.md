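# oddballiem

Inverted (forward) encoding models for roving-oddball EEG experiments:
counterbalanced stimulus-design generation, synthetic epoch simulation with
known ground truth, shrinkage-regularized channel decoding, exponentiated-
cosine tuning quantification, and cluster-based permutation inference.

## The problem

Predictive-coding accounts disagree about what attention does to the neural
response evoked by a *surprising* stimulus: does it boost the encoding of
the stimulus feature itself, or of the *mismatch* between what was predicted
and what was observed? Roving-oddball EEG designs probe this by repeating a
grating orientation (standards), jumping to a new one (deviants), and
comparing against equiprobable controls that never establish an expectation,
while attention is manipulated between sessions. The analysis decodes, from
64-channel EEG epochs, both the presented orientation and the signed
orientation *mismatch* (current − previous, in 180° space), and quantifies
the selectivity of the decoded response profiles over time.

This package implements that analysis pipeline end to end and, because the
original human recordings are not required, ships a generative simulator
that emulates exactly the statistical structure the estimator assumes —
orientation-tuned spatial patterns with condition-dependent gain, a
deviant-only mismatch component gated by attention, repetition count, and
deviation magnitude, and spatially correlated noise — so every stage is
testable by parameter recovery.

## The model

EEG epochs are modelled as **B = WC + N**: sensor data **B** (electrodes ×
trials) arise from nine hypothetical feature channels **C** (half-wave
rectified cosines raised to the 8th power on the 180° orientation circle)
through a spatial weight matrix **W**. Per time point (27.3 ms moving
average) and channel *i*:

    w_i = B c_iᵀ (c_i c_iᵀ)⁻¹                      (per-channel least squares)
    Σ̃_i = shrink( ε_i ε_iᵀ / (n−1) )               (Ledoit–Wolf, identity target)
    v_i = Σ̃_i⁻¹ w_i / (w_iᵀ Σ̃_i⁻¹ w_i)            (unit-gain spatial filter)
    C_test = Vᵀ B_test                              (decoding)

under 3-fold, many-iteration cross-validation at block granularity with
per-fold condition balancing. Decoded profiles are recentred on the coded
channel and summarised by a constrained exponentiated-cosine fit
y(x) = A·exp(κ(cos 2x̃ − 1)) + b, whose amplitude A indexes feature (or
mismatch) selectivity. Group inference uses cluster-based permutation tests
(dependent t / repeated-measures F, maxsum), permutation-normalised
univariate electrode sensitivity S = √(β_sin² + β_cos²), and uniform-prior
Bayes factors. See `docs/methods.md` for the full account.

## Worked example

Simulate one participant (attended + ignored sessions, 3 roving + 3
equiprobable 415-grating blocks each, 32 electrodes), decode orientation and
mismatch information with 10 cross-validation iterations, and summarise the
fitted amplitudes over a priori windows (orientation 80–300 ms, mismatch
300–500 ms):

```python
from oddballiem.pipeline import parameter_recovery
parameter_recovery(seed=1)
```

prints (amplitudes in arbitrary units of decoded channel activation):

```
{'n_trials': 4980,
 'orientation_attended': 0.855,  'orientation_ignored': 0.552,
 'mismatch_deviant_attended': 1.029, 'mismatch_deviant_ignored': 0.403,
 'mismatch_control_attended': -0.019, 'mismatch_control_ignored': -0.017,
 'repetition_short': 0.970, 'repetition_long': 1.367,
 'deviation_20': 0.587, 'deviation_40': 1.086,
 'deviation_60': 1.530, 'deviation_80': 0.965}
```

Reading the numbers: attention boosts orientation selectivity (0.855 vs
0.552); deviants carry mismatch information that attention amplifies (1.029
vs 0.403) while adaptation-matched controls carry none (≈ 0); mismatch
responses are larger after long standard trains (8–11 repetitions, 1.367)
than short ones (4–7, 0.970) and larger for ±80° than ±20° deviations —
the qualitative effect structure the generative model encodes.

The same machinery is scriptable:

```bash
oddballiem simulate-design --seed 3 --out events.tsv
oddballiem simulate-epochs --seed 3 --out epochs/
oddballiem decode --epochs epochs/ --feature mismatch --iters 10 --seed 4 --out decoded/
oddballiem run-all --seed 0 --out results/
```

and as statsmodels-style objects:

```python
from oddballiem import EpochSet, InvertedEncoding
epochs = EpochSet.load("epochs/")
res = InvertedEncoding(epochs, feature="orientation").fit(iterations=10, seed=0)
print(res.summary())          # peak fitted amplitude per condition
res.tuning()                  # long-format (condition, time, A, kappa, b, rss)
```

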