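# soctouch

Spike-train analysis of cortical single-unit activity during naturalistic
social facial touch, for systems neuroscientists working with freely
interacting animals.  Natural touch episodes are short (median ≈1.3 s),
irregular, and separated by intervals spanning orders of magnitude, so
PSTH-style trial averaging both underestimates response magnitude and
overestimates variability.  `soctouch` instead models each unit's spiking
as a point process and asks, nonparametrically, whether touch — and the sex
of the touch partner — modulates firing.

## The model

Spike counts on a 1-ms grid follow a Poisson GLM with log link,

    λ_i = exp(P_i · β),
    β = [β₀, h₁…h₁₁, β_rec₁…β_rec₍n−1₎, β_touch, β_sex]

where the predictor matrix `P` holds a constant, eleven spike-history terms
(five 1-ms lags, six 25-ms windows spanning the previous 155 ms),
per-recording baseline offsets, a touch indicator, and a male-partner touch
indicator.  `exp(β_touch)` is the fold change of rate during touch with a
female partner; `exp(β_touch + β_sex)` during touch with a male partner;
β = 1 is an e-fold increase.  Significance comes from shuffle nulls that
refit the model after circularly rotating the touch column (touch test,
preserving episode durations and autocorrelation) or permuting partner-sex
labels at the partner-animal level (sex test).  Units are labeled
`sex_touch` (p_sex < 0.05), `touch` (p_touch < 0.05 only), or
`nonsignificant`.

Around this core the package provides: an information-per-spike statistic
over partner categories with a circular-shift null and a random-intercept
test of sex- vs identity-coding; a mixed-effects population model
`male_mod ~ 1 + female_mod + subject_sex + female_mod×subject_sex +
(1|subject)` that separates additive *bias* from multiplicative
*potentiation*; a 77,169-neuron layered LIF cortical microcircuit with
thalamic touch input and inhibitory-drive neuromodulation, plus BIC
selection over bias/potentiation/full response models; spike-shape E/I
classification; and a calibrated synthetic-session generator so the whole
pipeline is testable without recorded data.

## Worked example

Generate a synthetic session (eight 60-s blocks, four partners of each
sex) whose unit `u0` has known coefficients β_touch = 0.8, β_sex = 0.5,
baseline 9 Hz and a refractory spike history, then fit and test it:

```python
import numpy as np
from soctouch import GeneratorParams, generate_session, make_beta, write_session

partners = (("f1", "F"), ("m1", "M"), ("f2", "F"), ("m2", "M"),
            ("f3", "F"), ("m3", "M"), ("f4", "F"), ("m4", "M"))
params = GeneratorParams(n_blocks=8, block_length=60.0, partners=partners)
sess = generate_session(params, {
    "u0": make_beta(np.log(9.0), touch=0.8, sex=0.5,
                    h=[-2, -1, -0.5, 0, 0, 0, 0, 0, 0, 0, 0]),
    "u1": make_beta(np.log(6.0)),
}, seed=11)
write_session(sess, "demo")
```

```bash
soctouch stats demo
soctouch fit-glm demo --unit u0 --shuffles 100 --seed 7
```

prints (abridged):

```
episodes: 36
duration  median 1.23 s  IQR 0.73-2.03 s
interval  median 9.17 s  IQR 1.69-21.07 s

Poisson point-process GLM (touch+sex)
unit: u0   n_bins: 278833   log-likelihood: -18544.69   converged: True
    coef   estimate   std err        z    P>|z|
   const     2.1403    0.0623    34.35   0.0000
     h_1    -2.1115    0.3535    -5.97   0.0000
   ...
   touch     0.7968    0.0677    11.76   0.0000
     sex     0.5536    0.0798     6.94   0.0000
p_touch = 0.0099  p_sex = 0.0297  label = sex_touch
```

The fit recovers the generating coefficients (0.80 vs 0.8; 0.55 vs 0.5):
this unit fires `exp(0.80) ≈ 2.2`-fold above baseline during touch with
female partners and `exp(0.80 + 0.55) ≈ 3.9`-fold with male partners, and
both shuffle tests flag it — a sex-touch neuron.  The same objects are
available from Python:

```python
from soctouch import TouchGLM, classify_unit, read_session
sess = read_session("demo")
res = TouchGLM(sess, "u0").fit()      # results object with params, llf, summary()
sig = classify_unit(sess, "u0", n_shuffles=100, seed=7)
```

See `docs/methods.md` for the model details, the synthetic-data
calibration, the microcircuit, and the desk-scale limits of the network
downscaling.

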