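# dhlearn

Temporal-Hebbian credit assignment in feedback-controlled rate
networks — for computational neuroscientists studying how biologically
observed plasticity rules (STDP and its rate-based form, differential
Hebbian learning) can train multilayer networks without explicit error
signals.

## The idea

A layered network of leaky rate neurons,

    dv/dt = −v + W r_pre + Q c,     r = φ(v),

receives, besides its feedforward drive, an "apical" feedback signal
`Q c(t)` computed by a single PI controller that watches the output
error `e(t) = y* − r_out(t)`:

    c(t) = c_int(t) + k e(t),     τ_u ċ_int = e/α − c_int.

The controller pushes every neuron's rate toward a state in which the
output matches its target.  Each synapse then learns from the *change*
of its postsynaptic rate:

    Δw  ∝  ∫ r_pre(t) ṙ_post(t) dt            (differential Hebbian, DH)

— no comparison of dendritic compartments, no error neurons; the
teaching signal is carried by the temporal dynamics the feedback
induces.  When the presynaptic rate is fixed this integral telescopes
to the dendritic-error rule `r_pre [r_post(T) − r_post(0)]`, and on
Poisson spike trains the same rule is classical pair-based STDP
(pre-before-post potentiates, post-before-pre depresses).  The feedback
weights `Q` are themselves learned with an anti-Hebbian rule,
`Q̇ = −δv cᵀ − βQ`, from noise-driven fluctuations.

Training minimises three equivalent losses, all of which the package
logs: the pre-feedback output MSE `L`, the integrated control cost
`H = ∫‖c‖²dt`, and the latency `T` to hold the output within tolerance
of its target.

The package provides the network/controller simulator, the DH, delta
and backprop-reference update rules, the Poisson/STDP bridge, a
supervised predictive-coding variant (errors as implicit feedback,
trainable with its standard Hebbian-error rule or with DH), synthetic
tasks, and Model/Results classes with a CLI for the standard
experiments.

## Worked example

```python
from dhlearn import SingleNeuronModel

res = SingleNeuronModel().fit(epochs=60, seed=0)
print(res.summary())
```

```
Single-neuron DH supervision
==================================
epochs                 60
w_A  first -> last     +1.0000 -> -0.7877
w_B  first -> last     +1.0000 -> +1.5669
L    first -> last     0.2559 -> 0.0420
H    first -> last     28.7593 -> 7.0165
T    first -> last     5.690 -> 1.110
DH~STDP Pearson r      0.598
```

One sigmoid neuron receives stimuli from inputs A and B and must fire
low (0.05) for A, high (0.95) for B.  The controller imposes those
targets; the DH rule drives `w_A` down and `w_B` up, and as the neuron's
own output starts closer to its targets all three losses fall: the
initial error `L`, the feedback the controller still has to spend `H`,
and the time `T` to reach the target.  The last line is the Pearson
correlation between the per-trial DH updates and the updates an STDP
kernel produces on Poisson spike trains of the same trajectories —
strongly positive, though noisy, which is the point: the rate-based
rule is the expectation of the spike-based one.

The multilayer version (here a 2-16-16-4 network on a 4-class
Gaussian-blob task):

```python
from dhlearn.config import TrainConfig
from dhlearn.experiments import train_dh_dfc

res = train_dh_dfc(TrainConfig(seed=0))
print(res.summary())
```

```
DH-DFC training
==================================
layers                 (2, 16, 16, 4)
epochs                 30
train error            0.750 -> 0.010
mean L                 0.1644 -> 0.0658
mean H                 10.0720 -> 3.1631
mean T                 1.943 -> 0.643
```

The same experiments are available from the shell:

```bash
dhlearn single-neuron --seed 0 --out out/sn
dhlearn train         --seed 0 --out out/train
dhlearn correlate     --seed 0 --out out/corr      # DH vs BP/delta/STDP R²
dhlearn surprise      --seed 0 --out out/surprise  # label-shuffle protocol
```

each accepting `--config <yaml/json>` to override network sizes,
controller constants (`k`, `alpha`, `tau_u`), integration step, STDP
kernel, and dataset parameters.  Grayscale digit images in IDX format
can replace the blob task via the `idx_images`/`idx_labels` config keys.

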