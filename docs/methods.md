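# Methods

`dhlearn` implements supervised learning in layered rate networks where
the teaching signal is delivered as *activity change*: a feedback
controller pushes every neuron's firing rate toward a state in which the
network output matches its target, and each synapse updates with a
differential Hebbian (DH) rule — the time integral of presynaptic rate
times the rate of change of postsynaptic rate.  Because the same rule,
evaluated on Poisson spike trains, is classical pair-based STDP, the
package also provides the spiking bridge, and a predictive-coding
variant in which prediction errors play the role of the feedback.

## 1. Network model

Non-input neurons integrate leaky membrane potentials

    dv/dt = -v + W r_pre + Q c (+ noise),     r = phi(v),

with the membrane time constant fixed to 1; all times are in units of
it (for intuition, one unit can be read as of order 100 ms, and the
integration step `dt = 0.01`–`0.02` as ~1–2 ms).  The input layer is
clamped: input neurons *are* their firing rates, in [0, 1], and have no
dynamics.  `phi` is the logistic sigmoid by default (`tanh` and
`linear` exist for tests and analysis).  There are no bias terms.
Integration is forward Euler; a noise-free trajectory halves its
discretisation error when `dt` is halved, and the open-loop equilibrium
of the cascade is available in closed form (layer by layer) because the
input is clamped.

Numerical choices: state divergence (non-finite or ‖v‖ > 1e6) raises
immediately with the offending step; open-loop equilibria are computed
by the exact cascade rather than by relaxation; trajectories record
every Euler step.

## 2. Feedback controller

A single global PI controller watches the output error
`e(t) = y* - r_out(t)` and emits `c(t) = c_int(t) + k e(t)` with leaky
integral dynamics `tau_u dc_int/dt = e/alpha - c_int`.  The feedback
matrix `Q` maps this output-dimensional signal into every hidden and
output neuron ("apical" input).  The integral term is reset at each
stimulus onset (trials are independent presentations), and closed-loop
trials start from the open-loop equilibrium — the network has settled
on the stimulus before feedback engages, so the error at the first
recorded step is the pre-feedback error.

Defaults: `k = 0.5`, `alpha = 0.1`, `tau_u = 1`.  Because the integral
is leaky, its fixed point is `c_int = e/alpha`, so the loop gain is
`k + 1/alpha ≈ 10`.  This is deliberate: with a gain of order 1 the
controlled output stops far from a sigmoid-range target (steady-state
error ~0.5), the latency loss never becomes finite, and the framework's
strong-feedback regime — feedback large enough to actually impose the
target — is never entered.  The gain, not `‖Q‖`, sets the tracking
accuracy; doubling `Q` simply halves the control signal needed.

## 3. Feedback-weight (Q) learning

Before feedforward training, `Q` is learned by injecting independent
zero-mean Gaussian noise into every potential while the controller
tracks the *noise-free* output, with the anti-Hebbian rule

    dQ/dt = -(v - v_eq) c^T - beta Q,

where `v_eq` is the open-loop equilibrium for the current stimulus.
The fluctuation `v - v_eq` is what carries the credit information: a
neuron whose fluctuation reliably produces a corrective signal `c`
acquires the corresponding feedback weight, and at the fixed point `Q`
aligns with the transpose of the network Jacobian (up to the noise
covariance).  Using the raw potential instead (a strictly literal
reading of the rule) buries this correlation under the product of the
large constant baseline potential and the near-zero mean control; in
our measurements the raw form reaches a Jacobian correlation of ~0.19
(closed-loop terminal error 0.57 on a 2-16-16-4 net) versus ~0.84
(terminal error 0.077, near the ideal Jacobian-transpose feedback) for
the fluctuation form, which is therefore the default
(`subtract_baseline=False` restores the literal rule).

The anti-Hebbian fixed point fixes only the direction of `Q`; its norm
scales with noise variance over `beta` and is arbitrary relative to the
controller gain.  `DeepFeedbackModel` therefore rescales the trained
`Q` to Frobenius norm `sqrt(n_dynamic)` (the scale of the random
initialisation convention).  Defaults: `noise_sd = 1.0` (potential
fluctuations of sd ≈ 0.1 at `dt = 0.02`), `beta = 0.01`, `lr_q = 1.0`,
200 presentations.  `Q` is then frozen for feedforward training;
re-training cadence is exposed but off by default.

## 4. Plasticity rules

* **DH**: `dW = Σ_t [r_post(t+dt) - r_post(t)] ⊗ r_pre(t)`, forward
  difference paired with the presynaptic rate at the *earlier* step
  (pre-before-post causality; this preserves the LTP sign convention of
  the spike-pairing kernel).  Updates are computed once per
  presentation from the whole trajectory; an online per-step
  accumulation mode is provided and equals the batch sum exactly.
* **Delta / dendritic-error**: `dW = [r_post(T) - r_post(0)] ⊗ r_pre(T)`.
  For constant presynaptic rates the DH sum telescopes to this exactly
  (machine precision); `dh_decomposition` exposes the identity
  `DH = delta-like term − presynaptic-drift term` for the general case.
* **BP reference**: exact negative gradient of `½‖y − r_out‖²` through
  the open-loop pass, hand-written and verified against central finite
  differences.  It is a diagnostic baseline, never a training path.
* Proportionality constants are 1; learning rates are applied by the
  caller (`0.1` by default in both the single-neuron and multilayer
  loops).

Alignment between two update sets is summarised by the coefficient of
determination (R²) of the least-squares fit of one flattened set on the
other.

## 5. Spiking bridge

Rates are per-bin spike probabilities, exactly as the rate network's
[0, 1] convention suggests, so `dt` sets the rate scale; conversion is
an independent Bernoulli draw per neuron and bin (an inhomogeneous
Poisson process on the grid).  The STDP update superposes an
exponential kernel over spike pairs: pre-before-post potentiates by
`a₊ e^{-Δt/τ₊}`, the reverse order depresses by `a₋ e^{-Δt/τ₋}`;
simultaneous (same-bin) spikes contribute nothing.  Pairing is
all-to-all by default; nearest-neighbour pairing uses only the closest
earlier partner spike.

Kernel defaults: `a₊ = a₋ = 0.01`, `τ₊ = τ₋ = 0.02` time units (the
classical ~20 ms window when a unit is read as one second).  The
*balance* `a₊τ₊ = a₋τ₋` is a deliberate choice: under independent
Poisson sampling the expected pair-sum decomposes into a rate-product
term weighted by the kernel imbalance plus a term tracking the
postsynaptic rate derivative.  An imbalanced kernel (e.g. the often
quoted `a₋ = 1.2 a₊`) makes the first term dominate by an order of
magnitude at these time constants, severing the STDP–DH correspondence
the package is about; the balanced kernel cancels it, leaving the
expectation proportional to the DH update whenever presynaptic rates
are constant.  The biologically skewed profile remains available
through the kernel parameters.

`stdp_expected_update` averages the update over parallel conversions.
For all-to-all pairing it evaluates the pair sum with exponential
traces in O(T) — on a spike grid this is *identical* to the double sum
(no window truncation); a test pins it against the literal pairwise
implementation, which itself truncates pairs beyond `5τ` (per-pair
error < e⁻⁵).

## 6. Losses

* `L`: mean squared output error at trial onset, i.e. before feedback
  acts (trials start at the open-loop equilibrium).
* `H`: ∫‖c‖² dt over the trial — the control cost convention; a plain
  norm variant is a flag.
* `T`: first time ‖e‖∞ falls below `tol = 0.1` rate units *and stays
  below* for the rest of the trial (sustained crossing, so transients
  do not count).  Never reaching it returns +inf; epoch aggregates
  censor this at the trial duration, otherwise one unreached sample
  makes epoch means infinite and trend comparisons meaningless.

## 7. Experiments

**Single neuron** (two inputs A/B at rates (1,0)/(0,1), targets
0.05/0.95, `w_A = w_B = 1` initially, lr 0.1, trials of 10 time units
at `dt = 0.01`): the controller forces the output low for A and high
for B; DH updates drive `w_A` down and `w_B` up, and L, H, T all fall.
Each trial also draws one Poisson conversion and logs the pair-based
STDP update next to the DH update; across a run their Pearson
correlation is strongly positive (noisy, as expected from spiking).

**Multilayer DH-DFC** (default 2-16-16-4 on the 4-class blob task):
Q pre-training, then per-sample closed-loop trials of 3 time units at
`dt = 0.02` (150 controller steps — same order as the ~100 forward
passes per sample the full-scale runs require).  Learning rate 0.1,
held 15 epochs then decayed by 0.9 per epoch: the constant phase is
needed to escape the symmetric saddle created by a centrally located
class (whose mean hidden representation is the average of its
neighbours'), the decay settles the endpoint.  Feedforward weights are
initialised at 3× the `1/sqrt(fan_in)` scale: without biases, a
unit-gain sigmoid stack loses input-driven variance through depth
(layer-2 rate sd ≈ 0.1 across samples, unreadably flat) and 3× keeps
per-layer rate sd ≈ 0.25.  Classification is the argmax of the
open-loop output; targets are one-hot mapped to 0.95/0.05 because
exact 0/1 is unreachable by a sigmoid.

**Update alignment**: at mid-training, per-batch update
sets from DH, delta (same trajectories), BP (same samples) and expected
STDP are compared by R².  At desk scale DH–delta R² ≈ 0.95, DH–BP
≈ 0.65–0.8, DH–STDP positive but small — the same ordering the
full-scale experiments report.

**Surprise**: after 20 epochs of training, class labels are randomly
*swapped* — a random perfect matching of class identities, so every
class changes partner (an odd class count folds the leftover into a
3-cycle).  The feedback cost H jumps by ≥2× at the next epoch and then
re-declines.  The learning-rate schedule restarts at the shuffle (a new
task begins there).

**Digit images**: the standard big-endian IDX reader (magic 2051/2049)
scales pixels to [0, 1] and one-hot-encodes labels; a full-scale run
(three 256-unit hidden layers) is supported through the same model
class but is hours of CPU and is not part of the automated runs.

## 8. Predictive-coding variant

Activities `x_l` carry prediction errors
`ε_l = x_l − W_l r(x_{l−1})`, with `r = phi` for hidden/output layers
and the identity for the clamped input layer — inputs are already
rates; squashing them again compresses between-class separation to
~0.14 sigmoid units and stalls learning.  Inference is gradient descent
on `E = Σ ‖ε_l‖²/2` (error neurons are computed quantities — the
fast-error limit).  Training mode records the feedforward-initialised
state (output free) as step 0 and hard-clamps the output from step 1;
the initial output jump is precisely the activity change that gives the
DH rule its output-layer signal, mirroring the closed-loop setting.
Energy is non-increasing from the first clamped state for the default
step size (0.1, 30 steps).

Weight rules: Hebbian-error `ΔW_l = ε_l r(x_{l−1})ᵀ` at the inference
endpoint (exact descent on E), or DH along the inference trajectory
(DH-PC).  Both train the 4-class task to ≥90% with the same schedule
(lr 0.2, hold 25, decay 0.9, 50 epochs) and land within a few
percentage points of each other.

## 9. Synthetic data

`gaussian_blobs` rejection-samples class centers uniformly in
[0.2, 0.8]^dim with a minimum pairwise spacing and sets the isotropic
within-class sigma to (realised minimum spacing)/`sep`, so every seed
produces the same relative class separation and features are valid
firing rates directly.  Default: 4 classes × 25 points in 2-D at
`sep = 6` (near-zero Bayes error; a linear nearest-center rule can
separate any such configuration).  What this generator does *not*
emulate: high-dimensional inputs, within-class manifold structure,
label noise, or class imbalance — passing these tests shows the
learning dynamics work, not that the method is competitive on real
images; the IDX path exists for that.

`two_input_task` is deterministic: stimulus A = rates (1, 0) with
target 0.05, B = (0, 1) with target 0.95, alternating.

## 10. Known limitations

* The faster-recovery-after-surprise property is marginal at desk
  scale: re-learning must beat the settled pre-shuffle feedback-cost
  minimum within `shuffle_epoch − 1` epochs, and the feature-reuse
  advantage that makes recovery fast at full scale is small for a
  4-class 2-D task.  With the default configuration the property
  holds; across arbitrary shuffles it holds in roughly half of runs,
  and a 4-cycle relabelling (every readout row traversing from
  confident-wrong to confident-right) reliably takes *longer* than the
  initial decline.
* Poisson spiking makes single-trial STDP updates noisy by
  construction; all spike-level claims are about expectations over
  conversions.
* The controller gain is fixed; no stability analysis is performed
  beyond divergence detection (ill-conditioned random `Q` can make the
  closed loop unstable, which is precisely why `Q` is learned).
* Euler integration with `dt` in the defaults is first-order; halving
  `dt` roughly halves trajectory error but doubles cost.
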