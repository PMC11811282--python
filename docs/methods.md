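# Methods

## The generative model

`neurotwin` implements a hierarchical variational recurrent network that
generates multichannel cortical signals (e.g. ECoG) through top-down
prediction across three levels:

* **Global state level.** Latent units `z3` (default 2) are stochastic
  constants over a sequence: their posterior is a single diagonal Gaussian
  per sequence, shared by all time steps. They abstractly encode
  sequence-wide state — in our experiments the awake/anesthetized regime
  and, at full scale, individual identity. The level carries no
  deterministic units; `z3` enters the network-level dynamics directly.
* **Functional network level.** Latent units `z2` (default 3) and a bank
  of leaky-integrator deterministic units `d2` (default 15) with time
  constant `tau_network = 4`. `d2` projects top-down into every region
  module.
* **Local region level.** One module per cortical region, each with latent
  units `z1` (default 1), deterministic units `d1` (default 15,
  `tau_local = 2`) and a `tanh` read-out producing that region's channels
  (2 per region by default).

Deterministic dynamics follow the multiple-timescale update

    h_t = (1/tau) * (W_d d_{t-1} + W_z z_t + W_top (topdown) + b)
          + (1 - 1/tau) * h_{t-1},            d_t = tanh(h_t)

so small `tau` yields fast local dynamics and larger `tau` slower
network-level dynamics. Latent priors are diagonal Gaussians read out from
the previous deterministic state of the same module (`mu = tanh(W d)`,
`sigma = exp(W d)`); at the first step of a sequence every prior is
`N(0, 1)`. Posteriors are parameterised by per-step adaptive states
`(a_mu, a_sigma)` through the same `tanh`/`exp` links, and samples are
reparameterised: `z = mu + sigma * eps`, `eps ~ N(0, 1)`.

## Loss and optimisation

The per-step loss is the variational free energy (negative ELBO)

    F_t = 1/2 ||x_t - xhat_t||^2
          + sum_l W^(l) KL[ q(z_t^(l)) || p(z_t^(l)) ]

with the closed-form diagonal-Gaussian KL summed over units within each
level and weighted by the per-level meta-prior `W^(l)` (default 0.001 at
every level at full scale). The global level contributes its KL once per
sequence (against `N(0, 1)`), because its posterior is constant and its
only prior is the initial one. Training minimises the sum of `F_t` over
all sequences and steps *jointly* over the network weights and every
sequence's adaptive states, full-batch, with one reparameterised sample
per unit/step/update, by backpropagation through time.

Updates use Rectified Adam (alpha = 0.001, beta1 = 0.9, beta2 = 0.999);
plain Adam is available behind a config switch. Gradients are computed by
a hand-derived reverse pass compiled with numba; the test suite verifies
them against central finite differences at 1e-4 relative tolerance.

Numerical guards: all `exp` pre-activations (posterior and prior sigma)
are clamped to [-10, 10], with zero gradient outside the clamp; the
fine-grained ops additionally clamp `tanh` outputs to the largest double
below 1 so the open-interval invariants survive rounding.

## Data assimilation

Real-time latent-state estimation runs a sliding window of `H` steps
(default 500). For each incoming observation: the newest step's posterior
is initialised at the prior propagated from the previous posterior
(exactly invertible because the adaptive state and the prior
pre-activation live in the same space); then `K` cycles (default 100) of
top-down window prediction and Rectified-Adam updates of the window's
adaptive states minimise the windowed free energy, weights frozen. The
window then advances. A step inside a full window therefore accumulates
`H x K` updates before it leaves the window (50,000 at the default
settings). Posteriors that leave the window are frozen; optimiser moments
persist across window moves; the global latent is updated at every window
position. At startup the window grows from one step instead of waiting
for `H` observations.

Per-step noise draws are fresh at each update cycle; recorded trajectories
and state hand-offs use posterior means (a deterministic pass), which is
also what the plots and the classifier consume. Ahead prediction rolls
the generative model forward from the assimilated state using priors
only, with the global latent held at its current posterior mean.

During early posterior-only optimisation the *sampled* ELBO (the actual
objective) decreases while the deterministic mean-pass free energy can
transiently rise — posterior SDs start near 1 and must shrink before the
mean trajectory becomes an accurate summary. Tests therefore assert the
aggregate decrease of the objective, not per-iteration monotonicity of
the mean-pass value.

## Virtual interventions

Condition-specific posterior repertoires are estimated per labelled test
sequence with the window fixed to the whole sequence (so `z3` stays a
single constant summarising it) and 10,000 posterior updates. Two
intervention modes follow:

* **Global-state (virtual drug) intervention:** the stored posteriors of
  *all* levels of the chosen sequence are replayed while generating
  (sampled from the stored distributions; mean injection behind a flag).
* **Network/region-targeted interventions:** the target `z2` unit or
  region's `z1` replays a stored posterior trajectory while all non-target
  latents generate from their priors.

Generated signals are scored by the discriminator; the report is the mean
and SD over repertoire entries/draws of the proportion classified into the
intervention's target condition.

## Discriminator

Signals are segmented (2000 ms at full scale), converted channel-wise to
multitaper spectrograms (Slepian tapers, time-bandwidth 4, 7 tapers,
100 ms window, 10 ms step, 0-200 Hz), log-transformed, globally
standardised, and stacked into a channel x frequency x time volume. A
small 3-D convolutional network (configurable conv + ReLU + average-pool
blocks, global average pooling, linear head) is trained with
cross-entropy and Adam (learning rate 5e-4; 100 updates at full scale).
The conv layers use explicit im2col forward/backward passes that are
finite-difference-checked in the tests.

## Analysis metrics

* **Transfer entropy** from each network latent to each region's mean
  deterministic output: discrete plug-in estimator on quantile-binned
  series (default 4 bins, history 1 for source and target, natural log),
  bias-corrected by subtracting the mean over 100 source-permuted
  surrogates. The discrete estimator was chosen because it admits an
  exact brute-force oracle (enumerated joint distributions) used in the
  tests. The fingerprint table stacks (fold x latent unit) rows against
  (region x condition) columns — 12 x 20 at the reference geometry — and
  is z-scored matrix-wide for display and clustering.
* **Functional-network grouping:** average-linkage hierarchical
  clustering (Euclidean) of the z-scored TE rows; groups labelled FN1,
  FN2, ... in order of appearance; dendrogram exported as Newick text.
* **Silhouette width** with Euclidean distances, `s(i) = (b - a) /
  max(a, b)`; singleton clusters score 0; a one-sided t-test helper
  reports whether the mean silhouette exceeds zero.
* **Cluster assignment** either by the larger hypothetical silhouette or
  by k-NN whose k is selected by leave-one-out cross-validation over odd
  candidates (ties: smaller k; vote ties: first label in sorted order).

## Synthetic study conditions

The generator emulates the structure of two-regime multichannel cortical
recordings without any download. Each channel is a sum of band-limited
sinusoids (random phases, +-10% per-sequence amplitude jitter) plus AR(1)
noise (SD 25 uV, coefficient 0.9), in microvolts. Default regimes:

* awake: 12 Hz / 110 uV, 25 Hz / 90 uV, 40 Hz / 60 uV in every region;
* anesthetized: 4 Hz / 380 uV, 9 Hz / 300 uV, 18 Hz / 140 uV — higher
  broad-band power — except the two visual regions (HV, V1), where
  amplitudes (4 Hz / 130, 9 Hz / 110, 18 Hz / 80 uV) keep the difference
  from awake small.

Oscillation frequencies sit at or below 40 Hz so that a desk-scale
network (time constants 2 and 4 at 1000 Hz) can actually learn to
generate them — in pilot runs content at 85 Hz was reconstructed at under
2% of its power and the regime signature did not survive into generated
signals. Individuals differ by per-channel log-normal gains (SD 0.08) and
a mild spectral tilt (SD 0.05), deliberately smaller than the
between-regime contrast. What the generator does *not* emulate: 1/f
background spectra, nonstationarity within a condition, cross-channel
phase coupling, or artifacts; passing tests on these data show the
pipeline's mechanics and direction-of-effect behaviour, not performance
on real recordings.

## The desk benchmark

`neurotwin.presets.DeskBench` fixes the configuration shared by the
examples, the test suite and the acceptance script: 2 regions / 4
channels, 200-step training sequences (8 per regime from 3 training
individuals, one held out), 8 deterministic units per module, 20,000
training updates, assimilation with `H = 60`, `K = 30`, repertoire
estimation with 10,000 updates, and a 400-update discriminator on 500 ms
segments.

Two deliberate departures from the full-scale defaults, both consequences
of scale:

* **Meta-prior 0.02** (vs 0.001). With 4 channels and 200 steps the
  reconstruction term is roughly two orders of magnitude smaller than at
  full scale while per-step KL terms shrink less, so the balance between
  the two shifts. At 0.001 the per-sequence posteriors become
  idiosyncratic (global latents scatter without regime structure — the
  overfitting direction of a too-small meta-prior); at 0.1 optimisation
  destabilises. 0.02 keeps regime-organised global latents and stable
  training.
* **Discriminator updates 400** (vs 100). The small from-scratch conv net
  has no normalisation layers and full-batch gradients; 100 updates leave
  it at chance on the desk volumes.

Training beyond ~30,000 updates at this scale eventually destabilises
(loss spikes); the benchmark stops at 20,000, where the global-latent
regime clusters are well formed (silhouette ~0.7 in the reference run).

## Known limitations

* Posterior estimation from scratch needs on the order of 10^4 updates;
  shorter runs can leave the global latent near its initialisation (and
  the mean-pass free energy is not monotone during the early phase).
* The desk model underfits frequencies well above ~40 Hz; full-scale unit
  counts and update budgets would be required for faster content.
* Transfer entropy uses a discrete plug-in estimator with history 1;
  longer histories and continuous estimators are out of scope.
* The two-way ANOVA over intervention effects reported for the full-scale
  study is not re-implemented; the intervention tables can be fed to any
  stats package.
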