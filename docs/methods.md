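# Methods

This note documents the modelling choices behind `snm`: the simulator, the
training protocol, the three-phase unlearning method, the synthetic data it
is validated on, and the places where the design was genuinely open.

## Neuron and synapse model

Two point-neuron models are provided. The leaky integrate-and-fire (LIF)
neuron integrates dv/dt = −v/τ_m + I(t) by forward Euler; a spike is
registered at the end of any step in which v ≥ Θ (the comparison is ≥), and
v is reset. The Izhikevich neuron uses the standard two-variable form
(dv/dt = 0.04v² + 5v + 140 − u + I, du/dt = a(bv − u), cutoff v_peak = 30,
reset v ← c, u ← u + d) with the regular-spiking coefficients
(a, b, c, d) = (0.02, 0.2, −65, 8) as default. All quantities are
dimensionless except time (ms). Defaults: τ_m = 10 ms, v_reset = 0,
v_thresh = 0.5 (chosen so that unit-norm synaptic input drives neurons into
a responsive but non-saturated regime), integration step dt = 1 ms
(configurable; the per-module tests verify ≤ 1 % error against the
closed-form LIF decay at dt = τ_m/100 and ±1 spike/500 ms against a
fine-step Euler oracle for the Izhikevich model).

The per-neuron firing threshold Θ_i is mutable state, which is what the
unlearning method's adaptive-thresholding phase manipulates.

Synapses are dense pre×post weight matrices under a binary connectivity
mask (Bernoulli-sampled, default probability 0.1 in the large reference
architecture, higher for small control networks); masked-out entries carry
weight exactly zero and no operation writes into them. Transmission is
instantaneous: I_syn = Σ_j W_ji S_j(t). There are no conductances,
refractory periods or axonal delays.

## STDP and the training protocol

Pair-based STDP: ΔW = +A₊e^(−Δt/τ₊) (Δt > 0), −A₋e^(Δt/τ₋) (Δt < 0), 0 at
Δt = 0, with Δt = t_post − t_pre. Pairing is nearest-neighbour by default
(each postsynaptic spike pairs with the nearest strictly-preceding and
strictly-following presynaptic spike); all-pairs accumulation is available
and both are computed exactly on the binned spike grid via exponential
traces (verified against exhaustive pair enumeration). Updates are scaled
by the learning rate η = 0.01.

Supervision is teacher forcing in push–pull form: while a sample is
presented, +I_teach is injected into the true-class output neuron and
−I_teach into every other output (default I_teach = 1.0). The pull matters:
without it, hidden drive occasionally exceeds threshold on a wrong output
early in training and potentiation then runs away on the wrong pathway.
Because the teacher makes the forced output fire persistently,
pre/post pairings at the readout are nearly symmetric in time and the net
drift per co-active pathway is proportional to A₊ − A₋; the defaults are
therefore potentiation-dominant (A₊ = 0.1, A₋ = 0.05, τ₊ = τ₋ = 20 ms) so
that the teacher signal strengthens rather than erodes the correct
pathways.

Homeostasis, applied during training:

* **weight normalisation** — each postsynaptic neuron's incoming weight
  vector is rescaled to L2 norm 1 after every epoch (and once at network
  construction, so neurons start responsive);
* **synaptic dropout** — 20 % of synapses are silenced per batch
  (transmission and update);
* **readout-rate calibration** — after each epoch, output-neuron thresholds
  are multiplicatively adjusted (4 fixed-point iterations, exponent 0.7,
  clamped to [0.05, 10]) so mean output rates on a class-balanced training
  subsample are equal. Random sparse connectivity gives output neurons
  different excitability; without this intrinsic-homeostasis step one
  output can dominate the spike-count readout for every input. The step is
  skipped when the training set contains a single class (balancing rates
  there would be wrong by construction) and can be disabled
  (`calibrate_outputs=False`).

Training runs in batches (default 100 in the reference configuration, 20 in
the small study task), encodes each sample as Poisson spike trains (rate =
feature × 100 Hz, drawn per bin; 200–500 ms per sample), simulates with the
teacher on, and applies the STDP update to every connection. Prolonged
training degrades the readout on these small networks — the hidden code
drifts under potentiation-dominant STDP while the readout accumulates stale
associations — so the study protocol trains for a single epoch on ~100
samples, which reaches ≥ 0.9 training accuracy on the separable control
task for the large majority of seeds (mean ≈ 0.96 over random seeds). This
is a property of the plain-STDP setting (no lateral inhibition or
winner-take-all competition, which are out of scope), not of the
implementation.

## The unlearning method

Given a trained model, a forget specification (one class, or a sample index
set) and the training data, each iteration runs:

1. **Target identification.** The forget samples are encoded (fixed seeds)
   and simulated. The target-data drive d(t) is the mean fraction of active
   input channels per time bin over the encoded forget samples; per-neuron
   relevance is the discretised correlation integral
   Corr_i(d) = Σ_t S_i(t)·d(t)·dt, averaged over forget samples and
   computed for every layer including the input. The weight change
   attributable to the forget data, ΔW(d), is obtained by counterfactual
   replay: snapshot the weights, replay one teacher-forced STDP pass over
   the forget data alone, apply the same homeostatic unit-norm rescaling
   used after every training epoch, and diff. Including the rescaling is
   essential — raw replay pair-sums live on a different scale from the
   normalised trained weights and overshoot the attribution by an order of
   magnitude. Neurons with Corr_i(d) above the 75th percentile are
   selected; a synapse is selected (κ = 1) when |ΔW(d)| exceeds the 75th
   percentile over connected synapses *and* both endpoint neurons are
   selected.
2. **Selective retraining.** W′ = W − α·ΔW(d) on selected synapses
   (α = 1 by default), all other weights untouched.
3. **Pruning.** Within the selection, synapses with |ΔW(d)| above θ
   (default: 50th percentile of the selected |ΔW(d)|) are zeroed and
   permanently removed from the connectivity mask. A global-scope variant
   and an alternative criterion (prune non-positive contributions,
   ΔW(d) ≤ 0) are available behind flags.
4. **Adaptive thresholding.** For selected neurons,
   ΔΘ_i = −γ Σ_t (S_i(t) − Ŝ_i(t)) + β Σ_t (dS_i/dt − dŜ_i/dt), where
   S_i is the response aggregated (summed) over all forget presentations
   and Ŝ_i is the desired response (all-zero by default). Aggregating over
   presentations makes the threshold shift scale with the amount of data
   being forgotten, which produces the expected dose–response in the
   sample-wise sweep. Thresholds are floored just above the reset
   potential. **Sign convention:** as written, γ > 0 *lowers* the threshold
   of a neuron that spikes more than desired, increasing its excitability.
   Because the method's purpose is to suppress the response to the forget
   data, the pipeline default is γ = −0.002 (so excess response raises the
   threshold); the operator itself implements the formula literally and a
   positive γ recovers the other direction. β defaults to 0.01; the timing
   term telescopes to the difference between last- and first-bin rates and
   is a small correction.

Iterations repeat (default max 10) until the mean true-class output score
on the forget set falls below 1.5 × chance. On the two-class study task a
single iteration suffices.

`verify_unlearning` reports forget-set recall, retain-set accuracy and the
mean true-class score for the models before and after, with deltas; the
per-phase operators are exposed individually and the pipeline is tested to
equal their manual composition.

One caveat on readouts: the *normalised* score of the forget class is not
monotone in α at small scale — suppressing selected pathways can silence
the weaker (wrong-class) output first, which inflates the normalised ratio
even as the true-class response falls. The meaningful erased quantity is
the forget-class output spike count, which is monotone in α and is what
the corresponding invariant test measures.

## Evaluation

Multiclass metrics are macro-averaged over one-vs-rest confusion tables;
classes absent from the true labels are excluded with a warning. ROC AUC is
the macro one-vs-rest rank statistic on the normalised score matrix; the F1
score is reported as the harmonic mean of macro precision and macro recall.

The membership-inference attack is the minimal confidence-threshold
construction: per-sample confidence = max normalised output score; member
and non-member populations are split in half, the threshold maximising
balanced accuracy is chosen on the shadow halves, and accuracy / precision /
recall of membership prediction (member ⇔ confidence ≥ threshold) are
reported on the evaluation halves. The attack direction is fixed — members
are assumed to receive *higher* confidence — which is the standard
memorisation assumption; a direction-flipping attack would trivially
exploit the "silenced" signature of unlearned samples.

At this scale the network does not memorise individual samples (the
measured member/non-member confidence gap is ~0.002 even with frozen
per-sample encodings), so the only membership signal available before
unlearning is the trained network's class-conditional confidence bias.
Readout-rate calibration removes most of that bias; the membership audit is
therefore run against models trained in the plain (uncalibrated)
configuration, where the bias is a genuine attack surface (pre-unlearning
attack accuracy ≈ 0.5–0.75) that class-wise unlearning erases (post
accuracy pinned at chance). This reproduces the direction of the effect —
attack accuracy does not increase after unlearning — not the absolute
attack accuracies of heavily overfit models.

The trade-off sweep trains a fresh model per (fraction, seed), unlearns
that fraction sample-wise, and records baseline-minus-post test accuracy;
the reported curve is the per-fraction mean ± sd and its trend is
summarised by the Spearman correlation between fraction and mean loss.

## Synthetic data

Three generators, all deterministic under a seed, values clipped to [0, 1],
balanced classes:

* **images** — 28×28 grayscale, ≤ 10 classes; each class prototype is a
  seven-segment rendering of the class digit (deterministic in the class
  id, pairwise distinct) plus Gaussian pixel noise (default sd 0.05). A
  nearest-prototype oracle reads the default data at ≥ 99 %.
* **time series** — channels × timesteps in [0, 1]; each class has a
  distinct per-channel sinusoid frequency/phase signature (channel 0
  carries class c at c+1 cycles), plus noise. A spectral-peak oracle reads
  low-noise data at ≥ 99 %.
* **separable control task** — each class activates a disjoint block of
  input channels (active level 0.9, background 0.02, noise sd 0.05). This
  is the study task for the training/unlearning experiments: its oracle
  separability guarantees that any failure to learn or unlearn is
  attributable to the network, not the data.

The image and time-series generators emulate the *shapes* of common
benchmarks (digit images; wearable-sensor activity windows) so that
configurations transfer unchanged to real data a user supplies; they do not
emulate their within-class variability, and plain teacher-forced STDP
without lateral inhibition does not reach useful accuracy on the
overlapping seven-segment prototypes. Passing tests on the synthetic tasks
therefore demonstrate the mechanics and the directional behaviour of the
unlearning method, not benchmark-level image recognition.

Splits are label-stratified with largest-remainder allocation (default
70/15/15). Forget specifications select either all indices of one class or
a uniformly random sample fraction.

## Study conditions and problem sizes

The canonical study task used by the test suite and the acceptance script:
2 classes × 10 channels each (20 inputs), network 20 → 40 → 2, connectivity
0.5, LIF neurons, 200 ms per sample at dt = 1 ms, 100 training / 80 test
samples, one training epoch, batch 20. The default end-to-end experiment
(`ExperimentConfig()`) uses the same task with a 70/15/15 split and a
2-epoch retraining stage, and completes in a few seconds; the class-wise
unlearning study, membership audit and four-fraction sweep together run in
about two minutes on one CPU. The large reference architecture (two hidden
layers of 200 neurons at connectivity 0.1) is available through the
configuration but is not required by any shipped experiment.

## Reproducibility

Every source of randomness flows through explicit seeds;
`ExperimentConfig.seed` fans out to per-stage seeds via SHA-256 of the
stage name, so stages can be rerun in isolation and identical config + seed
produce byte-identical JSON reports. Model containers are versioned HDF5
files with a SHA-256 payload checksum; tampering surfaces as a format
error.

## Known limitations

* No lateral inhibition / winner-take-all competition, conductance
  synapses, refractory periods or delays; recurrence and convolutional
  topologies are out of scope.
* Plain STDP with teacher forcing learns linearly separable channel codes
  reliably but not overlapping image classes; deep (two-hidden-layer) STDP
  propagation degrades the class code.
* Prolonged training destabilises the readout (hidden-code drift); the
  protocol compensates with short training and readout calibration rather
  than with competition mechanisms.
* Percentile-based selection thresholds make the *amount* of collateral
  pruning roughly constant per iteration; the dose–response across
  forgotten fractions is carried by the attribution and thresholding
  phases.
* Unlearning erases a class's response by silencing its pathway; it does
  not provide certified or differentially private deletion guarantees.
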