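# snm-unlearn — machine unlearning in spiking neural networks

`snm` is a small, fully reproducible simulator for sparse feedforward
spiking neural networks together with a **hybrid machine-unlearning method**
that selectively removes the influence of specific training data (a whole
class, or an arbitrary sample subset) from a trained network without
retraining it from scratch. It is aimed at researchers studying data
deletion / right-to-be-forgotten mechanisms in brain-inspired models, and it
ships synthetic dataset generators so every experiment runs from a single
seed with no downloads.

## The model

Networks are layers of spiking neurons — leaky integrate-and-fire,

&nbsp;&nbsp;&nbsp;&nbsp;dv/dt = −v/τ_m + I(t), spike and reset v ← v_reset when v ≥ Θ,

or the standard two-variable Izhikevich model — connected by sparse,
Bernoulli-sampled synapse matrices W. Inputs are Poisson rate-coded;
synaptic input is I_syn,i(t) = Σ_j W_ji S_j(t). Learning is pair-based
spike-timing-dependent plasticity,

&nbsp;&nbsp;&nbsp;&nbsp;ΔW = +A₊ e^(−Δt/τ₊) for Δt > 0, −A₋ e^(Δt/τ₋) for Δt < 0 (Δt = t_post − t_pre),

made supervised by a push–pull teacher current on the output layer, with
homeostatic per-epoch weight normalisation, synaptic dropout, and
readout-rate calibration. Classification reads out normalised output spike
counts.

**Unlearning** runs three phases per iteration until the network's response
to the forget data falls below tolerance:

1. *Selective retraining* — score neurons by the correlation of their spike
   train with the forget-data drive, Corr_i(d) = Σ_t S_i(t)·d(t)·dt; attribute
   a weight change ΔW(d) to the forget data by counterfactual replay; revert
   W′ = W − α·ΔW(d) on synapses whose endpoints are both selected.
2. *Synaptic pruning* — permanently remove selected synapses with
   |ΔW(d)| > θ (weights zeroed, connectivity mask cleared).
3. *Adaptive thresholding* — shift selected neurons' firing thresholds by
   −γ Σ_t (S_i − Ŝ_i) + β Σ_t (dS_i/dt − dŜ_i/dt) toward a desired (silent)
   response to the forget data.

Forgetting is audited with classification metrics on forget/retain splits
and a confidence-threshold membership-inference attack (MIA).

## Worked example

The default experiment trains a 20 → 40 → 2 LIF network on the synthetic
linearly separable task, unlearns one class, retrains briefly on the
retained data, and audits with a membership-inference attack:

```python
import snm

cfg = snm.ExperimentConfig(seed=2)
report = snm.run_experiment(cfg, "out/")
```

which writes `report.json`, metric tables and model containers under
`out/`, and summarises as:

```text
forgotten class:             0 (53 training samples)
baseline test accuracy:      0.955
post-unlearning accuracy:    0.500
post-retraining accuracy:    1.000
forget-set true-class score: 0.534 -> 0.500 (converged: True)
MIA accuracy before/after:   0.50 / 0.50
```

Reading the numbers: the trained baseline classifies 95.5% of test samples.
After class-wise unlearning the forgotten class is no longer recognised —
its output neuron is silent, so overall test accuracy drops to the retained
class's share (0.500) while retained-class accuracy is unchanged; the mean
output score assigned to forgotten samples' true class falls to the uniform
floor (0.500 for two classes), i.e. the network expresses no preference for
the erased class. A short retraining pass on the retained data then recovers
full performance (1.000). The same pipeline is scriptable from the shell:

```bash
snm run --seed 2 --out-dir out/           # full experiment
snm gen-data --kind image --n-samples 1000 --out digits.npz
snm train --seed 0 --out model.h5
snm unlearn --model model.h5 --data digits.npz --mode class --target 3 \
    --out unlearned.h5 --report report.json
snm sweep --fractions 0.05,0.1,0.2,0.4 --seeds 0,1,2 --out sweep.csv
```

Every stage derives its randomness from the single run seed, so identical
config + seed reproduce every artifact byte-for-byte.

## Layout

| module | contents |
| --- | --- |
| `snm.neuron` | LIF / Izhikevich dynamics, spike trains, spike derivatives |
| `snm.plasticity` | synapse matrices, STDP, weight init / normalisation, dropout |
| `snm.network` | network construction, Poisson encoding, simulation, training, readout |
| `snm.unlearning` | the three-phase unlearning method and its operators |
| `snm.evaluation` | macro metrics, ROC AUC, MIA, trade-off sweeps |
| `snm.data` | synthetic image / time-series / separable generators, splits, forget specs |
| `snm.config`, `snm.io`, `snm.experiment`, `snm.cli` | YAML config, HDF5/npz/JSON containers, end-to-end experiments, CLI |

See `docs/methods.md` for the modelling assumptions, parameter defaults and
known limitations.
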