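# aptrans

Translate immature cardiac action potentials into adult ones — and tell
drug-free from drugged cells — with a multitask recurrent network trained
entirely on simulated data.

## The problem

Cardiomyocytes derived from induced pluripotent stem cells (iPSC-CMs) are
the workhorse of in vitro cardiac safety pharmacology, but they are
electrically *immature*: they beat spontaneously, rest at depolarized
potentials, and balance their ionic currents differently from adult
ventricular myocytes. A drug effect measured on an iPSC-CM action
potential (AP) therefore does not directly predict the effect on the
adult heart. `aptrans` implements a sequence-to-sequence translator for
this gap: a network that maps a 701-sample immature AP waveform
V(t), t = 0…701 ms, to the adult AP waveform at the same beating rate,
while simultaneously classifying whether the input cell was exposed to an
I_Kr (hERG-channel) blocking drug.

The package is aimed at computational electrophysiologists and ML
practitioners who want a complete, self-contained, single-CPU
reproduction of this workflow: a reduced ionic-model simulator generates
the paired training populations, so no external data are required.

## What is inside

* **Simulator** (`aptrans.simulator`) — a reduced Hodgkin–Huxley-style
  cell with currents I_Na, I_CaL, I_Kr, I_Ks, I_to, I_K1 (+ I_f and a
  background current for the immature phenotype), Forward-Euler
  integration at 0.01 ms, additive membrane noise
  `V_{t+Δt} = V_t − I(V_t)Δt/C_m + ξ n √Δt` with ξ = 0.3, and two drug
  models: a simple conductance scaling `G_Kr → (1−b)·G_Kr` for
  b = 1–50 %, and a state-dependent open-channel binding scheme
  `db/dt = k_on[D]·p_open·(1−b) − k_off·b` at 2.72 ng/mL.
* **Dataset builder** (`aptrans.dataset`) — the paired population:
  208 drug-free, 250 simple-block (50 levels × 5 beating rates) and 300
  state-dependent samples (758 total); each spontaneously beating
  immature trace is paired with an adult cell paced at the immature
  trace's own last-beat cycle length; stratified 70:10:20 split.
* **Preprocessing** (`aptrans.preprocess`) — zero-phase (forward–backward
  Butterworth) noise filtering, population centering/max-normalization
  with exact inversion, and AP morphology features (APD90, V_max, MDP,
  peak).
* **Network** (`aptrans.network`, `aptrans.training`) — two stacked LSTM
  layers scanning the 701-sample sequence, a linear translation head and
  a sigmoid classification head on the flattened hidden sequence; joint
  loss `J = MSE + CrossEntropy`; ADAM (α = 10⁻³, β₁ = 0.9, β₂ = 0.999,
  ε = 10⁻⁸), mini-batch 64, dropout 0.2, ≤ 300 epochs with
  validation-based early stopping. All of it is plain numpy with
  hand-derived backpropagation (verified against finite differences); no
  deep-learning framework is required.
* **Evaluation & ablation** (`aptrans.metrics`, `aptrans.ablation`) —
  MSE, pooled R², APD90 prediction error, AUROC/accuracy/recall/
  precision; time-window feature ablation (zero a 100-ms input window,
  retrain, compare) and model ablation (single-LSTM and
  translation-only variants).

## A worked example

`examples/train_translator.py` builds 60 paired samples, trains for 40
epochs and evaluates on the held-out test split (about three minutes on
one CPU):

```
population: 60 pairs (42/6/12 train/val/test)
...
Translation
  MSE        R2      APD90 error
  0.0137     0.9207  5.93%
Classification
  AUROC   Accuracy  Recall  Precision
  1       91.7      0.875   1
```

The translation MSE is on the normalized voltage scale (training traces
span [−1, 1]); R² is pooled over all test samples and time points; the
APD90 error says the predicted adult action-potential duration is within
~6 % of the simulated truth; and the classifier ranks every drugged test
input above every drug-free one (AUROC 1), misclassifying one weakly
blocked trace at the 0.5 threshold. With the full
758-sample population and the default 300-epoch budget the same code
approaches the regime MSE < 0.003, R² ≈ 0.99, APD90 error < 4 % and
~90 % accuracy — a multi-hour single-CPU run.

Other examples: `simulate_population.py` (morphology of the three drug
conditions), `membrane_resistance.py` (the high-resistance plateau phase
that makes the AP drug-sensitive), `feature_ablation.py` (what happens
when that window is hidden from the network), `translate_trace.py`
(translating a raw, unseen 1400-ms recording).

A thin CLI wraps the same library:

```bash
aptrans simulate --seed 1 --out pop/       # write a population as CSV
aptrans train --data pop/ --out model/     # train, save params + manifest
aptrans evaluate --data pop/ --model model/
aptrans translate --model model/ --input traces.csv --out adult.csv
```

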