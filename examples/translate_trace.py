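"""Translate an 'experimental-style' immature AP into an adult AP.

Trains a small model, then translates an immature trace that the network
never saw — simulated from a perturbed immature cell (10 % slower Ca
kinetics, different noise seed) to stand in for an experimentally
recorded AP, including a raw length (1400 ms) that must be windowed.
Prints the drug probability and the morphology of the translated adult
AP.
"""

from dataclasses import replace

import numpy as np

from aptrans import simulator as sim
from aptrans.dataset import PopulationConfig, build_population, split_dataset
from aptrans.io import translate_trace
from aptrans.metrics import evaluate
from aptrans.network import NetConfig, init_params
from aptrans.pipeline import prepare_data
from aptrans.preprocess import morphology_features
from aptrans.training import TrainConfig, train

# train a small translator
config = PopulationConfig(n_drug_free=16, block_min=0.1, block_max=0.5,
                          block_step=0.1, rates_per_level=2,
                          n_state_dependent=14)
population = build_population(config, seed=3)
data = prepare_data(split_dataset(population, seed=0))
params = init_params(NetConfig(dtype="float32"), seed=0)
best, _ = train(data, params,
                TrainConfig(epochs=40, patience=40, batch_size=10,
                            eval_every=5, seed=0))

# an unseen immature cell: slightly slower Ca inactivation, new seed
cell = replace(sim.immature_params(), tau_f_hi=720.0)
protocol = sim.PacingProtocol(stim_amplitude=0.0, cycle_length_ms=982.0,
                              conditioning_beats=12, noisy_beats=20)
raw = sim.simulate_trace(cell, protocol, noise=sim.NoiseSpec(xi=0.3), seed=99)
raw_tail = raw.voltage[-1400:]  # a 1400-ms recording, as a rig would save it

adult_mv, drug_prob = translate_trace(
    raw_tail, best, data["stats_immature"], data["stats_adult"])

f = morphology_features(adult_mv)
print(f"input:  1400-ms immature recording, windowed to 701 ms")
print(f"output: adult AP with APD90 {f.apd90_ms:.1f} ms, "
      f"peak {f.peak_mv:.1f} mV, resting {f.mdp_mv:.1f} mV")
print(f"drug probability: {drug_prob:.3f} (drug-free input, so near 0)")
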