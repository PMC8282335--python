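"""Train the multitask translator on a small simulated population.

Builds 60 paired samples, preprocesses them (zero-phase filtering and
population normalization), trains the two-layer LSTM multitask network
for 40 epochs (float32, mini-batch 14 so the small dataset still yields
a useful number of optimizer updates), and prints the held-out test
metrics: translation MSE on the normalized scale, pooled R^2, APD90
prediction error (%), and classification accuracy/AUROC for drug-free
vs. drugged inputs.
"""

from aptrans.dataset import PopulationConfig, build_population, split_dataset
from aptrans.network import NetConfig, init_params
from aptrans.pipeline import prepare_data
from aptrans.training import TrainConfig, train
from aptrans.metrics import evaluate

config = PopulationConfig(
    n_drug_free=20,
    block_min=0.05, block_max=0.50, block_step=0.05,
    rates_per_level=2,
    n_state_dependent=20,
)
population = build_population(config, seed=2)
split = split_dataset(population, seed=0)
data = prepare_data(split)
print(f"population: {len(population)} pairs "
      f"({len(data['X_train'])}/{len(data['X_val'])}/{len(data['X_test'])} "
      f"train/val/test)")

params = init_params(NetConfig(dtype="float32"), seed=0)
best, history = train(data, params,
                      TrainConfig(epochs=40, patience=40, batch_size=14,
                                  eval_every=5, seed=0),
                      verbose=True)
report = evaluate(best, data["X_test"], data["Y_test"], data["labels_test"],
                  data["stats_adult"])
print()
print(report.table())
print("\nMSE is on the normalized voltage scale; APD90 error is the mean "
      "absolute percentage error of the predicted adult action-potential "
      "duration; accuracy is at the 0.5 drug-probability threshold.")
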