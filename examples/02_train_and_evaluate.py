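"""Train the full collaborative model on a small corpus and evaluate it.

Uses a reduced corpus and model so the script runs in well under a minute;
see docs/methods.md for the desk-scale benchmark configuration used by the
acceptance suite.

Run:  python examples/02_train_and_evaluate.py
"""

import warnings

from mtloc import (SimConfig, generate_corpus, model_config_for_sim,
                   samples_from_corpus, train)
from mtloc.io_formats import split_dataset
from mtloc.training import evaluate_predictions, predict_dataset

sim = SimConfig(n_proteins=80, length_range=(25, 40), seed=7)
samples = samples_from_corpus(generate_corpus(sim))
train_set, valid_set, test_set = split_dataset(samples, seed=7)
print(f"split: {len(train_set)} train / {len(valid_set)} valid / "
      f"{len(test_set)} test")

config = model_config_for_sim(sim, d_p=32, d_fe=32, d_f=32, n_gt_layers=1,
                              learning_rate=3e-3, beta=0.1, epochs=10,
                              seed=1)
result = train(config, train_set, valid_set)

curve = result.loss_curve()
print(f"\ntraining loss: {curve[0]:.4f} (epoch 1) -> {curve[-1]:.4f} "
      f"(epoch {len(curve)}); best validation epoch {result.best_epoch}")

bundles = predict_dataset(result.model, test_set)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    reports = evaluate_predictions(bundles, test_set)

print("\ntest metrics per task:")
header = f"{'task':<6}{'AP':>8}{'AUROC':>8}{'Fmax':>8}{'Hloss':>8}"
print(header)
for task in ("bp", "cc", "mf", "sl"):
    r = reports[task]
    print(f"{task:<6}{r.ap:>8.3f}{r.auroc:>8.3f}{r.fmax:>8.3f}{r.hloss:>8.3f}")
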