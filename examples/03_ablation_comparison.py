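"""Compare the full collaborative model against its ablations.

Four ablation flags mirror the model's design components:

* ``no_gt``   — skip the graph-transformer layers (input projection only);
* ``no_funA`` — replace cross-attention fusion by a feature sum;
* ``no_feaE`` — bypass the graph autoencoders (reconstruction weight 0);
* ``no_colT`` — drop the collaborative objective (GO BCE and reconstruction
  weights both 0), leaving pure localization training.

Run:  python examples/03_ablation_comparison.py   (a few minutes)
"""

import dataclasses
import warnings

import numpy as np

from mtloc import (SimConfig, generate_corpus, model_config_for_sim,
                   samples_from_corpus, train)
from mtloc.io_formats import split_dataset
from mtloc.training import evaluate_predictions, predict_dataset

sim = SimConfig(n_proteins=120, length_range=(25, 40), seed=3)
samples = samples_from_corpus(generate_corpus(sim))
train_set, valid_set, test_set = split_dataset(samples, seed=3)

base = model_config_for_sim(sim, d_p=32, d_fe=32, d_f=32, n_gt_layers=1,
                            learning_rate=3e-3, beta=0.1, epochs=12, seed=1)

variants = [("full", {}), ("no_gt", {"no_gt": True}),
            ("no_funA", {"no_funA": True}), ("no_feaE", {"no_feaE": True}),
            ("no_colT", {"no_colT": True})]

print(f"{'variant':<10}{'SL AUROC':>10}{'SL AP':>8}{'GO AUROC (mean)':>17}")
for name, flags in variants:
    config = dataclasses.replace(base, **flags)
    result = train(config, train_set, valid_set)
    bundles = predict_dataset(result.model, test_set)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reports = evaluate_predictions(bundles, test_set)
    go_auroc = np.nanmean([reports[t].auroc for t in ("bp", "cc", "mf")])
    print(f"{name:<10}{reports['sl'].auroc:>10.3f}{reports['sl'].ap:>8.3f}"
          f"{go_auroc:>17.3f}")
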