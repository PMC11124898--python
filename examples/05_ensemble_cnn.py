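"""Train the CNN ensemble on selected features of a small dataset.

Ten base 1-D CNNs (the default optimal hyperparameter group and its nine
nearest grid neighbours) are stacked through a small convolutional
meta-learner that reads their concatenated class probabilities.
"""

import numpy as np

import enoserot as er
from enoserot import ecnn
from enoserot.evaluation import LABEL_TO_INT, stratified_split
from enoserot.preprocess import fit_normalizer, apply_normalizer

records = er.simulate_dataset(n_per_class=40, env=er.default_environment("storage"),
                              seed=4)
table = er.extract_features([er.baseline_correct(r) for r in records])
y = table["label"].map(LABEL_TO_INT).to_numpy()

split = stratified_split(len(table), table["label"].to_numpy(), seed=0)
stats = fit_normalizer(table.iloc[split.train])
norm = apply_normalizer(table, stats)
cols = [c for c in norm.columns if c not in ("sample_id", "label", "environment")]
X = norm[cols].to_numpy(dtype=float)

cfg = ecnn.EnsembleConfig(train=ecnn.TrainConfig(epochs=60, seed=0), oof_folds=3)
print(f"base specs (kernel size, kernels) x 2 conv layers, around the optimal "
      f"{cfg.optimal_spec}:")
for spec in ecnn.neighbor_specs(cfg.optimal_spec, 10, X.shape[1]):
    print("  ", spec)

ens = ecnn.train_ensemble(X[split.train], y[split.train], cfg)
base_accs = [(b.predict(X[split.test]) == y[split.test]).mean() for b in ens.bases]
ens_acc = (ens.predict(X[split.test]) == y[split.test]).mean()
print(f"\nbase test accuracies: {np.round(base_accs, 3)}")
print(f"ensemble test accuracy: {ens_acc:.3f}")
print("\nThe meta-learner fuses the bases' probability outputs; its")
print("accuracy should sit at or above the better bases.")
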