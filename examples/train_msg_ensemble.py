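"""Train and evaluate a modified stacked generalization ensemble.

Fits three diverse base MLPs plus the level-1 MSG combiner (which
receives the 9 base outputs concatenated with the 11 input features,
a 20-element meta input), evaluates on a held-out test set and prints
the confusion matrix with the four summary statistics.
"""

from ecgfusion import evaluation, stacking
from ecgfusion.datasets import make_split_dataset
from ecgfusion.experiments import base_configs
from ecgfusion.mlp import TrainConfig

data = make_split_dataset(n_train_per_class=100, n_val_per_class=30,
                          n_test=1000, seed=11)
cfgs = base_configs(3, seed=11)
combiner_cfg = TrainConfig(hidden_neurons=45, epochs=1000,
                           init_weight_range=2.0, seed=11)
ensemble = stacking.fit_stacked(data.train_X, data.train_y, cfgs,
                                combiner_cfg, mode="msg")

preds = stacking.predict_ensemble_batch(ensemble, data.test_X)
cm = evaluation.confusion_matrix(preds, data.test_y, 3)
print(evaluation.format_report(cm))
print("\nSpecificity is the normal-class recall; the two sensitivities are"
      "\nthe PVC and other-class recalls; overall accuracy is trace/total.")
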