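"""Ten combination methods on one synthetic dataset.

Trains the three diverse base MLPs on a balanced synthetic training set
and scores every combiner — algebraic rules, voting, Borda, decision
templates, PSO-weighted averaging, SG and MSG — on a held-out test set.
Scaled down (60 beats/class training, 600 test beats) so it runs in
about a minute.
"""

from ecgfusion.datasets import make_split_dataset
from ecgfusion.experiments import METHOD_ORDER, base_configs, evaluate_all_methods

data = make_split_dataset(n_train_per_class=60, n_val_per_class=20,
                          n_test=600, seed=3)
acc = evaluate_all_methods(data, base_configs(3, seed=3), seed=3,
                           combiner_epochs=800)

print("test accuracy (%):")
for i in range(3):
    print(f"  base classifier {i + 1}:  {100 * acc[f'base_{i}']:6.2f}")
for name in METHOD_ORDER:
    print(f"  {name:>8}:  {100 * acc[name]:6.2f}")
print("\nThe trainable combiners (sg, msg) usually sit at the top; msg sees"
      "\nthe input features next to the base outputs, so it can also learn"
      "\nwhere each base classifier is reliable.")
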