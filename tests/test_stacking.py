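"""Stacked and modified stacked generalization."""

import numpy as np
import pytest

from ecgfusion import mlp, stacking
from ecgfusion.datasets import make_split_dataset


def _tiny_cfgs(seed=0, epochs=150):
    return [mlp.TrainConfig(8, epochs, 2.0, seed=seed + i) for i in range(3)]


def _combiner_cfg(mode, seed=0, epochs=300):
    return mlp.TrainConfig(stacking.DEFAULT_COMBINER_HIDDEN[mode], epochs,
                           2.0, seed=seed)


@pytest.fixture(scope="module")
def fitted(small_dataset):
    data = small_dataset
    out = {}
    for mode in ("sg", "msg"):
        out[mode] = stacking.fit_stacked(
            data.train_X, data.train_y, _tiny_cfgs(), _combiner_cfg(mode),
            mode=mode)
    return out


class TestMetaInput:
    def test_sg_meta_input_has_nine_elements_for_three_by_three(self):
        dp = np.arange(9, dtype=float).reshape(3, 3) / 10
        assert stacking.build_meta_input(dp, None, "sg").shape == (9,)

    def test_msg_meta_input_has_twenty_elements_with_eleven_features(self):
        dp = np.zeros((3, 3))
        x = np.zeros(11)
        assert stacking.build_meta_input(dp, x, "msg").shape == (20,)

    def test_msg_prefix_equals_sg_vector(self):
        rng = np.random.default_rng(0)
        dp = rng.random((3, 3))
        x = rng.random(11)
        sg = stacking.build_meta_input(dp, None, "sg")
        msg = stacking.build_meta_input(dp, x, "msg")
        np.testing.assert_array_equal(msg[:9], sg)
        np.testing.assert_array_equal(msg[9:], x)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            stacking.build_meta_input(np.zeros((3, 3)), None, "stack")


class TestFitStacked:
    def test_modes_differ_only_in_combiner_input_width(self, fitted):
        sg, msg = fitted["sg"], fitted["msg"]
        assert sg.combiner.layer_sizes[0] == 9
        assert msg.combiner.layer_sizes[0] == 20
        for a, b in zip(sg.base_models, msg.base_models):
            np.testing.assert_array_equal(a.w_hidden, b.w_hidden)

    def test_training_is_bit_reproducible(self, small_dataset):
        data = small_dataset
        kw = dict(mode="msg")
        a = stacking.fit_stacked(data.train_X, data.train_y, _tiny_cfgs(),
                                 _combiner_cfg("msg"), **kw)
        b = stacking.fit_stacked(data.train_X, data.train_y, _tiny_cfgs(),
                                 _combiner_cfg("msg"), **kw)
        np.testing.assert_array_equal(a.combiner.w_hidden, b.combiner.w_hidden)
        np.testing.assert_array_equal(a.base_models[2].w_out,
                                      b.base_models[2].w_out)

    def test_absent_class_rejected(self, small_dataset):
        data = small_dataset
        keep = data.train_y != 1
        with pytest.raises(ValueError, match="absent"):
            stacking.fit_stacked(data.train_X[keep], data.train_y[keep],
                                 _tiny_cfgs(), _combiner_cfg("msg"))

    def test_fewer_than_two_bases_rejected(self, small_dataset):
        data = small_dataset
        with pytest.raises(ValueError, match="at least 2"):
            stacking.fit_stacked(data.train_X, data.train_y,
                                 _tiny_cfgs()[:1], _combiner_cfg("sg"),
                                 mode="sg")

    def test_pretrained_bases_are_not_mutated(self, small_dataset):
        data = small_dataset
        bases = [mlp.train_classifier(data.train_X, data.train_y, 3, c)[0]
                 for c in _tiny_cfgs()]
        snapshots = [m.w_hidden.copy() for m in bases]
        stacking.fit_stacked(data.train_X, data.train_y, _tiny_cfgs(),
                             _combiner_cfg("msg"), mode="msg",
                             base_models=bases)
        for m, snap in zip(bases, snapshots):
            np.testing.assert_array_equal(m.w_hidden, snap)


class TestPredict:
    def test_supports_have_one_entry_per_class(self, fitted, small_dataset):
        supports, decision = stacking.predict_ensemble(
            fitted["msg"], small_dataset.test_X[0])
        assert supports.shape == (3,)
        assert decision == int(np.argmax(supports))

    def test_dimension_mismatch_rejected(self, fitted):
        with pytest.raises(ValueError, match="feature_dim"):
            stacking.predict_ensemble(fitted["msg"], np.zeros(7))

    def test_prediction_invariant_to_serialization(self, fitted, tmp_path,
                                                   small_dataset):
        model = fitted["msg"]
        stacking.save_ensemble(model, tmp_path / "m.json",
                               run_config={"seed": 0})
        loaded = stacking.load_ensemble(tmp_path / "m.json")
        X = small_dataset.test_X[:50]
        np.testing.assert_array_equal(
            stacking.predict_ensemble_batch(model, X),
            stacking.predict_ensemble_batch(loaded, X))

    def test_unanimous_confident_bases_reproduce_block_structure(self,
                                                                 small_dataset):
        data = small_dataset
        cfgs = [mlp.TrainConfig(8, 150, 2.0, seed=3)] * 3  # identical bases
        ens = stacking.fit_stacked(data.train_X, data.train_y, cfgs,
                                   _combiner_cfg("sg"), mode="sg")
        profiles = stacking.decision_profiles(ens.base_models,
                                              data.train_X[:20])
        # identical bases -> identical rows in every profile
        np.testing.assert_allclose(profiles[:, 0, :], profiles[:, 1, :])
        preds = stacking.predict_ensemble_batch(ens, data.train_X[:200])
        base_preds = mlp.predict_batch(ens.base_models[0],
                                       data.train_X[:200])
        assert np.mean(preds == base_preds) > 0.95


class TestMsgGeneralizesSg:
    def test_zeroed_feature_weights_reproduce_sg_behaviour(self, fitted,
                                                           small_dataset):
        # structural equivalence: an MSG combiner that ignores the
        # appended features computes exactly the SG function
        sg = fitted["sg"]
        msg_combiner = mlp.MLPModel(
            w_hidden=np.concatenate(
                [sg.combiner.w_hidden[:, :9],
                 np.zeros((sg.combiner.w_hidden.shape[0], 11)),
                 sg.combiner.w_hidden[:, 9:]], axis=1),
            w_out=sg.combiner.w_out.copy())
        msg = stacking.EnsembleModel(base_models=sg.base_models,
                                     combiner=msg_combiner, mode="msg",
                                     feature_dim=11, class_count=3)
        X = small_dataset.test_X[:100]
        np.testing.assert_allclose(
            stacking.ensemble_supports(msg, X),
            stacking.ensemble_supports(sg, X), atol=1e-12)

    def test_msg_beats_sg_when_expertise_is_segregated(self):
        # each base over-trained on one class region: the combiner can
        # only exploit that if it sees where the input lies
        msgs, sgs = [], []
        for k in range(10):
            seed = 2000 + k
            data = make_split_dataset(n_train_per_class=150,
                                      n_val_per_class=30, n_test=900,
                                      seed=seed)
            rng = np.random.default_rng(seed)
            n = len(data.train_y)
            cfgs = [mlp.TrainConfig(12, 400, 2.0, seed=seed + i)
                    for i in range(3)]
            subsets = [np.flatnonzero((data.train_y == i)
                                      | (rng.random(n) < 0.10))
                       for i in range(3)]
            for mode, acc in (("sg", sgs), ("msg", msgs)):
                ccfg = mlp.TrainConfig(stacking.DEFAULT_COMBINER_HIDDEN[mode],
                                       800, 2.0, seed=seed + 7)
                ens = stacking.fit_stacked(data.train_X, data.train_y, cfgs,
                                           ccfg, mode=mode,
                                           base_subsets=subsets)
                acc.append(np.mean(stacking.predict_ensemble_batch(
                    ens, data.test_X) == data.test_y))
        assert np.mean(msgs) > np.mean(sgs)


class TestWidthSearch:
    def test_single_width_returned(self, small_dataset):
        data = small_dataset
        bases = [mlp.train_classifier(data.train_X, data.train_y, 3, c)[0]
                 for c in _tiny_cfgs()]
        best, table = stacking.search_combiner_width(
            bases, data.train_X, data.train_y, data.val_X, data.val_y,
            widths=[12], mode="msg", combiner_epochs=100)
        assert best == 12 and set(table) == {12}

    def test_returned_width_attains_table_maximum(self, small_dataset):
        data = small_dataset
        bases = [mlp.train_classifier(data.train_X, data.train_y, 3, c)[0]
                 for c in _tiny_cfgs()]
        best, table = stacking.search_combiner_width(
            bases, data.train_X, data.train_y, data.val_X, data.val_y,
            widths=[5, 15, 30], mode="sg", combiner_epochs=100)
        assert table[best] == max(table.values())

    def test_empty_validation_rejected(self, small_dataset):
        data = small_dataset
        bases = [mlp.train_classifier(data.train_X, data.train_y, 3, c)[0]
                 for c in _tiny_cfgs()[:2]]
        with pytest.raises(ValueError, match="validation"):
            stacking.search_combiner_width(
                bases, data.train_X, data.train_y, np.empty((0, 11)),
                np.empty(0, dtype=int), widths=[5])
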