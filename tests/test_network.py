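"""Architecture contracts, FLOPs accounting, training behaviour."""

import numpy as np
import pytest

from renalus.network import (
    DEFAULT_FILTERS,
    FastUnetSegmenter,
    NetworkConfig,
    TrainConfig,
    build_model,
    count_flops,
    grid_search,
    layer_plan,
    postprocess_probability,
    predict_mask,
    train,
)

SMALL = NetworkConfig(depth=3, filters_per_level=(4, 8, 16), input_shape=(32, 32, 1))


class TestArchitecture:
    def test_output_shape_and_range(self):
        model = build_model(SMALL, seed=0)
        x = np.random.default_rng(0).random((2, 32, 32), dtype=np.float32)
        y = model.forward(x)
        assert y.shape == (2, 1, 32, 32)
        assert y.min() >= 0.0 and y.max() <= 1.0

    def test_no_pooling_layers_anywhere(self):
        for nested in (True, False):
            cfg = NetworkConfig(depth=3, filters_per_level=(4, 8, 16),
                                input_shape=(32, 32, 1), nested=nested)
            ops = {s["op"] for s in layer_plan(cfg)}
            assert ops <= {"conv", "convT", "bn", "lrelu", "relu", "dropout",
                           "concat", "sigmoid"}

    def test_nested_grid_node_inputs(self):
        plan = {s["name"]: s for s in layer_plan(SMALL)}
        # group one: first nested column fuses encoder + upsampled deeper level
        assert plan["n0_1_cat"]["inputs"] == ["n0_1_b", "x0_0"]
        # group two: adds the previous node of the same level
        assert plan["n0_2_cat"]["inputs"] == ["n0_2_b", "x0_1", "x0_0"]

    def test_plain_variant_has_no_nested_nodes(self):
        cfg = NetworkConfig(depth=3, filters_per_level=(4, 8, 16),
                            input_shape=(32, 32, 1), nested=False)
        names = [s["name"] for s in layer_plan(cfg)]
        assert not any(n.startswith("n") for n in names)
        n_enc = sum(1 for n in names if n.startswith("enc") and n.count("_") == 0)
        n_dec = sum(1 for s in layer_plan(cfg) if s["op"] == "convT")
        assert n_enc == cfg.depth
        assert n_dec == cfg.depth  # depth-1 decoder stages + the output stage

    def test_seeded_build_reproducible(self):
        a = build_model(SMALL, seed=3)
        b = build_model(SMALL, seed=3)
        assert a.num_parameters() == b.num_parameters()
        for wa, wb in zip(a.get_weights(), b.get_weights()):
            assert np.array_equal(wa, wb)

    def test_indivisible_input_shape_rejected(self):
        cfg = NetworkConfig(depth=3, filters_per_level=(4, 8, 16), input_shape=(30, 32, 1))
        with pytest.raises(ValueError, match="divisible"):
            cfg.validate()


class TestFlops:
    def test_single_layer_formula(self):
        cfg = NetworkConfig(depth=3, filters_per_level=(4, 8, 16), input_shape=(32, 32, 1))
        report = count_flops(cfg)
        first = report.to_frame().iloc[0]
        # 2 * K^2 * C_in * C_out * N for the first encoder convolution
        assert first["flops"] == 2 * 25 * 1 * 4 * 16 * 16

    def test_default_config_near_printed_total(self):
        total = count_flops(NetworkConfig()).total
        assert abs(total - 1.5e10) / 1.5e10 < 0.10

    def test_total_is_sum_of_layers_and_weight_independent(self):
        report = count_flops(SMALL)
        assert report.total == report.to_frame()["flops"].sum()
        assert count_flops(SMALL).total == report.total

    def test_zero_filters_rejected(self):
        cfg = NetworkConfig(depth=3, filters_per_level=(4, 0, 16), input_shape=(32, 32, 1))
        with pytest.raises(ValueError):
            count_flops(cfg)


class TestTraining:
    def _toy_data(self, n=24, size=32, seed=0):
        from tests.conftest import ellipse_mask

        gen = np.random.default_rng(seed)
        xs, ys = [], []
        for _ in range(n):
            a = gen.uniform(8, 12)
            b = gen.uniform(4, 6)
            m = ellipse_mask((size, size), (size / 2, size / 2), a, b)
            img = np.where(m, 0.7, 0.2) + 0.05 * gen.standard_normal((size, size))
            xs.append(img.astype(np.float32))
            ys.append(m)
        return np.stack(xs), np.stack(ys).astype(np.float32)

    def test_learning_reduces_loss_and_history_bookkeeping(self):
        x, y = self._toy_data()
        model = build_model(SMALL, seed=0)
        tc = TrainConfig(batch_size=8, max_steps=6, learning_rate=1e-3, seed=0)
        model, hist = train(model, (x, y), tc)
        assert len(hist) == 6
        assert list(hist.columns) == ["step", "loss", "val_dsc"]
        assert hist["loss"].iloc[-1] < hist["loss"].iloc[0]

    def test_zero_learning_rate_leaves_loss_unchanged(self):
        x, y = self._toy_data()
        cfg = NetworkConfig(depth=3, filters_per_level=(4, 8, 16),
                            input_shape=(32, 32, 1), dropout_rate=0.0)
        model = build_model(cfg, seed=0)
        tc = TrainConfig(batch_size=8, max_steps=3, learning_rate=0.0, seed=0,
                         shuffle_each_epoch=False)
        _, hist = train(model, (x, y), tc)
        assert hist["loss"].std() == pytest.approx(0.0, abs=1e-6)

    def test_empty_dataset_and_shape_mismatch_rejected(self):
        model = build_model(SMALL, seed=0)
        tc = TrainConfig()
        with pytest.raises(ValueError, match="empty"):
            train(model, (np.zeros((0, 32, 32)), np.zeros((0, 32, 32))), tc)
        with pytest.raises(ValueError, match="mismatch"):
            train(model, (np.zeros((2, 32, 32)), np.zeros((2, 16, 16))), tc)


class TestPredictMask:
    def test_zero_probability_gives_empty_mask(self):
        assert not postprocess_probability(np.zeros((16, 16))).any()

    def test_clean_blob_is_idempotent(self, rng):
        from tests.conftest import ellipse_mask

        blob = ellipse_mask((32, 32), (16, 16), 10, 6)
        assert np.array_equal(postprocess_probability(blob.astype(float)), blob)

    def test_largest_component_survives(self):
        prob = np.zeros((64, 64))
        prob[5:30, 5:25] = 0.9   # 500 px
        prob[50:54, 50:55] = 0.9  # 20 px
        mask = postprocess_probability(prob)
        assert mask[10, 10] and not mask[51, 51]

    def test_resize_roundtrip_preserves_frame(self):
        model = build_model(SMALL, seed=0)
        img = np.random.default_rng(1).random((48, 48))
        prob, mask = predict_mask(model, img)
        assert prob.shape == (48, 48) and mask.shape == (48, 48)

    def test_non_grayscale_rejected(self):
        model = build_model(SMALL, seed=0)
        with pytest.raises(ValueError, match="grayscale|2-D"):
            predict_mask(model, np.zeros((16, 16, 3)))


class TestGridSearch:
    def test_single_combination_returned(self):
        best, score, _ = grid_search({"lr": [0.1]}, lambda p: p, lambda t: 0.5)
        assert best == {"lr": 0.1}

    def test_monotone_stub_selects_largest(self):
        grid = {"learning_rate": [1e-4, 1e-3, 1e-2], "batch_size": [8, 16]}
        best, score, results = grid_search(grid, lambda p: p, lambda t: t["learning_rate"])
        assert best["learning_rate"] == 1e-2
        assert len(results) == 6

    def test_tie_keeps_first_in_iteration_order(self):
        best, _, _ = grid_search({"k": [3, 5]}, lambda p: p, lambda t: 1.0)
        assert best == {"k": 3}

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            grid_search({}, lambda p: p, lambda t: 0.0)


def test_estimator_sklearn_contract():
    est = FastUnetSegmenter(depth=3, base_filters=4, max_steps=2, batch_size=8,
                            learning_rate=1e-3, random_state=0)
    params = est.get_params()
    assert params["depth"] == 3
    est.set_params(max_steps=1)
    assert est.max_steps == 1

    from tests.conftest import ellipse_mask

    x = np.stack([np.where(ellipse_mask((32, 32), (16, 16), 10, 5), 0.8, 0.2)] * 12)
    y = np.stack([ellipse_mask((32, 32), (16, 16), 10, 5)] * 12).astype(np.float32)
    est.fit(x, y)
    assert hasattr(est, "model_") and hasattr(est, "history_")
    masks = est.predict(x[:2])
    assert masks.shape == (2, 32, 32) and masks.dtype == bool

    assert DEFAULT_FILTERS == (14, 28, 56, 112, 224)
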