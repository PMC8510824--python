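"""Cascade assembly: augmentation, fusion, confidence gating, weighting."""

import numpy as np
import pytest

from cfnforest.cascade import (
    CascadeConfig,
    CascadeLayer,
    CascadeModel,
    ConfidenceRegion,
    augment,
    confidence_split,
    fit_cascade,
    fuse_outputs,
    layer_weight,
)
from cfnforest.evolution import GGGPConfig
from cfnforest.fnt import FunctionSet
from cfnforest.group_forest import ClassCodec, FNTGroup, FNTGroupForest
from cfnforest.pso import PSOConfig
from cfnforest.synth import SyntheticSpec, make_dataset, make_worked_example
from cfnforest.expression import preprocess

from test_group_forest import constant_tree


def constant_layer(bit_values, input_dim, codec):
    """Three distinct-function-set forests, each emitting fixed bit values."""
    fsets = [FunctionSet(a) for a in ((2, 3, 4), (2, 3, 5), (2, 4, 5))]
    forests = []
    for f_i, fs in enumerate(fsets):
        trees = [constant_tree(v, input_dim, fs) for v in bit_values[f_i]]
        forests.append(FNTGroupForest([FNTGroup(trees)], fs, codec))
    return CascadeLayer(forests)


class TestAugment:
    def test_width_formula(self, rng):
        X = rng.normal(size=(10, 10))
        outs = [rng.uniform(size=(10, 2)) for _ in range(3)]
        assert augment(X, outs).shape == (10, 16)  # 10 + 3*2

    def test_base_columns_preserved_bit_exact(self, rng):
        X = rng.normal(size=(6, 4))
        outs = [rng.uniform(size=(6, 1)) for _ in range(3)]
        assert np.array_equal(augment(X, outs)[:, :4], X)

    def test_zero_width_enhancement_rejected(self, rng):
        X = rng.normal(size=(5, 3))
        with pytest.raises(ValueError):
            augment(X, [np.empty((5, 0))] * 3)

    def test_row_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="row"):
            augment(rng.normal(size=(5, 3)), [rng.uniform(size=(4, 1))] * 3)


class TestFuse:
    def test_identical_outputs_idempotent(self, rng):
        o = rng.uniform(size=(4, 2))
        assert np.allclose(fuse_outputs([o, o.copy(), o.copy()]), o)

    def test_arithmetic_mean(self):
        outs = [np.array([[0.0, 0.0]]), np.array([[0.3, 0.6]]),
                np.array([[0.6, 0.0]])]
        assert np.allclose(fuse_outputs(outs), [[0.3, 0.2]])

    def test_bounded_by_envelope(self, rng):
        outs = [rng.uniform(size=(5, 2)) for _ in range(3)]
        fused = fuse_outputs(outs)
        stack = np.stack(outs)
        assert np.all(fused >= stack.min(0) - 1e-12)
        assert np.all(fused <= stack.max(0) + 1e-12)


class TestConfidenceSplit:
    def test_worked_vectors_split_by_component_rule(self):
        region = ConfidenceRegion(0.2, 0.8)
        outputs = np.stack(make_worked_example())
        conf, unc = confidence_split(outputs, region)
        # every component inside [0,0.2] U [0.8,1]: vectors 0, 3 and 4
        assert list(conf) == [0, 3, 4]
        assert list(unc) == [1, 2]

    def test_boundary_values_are_confident(self):
        conf, unc = confidence_split(np.array([[0.2, 0.8]]),
                                     ConfidenceRegion(0.2, 0.8))
        assert list(conf) == [0]

    def test_partition_exhaustive_and_disjoint(self, rng):
        out = rng.uniform(size=(50, 2))
        conf, unc = confidence_split(out, ConfidenceRegion(0.2, 0.8))
        merged = np.sort(np.concatenate([conf, unc]))
        assert np.array_equal(merged, np.arange(50))


class TestLayerWeight:
    def test_single_layer(self):
        assert layer_weight(1, 1) == 1.0

    def test_three_layer_normalized(self):
        w = [layer_weight(i, 3) for i in (1, 2, 3)]
        assert w == pytest.approx([1 / 6, 1 / 3, 1 / 2])
        assert sum(w) == pytest.approx(1.0)

    def test_literal_printed_form(self):
        assert layer_weight(2, 3, mode="literal") == pytest.approx(2 / 3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            layer_weight(0, 3)
        with pytest.raises(ValueError):
            layer_weight(4, 3)


class TestPredict:
    def _codec(self):
        return ClassCodec(("a", "b", "c", "d"))

    def test_single_layer_equals_fused_output(self, rng):
        codec = self._codec()
        layer = constant_layer([(0.2, 0.6), (0.4, 0.8), (0.3, 0.7)], 5, codec)
        model = CascadeModel([layer], codec, ConfidenceRegion(0.2, 0.8), 5)
        yf, exits = model.predict_scores(rng.normal(size=(4, 5)))
        assert np.allclose(yf, [[0.3, 0.7]] * 4)
        assert np.all(exits == 1)

    def test_confident_sample_uses_first_layer_only(self, rng):
        codec = self._codec()
        l1 = constant_layer([(0.1, 0.1)] * 3, 5, codec)       # confident
        l2 = constant_layer([(0.7, 0.9)] * 3, 5 + 6, codec)
        model = CascadeModel([l1, l2], codec, ConfidenceRegion(0.2, 0.8), 5)
        yf, exits = model.predict_scores(rng.normal(size=(3, 5)))
        assert np.all(exits == 1)
        assert np.allclose(yf, [[0.1, 0.1]] * 3)

    def test_two_layer_weighted_fusion_arithmetic(self, rng):
        codec = self._codec()
        l1 = constant_layer([(0.1, 0.1)] * 3, 5, codec)
        l2 = constant_layer([(0.7, 0.9)] * 3, 5 + 6, codec)
        # a region nothing falls into forces full traversal
        model = CascadeModel([l1, l2], codec, ConfidenceRegion(0.01, 0.99), 5)
        yf, exits = model.predict_scores(rng.normal(size=(2, 5)))
        assert np.all(exits == 2)
        # y_f = (1/3)*y1 + (2/3)*y2
        assert np.allclose(yf, [[0.5, 0.9 * 2 / 3 + 0.1 / 3]] * 2)

    def test_degenerate_region_disables_gate(self, rng):
        codec = self._codec()
        l1 = constant_layer([(0.4, 0.6)] * 3, 5, codec)
        l2 = constant_layer([(0.9, 0.9)] * 3, 11, codec)
        model = CascadeModel([l1, l2], codec, ConfidenceRegion(0.5, 0.5), 5)
        yf, exits = model.predict_scores(rng.normal(size=(3, 5)))
        assert np.all(exits == 1)
        assert np.allclose(yf, [[0.4, 0.6]] * 3)

    def test_scores_always_in_unit_interval_and_exits_stable(self, rng):
        codec = self._codec()
        l1 = constant_layer([(0.3, 0.9), (0.1, 0.5), (0.8, 0.2)], 5, codec)
        model = CascadeModel([l1], codec, ConfidenceRegion(0.2, 0.8), 5)
        X = rng.normal(size=(10, 5))
        yf1, e1 = model.predict_scores(X)
        yf2, e2 = model.predict_scores(X)
        assert np.all((yf1 >= 0) & (yf1 <= 1))
        assert np.array_equal(e1, e2) and np.array_equal(yf1, yf2)

    def test_width_mismatch_rejected(self, rng):
        codec = self._codec()
        layer = constant_layer([(0.3, 0.7)] * 3, 5, codec)
        model = CascadeModel([layer], codec, ConfidenceRegion(0.2, 0.8), 5)
        with pytest.raises(ValueError):
            model.predict_scores(rng.normal(size=(3, 6)))

    def test_serialization_round_trip(self, rng):
        codec = self._codec()
        layer = constant_layer([(0.3, 0.7), (0.2, 0.9), (0.5, 0.1)], 5, codec)
        model = CascadeModel([layer], codec, ConfidenceRegion(0.2, 0.8), 5)
        clone = CascadeModel.from_dict(model.to_dict())
        X = rng.normal(size=(4, 5))
        assert np.allclose(clone.predict_scores(X)[0],
                           model.predict_scores(X)[0])


class TestFit:
    def _small_data(self, seed=0):
        X, y = make_dataset(SyntheticSpec(
            n_per_class=(16, 16), n_genes=12, n_informative=4,
            shift=3.0, missing_rate=0.0, seed=seed,
        ))
        Xn, _, _ = preprocess(X)
        return Xn.values, y

    def _cfg(self, **kw):
        base = dict(
            K=2,
            gggp=GGGPConfig(population_size=10, generations=4),
            pso=PSOConfig(swarm_size=8, iterations=5),
            outer_rounds=1,
            max_layers=2,
        )
        base.update(kw)
        return CascadeConfig(**base)

    def test_single_layer_model_weight_one(self):
        Xv, y = self._small_data()
        model, info = fit_cascade(Xv, y, self._cfg(max_layers=1), seed=0)
        assert model.n_layers == 1
        assert np.allclose(model.layer_weights(), [1.0])

    def test_uncertain_counts_non_increasing(self):
        Xv, y = self._small_data()
        _, info = fit_cascade(Xv, y, self._cfg(max_layers=3, patience=3), seed=1)
        counts = info.uncertain_counts
        assert all(b <= a for a, b in zip(counts, counts[1:]))

    def test_fit_deterministic_under_seed(self):
        Xv, y = self._small_data()
        m1, _ = fit_cascade(Xv, y, self._cfg(), seed=5)
        m2, _ = fit_cascade(Xv, y, self._cfg(), seed=5)
        assert m1.to_dict() == m2.to_dict()

    def test_retained_depth_is_best_validated(self):
        Xv, y = self._small_data()
        model, info = fit_cascade(Xv, y, self._cfg(max_layers=2, patience=2),
                                  seed=2)
        accs = info.layer_val_accuracy[: model.n_layers]
        assert info.layer_val_accuracy[model.n_layers - 1] == max(
            info.layer_val_accuracy
        )

    def test_tiny_class_fails_validation_split(self):
        rng = np.random.default_rng(0)
        Xv = rng.normal(size=(9, 4))
        from cfnforest.expression import LabelSet

        y = LabelSet([f"s{i}" for i in range(9)], ["a"] * 8 + ["b"])
        with pytest.raises(ValueError, match="class"):
            fit_cascade(Xv, y, self._cfg(), seed=0)

    def test_exit_counts_cover_all_training_rows(self):
        Xv, y = self._small_data()
        model, info = fit_cascade(Xv, y, self._cfg(), seed=3)
        assert sum(info.exit_counts.values()) == info.n_train
        assert set(info.exit_counts) <= set(range(1, model.n_layers + 1))
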