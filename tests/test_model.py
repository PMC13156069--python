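import numpy as np
import pytest
from dataclasses import replace

from ssep.features import FeatureBundle
from ssep.model import (
    ConfigurationError,
    ModelConfig,
    build_model,
    fine_tune,
    grid_search,
    inverse_transform,
    predict_pair,
    pretrain,
    stack_bundles,
    target_transform,
)


def linear_config(dims, **kw):
    base = dict(encoder_width=0, trunk_widths=(), activation="identity",
                dropout=0.0, learning_rate=0.05, batch_size=512, max_epochs=3000)
    base.update(kw)
    return ModelConfig(block_dims=dims, **base)


@pytest.fixture
def linear_data(rng):
    Xa = rng.standard_normal((200, 3))
    Xb = rng.standard_normal((200, 2))
    beta = np.array([1.5, -2.0, 0.5, 0.7, -1.2])
    y = np.hstack([Xa, Xb]) @ beta + 0.3
    return {"a": Xa, "b": Xb}, y, beta


class TestTargetScale:
    @pytest.mark.parametrize("pct, expected", [(100.0, 0.0), (1000.0, 1.0), (0.0, -3.0)])
    def test_anchors_and_clip(self, pct, expected):
        assert target_transform(pct) == pytest.approx(expected)

    def test_monotone_and_invertible_above_floor(self, rng):
        pct = rng.uniform(0.2, 900, 50)
        t = target_transform(pct)
        assert np.all(np.diff(t[np.argsort(pct)]) >= 0)
        assert np.allclose(inverse_transform(t), pct)


class TestArchitecture:
    def test_degenerate_architecture_is_affine(self, rng):
        cfg = linear_config((("a", 3), ("b", 2)))
        m = build_model(cfg)
        X1 = {"a": rng.standard_normal((4, 3)), "b": rng.standard_normal((4, 2))}
        X2 = {"a": rng.standard_normal((4, 3)), "b": rng.standard_normal((4, 2))}
        lhs = m.predict({k: X1[k] + X2[k] for k in X1})
        rhs = m.predict(X1) + m.predict(X2) - m.predict({k: 0 * v for k, v in X1.items()})
        assert np.allclose(lhs, rhs)

    def test_forward_returns_finite_scalar_per_row(self, rng):
        cfg = ModelConfig(block_dims=(("a", 3), ("b", 2)))
        m = build_model(cfg)
        pred = m.predict({"a": rng.standard_normal((5, 3)), "b": rng.standard_normal((5, 2))})
        assert pred.shape == (5,)
        assert np.all(np.isfinite(pred))

    def test_unconfigured_block_rejected(self, rng):
        uv = build_model(ModelConfig(block_dims=(("mutation", 5),)), route="UV")
        with pytest.raises(ConfigurationError, match="ligand"):
            uv.predict({"mutation": rng.standard_normal((2, 5)),
                        "ligand": rng.standard_normal((2, 4))})

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            ModelConfig(block_dims=(("a", 3),), dropout=1.5)
        with pytest.raises(ConfigurationError):
            ModelConfig(block_dims=())


class TestPretrain:
    def test_linear_limit_matches_least_squares(self, linear_data):
        X, y, _ = linear_data
        m = build_model(linear_config((("a", 3), ("b", 2))))
        m = pretrain(m, X, y, split_fraction=1.0, seed=0)
        design = np.hstack([X["a"], X["b"], np.ones((y.size, 1))])
        beta_ols = np.linalg.lstsq(design, y, rcond=None)[0]
        learned = np.concatenate([m.net.params["out_W"].ravel(), m.net.params["out_b"]])
        assert np.abs(learned - beta_ols).max() < 1e-3
        assert np.mean((m.predict(X) - y) ** 2) < 1e-4

    def test_constant_targets_predicted(self, rng):
        X = {"a": rng.standard_normal((40, 3))}
        y = np.full(40, 0.7)
        m = build_model(linear_config((("a", 3),), max_epochs=800))
        m = pretrain(m, X, y, split_fraction=1.0, seed=0)
        assert np.allclose(m.predict(X), 0.7, atol=1e-2)

    def test_seeded_determinism(self, linear_data):
        X, y, _ = linear_data
        cfg = ModelConfig(block_dims=(("a", 3), ("b", 2)), max_epochs=25, seed=3)
        m1 = pretrain(build_model(cfg), X, y, seed=9)
        m2 = pretrain(build_model(cfg), X, y, seed=9)
        assert m1.training_log == m2.training_log
        assert np.array_equal(m1.predict(X), m2.predict(X))

    def test_too_few_pairs_rejected(self, rng):
        X = {"a": rng.standard_normal((5, 3))}
        with pytest.raises(ValueError, match=">= 10"):
            pretrain(build_model(ModelConfig(block_dims=(("a", 3),))), X, np.ones(5))

    def test_checkpoint_roundtrip(self, linear_data):
        from ssep.model import TrainedModel

        X, y, _ = linear_data
        cfg = ModelConfig(block_dims=(("a", 3), ("b", 2)), max_epochs=20)
        m = pretrain(build_model(cfg), X, y, seed=1)
        back = TrainedModel.from_dict(m.to_dict())
        assert np.array_equal(back.predict(X), m.predict(X))


class TestFineTune:
    def test_zero_learning_rate_is_noop(self, linear_data):
        X, y, _ = linear_data
        cfg = replace(linear_config((("a", 3), ("b", 2))), fine_tune_learning_rate=0.0,
                      max_epochs=50)
        m = pretrain(build_model(cfg), X, y, split_fraction=1.0, seed=0)
        before = {k: v.copy() for k, v in m.net.params.items()}
        m, _ = fine_tune(m, X, y, seed=0)
        assert all(np.array_equal(before[k], m.net.params[k]) for k in before)

    def test_empty_dms_warns_and_noops(self, linear_data):
        X, y, _ = linear_data
        cfg = linear_config((("a", 3), ("b", 2)), max_epochs=50)
        m = pretrain(build_model(cfg), X, y, split_fraction=1.0, seed=0)
        before = {k: v.copy() for k, v in m.net.params.items()}
        with pytest.warns(UserWarning, match="empty DMS"):
            m, rep = fine_tune(m, {"a": np.empty((0, 3)), "b": np.empty((0, 2))},
                               np.empty(0))
        assert rep.n_records == 0
        assert all(np.array_equal(before[k], m.net.params[k]) for k in before)

    def test_consistent_data_does_not_degrade(self, linear_data):
        X, y, _ = linear_data
        cfg = replace(linear_config((("a", 3), ("b", 2))), fine_tune_learning_rate=5e-3,
                      fine_tune_epochs=50)
        m = pretrain(build_model(cfg), X, y, split_fraction=1.0, seed=0)
        m, rep = fine_tune(m, X, y, seed=0, eval_set=(X, y))
        assert rep.rho_after >= rep.rho_before - 0.02


class TestGridSearch:
    def test_single_config_returned(self, linear_data):
        X, y, _ = linear_data
        base = ModelConfig(block_dims=(("a", 3), ("b", 2)), max_epochs=15)
        best, report = grid_search(base, [{"learning_rate": 1e-3}], X, y, n_repeats=1)
        assert best.learning_rate == 1e-3
        assert len(report) == 1

    def test_true_architecture_wins_on_linear_data(self, linear_data):
        X, y, _ = linear_data
        base = linear_config((("a", 3), ("b", 2)), max_epochs=300)
        grid = [
            {},  # the generating (linear) architecture
            {"encoder_width": 8, "trunk_widths": (8,), "activation": "relu",
             "dropout": 0.7, "learning_rate": 1e-3},
        ]
        best, report = grid_search(base, grid, X, y, n_repeats=2, seeds=[0, 1])
        assert best.trunk_widths == ()

    def test_tie_prefers_smaller_model(self, rng):
        # constant-ish targets: both configs reach the same (nan -> 0) rho
        X = {"a": rng.standard_normal((40, 2))}
        y = rng.standard_normal(40)
        base = ModelConfig(block_dims=(("a", 2),), max_epochs=2)
        grid = [{"trunk_widths": (32, 16)}, {"trunk_widths": (4,)}]
        best, report = grid_search(base, grid, X, y, n_repeats=1, seeds=[0])
        if report["mean_rho"].nunique() == 1:
            assert best.trunk_widths == (4,)

    def test_empty_grid_rejected(self, linear_data):
        X, y, _ = linear_data
        with pytest.raises(ValueError):
            grid_search(ModelConfig(block_dims=(("a", 3),)), [], X, y)


def _const_model(dims, value):
    """A model whose output is exactly `value` for any input."""
    m = build_model(linear_config(dims))
    m.net.params["out_W"][:] = 0.0
    m.net.params["out_b"][:] = value
    return m


class TestPredictPair:
    def _bundle(self, structure, full=True, interaction=0.0):
        blocks = {
            "embedding": np.zeros(4), "insilico": np.zeros(2) if full else None,
            "mutation": np.zeros(5), "ligand": np.zeros(4),
            "interaction": np.array([interaction, 0.0, 0.0]),
        }
        return FeatureBundle(variant="p.A2V", substrate="m", blocks=blocks,
                             structure_id=structure)

    def _models(self):
        full_dims = (("embedding", 4), ("insilico", 2), ("mutation", 5),
                     ("ligand", 4), ("interaction", 3))
        uv_dims = (("embedding", 4), ("mutation", 5), ("ligand", 4), ("interaction", 3))
        return {"SNV": _const_model(full_dims, 0.3), "UV": _const_model(uv_dims, -0.5)}

    def test_mean_over_structures(self):
        models = self._models()
        models["SNV"].net.params["out_W"][:] = 0.0
        # make SNV output depend on the first interaction coordinate
        idx = sum(d for _, d in models["SNV"].config.block_dims[:-1])
        models["SNV"].net.params["out_b"][:] = 0.0
        models["SNV"].net.params["out_W"][idx, 0] = 1.0
        score = predict_pair(models, [self._bundle("s1", interaction=0.2),
                                      self._bundle("s2", interaction=0.4)])
        assert score.score == pytest.approx(0.3)
        assert score.n_structures_averaged == 2
        assert score.route == "SNV"

    def test_structure_order_invariance(self):
        models = self._models()
        b1, b2 = self._bundle("s1", interaction=0.1), self._bundle("s2", interaction=0.9)
        assert predict_pair(models, [b1, b2]).score == predict_pair(models, [b2, b1]).score

    def test_majority_routes_to_uv(self):
        models = self._models()
        bundles = [self._bundle("s1", full=False), self._bundle("s2", full=False),
                   self._bundle("s3", full=True)]
        assert predict_pair(models, bundles).route == "UV"

    def test_tie_routes_to_snv(self):
        models = self._models()
        bundles = [self._bundle("s1", full=False), self._bundle("s2", full=True)]
        assert predict_pair(models, bundles).route == "SNV"

    def test_empty_bundles_error(self):
        with pytest.raises(ValueError):
            predict_pair(self._models(), [])

    def test_mixed_pairs_rejected(self):
        b1 = self._bundle("s1")
        b2 = self._bundle("s2")
        b2.substrate = "other"
        with pytest.raises(ValueError, match="multiple pairs"):
            predict_pair(self._models(), [b1, b2])
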