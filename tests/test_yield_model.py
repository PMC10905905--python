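"""Yield model: loss formula, set invariance, training, MC dropout, metrics."""

import math

import numpy as np
import pytest

from moldescpred import (
    FinetuneConfig,
    GINConfig,
    ReactionRecord,
    SyntheticSpec,
    YieldModel,
    evaluate,
    finetune_loss,
    generate_synthetic_corpus,
    initialize_from_pretrained,
    initialize_from_scratch,
    yield_forward,
)
from moldescpred._autodiff import Tensor
from moldescpred.experiments import records_from_rows
from moldescpred.gin import save_checkpoint
from moldescpred.yield_model import YieldHead


@pytest.fixture(scope="module")
def tiny_records(schema=None):
    _, rows = generate_synthetic_corpus(
        SyntheticSpec(num_molecules=60, num_reactions=40, noise_sd=0.0, seed=4)
    )
    return records_from_rows(rows)


@pytest.fixture(scope="module")
def tiny_cfg(tiny_records):
    g = tiny_records[0].reactants[0]
    return GINConfig(
        node_feature_dim=g.node_features.shape[1],
        edge_feature_dim=g.edge_features.shape[1],
        hidden_dim=16, representation_dim=24, dropout_rate=0.1,
    )


class TestFinetuneLoss:
    @pytest.mark.parametrize("y,mu", [(3.0, 1.5), (0.0, 0.0), (-2.0, 4.0)])
    def test_alpha_zero_is_squared_error(self, y, mu):
        assert finetune_loss(y, mu, 7.3, alpha=0.0) == pytest.approx((y - mu) ** 2)

    def test_alpha_one_perfect_prediction_unit_variance(self):
        assert finetune_loss(2.0, 2.0, 1.0, alpha=1.0) == pytest.approx(0.0)

    def test_mixture_plug_in(self):
        # y=1, mu=0, sigma2=1, alpha=0.5 -> 0.5*1 + 0.5*(1 + 0) = 1
        assert finetune_loss(1.0, 0.0, 1.0, alpha=0.5) == pytest.approx(1.0)

    @pytest.mark.parametrize("alpha", [0.0, 0.1, 0.5, 1.0])
    def test_mixture_interpolates(self, alpha):
        y, mu, s2 = 2.0, 0.5, 0.7
        expected = (1 - alpha) * (y - mu) ** 2 + alpha * ((y - mu) ** 2 / s2 + math.log(s2))
        assert finetune_loss(y, mu, s2, alpha) == pytest.approx(expected)

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError):
            finetune_loss(1.0, 0.0, 0.0, alpha=0.5)
        with pytest.raises(ValueError):
            finetune_loss(1.0, 0.0, -1.0, alpha=0.5)

    @pytest.mark.parametrize("alpha,logvar", [(0.0, 0.0), (0.3, -1.0), (1.0, 2.0)])
    def test_gradient_wrt_mean_vanishes_at_truth(self, alpha, logvar):
        """d loss / d mu = 0 at y = mu for any alpha and variance."""
        mu = Tensor(np.array(1.7), requires_grad=True)
        lv = Tensor(np.array(logvar), requires_grad=True)
        y = Tensor(np.array(1.7))
        sq = (y - mu).square()
        loss = sq * (1 - alpha) + (sq * (-lv).exp() + lv) * alpha
        loss.backward()
        assert mu.grad == pytest.approx(0.0, abs=1e-12)


class TestYieldForward:
    def test_variance_positive_for_random_inputs(self, tiny_records, tiny_cfg):
        for seed in range(5):
            gin, head = initialize_from_scratch(tiny_cfg, seed=seed)
            for rec in tiny_records[:20]:
                assert yield_forward(rec, gin, head).variance > 0

    def test_reactant_permutation_invariance(self, tiny_records, tiny_cfg, rng):
        gin, head = initialize_from_scratch(tiny_cfg, seed=0)
        for rec in tiny_records[:10]:
            base = yield_forward(rec, gin, head)
            perm = list(rng.permutation(len(rec.reactants)))
            shuffled = ReactionRecord([rec.reactants[i] for i in perm],
                                      rec.product, rec.yield_value)
            out = yield_forward(shuffled, gin, head)
            assert abs(out.mean - base.mean) < 1e-6
            assert abs(out.variance - base.variance) < 1e-6

    def test_deterministic_mode_bit_identical(self, tiny_records, tiny_cfg):
        gin, head = initialize_from_scratch(tiny_cfg, seed=1)
        a = yield_forward(tiny_records[0], gin, head)
        b = yield_forward(tiny_records[0], gin, head)
        assert a.mean == b.mean and a.variance == b.variance

    def test_zero_reactants_rejected(self, tiny_records):
        with pytest.raises(ValueError):
            ReactionRecord([], tiny_records[0].product, 50.0)


class TestInitialization:
    def test_pretrained_encoder_loaded_bit_exact(self, tiny_cfg, tmp_path):
        gin0, _ = initialize_from_scratch(tiny_cfg, seed=9)
        p = tmp_path / "pre.npz"
        save_checkpoint(p, gin0, extra_manifest={"phase": "pretrain"})
        gin, head = initialize_from_pretrained(p, tiny_cfg, head_init_seed=0)
        for k, v in gin0.state_dict().items():
            np.testing.assert_array_equal(gin.state_dict()[k], v)

    def test_head_seeds_vary_head_not_encoder(self, tiny_cfg, tmp_path):
        gin0, _ = initialize_from_scratch(tiny_cfg, seed=9)
        p = tmp_path / "pre.npz"
        save_checkpoint(p, gin0)
        gin_a, head_a = initialize_from_pretrained(p, tiny_cfg, head_init_seed=1)
        gin_b, head_b = initialize_from_pretrained(p, tiny_cfg, head_init_seed=2)
        np.testing.assert_array_equal(gin_a.state_dict()["phi_n.W"],
                                      gin_b.state_dict()["phi_n.W"])
        assert (head_a.params["yhead.W1"].value != head_b.params["yhead.W1"].value).any()

    def test_from_scratch_differs_from_checkpoint(self, tiny_cfg):
        a, _ = initialize_from_scratch(tiny_cfg, seed=0)
        b, _ = initialize_from_scratch(tiny_cfg, seed=1)
        assert (a.state_dict()["phi_n.W"] != b.state_dict()["phi_n.W"]).any()


class TestFinetuning:
    def test_zero_epochs_returns_initialization(self, tiny_records, tiny_cfg):
        init = initialize_from_scratch(tiny_cfg, seed=2)
        before = init[0].state_dict()
        res = YieldModel(tiny_records, tiny_cfg,
                         FinetuneConfig(epochs=0, seed=2), init=init).fit()
        for k, v in before.items():
            np.testing.assert_array_equal(res.gin.state_dict()[k], v)

    def test_training_loss_decreases_early(self, tiny_records, tiny_cfg):
        res = YieldModel(tiny_records, tiny_cfg,
                         FinetuneConfig(epochs=20, batch_size=20, seed=0)).fit()
        assert res.loss_history[-1] < res.loss_history[0]
        assert np.mean(res.loss_history[-5:]) < np.mean(res.loss_history[:5])

    def test_overfits_tiny_training_set(self, tiny_records, tiny_cfg):
        """Capacity: <= 20 noise-free reactions, long training -> RMSE < 2."""
        cfg = GINConfig(**{**tiny_cfg.to_dict(), "dropout_rate": 0.0})
        train = tiny_records[:20]
        res = YieldModel(train, cfg,
                         FinetuneConfig(epochs=500, batch_size=20, alpha=0.1,
                                        weight_decay=0.0, seed=0)).fit()
        preds = res.predict_deterministic(train)
        rmse, _, _ = evaluate([p.mean for p in preds],
                              [r.yield_value for r in train])
        assert rmse < 2.0

    def test_lr_schedule_steps(self):
        cfg = FinetuneConfig()
        assert cfg.lr_at(0) == 5e-4
        assert cfg.lr_at(399) == 5e-4
        assert cfg.lr_at(400) == 5e-5
        assert cfg.lr_at(450) == 5e-6
        with pytest.raises(ValueError):
            FinetuneConfig(lr_schedule=((450, 5e-5), (400, 5e-6)))

    def test_alpha_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            FinetuneConfig(alpha=1.5)

    def test_save_load_round_trip(self, tiny_records, tiny_cfg, tmp_path):
        res = YieldModel(tiny_records, tiny_cfg,
                         FinetuneConfig(epochs=2, batch_size=20, seed=0)).fit()
        p = tmp_path / "model.npz"
        res.save(p)
        from moldescpred import YieldResults

        back = YieldResults.load(p)
        a = res.predict_deterministic(tiny_records[:5])
        b = back.predict_deterministic(tiny_records[:5])
        for x, y in zip(a, b):
            assert x.mean == y.mean and x.variance == y.variance


@pytest.fixture(scope="module")
def fitted(tiny_records, tiny_cfg):
    return YieldModel(tiny_records, tiny_cfg,
                      FinetuneConfig(epochs=3, batch_size=20, seed=0)).fit()


class TestMCDropout:
    def test_zero_dropout_passes_identical(self, tiny_records, tiny_cfg):
        cfg0 = GINConfig(**{**tiny_cfg.to_dict(), "dropout_rate": 0.0})
        res = YieldModel(tiny_records, cfg0,
                         FinetuneConfig(epochs=1, batch_size=20, seed=0)).fit()
        preds = res.predict(tiny_records[:5], T=30, seed=0)
        det = res.predict_deterministic(tiny_records[:5])
        for p, d in zip(preds, det):
            assert np.ptp(p.mc_samples) == 0.0
            assert p.mean == pytest.approx(d.mean)

    def test_single_pass_is_that_pass(self, fitted, tiny_records):
        p = fitted.predict(tiny_records[:3], T=1, seed=7)
        for pred in p:
            assert len(pred.mc_samples) == 1
            assert pred.mean == pred.mc_samples[0]

    def test_default_pass_count_is_thirty(self, fitted, tiny_records):
        p = fitted.predict(tiny_records[:1], seed=0)
        assert len(p[0].mc_samples) == 30

    def test_final_prediction_averages_passes(self, fitted, tiny_records):
        p = fitted.predict(tiny_records[:3], T=8, seed=3)
        for pred in p:
            assert pred.mean == pytest.approx(np.mean(pred.mc_samples))

    def test_seeded_reproducibility(self, fitted, tiny_records):
        a = fitted.predict(tiny_records[:3], T=5, seed=9)
        b = fitted.predict(tiny_records[:3], T=5, seed=9)
        assert [p.mean for p in a] == [p.mean for p in b]

    def test_invalid_pass_count(self, fitted, tiny_records):
        with pytest.raises(ValueError):
            fitted.predict(tiny_records[:1], T=0)


class TestEvaluate:
    def test_perfect_predictions(self):
        rmse, mae, r2 = evaluate([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (rmse, mae, r2) == (0.0, 0.0, 1.0)

    def test_mean_predictor_has_zero_r2(self):
        truths = [10.0, 20.0, 30.0, 40.0]
        rmse, mae, r2 = evaluate([25.0] * 4, truths)
        assert r2 == pytest.approx(0.0)

    def test_hand_computed_example(self):
        rmse, mae, r2 = evaluate([0.0, 0.0], [0.0, 10.0])
        assert rmse == pytest.approx(math.sqrt(50.0))
        assert mae == pytest.approx(5.0)
        assert r2 == pytest.approx(-1.0)

    def test_constant_truths_r2_undefined(self):
        rmse, mae, r2 = evaluate([1.0, 2.0], [5.0, 5.0])
        assert r2 is None

    def test_rmse_at_least_mae(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 30))
            pred, truth = rng.normal(size=(2, n)) * 10
            rmse, mae, _ = evaluate(pred, truth)
            assert rmse >= mae - 1e-12

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            evaluate([1.0], [1.0, 2.0])
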