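"""Ensemble MLP training protocol, weighting, schedule and attributions."""

import math

import numpy as np
import pytest

from alchemspace import (
    AffinityRecord,
    FeatureBlock,
    TrainHyper,
    importance_filter,
    inverse_frequency_weights,
    lr_schedule,
    predict,
    train_ensemble,
)
from alchemspace.ensemble import _Member, _MLP, Ensemble, integrated_gradients


def _block(X, name="latent"):
    n, d = X.shape
    return FeatureBlock(name, X, [f"z{j}" for j in range(d)],
                        [f"m{i:04d}" for i in range(n)])


def _records(ids, y):
    return [AffinityRecord(i, float(v), source="synthetic")
            for i, v in zip(ids, y)]


class TestLrSchedule:
    def test_printed_formula_values(self):
        assert lr_schedule(0) == 0.005
        assert lr_schedule(10000) == pytest.approx(0.0005)
        assert lr_schedule(20000) == pytest.approx(5e-5)
        assert lr_schedule(5000) == pytest.approx(0.005 * 10 ** -0.5)

    def test_custom_decay_period(self):
        assert lr_schedule(100, lr0=0.1, decay_per=100) == pytest.approx(0.01)


class TestInverseFrequencyWeights:
    def test_uniform_targets_give_unit_weights(self):
        w = inverse_frequency_weights([-9.0] * 20, bandwidth=0.5)
        assert np.allclose(w, 1.0)

    def test_minority_mode_outweighs_majority(self):
        targets = [-8.0] * 90 + [-14.0] * 10
        w = inverse_frequency_weights(targets, bandwidth=0.7)
        assert w[90:].min() > w[:90].max()

    def test_matches_independent_kde_reciprocal(self):
        """Weights equal the reciprocal of a hand-rolled Gaussian KDE with
        absolute bandwidth h, renormalized to mean 1."""
        rng = np.random.default_rng(3)
        t = rng.normal(-10.0, 2.0, size=20)
        h = 0.5
        diff = t[:, None] - t[None, :]
        density = np.exp(-diff ** 2 / (2 * h * h)).sum(axis=1) / (
            len(t) * h * math.sqrt(2 * math.pi)
        )
        want = (1.0 / density) / np.mean(1.0 / density)
        got = inverse_frequency_weights(t, bandwidth=h)
        assert np.abs(got - want).max() < 1e-8

    def test_mean_weight_is_one(self):
        rng = np.random.default_rng(4)
        w = inverse_frequency_weights(rng.normal(size=50))
        assert w.mean() == pytest.approx(1.0)
        assert (w > 0).all()


class TestTraining:
    def test_constant_targets_learned_everywhere(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((100, 5))
        block = _block(X)
        recs = _records(block.ligand_ids, np.full(100, -9.5))
        hyper = TrainHyper(epochs=2000, target_scale=2.0, target_bias=-7.0,
                           seed=5)
        ens = train_ensemble([block], recs, hyper=hyper)
        preds = predict(ens, [block], block.ligand_ids)
        assert all(abs(p.mean_dg + 9.5) < 0.1 for p in preds)

    def test_linear_map_recovered_below_02_kcal(self, linear_problem):
        block, records, y = linear_problem
        hyper = TrainHyper(epochs=2000, seed=1)
        ens = train_ensemble([block], records[:400], hyper=hyper)
        preds = predict(ens, [block], block.ligand_ids[400:])
        pred = np.array([p.mean_dg for p in preds])
        rmse = float(np.sqrt(np.mean((pred - y[400:]) ** 2)))
        assert rmse < 0.2

    def test_seeded_retraining_is_bitwise_identical(self, linear_problem):
        block, records, _ = linear_problem
        hyper = TrainHyper(epochs=120, seed=7)
        a = train_ensemble([block], records[:100], hyper=hyper)
        b = train_ensemble([block], records[:100], hyper=hyper)
        pa = predict(a, [block], block.ligand_ids[:50])
        pb = predict(b, [block], block.ligand_ids[:50])
        assert [p.member_values for p in pa] == [p.member_values for p in pb]

    def test_fold_assignments_partition_training_set(self, linear_problem):
        block, records, _ = linear_problem
        hyper = TrainHyper(epochs=50, seed=2)
        ens = train_ensemble([block], records[:100], hyper=hyper,
                             k_folds=5, n_repeats=2)
        assert len(ens.members) == 10
        for rep, labels in ens.fold_assignments.items():
            assert labels.shape == (100,)
            assert set(labels) == set(range(5))

    def test_checkpoint_round_trip_preserves_predictions(
        self, linear_problem, tmp_path
    ):
        from alchemspace.ensemble import Ensemble

        block, records, _ = linear_problem
        ens = train_ensemble([block], records[:100],
                             hyper=TrainHyper(epochs=60, seed=9))
        path = tmp_path / "ensemble.json"
        ens.save(path)
        back = Ensemble.load(path)
        pa = predict(ens, [block], block.ligand_ids[:30])
        pb = predict(back, [block], block.ligand_ids[:30])
        assert [p.member_values for p in pa] == \
            [p.member_values for p in pb]
        assert back.cv_rmse == ens.cv_rmse
        assert back.hyper == ens.hyper

    def test_too_few_records_for_folds(self, linear_problem):
        block, records, _ = linear_problem
        with pytest.raises(ValueError, match="folds"):
            train_ensemble([block], records[:3], k_folds=5)

    def test_ensemble_spread_shrinks_with_more_repeats(self, linear_problem):
        """The variance over seeds of the ensemble-mean prediction drops as
        repeats grow from 1 to 5 (averaging over 5× more members)."""
        block, records, _ = linear_problem
        probe = block.ligand_ids[200:240]

        def seed_variance(n_repeats):
            means = []
            for seed in range(4):
                hyper = TrainHyper(epochs=80, seed=seed)
                ens = train_ensemble([block], records[:100], hyper=hyper,
                                     n_repeats=n_repeats)
                means.append([p.mean_dg for p in predict(ens, [block], probe)])
            return np.var(np.array(means), axis=0).mean()

        assert seed_variance(5) < seed_variance(1)


class TestPredict:
    def _constant_member(self, d_in, value, hyper):
        net = _MLP(d_in, (), np.random.default_rng(0))
        net.W = [np.zeros((d_in, 1))]
        net.b = [np.array([(value - hyper.target_bias) / hyper.target_scale])]
        return net

    def _manual_ensemble(self, values, hyper):
        members = [
            _Member(net=self._constant_member(2, v, hyper), fold=i, repeat=0)
            for i, v in enumerate(values)
        ]
        return Ensemble(
            members=members, fold_assignments={0: np.zeros(2, int)},
            training_ids=["a", "b"], cv_rmse=0.0,
            feature_block_names=["latent"], feature_names=["z0", "z1"],
            feature_means=np.zeros(2), feature_stds=np.ones(2), hyper=hyper,
        )

    def test_mean_is_exact_member_mean_and_345_stderr(self):
        hyper = TrainHyper(uncertainty="stderr")
        ens = self._manual_ensemble([-10.0, -12.0], hyper)
        block = _block(np.zeros((2, 2)))
        p = predict(ens, [block], ["m0000"])[0]
        assert p.mean_dg == pytest.approx(-11.0)
        # std of (−10, −12) is √2, stderr over 2 members = 1
        assert p.stderr_dg == pytest.approx(1.0)
        assert p.mean_dg == pytest.approx(np.mean(p.member_values))

    def test_single_member_has_zero_stderr(self):
        hyper = TrainHyper()
        ens = self._manual_ensemble([-10.0], hyper)
        block = _block(np.zeros((2, 2)))
        assert predict(ens, [block], ["m0000"])[0].stderr_dg == 0.0

    def test_std_uncertainty_mode(self):
        hyper = TrainHyper(uncertainty="std")
        ens = self._manual_ensemble([-10.0, -12.0], hyper)
        block = _block(np.zeros((2, 2)))
        p = predict(ens, [block], ["m0000"])[0]
        assert p.stderr_dg == pytest.approx(math.sqrt(2.0))

    def test_missing_features_is_hard_error(self):
        hyper = TrainHyper()
        ens = self._manual_ensemble([-10.0], hyper)
        block = _block(np.zeros((2, 2)))
        with pytest.raises(KeyError):
            predict(ens, [block], ["nope"])


class TestIntegratedGradients:
    def test_linear_model_matches_closed_form(self):
        """For a trained linear surrogate, IG attribution is exactly
        weight × (input − baseline), independent of step count."""
        rng = np.random.default_rng(8)
        X = rng.standard_normal((200, 1))
        y = 2.5 * X[:, 0] - 10.0
        block = _block(X)
        hyper = TrainHyper(hidden_layer_widths=(), epochs=600, seed=3)
        ens = train_ensemble([block], _records(block.ligand_ids, y),
                             hyper=hyper)
        net = ens.members[0].net
        probe = ens.design_matrix([block], block.ligand_ids[:20])
        attr = integrated_gradients(net, probe, m_steps=256)
        closed = probe * net.W[0][0, 0]
        assert np.abs(attr - closed).max() < 1e-6

    def test_constant_feature_dropped_and_threshold_zero_keeps_all(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((150, 3))
        X[:, 2] = 4.2  # constant column
        y = 1.5 * X[:, 0] - 0.8 * X[:, 1] - 10.0
        block = _block(X)
        hyper = TrainHyper(epochs=400, seed=4)
        ens = train_ensemble([block], _records(block.ligand_ids, y),
                             hyper=hyper)
        kept = importance_filter(ens, [block], threshold=0.02)
        assert "latent::z2" not in kept
        assert "latent::z0" in kept and "latent::z1" in kept
        assert importance_filter(ens, [block], threshold=0.0) == \
            ens.feature_names

    def test_all_dropped_raises_advice(self):
        rng = np.random.default_rng(10)
        X = rng.standard_normal((80, 2))
        y = 0.001 * X[:, 0] - 10.0
        block = _block(X)
        ens = train_ensemble([block], _records(block.ligand_ids, y),
                             hyper=TrainHyper(epochs=50, seed=5))
        with pytest.raises(ValueError, match="threshold"):
            importance_filter(ens, [block], threshold=1e9)
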