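"""The sequence→ΔΔF regression stack: tokenizer, additive baseline, and
the numpy transformer (gradient correctness, determinism, persistence)."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from memsense import (
    AdditiveDdgModel,
    ConstantPredictor,
    ModelConfig,
    SyntheticDatasetSpec,
    TrainingExample,
    TransformerDdgModel,
    generate_synthetic_dataset,
)
from memsense.constants import AMINO_ACIDS
from memsense.data import additive_ddF
from memsense.regression import (
    TransformerDdgResults,
    detokenize,
    evaluate_rmse,
    tokenize,
)
from memsense.regression.tokenizer import PAD
from memsense.regression.transformer import _Network

sequences = st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=24)


class TestTokenizer:
    def test_padding_contract(self):
        tokens = tokenize("AAA")
        assert tokens.shape == (24,)
        assert (tokens[3:] == PAD).all()
        assert (tokens[:3] == tokens[0]).all() and tokens[0] != PAD

    @given(sequences)
    def test_round_trip(self, seq):
        assert detokenize(tokenize(seq)) == seq

    def test_overlong_input_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            tokenize("A" * 25)


class TestAdditiveBaseline:
    def test_noise_free_exact_recovery(self):
        examples, truth = generate_synthetic_dataset(
            SyntheticDatasetSpec(n_examples=400, seed=11, noise_sd=0.0)
        )
        results = AdditiveDdgModel(examples).fit()
        for aa, c in truth.items():
            assert results.params[aa] == pytest.approx(c, abs=1e-6)
        assert results.rmse == pytest.approx(0.0, abs=1e-9)
        assert not results.rank_deficient

    def test_prediction_matches_additive_truth(self):
        examples, truth = generate_synthetic_dataset(
            SyntheticDatasetSpec(n_examples=400, seed=11, noise_sd=0.0)
        )
        results = AdditiveDdgModel(examples).fit()
        seq = examples[0].sequence
        assert results.predict(seq) == pytest.approx(
            additive_ddF(seq, truth), abs=1e-6
        )

    def test_absent_residue_is_flagged_not_fatal(self):
        rng = np.random.default_rng(0)
        alphabet = AMINO_ACIDS.replace("W", "")
        examples = [
            TrainingExample(
                "".join(rng.choice(list(alphabet), size=24)), float(rng.normal())
            )
            for _ in range(150)
        ]
        results = AdditiveDdgModel(examples).fit()
        assert results.absent_residues == ("W",)
        assert np.isnan(results.params["W"])
        with pytest.raises(ValueError, match="W"):
            results.predict("W" * 24)

    def test_identical_sequences_flag_rank_deficiency(self):
        examples = [TrainingExample("ACDEFGHIKLMNPQRSTVWYACDE", -5.0)] * 120
        results = AdditiveDdgModel(examples).fit()
        assert results.rank_deficient

    def test_gauge_fixed_recovery_with_intercept(self):
        examples, truth = generate_synthetic_dataset(
            SyntheticDatasetSpec(n_examples=400, seed=4, noise_sd=0.0)
        )
        results = AdditiveDdgModel(examples, fit_intercept=True).fit()
        assert results.recovery_r2(truth) == pytest.approx(1.0, abs=1e-9)

    def test_summary_mentions_fit_quality(self):
        examples, _ = generate_synthetic_dataset(
            SyntheticDatasetSpec(n_examples=150, seed=1)
        )
        text = AdditiveDdgModel(examples).fit().summary()
        assert "RMSE" in text and "coefficients" in text


TINY = ModelConfig(
    embed_dim=16, n_heads=4, n_layers=1, feedforward_dim=32,
    batch_size=8, epochs=3, seed=0, patience=10,
)


def tiny_dataset(n=32, seed=0, noise=0.5):
    examples, _ = generate_synthetic_dataset(
        SyntheticDatasetSpec(n_examples=n, seed=seed, noise_sd=noise)
    )
    return examples


class TestTransformerGradients:
    def test_analytic_gradients_match_finite_differences(self):
        """Backprop through embedding, attention, layer norm, feed-forward
        and pooling agrees with central finite differences."""
        cfg = ModelConfig(embed_dim=8, n_heads=2, n_layers=2, feedforward_dim=16)
        net = _Network(cfg, np.random.default_rng(0))
        toks = np.stack([tokenize(s) for s in ["ACDEFGHIK", "LMNPQRSTVWYA", "KKKKKKK"]])
        y = np.array([1.0, -2.0, 0.5])

        def loss():
            return float(np.mean((net.forward(toks) - y) ** 2))

        net.zero_grad()
        net.backward(2.0 * (net.forward(toks) - y) / len(y))
        rng = np.random.default_rng(1)
        eps = 1e-6
        for p in net.parameters():
            flat, grad = p.value.ravel(), p.grad.ravel()
            for i in rng.integers(flat.size, size=5):
                orig = flat[i]
                flat[i] = orig + eps
                lp = loss()
                flat[i] = orig - eps
                lm = loss()
                flat[i] = orig
                numeric = (lp - lm) / (2 * eps)
                assert abs(numeric - grad[i]) <= 1e-6 + 1e-4 * abs(numeric)


class TestTransformerTraining:
    def test_seeded_determinism(self):
        data = tiny_dataset()
        r1 = TransformerDdgModel(data, TINY).fit()
        r2 = TransformerDdgModel(data, TINY).fit()
        assert r1.history == r2.history
        seq = data[0].sequence
        assert r1.predict(seq) == r2.predict(seq)

    def test_inference_is_deterministic(self):
        results = TransformerDdgModel(tiny_dataset(), TINY).fit()
        seq = "ACDEFGHIKLMNPQRSTVWYACDE"
        assert results.predict(seq) == results.predict(seq)

    def test_memorizes_small_dataset(self):
        """Overfit contract: ample capacity and epochs drive training RMSE
        under 0.5 kJ/mol on 50 examples."""
        examples = tiny_dataset(n=50, seed=3, noise=1.0)
        cfg = ModelConfig(
            embed_dim=32, n_heads=4, n_layers=1, feedforward_dim=64,
            batch_size=16, epochs=300, learning_rate=3e-3,
            splits=(1.0, 0.0, 0.0), patience=300, seed=3,
        )
        results = TransformerDdgModel(examples, cfg).fit()
        assert results.evaluate_rmse(examples)["rmse"] < 0.5

    def test_divergence_raises_named_epoch(self):
        from memsense.regression import DivergenceError

        import dataclasses

        bad = tiny_dataset()[:-1] + [TrainingExample("A" * 24, float("nan"))]
        cfg = dataclasses.replace(TINY, splits=(1.0, 0.0, 0.0))
        with pytest.raises(DivergenceError, match="epoch"):
            TransformerDdgModel(bad, cfg).fit()

    def test_history_tracks_train_and_val_loss(self):
        results = TransformerDdgModel(tiny_dataset(), TINY).fit()
        assert len(results.history) <= TINY.epochs
        assert {"epoch", "train_loss", "val_loss"} <= set(results.history[0])

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ModelConfig(embed_dim=30, n_heads=8)
        with pytest.raises(ValueError):
            ModelConfig(splits=(0.5, 0.2, 0.2))


class TestPersistence:
    def test_save_load_round_trip_is_bit_identical(self, tmp_path):
        results = TransformerDdgModel(tiny_dataset(), TINY).fit()
        sequences = [e.sequence for e in tiny_dataset(n=8, seed=9)]
        before = results.predict_batch(sequences)
        path = tmp_path / "model.npz"
        results.save(path)
        loaded = TransformerDdgResults.load(path)
        after = loaded.predict_batch(sequences)
        assert (before == after).all()
        assert loaded.dataset_fingerprint == results.dataset_fingerprint

    def test_missing_checkpoint_raises(self, tmp_path):
        with pytest.raises(RuntimeError, match="checkpoint"):
            TransformerDdgResults.load(tmp_path / "absent.npz")


class TestEvaluateRmse:
    def test_perfect_predictions(self):
        examples = [TrainingExample("A" * 24, -3.0)] * 4
        assert evaluate_rmse(ConstantPredictor(-3.0), examples)["rmse"] == 0.0

    def test_constant_offset(self):
        examples = [TrainingExample("A" * 24, -3.0)] * 4
        report = evaluate_rmse(ConstantPredictor(-2.0), examples)
        assert report["rmse"] == pytest.approx(1.0)
        assert report["resid_mean"] == pytest.approx(1.0)

    def test_alternating_unit_residuals(self):
        examples = [
            TrainingExample("A" * 24, -1.0),
            TrainingExample("A" * 24, 1.0),
            TrainingExample("A" * 24, -1.0),
            TrainingExample("A" * 24, 1.0),
        ]
        assert evaluate_rmse(ConstantPredictor(0.0), examples)["rmse"] == (
            pytest.approx(1.0)
        )

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            evaluate_rmse(ConstantPredictor(0.0), [])
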