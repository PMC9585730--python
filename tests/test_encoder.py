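"""Masking, encoding, MLM loss, and pre-training contracts."""

import numpy as np
import pytest

import molsent.encoder as encoder_mod
from molsent.encoder import (
    EncoderConfig,
    MaskingPlan,
    PretrainSettings,
    TransformerEncoder,
    encode,
    load_checkpoint,
    mask_sequence,
    mlm_loss,
    pretrain,
    save_checkpoint,
)
from molsent.nn import Tensor
from molsent.vocab import CLS_ID, MASK_ID, PAD_ID, SEP_ID, encode_tokens


def make_seq(n_sub, vocab, max_len=None):
    tokens = [vocab.tokens[5 + (i % (len(vocab) - 5))] for i in range(n_sub)]
    return encode_tokens(tokens, vocab, max_len=max_len or n_sub + 2)


class TestMaskSequence:
    def test_selection_count_floor(self, tiny_vocab, rng):
        seq = make_seq(20, tiny_vocab)
        _, plan = mask_sequence(seq, rng, EncoderConfig(hidden_size=32, n_heads=2), len(tiny_vocab))
        assert len(plan.selected_positions) == 3  # floor(0.15 * 20)

    def test_minimum_one_selection(self, tiny_vocab, rng):
        seq = make_seq(3, tiny_vocab)
        _, plan = mask_sequence(seq, rng, EncoderConfig(hidden_size=32, n_heads=2), len(tiny_vocab))
        assert len(plan.selected_positions) == 1

    def test_never_selects_special_positions(self, tiny_vocab, rng):
        cfg = EncoderConfig(hidden_size=32, n_heads=2)
        for n_sub in (1, 2, 7, 30):
            seq = make_seq(n_sub, tiny_vocab, max_len=n_sub + 6)
            corrupted, plan = mask_sequence(seq, rng, cfg, len(tiny_vocab))
            for pos in plan.selected_positions:
                assert seq.ids[pos] not in (CLS_ID, SEP_ID, PAD_ID)
            # specials and pads unchanged in the corrupted copy
            assert corrupted.ids[0] == CLS_ID
            assert corrupted.ids[n_sub + 1] == SEP_ID
            assert corrupted.ids[n_sub + 2 :] == seq.ids[n_sub + 2 :]

    def test_fraction_bound_for_long_sentences(self, tiny_vocab, rng):
        cfg = EncoderConfig(hidden_size=32, n_heads=2)
        for n_sub in range(7, 40):
            seq = make_seq(n_sub, tiny_vocab)
            _, plan = mask_sequence(seq, rng, cfg, len(tiny_vocab))
            assert len(plan.selected_positions) / n_sub <= 0.15

    def test_action_frequencies_converge(self, tiny_vocab):
        rng = np.random.default_rng(42)
        cfg = EncoderConfig(hidden_size=32, n_heads=2)
        seq = make_seq(30, tiny_vocab)
        counts = {"mask": 0, "random": 0, "keep": 0}
        n_draws = 0
        for _ in range(2000):
            _, plan = mask_sequence(seq, rng, cfg, len(tiny_vocab))
            for a in plan.actions:
                counts[a] += 1
                n_draws += 1
        for action, p in zip(("mask", "random", "keep"), (0.8, 0.1, 0.1)):
            sd = np.sqrt(p * (1 - p) * n_draws)
            assert abs(counts[action] - p * n_draws) < 3 * sd

    def test_masked_positions_get_mask_token(self, tiny_vocab, rng):
        cfg = EncoderConfig(hidden_size=32, n_heads=2)
        seq = make_seq(30, tiny_vocab)
        corrupted, plan = mask_sequence(seq, rng, cfg, len(tiny_vocab))
        for pos, action, orig in zip(
            plan.selected_positions, plan.actions, plan.original_ids
        ):
            if action == "mask":
                assert corrupted.ids[pos] == MASK_ID
            elif action == "keep":
                assert corrupted.ids[pos] == orig
            else:
                assert corrupted.ids[pos] >= 5  # random draws are non-special

    def test_specials_only_sequence_errors(self, tiny_vocab, rng):
        seq = encode_tokens([], tiny_vocab, max_len=4)
        with pytest.raises(ValueError):
            mask_sequence(seq, rng, EncoderConfig(hidden_size=32, n_heads=2), len(tiny_vocab))


class TestEncode:
    def test_default_config_state_dimension(self, tiny_vocab):
        model = TransformerEncoder(EncoderConfig(), len(tiny_vocab), seed=1)
        seq = make_seq(5, tiny_vocab)
        enc = encode(model, seq)
        assert enc.states.shape == (7, 256)
        assert enc.valid_mask.sum() == 5

    def test_pad_invariance(self, tiny_encoder, tiny_vocab):
        model, _ = tiny_encoder
        short = make_seq(8, tiny_vocab, max_len=10)
        padded = make_seq(8, tiny_vocab, max_len=20)
        np.testing.assert_allclose(
            encode(model, short).states[:10],
            encode(model, padded).states[:10],
            atol=1e-5,
        )

    def test_pad_invariance_across_random_models(self, tiny_vocab):
        cfg = EncoderConfig(hidden_size=16, n_layers=1, n_heads=2, max_positions=32)
        for seed in range(20):
            model = TransformerEncoder(cfg, len(tiny_vocab), seed=seed)
            short = make_seq(6, tiny_vocab, max_len=8)
            padded = make_seq(6, tiny_vocab, max_len=18)
            np.testing.assert_allclose(
                encode(model, short).states[:8],
                encode(model, padded).states[:8],
                atol=1e-5,
            )

    def test_states_are_contextual(self, tiny_encoder, tiny_vocab):
        """The same token in different molecular contexts encodes differently."""
        model, _ = tiny_encoder
        shared = tiny_vocab.tokens[5]
        other_a, other_b = tiny_vocab.tokens[6], tiny_vocab.tokens[7]
        seq_a = encode_tokens([shared, other_a], tiny_vocab, max_len=8)
        seq_b = encode_tokens([shared, other_b], tiny_vocab, max_len=8)
        state_a = encode(model, seq_a).states[1]
        state_b = encode(model, seq_b).states[1]
        assert not np.allclose(state_a, state_b, atol=1e-4)

    def test_too_long_sequence_errors(self, tiny_vocab):
        cfg = EncoderConfig(hidden_size=16, n_layers=1, n_heads=2, max_positions=8)
        model = TransformerEncoder(cfg, len(tiny_vocab), seed=0)
        seq = make_seq(10, tiny_vocab)
        with pytest.raises(ValueError, match="max_positions"):
            encode(model, seq)


class TestMlmLoss:
    def test_perfect_prediction_gives_zero(self):
        plan = MaskingPlan([1, 2], ["mask", "mask"], [3, 4])
        logits = np.zeros((1, 5, 8), dtype=np.float32)
        logits[0, 1, 3] = 50.0
        logits[0, 2, 4] = 50.0
        assert float(mlm_loss(Tensor(logits), plan).data) == pytest.approx(0.0, abs=1e-5)

    def test_uniform_logits_give_log_vocab(self):
        plan = MaskingPlan([1], ["mask"], [2])
        logits = np.zeros((1, 4, 30), dtype=np.float32)
        assert float(mlm_loss(Tensor(logits), plan).data) == pytest.approx(np.log(30), rel=1e-6)

    def test_unselected_positions_do_not_affect_loss(self, rng):
        plan = MaskingPlan([2], ["mask"], [1])
        logits = rng.standard_normal((1, 6, 10)).astype(np.float32)
        base = float(mlm_loss(Tensor(logits.copy()), plan).data)
        logits[0, 4] += 100.0  # unselected position
        assert float(mlm_loss(Tensor(logits), plan).data) == pytest.approx(base, rel=1e-6)

    def test_empty_plan_errors(self):
        with pytest.raises(ValueError):
            mlm_loss(Tensor(np.zeros((1, 3, 5))), MaskingPlan([], [], []))


class TestPretrain:
    def test_loss_decreases_on_tiny_corpus(self, tiny_encoder):
        _, log = tiny_encoder
        assert log[-1]["train_loss"] < log[0]["train_loss"]

    def test_seeded_determinism(self, tiny_corpus, tiny_vocab):
        cfg = EncoderConfig(hidden_size=16, n_layers=1, n_heads=2, max_positions=64)
        settings = PretrainSettings(max_epochs=2)
        _, log_a = pretrain(tiny_corpus, tiny_vocab, cfg, settings, seed=3)
        _, log_b = pretrain(tiny_corpus, tiny_vocab, cfg, settings, seed=3)
        assert log_a == log_b

    def test_early_stopping_reverts_to_best_epoch(
        self, tiny_corpus, tiny_vocab, monkeypatch
    ):
        """With a scripted, strictly decreasing validation metric from epoch 2
        and patience 3, training stops at epoch 5 with epoch-1 weights."""
        scripted = iter([0.9, 0.8, 0.7, 0.6, 0.5, 0.4])
        snapshots = {}
        real_accuracy = encoder_mod._masked_accuracy

        def fake_accuracy(model, seqs, config, vocab_size, seed):
            epoch = len(snapshots) + 1
            snapshots[epoch] = model.state_dict()
            return next(scripted)

        monkeypatch.setattr(encoder_mod, "_masked_accuracy", fake_accuracy)
        cfg = EncoderConfig(hidden_size=16, n_layers=1, n_heads=2, max_positions=64)
        model, log = pretrain(
            tiny_corpus,
            tiny_vocab,
            cfg,
            PretrainSettings(max_epochs=10, patience=3),
            seed=0,
        )
        assert len(log) == 4  # epoch 1 best, then 3 non-improving epochs
        best = snapshots[1]
        current = model.state_dict()
        for key in best:
            np.testing.assert_array_equal(best[key], current[key])
        assert callable(real_accuracy)

    def test_checkpoint_round_trip_is_bitwise(self, tiny_encoder, tiny_vocab, tmp_path):
        model, _ = tiny_encoder
        path = tmp_path / "ckpt.zip"
        save_checkpoint(path, model, tiny_vocab)
        reloaded, vocab2 = load_checkpoint(path)
        assert vocab2.tokens == tiny_vocab.tokens
        seq = make_seq(7, tiny_vocab)
        np.testing.assert_array_equal(
            encode(model, seq).states, encode(reloaded, seq).states
        )

    def test_mlm_beats_uniform_baseline(self, tiny_corpus, tiny_vocab):
        """After 20 epochs on 200 sentences, masked-token validation accuracy
        exceeds the uniform-guess baseline 1/V by a factor of at least 5."""
        cfg = EncoderConfig(hidden_size=32, n_layers=2, n_heads=2, max_positions=64)
        _, log = pretrain(
            tiny_corpus,
            tiny_vocab,
            cfg,
            PretrainSettings(max_epochs=20, learning_rate=1e-3, patience=20),
            seed=1,
        )
        best = max(r["val_accuracy"] for r in log)
        assert best >= 5.0 / len(tiny_vocab)
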