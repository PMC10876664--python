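"""Causal-LM classifier: encoding, fine-tuning strategies, zero-shot path."""

import numpy as np
import pytest

from promptsyn.backbone import PAD_ID, BackboneSpec, ByteTokenizer, TinyCausalLM
from promptsyn.data import LabeledExample
from promptsyn.model import (
    ClassifierModel,
    FineTuneConfig,
    fine_tune,
    load_checkpoint,
    predict,
    save_checkpoint,
    zero_shot_label,
)
from promptsyn.textgen import prompt_for_record

from .conftest import make_record

SPEC = BackboneSpec.tiny(hidden_size=32, n_layers=2, n_heads=2, max_context_length=96)


@pytest.fixture(scope="module")
def model():
    return ClassifierModel(TinyCausalLM(SPEC, seed=3, init_std=0.1))


def separable_examples(n=16):
    """Labels readable from the sensitivity digits, which sit near the end
    of the prompt and therefore survive left-truncation at short contexts."""
    out = []
    for i in range(n):
        y = i % 2
        rec = make_record(
            drug1=f"D{i:02d}",
            drug2="DX",
            ri1=88.0 if y else 11.0,
            ri2=float(10 + i),
            loewe=30.0 if y else -10.0,
        )
        out.append(LabeledExample(rec, y))
    return out


class TestTokenizer:
    def test_left_padding_and_truncation(self):
        ids = ByteTokenizer.batch(["ab", "abcdef"], max_len=4)
        assert ids.shape == (2, 4)
        assert list(ids[0][:2]) == [PAD_ID, PAD_ID]
        # truncation keeps the suffix
        assert bytes(ids[1].astype(np.uint8)).decode() == "cdef"

    def test_empty_prompt_rejected(self):
        with pytest.raises(ValueError):
            ByteTokenizer.encode("")


class TestEncoding:
    def test_batch_invariance_under_left_padding(self, model):
        short = "short prompt Synergy:"
        long = "a considerably longer prompt with more content Synergy:"
        solo = model.encode_last_token([short])
        batched = model.encode_last_token([short, long])
        assert np.abs(solo[0] - batched[0]).max() < 1e-4

    def test_identical_prompts_identical_vectors(self, model):
        v = model.encode_last_token(["same prompt Synergy:"] * 3)
        assert np.array_equal(v[0], v[1]) and np.array_equal(v[1], v[2])

    def test_reproducible_across_fresh_models(self):
        p = ["deterministic encoding check Synergy:"]
        a = ClassifierModel(TinyCausalLM(SPEC, seed=11)).encode_last_token(p)
        b = ClassifierModel(TinyCausalLM(SPEC, seed=11)).encode_last_token(p)
        assert np.array_equal(a, b)

    def test_empty_prompt_list_rejected(self, model):
        with pytest.raises(ValueError):
            model.encode_last_token([])


class TestPredict:
    def test_zero_weight_head_gives_half(self):
        model = ClassifierModel(TinyCausalLM(SPEC, seed=0))  # zero head weights
        preds = predict(model, [make_record(), make_record(drug1="OTHER")])
        assert all(p.p_positive == 0.5 for p in preds)

    def test_probability_is_softmax_of_logits(self, model):
        preds = predict(model, [make_record()])
        l0, l1 = preds[0].logits
        expected = np.exp(l1) / (np.exp(l0) + np.exp(l1))
        assert abs(preds[0].p_positive - expected) < 1e-6

    def test_batch_size_invariance(self, model):
        records = [make_record(drug1=f"D{i}") for i in range(5)]
        a = [p.p_positive for p in predict(model, records, batch_size=2)]
        b = [p.p_positive for p in predict(model, records, batch_size=5)]
        np.testing.assert_allclose(a, b, atol=1e-6)

    def test_separable_examples_fit_by_head_probe(self):
        model = ClassifierModel(TinyCausalLM(SPEC, seed=5, init_std=0.1))
        examples = separable_examples()
        fine_tune(
            model,
            examples,
            FineTuneConfig(learning_rate=0.05, epochs=60, batch_size=8,
                           seed=0, strategy="head_only"),
        )
        preds = predict(model, [ex.record for ex in examples])
        assert all(
            (p.p_positive > 0.5) == bool(ex.y) for p, ex in zip(preds, examples)
        )


class TestFineTune:
    def test_head_only_freezes_backbone_bit_exactly(self):
        model = ClassifierModel(TinyCausalLM(SPEC, seed=7, init_std=0.1))
        before = model.backbone.checksum()
        fine_tune(
            model,
            separable_examples(8),
            FineTuneConfig(learning_rate=1e-2, epochs=2, seed=0, strategy="head_only"),
        )
        assert model.backbone.checksum() == before

    def test_full_mode_updates_backbone(self):
        model = ClassifierModel(TinyCausalLM(SPEC, seed=7, init_std=0.1), head_init_std=0.1)
        before = model.backbone.checksum()
        fine_tune(
            model,
            separable_examples(8),
            FineTuneConfig(learning_rate=1e-3, epochs=1, seed=0, strategy="full"),
        )
        assert model.backbone.checksum() != before

    def test_head_only_loss_strictly_decreases(self):
        model = ClassifierModel(TinyCausalLM(SPEC, seed=9, init_std=0.1))
        fine_tune(
            model,
            separable_examples(32),
            FineTuneConfig(learning_rate=0.05, epochs=4, batch_size=8,
                           seed=1, strategy="head_only"),
        )
        losses = model.train_loss_history
        assert all(b < a for a, b in zip(losses, losses[1:]))

    def test_single_class_warns_but_trains(self):
        model = ClassifierModel(TinyCausalLM(SPEC, seed=2))
        ones = [ex for ex in separable_examples(8) if ex.y == 1]
        with pytest.warns(UserWarning):
            fine_tune(model, ones, FineTuneConfig(
                learning_rate=1e-2, epochs=1, seed=0, strategy="head_only"))

    def test_empty_examples_rejected(self):
        model = ClassifierModel(TinyCausalLM(SPEC, seed=2))
        with pytest.raises(ValueError):
            fine_tune(model, [], FineTuneConfig())

    def test_reproducible_with_fixed_seed(self):
        results = []
        for _ in range(2):
            model = ClassifierModel(TinyCausalLM(SPEC, seed=4, init_std=0.1), head_init_std=0.1)
            fine_tune(model, separable_examples(16), FineTuneConfig(
                learning_rate=1e-3, epochs=1, batch_size=8, seed=6, strategy="full"))
            results.append(model.backbone.checksum())
        assert results[0] == results[1]

    def test_config_validation(self):
        with pytest.raises(ValueError):
            FineTuneConfig(learning_rate=0.0)
        with pytest.raises(ValueError):
            FineTuneConfig(epochs=0)
        with pytest.raises(ValueError):
            FineTuneConfig(strategy="adapter")


class TestZeroShot:
    def test_two_way_softmax(self, model):
        pred = zero_shot_label(model, prompt_for_record(make_record()))
        ll_neg, ll_pos = pred.logits
        expected = 1.0 / (1.0 + np.exp(ll_neg - ll_pos))
        assert abs(pred.p_positive - expected) < 1e-9
        assert 0.0 < pred.p_positive < 1.0

    def test_biased_model_prefers_positive(self, model):
        biased = ClassifierModel(model.backbone.clone())
        # boost the output row of byte "P": "Positive" contains it, the
        # negative continuation does not
        biased.backbone.params["tok_emb"].data[ord("P")] += 1.0
        prompt = prompt_for_record(make_record())
        assert zero_shot_label(biased, prompt).p_positive > 0.5

    def test_deterministic(self, model):
        prompt = prompt_for_record(make_record())
        a = zero_shot_label(model, prompt)
        b = zero_shot_label(model, prompt)
        assert a.p_positive == b.p_positive


class TestCheckpoint:
    def test_round_trip(self, tmp_path, model):
        save_checkpoint(model, tmp_path / "ckpt")
        loaded = load_checkpoint(tmp_path / "ckpt")
        assert loaded.backbone.checksum() == model.backbone.checksum()
        rec = make_record()
        a = predict(model, [rec])[0].p_positive
        b = predict(loaded, [rec])[0].p_positive
        assert a == b
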