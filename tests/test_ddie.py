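import numpy as np
import pytest

from kgddi import ddie
from kgddi.corpus import Mention, RelationInstance
from kgddi.ddie import (
    CLS,
    DRUG1,
    DRUG2,
    KG1,
    KG2,
    SEP,
    AblationConfig,
    DDIEModel,
    DDIETrainConfig,
    EncoderConfig,
    Vocabulary,
    build_input,
    predict,
    tokenize,
    train,
)
from kgddi.kg_embed import KGEmbeddingModel


def _instance(masked="DRUG1 inhibits DRUG2", label="Effect", kg1="e0", kg2="e1"):
    return RelationInstance(
        sentence_masked=masked,
        m1=Mention("m1", 0, 5, "a"),
        m2=Mention("m2", 6, 11, "b"),
        label=label,
        kg1=kg1,
        kg2=kg2,
    )


@pytest.fixture
def vocab():
    return Vocabulary.build(["DRUG1 inhibits DRUG2", "DRUG1 boosts DRUG2 and DRUGOTHER"])


@pytest.fixture
def kg_model():
    m = KGEmbeddingModel.create([f"e{i}" for i in range(4)], ["interact"],
                                "distmult", 16, seed=3)
    m.E = np.random.default_rng(3).standard_normal(m.E.shape)
    return m


@pytest.fixture
def small_model(vocab, kg_model):
    return DDIEModel(vocab, kg_model, EncoderConfig(L=1, d=16, heads=2, d_m=8, seed=0))


class TestBuildInput:
    def test_marker_layout_and_shared_positions(self, vocab):
        inp = build_input(_instance(), vocab, AblationConfig())
        # [CLS] DRUG1 inhibits DRUG2 [SEP] [KG1] [KG2]
        assert inp.token_ids[0] == CLS
        assert inp.token_ids[-3] == SEP
        assert inp.token_ids[-2:] == [KG1, KG2]
        assert (inp.m1_index, inp.m2_index) == (1, 3)
        assert inp.position_ids[:5] == [0, 1, 2, 3, 4]
        # markers carry the mention positions: first mention at position 1
        assert inp.position_ids[-2:] == [1, 3]

    def test_unshared_positions_follow_sep(self, vocab):
        abl = AblationConfig(share_position_ids=False)
        inp = build_input(_instance(), vocab, abl)
        sep_pos = len(inp.token_ids) - 3
        assert inp.position_ids[-2:] == [sep_pos + 1, sep_pos + 2]

    def test_toggling_sharing_changes_only_marker_positions(self, vocab):
        on = build_input(_instance(), vocab, AblationConfig(share_position_ids=True))
        off = build_input(_instance(), vocab, AblationConfig(share_position_ids=False))
        assert on.token_ids == off.token_ids
        assert on.kg_entity_ids == off.kg_entity_ids
        assert (on.m1_index, on.m2_index) == (off.m1_index, off.m2_index)
        assert on.position_ids[:-2] == off.position_ids[:-2]
        assert on.position_ids[-2:] != off.position_ids[-2:]

    def test_without_kg_no_marker_slots(self, vocab):
        inp = build_input(_instance(), vocab, AblationConfig(use_kg=False))
        assert inp.token_ids[-1] == SEP
        assert KG1 not in inp.token_ids and KG2 not in inp.token_ids
        assert len(inp.token_ids) == len(inp.position_ids)

    def test_missing_or_duplicate_drug_tokens_are_errors(self, vocab):
        with pytest.raises(ValueError, match="exactly once"):
            build_input(_instance("DRUG1 alone"), vocab, AblationConfig())
        with pytest.raises(ValueError, match="exactly once"):
            build_input(_instance("DRUG1 DRUG2 DRUG2"), vocab, AblationConfig())

    def test_over_length_sequence_is_an_error(self, vocab):
        long = "DRUG1 " + "very " * 200 + "DRUG2"
        with pytest.raises(ValueError, match="max_len"):
            build_input(_instance(long), vocab, AblationConfig(), max_len=64)

    def test_reserved_tokens_stay_atomic(self):
        assert tokenize("DRUG1, DRUG2-DRUGOTHER.") == [
            "DRUG1", ",", "DRUG2", "-", "DRUGOTHER", ".",
        ]


class TestEmbedding:
    def test_marker_slot_carries_kg_row_plus_position(self, small_model, kg_model):
        inp = build_input(_instance(kg1="e2", kg2="e0"), small_model.vocab,
                          AblationConfig())
        tok, pos, mask, mpos, kg_rows, kg_known, m_idx, _ = small_model._collate([inp])
        x = small_model.embed(tok, pos, mpos, kg_rows, kg_known).data
        expected = kg_model.E[2] + small_model.params["pos_table"].data[inp.position_ids[-2]]
        np.testing.assert_allclose(x[0, -2], expected, atol=1e-12)

    def test_unlinked_mention_uses_unk_entity_vector(self, small_model):
        inp = build_input(_instance(kg1=None, kg2="e1"), small_model.vocab,
                          AblationConfig())
        tok, pos, mask, mpos, kg_rows, kg_known, m_idx, _ = small_model._collate([inp])
        x = small_model.embed(tok, pos, mpos, kg_rows, kg_known).data
        expected = (small_model.params["unk_entity"].data
                    + small_model.params["pos_table"].data[inp.position_ids[-2]])
        np.testing.assert_allclose(x[0, -2], expected, atol=1e-12)

    def test_shared_entity_gives_identical_marker_content(self, small_model):
        insts = [_instance(kg1="e1"), _instance("DRUG1 boosts DRUG2", kg1="e1")]
        abl = AblationConfig()
        inputs = [build_input(i, small_model.vocab, abl) for i in insts]
        tok, pos, mask, mpos, kg_rows, kg_known, m_idx, _ = small_model._collate(inputs)
        # strip position embedding to compare content only
        x = small_model.embed(tok, pos, mpos, kg_rows, kg_known).data
        p = small_model.params["pos_table"].data
        c0 = x[0, mpos[0, 0]] - p[inputs[0].position_ids[-2]]
        c1 = x[1, mpos[1, 0]] - p[inputs[1].position_ids[-2]]
        np.testing.assert_allclose(c0, c1, atol=1e-12)

    def test_forward_without_kg_never_reads_kg_table(self, vocab, kg_model):
        model = DDIEModel(vocab, kg_model, EncoderConfig(L=1, d=16, heads=2, seed=0),
                          AblationConfig(use_kg=False))
        inputs = [build_input(_instance(), vocab, model.ablation)]
        model.forward(inputs)
        assert model.kg_lookup_count == 0

    def test_forward_with_kg_reads_kg_table(self, small_model):
        inputs = [build_input(_instance(), small_model.vocab, small_model.ablation)]
        small_model.forward(inputs)
        assert small_model.kg_lookup_count == 1


class TestEncoder:
    def test_output_length_equals_input_length(self, small_model):
        inputs = [build_input(_instance(), small_model.vocab, small_model.ablation)]
        tok, pos, mask, mpos, kg_rows, kg_known, m_idx, _ = small_model._collate(inputs)
        x = small_model.embed(tok, pos, mpos, kg_rows, kg_known)
        h = small_model.encode(x, mask)
        assert h.shape == x.shape

    def test_padding_does_not_change_real_token_states(self, small_model):
        abl = small_model.ablation
        short = build_input(_instance(), small_model.vocab, abl)
        longer = build_input(
            _instance("DRUG1 boosts DRUG2 and DRUGOTHER strongly today"),
            small_model.vocab, abl,
        )
        # encode the short instance alone vs padded next to a longer one
        alone = small_model.forward([short])[0].data
        padded = small_model.forward([short, longer])[0].data[0]
        np.testing.assert_allclose(alone[0], padded, atol=1e-9)

    def test_layer_count_validation(self):
        with pytest.raises(ValueError):
            EncoderConfig(L=0)
        EncoderConfig(L=1)  # fine


class TestClassify:
    def test_probabilities_form_a_simplex(self, small_model):
        inputs = [build_input(_instance(), small_model.vocab, small_model.ablation)]
        probs = small_model.probabilities(inputs)
        assert np.all(probs >= 0)
        assert probs.sum(axis=-1) == pytest.approx(1.0, abs=1e-6)

    def test_zero_head_gives_uniform_probabilities(self, small_model):
        small_model.params["W_mid"].data[:] = 0
        small_model.params["b_mid"].data[:] = 0
        small_model.params["W_fc"].data[:] = 0
        small_model.params["b_fc"].data[:] = 0
        inputs = [build_input(_instance(), small_model.vocab, small_model.ablation)]
        probs = small_model.probabilities(inputs)
        np.testing.assert_allclose(probs, 1 / 5, atol=1e-12)

    def test_head_needs_some_input(self):
        with pytest.raises(ValueError):
            AblationConfig(use_cls=False, use_mentions=False)


def _tiny_training_set():
    rng = np.random.default_rng(0)
    insts = []
    for i in range(40):
        kg1, kg2 = f"e{rng.integers(4)}", f"e{rng.integers(4)}"
        label = "Effect" if (kg1 == kg2) else "negative"
        verb = rng.choice(["inhibits", "boosts", "alters"])
        insts.append(_instance(f"DRUG1 {verb} DRUG2", label, kg1, kg2))
    return insts


class TestTraining:
    def test_loss_decreases(self, vocab, kg_model):
        insts = _tiny_training_set()
        model = DDIEModel(vocab, kg_model, EncoderConfig(L=1, d=16, heads=2, seed=0))
        state = train(insts, model, DDIETrainConfig(epochs=6, seed=0))
        assert state.epoch_losses[-1] < state.epoch_losses[0]

    def test_frozen_tables_are_bit_identical_after_training(self, vocab, kg_model):
        model = DDIEModel(vocab, kg_model, EncoderConfig(L=1, d=16, heads=2, seed=0),
                          AblationConfig(freeze_embeddings=True))
        word_before = model.params["word_table"].data.copy()
        kg_before = model.params["kg_table"].data.copy()
        pos_before = model.params["pos_table"].data.copy()
        train(_tiny_training_set(), model, DDIETrainConfig(epochs=2, seed=0))
        assert np.array_equal(model.params["word_table"].data, word_before)
        assert np.array_equal(model.params["kg_table"].data, kg_before)
        # position embeddings are NOT frozen
        assert not np.array_equal(model.params["pos_table"].data, pos_before)

    def test_unfrozen_tables_change(self, vocab, kg_model):
        model = DDIEModel(vocab, kg_model, EncoderConfig(L=1, d=16, heads=2, seed=0),
                          AblationConfig(freeze_embeddings=False))
        kg_before = model.params["kg_table"].data.copy()
        train(_tiny_training_set(), model, DDIETrainConfig(epochs=2, seed=0))
        assert not np.array_equal(model.params["kg_table"].data, kg_before)

    def test_average_after_one_update_equals_current(self, vocab, kg_model):
        insts = _tiny_training_set()
        model = DDIEModel(vocab, kg_model, EncoderConfig(L=1, d=16, heads=2, seed=0))
        state = train(insts, model,
                      DDIETrainConfig(epochs=1, batch_size=len(insts), seed=0))
        assert state.update_count == 1
        for name, avg in state.averaged.items():
            np.testing.assert_array_equal(avg, model.params[name].data)
        lab_avg, _ = predict(state, insts, use_average=True)
        lab_cur, _ = predict(state, insts, use_average=False)
        assert lab_avg == lab_cur

    def test_training_is_reproducible_under_seed(self, vocab, kg_model):
        insts = _tiny_training_set()
        outs = []
        for _ in range(2):
            model = DDIEModel(vocab, kg_model,
                              EncoderConfig(L=1, d=16, heads=2, seed=1))
            state = train(insts, model, DDIETrainConfig(epochs=3, seed=1))
            outs.append(predict(state, insts)[1])
        np.testing.assert_array_equal(outs[0], outs[1])

    def test_empty_training_set_is_an_error(self, small_model):
        with pytest.raises(ValueError):
            train([], small_model, DDIETrainConfig())
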