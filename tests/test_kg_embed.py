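import numpy as np
import pytest

from kgddi.kg_embed import (
    KGEmbeddingModel,
    KGTrainConfig,
    TripleBatch,
    _raw_grads,
    _raw_scores,
    fit,
    init_from_vectors,
    logistic_loss,
    sample_negatives,
    score,
    score_batch,
)
from kgddi.kg_store import Triple


def _model(kind, d=6, n_e=5, n_r=3, seed=0, zero=False):
    m = KGEmbeddingModel.create(
        [f"e{i}" for i in range(n_e)], [f"r{i}" for i in range(n_r)], kind, d, seed=seed
    )
    if zero:
        m.E[:] = 0.0
        m.R[:] = 0.0
    else:
        rng = np.random.default_rng(seed)
        m.E = rng.standard_normal(m.E.shape)
        m.R = rng.standard_normal(m.R.shape)
    return m


class TestScoreFunctions:
    def test_transe_zero_vectors_score_zero(self):
        m = _model("transe", zero=True)
        assert score(m, Triple("e0", "r0", "e1")) == 0.0

    def test_distmult_is_head_tail_symmetric(self, rng):
        m = _model("distmult")
        for _ in range(20):
            h, t = rng.choice(5, size=2, replace=False)
            r = rng.integers(3)
            assert score(m, Triple(f"e{h}", f"r{r}", f"e{t}")) == pytest.approx(
                score(m, Triple(f"e{t}", f"r{r}", f"e{h}")), abs=1e-12
            )

    def test_transe_is_not_symmetric_for_generic_vectors(self):
        m = _model("transe")
        tr = Triple("e0", "r0", "e1")
        rev = Triple("e1", "r0", "e0")
        assert abs(score(m, tr) - score(m, rev)) > 1e-6

    def test_complex_with_zero_imaginary_equals_distmult(self, rng):
        # oracle: an independent DistMult on the real halves
        m = _model("complex", d=8)
        k = 4
        m.E[:, k:] = 0.0
        m.R[:, k:] = 0.0
        dm = _model("distmult", d=4)
        dm.E = m.E[:, :k].copy()
        dm.R = m.R[:, :k].copy()
        for _ in range(10):
            h, t = rng.integers(5, size=2)
            r = rng.integers(3)
            tr = Triple(f"e{h}", f"r{r}", f"e{t}")
            assert score(m, tr) == pytest.approx(score(dm, tr), abs=1e-10)

    def test_complex_matches_complex_arithmetic_oracle(self, rng):
        m = _model("complex", d=8)
        k = 4
        for _ in range(10):
            h, t = rng.integers(5, size=2)
            r = rng.integers(3)
            eh = m.E[h, :k] + 1j * m.E[h, k:]
            wr = m.R[r, :k] + 1j * m.R[r, k:]
            et = m.E[t, :k] + 1j * m.E[t, k:]
            expected = float(np.real(np.sum(eh * wr * np.conj(et))))
            assert score(m, Triple(f"e{h}", f"r{r}", f"e{t}")) == pytest.approx(
                expected, abs=1e-10
            )

    def test_simple_with_tied_halves_equals_distmult(self):
        m = _model("simple", d=8)
        k = 4
        m.E[:, k:] = m.E[:, :k]  # head-vector = tail-vector
        m.R[:, k:] = m.R[:, :k]  # forward = inverse
        dm = _model("distmult", d=4)
        dm.E = m.E[:, :k].copy()
        dm.R = m.R[:, :k].copy()
        tr = Triple("e0", "r1", "e2")
        assert score(m, tr) == pytest.approx(score(dm, tr), abs=1e-10)

    def test_unknown_entity_is_a_lookup_error(self):
        m = _model("distmult")
        with pytest.raises(KeyError, match="ghost"):
            score(m, Triple("ghost", "r0", "e1"))


@pytest.mark.parametrize("kind", ["transe", "distmult", "complex", "simple"])
def test_analytic_gradients_match_finite_differences(kind):
    rng = np.random.default_rng(3)
    d = 6
    E = rng.standard_normal((4, d))
    R = rng.standard_normal((2, d))
    h = np.array([0, 1, 2])
    r = np.array([0, 1, 0])
    t = np.array([1, 3, 0])
    df = rng.standard_normal(3)
    gh, gr, gt = _raw_grads(kind, E, R, h, r, t, df)
    accE = np.zeros_like(E)
    np.add.at(accE, h, gh)
    np.add.at(accE, t, gt)
    accR = np.zeros_like(R)
    np.add.at(accR, r, gr)
    eps = 1e-6

    def total():
        return float(np.sum(df * _raw_scores(kind, E, R, h, r, t)))

    for arr, acc in ((E, accE), (R, accR)):
        for row in range(arr.shape[0]):
            for j in range(d):
                orig = arr[row, j]
                arr[row, j] = orig + eps
                up = total()
                arr[row, j] = orig - eps
                dn = total()
                arr[row, j] = orig
                assert acc[row, j] == pytest.approx((up - dn) / (2 * eps), abs=1e-5)


class TestLogisticLoss:
    def test_single_positive_zero_score_gives_log_two(self):
        m = _model("distmult", zero=True)
        batch = TripleBatch([Triple("e0", "r0", "e1")], [])
        cfg = KGTrainConfig(lambda_l2=0.0)
        assert logistic_loss(m, batch, cfg) == pytest.approx(np.log(2), abs=1e-12)

    def test_confident_scores_give_near_zero_loss(self):
        # craft f=+10 for the positive and f=-10 for the negative
        m = _model("distmult", d=2, zero=True)
        m.R[0] = [1.0, 0.0]
        m.E[0] = [10.0, 0.0]
        m.E[1] = [1.0, 0.0]
        m.E[2] = [-1.0, 0.0]
        batch = TripleBatch([Triple("e0", "r0", "e1")], [Triple("e0", "r0", "e2")])
        cfg = KGTrainConfig(lambda_l2=0.0)
        expected = 2 * np.log(1 + np.exp(-10))
        assert logistic_loss(m, batch, cfg) == pytest.approx(expected, rel=1e-9)

    def test_l2_term_is_lambda_times_touched_norms(self):
        m = _model("distmult", d=2)
        batch = TripleBatch([Triple("e0", "r0", "e1")], [])
        base = logistic_loss(m, batch, KGTrainConfig(lambda_l2=0.0))
        lam = 0.7
        # hand sum over the touched rows e0, e1, r0
        touched = np.sum(m.E[0] ** 2) + np.sum(m.E[1] ** 2) + np.sum(m.R[0] ** 2)
        loss = logistic_loss(m, batch, KGTrainConfig(lambda_l2=lam))
        assert loss == pytest.approx(base + lam * touched, rel=1e-12)

    def test_empty_batch_is_an_error(self):
        m = _model("distmult")
        with pytest.raises(ValueError):
            logistic_loss(m, TripleBatch([], []), KGTrainConfig())


class TestSampleNegatives:
    def test_only_admissible_corruption_is_used(self, toy_kg):
        # corrupting (d1, interact, d2): the only fresh drug is d3 on either
        # side, because (d3,i,d2)/(d1,i,d3) are not train triples
        batch = sample_negatives(toy_kg, [Triple("d1", "interact", "d2")], k=1, seed=4)
        (neg,) = batch.negatives
        assert {neg.h, neg.t} & {"d3"}
        assert neg != Triple("d1", "interact", "d2")

    def test_same_seed_reproduces_batch(self, toy_kg):
        pos = toy_kg.splits["train"][:3]
        a = sample_negatives(toy_kg, pos, k=3, seed=7)
        b = sample_negatives(toy_kg, pos, k=3, seed=7)
        assert a.negatives == b.negatives

    def test_k_negatives_per_positive(self, toy_kg):
        pos = toy_kg.splits["train"][:2]
        batch = sample_negatives(toy_kg, pos, k=4, seed=0)
        assert len(batch.negatives) == 8

    def test_corruption_preserves_endpoint_types(self, planted):
        kg, _, _ = planted
        pos = kg.splits["train"][:50]
        k = 2
        batch = sample_negatives(kg, pos, k=k, seed=1)
        types = {eid: e.type for eid, e in kg.entities.items()}
        for i, n in enumerate(batch.negatives):
            p = pos[i // k]
            assert types[n.h] == types[p.h]
            assert types[n.t] == types[p.t]

    def test_negatives_avoid_known_train_triples(self, planted):
        kg, _, _ = planted
        known = set(kg.splits["train"])
        batch = sample_negatives(kg, kg.splits["train"][:100], k=2, seed=2)
        hits = sum(1 for n in batch.negatives if n in known)
        assert hits == 0

    def test_single_member_type_falls_back_to_other_side(self, toy_kg):
        # p1 is the only protein: corrupting (d1, target, p1) must corrupt
        # the drug side instead
        batch = sample_negatives(toy_kg, [Triple("d1", "target", "p1")], k=2, seed=0)
        for n in batch.negatives:
            assert n.t == "p1" and n.h != "d1"


class TestInitFromVectors:
    def test_covered_rows_overwritten_others_kept(self):
        m = _model("distmult", d=4)
        before = m.E.copy()
        provider = {"e1": np.ones(4), "e3": np.full(4, 2.0)}
        init_from_vectors(m, provider)
        assert np.array_equal(m.E[1], np.ones(4))
        assert np.array_equal(m.E[3], np.full(4, 2.0))
        assert np.array_equal(m.E[0], before[0])

    def test_empty_provider_is_a_no_op(self):
        m = _model("distmult")
        before = m.E.copy()
        init_from_vectors(m, {})
        assert np.array_equal(m.E, before)

    def test_projection_is_deterministic(self):
        v = np.arange(12.0)
        m1, m2 = _model("distmult", d=4), _model("distmult", d=4)
        init_from_vectors(m1, {"e0": v}, projection_seed=9)
        init_from_vectors(m2, {"e0": v.copy()}, projection_seed=9)
        assert np.array_equal(m1.E[0], m2.E[0])
        assert m1.E[0].shape == (4,)

    def test_dimension_mismatch_without_projection_is_an_error(self):
        m = _model("distmult", d=4)
        with pytest.raises(ValueError, match="dimension"):
            init_from_vectors(m, {"e0": np.ones(7)})


class TestFit:
    def test_loss_descends_on_toy_graph(self, toy_kg):
        m = fit(toy_kg, "distmult", KGTrainConfig(d=8, epochs=5, seed=0))
        assert m.history[-1] < m.history[0]

    def test_same_seed_gives_identical_tables(self, toy_kg):
        cfg = KGTrainConfig(d=8, epochs=3, seed=5)
        a = fit(toy_kg, "distmult", cfg)
        b = fit(toy_kg, "distmult", cfg)
        assert np.array_equal(a.E, b.E)
        assert np.array_equal(a.R, b.R)

    def test_empty_train_split_is_an_error(self, toy_kg):
        toy_kg.splits["train"] = []
        with pytest.raises(ValueError, match="empty"):
            fit(toy_kg, "distmult", KGTrainConfig(epochs=1))


def test_model_round_trips_through_serialization(tmp_path, planted):
    from kgddi.kg_embed import load_model, save_model

    _, _, model = planted
    save_model(model, tmp_path / "m")
    back = load_model(tmp_path / "m")
    assert back.score_kind == model.score_kind
    assert back.entity_ids == model.entity_ids
    np.testing.assert_allclose(back.E, model.E, atol=1e-12)
    tr = Triple(model.entity_ids[0], model.relation_names[0], model.entity_ids[1])
    assert score(back, tr) == pytest.approx(score(model, tr), abs=1e-9)
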