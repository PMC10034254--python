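"""Conditional recurrent generator: losses, forward contract, training,
iterative generation."""

import math

import numpy as np
import pandas as pd
import pytest

from longsynth import (AttributeDef, Cohort, CohortSchema, ModelConfig,
                       attribute_loss, chunk, encode_cohort, generate,
                       label_loss, total_loss, train)
from longsynth.baseline_synth import FIRST_LABEL
from longsynth.recurrent import CondLSTM


# ---------------------------------------------------------------------------
# loss oracles
# ---------------------------------------------------------------------------

def _brute_label_loss(logits, true, mask):
    terms = []
    n, t, C = logits.shape
    for a in range(n):
        for b in range(t):
            if not mask[a, b]:
                continue
            lse = math.log(sum(math.exp(v) for v in logits[a, b]))
            terms.append(-logits[a, b, true[a, b]] + lse)
    return sum(terms) / len(terms)


def _brute_attr_loss(attr_logits, true_labels, true_attrs, relevance, mask):
    terms = []
    n, t = true_labels.shape
    for i, logits in enumerate(attr_logits):
        for a in range(n):
            for b in range(t):
                if not mask[a, b]:
                    continue
                if not relevance[true_labels[a, b], i]:
                    continue
                lse = math.log(sum(math.exp(v) for v in logits[a, b]))
                terms.append(-logits[a, b, true_attrs[a, b, i]] + lse)
    return sum(terms) / len(terms)


@pytest.fixture()
def random_instance():
    rng = np.random.default_rng(42)
    n, t, C = 3, 4, 5
    cards = [4, 3]
    label_logits = rng.normal(size=(n, t, C))
    attr_logits = [rng.normal(size=(n, t, c)) for c in cards]
    true_labels = rng.integers(1, C, size=(n, t))
    true_attrs = np.stack([rng.integers(0, c, size=(n, t)) for c in cards],
                          axis=2)
    relevance = rng.random((C, 2)) < 0.5
    relevance[0] = False
    mask = rng.random((n, t)) < 0.8
    mask[0, 0] = True
    return (label_logits, attr_logits, true_labels, true_attrs, relevance,
            mask)


class TestLosses:
    def test_uniform_logits_give_log_C(self):
        logits = np.zeros((2, 3, 7))
        true = np.ones((2, 3), dtype=int)
        mask = np.ones((2, 3), dtype=bool)
        assert label_loss(logits, true, mask) == pytest.approx(math.log(7))

    def test_saturated_true_class_gives_zero(self):
        logits = np.zeros((1, 2, 4))
        true = np.array([[2, 1]])
        logits[0, 0, 2] = 1000.0
        logits[0, 1, 1] = 1000.0
        assert label_loss(logits, true, np.ones((1, 2), bool)) \
            == pytest.approx(0.0, abs=1e-6)

    def test_label_loss_matches_bruteforce(self, random_instance):
        ll, _, true_l, _, _, mask = random_instance
        assert label_loss(ll, true_l, mask) == pytest.approx(
            _brute_label_loss(ll, true_l, mask), rel=1e-12)

    def test_all_padded_raises(self):
        with pytest.raises(ValueError, match="padded"):
            label_loss(np.zeros((1, 2, 3)), np.zeros((1, 2), int),
                       np.zeros((1, 2), bool))

    def test_attr_loss_matches_bruteforce(self, random_instance):
        _, al, true_l, true_a, rel, mask = random_instance
        assert attribute_loss(al, true_l, true_a, rel, mask) == pytest.approx(
            _brute_attr_loss(al, true_l, true_a, rel, mask), rel=1e-12)

    def test_all_relevant_equals_unmasked_mean(self, random_instance):
        _, al, true_l, true_a, rel, mask = random_instance
        rel_all = np.ones_like(rel)
        mask_all = np.ones_like(mask)
        expect = np.mean([
            _brute_attr_loss([al[i]], true_l, true_a[:, :, [i]].copy(),
                             np.ones((rel.shape[0], 1), bool), mask_all)
            * mask_all.size
            for i in range(len(al))]) / mask_all.size
        got = attribute_loss(al, true_l, true_a, rel_all, mask_all)
        assert got == pytest.approx(expect, rel=1e-9)

    def test_empty_relevance_raises(self, random_instance):
        _, al, true_l, true_a, rel, mask = random_instance
        with pytest.raises(ValueError, match="relevant"):
            attribute_loss(al, true_l, true_a, np.zeros_like(rel), mask)

    def test_irrelevant_logit_perturbation_changes_nothing(
            self, random_instance):
        """Masking correctness: logits of an attribute irrelevant for the
        true label contribute exactly zero."""
        _, al, true_l, true_a, rel, mask = random_instance
        before = attribute_loss(al, true_l, true_a, rel, mask)
        perturbed = [a.copy() for a in al]
        bumped = 0
        for i in range(len(al)):
            irrelevant = ~rel[true_l, i] & mask
            perturbed[i][irrelevant] += 1e6
            bumped += irrelevant.sum()
        assert bumped > 0
        after = attribute_loss(perturbed, true_l, true_a, rel, mask)
        assert after == before

    def test_total_loss_arithmetic(self, random_instance):
        ll, al, true_l, true_a, rel, mask = random_instance
        l1 = label_loss(ll, true_l, mask)
        l2 = attribute_loss(al, true_l, true_a, rel, mask)
        assert total_loss(l1, l2, 0.0) == pytest.approx(l1)
        assert total_loss(l1, l1, 1.0) == pytest.approx(2 * l1)
        assert total_loss(l1, l2, 0.5) == pytest.approx(l1 + 0.5 * l2)


# ---------------------------------------------------------------------------
# forward contract
# ---------------------------------------------------------------------------

class TestForward:
    @pytest.fixture()
    def net(self):
        return CondLSTM(n_labels=5, attr_cards=[4, 3], base_cards=[3, 2],
                        hidden=12, seed=0)

    @pytest.fixture()
    def batch(self):
        rng = np.random.default_rng(0)
        return (rng.integers(0, 5, (6, 7)), rng.integers(0, 3, (6, 7, 2)),
                rng.integers(0, 2, (6, 2)))

    def test_single_step_shapes(self, net, batch):
        labels, attrs, base = batch
        ll, al, _, _ = net.forward(labels[:, :1], attrs[:, :1], base)
        assert ll.shape == (6, 1, 5)
        assert [a.shape for a in al] == [(6, 1, 4), (6, 1, 3)]

    def test_chained_steps_equal_joint_forward(self, net, batch):
        """Two 1-step calls passing the state match one 2-step call."""
        labels, attrs, base = batch
        joint, joint_a, _, _ = net.forward(labels[:, :2], attrs[:, :2], base)
        l1, a1, s1, _ = net.forward(labels[:, :1], attrs[:, :1], base)
        l2, a2, _, _ = net.forward(labels[:, 1:2], attrs[:, 1:2], base, s1)
        assert np.allclose(joint[:, 0], l1[:, 0])
        assert np.allclose(joint[:, 1], l2[:, 0])
        for j in range(2):
            assert np.allclose(joint_a[j][:, 1], a2[j][:, 0])

    def test_batch_permutation_equivariance(self, net, batch):
        labels, attrs, base = batch
        perm = np.array([3, 0, 5, 1, 4, 2])
        ll, _, _, _ = net.forward(labels, attrs, base)
        lp, _, _, _ = net.forward(labels[perm], attrs[perm], base[perm])
        assert np.allclose(ll[perm], lp)

    def test_out_of_range_codes_rejected(self, net, batch):
        labels, attrs, base = batch
        labels = labels.copy()
        labels[0, 0] = 99
        with pytest.raises(ValueError):
            net.forward(labels, attrs, base)


# ---------------------------------------------------------------------------
# training and generation
# ---------------------------------------------------------------------------

def _chain_schema():
    return CohortSchema(
        event_labels=["A", "B"],
        attributes=[AttributeDef(name="step", categories=["s"])],
        relevance={"A": {"step"}, "B": {"step"}},
        baseline_vars=[],
    )


def _chain_cohort(n=120, length=24):
    schema = _chain_schema()
    recs = []
    for pid in range(n):
        for t in range(length):
            recs.append({"pid": pid, "pos": t,
                         "label": "AB"[t % 2], "date": float(t),
                         "sojourn": 1.0, "step": "s"})
    events = pd.DataFrame(recs)
    baseline = pd.DataFrame({"pid": range(n)})
    return Cohort(baseline=baseline, events=events, schema=schema), schema


@pytest.fixture(scope="module")
def chain_model():
    cohort, schema = _chain_cohort()
    enc = encode_cohort(cohort, schema)
    chunks = chunk(enc, window=24)
    cfg = ModelConfig(epochs=30, hidden=8, embed_label=4, embed_attr=2,
                      embed_base=2, window=24, seed=0, lr=2e-2,
                      batch_size=32)
    return train(chunks, cfg), enc, schema


class TestTraining:
    def test_initial_loss_near_uniform_softmax(self, sim_spec, sim_cohort):
        """Before any update, near-zero heads give loss ~ ln C + lam *
        (mean over relevant attrs of ln C_i)."""
        from longsynth.generator import build_net
        enc = encode_cohort(sim_cohort, sim_spec.schema)
        chunks = chunk(enc, window=40)
        cfg = ModelConfig(seed=1)
        net = build_net(enc.codebook, cfg)
        rel = sim_spec.schema.relevance_matrix()
        in_l, tgt_l = chunks.labels[:, :-1], chunks.labels[:, 1:]
        in_a, tgt_a = chunks.attrs[:, :-1], chunks.attrs[:, 1:]
        valid = np.arange(1, 40)[None, :] < chunks.lengths[:, None]
        ll, al, _, _ = net.forward(in_l, in_a, chunks.baseline)
        l1 = label_loss(ll, tgt_l, valid)
        l2 = attribute_loss(al, tgt_l, tgt_a, rel, valid)
        C = sim_spec.schema.n_labels
        cards = [enc.codebook.attr_cardinality(a)
                 for a in sim_spec.schema.attr_names]
        masks = [valid & rel[tgt_l, i] for i in range(len(cards))]
        counts = np.array([m.sum() for m in masks], dtype=float)
        expect_attr = float(np.dot(np.log(cards), counts) / counts.sum())
        assert l1 == pytest.approx(math.log(C), rel=0.02)
        assert l2 == pytest.approx(expect_attr, rel=0.02)

    def test_deterministic_chain_reaches_full_accuracy(self, chain_model):
        model, enc, schema = chain_model
        # held-out chains are identical alternations; accuracy by argmax
        hold, _ = _chain_cohort(n=10, length=24)
        henc = encode_cohort(hold, schema, codebook=enc.codebook)
        chunks = chunk(henc, window=24)
        ll, _, _, _ = model.net.forward(chunks.labels[:, :-1],
                                        chunks.attrs[:, :-1],
                                        chunks.baseline)
        pred = ll.argmax(axis=2)
        tgt = chunks.labels[:, 1:]
        valid = np.arange(1, 24)[None, :] < chunks.lengths[:, None]
        assert (pred[valid] == tgt[valid]).all()

    def test_loss_trend_decreases(self, chain_model):
        model, _, _ = chain_model
        trace = [e["total_loss"] for e in model.loss_trace]
        assert trace[-1] < trace[0]

    def test_constant_label_converges_to_certainty(self):
        schema = CohortSchema(
            event_labels=["A"],
            attributes=[AttributeDef(name="step", categories=["s"])],
            relevance={"A": {"step"}}, baseline_vars=[])
        recs = [{"pid": p, "pos": t, "label": "A", "date": float(t),
                 "sojourn": 1.0, "step": "s"}
                for p in range(40) for t in range(10)]
        cohort = Cohort(pd.DataFrame({"pid": range(40)}),
                        pd.DataFrame(recs), schema)
        enc = encode_cohort(cohort, schema)
        model = train(chunk(enc, window=10),
                      ModelConfig(epochs=10, hidden=6, window=10, seed=0,
                                  lr=3e-2, batch_size=16))
        from longsynth.recurrent import softmax
        ll, _, _, _ = model.net.forward(np.array([[1]]),
                                        np.array([[[1]]]),
                                        np.zeros((1, 0), int))
        assert softmax(ll[0, 0])[1] > 0.95


class TestGeneration:
    def test_chain_generation_is_exact(self, chain_model):
        model, enc, schema = chain_model
        seeds = pd.DataFrame({FIRST_LABEL: [schema.label_code("A")] * 5,
                              "first_step": [1] * 5})
        syn = generate(model, seeds, max_length=12, temperature=0.1, seed=0)
        for seq in syn.label_sequences().values():
            assert seq == list("AB" * 6)

    def test_max_length_one_returns_seed_only(self, chain_model):
        model, _, schema = chain_model
        seeds = pd.DataFrame({FIRST_LABEL: [schema.label_code("B")] * 4,
                              "first_step": [1] * 4})
        syn = generate(model, seeds, max_length=1, seed=0)
        assert (syn.sequence_lengths() == 1).all()
        assert set(syn.events.label) == {"B"}

    def test_temperature_zero_is_deterministic(self, chain_model):
        model, _, schema = chain_model
        seeds = pd.DataFrame({FIRST_LABEL: [schema.label_code("A")] * 3,
                              "first_step": [1] * 3})
        a = generate(model, seeds, max_length=9, temperature=0.0, seed=1)
        b = generate(model, seeds, max_length=9, temperature=0.0, seed=999)
        pd.testing.assert_frame_equal(a.events, b.events)

    def test_terminal_trim_and_masking(self, sim_spec, sim_cohort):
        """Generated cohorts never contain events after a terminal label and
        keep irrelevant attributes missing."""
        from longsynth import fit_and_generate
        cfg = ModelConfig(epochs=4, hidden=16, window=40, seed=0,
                          batch_size=64)
        _, syn = fit_and_generate(sim_cohort, sim_spec.schema, cfg,
                                  max_length=sim_spec.max_length, seed=0)
        for seq in syn.label_sequences().values():
            assert "EOS" not in seq[:-1]
        syn.validate()  # checks relevance-driven missingness

    def test_bad_seed_labels_rejected(self, chain_model):
        model, _, _ = chain_model
        seeds = pd.DataFrame({FIRST_LABEL: [77], "first_step": [1]})
        with pytest.raises(ValueError):
            generate(model, seeds, max_length=3, seed=0)
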