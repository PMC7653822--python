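"""Scores, NCE losses, analytic gradients and the training loop."""

import math

import numpy as np
import pytest

from enzopt import (
    SyntheticSpec,
    TrainingConfig,
    generate_synthetic_family,
    partition_by_threshold,
    train,
)
from enzopt.embedding_model import (
    EmbeddingTable,
    Event,
    NoiseModel,
    PairEvent,
    _Batch,
    batch_loss_and_gradients,
    capability_matrix,
    capability_score,
    combined_loss,
    joint_embedding,
    nce_loss_pair,
    nce_loss_single,
    pair_unnormalized_logprob,
    suitability_score,
    unnormalized_logprob,
)
from enzopt.msa_io import ALPHABET, SYMBOL_INDEX
from enzopt.site_statistics import N_SYMBOLS, compute_site_statistics

from conftest import random_table


def _uniform_noise(l: int) -> NoiseModel:
    return NoiseModel.uniform(l, np.arange(l))


class TestScores:
    def test_capability_is_dot_product(self, rng):
        table = random_table(4, 5, rng)
        e = Event(site=2, symbol="K")
        expected = sum(
            table.site_vectors[1][i] * table.symbol_vectors[SYMBOL_INDEX["K"]][i]
            for i in range(5)
        )
        assert capability_score(table, e) == pytest.approx(expected, abs=1e-12)

    def test_zero_site_vector_scores_zero_for_every_symbol(self, rng):
        table = random_table(3, 4, rng)
        table.site_vectors[0] = 0.0
        for s in ALPHABET:
            assert capability_score(table, Event(1, s)) == 0.0

    def test_joint_embedding_concatenates_site_then_symbol(self, rng):
        table = random_table(3, 2, rng)
        v = joint_embedding(table, Event(2, "R"))
        assert v.shape == (4,)
        assert np.array_equal(v[:2], table.site_vectors[1])
        assert np.array_equal(v[2:], table.symbol_vectors[SYMBOL_INDEX["R"]])

    def test_suitability_decomposes_into_two_dot_products(self, rng):
        table = random_table(5, 4, rng)
        p = PairEvent(Event(1, "K"), Event(4, "D"))
        expected = float(
            table.site_vectors[0] @ table.site_vectors[3]
            + table.symbol_vectors[SYMBOL_INDEX["K"]]
            @ table.symbol_vectors[SYMBOL_INDEX["D"]]
        )
        assert suitability_score(table, p) == pytest.approx(expected, abs=1e-12)
        # and equals the explicit 2d-dimensional dot product
        assert suitability_score(table, p) == pytest.approx(
            float(joint_embedding(table, p.first) @ joint_embedding(table, p.second)),
            abs=1e-12,
        )

    def test_same_site_pair_rejected(self):
        with pytest.raises(ValueError):
            PairEvent(Event(1, "K"), Event(1, "D"))

    def test_unnormalized_logprob_shifts_with_C(self, rng):
        table = random_table(3, 4, rng)
        e = Event(2, "E")
        base = unnormalized_logprob(table, e)
        table.C += 0.75
        assert unnormalized_logprob(table, e) == pytest.approx(base + 0.75)

    def test_explicit_normalizer_makes_probabilities_sum_to_one(self, rng):
        """With C = -log sum exp s the exp of the logprob is the softmax."""
        table = random_table(3, 4, rng)
        scores = [
            capability_score(table, Event(k, s))
            for k in (1, 2, 3)
            for s in ALPHABET
        ]
        table.C = -float(np.log(np.sum(np.exp(scores))))
        total = sum(
            math.exp(unnormalized_logprob(table, Event(k, s)))
            for k in (1, 2, 3)
            for s in ALPHABET
        )
        assert total == pytest.approx(1.0, rel=1e-9)

    def test_capability_matrix_matches_scalar_scores(self, rng):
        table = random_table(4, 3, rng)
        mat = capability_matrix(table)
        assert mat.shape == (4, N_SYMBOLS)
        for k in (1, 3):
            for s in ("A", "K", "-"):
                assert mat[k - 1, SYMBOL_INDEX[s]] == pytest.approx(
                    capability_score(table, Event(k, s))
                )


class TestNCELosses:
    def test_equal_model_and_noise_logprobs_give_two_ln_two(self):
        """sigma(0) = 1/2 on both terms gives loss 2 ln 2."""
        l, d = 3, 2
        noise = _uniform_noise(l)
        table = EmbeddingTable(
            site_vectors=np.zeros((l, d)), symbol_vectors=np.zeros((N_SYMBOLS, d))
        )
        table.C = float(noise.event_logprob(np.array([0]), np.array([0]))[0])
        loss = nce_loss_single(table, Event(1, "A"), [Event(2, "K")], noise)
        assert loss == pytest.approx(2 * math.log(2), rel=1e-12)
        table.C_pair = float(
            noise.pair_logprob(
                np.array([0]), np.array([1]), np.array([0]), np.array([0])
            )[0]
        )
        pair_loss = nce_loss_pair(
            table,
            PairEvent(Event(1, "A"), Event(2, "A")),
            [PairEvent(Event(2, "K"), Event(3, "D"))],
            noise,
        )
        assert pair_loss == pytest.approx(2 * math.log(2), rel=1e-12)

    def test_losses_are_nonnegative(self, rng):
        table = random_table(4, 3, rng)
        noise = _uniform_noise(4)
        for _ in range(10):
            pos = Event(int(rng.integers(1, 5)), str(rng.choice(list(ALPHABET))))
            neg = Event(int(rng.integers(1, 5)), str(rng.choice(list(ALPHABET))))
            assert nce_loss_single(table, pos, [neg], noise) >= 0.0

    def test_single_loss_matches_step_by_step_oracle(self, rng):
        """Independent evaluation: logistic posterior of data vs noise."""
        table = random_table(5, 4, rng)
        noise = _uniform_noise(5)
        pos = Event(2, "K")
        negs = [Event(4, "D"), Event(1, "-")]

        def sigma(x):
            return 1.0 / (1.0 + math.exp(-x))

        logpn = -math.log(5) - math.log(N_SYMBOLS)
        dpos = capability_score(table, pos) + table.C - logpn
        dnegs = [capability_score(table, e) + table.C - logpn for e in negs]
        expected = -math.log(sigma(dpos)) - np.mean(
            [math.log(1 - sigma(x)) for x in dnegs]
        )
        assert nce_loss_single(table, pos, negs, noise) == pytest.approx(
            expected, rel=1e-10
        )

    def test_pair_loss_matches_step_by_step_oracle(self, rng):
        table = random_table(5, 3, rng)
        noise = _uniform_noise(5)
        pos = PairEvent(Event(1, "K"), Event(3, "R"))
        neg = PairEvent(Event(2, "D"), Event(5, "E"))

        def sigma(x):
            return 1.0 / (1.0 + math.exp(-x))

        logpn = -math.log(5 * 4) - 2 * math.log(N_SYMBOLS)
        dpos = pair_unnormalized_logprob(table, pos) - logpn
        dneg = pair_unnormalized_logprob(table, neg) - logpn
        expected = -math.log(sigma(dpos)) - math.log(1 - sigma(dneg))
        assert nce_loss_pair(table, pos, [neg], noise) == pytest.approx(
            expected, rel=1e-10
        )

    @pytest.mark.parametrize(
        "alpha,expected", [(1.0, 1.0), (0.0, 2.0), (0.4, 1.6)]
    )
    def test_combined_loss_convex_combination(self, alpha, expected, rng):
        table = random_table(2, 2, rng)
        assert combined_loss(table, 1.0, 2.0, alpha) == pytest.approx(expected)

    def test_combined_loss_rejects_alpha_outside_unit_interval(self, rng):
        table = random_table(2, 2, rng)
        with pytest.raises(ValueError):
            combined_loss(table, 1.0, 2.0, 1.5)

    def test_combined_loss_monotone_in_components(self, rng):
        table = random_table(2, 2, rng)
        base = combined_loss(table, 1.0, 2.0, 0.3)
        assert combined_loss(table, 1.5, 2.0, 0.3) > base
        assert combined_loss(table, 1.0, 2.5, 0.3) > base


def _finite_difference_check(table, batch, noise, alpha, h=1e-5):
    """Max relative error of analytic vs central-difference gradients."""
    grads = batch_loss_and_gradients(table, batch, noise, alpha)

    def loss_of(site_v, sym_v, C, Cp):
        t = EmbeddingTable(
            site_vectors=site_v, symbol_vectors=sym_v, C=C, C_pair=Cp
        )
        return batch_loss_and_gradients(t, batch, noise, alpha).loss

    worst = 0.0
    scale = max(
        np.abs(grads.site_vectors).max(),
        np.abs(grads.symbol_vectors).max(),
        abs(grads.C),
        abs(grads.C_pair),
        1e-8,
    )
    for (arr, garr) in (
        (table.site_vectors, grads.site_vectors),
        (table.symbol_vectors, grads.symbol_vectors),
    ):
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = arr[idx]
            arr[idx] = orig + h
            up = loss_of(table.site_vectors, table.symbol_vectors, table.C, table.C_pair)
            arr[idx] = orig - h
            dn = loss_of(table.site_vectors, table.symbol_vectors, table.C, table.C_pair)
            arr[idx] = orig
            num = (up - dn) / (2 * h)
            worst = max(worst, abs(num - garr[idx]) / scale)
    for attr, g in (("C", grads.C), ("C_pair", grads.C_pair)):
        orig = getattr(table, attr)
        setattr(table, attr, orig + h)
        up = batch_loss_and_gradients(table, batch, noise, alpha).loss
        setattr(table, attr, orig - h)
        dn = batch_loss_and_gradients(table, batch, noise, alpha).loss
        setattr(table, attr, orig)
        worst = max(worst, abs((up - dn) / (2 * h) - g) / scale)
    return worst


def make_random_batch(l, rng, n=3):
    pos_sites = rng.integers(0, l, size=n)
    pos_syms = rng.integers(0, N_SYMBOLS, size=n)
    neg_sites = rng.integers(0, l, size=n)
    neg_syms = rng.integers(0, N_SYMBOLS, size=n)

    def pair(npair):
        i = rng.integers(0, l, size=npair)
        j = rng.integers(0, l - 1, size=npair)
        j = np.where(j >= i, j + 1, j)
        return i, j, rng.integers(0, N_SYMBOLS, size=npair), rng.integers(
            0, N_SYMBOLS, size=npair
        )

    return _Batch(pos_sites, pos_syms, neg_sites, neg_syms, pair(n), pair(n))


class TestGradients:
    @pytest.mark.parametrize("alpha", [0.0, 0.4, 1.0])
    def test_analytic_gradients_match_finite_differences(self, alpha, rng):
        for _ in range(5):
            l, d = int(rng.integers(2, 6)), int(rng.integers(1, 7))
            table = random_table(l, d, rng)
            noise = _uniform_noise(l)
            batch = make_random_batch(l, rng)
            assert _finite_difference_check(table, batch, noise, alpha) < 1e-5

    def test_positive_gradient_saturates_when_model_dominates(self):
        """When sigma(Delta+) -> 1 the positive-sample gradient vanishes."""
        l, d = 3, 2
        table = EmbeddingTable(
            site_vectors=np.ones((l, d)) * 10.0,
            symbol_vectors=np.ones((N_SYMBOLS, d)) * 10.0,
            C=100.0,
        )
        noise = _uniform_noise(l)
        batch = _Batch(
            pos_sites=np.array([0]),
            pos_syms=np.array([0]),
            neg_sites=np.array([0]),
            neg_syms=np.array([0]),
            pair_pos=(np.array([0]), np.array([1]), np.array([0]), np.array([0])),
            pair_neg=(np.array([0]), np.array([1]), np.array([0]), np.array([0])),
        )
        grads = batch_loss_and_gradients(table, batch, noise, alpha=1.0)
        # positive and noise events coincide; the noise coefficient sigma(Delta)
        # dominates, so the net gradient equals +sigma ~ 1 times the vectors
        assert np.isfinite(grads.loss)

    def test_single_positive_gradient_collinear_with_symbol_vector(self, rng):
        """For one positive single event, dL/dv_i is a multiple of c_i^a."""
        l, d = 4, 3
        table = random_table(l, d, rng)
        noise = _uniform_noise(l)
        batch = _Batch(
            pos_sites=np.array([2]),
            pos_syms=np.array([5]),
            neg_sites=np.array([0]),
            neg_syms=np.array([1]),
            pair_pos=(np.array([0]), np.array([1]), np.array([0]), np.array([0])),
            pair_neg=(np.array([0]), np.array([1]), np.array([0]), np.array([0])),
        )
        grads = batch_loss_and_gradients(table, batch, noise, alpha=1.0)
        g = grads.site_vectors[2]
        c = table.symbol_vectors[5]
        cross = np.linalg.norm(np.cross(g, c)) if d == 3 else None
        assert cross == pytest.approx(0.0, abs=1e-10)


@pytest.fixture(scope="module")
def trained():
    family, planted = generate_synthetic_family(
        SyntheticSpec(n_sequences=60, l=24, n_planted=4, effect=0.95, seed=21)
    )
    part = partition_by_threshold(family, 7.0)
    stats = compute_site_statistics(family, part)
    cfg = TrainingConfig(d=8, steps=1200, seed=3, augment_factor=2)
    high = [family[i] for i in sorted(part.S_h)]
    low = [family[i] for i in sorted(part.S_l)]
    table, hist = train(high, low, stats, cfg, return_history=True)
    return family, planted, stats, cfg, table, hist


class TestTraining:
    def test_training_is_deterministic(self, trained):
        family, planted, stats, cfg, table, _ = trained
        part = partition_by_threshold(family, 7.0)
        high = [family[i] for i in sorted(part.S_h)]
        low = [family[i] for i in sorted(part.S_l)]
        again = train(high, low, stats, cfg)
        assert np.array_equal(table.site_vectors, again.site_vectors)
        assert np.array_equal(table.symbol_vectors, again.symbol_vectors)
        assert table.C == again.C and table.C_pair == again.C_pair

    def test_loss_decreases(self, trained):
        *_, hist = trained
        w = 200
        assert hist[-w:].mean() < hist[:w].mean()

    def test_planted_sites_learn_alkali_preference(self, trained):
        family, planted, stats, cfg, table, _ = trained
        cap = capability_matrix(table)
        alk = [SYMBOL_INDEX[s] for s in "KR"]
        acid = [SYMBOL_INDEX[s] for s in "DE"]
        pl = [k - 1 for k in sorted(planted)]
        assert cap[pl][:, alk].mean() > cap[pl][:, acid].mean()

    def test_empty_class_rejected(self, trained):
        family, _, stats, cfg, *_ = trained
        with pytest.raises(ValueError):
            train([], [family.sequences[0]], stats, cfg)

    def test_table_round_trips_through_tsv(self, trained, tmp_path):
        *_, table, _ = trained
        path = tmp_path / "model.tsv"
        table.save(path)
        again = EmbeddingTable.load(path)
        assert np.array_equal(table.site_vectors, again.site_vectors)
        assert np.array_equal(table.symbol_vectors, again.symbol_vectors)
        assert table.C == again.C and table.C_pair == again.C_pair
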