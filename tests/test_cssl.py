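"""Contrastive loss, queue mechanics, momentum update and pretraining tests."""

import math

import numpy as np
import pytest

from subtomocl import cssl
from subtomocl.augment import AugmentPolicy
from subtomocl.encoder import EncoderConfig
from tests.conftest import unit_rows


def naive_queue_loss(q, k_pos, queue, tau):
    """Independent naive-loop oracle for the queue-based contrastive loss."""
    total = 0.0
    for j in range(q.shape[0]):
        num = math.exp(float(q[j] @ k_pos[j]) / tau)
        den = num + sum(math.exp(float(q[j] @ queue[i]) / tau)
                        for i in range(queue.shape[0]))
        total += -math.log(num / den)
    return total / q.shape[0]


class TestContrastiveLoss:
    def test_matches_naive_oracle_on_random_instances(self, rng):
        for _ in range(30):
            B = int(rng.integers(1, 9))
            L = int(rng.integers(4, 33))
            K = int(rng.integers(4, 65))
            tau = float(rng.uniform(0.05, 2.0))
            q, k = unit_rows(rng, B, L), unit_rows(rng, B, L)
            queue = unit_rows(rng, K, L)
            assert abs(
                cssl.contrastive_loss(q, k, queue, tau)
                - naive_queue_loss(q, k, queue, tau)
            ) < 1e-9

    def test_uniform_similarity_closed_form(self):
        """If q.k_pos == q.k_i for every queue entry, the softmax is uniform
        over 1+K logits and the loss is exactly ln(K+1), any temperature."""
        for K, tau in [(8, 0.2), (64, 0.07), (128, 1.7)]:
            q = np.tile(np.eye(1, 16), (4, 1))
            queue = np.tile(np.eye(1, 16), (K, 1))
            loss = cssl.contrastive_loss(q, q.copy(), queue, tau)
            assert abs(loss - math.log(K + 1)) < 1e-12

    def test_separated_pair_closed_form(self):
        """q.k_pos = 1 and q.k_i = -1 at tau=0.2 gives
        -log(e^5 / (e^5 + K e^-5))."""
        K, L = 16, 8
        q = np.tile(np.eye(1, L), (2, 1))
        queue = -np.tile(np.eye(1, L), (K, 1))
        expected = -math.log(math.exp(5) / (math.exp(5) + K * math.exp(-5)))
        assert abs(cssl.contrastive_loss(q, q.copy(), queue, 0.2) - expected) < 1e-12

    def test_gradient_matches_numeric(self, rng):
        q, k = unit_rows(rng, 3, 6), unit_rows(rng, 3, 6)
        queue = unit_rows(rng, 8, 6)
        _, dq = cssl.contrastive_loss_and_grad(q, k, queue, 0.2)
        eps = 1e-6
        for i in range(3):
            for l in range(6):
                qp, qm = q.copy(), q.copy()
                qp[i, l] += eps
                qm[i, l] -= eps
                lp, _ = cssl.contrastive_loss_and_grad(qp, k, queue, 0.2)
                lm, _ = cssl.contrastive_loss_and_grad(qm, k, queue, 0.2)
                assert abs((lp - lm) / (2 * eps) - dq[i, l]) < 1e-7

    def test_invalid_inputs_rejected(self, rng):
        q = unit_rows(rng, 2, 4)
        with pytest.raises(ValueError):
            cssl.contrastive_loss(q, q, unit_rows(rng, 4, 4), 0.0)
        bad = q.copy()
        bad[0, 0] = np.nan
        with pytest.raises(ValueError):
            cssl.contrastive_loss(bad, q, unit_rows(rng, 4, 4), 0.2)


class TestSimclrLoss:
    def test_matches_naive_oracle(self, rng):
        for B in (2, 3, 5):
            z = unit_rows(rng, 2 * B, 7)
            loss, _ = cssl.simclr_loss_and_grad(z, 0.3)
            naive = 0.0
            for i in range(2 * B):
                p = (i + B) % (2 * B)
                den = sum(
                    math.exp(float(z[i] @ z[j]) / 0.3)
                    for j in range(2 * B) if j != i
                )
                naive += -math.log(math.exp(float(z[i] @ z[p]) / 0.3) / den)
            assert abs(loss - naive / (2 * B)) < 1e-9

    def test_uniform_similarity_closed_form(self):
        """All views identical -> uniform softmax over 2B-1 logits."""
        B = 4
        z = np.tile(np.eye(1, 8), (2 * B, 1))
        loss, _ = cssl.simclr_loss_and_grad(z, 0.5)
        assert abs(loss - math.log(2 * B - 1)) < 1e-12

    def test_single_pair_has_two_negatives(self, rng):
        z = unit_rows(rng, 4, 5)  # B=2: anchors see 2 negatives + 1 positive
        loss, _ = cssl.simclr_loss_and_grad(z, 0.2)
        assert np.isfinite(loss) and loss > 0

    def test_batch_of_one_rejected(self, rng):
        with pytest.raises(ValueError):
            cssl.simclr_loss_and_grad(unit_rows(rng, 2, 5), 0.2)


class TestMomentumUpdate:
    def _params(self, rng, scale=1.0):
        return {
            "a": (rng.normal(size=(3, 4)) * scale),
            "b": (rng.normal(size=(5,)) * scale),
        }

    def test_m_one_freezes_keys(self, rng):
        tq, tk = self._params(rng), self._params(rng)
        ref = {k: v.copy() for k, v in tk.items()}
        cssl.momentum_update(tq, tk, 1.0)
        for k in tk:
            np.testing.assert_array_equal(tk[k], ref[k])

    def test_m_zero_copies_queries(self, rng):
        tq, tk = self._params(rng), self._params(rng)
        cssl.momentum_update(tq, tk, 0.0)
        for k in tk:
            np.testing.assert_array_equal(tk[k], tq[k])

    def test_geometric_decay_with_frozen_queries(self, rng):
        """With theta_q frozen, ||theta_k(t) - theta_q|| = m^t ||theta_k(0)
        - theta_q|| exactly."""
        tq, tk = self._params(rng), self._params(rng)
        m = 0.9
        d0 = math.sqrt(sum(((tk[k] - tq[k]) ** 2).sum() for k in tk))
        for t in range(1, 21):
            cssl.momentum_update(tq, tk, m)
            d = math.sqrt(sum(((tk[k] - tq[k]) ** 2).sum() for k in tk))
            assert abs(d - m**t * d0) < 1e-9 * d0

    def test_structure_mismatch_rejected(self, rng):
        tq = self._params(rng)
        with pytest.raises(ValueError):
            cssl.momentum_update(tq, {"a": tq["a"].copy()}, 0.5)


class TestQueue:
    def test_two_enqueues_cycle_small_queue(self, rng):
        queue = unit_rows(rng, 8, 3)
        b1, b2 = unit_rows(rng, 4, 3), unit_rows(rng, 4, 3)
        queue, ptr = cssl.enqueue_dequeue(queue, 0, b1)
        queue, ptr = cssl.enqueue_dequeue(queue, ptr, b2)
        assert ptr == 0
        np.testing.assert_array_equal(queue, np.concatenate([b1, b2]))

    def test_third_enqueue_overwrites_oldest(self, rng):
        batches = [np.full((4, 2), float(i)) for i in range(1, 4)]
        queue, ptr = np.zeros((8, 2)), 0
        for b in batches:
            queue, ptr = cssl.enqueue_dequeue(queue, ptr, b)
        # position order now holds batch 3 (overwrote batch 1) then batch 2
        np.testing.assert_array_equal(queue[:4], batches[2])
        np.testing.assert_array_equal(queue[4:], batches[1])
        assert ptr == 4

    def test_untouched_rows_bit_identical(self, rng):
        queue = unit_rows(rng, 16, 5)
        out, _ = cssl.enqueue_dequeue(queue, 4, unit_rows(rng, 4, 5))
        np.testing.assert_array_equal(out[:4], queue[:4])
        np.testing.assert_array_equal(out[8:], queue[8:])

    def test_oversized_batch_rejected(self, rng):
        with pytest.raises(ValueError):
            cssl.enqueue_dequeue(unit_rows(rng, 4, 3), 0, unit_rows(rng, 8, 3))


class TestPretrainConfig:
    def test_queue_divisibility_enforced(self):
        with pytest.raises(ValueError):
            cssl.PretrainConfig(queue_size=100, batch_size=16)
        assert cssl.PretrainConfig(queue_size=128, batch_size=16).queue_size == 128
        assert cssl.PretrainConfig(queue_size=64, batch_size=16).queue_size == 64

    def test_defaults_are_operative_settings(self):
        hp = cssl.PretrainConfig()
        assert (hp.queue_size, hp.momentum, hp.temperature) == (128, 0.999, 0.2)
        assert (hp.lr, hp.weight_decay, hp.batch_size, hp.epochs) == (
            1e-4, 1e-4, 16, 200,
        )


@pytest.fixture(scope="module")
def small_train(tiny_dataset):
    vols, _, train, _, _ = tiny_dataset
    return cssl.UnlabelledVolumes(vols[train][:32])


class TestPretrainLoops:
    def test_unlabelled_view_exposes_no_labels(self, small_train):
        assert not hasattr(small_train, "labels")
        assert not hasattr(small_train, "class_id")

    def test_moco_seeded_reproducibility_and_queue_hygiene(self, small_train):
        cfg = EncoderConfig.tiny(n_classes=3)
        hp = cssl.PretrainConfig(queue_size=32, batch_size=8, epochs=2)
        pol = AugmentPolicy()
        w1, log1 = cssl.pretrain_moco(small_train, pol, cfg, hp, seed=3)
        w2, log2 = cssl.pretrain_moco(small_train, pol, cfg, hp, seed=3)
        assert log1.equals(log2)
        for k in w1.params:
            np.testing.assert_array_equal(w1.params[k], w2.params[k])
        assert w1.provenance == "cssl_pretrained"
        assert np.isfinite(log1["mean_loss"]).all()

    def test_moco_first_epoch_near_uniform_loss(self, small_train):
        """Keys from an untrained encoder are nearly interchangeable, so the
        first epoch's loss sits near ln(K+1)."""
        cfg = EncoderConfig.tiny(n_classes=3)
        hp = cssl.PretrainConfig(queue_size=32, batch_size=8, epochs=1)
        _, log = cssl.pretrain_moco(small_train, AugmentPolicy(), cfg, hp, seed=1)
        assert abs(log["mean_loss"].iloc[0] - math.log(33)) < 0.5

    def test_momentum_running_average_conservation(self, small_train):
        """theta_k after training equals an explicit recomputation of the
        exponential running average of the theta_q trajectory."""
        from subtomocl._nn import Adam
        from subtomocl.encoder import Encoder

        cfg = EncoderConfig.tiny(n_classes=3)
        enc_q = Encoder(cfg, seed=0)
        enc_k = Encoder(cfg, seed=1)
        name = "stem.W"
        m = 0.9
        expected = enc_k.parameters()[name].copy()
        rng = np.random.default_rng(0)
        for _ in range(5):
            # arbitrary gradient step on theta_q, then the momentum copy
            for p in enc_q.parameters().values():
                p += rng.normal(scale=1e-3, size=p.shape).astype(p.dtype)
            cssl.momentum_update(enc_q.parameters(), enc_k.parameters(), m)
            expected = m * expected + (1 - m) * enc_q.parameters()[name]
        np.testing.assert_allclose(
            enc_k.parameters()[name], expected, rtol=0, atol=1e-6
        )

    def test_simclr_seeded_reproducibility(self, small_train):
        cfg = EncoderConfig.tiny(n_classes=3)
        hp = cssl.PretrainConfig(queue_size=32, batch_size=8, epochs=2)
        w1, log1 = cssl.pretrain_simclr(small_train, AugmentPolicy(), cfg, hp, seed=5)
        w2, log2 = cssl.pretrain_simclr(small_train, AugmentPolicy(), cfg, hp, seed=5)
        assert log1.equals(log2)
        for k in w1.params:
            np.testing.assert_array_equal(w1.params[k], w2.params[k])

    def test_queue_smaller_than_batch_rejected(self, small_train):
        with pytest.raises(ValueError):
            cssl.PretrainConfig(queue_size=8, batch_size=16)
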