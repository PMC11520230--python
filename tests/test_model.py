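"""Core contrastive-model tests: loss correctness against a scalar reference
implementation, analytic gradients against finite differences, and the
training-loop contracts."""

import math

import numpy as np
import pytest

from dice.data_io import ModalityMatrix, PairedDataset
from dice.model import (
    DiceModel,
    ProjectionHead,
    TrainConfig,
    _loss_and_sim_grads,
    contrastive_loss,
    cosine_sim,
    embed,
    fuse,
    project,
    train,
)
from dice.synthetic import SyntheticConfig, generate


def loss_reference(Zv, Zx, tau, variant="dice"):
    """Independent scalar double-loop evaluation of the contrastive loss."""
    B = len(Zv)

    def cs(a, b):
        return float(np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b)))

    total = 0.0
    for i in range(B):
        den_v = sum(math.exp(tau * cs(Zv[i], Zx[j])) for j in range(B))
        den_x = sum(math.exp(tau * cs(Zx[i], Zv[j])) for j in range(B))
        if variant == "dice":
            den_v += sum(math.exp(tau * cs(Zv[i], Zv[j])) for j in range(B) if j != i)
            den_x += sum(math.exp(tau * cs(Zx[i], Zx[j])) for j in range(B) if j != i)
        total -= math.log(math.exp(tau * cs(Zv[i], Zx[i])) / den_v)
        total -= math.log(math.exp(tau * cs(Zx[i], Zv[i])) / den_x)
    return total


class TestCosine:
    @pytest.mark.parametrize("a,b,expected", [
        ((1, 0), (1, 0), 1.0),
        ((1, 0), (0, 1), 0.0),
        ((1, 2), (2, 1), 0.8),
    ])
    def test_values(self, a, b, expected):
        assert cosine_sim(np.array(a, float), np.array(b, float)) == pytest.approx(expected)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine_sim(np.zeros(3), np.ones(3))


class TestProject:
    def test_relu_zeroes_negatives(self):
        head = ProjectionHead(np.eye(2), np.eye(2))
        np.testing.assert_array_equal(project(head, np.array([[1.0, -2.0]])), [[1.0, 0.0]])

    def test_zero_weights_give_zero(self):
        head = ProjectionHead(np.zeros((3, 2)), np.zeros((2, 3)))
        assert np.all(project(head, np.ones((4, 2))) == 0)

    def test_matches_scalar_oracle(self, rng):
        W1 = rng.normal(size=(4, 3))
        W2 = rng.normal(size=(2, 4))
        head = ProjectionHead(W1, W2)
        rows = rng.normal(size=(6, 3))
        got = project(head, rows)
        for r in range(6):
            hidden = [max(0.0, sum(W1[h, c] * rows[r, c] for c in range(3))) for h in range(4)]
            out = [sum(W2[o, h] * hidden[h] for h in range(4)) for o in range(2)]
            np.testing.assert_allclose(got[r], out, atol=1e-10)

    def test_shape_mismatch(self):
        head = ProjectionHead(np.eye(2), np.eye(2))
        with pytest.raises(ValueError):
            project(head, np.ones((1, 3)))


class TestContrastiveLoss:
    @pytest.mark.parametrize("B", [1, 2, 4, 128])
    def test_closed_form_at_tau_zero(self, B, rng):
        Zv = rng.normal(size=(B, 6))
        Zx = rng.normal(size=(B, 6))
        expected = 2 * B * math.log(2 * B - 1) if B > 1 else 0.0
        assert contrastive_loss(Zv, Zx, 0.0) == pytest.approx(expected, abs=1e-9)

    def test_single_pair_is_zero(self, rng):
        assert contrastive_loss(rng.normal(size=(1, 4)), rng.normal(size=(1, 4)), 3.0) == pytest.approx(0.0)

    @pytest.mark.parametrize("B", [2, 4, 8, 16])
    @pytest.mark.parametrize("tau", [0.5, 1.0, 14.3])
    @pytest.mark.parametrize("variant", ["dice", "clip"])
    def test_matches_double_loop_reference(self, B, tau, variant, rng):
        Zv = rng.normal(size=(B, 5))
        Zx = rng.normal(size=(B, 5))
        got = contrastive_loss(Zv, Zx, tau, variant=variant)
        want = loss_reference(Zv, Zx, tau, variant=variant)
        assert abs(got - want) / abs(want) < 1e-6

    def test_worked_example_b2(self):
        Zv = np.array([[1.0, 0.0], [0.0, 1.0]])
        Zx = np.array([[1.0, 0.0], [0.0, 1.0]])
        got = contrastive_loss(Zv, Zx, 1.0)
        want = loss_reference(Zv, Zx, 1.0)
        assert got == pytest.approx(want, abs=1e-9)

    def test_anchor_permutation_invariance(self, rng):
        Zv = rng.normal(size=(8, 4))
        Zx = rng.normal(size=(8, 4))
        perm = rng.permutation(8)
        a = contrastive_loss(Zv, Zx, 2.0)
        b = contrastive_loss(Zv[perm], Zx[perm], 2.0)
        assert a == pytest.approx(b, rel=1e-12)

    def test_row_rescaling_invariance(self, rng):
        Zv = rng.normal(size=(5, 4))
        Zx = rng.normal(size=(5, 4))
        scales = rng.uniform(0.1, 50, size=5)
        a = contrastive_loss(Zv, Zx, 3.0)
        b = contrastive_loss(Zv * scales[:, None], Zx, 3.0)
        assert a == pytest.approx(b, rel=1e-10)

    def test_monotone_in_tau_when_aligned(self):
        Z = np.eye(4)  # mutually orthogonal, perfectly aligned across modalities
        losses = [contrastive_loss(Z, Z, t) for t in (0.0, 1.0, 5.0, 10.0)]
        assert all(a > b for a, b in zip(losses, losses[1:]))

    def test_negative_tau_rejected(self, rng):
        with pytest.raises(ValueError):
            contrastive_loss(rng.normal(size=(2, 3)), rng.normal(size=(2, 3)), -1.0)

    def test_zero_rows_are_nudged_not_nan(self, rng, caplog):
        Zv = np.vstack([np.zeros(3), rng.normal(size=3)])
        Zx = rng.normal(size=(2, 3))
        with caplog.at_level("WARNING"):
            val = contrastive_loss(Zv, Zx, 1.0)
        assert math.isfinite(val)
        assert "zero-norm" in caplog.text


class TestGradients:
    @pytest.mark.parametrize("variant", ["dice", "clip"])
    def test_analytic_matches_finite_differences(self, variant, rng):
        B, l, tau = 5, 4, 2.0
        Zv = rng.normal(size=(B, l))
        Zx = rng.normal(size=(B, l))
        _, dv, dx, dtau = _loss_and_sim_grads(Zv, Zx, tau, variant)
        eps = 1e-6

        def num_grad(Z, other, is_v):
            g = np.zeros_like(Z)
            for i in range(B):
                for j in range(l):
                    zp, zm = Z.copy(), Z.copy()
                    zp[i, j] += eps
                    zm[i, j] -= eps
                    if is_v:
                        g[i, j] = (contrastive_loss(zp, other, tau, variant=variant)
                                   - contrastive_loss(zm, other, tau, variant=variant)) / (2 * eps)
                    else:
                        g[i, j] = (contrastive_loss(other, zp, tau, variant=variant)
                                   - contrastive_loss(other, zm, tau, variant=variant)) / (2 * eps)
            return g

        np.testing.assert_allclose(dv, num_grad(Zv, Zx, True), atol=1e-7)
        np.testing.assert_allclose(dx, num_grad(Zx, Zv, False), atol=1e-7)
        num_dtau = (contrastive_loss(Zv, Zx, tau + eps, variant=variant)
                    - contrastive_loss(Zv, Zx, tau - eps, variant=variant)) / (2 * eps)
        assert dtau == pytest.approx(num_dtau, abs=1e-7)


class TestFuse:
    def test_definition_and_symmetry(self):
        np.testing.assert_array_equal(
            fuse(np.array([[1.0, 2.0]]), np.array([[3.0, 4.0]])), [[1, 2, 3, 4]])
        Z = np.random.default_rng(0).normal(size=(3, 2))
        fused = fuse(Z, Z)
        np.testing.assert_array_equal(fused[:, :2], fused[:, 2:])

    def test_slice_back_identity(self, rng):
        Zv = rng.normal(size=(7, 5))
        Zx = rng.normal(size=(7, 5))
        fused = fuse(Zv, Zx)
        np.testing.assert_array_equal(fused[:, :5], Zv)
        np.testing.assert_array_equal(fused[:, 5:], Zx)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            fuse(np.ones((2, 3)), np.ones((2, 4)))


def _quick_cfg(**kw):
    base = dict(batch_size=32, epochs=20, hidden_dim=32, latent_dim=16,
                learning_rate=1e-4, seed=3)
    base.update(kw)
    return TrainConfig(**base)


class TestTrain:
    def test_loss_decreases_on_aligned_data(self):
        res = generate(SyntheticConfig(n=300, n_clusters=8, latent_dim=8,
                                       dim_v=16, dim_x=16, noise_sd=0.1, seed=2))
        _, trace = train(res.dataset, _quick_cfg(epochs=40))
        assert trace[-1] < trace[0]

    def test_same_seed_reproduces_trace_bitwise(self, small_result):
        _, t1 = train(small_result.dataset, _quick_cfg(epochs=5))
        _, t2 = train(small_result.dataset, _quick_cfg(epochs=5))
        assert t1 == t2

    def test_zero_epochs_returns_initialization(self, small_result):
        m0, trace = train(small_result.dataset, _quick_cfg(epochs=0))
        assert trace == []
        m0b, _ = train(small_result.dataset, _quick_cfg(epochs=0))
        np.testing.assert_array_equal(m0.head_v.W1, m0b.head_v.W1)
        m1, _ = train(small_result.dataset, _quick_cfg(epochs=2))
        assert not np.array_equal(m0.head_v.W1, m1.head_v.W1)

    def test_batch_of_one_rejected_by_config(self):
        with pytest.raises(ValueError):
            TrainConfig(batch_size=1)

    def test_embed_fuses_in_declared_order(self, small_result):
        model, _ = train(small_result.dataset, _quick_cfg(epochs=1))
        emb = embed(model, small_result.dataset)
        np.testing.assert_array_equal(emb.Z[:, :16], emb.Zv)
        np.testing.assert_array_equal(emb.Z[:, 16:], emb.Zx)
        assert emb.ids == small_result.dataset.ids

    def test_standardization_makes_training_scale_invariant(self, small_result):
        ds = small_result.dataset
        scaled = PairedDataset(
            ds.ids,
            ModalityMatrix(ds.ids, ds.modality_v.values * 100.0, "v"),
            ds.modality_x,
        )
        _, t1 = train(ds, _quick_cfg(epochs=3))
        _, t2 = train(scaled, _quick_cfg(epochs=3))
        np.testing.assert_allclose(t1, t2, rtol=1e-9)

    def test_model_invariants(self):
        with pytest.raises(ValueError):
            DiceModel(ProjectionHead(np.eye(2), np.eye(2)),
                      ProjectionHead(np.eye(3), np.eye(3)), 0.0)
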