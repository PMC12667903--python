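"""Encoder invariances, contrastive-loss closed forms, and the retrieval metric."""

import dataclasses

import numpy as np
import pytest

from cpsearch import encoder, structio
from cpsearch.graphs import build_graph
from cpsearch.encoder import (
    ModelConfig,
    encode,
    encode_batch,
    fresh_model,
    node_embeddings,
    retrieval_sensitivity,
    supcon_loss,
)

from conftest import random_trace


def _cos(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))


@pytest.fixture(scope="module")
def model():
    return fresh_model(ModelConfig(n_layers=2, hidden_dim=32, embed_dim=16, seed=3))


@pytest.fixture(scope="module")
def trace():
    return random_trace(np.random.default_rng(0), 40)


class TestEncodeInvariance:
    def test_rigid_motion_leaves_embedding_unchanged(self, model, trace):
        """E(3) invariance holds for any weights — it is architectural."""
        rng = np.random.default_rng(1)
        e0 = encode(build_graph(trace), model).values
        for _ in range(10):
            R = structio._random_rotation(rng)
            moved = dataclasses.replace(trace, coords=trace.coords @ R.T + rng.uniform(-30, 30, 3))
            e1 = encode(build_graph(moved), model).values
            assert _cos(e0, e1) >= 0.999

    def test_node_storage_order_is_immaterial(self, model, trace):
        g = build_graph(trace)
        e0 = encode(g, model).values
        rng = np.random.default_rng(2)
        shuffled = dataclasses.replace(g, edges=g.edges[rng.permutation(len(g.edges))])
        e1 = encode(shuffled, model).values
        np.testing.assert_allclose(e0, e1, atol=1e-5)

    def test_identical_template_members_embed_identically(self, model):
        fam = structio.make_synthetic_family(2, 40, 0.0, seed=9)
        e = encode_batch([build_graph(t) for t in fam], model)
        assert _cos(e[0], e[1]) >= 0.999

    def test_feature_width_mismatch_rejected(self, model, trace):
        g = build_graph(trace)
        bad = dataclasses.replace(g, features=g.features[:, :50])
        with pytest.raises(ValueError, match="feature width"):
            encode(bad, model)


class TestNodeEmbeddings:
    def test_pooling_consistency_with_encode(self, model, trace):
        """projection(mean of node rows) must equal the pooled embedding."""
        g = build_graph(trace)
        h = node_embeddings(g, model)
        net = model.network
        proj = h.mean(axis=0) @ net.project.W.data + net.project.b.data
        np.testing.assert_allclose(proj, encode(g, model).values, atol=1e-5)

    def test_rows_are_rigid_motion_invariant(self, model, trace):
        rng = np.random.default_rng(3)
        R = structio._random_rotation(rng)
        moved = dataclasses.replace(trace, coords=trace.coords @ R.T - 11.0)
        h0 = node_embeddings(build_graph(trace), model)
        h1 = node_embeddings(build_graph(moved), model)
        np.testing.assert_allclose(h0, h1, atol=1e-4)


class TestSupConLoss:
    def test_uniform_batch_closed_form_log3(self):
        """Four identical embeddings in two classes of two: softmax is uniform
        over the 3 non-anchors, so -log(1/3) per anchor."""
        z = np.ones((4, 8))
        loss = supcon_loss(z, ["a", "a", "b", "b"], temperature=0.1)
        assert loss == pytest.approx(np.log(3.0), abs=1e-9)

    def test_separated_classes_drive_loss_to_zero(self):
        z = np.zeros((4, 8))
        z[0, 0] = z[1, 0] = 1.0
        z[2, 1] = z[3, 1] = 1.0
        assert supcon_loss(z, ["a", "a", "b", "b"], temperature=0.05) < 1e-5

    def test_label_renaming_symmetry(self):
        rng = np.random.default_rng(4)
        z = rng.normal(size=(6, 8))
        labels = ["u", "u", "v", "v", "w", "w"]
        renamed = ["w", "w", "u", "u", "v", "v"]
        assert supcon_loss(z, labels) == pytest.approx(supcon_loss(z, renamed), abs=1e-12)

    def test_numeric_gradient_agreement(self):
        rng = np.random.default_rng(5)
        z = rng.normal(size=(6, 5))
        labels = ["a", "a", "b", "b", "c", "c"]
        from cpsearch import nn

        t = nn.Tensor(z.copy())
        supcon_loss(t, labels).backward()
        eps = 1e-6
        num = np.zeros_like(z)
        for i in range(6):
            for j in range(5):
                zp, zm = z.copy(), z.copy()
                zp[i, j] += eps
                zm[i, j] -= eps
                num[i, j] = (supcon_loss(zp, labels) - supcon_loss(zm, labels)) / (2 * eps)
        np.testing.assert_allclose(t.grad, num, atol=1e-4)

    def test_all_unique_labels_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            supcon_loss(np.eye(3), ["a", "b", "c"])

    def test_anchors_without_positives_are_excluded(self):
        """A singleton class changes nothing for the other anchors' average."""
        rng = np.random.default_rng(6)
        z = rng.normal(size=(4, 6))
        with_single = supcon_loss(z, ["a", "a", "a", "z"])
        assert np.isfinite(with_single) and with_single > 0


class TestRetrievalSensitivity:
    def test_hand_counted_ranking(self):
        # [TP, TP, FP, TP] with 3 family-level TPs -> 2/3
        ranked = ["a.1.1.1", "a.1.1.1", "b.9.9.9", "a.1.1.1"]
        assert retrieval_sensitivity("a.1.1.1", ranked, "family") == pytest.approx(2 / 3)

    def test_perfect_and_worst_case(self):
        assert retrieval_sensitivity("a.1.1.1", ["a.1.1.1", "b.2.2.2"], "family") == 1.0
        assert retrieval_sensitivity("a.1.1.1", ["b.2.2.2", "a.1.1.1"], "family") == 0.0

    def test_level_specific_tp_definitions(self):
        # superfamily TP: same superfamily, different family; fold TP: same fold, different sf
        ranked = ["a.1.1.2", "a.1.2.1", "b.5.5.5", "a.1.1.1"]
        assert retrieval_sensitivity("a.1.1.1", ranked, "superfamily") == 1.0
        assert retrieval_sensitivity("a.1.1.1", ranked, "fold") == 1.0
        assert retrieval_sensitivity("a.1.1.1", ranked, "family") == pytest.approx(0.0)

    def test_undefined_when_no_true_positives(self):
        assert retrieval_sensitivity("a.1.1.1", ["b.2.2.2", "c.3.3.3"], "family") is None


class TestTrainingSmoke:
    """Small-scale training behavior; the full study runs in the acceptance suite."""

    def test_loss_decreases_and_is_deterministic(self):
        from conftest import make_labeled_set

        traces = make_labeled_set(6, 4, 30, 0.3, seed=50)
        config = ModelConfig(
            n_layers=2, hidden_dim=32, embed_dim=16, epochs=8,
            batch_families=4, members_per_family=2, seed=11,
        )
        m1 = encoder.train(traces, config)
        losses = [e["loss"] for e in m1.training_log]
        assert losses[-1] < losses[0]
        m2 = encoder.train(traces, dataclasses.replace(config))
        np.testing.assert_array_equal(m1.state_arrays()[0], m2.state_arrays()[0])

    def test_degenerate_label_structure_rejected(self):
        fam = structio.make_synthetic_family(4, 30, 0.2, seed=51)
        with pytest.raises(ValueError, match="famil"):
            encoder.train(fam, ModelConfig(n_layers=1, hidden_dim=16, embed_dim=8, epochs=1))


class TestCheckpointRoundtrip:
    def test_save_load_preserves_embeddings(self, tmp_path, model, trace):
        g = build_graph(trace)
        e0 = encode(g, model).values
        encoder.save_model(model, tmp_path / "ckpt")
        loaded = encoder.load_model(tmp_path / "ckpt")
        np.testing.assert_allclose(encode(g, loaded).values, e0, atol=1e-6)
        assert loaded.config == model.config
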