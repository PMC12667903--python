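"""E(3)-invariant graph encoder with synCP-augmented contrastive training.

The encoder is a message-passing network over the 10 Å contact graph.  Every
message is a function of the two incident node feature vectors and the
*squared distance* between them — never of raw coordinates — so the pooled
structure embedding is exactly invariant to rotations and translations, and
to the storage order of nodes.  Invariance to *circular permutation*, by
contrast, is not architectural: the τ and positional-encoding features move
when the chain is re-cut.  It has to be learned, and the training loop here
learns it by replacing each sampled structure with a random synCP of itself
in every iteration while a supervised contrastive loss pulls members of the
same family together.

Training a second model with the augmentation switched off yields the
CP-*sensitive* baseline that the discovery pipeline contrasts against.
"""

from __future__ import annotations


import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from . import nn
from .graphs import FEATURE_DIM, ProteinGraph, build_graph
from .structio import CaTrace, syncp

__all__ = [
    "ModelConfig",
    "EmbeddingVector",
    "TrainedModel",
    "encode",
    "encode_batch",
    "node_embeddings",
    "supcon_loss",
    "train",
    "retrieval_sensitivity",
    "save_model",
    "load_model",
]


@dataclass
class ModelConfig:
    """Hyperparameters of the encoder and its contrastive training run."""

    n_layers: int = 6
    hidden_dim: int = 128
    embed_dim: int = 128
    edge_dim: int | None = None  # message width; defaults to hidden_dim // 2
    temperature: float = 0.1
    lr: float = 1e-3
    batch_families: int = 8
    members_per_family: int = 4
    epochs: int = 100
    seed: int = 0
    syncp_augment: bool = True
    val_every: int = 5

    def __post_init__(self) -> None:
        if min(self.n_layers, self.hidden_dim, self.embed_dim,
               self.batch_families, self.members_per_family, self.epochs) < 1:
            raise ValueError("all size parameters must be positive")
        if self.temperature <= 0 or self.lr <= 0:
            raise ValueError("temperature and lr must be positive")
        if self.edge_dim is None:
            self.edge_dim = max(16, self.hidden_dim // 2)


@dataclass(frozen=True)
class EmbeddingVector:
    values: np.ndarray
    structure_id: str


class _EdgeBlock:
    """One round of distance-aware message passing.

    Messages m_ij = φ([h_i, h_j, d²_ij]) are mean-aggregated per receiving
    node.  The first affine layer is evaluated on nodes and gathered to edges
    (the affine map distributes over the concat), and the second affine layer
    is applied after the mean (affine maps commute with means) — both exact
    algebraic rewrites that keep all heavy matmuls at node count, not edge
    count.
    """

    def __init__(self, hidden: int, edge_dim: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (2 * hidden + 1))
        self.W_src = nn.Tensor(rng.normal(scale=scale, size=(hidden, edge_dim)))
        self.W_dst = nn.Tensor(rng.normal(scale=scale, size=(hidden, edge_dim)))
        self.w_d2 = nn.Tensor(rng.normal(scale=scale, size=(1, edge_dim)))
        self.b1 = nn.Tensor(np.zeros(edge_dim))
        self.out = nn.Linear(edge_dim, hidden, rng)

    def __call__(
        self,
        h: nn.Tensor,
        src: np.ndarray,
        dst: np.ndarray,
        d2: nn.Tensor,
        inv_deg: nn.Tensor,
        n_total: int,
    ) -> nn.Tensor:
        pre = (
            (h @ self.W_src).gather_rows(src)
            + (h @ self.W_dst).gather_rows(dst)
            + d2 @ self.w_d2
            + self.b1
        )
        mean_msg = pre.silu().segment_sum(dst, n_total) * inv_deg
        return self.out(mean_msg)

    def parameters(self) -> list[nn.Tensor]:
        return [self.W_src, self.W_dst, self.w_d2, self.b1] + self.out.parameters()


class _GraphNetwork:
    """Message-passing layers (features + squared edge distances only)."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        h = config.hidden_dim
        self.embed_in = nn.Linear(FEATURE_DIM, h, rng)
        self.edge_blocks = [_EdgeBlock(h, config.edge_dim, rng) for _ in range(config.n_layers)]
        self.node_mlps = [nn.MLP(2 * h, h, h, rng) for _ in range(config.n_layers)]
        self.project = nn.Linear(h, config.embed_dim, rng)
        for p in self.parameters():  # float32: training is memory-bound on CPU
            p.data = p.data.astype(np.float32)

    def parameters(self) -> list[nn.Tensor]:
        params = self.embed_in.parameters() + self.project.parameters()
        for m in self.edge_blocks + self.node_mlps:
            params += m.parameters()
        return params

    def forward(self, graphs: Sequence[ProteinGraph]) -> tuple[nn.Tensor, nn.Tensor, np.ndarray]:
        """Batched forward over a disjoint union of graphs.

        Returns (per-node features, per-graph embeddings, node→graph ids).
        """
        feats, src_all, dst_all, d2_all, gids = [], [], [], [], []
        offset = 0
        for gi, g in enumerate(graphs):
            feats.append(g.features)
            if len(g.edges):
                i, j = g.edges[:, 0], g.edges[:, 1]
                src = np.concatenate([i, j]) + offset
                dst = np.concatenate([j, i]) + offset
                d2 = np.sum((g.coords[i] - g.coords[j]) ** 2, axis=1)
                src_all.append(src)
                dst_all.append(dst)
                d2_all.append(np.concatenate([d2, d2]))
            gids.append(np.full(g.n_nodes, gi))
            offset += g.n_nodes
        n_total = offset
        x = nn.Tensor(np.vstack(feats).astype(np.float32))
        gids = np.concatenate(gids)
        if src_all:
            src = np.concatenate(src_all)
            dst = np.concatenate(dst_all)
            # d² / 100 keeps edge inputs on the same O(1) scale as features
            d2 = nn.Tensor((np.concatenate(d2_all)[:, None] / 100.0).astype(np.float32))
        else:
            src = dst = np.zeros(0, dtype=int)
            d2 = nn.Tensor(np.zeros((0, 1), dtype=np.float32))
        deg = np.maximum(np.bincount(dst, minlength=n_total), 1)
        inv_deg = nn.Tensor((1.0 / deg[:, None]).astype(np.float32))

        h = self.embed_in(x)
        for edge_block, node_mlp in zip(self.edge_blocks, self.node_mlps):
            if len(src):
                agg = edge_block(h, src, dst, d2, inv_deg, n_total)
            else:
                agg = nn.Tensor(np.zeros(h.shape, dtype=np.float32))
            h = h + node_mlp(nn.concat([h, agg]))
        counts = np.bincount(gids, minlength=len(graphs)).astype(float)
        pooled = h.segment_sum(gids, len(graphs)) * nn.Tensor(1.0 / counts[:, None])
        return h, self.project(pooled), gids


@dataclass
class TrainedModel:
    """Encoder weights plus the config and per-epoch training log."""

    network: _GraphNetwork
    config: ModelConfig
    training_log: list[dict] = field(default_factory=list)

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.network.parameters()]


def fresh_model(config: ModelConfig) -> TrainedModel:
    """Randomly initialized (untrained) model — used for architectural checks."""
    rng = np.random.default_rng(config.seed)
    return TrainedModel(network=_GraphNetwork(config, rng), config=config)


# ---------------------------------------------------------------------------
# encoding


def encode_batch(graphs: Sequence[ProteinGraph], model: TrainedModel) -> np.ndarray:
    """(len(graphs), embed_dim) matrix of structure embeddings."""
    if not graphs:
        return np.zeros((0, model.config.embed_dim))
    for g in graphs:
        if g.features.shape[1] != FEATURE_DIM:
            raise ValueError(
                f"graph '{g.id}' has feature width {g.features.shape[1]}; expected {FEATURE_DIM}"
            )
    _, emb, _ = model.network.forward(graphs)
    return emb.data.copy()


def encode(graph: ProteinGraph, model: TrainedModel) -> EmbeddingVector:
    """Embed one structure; invariant to rigid motion and node storage order."""
    return EmbeddingVector(values=encode_batch([graph], model)[0], structure_id=graph.id)


def node_embeddings(graph: ProteinGraph, model: TrainedModel) -> np.ndarray:
    """Final-layer per-node features (n, hidden_dim) before pooling.

    The mean of these rows, passed through the model's linear projection,
    equals the pooled structure embedding.
    """
    h, _, _ = model.network.forward([graph])
    return h.data.copy()


# ---------------------------------------------------------------------------
# supervised contrastive loss


def supcon_loss(
    embeddings: "nn.Tensor | np.ndarray",
    labels: Sequence[str],
    temperature: float = 0.1,
) -> "nn.Tensor | float":
    """Supervised contrastive loss over L2-normalized embeddings.

    L = mean over anchors i with positives of
        -(1/|P(i)|) Σ_{p∈P(i)} log[ exp(z_i·z_p/τ) / Σ_{a≠i} exp(z_i·z_a/τ) ].

    Accepts a raw array (returns a float) or a Tensor (returns a Tensor for
    backprop).  Anchors whose label has no second member are excluded from
    the average; if no anchor has a positive the batch is degenerate.
    """
    is_tensor = isinstance(embeddings, nn.Tensor)
    z = embeddings if is_tensor else nn.Tensor(np.asarray(embeddings, dtype=float))
    b = z.shape[0]
    if b < 2:
        raise ValueError("supcon_loss needs a batch of at least 2")
    labels = np.asarray(labels)
    pos_mask = (labels[:, None] == labels[None, :]) & ~np.eye(b, dtype=bool)
    n_pos = pos_mask.sum(axis=1)
    if not np.any(n_pos):
        raise ValueError("no anchor has a positive (all labels unique)")

    z = z.normalize_rows()
    sim = (z @ z.T) * (1.0 / temperature)
    off_diag = 1.0 - np.eye(b)
    row_max = np.where(off_diag > 0, sim.data, -np.inf).max(axis=1, keepdims=True)
    shifted = sim - nn.Tensor(row_max)  # detached shift: softmax-invariant
    denom = (shifted.exp() * nn.Tensor(off_diag)).sum(axis=1, keepdims=True)
    log_prob = shifted - denom.log()
    valid = n_pos > 0
    weights = np.where(valid, 1.0 / np.maximum(n_pos, 1), 0.0) / valid.sum()
    loss = -(nn.Tensor(pos_mask * weights[:, None]) * log_prob).sum()
    return loss if is_tensor else float(loss.data)


# ---------------------------------------------------------------------------
# retrieval metric


_LEVEL_DEPTH = {"fold": 2, "superfamily": 3, "family": 4}


def _prefix(label: str, depth: int) -> str:
    return ".".join(label.split(".")[:depth])


def retrieval_sensitivity(
    query_label: str,
    ranked_target_labels: Sequence[str],
    level: str,
) -> float | None:
    """Fraction of a query's true positives ranked above its first false positive.

    True positives at ``family`` share the family; at ``superfamily`` share the
    superfamily but not the family; at ``fold`` share the fold but not the
    superfamily.  False positives are different-fold hits; same-fold hits that
    are neither TP nor FP are ignored.  Returns None when the level has no
    true positives (undefined, not zero).
    """
    if level not in _LEVEL_DEPTH:
        raise ValueError(f"unknown level {level!r}")
    q_fam = _prefix(query_label, 4)
    q_sf = _prefix(query_label, 3)
    q_fold = _prefix(query_label, 2)
    n_tp = 0
    tp_above = 0
    seen_fp = False
    for label in ranked_target_labels:
        fam, sf, fold = _prefix(label, 4), _prefix(label, 3), _prefix(label, 2)
        if level == "family":
            is_tp = fam == q_fam
        elif level == "superfamily":
            is_tp = sf == q_sf and fam != q_fam
        else:
            is_tp = fold == q_fold and sf != q_sf
        is_fp = fold != q_fold
        if is_tp:
            n_tp += 1
            if not seen_fp:
                tp_above += 1
        elif is_fp:
            seen_fp = True
    if n_tp == 0:
        return None
    return tp_above / n_tp


def _mean_level_sensitivity(
    emb: np.ndarray, labels: list[str], levels: tuple[str, ...] = ("family", "superfamily", "fold")
) -> float:
    """All-vs-all cosine retrieval; mean over queries of mean defined-level sensitivity."""
    z = emb / np.linalg.norm(emb, axis=1, keepdims=True)
    sim = z @ z.T
    per_level: dict[str, list[float]] = {lv: [] for lv in levels}
    for qi in range(len(labels)):
        order = np.argsort(-np.delete(sim[qi], qi), kind="stable")
        ranked = [labels[j] for j in np.delete(np.arange(len(labels)), qi)[order]]
        for lv in levels:
            s = retrieval_sensitivity(labels[qi], ranked, lv)
            if s is not None:
                per_level[lv].append(s)
    level_means = [np.mean(v) for v in per_level.values() if v]
    return float(np.mean(level_means)) if level_means else float("nan")


# ---------------------------------------------------------------------------
# training


def _group_by_family(traces: Sequence[CaTrace]) -> dict[str, list[CaTrace]]:
    groups: dict[str, list[CaTrace]] = {}
    for t in traces:
        if t.labels is None:
            raise ValueError(f"trace '{t.id}' has no family label")
        groups.setdefault(t.labels, []).append(t)
    return groups


def train(
    traces: Sequence[CaTrace],
    config: ModelConfig,
    val_traces: Sequence[CaTrace] | None = None,
) -> TrainedModel:
    """synCP-augmented supervised contrastive training.

    Per iteration: sample ``batch_families`` families × ``members_per_family``
    structures; when augmentation is on, each sampled trace is *replaced* by a
    random synCP of itself (k uniform over 0..n-1, k=0 allowed) and its graph
    rebuilt, so the fresh termini flags and positional encodings are what the
    model sees.  Positives are same-family structures.  The returned model
    carries the weights with the best validation retrieval sensitivity (mean
    over the label levels defined in the validation set); if no validation
    set can be formed, the final weights are returned.  Deterministic for a
    fixed config seed.
    """
    groups = _group_by_family(traces)
    trainable = {k: v for k, v in groups.items() if len(v) >= 2}
    if len(trainable) < 2:
        raise ValueError("need >= 2 families with >= 2 members each")
    if val_traces is None:
        # hold out two members per family so same-family retrieval is defined
        # within the validation set (all-vs-all validation search)
        val_traces = []
        for fam, members in trainable.items():
            if len(members) >= 4:
                val_traces.extend([members.pop(), members.pop()])
        if len(val_traces) < 4 or len({t.labels for t in val_traces}) < 2:
            val_traces = [m for ms in trainable.values() for m in ms]

    rng = np.random.default_rng(config.seed)
    model = TrainedModel(network=_GraphNetwork(config, rng), config=config)
    opt = nn.Adam(model.network.parameters(), lr=config.lr)

    val_graphs = [build_graph(t) for t in val_traces]
    val_labels = [t.labels for t in val_traces]
    fam_names = sorted(trainable)
    iters_per_epoch = max(1, math.ceil(len(fam_names) / config.batch_families))
    best_val = -np.inf
    best_state: list[np.ndarray] | None = None

    for epoch in range(config.epochs):
        order = rng.permutation(len(fam_names))
        losses = []
        for it in range(iters_per_epoch):
            chosen = order[it * config.batch_families:(it + 1) * config.batch_families]
            if len(chosen) < 2:
                chosen = order[: config.batch_families]
            batch_graphs, batch_labels = [], []
            for fi in chosen:
                members = trainable[fam_names[fi]]
                replace = len(members) < config.members_per_family
                idx = rng.choice(len(members), size=config.members_per_family, replace=replace)
                for mi in idx:
                    t = members[mi]
                    if config.syncp_augment:
                        t = syncp(t, int(rng.integers(0, len(t)))).child
                    batch_graphs.append(build_graph(t))
                    batch_labels.append(fam_names[fi])
            _, emb, _ = model.network.forward(batch_graphs)
            loss = supcon_loss(emb, batch_labels, config.temperature)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        entry = {"epoch": epoch, "loss": float(np.mean(losses))}
        if (epoch + 1) % config.val_every == 0 or epoch == config.epochs - 1:
            val_emb = encode_batch(val_graphs, model)
            sens = _mean_level_sensitivity(val_emb, val_labels)
            entry["val_sensitivity"] = sens
            if sens >= best_val:
                best_val = sens
                best_state = [p.data.copy() for p in model.network.parameters()]
        model.training_log.append(entry)

    if best_state is not None:
        for p, w in zip(model.network.parameters(), best_state):
            p.data = w
    return model


# ---------------------------------------------------------------------------
# checkpoint I/O (binary weights + JSON sidecar)


def save_model(model: TrainedModel, path: str | Path) -> None:
    path = Path(path)
    arrays = {f"p{i}": p.data for i, p in enumerate(model.network.parameters())}
    np.savez(path.with_suffix(".npz"), **arrays)
    sidecar = {"config": asdict(model.config), "training_log": model.training_log}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_model(path: str | Path) -> TrainedModel:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    config = ModelConfig(**sidecar["config"])
    model = fresh_model(config)
    with np.load(path.with_suffix(".npz")) as data:
        for i, p in enumerate(model.network.parameters()):
            p.data = data[f"p{i}"].astype(float)
    model.training_log = sidecar["training_log"]
    return model
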