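"""Embedding database, cosine search, and the dual-model CP-discovery pipeline.

The discovery pipeline exploits a contrast between two encoders trained on
the same data: a CP-*sensitive* baseline (no synCP augmentation, so its
embeddings move when a chain is re-cut) and a CP-*invariant* model (synCP
augmented).  A pair that the invariant model scores as highly similar while
the baseline does not is a putative circular permutant; each candidate is
then verified with the CP-aware structural aligner (TM-cp > 0.5 and ΔCP > 0).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA

from . import cpalign, encoder as enc
from .encoder import EmbeddingVector, TrainedModel
from .graphs import ProteinGraph, build_graph
from .structio import CaTrace

__all__ = [
    "EmbeddingDB",
    "CandidatePair",
    "PipelineConfig",
    "SearchHit",
    "embed_database",
    "cosine_search",
    "discover_cp",
    "node_similarity_map",
    "project_pca",
    "RETRIEVAL_CUTOFF",
]

logger = logging.getLogger(__name__)

RETRIEVAL_CUTOFF = 0.8  # cosine above this counts as a recovered homolog


@dataclass
class EmbeddingDB:
    """Structure embeddings (N × embed_dim) with stable ids."""

    ids: list[str]
    matrix: np.ndarray
    model_tag: str = ""
    config_hash: str = ""

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.matrix) or len(self.ids) < 1:
            raise ValueError("need one matrix row per id and at least one entry")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("ids must be unique")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("embedding matrix contains non-finite values")

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), matrix=self.matrix)
        path.with_suffix(".tsv").write_text(
            "\n".join(self.ids) + "\n"
        )
        path.with_suffix(".meta.json").write_text(
            json.dumps({"model_tag": self.model_tag, "config_hash": self.config_hash})
        )

    @classmethod
    def load(cls, path: str | Path) -> "EmbeddingDB":
        path = Path(path)
        with np.load(path.with_suffix(".npz")) as data:
            matrix = data["matrix"]
        ids = path.with_suffix(".tsv").read_text().splitlines()
        meta = json.loads(path.with_suffix(".meta.json").read_text())
        return cls(ids=ids, matrix=matrix, **meta)


@dataclass(frozen=True)
class SearchHit:
    target_id: str
    cosine: float
    rank: int


@dataclass(frozen=True)
class CandidatePair:
    """A pair scored under both models; diff = invariant − baseline cosine."""

    id_a: str
    id_b: str
    score_baseline: float
    score_invariant: float

    @property
    def diff(self) -> float:
        return self.score_invariant - self.score_baseline


@dataclass(frozen=True)
class PipelineConfig:
    """Filter thresholds of the CP-discovery pipeline.

    ``threshold`` mode keeps pairs the baseline model misses
    (cosine < ``baseline_max``) but the invariant model matches
    (cosine > ``invariant_min``); ``difference`` mode keeps pairs with an
    invariant-minus-baseline score gap of at least ``diff_min``.
    """

    mode: str = "threshold"
    baseline_max: float = 0.6
    invariant_min: float = 0.9
    diff_min: float = 0.7
    retrieval_cutoff: float = RETRIEVAL_CUTOFF
    tm_cp_min: float = cpalign.TM_CP_CUTOFF

    def __post_init__(self) -> None:
        if self.mode not in ("threshold", "difference"):
            raise ValueError(f"unknown pipeline mode {self.mode!r}")

    def selects(self, pair: CandidatePair) -> bool:
        if self.mode == "threshold":
            return pair.score_baseline < self.baseline_max and pair.score_invariant > self.invariant_min
        return pair.diff >= self.diff_min


def _config_hash(model: TrainedModel) -> str:
    payload = json.dumps(vars(model.config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def embed_database(
    traces: Sequence[CaTrace], model: TrainedModel, model_tag: str = ""
) -> EmbeddingDB:
    """Embed every trace; traces that fail graph preconditions are logged and skipped."""
    ids: list[str] = []
    graphs: list[ProteinGraph] = []
    for t in traces:
        try:
            graphs.append(build_graph(t))
            ids.append(t.id)
        except ValueError as exc:
            logger.warning("skipping %s: %s", t.id, exc)
    if not ids:
        raise ValueError("no embeddable traces")
    matrix = enc.encode_batch(graphs, model)
    return EmbeddingDB(ids=ids, matrix=matrix, model_tag=model_tag, config_hash=_config_hash(model))


def cosine_search(query: EmbeddingVector, db: EmbeddingDB, top_k: int = 10) -> list[SearchHit]:
    """Hits sorted by descending cosine; exact ties broken by id lexicographic order."""
    q = np.asarray(query.values, dtype=float)
    if q.shape[0] != db.matrix.shape[1]:
        raise ValueError(
            f"query dim {q.shape[0]} does not match database dim {db.matrix.shape[1]}"
        )
    z = db.matrix / np.linalg.norm(db.matrix, axis=1, keepdims=True)
    cos = z @ (q / np.linalg.norm(q))
    order = sorted(range(len(db.ids)), key=lambda i: (-cos[i], db.ids[i]))
    return [
        SearchHit(target_id=db.ids[i], cosine=float(cos[i]), rank=r + 1)
        for r, i in enumerate(order[:top_k])
    ]


def _pairwise_cosine(matrix: np.ndarray) -> np.ndarray:
    z = matrix / np.linalg.norm(matrix, axis=1, keepdims=True)
    return z @ z.T


def discover_cp(
    traces: Sequence[CaTrace],
    model_baseline: TrainedModel,
    model_invariant: TrainedModel,
    cfg: PipelineConfig | None = None,
) -> tuple[list[tuple[CandidatePair, cpalign.CPVerdict]], list[tuple[CandidatePair, cpalign.CPVerdict]]]:
    """All-vs-all dual-model filter plus structural verification.

    Returns ``(verified, audited)``: ``audited`` is every candidate that
    passed the embedding filter with its alignment verdict; ``verified`` is
    the subset with ``is_cp`` true (TM-cp > 0.5 and ΔCP > 0).
    """
    cfg = cfg or PipelineConfig()
    if len(traces) < 2:
        raise ValueError("need at least two traces")
    if model_baseline.config.embed_dim != model_invariant.config.embed_dim:
        raise ValueError("models must share embedding conventions")
    db_base = embed_database(traces, model_baseline, model_tag="baseline")
    db_inv = embed_database(traces, model_invariant, model_tag="invariant")
    if db_base.ids != db_inv.ids:
        raise ValueError("models embedded different trace subsets")
    cos_base = _pairwise_cosine(db_base.matrix)
    cos_inv = _pairwise_cosine(db_inv.matrix)
    by_id = {t.id: t for t in traces}
    audited: list[tuple[CandidatePair, cpalign.CPVerdict]] = []
    for i, j in combinations(range(len(db_base.ids)), 2):
        pair = CandidatePair(
            id_a=db_base.ids[i],
            id_b=db_base.ids[j],
            score_baseline=float(cos_base[i, j]),
            score_invariant=float(cos_inv[i, j]),
        )
        if cfg.selects(pair):
            verdict = cpalign.delta_cp(by_id[pair.id_a], by_id[pair.id_b])
            audited.append((pair, verdict))
    verified = [
        (pair, verdict)
        for pair, verdict in audited
        if verdict.is_cp and verdict.tm_cp > cfg.tm_cp_min
    ]
    return verified, audited


def node_similarity_map(
    trace_a: CaTrace, trace_b: CaTrace, model: TrainedModel
) -> np.ndarray:
    """(n_a, n_b) cosine matrix between per-residue embeddings of two traces."""
    ha = enc.node_embeddings(build_graph(trace_a), model)
    hb = enc.node_embeddings(build_graph(trace_b), model)
    za = ha / np.linalg.norm(ha, axis=1, keepdims=True)
    zb = hb / np.linalg.norm(hb, axis=1, keepdims=True)
    return za @ zb.T


def project_pca(db: EmbeddingDB, n_components: int = 2) -> np.ndarray:
    """Centered principal-component scores of the embedding matrix.

    Components are ordered by decreasing variance, with the sign convention
    that each component's largest-magnitude loading is positive.
    """
    n = len(db.matrix)
    if n <= n_components:
        raise ValueError(f"need more than {n_components} entries; got {n}")
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(db.matrix)
    for c in range(n_components):
        loading = pca.components_[c]
        if loading[np.argmax(np.abs(loading))] < 0:
            scores[:, c] *= -1.0
    return scores
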