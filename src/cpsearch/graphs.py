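"""Contact-graph construction with the three residue-level node features.

A structure becomes a graph whose nodes are Cα atoms and whose undirected
edges connect pairs within 10 Å.  Each node i carries a 67-dimensional
feature vector f_i = (ρ_i, τ_i, s_i):

* ρ_i — local density: neighbor count within 10 Å (self included), divided by
  the maximum count over the protein, so 0 < ρ_i <= 1 and max_i ρ_i = 1.
* τ_i ∈ {(1,0), (0,1), (0,0)} — N-terminal / C-terminal / interior flag.
* s_i ∈ R^64 — transformer-style sinusoidal positional encoding of the
  residue's position in the *current* chain order.

Edges and ρ depend only on inter-atomic distances, so they are invariant to
rigid motions and to circular permutation of the chain; τ and s depend only
on chain order.  A synCP therefore changes exactly the τ rows and the s
matrix — this asymmetry is what separates a CP-sensitive from a CP-invariant
embedding model downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .structio import CaTrace

__all__ = [
    "ProteinGraph",
    "CONTACT_CUTOFF",
    "MIN_GRAPH_LEN",
    "build_graph",
    "local_density",
    "terminal_flags",
    "positional_encoding",
]

CONTACT_CUTOFF = 10.0  # Å, inclusive
MIN_GRAPH_LEN = 20
ENCODING_DIM = 64
FEATURE_DIM = 1 + 2 + ENCODING_DIM


@dataclass(frozen=True)
class ProteinGraph:
    """Contact graph of one structure: edges, coordinates, node features."""

    n_nodes: int
    edges: np.ndarray  # (E, 2) int, i < j, undirected
    coords: np.ndarray  # (n, 3) Å — carried for the distance-aware encoder
    features: np.ndarray  # (n, 67): [rho | tau_N tau_C | s]
    id: str = ""

    @property
    def edge_set(self) -> set[tuple[int, int]]:
        return {(int(i), int(j)) for i, j in self.edges}


def local_density(coords: np.ndarray) -> np.ndarray:
    """Normalized 10 Å neighbor density ρ_i = α_i / max_j α_j (self included)."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or len(coords) < 1:
        raise ValueError("coords must be a nonempty (n, 3) array")
    if len(coords) == 1:
        return np.ones(1)
    dist = squareform(pdist(coords))
    alpha = np.sum(dist <= CONTACT_CUTOFF, axis=1).astype(float)  # includes self
    return alpha / alpha.max()


def terminal_flags(n: int) -> np.ndarray:
    """(n, 2) τ matrix: row 0 = (1,0) [N-terminus], row n-1 = (0,1), else (0,0)."""
    if n < 2:
        raise ValueError("need at least 2 residues for terminal flags")
    tau = np.zeros((n, 2))
    tau[0, 0] = 1.0
    tau[-1, 1] = 1.0
    return tau


def positional_encoding(n: int, d: int = ENCODING_DIM) -> np.ndarray:
    """Sinusoidal positional encoding, positions 0-based in current chain order.

    s_i[2j] = sin(i / 10000^(2j/d)),  s_i[2j+1] = cos(i / 10000^(2j/d)).
    """
    if d % 2 != 0:
        raise ValueError("encoding dimension d must be even")
    if n < 1:
        raise ValueError("n must be >= 1")
    pos = np.arange(n, dtype=float)[:, None]
    freq = 1.0 / np.power(10000.0, 2.0 * np.arange(d // 2, dtype=float) / d)
    angles = pos * freq[None, :]
    s = np.empty((n, d))
    s[:, 0::2] = np.sin(angles)
    s[:, 1::2] = np.cos(angles)
    return s


def build_graph(trace: CaTrace) -> ProteinGraph:
    """Contact graph with ρ/τ/s node features for a trace of >= 20 residues."""
    n = len(trace)
    if n < MIN_GRAPH_LEN:
        raise ValueError(f"trace '{trace.id}' has {n} residues; graphs need >= {MIN_GRAPH_LEN}")
    coords = trace.coords
    dist = squareform(pdist(coords))
    iu, ju = np.triu_indices(n, k=1)
    mask = dist[iu, ju] <= CONTACT_CUTOFF
    edges = np.column_stack([iu[mask], ju[mask]]).astype(np.int64)
    alpha = np.sum(dist <= CONTACT_CUTOFF, axis=1).astype(float)
    features = np.concatenate(
        [(alpha / alpha.max())[:, None], terminal_flags(n), positional_encoding(n)],
        axis=1,
    )
    return ProteinGraph(n_nodes=n, edges=edges, coords=coords.copy(), features=features, id=trace.id)
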