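"""Structural alignment: Kabsch superposition, TM-score, DP alignment, CP mode.

The aligner is a self-contained TM-score-based heuristic in the TM-align
mold: alignment seeds (gapless threadings and fragment superpositions) are
refined by iterating superposition → residue-pair score matrix → global
dynamic programming until the mapping is stable, and the best mapping by
TM-score wins.  Scores are normalized by each chain length separately and
the *minimum* of the two is reported as the global-similarity score.

Circular permutations are handled by the duplicate-and-align idea: the query
chain is allowed to wrap around its termini, implemented as a search over
all cyclic re-cuts of the query (each re-cut is aligned conventionally, so
every original residue is used at most once and the mapping stays monotone
in a single cyclic frame).  The ΔCP statistic is the gain in TM-score from
allowing the wrap; a pair is called circularly permuted when the CP-aware
score clears the 0.5 fold-similarity threshold *and* ΔCP is positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.spatial.distance import cdist

from .structio import CaTrace

__all__ = [
    "Alignment",
    "CPVerdict",
    "DegenerateGeometryError",
    "kabsch",
    "tm_d0",
    "tm_score",
    "align",
    "align_cp",
    "delta_cp",
    "GAP_PENALTY",
    "TM_CP_CUTOFF",
]

GAP_PENALTY = 0.6  # charged once per internal gap block, no extension cost
MAX_ITER = 30
MIN_ALIGN_LEN = 20
TM_CP_CUTOFF = 0.5  # TM > 0.5: same fold; TM < 0.17: random similarity


class DegenerateGeometryError(ValueError):
    """Raised when a point set is too degenerate (collinear) to superpose."""


@dataclass(frozen=True)
class Alignment:
    """Residue mapping plus superposition and TM scores for one pair."""

    mapping: list[tuple[int, int]]
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    tm_query: float
    tm_target: float
    cp_mode: bool = False
    cp_offset: int | None = None

    @property
    def tm_min(self) -> float:
        return min(self.tm_query, self.tm_target)

    @property
    def n_aligned(self) -> int:
        return len(self.mapping)


@dataclass(frozen=True)
class CPVerdict:
    """Plain and CP-aware TM scores for a pair plus the CP call."""

    tm: float
    tm_cp: float
    delta_cp: float
    is_cp: bool


# ---------------------------------------------------------------------------
# superposition and TM-score


def kabsch(
    X: np.ndarray, Y: np.ndarray, check_degenerate: bool = True
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares superposition of X onto Y (rows in correspondence).

    Returns (R, t, rmsd) with X @ R.T + t ≈ Y and R a proper rotation
    (reflections are corrected by flipping the smallest singular direction).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3 or len(X) < 3:
        raise ValueError("kabsch needs matching (m, 3) arrays with m >= 3")
    xm, ym = X.mean(axis=0), Y.mean(axis=0)
    Xc, Yc = X - xm, Y - ym
    H = Xc.T @ Yc
    U, S, Vt = np.linalg.svd(H)
    if check_degenerate and S[0] > 0 and S[1] / S[0] < 1e-8:
        raise DegenerateGeometryError("point set is (nearly) collinear; rotation ill-defined")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = ym - R @ xm
    rmsd = float(np.sqrt(np.mean(np.sum((Xc @ R.T - Yc) ** 2, axis=1))))
    return R, t, rmsd


def tm_d0(L_norm: int) -> float:
    """Length-dependent TM-score distance scale, floored at 0.5 Å."""
    if L_norm < 15:
        return 0.5
    return max(0.5, 1.24 * (L_norm - 15) ** (1.0 / 3.0) - 1.8)


def _superpose_mapped(Xm: np.ndarray, Ym: np.ndarray, subset: np.ndarray) -> np.ndarray:
    """Distances of all mapped pairs after superposing on a subset of them."""
    if subset.sum() >= 3:
        R, t, _ = kabsch(Xm[subset], Ym[subset], check_degenerate=False)
    else:
        R = np.eye(3)
        t = Ym.mean(axis=0) - Xm.mean(axis=0)
    return np.linalg.norm(Xm @ R.T + t - Ym, axis=1)


def tm_score(
    X: np.ndarray,
    Y: np.ndarray,
    mapping: "list[tuple[int, int]] | np.ndarray",
    L_norm: int,
) -> float:
    """TM-score of a fixed residue mapping, normalized by ``L_norm``.

    TM = (1/L_norm) Σ 1/(1 + (d_i/d0)²) under the TM-score-optimal
    superposition, found by iterative subset refinement: superpose on the
    current subset, rescore all mapped pairs, keep the pairs within a
    distance cut, repeat.  Several fragment seeds guard against a bad global
    initial superposition.
    """
    mapping = np.asarray(mapping, dtype=int)
    if mapping.size == 0:
        raise ValueError("mapping is empty")
    Xm = np.asarray(X, dtype=float)[mapping[:, 0]]
    Ym = np.asarray(Y, dtype=float)[mapping[:, 1]]
    m = len(Xm)
    d0 = tm_d0(L_norm)
    seeds = [np.ones(m, dtype=bool)]
    frag = max(4, m // 2)
    for start in {0, max(0, (m - frag) // 2), max(0, m - frag)}:
        s = np.zeros(m, dtype=bool)
        s[start:start + frag] = True
        seeds.append(s)
    best = 0.0
    for subset in seeds:
        prev = None
        for _ in range(20):
            d = _superpose_mapped(Xm, Ym, subset)
            best = max(best, float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / L_norm))
            d_cut = max(d0, 0.5)
            new = d < d_cut
            while new.sum() < 3 and d_cut < 50.0:
                d_cut += 0.5
                new = d < d_cut
            if prev is not None and np.array_equal(new, prev):
                break
            prev = subset = new
    return best


# ---------------------------------------------------------------------------
# dynamic-programming alignment stage


@njit(cache=True)
def _dp_core(S: np.ndarray, gap: float):  # pragma: no cover - exercised via dp_align
    """Best monotone mapping under Σ S − gap·(# internal gap blocks).

    A gap block is a maximal run of skipped residues in either chain between
    two consecutive matched pairs; terminal overhangs are free.  Returns the
    score and the matched index pairs (0-based).
    """
    n, m = S.shape
    NEG = -1.0e18
    M = np.full((n + 1, m + 1), NEG)
    rowmax = np.full((n + 1, m + 1), NEG)  # max_{j'<=j} M[i][j']
    colmax = np.full((n + 1, m + 1), NEG)  # max_{i'<=i} M[i'][j]
    allmax = np.full((n + 1, m + 1), NEG)  # max over prefix rectangle
    rm_arg = np.zeros((n + 1, m + 1), np.int32)
    cm_arg = np.zeros((n + 1, m + 1), np.int32)
    am_arg_i = np.zeros((n + 1, m + 1), np.int32)
    am_arg_j = np.zeros((n + 1, m + 1), np.int32)
    pred_i = np.zeros((n + 1, m + 1), np.int32)
    pred_j = np.zeros((n + 1, m + 1), np.int32)
    best = NEG
    bi = bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            cand = 0.0  # start a new alignment here (leading overhang free)
            pi = 0
            pj = 0
            if i > 1 and j > 1 and M[i - 1][j - 1] > cand:
                cand = M[i - 1][j - 1]
                pi, pj = i - 1, j - 1
            if i > 1 and j > 2 and rowmax[i - 1][j - 2] - gap > cand:
                cand = rowmax[i - 1][j - 2] - gap
                pi, pj = i - 1, rm_arg[i - 1][j - 2]
            if i > 2 and j > 1 and colmax[i - 2][j - 1] - gap > cand:
                cand = colmax[i - 2][j - 1] - gap
                pi, pj = cm_arg[i - 2][j - 1], j - 1
            if i > 2 and j > 2 and allmax[i - 2][j - 2] - 2.0 * gap > cand:
                cand = allmax[i - 2][j - 2] - 2.0 * gap
                pi, pj = am_arg_i[i - 2][j - 2], am_arg_j[i - 2][j - 2]
            M[i][j] = S[i - 1, j - 1] + cand
            pred_i[i][j] = pi
            pred_j[i][j] = pj
            if M[i][j] > best:
                best = M[i][j]
                bi, bj = i, j
            # running prefix maxima with argmaxes
            if j > 1 and rowmax[i][j - 1] >= M[i][j]:
                rowmax[i][j] = rowmax[i][j - 1]
                rm_arg[i][j] = rm_arg[i][j - 1]
            else:
                rowmax[i][j] = M[i][j]
                rm_arg[i][j] = j
            if i > 1 and colmax[i - 1][j] >= M[i][j]:
                colmax[i][j] = colmax[i - 1][j]
                cm_arg[i][j] = cm_arg[i - 1][j]
            else:
                colmax[i][j] = M[i][j]
                cm_arg[i][j] = i
            amax = M[i][j]
            ai, aj = i, j
            if i > 1 and allmax[i - 1][j] > amax:
                amax = allmax[i - 1][j]
                ai, aj = am_arg_i[i - 1][j], am_arg_j[i - 1][j]
            if j > 1 and allmax[i][j - 1] > amax:
                amax = allmax[i][j - 1]
                ai, aj = am_arg_i[i][j - 1], am_arg_j[i][j - 1]
            allmax[i][j] = amax
            am_arg_i[i][j] = ai
            am_arg_j[i][j] = aj
    # traceback
    out_i = np.empty(min(n, m), np.int64)
    out_j = np.empty(min(n, m), np.int64)
    count = 0
    ci, cj = bi, bj
    while ci > 0:
        out_i[count] = ci - 1
        out_j[count] = cj - 1
        count += 1
        ci, cj = pred_i[ci][cj], pred_j[ci][cj]
    return best, out_i[:count][::-1].copy(), out_j[:count][::-1].copy()


def dp_align(S: np.ndarray, gap: float = GAP_PENALTY) -> tuple[float, np.ndarray]:
    """Optimal monotone mapping for a similarity matrix; see :func:`_dp_core`."""
    score, ai, bi = _dp_core(np.ascontiguousarray(S, dtype=float), float(gap))
    return float(score), np.column_stack([ai, bi])


# ---------------------------------------------------------------------------
# full pairwise alignment


def _thread_seeds(n: int, m: int) -> list[np.ndarray]:
    """Gapless threadings of the shorter chain onto the longer, all offsets."""
    seeds = []
    span = abs(n - m)
    stride = max(1, (span + 1) // 20)
    offsets = sorted(set(range(0, span + 1, stride)) | {span})
    short = min(n, m)
    for off in offsets:
        idx = np.arange(short)
        if n >= m:
            seeds.append(np.column_stack([idx + off, idx]))
        else:
            seeds.append(np.column_stack([idx, idx + off]))
    return seeds


def _fragment_seeds(n: int, m: int) -> list[np.ndarray]:
    f = min(n, m, 20)
    idx = np.arange(f)
    anchors = {(0, 0), (n - f, m - f), (0, m - f), (n - f, 0),
               ((n - f) // 2, (m - f) // 2)}
    return [np.column_stack([idx + a, idx + b]) for a, b in anchors]


def _refine(
    A: np.ndarray, B: np.ndarray, seed: np.ndarray, d0_ref: float
) -> np.ndarray:
    """Iterate superpose → score matrix → DP until the mapping is stable."""
    mapping = seed
    seen: set[bytes] = set()
    for _ in range(MAX_ITER):
        if len(mapping) < 3:
            break
        R, t, _ = kabsch(A[mapping[:, 0]], B[mapping[:, 1]], check_degenerate=False)
        D = cdist(A @ R.T + t, B)
        S = 1.0 / (1.0 + (D / d0_ref) ** 2)
        _, mapping = dp_align(S)
        key = mapping.tobytes()
        if key in seen:
            break
        seen.add(key)
    return mapping


def _score_mapping(A: np.ndarray, B: np.ndarray, mapping: np.ndarray) -> tuple[float, float]:
    return (
        tm_score(A, B, mapping, len(A)),
        tm_score(A, B, mapping, len(B)),
    )


def align(A: CaTrace, B: CaTrace) -> Alignment:
    """Sequence-order-dependent structural alignment of two Cα traces.

    ``tm_query`` is normalized by len(A), ``tm_target`` by len(B); the global
    similarity score is their minimum.
    """
    n, m = len(A), len(B)
    if n < MIN_ALIGN_LEN or m < MIN_ALIGN_LEN:
        raise ValueError(f"alignment needs traces of >= {MIN_ALIGN_LEN} residues")
    d0_ref = tm_d0(min(n, m))
    best_tm = -1.0
    best_mapping: np.ndarray | None = None
    tried: set[bytes] = set()
    for seed in _thread_seeds(n, m) + _fragment_seeds(n, m):
        mapping = _refine(A.coords, B.coords, seed, d0_ref)
        if len(mapping) == 0:
            continue
        key = mapping.tobytes()
        if key in tried:
            continue
        tried.add(key)
        tm_q, tm_t = _score_mapping(A.coords, B.coords, mapping)
        if min(tm_q, tm_t) > best_tm:
            best_tm = min(tm_q, tm_t)
            best_mapping = mapping
            best_scores = (tm_q, tm_t)
    assert best_mapping is not None
    R, t, rmsd = kabsch(
        A.coords[best_mapping[:, 0]], B.coords[best_mapping[:, 1]], check_degenerate=False
    )
    return Alignment(
        mapping=[(int(i), int(j)) for i, j in best_mapping],
        rotation=R,
        translation=t,
        rmsd=rmsd,
        tm_query=best_scores[0],
        tm_target=best_scores[1],
    )


def _quick_cut_score(rolled: np.ndarray, B: np.ndarray, d0: float) -> float:
    """Cheap gapless-threading TM estimate used to rank candidate re-cuts."""
    n, m = len(rolled), len(B)
    short = min(n, m)
    span = abs(n - m)
    best = 0.0
    for off in {0, span // 2, span}:
        if n >= m:
            Xm, Ym = rolled[off:off + short], B
        else:
            Xm, Ym = rolled, B[off:off + short]
        d = _superpose_mapped(Xm, Ym, np.ones(short, dtype=bool))
        best = max(best, float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / short))
    return best


def align_cp(A: CaTrace, B: CaTrace, n_refine_cuts: int = 5) -> Alignment:
    """Circular-permutation-aware alignment (duplicate-and-align).

    Conceptually the query is concatenated with itself so the alignment may
    wrap around the termini; equivalently, every cyclic re-cut of A is
    aligned conventionally and the best re-cut wins, which enforces that each
    original residue is used at most once and the mapping is monotone in a
    single cyclic frame.  TM scores stay normalized by the original chain
    lengths.  ``cp_offset`` is the winning cut; mapping indices refer to the
    original residue numbering of A.
    """
    n = len(A)
    if n < MIN_ALIGN_LEN or len(B) < MIN_ALIGN_LEN:
        raise ValueError(f"alignment needs traces of >= {MIN_ALIGN_LEN} residues")
    d0_ref = tm_d0(min(n, len(B)))
    quick = np.array(
        [_quick_cut_score(np.roll(A.coords, -c, axis=0), B.coords, d0_ref) for c in range(n)]
    )
    candidates = np.argsort(-quick, kind="stable")[:n_refine_cuts]
    best: Alignment | None = None
    best_cut = 0
    for c in sorted(int(c) for c in candidates):
        rolled = CaTrace(id=A.id, coords=np.roll(A.coords, -c, axis=0))
        result = align(rolled, B)
        if best is None or result.tm_min > best.tm_min + 1e-12:
            best = result
            best_cut = c
    assert best is not None
    mapping = [((i + best_cut) % n, j) for i, j in best.mapping]
    return Alignment(
        mapping=mapping,
        rotation=best.rotation,
        translation=best.translation,
        rmsd=best.rmsd,
        tm_query=best.tm_query,
        tm_target=best.tm_target,
        cp_mode=True,
        cp_offset=best_cut,
    )


def delta_cp(A: CaTrace, B: CaTrace) -> CPVerdict:
    """ΔCP = TM(CP-aware) − TM(plain); CP call = (tm_cp > 0.5) ∧ (ΔCP > 0)."""
    tm = align(A, B).tm_min
    tm_cp = align_cp(A, B).tm_min
    delta = tm_cp - tm
    return CPVerdict(tm=tm, tm_cp=tm_cp, delta_cp=delta,
                     is_cp=bool(tm_cp > TM_CP_CUTOFF and delta > 0))
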