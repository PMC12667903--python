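# Methods

This note documents the models, algorithms, and design choices in `cpsearch`,
including what the synthetic data does and does not emulate, and what the
test suite does and does not establish about behavior on real structures.

## Problem setting

Two proteins are related by circular permutation (CP) when they share a
global fold but their chain termini sit at different positions — as if one
chain had been circularized and re-cut elsewhere. Embedding-based structure
search tools score such pairs poorly because their representations carry
sequence-order information, while alignment tools (TM-align-style dynamic
programming) are order-dependent unless given an explicit CP mode.
`cpsearch` implements both halves of a CP-discovery strategy: a pair of
structure encoders whose *disagreement* flags putative CPs, and a CP-aware
structural aligner that verifies them.

## Structure representation

A structure is reduced to its Cα trace 𝒫 = (p_1, …, p_n), N→C order. The
contact graph connects residues i ≠ j whenever ‖p_i − p_j‖ ≤ 10 Å
(inclusive; ties at exactly 10 Å are edges — a fixed convention with
measure-zero effect on real coordinates). Each node carries 67 features:

- **ρ_i** — local density: the count α_i of Cα atoms within 10 Å (the
  residue itself included), divided by max_j α_j. The self-count convention
  is immaterial because of the max-normalization.
- **τ_i ∈ {(1,0), (0,1), (0,0)}** — N-terminal / C-terminal / interior flag.
- **s_i ∈ R⁶⁴** — the standard transformer sinusoidal positional encoding,
  s_i[2j] = sin(i / 10000^(2j/64)), s_i[2j+1] = cos(·), positions 0-based in
  the current chain order. (Whether positions start at 0 or 1 is a free
  convention; no invariance property depends on it.)

A *synthetic circular permutation* (synCP) with cut offset k reorders the
trace to 𝒫_k = (p_{k+1}, …, p_n, p_1, …, p_k) without moving any atom. We
canonicalize k to [0, n), so k = 0 is the identity and k and k+n coincide.
Because edges depend only on distances and coordinates are untouched, a
synCP leaves the edge set exactly invariant under the cyclic relabeling;
only the τ rows and the s matrix change. (Descriptions of this operation
sometimes expect edge changes at the old and new termini; that would require
explicit backbone-adjacency edges, which this graph does not have — we use
distance edges only and note the discrepancy here.)

## Encoder

The encoder is an E(3)-invariant message-passing network. Per layer,
messages m_ij = φ([h_i, h_j, d²_ij/100]) flow along directed edges and are
mean-aggregated at the receiving node; the node state is updated residually
by a two-layer MLP on [h_i, agg_i]. No raw coordinates enter any channel —
only squared distances — so rigid-motion invariance is exact by
construction rather than approximate, and mean pooling makes the structure
embedding invariant to node storage order. We deliberately omit the
equivariant coordinate-update channel found in some E(n) graph network
variants: a pooled *invariant* embedding would discard its output anyway.

Two exact algebraic rewrites keep CPU cost proportional to node count
rather than edge count: the first affine layer of the message MLP is
evaluated on nodes and gathered to edges (an affine map distributes over
concatenation), and the second affine layer is applied after the mean
aggregation (affine maps commute with means). The message width defaults to
half the node width. Parameters are float32; the network runs on a small
NumPy reverse-mode autodiff core (`cpsearch.nn`) whose gradients are
property-tested against central differences.

Defaults mirror the scale of published graph-embedding search models
(6 layers, 128 hidden, 128-dim embeddings); the desk-scale studies in the
test suite and acceptance script use 4 layers / 64 hidden / 64-dim
embeddings, which train in minutes on one CPU core while preserving every
qualitative behavior of interest.

## Training

Supervised contrastive loss on L2-normalized embeddings z, temperature
τ = 0.1:

L = mean over anchors i with positives of
    −(1/|P(i)|) Σ_{p∈P(i)} log[ exp(z_i·z_p/τ) / Σ_{a≠i} exp(z_i·z_a/τ) ]

Positives are same-family structures. Anchors whose label has no second
member are excluded from the average. Each iteration samples
`batch_families` families × `members_per_family` members; with synCP
augmentation on, every sampled structure is *replaced* by a random synCP of
itself (k uniform over 0..n−1, k = 0 allowed) and its graph rebuilt, so the
model sees fresh termini flags and positional encodings each time. The
augmented children are not added as extra positives — they replace the
parent. Optimization is Adam (lr 1e-3).

Validation: two members per family are held out (when the family can spare
them) and retrieval is evaluated all-vs-all *within* the validation set,
using sensitivity-to-first-false-positive at family, superfamily and fold
levels; levels undefined for the label set are skipped and the defined
levels averaged. The weights with the best validation sensitivity are
returned. Training is deterministic given the config seed.

The CP-**sensitive baseline** is the identical architecture trained on the
identical data with augmentation off. This makes the dual-model contrast
self-contained: no published weights are required.

## Alignment

`kabsch` computes the proper-rotation least-squares superposition (SVD with
determinant correction; near-collinear point sets are flagged because the
rotation is ill-defined). `tm_score` evaluates a fixed residue mapping as
TM = (1/L_norm) Σ 1/(1 + (d_i/d0)²), d0 = max(0.5, 1.24·(L_norm−15)^⅓ −
1.8) (lengths below 15 use the 0.5 Å floor directly), under the
TM-score-optimal superposition found by iterative subset refinement from
several fragment seeds.

`align` is a TM-align-style heuristic: seeds from gapless threadings at all
offsets plus fragment superpositions, each refined by iterating
{superpose on the current mapping → score matrix S_ij = 1/(1+(d_ij/d0)²) →
global DP → new mapping} to a fixed point (at most 30 rounds). The DP
objective is Σ S over matched pairs minus 0.6 per *internal gap block* on
either chain (no extension cost, free terminal overhangs); the
implementation is an O(nm) prefix-maximum recursion verified against
exhaustive enumeration of all monotone mappings on small problems. TM
scores are normalized by each chain length separately; the reported global
score is the minimum of the two. The aligner does not reuse TM-align
source or its secondary-structure seeding, so absolute scores can deviate
from the reference tool; all CP logic uses this aligner on both arms, which
is what the ΔCP semantics require.

`align_cp` realizes duplicate-and-align: conceptually the query is
concatenated with itself so the alignment can wrap around the termini.
Operationally every cyclic re-cut of the query is aligned conventionally —
an exactly equivalent search space given the constraints that each original
residue maps at most once and the mapping stays monotone in a single cyclic
frame — with a cheap gapless-superposition screen ranking the n cuts and
the top 5 refined fully. Ties prefer the smaller cut offset. Scores stay
normalized by the original lengths.

`delta_cp` reports tm = plain min-normalized score, tm_cp = CP-aware score,
ΔCP = tm_cp − tm, and the call is_cp ⇔ (tm_cp > 0.5 ∧ ΔCP > 0). The 0.5
threshold is the conventional same-fold TM cutoff; min-normalization is
used on both arms.

## Discovery pipeline

All-vs-all cosine under both models. Threshold mode keeps pairs with
baseline cosine < 0.6 **and** invariant cosine > 0.9 (the baseline misses
what the invariant model matches); difference mode keeps pairs with
invariant − baseline ≥ 0.7. The cutoff directions are our reading of the
filter's purpose. Every candidate is verified by `delta_cp`; the verified
set is the is_cp subset, and the full audited candidate table is returned
alongside. A cosine of 0.8 is treated as the homolog-recovery cutoff in
retrieval evaluations. Structures failing graph preconditions are logged
and skipped, not fatal — the robustness posture a large database scan
needs. The candidate set typically contains many cross-family pairs that
the invariant model scores high but verification rejects (their TM-cp stays
below 0.5); this mirrors the intended division of labor between a permissive
fast filter and a strict aligner.

## Synthetic data

`make_synthetic_family` builds a rigid family template by chaining idealized
secondary-structure elements — helix: 1.5 Å rise, 100° turn, 2.3 Å radius;
strand: 3.4 Å rise with a zig-zag sized for 3.8 Å Cα spacing; short
persistent-walk loops — with composition drawn from the seeded generator.
Members add i.i.d. Gaussian coordinate noise and an independent random
rigid motion. `make_cp_benchmark` additionally replaces one member per
family with a synCP of the first member (cut uniform in [n/4, 3n/4]) plus
fresh noise, and lists cross-family decoy pairs.

Desk-scale study conditions used throughout the suite and the acceptance
script: 30 families × 8 members, length 80, noise SD 0.3 Å, ~100 epochs.
The noise level keeps within-family Cα RMSD well under the 10 Å contact
scale (realistic for a tight structural family); lengths near 80 residues
match a typical single domain.

What the generator does **not** emulate: real secondary-structure packing
(elements are joined at random orientations and may clash), side chains,
variable domain lengths within a family, evolutionary divergence beyond
isotropic noise, and real CPs (which involve loop remodeling at the old and
new termini, not a pure re-indexing). Passing tests therefore demonstrate
the *mechanism* — learned CP invariance, the dual-model contrast, CP-aware
alignment — not retrieval performance on real databases.

## Observations and limitations

- **Node-level embeddings.** At desk scale, per-residue embeddings retain a
  strong sequence-position component (a "carrier"): after training, a
  node's embedding is more similar to the same *index* in a re-cut chain
  than to the same *atom*. Pooled-embedding CP invariance is achieved by
  the stability of the mean, not by position-free node embeddings. Raw
  node-cosine maps consequently do not show residue-level correspondence
  between duplicated substructures. A controlled contrast does: comparing
  the cross-block cosine of a duplicated-block chain against the same
  chain with the duplicate replaced by an irregular coil (identical index
  layout, so the carrier cancels), the trained invariant model shows a
  clear elevation and an untrained network none. Training on a single
  fixed length (all families length 80) likely strengthens the carrier;
  larger and length-diverse training sets should weaken it.
- The baseline model is *mostly* CP-sensitive: for a minority of planted
  permutants its score stays high (geometry alone, which the permutation
  preserves, suffices for those folds), so a planted pair can occasionally
  slip past the threshold filter. The verification stage never converts
  misses into false positives.
- The aligner's DP stage is optimal for its objective, but the overall
  heuristic (seeding + iteration) is not guaranteed globally optimal;
  pairwise symmetry holds only to ~0.02 TM.
- Determinism: all randomness flows from explicit seeds (generators,
  training, evaluation); repeated runs are bit-identical.
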