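"""Cα-trace I/O, synthetic circular permutation, and synthetic benchmark generation.

The universal structural currency of this package is the :class:`CaTrace`: the
ordered alpha-carbon coordinates of a single protein chain, N- to C-terminus.
A synthetic circular permutation (synCP) cyclically reorders that sequence
without moving a single atom; two structures related by a circular permutation
share a global fold but have their termini at different chain positions.

Synthetic families of rigid backbones (idealized helices/strands joined by
loops, plus Gaussian coordinate noise and random rigid motions) let the whole
training and search pipeline run without any database download.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterator

import gemmi
import numpy as np

__all__ = [
    "CaTrace",
    "SynCPRecord",
    "SyntheticBenchmark",
    "read_ca_trace",
    "write_ca_trace",
    "syncp",
    "enumerate_syncps",
    "make_synthetic_family",
    "make_cp_benchmark",
]

MIN_TRACE_LEN = 5

# Idealized secondary-structure geometry (Å / degrees): an alpha helix rises
# 1.5 Å per residue with a 100 deg turn at 2.3 Å radius; a beta strand rises
# 3.4 Å per residue with an alternating lateral zig-zag sized so consecutive
# Cα atoms sit ~3.8 Å apart.
HELIX_RISE = 1.5
HELIX_TURN_DEG = 100.0
HELIX_RADIUS = 2.3
STRAND_RISE = 3.4
CA_CA = 3.8


@dataclass(frozen=True)
class CaTrace:
    """Ordered Cα coordinates of one chain with optional hierarchy label.

    ``labels`` follows the SCOPe sccs convention ``class.fold.superfamily.family``
    when present.  Coordinates are an (n, 3) float array in Å, N→C order.
    """

    id: str
    coords: np.ndarray
    labels: str | None = None
    source: str | None = None

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError(f"coords must be (n, 3); got {coords.shape}")
        if len(coords) < MIN_TRACE_LEN:
            raise ValueError(
                f"trace '{self.id}' has {len(coords)} residues; need >= {MIN_TRACE_LEN}"
            )
        if not np.all(np.isfinite(coords)):
            raise ValueError(f"trace '{self.id}' contains non-finite coordinates")
        step = np.linalg.norm(np.diff(coords, axis=0), axis=1)
        if np.any(step == 0.0):
            raise ValueError(f"trace '{self.id}' has coincident consecutive Cα atoms")

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def family(self) -> str | None:
        return self.labels

    def label_at(self, level: str) -> str | None:
        """Prefix of the sccs label at ``family``/``superfamily``/``fold`` depth."""
        if self.labels is None:
            return None
        parts = self.labels.split(".")
        depth = {"fold": 2, "superfamily": 3, "family": 4}[level]
        if len(parts) < depth:
            return None
        return ".".join(parts[:depth])


@dataclass(frozen=True)
class SynCPRecord:
    """A k-synCP child: parent coordinates cyclically reordered by cut offset k."""

    parent_id: str
    k: int
    child: CaTrace


@dataclass(frozen=True)
class SyntheticBenchmark:
    """Labeled traces with planted circular-permutant pairs and non-CP decoys."""

    traces: list[CaTrace]
    cp_pairs: list[tuple[str, str]]
    decoy_pairs: list[tuple[str, str]]
    seed: int

    def __post_init__(self) -> None:
        ids = {t.id for t in self.traces}
        for a, b in [*self.cp_pairs, *self.decoy_pairs]:
            if a not in ids or b not in ids:
                raise ValueError(f"pair ({a}, {b}) references unknown trace id")
        if set(self.cp_pairs) & set(self.decoy_pairs):
            raise ValueError("cp_pairs and decoy_pairs overlap")

    def trace(self, trace_id: str) -> CaTrace:
        for t in self.traces:
            if t.id == trace_id:
                return t
        raise KeyError(trace_id)


# ---------------------------------------------------------------------------
# structure file I/O


def _pick_ca(residue: gemmi.Residue) -> gemmi.Atom | None:
    """Highest-occupancy CA of a residue; first-seen wins ties."""
    best = None
    for atom in residue:
        if atom.name != "CA" or atom.element == gemmi.Element("Ca"):
            continue
        if best is None or atom.occ > best.occ:
            best = atom
    return best


def read_ca_trace(
    path: str | Path,
    format: str = "auto",
    chain: str | None = None,
    label: str | None = None,
) -> CaTrace:
    """Read the Cα trace of one chain from a PDB or mmCIF file.

    Uses the first model and the first chain unless ``chain`` names one.
    Residues without a Cα are skipped; altlocs resolve to the highest-occupancy
    copy (first seen on ties); file residue order is kept, gaps are not
    renumbered.
    """
    path = Path(path)
    fmt = {
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
        "auto": gemmi.CoorFormat.Detect,
    }.get(format)
    if fmt is None:
        raise ValueError(f"unknown format {format!r}")
    try:
        structure = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"could not parse {path}: {exc}") from exc
    if len(structure) == 0:
        raise ValueError(f"{path} contains no models")
    model = structure[0]
    if chain is not None:
        gchain = model.find_chain(chain)
        if gchain is None:
            raise ValueError(f"chain {chain!r} not found in {path}")
    else:
        if len(model) == 0:
            raise ValueError(f"{path} contains no chains")
        gchain = model[0]
    coords = []
    for residue in gchain:
        ca = _pick_ca(residue)
        if ca is not None:
            coords.append([ca.pos.x, ca.pos.y, ca.pos.z])
    if not coords:
        raise ValueError(f"no Cα atoms found in {path} chain {gchain.name!r}")
    if len(coords) < MIN_TRACE_LEN:
        raise ValueError(
            f"{path} chain {gchain.name!r} has only {len(coords)} Cα atoms; "
            f"need >= {MIN_TRACE_LEN}"
        )
    return CaTrace(
        id=path.stem,
        coords=np.array(coords, dtype=float),
        labels=label,
        source=f"{path}:{gchain.name}",
    )


_ATOM_FMT = (
    "ATOM  {serial:>5d}  CA  GLY {chain}{resseq:>4d}    "
    "{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
)


def write_ca_trace(trace: CaTrace, path: str | Path) -> None:
    """Write a Cα-only PDB file (one GLY CA record per residue).

    PDB fixed-width coordinate fields hold |coord| < 10000 Å at 3 decimals;
    larger values raise instead of silently corrupting columns.
    """
    if np.any(np.abs(trace.coords) >= 10000.0):
        raise ValueError("coordinates overflow the fixed-width PDB field (|x| >= 10000 Å)")
    path = Path(path)
    with open(path, "w") as fh:
        for i, (x, y, z) in enumerate(trace.coords):
            fh.write(_ATOM_FMT.format(serial=i + 1, chain="A", resseq=i + 1, x=x, y=y, z=z))
        fh.write("TER\nEND\n")


# ---------------------------------------------------------------------------
# synthetic circular permutation


def syncp(trace: CaTrace, k: int) -> SynCPRecord:
    """k-synCP: reorder 𝒫 = (p_1..p_n) to (p_{k+1}..p_n, p_1..p_k).

    Coordinates are untouched — only the chain order (and hence the termini)
    changes.  k = 0 is the identity; valid cuts are 0 <= k < n.
    """
    n = len(trace)
    if not 0 <= k < n:
        raise ValueError(f"cut offset k={k} out of range [0, {n})")
    child = replace(
        trace,
        id=f"{trace.id}~cp{k}",
        coords=np.roll(trace.coords, -k, axis=0),
    )
    return SynCPRecord(parent_id=trace.id, k=k, child=child)


def enumerate_syncps(trace: CaTrace) -> Iterator[SynCPRecord]:
    """All n circular permutations of a length-n trace, k = 0..n-1."""
    for k in range(len(trace)):
        yield syncp(trace, k)


# ---------------------------------------------------------------------------
# synthetic structure generation


def _helix(length: int) -> np.ndarray:
    theta = np.deg2rad(HELIX_TURN_DEG) * np.arange(length)
    return np.column_stack(
        [
            HELIX_RADIUS * np.cos(theta),
            HELIX_RADIUS * np.sin(theta),
            HELIX_RISE * np.arange(length, dtype=float),
        ]
    )


def _strand(length: int) -> np.ndarray:
    # zig-zag amplitude chosen so consecutive Cα sit CA_CA apart
    amp = math.sqrt(CA_CA**2 - STRAND_RISE**2) / 2.0
    return np.column_stack(
        [
            amp * np.where(np.arange(length) % 2 == 0, 1.0, -1.0),
            np.zeros(length),
            STRAND_RISE * np.arange(length, dtype=float),
        ]
    )


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation via QR of a Gaussian matrix."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1.0
    return q


def _append_element(points: list[np.ndarray], element: np.ndarray, rng: np.random.Generator) -> None:
    """Rotate a local-frame element randomly and chain it ~3.8 Å past the tail."""
    rot = _random_rotation(rng)
    elem = element @ rot.T
    elem -= elem[0]
    if points:
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        start = points[-1] + CA_CA * direction
    else:
        start = np.zeros(3)
    for p in elem + start:
        points.append(p)


def _family_template(length: int, rng: np.random.Generator) -> np.ndarray:
    """One rigid backbone: random helix/strand/loop composition of `length` residues."""
    points: list[np.ndarray] = []
    while len(points) < length:
        kind = rng.choice(["helix", "strand", "loop"], p=[0.45, 0.35, 0.2])
        if kind == "helix":
            elem = _helix(int(rng.integers(6, 16)))
        elif kind == "strand":
            elem = _strand(int(rng.integers(4, 9)))
        else:  # loop: short persistent random walk at Cα spacing
            m = int(rng.integers(2, 6))
            steps = rng.normal(size=(m, 3))
            steps = np.cumsum(
                CA_CA * steps / np.linalg.norm(steps, axis=1, keepdims=True), axis=0
            )
            elem = np.vstack([np.zeros(3), steps])
        _append_element(points, elem, rng)
    return np.array(points[:length])


def _jittered_member(
    template: np.ndarray, noise_sd: float, rng: np.random.Generator
) -> np.ndarray:
    coords = template + rng.normal(scale=noise_sd, size=template.shape) if noise_sd > 0 else template.copy()
    rot = _random_rotation(rng)
    shift = rng.uniform(-50.0, 50.0, size=3)
    return coords @ rot.T + shift


def make_synthetic_family(
    n_members: int,
    length: int,
    noise_sd: float,
    seed: int,
    family_label: str | None = None,
    id_prefix: str | None = None,
) -> list[CaTrace]:
    """Generate one labeled family: a rigid template plus noisy rigid-moved members.

    The template concatenates idealized helices, strands and loop segments with
    composition drawn from the seeded generator; each member adds i.i.d.
    Gaussian coordinate noise (``noise_sd`` Å) and an independent random rigid
    motion.  Deterministic for a fixed seed.
    """
    if n_members < 1:
        raise ValueError("n_members must be >= 1")
    if length < 20:
        raise ValueError("length must be >= 20")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    template = _family_template(length, rng)
    label = family_label if family_label is not None else f"x.{seed}.1.1"
    prefix = id_prefix if id_prefix is not None else f"fam{seed}"
    return [
        CaTrace(
            id=f"{prefix}_m{i}",
            coords=_jittered_member(template, noise_sd, rng),
            labels=label,
            source="synthetic",
        )
        for i in range(n_members)
    ]


def make_cp_benchmark(
    n_families: int,
    members: int,
    length: int,
    noise_sd: float,
    seed: int,
) -> SyntheticBenchmark:
    """Families with one planted circular permutant each, plus cross-family decoys.

    In every family the last member is replaced by a synCP of the first member
    (cut drawn uniformly from [length/4, 3·length/4]) plus fresh coordinate
    noise, so each planted pair shares a coordinate multiset up to that noise.
    Decoy pairs join first members of consecutive families (guaranteed non-CP).
    """
    if n_families < 1 or members < 2 or length < 20 or noise_sd < 0:
        raise ValueError("need n_families >= 1, members >= 2, length >= 20, noise_sd >= 0")
    rng = np.random.default_rng(seed)
    traces: list[CaTrace] = []
    cp_pairs: list[tuple[str, str]] = []
    for f in range(n_families):
        fam_seed = int(rng.integers(0, 2**31 - 1))
        fam = make_synthetic_family(
            members,
            length,
            noise_sd,
            fam_seed,
            family_label=f"x.{f + 1}.1.1",
            id_prefix=f"bm{f}",
        )
        k = int(rng.integers(length // 4, 3 * length // 4 + 1))
        parent = fam[0]
        permuted = syncp(parent, k).child.coords
        if noise_sd > 0:
            permuted = permuted + rng.normal(scale=noise_sd, size=permuted.shape)
        cp_member = CaTrace(
            id=f"bm{f}_cp",
            coords=permuted,
            labels=parent.labels,
            source=f"syncp(k={k}) of {parent.id}",
        )
        fam = fam[:-1] + [cp_member]
        traces.extend(fam)
        cp_pairs.append((parent.id, cp_member.id))
    decoy_pairs = [(f"bm{f}_m0", f"bm{f + 1}_m0") for f in range(n_families - 1)]
    return SyntheticBenchmark(traces=traces, cp_pairs=cp_pairs, decoy_pairs=decoy_pairs, seed=seed)
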