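"""Synthetic labelled fragment generation.

Stands in for a real genome corpus so the whole pipeline is trainable
and testable offline. Each class (phage / chromosome / plasmid) gets a
seeded order-k Markov "genome" generator; fragments are drawn with
uniform lengths over a group's closed range and uniform start positions,
optionally corrupted by independent substitution and insertion/deletion
error channels (events split 50/50 between insertion and deletion, as in
the 1% error regime used for robustness testing).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .encoding import GROUP_LENGTH_RANGES
from .fragments import CLASSES, DnaFragment

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_TO_INT = {"A": 0, "C": 1, "G": 2, "T": 3}

#: Per-class, per-group fragment count of the full-scale training corpus
#: (groups A-C); desk-scale runs use far fewer. With 3 classes and 3
#: trained groups this implies a 2,700,000-fragment corpus.
FULL_SCALE_FRAGMENTS_PER_CLASS_PER_GROUP = 300_000
TRAINED_GROUPS = ("A", "B", "C")


@dataclass
class ClassGenomeModel:
    """Order-k Markov generator over {A,C,G,T} for one class."""

    label: str
    transitions: np.ndarray  # shape (4**order, 4), rows sum to 1
    order: int = 3

    def __post_init__(self) -> None:
        self.transitions = np.asarray(self.transitions, dtype=np.float64)
        expected = (4 ** self.order, 4)
        if self.transitions.shape != expected:
            raise ValueError(
                f"transition matrix must have shape {expected}, "
                f"got {self.transitions.shape}")
        if (self.transitions < 0).any() or not np.allclose(
                self.transitions.sum(axis=1), 1.0):
            raise ValueError("transition rows must be non-negative and sum to 1")


def make_class_models(order: int = 3, concentration: float = 0.5,
                      seed: int = 0) -> dict[str, ClassGenomeModel]:
    """Three pairwise-distinct Markov models, one per class.

    Rows are drawn from a symmetric Dirichlet; small ``concentration``
    gives strongly skewed rows and therefore easily separable classes.
    """
    rng = np.random.default_rng(seed)
    models = {}
    for label in CLASSES:
        trans = rng.dirichlet([concentration] * 4, size=4 ** order)
        models[label] = ClassGenomeModel(label=label, transitions=trans,
                                         order=order)
    floor = min(
        np.abs(models[a].transitions - models[b].transitions).sum() / 2
        for a in CLASSES for b in CLASSES if a < b)
    if floor == 0:
        raise ValueError("class models are not pairwise distinct")
    return models


def synth_genome(model: ClassGenomeModel, length: int,
                 seed: int | np.random.Generator = 0) -> str:
    """Sample a genome of the given length from the Markov model."""
    if length < model.order + 1:
        raise ValueError(f"genome length {length} too short for order "
                         f"{model.order}")
    rng = np.random.default_rng(seed)
    order = model.order
    cum = model.transitions.cumsum(axis=1)
    out = np.empty(length, dtype=np.int64)
    out[:order] = rng.integers(0, 4, size=order)
    state = 0
    for i in range(order):
        state = state * 4 + out[i]
    mask = 4 ** order
    u = rng.random(length)
    for i in range(order, length):
        nxt = int(np.searchsorted(cum[state], u[i], side="right"))
        nxt = min(nxt, 3)
        out[i] = nxt
        state = (state * 4 + nxt) % mask
    return _BASES[out].tobytes().decode("ascii")


@dataclass
class FragmentSet:
    fragments: list[DnaFragment]
    group: str
    p_sub: float = 0.0
    p_indel: float = 0.0
    meta: dict = field(default_factory=dict)

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for frag in self.fragments:
                label = f" label={frag.label}" if frag.label else ""
                fh.write(f">{frag.id}{label} group={self.group}\n")
                for lo in range(0, len(frag.seq), 70):
                    fh.write(frag.seq[lo:lo + 70] + "\n")

    def write_truth_table(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("id\tlabel\tlength\tgroup\tp_sub\tp_indel\n")
            for frag in self.fragments:
                fh.write(f"{frag.id}\t{frag.label}\t{len(frag)}\t"
                         f"{self.group}\t{self.p_sub}\t{self.p_indel}\n")


def draw_fragments(genome: str, group: str, n: int,
                   seed: int | np.random.Generator = 0,
                   label: str | None = None,
                   id_prefix: str = "frag") -> FragmentSet:
    """Draw n exact fragments with i.i.d. uniform lengths over the
    group's closed range and uniform start positions."""
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    lo, hi = GROUP_LENGTH_RANGES[group]
    if len(genome) <= hi:
        raise ValueError(
            f"genome length {len(genome)} must exceed group {group} "
            f"maximum {hi}")
    rng = np.random.default_rng(seed)
    lengths = rng.integers(lo, hi + 1, size=n)
    starts = rng.integers(0, len(genome) - lengths + 1)
    frags = [
        DnaFragment(id=f"{id_prefix}_{i:06d}",
                    seq=genome[s:s + l], label=label)
        for i, (s, l) in enumerate(zip(starts, lengths))
    ]
    return FragmentSet(fragments=frags, group=group)


def apply_substitutions(seq: str, p_sub: float,
                        seed: int | np.random.Generator = 0) -> str:
    """Independently replace each base by a uniformly chosen different
    base with probability p_sub; length preserved."""
    if not 0 <= p_sub <= 1:
        raise ValueError(f"p_sub must be in [0, 1], got {p_sub}")
    if p_sub == 0:
        return seq
    rng = np.random.default_rng(seed)
    arr = np.array([_BASE_TO_INT.get(b, -1) for b in seq], dtype=np.int64)
    hit = rng.random(arr.shape[0]) < p_sub
    hit &= arr >= 0  # ambiguous bases left untouched
    # shift by 1..3 mod 4 guarantees a different base
    arr[hit] = (arr[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
    out = _BASES[np.clip(arr, 0, 3)]
    out[arr < 0] = ord("N")
    return out.tobytes().decode("ascii")


def apply_indels(seq: str, p_indel: float,
                 seed: int | np.random.Generator = 0,
                 insertion_fraction: float = 0.5) -> str:
    """Each position independently triggers an event with probability
    p_indel; the event inserts a random base before the position or
    deletes the position (50/50 by default)."""
    if not 0 <= p_indel <= 1:
        raise ValueError(f"p_indel must be in [0, 1], got {p_indel}")
    if p_indel == 0:
        return seq
    rng = np.random.default_rng(seed)
    n = len(seq)
    events = rng.random(n) < p_indel
    is_insert = rng.random(n) < insertion_fraction
    pieces = []
    cursor = 0
    for pos in np.nonzero(events)[0]:
        pieces.append(seq[cursor:pos])
        if is_insert[pos]:
            pieces.append(chr(_BASES[rng.integers(0, 4)]) + seq[pos])
        cursor = pos + 1
    pieces.append(seq[cursor:])
    return "".join(pieces)


def simulate_dataset(group: str, n_per_class: int, seed: int = 0,
                     genome_length: int = 200_000, order: int = 3,
                     concentration: float = 0.5, p_sub: float = 0.0,
                     p_indel: float = 0.0) -> FragmentSet:
    """End-to-end labelled dataset: one synthetic genome per class,
    balanced exact fragments, optional error channels.

    Bit-reproducible for a fixed (seed, configuration) pair.
    """
    models = make_class_models(order=order, concentration=concentration,
                               seed=seed)
    rng = np.random.default_rng(seed + 1)
    all_frags: list[DnaFragment] = []
    for label in CLASSES:
        genome = synth_genome(models[label], genome_length, rng)
        fset = draw_fragments(genome, group, n_per_class, rng, label=label,
                              id_prefix=f"{label[:4]}")
        for frag in fset.fragments:
            seq = frag.seq
            if p_sub > 0:
                seq = apply_substitutions(seq, p_sub, rng)
            if p_indel > 0:
                seq = apply_indels(seq, p_indel, rng)
            frag.seq = seq
        all_frags.extend(fset.fragments)
    return FragmentSet(fragments=all_frags, group=group, p_sub=p_sub,
                       p_indel=p_indel,
                       meta={"seed": seed, "order": order,
                             "concentration": concentration,
                             "genome_length": genome_length})


# ---- calibration helper --------------------------------------------------

def kmer_centroid_accuracy(train: list[DnaFragment], test: list[DnaFragment],
                           k: int = 3) -> float:
    """Accuracy of a naive k-mer-frequency nearest-centroid classifier.

    Used to calibrate how separable a generated dataset is, independent
    of the neural network.
    """
    def freqs(frag: DnaFragment) -> np.ndarray:
        arr = np.array([_BASE_TO_INT.get(b, -1) for b in frag.seq])
        valid = np.lib.stride_tricks.sliding_window_view(arr, k)
        ok = (valid >= 0).all(axis=1)
        idx = np.zeros(valid.shape[0], dtype=np.int64)
        for j in range(k):
            idx = idx * 4 + np.clip(valid[:, j], 0, 3)
        counts = np.bincount(idx[ok], minlength=4 ** k).astype(np.float64)
        total = counts.sum()
        return counts / total if total else counts

    centroids = {}
    for label in CLASSES:
        rows = [freqs(f) for f in train if f.label == label]
        if not rows:
            raise ValueError(f"no training fragments for class {label}")
        centroids[label] = np.mean(rows, axis=0)
    correct = 0
    for frag in test:
        vec = freqs(frag)
        pred = min(centroids, key=lambda c: np.sum((vec - centroids[c]) ** 2))
        correct += pred == frag.label
    return correct / len(test)
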