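"""Build, train, persist, and run the dual-path group classifiers.

One model is trained per fragment-length group (A: up to 400 bp,
B: up to 800 bp, C: up to 1,200 bp). Each path stacks three 1D
convolutions (64 kernels of length 6, then 128 and 256 kernels of
length 3) with max pooling of length 3 and batchnorm+dropout blocks
between them, ends in global average pooling, and the two 256-vectors
are concatenated and sent through a 512-node dense layer into a 3-way
softmax. Training uses Adam and categorical cross-entropy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .encoding import GROUP_MAX_LEN, base_index_track, codon_index_track
from .fragments import CLASS_TO_INDEX, CLASSES, DnaFragment, ScoreTriple
from .nn import (
    Adam,
    BatchNorm,
    BiPathNetwork,
    Conv1D,
    Dense,
    Dropout,
    GlobalAvgPool,
    MaxPool1D,
    OneHotConv1D,
    ReLU,
)

# printed layer hyperparameters, shared by both paths
CONV_KERNELS = (64, 128, 256)
CONV_KERNEL_LENGTHS = (6, 3, 3)
POOL_LENGTH = 3
PATH_OUTPUT_WIDTH = 256  # global average over 256 feature maps


@dataclass
class ArchitectureSpec:
    """Declarative description of one group's network."""

    group: str
    dropout_rate: float = 0.3
    paths: str = "both"  # "both" | "base" | "codon" (ablation variants)
    seed: int = 0

    @property
    def max_len(self) -> int:
        return GROUP_MAX_LEN[self.group]

    @property
    def input_rows(self) -> int:
        return 2 * self.max_len

    @property
    def merged_width(self) -> int:
        return PATH_OUTPUT_WIDTH * (2 if self.paths == "both" else 1)

    def to_dict(self) -> dict:
        return {"group": self.group, "dropout_rate": self.dropout_rate,
                "paths": self.paths, "seed": self.seed}


def _conv_path(c_in: int, dropout_rate: float, rng: np.random.Generator):
    layers = []
    c_prev = c_in
    for i, (kernels, klen) in enumerate(zip(CONV_KERNELS, CONV_KERNEL_LENGTHS)):
        # first convolution sees a one-hot input and runs sparse
        conv_cls = OneHotConv1D if i == 0 else Conv1D
        layers += [conv_cls(c_prev, kernels, klen, rng), ReLU()]
        if i < len(CONV_KERNELS) - 1:
            layers += [MaxPool1D(POOL_LENGTH), BatchNorm(kernels),
                       Dropout(dropout_rate, rng)]
        c_prev = kernels
    layers.append(GlobalAvgPool())
    return layers


@dataclass
class GroupModel:
    """A network for one length group plus its training metadata."""

    spec: ArchitectureSpec
    network: BiPathNetwork
    metadata: dict = field(default_factory=dict)

    def predict_batch(self, fragments: list[DnaFragment | str],
                      batch_size: int = 256) -> list[ScoreTriple]:
        """Score fragments; lengths must not exceed the group maximum."""
        seqs = [f.seq if isinstance(f, DnaFragment) else f for f in fragments]
        probs = self.predict_proba(seqs, batch_size=batch_size)
        return [ScoreTriple(*map(float, row)) for row in probs]

    def predict_proba(self, seqs: list[str],
                      batch_size: int = 256) -> np.ndarray:
        out = np.empty((len(seqs), 3), dtype=np.float64)
        for lo in range(0, len(seqs), batch_size):
            chunk = seqs[lo:lo + batch_size]
            bt, ct = _index_tracks(chunk, self.spec.group)
            out[lo:lo + len(chunk)] = self.network.predict_proba(bt, ct)
        return out

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        arrays = {}
        for name, layer, key in self.network.parameters():
            arrays[name] = layer.params[key]
        for prefix, layers in (("base", self.network.base_path),
                               ("codon", self.network.codon_path)):
            for i, layer in enumerate(layers):
                if isinstance(layer, BatchNorm):
                    arrays[f"{prefix}.{i}.running_mean"] = layer.running_mean
                    arrays[f"{prefix}.{i}.running_var"] = layer.running_var
        np.savez(path / "weights.npz", **arrays)
        manifest = {
            "architecture": self.spec.to_dict(),
            "max_len": self.spec.max_len,
            "class_order": list(CLASSES),
            "metadata": self.metadata,
        }
        (path / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "GroupModel":
        path = Path(path)
        manifest = json.loads((path / "manifest.json").read_text())
        if manifest["class_order"] != list(CLASSES):
            raise ValueError("model class order does not match this package")
        spec = ArchitectureSpec(**manifest["architecture"])
        model = build_architecture(**manifest["architecture"])
        model.metadata = manifest["metadata"]
        with np.load(path / "weights.npz") as data:
            for name, layer, key in model.network.parameters():
                layer.params[key] = data[name].copy()
            for prefix, layers in (("base", model.network.base_path),
                                   ("codon", model.network.codon_path)):
                for i, layer in enumerate(layers):
                    if isinstance(layer, BatchNorm):
                        layer.running_mean = data[f"{prefix}.{i}.running_mean"].copy()
                        layer.running_var = data[f"{prefix}.{i}.running_var"].copy()
        return model


def build_architecture(group: str, dropout_rate: float = 0.3, seed: int = 0,
                       paths: str = "both") -> GroupModel:
    """Construct a seeded, untrained model for one length group.

    ``paths`` selects the full dual-path network or a single-path
    ablation variant ("base" or "codon").
    """
    if group not in GROUP_MAX_LEN:
        raise ValueError(f"unknown group {group!r}; expected one of A, B, C")
    if paths not in ("both", "base", "codon"):
        raise ValueError(f"paths must be 'both', 'base' or 'codon', got {paths!r}")
    spec = ArchitectureSpec(group=group, dropout_rate=dropout_rate,
                            paths=paths, seed=seed)
    rng = np.random.default_rng(seed)
    base = _conv_path(4, dropout_rate, rng) if paths in ("both", "base") else []
    codon = _conv_path(64, dropout_rate, rng) if paths in ("both", "codon") else []
    width = spec.merged_width
    head = [Dense(width, width, rng), ReLU(), Dense(width, 3, rng)]
    network = BiPathNetwork(base, codon, head)
    return GroupModel(spec=spec, network=network,
                      metadata={"seed": seed, "trained": False})


def train(model: GroupModel, fragments: list[DnaFragment], epochs: int = 20,
          batch_size: int = 128, seed: int = 0, learning_rate: float = 1e-3,
          verbose: bool = False) -> GroupModel:
    """Train in place on labelled fragments; returns the model.

    Requires all three classes to be present and every fragment to fit
    the model's group. Reproducible for a fixed (model seed, train seed)
    pair. Appends per-epoch mean loss to ``metadata['loss_history']``.
    """
    max_len = model.spec.max_len
    labels_seen = set()
    for frag in fragments:
        if frag.label is None:
            raise ValueError(f"fragment {frag.id!r} has no label")
        if not 3 <= len(frag) <= max_len:
            raise ValueError(
                f"fragment {frag.id!r} has length {len(frag)}, outside the "
                f"[3, {max_len}] range of group {model.spec.group}")
        labels_seen.add(frag.label)
    missing = set(CLASSES) - labels_seen
    if missing:
        raise ValueError(f"no training fragments for class(es): {sorted(missing)}")

    rng = np.random.default_rng(seed)
    y = np.array([CLASS_TO_INDEX[f.label] for f in fragments])
    y_onehot = np.eye(3, dtype=np.float32)[y]
    # index tracks are precomputed once and sliced per minibatch
    bt, ct = _index_tracks([f.seq for f in fragments], model.spec.group)

    optimizer = Adam(lr=learning_rate)
    history = model.metadata.setdefault("loss_history", [])
    n = len(fragments)
    for epoch in range(epochs):
        order = rng.permutation(n)
        losses = []
        for lo in range(0, n, batch_size):
            idx = order[lo:lo + batch_size]
            losses.append(model.network.train_step(
                bt[idx], ct[idx], y_onehot[idx], optimizer))
        history.append(float(np.mean(losses)))
        if verbose:
            print(f"epoch {epoch + 1}/{epochs}: loss {history[-1]:.4f}")
    model.metadata.update(trained=True, epochs=epochs, train_seed=seed,
                          batch_size=batch_size, learning_rate=learning_rate)
    return model


def architecture_summary(model: GroupModel) -> dict:
    """Introspect the live layers for auditing against the printed design."""

    def describe(path):
        out = []
        for layer in path:
            entry = {"type": type(layer).__name__}
            if isinstance(layer, Conv1D):
                entry.update(kernels=layer.c_out, kernel_length=layer.kernel)
            elif isinstance(layer, MaxPool1D):
                entry.update(pool_length=layer.pool)
            elif isinstance(layer, Dropout):
                entry.update(rate=layer.rate)
            elif isinstance(layer, Dense):
                entry.update(units=layer.params["W"].shape[1])
            out.append(entry)
        return out

    return {
        "group": model.spec.group,
        "input_shapes": {"boh": (model.spec.input_rows, 4),
                         "coh": (model.spec.input_rows, 64)},
        "base_path": describe(model.network.base_path),
        "codon_path": describe(model.network.codon_path),
        "head": describe(model.network.head),
        "softmax_units": 3,
    }


# ---- batched encoding helpers -------------------------------------------

def _index_tracks(seqs: list[str], group: str) -> tuple[np.ndarray, np.ndarray]:
    """Padded one-hot column indices for a batch; -1 marks zero rows."""
    rows = 2 * GROUP_MAX_LEN[group]
    n = len(seqs)
    bt = np.full((n, rows), -1, dtype=np.int16)
    ct = np.full((n, rows), -1, dtype=np.int16)
    for i, seq in enumerate(seqs):
        if len(seq) > GROUP_MAX_LEN[group]:
            raise ValueError(
                f"sequence of length {len(seq)} exceeds group {group} "
                f"maximum {GROUP_MAX_LEN[group]}")
        b = base_index_track(seq)
        bt[i, : b.shape[0]] = b
        if len(seq) >= 3:
            c = codon_index_track(seq)
            ct[i, : c.shape[0]] = c
    return bt, ct


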