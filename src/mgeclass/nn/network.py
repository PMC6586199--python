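"""Dual-path network container, softmax cross-entropy loss, and Adam."""

from __future__ import annotations

import numpy as np

from .layers import Concatenate, Layer


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class BiPathNetwork:
    """Two convolutional stacks whose pooled outputs are concatenated and
    passed through a dense head ending in 3-way logits.

    ``base_path`` consumes the base one-hot input, ``codon_path`` the
    codon one-hot input; ``head`` maps the merged vector to class logits
    (softmax is applied by the loss / prediction helpers). Either path
    may be empty to obtain a single-path ablation model.
    """

    def __init__(self, base_path: list[Layer], codon_path: list[Layer],
                 head: list[Layer]) -> None:
        if not base_path and not codon_path:
            raise ValueError("at least one path is required")
        self.base_path = base_path
        self.codon_path = codon_path
        self.head = head
        self.merge = Concatenate()

    # ---- plumbing -------------------------------------------------------

    def layers(self) -> list[Layer]:
        return [*self.base_path, *self.codon_path, *self.head]

    def parameters(self) -> list[tuple[str, Layer, str]]:
        """Stable (name, layer, key) triples for optimizer and persistence."""
        out = []
        for path_name, path in (("base", self.base_path),
                                ("codon", self.codon_path),
                                ("head", self.head)):
            for i, layer in enumerate(path):
                for key in layer.params:
                    out.append((f"{path_name}.{i}.{key}", layer, key))
        return out

    # ---- forward / backward ---------------------------------------------

    @staticmethod
    def _run(path: list[Layer], x: np.ndarray, training: bool) -> np.ndarray:
        for layer in path:
            x = layer.forward(x, training)
        return x

    def forward(self, boh: np.ndarray, coh: np.ndarray,
                training: bool) -> np.ndarray:
        """Class logits of shape (n, 3)."""
        if self.base_path and self.codon_path:
            merged = self.merge.forward_pair(
                self._run(self.base_path, boh, training),
                self._run(self.codon_path, coh, training))
        elif self.base_path:
            merged = self._run(self.base_path, boh, training)
        else:
            merged = self._run(self.codon_path, coh, training)
        return self._run(self.head, merged, training)

    def backward(self, dlogits: np.ndarray) -> None:
        grad = dlogits
        for layer in reversed(self.head):
            grad = layer.backward(grad)
        if self.base_path and self.codon_path:
            grad_b, grad_c = self.merge.backward(grad)
        elif self.base_path:
            grad_b, grad_c = grad, None
        else:
            grad_b, grad_c = None, grad
        if self.base_path:
            g = grad_b
            for layer in reversed(self.base_path):
                g = layer.backward(g)
        if self.codon_path:
            g = grad_c
            for layer in reversed(self.codon_path):
                g = layer.backward(g)

    def predict_proba(self, boh: np.ndarray, coh: np.ndarray) -> np.ndarray:
        return softmax(self.forward(boh, coh, training=False))

    def train_step(self, boh: np.ndarray, coh: np.ndarray,
                   y_onehot: np.ndarray, optimizer: "Adam") -> float:
        """One minibatch update; returns the batch cross-entropy."""
        logits = self.forward(boh, coh, training=True)
        probs = softmax(logits)
        n = probs.shape[0]
        eps = np.finfo(probs.dtype).tiny
        loss = float(-(y_onehot * np.log(probs + eps)).sum() / n)
        self.backward((probs - y_onehot) / n)
        optimizer.step(self)
        return loss


class Adam:
    """Adam optimizer with the conventional defaults."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m: dict[str, np.ndarray] = {}
        self._v: dict[str, np.ndarray] = {}

    def step(self, net: BiPathNetwork) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1 ** self.t
        bias2 = 1 - b2 ** self.t
        for name, layer, key in net.parameters():
            g = layer.grads[key]
            m = self._m.setdefault(name, np.zeros_like(g))
            v = self._v.setdefault(name, np.zeros_like(g))
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            layer.params[key] -= (self.lr * (m / bias1)
                                  / (np.sqrt(v / bias2) + self.eps))
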