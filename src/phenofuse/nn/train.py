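"""Loss and optimizer for head training / small-model fine-tuning."""

from __future__ import annotations

import numpy as np


def cross_entropy_with_logits(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy and its gradient w.r.t. logits.

    ``labels`` are integer class indices. Uses the log-sum-exp trick.
    """
    n = logits.shape[0]
    z = logits - logits.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    loss = -logp[np.arange(n), labels].mean()
    grad = np.exp(logp)
    grad[np.arange(n), labels] -= 1.0
    return float(loss), (grad / n).astype(np.float32)


class SGD:
    """Plain SGD with momentum over a network's unfrozen parameters."""

    def __init__(self, network, learning_rate: float, momentum: float = 0.9):
        self.network = network
        self.lr = learning_rate
        self.momentum = momentum
        self._velocity: dict[str, np.ndarray] = {}

    def step(self):
        for node_name, pname, layer in self.network.parameters():
            if layer.frozen or pname not in layer.grads:
                continue
            key = f"{node_name}.{pname}"
            v = self._velocity.get(key)
            g = layer.grads[pname]
            v = self.momentum * v - self.lr * g if v is not None else -self.lr * g
            self._velocity[key] = v
            layer.params[pname] += v.astype(np.float32)
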