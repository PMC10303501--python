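"""Named-node computation graph.

A :class:`Network` is a topologically ordered list of :class:`Node`; each
node applies one layer to the outputs of named predecessor nodes. Feature
extraction captures any node's output by name; reverse-mode gradients run
from any seeded node back towards the input, optionally stopping at a
target node (Grad-CAM needs the gradient at an interior conv layer).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import ConfigError
from .layers import Layer

INPUT = "input"


@dataclass
class Node:
    name: str
    layer: Layer
    inputs: list[str] = field(default_factory=lambda: [INPUT])


class Network:
    def __init__(self, nodes: list[Node]):
        self.nodes = nodes
        self._by_name = {}
        known = {INPUT}
        for node in nodes:
            if node.name in self._by_name or node.name == INPUT:
                raise ConfigError(f"duplicate node name {node.name!r}")
            for inp in node.inputs:
                if inp not in known:
                    raise ConfigError(f"node {node.name!r} references unknown input {inp!r}")
            self._by_name[node.name] = node
            known.add(node.name)
        self.output_name = nodes[-1].name

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def forward(self, x: np.ndarray, capture: set[str] | None = None,
                retain: bool = False) -> dict[str, np.ndarray]:
        """Run the graph on a batch; return ``{node_name: output}``.

        With ``capture=None`` only the final output is kept; otherwise the
        named nodes are kept as well. ``retain=True`` stores the per-layer
        caches needed by :meth:`backward`.
        """
        if capture:
            missing = set(capture) - set(self._by_name)
            if missing:
                raise ConfigError(f"unknown capture nodes: {sorted(missing)}")
        acts: dict[str, np.ndarray] = {INPUT: np.asarray(x, dtype=np.float32)}
        # simple liveness: free an activation once no later node consumes it
        last_use: dict[str, int] = {}
        for i, node in enumerate(self.nodes):
            for inp in node.inputs:
                last_use[inp] = i
        out: dict[str, np.ndarray] = {}
        for i, node in enumerate(self.nodes):
            acts[node.name] = node.layer.forward(*(acts[n] for n in node.inputs),
                                                 retain=retain)
            if capture and node.name in capture:
                out[node.name] = acts[node.name]
            if not retain:
                for inp in node.inputs:
                    if last_use.get(inp) == i and inp != INPUT and inp not in (capture or ()):
                        acts.pop(inp, None)
        out[self.output_name] = acts[self.output_name]
        return out

    def backward(self, seed_grads: dict[str, np.ndarray],
                 until: str | None = None) -> dict[str, np.ndarray]:
        """Back-propagate from seeded node outputs; return per-node output grads.

        Must follow a ``forward(..., retain=True)``. If ``until`` is given,
        traversal stops once that node's output gradient is complete (its
        own layer backward is not run).
        """
        grads: dict[str, np.ndarray] = {k: np.asarray(v, dtype=np.float32)
                                        for k, v in seed_grads.items()}
        for node in reversed(self.nodes):
            if node.name == until:
                break
            g = grads.get(node.name)
            if g is None:
                continue
            gins = node.layer.backward(g)
            for inp, gi in zip(node.inputs, gins):
                if inp in grads:
                    grads[inp] = grads[inp] + gi
                else:
                    grads[inp] = gi
        return grads

    def parameters(self):
        """Yield (node_name, param_name, layer) for every trainable tensor."""
        for node in self.nodes:
            for pname in node.layer.params:
                yield node.name, pname, node.layer

    def zero_grad(self):
        for node in self.nodes:
            node.layer.zero_grad()

    def state_snapshot(self) -> dict[str, np.ndarray]:
        """Copies of all parameter tensors, keyed ``node.param``."""
        return {f"{n}.{p}": layer.params[p].copy() for n, p, layer in self.parameters()}
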