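"""Dense message-passing layers for complete weighted vascular graphs.

Because every vascular graph is complete with a fixed node count, message
passing is implemented densely: a batch of graphs is a feature tensor of
shape (batch, nodes, channels) plus a (batch, nodes, nodes) edge-weight
matrix.  Two mechanisms are provided:

* :class:`GINLayer` — multilayer-perceptron aggregation, with neighbor
  messages scaled multiplicatively by the (row-normalized) edge weights;
* :class:`GATLayer` — multi-head attention over the complete graph, with
  the edge weight entering each head's attention logits as a scalar edge
  feature through a learned coefficient.

The classifier stack interleaves the two with residual connections,
followed by global mean pooling and a two-layer perceptron head.
"""

from __future__ import annotations

from typing import Dict, List, Sequence

import numpy as np

from .autodiff import Tensor

#: Network compute dtype.  Single precision keeps the dense per-graph
#: attention tensors small enough for the allocator to recycle, which
#: dominates wall time on complete 205-node graphs.
DTYPE = np.float32


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int, *shape: int) -> Tensor:
    """Glorot/Xavier uniform initialization."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    size = shape if shape else (fan_in, fan_out)
    return Tensor(rng.uniform(-limit, limit, size=size).astype(DTYPE), requires_grad=True)


class Module:
    """Base class: recursively collects trainable parameters."""

    def parameters(self) -> List[Tensor]:
        params: List[Tensor] = []
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def state(self) -> List[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state(self, state: Sequence[np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError(
                f"state has {len(state)} arrays but the model has {len(params)} parameters"
            )
        for p, arr in zip(params, state):
            if p.data.shape != arr.shape:
                raise ValueError(f"parameter shape mismatch: {p.data.shape} vs {arr.shape}")
            p.data = np.asarray(arr, dtype=p.data.dtype).copy()


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.weight = glorot(rng, in_dim, out_dim)
        self.bias = Tensor(np.zeros(out_dim, dtype=DTYPE), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class MLP(Module):
    """Two-layer perceptron with an internal ReLU."""

    def __init__(self, in_dim: int, hidden: int, out_dim: int, rng: np.random.Generator):
        self.fc1 = Linear(in_dim, hidden, rng)
        self.fc2 = Linear(hidden, out_dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())


class GINLayer(Module):
    """Graph-isomorphism-style aggregation on a dense weighted graph.

    ``h' = MLP((1 + eps) * h + A_hat @ h)`` where ``A_hat`` is the
    edge-weight matrix (row-normalized upstream) and ``eps`` a trainable
    scalar.  Neighbor messages are thus weighted multiplicatively by the
    edge weight.
    """

    def __init__(self, dim: int, rng: np.random.Generator):
        self.eps = Tensor(np.zeros((), dtype=DTYPE), requires_grad=True)
        self.mlp = MLP(dim, dim, dim, rng)

    def __call__(self, h: Tensor, adj: Tensor) -> Tensor:
        agg = h * (self.eps + 1.0) + adj @ h
        return self.mlp(agg)


class GATLayer(Module):
    """Multi-head graph attention over the complete weighted graph.

    Per head, attention logits follow the additive GAT form
    ``leaky_relu(a_src . z_i + a_dst . z_j)`` with the scalar edge weight
    added through a learned per-head coefficient; a softmax over neighbors
    yields the attention, and head outputs are concatenated.

    The (batch, heads, n, n) attention maps dominate both memory traffic
    and allocator pressure, so the whole attention block is implemented as
    one fused autodiff primitive operating in-place on persistent
    per-layer buffers that are reused across steps.
    """

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator,
                 negative_slope: float = 0.2):
        if dim % n_heads != 0:
            raise ValueError(f"hidden dim {dim} not divisible by {n_heads} heads")
        self.n_heads = n_heads
        self.head_dim = dim // n_heads
        self.negative_slope = negative_slope
        self.proj = glorot(rng, dim, dim)
        self.att_src = glorot(rng, self.head_dim, 1, 1, n_heads, 1, self.head_dim)
        self.att_dst = glorot(rng, self.head_dim, 1, 1, n_heads, 1, self.head_dim)
        self.edge_coef = Tensor(np.ones((1, n_heads, 1, 1), dtype=DTYPE), requires_grad=True)
        self._buffers: Dict[tuple, np.ndarray] = {}

    def _buffer(self, name: str, shape, dtype) -> np.ndarray:
        # keyed by shape so alternating batch sizes (train/validation)
        # keep their own warm buffers instead of reallocating each epoch
        key = (name, tuple(shape), np.dtype(dtype).str)
        buf = self._buffers.get(key)
        if buf is None:
            buf = np.empty(shape, dtype=dtype)
            self._buffers[key] = buf
        return buf

    def _attention(self, zh: Tensor, adj: Tensor) -> Tensor:
        """Fused multi-head attention: logits, softmax and mixing in one op."""
        z = zh.data
        batch, n_heads, n, _ = z.shape
        dt = z.dtype
        a = adj.data.reshape(batch, n, n)
        slope = dt.type(self.negative_slope)
        beta = self.edge_coef.data.reshape(n_heads)

        s = (z * self.att_src.data).sum(-1)  # (B, H, n)
        d = (z * self.att_dst.data).sum(-1)
        E = self._buffer("alpha", (batch, n_heads, n, n), dt)
        neg = self._buffer("neg", (batch, n_heads, n, n), np.bool_)
        tmp = self._buffer("tmp", (batch, n, n), dt)

        np.add(s[..., :, None], d[..., None, :], out=E)
        np.less(E, 0, out=neg)
        np.multiply(E, slope, out=E, where=neg)  # leaky ReLU in place
        for h_idx in range(n_heads):  # logits += beta_h * adj
            np.multiply(a, beta[h_idx], out=tmp)
            np.add(E[:, h_idx], tmp, out=E[:, h_idx])
        np.subtract(E, E.max(-1, keepdims=True), out=E)
        np.exp(E, out=E)
        np.divide(E, E.sum(-1, keepdims=True), out=E)  # E is now alpha

        out_data = np.matmul(E, z)

        def backward(g: np.ndarray) -> None:
            galpha = self._buffer("scratch", E.shape, dt)
            np.matmul(g, np.swapaxes(z, -1, -2), out=galpha)
            gzh = np.matmul(np.swapaxes(E, -1, -2), g)
            # softmax backward, in place on galpha
            inner = np.einsum("bhij,bhij->bhi", galpha, E)
            np.subtract(galpha, inner[..., :, None], out=galpha)
            np.multiply(galpha, E, out=galpha)
            if self.edge_coef.requires_grad:
                gbeta = np.einsum("bhij,bij->h", galpha, a)
                self.edge_coef._accumulate(gbeta.reshape(1, n_heads, 1, 1))
            np.multiply(galpha, slope, out=galpha, where=neg)  # leaky backward
            gs = galpha.sum(-1)  # (B, H, n)
            gd = galpha.sum(-2)
            gzh += gs[..., :, None] * self.att_src.data
            gzh += gd[..., :, None] * self.att_dst.data
            if zh.requires_grad:
                zh._accumulate(gzh)
            if self.att_src.requires_grad:
                ga = np.einsum("bhn,bhnd->hd", gs, z).reshape(1, n_heads, 1, self.head_dim)
                self.att_src._accumulate(ga)
            if self.att_dst.requires_grad:
                ga = np.einsum("bhn,bhnd->hd", gd, z).reshape(1, n_heads, 1, self.head_dim)
                self.att_dst._accumulate(ga)

        return Tensor._make(
            out_data, (zh, self.att_src, self.att_dst, self.edge_coef), backward
        )

    def __call__(self, h: Tensor, adj: Tensor) -> Tensor:
        batch, n, dim = h.shape
        z = h @ self.proj  # (B, n, d)
        zh = z.reshape(batch, n, self.n_heads, self.head_dim).permute(0, 2, 1, 3)
        out = self._attention(zh, adj)  # (B, H, n, hd)
        return out.permute(0, 2, 1, 3).reshape(batch, n, dim)


class VGNNetwork(Module):
    """The hybrid graph classifier: [GIN, GAT, GIN, GAT] with residuals.

    Input features are embedded to the hidden width, passed through the
    alternating message-passing stack (each block applied residually),
    mean-pooled over nodes, and classified by a two-layer head with a
    softmax over the five lesion categories.
    """

    def __init__(
        self,
        in_dim: int = 7,
        hidden_dim: int = 64,
        n_heads: int = 4,
        n_layers: int = 4,
        n_classes: int = 5,
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        self.embed = Linear(in_dim, hidden_dim, rng)
        self.layers = [
            GINLayer(hidden_dim, rng) if i % 2 == 0 else GATLayer(hidden_dim, n_heads, rng)
            for i in range(n_layers)
        ]
        self.head = MLP(hidden_dim, hidden_dim, n_classes, rng)
        self.in_dim = in_dim

    def __call__(self, x: Tensor, adj: Tensor) -> Tensor:
        """Class probabilities, shape (batch, n_classes)."""
        if x.shape[-1] != self.in_dim:
            raise ValueError(
                f"expected node feature dimension {self.in_dim}, got {x.shape[-1]}"
            )
        h = self.embed(x).relu()
        for layer in self.layers:
            if isinstance(layer, GINLayer):
                h = h + layer(h, adj)
            else:
                h = h + layer(h, adj).relu()
        pooled = h.mean(axis=1)  # global mean pooling over nodes
        return self.head(pooled).softmax(axis=-1)


def normalize_adjacency(weights: np.ndarray) -> np.ndarray:
    """Row-normalize an edge-weight matrix (random-walk normalization).

    Raw inverse-distance weights span several orders of magnitude
    (up to 1/pixel-pitch); normalizing each row to sum to 1 keeps message
    magnitudes commensurate with the node features while preserving the
    relative inverse-distance weighting.
    """
    w = np.asarray(weights, dtype=np.float64)
    row = w.sum(axis=-1, keepdims=True)
    return w / np.maximum(row, np.finfo(float).tiny)


def batch_graphs(graphs: Sequence, dtype=DTYPE) -> Dict[str, np.ndarray]:
    """Stack equally sized graphs into dense batch arrays."""
    x = np.stack([g.node_features for g in graphs]).astype(dtype)
    adj = np.stack([normalize_adjacency(g.weights) for g in graphs]).astype(dtype)
    return {"x": x, "adj": adj}
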