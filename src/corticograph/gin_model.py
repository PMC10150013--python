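"""Graph Isomorphism Network classifier for channel graphs, in NumPy.

The model is the standard GIN:

    x'_i = MLP((1 + eps) * x_i + sum_{j in N(i)} x_j)

with a learnable eps per layer (init 0) and a two-layer MLP
(Linear -> BatchNorm -> ReLU -> Linear).  Sum aggregation is the injective
choice that gives GIN its Weisfeiler-Lehman discriminative power.  The
graph embedding concatenates a readout from every depth k = 0..K
(sum-pool over nodes, then a linear map per depth), so both early,
better-generalizing features and deep structural features reach the
classifier head.

Training minimizes the sum of two cross-entropies: over the 12 sub-action
classes, and over the 2 movements with movement probabilities obtained by
marginalizing the 12-way softmax within each movement block.  Forward,
backward and the Adam optimizer are implemented directly on arrays; graphs
are mini-batched by stacking nodes and taking a block-diagonal sparse
adjacency.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass

import numpy as np
from scipy import sparse

from .graphs import ChannelGraph, N_SUBACTIONS, decode_label, encode_label
from .synthetic_data import MOVEMENTS

__all__ = [
    "GINConfig",
    "GINClassifier",
    "gin_layer",
    "sum_readout",
    "joint_loss",
    "train",
    "predict_sequence",
]

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


@dataclass
class GINConfig:
    """Architecture and optimization settings.

    Defaults follow the decoding task's stated recipe: 7 input channels,
    64 hidden channels, 2-layer MLPs, Adam at lr 0.005, 300 epochs,
    batch size 128.  ``num_layers`` (the number of GIN iterations K) is a
    free choice; 3 keeps the model desk-scale while still aggregating
    3-hop neighborhoods.
    """

    num_layers: int = 3
    hidden: int = 64
    in_dim: int = 7
    n_classes: int = N_SUBACTIONS
    epochs: int = 300
    batch_size: int = 128
    learning_rate: float = 0.005
    movement_loss_weight: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.num_layers < 1:
            raise ValueError("need at least one GIN iteration")
        if self.hidden < 1:
            raise ValueError("hidden width must be >= 1")


# ---------------------------------------------------------------------------
# functional pieces (also used directly by tests and small experiments)

def gin_layer(node_features, edges, epsilon: float = 0.0, mlp=None):
    """One GIN update on a single graph: h((1+eps) x_i + sum of neighbors).

    ``edges`` is an (E, 2) undirected pair list; both directions contribute
    to the neighbor sum.  ``mlp`` is any callable on the aggregated matrix
    (identity if None).  Isolated nodes keep h((1+eps) x_i).
    """
    x_in = np.asarray(node_features, dtype=float)
    was_1d = x_in.ndim == 1
    x = x_in[:, None] if was_1d else x_in
    edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
    n = x.shape[0]
    if edges.size and (edges.min() < 0 or edges.max() >= n):
        raise ValueError("edge references a nonexistent node")
    agg = (1.0 + epsilon) * x
    for i, j in edges:
        agg[i] = agg[i] + x[j]
        agg[j] = agg[j] + x[i]
    out = agg if mlp is None else mlp(agg)
    return out[:, 0] if was_1d else out


def sum_readout(per_iteration_embeddings, linear_maps=None):
    """Eq-style readout: per-depth sum pooling over nodes, optional linear
    map per depth, concatenation across depths.  Node-permutation invariant."""
    if not per_iteration_embeddings:
        raise ValueError("need embeddings for at least iteration k=0")
    parts = []
    for k, h in enumerate(per_iteration_embeddings):
        h = np.atleast_2d(np.asarray(h, dtype=float))
        pooled = h.sum(axis=0)
        if linear_maps is not None:
            if len(linear_maps) <= k:
                raise ValueError(f"missing linear map for iteration {k}")
            pooled = pooled @ linear_maps[k]
        parts.append(pooled)
    return np.concatenate(parts)


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _movement_blocks(n_classes: int) -> int:
    return n_classes // len(MOVEMENTS)


def joint_loss(logits, subaction_labels, weight: float = 1.0) -> float:
    """Cross-entropy over sub-actions plus weighted cross-entropy over
    movements, the latter via marginalizing the sub-action softmax within
    each movement's block of classes."""
    logits = np.atleast_2d(np.asarray(logits, dtype=float))
    labels = np.atleast_1d(np.asarray(subaction_labels, dtype=np.int64))
    if labels.min() < 0 or labels.max() >= logits.shape[1]:
        raise ValueError("sub-action label out of range")
    b = logits.shape[0]
    block = _movement_blocks(logits.shape[1])
    p = _softmax(logits)
    l_sub = -np.log(p[np.arange(b), labels] + 1e-300)
    q = p.reshape(b, len(MOVEMENTS), block).sum(axis=2)
    mov = labels // block
    l_mov = -np.log(q[np.arange(b), mov] + 1e-300)
    return float((l_sub + weight * l_mov).mean())


def _loss_grad(logits: np.ndarray, labels: np.ndarray, weight: float
               ) -> tuple[float, np.ndarray]:
    b, c = logits.shape
    block = _movement_blocks(c)
    p = _softmax(logits)
    y = np.zeros_like(p)
    y[np.arange(b), labels] = 1.0
    q = p.reshape(b, len(MOVEMENTS), block).sum(axis=2)
    mov = labels // block
    q_true = q[np.arange(b), mov]
    in_block = np.zeros_like(p)
    for m in range(len(MOVEMENTS)):
        in_block[mov == m, m * block:(m + 1) * block] = 1.0
    loss = float((-np.log(p[np.arange(b), labels] + 1e-300)
                  - weight * np.log(q_true + 1e-300)).mean())
    grad = (p - y) + weight * p * (1.0 - in_block / q_true[:, None])
    return loss, grad / b


# ---------------------------------------------------------------------------

class GINClassifier:
    """Trainable GIN over fixed-size (40-node) channel graphs."""

    def __init__(self, config: GINConfig | None = None):
        self.config = config or GINConfig()
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        self.params: dict[str, np.ndarray] = {}
        self.running: dict[str, np.ndarray] = {}
        d_in = cfg.in_dim
        for k in range(1, cfg.num_layers + 1):
            h = cfg.hidden
            self.params[f"l{k}_W1"] = rng.normal(0, np.sqrt(2.0 / d_in), (d_in, h))
            self.params[f"l{k}_b1"] = np.zeros(h)
            self.params[f"l{k}_gamma"] = np.ones(h)
            self.params[f"l{k}_beta"] = np.zeros(h)
            self.params[f"l{k}_W2"] = rng.normal(0, np.sqrt(2.0 / h), (h, h))
            self.params[f"l{k}_b2"] = np.zeros(h)
            self.params[f"l{k}_eps"] = np.zeros(1)
            self.running[f"l{k}_mean"] = np.zeros(h)
            self.running[f"l{k}_var"] = np.ones(h)
            d_in = h
        dims = [cfg.in_dim] + [cfg.hidden] * cfg.num_layers
        for k, d in enumerate(dims):
            self.params[f"r{k}_W"] = rng.normal(0, np.sqrt(1.0 / d), (d, cfg.hidden))
            self.params[f"r{k}_b"] = np.zeros(cfg.hidden)
        total = (cfg.num_layers + 1) * cfg.hidden
        self.params["cls_W"] = rng.normal(0, np.sqrt(1.0 / total),
                                          (total, cfg.n_classes))
        self.params["cls_b"] = np.zeros(cfg.n_classes)
        self.mu = np.zeros(cfg.in_dim)
        self.sigma = np.ones(cfg.in_dim)
        self.history: list[dict] = []
        self._adam_m: dict[str, np.ndarray] = {}
        self._adam_v: dict[str, np.ndarray] = {}
        self._adam_t = 0

    # -- batching -----------------------------------------------------------

    @staticmethod
    def _batch(graphs: list[ChannelGraph]):
        n_nodes = graphs[0].n_nodes
        feats = np.concatenate([g.node_features for g in graphs])  # (B*n, d)
        rows, cols = [], []
        for gi, g in enumerate(graphs):
            if len(g.edges) == 0:
                continue
            off = gi * n_nodes
            e = g.edges + off
            rows.append(e[:, 0]); cols.append(e[:, 1])
            rows.append(e[:, 1]); cols.append(e[:, 0])
        if rows:
            rows = np.concatenate(rows)
            cols = np.concatenate(cols)
            data = np.ones(rows.size)
            a = sparse.csr_matrix((data, (rows, cols)),
                                  shape=(feats.shape[0], feats.shape[0]))
        else:
            a = sparse.csr_matrix((feats.shape[0], feats.shape[0]))
        labels = np.array([g.subaction_class for g in graphs], dtype=np.int64)
        return feats, a, labels, n_nodes

    # -- forward ------------------------------------------------------------

    def _forward(self, feats: np.ndarray, a, n_nodes: int, training: bool):
        cfg = self.config
        x = (feats - self.mu) / self.sigma
        b = feats.shape[0] // n_nodes
        xs = [x]
        caches = []
        for k in range(1, cfg.num_layers + 1):
            eps = float(self.params[f"l{k}_eps"][0])
            s = a @ x + (1.0 + eps) * x
            z1 = s @ self.params[f"l{k}_W1"] + self.params[f"l{k}_b1"]
            if training:
                mean = z1.mean(axis=0)
                var = z1.var(axis=0)
                self.running[f"l{k}_mean"] = (
                    (1 - _BN_MOMENTUM) * self.running[f"l{k}_mean"]
                    + _BN_MOMENTUM * mean)
                self.running[f"l{k}_var"] = (
                    (1 - _BN_MOMENTUM) * self.running[f"l{k}_var"]
                    + _BN_MOMENTUM * var)
            else:
                mean = self.running[f"l{k}_mean"]
                var = self.running[f"l{k}_var"]
            invstd = 1.0 / np.sqrt(var + _BN_EPS)
            xhat = (z1 - mean) * invstd
            y = self.params[f"l{k}_gamma"] * xhat + self.params[f"l{k}_beta"]
            h = np.maximum(y, 0.0)
            x = h @ self.params[f"l{k}_W2"] + self.params[f"l{k}_b2"]
            caches.append({"s": s, "z1": z1, "xhat": xhat, "invstd": invstd,
                           "y": y, "h": h, "xin": xs[-1]})
            xs.append(x)
        pooled = [xk.reshape(b, n_nodes, -1).sum(axis=1) for xk in xs]
        zs = [pooled[k] @ self.params[f"r{k}_W"] + self.params[f"r{k}_b"]
              for k in range(len(pooled))]
        z = np.concatenate(zs, axis=1)
        logits = z @ self.params["cls_W"] + self.params["cls_b"]
        return logits, {"xs": xs, "caches": caches, "pooled": pooled, "z": z,
                        "b": b, "n_nodes": n_nodes, "a": a}

    # -- backward -----------------------------------------------------------

    def _backward(self, dlogits: np.ndarray, fw: dict) -> dict[str, np.ndarray]:
        cfg = self.config
        g: dict[str, np.ndarray] = {}
        z, b, n_nodes, a = fw["z"], fw["b"], fw["n_nodes"], fw["a"]
        g["cls_W"] = z.T @ dlogits
        g["cls_b"] = dlogits.sum(axis=0)
        dz = dlogits @ self.params["cls_W"].T
        h = cfg.hidden
        d_readout_x = []
        for k in range(cfg.num_layers + 1):
            dzk = dz[:, k * h:(k + 1) * h]
            g[f"r{k}_W"] = fw["pooled"][k].T @ dzk
            g[f"r{k}_b"] = dzk.sum(axis=0)
            dpool = dzk @ self.params[f"r{k}_W"].T          # (B, d_k)
            d_readout_x.append(np.repeat(dpool, n_nodes, axis=0))
        dx = d_readout_x[cfg.num_layers]
        for k in range(cfg.num_layers, 0, -1):
            c = fw["caches"][k - 1]
            g[f"l{k}_W2"] = c["h"].T @ dx
            g[f"l{k}_b2"] = dx.sum(axis=0)
            dh = dx @ self.params[f"l{k}_W2"].T
            dy = dh * (c["y"] > 0)
            g[f"l{k}_gamma"] = (dy * c["xhat"]).sum(axis=0)
            g[f"l{k}_beta"] = dy.sum(axis=0)
            dxhat = dy * self.params[f"l{k}_gamma"]
            n = dxhat.shape[0]
            dz1 = (c["invstd"] / n) * (
                n * dxhat - dxhat.sum(axis=0)
                - c["xhat"] * (dxhat * c["xhat"]).sum(axis=0)
            )
            g[f"l{k}_W1"] = c["s"].T @ dz1
            g[f"l{k}_b1"] = dz1.sum(axis=0)
            ds = dz1 @ self.params[f"l{k}_W1"].T
            g[f"l{k}_eps"] = np.array([(ds * c["xin"]).sum()])
            eps = float(self.params[f"l{k}_eps"][0])
            dx = a @ ds + (1.0 + eps) * ds
            dx = dx + d_readout_x[k - 1]
        return g

    def _adam_step(self, grads: dict[str, np.ndarray]) -> None:
        lr = self.config.learning_rate
        b1, b2, eps = 0.9, 0.999, 1e-8
        self._adam_t += 1
        t = self._adam_t
        for name, grad in grads.items():
            m = self._adam_m.setdefault(name, np.zeros_like(grad))
            v = self._adam_v.setdefault(name, np.zeros_like(grad))
            m[:] = b1 * m + (1 - b1) * grad
            v[:] = b2 * v + (1 - b2) * grad ** 2
            mhat = m / (1 - b1 ** t)
            vhat = v / (1 - b2 ** t)
            self.params[name] -= lr * mhat / (np.sqrt(vhat) + eps)

    # -- public API ---------------------------------------------------------

    def fit(self, graphs: list[ChannelGraph]) -> "GINClassifier":
        """Train on labeled graphs; seeded and reproducible on one device."""
        if not graphs:
            raise ValueError("empty training set")
        cfg = self.config
        all_feats = np.concatenate([g.node_features for g in graphs])
        self.mu = all_feats.mean(axis=0)
        self.sigma = np.maximum(all_feats.std(axis=0), 1e-8)
        rng = np.random.default_rng(cfg.seed + 1)
        idx = np.arange(len(graphs))
        for epoch in range(cfg.epochs):
            rng.shuffle(idx)
            losses, n_correct, n_seen = [], 0, 0
            for start in range(0, len(idx), cfg.batch_size):
                batch = [graphs[i] for i in idx[start:start + cfg.batch_size]]
                feats, a, labels, n_nodes = self._batch(batch)
                logits, fw = self._forward(feats, a, n_nodes, training=True)
                loss, dlogits = _loss_grad(logits, labels,
                                           cfg.movement_loss_weight)
                grads = self._backward(dlogits, fw)
                self._adam_step(grads)
                losses.append(loss)
                n_correct += int((logits.argmax(axis=1) == labels).sum())
                n_seen += len(batch)
            self.history.append({
                "epoch": epoch,
                "loss": float(np.mean(losses)),
                "train_accuracy": n_correct / n_seen,
            })
        return self

    def predict_logits(self, graphs: list[ChannelGraph]) -> np.ndarray:
        """Evaluation-mode logits (deterministic; uses running BN stats)."""
        out = []
        for start in range(0, len(graphs), 256):
            batch = graphs[start:start + 256]
            feats, a, _, n_nodes = self._batch(batch)
            logits, _ = self._forward(feats, a, n_nodes, training=False)
            out.append(logits)
        return np.concatenate(out)

    def predict(self, graphs: list[ChannelGraph]) -> np.ndarray:
        return self.predict_logits(graphs).argmax(axis=1)

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        """Single-archive checkpoint: weights, BN stats, standardization
        constants and config."""
        arrays = {f"param_{k}": v for k, v in self.params.items()}
        arrays.update({f"run_{k}": v for k, v in self.running.items()})
        arrays["mu"] = self.mu
        arrays["sigma"] = self.sigma
        arrays["config_json"] = np.frombuffer(
            json.dumps(asdict(self.config)).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "GINClassifier":
        with np.load(path) as data:
            cfg = GINConfig(**json.loads(bytes(data["config_json"]).decode()))
            model = cls(cfg)
            for key in data.files:
                if key.startswith("param_"):
                    model.params[key[len("param_"):]] = data[key]
                elif key.startswith("run_"):
                    model.running[key[len("run_"):]] = data[key]
            model.mu = data["mu"]
            model.sigma = data["sigma"]
        return model


def train(graphs: list[ChannelGraph], config: GINConfig | None = None
          ) -> GINClassifier:
    """Convenience wrapper: construct and fit a :class:`GINClassifier`."""
    return GINClassifier(config).fit(graphs)


def predict_sequence(model: GINClassifier, trial_graphs: list[ChannelGraph],
                     n_segments: int = 6) -> list[tuple[str, int]]:
    """Predict the sub-action sequence of one trial (its 6 ordered graphs).

    Returns the decoded (movement, position) label per segment, in segment
    order; deterministic in evaluation mode.
    """
    if len(trial_graphs) != n_segments:
        raise ValueError(
            f"expected {n_segments} segment graphs, got {len(trial_graphs)}"
        )
    ordered = sorted(trial_graphs, key=lambda g: g.position)
    classes = model.predict(ordered)
    return [decode_label(int(c)) for c in classes]
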