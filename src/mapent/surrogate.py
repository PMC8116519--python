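"""Graph-network surrogate for the mapping entropy.

The model is a graph isomorphism network with scalar edge weights.  Layer 1
embeds the 10 binary vertex features into R^K with an affine map + ReLU; each
of the following L-1 graph-convolution layers updates vertex v as

    h_v^{l+1} = ReLU(W_l [(1 + eps_l) h_v^l + sum_{u in N(v)} h_u^l e_uv] + b_l)

with a per-layer adaptive scalar eps_l and the inverse inter-atomic distance
e_uv as edge weight.  The readout concatenates each vertex's L per-layer
states, scales retained (CG-site) vertices by a scalar w_s and the rest by
w_n, sums over vertices and projects with a weight vector w_out of length
K*L.  Excluding biases the trainable-scalar census is

    10*K + K^2*(L-1) + K*L + (L-1) + 2     (= 17350 at K=64, L=5).

Training minimizes the mean absolute error with Adam (no weight decay),
mini-batches of 8 and early stopping on the validation MAE.  Everything is
plain NumPy: forward, backward and the optimizer are implemented here, in
float32 for speed, with all randomness drawn from a single seeded generator.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .mapping_space import Mapping
from .protein_graph import ProteinGraph, encode_mapping

__all__ = [
    "SurrogateConfig",
    "SurrogateModel",
    "MappingSample",
    "TrainResult",
    "TrainingDivergedError",
    "count_weights",
    "embed_vertices",
    "gin_layer",
    "readout",
    "predict",
    "train",
    "evaluate",
    "save_dataset",
    "load_dataset",
    "save_model",
    "load_model",
]


class TrainingDivergedError(RuntimeError):
    """The training loss became non-finite."""


@dataclass
class SurrogateConfig:
    """Architecture and training hyperparameters.

    ``L`` counts the embedding layer plus L-1 graph convolutions.  ``split``
    is the train/validation/test hold-out fractions.  ``readout_mode``
    selects the site/non-site weighted sum (default) or a plain mean over
    vertices.  ``normalize_targets`` optionally standardizes labels during
    training (predictions are always returned on the original scale).
    """

    K: int = 64
    L: int = 5
    in_dim: int = 10
    learning_rate: float = 0.001
    batch_size: int = 8
    max_epochs: int = 10_000
    patience: int = 1_000
    split: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0
    readout_mode: str = "weighted_sum"
    normalize_targets: bool = False

    def __post_init__(self) -> None:
        if self.K < 1 or self.L < 1:
            raise ValueError("K and L must be >= 1")
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.readout_mode not in ("weighted_sum", "mean"):
            raise ValueError(f"unknown readout mode {self.readout_mode!r}")


def count_weights(config: SurrogateConfig) -> int:
    """Closed-form trainable-scalar census, biases excluded."""
    K, L, D = config.K, config.L, config.in_dim
    return D * K + K * K * (L - 1) + K * L + (L - 1) + 2


@dataclass
class MappingSample:
    """A labeled training example: one mapping with its mapping entropy."""

    mapping: Mapping
    smap: float  # kJ/mol/K
    origin: str = "random"  # "random" | "optimized"

    def __post_init__(self) -> None:
        if not math.isfinite(self.smap):
            raise ValueError("smap label must be finite")
        if self.origin not in ("random", "optimized"):
            raise ValueError(f"unknown origin {self.origin!r}")


class SurrogateModel:
    """Weights of one surrogate instance, tied to a :class:`SurrogateConfig`.

    All weight arrays follow a symmetric fan-in-scaled uniform initialization
    and live at unit scale.  The convolution layers are parameterized with an
    explicit gain: the forward pass uses ``conv_gain * W_l``, where
    ``conv_gain`` is the inverse of the graph's mean total edge weight per
    vertex (1 + 2*sum(e_uv)/n).  The edge-weighted neighbour sum multiplies
    activation magnitude by roughly that factor per layer, so the gain keeps
    activations O(1) while the stored parameters keep the natural scale that
    a uniform-step optimizer expects.  Epsilons start at 0; the readout
    starts from the retained-vertex sum (w_site = 1, w_nonsite = 0).
    """

    def __init__(
        self,
        config: SurrogateConfig,
        rng: np.random.Generator | None = None,
        aggregation_scale: float = 1.0,
        dtype=np.float32,
    ):
        self.config = config
        self.dtype = dtype
        rng = rng if rng is not None else np.random.default_rng(config.seed)
        K, L, D = config.K, config.L, config.in_dim

        def uniform(shape, fan_in):
            bound = 1.0 / math.sqrt(fan_in)
            return rng.uniform(-bound, bound, size=shape).astype(dtype)

        self.conv_gain = 1.0 / max(1.0, float(aggregation_scale))
        self.W_embed = uniform((D, K), D)
        self.b_embed = uniform((K,), D)
        self.W_conv = [uniform((K, K), K) for _ in range(L - 1)]
        self.b_conv = [uniform((K,), K) for _ in range(L - 1)]
        # w_site = 1, w_nonsite = 0: the readout starts from the sum over
        # retained vertices only, breaking the site/non-site symmetry (equal
        # scalars sit on a slow manifold of the bilinear readout) and keeping
        # the initial common-mode component of the pooled state small.
        self.eps = np.zeros(L - 1, dtype=dtype)
        self.w_site = np.array(1.0, dtype=dtype)
        self.w_nonsite = np.array(0.0, dtype=dtype)
        self.w_out = uniform((K * L,), K * L)
        self.b_out = np.array(0.0, dtype=dtype)
        # target scaling (identity unless normalize_targets was used in train)
        self.y_mean = 0.0
        self.y_scale = 1.0

    # -- parameter bookkeeping -------------------------------------------------

    def parameters(self) -> list[np.ndarray]:
        """All trainable arrays, biases included."""
        return (
            [self.W_embed, self.b_embed]
            + self.W_conv
            + self.b_conv
            + [self.eps, self.w_site, self.w_nonsite, self.w_out, self.b_out]
        )

    def num_weights(self, exclude_bias: bool = True) -> int:
        """Census of trainable scalars; biases excluded by default."""
        arrays = [self.W_embed] + self.W_conv + [self.eps, self.w_site,
                                                 self.w_nonsite, self.w_out]
        if not exclude_bias:
            arrays += [self.b_embed, self.b_out] + self.b_conv
        return int(sum(a.size for a in arrays))

    def set_parameters(self, params: Sequence[np.ndarray]) -> None:
        for dst, src in zip(self.parameters(), params):
            if np.isscalar(dst) or dst.ndim == 0:
                dst[...] = src
            else:
                dst[...] = src

    def copy_parameters(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]


# -- single-graph operations (the documented forward pieces) -------------------


def embed_vertices(graph: ProteinGraph, model: SurrogateModel) -> np.ndarray:
    """Layer-1 states h^1 = ReLU(affine(x_v)); independent of the edges."""
    X = graph.features.astype(model.dtype)
    if X.shape[1] != model.config.in_dim:
        raise ValueError(
            f"graph features are {X.shape[1]}-wide, expected {model.config.in_dim}"
        )
    return np.maximum(X @ model.W_embed + model.b_embed, 0.0)


def gin_layer(
    h: np.ndarray, graph: ProteinGraph, layer: int, model: SurrogateModel
) -> np.ndarray:
    """One edge-weighted graph convolution (layer index 0..L-2)."""
    if not 0 <= layer < model.config.L - 1:
        raise ValueError(f"convolution layer index {layer} out of range")
    n = graph.n_vertices
    if h.shape[0] != n:
        raise ValueError("vertex states do not match the graph")
    if graph.edges.size and graph.edges.max() >= n:
        raise ValueError("edge references a missing vertex")
    A = graph.adjacency(dtype=model.dtype)
    pre = (1.0 + model.eps[layer]) * h + A @ h
    g = model.conv_gain
    return np.maximum(pre @ (g * model.W_conv[layer]) + g * model.b_conv[layer], 0.0)


def readout(
    states: Sequence[np.ndarray], mapping: Mapping, model: SurrogateModel
) -> float:
    """Concatenated-layer readout: site/non-site weighted vertex sum, then w_out."""
    cfg = model.config
    if len(states) != cfg.L:
        raise ValueError(f"need {cfg.L} per-layer state blocks, got {len(states)}")
    n = states[0].shape[0]
    if mapping.n != n:
        raise ValueError("mapping and graph sizes do not match")
    H = np.concatenate(states, axis=1)  # (n, K*L)
    if cfg.readout_mode == "mean":
        z = H.mean(axis=0)
    else:
        c = np.where(mapping.indicator(), model.w_site, model.w_nonsite)
        z = c @ H
    raw = float(z @ model.w_out + model.b_out)
    return raw * model.y_scale + model.y_mean


def predict(graph: ProteinGraph, mapping: Mapping, model: SurrogateModel) -> float:
    """Full forward pass for one mapping: encode, embed, convolve, read out."""
    g = encode_mapping(graph, mapping)
    states = [embed_vertices(g, model)]
    for layer in range(model.config.L - 1):
        states.append(gin_layer(states[-1], g, layer, model))
    return readout(states, mapping, model)


# -- batched forward/backward used by training and bulk prediction -------------


class _BatchEngine:
    """Vectorized forward/backward over batches of mappings on one fixed graph."""

    def __init__(self, graph: ProteinGraph, model: SurrogateModel):
        self.model = model
        self.dtype = model.dtype
        self.A = graph.adjacency(dtype=model.dtype)
        self.X_base = graph.features.astype(model.dtype)
        self.X_base[:, 9] = 0.0
        self.n = graph.n_vertices

    def _neighbor(self, h: np.ndarray) -> np.ndarray:
        # h: (B, n, K) -> (B, n, K) with out[b, v] = sum_u A[v, u] h[b, u]
        B, n, K = h.shape
        flat = h.transpose(1, 0, 2).reshape(n, B * K)
        return (self.A @ flat).reshape(n, B, K).transpose(1, 0, 2)

    def forward(self, site: np.ndarray, need_cache: bool = False):
        """site: (B, n) float {0,1}.  Returns predictions (B,) [and caches]."""
        m = self.model
        cfg = m.config
        B, n = site.shape
        X = np.broadcast_to(self.X_base, (B, n, cfg.in_dim)).copy()
        X[:, :, 9] = site
        a = X.reshape(B * n, -1) @ m.W_embed + m.b_embed
        h = np.maximum(a, 0.0).reshape(B, n, cfg.K)
        states = [h]
        pres = []
        gain = m.conv_gain
        for layer in range(cfg.L - 1):
            p = (1.0 + m.eps[layer]) * h + self._neighbor(h)
            a = p.reshape(B * n, cfg.K) @ (gain * m.W_conv[layer]) + gain * m.b_conv[layer]
            h = np.maximum(a, 0.0).reshape(B, n, cfg.K)
            if need_cache:
                pres.append(p)
            states.append(h)
        if cfg.readout_mode == "mean":
            c = np.full((B, n), 1.0 / n, dtype=self.dtype)
        else:
            c = np.where(site > 0.5, m.w_site, m.w_nonsite).astype(self.dtype)
        K = cfg.K
        z = np.empty((B, cfg.K * cfg.L), dtype=self.dtype)
        for l, hl in enumerate(states):
            z[:, l * K:(l + 1) * K] = np.einsum("bu,buk->bk", c, hl)
        pred = z @ m.w_out + m.b_out
        if need_cache:
            return pred, (X, states, pres, c, z, site)
        return pred

    def backward(self, dpred: np.ndarray, cache) -> list[np.ndarray]:
        """Gradients w.r.t. model.parameters(), given d loss / d pred (B,)."""
        m = self.model
        cfg = m.config
        X, states, pres, c, z, site = cache
        B, n, K = states[0].shape
        L = cfg.L

        g_w_out = dpred @ z
        g_b_out = np.array(dpred.sum(), dtype=self.dtype)
        dz = np.outer(dpred, m.w_out).astype(self.dtype)  # (B, K*L)

        # readout contribution to each layer's states, and to c
        dh_ro = []
        dc = np.zeros((B, n), dtype=self.dtype)
        for l in range(L):
            dzl = dz[:, l * K:(l + 1) * K]
            dh_ro.append(c[:, :, None] * dzl[:, None, :])
            dc += np.einsum("bk,buk->bu", dzl, states[l])
        if cfg.readout_mode == "mean":
            g_w_site = np.array(0.0, dtype=self.dtype)
            g_w_nonsite = np.array(0.0, dtype=self.dtype)
        else:
            sel = site > 0.5
            g_w_site = np.array((dc * sel).sum(), dtype=self.dtype)
            g_w_nonsite = np.array((dc * ~sel).sum(), dtype=self.dtype)

        g_W_conv = [None] * (L - 1)
        g_b_conv = [None] * (L - 1)
        g_eps = np.zeros(L - 1, dtype=self.dtype)
        gain = m.conv_gain

        delta = dh_ro[L - 1]
        for layer in range(L - 2, -1, -1):
            h_out = states[layer + 1]
            da = (delta * (h_out > 0)).reshape(B * n, K)
            p_flat = pres[layer].reshape(B * n, K)
            g_W_conv[layer] = gain * (p_flat.T @ da)
            g_b_conv[layer] = gain * da.sum(axis=0)
            dp = (da @ (gain * m.W_conv[layer]).T).reshape(B, n, K)
            h_in = states[layer]
            g_eps[layer] = float(np.sum(dp * h_in))
            delta = dh_ro[layer] + (1.0 + m.eps[layer]) * dp + self._neighbor(dp)

        da1 = (delta * (states[0] > 0)).reshape(B * n, K)
        g_W_embed = X.reshape(B * n, -1).T @ da1
        g_b_embed = da1.sum(axis=0)

        return (
            [g_W_embed, g_b_embed]
            + g_W_conv
            + g_b_conv
            + [g_eps, g_w_site, g_w_nonsite, g_w_out.astype(self.dtype), g_b_out]
        )


def predict_batch(
    graph: ProteinGraph,
    mappings: Sequence[Mapping],
    model: SurrogateModel,
    chunk: int = 256,
) -> np.ndarray:
    """Vectorized :func:`predict` over many mappings (same graph)."""
    engine = _BatchEngine(graph, model)
    site = np.zeros((len(mappings), graph.n_vertices), dtype=model.dtype)
    for i, mp in enumerate(mappings):
        if mp.n != graph.n_vertices:
            raise ValueError("mapping and graph sizes do not match")
        site[i, list(mp.retained)] = 1.0
    out = np.empty(len(mappings))
    for start in range(0, len(mappings), chunk):
        stop = min(len(mappings), start + chunk)
        out[start:stop] = engine.forward(site[start:stop])
    return out * model.y_scale + model.y_mean


class _Adam:
    def __init__(self, params: Sequence[np.ndarray], lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = [np.zeros_like(np.asarray(p, dtype=np.float64)) for p in params]
        self.v = [np.zeros_like(np.asarray(p, dtype=np.float64)) for p in params]

    def step(self, params: Sequence[np.ndarray], grads: Sequence[np.ndarray]) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            g64 = np.asarray(g, dtype=np.float64)
            m *= self.b1
            m += (1 - self.b1) * g64
            v *= self.b2
            v += (1 - self.b2) * g64 * g64
            update = self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            p[...] = (np.asarray(p, dtype=np.float64) - update).astype(p.dtype)


@dataclass
class TrainResult:
    model: SurrogateModel
    log: list[dict]  # per-epoch: epoch, train_mae, val_mae, best_val_mae
    best_epoch: int
    split_indices: dict[str, np.ndarray]  # "train" / "val" / "test"


def _mean_aggregation_scale(graph: ProteinGraph) -> float:
    n = graph.n_vertices
    return 1.0 + 2.0 * float(graph.edge_weight.sum()) / n


def train(
    graph: ProteinGraph,
    samples: Sequence[MappingSample],
    config: SurrogateConfig,
) -> TrainResult:
    """Train the surrogate on labeled mappings of one protein graph.

    Samples are shuffled with ``config.seed`` and split by the hold-out
    fractions; Adam minimizes the batch MAE; the epoch with the best
    validation MAE supplies the returned weights.  The per-epoch log is
    fully determined by the seed.
    """
    if len(samples) < 10:
        raise ValueError("need at least 10 samples to train")
    rng = np.random.default_rng(config.seed)
    S = len(samples)
    perm = rng.permutation(S)
    n_tr = int(S * config.split[0])
    n_va = int(S * config.split[1])
    if n_tr < 1 or n_va < 1 or n_tr + n_va >= S:
        raise ValueError(f"split {config.split} infeasible for {S} samples")
    idx_tr, idx_va = perm[:n_tr], perm[n_tr:n_tr + n_va]
    idx_te = perm[n_tr + n_va:]

    y = np.array([s.smap for s in samples], dtype=np.float64)
    model = SurrogateModel(
        config, rng=rng, aggregation_scale=_mean_aggregation_scale(graph)
    )
    if config.normalize_targets:
        model.y_mean = float(y[idx_tr].mean())
        model.y_scale = float(y[idx_tr].std()) or 1.0
    else:
        # start the output bias at the training-target mean
        model.b_out[...] = np.array(y[idx_tr].mean(), dtype=model.dtype)
    y_scaled = (y - model.y_mean) / model.y_scale

    engine = _BatchEngine(graph, model)
    n = graph.n_vertices
    site_all = np.zeros((S, n), dtype=model.dtype)
    for i, s in enumerate(samples):
        if s.mapping.n != n:
            raise ValueError("sample mapping does not match the graph size")
        site_all[i, list(s.mapping.retained)] = 1.0

    params = model.parameters()
    opt = _Adam(params, config.learning_rate)

    def eval_mae(idx: np.ndarray, chunk: int = 512) -> float:
        err = 0.0
        for start in range(0, idx.size, chunk):
            sub = idx[start:start + chunk]
            pred = engine.forward(site_all[sub])
            err += float(np.abs(pred - y_scaled[sub]).sum())
        return err / idx.size

    log: list[dict] = []
    best_val = math.inf
    best_epoch = -1
    best_params = model.copy_parameters()
    B = config.batch_size

    for epoch in range(config.max_epochs):
        order = rng.permutation(n_tr)
        train_err = 0.0
        for start in range(0, n_tr, B):
            sub = idx_tr[order[start:start + B]]
            pred, cache = engine.forward(site_all[sub], need_cache=True)
            resid = pred - y_scaled[sub]
            loss = float(np.abs(resid).mean())
            if not math.isfinite(loss):
                raise TrainingDivergedError(f"non-finite loss at epoch {epoch}")
            train_err += float(np.abs(resid).sum())
            dpred = (np.sign(resid) / resid.size).astype(model.dtype)
            grads = engine.backward(dpred, cache)
            opt.step(params, grads)
        train_mae = train_err / n_tr
        val_mae = eval_mae(idx_va)
        if not math.isfinite(val_mae):
            raise TrainingDivergedError(f"non-finite validation MAE at epoch {epoch}")
        if val_mae < best_val:
            best_val = val_mae
            best_epoch = epoch
            best_params = model.copy_parameters()
        log.append(
            {
                "epoch": epoch,
                "train_mae": train_mae * model.y_scale,
                "val_mae": val_mae * model.y_scale,
                "best_val_mae": best_val * model.y_scale,
            }
        )
        if epoch - best_epoch >= config.patience:
            break

    model.set_parameters(best_params)
    return TrainResult(
        model=model,
        log=log,
        best_epoch=best_epoch,
        split_indices={"train": idx_tr, "val": idx_va, "test": idx_te},
    )


def evaluate(truth: np.ndarray, predictions: np.ndarray) -> tuple[float, float]:
    """(R^2, MAE) of predictions against ground truth."""
    truth = np.asarray(truth, dtype=float)
    predictions = np.asarray(predictions, dtype=float)
    if truth.shape != predictions.shape or truth.size < 2:
        raise ValueError("need matching vectors of length >= 2")
    ss_tot = float(np.sum((truth - truth.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R^2 is undefined for constant truth values")
    ss_res = float(np.sum((truth - predictions) ** 2))
    mae = float(np.abs(truth - predictions).mean())
    return 1.0 - ss_res / ss_tot, mae


# -- dataset and checkpoint I/O ------------------------------------------------


def save_dataset(samples: Sequence[MappingSample], path: str | Path) -> None:
    """Write samples as JSON Lines: {"retained": [...], "smap": x, "origin": o}."""
    with open(path, "w") as fh:
        for s in samples:
            fh.write(
                json.dumps(
                    {
                        "retained": list(s.mapping.retained),
                        "smap": s.smap,
                        "origin": s.origin,
                    }
                )
                + "\n"
            )


def load_dataset(path: str | Path, n: int) -> list[MappingSample]:
    """Read a JSON Lines dataset; ``n`` is the total atom count of the graph."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            out.append(
                MappingSample(
                    mapping=Mapping(n=n, retained=tuple(obj["retained"])),
                    smap=float(obj["smap"]),
                    origin=obj.get("origin", "random"),
                )
            )
    return out


def save_model(model: SurrogateModel, path: str | Path) -> None:
    """Single-file checkpoint: weights + config (.npz)."""
    cfg = asdict(model.config)
    cfg["split"] = list(cfg["split"])
    arrays = {
        "W_embed": model.W_embed,
        "b_embed": model.b_embed,
        "eps": model.eps,
        "w_site": model.w_site,
        "w_nonsite": model.w_nonsite,
        "w_out": model.w_out,
        "b_out": model.b_out,
        "y_mean": np.array(model.y_mean),
        "y_scale": np.array(model.y_scale),
        "conv_gain": np.array(model.conv_gain),
        "config_json": np.array(json.dumps(cfg)),
    }
    for i, (W, b) in enumerate(zip(model.W_conv, model.b_conv)):
        arrays[f"W_conv_{i}"] = W
        arrays[f"b_conv_{i}"] = b
    np.savez(path, **arrays)


def load_model(path: str | Path) -> SurrogateModel:
    with np.load(path) as data:
        cfg_dict = json.loads(str(data["config_json"]))
        cfg_dict["split"] = tuple(cfg_dict["split"])
        config = SurrogateConfig(**cfg_dict)
        model = SurrogateModel(config)
        model.W_embed = data["W_embed"]
        model.b_embed = data["b_embed"]
        model.eps = data["eps"]
        model.w_site = data["w_site"]
        model.w_nonsite = data["w_nonsite"]
        model.w_out = data["w_out"]
        model.b_out = data["b_out"]
        model.y_mean = float(data["y_mean"])
        model.y_scale = float(data["y_scale"])
        model.conv_gain = float(data["conv_gain"])
        model.W_conv = [data[f"W_conv_{i}"] for i in range(config.L - 1)]
        model.b_conv = [data[f"b_conv_{i}"] for i in range(config.L - 1)]
    return model
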