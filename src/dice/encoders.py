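"""Per-protein modality vectors from raw inputs.

The network side produces node embeddings from an interaction edge list by the
classic two-step recipe: biased second-order random walks over the graph
followed by skip-gram training with negative sampling on the walk corpus, so
nodes that co-occur on walks (i.e. are close in the network) receive similar
vectors. The image side is deliberately thin: image encoders are assumed
pre-trained and their per-image embeddings are consumed as tables, with an
aggregation step collapsing repeated per-image rows to one vector per protein.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .data_io import ModalityMatrix

__all__ = ["NetworkEmbeddingConfig", "embed_network", "aggregate_per_protein"]


@dataclass
class NetworkEmbeddingConfig:
    """Random-walk embedding knobs. Defaults are the standard node2vec setting
    (128 dims, 10 walks of length 80 per node, window 10, p = q = 1, i.e.
    unbiased walks)."""

    dimensions: int = 128
    walk_length: int = 80
    num_walks: int = 10
    window: int = 10
    p: float = 1.0
    q: float = 1.0
    seed: int = 0
    sgd_epochs: int = 3
    negative: int = 5
    learning_rate: float = 0.025

    def __post_init__(self) -> None:
        if self.dimensions < 2:
            raise ValueError("dimensions must be >= 2")
        if min(self.walk_length, self.num_walks, self.window) < 1:
            raise ValueError("walk_length, num_walks and window must be >= 1")
        if self.p <= 0 or self.q <= 0:
            raise ValueError("p and q must be positive")


def _build_adjacency(
    edges: Iterable[tuple], ids: list[str]
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    index = {u: i for i, u in enumerate(ids)}
    nbrs: list[dict[int, float]] = [dict() for _ in ids]
    for e in edges:
        u, v = str(e[0]), str(e[1])
        w = float(e[2]) if len(e) > 2 else 1.0
        if u == v:
            continue
        iu, iv = index[u], index[v]
        nbrs[iu][iv] = max(w, nbrs[iu].get(iv, 0.0))
        nbrs[iv][iu] = max(w, nbrs[iv].get(iu, 0.0))
    # neighbor arrays sorted by id so runs are order-independent
    neigh, weights = [], []
    for d in nbrs:
        ks = np.array(sorted(d), dtype=np.int64)
        neigh.append(ks)
        ws = np.array([d[k] for k in ks], dtype=float)
        weights.append(ws / ws.sum() if ws.size else ws)
    return neigh, weights


def _walks(
    neigh: list[np.ndarray],
    weights: list[np.ndarray],
    config: NetworkEmbeddingConfig,
    rng: np.random.Generator,
) -> list[list[int]]:
    n = len(neigh)
    walks: list[list[int]] = []
    uniform = config.p == 1.0 and config.q == 1.0
    for _ in range(config.num_walks):
        for start in range(n):  # node order fixed (sorted ids)
            if neigh[start].size == 0:
                continue
            walk = [start]
            while len(walk) < config.walk_length:
                cur = walk[-1]
                ks, ws = neigh[cur], weights[cur]
                if ks.size == 0:
                    break
                if uniform or len(walk) < 2:
                    nxt = int(ks[rng.choice(ks.size, p=ws)])
                else:
                    prev = walk[-2]
                    prev_nbrs = neigh[prev]
                    bias = np.where(
                        ks == prev,
                        1.0 / config.p,
                        np.where(np.isin(ks, prev_nbrs), 1.0, 1.0 / config.q),
                    )
                    probs = ws * bias
                    probs /= probs.sum()
                    nxt = int(ks[rng.choice(ks.size, p=probs)])
                walk.append(nxt)
            walks.append(walk)
    return walks


def _skipgram(
    walks: list[list[int]],
    n_nodes: int,
    config: NetworkEmbeddingConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Skip-gram with negative sampling over the walk corpus (SGD, lr decay)."""
    dim = config.dimensions
    U = (rng.random((n_nodes, dim)) - 0.5) / dim  # input vectors (the embedding)
    Wout = np.zeros((n_nodes, dim))

    counts = Counter(node for walk in walks for node in walk)
    freq = np.zeros(n_nodes)
    for node, c in counts.items():
        freq[node] = c
    noise = freq ** 0.75
    noise /= noise.sum()

    pairs: list[tuple[int, int]] = []
    for walk in walks:
        for i, center in enumerate(walk):
            lo = max(0, i - config.window)
            hi = min(len(walk), i + config.window + 1)
            for j in range(lo, hi):
                if j != i:
                    pairs.append((center, walk[j]))
    pairs_arr = np.array(pairs, dtype=np.int64)
    total = config.sgd_epochs * len(pairs_arr)
    done = 0
    for _ in range(config.sgd_epochs):
        order = rng.permutation(len(pairs_arr))
        negs = rng.choice(n_nodes, size=(len(pairs_arr), config.negative), p=noise)
        for row, (center, context) in enumerate(pairs_arr[order]):
            lr = config.learning_rate * max(1e-4, 1.0 - done / total)
            done += 1
            u = U[center]
            targets = np.concatenate([[context], negs[row]])
            labels = np.zeros(len(targets))
            labels[0] = 1.0
            out = Wout[targets]
            scores = 1.0 / (1.0 + np.exp(-out @ u))
            gscore = (scores - labels) * lr
            gu = gscore @ out
            Wout[targets] -= gscore[:, None] * u
            U[center] = u - gu
    return U


def embed_network(
    edges: Sequence[tuple], config: NetworkEmbeddingConfig | None = None
) -> ModalityMatrix:
    """Embed the nodes of an interaction edge list into ``config.dimensions``
    real dimensions via random walks + skip-gram. One row per node appearing in
    the edge list (sorted id order); fixed seed gives reproducible output.
    """
    if config is None:
        config = NetworkEmbeddingConfig()
    edges = list(edges)
    if not edges:
        raise ValueError("empty edge list")
    ids = sorted({str(e[0]) for e in edges} | {str(e[1]) for e in edges})
    neigh, weights = _build_adjacency(edges, ids)
    if all(k.size == 0 for k in neigh):
        raise ValueError("graph has no non-self-loop edges")
    rng = np.random.default_rng(config.seed)
    walks = _walks(neigh, weights, config, rng)
    U = _skipgram(walks, len(ids), config, rng)
    return ModalityMatrix(ids, U, "network_embedding")


def aggregate_per_protein(
    labels: Sequence[str],
    values: np.ndarray,
    method: str = "mean",
) -> ModalityMatrix:
    """Collapse repeated per-image rows to one row per protein.

    ``labels`` carries one protein label per input row (repeats expected);
    output rows follow first-appearance order of the labels. ``mean``
    aggregates element-wise; ``first`` keeps the first row seen.
    """
    if method not in ("mean", "first"):
        raise ValueError(f"unknown aggregation method {method!r}")
    values = np.atleast_2d(np.asarray(values, dtype=float))
    labels = [str(l) for l in labels]
    if len(labels) != values.shape[0]:
        raise ValueError("one label per row required")
    order: list[str] = []
    groups: dict[str, list[int]] = {}
    for i, lab in enumerate(labels):
        if lab not in groups:
            groups[lab] = []
            order.append(lab)
        groups[lab].append(i)
    if method == "mean":
        out = np.vstack([values[groups[lab]].mean(axis=0) for lab in order])
    else:
        out = np.vstack([values[groups[lab][0]] for lab in order])
    return ModalityMatrix(order, out, "aggregated")
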