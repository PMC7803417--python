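"""Node embeddings: random-walk-with-restart diffusion plus Mashup factorization.

Stage one runs a random walk with restart (RWR) from every node of the
heterogeneous network. The walker follows edges with probability proportional
to their weight and teleports back to its seed with probability
``restart_prob`` per step; the fixed point of

    p <- (1 - r) * P @ p + r * e_seed

is the seed's diffusion state, a probability distribution over all nodes that
summarizes the seed's weighted neighborhood at all scales. Stacking the n
diffusion states column-wise gives an n x n column-stochastic matrix V.

Stage two compresses V into d-dimensional feature vectors X_i (one per node)
and context vectors W_k by fitting the softmax model

    V~[k, i] = exp(X_i . W_k) / sum_k' exp(X_i . W_k')

so that the model columns match the diffusion states, minimizing the mean
KL divergence (1/n) * sum_i KL(V_i || V~_i). Two optimizers are provided:

* ``svd`` (default): truncated rank-d SVD of log V. Exact at d = n and
  deterministic; the per-column log shift left unexplained by the
  factorization is absorbed by the softmax normalization.
* ``kl_gradient``: full-batch gradient descent on the KL objective itself,
  from a seeded small random initialization, with an adaptive step size
  (grown 1.05x on accepted steps, halved on objective increase). Records
  the accepted objective per iteration, which is therefore non-increasing.

X is the feature representation used downstream for classification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .net_builder import HeteroNetwork

_EMBED_METHODS = ("svd", "kl_gradient")


@dataclass
class RwrConfig:
    """RWR parameters: restart probability, L1 convergence tolerance and
    iteration cap. Defaults follow the common Mashup convention."""

    restart_prob: float = 0.5
    tol: float = 1e-8
    max_iter: int = 1000

    def __post_init__(self) -> None:
        if not 0.0 < self.restart_prob <= 1.0:
            raise ValueError(f"restart_prob must be in (0, 1], got {self.restart_prob}")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be at least 1")


@dataclass
class DiffusionState:
    """n x n matrix of RWR stationary distributions; column i is the
    diffusion state seeded at node i (canonical node order)."""

    matrix: np.ndarray
    node_ids: list[str] = field(default_factory=list)
    n_unconverged: int = 0

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass
class EmbeddingModel:
    """Fitted factorization: node features X (n x d), context vectors W
    (n x d), and the per-iteration KL objective for the gradient method."""

    X: np.ndarray
    W: np.ndarray
    d: int
    objective_trace: list[float] | None = None
    node_ids: list[str] = field(default_factory=list)


def transition_matrix(network: HeteroNetwork) -> np.ndarray:
    """Column-stochastic transition matrix of the weighted network.

    Entry (i, j) = weight(i, j) / weighted degree of j, in canonical node
    order. Requires every node to have at least one edge; run
    :func:`hetpath.net_builder.drop_isolated` first otherwise.
    """
    A = network.adjacency_matrix()
    degrees = A.sum(axis=0)
    if np.any(degrees == 0):
        isolated = [network.nodes[i] for i in np.flatnonzero(degrees == 0)]
        raise ValueError(
            f"network has isolated nodes {isolated[:5]}; apply drop_isolated first"
        )
    return A / degrees[np.newaxis, :]


def rwr(P: np.ndarray, seed: int, cfg: RwrConfig | None = None) -> np.ndarray:
    """Power-iterate the RWR fixed-point equation from the seed indicator.

    Returns the converged probability vector (sums to 1, nonnegative). If
    the iteration cap is hit first, warns and returns the current iterate.
    """
    cfg = cfg or RwrConfig()
    n = P.shape[0]
    if P.shape != (n, n):
        raise ValueError("P must be square")
    if not 0 <= seed < n:
        raise IndexError(f"seed index {seed} out of range for n={n}")
    e = np.zeros(n)
    e[seed] = 1.0
    r = cfg.restart_prob
    p = e.copy()
    for _ in range(cfg.max_iter):
        p_next = (1.0 - r) * (P @ p) + r * e
        delta = np.abs(p_next - p).sum()
        p = p_next
        if delta < cfg.tol:
            return p
    warnings.warn(f"RWR from seed {seed} unconverged after {cfg.max_iter} iterations")
    return p


def diffusion_states(
    network: HeteroNetwork, cfg: RwrConfig | None = None
) -> DiffusionState:
    """Run RWR from every node; column i of the result is the diffusion
    state of node i. Deterministic given the network and configuration.

    All seeds are iterated simultaneously in matrix form, which is exactly
    the per-seed power iteration applied column-wise.
    """
    cfg = cfg or RwrConfig()
    P = transition_matrix(network)
    n = P.shape[0]
    r = cfg.restart_prob
    identity = np.eye(n)
    Q = identity.copy()
    unconverged = n
    for _ in range(cfg.max_iter):
        Q_next = (1.0 - r) * (P @ Q) + r * identity
        deltas = np.abs(Q_next - Q).sum(axis=0)
        Q = Q_next
        unconverged = int(np.count_nonzero(deltas >= cfg.tol))
        if unconverged == 0:
            break
    if unconverged:
        warnings.warn(f"{unconverged} RWR seeds unconverged after {cfg.max_iter} iterations")
    return DiffusionState(Q, list(network.nodes), unconverged)


def _column_log_softmax(scores: np.ndarray) -> np.ndarray:
    return scores - logsumexp(scores, axis=0, keepdims=True)


def kl_objective(X: np.ndarray, W: np.ndarray, V: np.ndarray) -> float:
    """Mean KL divergence between diffusion columns and the softmax model.

    Column i of the model is softmax over k of X_i . W_k. Terms where
    V[k, i] = 0 contribute zero.
    """
    n = V.shape[0]
    if V.shape != (n, n) or X.shape[0] != n or W.shape != X.shape:
        raise ValueError("inconsistent shapes for X, W, V")
    log_model = _column_log_softmax(W @ X.T)
    mask = V > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(mask, V * (np.log(np.where(mask, V, 1.0)) - log_model), 0.0)
    value = float(terms.sum() / n)
    # KL is nonnegative; snap float-cancellation residue to zero
    return 0.0 if -1e-9 < value < 0.0 else value


def _svd_embed(V: np.ndarray, d: int, eps: float) -> tuple[np.ndarray, np.ndarray]:
    L = np.log(V + eps)
    U, s, Vt = np.linalg.svd(L, full_matrices=False)
    scale = np.sqrt(s[:d])
    W = U[:, :d] * scale
    X = Vt[:d].T * scale
    return X, W


def mashup_embed(
    V: DiffusionState | np.ndarray,
    d: int,
    method: str = "svd",
    seed: int = 0,
    iters: int = 500,
    lr: float = 0.1,
    eps: float | None = None,
) -> EmbeddingModel:
    """Factorize the diffusion-state matrix into d-dimensional embeddings.

    ``eps`` is a pseudo-count added inside the log for the SVD method to keep
    it finite when diffusion entries are exactly zero (disconnected
    networks); by default it is 0 for a strictly positive V and 1/n
    otherwise. The gradient method works on V directly and needs no
    smoothing.
    """
    node_ids: list[str] = []
    if isinstance(V, DiffusionState):
        node_ids = V.node_ids
        V = V.matrix
    n = V.shape[0]
    if not 1 <= d <= n:
        raise ValueError(f"embedding dimension d={d} must satisfy 1 <= d <= n={n}")
    if method not in _EMBED_METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {_EMBED_METHODS}")

    if method == "svd":
        if eps is None:
            eps = 0.0 if V.min() > 0 else 1.0 / n
        X, W = _svd_embed(V, d, eps)
        return EmbeddingModel(X, W, d, None, node_ids)

    rng = np.random.default_rng(seed)
    X = rng.uniform(-0.01, 0.01, size=(n, d))
    W = rng.uniform(-0.01, 0.01, size=(n, d))
    obj = kl_objective(X, W, V)
    if not np.isfinite(obj):
        raise FloatingPointError("non-finite KL objective at initialization")
    trace = [obj]
    step = lr
    for it in range(iters):
        log_model = _column_log_softmax(W @ X.T)
        G = (np.exp(log_model) - V) / n
        X_new = X - step * (G.T @ W)
        W_new = W - step * (G @ X)
        obj_new = kl_objective(X_new, W_new, V)
        if not np.isfinite(obj_new):
            raise FloatingPointError(f"non-finite KL objective at iteration {it + 1}")
        if obj_new <= obj:
            X, W, obj = X_new, W_new, obj_new
            step *= 1.05
        else:
            step *= 0.5  # reject the step, keep the previous iterate
        trace.append(obj)
    return EmbeddingModel(X, W, d, trace, node_ids)


def write_embedding(model: EmbeddingModel, kinds: list[str], path) -> None:
    """Embedding TSV: node id, kind, then d feature values at 8 decimals."""
    if len(model.node_ids) != model.X.shape[0]:
        raise ValueError("embedding model lacks node ids; cannot write TSV")
    with open(path, "wt", encoding="utf-8") as fh:
        cols = "\t".join(f"x{j}" for j in range(model.d))
        fh.write(f"node\tkind\t{cols}\n")
        for node, kind, row in zip(model.node_ids, kinds, model.X):
            values = "\t".join(f"{v:.8f}" for v in row)
            fh.write(f"{node}\t{kind}\t{values}\n")


def read_embedding(path) -> tuple[list[str], list[str], np.ndarray]:
    """Read an embedding TSV back as (node ids, kinds, feature matrix)."""
    nodes: list[str] = []
    kinds: list[str] = []
    rows: list[list[float]] = []
    with open(path, "rt", encoding="utf-8") as fh:
        fh.readline()
        for line in fh:
            line = line.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("\t")
            nodes.append(fields[0])
            kinds.append(fields[1])
            rows.append([float(v) for v in fields[2:]])
    return nodes, kinds, np.asarray(rows)
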