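"""Aranda-activated graph attention classifier over selected features.

Features act as graph nodes: one graph is shared across samples and each
node carries the sample's scalar value for that feature. The adjacency
comes from a |Pearson correlation| k-nearest-neighbor graph computed on
training rows only (self-loops always included; a fully connected option
exists for small feature counts). A sample is classified by

    H0_u   = x_u * Wg + bg                       (node embedding)
    e_uv   = LeakyReLU(a^T [H0_u || H0_v])       (attention logits)
    alpha  = softmax over v in N(u)
    H1_u   = phi_Aranda( sum_v alpha_uv H0_v )   (node update)
    r      = mean_u H1_u                         (readout)
    y_hat  = softmax(Wo r + bo)

with the asymmetric Aranda-Ordaz transformation
phi(z) = 1 - (1 + lambda e^z)^(-1/lambda) as the node nonlinearity
(lambda = 1 recovers the logistic function). Training minimizes
cross-entropy with full-batch Adam, hand-derived gradients, and early
stopping on an inner validation split. Ablation flags swap the Aranda
activation for ReLU or the whole graph head for a plain multilayer
perceptron.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

NEG_INF = -1e30


def aranda_activation(z: np.ndarray, lam: float) -> np.ndarray:
    """Aranda-Ordaz link: phi(z) = 1 - (1 + lam * e^z)^(-1/lam).

    Strictly increasing, maps R onto (0, 1); lam = 1 is exactly the
    logistic function. Computed in log space for stability.
    """
    if lam <= 0:
        raise ValueError("lambda must be positive")
    z = np.asarray(z, dtype=float)
    u = np.logaddexp(0.0, z + np.log(lam))  # log(1 + lam e^z)
    return -np.expm1(-u / lam)


def aranda_derivative(z: np.ndarray, lam: float) -> np.ndarray:
    """phi'(z) = e^z (1 + lam e^z)^(-(1 + lam)/lam)."""
    z = np.asarray(z, dtype=float)
    u = np.logaddexp(0.0, z + np.log(lam))
    return np.exp(z - (1.0 + 1.0 / lam) * u)


# ---------------------------------------------------------------------------
# Feature graph
# ---------------------------------------------------------------------------


def build_feature_graph(
    X_train: np.ndarray, k: int = 10, fully_connected: bool = False
) -> np.ndarray:
    """Boolean adjacency over feature nodes with guaranteed self-loops.

    Edges join each feature to its k strongest |Pearson| correlates on
    the training rows; the matrix is symmetrized by union.
    """
    X = np.asarray(X_train, dtype=float)
    n = X.shape[1]
    if fully_connected or n <= 2:
        return np.ones((n, n), dtype=bool)
    sd = X.std(axis=0)
    Xc = (X - X.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
    corr = np.abs(Xc.T @ Xc) / max(X.shape[0], 1)
    corr[:, sd == 0] = 0.0
    corr[sd == 0, :] = 0.0
    np.fill_diagonal(corr, -np.inf)
    k = min(k, n - 1)
    adj = np.zeros((n, n), dtype=bool)
    nbr = np.argpartition(-corr, k - 1, axis=1)[:, :k]
    rows = np.repeat(np.arange(n), k)
    adj[rows, nbr.ravel()] = True
    adj |= adj.T
    np.fill_diagonal(adj, True)
    return adj


# ---------------------------------------------------------------------------
# Parameters and forward pass
# ---------------------------------------------------------------------------


@dataclass
class EAGATConfig:
    hidden: int = 16
    lam: float = 2.0
    leaky_slope: float = 0.2
    activation: str = "aranda"  # or "relu" (ablation)
    learning_rate: float = 0.05
    epochs: int = 400
    l2: float = 1e-4
    val_fraction: float = 0.15
    patience: int = 40
    seed: int = 0
    graph_k: int = 10
    fully_connected: bool = False


@dataclass
class EAGATParams:
    Wg: np.ndarray  # (n, h): per-node embedding weights
    bg: np.ndarray  # (n, h)
    a: np.ndarray   # (2h,)
    Wo: np.ndarray  # (2, h)
    bo: np.ndarray  # (2,)
    config: EAGATConfig = field(default_factory=EAGATConfig)
    adjacency: Optional[np.ndarray] = None

    def flat(self) -> list[np.ndarray]:
        return [self.Wg, self.bg, self.a, self.Wo, self.bo]


def init_eagat(n_features: int, config: EAGATConfig,
               adjacency: Optional[np.ndarray] = None) -> EAGATParams:
    rng = np.random.default_rng(config.seed)
    h = config.hidden
    return EAGATParams(
        Wg=rng.standard_normal((n_features, h)) * 0.5,
        bg=rng.standard_normal((n_features, h)) * 0.1,
        a=rng.standard_normal(2 * h) * 0.5,
        Wo=rng.standard_normal((2, h)) * 0.5,
        bo=np.zeros(2),
        config=config,
        adjacency=adjacency,
    )


def attention_coefficients(
    H0: np.ndarray, adjacency: np.ndarray, a: np.ndarray, leaky_slope: float = 0.2
) -> np.ndarray:
    """Neighborhood-normalized attention; each row sums to one.

    ``H0`` is (B, n, h); returns alpha of shape (B, n, n) with zeros off
    the neighborhood.
    """
    if not adjacency.any(axis=1).all():
        raise ValueError("every node needs at least one neighbor (self-loop)")
    h = H0.shape[2]
    a1, a2 = a[:h], a[h:]
    f = H0 @ a1  # (B, n)
    g = H0 @ a2
    pre = f[:, :, None] + g[:, None, :]
    pre = np.where(pre > 0, pre, leaky_slope * pre)
    pre = np.where(adjacency[None, :, :], pre, NEG_INF)
    pre = pre - pre.max(axis=2, keepdims=True)
    ex = np.exp(pre) * adjacency[None, :, :]
    return ex / ex.sum(axis=2, keepdims=True)


def forward(
    X: np.ndarray, params: EAGATParams, return_cache: bool = False
):
    """Class probabilities (B, 2) for samples over the shared feature graph."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    adj = params.adjacency
    if adj is None or adj.shape[0] != X.shape[1] or params.Wg.shape[0] != X.shape[1]:
        raise ValueError("feature count does not match the feature graph")
    cfg = params.config
    h = cfg.hidden
    H0 = X[:, :, None] * params.Wg[None, :, :] + params.bg[None, :, :]
    alpha = attention_coefficients(H0, adj, params.a, cfg.leaky_slope)
    M = np.einsum("buv,bvh->buh", alpha, H0, optimize=True)
    if cfg.activation == "aranda":
        H1 = aranda_activation(M, cfg.lam)
    elif cfg.activation == "relu":
        H1 = np.maximum(M, 0.0)
    else:
        raise ValueError(f"unknown activation {cfg.activation!r}")
    r = H1.mean(axis=1)
    logits = r @ params.Wo.T + params.bo
    logits = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(logits)
    probs = ez / ez.sum(axis=1, keepdims=True)
    if return_cache:
        a1, a2 = params.a[:h], params.a[h:]
        f = H0 @ a1
        g = H0 @ a2
        pre = f[:, :, None] + g[:, None, :]
        cache = dict(X=X, H0=H0, alpha=alpha, M=M, H1=H1, r=r, probs=probs,
                     pre=pre)
        return probs, cache
    return probs


def loss_and_grads(
    X: np.ndarray, y: np.ndarray, params: EAGATParams
) -> tuple[float, dict[str, np.ndarray]]:
    """Cross-entropy (with L2) and analytic gradients for all parameters."""
    cfg = params.config
    h = cfg.hidden
    probs, cache = forward(X, params, return_cache=True)
    B, n = cache["X"].shape
    y = np.asarray(y, dtype=int)
    onehot = np.zeros((B, 2))
    onehot[np.arange(B), y] = 1.0
    ce = -np.log(probs[np.arange(B), y] + 1e-12).mean()
    l2 = cfg.l2 * (
        (params.Wg**2).sum() + (params.a**2).sum() + (params.Wo**2).sum()
    )
    loss = ce + l2

    H0, alpha, M, H1 = cache["H0"], cache["alpha"], cache["M"], cache["H1"]
    dlogits = (probs - onehot) / B
    dWo = dlogits.T @ cache["r"] + 2 * cfg.l2 * params.Wo
    dbo = dlogits.sum(axis=0)
    dr = dlogits @ params.Wo                       # (B, h)
    dH1 = np.repeat(dr[:, None, :], n, axis=1) / n  # (B, n, h)
    if cfg.activation == "aranda":
        dM = dH1 * aranda_derivative(M, cfg.lam)
    else:
        dM = dH1 * (M > 0)
    dalpha = np.einsum("buh,bvh->buv", dM, H0, optimize=True)
    dH0 = np.einsum("buv,buh->bvh", alpha, dM, optimize=True)
    # softmax backward per attention row
    inner = (alpha * dalpha).sum(axis=2, keepdims=True)
    dE = alpha * (dalpha - inner)
    dpre = dE * np.where(cache["pre"] > 0, 1.0, cfg.leaky_slope)
    df = dpre.sum(axis=2)  # (B, n)
    dg = dpre.sum(axis=1)
    a1, a2 = params.a[:h], params.a[h:]
    dH0 += df[:, :, None] * a1[None, None, :] + dg[:, :, None] * a2[None, None, :]
    da1 = np.einsum("bu,buh->h", df, H0, optimize=True)
    da2 = np.einsum("bu,buh->h", dg, H0, optimize=True)
    da = np.concatenate([da1, da2]) + 2 * cfg.l2 * params.a
    dWg = np.einsum("bu,buh->uh", cache["X"], dH0, optimize=True) + 2 * cfg.l2 * params.Wg
    dbg = dH0.sum(axis=0)
    return loss, {"Wg": dWg, "bg": dbg, "a": da, "Wo": dWo, "bo": dbo}


def train(
    X: np.ndarray,
    y: np.ndarray,
    config: Optional[EAGATConfig] = None,
    adjacency: Optional[np.ndarray] = None,
) -> EAGATParams:
    """Fit EA-GAT with full-batch Adam and early stopping.

    The feature graph, inner validation split, and all parameter
    initialization derive from the config seed, so training is
    reproducible. Raises on single-class input.
    """
    from sklearn.model_selection import train_test_split

    config = config or EAGATConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("training requires both classes")
    if adjacency is None:
        adjacency = build_feature_graph(
            X, k=config.graph_k, fully_connected=config.fully_connected
        )
    idx_tr, idx_va = train_test_split(
        np.arange(len(y)), test_size=config.val_fraction, stratify=y,
        random_state=config.seed,
    )
    params = init_eagat(X.shape[1], config, adjacency)

    names = ["Wg", "bg", "a", "Wo", "bo"]
    m = {k: np.zeros_like(getattr(params, k)) for k in names}
    v = {k: np.zeros_like(getattr(params, k)) for k in names}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    best_val = np.inf
    best_snapshot = {k: getattr(params, k).copy() for k in names}
    accepted_train_losses: list[float] = []
    stall = 0
    for epoch in range(1, config.epochs + 1):
        loss, grads = loss_and_grads(X[idx_tr], y[idx_tr], params)
        for k in names:
            m[k] = beta1 * m[k] + (1 - beta1) * grads[k]
            v[k] = beta2 * v[k] + (1 - beta2) * grads[k] ** 2
            mh = m[k] / (1 - beta1**epoch)
            vh = v[k] / (1 - beta2**epoch)
            getattr(params, k)[...] -= config.learning_rate * mh / (np.sqrt(vh) + eps)
        val_probs = forward(X[idx_va], params)
        val_loss = -np.log(
            val_probs[np.arange(len(idx_va)), y[idx_va]] + 1e-12
        ).mean()
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_snapshot = {k: getattr(params, k).copy() for k in names}
            accepted_train_losses.append(loss)
            stall = 0
        else:
            stall += 1
            if stall >= config.patience:
                break
    for k in names:
        getattr(params, k)[...] = best_snapshot[k]
    params.accepted_train_losses = accepted_train_losses
    return params


def predict_proba(X: np.ndarray, params: EAGATParams) -> np.ndarray:
    return forward(X, params)


def sensitivity_score(X: np.ndarray, params: EAGATParams) -> np.ndarray:
    """P(sensitive): probability of class 1."""
    return forward(X, params)[:, 1]


# ---------------------------------------------------------------------------
# Non-graph ablation baseline
# ---------------------------------------------------------------------------


def train_mlp(X: np.ndarray, y: np.ndarray, seed: int = 0):
    """Plain multilayer-perceptron baseline for the non-graph ablation."""
    from sklearn.neural_network import MLPClassifier

    clf = MLPClassifier(
        hidden_layer_sizes=(32,), max_iter=800, random_state=seed,
        early_stopping=True,
    )
    clf.fit(np.asarray(X, dtype=float), np.asarray(y, dtype=int))
    return clf
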