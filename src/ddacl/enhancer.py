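"""Contrastive cross-modal feature enhancement.

Pooled drug vectors and projected disease vectors are mapped into a shared
space by two projection heads (linear -> ReLU -> linear -> layer norm).  For a
batch of known drug-disease pairs the temperature-scaled similarity matrix
S_ij = z_drug_i . z_disease_j / tau is formed, and an InfoNCE loss pushes each
drug's matched disease above the in-batch alternatives:

    loss(d, i) = -log( exp(S_di) / sum_j exp(S_dj) )

reduced as the mean over positives (batch-size independent; the summed form
differs only by the constant factor |positives|).  A third head turns the
concatenated projected pair into an interaction feature; the final enhanced
feature concatenates [drug ; disease ; z_drug ; z_disease ; z_interact].

Everything is plain NumPy with hand-written gradients and Adam, so training is
deterministic per seed and dependency-free.  When token matrices are supplied,
the attention-pooling network is trained jointly under the same objective;
otherwise drug vectors are treated as fixed inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ddacl.encoding import AttentionPoolParams, TokenMatrix
from ddacl.errors import (
    ConfigurationError,
    InputError,
    NumericError,
    TrainingError,
)

LN_EPS = 1e-5


# ---------------------------------------------------------------------------
# heads
# ---------------------------------------------------------------------------


class ProjectionHead:
    """Two affine layers with ReLU between and layer normalization on top.

    ``forward`` caches activations; ``backward`` returns the gradient w.r.t.
    the input and accumulates parameter gradients in ``grads``.
    """

    def __init__(self, input_dim: int, proj_dim: int, seed: int = 0):
        if proj_dim < 1:
            raise ConfigurationError("proj_dim must be >= 1")
        rng = np.random.default_rng(seed)
        self.input_dim = input_dim
        self.proj_dim = proj_dim
        self.params = {
            "W1": rng.standard_normal((input_dim, proj_dim)) / np.sqrt(input_dim),
            "b1": np.zeros(proj_dim),
            "W2": rng.standard_normal((proj_dim, proj_dim)) / np.sqrt(proj_dim),
            "b2": np.zeros(proj_dim),
            "gamma": np.ones(proj_dim),
            "beta": np.zeros(proj_dim),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._cache = None

    def forward(self, X: np.ndarray, train: bool = False) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.input_dim:
            raise ConfigurationError(
                f"projection head expects input dim {self.input_dim}, got {X.shape[1]}")
        p = self.params
        H1 = X @ p["W1"] + p["b1"]
        A = np.maximum(H1, 0.0)
        H2 = A @ p["W2"] + p["b2"]
        mu = H2.mean(axis=1, keepdims=True)
        var = H2.var(axis=1, keepdims=True)
        std = np.sqrt(var + LN_EPS)
        xhat = (H2 - mu) / std
        Y = p["gamma"] * xhat + p["beta"]
        if train:
            self._cache = (X, H1, A, std, xhat)
        return Y

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)

    def project(self, v: np.ndarray) -> np.ndarray:
        """Single-vector convenience wrapper around ``forward``."""
        return self.forward(np.asarray(v, dtype=float).reshape(1, -1))[0]

    def backward(self, dY: np.ndarray) -> np.ndarray:
        if self._cache is None:
            raise TrainingError("backward called before a training-mode forward")
        X, H1, A, std, xhat = self._cache
        p, g = self.params, self.grads
        D = self.proj_dim
        g["gamma"] += (dY * xhat).sum(axis=0)
        g["beta"] += dY.sum(axis=0)
        dxhat = dY * p["gamma"]
        # layer-norm backward, per row
        dH2 = (dxhat - dxhat.mean(axis=1, keepdims=True)
               - xhat * (dxhat * xhat).mean(axis=1, keepdims=True)) / std
        g["W2"] += A.T @ dH2
        g["b2"] += dH2.sum(axis=0)
        dA = dH2 @ p["W2"].T
        dH1 = dA * (H1 > 0)
        g["W1"] += X.T @ dH1
        g["b1"] += dH1.sum(axis=0)
        return dH1 @ p["W1"].T

    def zero_grad(self):
        for v in self.grads.values():
            v[...] = 0.0


class InteractionHead:
    """Affine + ReLU map from a concatenated projected pair to an interaction feature.

    Receives no gradient from the contrastive loss (the interaction feature
    does not enter the similarity matrix), so it acts as a fixed random
    cross-modal feature map.
    """

    def __init__(self, proj_dim: int, interact_dim: int | None = None, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.proj_dim = proj_dim
        self.interact_dim = interact_dim or proj_dim
        self.W = rng.standard_normal((2 * proj_dim, self.interact_dim)) / np.sqrt(2 * proj_dim)
        self.b = np.zeros(self.interact_dim)

    def forward(self, Zd: np.ndarray, Zi: np.ndarray) -> np.ndarray:
        Zd = np.atleast_2d(np.asarray(Zd, dtype=float))
        Zi = np.atleast_2d(np.asarray(Zi, dtype=float))
        if Zd.shape[1] != self.proj_dim or Zi.shape[1] != self.proj_dim:
            raise ConfigurationError("interaction head inputs must have proj_dim columns")
        C = np.concatenate([Zd, Zi], axis=1)
        return np.maximum(C @ self.W + self.b, 0.0)

    def interact(self, zd: np.ndarray, zi: np.ndarray) -> np.ndarray:
        return self.forward(zd.reshape(1, -1), zi.reshape(1, -1))[0]


# ---------------------------------------------------------------------------
# enhanced features
# ---------------------------------------------------------------------------


@dataclass
class EnhancedFeature:
    """Concatenation [drug ; disease ; z_drug ; z_disease ; z_interact]."""

    values: np.ndarray
    block_dims: tuple[int, ...]

    def __post_init__(self):
        if self.values.shape[0] != sum(self.block_dims):
            raise InputError("enhanced feature length does not match its block dims")

    def split(self) -> list[np.ndarray]:
        return np.split(self.values, np.cumsum(self.block_dims)[:-1])


def assemble_enhanced(M_d: np.ndarray, D_i: np.ndarray,
                      zd: np.ndarray | None = None, zi: np.ndarray | None = None,
                      zint: np.ndarray | None = None) -> EnhancedFeature:
    """Concatenate the feature blocks in fixed order.

    With ``zd``/``zi``/``zint`` all None the result is the contrastive-free
    ablation feature [drug ; disease].  A partially supplied projected triple
    is an assembly error.
    """
    named = {"drug": M_d, "disease": D_i}
    proj = {"z_drug": zd, "z_disease": zi, "z_interact": zint}
    if any(v is None for v in named.values()):
        missing = [k for k, v in named.items() if v is None]
        raise InputError(f"missing feature block(s): {', '.join(missing)}")
    if any(v is not None for v in proj.values()):
        missing = [k for k, v in proj.items() if v is None]
        if missing:
            raise InputError(f"missing feature block(s): {', '.join(missing)}")
        named.update(proj)
    blocks = [np.asarray(v, dtype=float).ravel() for v in named.values()]
    for name, b in zip(named, blocks):
        if not np.all(np.isfinite(b)):
            raise NumericError(f"feature block {name!r} contains non-finite entries")
    return EnhancedFeature(values=np.concatenate(blocks),
                           block_dims=tuple(len(b) for b in blocks))


# ---------------------------------------------------------------------------
# similarity + loss
# ---------------------------------------------------------------------------


@dataclass
class SimMatrix:
    values: np.ndarray  # (B, B)
    tau: float


@dataclass
class ContrastiveLoss:
    value: float
    per_pair: np.ndarray


def similarity_matrix(Zd: np.ndarray, Zi: np.ndarray, tau: float) -> SimMatrix:
    """Temperature-scaled pairwise dot products between projected batches."""
    if tau <= 0:
        raise ConfigurationError("temperature tau must be positive")
    Zd = np.atleast_2d(np.asarray(Zd, dtype=float))
    Zi = np.atleast_2d(np.asarray(Zi, dtype=float))
    if Zd.shape[0] != Zi.shape[0]:
        raise ConfigurationError("similarity matrix requires equal batch sizes")
    return SimMatrix(values=(Zd @ Zi.T) / tau, tau=float(tau))


def infonce_loss(S: SimMatrix, positives: list[tuple[int, int]] | None = None) -> ContrastiveLoss:
    """InfoNCE over rows of the similarity matrix, mean-reduced over positives.

    Each positive (d, i) contributes -log softmax_i(S_d.), computed with
    max-subtraction so arbitrarily large scores stay finite.  ``positives``
    defaults to the diagonal (the in-batch matched pairs).
    """
    V = S.values
    B = V.shape[0]
    if positives is None:
        positives = [(k, k) for k in range(B)]
    if not positives:
        raise TrainingError("infonce_loss requires at least one positive pair")
    per = np.empty(len(positives))
    for n, (d, i) in enumerate(positives):
        row = V[d]
        if not np.any(np.isfinite(row)):
            raise NumericError(f"similarity row {d} has no finite entries")
        m = row.max()
        lse = m + np.log(np.exp(row - m).sum())
        per[n] = lse - row[i]
    return ContrastiveLoss(value=float(per.mean()), per_pair=per)


def _infonce_grad_diag(S: SimMatrix) -> np.ndarray:
    """d(mean diagonal InfoNCE)/dS for diagonal positives."""
    V = S.values
    B = V.shape[0]
    m = V.max(axis=1, keepdims=True)
    E = np.exp(V - m)
    P = E / E.sum(axis=1, keepdims=True)
    return (P - np.eye(B)) / B


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


@dataclass
class EnhancerConfig:
    """Knobs of the contrastive stage.

    tau and proj_dim default to the tuned values (0.25 and 256); the learning
    rate matches the published training setting.  interact_dim defaults to
    proj_dim.
    """

    proj_dim: int = 256
    interact_dim: int | None = None
    tau: float = 0.25
    batch_size: int = 128
    epochs: int = 25
    learning_rate: float = 5e-4
    early_stopping_patience: int = 8
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.tau <= 0:
            raise ConfigurationError("tau must be positive")
        if self.proj_dim < 1:
            raise ConfigurationError("proj_dim must be >= 1")


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]):
        self.t += 1
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _pad_token_matrices(mats: list[TokenMatrix]) -> tuple[np.ndarray, np.ndarray]:
    """Stack variable-length token matrices into (n, Lmax, d) with a row mask."""
    Lmax = max(m.L for m in mats)
    d = mats[0].d_tok
    P3 = np.zeros((len(mats), Lmax, d))
    mask = np.zeros((len(mats), Lmax), dtype=bool)
    for k, m in enumerate(mats):
        P3[k, : m.L] = m.values
        mask[k, : m.L] = True
    return P3, mask


def _pool_batch_forward(P3: np.ndarray, mask: np.ndarray, P: AttentionPoolParams):
    """Masked attention pooling over a padded batch; caches for backward."""
    T = np.tanh(P3 @ P.W1.T + P.b1)  # (B, L, h)
    e = T @ P.W2.ravel() + P.b2  # (B, L)
    e = np.where(mask, e, -np.inf)
    z = np.exp(e - e.max(axis=1, keepdims=True))
    alpha = z / z.sum(axis=1, keepdims=True)
    v = (alpha[:, None, :] @ P3)[:, 0, :]
    return v, (P3, T, alpha)


def _pool_batch_backward(dV: np.ndarray, cache, P: AttentionPoolParams,
                         grads: dict[str, np.ndarray]):
    P3, T, alpha = cache
    dalpha = (P3 @ dV[:, :, None])[:, :, 0]  # (B, L)
    de = alpha * (dalpha - (alpha * dalpha).sum(axis=1, keepdims=True))
    grads["W2"] += np.tensordot(de, T, axes=([0, 1], [0, 1])).reshape(1, -1)
    grads["b2"] += de.sum()
    dpre = de[:, :, None] * P.W2.ravel() * (1.0 - T * T)
    grads["W1"] += np.tensordot(dpre, P3, axes=([0, 1], [0, 1]))
    grads["b1"] += dpre.sum(axis=(0, 1))


@dataclass
class TrainedEnhancer:
    drug_head: ProjectionHead
    disease_head: ProjectionHead
    interaction_head: InteractionHead
    attn_params: AttentionPoolParams | None
    config: EnhancerConfig
    loss_history: list[float] = field(default_factory=list)
    val_history: list[float] = field(default_factory=list)

    def enhance_batch(self, Md: np.ndarray, Di: np.ndarray) -> np.ndarray:
        """Enhanced feature rows for aligned drug/disease vector batches."""
        Zd = self.drug_head.forward(Md)
        Zi = self.disease_head.forward(Di)
        Zint = self.interaction_head.forward(Zd, Zi)
        return np.concatenate([Md, Di, Zd, Zi, Zint], axis=1)


def train_enhancer(
    pairs: list[tuple[int, int]],
    drug_vectors: np.ndarray,
    disease_vectors: np.ndarray,
    cfg: EnhancerConfig,
    token_matrices: list[TokenMatrix] | None = None,
    attn_params: AttentionPoolParams | None = None,
) -> TrainedEnhancer:
    """Fit the projection heads (and optionally the attention pool) by InfoNCE.

    ``pairs`` are positive (drug_index, disease_index) pairs indexing into
    ``drug_vectors`` / ``disease_vectors``.  When ``token_matrices`` and
    ``attn_params`` are given, batch drug vectors are re-pooled from tokens at
    every step and the pooling network receives gradients through the loss;
    ``attn_params`` is updated in place and ``drug_vectors`` is then ignored
    for the trained representation.

    A 10% split of the positives (at least one pair when possible) is held out
    for early stopping; training halts once the held-out loss fails to improve
    for ``early_stopping_patience`` epochs.
    """
    if not pairs:
        raise TrainingError("contrastive training requires at least one positive pair")
    drug_vectors = np.asarray(drug_vectors, dtype=float)
    disease_vectors = np.asarray(disease_vectors, dtype=float)
    rng = np.random.default_rng(cfg.seed)

    d_drug = drug_vectors.shape[1] if token_matrices is None else token_matrices[0].d_tok
    d_dis = disease_vectors.shape[1]
    interact_dim = cfg.interact_dim or cfg.proj_dim
    drug_head = ProjectionHead(d_drug, cfg.proj_dim, seed=cfg.seed)
    disease_head = ProjectionHead(d_dis, cfg.proj_dim, seed=cfg.seed + 1)
    inter_head = InteractionHead(cfg.proj_dim, interact_dim, seed=cfg.seed + 2)

    joint_attention = token_matrices is not None and attn_params is not None
    attn_param_dict = None
    P3 = mask = None
    if joint_attention:
        # training runs in float32: halves BLAS time, still deterministic
        attn_params.W1 = attn_params.W1.astype(np.float32)
        attn_params.b1 = attn_params.b1.astype(np.float32)
        attn_params.W2 = attn_params.W2.astype(np.float32)
        attn_param_dict = {"W1": attn_params.W1, "b1": attn_params.b1,
                           "W2": attn_params.W2, "b2": np.array([attn_params.b2], np.float32)}
        P3, mask = _pad_token_matrices(list(token_matrices))
        P3 = P3.astype(np.float32)
    for head in (drug_head, disease_head):
        head.params = {k: v.astype(np.float32) for k, v in head.params.items()}
        head.grads = {k: np.zeros_like(v) for k, v in head.params.items()}
    disease_vectors32 = disease_vectors.astype(np.float32)

    pairs = list(pairs)
    order = rng.permutation(len(pairs))
    n_val = min(max(int(round(cfg.val_fraction * len(pairs))), 1), len(pairs) - 1) \
        if len(pairs) > 1 else 0
    val_pairs = [pairs[k] for k in order[:n_val]]
    train_pairs = [pairs[k] for k in order[n_val:]]

    opt_params: dict[str, np.ndarray] = {}
    for tag, head in (("d", drug_head), ("i", disease_head)):
        for k, v in head.params.items():
            opt_params[f"{tag}.{k}"] = v
    if joint_attention:
        for k, v in attn_param_dict.items():
            opt_params[f"a.{k}"] = v
    opt = _Adam(opt_params, lr=cfg.learning_rate)

    def batch_loss(batch: list[tuple[int, int]], train: bool):
        didx = np.array([d for d, _ in batch])
        pool_cache = None
        uniq = inv = None
        if joint_attention:
            # attn_params.b2 is a python float; refresh from the optimizer view
            attn_params.b2 = float(attn_param_dict["b2"][0])
            uniq, inv = np.unique(didx, return_inverse=True)
            Mu, pool_cache = _pool_batch_forward(P3[uniq], mask[uniq], attn_params)
            Md = Mu[inv]
        else:
            Md = drug_vectors[didx]
        Di = disease_vectors32[[i for _, i in batch]]
        Zd = drug_head.forward(Md, train=train)
        Zi = disease_head.forward(Di, train=train)
        S = similarity_matrix(Zd, Zi, cfg.tau)
        loss = infonce_loss(S)
        if train:
            dS = _infonce_grad_diag(S)
            dZd = dS @ Zi / cfg.tau
            dZi = dS.T @ Zd / cfg.tau
            drug_head.zero_grad()
            disease_head.zero_grad()
            dMd = drug_head.backward(dZd)
            disease_head.backward(dZi)
            grads = {}
            for tag, head in (("d", drug_head), ("i", disease_head)):
                for k, v in head.grads.items():
                    grads[f"{tag}.{k}"] = v
            if joint_attention:
                agrads = {k: np.zeros_like(v) for k, v in attn_param_dict.items()}
                dMu = np.zeros((len(uniq), dMd.shape[1]), dtype=dMd.dtype)
                np.add.at(dMu, inv, dMd)
                _pool_batch_backward(dMu, pool_cache, attn_params, agrads)
                for k in attn_param_dict:
                    grads[f"a.{k}"] = agrads[k]
            opt.step(grads)
            if joint_attention:
                attn_params.b2 = float(attn_param_dict["b2"][0])
        return loss.value

    history: list[float] = []
    val_history: list[float] = []
    best_val = np.inf
    stall = 0
    for _epoch in range(cfg.epochs):
        perm = rng.permutation(len(train_pairs))
        epoch_losses = []
        for start in range(0, len(train_pairs), cfg.batch_size):
            batch = [train_pairs[k] for k in perm[start:start + cfg.batch_size]]
            epoch_losses.append(batch_loss(batch, train=True))
        history.append(float(np.mean(epoch_losses)))
        if val_pairs:
            val = batch_loss(val_pairs, train=False)
            val_history.append(val)
            if val < best_val - 1e-6:
                best_val = val
                stall = 0
            else:
                stall += 1
                if stall >= cfg.early_stopping_patience:
                    break

    for head in (drug_head, disease_head):
        head.params = {k: v.astype(np.float64) for k, v in head.params.items()}
        head.grads = {k: np.zeros_like(v) for k, v in head.params.items()}
    if joint_attention:
        attn_params.W1 = attn_params.W1.astype(np.float64)
        attn_params.b1 = attn_params.b1.astype(np.float64)
        attn_params.W2 = attn_params.W2.astype(np.float64)
        attn_params.b2 = float(attn_param_dict["b2"][0])

    return TrainedEnhancer(
        drug_head=drug_head,
        disease_head=disease_head,
        interaction_head=inter_head,
        attn_params=attn_params if joint_attention else None,
        config=cfg,
        loss_history=history,
        val_history=val_history,
    )


def untrained_enhancer(d_drug: int, d_dis: int, cfg: EnhancerConfig) -> TrainedEnhancer:
    """Seeded random heads with no training — the baseline for benefit checks."""
    interact_dim = cfg.interact_dim or cfg.proj_dim
    return TrainedEnhancer(
        drug_head=ProjectionHead(d_drug, cfg.proj_dim, seed=cfg.seed),
        disease_head=ProjectionHead(d_dis, cfg.proj_dim, seed=cfg.seed + 1),
        interaction_head=InteractionHead(cfg.proj_dim, interact_dim, seed=cfg.seed + 2),
        attn_params=None,
        config=cfg,
    )
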