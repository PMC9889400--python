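"""Attention-based multiple-instance learning (MIL) classifier.

The client-side model for weakly supervised slide classification.  A slide
is a bag ``X`` of K instance feature vectors; only the bag label is
observed, and a bag is positive iff at least one instance is positive.

The classifier scores instances with a gated attention network

    a_k  proportional to  exp{ w^T ( tanh(V x_k) * sigm(U x_k) ) },

pools the bag into a single D-vector (attention-weighted sum by default;
mean and max pooling are provided as ablation baselines), and maps the
pooled vector through a small MLP ``rho`` to a bag logit.  Training
minimises binary cross-entropy on the sigmoid of that logit.

Everything, including the exact gradient of the bag loss with respect to
every parameter, is implemented directly in numpy: the models are small
enough that hand-written backpropagation is simpler and lighter than a
deep-learning framework, and it keeps the parameter vector trivially
serialisable for the federated hypernetwork.  All operations are
complex-safe so derivative checks can use complex-step differentiation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import truncnorm

__all__ = [
    "MILParameters",
    "AttentionWeights",
    "init_mil_params",
    "bag_label_from_instances",
    "attention_scores",
    "pool",
    "predict_bag",
    "bag_logit",
    "bag_loss",
    "client_gradient",
    "zeros_like_params",
    "POOLING_MODES",
]

POOLING_MODES = ("attention", "max", "mean")

CE_EPS = 1e-12  # probability clamp keeping the loss finite


@dataclass
class MILParameters:
    """Structured weights of the client classifier.

    ``w`` (h,), ``V`` (h, D) and ``U`` (h, D) parameterise the gated
    attention; ``rho`` is an ordered list of affine layers ``(W, b)``
    ending in a 1-d logit, with tanh between hidden layers.
    """

    w: np.ndarray
    V: np.ndarray
    U: np.ndarray
    rho: list[tuple[np.ndarray, np.ndarray]]
    pooling_mode: str = "attention"

    def __post_init__(self) -> None:
        if self.V.shape != self.U.shape:
            raise ValueError("V and U must share shape")
        if self.w.shape != (self.V.shape[0],):
            raise ValueError("w length must equal the attention width h")
        if self.rho[0][0].shape[1] != self.V.shape[1]:
            raise ValueError("rho input width must equal feature dim D")
        if self.rho[-1][0].shape[0] != 1:
            raise ValueError("rho must end in a 1-d logit")
        if self.pooling_mode not in POOLING_MODES:
            raise ValueError(f"unknown pooling mode {self.pooling_mode!r}")

    @property
    def feature_dim(self) -> int:
        return int(self.V.shape[1])


@dataclass
class AttentionWeights:
    """Normalised attention over a bag's K instances (positive, sums to 1)."""

    alpha: np.ndarray


def init_mil_params(
    feature_dim: int,
    attn_dim: int = 16,
    rho_hidden: Sequence[int] = (64,),
    pooling_mode: str = "attention",
    rng: np.random.Generator | None = None,
    init_std: float = 0.02,
) -> MILParameters:
    """Initialise parameters from a truncated normal (cut at +/-2 std)."""
    rng = rng if rng is not None else np.random.default_rng(0)

    def tn(shape):
        n = int(np.prod(shape))
        return truncnorm.rvs(-2, 2, scale=init_std, size=n, random_state=rng).reshape(shape)

    widths = [feature_dim, *rho_hidden, 1]
    rho = [(tn((widths[i + 1], widths[i])), np.zeros(widths[i + 1])) for i in range(len(widths) - 1)]
    return MILParameters(
        w=tn((attn_dim,)),
        V=tn((attn_dim, feature_dim)),
        U=tn((attn_dim, feature_dim)),
        rho=rho,
        pooling_mode=pooling_mode,
    )


def zeros_like_params(params: MILParameters) -> MILParameters:
    return MILParameters(
        w=np.zeros_like(params.w),
        V=np.zeros_like(params.V),
        U=np.zeros_like(params.U),
        rho=[(np.zeros_like(W), np.zeros_like(b)) for W, b in params.rho],
        pooling_mode=params.pooling_mode,
    )


def bag_label_from_instances(instance_labels: Sequence[int]) -> int:
    """Bag label rule: 0 iff every instance label is 0, else 1."""
    y = np.asarray(instance_labels)
    if y.size == 0:
        raise ValueError("bag must contain at least one instance")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("instance labels must be binary")
    return int(y.sum() != 0)


def _sigm(x):
    # complex-safe logistic; for real input uses the overflow-free split form
    if np.iscomplexobj(x):
        return 1.0 / (1.0 + np.exp(-x))
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _softmax(s):
    z = s - np.max(s.real if np.iscomplexobj(s) else s)
    e = np.exp(z)
    return e / e.sum()


def _attention_forward(X, params):
    """Returns (alpha, cache) for the gated attention of a K x D bag."""
    H = np.tanh(params.V @ X.T)  # (h, K)
    G = _sigm(params.U @ X.T)  # (h, K)
    M = H * G
    s = params.w @ M  # (K,) attention logits
    alpha = _softmax(s)
    return alpha, (H, G, M, s)


def attention_scores(X: np.ndarray, params: MILParameters) -> AttentionWeights:
    """Gated-attention weights for a bag, softmax-normalised over instances.

    The softmax subtracts the maximum logit first, so weights stay finite
    for logits up to +/-1e3 and beyond.
    """
    X = np.asarray(X)
    if X.ndim != 2 or X.shape[1] != params.feature_dim:
        raise ValueError(f"expected K x {params.feature_dim} features, got {X.shape}")
    alpha, _ = _attention_forward(X, params)
    return AttentionWeights(alpha=alpha)


def _rho_forward(z, params):
    """MLP forward; tanh between hidden layers, linear final logit."""
    acts = [z]
    a = z
    for li, (W, b) in enumerate(params.rho):
        pre = W @ a + b
        a = pre if li == len(params.rho) - 1 else np.tanh(pre)
        acts.append(a)
    return a[0], acts


def _rho_backward(dlogit, acts, params):
    """Gradients of the scalar logit wrt rho layers and wrt the input z."""
    grads = []
    da = np.asarray([dlogit], dtype=float)
    for li in range(len(params.rho) - 1, -1, -1):
        W, _ = params.rho[li]
        a_in, a_out = acts[li], acts[li + 1]
        dpre = da if li == len(params.rho) - 1 else da * (1.0 - a_out**2)
        grads.append((np.outer(dpre, a_in), dpre.copy()))
        da = W.T @ dpre
    grads.reverse()
    return grads, da  # da is dlogit/dz


def pool(X: np.ndarray, params: MILParameters) -> np.ndarray:
    """Pool a K x D bag into one D-vector under the configured mode.

    attention: alpha-weighted sum of instances.
    mean: per-coordinate average (every instance weighted equally).
    max: the single instance with the largest classifier logit rho(x_k)
    (the "critical instance").
    """
    X = np.asarray(X)
    if X.shape[0] < 1:
        raise ValueError("bag must contain at least one instance")
    mode = params.pooling_mode
    if mode == "attention":
        alpha, _ = _attention_forward(X, params)
        return alpha @ X
    if mode == "mean":
        return X.mean(axis=0)
    if mode == "max":
        logits = np.array([_rho_forward(x, params)[0] for x in X])
        return X[int(np.argmax(logits))]
    raise ValueError(f"unknown pooling mode {mode!r}")


def bag_logit(X: np.ndarray, params: MILParameters) -> float:
    """Raw bag classification logit (pre-sigmoid)."""
    z = pool(np.asarray(X), params)
    logit, _ = _rho_forward(z, params)
    return logit


def predict_bag(bag, params: MILParameters) -> float:
    """Predicted probability that the bag (slide) is positive."""
    X = bag.features if hasattr(bag, "features") else np.asarray(bag)
    if X.shape[1] != params.feature_dim:
        raise ValueError(f"bag feature dim {X.shape[1]} != model dim {params.feature_dim}")
    return float(_sigm(np.asarray([bag_logit(X, params)]))[0])


def bag_loss(y_pred: float, y_gt: int) -> float:
    """Binary cross-entropy with probability clamping at 1e-12."""
    if y_gt not in (0, 1):
        raise ValueError(f"ground-truth label must be 0 or 1, got {y_gt}")
    p = min(max(float(y_pred), CE_EPS), 1.0 - CE_EPS)
    return -(y_gt * np.log(p) + (1 - y_gt) * np.log1p(-p))


def _bag_gradient(X, y, params):
    """Exact gradient of BCE(sigmoid(bag_logit)), plus the loss value."""
    mode = params.pooling_mode
    g = zeros_like_params(params)

    if mode == "attention":
        alpha, (H, G, M, _) = _attention_forward(X, params)
        z = alpha @ X
    elif mode == "mean":
        z = X.mean(axis=0)
    else:  # max
        logits = np.array([_rho_forward(x, params)[0] for x in X])
        kstar = int(np.argmax(logits))
        z = X[kstar]

    logit, acts = _rho_forward(z, params)
    p = _sigm(np.asarray([logit]))[0]
    loss = bag_loss(p, y)
    dlogit = p - y  # d BCE(sigm(t)) / dt, exact while the clamp is inactive

    rho_grads, dz = _rho_backward(dlogit, acts, params)
    g.rho = rho_grads

    if mode == "attention":
        dalpha = X @ dz  # (K,)
        ds = alpha * (dalpha - float(alpha @ dalpha))  # softmax backward
        g.w = M @ ds
        dM = np.outer(params.w, ds)  # (h, K)
        dpreV = dM * G * (1.0 - H**2)
        dpreU = dM * H * G * (1.0 - G)
        g.V = dpreV @ X
        g.U = dpreU @ X
    # mean: z independent of attention params; max: subgradient routes the
    # whole signal through rho at the critical instance (attention grads 0)
    return g, loss


def client_gradient(
    bags: Sequence, params: MILParameters
) -> tuple[MILParameters, float]:
    """Gradient of the mean bag loss over a batch, and that mean loss.

    Returns a structure shaped like ``MILParameters`` holding the
    gradient of every parameter.  Verified against central finite
    differences and complex-step derivatives in the test-suite.
    """
    if len(bags) == 0:
        raise ValueError("empty batch")
    total = zeros_like_params(params)
    loss_sum = 0.0
    for bag in bags:
        X = bag.features if hasattr(bag, "features") else np.asarray(bag[0])
        y = bag.label if hasattr(bag, "label") else int(bag[1])
        g, loss = _bag_gradient(np.asarray(X), y, params)
        loss_sum += loss
        total.w += g.w
        total.V += g.V
        total.U += g.U
        for (tW, tb), (gW, gb) in zip(total.rho, g.rho):
            tW += gW
            tb += gb
    n = len(bags)
    total.w /= n
    total.V /= n
    total.U /= n
    total.rho = [(W / n, b / n) for W, b in total.rho]
    return total, loss_sum / n
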