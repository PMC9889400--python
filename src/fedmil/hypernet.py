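"""Server-side hypernetwork generating per-client MIL classifier weights.

One feed-forward network ``h(v; phi)`` maps a low-dimensional learnable
client embedding ``v_i`` to the full flat parameter vector of that
client's MIL classifier.  All clients share ``phi``, so the hypernetwork
learns a family of personalised models at once, while each embedding
gives its client a site-specific bias.

The server update is the chain rule

    grad_phi L_i = (grad_phi theta_i)^T  grad_theta L_i,

implemented as a vector-Jacobian product through ``h`` (the Jacobian,
of size P x |phi|, is never materialised).  The client embedding is
updated by the same rule.  The per-round payload is two flat P-vectors
(theta down, an update signal up), independent of the size of ``phi``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import truncnorm

from .mil import MILParameters
from .optim import Adam

__all__ = [
    "TargetSpec",
    "ClientEmbedding",
    "HypernetworkState",
    "pack",
    "unpack",
    "packed_size",
    "init_hypernetwork",
    "generate_flat",
    "generate_params",
    "hypernet_vjp",
    "hypernet_update",
    "hnet_objective",
]


@dataclass(frozen=True)
class TargetSpec:
    """Shape record needed to unpack a flat vector into MILParameters."""

    feature_dim: int
    attn_dim: int
    rho_widths: tuple[int, ...]  # layer widths including input D and final 1
    pooling_mode: str = "attention"

    @property
    def packed_size(self) -> int:
        h, d = self.attn_dim, self.feature_dim
        p = h + 2 * h * d
        for a, b in zip(self.rho_widths[:-1], self.rho_widths[1:]):
            p += b * a + b
        return p


def packed_size(spec: TargetSpec) -> int:
    return spec.packed_size


def spec_of(params: MILParameters) -> TargetSpec:
    widths = [params.rho[0][0].shape[1]] + [W.shape[0] for W, _ in params.rho]
    return TargetSpec(
        feature_dim=params.feature_dim,
        attn_dim=params.w.shape[0],
        rho_widths=tuple(widths),
        pooling_mode=params.pooling_mode,
    )


def pack(params: MILParameters) -> np.ndarray:
    """Flatten to the canonical order: w, V (row-major), U, then each rho
    layer's weights before its bias."""
    parts = [params.w.ravel(), params.V.ravel(), params.U.ravel()]
    for W, b in params.rho:
        parts.append(W.ravel())
        parts.append(b.ravel())
    return np.concatenate(parts)


def unpack(flat: np.ndarray, spec: TargetSpec) -> MILParameters:
    flat = np.asarray(flat)
    if flat.shape != (spec.packed_size,):
        raise ValueError(f"expected flat vector of length {spec.packed_size}, got {flat.shape}")
    h, d = spec.attn_dim, spec.feature_dim
    i = 0

    def take(shape):
        nonlocal i
        n = int(np.prod(shape))
        out = flat[i : i + n].reshape(shape)
        i += n
        return out

    w = take((h,))
    V = take((h, d))
    U = take((h, d))
    rho = []
    for a, b in zip(spec.rho_widths[:-1], spec.rho_widths[1:]):
        rho.append((take((b, a)), take((b,))))
    return MILParameters(w=w, V=V, U=U, rho=rho, pooling_mode=spec.pooling_mode)


@dataclass
class ClientEmbedding:
    client_id: str
    v: np.ndarray  # (E,)


@dataclass
class HypernetworkState:
    """Hypernetwork weights phi, client embedding table, and target shapes.

    ``layers`` is a feed-forward stack (ReLU between hidden layers, linear
    P-wide head) mapping an E-dim embedding to the flat MIL parameter
    vector.
    """

    layers: list[tuple[np.ndarray, np.ndarray]]
    embeddings: dict[str, ClientEmbedding]
    target_spec: TargetSpec
    phi_optimizer: Adam = field(default_factory=Adam)
    embed_optimizers: dict[str, Adam] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.layers[-1][0].shape[0] != self.target_spec.packed_size:
            raise ValueError("hypernetwork head width must equal the packed MIL size")

    @property
    def embed_dim(self) -> int:
        return int(self.layers[0][0].shape[1])

    def embedding(self, client_id: str) -> ClientEmbedding:
        try:
            return self.embeddings[client_id]
        except KeyError:
            raise KeyError(f"unknown client {client_id!r}") from None


def init_hypernetwork(
    target_spec: TargetSpec,
    client_ids: list[str],
    embed_dim: int = 8,
    hidden: tuple[int, ...] = (100, 100),
    lr_phi: float = 1e-4,
    lr_embed: float = 1e-4,
    adam_betas: tuple[float, float] = (0.9, 0.999),
    adam_eps: float = 1e-8,
    rng: np.random.Generator | None = None,
    init_std: float = 0.02,
) -> HypernetworkState:
    """Build a hypernetwork with truncated-normal weights (cut +/-2 std)."""
    rng = rng if rng is not None else np.random.default_rng(0)

    def tn(shape):
        n = int(np.prod(shape))
        return truncnorm.rvs(-2, 2, scale=init_std, size=n, random_state=rng).reshape(shape)

    widths = [embed_dim, *hidden, target_spec.packed_size]
    layers = [
        (tn((widths[i + 1], widths[i])), np.zeros(widths[i + 1]))
        for i in range(len(widths) - 1)
    ]
    embeddings = {cid: ClientEmbedding(cid, tn((embed_dim,))) for cid in client_ids}
    b1, b2 = adam_betas
    return HypernetworkState(
        layers=layers,
        embeddings=embeddings,
        target_spec=target_spec,
        phi_optimizer=Adam(lr=lr_phi, beta1=b1, beta2=b2, eps=adam_eps),
        embed_optimizers={
            cid: Adam(lr=lr_embed, beta1=b1, beta2=b2, eps=adam_eps) for cid in client_ids
        },
    )


def _relu(x):
    if np.iscomplexobj(x):
        return np.where(x.real > 0, x, 0.0)
    return np.maximum(x, 0.0)


def _forward(layers, v):
    acts = [v]
    a = v
    for li, (W, b) in enumerate(layers):
        pre = W @ a + b
        a = pre if li == len(layers) - 1 else _relu(pre)
        acts.append(a)
    return a, acts


def generate_flat(state: HypernetworkState, client_id: str) -> np.ndarray:
    """Flat P-dim parameter vector for one client: h(v_i; phi)."""
    emb = state.embedding(client_id)
    out, _ = _forward(state.layers, emb.v)
    return out


def generate_params(state: HypernetworkState, client_id: str) -> MILParameters:
    """Deterministic MIL parameters for a registered client."""
    return unpack(generate_flat(state, client_id), state.target_spec)


def hypernet_vjp(
    state: HypernetworkState, client_id: str, g_theta: np.ndarray
) -> tuple[list[tuple[np.ndarray, np.ndarray]], np.ndarray]:
    """Vector-Jacobian product of the client loss through the hypernetwork.

    Given the client-side cotangent ``g_theta = grad_theta L_i`` (a flat
    P-vector), returns ``grad_phi L_i`` shaped like the layer list and
    ``grad_v L_i`` for the client's embedding, without ever forming the
    P x |phi| Jacobian.
    """
    g_theta = np.asarray(g_theta, dtype=float)
    P = state.target_spec.packed_size
    if g_theta.shape != (P,):
        raise ValueError(f"expected flat gradient of length {P}, got {g_theta.shape}")
    emb = state.embedding(client_id)
    _, acts = _forward(state.layers, emb.v)

    layer_grads: list[tuple[np.ndarray, np.ndarray]] = []
    da = g_theta
    n = len(state.layers)
    for li in range(n - 1, -1, -1):
        W, _ = state.layers[li]
        a_in, a_out = acts[li], acts[li + 1]
        dpre = da if li == n - 1 else da * (a_out > 0)
        layer_grads.append((np.outer(dpre, a_in), dpre.copy()))
        da = W.T @ dpre
    layer_grads.reverse()
    return layer_grads, da


def hypernet_update(
    state: HypernetworkState, client_id: str, g_theta: np.ndarray
) -> HypernetworkState:
    """One chain-rule server step: update phi and the client's embedding.

    Applies the VJP of ``g_theta`` through ``h`` and takes one Adam step
    on phi and one on v_i (each with its own optimiser state).  Other
    clients' embeddings are untouched.  Mutates and returns ``state``.
    """
    layer_grads, dv = hypernet_vjp(state, client_id, g_theta)
    flat_params = [arr for Wb in state.layers for arr in Wb]
    flat_grads = [arr for Wb in layer_grads for arr in Wb]
    state.phi_optimizer.step(flat_params, flat_grads)
    emb = state.embedding(client_id)
    state.embed_optimizers[client_id].step([emb.v], [dv])
    return state


def hnet_objective(client_losses: dict[str, float] | list[float]) -> float:
    """Federation objective: the sum of per-client losses."""
    vals = list(client_losses.values()) if isinstance(client_losses, dict) else list(client_losses)
    return float(np.sum(vals))
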