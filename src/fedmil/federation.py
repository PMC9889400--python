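"""In-process simulation of multi-site training protocols.

Four strategies over the same per-site train/val/test data:

``local_only``
    one independent MIL model per site, trained on that site alone.
``centralized``
    a single model trained on the pooled training data of every site
    (the privacy-free upper bound).
``fedavg``
    federated averaging: each round every client trains locally from the
    current global parameters and uplinks its (optionally noise-injected)
    parameters; the server takes the unweighted mean.
``fedhn``
    federated hypernetwork: each round the server generates each client's
    parameters from its embedding, the client trains locally and returns
    an update signal (parameter delta by default, or an accumulated
    gradient), and the server applies the chain-rule (VJP) update to the
    hypernetwork weights and the client embedding.

All strategies select the best checkpoint by validation loss and are
finally evaluated on the global test set (the union of every site's test
bags); personalised models score each bag with the model of its own site.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import hypernet as hn
from . import mil
from .metrics import MetricsReport, aggregate_runs, report_from_scores
from .optim import Adam
from .synthetic import FeatureBag, SiteDataset

__all__ = [
    "FederationConfig",
    "TrainedRun",
    "fedavg_aggregate",
    "add_parameter_noise",
    "local_train",
    "run_strategy",
    "evaluate_global",
]

STRATEGIES = ("local_only", "centralized", "fedavg", "fedhn")


@dataclass(frozen=True)
class FederationConfig:
    """All hyperparameters of a federated (or baseline) run.

    ``rounds`` of ``local_steps`` Adam steps each; with ``rounds`` unset
    it is derived as ``ceil(epochs_total / local_steps)`` so the total
    local-step budget matches the epoch bookkeeping.  ``noise_sigma``
    unset resolves to 1e-3 for fedavg uplinks and 0 otherwise.
    """

    strategy: str = "fedhn"
    rounds: int | None = None
    local_steps: int = 20
    batch_size: int = 1
    lr_client: float = 1e-4
    lr_phi: float = 1e-4
    lr_embed: float = 1e-4
    adam_betas: tuple[float, float] = (0.9, 0.999)
    adam_eps: float = 1e-8
    noise_sigma: float | None = None
    pooling_mode: str = "attention"
    attn_dim: int = 16
    rho_hidden: tuple[int, ...] = (64,)
    embed_dim: int = 8
    hyper_hidden: tuple[int, ...] = (100, 100)
    update_signal: str = "delta"  # or "gradient"
    epochs_total: int = 200
    repeats: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}; choose from {STRATEGIES}")
        if min(self.lr_client, self.lr_phi, self.lr_embed) <= 0:
            raise ValueError("learning rates must be positive")
        if self.noise_sigma is not None and self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        if self.update_signal not in ("delta", "gradient"):
            raise ValueError("update_signal must be 'delta' or 'gradient'")
        if self.local_steps < 0 or self.batch_size < 1 or self.repeats < 1:
            raise ValueError("invalid step/batch/repeat counts")

    @property
    def resolved_rounds(self) -> int:
        if self.rounds is not None:
            return self.rounds
        return max(1, int(np.ceil(self.epochs_total / max(1, self.local_steps))))

    @property
    def resolved_noise_sigma(self) -> float:
        if self.noise_sigma is not None:
            return self.noise_sigma
        return 1e-3 if self.strategy == "fedavg" else 0.0


@dataclass
class TrainedRun:
    """Outcome of ``run_strategy``: models, traces and global-test metrics."""

    strategy: str
    config: FederationConfig
    seed: int
    models: dict[str, mil.MILParameters] | mil.MILParameters | None = None
    hypernet_state: hn.HypernetworkState | None = None
    loss_traces: list[np.ndarray] = field(default_factory=list)  # one (rounds, clients) array per repeat
    per_run_reports: list[MetricsReport] = field(default_factory=list)
    report: MetricsReport | None = None


def fedavg_aggregate(
    client_params: Sequence[np.ndarray], weights: Sequence[float] | None = None
) -> np.ndarray:
    """Unweighted arithmetic mean of flat client parameter vectors.

    Pass ``weights`` (e.g. per-client sample counts) for the optional
    weighted variant; the default follows the plain 1/n average.
    """
    if len(client_params) == 0:
        raise ValueError("nothing to aggregate")
    mat = np.stack([np.asarray(p, dtype=float) for p in client_params])
    if weights is None:
        return mat.mean(axis=0)
    w = np.asarray(weights, dtype=float)
    if w.shape != (mat.shape[0],) or w.sum() <= 0:
        raise ValueError("weights must be one positive value per client")
    return (w / w.sum()) @ mat


def add_parameter_noise(
    flat_params: np.ndarray, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """Privacy-style perturbation: i.i.d. Gaussian noise on every entry."""
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    flat_params = np.asarray(flat_params, dtype=float)
    if sigma == 0:
        return flat_params.copy()
    return flat_params + sigma * rng.standard_normal(flat_params.shape)


def _mean_loss(bags: Sequence[FeatureBag], params: mil.MILParameters) -> float:
    return float(
        np.mean([mil.bag_loss(mil.predict_bag(b, params), b.label) for b in bags])
    )


def _sample_batch(bags: Sequence[FeatureBag], size: int, rng: np.random.Generator):
    idx = rng.integers(0, len(bags), size=min(size, len(bags)))
    return [bags[i] for i in idx]


def local_train(
    site_train: Sequence[FeatureBag],
    theta0: mil.MILParameters,
    cfg: FederationConfig,
    rng: np.random.Generator,
    steps: int | None = None,
    optimizer: Adam | None = None,
) -> tuple[mil.MILParameters, np.ndarray, list[float]]:
    """Run local Adam steps of the bag loss from ``theta0``.

    Returns the trained parameters, the flat update signal for the server
    (``theta0 - theta_k`` in delta mode, the accumulated batch gradient in
    gradient mode — both aligned with the ascent direction of the loss),
    and the per-step training losses.
    """
    if len(site_train) == 0:
        raise ValueError("empty training set")
    k = cfg.local_steps if steps is None else steps
    spec = hn.spec_of(theta0)
    flat0 = hn.pack(theta0)
    flat = flat0.copy()
    b1, b2 = cfg.adam_betas
    opt = optimizer or Adam(lr=cfg.lr_client, beta1=b1, beta2=b2, eps=cfg.adam_eps)
    losses: list[float] = []
    grad_accum = np.zeros_like(flat)
    for _ in range(k):
        batch = _sample_batch(site_train, cfg.batch_size, rng)
        g, loss = mil.client_gradient(batch, hn.unpack(flat, spec))
        gflat = hn.pack(g)
        grad_accum += gflat
        opt.step([flat], [gflat])
        losses.append(loss)
    signal = (flat0 - flat) if cfg.update_signal == "delta" else grad_accum
    return hn.unpack(flat, spec), signal, losses


def evaluate_global(
    models: dict[str, mil.MILParameters] | mil.MILParameters,
    sites: Sequence[SiteDataset],
    threshold: float = 0.5,
    routing: str = "own",
) -> MetricsReport:
    """Score the global test set (union of all sites' test bags).

    A single shared model scores every bag; a per-site model dict scores
    each bag with its own site's model (``routing='own'``) or with the
    average score over all site models (``routing='average'``).
    """
    y_true: list[int] = []
    y_prob: list[float] = []
    for site in sites:
        if len(site.test) == 0:
            raise ValueError(f"site {site.site_id} has no test bags")
        for bag in site.test:
            if isinstance(models, dict):
                if routing == "own":
                    if bag.site_id not in models:
                        raise KeyError(f"no model for site {bag.site_id}")
                    p = mil.predict_bag(bag, models[bag.site_id])
                elif routing == "average":
                    p = float(np.mean([mil.predict_bag(bag, m) for m in models.values()]))
                else:
                    raise ValueError(f"unknown routing {routing!r}")
            else:
                p = mil.predict_bag(bag, models)
            y_true.append(bag.label)
            y_prob.append(p)
    return report_from_scores(y_true, y_prob, threshold)


def _init_params(cfg: FederationConfig, feature_dim: int, rng) -> mil.MILParameters:
    return mil.init_mil_params(
        feature_dim,
        attn_dim=cfg.attn_dim,
        rho_hidden=cfg.rho_hidden,
        pooling_mode=cfg.pooling_mode,
        rng=rng,
    )


def _run_local_only(sites, cfg, rng_seq):
    models, trace = {}, []
    for site, ss in zip(sites, rng_seq.spawn(len(sites))):
        rng = np.random.default_rng(ss)
        params = _init_params(cfg, site.train[0].feature_dim, rng)
        b1, b2 = cfg.adam_betas
        opt = Adam(lr=cfg.lr_client, beta1=b1, beta2=b2, eps=cfg.adam_eps)
        best, best_val, site_trace = copy.deepcopy(params), np.inf, []
        for _ in range(cfg.resolved_rounds):
            params, _, losses = local_train(site.train, params, cfg, rng, optimizer=opt)
            site_trace.append(np.mean(losses) if losses else np.nan)
            val = _mean_loss(site.val, params) if site.val else losses[-1]
            if val < best_val:
                best_val, best = val, copy.deepcopy(params)
        models[site.site_id] = best
        trace.append(site_trace)
    return models, None, np.asarray(trace).T  # (rounds, clients)


def _run_centralized(sites, cfg, rng_seq):
    rng = np.random.default_rng(rng_seq.spawn(1)[0])
    train = [b for s in sites for b in s.train]
    val = [b for s in sites for b in s.val]
    params = _init_params(cfg, train[0].feature_dim, rng)
    b1, b2 = cfg.adam_betas
    opt = Adam(lr=cfg.lr_client, beta1=b1, beta2=b2, eps=cfg.adam_eps)
    best, best_val, trace = copy.deepcopy(params), np.inf, []
    for _ in range(cfg.resolved_rounds):
        params, _, losses = local_train(train, params, cfg, rng, optimizer=opt)
        trace.append([np.mean(losses)])
        val_loss = _mean_loss(val, params) if val else losses[-1]
        if val_loss < best_val:
            best_val, best = val_loss, copy.deepcopy(params)
    return best, None, np.asarray(trace)


def _run_fedavg(sites, cfg, rng_seq):
    seeds = rng_seq.spawn(len(sites) + 1)
    server_rng = np.random.default_rng(seeds[-1])
    client_rngs = [np.random.default_rng(s) for s in seeds[:-1]]
    spec0 = _init_params(cfg, sites[0].train[0].feature_dim, server_rng)
    spec = hn.spec_of(spec0)
    global_flat = hn.pack(spec0)
    sigma = cfg.resolved_noise_sigma
    val = [b for s in sites for b in s.val]
    best_flat, best_val, trace = global_flat.copy(), np.inf, []
    for _ in range(cfg.resolved_rounds):
        uplinks, round_losses = [], []
        for site, crng in zip(sites, client_rngs):
            theta_k, _, losses = local_train(
                site.train, hn.unpack(global_flat, spec), cfg, crng
            )
            uplinks.append(add_parameter_noise(hn.pack(theta_k), sigma, crng))
            round_losses.append(np.mean(losses))
        global_flat = fedavg_aggregate(uplinks)
        trace.append(round_losses)
        val_loss = _mean_loss(val, hn.unpack(global_flat, spec)) if val else np.mean(round_losses)
        if val_loss < best_val:
            best_val, best_flat = val_loss, global_flat.copy()
    return hn.unpack(best_flat, spec), None, np.asarray(trace)


def _run_fedhn(sites, cfg, rng_seq):
    seeds = rng_seq.spawn(len(sites) + 1)
    server_rng = np.random.default_rng(seeds[-1])
    client_rngs = [np.random.default_rng(s) for s in seeds[:-1]]
    template = _init_params(cfg, sites[0].train[0].feature_dim, server_rng)
    state = hn.init_hypernetwork(
        hn.spec_of(template),
        client_ids=[s.site_id for s in sites],
        embed_dim=cfg.embed_dim,
        hidden=cfg.hyper_hidden,
        lr_phi=cfg.lr_phi,
        lr_embed=cfg.lr_embed,
        adam_betas=cfg.adam_betas,
        adam_eps=cfg.adam_eps,
        rng=server_rng,
    )
    sigma = cfg.resolved_noise_sigma
    models: dict[str, mil.MILParameters] = {}
    best_val = {s.site_id: np.inf for s in sites}
    trace = []
    for _ in range(cfg.resolved_rounds):
        round_losses = []
        for site, crng in zip(sites, client_rngs):
            theta0 = hn.generate_params(state, site.site_id)
            theta_k, signal, losses = local_train(site.train, theta0, cfg, crng)
            signal = add_parameter_noise(signal, sigma, crng)
            hn.hypernet_update(state, site.site_id, signal)
            round_losses.append(np.mean(losses))
            # personalised model selection: each client keeps its best
            # locally-refined checkpoint by its own validation loss
            val_loss = _mean_loss(site.val, theta_k) if site.val else losses[-1]
            if val_loss < best_val[site.site_id]:
                best_val[site.site_id] = val_loss
                models[site.site_id] = copy.deepcopy(theta_k)
        trace.append(round_losses)
    return models, state, np.asarray(trace)


_RUNNERS = {
    "local_only": _run_local_only,
    "centralized": _run_centralized,
    "fedavg": _run_fedavg,
    "fedhn": _run_fedhn,
}


def run_strategy(sites: Sequence[SiteDataset], cfg: FederationConfig) -> TrainedRun:
    """Train under ``cfg.strategy`` and evaluate on the global test set.

    Runs ``cfg.repeats`` independently seeded repetitions (data fixed,
    initialisation and batch order reseeded) and aggregates their
    global-test metrics into mean +/- std.  The models kept on the result
    come from the last repetition.
    """
    if len(sites) == 0:
        raise ValueError("need at least one site")
    for s in sites:
        if len(s.train) == 0:
            raise ValueError(f"site {s.site_id} has no training bags")
    run = TrainedRun(strategy=cfg.strategy, config=cfg, seed=cfg.seed)
    runner = _RUNNERS[cfg.strategy]
    for rep, ss in enumerate(np.random.SeedSequence(cfg.seed).spawn(cfg.repeats)):
        models, state, trace = runner(sites, cfg, ss)
        run.loss_traces.append(trace)
        run.per_run_reports.append(evaluate_global(models, sites))
        if rep == cfg.repeats - 1:
            run.models, run.hypernet_state = models, state
    run.report = aggregate_runs(run.per_run_reports)
    return run
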