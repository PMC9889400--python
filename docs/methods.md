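# Methods

## Problem setting

Weakly supervised whole-slide-image (WSI) classification across `T`
sites that cannot share data. Each slide is a bag of `K` patch feature
vectors in `R^D`; only the slide label is observed, and a slide is
positive iff at least one patch is positive (the standard MIL rule).
The package simulates the whole federation in one process: "clients"
are per-site training loops, the "server" is the aggregation or
hypernetwork code, and the only state exchanged between them is flat
parameter vectors — mirroring what a real deployment would transmit.

## Client classifier

Gated attention MIL. For instance `x_k`, the attention logit is
`wᵀ(tanh(V x_k) ⊙ sigm(U x_k))` with `V, U ∈ R^{h×D}`, `w ∈ R^h`;
weights `α` are the softmax over the bag (max-subtraction stabilised, so
logits up to ±1e3 are safe). The bag representation is `Σ_k α_k x_k`,
classified by an MLP ρ (affine layers, tanh between hidden layers,
1-d logit) through a sigmoid. Loss is binary cross-entropy with the
probability clamped to `[1e-12, 1-1e-12]` so it stays finite.

Ablation pooling modes: *mean* averages all instances; *max* selects
the critical instance with the largest classifier logit `ρ(x_k)` (its
gradient routes entirely through that instance — the standard MIL
max-pooling subgradient). ρ's architecture is a free choice (the
attention mechanism does not constrain it); the default is one hidden
layer, configurable.

Gradients are exact hand-written backpropagation, using
`dL/dlogit = sigm(logit) − y` (exact whenever the clamp is inactive,
i.e. |logit| ≲ 27). All math is complex-safe so tests can check
derivatives by complex-step differentiation, which is accurate to
machine precision and independent of the backprop code path; central
finite differences serve as a second, cruder oracle.

## Server hypernetwork

`h(v_i; φ)`: feed-forward map from an E-dim client embedding to the
P-dim flat client parameter vector (canonical packing order: `w`, `V`
row-major, `U` row-major, ρ layers in order with weights before
biases). Default: hidden widths (100, 100), ReLU, linear P-wide head,
E = 8. The architecture is intentionally free — only the head width is
constrained by P — because the communication cost per round is two
P-vectors (θ down, update signal up), independent of |φ|.

The server update is the chain rule
`∇_φ L_i = (∇_φ θ_i)ᵀ ∇_{θ_i} L_i`, computed as a vector-Jacobian
product by backpropagating the client's flat signal through `h`; the
embedding gradient falls out of the same backward pass. φ and each
`v_i` have separate Adam optimisers. Updating client i never touches
`v_j` (j ≠ i).

The uplink signal is configurable: `delta` (default) sends
`θ_0 − θ_k` after k local steps — the ascent-aligned direction used by
personalised-hypernetwork federated learning — while `gradient` sends
the accumulated per-step batch gradient. Delta is the default because
the local client genuinely optimises θ before reporting back, which is
both cheaper in rounds and closer to how the protocol is described.

## Federation protocols

All strategies share: Adam (β₁=0.9, β₂=0.999, ε=1e-8), truncated-normal
initialisation (std 0.02, cut at ±2 std), batch size 1 bag, `rounds`
of `local_steps` steps, best-checkpoint selection by validation loss,
final evaluation on the global test set (union of all sites' test
bags).

- **local_only** — one model per site; selection by that site's
  validation loss.
- **centralized** — one model on the pooled training data; selection by
  pooled validation loss.
- **fedavg** — per round, every client trains from the current global
  parameters and uplinks them with i.i.d. Gaussian noise (σ defaults to
  1e-3 on this path, a privacy-style perturbation; the distribution and
  scale are package choices); the server takes the unweighted 1/n mean
  (a data-size-weighted variant exists but is off by default). Client
  participation is full — no sampling at these federation sizes.
- **fedhn** — per round and client: generate θ from the hypernetwork,
  train locally, uplink the signal (noise off by default on this path),
  apply the VJP update. Model selection is personalised: each client
  keeps its best locally-refined checkpoint by its own validation loss.

Rounds-vs-epochs bookkeeping: `rounds` may be given directly or derived
as `ceil(epochs_total / local_steps)`; the per-client step budget is
`rounds × local_steps` regardless of strategy, so comparisons are
compute-matched.

Evaluation routing for per-site models: each test bag is scored by its
own site's model (the only routing consistent with personalised
models). Single-site *baselines*, however, are reported the way such
baselines are conventionally tabulated: one site's model scored on the
entire global test set — this is what exposes their failure to
generalise, and is what `ordering_experiment` reports (best and worst
site). An all-models-average-score routing is available for ablation.

Thresholded metrics call a bag positive iff its probability strictly
exceeds 0.5; recall/precision/F1 return 0 on zero denominators so
aggregation never propagates NaNs; AUC follows the Mann–Whitney
convention with half-credit ties; across-run aggregation reports the
sample standard deviation (ddof=1).

## Synthetic data generator

Emulates feature-extracted multi-site WSI cohorts. Negative instances
at site `s` are drawn `Normal(μ_s, σ²I)`; positive instances add
`signal_strength · e₁` (a fixed unit direction shared by all sites).
`μ_s` is a random direction scaled to exactly the heterogeneity
magnitude, per site; heterogeneity 0 gives identically distributed
sites. A positive bag receives `ceil(witness_rate · K)` positive
instances at random positions; negative bags receive none, so the MIL
bag rule holds by construction. The positive-bag count is the
deterministic `round(n_bags · prevalence)` (not Bernoulli) so tests are
exact; splits use largest-remainder rounding of `N · ratio`. Instance
ground truth and a square-ish patch grid are attached for evaluation
and heatmaps.

Defaults (desk scale): D=32, K∈[20,80], noise 1.0, signal 2.0,
prevalence 0.5, witness 0.3, heterogeneity 2.0 in the ordering study,
witness 0.1 in the pooling ablation. Rationale: per-instance
signal-to-noise of 2 makes witnesses detectable but not trivial; a
mean shift comparable to the signal makes single-site models misrank
foreign sites' bags without destroying within-site structure; witness
0.1 is the regime where instance-weighting should matter. D=1024 and
thousands of instances (the scale of real feature-extracted slides)
are configurable but unnecessary for the qualitative behaviour.

What the generator does *not* emulate: spatial correlation between
neighbouring patches, heavy-tailed and highly anisotropic real feature
distributions, label noise, class-imbalance differences between sites,
and encoder-induced geometry. Passing tests therefore demonstrate the
*mechanics* (correct gradients, protocols, metrics) and the *relative*
behaviour of the strategies under controlled shift — not clinical-grade
performance on real slides.

## Experiment and numerical choices

The packaged studies (`fedmil.experiments`) use 5 sites × 200 bags,
5 replicate seeds with fresh data and initialisation each, and a
desk-scale schedule: 30 rounds × 20 local steps, Adam 1e-3, attention
width 16, ρ hidden width 32 — sized so the full strategy comparison
plus the pooling ablation complete in about a minute on one CPU. The
paper-scale schedule (learning rate 1e-4, 200 epochs, 5 repeats)
remains the `FederationConfig` default for larger runs.

Other numerics: softmax max-subtraction; CE clamp 1e-12; attention-free
pooling modes simply carry zero gradients for `w, V, U`; all-equal
attention normalises to 0.5 in heatmaps (min-max undefined);
largest-remainder split ties break toward the earlier split; all
randomness flows through `numpy` `SeedSequence` derivation, so every
entry point is reproducible from one integer seed.

## Known limitations

- Federation is simulated in-process: no transport, stragglers,
  asynchrony, or secure aggregation.
- Uplink Gaussian noise is a perturbation, not a calibrated
  differential-privacy mechanism — no (ε, δ) accounting.
- Binary slide labels only; no multi-class grading.
- The max-pooling gradient is a subgradient (argmax ties broken by
  first index), which is standard but makes that mode noisier to train.
- Desk-scale synthetic results support ordering claims, not absolute
  performance numbers on real cohorts.
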