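"""Synthetic multi-site bag-of-features data.

Emulates the output of a whole-slide-image preprocessing pipeline (tiling
plus a pretrained patch encoder) at a configurable, desk-friendly scale:
each "slide" is a bag of K patch feature vectors in R^D.  Negative
instances are drawn from a site-specific Gaussian cloud; positive
instances are shifted along a fixed unit "signal" direction.  A positive
bag contains a small witness fraction of positive instances, a negative
bag contains none, so the standard MIL bag-labelling rule holds by
construction.

Site heterogeneity is modelled as a per-site mean offset of controllable
magnitude, the simplest form of the distribution shift observed between
tissue source sites in multi-centre pathology cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "SiteGenConfig",
    "FeatureBag",
    "SiteDataset",
    "generate_site",
    "generate_federation",
    "split_bags",
    "bag_label_consistent",
]


@dataclass(frozen=True)
class SiteGenConfig:
    """Generation parameters for one site (centre).

    Parameters
    ----------
    site_id : str
        Identifier recorded on every bag.
    n_bags : int
        Number of bags (slides) to generate.
    prevalence : float
        Fraction of positive bags in [0, 1]; the positive count is
        ``round(n_bags * prevalence)``, assigned deterministically.
    k_range : (int, int)
        Inclusive bounds on instances per bag.
    feature_dim : int
        Dimension D of each instance feature vector.  32 is the desk-scale
        default; 1024 mimics common pretrained-encoder output.
    witness_rate : float
        Fraction of positive instances inside a positive bag, in (0, 1];
        each positive bag gets ``ceil(witness_rate * K)`` witnesses.
    site_shift : float
        Magnitude of this site's mean-offset vector (heterogeneity knob).
    signal_strength : float
        Offset of positive instances along the fixed signal direction.
    noise_scale : float
        Instance standard deviation (isotropic).
    seed : int
        Seed controlling everything generated for this site.
    """

    site_id: str = "site0"
    n_bags: int = 100
    prevalence: float = 0.5
    k_range: tuple[int, int] = (20, 80)
    feature_dim: int = 32
    witness_rate: float = 0.3
    site_shift: float = 0.0
    signal_strength: float = 2.0
    noise_scale: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.prevalence <= 1.0):
            raise ValueError(f"prevalence must be in [0,1], got {self.prevalence}")
        if not (0.0 < self.witness_rate <= 1.0):
            raise ValueError(f"witness_rate must be in (0,1], got {self.witness_rate}")
        kmin, kmax = self.k_range
        if kmin < 1 or kmax < kmin:
            raise ValueError(f"invalid k_range {self.k_range}")
        if self.feature_dim < 1:
            raise ValueError(f"feature_dim must be >= 1, got {self.feature_dim}")
        if self.n_bags < 0:
            raise ValueError(f"n_bags must be >= 0, got {self.n_bags}")
        if self.noise_scale < 0 or self.site_shift < 0:
            raise ValueError("noise_scale and site_shift must be nonnegative")


@dataclass
class FeatureBag:
    """One slide as a K x D instance-feature matrix with a binary label.

    ``instance_labels`` carries the synthetic ground truth per instance
    (real feature-extracted slides do not have it); when present, the bag
    label always equals the OR of the instance labels.
    """

    slide_id: str
    site_id: str
    features: np.ndarray  # (K, D) float
    label: int
    grid_coords: np.ndarray | None = None  # (K, 2) int patch positions
    instance_labels: np.ndarray | None = None  # (K,) in {0,1}

    @property
    def n_instances(self) -> int:
        return int(self.features.shape[0])

    @property
    def feature_dim(self) -> int:
        return int(self.features.shape[1])


@dataclass
class SiteDataset:
    """Train/validation/test partition of one site's bags."""

    site_id: str
    train: list[FeatureBag] = field(default_factory=list)
    val: list[FeatureBag] = field(default_factory=list)
    test: list[FeatureBag] = field(default_factory=list)

    @property
    def all_bags(self) -> list[FeatureBag]:
        return list(self.train) + list(self.val) + list(self.test)


def bag_label_consistent(bag: FeatureBag) -> bool:
    """Check the MIL rule: bag positive iff at least one instance positive."""
    if bag.instance_labels is None:
        return True
    return bag.label == int(np.any(bag.instance_labels > 0))


def _signal_direction(dim: int) -> np.ndarray:
    # fixed unit direction shared by all sites: the first coordinate axis
    e = np.zeros(dim)
    e[0] = 1.0
    return e


def generate_site(cfg: SiteGenConfig) -> list[FeatureBag]:
    """Generate one site's bags.

    Exactly ``round(n_bags * prevalence)`` bags are positive; the
    assignment is deterministic and then shuffled by the seed, so counts
    are exact rather than Bernoulli.  Reproducible: the same config yields
    byte-identical feature arrays.
    """
    cfg.validate()
    if cfg.n_bags == 0:
        return []

    rng = np.random.default_rng(cfg.seed)
    dim = cfg.feature_dim
    # per-site mean offset: random direction scaled to exactly site_shift
    if cfg.site_shift > 0:
        raw = rng.standard_normal(dim)
        offset = cfg.site_shift * raw / np.linalg.norm(raw)
    else:
        rng.standard_normal(dim)  # keep the stream aligned across shift values
        offset = np.zeros(dim)
    signal = cfg.signal_strength * _signal_direction(dim)

    n_pos = int(round(cfg.n_bags * cfg.prevalence))
    labels = np.zeros(cfg.n_bags, dtype=int)
    labels[:n_pos] = 1
    rng.shuffle(labels)

    kmin, kmax = cfg.k_range
    bags: list[FeatureBag] = []
    for b in range(cfg.n_bags):
        k = int(rng.integers(kmin, kmax + 1))
        y = int(labels[b])
        inst = np.zeros(k, dtype=int)
        if y == 1:
            n_wit = int(math.ceil(cfg.witness_rate * k))
            wit_idx = rng.choice(k, size=n_wit, replace=False)
            inst[wit_idx] = 1
        x = offset + cfg.noise_scale * rng.standard_normal((k, dim))
        x[inst == 1] += signal
        # square-ish patch grid so attention maps can be rendered
        ncols = int(math.ceil(math.sqrt(k)))
        coords = np.stack([np.arange(k) // ncols, np.arange(k) % ncols], axis=1)
        bags.append(
            FeatureBag(
                slide_id=f"{cfg.site_id}_slide{b:05d}",
                site_id=cfg.site_id,
                features=x,
                label=y,
                grid_coords=coords.astype(np.int64),
                instance_labels=inst,
            )
        )
    return bags


def split_bags(
    bags: Sequence[FeatureBag],
    ratios: tuple[float, float, float] = (0.60, 0.15, 0.25),
    seed: int = 0,
    site_id: str | None = None,
) -> SiteDataset:
    """Shuffle and partition bags into train/val/test.

    Counts follow largest-remainder rounding of ``N * ratio`` so they sum
    to N exactly and each differs from the ideal by less than one.
    """
    r = np.asarray(ratios, dtype=float)
    if np.any(r < 0) or abs(r.sum() - 1.0) > 1e-9:
        raise ValueError(f"ratios must be nonnegative and sum to 1, got {ratios}")
    n = len(bags)
    ideal = n * r
    counts = np.floor(ideal).astype(int)
    rem = ideal - counts
    # distribute leftover units to the largest remainders (ties: first wins)
    for i in np.argsort(-rem, kind="stable")[: n - counts.sum()]:
        counts[i] += 1
    assert counts.sum() == n

    order = np.random.default_rng(seed).permutation(n)
    shuffled = [bags[i] for i in order]
    t, v = counts[0], counts[1]
    sid = site_id if site_id is not None else (bags[0].site_id if n else "empty")
    return SiteDataset(
        site_id=sid,
        train=shuffled[:t],
        val=shuffled[t : t + v],
        test=shuffled[t + v :],
    )


def generate_federation(
    n_sites: int,
    base_cfg: SiteGenConfig,
    heterogeneity: float = 0.0,
    seed: int = 0,
    split_ratios: tuple[float, float, float] = (0.60, 0.15, 0.25),
) -> list[SiteDataset]:
    """Generate a multi-site federation with controlled heterogeneity.

    Each site gets an independent mean-offset vector of magnitude
    ``heterogeneity`` and a seed derived from ``seed``; heterogeneity 0
    yields identically distributed sites.  Every site is split
    train/val/test with the given ratios.
    """
    if n_sites < 1:
        raise ValueError(f"n_sites must be >= 1, got {n_sites}")
    if heterogeneity < 0:
        raise ValueError("heterogeneity must be nonnegative")
    seeds = np.random.SeedSequence(seed).generate_state(2 * n_sites) % (2**31)
    datasets = []
    for i in range(n_sites):
        cfg_i = replace(
            base_cfg,
            site_id=f"site{i + 1}",
            site_shift=float(heterogeneity),
            seed=int(seeds[2 * i]),
        )
        bags = generate_site(cfg_i)
        datasets.append(
            split_bags(bags, split_ratios, seed=int(seeds[2 * i + 1]), site_id=cfg_i.site_id)
        )
    return datasets
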