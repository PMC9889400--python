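"""Generate one site's bag-of-features data and inspect its structure.

Each bag stands for one slide: K patch feature vectors in R^D with only
a slide-level label.  Positive bags carry a small fraction of "witness"
instances shifted along the signal direction; negative bags carry none.
"""

import numpy as np

from fedmil import SiteGenConfig, generate_site, split_bags

cfg = SiteGenConfig(site_id="demo", n_bags=100, prevalence=0.5, witness_rate=0.3, seed=7)
bags = generate_site(cfg)

n_pos = sum(b.label for b in bags)
ks = [b.n_instances for b in bags]
wit = [b.instance_labels.sum() / b.n_instances for b in bags if b.label == 1]
print(f"{len(bags)} bags, D={bags[0].feature_dim}, K in [{min(ks)}, {max(ks)}]")
print(f"positive bags: {n_pos} (exactly round(n_bags * prevalence))")
print(f"witness fraction in positive bags: {np.mean(wit):.3f} (target {cfg.witness_rate})")

ds = split_bags(bags, (0.60, 0.15, 0.25), seed=7)
print(f"split 60:15:25 -> {len(ds.train)}/{len(ds.val)}/{len(ds.test)} bags")
# The split counts follow largest-remainder rounding, so they always sum
# to the total and each deviates from the exact ratio by less than one bag.
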