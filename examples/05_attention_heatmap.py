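"""Export an attention heatmap for one synthetic slide.

Attention weights are min-max normalised to [0, 1] and rasterised onto
the slide's patch grid; the CSV lists per-patch scores and the PNG is a
colormap rendering (transparent where the grid has no patch).
"""

from pathlib import Path

import numpy as np

from fedmil import SiteGenConfig, attention_scores, generate_site, init_mil_params, split_bags
from fedmil.federation import FederationConfig, local_train
from fedmil.heatmap import export_heatmap

rng = np.random.default_rng(1)
site = split_bags(generate_site(SiteGenConfig(n_bags=120, seed=11)), seed=11)
cfg = FederationConfig(lr_client=1e-3, local_steps=400, repeats=1)
params, _, _ = local_train(site.train, init_mil_params(32, rho_hidden=(32,), rng=rng), cfg, rng)

bag = next(b for b in site.test if b.label == 1)
alpha = attention_scores(bag.features, params)
out = Path("scratch") if Path("scratch").exists() else Path(".")
grid = export_heatmap(bag, alpha, csv_path=out / "heatmap.csv", png_path=out / "heatmap.png")
occ = grid.raster[grid.occupied]
print(f"slide {bag.slide_id}: {bag.n_instances} patches on a "
      f"{grid.raster.shape[0]}x{grid.raster.shape[1]} grid")
print(f"normalised attention spans [{occ.min():.1f}, {occ.max():.1f}]")
print(f"wrote {out/'heatmap.csv'} and {out/'heatmap.png'}")
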