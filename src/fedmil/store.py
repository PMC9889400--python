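"""Bag dataset persistence: HDF5 feature container + CSV manifest.

Layout: one HDF5 group per slide holding a ``features`` dataset
(K x D float32) with ``label`` and ``site_id`` attributes and optional
``grid_coords`` / ``instance_labels`` datasets.  A CSV manifest beside
the container lists slide_id, site_id, label, K and an optional split
tag; container and manifest must agree row for row.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import h5py
import numpy as np
import pandas as pd

from .synthetic import FeatureBag

__all__ = ["BagStore", "write_bags", "read_bags", "manifest_path"]

PATCH_SIZE_PX = 256  # nominal patch edge recorded as container metadata


@dataclass(frozen=True)
class BagStore:
    """Paths of a persisted bag dataset."""

    container: Path
    manifest: Path


def manifest_path(container: Path | str) -> Path:
    return Path(container).with_suffix(".manifest.csv")


def write_bags(
    bags: Sequence[FeatureBag],
    container: Path | str,
    splits: Mapping[str, str] | None = None,
) -> BagStore:
    """Write bags to an HDF5 container and its CSV manifest.

    ``splits`` optionally maps slide_id to a split tag (train/val/test)
    recorded in the manifest.  Features are stored as float32.
    """
    if len(bags) == 0:
        raise ValueError("no bags to write")
    dim = bags[0].feature_dim
    for b in bags:
        if b.feature_dim != dim:
            raise ValueError(
                f"inconsistent feature dim for slide {b.slide_id}: {b.feature_dim} != {dim}"
            )
    container = Path(container)
    container.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    with h5py.File(container, "w") as f:
        f.attrs["feature_dim"] = dim
        f.attrs["patch_size_px"] = PATCH_SIZE_PX
        for b in bags:
            grp = f.create_group(f"bags/{b.slide_id}")
            grp.create_dataset("features", data=b.features.astype(np.float32))
            grp.attrs["label"] = int(b.label)
            grp.attrs["site_id"] = b.site_id
            if b.grid_coords is not None:
                grp.create_dataset("grid_coords", data=b.grid_coords.astype(np.int64))
            if b.instance_labels is not None:
                grp.create_dataset("instance_labels", data=b.instance_labels.astype(np.int8))
            rows.append(
                {
                    "slide_id": b.slide_id,
                    "site_id": b.site_id,
                    "label": int(b.label),
                    "K": b.n_instances,
                    "split": (splits or {}).get(b.slide_id, ""),
                }
            )
    mpath = manifest_path(container)
    pd.DataFrame(rows).to_csv(mpath, index=False)
    return BagStore(container=container, manifest=mpath)


def read_bags(
    container: Path | str, manifest: Path | str | None = None
) -> tuple[list[FeatureBag], pd.DataFrame]:
    """Read a bag store back, checking container/manifest consistency.

    Raises an I/O error naming the offending slide when the manifest and
    container disagree.
    """
    container = Path(container)
    mpath = Path(manifest) if manifest is not None else manifest_path(container)
    if not container.exists():
        raise IOError(f"missing container {container}")
    if not mpath.exists():
        raise IOError(f"missing manifest {mpath}")
    mf = pd.read_csv(mpath, dtype={"slide_id": str, "site_id": str}, keep_default_na=False)
    bags: list[FeatureBag] = []
    with h5py.File(container, "r") as f:
        stored = set(f["bags"].keys()) if "bags" in f else set()
        listed = set(mf["slide_id"])
        for sid in sorted(stored - listed):
            raise IOError(f"slide {sid!r} present in container but missing from manifest")
        for sid in sorted(listed - stored):
            raise IOError(f"slide {sid!r} listed in manifest but missing from container")
        dims = set()
        for _, row in mf.iterrows():
            grp = f[f"bags/{row.slide_id}"]
            feats = grp["features"][()]
            dims.add(feats.shape[1])
            if feats.shape[0] != int(row.K):
                raise IOError(f"slide {row.slide_id!r}: manifest K={row.K} != stored {feats.shape[0]}")
            if int(grp.attrs["label"]) != int(row.label):
                raise IOError(f"slide {row.slide_id!r}: manifest/container label mismatch")
            bags.append(
                FeatureBag(
                    slide_id=str(row.slide_id),
                    site_id=str(grp.attrs["site_id"]),
                    features=feats,
                    label=int(grp.attrs["label"]),
                    grid_coords=grp["grid_coords"][()] if "grid_coords" in grp else None,
                    instance_labels=grp["instance_labels"][()] if "instance_labels" in grp else None,
                )
            )
        if len(dims) > 1:
            raise IOError(f"inconsistent feature dims in store: {sorted(dims)}")
    return bags, mf
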