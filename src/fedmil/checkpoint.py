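"""Checkpoint serialisation: models and hypernetwork state.

Arrays go into a single ``.npz`` container; a JSON sidecar records the
shape information (the MIL target spec and, for hypernetworks, the
client ids) needed to rebuild the structured objects.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from . import hypernet as hn
from .mil import MILParameters

__all__ = ["save_models", "load_models", "save_hypernet", "load_hypernet"]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def _spec_to_dict(spec: hn.TargetSpec) -> dict:
    d = asdict(spec)
    d["rho_widths"] = list(spec.rho_widths)
    return d


def _spec_from_dict(d: dict) -> hn.TargetSpec:
    return hn.TargetSpec(
        feature_dim=d["feature_dim"],
        attn_dim=d["attn_dim"],
        rho_widths=tuple(d["rho_widths"]),
        pooling_mode=d["pooling_mode"],
    )


def save_models(models: dict[str, MILParameters], path: Path | str) -> None:
    path = Path(path)
    first = next(iter(models.values()))
    spec = hn.spec_of(first)
    np.savez(path, **{sid: hn.pack(p) for sid, p in models.items()})
    _sidecar(path).write_text(
        json.dumps({"kind": "models", "target_spec": _spec_to_dict(spec),
                    "sites": sorted(models)}, indent=2)
    )


def load_models(path: Path | str) -> dict[str, MILParameters]:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    spec = _spec_from_dict(meta["target_spec"])
    with np.load(path) as z:
        return {sid: hn.unpack(z[sid], spec) for sid in meta["sites"]}


def save_hypernet(state: hn.HypernetworkState, path: Path | str) -> None:
    path = Path(path)
    arrays = {}
    for i, (W, b) in enumerate(state.layers):
        arrays[f"layer{i}_W"] = W
        arrays[f"layer{i}_b"] = b
    for cid, emb in state.embeddings.items():
        arrays[f"embed_{cid}"] = emb.v
    np.savez(path, **arrays)
    _sidecar(path).write_text(
        json.dumps(
            {
                "kind": "hypernet",
                "target_spec": _spec_to_dict(state.target_spec),
                "n_layers": len(state.layers),
                "clients": sorted(state.embeddings),
            },
            indent=2,
        )
    )


def load_hypernet(path: Path | str) -> hn.HypernetworkState:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    spec = _spec_from_dict(meta["target_spec"])
    with np.load(path) as z:
        layers = [
            (z[f"layer{i}_W"], z[f"layer{i}_b"]) for i in range(meta["n_layers"])
        ]
        embeddings = {
            cid: hn.ClientEmbedding(cid, z[f"embed_{cid}"]) for cid in meta["clients"]
        }
    return hn.HypernetworkState(layers=layers, embeddings=embeddings, target_spec=spec)
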