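"""Parameter checkpoints: named arrays plus JSON metadata in one NumPy
``.npz`` container.  Round trips are deterministic (write -> read gives
bitwise-equal arrays)."""

from __future__ import annotations

import json

import numpy as np

from .exceptions import ValidationError
from .network import NetworkConfig, NetworkParams, init_network

__all__ = ["save_network", "load_network"]

_META_KEY = "__meta__"


def save_network(path, params: NetworkParams) -> None:
    meta = json.dumps({"kind": "ppilstm-network", "config": params.config.to_dict(),
                       "has_scaler": params.feature_mean is not None})
    arrays = dict(params.named_arrays())
    if params.feature_mean is not None:
        arrays["scaler.mean"] = params.feature_mean
        arrays["scaler.std"] = params.feature_std
    np.savez(path, **{_META_KEY: np.frombuffer(meta.encode(), dtype=np.uint8)},
             **arrays)


def load_network(path) -> NetworkParams:
    with np.load(path) as data:
        if _META_KEY not in data:
            raise ValidationError(f"{path}: not a ppilstm checkpoint")
        meta = json.loads(bytes(data[_META_KEY]).decode())
        if meta.get("kind") != "ppilstm-network":
            raise ValidationError(f"{path}: unrecognized checkpoint kind")
        cfg = NetworkConfig(**meta["config"])
        params = init_network(cfg)
        arrays = params.named_arrays()
        missing = set(arrays) - set(data.files)
        if missing:
            raise ValidationError(f"{path}: checkpoint missing arrays {sorted(missing)}")
        for name, arr in arrays.items():
            stored = data[name]
            if stored.shape != arr.shape:
                raise ValidationError(f"{path}: shape mismatch for {name}")
            arr[...] = stored
        if meta.get("has_scaler"):
            params.feature_mean = np.array(data["scaler.mean"])
            params.feature_std = np.array(data["scaler.std"])
    return params
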