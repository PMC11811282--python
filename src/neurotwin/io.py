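"""Readers and writers for signal sequences.

Two interchangeable formats:

* delimited text (``.csv``): time x channels matrix with a header row of
  channel names, plus a JSON metadata sidecar (``<name>.meta.json``);
* binary array archive (``.npz``): values plus metadata embedded as a JSON
  string, lossless round-trip.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .signals import SignalSequence


class SignalFormatError(ValueError):
    """Malformed signal file or missing metadata."""


def _meta_dict(seq: SignalSequence) -> dict:
    return {
        "sampling_rate": seq.sampling_rate,
        "condition": seq.condition,
        "individual": seq.individual,
        "region_map": list(seq.region_map),
        "switch_step": seq.switch_step,
        "provenance": list(seq.provenance),
    }


def _seq_from_meta(values: np.ndarray, meta: dict, source: str) -> SignalSequence:
    for fieldname in ("sampling_rate", "region_map"):
        if meta.get(fieldname) is None:
            raise SignalFormatError(
                f"{source}: metadata is missing required field "
                f"'{fieldname}'")
    if np.isnan(values).any():
        raise SignalFormatError(f"{source}: signal values contain NaN")
    return SignalSequence(
        values=values,
        sampling_rate=float(meta["sampling_rate"]),
        condition=meta.get("condition", "awake"),
        individual=meta.get("individual", "ind0"),
        region_map=tuple(meta["region_map"]),
        switch_step=meta.get("switch_step"),
        provenance=tuple(meta.get("provenance", ())),
    )


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json") \
        if path.suffix != ".csv" else path.with_suffix(".meta.json")


def write_signals(seq: SignalSequence, path) -> None:
    """Write a sequence as ``.csv`` (+ JSON sidecar) or ``.npz``."""
    path = Path(path)
    if path.suffix == ".csv":
        # disambiguate duplicate region labels while keeping them readable
        counts: dict[str, int] = {}
        names = []
        for r in seq.region_map:
            counts[r] = counts.get(r, 0) + 1
            names.append(f"{r}_{counts[r]}")
        df = pd.DataFrame(seq.values.T, columns=names)
        df.to_csv(path, index=False)
        _sidecar(path).write_text(json.dumps(_meta_dict(seq), indent=1))
    elif path.suffix == ".npz":
        np.savez(path, values=seq.values,
                 meta=np.array(json.dumps(_meta_dict(seq))))
    else:
        raise SignalFormatError(f"unsupported extension: {path.suffix}")


def read_signals(path) -> SignalSequence:
    """Read a sequence written by :func:`write_signals`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".csv":
        try:
            df = pd.read_csv(path)
        except Exception as exc:  # malformed delimited text
            raise SignalFormatError(f"{path}: cannot parse ({exc})") from exc
        if df.shape[1] < 1 or not all(isinstance(c, str) for c in df.columns):
            raise SignalFormatError(f"{path}: missing channel-name header")
        side = _sidecar(path)
        if not side.exists():
            raise SignalFormatError(
                f"{path}: metadata sidecar {side.name} not found")
        meta = json.loads(side.read_text())
        return _seq_from_meta(df.to_numpy(dtype=float).T, meta, str(path))
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            return _seq_from_meta(np.asarray(data["values"], dtype=float),
                                  meta, str(path))
    raise SignalFormatError(f"unsupported extension: {path.suffix}")
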