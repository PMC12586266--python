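"""Dataset CSV round-tripping and NeurAM (de)serialization.

Datasets are delimited text with a `x1,...,xd,y` header, one row per sample,
full float precision.  Trained triples are stored as a single JSON document
(parameters, architecture, normalization, latent interval, seed) with the
training history in a JSON sidecar next to it.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import MLPCurve, MLPScalar1D, MLPScalarField, NeurAM
from .models import Dataset, InputDistribution

__all__ = ["read_dataset", "write_dataset", "save_neuram", "load_neuram",
           "validate_report"]


class DatasetFormatError(ValueError):
    pass


def write_dataset(ds: Dataset, path) -> None:
    d = ds.inputs.shape[1]
    cols = [f"x{i + 1}" for i in range(d)] + ["y"]
    df = pd.DataFrame(np.column_stack([ds.inputs, ds.outputs]), columns=cols)
    df.to_csv(path, index=False, float_format="%.17g")


def read_dataset(path) -> Dataset:
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise DatasetFormatError(f"{path}: empty file is not a dataset")
    header = [c.strip() for c in lines[0].split(",")]
    d = len(header) - 1
    expected = [f"x{i + 1}" for i in range(d)] + ["y"]
    if d < 1 or header != expected:
        raise DatasetFormatError(
            f"{path}: malformed header {header!r}; expected x1,...,xd,y")
    rows = []
    for i, ln in enumerate(lines[1:], start=2):
        cells = ln.split(",")
        if len(cells) != d + 1:
            raise DatasetFormatError(f"{path}: line {i}: expected {d + 1} "
                                     f"columns, got {len(cells)}")
        try:
            rows.append([float(c) for c in cells])
        except ValueError as exc:
            raise DatasetFormatError(f"{path}: line {i}: non-numeric cell "
                                     f"({exc})") from None
    if not rows:
        raise DatasetFormatError(f"{path}: header only, no data rows")
    arr = np.asarray(rows)
    return Dataset(inputs=arr[:, :d], outputs=arr[:, d])


# ---------------------------------------------------------------------------
# NeurAM serialization (MLP-backed triples)
# ---------------------------------------------------------------------------

def _params_to_json(params):
    return [[W.tolist(), b.tolist()] for W, b in params]


def _params_from_json(obj):
    return [(np.asarray(W, dtype=float), np.asarray(b, dtype=float))
            for W, b in obj]


def save_neuram(nam: NeurAM, path) -> None:
    """Write a trained triple to JSON; history goes to `<path>.history.json`."""
    if not isinstance(nam.encoder, MLPScalarField):
        raise TypeError("only network-backed triples can be serialized")
    doc = {
        "format": "neuram-v1",
        "encoder": _params_to_json(nam.encoder.params),
        "decoder": _params_to_json(nam.decoder.params),
        "surrogate": _params_to_json(nam.surrogate.params),
        "latent_interval": list(nam.latent_interval),
        "seed": nam.seed,
        "dist": None if nam.dist is None else {
            "kinds": list(nam.dist.kinds),
            "lo": nam.dist.lo.tolist(),
            "hi": nam.dist.hi.tolist(),
        },
        "meta": {k: repr(v) for k, v in nam.meta.items()},
    }
    path = Path(path)
    path.write_text(json.dumps(doc), encoding="utf-8")
    hist = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in nam.history.items()}
    path.with_suffix(path.suffix + ".history.json").write_text(
        json.dumps(hist), encoding="utf-8")


def load_neuram(path) -> NeurAM:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    if doc.get("format") != "neuram-v1":
        raise ValueError(f"{path}: not a serialized NeurAM")
    dist = None
    if doc["dist"] is not None:
        dist = InputDistribution(kinds=tuple(doc["dist"]["kinds"]),
                                 lo=doc["dist"]["lo"], hi=doc["dist"]["hi"])
    hist_path = Path(path).with_suffix(Path(path).suffix + ".history.json")
    history = json.loads(hist_path.read_text()) if hist_path.exists() else {}
    return NeurAM(
        encoder=MLPScalarField(_params_from_json(doc["encoder"])),
        decoder=MLPCurve(_params_from_json(doc["decoder"]), squash=True),
        surrogate=MLPScalar1D(_params_from_json(doc["surrogate"])),
        latent_interval=tuple(doc["latent_interval"]),
        dist=dist,
        history=history,
        seed=doc.get("seed"),
    )


# ---------------------------------------------------------------------------
# report schema check (structural; shipped schema in neuram/schemas/)
# ---------------------------------------------------------------------------

def _schema_path(name: str) -> Path:
    return Path(__file__).parent / "schemas" / name


def validate_report(report: dict) -> None:
    """Check an experiment report against the shipped JSON schema.

    A small structural validator (required keys and primitive types); raises
    ValueError on the first violation.
    """
    schema = json.loads(_schema_path("report.schema.json").read_text())
    _validate(report, schema, "$")


_TYPES = {"object": dict, "array": list, "string": str, "number": (int, float),
          "integer": int, "boolean": bool, "null": type(None)}


def _validate(obj, schema, where):
    t = schema.get("type")
    if t is not None and not isinstance(obj, _TYPES[t]):
        raise ValueError(f"{where}: expected {t}, got {type(obj).__name__}")
    for key in schema.get("required", []):
        if key not in obj:
            raise ValueError(f"{where}: missing required key '{key}'")
    for key, sub in schema.get("properties", {}).items():
        if isinstance(obj, dict) and key in obj:
            _validate(obj[key], sub, f"{where}.{key}")
    if "items" in schema and isinstance(obj, list):
        for i, item in enumerate(obj):
            _validate(item, schema["items"], f"{where}[{i}]")
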