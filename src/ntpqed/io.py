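"""Plain-text sample I/O and seeded fixture generation.

Samples are one numeric value per line (or a single CSV column); ``#`` starts
a comment.  Reports are emitted as JSON (full precision, round-trippable) or
TSV (6 significant digits, columns in table order).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .distribution import Params, mixture_weights, rvs
from .estimation import Sample

__all__ = ["read_sample", "write_report", "make_fixture"]


def read_sample(path) -> Sample:
    """Parse a plain-text/CSV numeric column into a Sample.

    Raises a descriptive error naming the offending line for nonpositive or
    non-numeric entries; empty input (or comments only) is an error.
    """
    path = Path(path)
    values = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        text = raw.split("#", 1)[0].strip().rstrip(",")
        if not text:
            continue
        for tok in text.split(","):
            tok = tok.strip()
            if not tok:
                continue
            try:
                v = float(tok)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: not a number: {tok!r}") from None
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{path}:{lineno}: values must be positive, got {tok}")
            values.append(v)
    if not values:
        raise ValueError(f"{path}: no data values found")
    return Sample(np.array(values), provenance=str(path))


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    return obj


def write_report(obj, path, format: str = "json") -> None:
    """Serialize a result object (dataclass, dict or DataFrame) to disk."""
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(_to_jsonable(obj), indent=2, allow_nan=True) + "\n")
    elif format == "tsv":
        df = obj if isinstance(obj, pd.DataFrame) else pd.DataFrame([_to_jsonable(obj)])
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    else:
        raise ValueError("format must be 'json' or 'tsv'")


def make_fixture(p: Params, n: int, seed: int, path) -> None:
    """Write a seeded synthetic sample plus a sidecar JSON of its recipe.

    The sidecar records (alpha, beta, n, seed, mixture weights) so the file
    is re-derivable offline; identical inputs produce byte-identical files.
    """
    path = Path(path)
    draws = rvs(n, p, seed)
    path.write_text("".join(f"{float(v)!r}\n" for v in draws))
    sidecar = {
        "alpha": p.alpha, "beta": p.beta, "n": int(n), "seed": int(seed),
        "mixture_weights": mixture_weights(p).tolist(),
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True) + "\n")
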