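"""Plain-text tables with '#'-prefixed metadata headers, plus truth sidecars.

All on-disk formats are text: numeric columns as CSV, preceded by header
lines of the form ``# key = value``. Ground-truth parameter records from the
synthetic generators are written as sidecar JSON files next to the data.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

__all__ = ["write_table", "read_table", "write_truth", "read_truth"]


def _format_value(v: Any) -> str:
    if isinstance(v, float):
        return repr(v)
    return str(v)


def write_table(path: "str | Path", df: pd.DataFrame, metadata: "dict[str, Any] | None" = None) -> None:
    """CSV with ``# key = value`` metadata lines before the header row."""
    path = Path(path)
    with path.open("w") as fh:
        for k, v in (metadata or {}).items():
            fh.write(f"# {k} = {_format_value(v)}\n")
        df.to_csv(fh, index=False)


def _parse_value(s: str) -> Any:
    s = s.strip()
    for cast in (int, float):
        try:
            return cast(s)
        except ValueError:
            pass
    return s


def read_table(path: "str | Path") -> tuple[pd.DataFrame, dict[str, Any]]:
    """Read a metadata-headed CSV; returns (frame, metadata dict)."""
    path = Path(path)
    metadata: dict[str, Any] = {}
    n_header = 0
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            body = line.lstrip("#").strip()
            if "=" in body:
                k, v = body.split("=", 1)
                metadata[k.strip()] = _parse_value(v)
    df = pd.read_csv(path, skiprows=n_header)
    return df, metadata


class _TruthEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, dict):
            return o
        return super().default(o)


def write_truth(path: "str | Path", truth: dict[str, Any]) -> None:
    """Ground-truth sidecar JSON (numpy types converted to plain lists)."""
    clean = json.loads(json.dumps(_stringify_keys(truth), cls=_TruthEncoder))
    Path(path).write_text(json.dumps(clean, indent=1, sort_keys=True))


def _stringify_keys(obj):
    if isinstance(obj, dict):
        return {str(k): _stringify_keys(v) for k, v in obj.items()}
    return obj


def read_truth(path: "str | Path") -> dict[str, Any]:
    return json.loads(Path(path).read_text())
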