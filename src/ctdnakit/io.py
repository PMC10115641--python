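"""Delimited-table and JSON artifact I/O with provenance headers.

Every table written by the pipeline starts with ``#``-prefixed metadata
lines (package version plus any stage-specific keys such as seed and config
hash) so outputs are self-describing and diffable.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import __version__


def config_hash(obj: Any) -> str:
    """Short stable hash of a JSON-serializable configuration object."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_table(df: pd.DataFrame, path: str | Path,
                metadata: Mapping[str, Any] | None = None,
                sep: str = "\t", index: bool = False) -> None:
    path = Path(path)
    meta = {"package": f"ctdnakit {__version__}", **(metadata or {})}
    with open(path, "w", encoding="utf-8") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep=sep, index=index, lineterminator="\n")


def read_table(path: str | Path, sep: str = "\t",
               index_col: int | str | None = None) -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#", index_col=index_col,
                       keep_default_na=True, na_values=[""],
                       float_precision="round_trip")


def write_json(obj: Any, path: str | Path,
               metadata: Mapping[str, Any] | None = None) -> None:
    payload = {"_meta": {"package": f"ctdnakit {__version__}",
                         **(metadata or {})}, **obj}
    Path(path).write_text(json.dumps(payload, indent=2, default=float) + "\n",
                          encoding="utf-8")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))
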