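"""TSV read/write helpers.

All on-disk tables are plain tab-separated text with a single commented
header line carrying the package version and a short hash of the
parameters that produced the file, so outputs are self-describing and
reruns are byte-comparable.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__


def params_hash(params: dict | None) -> str:
    """Stable 12-hex-digit digest of a parameter mapping."""
    blob = json.dumps(params or {}, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def write_table(df: pd.DataFrame, path: str | Path, params: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# ascn v{__version__} config={params_hash(params)}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA")


def read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=["NA"], **kwargs)
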