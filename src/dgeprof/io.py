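"""TSV serialization with provenance header comments.

Every table written by the pipeline carries a leading comment block with
the package version, a config hash and the column schema, so outputs are
self-describing and byte-reproducible under a fixed seed (no timestamps).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__

FLOAT_FORMAT = "%.10g"


def config_hash(config: dict) -> str:
    """Hash of the analysis-relevant config; filesystem locations are
    excluded so identical analyses hash identically wherever they run."""
    stripped = {k: v for k, v in config.items() if k not in ("outdir", "paths")}
    blob = json.dumps(stripped, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_tsv(
    frame: pd.DataFrame,
    path,
    config: dict | None = None,
    index: bool = False,
    extra_header: dict | None = None,
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as handle:
        handle.write(f"# dgeprof {__version__}\n")
        if config is not None:
            handle.write(f"# config_hash {config_hash(config)}\n")
        for key, value in (extra_header or {}).items():
            handle.write(f"# {key} {value}\n")
        cols = list(frame.index.names) + list(frame.columns) if index else list(frame.columns)
        handle.write(f"# columns {','.join(str(c) for c in cols)}\n")
        frame.to_csv(handle, sep="\t", index=index, float_format=FLOAT_FORMAT)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def sha256_file(path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()
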