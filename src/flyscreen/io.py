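"""TSV/BED/JSON readers and writers for the screen's tables.

All tabular outputs are tab-separated with a fixed column order and an
optional leading ``#`` comment carrying the config hash, so re-runs diff
cleanly. Gene annotation travels as BED3+name (0-based, half-open).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

import pandas as pd
import yaml


def config_hash(obj: Any) -> str:
    """Short stable hash of a JSON-serialisable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_tsv(df: pd.DataFrame, path: str | Path, comment: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_bed(genes: pd.DataFrame, path: str | Path) -> None:
    """Write gene annotation as BED3+name (chrom, start, end, gene)."""
    bed = genes[["chromosome", "start", "end", "gene"]]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    bed.to_csv(path, sep="\t", index=False, header=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    bed = pd.read_csv(
        path, sep="\t", header=None,
        names=["chromosome", "start", "end", "gene"], comment="#",
    )
    return bed[["gene", "chromosome", "start", "end"]]


def write_json(obj: Any, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def read_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
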