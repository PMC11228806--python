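"""Readers and writers for the plain-text formats used throughout the package.

Matrices travel as TSV (first column = row id), segment annotations as CSV,
gene sets as GMT, ligand-receptor annotations as TSV with ';'-joined gene
lists, and reports as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd


def read_matrix_tsv(path: str | Path, index_col: int = 0) -> pd.DataFrame:
    """Read a TSV matrix with row ids in the first column."""
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_matrix_tsv(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file into ``{set_name: [genes]}``.

    GMT lines are ``name<TAB>description<TAB>gene1<TAB>gene2...``. The
    description field is discarded. Duplicate genes within a set are removed
    preserving first occurrence.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            name, genes = fields[0], fields[2:]
            seen: dict[str, None] = {}
            for g in genes:
                if g and g not in seen:
                    seen[g] = None
            sets[name] = list(seen)
    return sets


def write_gmt(sets: Mapping[str, list[str]], path: str | Path,
              descriptions: Mapping[str, str] | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name, genes in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def write_json(obj, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def _json_default(o):
    import numpy as np

    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
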