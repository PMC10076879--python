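"""TSV/JSON readers and writers with diff-stable formatting.

All tables are tab-separated; floats are serialized at 9 significant
digits so repeated runs under the same seed are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

FLOAT_FORMAT = "%.9g"


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def read_matrix(path) -> pd.DataFrame:
    """Read a feature x sample matrix TSV (first column = feature id)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_samples(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "group"}
    if not required <= set(df.columns):
        raise ValueError("sample sheet needs sample_id and group columns")
    return df


def read_gene_list(path) -> list[str]:
    text = Path(path).read_text()
    return [line.strip() for line in text.splitlines() if line.strip()]


def write_gene_list(genes, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text("\n".join(genes) + ("\n" if len(list(genes)) else ""))


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True, default=str))
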