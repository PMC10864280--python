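"""TSV input/output helpers.

All tabular files are tab-separated with a header row; the first column is
``sample_id`` for feature tables (samples as rows, features as columns).
Missing metabolite measurements are empty cells, never zeros.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a samples x features TSV into a DataFrame indexed by sample_id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample IDs in {path}: {dupes[:5]}")
    return df


def write_feature_table(df: pd.DataFrame, path: str | Path) -> None:
    df = df.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", na_rep="")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the sample metadata TSV (sample_id, pair_id, zygosity, md, ...)."""
    md = pd.read_csv(path, sep="\t", index_col=0)
    md.index = md.index.astype(str)
    required = {"pair_id", "zygosity", "md"}
    missing = required - set(md.columns)
    if missing:
        raise ValueError(f"metadata missing required columns: {sorted(missing)}")
    bad = set(md["zygosity"].unique()) - {"MZ", "DZ"}
    if bad:
        raise ValueError(f"zygosity values must be MZ/DZ, got {sorted(bad)}")
    return md


def write_metadata(md: pd.DataFrame, path: str | Path) -> None:
    md = md.copy()
    md.index.name = "sample_id"
    md.to_csv(path, sep="\t", na_rep="")


def read_taxonomy(path: str | Path) -> dict[str, str]:
    """Read a two-column (feature_id, genus) TSV into a mapping."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("taxonomy map needs two columns: feature_id, genus")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
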