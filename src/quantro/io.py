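"""Matrix / group-label / config readers and writers for the CLI.

Matrix format: TSV or CSV, first column feature ids, header row sample ids,
numeric cells. Group labels: a two-column file (sample_id, group; optional
header) or an inline comma-separated list aligned to the sample columns.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .data import DataError, FeatureMatrix

logger = logging.getLogger(__name__)

__all__ = ["read_matrix", "write_matrix", "read_groups", "read_feature_list", "load_config"]


def _sep_for(path: Path, fmt: str | None) -> str:
    if fmt:
        return {"tsv": "\t", "csv": ","}.get(fmt.lower()) or fmt
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_matrix(path, fmt: str | None = None, drop_na: bool = False) -> FeatureMatrix:
    """Read a features x samples matrix (no group assignment yet).

    Raises :class:`DataError` with the offending row/column named for
    duplicate ids, non-numeric cells and ragged rows.
    """
    path = Path(path)
    sep = _sep_for(path, fmt)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    sample_ids = [h.strip() for h in header[1:]]
    if len(sample_ids) != len(set(sample_ids)):
        dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise DataError(f"duplicate sample ids in header: {dupes}")
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, on_bad_lines="error")
    except pd.errors.ParserError as exc:
        raise DataError(f"malformed matrix file {path.name}: {exc}") from exc
    df.columns = sample_ids
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise DataError(f"duplicate feature ids: {dupes[:5]}")
    for j, col in enumerate(df.columns):
        if df[col].dtype == object:
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            i = int(np.flatnonzero(bad)[0]) if bad.any() else 0
            raise DataError(
                f"non-numeric cell at feature {df.index[i]!r}, sample {col!r} "
                f"(file line {i + 2})"
            )
    return FeatureMatrix.from_dataframe(df, drop_na=drop_na)


def write_matrix(matrix, path, fmt: str | None = None) -> None:
    """Write a FeatureMatrix (or NormalizedMatrix) in the documented format."""
    fm = getattr(matrix, "matrix", matrix)  # accept NormalizedMatrix
    path = Path(path)
    sep = _sep_for(path, fmt)
    fm.to_dataframe().to_csv(path, sep=sep, index_label="feature_id")


def read_groups(source: str, sample_ids: Sequence[str]) -> np.ndarray:
    """Resolve a group assignment from a file path or an inline spec.

    A path points at a two-column (sample_id, group) table; otherwise the
    string is a comma-separated label list aligned to the sample columns.
    Every sample must be assigned exactly once.
    """
    sample_ids = [str(s) for s in sample_ids]
    p = Path(source)
    if p.exists():
        tab = pd.read_csv(p, sep=None, engine="python", header=None, dtype=str)
        if tab.shape[1] != 2:
            raise DataError(f"group file {p.name} must have two columns (sample_id, group)")
        first = str(tab.iloc[0, 0]).lower()
        if first in {"sample", "sample_id", "id"}:
            tab = tab.iloc[1:]
        mapping: dict[str, str] = {}
        for _, (sid, grp) in tab.iterrows():
            sid = str(sid).strip()
            if sid in mapping:
                raise DataError(f"sample {sid!r} assigned more than once")
            mapping[sid] = str(grp).strip()
        missing = [s for s in sample_ids if s not in mapping]
        if missing:
            raise DataError(f"samples without a group assignment: {missing}")
        unknown = [s for s in mapping if s not in set(sample_ids)]
        if unknown:
            raise DataError(f"group file names unknown samples: {unknown}")
        labels = [mapping[s] for s in sample_ids]
    else:
        labels = [x.strip() for x in str(source).split(",")]
        if len(labels) != len(sample_ids):
            raise DataError(
                f"inline group list has {len(labels)} labels for "
                f"{len(sample_ids)} samples"
            )
    return np.asarray(labels, dtype=object)


def read_feature_list(path) -> list[str]:
    """One feature id per line (e.g. spike-in probes)."""
    with open(path) as fh:
        ids = [line.strip() for line in fh if line.strip()]
    if not ids:
        raise DataError(f"feature list {path} is empty")
    return ids


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise DataError(f"config {path} must be a YAML mapping")
    return cfg
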