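"""Tab-separated readers/writers for OTU tables, metadata and results.

All writers prepend ``#``-prefixed header comments recording the package
version and any seeds/parameters, so every output file is self-describing;
all readers skip such comments.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .model import OtuTable, SampleMetadata, STAND_TYPES

__all__ = [
    "read_otu_table",
    "write_otu_table",
    "read_sample_metadata",
    "write_sample_metadata",
    "write_tsv",
    "read_tsv",
]

_ORIENTATIONS = ("otus_as_rows", "samples_as_rows")


def _version() -> str:
    from . import __version__

    return __version__


def _header_lines(params: Mapping | None) -> list[str]:
    lines = [f"# nichegrad {_version()}"]
    for key, value in (params or {}).items():
        lines.append(f"# {key}: {value}")
    return lines


def write_tsv(df: pd.DataFrame, path, params: Mapping | None = None,
              index_label: str | None = None) -> None:
    """Write a result frame as TSV with provenance header comments."""
    with open(path, "w") as fh:
        for line in _header_lines(params):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index_label=index_label)


def read_tsv(path, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def read_otu_table(path, orientation: str = "otus_as_rows") -> OtuTable:
    """Read a classic tab-separated OTU table.

    Parameters
    ----------
    path : str or PathLike
        TSV file with a header row of ids and a leading id column.
    orientation : {"otus_as_rows", "samples_as_rows"}
        Layout of the file.  Classic QIIME-style tables are OTUs x samples
        (``otus_as_rows``, the default); the returned table is always in
        canonical samples x OTUs orientation.
    """
    if orientation not in _ORIENTATIONS:
        raise ValueError(
            f"unknown orientation {orientation!r}; allowed: {_ORIENTATIONS}"
        )
    raw = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)

    values = np.empty(raw.shape, dtype=np.int64)
    for j, col in enumerate(raw.columns):
        try:
            parsed = pd.to_numeric(raw[col], errors="raise")
        except (ValueError, TypeError):
            bad = raw[col][pd.to_numeric(raw[col], errors="coerce").isna()]
            raise ValueError(
                f"non-numeric count {bad.iloc[0]!r} at row {bad.index[0]!r}, "
                f"column {col!r} in {os.fspath(path)}"
            ) from None
        arr = parsed.to_numpy()
        if not np.allclose(arr, np.round(arr), atol=0):
            i = int(np.argmax(arr != np.round(arr)))
            raise ValueError(
                f"non-integer count {arr[i]} at row {raw.index[i]!r}, "
                f"column {col!r}; OTU tables must hold read counts"
            )
        if (arr < 0).any():
            i = int(np.argmax(arr < 0))
            raise ValueError(
                f"negative count {int(arr[i])} at row {raw.index[i]!r}, "
                f"column {col!r}"
            )
        values[:, j] = arr.astype(np.int64)

    frame = pd.DataFrame(values, index=raw.index, columns=raw.columns)
    if orientation == "otus_as_rows":
        frame = frame.T
    frame.index.name = None
    frame.columns.name = None
    return OtuTable(frame)


def write_otu_table(t: OtuTable, path, orientation: str = "otus_as_rows",
                    params: Mapping | None = None) -> None:
    if orientation not in _ORIENTATIONS:
        raise ValueError(
            f"unknown orientation {orientation!r}; allowed: {_ORIENTATIONS}"
        )
    frame = t.counts.T if orientation == "otus_as_rows" else t.counts
    label = "otu_id" if orientation == "otus_as_rows" else "sample_id"
    write_tsv(frame, path, params=params, index_label=label)


def read_sample_metadata(path) -> SampleMetadata:
    """Read a sample metadata TSV (one row per sample).

    Required columns: ``sample_id``, ``stand_type`` (one of S/CF/MF/BF) and
    ``soil_layer`` (topsoil/subsoil).  Optional covariate columns are kept;
    missing optional values stay as NaN and are reported absent by the
    accessors, never imputed to zero.
    """
    frame = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str})
    if "sample_id" not in frame.columns:
        raise ValueError(f"{os.fspath(path)} has no sample_id column")
    frame = frame.set_index("sample_id")
    unknown = set(frame.get("stand_type", pd.Series(dtype=str))) - set(STAND_TYPES)
    if unknown:
        raise ValueError(
            f"unknown stand_type value(s) {sorted(unknown)} in "
            f"{os.fspath(path)}; allowed values: {list(STAND_TYPES)}"
        )
    return SampleMetadata(frame)


def write_sample_metadata(meta: SampleMetadata, path,
                          params: Mapping | None = None) -> None:
    write_tsv(meta.frame, path, params=params, index_label="sample_id")
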