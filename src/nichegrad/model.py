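"""Shared data model for dual-gradient OTU-table analyses.

The canonical in-memory orientation for community tables is samples (rows)
by OTUs (columns), mirroring how distance and ordination routines consume
them.  Classic OTU-table files on disk are usually the transpose; the
readers in :mod:`nichegrad.io` handle both orientations explicitly.

Distance matrices reuse :class:`skbio.DistanceMatrix`, the field's standard
container (symmetric, hollow, id-labelled).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

__all__ = [
    "STAND_TYPES",
    "SOIL_LAYERS",
    "CORE_METADATA_COLUMNS",
    "VARIABLE_GROUP_PREFIXES",
    "OtuTable",
    "RelativeAbundanceTable",
    "SampleMetadata",
    "DistanceMatrix",
]

#: Stand (afforestation) types: shrub, coniferous, mixed and broad-leaved
#: forest, in the fixed vocabulary order used throughout.
STAND_TYPES = ("S", "CF", "MF", "BF")

#: The two sampled soil layers (0-10 cm and 20-30 cm).
SOIL_LAYERS = ("topsoil", "subsoil")

CORE_METADATA_COLUMNS = (
    "stand_type",
    "soil_layer",
    "longitude_deg",
    "latitude_deg",
    "elevation_m",
)

#: Column-name prefixes marking named covariate vectors in metadata tables.
VARIABLE_GROUP_PREFIXES = {
    "soil_vars": "soil_",
    "plant_diversity": "plantdiv_",
    "tree_importance": "tree_",
    "shrub_importance": "shrub_",
}


def _check_unique(ids, what: str) -> None:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dups = ids[ids.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dups}")


@dataclass
class OtuTable:
    """Non-negative integer read-count matrix, samples x OTUs.

    Parameters
    ----------
    counts : pandas.DataFrame
        Rows indexed by sample id, columns by OTU id.  Values must be
        non-negative integers (read counts).
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        c = self.counts
        _check_unique(c.index, "sample_id")
        _check_unique(c.columns, "otu_id")
        values = c.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values), atol=0):
                raise ValueError(
                    "OTU table contains non-integer counts; pass "
                    "relative-abundance input through its own type instead"
                )
            c = c.astype(np.int64)
            object.__setattr__(self, "counts", c)
            values = c.to_numpy()
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative count at sample {c.index[i]!r}, OTU {c.columns[j]!r}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    def sample_depths(self) -> pd.Series:
        """Total reads per sample."""
        return self.counts.sum(axis=1)

    def require_positive_depths(self) -> None:
        depths = self.sample_depths()
        empty = depths[depths == 0]
        if len(empty):
            raise ValueError(
                f"sample(s) with zero total reads: {list(empty.index)}"
            )

    def subset_samples(self, sample_ids) -> "OtuTable":
        return OtuTable(self.counts.loc[list(sample_ids)])

    def subset_otus(self, otu_ids) -> "OtuTable":
        return OtuTable(self.counts[list(otu_ids)])

    def drop_empty_otus(self) -> tuple["OtuTable", int]:
        """Remove OTUs absent from every sample; return (table, n_dropped)."""
        present = self.counts.sum(axis=0) > 0
        return OtuTable(self.counts.loc[:, present]), int((~present).sum())


@dataclass
class RelativeAbundanceTable:
    """Per-sample proportions with the same indexing as :class:`OtuTable`."""

    fractions: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.fractions.index, "sample_id")
        _check_unique(self.fractions.columns, "otu_id")
        values = self.fractions.to_numpy(dtype=float)
        if (values < 0).any() or (values > 1).any():
            raise ValueError("relative abundances must lie in [0, 1]")
        rowsums = values.sum(axis=1)
        if not np.allclose(rowsums, 1.0, atol=1e-9):
            bad = self.fractions.index[np.argmax(np.abs(rowsums - 1))]
            raise ValueError(f"row of sample {bad!r} does not sum to 1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.fractions.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.fractions.columns)

    def subset_samples(self, sample_ids) -> "RelativeAbundanceTable":
        # Subsetting samples keeps valid rows; OTU subsetting would break
        # the row-sum invariant and is deliberately not offered.
        return RelativeAbundanceTable(self.fractions.loc[list(sample_ids)])


def to_relative_abundance(t: OtuTable) -> RelativeAbundanceTable:
    """Convert counts to within-sample proportions.

    Every abundance threshold in the classification modules acts on these
    per-sample fractions.  Raises if any sample has zero reads.
    """
    t.require_positive_depths()
    depths = t.counts.sum(axis=1)
    return RelativeAbundanceTable(t.counts.div(depths, axis=0))


@dataclass
class SampleMetadata:
    """Per-sample design and covariate records.

    One row per sample.  Core columns are stand type, soil layer and 3-D
    coordinates; optional named covariate vectors (soil physicochemistry,
    plant diversity indices, tree/shrub species importance values) are
    stored as prefixed columns (``soil_``, ``plantdiv_``, ``tree_``,
    ``shrub_``) and exposed as separate frames.  A missing group is
    reported as absent (``None``), never silently imputed.
    """

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        f = self.frame
        _check_unique(f.index, "sample_id")
        for col in ("stand_type", "soil_layer"):
            if col not in f.columns:
                raise ValueError(f"metadata missing required column {col!r}")
        bad = set(f["stand_type"]) - set(STAND_TYPES)
        if bad:
            raise ValueError(
                f"unknown stand_type value(s) {sorted(bad)}; "
                f"allowed: {list(STAND_TYPES)}"
            )
        bad = set(f["soil_layer"]) - set(SOIL_LAYERS)
        if bad:
            raise ValueError(
                f"unknown soil_layer value(s) {sorted(bad)}; "
                f"allowed: {list(SOIL_LAYERS)}"
            )
        for col in ("longitude_deg", "latitude_deg", "elevation_m"):
            if col in f.columns and np.isinf(
                f[col].to_numpy(dtype=float)
            ).any():
                raise ValueError(f"non-finite values in {col!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def stand_type(self) -> pd.Series:
        return self.frame["stand_type"]

    @property
    def soil_layer(self) -> pd.Series:
        return self.frame["soil_layer"]

    def coordinates(self) -> pd.DataFrame:
        cols = ["longitude_deg", "latitude_deg", "elevation_m"]
        missing = [c for c in cols if c not in self.frame.columns]
        if missing:
            raise ValueError(f"metadata has no coordinate column(s) {missing}")
        coords = self.frame[cols].astype(float)
        if coords.isna().any().any():
            bad = coords.index[coords.isna().any(axis=1)].tolist()
            raise ValueError(f"missing coordinates for sample(s) {bad}")
        return coords

    def variable_group(self, name: str) -> pd.DataFrame | None:
        """Return the named covariate frame (unprefixed columns) or None."""
        try:
            prefix = VARIABLE_GROUP_PREFIXES[name]
        except KeyError:
            raise ValueError(
                f"unknown variable group {name!r}; "
                f"known: {sorted(VARIABLE_GROUP_PREFIXES)}"
            ) from None
        reserved = set(CORE_METADATA_COLUMNS) | {"quadrat"}
        cols = [
            c for c in self.frame.columns
            if c.startswith(prefix) and c not in reserved
        ]
        if not cols:
            return None
        sub = self.frame[cols].astype(float)
        sub.columns = [c[len(prefix):] for c in cols]
        if sub.isna().all().all():
            return None
        return sub

    def samples_in_layer(self, layer: str) -> list[str]:
        if layer not in SOIL_LAYERS:
            raise ValueError(
                f"unknown soil layer {layer!r}; allowed: {list(SOIL_LAYERS)}"
            )
        mask = self.frame["soil_layer"] == layer
        return list(self.frame.index[mask])

    def subset(self, sample_ids) -> "SampleMetadata":
        return SampleMetadata(self.frame.loc[list(sample_ids)])
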