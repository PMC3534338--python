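"""Bin-by-lane read count matrices: ingestion, validation, filtering.

The shared data model for the whole package is a matrix of non-negative
integer read counts ``y_ij`` indexed by *bin* (the counting unit — an exon,
a gene, a k-mer; treated as an opaque identifier) and *lane* (one sequencing
dataset, a column).  Derived margins follow the usual notation:

* ``L_j`` — total read count of lane *j*
* ``E_i`` — total read count of bin *i* across the compared lanes
* ``T``   — grand total, with the conservation identity ``Σ L_j = Σ E_i = T``
* ``N``, ``M`` — number of bins and lanes.

Counts must be raw integers.  Normalised input (RPKM, CPM, ...) is rejected
at parse time because the Poisson sampling model behind the SERE statistic
only applies to raw counts; normalisation for the comparator statistics is
performed downstream, on demand.

On-disk format is plain UTF-8 tab-separated text with a header row: the
first column holds bin identifiers, an optional column named ``length``
holds bin lengths in base pairs, and every remaining (or explicitly named)
column is a lane of counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "SereError",
    "CountTableParseError",
    "ValidationError",
    "DimensionError",
    "LaneLookupError",
    "read_count_table",
    "write_count_table",
    "select_lanes",
    "drop_uninformative_bins",
    "singleton_mask",
]

LENGTH_COLUMN = "length"  # the single reserved non-lane column name


class SereError(Exception):
    """Base class for all errors raised by this package."""


class CountTableParseError(SereError, ValueError):
    """A count table cell could not be parsed as a non-negative integer."""


class ValidationError(SereError, ValueError):
    """A count matrix violates a structural invariant (e.g. duplicate ids)."""


class DimensionError(SereError, ValueError):
    """Too few lanes or bins for the requested operation."""


class LaneLookupError(SereError, KeyError):
    """A requested lane identifier does not exist."""


@dataclass(frozen=True)
class CountMatrix:
    """An immutable bins × lanes table of raw read counts.

    Parameters
    ----------
    bin_ids
        Unique string identifiers, one per row.
    lane_ids
        Unique string identifiers, one per column.
    counts
        Integer array of shape ``(n_bins, n_lanes)``; every entry ``>= 0``.
    bin_lengths
        Optional positive integer lengths (base pairs), parallel to
        ``bin_ids``; required only by RPKM-based comparator statistics.
    """

    bin_ids: np.ndarray
    lane_ids: np.ndarray
    counts: np.ndarray
    bin_lengths: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "bin_ids", np.asarray(self.bin_ids, dtype=object))
        object.__setattr__(self, "lane_ids", np.asarray(self.lane_ids, dtype=object))
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValidationError(f"counts must be 2-D, got shape {counts.shape}")
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                raise ValidationError("counts must be integral")
        counts = counts.astype(np.int64, copy=False)
        if counts.size and counts.min() < 0:
            i, j = np.argwhere(counts < 0)[0]
            raise ValidationError(
                f"negative count at bin {self.bin_ids[i]!r}, lane {self.lane_ids[j]!r}"
            )
        object.__setattr__(self, "counts", counts)
        if counts.shape != (len(self.bin_ids), len(self.lane_ids)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.bin_ids)} bins x {len(self.lane_ids)} lanes"
            )
        # pd.unique is hash-based: much faster than np.unique on string ids
        if len(pd.unique(self.bin_ids)) != len(self.bin_ids):
            raise ValidationError("duplicate bin identifiers")
        if len(pd.unique(self.lane_ids)) != len(self.lane_ids):
            raise ValidationError("duplicate lane identifiers")
        if self.bin_lengths is not None:
            lengths = np.asarray(self.bin_lengths, dtype=np.int64)
            if lengths.shape != (len(self.bin_ids),):
                raise ValidationError("bin_lengths not parallel to bin_ids")
            if lengths.size and lengths.min() <= 0:
                raise ValidationError("bin lengths must be positive")
            object.__setattr__(self, "bin_lengths", lengths)

    # -- derived margins ---------------------------------------------------

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    @property
    def n_lanes(self) -> int:
        return self.counts.shape[1]

    @property
    def lane_totals(self) -> np.ndarray:
        """``L_j``: per-lane read totals."""
        return self.counts.sum(axis=0)

    @property
    def bin_totals(self) -> np.ndarray:
        """``E_i``: per-bin read totals across lanes."""
        return self.counts.sum(axis=1)

    @property
    def grand_total(self) -> int:
        """``T``: total reads in the matrix."""
        return int(self.counts.sum())

    def lane_index(self, lane_id: str) -> int:
        hits = np.flatnonzero(self.lane_ids == lane_id)
        if hits.size == 0:
            raise LaneLookupError(f"unknown lane id: {lane_id!r}")
        return int(hits[0])

    def equals(self, other: "CountMatrix") -> bool:
        """Exact equality of ids, lengths and counts."""
        if not isinstance(other, CountMatrix):
            return False
        if (self.bin_lengths is None) != (other.bin_lengths is None):
            return False
        return (
            np.array_equal(self.bin_ids, other.bin_ids)
            and np.array_equal(self.lane_ids, other.lane_ids)
            and np.array_equal(self.counts, other.counts)
            and (
                self.bin_lengths is None
                or np.array_equal(self.bin_lengths, other.bin_lengths)
            )
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"bin_id": self.bin_ids})
        if self.bin_lengths is not None:
            df[LENGTH_COLUMN] = self.bin_lengths
        for j, lane in enumerate(self.lane_ids):
            df[str(lane)] = self.counts[:, j]
        return df


def read_count_table(
    path: str | Path, lane_columns: Sequence[str] | None = None
) -> CountMatrix:
    """Read a tab-separated count table into a validated :class:`CountMatrix`.

    The first column is taken as the bin identifier; a column named
    ``length`` (if present) provides bin lengths; all other columns — or the
    subset named in ``lane_columns`` — are lanes of raw integer counts.

    Raises
    ------
    CountTableParseError
        If a count cell is negative or not an integer (the offending bin and
        lane are named).
    ValidationError
        On duplicate bin identifiers.
    DimensionError
        If fewer than two lane columns are selected.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=0, dtype={0: str})
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise CountTableParseError(f"{path}: {exc}") from exc
    if df.shape[1] < 2:
        raise DimensionError(f"{path}: need a bin-id column plus count columns")
    id_col = df.columns[0]
    bin_ids = df[id_col].to_numpy(dtype=object)

    lengths = None
    if LENGTH_COLUMN in df.columns[1:]:
        lengths = _parse_int_column(df, LENGTH_COLUMN, path, allow_zero=False)

    if lane_columns is None:
        lane_columns = [c for c in df.columns[1:] if c != LENGTH_COLUMN]
    else:
        missing = [c for c in lane_columns if c not in df.columns]
        if missing:
            raise LaneLookupError(f"{path}: no such lane column(s): {missing}")
    if len(lane_columns) < 2:
        raise DimensionError(
            f"{path}: at least 2 lane columns required, got {len(lane_columns)}"
        )

    counts = np.empty((len(df), len(lane_columns)), dtype=np.int64)
    for j, col in enumerate(lane_columns):
        counts[:, j] = _parse_int_column(df, col, path, allow_zero=True)

    return CountMatrix(
        bin_ids=bin_ids,
        lane_ids=np.asarray(list(lane_columns), dtype=object),
        counts=counts,
        bin_lengths=lengths,
    )


def _parse_int_column(
    df: pd.DataFrame, col: str, path: Path, allow_zero: bool
) -> np.ndarray:
    series = df[col]
    numeric = pd.to_numeric(series, errors="coerce")
    bad = numeric.isna() | (np.mod(numeric.fillna(0), 1) != 0)
    if not bad.any():
        low = 0 if allow_zero else 1
        bad = numeric < low
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise CountTableParseError(
            f"{path}: invalid value {series.iloc[row]!r} in column {col!r}, "
            f"row {row + 2} (bin {df.iloc[row, 0]!r}): expected a "
            f"non-negative integer"
        )
    return numeric.to_numpy(dtype=np.int64)


def write_count_table(matrix: CountMatrix, path: str | Path) -> None:
    """Write ``matrix`` as a tab-separated table; inverse of
    :func:`read_count_table`."""
    matrix.to_dataframe().to_csv(Path(path), sep="\t", index=False)


def select_lanes(matrix: CountMatrix, lanes: Sequence[str]) -> CountMatrix:
    """Column-subset ``matrix`` to ``lanes``, in the requested order.

    The bin set is unchanged.  Raises :class:`LaneLookupError` for unknown
    lane ids.
    """
    idx = [matrix.lane_index(lane) for lane in lanes]
    return CountMatrix(
        bin_ids=matrix.bin_ids,
        lane_ids=np.asarray(list(lanes), dtype=object),
        counts=matrix.counts[:, idx],
        bin_lengths=matrix.bin_lengths,
    )


def drop_uninformative_bins(matrix: CountMatrix) -> CountMatrix:
    """Drop bins whose count is zero in every compared lane.

    Such bins carry no information about lane agreement and are excluded
    before any of the comparison statistics.  Lane totals are unchanged; the
    result may have zero bins.
    """
    keep = matrix.bin_totals > 0
    return CountMatrix(
        bin_ids=matrix.bin_ids[keep],
        lane_ids=matrix.lane_ids,
        counts=matrix.counts[keep, :],
        bin_lengths=None if matrix.bin_lengths is None else matrix.bin_lengths[keep],
    )


def singleton_mask(matrix: CountMatrix) -> np.ndarray:
    """Boolean mask, true where a bin is a *singleton*: total count across
    all compared lanes exactly 1.

    A singleton's per-bin dispersion is exactly 1 whenever lane totals are
    balanced, so singletons pull the SERE statistic toward 1 regardless of
    sample similarity and are excluded from its average by default.
    """
    return matrix.bin_totals == 1
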