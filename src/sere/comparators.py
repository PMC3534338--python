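"""Competitor statistics: Pearson's r on transformed counts and Cohen's
kappa on RPKM bins.

Both are widely used to argue that two RNA-Seq lanes are faithful
replicates, and both are benchmarked here against SERE.  Pearson's r is
computed on log-transformed RPKM after adding a pseudo-count of one read
(the most common normalisation), with log-count and square-root-count
variants for sensitivity checks.  Cohen's kappa is computed after binning
RPKM values into K ordered expression categories; the default scheme is the
9-bin ladder 0, 1-10, 11-20, 21-40, 41-80, 81-160, 161-320, 321-1000, >1000
RPKM, resolved as half-open intervals {0}, (0,10], (10,20], ..., (1000, inf).

RPKM for the kappa path is computed *without* the pseudo-count so that the
"0" category stays reachable; the Pearson path keeps the pseudo-count.  When
bin lengths are unavailable (pure simulations over a common bin set), unit
lengths are used: the resulting scale is reads-per-million x 10^3 and the
bin edges apply to that scale.  All-zero bins are excluded before either
statistic, mirroring the filtering applied to SERE.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .count_data import (
    CountMatrix,
    DimensionError,
    SereError,
    drop_uninformative_bins,
)

__all__ = [
    "BinScheme",
    "ContingencyTable",
    "ConfigurationError",
    "UndefinedCorrelationError",
    "UndefinedKappaError",
    "DEFAULT_BIN_SCHEME",
    "rpkm_transform",
    "pearson_log_rpkm",
    "assign_bins",
    "contingency_table",
    "cohens_kappa",
    "weighted_kappa",
    "kappa_for_lanes",
]

Transform = Literal["log-rpkm-pseudo", "log-count-pseudo", "sqrt-count"]


class ConfigurationError(SereError, ValueError):
    """A comparator was configured inconsistently with the input data."""


class UndefinedCorrelationError(SereError, ValueError):
    """Pearson's r is undefined (zero variance in a compared vector)."""


class UndefinedKappaError(SereError, ValueError):
    """Kappa is undefined (chance agreement is exactly 1)."""


@dataclass(frozen=True)
class BinScheme:
    """Ordered expression categories over the non-negative RPKM scale.

    ``edges`` are the K-1 strictly increasing thresholds; value ``v`` falls
    in category ``k`` = number of edges strictly below ``v``.  With the
    default edges ``(0, 10, 20, ...)`` this yields the half-open partition
    {0}, (0, 10], (10, 20], ..., (last, inf): category 0 is the exact value
    0, and a value sitting on a threshold belongs to the lower category.
    """

    edges: tuple[float, ...]
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        edges = tuple(float(e) for e in self.edges)
        if len(edges) < 1 or any(b <= a for a, b in zip(edges, edges[1:])):
            raise ConfigurationError("bin edges must be strictly increasing, K >= 2")
        object.__setattr__(self, "edges", edges)
        if self.labels is not None and len(self.labels) != self.n_categories:
            raise ConfigurationError(
                f"{len(self.labels)} labels for {self.n_categories} categories"
            )

    @property
    def n_categories(self) -> int:
        return len(self.edges) + 1

    def category_labels(self) -> tuple[str, ...]:
        if self.labels is not None:
            return self.labels
        edges = self.edges
        out = [f"<={edges[0]:g}"]
        out += [f"({a:g},{b:g}]" for a, b in zip(edges, edges[1:])]
        out.append(f">{edges[-1]:g}")
        return tuple(out)

    @classmethod
    def from_edges_text(cls, text: str) -> "BinScheme":
        """Parse a comma- or whitespace-separated list of edges."""
        parts = [p for p in text.replace(",", " ").split() if p]
        return cls(edges=tuple(float(p) for p in parts))


DEFAULT_BIN_SCHEME = BinScheme(
    edges=(0.0, 10.0, 20.0, 40.0, 80.0, 160.0, 320.0, 1000.0),
    labels=(
        "0",
        "1-10",
        "11-20",
        "21-40",
        "41-80",
        "81-160",
        "161-320",
        "321-1000",
        ">1000",
    ),
)


@dataclass(frozen=True)
class ContingencyTable:
    """K x K agreement table: rows are lane-A categories, columns lane-B."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("contingency table must be square")
        if c.size and c.min() < 0:
            raise ValueError("contingency table counts must be non-negative")
        object.__setattr__(self, "counts", c)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def row_marginals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_marginals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def observed_agreement(self) -> float:
        """p_o: fraction of compared bins on the diagonal."""
        return float(np.trace(self.counts)) / self.total

    @property
    def chance_agreement(self) -> float:
        """p_e: agreement expected from the marginals alone."""
        t = float(self.total)
        return float(self.row_marginals @ self.col_marginals) / (t * t)


def rpkm_transform(
    counts: np.ndarray,
    lengths: np.ndarray | None,
    lane_total: int,
    pseudo_count: int = 1,
) -> np.ndarray:
    """Reads per kilobase of bin per million mapped reads.

    ``value_i = (counts_i + pseudo_count) * 1e9 / (lengths_i * lane_total)``.
    Pass ``lengths=np.ones(n)`` explicitly (unit-length mode) when bin
    lengths are unknown, as in simulations over a common bin set.
    """
    if lengths is None:
        raise ConfigurationError(
            "bin lengths are required for RPKM; pass unit lengths "
            "(np.ones(n_bins)) to use the length-free reads-per-million scale"
        )
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if np.any(lengths <= 0):
        raise ConfigurationError("bin lengths must be positive")
    if lane_total <= 0:
        raise ConfigurationError("lane total must be positive")
    return (counts + pseudo_count) * 1e9 / (lengths * lane_total)


def _transform_lane(
    counts: np.ndarray,
    lengths: np.ndarray | None,
    lane_total: int,
    transform: Transform,
    pseudo_count: int,
    log_base: float,
) -> np.ndarray:
    if transform == "log-rpkm-pseudo":
        if lengths is None:
            lengths = np.ones(len(counts))
        values = rpkm_transform(counts, lengths, lane_total, pseudo_count)
        return np.log(values) / np.log(log_base)
    if transform == "log-count-pseudo":
        return np.log(np.asarray(counts, dtype=float) + pseudo_count) / np.log(log_base)
    if transform == "sqrt-count":
        return np.sqrt(np.asarray(counts, dtype=float))
    raise ConfigurationError(f"unknown transform: {transform!r}")


def pearson_log_rpkm(
    matrix: CountMatrix,
    transform: Transform = "log-rpkm-pseudo",
    pseudo_count: int = 1,
    log_base: float = 10.0,
) -> float:
    """Pearson product-moment correlation of two transformed lanes.

    The matrix must hold exactly 2 lanes; all-zero bins are dropped first.
    The default transform is log10 of pseudo-counted RPKM (unit lengths if
    the matrix has none); r itself is invariant to the log base.
    """
    if matrix.n_lanes != 2:
        raise DimensionError("Pearson comparison is defined for exactly 2 lanes")
    informative = drop_uninformative_bins(matrix)
    if informative.n_bins < 2:
        raise DimensionError("need at least 2 informative bins for correlation")
    totals = informative.lane_totals
    vectors = [
        _transform_lane(
            informative.counts[:, j],
            informative.bin_lengths,
            int(totals[j]),
            transform,
            pseudo_count,
            log_base,
        )
        for j in (0, 1)
    ]
    if np.std(vectors[0]) == 0.0 or np.std(vectors[1]) == 0.0:
        raise UndefinedCorrelationError(
            "correlation undefined: a transformed lane has zero variance"
        )
    return float(stats.pearsonr(vectors[0], vectors[1]).statistic)


def assign_bins(rpkm: np.ndarray, scheme: BinScheme = DEFAULT_BIN_SCHEME) -> np.ndarray:
    """Map non-negative RPKM values to category indices under ``scheme``."""
    values = np.asarray(rpkm, dtype=float)
    if values.size and values.min() < 0:
        raise ValueError("RPKM values must be non-negative")
    return np.searchsorted(np.asarray(scheme.edges), values, side="left")


def contingency_table(
    categories_a: np.ndarray, categories_b: np.ndarray, k: int
) -> ContingencyTable:
    """Cross-tabulate two equal-length category vectors into a K x K table."""
    a = np.asarray(categories_a, dtype=np.int64)
    b = np.asarray(categories_b, dtype=np.int64)
    if a.shape != b.shape:
        raise ValueError("category vectors must have equal length")
    if a.size and (a.min() < 0 or a.max() >= k or b.min() < 0 or b.max() >= k):
        raise ValueError(f"category index out of range for k={k}")
    flat = np.bincount(a * k + b, minlength=k * k)
    return ContingencyTable(counts=flat.reshape(k, k))


def cohens_kappa(table: ContingencyTable) -> float:
    """Cohen's simple kappa: chance-corrected agreement
    ``(p_o - p_e) / (1 - p_e)``."""
    if table.total == 0:
        raise UndefinedKappaError("empty contingency table")
    p_o = table.observed_agreement
    p_e = table.chance_agreement
    if p_e >= 1.0:
        raise UndefinedKappaError(
            "kappa undefined: chance agreement is 1 (all mass in one cell)"
        )
    return (p_o - p_e) / (1.0 - p_e)


def weighted_kappa(
    table: ContingencyTable, weights: Literal["linear"] = "linear"
) -> float:
    """Linearly weighted kappa: disagreement proportional to the distance
    from the diagonal, ``w_ab = |a - b| / (K - 1)``."""
    if weights != "linear":
        raise ConfigurationError(f"unsupported weighting: {weights!r}")
    if table.total == 0:
        raise UndefinedKappaError("empty contingency table")
    k = table.counts.shape[0]
    idx = np.arange(k)
    w = np.abs(idx[:, None] - idx[None, :]) / (k - 1) if k > 1 else np.zeros((1, 1))
    t = float(table.total)
    observed = float((w * table.counts).sum()) / t
    expected = float(
        (w * np.outer(table.row_marginals, table.col_marginals)).sum()
    ) / (t * t)
    if expected == 0.0:
        raise UndefinedKappaError(
            "weighted kappa undefined: expected disagreement is 0"
        )
    return 1.0 - observed / expected


def kappa_for_lanes(
    matrix: CountMatrix,
    scheme: BinScheme = DEFAULT_BIN_SCHEME,
    weighted: bool = False,
) -> float:
    """Kappa between two lanes after RPKM binning.

    Counts are converted to RPKM *without* a pseudo-count (so the zero
    category is reachable), unit lengths standing in when the matrix has
    none; all-zero bins are dropped first.
    """
    if matrix.n_lanes != 2:
        raise DimensionError("kappa comparison is defined for exactly 2 lanes")
    informative = drop_uninformative_bins(matrix)
    if informative.n_bins == 0:
        raise DimensionError("no informative bins for kappa")
    lengths = (
        informative.bin_lengths
        if informative.bin_lengths is not None
        else np.ones(informative.n_bins)
    )
    totals = informative.lane_totals
    cats = [
        assign_bins(
            rpkm_transform(
                informative.counts[:, j], lengths, int(totals[j]), pseudo_count=0
            ),
            scheme,
        )
        for j in (0, 1)
    ]
    table = contingency_table(cats[0], cats[1], scheme.n_categories)
    return weighted_kappa(table) if weighted else cohens_kappa(table)
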