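"""The SERE statistic: Poisson dispersion ratio, confidence intervals,
pairwise matrices and clustering.

Given raw counts ``y_ij`` for bin *i* in lane *j*, the null hypothesis of
faithful technical replication says every lane samples the same underlying
transcript population, so each ``y_ij`` is Poisson with expectation

    yhat_ij = E_i * L_j / T

(the margin-preserving independence fit).  The per-bin overdispersion is the
Pearson ratio

    s_i^2 = 1/(M-1) * sum_j (y_ij - yhat_ij)^2 / yhat_ij

with ``M-1`` degrees of freedom because the deviations of a bin sum to zero
across lanes.  Averaging over the informative, non-singleton bins gives
``s^2``, and SERE is ``s = sqrt(s^2)``:

* ``s = 1``  — lanes differ exactly as Poisson sampling predicts (faithful
  replicates);
* ``s > 1``  — overdispersion: genuine global differences between lanes;
* ``s < 1``  — underdispersion: suspicious excess agreement;
* ``s = 0``  — perfect identity, e.g. an accidentally duplicated file.

Singletons (bins with a single read across all compared lanes) have
``s_i^2 = 1`` identically under balanced lane totals, so they shrink the
average toward 1 whatever the samples are; they are excluded by default.

Under the null, ``nu * s^2`` with ``nu = n_used * (M-1)`` is approximately
chi-square with ``nu`` degrees of freedom; under a fixed alternative it is
noncentral chi-square with noncentrality ``lambda = sum_ij L_j^2 *
(p_ij - pbar_i)^2 / ...`` driven by the divergence of the true per-lane bin
fractions ``p_ij`` from the pooled fractions ``pbar_i``.  Confidence
intervals invert this family (see :func:`sere_confidence_interval`).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.optimize import brentq
from scipy.spatial.distance import squareform

from .count_data import (
    CountMatrix,
    DimensionError,
    SereError,
    drop_uninformative_bins,
    select_lanes,
    singleton_mask,
)

__all__ = [
    "DispersionResult",
    "SereMatrix",
    "SereDendrogram",
    "DegenerateInputError",
    "EmptyComparisonError",
    "DegenerateLaneError",
    "expected_counts",
    "bin_dispersions",
    "sere_statistic",
    "sere_confidence_interval",
    "pairwise_sere",
    "sere_cluster",
]


class DegenerateInputError(SereError, ValueError):
    """Input has no usable signal (e.g. grand total of zero)."""


class EmptyComparisonError(SereError, ValueError):
    """No bins remain after filtering; the comparison is empty."""


class DegenerateLaneError(SereError, ValueError):
    """A compared lane has a total count of zero.

    An empty lane almost always signals an upstream processing error —
    detecting exactly that kind of failure is this statistic's purpose — so
    it is rejected rather than silently dropped.
    """


@dataclass(frozen=True)
class DispersionResult:
    """Outcome of a SERE computation on one set of lanes.

    Attributes
    ----------
    per_bin_dispersion
        ``s_i^2`` for each of the ``n_used`` bins entering the average.
    n_used
        Informative, non-singleton bins averaged over.
    n_singletons_excluded
        Singleton bins removed before averaging (0 if exclusion was off).
    m_lanes
        Number of compared lanes ``M``.
    s_squared, sere
        The mean dispersion ``s^2`` and its square root ``s`` (SERE).
    dof
        ``nu = n_used * (M - 1)``.
    ci_level, ci_lower, ci_upper
        Confidence interval on the SERE scale (None if not requested).
    """

    per_bin_dispersion: np.ndarray
    n_used: int
    n_singletons_excluded: int
    m_lanes: int
    s_squared: float
    sere: float
    dof: int
    ci_level: float | None = None
    ci_lower: float | None = None
    ci_upper: float | None = None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        ci = (
            f", {self.ci_level:.0%} CI [{self.ci_lower:.3f}, {self.ci_upper:.3f}]"
            if self.ci_level is not None
            else ""
        )
        return (
            f"SERE = {self.sere:.3f} ({self.n_used} bins, {self.m_lanes} lanes, "
            f"{self.n_singletons_excluded} singletons excluded{ci})"
        )


def expected_counts(matrix: CountMatrix) -> np.ndarray:
    """Expected counts ``yhat_ij = E_i * L_j / T`` under the replication null.

    Row sums of the result equal the bin totals ``E_i`` and column sums the
    lane totals ``L_j`` (margins are preserved).  The matrix must already be
    stripped of all-zero bins; a grand total of zero raises
    :class:`DegenerateInputError`.
    """
    T = matrix.grand_total
    if T == 0:
        raise DegenerateInputError("grand total is zero; no reads to compare")
    return np.outer(matrix.bin_totals, matrix.lane_totals) / float(T)


def bin_dispersions(matrix: CountMatrix) -> np.ndarray:
    """Per-bin Poisson overdispersion ``s_i^2``.

    Every bin must be informative (``E_i > 0``) so that all ``yhat_ij > 0``;
    an all-zero bin reaching this function is a contract violation upstream.
    """
    if np.any(matrix.bin_totals == 0):
        raise DegenerateInputError(
            "bin with zero total reached bin_dispersions; "
            "apply drop_uninformative_bins first"
        )
    yhat = expected_counts(matrix)
    y = matrix.counts.astype(float)
    return ((y - yhat) ** 2 / yhat).sum(axis=1) / (matrix.n_lanes - 1)


def sere_statistic(
    matrix: CountMatrix,
    exclude_singletons: bool = True,
    ci_level: float | None = 0.99,
    ci_mode: Literal["noncentral", "null"] = "noncentral",
) -> DispersionResult:
    """Compute SERE for a set of ``M >= 2`` lanes.

    All-zero bins are dropped, and (by default) singleton bins are excluded
    from both the numerator and the divisor of the dispersion average.

    Raises
    ------
    DimensionError
        Fewer than two lanes.
    DegenerateLaneError
        Any lane with zero total count.
    EmptyComparisonError
        No informative (non-singleton, if excluded) bins remain.
    """
    if matrix.n_lanes < 2:
        raise DimensionError("SERE requires at least 2 lanes")
    if np.any(matrix.lane_totals == 0):
        empty = matrix.lane_ids[matrix.lane_totals == 0]
        raise DegenerateLaneError(f"lane(s) with zero total count: {list(empty)}")

    informative = drop_uninformative_bins(matrix)
    n_singletons = 0
    if exclude_singletons:
        singles = singleton_mask(informative)
        n_singletons = int(singles.sum())
        keep = ~singles
        informative = CountMatrix(
            bin_ids=informative.bin_ids[keep],
            lane_ids=informative.lane_ids,
            counts=informative.counts[keep, :],
            bin_lengths=None
            if informative.bin_lengths is None
            else informative.bin_lengths[keep],
        )
    if informative.n_bins == 0:
        raise EmptyComparisonError(
            "no informative bins remain after filtering; nothing to compare"
        )
    if np.any(informative.lane_totals == 0):
        empty = informative.lane_ids[informative.lane_totals == 0]
        raise DegenerateLaneError(
            f"lane(s) with zero total count after filtering: {list(empty)}"
        )

    s_i2 = bin_dispersions(informative)
    s2 = float(s_i2.mean())
    m = matrix.n_lanes
    dof = informative.n_bins * (m - 1)
    result = DispersionResult(
        per_bin_dispersion=s_i2,
        n_used=informative.n_bins,
        n_singletons_excluded=n_singletons,
        m_lanes=m,
        s_squared=s2,
        sere=float(np.sqrt(s2)),
        dof=dof,
    )
    if ci_level is None:
        return result
    lower, upper = sere_confidence_interval(result, level=ci_level, mode=ci_mode)
    return DispersionResult(
        **{
            **result.__dict__,
            "ci_level": ci_level,
            "ci_lower": lower,
            "ci_upper": upper,
        }
    )


def _solve_noncentrality(x: float, dof: int, q: float) -> float:
    """Largest-bracket solve of ``P(X <= x | chi2(dof, nc)) = q`` for nc >= 0.

    The CDF is strictly decreasing in the noncentrality ``nc``; if even
    ``nc = 0`` gives a CDF at or below ``q`` the solution is floored at 0.
    """

    def cdf(nc: float) -> float:
        if nc == 0.0:
            return stats.chi2.cdf(x, dof)
        return stats.ncx2.cdf(x, dof, nc)

    if cdf(0.0) <= q:
        return 0.0
    hi = max(1.0, x - dof, 2.0 * np.sqrt(2.0 * dof))
    while cdf(hi) > q:
        hi *= 2.0
        if hi > 1e12:  # pragma: no cover - pathological
            return hi
    return float(brentq(lambda nc: cdf(nc) - q, 0.0, hi, xtol=1e-9, rtol=1e-12))


def sere_confidence_interval(
    result: DispersionResult,
    level: float = 0.99,
    mode: Literal["noncentral", "null"] = "noncentral",
) -> tuple[float, float]:
    """Confidence interval for SERE from the chi-square dispersion relation.

    ``nu * s^2`` is chi-square with ``nu = n_used * (M-1)`` degrees of
    freedom under the replication null, and noncentral chi-square with
    noncentrality ``lambda`` under a fixed alternative.

    ``mode="noncentral"`` (default) inverts that family: it finds the
    noncentralities ``lambda_lo <= lambda_hi`` at which the observed
    ``nu * s^2`` sits at the upper and lower ``(1-level)/2`` tail quantiles,
    floors them at 0, and maps to the SERE scale through the mean relation
    ``E[chi2(nu, lambda)] = nu + lambda``, i.e. ``bound =
    sqrt((nu + lambda)/nu)``.  The interval therefore describes the
    *model-implied* SERE (which is >= 1 by construction) and contains the
    point estimate exactly when ``s >= 1``; for strongly underdispersed data
    it degenerates to [1, 1] — the noncentral family cannot represent
    underdispersion, which is a finding in itself.

    ``mode="null"`` scales the point estimate by central chi-square
    quantiles, ``s * sqrt(chi2_q(nu)/nu)``; it always brackets ``s`` and its
    width shrinks as ``O(nu^{-1/2})``.
    """
    if not (0.0 < level < 1.0):
        raise ValueError(f"confidence level must be in (0, 1), got {level}")
    if result.dof < 1:
        raise DegenerateInputError("confidence interval requires dof >= 1")
    nu = result.dof
    alpha = 1.0 - level
    if mode == "null":
        lo = float(np.sqrt(stats.chi2.ppf(alpha / 2.0, nu) / nu)) * result.sere
        hi = float(np.sqrt(stats.chi2.ppf(1.0 - alpha / 2.0, nu) / nu)) * result.sere
        return lo, hi
    if mode != "noncentral":
        raise ValueError(f"unknown CI mode: {mode!r}")
    x = nu * result.s_squared
    nc_lo = _solve_noncentrality(x, nu, 1.0 - alpha / 2.0)
    nc_hi = _solve_noncentrality(x, nu, alpha / 2.0)
    return float(np.sqrt((nu + nc_lo) / nu)), float(np.sqrt((nu + nc_hi) / nu))


# -- pairwise comparison and clustering ------------------------------------


@dataclass(frozen=True)
class SereMatrix:
    """Symmetric matrix of pairwise SERE scores; diagonal 0 by convention
    (a lane against itself is a duplication)."""

    lane_ids: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "lane_ids", np.asarray(self.lane_ids, dtype=object))
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.lane_ids),) * 2 or not np.allclose(v, v.T):
            raise ValueError("pairwise SERE values must be a symmetric square matrix")
        object.__setattr__(self, "values", v)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.lane_ids, columns=self.lane_ids)

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(Path(path), sep="\t", index_label="lane")


def pairwise_sere(
    matrix: CountMatrix, exclude_singletons: bool = True
) -> SereMatrix:
    """SERE for every lane pair, as a symmetric matrix.

    Zero-bin and singleton filtering are re-applied per pair (a bin empty in
    both members of a pair is uninformative for that pair even if expressed
    elsewhere), matching the pair-level definition of the statistic.
    """
    if matrix.n_lanes < 2:
        raise DimensionError("pairwise SERE requires at least 2 lanes")
    m = matrix.n_lanes
    out = np.zeros((m, m))
    for a in range(m):
        for b in range(a + 1, m):
            pair = select_lanes(matrix, [matrix.lane_ids[a], matrix.lane_ids[b]])
            res = sere_statistic(
                pair, exclude_singletons=exclude_singletons, ci_level=None
            )
            out[a, b] = out[b, a] = res.sere
    return SereMatrix(lane_ids=matrix.lane_ids, values=out)


@dataclass(frozen=True)
class SereDendrogram:
    """Hierarchical clustering of lanes on the pairwise SERE dissimilarity.

    Merge heights read directly as excess dispersion: lanes merging near 1
    behave as faithful replicates of one another, heights well above 1 mark
    genuine global differences, and heights near 0 flag duplicated data.
    """

    lane_ids: np.ndarray
    linkage_matrix: np.ndarray
    method: str
    pairwise: SereMatrix

    def to_newick(self) -> str:
        """Serialise as a Newick string with branch lengths derived from
        merge heights."""
        from skbio import TreeNode  # deferred: slow import

        tree = TreeNode.from_linkage_matrix(
            self.linkage_matrix, [str(x) for x in self.lane_ids]
        )
        return str(tree)

    def write_newick(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick())


def sere_cluster(
    matrix: CountMatrix,
    method: Literal["average", "single", "complete"] = "average",
    exclude_singletons: bool = True,
) -> SereDendrogram:
    """Agglomeratively cluster ``M >= 3`` lanes using pairwise SERE as the
    dissimilarity (average linkage by default).

    With single, complete or average linkage on a precomputed dissimilarity
    the merge heights are non-decreasing along the agglomeration.
    """
    if matrix.n_lanes < 3:
        raise DimensionError("clustering requires at least 3 lanes")
    pw = pairwise_sere(matrix, exclude_singletons=exclude_singletons)
    condensed = squareform(pw.values, checks=False)
    linkage = hierarchy.linkage(condensed, method=method)
    return SereDendrogram(
        lane_ids=matrix.lane_ids,
        linkage_matrix=linkage,
        method=method,
        pairwise=pw,
    )
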