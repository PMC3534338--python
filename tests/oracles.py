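"""Independent brute-force oracles, written as literal loop translations of
the defining formulas.  They deliberately share no code with the package
implementation they are used to check."""

from __future__ import annotations

import numpy as np


def sere_oracle(counts, exclude_singletons: bool = True) -> float:
    """Literal evaluation of the dispersion-ratio statistic.

    Drops all-zero rows, optionally drops rows with total 1, recomputes
    margins from the retained rows, then loops over cells.
    """
    rows = [list(map(float, row)) for row in counts]
    m = len(rows[0])
    kept = []
    for row in rows:
        total = sum(row)
        if total == 0:
            continue
        if exclude_singletons and total == 1:
            continue
        kept.append(row)
    if not kept:
        raise ValueError("no informative bins")
    lane_totals = [sum(row[j] for row in kept) for j in range(m)]
    if any(lane == 0 for lane in lane_totals):
        raise ValueError("degenerate lane")
    grand = sum(lane_totals)
    s2_sum = 0.0
    for row in kept:
        e_i = sum(row)
        s_i2 = 0.0
        for j in range(m):
            yhat = e_i * lane_totals[j] / grand
            s_i2 += (row[j] - yhat) ** 2 / yhat
        s2_sum += s_i2 / (m - 1)
    return float(np.sqrt(s2_sum / len(kept)))


def kappa_oracle(table) -> float:
    """Cohen's kappa by explicit double loops over a square table."""
    table = [list(map(float, row)) for row in table]
    k = len(table)
    total = sum(sum(row) for row in table)
    p_o = sum(table[i][i] for i in range(k)) / total
    p_e = 0.0
    for c in range(k):
        row_marginal = sum(table[c][j] for j in range(k))
        col_marginal = sum(table[i][c] for i in range(k))
        p_e += (row_marginal * col_marginal) / (total * total)
    return (p_o - p_e) / (1.0 - p_e)


def weighted_kappa_oracle(table) -> float:
    """Linearly weighted kappa by explicit double loops."""
    table = [list(map(float, row)) for row in table]
    k = len(table)
    total = sum(sum(row) for row in table)
    observed = 0.0
    expected = 0.0
    for a in range(k):
        for b in range(k):
            w = abs(a - b) / (k - 1)
            row_marginal = sum(table[a][j] for j in range(k))
            col_marginal = sum(table[i][b] for i in range(k))
            observed += w * table[a][b] / total
            expected += w * row_marginal * col_marginal / (total * total)
    return 1.0 - observed / expected
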