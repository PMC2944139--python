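"""Per-study co-expression: Pearson correlation, ranking, rank ratios.

For each study, every unordered pair of eligible metagenes is scored with
the Pearson correlation of its members' expression profiles over the
prophase timepoints,

    r_xy = sum_i (x_i - xbar)(y_i - ybar) / ((n - 1) s_x s_y),

with sample (n-1) standard deviations.  Multi-gene metagenes average the
gene-gene correlations over all cross-products of members.  Pairs are then
ranked within the study (rank 1 = largest r, ties get their mean rank) and
each pair receives a rank ratio rank/total — a Uniform(0, 1] variate under
the null of no conserved co-expression, which is what the cross-study
order-statistics P-value consumes.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import UndefinedCorrelationError
from .expression import ExpressionMatrix
from .orthology import Metagene

logger = logging.getLogger(__name__)

#: columns of a per-study pair table
PAIR_COLUMNS = ("metagene_a", "metagene_b", "r", "n_gene_pairs")


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson correlation of two expression vectors (length >= 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError("correlation needs >= 3 timepoints")
    sx = x.std(ddof=1)
    sy = y.std(ddof=1)
    if sx == 0.0 or sy == 0.0:
        raise UndefinedCorrelationError("zero-variance expression vector")
    r = float(np.dot(x - x.mean(), y - y.mean()) / ((n - 1) * sx * sy))
    return min(1.0, max(-1.0, r))


def metagene_pair_correlations(
    metagenes: Sequence[Metagene],
    matrix: ExpressionMatrix,
    organism: str,
    eligible_types: Iterable[str],
) -> pd.DataFrame:
    """Averaged Pearson correlations for all eligible metagene pairs.

    A metagene is eligible if its type is in ``eligible_types`` and at
    least one of its ``organism`` members survives in ``matrix`` with
    non-zero variance.  The pair correlation is the mean gene-gene Pearson
    correlation over all cross-products of surviving members (a plain
    gene-gene correlation for singleton metagenes).  Returns a DataFrame
    with columns ``metagene_a, metagene_b, r, n_gene_pairs``; metagene ids
    within a pair are in sorted order.
    """
    eligible_types = set(eligible_types)
    values = matrix.values.to_numpy(dtype=float)
    gene_row = {g: i for i, g in enumerate(matrix.values.index)}

    # drop zero-variance genes: their correlations are undefined
    sd = values.std(axis=1, ddof=1)
    n_zero_var = int((sd == 0).sum())
    if n_zero_var:
        logger.info(
            "%s: skipping %d zero-variance genes", matrix.study, n_zero_var
        )

    kept: list[Metagene] = []
    member_rows: list[list[int]] = []
    for mg in sorted(metagenes, key=lambda m: m.id):
        if mg.mtype not in eligible_types:
            continue
        rows = [
            gene_row[g]
            for g in mg.genes(organism)
            if g in gene_row and sd[gene_row[g]] > 0
        ]
        if rows:
            kept.append(mg)
            member_rows.append(rows)
    if len(kept) < 2:
        return pd.DataFrame(columns=list(PAIR_COLUMNS))

    used = sorted({row for rows in member_rows for row in rows})
    remap = {row: j for j, row in enumerate(used)}
    corr = np.corrcoef(values[used])
    # weight matrix: W[m, g] = 1/|members_m|; mean cross-product correlation
    # of metagenes (a, b) is then (W corr W^T)[a, b]
    n_mg = len(kept)
    weights = np.zeros((n_mg, len(used)))
    counts = np.empty(n_mg, dtype=int)
    for i, rows in enumerate(member_rows):
        weights[i, [remap[r] for r in rows]] = 1.0 / len(rows)
        counts[i] = len(rows)
    pair_r = weights @ corr @ weights.T

    ia, ib = np.triu_indices(n_mg, k=1)
    ids = np.array([mg.id for mg in kept])
    return pd.DataFrame(
        {
            "metagene_a": ids[ia],
            "metagene_b": ids[ib],
            "r": np.clip(pair_r[ia, ib], -1.0, 1.0),
            "n_gene_pairs": counts[ia] * counts[ib],
        }
    )


def rank_ratios(correlations: pd.DataFrame, rank_by: str = "signed") -> pd.DataFrame:
    """Rank a study's pair table and attach rank ratios.

    Rank 1 is the largest r (``rank_by="signed"``, the default: positive
    co-expression ranks best) or largest ``|r|`` (``rank_by="abs"``); ties
    receive the mean of their covered ranks.  Adds ``rank``, ``total`` and
    ``rank_ratio`` columns.
    """
    if len(correlations) == 0:
        raise ValueError("cannot rank an empty correlation table")
    if rank_by not in ("signed", "abs"):
        raise ValueError("rank_by must be 'signed' or 'abs'")
    r = correlations["r"].to_numpy(dtype=float)
    key = -np.abs(r) if rank_by == "abs" else -r
    out = correlations.copy()
    out["rank"] = rankdata(key, method="average")
    out["total"] = len(out)
    out["rank_ratio"] = out["rank"] / out["total"]
    return out


def write_pair_table(table: pd.DataFrame, path) -> None:
    """Write a per-study pair table as TSV."""
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")
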