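"""Consensus-correlation clustering: the alternative module-detection route.

Per-study metagene correlation matrices are merged by taking the
elementwise *minimum* correlation for each pair — a pair is only as
conserved as its worst study.  The consensus matrix is converted to a
dissimilarity (d = 1 - r by default) and clustered with average-linkage
agglomeration; branches are defined by scanning cut heights and keeping
the most *persistent* branch structure: the count of clusters of size >=
``min_cluster_size`` is tracked along all cut heights, and the cut is
placed at the lowest height of the longest height interval over which
that count is constant.  This is a documented simplification of
shape-adaptive dynamic tree cutting; simply maximizing the big-cluster
count instead selects arbitrarily high cuts where loose background
agglomerates masquerade as clusters.  Metagenes in smaller branches are
labeled unassigned (module 0).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)


@dataclass
class ConsensusMatrix:
    """Minimum-over-studies correlation matrix (diagonal fixed at 1)."""

    ids: tuple[str, ...]
    values: np.ndarray  # symmetric, in [-1, 1]
    studies: tuple[str, ...] = ()


@dataclass(frozen=True)
class ClusterConfig:
    min_cluster_size: int = 40
    linkage: str = "average"
    dissimilarity: str = "one-minus-r"  # or "half-one-minus-r"

    def __post_init__(self) -> None:
        if self.min_cluster_size < 2:
            raise ValueError("min_cluster_size must be >= 2")
        if self.linkage != "average":
            raise ValueError("only average linkage is supported")


def consensus_matrix(
    pair_tables: Mapping[str, pd.DataFrame]
) -> ConsensusMatrix:
    """Merge per-study pair correlation tables by elementwise minimum.

    Each table must have columns ``metagene_a, metagene_b, r``.  Only
    metagenes present in every study are kept, and any metagene with a
    missing pair entry in some study is dropped (logged) so the consensus
    is complete.  The diagonal is 1.
    """
    if len(pair_tables) < 2:
        raise ValueError("need >= 2 studies for a consensus matrix")
    studies = tuple(sorted(pair_tables))
    common: set[str] | None = None
    for table in pair_tables.values():
        ids = set(table["metagene_a"]) | set(table["metagene_b"])
        common = ids if common is None else common & ids
    ids = sorted(common or ())
    index = {m: i for i, m in enumerate(ids)}
    n = len(ids)
    consensus = np.full((n, n), np.inf)
    filled = np.zeros((n, n), dtype=int)
    for study in studies:
        for row in pair_tables[study].itertuples(index=False):
            i = index.get(row.metagene_a)
            j = index.get(row.metagene_b)
            if i is None or j is None:
                continue
            consensus[i, j] = consensus[j, i] = min(consensus[i, j], row.r)
            filled[i, j] = filled[j, i] = filled[i, j] + 1
    complete = filled == len(studies)
    np.fill_diagonal(complete, True)
    # drop metagenes with incomplete coverage, most-missing first
    keep = np.ones(n, dtype=bool)
    while True:
        missing = (~complete & keep[None, :] & keep[:, None]).sum(axis=1)
        worst = int(np.argmax(missing))
        if missing[worst] == 0:
            break
        keep[worst] = False
    if (~keep).sum():
        logger.info("dropped %d metagenes with incomplete pair coverage", (~keep).sum())
    sel = np.where(keep)[0]
    values = consensus[np.ix_(sel, sel)]
    np.fill_diagonal(values, 1.0)
    return ConsensusMatrix(
        ids=tuple(ids[i] for i in sel), values=values, studies=studies
    )


def cluster_modules(
    consensus: ConsensusMatrix, config: ClusterConfig = ClusterConfig()
) -> dict[str, int]:
    """Cut an average-linkage dendrogram into size-constrained modules.

    Returns metagene id -> module id (1..k by order of first member in the
    id-sorted input; 0 = unassigned).  The cut height is the lowest height
    of the most persistent run: the number of clusters of size >=
    ``min_cluster_size`` is computed at every merge height, and the
    contiguous height interval over which that (non-zero) count stays
    constant for the longest wins; ties go to the lower height.
    """
    n = len(consensus.ids)
    if n < config.min_cluster_size:
        warnings.warn(
            f"min_cluster_size={config.min_cluster_size} exceeds {n} metagenes; "
            "all unassigned"
        )
        return {m: 0 for m in consensus.ids}
    d = 1.0 - consensus.values
    if config.dissimilarity == "half-one-minus-r":
        d = d / 2.0
    np.fill_diagonal(d, 0.0)
    d = np.maximum(d, 0.0)
    condensed = squareform((d + d.T) / 2.0, checks=False)
    if np.allclose(condensed, condensed[0] if condensed.size else 0.0):
        warnings.warn("constant dissimilarity matrix; returning a single module")
        return {m: 1 for m in consensus.ids}
    link = linkage(condensed, method="average")

    heights = np.unique(link[:, 2])
    n_big_at = np.empty(len(heights), dtype=int)
    for j, h in enumerate(heights):
        sizes = np.bincount(fcluster(link, t=h, criterion="distance"))
        n_big_at[j] = int((sizes[1:] >= config.min_cluster_size).sum())
    if not n_big_at.any():
        warnings.warn("no cluster reaches min_cluster_size; all unassigned")
        return {m: 0 for m in consensus.ids}
    # persistence of each contiguous equal-count run of cut heights; cut at
    # the run's last height so late-merging cluster members are absorbed
    widths = np.append(np.diff(heights), 0.0)
    runs: list[tuple[float, float, float, int]] = []  # (persist, start, end, count)
    j = 0
    while j < len(heights):
        k = j
        while k + 1 < len(heights) and n_big_at[k + 1] == n_big_at[j]:
            k += 1
        runs.append(
            (
                float(widths[j : k + 1].sum()),
                float(heights[j]),
                float(heights[k]),
                int(n_big_at[j]),
            )
        )
        j = k + 1
    _, _, cut_height, _ = max(
        (r for r in runs if r[3] > 0), key=lambda r: (r[0], -r[1])
    )
    labels = fcluster(link, t=cut_height, criterion="distance")
    sizes = np.bincount(labels)
    # relabel: big clusters numbered by first appearance, small -> 0
    mapping: dict[int, int] = {}
    next_id = 1
    out: dict[str, int] = {}
    for mg, lab in zip(consensus.ids, labels):
        if sizes[lab] >= config.min_cluster_size:
            if lab not in mapping:
                mapping[lab] = next_id
                next_id += 1
            out[mg] = mapping[lab]
        else:
            out[mg] = 0
    return out


def write_modules(modules: Mapping[str, int], path) -> None:
    pd.DataFrame(
        sorted(modules.items()), columns=["metagene", "module_id"]
    ).to_csv(path, sep="\t", index=False)


def read_matrix_tsv(path) -> ConsensusMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ConsensusMatrix(ids=tuple(df.index), values=df.to_numpy(dtype=float))


def write_matrix_tsv(matrix: ConsensusMatrix, path) -> None:
    pd.DataFrame(matrix.values, index=matrix.ids, columns=matrix.ids).to_csv(
        path, sep="\t", float_format="%.10g"
    )
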