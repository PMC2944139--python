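"""Cross-study conservation P-values via joint uniform order statistics.

Under the null, a pair's rank ratio in each study is an independent
Uniform(0, 1] draw.  Given the ascending-sorted ratios r_1 <= ... <= r_n
over the n studies of a network, the conservation P-value is the joint
cumulative probability that the n sorted uniforms fall below the observed
bounds,

    P(r_1, ..., r_n) = n! * Integral_0^{r_1} Integral_{s_1}^{r_2} ...
                       Integral_{s_{n-1}}^{r_n} ds_1 ... ds_n ,

evaluated exactly with the closed-form recursion

    V_0 = 1,
    V_k = sum_{i=1..k} (-1)^(i-1) * V_{k-i} / i! * r_{n-k+1}^i,
    P   = n! * V_n ,

which is polynomial-time and exact (no quadrature).  Small P means the
pair is ranked near the top of every study — conserved co-expression.

This module also turns scored pairs into top-K networks, intersects
networks, and extracts seed-gene modules.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigError

logger = logging.getLogger(__name__)


def joint_orderstat_cdf(ratios: Sequence[float]) -> float:
    """Joint CDF of n-dimensional uniform order statistics at ``ratios``.

    Input order is irrelevant (sorted internally); each ratio must lie in
    (0, 1].  Returns a probability in [0, 1], monotone non-decreasing in
    every coordinate.
    """
    p = _joint_orderstat_cdf_rows(np.asarray(ratios, dtype=float)[None, :])
    return float(p[0])


def _joint_orderstat_cdf_rows(ratios: np.ndarray) -> np.ndarray:
    """Vectorized joint order-statistics CDF, one value per row."""
    if ratios.ndim != 2 or ratios.shape[1] == 0:
        raise ValueError("ratios must be a non-empty 2-d array (pairs x studies)")
    if np.any(ratios <= 0) or np.any(ratios > 1):
        raise ValueError("rank ratios must lie in (0, 1]")
    r = np.sort(ratios, axis=1)  # r[:, j] = r_{j+1}, ascending
    n = r.shape[1]
    v = [np.ones(r.shape[0])]  # V_0
    inv_fact = [1.0 / math.factorial(i) for i in range(n + 1)]
    for k in range(1, n + 1):
        bound = r[:, n - k]  # r_{n-k+1}, 1-indexed
        acc = np.zeros(r.shape[0])
        power = np.ones(r.shape[0])
        for i in range(1, k + 1):
            power = power * bound  # bound**i
            acc += (-1.0) ** (i - 1) * inv_fact[i] * v[k - i] * power
        v.append(acc)
    return np.clip(math.factorial(n) * v[n], 0.0, 1.0)


@dataclass
class CoexpressionNetwork:
    """A named conserved co-expression network.

    ``edges`` holds one row per conserved pair, ascending by P-value, with
    columns ``metagene_a, metagene_b, p_value`` plus one
    ``rank_ratio_<study>`` column per member study.
    """

    name: str
    studies: tuple[str, ...]
    eligible_types: frozenset[str]
    edges: pd.DataFrame
    node_attrs: dict[str, dict] = field(default_factory=dict)

    @property
    def nodes(self) -> list[str]:
        return sorted(
            set(self.edges["metagene_a"]) | set(self.edges["metagene_b"])
        )

    def graph(self) -> nx.Graph:
        g = nx.Graph(name=self.name)
        for row in self.edges.itertuples(index=False):
            g.add_edge(row.metagene_a, row.metagene_b, p_value=row.p_value)
        for node, attrs in self.node_attrs.items():
            if node in g:
                g.nodes[node].update(attrs)
        return g


def score_conserved_pairs(
    rank_tables: Mapping[str, pd.DataFrame], studies: Sequence[str]
) -> pd.DataFrame:
    """Attach the cross-study order-statistics P-value to every pair
    rankable in all ``studies``.

    ``rank_tables`` maps study id to a table from
    :func:`meionet.coexpression.rank_ratios`.  Pairs absent from any member
    study are dropped (logged); n for the joint CDF is the number of
    studies (mouse male and mouse female count separately).  The result is
    sorted ascending by P-value, ties broken by pair id.
    """
    missing = [s for s in studies if s not in rank_tables]
    if missing:
        raise ConfigError(f"network recipe references missing studies: {missing}")
    if len(studies) < 1:
        raise ConfigError("a network recipe needs >= 1 study")

    merged: pd.DataFrame | None = None
    sizes = {}
    for study in studies:
        t = rank_tables[study][["metagene_a", "metagene_b", "rank_ratio"]].rename(
            columns={"rank_ratio": f"rank_ratio_{study}"}
        )
        sizes[study] = len(t)
        merged = t if merged is None else merged.merge(
            t, on=["metagene_a", "metagene_b"], how="inner"
        )
    assert merged is not None
    n_dropped = max(sizes.values()) - len(merged)
    if n_dropped > 0:
        logger.info(
            "dropped %d pairs not rankable in all of %s", n_dropped, list(studies)
        )
    ratio_cols = [f"rank_ratio_{s}" for s in studies]
    merged["p_value"] = _joint_orderstat_cdf_rows(merged[ratio_cols].to_numpy())
    merged = merged.sort_values(
        ["p_value", "metagene_a", "metagene_b"], kind="mergesort"
    ).reset_index(drop=True)
    return merged[["metagene_a", "metagene_b", "p_value", *ratio_cols]]


def build_network(
    scored: pd.DataFrame,
    top_k: int = 100,
    name: str = "network",
    studies: Sequence[str] = (),
    eligible_types: Iterable[str] = (),
) -> CoexpressionNetwork:
    """Connect the ``top_k`` most significant pairs into a network."""
    if top_k > len(scored):
        logger.warning(
            "%s: top_k=%d exceeds %d scored pairs; truncating", name, top_k, len(scored)
        )
        top_k = len(scored)
    edges = scored.iloc[:top_k].reset_index(drop=True)
    return CoexpressionNetwork(
        name=name,
        studies=tuple(studies),
        eligible_types=frozenset(eligible_types),
        edges=edges,
    )


def extract_seed_modules(
    network: CoexpressionNetwork,
    seed_genes: set[str],
    yeast_members: Mapping[str, Iterable[str]],
) -> list[nx.Graph]:
    """Connected components containing a seed-annotated metagene.

    ``yeast_members`` maps metagene id to its yeast gene ids; a component
    is kept if any of its metagenes carries a seed gene (known meiotic,
    sporulation-deficient, ...).  Edge/node decorations are preserved on
    the returned subgraphs.
    """
    if not seed_genes:
        raise ValueError("seed gene set must be non-empty")
    g = network.graph()
    modules = []
    for component in sorted(nx.connected_components(g), key=lambda c: sorted(c)[0]):
        hit = any(
            set(yeast_members.get(node, ())) & seed_genes for node in component
        )
        if hit:
            modules.append(g.subgraph(component).copy())
    return modules


def network_intersection(networks: Sequence[CoexpressionNetwork]) -> pd.DataFrame:
    """Pairs shared by at least two networks, with per-network flags.

    Rows are sorted by the number of networks containing the pair
    (descending), then by pair id.
    """
    if len(networks) < 2:
        raise ValueError("need >= 2 networks to intersect")
    edge_sets = {
        net.name: {
            tuple(sorted(p))
            for p in zip(net.edges["metagene_a"], net.edges["metagene_b"])
        }
        for net in networks
    }
    all_pairs = sorted(set().union(*edge_sets.values()))
    rows = []
    for pair in all_pairs:
        flags = {name: pair in s for name, s in edge_sets.items()}
        count = sum(flags.values())
        if count >= 2:
            rows.append(
                {"metagene_a": pair[0], "metagene_b": pair[1], **flags, "n_networks": count}
            )
    df = pd.DataFrame(
        rows,
        columns=["metagene_a", "metagene_b", *edge_sets, "n_networks"],
    )
    if len(df):
        df = df.sort_values(
            ["n_networks", "metagene_a", "metagene_b"],
            ascending=[False, True, True],
            kind="mergesort",
        ).reset_index(drop=True)
    return df


def write_network(network: CoexpressionNetwork, tsv_path, json_path=None) -> None:
    """Write the edge list as TSV and optionally a JSON network document."""
    network.edges.to_csv(tsv_path, sep="\t", index=False, float_format="%.10g")
    if json_path is not None:
        import json

        doc = {
            "name": network.name,
            "studies": list(network.studies),
            "eligible_types": sorted(network.eligible_types),
            "nodes": [
                {"id": n, **network.node_attrs.get(n, {})} for n in network.nodes
            ],
            "edges": network.edges.to_dict(orient="records"),
        }
        with open(json_path, "w") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)
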