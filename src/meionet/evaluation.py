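"""Evaluation suite: precision-coverage, GO enrichment and semantic
similarity, annotation-overlap statistics, and transcript-abundance classes.

Precision at a network depth d counts distinct metagenes among the top-d
pairs and reports the fraction containing at least one known gene of the
evaluation organism; coverage is the number of distinct known genes
recovered.  Baselines permute the order of the same pair list with a
seeded generator and are compared to the observed curve with Welch's
unequal-variance t-test.

GO term enrichment uses the hypergeometric upper tail

    p(x >= k) = sum_{x=k}^{min(m,n)} C(m, x) C(t-m, n-x) / C(t, n)

with t the network gene universe, n the universe genes annotated to the
term, m the query size and k the annotated query genes; annotations are
propagated to ancestors (is_a closure) before counting.  Semantic
similarity of a gene pair is -log10 of the minimal occurrence probability
p(c) over ontology terms ancestral to both genes' annotations, where p(c)
is the fraction of corpus genes annotated to c or any descendant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import IO, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import ttest_1samp, ttest_ind

from .errors import UnannotatedGeneError
from .orthology import Metagene

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# GO resources
# ---------------------------------------------------------------------------

@dataclass
class GOResources:
    """A GO DAG (is_a only), gene annotations, and term probabilities.

    ``dag`` is a directed graph with edges child -> parent; ``term_prob``
    maps term -> p(c), the chance a corpus gene is annotated to the term
    or any of its descendants (p(root) = 1).
    """

    dag: nx.DiGraph
    annotations: Mapping[str, frozenset[str]]  # gene -> direct terms
    term_prob: Mapping[str, float]

    def ancestors(self, term: str) -> set[str]:
        """Self-inclusive is_a ancestor closure of a term."""
        return {term} | nx.descendants(self.dag, term)


def load_obo_dag(path_or_stream, namespace: str | None = None) -> nx.DiGraph:
    """Read an OBO file into a child->parent is_a DiGraph (via obonet)."""
    import obonet

    multi = obonet.read_obo(path_or_stream)
    dag = nx.DiGraph()
    for node, data in multi.nodes(data=True):
        if namespace is None or data.get("namespace") == namespace:
            dag.add_node(node, **data)
    for child, parent, key in multi.edges(keys=True):
        if key == "is_a" and child in dag and parent in dag:
            dag.add_edge(child, parent)
    return dag


def read_annotations(stream: IO[str] | str) -> dict[str, frozenset[str]]:
    """Read a two-column (gene, term) TSV into gene -> direct terms."""
    df = pd.read_csv(stream, sep="\t", comment="#", header=None, names=["gene", "term"])
    out: dict[str, set[str]] = {}
    for gene, term in zip(df["gene"].astype(str), df["term"].astype(str)):
        out.setdefault(gene, set()).add(term)
    return {g: frozenset(t) for g, t in out.items()}


def term_probability(
    dag: nx.DiGraph,
    annotations: Mapping[str, Iterable[str]],
    corpus: set[str],
) -> dict[str, float]:
    """Occurrence probability p(c) for every term.

    count(c) = corpus genes annotated to c or any descendant (i.e. whose
    propagated annotation set contains c); p(c) = count(c) / number of
    annotated corpus genes.  p is monotone non-decreasing child -> parent
    and equals 1 at every root above an annotated gene.
    """
    if not nx.is_directed_acyclic_graph(dag):
        raise ValueError("GO graph contains a cycle")
    counts: dict[str, int] = {term: 0 for term in dag.nodes}
    n_annotated = 0
    for gene in sorted(corpus):
        terms = annotations.get(gene)
        if not terms:
            continue
        n_annotated += 1
        closure: set[str] = set()
        for term in terms:
            if term not in dag:
                raise ValueError(f"annotation term {term!r} absent from DAG")
            closure |= {term} | nx.descendants(dag, term)
        for term in closure:
            counts[term] += 1
    if n_annotated == 0:
        return {term: 0.0 for term in dag.nodes}
    return {term: counts[term] / n_annotated for term in dag.nodes}


def build_go_resources(
    dag: nx.DiGraph,
    annotations: Mapping[str, frozenset[str]],
    corpus: set[str],
) -> GOResources:
    return GOResources(
        dag=dag,
        annotations=annotations,
        term_prob=term_probability(dag, annotations, corpus),
    )


# ---------------------------------------------------------------------------
# Hypergeometric enrichment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnrichmentQuery:
    """Counts for one hypergeometric upper-tail test.

    t: genes in the network universe; n: universe genes annotated with the
    term; m: query genes; k: annotated query genes.
    """

    t: int
    n: int
    m: int
    k: int

    def __post_init__(self) -> None:
        if not (0 <= self.n <= self.t and 0 <= self.m <= self.t):
            raise ValueError(f"inconsistent counts {self}")
        if not 0 <= self.k <= min(self.m, self.n):
            raise ValueError(f"k={self.k} exceeds min(m, n) in {self}")


def hypergeom_upper_tail(q: EnrichmentQuery) -> float:
    """p(x >= k): probability of k or more annotated genes in the query.

    Evaluated by log-space summation of the hypergeometric point masses
    for numerical stability.
    """
    if q.k == 0:
        return 1.0
    xs = np.arange(q.k, min(q.m, q.n) + 1)
    log_terms = (
        _log_comb(q.m, xs)
        + _log_comb(q.t - q.m, q.n - xs)
        - _log_comb(q.t, q.n)
    )
    return float(min(1.0, np.exp(logsumexp(log_terms))))


def _log_comb(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    out = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    return np.where((k < 0) | (k > n), -np.inf, out)


def propagate_annotations(
    resources: GOResources, genes: Iterable[str]
) -> dict[str, set[str]]:
    """Gene -> is_a ancestor closure of its direct annotation terms."""
    out = {}
    for gene in genes:
        terms = resources.annotations.get(gene, frozenset())
        closure: set[str] = set()
        for term in terms:
            if term in resources.dag:
                closure |= resources.ancestors(term)
        out[gene] = closure
    return out


def go_term_enrichment(
    query_genes: set[str],
    universe: set[str],
    resources: GOResources,
    alpha: float = 0.05,
    benjamini_hochberg: bool = False,
) -> pd.DataFrame:
    """Hypergeometric enrichment of every term hit by the query.

    Annotations are propagated to ancestors before counting.  P-values are
    raw by default (``benjamini_hochberg=True`` adds an adjusted column and
    flags on it instead).  Rows sorted by ascending p, then term id.
    """
    if not query_genes:
        raise ValueError("query gene set must be non-empty")
    if not query_genes <= universe:
        raise ValueError("query genes must be a subset of the universe")
    closure = propagate_annotations(resources, universe)
    term_universe: dict[str, int] = {}
    term_query: dict[str, int] = {}
    for gene, terms in closure.items():
        for term in terms:
            term_universe[term] = term_universe.get(term, 0) + 1
            if gene in query_genes:
                term_query[term] = term_query.get(term, 0) + 1
    t, m = len(universe), len(query_genes)
    rows = []
    for term in sorted(term_query):
        k, n = term_query[term], term_universe[term]
        p = hypergeom_upper_tail(EnrichmentQuery(t=t, n=n, m=m, k=k))
        rows.append({"term": term, "k": k, "n": n, "p": p})
    df = pd.DataFrame(rows, columns=["term", "k", "n", "p"])
    if benjamini_hochberg and len(df):
        order = np.argsort(df["p"].to_numpy(), kind="mergesort")
        ranked = df["p"].to_numpy()[order] * len(df) / (np.arange(len(df)) + 1)
        adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
        adj = np.empty(len(df))
        adj[order] = np.minimum(adjusted, 1.0)
        df["p_adjusted"] = adj
        df["significant"] = df["p_adjusted"] < alpha
    else:
        df["significant"] = df["p"] < alpha
    return df.sort_values(["p", "term"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Semantic similarity
# ---------------------------------------------------------------------------

def semantic_similarity_pair(
    gene_a: str, gene_b: str, resources: GOResources
) -> float:
    """-log10 of the minimal p(c) over terms ancestral to both genes.

    Ancestor closures are self-inclusive; genes sharing only the root
    (p = 1) score 0.  Terms with p(c) = 0 cannot be shared ancestors of
    annotated corpus genes and are ignored.
    """
    closures = []
    for gene in (gene_a, gene_b):
        terms = resources.annotations.get(gene, frozenset())
        closure: set[str] = set()
        for term in terms:
            if term in resources.dag:
                closure |= resources.ancestors(term)
        if not closure:
            raise UnannotatedGeneError(f"gene {gene!r} has no usable annotation")
        closures.append(closure)
    shared = closures[0] & closures[1]
    probs = [resources.term_prob.get(t, 0.0) for t in shared]
    probs = [p for p in probs if p > 0]
    if not probs:
        raise UnannotatedGeneError(
            f"genes {gene_a!r}, {gene_b!r} share no term with p > 0"
        )
    return float(-np.log10(min(probs)))


@dataclass(frozen=True)
class SimilarityResult:
    mean: float
    n_scored: int
    n_skipped: int


def mean_semantic_similarity(
    pairs: Iterable[tuple[str, str]], resources: GOResources
) -> SimilarityResult:
    """Mean pair similarity; unannotated pairs are skipped and counted."""
    scores = []
    n_skipped = 0
    for a, b in pairs:
        try:
            scores.append(semantic_similarity_pair(a, b, resources))
        except UnannotatedGeneError:
            n_skipped += 1
    if not scores:
        raise ValueError("no scorable gene pairs")
    return SimilarityResult(
        mean=float(np.mean(scores)), n_scored=len(scores), n_skipped=n_skipped
    )


# ---------------------------------------------------------------------------
# Precision-coverage and permutation baselines
# ---------------------------------------------------------------------------

def _depths(n_pairs: int, increment: int) -> list[int]:
    depths = list(range(increment, n_pairs + 1, increment))
    return depths or [n_pairs]


def _pair_endpoints(pairs: pd.DataFrame) -> np.ndarray:
    return pairs[["metagene_a", "metagene_b"]].to_numpy()


def precision_coverage(
    sorted_pairs: pd.DataFrame,
    known: set[str],
    members: Mapping[str, Iterable[str]],
    increment: int = 100,
) -> pd.DataFrame:
    """Precision/coverage of known genes at cumulative pair depths.

    ``sorted_pairs`` is an edge table sorted ascending by P-value;
    ``members`` maps metagene id -> gene ids of the evaluation organism.
    At each depth: precision = fraction of distinct metagenes containing a
    known gene, coverage = number of distinct known genes recovered.
    """
    if not known:
        raise ValueError("known gene set must be non-empty")
    endpoints = _pair_endpoints(sorted_pairs)
    rows = []
    for depth in _depths(len(sorted_pairs), increment):
        mgs = set(endpoints[:depth].ravel())
        known_mgs = {m for m in mgs if set(members.get(m, ())) & known}
        covered = set().union(*(set(members.get(m, ())) & known for m in known_mgs)) if known_mgs else set()
        rows.append(
            {
                "depth": depth,
                "precision": len(known_mgs) / len(mgs) if mgs else 0.0,
                "coverage": len(covered),
            }
        )
    return pd.DataFrame(rows)


def permutation_baseline(
    pairs: pd.DataFrame,
    known: set[str],
    members: Mapping[str, Iterable[str]],
    trials: int = 100,
    seed: int = 0,
    increment: int = 100,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Mean +/- sd precision over shuffles of the pair order.

    Returns the summary table (depth, random_mean, random_sd) and the raw
    per-trial precision samples (trials x depths).
    """
    if trials < 2:
        raise ValueError("need >= 2 permutation trials")
    rng = np.random.default_rng(seed)
    depths = _depths(len(pairs), increment)
    samples = np.empty((trials, len(depths)))
    for t in range(trials):
        shuffled = pairs.iloc[rng.permutation(len(pairs))].reset_index(drop=True)
        curve = precision_coverage(shuffled, known, members, increment)
        samples[t] = curve["precision"].to_numpy()
    return pd.DataFrame(
        {
            "depth": depths,
            "random_mean": samples.mean(axis=0),
            "random_sd": samples.std(axis=0, ddof=1),
        }
    ), samples


def compare_observed_random(
    observed: Sequence[float], random_trials: np.ndarray
) -> dict:
    """Observed curve vs permutation trials.

    ``random_trials`` has shape (trials, depths).  The pooled p-value is
    Welch's unequal-variance two-sample t-test of the observed curve
    values against all trial values.  Because the observed curve has a
    single value per depth, the per-depth p-value is a one-sample t-test
    of the trial values against the observed value; with a single observed
    depth only the pooled test is meaningful.
    """
    observed = np.asarray(observed, dtype=float)
    random_trials = np.asarray(random_trials, dtype=float)
    if random_trials.ndim != 2 or random_trials.shape[0] < 2:
        raise ValueError("need >= 2 random trials per depth")
    per_depth = []
    for j in range(random_trials.shape[1]):
        col = random_trials[:, j]
        if np.allclose(col.std(ddof=1), 0.0):
            per_depth.append(1.0 if np.isclose(col.mean(), observed[j]) else 0.0)
        else:
            per_depth.append(float(ttest_1samp(col, observed[j]).pvalue))
    pooled_random = random_trials.ravel()
    if observed.size >= 2 and (observed.std(ddof=1) > 0 or pooled_random.std(ddof=1) > 0):
        pooled = float(
            ttest_ind(observed, pooled_random, equal_var=False).pvalue
        )
    elif np.isclose(observed.mean(), pooled_random.mean()):
        pooled = 1.0
    else:
        pooled = float("nan") if observed.size < 2 else 0.0
    return {"per_depth": per_depth, "pooled": pooled}


# ---------------------------------------------------------------------------
# Annotation overlap statistics
# ---------------------------------------------------------------------------

def _pair_flags(
    pairs: pd.DataFrame,
    members: Mapping[str, Iterable[str]],
    relation,
    mode: str,
) -> np.ndarray:
    """Boolean per-pair overlap flags (pairwise relation or co-group)."""
    flags = np.zeros(len(pairs), dtype=bool)
    endpoints = _pair_endpoints(pairs)
    if mode == "pairwise":
        rel = {tuple(sorted(p)) for p in relation}
        for i, (a, b) in enumerate(endpoints):
            flags[i] = any(
                tuple(sorted((ga, gb))) in rel
                for ga in members.get(a, ())
                for gb in members.get(b, ())
            )
    elif mode == "co-group":
        for i, (a, b) in enumerate(endpoints):
            groups_a = {relation[g] for g in members.get(a, ()) if g in relation}
            groups_b = {relation[g] for g in members.get(b, ()) if g in relation}
            flags[i] = bool(groups_a & groups_b)
    else:
        raise ValueError("mode must be 'pairwise' or 'co-group'")
    return flags


def overlap_fraction(
    top_pairs: pd.DataFrame,
    relation,
    members: Mapping[str, Iterable[str]],
    mode: str = "pairwise",
    random_trials: int = 100,
    seed: int = 0,
    increment: int = 100,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Fraction of overlapping pairs at cumulative depths, with baseline.

    ``relation`` is a set of unordered yeast gene pairs (``pairwise``) or a
    mapping gene -> group id (``co-group``); a metagene pair overlaps if
    any cross-product of its yeast members is related.  The baseline
    shuffles the pair order with a seeded generator.  Returns the curve
    table (depth, observed, random_mean, random_sd) and the raw trial
    samples (trials x depths).
    """
    if relation is None or len(relation) == 0:
        raise ValueError("relation must be non-empty")
    flags = _pair_flags(top_pairs, members, relation, mode)
    return _flag_curves(flags, random_trials, seed, increment)


def _flag_curves(
    flags: np.ndarray, random_trials: int, seed: int, increment: int
) -> tuple[pd.DataFrame, np.ndarray]:
    depths = np.asarray(_depths(len(flags), increment))
    cum = np.cumsum(flags.astype(float))
    observed = cum[depths - 1] / depths
    rng = np.random.default_rng(seed)
    samples = np.empty((random_trials, len(depths)))
    for t in range(random_trials):
        cum = np.cumsum(flags[rng.permutation(len(flags))].astype(float))
        samples[t] = cum[depths - 1] / depths
    table = pd.DataFrame(
        {
            "depth": depths,
            "observed": observed,
            "random_mean": samples.mean(axis=0),
            "random_sd": samples.std(axis=0, ddof=1),
        }
    )
    return table, samples


def node_property_fraction(
    top_pairs: pd.DataFrame,
    property_genes: set[str],
    members: Mapping[str, Iterable[str]],
    random_trials: int = 100,
    seed: int = 0,
    increment: int = 100,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Fraction of distinct metagenes carrying a gene property, by depth.

    A metagene has the property iff any of its yeast members is in
    ``property_genes``; the baseline shuffles pair order.
    """
    if not property_genes:
        raise ValueError("property gene set must be non-empty")
    endpoints = _pair_endpoints(top_pairs)

    def curve(order: np.ndarray) -> list[float]:
        vals = []
        for d in _depths(len(top_pairs), increment):
            mgs = set(endpoints[order[:d]].ravel())
            hit = sum(1 for m in mgs if set(members.get(m, ())) & property_genes)
            vals.append(hit / len(mgs) if mgs else 0.0)
        return vals

    depths = _depths(len(top_pairs), increment)
    identity = np.arange(len(top_pairs))
    observed = curve(identity)
    rng = np.random.default_rng(seed)
    samples = np.empty((random_trials, len(depths)))
    for t in range(random_trials):
        samples[t] = curve(rng.permutation(len(top_pairs)))
    table = pd.DataFrame(
        {
            "depth": depths,
            "observed": observed,
            "random_mean": samples.mean(axis=0),
            "random_sd": samples.std(axis=0, ddof=1),
        }
    )
    return table, samples


# ---------------------------------------------------------------------------
# Transcript-abundance classes
# ---------------------------------------------------------------------------

_JOINT_CLASSES = ("low,low", "low,high", "high,high")


def _metagene_label(
    mg_id: str,
    metagenes: Mapping[str, Metagene],
    organism: str,
    labels: Mapping[str, str],
) -> str | None:
    """high iff ANY member gene of the organism is labeled high."""
    genes = metagenes[mg_id].genes(organism) if mg_id in metagenes else ()
    got = [labels[g] for g in genes if g in labels]
    if not got:
        return None
    return "high" if "high" in got else "low"


def pair_abundance_classes(
    network,
    metagenes: Mapping[str, Metagene],
    study_organism: Mapping[str, str],
    labels_by_study: Mapping[str, Mapping[str, str]],
) -> dict:
    """Joint high/low abundance classes for a two-study network.

    Each edge gets, per study, the unordered pair class of its endpoint
    metagenes — (low,low), (low,high) or (high,high) — and the result
    includes the 3x3 contingency between the two studies' classes (counts
    and fractions).  Edges with an unclassifiable gene are skipped and
    counted.
    """
    if len(network.studies) != 2:
        raise ValueError("abundance contingency is defined for two-study networks")
    s1, s2 = network.studies
    rows = []
    n_skipped = 0
    for edge in network.edges.itertuples(index=False):
        classes = {}
        for study in (s1, s2):
            la = _metagene_label(
                edge.metagene_a, metagenes, study_organism[study], labels_by_study[study]
            )
            lb = _metagene_label(
                edge.metagene_b, metagenes, study_organism[study], labels_by_study[study]
            )
            if la is None or lb is None:
                classes = None
                break
            classes[study] = ",".join(sorted((la, lb), key=("low", "high").index))
        if classes is None:
            n_skipped += 1
            continue
        rows.append(
            {
                "metagene_a": edge.metagene_a,
                "metagene_b": edge.metagene_b,
                s1: classes[s1],
                s2: classes[s2],
            }
        )
    per_edge = pd.DataFrame(rows, columns=["metagene_a", "metagene_b", s1, s2])
    counts = pd.DataFrame(
        0, index=list(_JOINT_CLASSES), columns=list(_JOINT_CLASSES), dtype=int
    )
    for row in rows:
        counts.loc[row[s1], row[s2]] += 1
    total = counts.to_numpy().sum()
    fractions = counts / total if total else counts.astype(float)
    return {
        "per_edge": per_edge,
        "contingency": counts,
        "fractions": fractions,
        "n_skipped": n_skipped,
        "studies": (s1, s2),
    }
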