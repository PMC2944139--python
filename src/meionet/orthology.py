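"""Ortholog tables and metagene construction.

A *metagene* is a set of orthologous genes across two or three genomes
treated as a single cross-study unit.  Metagenes are assembled from seed
(reciprocal-best-match) ortholog pairs of two genome pairs sharing a pivot
organism (yeast): genes are grouped into connected components over the
union of all seed pairs, and every component containing at least one pivot
gene becomes one metagene.  Components are typed by the set of organisms
they span — YMH (pivot + both partners), YM (pivot + first partner), YH
(pivot + second partner) — which makes the three types mutually exclusive
and every metagene anchored in the pivot genome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigError, ParseError

logger = logging.getLogger(__name__)

#: canonical organism labels used by the shipped study designs
YEAST, MOUSE, HUMAN = "yeast", "mouse", "human"


@dataclass(frozen=True, order=True)
class Gene:
    """A gene identified by (id, organism)."""

    id: str
    organism: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("gene id must be non-empty")
        if not self.organism:
            raise ValueError("organism label must be non-empty")


@dataclass(frozen=True)
class OrthologPair:
    """A seed ortholog pair between two genes of different organisms."""

    gene_a: Gene
    gene_b: Gene
    seed: bool = True

    def __post_init__(self) -> None:
        if self.gene_a.organism == self.gene_b.organism:
            raise ValueError(
                f"ortholog pair within one organism: {self.gene_a}, {self.gene_b}"
            )


@dataclass(frozen=True)
class Metagene:
    """A connected set of orthologs with a type label.

    ``members`` maps organism -> sorted tuple of gene ids; every metagene
    contains at least one pivot (yeast) gene, and each organism's member
    list is non-empty for the organisms its type spans.
    """

    id: str
    mtype: str  # "YMH" | "YM" | "YH"
    members: Mapping[str, tuple[str, ...]] = field(hash=False)

    def genes(self, organism: str) -> tuple[str, ...]:
        return self.members.get(organism, ())


def parse_ortholog_table(
    stream: IO[str] | Iterable[str], organism_a: str, organism_b: str
) -> list[OrthologPair]:
    """Parse a two-column seed-ortholog table.

    Lines starting with ``#`` and blank lines are skipped; the first two
    whitespace-separated fields are the gene ids of ``organism_a`` and
    ``organism_b``.  Duplicate lines are deduplicated (first occurrence
    order kept); all returned pairs are seed pairs.
    """
    if not organism_a or not organism_b:
        raise ConfigError("organism labels must be non-empty")
    pairs: list[OrthologPair] = []
    seen: set[tuple[str, str]] = set()
    for lineno, line in enumerate(stream, start=1):
        text = line.strip()
        if not text or text.startswith("#"):
            continue
        fields = text.split()
        if len(fields) < 2:
            raise ParseError(f"line {lineno}: expected 2 fields, got {len(fields)}")
        key = (fields[0], fields[1])
        if key in seen:
            continue
        seen.add(key)
        pairs.append(
            OrthologPair(Gene(fields[0], organism_a), Gene(fields[1], organism_b))
        )
    return pairs


def _mtype_for_span(span: frozenset[str], pivot: str, partners: Sequence[str]) -> str:
    if span == frozenset({pivot, *partners}):
        return "YMH"
    if span == frozenset({pivot, partners[0]}):
        return "YM"
    if span == frozenset({pivot, partners[1]}):
        return "YH"
    raise ConfigError(f"unexpected organism span {sorted(span)}")


def build_metagenes(
    pairs_ym: Sequence[OrthologPair],
    pairs_yh: Sequence[OrthologPair],
    pivot: str = YEAST,
    partners: Sequence[str] = (MOUSE, HUMAN),
) -> list[Metagene]:
    """Group seed pairs into metagenes by connected components.

    Two pairs sharing any gene merge into one component; each component
    with >= 1 pivot gene becomes a metagene typed by its organism span.
    Components without a pivot gene (e.g. from stray partner-partner
    pairs) are discarded with a logged count.  The metagene id is the
    '+'-joined sorted list of its pivot gene ids, which is stable under
    any input line order.
    """
    parent: dict[Gene, Gene] = {}

    def find(g: Gene) -> Gene:
        root = g
        while parent[root] != root:
            root = parent[root]
        while parent[g] != root:  # path compression
            parent[g], g = root, parent[g]
        return root

    def union(a: Gene, b: Gene) -> None:
        for g in (a, b):
            parent.setdefault(g, g)
        ra, rb = find(a), find(b)
        if ra != rb:
            # deterministic root choice: smaller (id, organism) wins
            if (rb.id, rb.organism) < (ra.id, ra.organism):
                ra, rb = rb, ra
            parent[rb] = ra

    for pair in (*pairs_ym, *pairs_yh):
        if not pair.seed:
            continue
        union(pair.gene_a, pair.gene_b)

    components: dict[Gene, list[Gene]] = {}
    for g in parent:
        components.setdefault(find(g), []).append(g)

    metagenes: list[Metagene] = []
    n_discarded = 0
    for genes in components.values():
        members: dict[str, list[str]] = {}
        for g in genes:
            members.setdefault(g.organism, []).append(g.id)
        if pivot not in members:
            n_discarded += 1
            continue
        span = frozenset(members)
        metagenes.append(
            Metagene(
                id="+".join(sorted(members[pivot])),
                mtype=_mtype_for_span(span, pivot, partners),
                members={org: tuple(sorted(ids)) for org, ids in members.items()},
            )
        )
    if n_discarded:
        logger.info("discarded %d components without a %s gene", n_discarded, pivot)
    metagenes.sort(key=lambda m: m.id)
    _assert_disjoint(metagenes)
    return metagenes


def _assert_disjoint(metagenes: Sequence[Metagene]) -> None:
    seen: set[tuple[str, str]] = set()
    for mg in metagenes:
        for org, ids in mg.members.items():
            for gid in ids:
                key = (gid, org)
                if key in seen:
                    raise AssertionError(f"gene {key} assigned to two metagenes")
                seen.add(key)


@dataclass(frozen=True)
class MetageneSummary:
    """Counts in the style of a per-type / per-organism conservation table."""

    by_type: pd.DataFrame  # index mtype; metagene_count + <org>_genes columns
    by_organism: pd.DataFrame  # index organism; totals, coverage, genes/metagene


def metagene_summary(
    metagenes: Sequence[Metagene],
    genome_sizes: Mapping[str, int] | None = None,
) -> MetageneSummary:
    """Tabulate metagene and conserved-gene counts per type and organism.

    Genome coverage is the fraction of an organism's genome assigned to any
    metagene; it is reported as NA for organisms absent from
    ``genome_sizes``.
    """
    genome_sizes = genome_sizes or {}
    mtypes = ("YMH", "YM", "YH")
    organisms: list[str] = sorted({org for mg in metagenes for org in mg.members})
    type_rows = {}
    for mt in mtypes:
        sub = [mg for mg in metagenes if mg.mtype == mt]
        row: dict[str, float] = {"metagene_count": len(sub)}
        for org in organisms:
            row[f"{org}_genes"] = sum(len(mg.genes(org)) for mg in sub)
        type_rows[mt] = row
    by_type = pd.DataFrame.from_dict(type_rows, orient="index")

    org_rows = {}
    for org in organisms:
        with_org = [mg for mg in metagenes if mg.genes(org)]
        total = sum(len(mg.genes(org)) for mg in with_org)
        size = genome_sizes.get(org)
        org_rows[org] = {
            "conserved_genes": total,
            "genome_coverage": (total / size) if size else float("nan"),
            "genes_per_metagene": (total / len(with_org)) if with_org else 0.0,
        }
    by_organism = pd.DataFrame.from_dict(org_rows, orient="index")
    return MetageneSummary(by_type=by_type, by_organism=by_organism)
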