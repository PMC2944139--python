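"""End-to-end orchestration: files or in-memory scenario -> networks.

``run_scenario`` drives the whole analysis on an in-memory
:class:`~meionet.synthetic.Scenario` (the route tests use);
``run_pipeline`` reads a YAML-configured set of input files, calls the
same stages, and writes every table plus a run manifest with input
digests so identical config + inputs give byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import clustering, coexpression, evaluation, orderstats
from .errors import ConfigError
from .expression import (
    ExpressionMatrix,
    ProphaseWindow,
    RawMatrix,
    abundance_labels,
    average_replicates,
    classify_abundance,
    collapse_probes,
    filter_low_expressed,
    read_expression_matrix,
    restrict_to_prophase,
)
from .orthology import (
    Gene,
    HUMAN,
    MOUSE,
    Metagene,
    OrthologPair,
    YEAST,
    build_metagenes,
    parse_ortholog_table,
)
from .synthetic import Scenario

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NetworkRecipe:
    """Which studies and metagene types feed one conserved network."""

    name: str
    studies: tuple[str, ...]
    eligible_types: frozenset[str]


#: the four shipped network recipes
DEFAULT_RECIPES: tuple[NetworkRecipe, ...] = (
    NetworkRecipe("Y-Mm", ("Y", "Mm"), frozenset({"YMH", "YM"})),
    NetworkRecipe("Y-Mf", ("Y", "Mf"), frozenset({"YMH", "YM"})),
    NetworkRecipe("Y-Hf", ("Y", "Hf"), frozenset({"YMH", "YH"})),
    NetworkRecipe("Y-Mm-Mf-Hf", ("Y", "Mm", "Mf", "Hf"), frozenset({"YMH"})),
)


@dataclass
class PipelineResult:
    """Everything the pipeline computes, keyed for downstream evaluation."""

    metagenes: list[Metagene]
    windowed: dict[str, ExpressionMatrix]  # prophase-restricted, pre-filter
    filtered: dict[str, ExpressionMatrix]  # after bottom-fraction removal
    dropped: dict[str, list[str]]
    abundance: dict[str, dict[str, str]]  # study -> gene -> high/low
    rank_tables: dict[tuple[str, str], pd.DataFrame]  # (recipe, study) -> table
    scored: dict[str, pd.DataFrame]  # recipe name -> scored pair table
    networks: dict[str, orderstats.CoexpressionNetwork]
    study_organism: dict[str, str]

    def metagene_members(self, organism: str) -> dict[str, tuple[str, ...]]:
        return {m.id: m.genes(organism) for m in self.metagenes}


def preprocess_study(
    raw: RawMatrix,
    study: str,
    window: ProphaseWindow,
    tolerance: float = 0.5,
    drop_fraction: float = 0.10,
    time_unit: str = "",
) -> tuple[ExpressionMatrix, ExpressionMatrix, list[str]]:
    """Replicate-average, window, and low-expression-filter one study.

    Returns (windowed pre-filter matrix, filtered matrix, dropped genes).
    The pre-filter matrix is kept because the high/low abundance median is
    genome-wide.
    """
    averaged = average_replicates(raw, study=study, time_unit=time_unit)
    windowed = restrict_to_prophase(averaged, window, tolerance=tolerance)
    filtered, dropped = filter_low_expressed(windowed, drop_fraction=drop_fraction)
    assert len(windowed.genes) == len(filtered.genes) + len(dropped)
    logger.info(
        "%s: %d genes in, %d kept, %d dropped (bottom %.0f%%)",
        study,
        len(windowed.genes),
        len(filtered.genes),
        len(dropped),
        100 * drop_fraction,
    )
    return windowed, filtered, dropped


def run_scenario(
    scenario: Scenario,
    recipes: Sequence[NetworkRecipe] = DEFAULT_RECIPES,
    top_k: int = 100,
    drop_fraction: float = 0.10,
    tolerance: float = 0.5,
    rank_by: str = "signed",
) -> PipelineResult:
    """Run orthology -> expression -> correlation -> order statistics on an
    in-memory scenario and build one network per recipe."""
    pairs_ym = [
        OrthologPair(Gene(a, YEAST), Gene(b, MOUSE))
        for a, b in scenario.ortholog_pairs_ym
    ]
    pairs_yh = [
        OrthologPair(Gene(a, YEAST), Gene(b, HUMAN))
        for a, b in scenario.ortholog_pairs_yh
    ]
    metagenes = build_metagenes(pairs_ym, pairs_yh)
    study_organism = scenario.study_organism

    windowed: dict[str, ExpressionMatrix] = {}
    filtered: dict[str, ExpressionMatrix] = {}
    dropped: dict[str, list[str]] = {}
    abundance: dict[str, dict[str, str]] = {}
    for study_id, raw in scenario.matrices.items():
        win, filt, drop = preprocess_study(
            raw,
            study=study_id,
            window=scenario.windows[study_id],
            tolerance=tolerance,
            drop_fraction=drop_fraction,
        )
        windowed[study_id], filtered[study_id], dropped[study_id] = win, filt, drop
        abundance[study_id] = abundance_labels(classify_abundance(win))

    return _score_networks(
        metagenes,
        filtered,
        study_organism,
        recipes,
        top_k,
        rank_by,
        windowed=windowed,
        dropped=dropped,
        abundance=abundance,
    )


def _score_networks(
    metagenes: list[Metagene],
    filtered: Mapping[str, ExpressionMatrix],
    study_organism: Mapping[str, str],
    recipes: Sequence[NetworkRecipe],
    top_k: int,
    rank_by: str,
    windowed: dict[str, ExpressionMatrix] | None = None,
    dropped: dict[str, list[str]] | None = None,
    abundance: dict[str, dict[str, str]] | None = None,
) -> PipelineResult:
    corr_cache: dict[tuple[str, frozenset[str]], pd.DataFrame] = {}
    rank_tables: dict[tuple[str, str], pd.DataFrame] = {}
    scored: dict[str, pd.DataFrame] = {}
    networks: dict[str, orderstats.CoexpressionNetwork] = {}
    for recipe in recipes:
        missing = [s for s in recipe.studies if s not in filtered]
        if missing:
            raise ConfigError(f"recipe {recipe.name}: missing studies {missing}")
        per_study: dict[str, pd.DataFrame] = {}
        for study in recipe.studies:
            key = (study, recipe.eligible_types)
            if key not in corr_cache:
                corr = coexpression.metagene_pair_correlations(
                    metagenes,
                    filtered[study],
                    organism=study_organism[study],
                    eligible_types=recipe.eligible_types,
                )
                corr_cache[key] = coexpression.rank_ratios(corr, rank_by=rank_by)
            per_study[study] = corr_cache[key]
            rank_tables[(recipe.name, study)] = corr_cache[key]
        table = orderstats.score_conserved_pairs(per_study, recipe.studies)
        scored[recipe.name] = table
        networks[recipe.name] = orderstats.build_network(
            table,
            top_k=top_k,
            name=recipe.name,
            studies=recipe.studies,
            eligible_types=recipe.eligible_types,
        )
    return PipelineResult(
        metagenes=metagenes,
        windowed=windowed or {},
        filtered=dict(filtered),
        dropped=dropped or {},
        abundance=abundance or {},
        rank_tables=rank_tables,
        scored=scored,
        networks=networks,
        study_organism=dict(study_organism),
    )


# ---------------------------------------------------------------------------
# File-driven pipeline
# ---------------------------------------------------------------------------

@dataclass
class StudyInput:
    id: str
    organism: str
    expression: str
    samples: str
    probes: str | None
    window: tuple[float, float]
    time_unit: str = ""


@dataclass
class PipelineConfig:
    studies: list[StudyInput]
    ortholog_ym: str
    ortholog_yh: str
    outdir: str
    recipes: Sequence[NetworkRecipe] = DEFAULT_RECIPES
    go_obo: str | None = None
    go_annotations: str | None = None
    known_genes: str | None = None
    top_k: int = 100
    drop_fraction: float = 0.10
    tolerance: float = 0.5
    rank_by: str = "signed"
    permutation_trials: int = 100
    increment: int = 100
    seed: int = 0
    run_clustering: bool = False
    min_cluster_size: int = 40

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        studies = [
            StudyInput(
                id=s["id"],
                organism=s["organism"],
                expression=s["expression"],
                samples=s["samples"],
                probes=s.get("probes"),
                window=(float(s["window"][0]), float(s["window"][1])),
                time_unit=s.get("time_unit", ""),
            )
            for s in doc["studies"]
        ]
        recipes = tuple(
            NetworkRecipe(r["name"], tuple(r["studies"]), frozenset(r["types"]))
            for r in doc.get("recipes", [])
        ) or DEFAULT_RECIPES
        keys = (
            "ortholog_ym ortholog_yh outdir go_obo go_annotations known_genes "
            "top_k drop_fraction tolerance rank_by permutation_trials increment "
            "seed run_clustering min_cluster_size"
        ).split()
        kwargs = {k: doc[k] for k in keys if k in doc}
        return cls(studies=studies, recipes=recipes, **kwargs)


def read_sample_map(path) -> dict[str, tuple[float, int]]:
    """(sample, timepoint, replicate) TSV -> sample -> (time, replicate)."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["sample", "timepoint", "replicate"],
    )
    return {
        str(r.sample): (float(r.timepoint), int(r.replicate))
        for r in df.itertuples(index=False)
    }


def read_probe_map(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=["probe", "gene"])
    return {str(r.probe): str(r.gene) for r in df.itertuples(index=False)}


def read_gene_set(path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip() and not line.startswith("#")}


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """File-driven end-to-end run; writes all tables and a manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = [config.ortholog_ym, config.ortholog_yh]

    with open(config.ortholog_ym) as fh:
        pairs_ym = parse_ortholog_table(fh, YEAST, MOUSE)
    with open(config.ortholog_yh) as fh:
        pairs_yh = parse_ortholog_table(fh, YEAST, HUMAN)
    metagenes = build_metagenes(pairs_ym, pairs_yh)

    windowed: dict[str, ExpressionMatrix] = {}
    filtered: dict[str, ExpressionMatrix] = {}
    abundance: dict[str, dict[str, str]] = {}
    study_organism: dict[str, str] = {}
    for study in config.studies:
        for path in (study.expression, study.samples):
            if not Path(path).exists():
                raise ConfigError(f"study {study.id}: missing input file {path}")
        inputs += [study.expression, study.samples]
        sample_map = read_sample_map(study.samples)
        raw = read_expression_matrix(study.expression, sample_map)
        if study.probes:
            inputs.append(study.probes)
            raw = collapse_probes(raw, read_probe_map(study.probes))
        win, filt, _ = preprocess_study(
            raw,
            study=study.id,
            window=ProphaseWindow(study.id, *study.window),
            tolerance=config.tolerance,
            drop_fraction=config.drop_fraction,
            time_unit=study.time_unit,
        )
        windowed[study.id], filtered[study.id] = win, filt
        abundance[study.id] = abundance_labels(classify_abundance(win))
        study_organism[study.id] = study.organism

    result = _score_networks(
        metagenes,
        filtered,
        study_organism,
        config.recipes,
        config.top_k,
        config.rank_by,
        windowed=windowed,
        abundance=abundance,
    )

    written: list[str] = []
    for (recipe, study), table in result.rank_tables.items():
        path = outdir / f"pairs_{recipe}_{study}.tsv"
        coexpression.write_pair_table(table, path)
        written.append(path.name)
    for name, network in result.networks.items():
        tsv = outdir / f"network_{name}.tsv"
        orderstats.write_network(network, tsv, outdir / f"network_{name}.json")
        written += [tsv.name, f"network_{name}.json"]

    if config.known_genes:
        inputs.append(config.known_genes)
        known = read_gene_set(config.known_genes)
        members = result.metagene_members(YEAST)
        for name, table in result.scored.items():
            curve = evaluation.precision_coverage(
                table, known, members, increment=config.increment
            )
            baseline, samples = evaluation.permutation_baseline(
                table,
                known,
                members,
                trials=config.permutation_trials,
                seed=config.seed,
                increment=config.increment,
            )
            tests = evaluation.compare_observed_random(
                curve["precision"].to_numpy(), samples
            )
            out = curve.merge(baseline, on="depth")
            out["p_per_depth"] = tests["per_depth"]
            out.attrs["pooled_p"] = tests["pooled"]
            path = outdir / f"curve_{name}.tsv"
            out.to_csv(path, sep="\t", index=False, float_format="%.10g")
            written.append(path.name)

    if config.go_obo and config.go_annotations:
        inputs += [config.go_obo, config.go_annotations]
        dag = evaluation.load_obo_dag(config.go_obo)
        annotations = evaluation.read_annotations(config.go_annotations)
        members = result.metagene_members(YEAST)
        for name, network in result.networks.items():
            universe = {
                g for m in result.scored[name][["metagene_a", "metagene_b"]].to_numpy().ravel()
                for g in members.get(m, ())
            }
            resources = evaluation.build_go_resources(dag, annotations, universe)
            query = {
                g for m in network.nodes for g in members.get(m, ())
            } & universe
            table = evaluation.go_term_enrichment(query, universe, resources)
            path = outdir / f"enrichment_{name}.tsv"
            table.to_csv(path, sep="\t", index=False, float_format="%.10g")
            written.append(path.name)

    if config.run_clustering:
        ymh_tables = {
            study: result.rank_tables[(config.recipes[-1].name, study)]
            for study in config.recipes[-1].studies
        }
        consensus = clustering.consensus_matrix(ymh_tables)
        modules = clustering.cluster_modules(
            consensus, clustering.ClusterConfig(min_cluster_size=config.min_cluster_size)
        )
        clustering.write_modules(modules, outdir / "modules.tsv")
        written.append("modules.tsv")

    manifest = {
        "seed": config.seed,
        "n_metagenes": len(metagenes),
        "networks": sorted(result.networks),
        "outputs": sorted(written),
        "input_digests": {str(p): _sha256(p) for p in sorted(set(map(str, inputs)))},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
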