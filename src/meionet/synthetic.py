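"""Synthetic multi-study scenario generator with planted ground truth.

The generator emulates the statistical structure the cross-study analysis
assumes: four time-series studies on unequal grids (a 5-point yeast
sporulation course in hours, a 4-point mouse postnatal-testis course in
days postpartum, a 3-point mouse embryonic-ovary course in days
postcoitum, and a 13-point human fetal-ovary course in weeks of
gestation), 1:1 ortholog maps with partial coverage yielding YMH/YM/YH
metagene types, planted co-expression modules that are conserved across
all studies or specific to exactly one, a multiplicative high/low
abundance model, and Gaussian noise.

Each conserved module m gets, per study, a smooth latent profile f_m(t)
(a cubic spline through seeded uniform control points, normalized to unit
amplitude); a member gene's signal is

    base_gene * (1 + f_m(t) + eps),   eps ~ Normal(0, noise_sd),

with base_gene alternating between the configured low and high levels.
Species-specific modules receive a latent profile in exactly one study and
independent noise elsewhere; background genes are pure noise around their
base level.  All randomness derives from the single scenario seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .errors import ConfigError
from .expression import RawMatrix, ProphaseWindow
from .orthology import YEAST, MOUSE, HUMAN


@dataclass(frozen=True)
class StudyDesign:
    """One emulated expression study."""

    id: str
    organism: str
    timepoints: tuple[float, ...]
    n_replicates: int = 1
    window: tuple[float, float] = (0.0, 1.0)
    time_unit: str = ""


#: the four shipped study designs (grids and prophase windows)
DEFAULT_STUDIES: tuple[StudyDesign, ...] = (
    StudyDesign("Y", YEAST, (0.0, 1.0, 2.0, 3.0, 4.0), 1, (0.0, 4.0), "hours"),
    StudyDesign("Mm", MOUSE, (6.0, 8.0, 10.0, 14.0), 2, (6.0, 14.0), "days postpartum"),
    StudyDesign("Mf", MOUSE, (11.5, 12.5, 14.5), 2, (11.0, 14.0), "days postcoitum"),
    StudyDesign(
        "Hf",
        HUMAN,
        (9.1, 9.6, 11.0, 12.0, 12.9, 13.6, 13.9, 14.4, 16.1, 16.4, 16.9, 17.1, 18.1),
        1,
        (9.0, 18.0),
        "weeks gestation",
    ),
)

_ORGANISM_PREFIX = {YEAST: "y", MOUSE: "m", HUMAN: "h"}


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for one synthetic scenario."""

    studies: tuple[StudyDesign, ...] = DEFAULT_STUDIES
    n_metagenes: int = 500
    n_conserved_modules: int = 5
    n_species_specific_modules: int = 3
    module_size: int = 20
    noise_sd: float = 0.25
    abundance_levels: tuple[float, float] = (10.0, 1000.0)  # (low, high)
    ortholog_coverage: float = 0.88  # fraction of background metagenes YMH
    extra_genes_fraction: float = 0.15  # per-organism genes with no ortholog
    seed: int = 0

    def __post_init__(self) -> None:
        n_module_genes = self.module_size * (
            self.n_conserved_modules + self.n_species_specific_modules
        )
        if n_module_genes > self.n_metagenes:
            raise ConfigError(
                f"{n_module_genes} module metagenes exceed n_metagenes={self.n_metagenes}"
            )
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")


@dataclass
class GroundTruth:
    """Planted structure of a scenario (metagene ids are yeast gene ids)."""

    conserved_modules: list[list[str]]
    specific_modules: list[tuple[str, list[str]]]  # (study id, members)
    known_genes: set[str]  # yeast genes of the designated "meiotic" module
    interactions: set[tuple[str, str]]  # planted within-module yeast pairs
    complexes: dict[str, str]  # yeast gene -> complex id
    essential: set[str]
    module_of: dict[str, tuple] = field(default_factory=dict)

    def conserved_pair_set(self) -> set[tuple[str, str]]:
        pairs = set()
        for members in self.conserved_modules:
            for i, a in enumerate(members):
                for b in members[i + 1 :]:
                    pairs.add(tuple(sorted((a, b))))
        return pairs

    def specific_pair_set(self) -> set[tuple[str, str]]:
        pairs = set()
        for _, members in self.specific_modules:
            for i, a in enumerate(members):
                for b in members[i + 1 :]:
                    pairs.add(tuple(sorted((a, b))))
        return pairs


@dataclass
class Scenario:
    """In-memory scenario bundle; ``write`` serializes the TSV/OBO fixture."""

    config: ScenarioConfig
    ortholog_pairs_ym: list[tuple[str, str]]
    ortholog_pairs_yh: list[tuple[str, str]]
    matrices: dict[str, RawMatrix]  # study id -> probe/gene x sample matrix
    windows: dict[str, ProphaseWindow]
    go_dag: nx.DiGraph
    go_annotations: dict[str, frozenset[str]]
    truth: GroundTruth

    @property
    def study_organism(self) -> dict[str, str]:
        return {s.id: s.organism for s in self.config.studies}

    def write(self, outdir) -> dict:
        """Write the full TSV/OBO fixture plus a manifest; returns the manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, str] = {}

        def _write(name: str, text: str) -> None:
            (outdir / name).write_text(text)
            paths[name.split(".")[0]] = str(outdir / name)

        _write(
            "orthologs_ym.tsv",
            "".join(f"{a}\t{b}\n" for a, b in self.ortholog_pairs_ym),
        )
        _write(
            "orthologs_yh.tsv",
            "".join(f"{a}\t{b}\n" for a, b in self.ortholog_pairs_yh),
        )
        for study_id, raw in self.matrices.items():
            raw.values.to_csv(
                outdir / f"expr_{study_id}.tsv", sep="\t", float_format="%.8g"
            )
            paths[f"expr_{study_id}"] = str(outdir / f"expr_{study_id}.tsv")
            sm = "\n".join(
                f"{s}\t{t:g}\t{rep}" for s, (t, rep) in raw.sample_times.items()
            )
            _write(f"samples_{study_id}.tsv", sm + "\n")
            pm = "\n".join(f"{g}\t{g}" for g in raw.values.index)
            _write(f"probes_{study_id}.tsv", pm + "\n")
        _write("go.obo", _dag_to_obo(self.go_dag))
        _write(
            "go_annotations.tsv",
            "".join(
                f"{g}\t{t}\n"
                for g in sorted(self.go_annotations)
                for t in sorted(self.go_annotations[g])
            ),
        )
        _write("known_genes.tsv", "".join(f"{g}\n" for g in sorted(self.truth.known_genes)))
        _write("essential.tsv", "".join(f"{g}\n" for g in sorted(self.truth.essential)))
        _write(
            "interactions.tsv",
            "".join(f"{a}\t{b}\n" for a, b in sorted(self.truth.interactions)),
        )
        _write(
            "complexes.tsv",
            "".join(f"{g}\t{c}\n" for g, c in sorted(self.truth.complexes.items())),
        )
        truth_doc = {
            "conserved_modules": self.truth.conserved_modules,
            "specific_modules": [
                {"study": s, "members": m} for s, m in self.truth.specific_modules
            ],
            "known_genes": sorted(self.truth.known_genes),
        }
        (outdir / "truth.json").write_text(json.dumps(truth_doc, indent=1))
        paths["truth"] = str(outdir / "truth.json")
        manifest = {
            "config": _config_doc(self.config),
            "windows": {
                s: {"t_min": w.t_min, "t_max": w.t_max}
                for s, w in self.windows.items()
            },
            "paths": paths,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        return manifest


def _config_doc(config: ScenarioConfig) -> dict:
    doc = asdict(config)
    doc["studies"] = [asdict(s) for s in config.studies]
    return doc


def _rng(seed: int, *tags: int) -> np.random.Generator:
    return np.random.default_rng([seed, *tags])


def _latent_profile(times: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Unit-amplitude smooth profile on a study's time grid."""
    n_knots = min(len(times), 4)
    knots = np.linspace(times[0], times[-1], n_knots)
    control = rng.uniform(-1.0, 1.0, n_knots)
    if n_knots < 2:
        f = np.full_like(times, control[0])
    else:
        f = CubicSpline(knots, control, bc_type="natural")(times)
    peak = np.max(np.abs(f))
    return f / peak if peak > 0 else f


def generate_scenario(config: ScenarioConfig = ScenarioConfig()) -> Scenario:
    """Generate a full scenario: orthologs, expression, GO, annotations, truth."""
    n = config.n_metagenes
    nc, ns, ms = (
        config.n_conserved_modules,
        config.n_species_specific_modules,
        config.module_size,
    )
    study_ids = [s.id for s in config.studies]

    # --- metagene index layout: modules first, then background -------------
    conserved_idx = [list(range(k * ms, (k + 1) * ms)) for k in range(nc)]
    specific_start = nc * ms
    specific_idx = [
        list(range(specific_start + k * ms, specific_start + (k + 1) * ms))
        for k in range(ns)
    ]
    specific_study = [study_ids[k % len(study_ids)] for k in range(ns)]
    module_indices = set(range(specific_start + ns * ms))

    # --- metagene types (modules always YMH; background per coverage) ------
    rng_types = _rng(config.seed, 0)
    mtypes: list[str] = []
    for i in range(n):
        if i in module_indices:
            mtypes.append("YMH")
        else:
            u = rng_types.uniform()
            if u < config.ortholog_coverage:
                mtypes.append("YMH")
            elif u < config.ortholog_coverage + (1 - config.ortholog_coverage) / 2:
                mtypes.append("YM")
            else:
                mtypes.append("YH")

    def gene(org: str, i: int) -> str:
        return f"{_ORGANISM_PREFIX[org]}{i + 1:04d}"

    pairs_ym = [
        (gene(YEAST, i), gene(MOUSE, i)) for i in range(n) if mtypes[i] in ("YMH", "YM")
    ]
    pairs_yh = [
        (gene(YEAST, i), gene(HUMAN, i)) for i in range(n) if mtypes[i] in ("YMH", "YH")
    ]

    # base abundance alternates low/high by metagene index
    low, high = config.abundance_levels
    base = np.where(np.arange(n) % 2 == 0, high, low).astype(float)

    n_extra = round(config.extra_genes_fraction * n)
    base_extra = np.where(np.arange(n_extra) % 2 == 0, high, low).astype(float)

    # module membership lookup: metagene index -> (kind, module, study|None)
    module_of_idx: dict[int, tuple] = {}
    for k, idx in enumerate(conserved_idx):
        for i in idx:
            module_of_idx[i] = ("conserved", k, None)
    for k, idx in enumerate(specific_idx):
        for i in idx:
            module_of_idx[i] = ("specific", k, specific_study[k])

    # --- expression matrices ------------------------------------------------
    matrices: dict[str, RawMatrix] = {}
    windows: dict[str, ProphaseWindow] = {}
    for s_pos, study in enumerate(config.studies):
        org = study.organism
        present = [
            i
            for i in range(n)
            if mtypes[i] == "YMH"
            or (mtypes[i] == "YM" and org in (YEAST, MOUSE))
            or (mtypes[i] == "YH" and org in (YEAST, HUMAN))
        ]
        times = np.asarray(study.timepoints, dtype=float)
        rng_prof = _rng(config.seed, 1, s_pos)
        rng_noise = _rng(config.seed, 2, s_pos)
        profiles: dict[tuple, np.ndarray] = {}
        for k in range(nc):
            profiles[("c", k)] = _latent_profile(times, rng_prof)
        for k in range(ns):
            # draw in a fixed order so streams stay aligned across studies
            f = _latent_profile(times, rng_prof)
            if specific_study[k] == study.id:
                profiles[("s", k)] = f

        samples = [
            f"{study.id}_t{t:g}_r{rep + 1}"
            for t in times
            for rep in range(study.n_replicates)
        ]
        sample_times = {
            f"{study.id}_t{t:g}_r{rep + 1}": (float(t), rep + 1)
            for t in times
            for rep in range(study.n_replicates)
        }
        n_cols = len(samples)
        time_of_col = np.repeat(np.arange(len(times)), study.n_replicates)

        rows = np.empty((len(present) + n_extra, n_cols))
        index = []
        for r, i in enumerate(present):
            signal = np.zeros(len(times))
            info = module_of_idx.get(i)
            if info is not None:
                kind, k, st = info
                key = ("c", k) if kind == "conserved" else ("s", k)
                if key in profiles:
                    signal = profiles[key]
            eps = rng_noise.normal(0.0, config.noise_sd, n_cols)
            vals = base[i] * (1.0 + signal[time_of_col] + eps)
            rows[r] = np.maximum(vals, 0.01 * base[i])
            index.append(gene(org, i))
        for r in range(n_extra):
            eps = rng_noise.normal(0.0, config.noise_sd, n_cols)
            vals = base_extra[r] * (1.0 + eps)
            rows[len(present) + r] = np.maximum(vals, 0.01 * base_extra[r])
            index.append(f"{_ORGANISM_PREFIX[org]}x{r + 1:04d}")
        matrices[study.id] = RawMatrix(
            values=pd.DataFrame(rows, index=index, columns=samples),
            sample_times=sample_times,
        )
        windows[study.id] = ProphaseWindow(study.id, *study.window)

    # --- ground truth -------------------------------------------------------
    yeast_ids = [gene(YEAST, i) for i in range(n)]
    truth = GroundTruth(
        conserved_modules=[[yeast_ids[i] for i in idx] for idx in conserved_idx],
        specific_modules=[
            (specific_study[k], [yeast_ids[i] for i in specific_idx[k]])
            for k in range(ns)
        ],
        known_genes=set(yeast_ids[i] for i in conserved_idx[0]) if nc else set(),
        interactions=set(),
        complexes={},
        essential=set(),
    )
    for i, info in module_of_idx.items():
        truth.module_of[yeast_ids[i]] = info

    rng_ann = _rng(config.seed, 3)
    for k, idx in enumerate(conserved_idx):
        members = [yeast_ids[i] for i in idx]
        for g in members:
            truth.complexes[g] = f"CPX{k + 1:03d}"
        within = [
            (a, b) for ai, a in enumerate(members) for b in members[ai + 1 :]
        ]
        chosen = rng_ann.choice(len(within), size=max(1, int(0.3 * len(within))), replace=False)
        for j in sorted(chosen):
            truth.interactions.add(tuple(sorted(within[j])))
    n_essential = int(0.18 * n)
    truth.essential = set(
        np.array(yeast_ids)[rng_ann.choice(n, size=n_essential, replace=False)]
    )
    module_yeast = [yeast_ids[i] for i in sorted(module_indices)]
    boost = rng_ann.choice(
        len(module_yeast), size=max(1, int(0.2 * len(module_yeast))), replace=False
    )
    truth.essential |= {module_yeast[j] for j in sorted(boost)}

    # --- GO fixture: 3-level DAG, meiosis-like term on conserved module 0 ---
    dag, annotations = _go_fixture(yeast_ids, truth, rng_ann)

    return Scenario(
        config=config,
        ortholog_pairs_ym=pairs_ym,
        ortholog_pairs_yh=pairs_yh,
        matrices=matrices,
        windows=windows,
        go_dag=dag,
        go_annotations=annotations,
        truth=truth,
    )


#: term ids of the planted ontology
GO_ROOT = "GO:0000001"
GO_MEIOSIS_PARENT = "GO:0000002"
GO_MEIOSIS_LIKE = "GO:0000010"


def _go_fixture(
    yeast_ids: Sequence[str], truth: GroundTruth, rng: np.random.Generator
) -> tuple[nx.DiGraph, dict[str, frozenset[str]]]:
    """Root -> 3 mid terms -> leaves; the meiosis-like leaf annotates the
    designated conserved module, other leaves annotate random gene sets."""
    dag = nx.DiGraph()
    names = {
        GO_ROOT: "biological_process",
        GO_MEIOSIS_PARENT: "meiotic cell cycle-like",
        "GO:0000003": "metabolic-like",
        "GO:0000004": "transport-like",
        GO_MEIOSIS_LIKE: "meiosis-like",
        "GO:0000011": "leaf-b",
        "GO:0000012": "leaf-c",
        "GO:0000013": "leaf-d",
        "GO:0000014": "leaf-e",
    }
    for term, name in names.items():
        dag.add_node(term, name=name, namespace="biological_process")
    for mid in (GO_MEIOSIS_PARENT, "GO:0000003", "GO:0000004"):
        dag.add_edge(mid, GO_ROOT)
    dag.add_edge(GO_MEIOSIS_LIKE, GO_MEIOSIS_PARENT)
    dag.add_edge("GO:0000011", GO_MEIOSIS_PARENT)
    for leaf in ("GO:0000012", "GO:0000013"):
        dag.add_edge(leaf, "GO:0000003")
    dag.add_edge("GO:0000014", "GO:0000004")

    annotations: dict[str, set[str]] = {}
    for g in sorted(truth.known_genes):
        annotations.setdefault(g, set()).add(GO_MEIOSIS_LIKE)
    n = len(yeast_ids)
    # unrelated leaves annotate background genes only: drawing them from
    # planted modules would make unrelated terms co-expression-enriched by
    # construction
    module_members = set(truth.module_of)
    background = [g for g in yeast_ids if g not in module_members]
    for leaf in ("GO:0000011", "GO:0000012", "GO:0000013", "GO:0000014"):
        size = max(1, min(int(0.05 * n), len(background)))
        for j in sorted(rng.choice(len(background), size=size, replace=False)):
            annotations.setdefault(background[j], set()).add(leaf)
    # give unannotated genes a generic mid-level annotation so similarity
    # and p(c) have a broad corpus
    size = max(1, int(0.30 * n))
    for j in sorted(rng.choice(n, size=size, replace=False)):
        annotations.setdefault(yeast_ids[j], set()).add("GO:0000004")
    return dag, {g: frozenset(t) for g, t in annotations.items()}


def _dag_to_obo(dag: nx.DiGraph) -> str:
    """Serialize the planted DAG as a minimal OBO document."""
    lines = ["format-version: 1.2", ""]
    for term in sorted(dag.nodes):
        data = dag.nodes[term]
        lines += [
            "[Term]",
            f"id: {term}",
            f"name: {data.get('name', term)}",
            f"namespace: {data.get('namespace', 'biological_process')}",
        ]
        for parent in sorted(dag.successors(term)):
            lines.append(f"is_a: {parent} ! {dag.nodes[parent].get('name', parent)}")
        lines.append("")
    return "\n".join(lines)


def evaluate_recovery(network, truth: GroundTruth, k: int | None = None) -> dict:
    """Quantify how well a network's top edges recover the planted modules.

    Returns pair precision (fraction of top-k edges joining two members of
    the same conserved module), the count of conserved- and specific-module
    within-pairs among the top-k, and metagene-level precision against the
    planted known set.
    """
    edges = network.edges if k is None else network.edges.iloc[:k]
    conserved = truth.conserved_pair_set()
    specific = truth.specific_pair_set()
    n_cons = n_spec = 0
    for a, b in zip(edges["metagene_a"], edges["metagene_b"]):
        key = tuple(sorted((a, b)))
        if key in conserved:
            n_cons += 1
        elif key in specific:
            n_spec += 1
    mgs = set(edges["metagene_a"]) | set(edges["metagene_b"])
    known_mgs = {m for m in mgs if m in truth.known_genes}
    return {
        "n_edges": len(edges),
        "pair_precision": n_cons / len(edges) if len(edges) else 0.0,
        "n_conserved_pairs": n_cons,
        "n_specific_pairs": n_spec,
        "metagene_precision": len(known_mgs) / len(mgs) if mgs else 0.0,
    }
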