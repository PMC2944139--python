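"""Time-series expression preprocessing.

Implements the preprocessing chain each study's matrix goes through before
correlation: probe-to-gene collapsing, replicate averaging, restriction to
the meiotic-prophase time window, removal of the lowest-expressed genes,
and genome-wide high/low transcript-abundance classification.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, WindowError

logger = logging.getLogger(__name__)


@dataclass
class RawMatrix:
    """Probe/gene x sample matrix with per-sample (timepoint, replicate)."""

    values: pd.DataFrame  # rows = probes or genes, columns = sample ids
    sample_times: Mapping[str, tuple[float, int]]  # sample -> (time, replicate)


@dataclass
class ExpressionMatrix:
    """Gene x timepoint signal-intensity matrix for one study.

    Columns are strictly increasing real timepoints in ``time_unit``.
    """

    study: str
    values: pd.DataFrame  # index gene ids, columns float timepoints
    time_unit: str = ""

    def __post_init__(self) -> None:
        times = list(self.values.columns)
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError(f"{self.study}: timepoints not strictly increasing")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def timepoints(self) -> list[float]:
        return [float(t) for t in self.values.columns]


@dataclass(frozen=True)
class ProphaseWindow:
    """Inclusive prophase time window for one study."""

    study: str
    t_min: float
    t_max: float

    def __post_init__(self) -> None:
        if not self.t_min < self.t_max:
            raise ValueError(f"{self.study}: t_min must be < t_max")


@dataclass(frozen=True)
class AbundanceClass:
    gene: str
    max_intensity: float
    label: str  # "high" | "low"


def read_expression_matrix(
    stream: IO[str] | str,
    sample_map: Mapping[str, tuple[float, int]],
) -> RawMatrix:
    """Read a TSV matrix (rows x samples, header of sample ids, '#' comments).

    Every sample column must be present in ``sample_map``; any non-numeric
    body cell is a parse error naming its row and column.
    """
    df = pd.read_csv(stream, sep="\t", comment="#", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    unmapped = [s for s in df.columns if s not in sample_map]
    if unmapped:
        raise ParseError(f"samples missing from sample map: {unmapped}")
    try:
        values = df.astype(float)
    except ValueError:
        for col in df.columns:
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any():
                row = df.index[bad.to_numpy().nonzero()[0][0]]
                raise ParseError(f"non-numeric value at row {row!r}, column {col!r}")
        raise
    return RawMatrix(values=values, sample_times={s: sample_map[s] for s in df.columns})


def collapse_probes(
    raw: RawMatrix, probe_map: Mapping[str, str | Iterable[str]]
) -> RawMatrix:
    """Average probe rows into gene rows.

    A probe mapping to exactly one gene is *unique*; a gene's signal is the
    mean of its unique probes.  A gene with no unique probe falls back to
    the mean of its multi-mapping probes whose ids end in ``_a``; a gene
    with no usable probe is absent from the output (logged).  Probes with
    no mapping are dropped and counted.
    """
    gene_unique: dict[str, list[str]] = {}
    gene_suffix: dict[str, list[str]] = {}
    n_unmapped = 0
    for probe in raw.values.index:
        target = probe_map.get(probe)
        if target is None:
            n_unmapped += 1
            continue
        genes = [target] if isinstance(target, str) else sorted(set(target))
        if len(genes) == 1:
            gene_unique.setdefault(genes[0], []).append(probe)
        else:
            for g in genes:
                if str(probe).endswith("_a"):
                    gene_suffix.setdefault(g, []).append(probe)
                else:
                    gene_suffix.setdefault(g, [])
    if n_unmapped:
        logger.info("dropped %d probes with no gene mapping", n_unmapped)

    rows, index = [], []
    n_skipped = 0
    for gene in sorted(set(gene_unique) | set(gene_suffix)):
        probes = gene_unique.get(gene) or gene_suffix.get(gene) or []
        if not probes:
            n_skipped += 1
            continue
        rows.append(raw.values.loc[probes].mean(axis=0))
        index.append(gene)
    if n_skipped:
        logger.info("dropped %d genes with no usable probe", n_skipped)
    values = pd.DataFrame(rows, index=index, columns=raw.values.columns)
    return RawMatrix(values=values, sample_times=raw.sample_times)


def average_replicates(raw: RawMatrix, study: str, time_unit: str = "") -> ExpressionMatrix:
    """Average replicate samples at each timepoint; sort timepoints ascending."""
    by_time: dict[float, list[str]] = {}
    for sample in raw.values.columns:
        t = float(raw.sample_times[sample][0])
        by_time.setdefault(t, []).append(sample)
    times = sorted(by_time)
    data = {t: raw.values[by_time[t]].mean(axis=1) for t in times}
    values = pd.DataFrame(data)
    values.columns = [float(t) for t in times]
    return ExpressionMatrix(study=study, values=values, time_unit=time_unit)


def restrict_to_prophase(
    matrix: ExpressionMatrix, window: ProphaseWindow, tolerance: float = 0.5
) -> ExpressionMatrix:
    """Keep timepoints within [t_min - tolerance, t_max + tolerance].

    Fewer than 3 surviving timepoints is an error: Pearson correlation on
    2 points is degenerate (always +/-1).
    """
    keep = [
        t
        for t in matrix.values.columns
        if window.t_min - tolerance <= float(t) <= window.t_max + tolerance
    ]
    if len(keep) < 3:
        raise WindowError(
            f"study {matrix.study!r}: window [{window.t_min}, {window.t_max}] "
            f"(tolerance {tolerance}) keeps {len(keep)} timepoints; >=3 required"
        )
    return ExpressionMatrix(
        study=matrix.study, values=matrix.values[keep], time_unit=matrix.time_unit
    )


def filter_low_expressed(
    matrix: ExpressionMatrix, drop_fraction: float = 0.10
) -> tuple[ExpressionMatrix, list[str]]:
    """Drop the floor(drop_fraction * n) genes with smallest max intensity.

    A gene's level is its maximal signal intensity over the retained
    timepoints; ties at the cut are broken by gene-id sort order so the
    result is deterministic.
    """
    if not 0 <= drop_fraction < 1:
        raise ValueError("drop_fraction must be in [0, 1)")
    n_drop = math.floor(drop_fraction * len(matrix.values))
    if n_drop == 0:
        return matrix, []
    max_intensity = matrix.values.max(axis=1)
    order = sorted(matrix.values.index, key=lambda g: (max_intensity[g], g))
    dropped = order[:n_drop]
    kept = matrix.values.drop(index=dropped)
    return (
        ExpressionMatrix(study=matrix.study, values=kept, time_unit=matrix.time_unit),
        dropped,
    )


def classify_abundance(matrix: ExpressionMatrix) -> list[AbundanceClass]:
    """Label each gene high/low by its max intensity vs the study median.

    The median is computed over all genes of the matrix passed in — callers
    wanting the genome-wide median (the default analysis) pass the
    pre-filter matrix.  Genes strictly above the median are ``high``;
    median-tied genes are ``low``.
    """
    if matrix.values.empty:
        raise ValueError("cannot classify an empty matrix")
    max_intensity = matrix.values.max(axis=1)
    median = float(np.median(max_intensity.to_numpy()))
    return [
        AbundanceClass(
            gene=g,
            max_intensity=float(max_intensity[g]),
            label="high" if max_intensity[g] > median else "low",
        )
        for g in matrix.values.index
    ]


def abundance_labels(classes: Sequence[AbundanceClass]) -> dict[str, str]:
    """Convenience mapping gene -> label."""
    return {c.gene: c.label for c in classes}
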