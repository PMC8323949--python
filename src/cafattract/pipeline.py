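"""End-to-end cohort analysis: from count matrices to attractor tables,
sample ordering, group consensus signatures and overlap statistics.

The pipeline mirrors a cohort-level CAF-transition analysis: read each
sample, log-normalize, call mesenchymal cells from markers, quality-filter,
drop samples with too few fibroblasts, run the LUM-seeded attractor per
sample, order samples by APOD rank, partition into early/late transition
groups, compute per-group consensus attractors, tabulate shared genes with
exact intersection P-values, and run the COL11A1 proxy test per sample.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .association import (
    AssociationRanking,
    SampleOrdering,
    apod_ordering,
    caf_proxy_test,
    partition_groups,
    rank_by_target,
)
from .attractor import (
    AttractorConfig,
    AttractorResult,
    DatasetWeight,
    consensus_attractor,
    find_attractor,
)
from .matrix import (
    FIBROBLAST_MARKERS,
    PERICYTE_MARKERS,
    ExpressionMatrix,
    filter_samples,
    identify_mesenchymal,
    log_normalize,
    quality_filter,
    read_counts,
)
from .mi import MIConfig
from .setstats import IntersectionProblem, multiset_intersection_pvalue, shared_genes

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "CohortReport", "run_cohort_analysis", "export_scatter"]

CROSS_STUDY_UNIVERSE = 20_000


@dataclass
class SampleEntry:
    sample: str
    path: str
    modality: str = "UMI"
    condition: str = "tumor"  # normal | tumor
    format: str = "mtx"


@dataclass
class PipelineConfig:
    samples: list[SampleEntry]
    output_dir: str = "cafattract_out"
    seed_gene: str = "LUM"
    anchor_gene: str = "APOD"
    counter_gene: str = "COL11A1"
    min_fibroblasts: int = 20
    quality_min_level: float = 3.0
    top_k: int = 30
    attractor: AttractorConfig = field(default_factory=AttractorConfig)
    master_seed: int = 0

    def __post_init__(self) -> None:
        ids = [s.sample for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("sample ids must be unique")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text())
        samples = [SampleEntry(**s) for s in doc.pop("samples")]
        att = doc.pop("attractor", None)
        cfg = cls(samples=samples, **doc)
        if att:
            mi_doc = att.pop("mi", None)
            cfg.attractor = AttractorConfig(
                mi=MIConfig(**mi_doc) if mi_doc else MIConfig(), **att
            )
        return cfg


@dataclass
class CohortReport:
    attractors: dict[str, AttractorResult]
    ordering: SampleOrdering
    groups: dict[str, str]
    consensus: dict[str, AttractorResult]
    shared: dict[str, int]
    shared_pvalue: float | None
    proxy_verdicts: dict
    excluded: dict[str, str]

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for sample, att in self.attractors.items():
            att.to_tsv(out_dir / f"attractor_{sample}.tsv")
        for group, att in self.consensus.items():
            att.to_tsv(out_dir / f"consensus_{group}.tsv")
        pd.DataFrame(
            {
                "sample": self.ordering.samples,
                "anchor_rank": [
                    self.ordering.anchor_ranks[s] for s in self.ordering.samples
                ],
                "counter_rank": [
                    self.ordering.counter_ranks[s] for s in self.ordering.samples
                ],
                "group": [self.groups[s] for s in self.ordering.samples],
            }
        ).to_csv(out_dir / "sample_ordering.tsv", sep="\t", index=False)
        pd.DataFrame(
            sorted(self.shared.items(), key=lambda kv: (-kv[1], kv[0])),
            columns=["gene", "n_samples"],
        ).to_csv(out_dir / "shared_genes.tsv", sep="\t", index=False)


def _load_entry(entry: SampleEntry) -> ExpressionMatrix:
    matrix = read_counts(entry.path, entry.format)
    matrix.sample = entry.sample
    matrix.modality = entry.modality
    return matrix


def run_cohort_analysis(
    config: PipelineConfig,
    matrices: dict[str, ExpressionMatrix] | None = None,
) -> CohortReport:
    """Run the full per-cohort analysis.

    ``matrices`` may supply in-memory inputs keyed by sample id, bypassing the
    manifest paths (used by the simulation workflow and the tests).
    """
    if not config.samples:
        raise ValueError("config lists no samples")
    if matrices is None:
        for entry in config.samples:
            if not Path(entry.path).exists():
                raise FileNotFoundError(f"sample {entry.sample}: {entry.path}")
        matrices = {e.sample: _load_entry(e) for e in config.samples}
    excluded: dict[str, str] = {}
    typed = []
    for entry in config.samples:
        t0 = time.perf_counter()
        matrix = log_normalize(matrices[entry.sample])
        calls = identify_mesenchymal(matrix)
        fibro_cells = [c.cell for c in calls if c.call == "fibroblast"]
        peri_cells = [c.cell for c in calls if c.call == "pericyte"]
        mesen = matrix.subset_cells(fibro_cells + peri_cells)
        mesen = quality_filter(
            mesen,
            marker_genes=tuple(FIBROBLAST_MARKERS) + tuple(PERICYTE_MARKERS),
            min_level=config.quality_min_level,
        )
        mesen_calls = [c for c in calls if c.cell in set(mesen.cells)]
        typed.append((mesen, mesen_calls))
        logger.info(
            "stage=typing sample=%s cells_in=%d mesenchymal=%d wall=%.2fs",
            entry.sample,
            matrix.n_cells,
            mesen.n_cells,
            time.perf_counter() - t0,
        )
    kept = filter_samples(typed, min_fibroblasts=config.min_fibroblasts)
    kept_ids = {m.sample for m, _ in kept}
    for m, calls in typed:
        if m.sample not in kept_ids:
            n = sum(c.call == "fibroblast" for c in calls)
            excluded[m.sample] = f"only {n} fibroblasts"
    if not kept:
        raise ValueError(f"no samples survive filtering; exclusions: {excluded}")

    attractors: dict[str, AttractorResult] = {}
    for matrix, _ in kept:
        t0 = time.perf_counter()
        attractors[matrix.sample] = find_attractor(
            matrix, config.seed_gene, config.attractor
        )
        logger.info(
            "stage=attractor sample=%s iterations=%d wall=%.2fs",
            matrix.sample,
            attractors[matrix.sample].iterations,
            time.perf_counter() - t0,
        )
    condition = {e.sample: e.condition for e in config.samples}
    tumor_attractors = {
        s: a for s, a in attractors.items() if condition.get(s) == "tumor"
    }
    ordering = apod_ordering(
        tumor_attractors or attractors, config.anchor_gene, config.counter_gene
    )
    groups = partition_groups(ordering)
    for s in attractors:
        if s not in groups:
            groups[s] = "normal"

    consensus: dict[str, AttractorResult] = {}
    by_matrix = {m.sample: m for m, _ in kept}
    for label in ("normal", "early", "late"):
        members = [by_matrix[s] for s, g in groups.items() if g == label]
        if len(members) >= 2:
            weights = [
                DatasetWeight(dataset=m.sample, n_units=m.n_cells) for m in members
            ]
            consensus[label] = consensus_attractor(
                members, config.seed_gene, weights, config.attractor
            )
        elif members:
            logger.info("group %s has one sample; no consensus computed", label)

    top_lists = [a.top(config.top_k) for a in attractors.values()]
    shared = shared_genes(top_lists, k_top=config.top_k, min_count=len(top_lists))
    shared_p = None
    if len(top_lists) >= 2 and shared:
        problem = IntersectionProblem(
            universe=CROSS_STUDY_UNIVERSE,
            sizes=tuple(min(config.top_k, len(t)) for t in top_lists),
            overlap=len(shared),
        )
        shared_p = multiset_intersection_pvalue(problem).p_value

    proxy = {}
    for matrix, _ in kept:
        if config.counter_gene in matrix.genes:
            expr = matrix.expression(config.counter_gene)
            if expr.max() > expr.min():
                ranking = rank_by_target(matrix, config.counter_gene)
                proxy[matrix.sample] = caf_proxy_test(ranking)
    return CohortReport(
        attractors=attractors,
        ordering=ordering,
        groups=groups,
        consensus=consensus,
        shared=shared,
        shared_pvalue=shared_p,
        proxy_verdicts=proxy,
        excluded=excluded,
    )


def export_scatter(
    matrix: ExpressionMatrix,
    cells: list[str],
    x_gene: str = "COL11A1",
    y_gene: str = "APOD",
    color_gene: str = "LUM",
) -> pd.DataFrame:
    """Per-cell table of normalized (x, y, color) expression for scatter plots.

    One row per selected cell; the classic view is COL11A1 on x, APOD on y,
    colored by LUM, which makes intermediate transition states visible as
    double-positive cells.
    """
    for g in (x_gene, y_gene, color_gene):
        if g not in matrix.genes:
            raise KeyError(f"gene {g!r} not in matrix")
    data = matrix.layer("normalized")
    rows = []
    for cell in cells:
        j = matrix.cells.get_loc(cell)
        rows.append(
            {
                "cell": cell,
                x_gene: data[matrix.genes.get_loc(x_gene), j],
                y_gene: data[matrix.genes.get_loc(y_gene), j],
                color_gene: data[matrix.genes.get_loc(color_gene), j],
            }
        )
    return pd.DataFrame(rows, columns=["cell", x_gene, y_gene, color_gene])
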