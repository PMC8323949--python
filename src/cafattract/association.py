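"""Target-gene association rankings, the CAF proxy test, APOD-rank sample
ordering, and the pan-cancer ncRNA screen.

COL11A1 acts as a proxy for the full CAF signature: in a sample that contains
COL11A1-expressing CAFs, ranking all genes by normalized MI with COL11A1 puts
INHBA and THBS2 near the top.  Ordering samples by how strongly APOD (the ASC
marker) ranks inside their attractors recovers the progression of the
ASC -> CAF transition across a cohort, and comparing the APOD and COL11A1
ranks splits samples into early and late transition groups.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .attractor import AttractorResult
from .matrix import ExpressionMatrix
from .mi import MIConfig, mi_vector

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationRanking",
    "SampleOrdering",
    "ScreenResult",
    "rank_by_target",
    "caf_proxy_test",
    "apod_ordering",
    "partition_groups",
    "quantile_normalize",
    "pan_cancer_screen",
]


@dataclass
class AssociationRanking:
    """Genes ranked by normalized MI with one target gene."""

    target: str
    table: pd.DataFrame  # columns: rank, gene, mi
    dataset: str = ""

    def rank_of(self, gene: str) -> float:
        hit = self.table.loc[self.table["gene"] == gene, "rank"]
        return float(hit.iloc[0]) if not hit.empty else float("inf")

    def top(self, k: int) -> list[str]:
        return self.table["gene"].head(k).tolist()


def rank_by_target(
    matrix: ExpressionMatrix,
    target_gene: str,
    config: MIConfig | None = None,
    layer: str = "normalized",
) -> AssociationRanking:
    """Rank every gene by its normalized MI with ``target_gene``.

    The target itself comes out rank 1 with MI 1; ties break lexicographically
    by gene identifier.
    """
    target = matrix.expression(target_gene, layer)
    if target.max() == target.min():
        raise ValueError(f"target gene {target_gene!r} has zero variance")
    scores = mi_vector(target, matrix, config, layer)
    genes = np.array(list(scores))
    mis = np.array([s.value for s in scores.values()])
    # ties break lexicographically, except the target itself always wins its tie
    order = np.lexsort((genes, genes != target_gene, -mis))
    table = pd.DataFrame(
        {
            "rank": np.arange(1, len(genes) + 1),
            "gene": genes[order],
            "mi": mis[order],
        }
    )
    return AssociationRanking(target=target_gene, table=table, dataset=matrix.sample)


@dataclass(frozen=True)
class ProxyVerdict:
    positive: bool
    ranks: dict
    reason: str = ""


def caf_proxy_test(
    ranking: AssociationRanking,
    k: int = 20,
    required: tuple[str, ...] = ("INHBA", "THBS2"),
) -> ProxyVerdict:
    """Positive iff every required sentinel gene ranks within the top ``k``."""
    ranks = {g: ranking.rank_of(g) for g in required}
    missing = [g for g, r in ranks.items() if math.isinf(r)]
    if missing:
        return ProxyVerdict(False, ranks, f"absent from universe: {missing}")
    positive = all(r <= k for r in ranks.values())
    return ProxyVerdict(positive, ranks, "" if positive else f"not all within top {k}")


@dataclass
class SampleOrdering:
    """Samples sorted by the strength of the anchor gene's attractor rank."""

    samples: list[str]
    anchor_ranks: dict
    counter_ranks: dict
    anchor: str = "APOD"
    counter: str = "COL11A1"


def apod_ordering(
    attractors: dict[str, AttractorResult],
    anchor_gene: str = "APOD",
    counter_gene: str = "COL11A1",
) -> SampleOrdering:
    """Order samples with the strongest anchor membership first.

    Smaller 1-based anchor rank sorts earlier; samples lacking the anchor sort
    last.  Ties break by weaker counter-gene membership first (larger counter
    rank, i.e. less transitioned), then by sample id for stability.
    """
    if not attractors:
        raise ValueError("need at least one attractor")
    anchor_ranks = {s: a.rank_of(anchor_gene) for s, a in attractors.items()}
    counter_ranks = {s: a.rank_of(counter_gene) for s, a in attractors.items()}
    ordered = sorted(
        attractors,
        key=lambda s: (anchor_ranks[s], -counter_ranks[s], s),
    )
    return SampleOrdering(
        samples=ordered,
        anchor_ranks=anchor_ranks,
        counter_ranks=counter_ranks,
        anchor=anchor_gene,
        counter=counter_gene,
    )


def partition_groups(ordering: SampleOrdering) -> dict[str, str]:
    """Label each sample early/late by whether the anchor outranks the counter.

    ``early``: anchor (APOD) ranked before counter (COL11A1), or counter
    absent; both absent also counts as early (no evidence the transition has
    begun, logged).  ``late``: the rest.
    """
    labels = {}
    for s in ordering.samples:
        a, c = ordering.anchor_ranks[s], ordering.counter_ranks[s]
        if math.isinf(a) and math.isinf(c):
            logger.info("sample %s lacks both %s and %s; labelled early", s,
                        ordering.anchor, ordering.counter)
            labels[s] = "early"
        elif math.isinf(c) or a < c:
            labels[s] = "early"
        else:
            labels[s] = "late"
    return labels


# -- pan-cancer ncRNA screen ----------------------------------------------


def quantile_normalize(values: np.ndarray) -> np.ndarray:
    """Quantile-normalize columns of a (genes x samples) array.

    The reference distribution is the mean of order statistics across samples;
    ties within a sample share the mean of their positions' reference values.
    After normalization every sample has the identical sorted value vector.
    """
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    order = np.argsort(values, axis=0, kind="mergesort")
    sorted_vals = np.take_along_axis(values, order, axis=0)
    reference = sorted_vals.mean(axis=1)
    out = np.empty_like(values)
    for j in range(n_samples):
        col = values[:, j]
        # average reference values over tied ranks
        ranks = pd.Series(col).rank(method="average").to_numpy() - 1.0
        lo = np.floor(ranks).astype(int)
        hi = np.ceil(ranks).astype(int)
        out[:, j] = (reference[lo] + reference[hi]) / 2.0
    return out


@dataclass
class ScreenResult:
    """Per-type rankings, exclusions, and the pan-cancer ncRNA consensus."""

    coding_rankings: dict[str, AssociationRanking]
    ncrna_rankings: dict[str, AssociationRanking]
    excluded: dict[str, str]
    consensus: pd.DataFrame  # columns: gene, median_rank, mean_rank


def pan_cancer_screen(
    cohort: list[ExpressionMatrix],
    target: str = "COL11A1",
    sentinels: tuple[str, ...] = ("THBS2", "INHBA"),
    sentinel_depth: int = 50,
    zero_fraction: float = 0.5,
    config: MIConfig | None = None,
) -> ScreenResult:
    """Screen bulk cohorts for non-coding genes tracking the CAF signature.

    Per type: drop genes with more than ``zero_fraction`` zero-count samples;
    quantile-normalize log2(count+1) across samples; rank protein-coding genes
    by MI with the target and exclude the type unless at least one sentinel
    (THBS2/INHBA) is within the top ``sentinel_depth``; rank ncRNAs by MI with
    the target in the surviving types.  The consensus sorts ncRNAs by
    ascending median rank across included types, ties by mean rank.
    """
    coding_rankings: dict[str, AssociationRanking] = {}
    ncrna_rankings: dict[str, AssociationRanking] = {}
    excluded: dict[str, str] = {}
    for matrix in cohort:
        type_id = matrix.sample
        if matrix.n_cells < 2:
            excluded[type_id] = "fewer than 2 samples"
            continue
        if matrix.gene_annotation is None or "biotype" not in matrix.gene_annotation:
            raise ValueError(f"type {type_id}: biotype annotation required")
        zero_frac = (matrix.counts == 0).mean(axis=1)
        kept = matrix.subset_genes(list(matrix.genes[zero_frac <= zero_fraction]))
        if target not in kept.genes:
            excluded[type_id] = f"target {target} filtered out"
            continue
        log2 = np.log2(kept.counts + 1.0)
        normalized = quantile_normalize(log2)
        normed = ExpressionMatrix(
            counts=kept.counts,
            genes=kept.genes,
            cells=kept.cells,
            sample=type_id,
            modality="bulk",
            normalized=normalized,
            gene_annotation=kept.gene_annotation,
        )
        biotype = normed.gene_annotation["biotype"]
        coding = normed.subset_genes(list(normed.genes[biotype == "coding"]))
        coding_rank = rank_by_target(coding, target, config)
        coding_rankings[type_id] = coding_rank
        if not any(coding_rank.rank_of(s) <= sentinel_depth for s in sentinels):
            excluded[type_id] = (
                f"neither sentinel within top {sentinel_depth} coding genes"
            )
            continue
        nc_genes = list(normed.genes[biotype.isin(["lncRNA", "miRNA"])])
        nc = normed.subset_genes(nc_genes + [target])
        nc_rank = rank_by_target(nc, target, config)
        # drop the target itself from the ncRNA table and re-rank
        tbl = nc_rank.table[nc_rank.table["gene"] != target].reset_index(drop=True)
        tbl["rank"] = np.arange(1, len(tbl) + 1)
        ncrna_rankings[type_id] = AssociationRanking(
            target=target, table=tbl, dataset=type_id
        )
    included = list(ncrna_rankings)
    if included:
        all_nc = sorted(
            set().union(*[r.table["gene"] for r in ncrna_rankings.values()])
        )
        rows = []
        for g in all_nc:
            ranks = [ncrna_rankings[t].rank_of(g) for t in included]
            finite = [r for r in ranks if math.isfinite(r)]
            worst = max(
                len(ncrna_rankings[t].table) for t in included
            )
            filled = [r if math.isfinite(r) else worst + 1 for r in ranks]
            rows.append(
                {
                    "gene": g,
                    "median_rank": float(np.median(filled)),
                    "mean_rank": float(np.mean(filled)),
                }
            )
        consensus = (
            pd.DataFrame(rows)
            .sort_values(["median_rank", "mean_rank", "gene"])
            .reset_index(drop=True)
        )
    else:
        consensus = pd.DataFrame(columns=["gene", "median_rank", "mean_rank"])
    return ScreenResult(
        coding_rankings=coding_rankings,
        ncrna_rankings=ncrna_rankings,
        excluded=excluded,
        consensus=consensus,
    )
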