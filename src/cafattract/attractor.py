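"""The seeded attractor-metagene algorithm and its multi-dataset consensus.

An attractor metagene is the fixed point of an alternating iteration on an
expression matrix: starting from a seed gene's expression vector, each gene is
weighted by its normalized mutual information with the current metagene raised
to an exponent ``a``, the weights are renormalized to sum to one, and the
metagene is replaced by the weighted average expression profile.  On
convergence the genes ranked by their final MI with the metagene form a
co-expression signature whose top is the "core" of the co-expressed module.

The exponent sharpens the weighting: larger ``a`` concentrates the metagene on
fewer genes.  UMI-based single-cell data conventionally uses ``a = 3`` and
full-length protocols ``a = 5``.

The estimation is exposed statsmodels-style: build an :class:`AttractorModel`
from a matrix and a seed, call :meth:`~AttractorModel.fit`, and read the
ranked signature, diagnostics and ``summary()`` off the returned
:class:`AttractorResult`.  :func:`find_attractor` is the one-call shorthand.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix
from .mi import (
    MIConfig,
    _entropy_from_p,
    _pearson_sign,
    _self_raw,
    spline_weights,
)

__all__ = [
    "AttractorConfig",
    "AttractorModel",
    "AttractorResult",
    "DatasetWeight",
    "find_attractor",
    "scan_seeds",
    "consensus_attractor",
    "top_genes",
    "weighted_median",
]

#: protocol-specific default exponents
EXPONENT_BY_MODALITY = {"UMI": 3.0, "full-length": 5.0, "bulk": 5.0}


@dataclass(frozen=True)
class AttractorConfig:
    """Iteration settings.

    ``exponent`` defaults to the modality-appropriate value when left None
    (UMI -> 3, full-length/bulk -> 5).  ``tol`` is the L-infinity change of
    the full MI vector between successive iterations.
    """

    exponent: float | None = None
    tol: float = 1e-4
    max_iterations: int = 100
    min_cells: int = 50
    mi: MIConfig = field(default_factory=MIConfig)
    #: 2nd-ranked score below this marks a degenerate (seed-only) attractor
    degenerate_score: float = 0.2

    def __post_init__(self) -> None:
        if self.exponent is not None and self.exponent <= 0:
            raise ValueError("exponent must be positive")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")

    def resolve_exponent(self, modality: str) -> float:
        if self.exponent is not None:
            return self.exponent
        return EXPONENT_BY_MODALITY.get(modality, 3.0)


@dataclass(frozen=True)
class DatasetWeight:
    """Log-scale dataset weight for consensus runs: ``weight = log(n_units)``."""

    dataset: str
    n_units: int

    @property
    def weight(self) -> float:
        if self.n_units < 2:
            raise ValueError("n_units must be >= 2 for a positive weight")
        return float(np.log(self.n_units))


class _GeneMICache:
    """Fixed per-gene spline weights/entropies for fast metagene-vs-all MI."""

    def __init__(self, data: np.ndarray, config: MIConfig):
        self.config = config
        self.data = data
        n_genes, n = data.shape
        b = config.bins
        self.weights = np.empty((n_genes, n, b))
        self.entropies = np.empty(n_genes)
        self.self_mi = np.zeros(n_genes)
        self.constant = np.zeros(n_genes, dtype=bool)
        for i in range(n_genes):
            row = data[i]
            if row.max() == row.min():
                self.constant[i] = True
                self.weights[i] = 0.0
                self.entropies[i] = 0.0
                continue
            w = spline_weights(row, config)
            self.weights[i] = w
            self.entropies[i] = _entropy_from_p(w.mean(axis=0))
            self.self_mi[i] = _self_raw(w, self.entropies[i])
        # centred rows for fast Pearson signs against an arbitrary vector
        self._centered = data - data.mean(axis=1, keepdims=True)
        self._norms = np.sqrt((self._centered**2).sum(axis=1))

    def mi_with(self, metagene: np.ndarray) -> np.ndarray:
        """Normalized, clipped MI of every gene with ``metagene``."""
        n = self.data.shape[1]
        if metagene.max() == metagene.min():
            return np.zeros(len(self.entropies))
        wm = spline_weights(metagene, self.config)
        h_m = _entropy_from_p(wm.mean(axis=0))
        self_m = _self_raw(wm, h_m)
        # joint distributions for all genes at once: (G, B, B)
        joint = np.einsum("nb,gnc->gbc", wm, self.weights) / n
        with np.errstate(divide="ignore", invalid="ignore"):
            logj = np.where(joint > 0, np.log2(np.where(joint > 0, joint, 1.0)), 0.0)
        h_joint = -(joint * logj).sum(axis=(1, 2))
        raw = self.entropies + h_m - h_joint
        denom = np.minimum(self.self_mi, self_m)
        with np.errstate(divide="ignore", invalid="ignore"):
            value = np.where(denom > 0, raw / np.maximum(denom, 1e-300), 0.0)
        value = np.clip(value, 0.0, 1.0)
        if self.config.clip_negative:
            centered_m = metagene - metagene.mean()
            norm_m = np.sqrt((centered_m**2).sum())
            if norm_m > 0:
                corr_num = self._centered @ centered_m
                value = np.where(corr_num < 0, 0.0, value)
        value[self.constant] = 0.0
        return value


@dataclass
class AttractorResult:
    """A converged (or flagged non-converged) attractor signature.

    ``table`` holds the 1-based ranks, genes and final MI scores sorted
    non-increasingly; ``deltas`` is the per-iteration L-infinity change of the
    MI vector.
    """

    seed: str
    table: pd.DataFrame  # columns: rank, gene, score
    converged: bool
    iterations: int
    deltas: list[float]
    exponent: float
    degenerate: bool
    sample: str = ""

    @property
    def genes(self) -> list[str]:
        return self.table["gene"].tolist()

    @property
    def scores(self) -> np.ndarray:
        return self.table["score"].to_numpy()

    def score_of(self, gene: str) -> float:
        hit = self.table.loc[self.table["gene"] == gene, "score"]
        if hit.empty:
            raise KeyError(gene)
        return float(hit.iloc[0])

    def rank_of(self, gene: str) -> float:
        """1-based rank of ``gene``; ``inf`` when absent from the signature."""
        hit = self.table.loc[self.table["gene"] == gene, "rank"]
        return float(hit.iloc[0]) if not hit.empty else float("inf")

    def top(self, k: int = 20) -> list[str]:
        return top_genes(self, k)

    def summary(self, k: int = 20) -> str:
        head = self.table.head(k).to_string(index=False)
        status = "converged" if self.converged else "NOT converged"
        extra = " (degenerate)" if self.degenerate else ""
        return (
            f"Attractor seeded at {self.seed!r} [{status}{extra}] "
            f"after {self.iterations} iterations "
            f"(exponent a={self.exponent:g}, final delta="
            f"{self.deltas[-1] if self.deltas else float('nan'):.2e})\n{head}"
        )

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        self.table.to_csv(path, sep="\t", index=False)
        sidecar = path.with_suffix(".json")
        sidecar.write_text(
            json.dumps(
                {
                    "seed": self.seed,
                    "sample": self.sample,
                    "converged": self.converged,
                    "iterations": self.iterations,
                    "exponent": self.exponent,
                    "degenerate": self.degenerate,
                    "deltas": self.deltas,
                },
                indent=2,
            )
        )


def _rank_table(genes: pd.Index, scores: np.ndarray) -> pd.DataFrame:
    # sort by score descending, ties lexicographically by gene id
    order = np.lexsort((np.asarray(genes.astype(str)), -scores))
    return pd.DataFrame(
        {
            "rank": np.arange(1, len(genes) + 1),
            "gene": np.asarray(genes.astype(str))[order],
            "score": scores[order],
        }
    )


class AttractorModel:
    """Seeded attractor iteration on one expression matrix."""

    def __init__(
        self,
        matrix: ExpressionMatrix,
        seed_gene: str,
        config: AttractorConfig | None = None,
        layer: str = "normalized",
    ):
        self.config = config or AttractorConfig()
        if matrix.n_cells < self.config.min_cells:
            raise ValueError(
                f"matrix has {matrix.n_cells} cells; need >= {self.config.min_cells}"
            )
        if seed_gene not in matrix.genes:
            raise KeyError(f"seed gene {seed_gene!r} not in matrix")
        seed_expr = matrix.expression(seed_gene, layer)
        if seed_expr.max() == seed_expr.min():
            raise ValueError(f"seed gene {seed_gene!r} has zero variance")
        self.matrix = matrix
        self.seed_gene = seed_gene
        self.layer = layer

    def fit(self) -> AttractorResult:
        cfg = self.config
        data = self.matrix.layer(self.layer)
        cache = _GeneMICache(data, cfg.mi)
        a = cfg.resolve_exponent(self.matrix.modality)
        metagene = self.matrix.expression(self.seed_gene, self.layer).astype(float)
        prev_mi: np.ndarray | None = None
        deltas: list[float] = []
        converged = False
        mi_vec = cache.mi_with(metagene)
        iterations = 0
        for iterations in range(1, cfg.max_iterations + 1):
            w = mi_vec**a
            total = w.sum()
            if total <= 0:
                break  # signature collapsed entirely; keep last MI vector
            w = w / total
            metagene = w @ data
            new_mi = cache.mi_with(metagene)
            delta = float(np.max(np.abs(new_mi - mi_vec)))
            deltas.append(delta)
            mi_vec = new_mi
            if delta < cfg.tol:
                converged = True
                break
        table = _rank_table(self.matrix.genes, mi_vec)
        degenerate = bool(
            len(table) > 1 and table["score"].iloc[1] < cfg.degenerate_score
        )
        return AttractorResult(
            seed=self.seed_gene,
            table=table,
            converged=converged,
            iterations=iterations,
            deltas=deltas,
            exponent=a,
            degenerate=degenerate,
            sample=self.matrix.sample,
        )


def find_attractor(
    matrix: ExpressionMatrix,
    seed_gene: str,
    config: AttractorConfig | None = None,
    layer: str = "normalized",
) -> AttractorResult:
    """One-call shorthand for ``AttractorModel(...).fit()``."""
    return AttractorModel(matrix, seed_gene, config, layer).fit()


def top_genes(attractor: AttractorResult, k: int) -> list[str]:
    """First ``min(k, len)`` genes of the ranked signature."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return attractor.table["gene"].head(k).tolist()


def scan_seeds(
    matrix: ExpressionMatrix,
    seed_genes: list[str],
    config: AttractorConfig | None = None,
    k: int = 20,
    layer: str = "normalized",
) -> list[list[AttractorResult]]:
    """Run the iteration from several seeds and group identical outcomes.

    Attractors whose top-``k`` ranked gene lists coincide are considered the
    same attractor (seeds of one co-expression signature converge to one fixed
    point); one group per distinct top-``k`` list, in first-seen order.
    """
    groups: dict[tuple, list[AttractorResult]] = {}
    for seed in seed_genes:
        result = find_attractor(matrix, seed, config, layer)
        key = tuple(result.top(k))
        groups.setdefault(key, []).append(result)
    return list(groups.values())


def weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Lower weighted median: smallest v with cumulative weight >= half total."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    order = np.argsort(values, kind="mergesort")
    cum = np.cumsum(weights[order])
    cutoff = 0.5 * cum[-1]
    return float(values[order][np.searchsorted(cum, cutoff)])


class ConsensusAttractorModel:
    """Consensus attractor across datasets sharing a gene universe.

    Each dataset keeps its own metagene built from the shared gene-weight
    vector; per-dataset MI vectors are combined by weighted median (weights
    ``log(n_units)``) before exponentiation, so no single dataset's private
    co-expression can dominate.
    """

    def __init__(
        self,
        matrices: list[ExpressionMatrix],
        seed_gene: str,
        weights: list[DatasetWeight] | None = None,
        config: AttractorConfig | None = None,
        layer: str = "normalized",
    ):
        if len(matrices) < 2:
            raise ValueError("consensus needs >= 2 datasets")
        self.config = config or AttractorConfig()
        shared = matrices[0].genes
        for m in matrices[1:]:
            shared = shared.intersection(m.genes)
        if len(shared) == 0:
            raise ValueError("gene universes do not intersect")
        if seed_gene not in shared:
            raise KeyError(f"seed gene {seed_gene!r} not shared by all datasets")
        shared = pd.Index(sorted(shared))
        self.matrices = [m.subset_genes(list(shared)) for m in matrices]
        self.genes = shared
        self.seed_gene = seed_gene
        self.layer = layer
        if weights is None:
            weights = [
                DatasetWeight(dataset=m.sample or str(i), n_units=m.n_cells)
                for i, m in enumerate(matrices)
            ]
        if len(weights) != len(matrices):
            raise ValueError("one DatasetWeight per dataset required")
        self.weights = np.array([w.weight for w in weights])

    def fit(self) -> AttractorResult:
        cfg = self.config
        datasets = [m.layer(self.layer) for m in self.matrices]
        caches = [_GeneMICache(d, cfg.mi) for d in datasets]
        a = cfg.resolve_exponent(self.matrices[0].modality)
        seed_idx = self.genes.get_loc(self.seed_gene)

        def combined(mi_per_dataset: list[np.ndarray]) -> np.ndarray:
            stacked = np.stack(mi_per_dataset)  # (D, G)
            return np.apply_along_axis(
                lambda col: weighted_median(col, self.weights), 0, stacked
            )

        mi_vec = combined([c.mi_with(d[seed_idx]) for c, d in zip(caches, datasets)])
        deltas: list[float] = []
        converged = False
        iterations = 0
        for iterations in range(1, cfg.max_iterations + 1):
            w = mi_vec**a
            total = w.sum()
            if total <= 0:
                break
            w = w / total
            per_dataset = []
            for cache, data in zip(caches, datasets):
                metagene = w @ data
                per_dataset.append(cache.mi_with(metagene))
            new_mi = combined(per_dataset)
            delta = float(np.max(np.abs(new_mi - mi_vec)))
            deltas.append(delta)
            mi_vec = new_mi
            if delta < cfg.tol:
                converged = True
                break
        table = _rank_table(self.genes, mi_vec)
        degenerate = bool(
            len(table) > 1 and table["score"].iloc[1] < cfg.degenerate_score
        )
        return AttractorResult(
            seed=self.seed_gene,
            table=table,
            converged=converged,
            iterations=iterations,
            deltas=deltas,
            exponent=a,
            degenerate=degenerate,
            sample="consensus",
        )


def consensus_attractor(
    matrices: list[ExpressionMatrix],
    seed_gene: str,
    weights: list[DatasetWeight] | None = None,
    config: AttractorConfig | None = None,
    layer: str = "normalized",
) -> AttractorResult:
    """One-call shorthand for ``ConsensusAttractorModel(...).fit()``."""
    return ConsensusAttractorModel(matrices, seed_gene, weights, config, layer).fit()
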