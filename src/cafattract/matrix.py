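"""Gene-major expression matrices: containers, IO, normalization and cell typing.

The container is deliberately lightweight: a dense gene x cell (or gene x
sample, for bulk data) array with pandas indices, an optional log-normalized
layer, and optional per-gene annotation (e.g. biotype).  Matrices in this
package are small enough (cohort-level fibroblast subsets, simulated cohorts)
that sparse storage buys nothing, while dense arrays keep the mutual-
information machinery simple and fast.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

logger = logging.getLogger(__name__)

#: markers used for cell typing, following common CAF-literature conventions
FIBROBLAST_MARKERS = ("LUM", "DCN", "COL1A1")
PERICYTE_MARKERS = ("RGS5", "ACTA2", "PDGFRB", "ADIRF")


class FormatError(ValueError):
    """Raised when an on-disk matrix does not parse into a valid container."""


@dataclass
class ExpressionMatrix:
    """A gene-major count matrix with an optional log-normalized layer.

    Parameters
    ----------
    counts
        Non-negative array of shape ``(n_genes, n_cells)``.
    genes
        Unique, ordered gene identifiers (case-sensitive).
    cells
        Unique, ordered cell (or bulk sample) identifiers.
    sample
        Label of the sample this matrix came from.
    modality
        ``"UMI"``, ``"full-length"`` or ``"bulk"``; downstream code uses it to
        pick the attractor exponent.
    normalized
        Optional log-normalized layer with the same shape as ``counts``.
    gene_annotation
        Optional per-gene frame indexed like ``genes`` (e.g. a ``biotype``
        column with values ``coding`` / ``lncRNA`` / ``miRNA``).
    """

    counts: np.ndarray
    genes: pd.Index
    cells: pd.Index
    sample: str = ""
    modality: str = "UMI"
    normalized: np.ndarray | None = None
    gene_annotation: pd.DataFrame | None = None
    cell_annotation: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.genes = pd.Index(self.genes)
        self.cells = pd.Index(self.cells)
        if self.counts.ndim != 2:
            raise FormatError("counts must be 2-dimensional (genes x cells)")
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise FormatError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if self.counts.size and self.counts.min() < 0:
            raise FormatError("counts must be non-negative")
        for name, idx in (("gene", self.genes), ("cell", self.cells)):
            if idx.has_duplicates:
                dup = idx[idx.duplicated()][0]
                raise FormatError(f"duplicate {name} identifier: {dup!r}")
        if self.normalized is not None:
            self.normalized = np.asarray(self.normalized, dtype=float)
            if self.normalized.shape != self.counts.shape:
                raise FormatError("normalized layer shape differs from counts")
        if self.gene_annotation is not None and not self.gene_annotation.index.equals(
            self.genes
        ):
            self.gene_annotation = self.gene_annotation.reindex(self.genes)

    # -- basic accessors -------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def expression(self, gene: str, layer: str = "normalized") -> np.ndarray:
        """Return one gene's vector from the requested layer."""
        if gene not in self.genes:
            raise KeyError(f"gene {gene!r} not in matrix")
        i = self.genes.get_loc(gene)
        return self.layer(layer)[i]

    def layer(self, which: str = "normalized") -> np.ndarray:
        if which == "counts":
            return self.counts
        if which == "normalized":
            if self.normalized is None:
                raise ValueError("no normalized layer; call log_normalize first")
            return self.normalized
        raise KeyError(f"unknown layer {which!r}")

    def subset_cells(self, keep: np.ndarray | list) -> "ExpressionMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = np.asarray([self.cells.get_loc(c) for c in keep])
        return ExpressionMatrix(
            counts=self.counts[:, idx],
            genes=self.genes,
            cells=self.cells[idx],
            sample=self.sample,
            modality=self.modality,
            normalized=None if self.normalized is None else self.normalized[:, idx],
            gene_annotation=self.gene_annotation,
            cell_annotation=None
            if self.cell_annotation is None
            else self.cell_annotation.iloc[idx],
        )

    def subset_genes(self, keep: list) -> "ExpressionMatrix":
        idx = np.asarray([self.genes.get_loc(g) for g in keep])
        return ExpressionMatrix(
            counts=self.counts[idx],
            genes=self.genes[idx],
            cells=self.cells,
            sample=self.sample,
            modality=self.modality,
            normalized=None if self.normalized is None else self.normalized[idx],
            gene_annotation=None
            if self.gene_annotation is None
            else self.gene_annotation.iloc[idx],
            cell_annotation=self.cell_annotation,
        )

    def equals(self, other: "ExpressionMatrix") -> bool:
        return (
            self.genes.equals(other.genes)
            and self.cells.equals(other.cells)
            and np.allclose(self.counts, other.counts)
        )


# -- IO ------------------------------------------------------------------


def read_counts(path: str | Path, format: str = "mtx") -> ExpressionMatrix:
    """Load a gene x cell matrix from disk.

    ``mtx`` expects a Matrix Market triplet file with ``genes.tsv`` and
    ``barcodes.tsv`` sidecars in the same directory (gene-major orientation);
    ``dense-tsv`` expects genes as rows, cells as columns, with the first
    column holding gene identifiers.
    """
    path = Path(path)
    if format in ("mtx", "mtx-triplet"):
        mtx_file = path / "matrix.mtx" if path.is_dir() else path
        folder = mtx_file.parent
        if not mtx_file.exists():
            raise FormatError(f"no matrix file at {mtx_file}")
        mat = spio.mmread(mtx_file)
        mat = np.asarray(mat.todense() if sparse.issparse(mat) else mat, dtype=float)
        genes_df = pd.read_csv(folder / "genes.tsv", sep="\t", header=None)
        cells_df = pd.read_csv(folder / "barcodes.tsv", sep="\t", header=None)
        genes = pd.Index(genes_df.iloc[:, 0].astype(str))
        cells = pd.Index(cells_df.iloc[:, 0].astype(str))
        if mat.shape != (len(genes), len(cells)):
            raise FormatError(
                f"matrix {mat.shape} does not match {len(genes)} genes / "
                f"{len(cells)} barcodes"
            )
        annotation = None
        if genes_df.shape[1] > 1:
            annotation = pd.DataFrame(
                {"biotype": genes_df.iloc[:, 1].astype(str).values}, index=genes
            )
        meta = _read_meta(folder)
        return ExpressionMatrix(
            counts=mat,
            genes=genes,
            cells=cells,
            gene_annotation=annotation,
            **meta,
        )
    if format == "dense-tsv":
        if not Path(path).exists():
            raise FormatError(f"no such file: {path}")
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except pd.errors.EmptyDataError as err:
            raise FormatError(f"empty matrix file: {path}") from err
        if df.empty:
            raise FormatError(f"empty matrix file: {path}")
        annotation = None
        if "biotype" in df.columns:
            annotation = df[["biotype"]].copy()
            df = df.drop(columns=["biotype"])
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise FormatError(f"duplicate gene identifier: {dup!r}")
        return ExpressionMatrix(
            counts=df.to_numpy(dtype=float),
            genes=pd.Index(df.index.astype(str)),
            cells=pd.Index(df.columns.astype(str)),
            gene_annotation=annotation,
        )
    raise ValueError(f"unknown format {format!r}")


def _read_meta(folder: Path) -> dict:
    meta_file = folder / "meta.tsv"
    if not meta_file.exists():
        return {}
    kv = dict(
        line.split("\t", 1)
        for line in meta_file.read_text().splitlines()
        if "\t" in line
    )
    out = {}
    if "sample" in kv:
        out["sample"] = kv["sample"]
    if "modality" in kv:
        out["modality"] = kv["modality"]
    return out


def write_counts(
    matrix: ExpressionMatrix, path: str | Path, format: str = "mtx"
) -> None:
    """Write ``matrix`` so that :func:`read_counts` round-trips it losslessly."""
    path = Path(path)
    if format in ("mtx", "mtx-triplet"):
        path.mkdir(parents=True, exist_ok=True)
        spio.mmwrite(path / "matrix.mtx", sparse.coo_matrix(matrix.counts))
        genes = pd.DataFrame({0: matrix.genes})
        if matrix.gene_annotation is not None and "biotype" in matrix.gene_annotation:
            genes[1] = matrix.gene_annotation["biotype"].values
        genes.to_csv(path / "genes.tsv", sep="\t", header=False, index=False)
        pd.DataFrame({0: matrix.cells}).to_csv(
            path / "barcodes.tsv", sep="\t", header=False, index=False
        )
        (path / "meta.tsv").write_text(
            f"sample\t{matrix.sample}\nmodality\t{matrix.modality}\n"
        )
    elif format == "dense-tsv":
        path.parent.mkdir(parents=True, exist_ok=True)
        df = pd.DataFrame(matrix.counts, index=matrix.genes, columns=matrix.cells)
        if matrix.gene_annotation is not None and "biotype" in matrix.gene_annotation:
            df.insert(0, "biotype", matrix.gene_annotation["biotype"].values)
        df.to_csv(path, sep="\t")
    else:
        raise ValueError(f"unknown format {format!r}")


# -- normalization and cell identification --------------------------------


def log_normalize(matrix: ExpressionMatrix, scale: float = 1e4) -> ExpressionMatrix:
    """Library-size normalize then log-transform.

    Each count is divided by its cell's total, multiplied by ``scale``
    (default 10,000) and passed through ``log(1 + .)`` (natural log) — the
    standard log-normalization of scRNA-seq toolkits.  Cells whose total count
    is zero cannot be normalized and are dropped with a warning.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    totals = matrix.counts.sum(axis=0)
    nonzero = totals > 0
    if not nonzero.all():
        dropped = matrix.cells[~nonzero].tolist()
        msg = f"dropping {len(dropped)} all-zero cell(s): {dropped[:5]}"
        logger.warning(msg)
        warnings.warn(msg, UserWarning, stacklevel=2)
        matrix = matrix.subset_cells(nonzero)
        totals = totals[nonzero]
    normalized = np.log1p(matrix.counts / totals * scale)
    return ExpressionMatrix(
        counts=matrix.counts,
        genes=matrix.genes,
        cells=matrix.cells,
        sample=matrix.sample,
        modality=matrix.modality,
        normalized=normalized,
        gene_annotation=matrix.gene_annotation,
        cell_annotation=matrix.cell_annotation,
    )


@dataclass
class CellTypeCall:
    cell: str
    call: str  # fibroblast | pericyte | other
    scores: dict = field(default_factory=dict)


def _marker_score(matrix: ExpressionMatrix, markers) -> tuple[np.ndarray, list[str]]:
    present = [m for m in markers if m in matrix.genes]
    missing = [m for m in markers if m not in matrix.genes]
    if missing:
        logger.warning("markers missing from matrix: %s", missing)
    if not present:
        return np.zeros(matrix.n_cells), present
    idx = [matrix.genes.get_loc(m) for m in present]
    return matrix.layer("normalized")[idx].mean(axis=0), present


def identify_mesenchymal(
    matrix: ExpressionMatrix,
    fibro_markers=FIBROBLAST_MARKERS,
    pericyte_markers=PERICYTE_MARKERS,
    threshold: float = 1.0,
) -> list[CellTypeCall]:
    """Call each cell fibroblast / pericyte / other from marker expression.

    A cell is a fibroblast when its mean normalized fibroblast-marker score
    exceeds both the competing pericyte score and ``threshold``; symmetrically
    for pericytes; everything else is ``other``.  Marker-score typing stands in
    for graph-based clustering, which this package deliberately does not do.
    """
    fscore, fpresent = _marker_score(matrix, fibro_markers)
    pscore, ppresent = _marker_score(matrix, pericyte_markers)
    if not fpresent and not ppresent:
        raise ValueError("all marker genes missing from matrix")
    calls = []
    for j, cell in enumerate(matrix.cells):
        if fscore[j] > threshold and fscore[j] > pscore[j]:
            call = "fibroblast"
        elif pscore[j] > threshold and pscore[j] >= fscore[j]:
            call = "pericyte"
        else:
            call = "other"
        calls.append(
            CellTypeCall(
                cell=str(cell),
                call=call,
                scores={"fibroblast": float(fscore[j]), "pericyte": float(pscore[j])},
            )
        )
    return calls


def quality_filter(
    matrix: ExpressionMatrix,
    marker_genes=FIBROBLAST_MARKERS,
    min_level: float = 3.0,
) -> ExpressionMatrix:
    """Keep cells whose maximum normalized marker expression is >= ``min_level``.

    The bound is inclusive.  An empty result is returned (with a warning), not
    raised, so cohort loops can proceed.
    """
    present = [m for m in marker_genes if m in matrix.genes]
    if not present:
        raise ValueError("no marker genes present in matrix")
    idx = [matrix.genes.get_loc(m) for m in present]
    keep = matrix.layer("normalized")[idx].max(axis=0) >= min_level
    if not keep.any():
        warnings.warn("quality_filter removed every cell", UserWarning, stacklevel=2)
    return matrix.subset_cells(keep)


def filter_samples(
    cohort: list[tuple[ExpressionMatrix, list[CellTypeCall]]],
    min_fibroblasts: int = 20,
) -> list[tuple[ExpressionMatrix, list[CellTypeCall]]]:
    """Drop samples with fewer than ``min_fibroblasts`` fibroblast calls.

    The bound is strict: a sample with exactly ``min_fibroblasts`` is kept.
    """
    kept = []
    for matrix, calls in cohort:
        n_fibro = sum(c.call == "fibroblast" for c in calls)
        if n_fibro < min_fibroblasts:
            logger.info(
                "excluding sample %s: %d fibroblasts (< %d)",
                matrix.sample,
                n_fibro,
                min_fibroblasts,
            )
            continue
        kept.append((matrix, calls))
    return kept
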