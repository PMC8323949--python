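"""Two-group differential expression by Wilcoxon rank-sum test.

Significance follows the convention common in single-cell toolkits:
|log fold change| > 0.25 (strict) AND Bonferroni-adjusted P < 0.1.  The fold
change is computed on the de-logged normalized values with a pseudo-count of
1, i.e. ``log((mean(expm1 A) + 1) / (mean(expm1 B) + 1))`` in natural log, so
its scale matches thresholds stated for log-normalized data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ExpressionMatrix

__all__ = ["wilcoxon_de", "significant_de"]

LOGFC_THRESHOLD = 0.25
ADJ_P_THRESHOLD = 0.1


def _ranksum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided rank-sum P: exact for small tie-free groups, else normal
    approximation with continuity correction."""
    if a.max() == a.min() == b.max() == b.min() and a[0] == b[0]:
        return 1.0
    exact = (
        len(a) <= 25
        and len(b) <= 25
        and len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
    )
    method = "exact" if exact else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.pvalue)


def wilcoxon_de(
    matrix: ExpressionMatrix,
    group_a: list[str],
    group_b: list[str],
    layer: str = "normalized",
) -> pd.DataFrame:
    """Per-gene rank-sum DE table between two disjoint cell groups.

    Returns a frame with columns gene, logFC, p, p_adj (Bonferroni),
    direction (up/down, A relative to B) and significant.
    """
    set_a, set_b = set(group_a), set(group_b)
    if set_a & set_b:
        raise ValueError("groups overlap")
    if len(set_a) < 3 or len(set_b) < 3:
        raise ValueError("each group needs >= 3 cells")
    data = matrix.layer(layer)
    idx_a = [matrix.cells.get_loc(c) for c in group_a]
    idx_b = [matrix.cells.get_loc(c) for c in group_b]
    sub_a, sub_b = data[:, idx_a], data[:, idx_b]
    n_genes = matrix.n_genes
    logfc = np.log(
        (np.expm1(sub_a).mean(axis=1) + 1.0) / (np.expm1(sub_b).mean(axis=1) + 1.0)
    )
    pvals = np.array([_ranksum_p(sub_a[i], sub_b[i]) for i in range(n_genes)])
    p_adj = np.minimum(pvals * n_genes, 1.0)
    table = pd.DataFrame(
        {
            "gene": matrix.genes.astype(str),
            "logFC": logfc,
            "p": pvals,
            "p_adj": p_adj,
            "direction": np.where(logfc >= 0, "up", "down"),
        }
    )
    table["significant"] = (np.abs(table["logFC"]) > LOGFC_THRESHOLD) & (
        table["p_adj"] < ADJ_P_THRESHOLD
    )
    return table


def significant_de(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split the significant genes into up- and down-lists, each sorted by
    |logFC| descending."""
    sig = table.loc[table["significant"].astype(bool)]
    up = sig[sig["direction"] == "up"]
    down = sig[sig["direction"] == "down"]
    key = lambda df: df.reindex(
        df["logFC"].abs().sort_values(ascending=False).index
    ).reset_index(drop=True)
    return key(up), key(down)
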