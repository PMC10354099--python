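"""Per-cell program scoring and marker-based CSC gating.

Cells are gated into CSC / non-CSC by simple marker rules (e.g. CD44+CD24-);
each cell is then scored by ssGSEA against stemness (ESC), pluripotency
target (NANOG/MYC) and mitochondrial gene sets, and the groups compared by
Welch's two-sample t test. Counts are log1p-transformed before within-cell
ranking; dropout zeros tie at the bottom ranks and are broken
lexicographically by gene id, so scoring is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import ssgsea_matrix
from .types import ExpressionMatrix, GeneSetCollection

logger = logging.getLogger(__name__)


@dataclass
class GatingRule:
    """Ordered marker clauses: (gene, 'positive'|'negative')."""

    clauses: list[tuple[str, str]]
    name: str = "CSC"

    def __post_init__(self) -> None:
        genes = [g for g, _ in self.clauses]
        if not genes:
            raise ValueError("gating rule needs at least one clause")
        if len(set(genes)) != len(genes):
            raise ValueError("duplicate genes in gating rule")
        for _, rel in self.clauses:
            if rel not in ("positive", "negative"):
                raise ValueError(f"unknown relation {rel!r}")


def gate_cells(
    matrix: ExpressionMatrix, rule: GatingRule, threshold: float = 0.0
) -> pd.Series:
    """Label each cell CSC iff every positive marker count exceeds the
    threshold and every negative marker count does not."""
    if matrix.modality != "single_cell":
        raise ValueError("gating requires a single-cell matrix")
    index = {g: i for i, g in enumerate(matrix.gene_ids)}
    for gene, _ in rule.clauses:
        if gene not in index:
            raise KeyError(f"marker gene {gene!r} absent from the matrix")
    is_csc = np.ones(matrix.n_samples, dtype=bool)
    for gene, rel in rule.clauses:
        counts = matrix.values[index[gene]]
        is_csc &= counts > threshold if rel == "positive" else counts <= threshold
    if not is_csc.any():
        logger.warning("gating rule %r matched zero cells", rule.name)
    return pd.Series(
        np.where(is_csc, "CSC", "non-CSC"), index=matrix.sample_ids, name=rule.name
    )


def score_cells(
    matrix: ExpressionMatrix,
    collections: GeneSetCollection,
    labels: pd.Series | None = None,
    alpha: float = 0.25,
) -> pd.DataFrame:
    """Per-cell ssGSEA on log1p counts; cells x gene-set scores (+ label)."""
    if matrix.modality != "single_cell":
        raise ValueError("score_cells requires a single-cell matrix")
    logged = ExpressionMatrix(
        gene_ids=matrix.gene_ids,
        sample_ids=matrix.sample_ids,
        values=np.log1p(matrix.values),
        modality="bulk",
    )
    table = ssgsea_matrix(logged, collections, alpha=alpha)
    if labels is not None:
        table = table.copy()
        table["label"] = labels.loc[table.index]
    return table


def compare_groups(
    table: pd.DataFrame, set_name: str, label_col: str = "label"
) -> tuple[float, float, dict[str, float]]:
    """Welch two-sample t test of a score between CSC and non-CSC cells."""
    if label_col not in table.columns:
        raise ValueError("score table has no group labels")
    groups = [g for g, _ in table.groupby(label_col)]
    if len(groups) != 2:
        raise ValueError(f"expected exactly two groups, got {groups}")
    a = table.loc[table[label_col] == groups[0], set_name].to_numpy(float)
    b = table.loc[table[label_col] == groups[1], set_name].to_numpy(float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 cells")
    means = {groups[0]: float(a.mean()), groups[1]: float(b.mean())}
    if np.allclose(a.var(), 0) and np.allclose(b.var(), 0) and means[groups[0]] == means[groups[1]]:
        return 0.0, 1.0, means
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p), means
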