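"""Marker-set deconvolution of microenvironmental signals from bulk profiles.

Each cell type or program (neural signal, CRE activity, stemness, ...) is
represented by a marker gene set; its per-tumor "signal" is the ssGSEA
score of that set in the tumor's expression profile. Pairwise Pearson
correlations between signals form the correlation landscape, summarized
across cohorts as "k/n cohorts positively correlated" fractions.
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
class CorrelationLandscape:
    """Pairwise Pearson correlations between signal scores in one cohort."""

    table: pd.DataFrame  # columns: signal_a, signal_b, r, p, n
    cohort: str = "cohort"


def signal_scores(
    matrix: ExpressionMatrix,
    markers: GeneSetCollection,
    alpha: float = 0.25,
    normalize: bool = False,
) -> pd.DataFrame:
    """ssGSEA score of every marker set in every sample (samples x signals)."""
    present = set(matrix.gene_ids)
    usable = {n: g for n, g in markers if any(x in present for x in g)}
    dropped = [n for n in markers.names if n not in usable]
    if dropped:
        logger.warning("marker sets with no genes in the matrix dropped: %s", dropped)
    if not usable:
        raise ValueError("no marker set overlaps the expression matrix")
    coll = GeneSetCollection(sets=usable, category="cell_markers")
    return ssgsea_matrix(matrix, coll, alpha=alpha, normalize=normalize)


def correlate(
    table: pd.DataFrame,
    pairs: list[tuple[str, str]] | None = None,
    cohort: str = "cohort",
    min_n: int = 3,
) -> CorrelationLandscape:
    """Pearson r with two-sided p (t transform) for signal pairs.

    Uses pairwise-complete observations; constant columns are reported as
    missing with a warning.
    """
    if pairs is None:
        cols = list(table.columns)
        pairs = [(a, b) for i, a in enumerate(cols) for b in cols[i + 1 :]]
    rows = []
    for a, b in pairs:
        sub = table[[a, b]].dropna()
        n = len(sub)
        if n < min_n:
            logger.warning("pair (%s, %s) has %d < %d complete observations", a, b, n, min_n)
            rows.append((a, b, np.nan, np.nan, n))
            continue
        x, y = sub[a].to_numpy(), sub[b].to_numpy()
        if np.all(x == x[0]) or np.all(y == y[0]):
            logger.warning("pair (%s, %s): constant column, correlation undefined", a, b)
            rows.append((a, b, np.nan, np.nan, n))
            continue
        r, p = stats.pearsonr(x, y)
        rows.append((a, b, float(r), float(p), n))
    return CorrelationLandscape(
        table=pd.DataFrame(rows, columns=["signal_a", "signal_b", "r", "p", "n"]),
        cohort=cohort,
    )


def cohort_fractions(
    landscapes: list[CorrelationLandscape],
    pair: tuple[str, str],
    p_max: float = 0.05,
    direction: int = 1,
) -> tuple[str, pd.DataFrame]:
    """Count cohorts where a signal pair correlates in the given direction.

    A cohort qualifies when sign(r) == direction and p <= p_max. Returns
    the "k/n" fraction string plus the per-cohort table.
    """
    if not landscapes:
        raise ValueError("at least one cohort landscape is required")
    a, b = pair
    rows = []
    for land in landscapes:
        t = land.table
        match = t[((t.signal_a == a) & (t.signal_b == b)) | ((t.signal_a == b) & (t.signal_b == a))]
        if match.empty:
            rows.append((land.cohort, np.nan, np.nan, False))
            continue
        r, p = float(match.iloc[0]["r"]), float(match.iloc[0]["p"])
        ok = np.isfinite(r) and np.isfinite(p) and np.sign(r) == np.sign(direction) and p <= p_max
        rows.append((land.cohort, r, p, bool(ok)))
    df = pd.DataFrame(rows, columns=["cohort", "r", "p", "qualifies"])
    k = int(df["qualifies"].sum())
    return f"{k}/{len(df)}", df
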