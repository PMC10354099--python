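"""Survival association scores and Stouffer meta-z gene-signature prognosis.

Per-gene survival association is the Cox proportional-hazards score test at
beta = 0 with Breslow handling of tied event times:

    z = U(0) / sqrt(V(0)),
    U = sum over events of (x_i - mean of x over the risk set),
    V = sum over events of the risk-set variance of x.

Positive z means higher expression associates with events (worse outcome).
On a binary covariate this is exactly the two-group log-rank z. Signature
prognosis combines per-gene z with the unweighted Stouffer formula
meta-z = (sum_i Z_i) / sqrt(N) over the N signature genes present.

The optimized-cutoff Kaplan-Meier split scans a cutoff grid for the minimal
log-rank p; because scanning inflates type-I error, the minimal p is
reported together with an Altman-style selection-corrected companion.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import ExpressionMatrix, SurvivalTable

logger = logging.getLogger(__name__)


@dataclass
class MetaZResult:
    signature: str
    meta_z: float
    n_genes: int
    missing: list[str]


@dataclass
class CutoffResult:
    cutoff: float
    chi2: float
    p_min: float
    p_adjusted: float
    n_low: int
    n_high: int


def _cox_score_stats(
    x: np.ndarray, time: np.ndarray, event: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Score U and information V at beta=0 for each covariate column.

    x: (n_subjects, n_covariates). Breslow ties: every event at time t uses
    the full risk set {j : t_j >= t}.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] != len(time):
        x = x.T
    n = len(time)
    order = np.argsort(-time, kind="stable")  # descending time
    t_s, e_s, x_s = time[order], event[order], x[order]
    s1 = np.cumsum(x_s, axis=0)
    s2 = np.cumsum(x_s**2, axis=0)
    counts = np.arange(1, n + 1, dtype=float)
    # last index of each tie group in the descending order = risk-set boundary
    boundary = np.empty(n, dtype=np.intp)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and t_s[j + 1] == t_s[i]:
            j += 1
        boundary[i : j + 1] = j
        i = j + 1
    mu = s1[boundary] / counts[boundary, None]
    var = s2[boundary] / counts[boundary, None] - mu**2
    var = np.maximum(var, 0.0)
    ev = e_s == 1
    u = (x_s[ev] - mu[ev]).sum(axis=0)
    v = var[ev].sum(axis=0)
    return u, v


def gene_survival_z(
    expression: np.ndarray | pd.Series, survival: SurvivalTable
) -> float | None:
    """Cox score-test z for one continuous covariate; None when undefined."""
    x = np.asarray(expression, dtype=float)
    if len(x) != len(survival):
        raise ValueError("expression length must match survival table")
    if survival.event.sum() == 0:
        logger.warning("no events: survival z undefined")
        return None
    if np.all(x == x[0]):
        return 0.0
    u, v = _cox_score_stats(x[:, None], survival.time, survival.event)
    if v[0] <= 0:
        return 0.0
    return float(u[0] / math.sqrt(v[0]))


def gene_survival_z_matrix(matrix: ExpressionMatrix, survival: SurvivalTable) -> pd.Series:
    """Vectorized per-gene survival z over a whole expression matrix."""
    if matrix.sample_ids != survival.patient_ids:
        raise ValueError("matrix samples and survival patients must align")
    if survival.event.sum() == 0:
        raise ValueError("no events in survival table")
    u, v = _cox_score_stats(matrix.values.T, survival.time, survival.event)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(v > 0, u / np.sqrt(v), 0.0)
    return pd.Series(z, index=matrix.gene_ids, name="z")


def stouffer_meta_z(z_table: pd.Series, signature: list[str], name: str = "signature") -> MetaZResult:
    """Unweighted Stouffer combination: meta-z = (sum Z_i) / sqrt(N).

    N counts only signature genes present in the z table; omissions are
    listed and logged.
    """
    present = [g for g in signature if g in z_table.index]
    missing = [g for g in signature if g not in z_table.index]
    if not present:
        raise ValueError("no signature gene present in the z table")
    if missing:
        logger.warning("meta-z for %r: %d/%d genes missing", name, len(missing), len(signature))
    z = z_table.loc[present].to_numpy(dtype=float)
    return MetaZResult(
        signature=name,
        meta_z=float(z.sum() / math.sqrt(len(present))),
        n_genes=len(present),
        missing=missing,
    )


def logrank_test(groups: np.ndarray, survival: SurvivalTable) -> tuple[float, float]:
    """Two-group log-rank chi-square and p via the score test on a 0/1 split."""
    u, v = _cox_score_stats(np.asarray(groups, float)[:, None], survival.time, survival.event)
    if v[0] <= 0:
        return 0.0, 1.0
    chi2 = float(u[0] ** 2 / v[0])
    return chi2, float(stats.chi2.sf(chi2, df=1))


def _altman_adjusted_p(p_min: float) -> float:
    """Selection-corrected p for a minimal-p cutoff scan on the inner
    10th-90th percentile range (Altman-style); conservative clip to [p,1]."""
    if p_min <= 0:
        return 0.0
    if p_min >= 0.1:  # approximation not valid; report non-significant
        return 1.0
    adj = -1.63 * p_min * (1 + 2.35 * math.log(p_min))
    return float(min(1.0, max(p_min, adj)))


def km_optimized_cutoff(
    expression: np.ndarray | pd.Series,
    survival: SurvivalTable,
    grid: np.ndarray | None = None,
) -> CutoffResult:
    """Optimized-cutoff Kaplan-Meier split.

    Evaluates the two-group log-rank statistic at every candidate cutoff
    (default: deciles 10..90 of expression) and returns the cutoff with the
    minimal p, plus the selection-corrected p companion.
    """
    x = np.asarray(expression, dtype=float)
    if grid is None:
        grid = np.unique(np.percentile(x, np.arange(10, 91, 5)))
    lo, hi = np.percentile(x, [10, 90])
    grid = np.asarray(grid, dtype=float)
    grid = grid[(grid >= lo) & (grid <= hi)]
    best: CutoffResult | None = None
    for c in grid:
        high = (x > c).astype(float)
        n_high = int(high.sum())
        if n_high == 0 or n_high == len(x):
            continue
        chi2, p = logrank_test(high, survival)
        if best is None or p < best.p_min:
            best = CutoffResult(
                cutoff=float(c),
                chi2=chi2,
                p_min=p,
                p_adjusted=_altman_adjusted_p(p),
                n_low=len(x) - n_high,
                n_high=n_high,
            )
    if best is None:
        raise ValueError("no valid cutoff: every candidate leaves an empty group")
    return best


def signature_prognosis_panel(
    cohorts: dict[str, pd.Series],
    signatures: dict[str, list[str]],
) -> tuple[pd.DataFrame, dict[tuple[str, str], tuple[float, float]]]:
    """Meta-z of each signature in each cohort, plus paired signature tests.

    ``cohorts`` maps cohort id to a per-gene z table (computed here or
    supplied externally, e.g. precomputed pan-cancer prognostic z scores).
    Returns the cohort x signature meta-z table and, for every signature
    pair, the two-sided paired t test across cohorts (NaN, NaN when fewer
    than two cohorts are available).
    """
    rows = {}
    for cid, ztab in cohorts.items():
        rows[cid] = {
            sig: stouffer_meta_z(ztab, genes, name=sig).meta_z
            for sig, genes in signatures.items()
        }
    panel = pd.DataFrame(rows).T
    panel.index.name = "cohort"
    tests: dict[tuple[str, str], tuple[float, float]] = {}
    names = list(signatures)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if len(panel) < 2:
                logger.warning("paired test (%s, %s) undefined with one cohort", a, b)
                tests[(a, b)] = (float("nan"), float("nan"))
                continue
            diff = panel[a] - panel[b]
            if np.allclose(diff, 0):
                tests[(a, b)] = (0.0, 1.0)
                continue
            t, p = stats.ttest_rel(panel[a], panel[b])
            tests[(a, b)] = (float(t), float(p))
    return panel, tests
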