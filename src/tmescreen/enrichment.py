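"""Single-sample and two-class gene-set enrichment statistics.

Implements from scratch:

* ssGSEA — the weighted cumulative-rank difference between in-set and
  out-of-set genes, summed over all ranked positions:
  ``ES = sum_i [P_in(i) - P_out(i)]`` with ``P_in`` the cumulative
  ``|rank score|^alpha``-weighted fraction of set genes and ``P_out`` the
  cumulative uniform fraction of the remaining genes.
* GSEA — the maximum-magnitude deviation of the weighted Kolmogorov-Smirnov
  running sum, with gene-set or phenotype permutation significance,
  normalized enrichment scores and a permutation-based FDR.
* Hypergeometric over-representation and Benjamini-Hochberg FDR.

All ties in gene ranking are broken lexicographically by gene id so every
result is fully deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import ExpressionMatrix, GeneSetCollection

logger = logging.getLogger(__name__)

DEFAULT_SSGSEA_ALPHA = 0.25  # original ssGSEA weighting; 0.75 also common
DEFAULT_GSEA_EXPONENT = 1.0


@dataclass
class RankedProfile:
    """Genes ordered by descending ranking score, ties broken by gene id."""

    genes: list[str]
    scores: np.ndarray  # aligned with `genes`, descending

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.genes) != len(self.scores):
            raise ValueError("gene/score length mismatch")


@dataclass
class EnrichmentResult:
    unit: str
    set_name: str
    es: float
    nes: float | None = None
    p_nominal: float | None = None
    q_fdr: float | None = None
    recurrence: int | None = None
    extras: dict = field(default_factory=dict)


def _descending_order(values: np.ndarray, gene_ids: np.ndarray) -> np.ndarray:
    """Indices sorting by descending value, lexicographic gene id on ties."""
    # lexsort uses the last key as primary
    return np.lexsort((gene_ids, -values))


def rank_profile(matrix: ExpressionMatrix, sample: str) -> RankedProfile:
    """Rank one sample's genes by descending expression."""
    try:
        col = matrix.sample_ids.index(sample)
    except ValueError:
        raise KeyError(f"unknown sample {sample!r}") from None
    values = matrix.values[:, col]
    gene_ids = np.asarray(matrix.gene_ids)
    if np.all(values == values[0]):
        logger.warning("sample %r has a constant profile; ranking is degenerate", sample)
    order = _descending_order(values, gene_ids)
    return RankedProfile(genes=[matrix.gene_ids[i] for i in order], scores=values[order])


# ---------------------------------------------------------------------------
# ssGSEA


def ssgsea_score(profile: RankedProfile, gene_set: list[str], alpha: float = DEFAULT_SSGSEA_ALPHA) -> float:
    """ssGSEA enrichment score for one ranked profile and one gene set."""
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    members = set(gene_set)
    in_set = np.array([g in members for g in profile.genes])
    n_in = int(in_set.sum())
    n = len(profile.genes)
    if n_in == 0:
        raise ValueError("gene set absent from profile")
    if n_in == n:
        raise ValueError("gene set covers the whole universe")
    w = np.abs(profile.scores) ** alpha
    w_in = np.where(in_set, w, 0.0)
    p_in = np.cumsum(w_in) / w_in.sum()
    p_out = np.cumsum(~in_set) / (n - n_in)
    return float(np.sum(p_in - p_out))


def _rank_weight_matrix(matrix: ExpressionMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample descending order and positional rank scores.

    Ranking scores are cross-gene ranks within a sample (top gene gets rank
    G, bottom gene rank 1), which makes scores comparable across platforms.
    The rank score at ordered position i is therefore G - i for every
    sample, so only the ordering varies per sample.
    """
    gene_ids = np.asarray(matrix.gene_ids)
    n_genes, n_samples = matrix.values.shape
    order = np.empty((n_genes, n_samples), dtype=np.intp)
    for j in range(n_samples):
        order[:, j] = _descending_order(matrix.values[:, j], gene_ids)
    rank_scores = np.arange(n_genes, 0, -1, dtype=float)
    return order, rank_scores


def ssgsea_matrix(
    matrix: ExpressionMatrix,
    collection: GeneSetCollection,
    alpha: float = DEFAULT_SSGSEA_ALPHA,
    normalize: bool = False,
) -> pd.DataFrame:
    """ssGSEA scores for every (sample, gene set) pair.

    Scores use within-sample expression ranks as ranking scores. With
    ``normalize=True`` each set's scores are rescaled by the cross-sample
    range (min-max within set). Sets absent from the matrix are recorded as
    missing (NaN column) with a warning rather than aborting.
    """
    order, rank_scores = _rank_weight_matrix(matrix)
    n_genes, n_samples = matrix.values.shape
    w = rank_scores**alpha  # identical positional weights for all samples
    gene_index = {g: i for i, g in enumerate(matrix.gene_ids)}

    out = pd.DataFrame(index=matrix.sample_ids, columns=collection.names, dtype=float)
    for name, genes in collection:
        rows = [gene_index[g] for g in genes if g in gene_index]
        n_in = len(rows)
        if n_in == 0 or n_in == n_genes:
            logger.warning("gene set %r skipped (absent or covers universe)", name)
            out[name] = np.nan
            continue
        membership = np.zeros(n_genes, dtype=bool)
        membership[rows] = True
        m = membership[order]  # (genes, samples) in ranked order
        w_in = np.where(m, w[:, None], 0.0)
        p_in = np.cumsum(w_in, axis=0) / w_in.sum(axis=0)
        p_out = np.cumsum(~m, axis=0) / (n_genes - n_in)
        out[name] = np.sum(p_in - p_out, axis=0)
    if normalize:
        rng = out.max(axis=0) - out.min(axis=0)
        rng = rng.replace(0.0, 1.0)
        out = (out - out.min(axis=0)) / rng
    return out


# ---------------------------------------------------------------------------
# Two-class GSEA


def gsea_es(
    ranked: RankedProfile,
    gene_set: list[str],
    p_exponent: float = DEFAULT_GSEA_EXPONENT,
) -> tuple[float, np.ndarray]:
    """Weighted Kolmogorov-Smirnov enrichment score and its running sum."""
    members = set(gene_set)
    in_set = np.array([g in members for g in ranked.genes])
    n_in = int(in_set.sum())
    n = len(ranked.genes)
    if n_in == 0:
        raise ValueError("gene set absent from profile")
    if n_in == n:
        raise ValueError("gene set covers the whole universe")
    running = _running_sum(in_set, np.abs(ranked.scores) ** p_exponent)
    es = running[np.argmax(np.abs(running))]
    return float(es), running


def _running_sum(in_set: np.ndarray, weights: np.ndarray) -> np.ndarray:
    w_in = np.where(in_set, weights, 0.0)
    total = w_in.sum()
    if total == 0:  # all weights zero inside the set: fall back to uniform
        w_in = in_set.astype(float)
        total = w_in.sum()
    p_hit = np.cumsum(w_in) / total
    p_miss = np.cumsum(~in_set) / (len(in_set) - in_set.sum())
    return p_hit - p_miss


def _es_batch(membership: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """ES for many same-universe sets at once.

    membership: (n_sets, n_genes) boolean in ranked order.
    weights: (n_genes,) |metric|^p in ranked order.
    """
    w_in = membership * weights
    totals = w_in.sum(axis=1, keepdims=True)
    zero = (totals == 0).ravel()
    if zero.any():  # all in-set weights zero: fall back to uniform steps
        w_in[zero] = membership[zero].astype(float)
        totals = w_in.sum(axis=1, keepdims=True)
    p_hit = np.cumsum(w_in, axis=1) / totals
    n_out = (~membership).sum(axis=1, keepdims=True)
    p_miss = np.cumsum(~membership, axis=1) / n_out
    dev = p_hit - p_miss
    idx = np.argmax(np.abs(dev), axis=1)
    return dev[np.arange(dev.shape[0]), idx]


def signal_to_noise(
    matrix: ExpressionMatrix, labels: list[str], positive_class: str
) -> np.ndarray:
    """Signal-to-noise ranking metric with desktop-style variance floors.

    (mu_pos - mu_neg) / (sd_pos + sd_neg), each sd floored at 0.2*|mu|
    (0.2 when the mean is zero) so single-replicate classes stay defined.
    """
    lab = np.asarray(labels)
    if len(lab) != matrix.n_samples:
        raise ValueError("labels length must match samples")
    pos = matrix.values[:, lab == positive_class]
    neg = matrix.values[:, lab != positive_class]
    if pos.shape[1] < 1 or neg.shape[1] < 1:
        raise ValueError("both classes need at least one sample")

    def _floored_sd(x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=1)
        sd = x.std(axis=1, ddof=1) if x.shape[1] > 1 else np.zeros(x.shape[0])
        floor = 0.2 * np.abs(mu)
        floor[floor == 0] = 0.2
        return np.maximum(sd, floor)

    return (pos.mean(axis=1) - neg.mean(axis=1)) / (_floored_sd(pos) + _floored_sd(neg))


def rank_by_metric(matrix: ExpressionMatrix, metric: np.ndarray) -> RankedProfile:
    gene_ids = np.asarray(matrix.gene_ids)
    order = _descending_order(metric, gene_ids)
    return RankedProfile(genes=[matrix.gene_ids[i] for i in order], scores=metric[order])


def gsea_significance(
    matrix: ExpressionMatrix,
    labels: list[str],
    gene_set: list[str],
    positive_class: str,
    n_perm: int = 1000,
    mode: str = "gene_set",
    seed: int | None = None,
    p_exponent: float = DEFAULT_GSEA_EXPONENT,
) -> EnrichmentResult:
    """Permutation GSEA for a single gene set (sphere-vs-adherent style).

    Nominal p uses the +1/(n+1) estimator over same-signed permutation ES;
    NES = ES / mean(|same-signed permuted ES|). With a single set the FDR
    reduces to the permutation NES tail probability.
    """
    collection = GeneSetCollection(sets={"set": list(gene_set)})
    res = gsea_collection(
        matrix,
        labels,
        collection,
        positive_class,
        n_perm=n_perm,
        mode=mode,
        seed=seed,
        p_exponent=p_exponent,
    )
    row = res.iloc[0]
    return EnrichmentResult(
        unit=f"{positive_class}_vs_rest",
        set_name="set",
        es=float(row["es"]),
        nes=float(row["nes"]),
        p_nominal=float(row["p_nominal"]),
        q_fdr=float(row["q_fdr"]),
    )


def gsea_collection(
    matrix: ExpressionMatrix,
    labels: list[str],
    collection: GeneSetCollection,
    positive_class: str,
    n_perm: int = 1000,
    mode: str = "gene_set",
    seed: int | None = None,
    p_exponent: float = DEFAULT_GSEA_EXPONENT,
) -> pd.DataFrame:
    """Permutation GSEA for every set in a collection against one contrast.

    Returns a DataFrame indexed by set name with columns es, nes,
    p_nominal, q_fdr, n_genes. FDR follows the GSEA convention of pooling
    normalized permutation scores across sets.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    lab = np.asarray(labels)
    n_pos = int((lab == positive_class).sum())
    n_neg = len(lab) - n_pos
    if n_pos < 1 or n_neg < 1:
        raise ValueError("both classes must be present")
    if mode == "phenotype" and min(n_pos, n_neg) < 3:
        logger.warning(
            "phenotype permutation with <3 samples per class; falling back to gene_set mode"
        )
        mode = "gene_set"
    if mode not in ("gene_set", "phenotype"):
        raise ValueError(f"unknown permutation mode {mode!r}")

    rng = np.random.default_rng(seed)
    metric = signal_to_noise(matrix, labels, positive_class)
    ranked = rank_by_metric(matrix, metric)
    weights = np.abs(ranked.scores) ** p_exponent
    gene_pos = {g: i for i, g in enumerate(ranked.genes)}
    n_genes = len(ranked.genes)

    names, sizes, memberships = [], [], []
    for name, genes in collection:
        rows = [gene_pos[g] for g in genes if g in gene_pos]
        if not rows or len(rows) == n_genes:
            logger.warning("gene set %r skipped in GSEA (absent or full universe)", name)
            continue
        m = np.zeros(n_genes, dtype=bool)
        m[rows] = True
        names.append(name)
        sizes.append(len(rows))
        memberships.append(m)
    if not names:
        raise ValueError("no usable gene sets")
    membership = np.array(memberships)
    obs_es = _es_batch(membership, weights)

    if mode == "gene_set":
        null_es = _geneset_null(sizes, weights, n_perm, rng)
    else:
        null_es = _phenotype_null(
            matrix, lab, positive_class, membership, n_perm, rng, p_exponent
        )

    return _summarize_permutations(names, sizes, obs_es, null_es)


def _geneset_null(
    sizes: list[int], weights: np.ndarray, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Null ES per set from random same-size gene sets. Shape (n_sets, n_perm)."""
    n_genes = len(weights)
    unique_sizes = sorted(set(sizes))
    null_by_size: dict[int, np.ndarray] = {}
    for m in unique_sizes:
        picks = np.argsort(rng.random((n_perm, n_genes)), axis=1)[:, :m]
        memb = np.zeros((n_perm, n_genes), dtype=bool)
        np.put_along_axis(memb, picks, True, axis=1)
        null_by_size[m] = _es_batch(memb, weights)
    return np.array([null_by_size[m] for m in sizes])


def _phenotype_null(
    matrix: ExpressionMatrix,
    lab: np.ndarray,
    positive_class: str,
    membership_by_gene: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
    p_exponent: float,
) -> np.ndarray:
    gene_ids = np.asarray(matrix.gene_ids)
    # membership_by_gene is in observed ranked order; map back to gene order
    n_sets, n_genes = membership_by_gene.shape
    metric = signal_to_noise(matrix, list(lab), positive_class)
    obs_order = _descending_order(metric, gene_ids)
    member_gene_order = np.zeros((n_sets, n_genes), dtype=bool)
    member_gene_order[:, obs_order] = membership_by_gene
    null = np.empty((n_sets, n_perm))
    for k in range(n_perm):
        perm_lab = rng.permutation(lab)
        m = signal_to_noise(matrix, list(perm_lab), positive_class)
        order = _descending_order(m, gene_ids)
        w = np.abs(m[order]) ** p_exponent
        null[:, k] = _es_batch(member_gene_order[:, order], w)
    return null


def _summarize_permutations(
    names: list[str], sizes: list[int], obs_es: np.ndarray, null_es: np.ndarray
) -> pd.DataFrame:
    n_sets, n_perm = null_es.shape
    p_nom = np.empty(n_sets)
    nes = np.empty(n_sets)
    null_nes = np.empty_like(null_es)
    for i in range(n_sets):
        same_sign = null_es[i] * np.sign(obs_es[i]) >= 0 if obs_es[i] != 0 else np.ones(n_perm, bool)
        extreme = same_sign & (np.abs(null_es[i]) >= abs(obs_es[i]))
        p_nom[i] = (extreme.sum() + 1) / (n_perm + 1)
        pos_mean = np.abs(null_es[i][null_es[i] >= 0]).mean() if (null_es[i] >= 0).any() else np.nan
        neg_mean = np.abs(null_es[i][null_es[i] < 0]).mean() if (null_es[i] < 0).any() else np.nan
        denom = pos_mean if obs_es[i] >= 0 else neg_mean
        if not np.isfinite(denom) or denom == 0:
            denom = np.abs(null_es[i]).mean() or 1.0
        nes[i] = obs_es[i] / denom
        with np.errstate(invalid="ignore", divide="ignore"):
            null_nes[i] = np.where(
                null_es[i] >= 0,
                null_es[i] / (pos_mean if np.isfinite(pos_mean) and pos_mean > 0 else 1.0),
                null_es[i] / (neg_mean if np.isfinite(neg_mean) and neg_mean > 0 else 1.0),
            )
    q = _gsea_fdr(nes, null_nes)
    return pd.DataFrame(
        {"es": obs_es, "nes": nes, "p_nominal": p_nom, "q_fdr": q, "n_genes": sizes},
        index=pd.Index(names, name="set"),
    )


def _gsea_fdr(nes: np.ndarray, null_nes: np.ndarray) -> np.ndarray:
    """GSEA-style FDR: pooled null-NES tail over observed-NES tail, clipped."""
    pooled = null_nes.ravel()
    pooled = pooled[np.isfinite(pooled)]
    q = np.empty_like(nes)
    for i, v in enumerate(nes):
        if v >= 0:
            null_frac = np.mean(pooled[pooled >= 0] >= v) if (pooled >= 0).any() else 1.0
            obs_frac = np.mean(nes[nes >= 0] >= v)
        else:
            null_frac = np.mean(pooled[pooled < 0] <= v) if (pooled < 0).any() else 1.0
            obs_frac = np.mean(nes[nes < 0] <= v)
        q[i] = min(1.0, null_frac / obs_frac) if obs_frac > 0 else 1.0
    return q


# ---------------------------------------------------------------------------
# Over-representation and FDR


def hypergeom_enrichment(hits: list[str], gene_set: list[str], universe: list[str]) -> float:
    """Upper-tail hypergeometric p for over-representation of a set in hits."""
    if not universe:
        raise ValueError("empty universe")
    uni = set(universe)
    hit_set = set(hits) & uni
    if set(hits) - uni:
        raise ValueError("hits must be a subset of the universe")
    members = set(gene_set) & uni
    overlap = len(hit_set & members)
    if len(members) == 0:
        return 1.0
    # P[X >= overlap], X ~ Hypergeom(M=|universe|, n=|set|, N=|hits|)
    return float(stats.hypergeom.sf(overlap - 1, len(uni), len(members), len(hit_set)))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, clipped to 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q
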