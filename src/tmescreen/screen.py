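"""Two-arm screen for microenvironment-responsive stemness transcription factors.

Arm A ("in vivo"): rank tumors by a stemness score, find genes highly
expressed in stemness-high tumors, and test each transcription factor's
target set for over-representation among them (hypergeometric, P < 0.01 and
BH FDR q < 0.05 by default).

Arm B ("functional"): in paired sphere/adherent expression datasets, run
permutation GSEA of each TF target set on the sphere-vs-adherent contrast;
a factor is functional when its targets are positively enriched in spheres
(nominal P < 0.05, NES > 0) in at least ``min_datasets`` datasets.

The intersection of the two arms is the screen's output — the
TME-responsive stemness factors.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import bh_fdr, gsea_collection, hypergeom_enrichment, ssgsea_matrix
from .types import ExpressionMatrix, GeneSetCollection

logger = logging.getLogger(__name__)

DEFAULT_ARM_A_P = 0.01
DEFAULT_ARM_A_Q = 0.05
DEFAULT_ARM_B_P = 0.05
DEFAULT_SPLIT_FRACTION = 0.25
DEFAULT_MIN_LOG_FC = math.log2(1.5)  # 1.5-fold floor on the log2 scale


@dataclass
class StemnessScoreVector:
    """Per-sample stemness score with a tag naming the scorer."""

    scores: pd.Series
    scorer: str = "signature_ssgsea"


@dataclass
class ScreenReport:
    arm_a: pd.DataFrame  # factor, p, q
    arm_b: pd.DataFrame  # factor, recurrence, best_p, best_nes
    intersection: list[str]
    cutoffs: dict = field(default_factory=dict)

    @property
    def counts(self) -> tuple[int, int, int]:
        return len(self.arm_a), len(self.arm_b), len(self.intersection)

    def to_dict(self) -> dict:
        return {
            "n_arm_a": len(self.arm_a),
            "n_arm_b": len(self.arm_b),
            "n_intersection": len(self.intersection),
            "arm_a_factors": sorted(self.arm_a["factor"]),
            "arm_b_factors": sorted(self.arm_b["factor"]),
            "intersection": sorted(self.intersection),
            "cutoffs": self.cutoffs,
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def stemness_score(
    matrix: ExpressionMatrix,
    signature: list[str] | None = None,
    external: pd.Series | None = None,
    alpha: float = 0.25,
) -> StemnessScoreVector:
    """Per-sample stemness index.

    Default scorer is signature ssGSEA; an externally computed score table
    (e.g. a machine-learning stemness index) passes through unchanged.
    """
    if external is not None:
        missing = [s for s in matrix.sample_ids if s not in external.index]
        if missing:
            raise ValueError(f"external scores missing samples: {missing[:5]}")
        return StemnessScoreVector(scores=external.loc[matrix.sample_ids].astype(float), scorer="external")
    if signature is None:
        raise ValueError("either a signature or an external score table is required")
    present = [g for g in signature if g in set(matrix.gene_ids)]
    if not present:
        raise ValueError("stemness signature has zero overlap with the matrix")
    if len(present) < 0.5 * len(signature):
        logger.warning(
            "stemness signature overlaps only %d/%d genes", len(present), len(signature)
        )
    coll = GeneSetCollection(sets={"stemness": list(signature)}, category="signature")
    scores = ssgsea_matrix(matrix, coll, alpha=alpha)["stemness"]
    return StemnessScoreVector(scores=scores, scorer="signature_ssgsea")


def split_high_low(scores: pd.Series, fraction: float = DEFAULT_SPLIT_FRACTION) -> pd.Series:
    """Label top-`fraction` samples high, bottom-`fraction` low, rest mid.

    Boundary ties resolve by stable sample order (mergesort).
    """
    if not 0 < fraction <= 0.5:
        raise ValueError("fraction must be in (0, 0.5]")
    n = len(scores)
    k = int(round(fraction * n))
    if k < 2:
        raise ValueError("fewer than 2 samples per arm at this fraction")
    if scores.nunique() == 1:
        logger.warning("all stemness scores equal; high/low split is arbitrary but stable")
    order = np.argsort(-scores.to_numpy(), kind="stable")
    labels = pd.Series("mid", index=scores.index, dtype=object)
    labels.iloc[order[:k]] = "high"
    labels.iloc[order[-k:]] = "low"
    return labels


def high_genes(
    matrix: ExpressionMatrix,
    labels: pd.Series,
    min_log_fc: float = DEFAULT_MIN_LOG_FC,
    max_p: float = 0.01,
) -> list[str]:
    """Genes highly expressed in the high group vs the low group.

    Two-sided Wilcoxon rank-sum p <= max_p and mean(high) - mean(low) >=
    min_log_fc, sorted by effect size (descending).
    """
    lab = labels.loc[matrix.sample_ids]
    hi = matrix.values[:, (lab == "high").to_numpy()]
    lo = matrix.values[:, (lab == "low").to_numpy()]
    if hi.shape[1] == 0 or lo.shape[1] == 0:
        raise ValueError("high and low groups must be non-empty")
    effect = hi.mean(axis=1) - lo.mean(axis=1)
    keep_fc = effect >= min_log_fc
    p = np.ones(matrix.n_genes)
    if keep_fc.any():
        res = stats.mannwhitneyu(hi[keep_fc], lo[keep_fc], axis=1, alternative="two-sided")
        p[keep_fc] = res.pvalue
    keep = keep_fc & (p <= max_p)
    genes = np.asarray(matrix.gene_ids)[keep]
    return list(genes[np.argsort(-effect[keep], kind="stable")])


def arm_a_tme_factors(
    high_gene_list: list[str],
    tf_targets: GeneSetCollection,
    universe: list[str],
    p_cut: float = DEFAULT_ARM_A_P,
    q_cut: float = DEFAULT_ARM_A_Q,
) -> pd.DataFrame:
    """TFs whose target sets are over-represented among stemness-high genes."""
    if not high_gene_list:
        logger.warning("empty high-gene list: arm A returns no factors")
        return pd.DataFrame(columns=["factor", "p", "q", "overlap"])
    rows = []
    for name, genes in tf_targets:
        uni = set(universe)
        overlap = len(set(high_gene_list) & set(genes) & uni)
        p = hypergeom_enrichment(high_gene_list, genes, universe)
        rows.append((name, p, overlap))
    df = pd.DataFrame(rows, columns=["factor", "p", "overlap"])
    df["q"] = bh_fdr(df["p"].to_numpy())
    df = df[(df["p"] <= p_cut) & (df["q"] <= q_cut)]
    return df.sort_values("p", kind="stable").reset_index(drop=True)[
        ["factor", "p", "q", "overlap"]
    ]


def default_min_datasets(n_datasets: int) -> int:
    """Recurrence floor: a factor must qualify in >= 30% of datasets."""
    return max(1, math.ceil(0.3 * n_datasets))


def arm_b_functional_factors(
    paired_datasets: list[tuple[ExpressionMatrix, list[str]]],
    tf_targets: GeneSetCollection,
    p_cut: float = DEFAULT_ARM_B_P,
    min_datasets: int | None = None,
    sphere_label: str = "sphere",
    n_perm: int = 200,
    seed: int | None = None,
) -> pd.DataFrame:
    """Functional stemness factors from sphere-vs-adherent GSEA recurrence.

    Each dataset is a (matrix, labels) pair with labels naming sphere and
    adherent samples. A factor qualifies in a dataset when its target set
    has nominal p <= p_cut with positive NES on the sphere side.
    """
    rng = np.random.default_rng(seed)
    per_dataset: list[pd.DataFrame] = []
    for i, (matrix, labels) in enumerate(paired_datasets):
        classes = set(labels)
        if sphere_label not in classes or len(classes) < 2:
            logger.warning("dataset %d skipped: needs sphere and adherent classes", i)
            continue
        res = gsea_collection(
            matrix,
            labels,
            tf_targets,
            positive_class=sphere_label,
            n_perm=n_perm,
            mode="gene_set",
            seed=int(rng.integers(2**31 - 1)),
        )
        res["dataset"] = i
        per_dataset.append(res.reset_index())
    if not per_dataset:
        return pd.DataFrame(columns=["factor", "recurrence", "best_p", "best_nes"])
    all_res = pd.concat(per_dataset, ignore_index=True)
    qual = all_res[(all_res["p_nominal"] <= p_cut) & (all_res["nes"] > 0)]
    if min_datasets is None:
        min_datasets = default_min_datasets(len(per_dataset))
    rows = []
    for factor, grp in qual.groupby("set"):
        rows.append(
            (factor, len(grp), float(grp["p_nominal"].min()), float(grp["nes"].max()))
        )
    df = pd.DataFrame(rows, columns=["factor", "recurrence", "best_p", "best_nes"])
    df = df[df["recurrence"] >= min_datasets]
    return df.sort_values(
        ["recurrence", "best_p"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)


def intersect_factors(
    arm_a: pd.DataFrame,
    arm_b: pd.DataFrame,
    cutoffs: dict | None = None,
) -> ScreenReport:
    """Intersect the two arms into the final screen report."""
    a = set(arm_a["factor"]) if len(arm_a) else set()
    b = set(arm_b["factor"]) if len(arm_b) else set()
    inter = sorted(a & b)
    return ScreenReport(
        arm_a=arm_a.reset_index(drop=True),
        arm_b=arm_b.reset_index(drop=True),
        intersection=inter,
        cutoffs=cutoffs or {},
    )


def run_screen(
    cohort: ExpressionMatrix,
    stemness_signature: list[str],
    paired_datasets: list[tuple[ExpressionMatrix, list[str]]],
    tf_targets: GeneSetCollection,
    *,
    split_fraction: float = DEFAULT_SPLIT_FRACTION,
    min_log_fc: float = DEFAULT_MIN_LOG_FC,
    high_gene_p: float = 0.01,
    arm_a_p: float = DEFAULT_ARM_A_P,
    arm_a_q: float = DEFAULT_ARM_A_Q,
    arm_b_p: float = DEFAULT_ARM_B_P,
    min_datasets: int | None = None,
    n_perm: int = 200,
    seed: int | None = None,
) -> ScreenReport:
    """Full two-arm screen on one cohort plus paired sphere/adherent sets."""
    scores = stemness_score(cohort, signature=stemness_signature)
    labels = split_high_low(scores.scores, fraction=split_fraction)
    hits = high_genes(cohort, labels, min_log_fc=min_log_fc, max_p=high_gene_p)
    arm_a = arm_a_tme_factors(hits, tf_targets, cohort.gene_ids, p_cut=arm_a_p, q_cut=arm_a_q)
    arm_b = arm_b_functional_factors(
        paired_datasets,
        tf_targets,
        p_cut=arm_b_p,
        min_datasets=min_datasets,
        n_perm=n_perm,
        seed=seed,
    )
    cutoffs = {
        "split_fraction": split_fraction,
        "min_log_fc": min_log_fc,
        "high_gene_p": high_gene_p,
        "arm_a_p": arm_a_p,
        "arm_a_q": arm_a_q,
        "arm_b_p": arm_b_p,
        "min_datasets": min_datasets or default_min_datasets(len(paired_datasets)),
        "n_perm": n_perm,
    }
    return intersect_factors(arm_a, arm_b, cutoffs=cutoffs)
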