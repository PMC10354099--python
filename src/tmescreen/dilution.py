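"""Single-hit Poisson limiting-dilution analysis (ELDA-style).

A well seeded with ``d`` cells responds (forms a sphere / engrafts) with
probability ``1 - exp(-lambda * d)``, where ``lambda`` is the frequency of
active (stem-like) cells per cell; frequencies are conventionally displayed
as "1/x" with x = 1/lambda. The per-group maximum-likelihood estimate of
lambda is found by safeguarded Newton iteration on log(lambda), with Wald
confidence intervals on the log scale and likelihood-based one-sided
intervals at the boundaries (no responding well / no negative well).
Groups are compared with a likelihood-ratio chi-square test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .types import DilutionAssay

logger = logging.getLogger(__name__)

# dose ladders in cells per replicate: in vitro sphere assay wells and
# in vivo injections (100 uL of 5e5/1e5/1e4/1e3 per mL suspensions)
IN_VITRO_DOSES = (100.0, 50.0, 25.0, 12.0, 6.0, 3.0, 1.0)
IN_VIVO_DOSES = (50000.0, 10000.0, 1000.0, 100.0)

LAMBDA_MAX = 1.0  # at most one active cell per cell
_SCORE_TOL = 1e-10
_CHI2_95_HALF = stats.chi2.ppf(0.95, 1) / 2  # likelihood drop for 95% bounds


@dataclass
class FrequencyEstimate:
    group: str
    lam: float  # active cells per cell
    ci_low: float
    ci_high: float
    loglik: float
    flags: list[str] = field(default_factory=list)
    gof_chi2: float | None = None
    gof_p: float | None = None

    @property
    def frequency_display(self) -> str:
        if self.lam <= 0:
            return "1/inf"
        return f"1/{1.0 / self.lam:.1f}"


@dataclass
class GroupComparison:
    groups: list[str]
    chi2: float
    df: int
    p: float


def _loglik(lam: float, dose: np.ndarray, n: np.ndarray, x: np.ndarray) -> float:
    if lam <= 0:
        return 0.0 if x.sum() == 0 else -np.inf
    ld = lam * dose
    with np.errstate(over="ignore"):
        log1mexp = np.where(ld > 1e-8, np.log1p(-np.exp(-ld)), np.log(ld))
    return float(np.sum(x * log1mexp - (n - x) * ld))


def _score(lam: float, dose: np.ndarray, n: np.ndarray, x: np.ndarray) -> float:
    """d loglik / d lambda."""
    ld = lam * dose
    with np.errstate(over="ignore"):
        em1 = np.expm1(ld)
    term = np.where(em1 > 0, x * dose / np.where(em1 > 0, em1, 1.0), x * dose / np.maximum(ld, 1e-300))
    return float(np.sum(term - (n - x) * dose))


def _information(lam: float, dose: np.ndarray, n: np.ndarray, x: np.ndarray) -> float:
    """Observed information on log(lambda) at an interior MLE."""
    ld = lam * dose
    em = np.exp(-ld)  # stable: e/(e-1)^2 == em/(1-em)^2
    denom = np.square(-np.expm1(-ld))
    d2 = np.sum(np.where(denom > 0, x * dose**2 * em / np.maximum(denom, 1e-300), 0.0))
    return float(lam**2 * d2)


def fit_single_hit(assay: DilutionAssay, group: str, conf: float = 0.95) -> FrequencyEstimate:
    """Maximum-likelihood single-hit frequency for one assay group."""
    dose, n, x = assay.rows_for(group)
    flags: list[str] = []

    if x.sum() == 0:  # likelihood is monotone decreasing in lambda
        upper = _CHI2_95_HALF / float(np.sum(n * dose))
        return FrequencyEstimate(
            group=group, lam=0.0, ci_low=0.0, ci_high=upper,
            loglik=0.0, flags=["boundary", "all_negative"],
        )
    if np.all(x == n):  # likelihood is monotone increasing in lambda
        lam = LAMBDA_MAX
        ll = _loglik(lam, dose, n, x)
        lo = _profile_lower(lam, ll, dose, n, x)
        return FrequencyEstimate(
            group=group, lam=lam, ci_low=lo, ci_high=LAMBDA_MAX,
            loglik=ll, flags=["boundary", "all_positive"],
        )

    lam = _newton_mle(dose, n, x)
    ll = _loglik(lam, dose, n, x)
    if lam >= LAMBDA_MAX - 1e-12:
        flags.append("boundary")
        lo = _profile_lower(lam, ll, dose, n, x)
        est = FrequencyEstimate(group=group, lam=lam, ci_low=lo, ci_high=LAMBDA_MAX,
                                loglik=ll, flags=flags)
    else:
        info = _information(lam, dose, n, x)
        z = stats.norm.ppf(0.5 + conf / 2)
        if info > 0:
            half = z / math.sqrt(info)
            lo, hi = math.exp(math.log(lam) - half), math.exp(math.log(lam) + half)
        else:  # separation: flat curvature
            flags.append("separation")
            lo, hi = 0.0, LAMBDA_MAX
        est = FrequencyEstimate(group=group, lam=lam, ci_low=lo, ci_high=min(hi, LAMBDA_MAX),
                                loglik=ll, flags=flags)
    est.gof_chi2, est.gof_p = _goodness_of_fit(est.lam, dose, n, x)
    return est


def _newton_mle(dose: np.ndarray, n: np.ndarray, x: np.ndarray) -> float:
    """Safeguarded Newton on log(lambda); bisection fallback on the score.

    The score in lambda is strictly decreasing (concave log-likelihood), so
    the root is bracketed once the score changes sign.
    """
    lo, hi = 1e-12, LAMBDA_MAX
    if _score(hi, dose, n, x) >= 0:
        return LAMBDA_MAX
    if _score(lo, dose, n, x) <= 0:
        return lo
    # initialize from the highest-response dose
    p_hat = np.clip(x.sum() / n.sum(), 1e-6, 1 - 1e-6)
    lam = np.clip(-math.log(1 - p_hat) / float(np.average(dose, weights=n)), lo, hi)
    for _ in range(100):
        s = _score(lam, dose, n, x)
        if abs(s) < _SCORE_TOL:
            break
        if s > 0:
            lo = lam
        else:
            hi = lam
        info = _information(lam, dose, n, x)
        # Newton step on theta = log(lambda): dl/dtheta = lam * score
        step = lam * s / info if info > 0 else 0.0
        cand = lam * math.exp(np.clip(step, -5, 5)) if info > 0 else 0.0
        if not (lo < cand < hi):
            cand = math.sqrt(lo * hi)  # bisect in log space
        lam = cand
    return float(lam)


def _profile_lower(lam_hat: float, ll_hat: float, dose, n, x) -> float:
    """Likelihood-based lower bound when the MLE sits at the upper boundary."""
    target = ll_hat - _CHI2_95_HALF
    lo, hi = 1e-12, lam_hat
    if _loglik(lo, dose, n, x) >= target:
        return lo
    for _ in range(200):
        mid = math.sqrt(lo * hi)
        if _loglik(mid, dose, n, x) < target:
            lo = mid
        else:
            hi = mid
    return float(hi)


def _goodness_of_fit(lam, dose, n, x) -> tuple[float | None, float | None]:
    """Pearson chi-square of observed vs fitted per-dose responses.

    Secondary check of the single-hit assumption; df = n_doses - 1.
    """
    p = 1 - np.exp(-lam * dose)
    ok = (p > 1e-12) & (p < 1 - 1e-12)
    if ok.sum() < 2:
        return None, None
    chi2 = float(np.sum((x[ok] - n[ok] * p[ok]) ** 2 / (n[ok] * p[ok] * (1 - p[ok]))))
    df = int(ok.sum()) - 1
    return chi2, float(stats.chi2.sf(chi2, df)) if df > 0 else (chi2, None)[1]


def compare_frequencies(assay: DilutionAssay, groups: list[str] | None = None) -> GroupComparison:
    """Likelihood-ratio test of equal active-cell frequency across groups."""
    if groups is None:
        groups = assay.groups
    if len(groups) < 2:
        raise ValueError("at least two groups are required")
    fitted: dict[str, FrequencyEstimate] = {}
    for g in groups:
        try:
            fitted[g] = fit_single_hit(assay, g)
        except Exception as exc:  # pragma: no cover - defensive
            logger.warning("group %r excluded from comparison: %s", g, exc)
    if len(fitted) < 2:
        raise ValueError("fewer than two groups could be fitted")
    per_group_ll = sum(est.loglik for est in fitted.values())
    dose = np.concatenate([assay.rows_for(g)[0] for g in fitted])
    n = np.concatenate([assay.rows_for(g)[1] for g in fitted])
    x = np.concatenate([assay.rows_for(g)[2] for g in fitted])
    pooled = fit_single_hit(
        DilutionAssay(group=["pooled"] * len(dose), dose=dose, n_tested=n, n_response=x),
        "pooled",
    )
    chi2 = max(0.0, 2.0 * (per_group_ll - pooled.loglik))
    df = len(fitted) - 1
    return GroupComparison(
        groups=list(fitted), chi2=chi2, df=df, p=float(stats.chi2.sf(chi2, df))
    )


def simulate_assay(
    true_frequency: float,
    doses=IN_VITRO_DOSES,
    n_per_dose: int = 6,
    seed: int | None = None,
    group: str = "sim",
) -> DilutionAssay:
    """Draw a dilution plate: each well responds with prob 1 - exp(-lam*d)."""
    if not 0 <= true_frequency <= 1:
        raise ValueError("true_frequency must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    doses = np.asarray(doses, dtype=float)
    p = 1 - np.exp(-true_frequency * doses)
    x = rng.binomial(n_per_dose, p)
    return DilutionAssay(
        group=[group] * len(doses),
        dose=doses,
        n_tested=np.full(len(doses), n_per_dose),
        n_response=x,
    )
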