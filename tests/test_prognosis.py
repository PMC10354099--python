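import math

import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test as ll_logrank

from tmescreen import synthetic
from tmescreen.prognosis import (
    gene_survival_z,
    gene_survival_z_matrix,
    km_optimized_cutoff,
    logrank_test,
    signature_prognosis_panel,
    stouffer_meta_z,
)
from tmescreen.types import SurvivalTable


def _surv(time, event, ids=None):
    time = np.asarray(time, float)
    ids = ids or [f"p{i}" for i in range(len(time))]
    return SurvivalTable(patient_ids=ids, time=time, event=np.asarray(event, int))


class TestGeneSurvivalZ:
    def test_two_subject_worked_example(self):
        # x=(1,0), events at t=(1,2): U=0.5, V=0.25 -> z=1
        s = _surv([1.0, 2.0], [1, 1])
        assert gene_survival_z(np.array([1.0, 0.0]), s) == pytest.approx(1.0)

    def test_constant_covariate_is_zero(self):
        s = _surv([1, 2, 3], [1, 1, 0])
        assert gene_survival_z(np.array([2.0, 2.0, 2.0]), s) == 0.0

    def test_no_events_undefined(self):
        s = _surv([1, 2], [0, 0])
        assert gene_survival_z(np.array([1.0, 0.0]), s) is None

    def test_sign_convention_high_expression_worse(self):
        # subjects with high x die early
        rng = np.random.default_rng(0)
        x = rng.normal(size=100)
        time = np.exp(-x + 0.1 * rng.normal(size=100))
        s = _surv(time, np.ones(100))
        assert gene_survival_z(x, s) > 3

    @pytest.mark.parametrize("seed", range(25))
    def test_binary_covariate_matches_lifelines_logrank(self, seed):
        # tie-free times: the Breslow score test is exactly the log-rank test
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 25))
        time = rng.exponential(1.0, n)
        event = rng.integers(0, 2, n)
        if event.sum() == 0:
            event[0] = 1
        g = rng.integers(0, 2, n)
        if g.min() == g.max():
            g[0] = 1 - g[0]
        s = _surv(time, event)
        chi2, p = logrank_test(g.astype(float), s)
        res = ll_logrank(time[g == 0], time[g == 1], event[g == 0], event[g == 1])
        assert chi2 == pytest.approx(res.test_statistic, rel=1e-6, abs=1e-9)
        assert p == pytest.approx(res.p_value, rel=1e-6, abs=1e-12)

    @staticmethod
    def _score_oracle(x, time, event):
        # independent pure-python risk-set enumeration (Breslow ties)
        u = v = 0.0
        for i in range(len(time)):
            if event[i] != 1:
                continue
            risk = [j for j in range(len(time)) if time[j] >= time[i]]
            xs = [x[j] for j in risk]
            mu = sum(xs) / len(xs)
            u += x[i] - mu
            v += sum((xj - mu) ** 2 for xj in xs) / len(xs)
        return u / math.sqrt(v) if v > 0 else 0.0

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_risk_set_enumeration_oracle_with_ties(self, seed):
        rng = np.random.default_rng(200 + seed)
        n = int(rng.integers(6, 20))
        time = rng.exponential(1.0, n).round(1)  # rounding forces ties
        event = rng.integers(0, 2, n)
        if event.sum() == 0:
            event[0] = 1
        x = rng.normal(size=n)
        s = _surv(time, event)
        assert gene_survival_z(x, s) == pytest.approx(
            self._score_oracle(x, time, event), abs=1e-10
        )

    def test_null_matrix_is_standard_normal_calibrated(self):
        spec = synthetic.GeneratorSpec(
            n_genes=500, n_samples=150, survival_betas={"stemness": 0.0}, seed=9
        )
        cohort = synthetic.make_cohort(spec)
        z = gene_survival_z_matrix(cohort.matrix, cohort.survival)
        assert abs(z.mean()) < 0.15
        assert 0.8 < z.var() < 1.2


class TestStoufferMetaZ:
    def test_single_gene(self):
        z = pd.Series({"a": 1.7})
        res = stouffer_meta_z(z, ["a"])
        assert res.meta_z == pytest.approx(1.7) and res.n_genes == 1

    def test_two_unit_z(self):
        z = pd.Series({"a": 1.0, "b": 1.0})
        assert stouffer_meta_z(z, ["a", "b"]).meta_z == pytest.approx(math.sqrt(2))

    def test_three_gene_formula(self):
        z = pd.Series({"a": 1.0, "b": 2.0, "c": 3.0})
        assert stouffer_meta_z(z, ["a", "b", "c"]).meta_z == pytest.approx(6 / math.sqrt(3))

    def test_missing_genes_adjust_n(self, caplog):
        z = pd.Series({"a": 2.0})
        with caplog.at_level("WARNING"):
            res = stouffer_meta_z(z, ["a", "zz"])
        assert res.n_genes == 1 and res.missing == ["zz"]
        assert res.meta_z == pytest.approx(2.0)

    def test_no_overlap_errors(self):
        with pytest.raises(ValueError):
            stouffer_meta_z(pd.Series({"a": 1.0}), ["zz"])

    def test_permutation_invariance_and_scaling(self):
        rng = np.random.default_rng(0)
        z = pd.Series(rng.normal(size=10), index=[f"g{i}" for i in range(10)])
        genes = [f"g{i}" for i in range(10)]
        m1 = stouffer_meta_z(z, genes).meta_z
        m2 = stouffer_meta_z(z, genes[::-1]).meta_z
        assert m1 == pytest.approx(m2, abs=1e-12)
        m3 = stouffer_meta_z(3.0 * z, genes).meta_z
        assert m3 == pytest.approx(3.0 * m1, abs=1e-12)


class TestKmOptimizedCutoff:
    def test_two_subject_worked_example(self):
        s = _surv([1.0, 2.0], [1, 1])
        chi2, p = logrank_test(np.array([1.0, 0.0]), s)
        assert chi2 == pytest.approx(1.0)
        assert p == pytest.approx(0.3173, abs=1e-4)

    def test_identical_groups_null(self):
        # paired clones: both groups share the same survival experience
        time = [1, 2, 3, 4, 1, 2, 3, 4]
        event = [1, 1, 1, 1, 1, 1, 1, 1]
        s = _surv(time, event)
        chi2, p = logrank_test(np.array([0, 0, 0, 0, 1, 1, 1, 1], float), s)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_single_candidate_grid_equals_plain_logrank(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=60)
        time = rng.exponential(1, 60)
        s = _surv(time, np.ones(60))
        cut = float(np.median(x))
        res = km_optimized_cutoff(x, s, grid=np.array([cut]))
        chi2, p = logrank_test((x > cut).astype(float), s)
        assert res.chi2 == pytest.approx(chi2) and res.p_min == pytest.approx(p)
        assert res.p_adjusted >= res.p_min

    @pytest.mark.parametrize("seed", range(10))
    def test_planted_hazard_ratio_recovers_median_split(self, seed):
        rng = np.random.default_rng(1000 + seed)
        n = 300
        x = rng.normal(size=n)
        high = x > np.median(x)
        rate = np.where(high, 2.5, 1.0)
        time = rng.exponential(1 / rate)
        s = _surv(time, np.ones(n))
        res = km_optimized_cutoff(x, s)
        chosen_pct = (x <= res.cutoff).mean() * 100
        assert abs(chosen_pct - 50) <= 10
        assert res.p_min < 0.01

    def test_no_valid_cutoff_errors(self):
        s = _surv([1, 2], [1, 1])
        with pytest.raises(ValueError):
            km_optimized_cutoff(np.array([1.0, 1.0]), s, grid=np.array([5.0]))


class TestSignaturePanel:
    def test_identical_signatures_give_null_paired_test(self):
        cohorts = {
            "c1": pd.Series({"a": 1.0, "b": 2.0}),
            "c2": pd.Series({"a": 0.5, "b": 1.5}),
        }
        sigs = {"s1": ["a", "b"], "s2": ["a", "b"]}
        panel, tests = signature_prognosis_panel(cohorts, sigs)
        t, p = tests[("s1", "s2")]
        assert t == 0.0 and p == 1.0

    def test_single_cohort_paired_test_missing(self, caplog):
        cohorts = {"c1": pd.Series({"a": 1.0, "b": -1.0})}
        sigs = {"s1": ["a"], "s2": ["b"]}
        with caplog.at_level("WARNING"):
            _, tests = signature_prognosis_panel(cohorts, sigs)
        t, p = tests[("s1", "s2")]
        assert math.isnan(t) and math.isnan(p)

    def test_elevated_signature_beats_control_across_cohorts(self):
        # combined signature genes carry z ~ N(1,1); controls z ~ N(0,1)
        rng = np.random.default_rng(8)
        sig_genes = [f"s{i}" for i in range(20)]
        ctl_genes = [f"c{i}" for i in range(20)]
        cohorts = {}
        for k in range(20):
            z = pd.Series(
                np.concatenate([rng.normal(1, 1, 20), rng.normal(0, 1, 20)]),
                index=sig_genes + ctl_genes,
            )
            cohorts[f"cohort{k}"] = z
        panel, tests = signature_prognosis_panel(
            cohorts, {"combined": sig_genes, "control": ctl_genes}
        )
        frac = (panel["combined"] > panel["control"]).mean()
        assert frac >= 0.9
        t, p = tests[("combined", "control")]
        assert t > 0 and p < 0.01
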