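"""Nested GLM fitting, likelihood-ratio comparison, the sequential
marker table and genotype-stratified rank-sum tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from locuslens.models import (
    ModelSpec,
    PerfectSeparationError,
    compare_nested,
    fit_glm,
    genotype_stratified_test,
    sequential_marker_analysis,
)
from locuslens.sim import (
    PhenotypeSpec,
    SimulationConfig,
    simulate_expression,
    simulate_haplotypes,
    simulate_phenotype,
)
from locuslens.sim.config import CausalGene


def _expression_frame(seed, deltas=(0.15, 0.15), n=500, noise_sd=1.0):
    """Two causal markers in separate blocks plus a perfect proxy of the
    first (same founder subset, k=1 block)."""
    cfg = SimulationConfig(seed=seed, n_samples=n, block_spec=((4, 1), (4, 1)))
    panel = simulate_haplotypes(cfg)
    dosages = panel.dosages()
    v1, v2 = panel.variant_ids[0], panel.variant_ids[4]
    effects = tuple(
        (v, d) for v, d in zip((v1, v2), deltas) if d > 0
    )
    rng = np.random.default_rng(seed + 77_000)
    expr = simulate_expression(
        dosages, panel.variant_ids, (CausalGene("XP", effects),), noise_sd, rng
    )
    return pd.DataFrame(
        {
            "XP": expr["XP"].to_numpy(),
            "m1": dosages[:, 0],
            "proxy": dosages[:, 1],  # same block, r^2 = 1 with m1
            "m2": dosages[:, 4],
            "sex": rng.integers(0, 2, n),
            "age": rng.normal(60, 8, n),
        }
    )


class TestFitGlm:
    def test_gaussian_loglik_matches_closed_form(self):
        """Intercept-only Gaussian fit on y = (1, 2, 3): logLik at the MLE
        variance is -n/2·(log(2·pi·sigma2_hat) + 1)."""
        data = pd.DataFrame({"y": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]})
        fit = fit_glm(ModelSpec("y", "expression"), data)
        y = data["y"].to_numpy()
        s2 = np.mean((y - y.mean()) ** 2)
        expected = -len(y) / 2 * (np.log(2 * np.pi * s2) + 1)
        assert fit.loglik == pytest.approx(expected, abs=1e-8)
        # AIC identity: k counts intercept + variance
        assert fit.aic == pytest.approx(2 * 2 - 2 * expected, abs=1e-8)

    def test_logistic_null_slope_near_zero(self, rng):
        n = 400
        data = pd.DataFrame(
            {"disease": rng.integers(0, 2, n), "x": rng.normal(size=n)}
        )
        fit = fit_glm(ModelSpec("disease", "disease", markers=("x",)), data)
        assert abs(fit.params["x"]) < 3 * fit.bse["x"] + 0.2

    def test_duplicated_predictor_dropped_with_warning(self, rng):
        n = 100
        x = rng.normal(size=n)
        data = pd.DataFrame({"y": x + rng.normal(size=n), "a": x, "b": x})
        with pytest.warns(UserWarning, match="aliased"):
            fit = fit_glm(ModelSpec("y", "expression", markers=("a", "b")), data)
        assert fit.aliased == ("b",)
        assert fit.converged

    def test_perfect_separation_raises(self):
        data = pd.DataFrame(
            {"disease": [0] * 20 + [1] * 20, "x": list(range(20)) + list(range(30, 50))}
        )
        with pytest.raises(PerfectSeparationError):
            fit_glm(ModelSpec("disease", "disease", markers=("x",)), data)

    def test_too_few_complete_cases(self):
        data = pd.DataFrame({"y": [1.0, 2.0, 3.0], "x": [1.0, 2.0, np.nan]})
        with pytest.raises(ValueError, match="complete cases"):
            fit_glm(ModelSpec("y", "expression", markers=("x",)), data)


class TestCompareNested:
    def test_model_vs_itself_is_null(self, rng):
        data = pd.DataFrame({"y": rng.normal(size=50), "x": rng.normal(size=50)})
        fit = fit_glm(ModelSpec("y", "expression", markers=("x",)), data)
        cmp = compare_nested(fit, fit)
        assert cmp.statistic == pytest.approx(0.0, abs=1e-10)
        assert cmp.pvalue == 1.0

    def test_lrt_statistic_identity(self, rng):
        data = pd.DataFrame(
            {"y": rng.normal(size=200), "x": rng.normal(size=200)}
        )
        red = fit_glm(ModelSpec("y", "expression"), data)
        full = fit_glm(ModelSpec("y", "expression", markers=("x",)), data)
        cmp = compare_nested(red, full)
        assert cmp.statistic == pytest.approx(
            2 * (full.loglik - red.loglik), abs=1e-8
        )
        assert cmp.df == 1

    def test_non_nested_rejected(self, rng):
        data = pd.DataFrame(
            {"y": rng.normal(size=60), "a": rng.normal(size=60), "b": rng.normal(size=60)}
        )
        fa = fit_glm(ModelSpec("y", "expression", markers=("a",)), data)
        fb = fit_glm(ModelSpec("y", "expression", markers=("b",)), data)
        with pytest.raises(ValueError, match="nested"):
            compare_nested(fa, fb)

    def test_null_p_uniform(self):
        """Adding a pure-noise marker gives p ~ Uniform(0, 1) across 500
        simulations (KS test at alpha = 0.01)."""
        rng = np.random.default_rng(99)
        pvals = []
        for _ in range(500):
            n = 200
            data = pd.DataFrame(
                {"y": rng.normal(size=n), "x": rng.normal(size=n)}
            )
            red = fit_glm(ModelSpec("y", "expression"), data)
            full = fit_glm(ModelSpec("y", "expression", markers=("x",)), data)
            pvals.append(compare_nested(red, full).pvalue)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_perfect_proxy_is_uninformative(self):
        """Adding a marker in perfect LD with one already present yields a
        df = 0, p = 1 uninformative comparison."""
        data = _expression_frame(seed=13)
        with pytest.warns(UserWarning, match="aliased"):
            red = fit_glm(
                ModelSpec("XP", "expression", ("m1",), ("sex", "age")), data
            )
            full = fit_glm(
                ModelSpec("XP", "expression", ("m1", "proxy"), ("sex", "age")), data
            )
        cmp = compare_nested(red, full)
        assert not cmp.informative
        assert cmp.pvalue == 1.0
        assert cmp.df == 0

    def test_lrt_agrees_with_f_test_at_large_n(self):
        """For Gaussian responses, LRT and F-test reach the same verdict
        at alpha = 0.05 in >= 99% of simulations at n = 1000."""
        rng = np.random.default_rng(4)
        agree = 0
        n_sim = 200
        for _ in range(n_sim):
            n = 1000
            x = rng.normal(size=n)
            beta = rng.choice([0.0, 0.08])
            y = beta * x + rng.normal(size=n)
            data = pd.DataFrame({"y": y, "x": x})
            red = fit_glm(ModelSpec("y", "expression"), data)
            full = fit_glm(ModelSpec("y", "expression", markers=("x",)), data)
            lrt = compare_nested(red, full).pvalue < 0.05
            ols = stats.linregress(x, y).pvalue < 0.05
            agree += lrt == ols
        assert agree >= 0.99 * n_sim


class TestSequentialMarkerAnalysis:
    def test_true_markers_improve_fit(self):
        """Independent causal markers: each in-context addition is
        significant and lowers AIC in >= 90% of simulations."""
        ok = 0
        n_sim = 50
        for seed in range(n_sim):
            data = _expression_frame(seed=seed, deltas=(0.15, 0.15))
            tab = sequential_marker_analysis(
                data, "XP", "expression", ["m1", "m2"], ["sex", "age"]
            )
            ctx = tab[tab.variable_of_interest.str.contains("in context of")]
            ok += bool((ctx.anova_p < 0.05).all() and (ctx.aic2 < ctx.aic1).all())
        assert ok >= 0.9 * n_sim

    def test_perfect_proxy_row_uninformative(self):
        data = _expression_frame(seed=3)
        with pytest.warns(UserWarning, match="aliased"):
            tab = sequential_marker_analysis(
                data, "XP", "expression", ["m1", "proxy", "m2"], ["sex", "age"]
            )
        proxy_row = tab[tab.variable_of_interest == "m1 in context of proxy"].iloc[0]
        assert proxy_row.anova_p == 1.0
        assert not proxy_row.informative

    def test_empty_marker_list_gives_base_only(self):
        data = _expression_frame(seed=5)
        tab = sequential_marker_analysis(data, "XP", "expression", [], ["sex", "age"])
        assert len(tab) == 0

    def test_disease_response_table(self):
        cfg = SimulationConfig(seed=17, n_samples=800, block_spec=((3, 1),))
        panel = simulate_haplotypes(cfg)
        v1 = panel.variant_ids[0]
        pheno = simulate_phenotype(
            panel.dosages(), panel.variant_ids,
            PhenotypeSpec(log_or=((v1, 0.5),)), 18,
        )
        tab = sequential_marker_analysis(
            pheno, "disease", "disease", [v1], ["sex", "age"]
        )
        assert len(tab) == 1
        assert tab.iloc[0].anova_p < 0.05


class TestGenotypeStratified:
    def test_null_p_uniform(self):
        rng = np.random.default_rng(8)
        pvals = []
        for _ in range(300):
            n = 120
            dosage = rng.integers(0, 3, n)
            disease = rng.integers(0, 2, n)
            expr = rng.normal(size=n)
            tab = genotype_stratified_test(expr, disease, dosage)
            pvals.extend(tab.pvalue.dropna().tolist())
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_shift_only_in_homozygous_minor_group(self):
        """A 1-sd expression shift planted only in the dosage-2 group is
        detected there (and nowhere else) in >= 90% of simulations."""
        rng = np.random.default_rng(12)
        detected = 0
        false_hits = {0: 0, 1: 0}
        n_sim = 100
        for _ in range(n_sim):
            n_per = 50
            rows = []
            for g in (0, 1, 2):
                for d in (0, 1):
                    shift = 1.0 if (g == 2 and d == 0) else 0.0
                    rows.append(
                        pd.DataFrame(
                            {
                                "expr": rng.normal(shift, 1, n_per),
                                "disease": d,
                                "dosage": g,
                            }
                        )
                    )
            df = pd.concat(rows, ignore_index=True)
            tab = genotype_stratified_test(
                df["expr"].to_numpy(), df["disease"].to_numpy(), df["dosage"].to_numpy()
            ).set_index("dosage")
            detected += tab.loc[2, "pvalue"] < 0.05
            for g in (0, 1):
                false_hits[g] += tab.loc[g, "pvalue"] < 0.05
        # the shifted group is found nearly always; the unshifted groups
        # reject only at the nominal level
        assert detected >= 0.9 * n_sim
        for g in (0, 1):
            assert false_hits[g] <= 0.12 * n_sim

    def test_empty_class_untestable(self):
        tab = genotype_stratified_test(
            np.arange(8.0), np.array([1, 1, 1, 1, 0, 0, 0, 0]),
            np.array([0, 0, 0, 0, 0, 0, 0, 0]),
        )
        t = tab.set_index("dosage")
        assert t.loc[0, "testable"]
        assert not t.loc[1, "testable"] and not t.loc[2, "testable"]

    def test_tiny_tied_groups_give_p_one(self):
        tab = genotype_stratified_test(
            np.array([1.0, 1.0, 1.0, 1.0]),
            np.array([0, 0, 1, 1]),
            np.array([0, 0, 0, 0]),
        )
        assert tab.set_index("dosage").loc[0, "pvalue"] == pytest.approx(1.0)
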