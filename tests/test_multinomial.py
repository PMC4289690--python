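import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from crosspheno.datatypes import GenotypePanel
from crosspheno.meta import study_logistic_assoc
from crosspheno.multinomial import (
    MnmFitError,
    classify_mnm,
    fit_multinomial,
    stepwise_conditional,
    wald_tests,
)


def _panel(dosages, phenotype, extra_variants=None):
    dosages = np.atleast_2d(np.asarray(dosages, dtype=float))
    if dosages.shape[0] < dosages.shape[1] and dosages.shape[0] <= 2:
        dosages = dosages.T
    m = dosages.shape[1]
    variants = pd.DataFrame({
        "SNP": [f"v{i}" for i in range(m)],
        "CHR": "1", "POS": np.arange(1, m + 1) * 1000,
        "EA": "A", "OA": "G"})
    return GenotypePanel(
        sample_ids=np.array([f"s{i}" for i in range(dosages.shape[0])]),
        phenotype=np.asarray(phenotype, dtype=object),
        dosages=dosages, variants=variants)


def simulate_mnm_panel(n, beta_ad, beta_pso, eaf=0.3, seed=0, m=1,
                       intercepts=(-1.0, -1.0), ld_r=0.0):
    """Three-outcome draws from the multinomial logistic model itself."""
    rng = np.random.default_rng(seed)
    g = np.empty((n, m))
    g[:, 0] = rng.binomial(2, eaf, n)
    for j in range(1, m):
        # per-haplotype copy of the previous variant with prob ld_r
        h_prev = np.column_stack([(g[:, j - 1] > 0) & (rng.random(n) < 0.5)
                                  | (g[:, j - 1] == 2),
                                  (g[:, j - 1] == 2)])
        fresh = rng.binomial(1, eaf, (n, 2))
        copy = rng.random((n, 2)) < ld_r
        g[:, j] = np.where(copy, h_prev, fresh).sum(axis=1)
    lin_ad = intercepts[0] + beta_ad * g[:, 0]
    lin_pso = intercepts[1] + beta_pso * g[:, 0]
    e_ad, e_pso = np.exp(lin_ad), np.exp(lin_pso)
    den = 1 + e_ad + e_pso
    u = rng.random(n)
    pheno = np.where(u < e_ad / den, "AD",
                     np.where(u < (e_ad + e_pso) / den, "PSO", "control"))
    return _panel(g, pheno.astype(object))


class TestWaldTests:
    def test_null_point_gives_all_ones(self):
        p = wald_tests(0.0, 0.0, np.eye(2) * 0.01)
        assert all(v == pytest.approx(1.0) for v in p.values())

    def test_closed_form_shared_and_opposing(self):
        p = wald_tests(0.2, 0.2, np.eye(2) * 0.01)
        # shared: (0.4)^2 / 0.02 = 8; opposing: 0
        assert p["p_shared"] == pytest.approx(chi2.sf(8.0, 1), rel=1e-12)
        assert p["p_shared"] == pytest.approx(0.00468, abs=2e-4)
        assert p["p_opposing"] == pytest.approx(1.0)

    def test_overall_decomposes_for_spherical_covariance(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            b_pso, b_ad = rng.normal(0, 0.5, 2)
            s2 = rng.uniform(0.001, 0.1)
            cov = np.eye(2) * s2
            p = wald_tests(b_pso, b_ad, cov)
            stat_sh = chi2.isf(p["p_shared"], 1)
            stat_op = chi2.isf(p["p_opposing"], 1)
            stat_all = chi2.isf(p["p_overall"], 2)
            assert stat_all == pytest.approx(stat_sh + stat_op, rel=1e-8)

    def test_singular_covariance_rejected(self):
        with pytest.raises(ValueError):
            wald_tests(0.1, 0.1, np.ones((2, 2)))


class TestClassify:
    def test_argmin_selection(self):
        cat, p = classify_mnm({"p_ad": 0.001, "p_pso": 0.5,
                               "p_shared": 0.03, "p_opposing": 0.4,
                               "p_overall": 0.01})
        assert (cat, p) == ("AD", 0.001)

    def test_tie_breaks_in_fixed_order(self):
        cat, _ = classify_mnm({"p_ad": 0.2, "p_pso": 0.2,
                               "p_shared": 0.2, "p_opposing": 0.2})
        assert cat == "AD"

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            classify_mnm({"p_ad": -0.1, "p_pso": 0.5, "p_shared": 0.5,
                          "p_opposing": 0.5})


class TestFitMultinomial:
    def test_null_rarely_flags_either_disease(self):
        hits = 0
        for seed in range(100):
            panel = simulate_mnm_panel(3000, 0.0, 0.0, seed=seed)
            r = fit_multinomial(panel, "v0")
            hits += (abs(r.beta_ad) > 3 * r.se_ad
                     or abs(r.beta_pso) > 3 * r.se_pso)
        assert hits <= 3

    def test_recovers_ad_only_effect(self):
        beta = np.log(1.5)
        covered_ad = pso_null = 0
        for seed in range(100):
            panel = simulate_mnm_panel(4000, beta, 0.0, seed=200 + seed)
            r = fit_multinomial(panel, "v0")
            covered_ad += abs(r.beta_ad - beta) < 1.96 * r.se_ad
            pso_null += abs(r.beta_pso) < 1.96 * r.se_pso
        assert covered_ad >= 90
        assert pso_null >= 90

    def test_or_ci_identity(self):
        panel = simulate_mnm_panel(2000, 0.3, -0.3, seed=5)
        r = fit_multinomial(panel, "v0")
        assert r.or_ad == pytest.approx(np.exp(r.beta_ad), rel=1e-12)
        lo, hi = r.ci_ad()
        assert lo == pytest.approx(np.exp(r.beta_ad - 1.959963984540054
                                          * r.se_ad), rel=1e-12)
        assert hi == pytest.approx(np.exp(r.beta_ad + 1.959963984540054
                                          * r.se_ad), rel=1e-12)

    def test_two_category_data_refused(self):
        panel = simulate_mnm_panel(500, 0.0, 0.0, seed=1)
        panel.phenotype[panel.phenotype == "PSO"] = "control"
        with pytest.raises(MnmFitError):
            fit_multinomial(panel, "v0")

    def test_agrees_with_binary_logistic_for_ad(self):
        """p_AD from the joint fit tracks the AD-vs-control binary test."""
        for seed in (0, 1, 2):
            panel = simulate_mnm_panel(4000, np.log(1.4), 0.0,
                                       seed=300 + seed)
            r = fit_multinomial(panel, "v0")
            _, _, p_binary = study_logistic_assoc(panel, "v0", "AD")
            stat_mnm = chi2.isf(r.p_ad, 1)
            stat_bin = chi2.isf(p_binary, 1)
            assert stat_mnm == pytest.approx(stat_bin, rel=0.10)

    @pytest.mark.parametrize("b_ad,b_pso,want", [
        (np.log(1.4), np.log(0.7), "opposing"),
        (np.log(1.4), np.log(1.4), "shared"),
    ])
    def test_classification_of_simulated_effects(self, b_ad, b_pso, want):
        ok = 0
        for seed in range(30):
            panel = simulate_mnm_panel(6000, b_ad, b_pso, seed=400 + seed)
            r = fit_multinomial(panel, "v0")
            ok += r.category == want
        assert ok / 30 >= 0.9


class TestStepwise:
    def test_stop_p_zero_selects_nothing(self):
        panel = simulate_mnm_panel(2000, 0.5, 0.0, seed=9)
        res = stepwise_conditional(panel, ["v0"], stop_p=0.0)
        assert res.signals == [] and res.full_model == {}

    def test_two_independent_signals_recovered(self):
        found = 0
        trials = 15
        for seed in range(trials):
            rng = np.random.default_rng(1000 + seed)
            n = 6000
            g1 = rng.binomial(2, 0.3, n).astype(float)
            g2 = rng.binomial(2, 0.4, n).astype(float)   # independent
            lin_ad = -1.2 + 0.35 * g1 + 0.35 * g2
            lin_pso = -1.2
            e_ad, e_pso = np.exp(lin_ad), np.exp(lin_pso * np.ones(n))
            den = 1 + e_ad + e_pso
            u = rng.random(n)
            pheno = np.where(u < e_ad / den, "AD",
                             np.where(u < (e_ad + e_pso) / den, "PSO",
                                      "control")).astype(object)
            panel = _panel(np.column_stack([g1, g2]), pheno)
            res = stepwise_conditional(panel, ["v0", "v1"], stop_p=1e-3)
            ids = {s.variant_id for s in res.signals}
            found += ids == {"v0", "v1"}
        assert found / trials >= 0.9

    def test_proxy_cluster_yields_single_signal(self):
        hits = []
        for seed in range(10):
            panel = simulate_mnm_panel(6000, 0.5, -0.3, seed=2000 + seed,
                                       m=6, ld_r=0.95)
            res = stepwise_conditional(
                panel, [f"v{i}" for i in range(6)], stop_p=1e-4)
            hits.append(len(res.signals))
        assert np.mean([h == 1 for h in hits]) >= 0.9

    def test_full_model_refits_selected_jointly(self):
        panel = simulate_mnm_panel(4000, 0.5, 0.0, seed=3000)
        res = stepwise_conditional(panel, ["v0"], stop_p=1e-2)
        assert [s.variant_id for s in res.signals] == ["v0"]
        assert set(res.full_model) == {"v0"}
        only = res.full_model["v0"]
        assert only.beta_ad == pytest.approx(res.signals[0].result.beta_ad)
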