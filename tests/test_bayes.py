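import itertools
import math

import numpy as np
import pytest
from scipy import integrate
from scipy.stats import norm

from crosspheno.bayes import (
    DEFAULT_W,
    bfdp,
    build_distance_model,
    enumerate_partitions,
    log10_bayes_factor,
)


def six_study_model(inflate_disease=True):
    """3 AD (one childhood) + 3 PSO studies with small ethnic spread."""
    centroids = np.array([[0.0, 0.0], [0.1, 0.0], [0.05, 0.1],
                          [0.0, 0.05], [0.12, 0.02], [0.03, 0.08]])
    diseases = ["AD", "AD", "AD", "PSO", "PSO", "PSO"]
    subs = ["general", "general", "childhood",
            "general", "general", "general"]
    model = build_distance_model(centroids, diseases, subs)
    if not inflate_disease:
        model.d_disease[:] = 0.0
        model.d_total = model.d_ethnicity.copy()
    return model


class TestDistanceModel:
    def test_same_disease_same_subphenotype(self):
        m = build_distance_model([[0.0], [1.0]], ["AD", "AD"],
                                 ["general", "general"])
        assert m.d_total[0, 1] == pytest.approx(1.0)

    def test_cross_disease_inflation_is_twice_max(self):
        m = build_distance_model([[0.0], [1.0]], ["AD", "PSO"],
                                 ["general", "general"])
        assert m.d_disease[0, 1] == pytest.approx(2.0)
        assert m.d_total[0, 1] == pytest.approx(3.0)

    def test_subphenotype_inflation_is_max(self):
        m = build_distance_model([[0.0], [1.0]], ["AD", "AD"],
                                 ["general", "childhood"])
        assert m.d_disease[0, 1] == pytest.approx(1.0)
        assert m.d_total[0, 1] == pytest.approx(2.0)

    def test_matrix_invariants(self):
        m = six_study_model()
        for mat in (m.d_ethnicity, m.d_disease, m.d_total):
            np.testing.assert_allclose(mat, mat.T)
            np.testing.assert_allclose(np.diag(mat), 0.0)
            assert (mat >= 0).all()
        np.testing.assert_allclose(m.d_total,
                                   m.d_disease + m.d_ethnicity)

    def test_missing_labels_rejected(self):
        with pytest.raises(ValueError):
            build_distance_model([[0.0], [1.0]], ["AD", None],
                                 ["general", "general"])


class TestEnumeratePartitions:
    def test_two_studies_give_both_partitions(self):
        m = build_distance_model([[0.0], [1.0]], ["AD", "AD"],
                                 ["general", "general"])
        prior = enumerate_partitions(m)
        got = {tuple(sorted(tuple(sorted(c)) for c in p))
               for p in prior.partitions}
        assert got == {((0, 1),), ((0,), (1,))}
        assert prior.weights.sum() == pytest.approx(1.0)

    @pytest.mark.parametrize("weighting", ["uniform", "distance"])
    def test_matches_brute_force_center_scheme(self, weighting):
        m = six_study_model()
        prior = enumerate_partitions(m, weighting=weighting)
        # independent brute force over all (T, center-set) pairs
        n = 6
        off = m.d_ethnicity[~np.eye(n, dtype=bool)]
        scale = off.mean()
        seen = {}
        for t in range(1, n + 1):
            for centers in itertools.combinations(range(n), t):
                assign, cost = {}, 0.0
                for s in range(n):
                    best = min(centers, key=lambda c: (m.d_total[s, c], c))
                    assign.setdefault(best, []).append(s)
                    cost += m.d_total[s, best]
                part = tuple(sorted((frozenset(v) for v in assign.values()),
                                    key=min))
                w = math.exp(-cost / scale) if weighting == "distance" else 1.0
                seen[part] = seen.get(part, 0) + w
        total = sum(seen.values())
        got = dict(zip(prior.partitions, prior.weights))
        assert set(got) == set(seen)
        for p in seen:
            assert got[p] == pytest.approx(seen[p] / total)

    def test_equidistant_studies_weights_sum_to_one(self):
        m = build_distance_model(
            [[0.0, 0.0], [1.0, 0.0], [0.5, math.sqrt(3) / 2]],
            ["AD"] * 3, ["general"] * 3)
        prior = enumerate_partitions(m)
        assert prior.weights.sum() == pytest.approx(1.0)
        assert len(prior.partitions) <= 5   # Bell(3)

    def test_disease_inflated_prior_separates_diseases(self):
        prior = enumerate_partitions(six_study_model())
        ad, pso = {0, 1, 2}, {3, 4, 5}
        for part, w in zip(prior.partitions, prior.weights):
            if w > 0.01:
                for cluster in part:
                    assert cluster <= ad or cluster <= pso, (part, w)

    def test_too_many_studies_refused(self):
        m = build_distance_model(np.random.default_rng(0).normal(size=(13, 2)),
                                 ["AD"] * 13, ["general"] * 13)
        with pytest.raises(ValueError, match="sampling"):
            enumerate_partitions(m)


class TestBayesFactor:
    def test_null_data_gives_negative_log_bf(self):
        prior = enumerate_partitions(six_study_model())
        res = log10_bayes_factor([0.0] * 6, [0.1] * 6, prior, w=0.04)
        assert res.log10_bf < 0

    def test_single_study_closed_form(self):
        # one study, one partition: BF is the univariate normal Bayes factor
        # N(beta; 0, W + se^2) / N(beta; 0, se^2)
        from crosspheno.bayes import PartitionPrior
        prior = PartitionPrior([(frozenset({0}),)], np.array([1.0]), 1)
        beta, se, w = 0.25, 0.1, 0.04
        res = log10_bayes_factor([beta], [se], prior, w=w)
        want = (norm.logpdf(beta, 0, math.sqrt(w + se**2))
                - norm.logpdf(beta, 0, se)) / math.log(10)
        assert res.log10_bf == pytest.approx(want, abs=1e-10)

    def test_three_study_quadrature_oracle(self):
        m = build_distance_model([[0.0], [0.3], [0.6]], ["AD"] * 3,
                                 ["general"] * 3)
        prior = enumerate_partitions(m)
        rng = np.random.default_rng(3)
        for _ in range(5):
            beta = rng.normal(0, 0.2, 3)
            se = rng.uniform(0.05, 0.2, 3)
            res = log10_bayes_factor(beta, se, prior, w=DEFAULT_W)

            def cluster_integral(idx):
                def f(mu):
                    lik = norm.pdf(mu, 0, math.sqrt(DEFAULT_W))
                    for i in idx:
                        lik *= norm.pdf(beta[i], mu, se[i])
                    return lik
                val, _ = integrate.quad(f, -4, 4, epsabs=1e-15, limit=200)
                return val

            num = 0.0
            for part, wgt in zip(prior.partitions, prior.weights):
                num += wgt * np.prod([cluster_integral(sorted(c))
                                      for c in part])
            den = np.prod(norm.pdf(beta, 0, se))
            assert res.log10_bf == pytest.approx(math.log10(num / den),
                                                 abs=1e-6)

    def test_shared_effect_concentrates_on_one_cluster(self):
        """With no disease inflation, a common effect favours pooling as
        the evidence grows."""
        model = six_study_model(inflate_disease=False)
        prior = enumerate_partitions(model)
        pooled_mass = []
        for se in (0.2, 0.05, 0.002):
            res = log10_bayes_factor([0.2] * 6, [se] * 6, prior)
            mass = sum(w for p, w in zip(prior.partitions,
                                         res.posterior_weights)
                       if len(p) == 1)
            pooled_mass.append(mass)
        assert pooled_mass[0] < pooled_mass[1] < pooled_mass[2]
        assert pooled_mass[-1] > 0.9

    def test_opposing_effects_split_diseases(self):
        prior = enumerate_partitions(six_study_model())
        rng = np.random.default_rng(4)
        ok = 0
        for _ in range(60):
            se = 0.1
            b = 3 * se
            beta = rng.normal([b] * 3 + [-b] * 3, se)
            res = log10_bayes_factor(beta, [se] * 6, prior)
            split = all(c <= {0, 1, 2} or c <= {3, 4, 5}
                        for c in res.map_partition)
            ok += split
        assert ok / 60 >= 0.95


class TestBfdp:
    def test_indifference_point(self):
        assert bfdp(0.0, 1.0) == pytest.approx(0.5)

    def test_threshold_inversion(self):
        # BFDP = 0.05 at PO = 99 requires BF = 99 * 19 = 1881
        target_bf = 99 * 19
        assert bfdp(math.log10(target_bf), 99.0) == pytest.approx(0.05)

    def test_limits_and_monotonicity(self):
        assert bfdp(300.0, 99.0) == pytest.approx(0.0, abs=1e-200)
        assert bfdp(-300.0, 99.0) == pytest.approx(1.0)
        grid = [bfdp(x, 99.0) for x in np.linspace(-5, 5, 30)]
        assert np.all(np.diff(grid) < 0)

    def test_invalid_prior_odds(self):
        with pytest.raises(ValueError):
            bfdp(1.0, 0.0)
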