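import numpy as np
import pandas as pd
import pytest

from crosspheno.datatypes import GenotypePanel
from crosspheno.ld import clump, define_locus, genotype_r2, shared_regions

from conftest import hwe_panel


def panel_with_positions(dosages, positions, chrom=None):
    dosages = np.asarray(dosages, dtype=float)
    m = dosages.shape[1]
    variants = pd.DataFrame({
        "SNP": [f"v{i}" for i in range(m)],
        "CHR": chrom if chrom is not None else ["1"] * m,
        "POS": positions, "EA": "A", "OA": "G"})
    return GenotypePanel(
        sample_ids=np.array([f"s{i}" for i in range(dosages.shape[0])]),
        phenotype=np.full(dosages.shape[0], "control", dtype=object),
        dosages=dosages, variants=variants)


def brute_force_clump(results, r2_fn, max_dist, min_r2, threshold):
    """Independent straightforward reference for the greedy procedure."""
    rows = [r for _, r in results.iterrows() if r["STAT"] >= threshold]
    rows.sort(key=lambda r: (-r["STAT"], r["POS"]))
    out, used = [], set()
    for lead in rows:
        if lead["SNP"] in used:
            continue
        members = [lead["SNP"]]
        used.add(lead["SNP"])
        for other in rows:
            if other["SNP"] in used:
                continue
            if str(other["CHR"]) == str(lead["CHR"]) \
                    and abs(other["POS"] - lead["POS"]) <= max_dist \
                    and r2_fn(lead["SNP"], other["SNP"]) >= min_r2:
                members.append(other["SNP"])
                used.add(other["SNP"])
        out.append((lead["SNP"], frozenset(members)))
    return out


class TestGenotypeR2:
    def test_identical_vectors(self):
        v = np.array([0, 1, 2, 1, 0, 2], dtype=float)
        assert genotype_r2(v, v) == pytest.approx(1.0)

    def test_independent_variants(self):
        rng = np.random.default_rng(0)
        a = rng.binomial(2, 0.4, 10_000).astype(float)
        b = rng.binomial(2, 0.4, 10_000).astype(float)
        assert genotype_r2(a, b) < 0.01

    def test_symmetric(self):
        rng = np.random.default_rng(1)
        a, b = rng.binomial(2, 0.5, (2, 500)).astype(float)
        assert genotype_r2(a, b) == pytest.approx(genotype_r2(b, a))

    def test_zero_variance_is_missing(self):
        assert np.isnan(genotype_r2(np.ones(10), np.arange(10, dtype=float)))

    def test_perfect_ld_haplotype_oracle(self):
        """D' = 1 haplotypes: r^2 must match the closed form pq ratio."""
        rng = np.random.default_rng(2)
        n = 20_000
        pa, pb = 0.3, 0.6   # allele A always on B background: D' = 1
        # haplotypes: P(AB) = pa, P(aB) = pb - pa, P(ab) = 1 - pb
        hap_probs = [pa, pb - pa, 1 - pb]
        haps = rng.choice(3, size=(n, 2), p=hap_probs)
        a = (haps == 0).sum(axis=1).astype(float)
        b = (haps <= 1).sum(axis=1).astype(float)
        want = (pa * (1 - pb)) / ((1 - pa) * pb)  # D^2/(papb qa qb), D=pa(1-pb)
        assert genotype_r2(a, b) == pytest.approx(want, abs=0.02)

    def test_missing_entries_excluded_pairwise(self):
        a = np.array([0, 1, 2, -1, 1, 2], dtype=float)
        b = np.array([0, 1, 2, 2, -1, 2], dtype=float)
        keep = (a != -1) & (b != -1)
        assert genotype_r2(a, b) == pytest.approx(
            np.corrcoef(a[keep], b[keep])[0, 1] ** 2)


class TestClump:
    def _tight_ld_panel(self, positions, n=400, seed=0, r=0.97):
        rng = np.random.default_rng(seed)
        base = rng.binomial(2, 0.5, n).astype(float)
        cols = [base]
        for _ in range(len(positions) - 1):
            flip = rng.random(n) < (1 - r) / 2
            nxt = np.where(flip, rng.binomial(2, 0.5, n), cols[-1])
            cols.append(nxt.astype(float))
        return panel_with_positions(np.column_stack(cols), positions)

    def test_three_nearby_correlated_variants_one_clump(self):
        panel = self._tight_ld_panel([100_000, 120_000, 150_000])
        results = pd.DataFrame({
            "SNP": ["v0", "v1", "v2"], "CHR": "1",
            "POS": [100_000, 120_000, 150_000],
            "TMAX": [8.0, 6.0, 5.0]})
        clumps = clump(results, panel, stat_threshold=4.7)
        assert len(clumps) == 1
        assert clumps[0].lead == "v0"
        assert {m[0] for m in clumps[0].members} == {"v0", "v1", "v2"}

    def test_distance_rule_binds_beyond_250kb(self):
        panel = self._tight_ld_panel([100_000, 400_001])
        results = pd.DataFrame({
            "SNP": ["v0", "v1"], "CHR": "1", "POS": [100_000, 400_001],
            "TMAX": [8.0, 6.0]})
        clumps = clump(results, panel, stat_threshold=4.7)
        assert len(clumps) == 2

    def test_exact_boundary_distance_included(self):
        panel = self._tight_ld_panel([100_000, 350_000])
        results = pd.DataFrame({
            "SNP": ["v0", "v1"], "CHR": "1", "POS": [100_000, 350_000],
            "TMAX": [8.0, 6.0]})
        assert len(clump(results, panel, stat_threshold=4.7)) == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_on_random_configurations(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(2, 20))
        n = 300
        # random LD structure: mixture of fresh and copied columns
        cols = [rng.binomial(2, rng.uniform(0.2, 0.8), n).astype(float)]
        for _ in range(m - 1):
            if rng.random() < 0.5:
                src = cols[int(rng.integers(len(cols)))]
                flip = rng.random(n) < 0.1
                cols.append(np.where(flip, rng.binomial(2, 0.5, n),
                                     src).astype(float))
            else:
                cols.append(rng.binomial(2, rng.uniform(0.2, 0.8),
                                         n).astype(float))
        positions = np.sort(rng.choice(np.arange(1, 1_000_000), m,
                                       replace=False))
        panel = panel_with_positions(np.column_stack(cols), positions)
        results = pd.DataFrame({
            "SNP": [f"v{i}" for i in range(m)], "CHR": "1",
            "POS": positions, "STAT": rng.uniform(0, 10, m)})
        got = clump(results, panel, stat_col="STAT", stat_threshold=3.0,
                    controls_only=False)
        r2_fn = lambda a, b: genotype_r2(panel.dosage_of(a),
                                         panel.dosage_of(b))
        want = brute_force_clump(results, r2_fn, 250_000, 0.5, 3.0)
        got_sets = [(c.lead, frozenset(v for v, _ in c.members))
                    for c in got]
        assert got_sets == want

    def test_clumps_partition_passing_variants(self):
        rng = np.random.default_rng(99)
        m, n = 15, 200
        panel = panel_with_positions(
            rng.binomial(2, 0.5, (n, m)).astype(float),
            np.arange(m) * 40_000 + 1)
        results = pd.DataFrame({
            "SNP": [f"v{i}" for i in range(m)], "CHR": "1",
            "POS": panel.variants["POS"], "TMAX": rng.uniform(3, 9, m)})
        clumps = clump(results, panel, stat_threshold=5.0,
                       controls_only=False)
        seen = [v for c in clumps for v, _ in c.members]
        passing = set(results.loc[results["TMAX"] >= 5.0, "SNP"])
        assert sorted(seen) == sorted(passing)
        assert len(seen) == len(set(seen))


class TestDefineLocus:
    def test_strict_vs_inclusive_boundary(self):
        rng = np.random.default_rng(5)
        a = rng.binomial(2, 0.5, 500).astype(float)
        b = rng.binomial(2, 0.5, 500).astype(float)
        panel = panel_with_positions(np.column_stack([a, b]),
                                     [100_000, 110_000])
        r2 = genotype_r2(a, b)
        # at the exact observed r2: locus (strict >) excludes, clump (>=) keeps
        locus = define_locus("v0", ["v1"], panel, min_r2=r2,
                             controls_only=False)
        assert [m[0] for m in locus.members] == ["v0"]
        results = pd.DataFrame({"SNP": ["v0", "v1"], "CHR": "1",
                                "POS": [100_000, 110_000],
                                "TMAX": [9.0, 8.0]})
        clumps = clump(results, panel, min_r2=r2, stat_threshold=0.0,
                       controls_only=False)
        assert len(clumps) == 1 and len(clumps[0].members) == 2

    def test_no_candidates_above_threshold_singleton(self):
        panel = hwe_panel(300, [0.5, 0.5], seed=1)
        locus = define_locus("v0", ["v1"], panel, controls_only=False)
        assert [m[0] for m in locus.members] == ["v0"]


class TestSharedRegions:
    def test_cross_disease_window(self):
        from crosspheno.ld import LocusClump
        ad = [LocusClump("a1", 8.0, "1", [("a1", 1.0)], 1_000_000, 1_000_000)]
        pso = [LocusClump("p1", 7.0, "1", [("p1", 1.0)], 2_500_000,
                          2_500_000),
               LocusClump("p2", 7.0, "2", [("p2", 1.0)], 2_500_000,
                          2_500_000)]
        regions = shared_regions(ad, pso)
        assert len(regions) == 1
        assert regions[0]["chrom"] == "1"
        assert regions[0]["pairs"] == [("a1", "p1")]
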