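"""Synthetic multi-cohort two-disease case-control data with known truth.

The generator emulates the study design the package targets: three atopic
dermatitis (AD) cohorts — one of them a childhood-onset subphenotype — and
three psoriasis (PSO) cohorts, each an independent case-control sample with
its own mild ancestry offset in allele frequency.  Variants carry known
classes: ``AD_only``, ``PSO_only``, ``shared`` (same-direction effect on
both diseases), ``opposing`` (antagonistic), and ``null``.

Two paths are provided.  :func:`simulate_cohorts` draws individual-level
genotypes: haplotypes with LD blocks produced by a first-order copying
process (adjacent alleles copied with the configured probability, so
dosages stay integral and Hardy-Weinberg holds within each cohort), disease
status from a log-additive logistic model whose intercept is solved
numerically so the population prevalence matches the configuration, and
case/control sampling to the requested counts.  :func:`simulate_summary_stats`
is the fast path: it draws per-study effect estimates directly from
``N(true beta, se^2)`` with the standard allele-count variance
approximation for the standard error — sufficient for testing the
meta-analysis, CCMA and partition-model layers without genotype data.

Default cohort sizes are roughly one tenth of the consortium scale the
design emulates (a few hundred cases per cohort), so full pipelines run in
seconds to minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit
from scipy.stats import norm

from .datatypes import GenotypePanel, StudySummary

VARIANT_CLASSES = ("AD_only", "PSO_only", "shared", "opposing", "null")

#: Odds ratios (OR_AD, OR_PSO) per variant class.
DEFAULT_EFFECTS = {
    "AD_only": (1.4, 1.0),
    "PSO_only": (1.0, 1.4),
    "shared": (1.4, 1.4),
    "opposing": (1.4, 1 / 1.4),
    "null": (1.0, 1.0),
}


@dataclass(frozen=True)
class CohortSpec:
    name: str
    disease: str                 # "AD" or "PSO"
    subphenotype: str = "general"
    ancestry_offset: float = 0.0  # sd of the per-variant frequency offset
    n_cases: int = 250
    n_controls: int = 500


def default_cohorts() -> list[CohortSpec]:
    """Three AD cohorts (one childhood-onset) and three psoriasis cohorts."""
    return [
        CohortSpec("AD_DE", "AD", "general", 0.005, 250, 600),
        CohortSpec("AD_IE", "AD", "general", 0.015, 200, 450),
        CohortSpec("AD_DE_child", "AD", "childhood", 0.005, 240, 500),
        CohortSpec("PSO_DE", "PSO", "general", 0.005, 450, 900),
        CohortSpec("PSO_US", "PSO", "general", 0.020, 400, 800),
        CohortSpec("PSO_UK", "PSO", "general", 0.010, 350, 700),
    ]


@dataclass
class SimulationConfig:
    cohorts: list = field(default_factory=default_cohorts)
    n_variants: dict = field(default_factory=lambda: {
        "AD_only": 40, "PSO_only": 40, "shared": 40, "opposing": 40,
        "null": 120})
    effects: dict = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    eaf_bounds: tuple = (0.10, 0.90)
    ld_block_len: int = 5
    ld_copy_prob: float = 0.8
    prevalence_ad: float = 0.10
    prevalence_pso: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.eaf_bounds
        if not (0.05 <= lo < hi <= 0.95):
            raise ValueError("eaf bounds must lie within (0.05, 0.95)")
        for cls, n in self.n_variants.items():
            if cls not in VARIANT_CLASSES:
                raise ValueError(f"unknown variant class {cls}")
            if n < 0:
                raise ValueError("variant counts must be non-negative")
        for c in self.cohorts:
            if c.n_cases <= 0 or c.n_controls <= 0:
                raise ValueError("cohort counts must be positive")
        for ors in self.effects.values():
            if min(ors) <= 0:
                raise ValueError("odds ratios must be positive")


@dataclass
class SimTruth:
    """Ground truth per simulated variant."""

    table: pd.DataFrame         # SNP CHR POS EA OA CLASS BETA_AD BETA_PSO EAF
    cohort_eaf: pd.DataFrame    # one column per cohort, rows align with table


def _truth_table(config: SimulationConfig, rng) -> pd.DataFrame:
    """Lay out variants in LD blocks that never straddle a class boundary.

    Within each non-null block only the *first* variant is causal and
    carries the class's full effect; its neighbours are tag variants whose
    recorded ``BETA_*`` is the expected marginal (GWAS-visible) effect,
    attenuated by the copying correlation ``rho^k`` at offset k.  The sign
    pattern — hence the class label — is shared by the whole block.
    """
    rows = []
    i = 0
    block_id = 0
    for cls in VARIANT_CLASSES:
        n_cls = config.n_variants.get(cls, 0)
        offset_in_block = 0
        for _ in range(n_cls):
            if offset_in_block == 0:
                block_id += 1
            or_ad, or_pso = config.effects[cls]
            causal = offset_in_block == 0 and cls != "null"
            atten = config.ld_copy_prob ** offset_in_block
            b_ad = np.log(or_ad) * (1.0 if causal else atten)
            b_pso = np.log(or_pso) * (1.0 if causal else atten)
            if cls == "null":
                b_ad = b_pso = 0.0
            ea, oa = rng.choice([("A", "G"), ("C", "T"), ("G", "A"),
                                 ("T", "C")])
            rows.append((f"rs{i + 1:06d}", "1", 100_000 + 10_000 * i, ea, oa,
                         cls, b_ad, b_pso,
                         rng.uniform(*config.eaf_bounds), causal, block_id))
            i += 1
            offset_in_block = (offset_in_block + 1) % config.ld_block_len
        # next class starts a fresh block
    return pd.DataFrame(rows, columns=["SNP", "CHR", "POS", "EA", "OA",
                                       "CLASS", "BETA_AD", "BETA_PSO", "EAF",
                                       "CAUSAL", "BLOCK"])


def _cohort_eafs(truth: pd.DataFrame, config: SimulationConfig,
                 rng) -> pd.DataFrame:
    lo, hi = config.eaf_bounds
    out = {}
    for c in config.cohorts:
        offset = rng.normal(0.0, c.ancestry_offset, size=len(truth))
        out[c.name] = np.clip(truth["EAF"].to_numpy() + offset, lo, hi)
    return pd.DataFrame(out)


def _simulate_haplotypes(n: int, eaf: np.ndarray, blocks: np.ndarray,
                         copy_prob: float, rng) -> np.ndarray:
    """First-order copying process within LD blocks; (n, m) 0/1 array."""
    m = len(eaf)
    hap = np.empty((n, m), dtype=np.int8)
    for j in range(m):
        fresh = rng.random(n) < eaf[j]
        if j == 0 or blocks[j] != blocks[j - 1]:
            hap[:, j] = fresh
        else:
            copy = rng.random(n) < copy_prob
            hap[:, j] = np.where(copy, hap[:, j - 1], fresh)
    return hap


def _solve_intercept(scores: np.ndarray, prevalence: float) -> float:
    """Intercept a with mean(expit(a + scores)) = prevalence."""
    def gap(a):
        return expit(a + scores).mean() - prevalence
    lo, hi = -30.0, 10.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise ValueError("prevalence unreachable with the given effects")
    return float(optimize.brentq(gap, lo, hi, xtol=1e-10))


def simulate_cohorts(config: SimulationConfig):
    """Individual-level simulation of every cohort.

    Returns ``(panels, truth)``: one :class:`GenotypePanel` per cohort
    (phenotype labels "AD"/"PSO"/"control", sex 1/2 at random, no covariate
    columns) and the :class:`SimTruth`.  Fully reproducible from
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    truth = _truth_table(config, rng)
    eafs = _cohort_eafs(truth, config, rng)
    causal = truth["CAUSAL"].to_numpy()
    blocks = truth["BLOCK"].to_numpy()
    # only the causal variant of each block enters the liability
    beta = {"AD": np.where(causal, truth["BETA_AD"].to_numpy(), 0.0),
            "PSO": np.where(causal, truth["BETA_PSO"].to_numpy(), 0.0)}
    prev = {"AD": config.prevalence_ad, "PSO": config.prevalence_pso}

    panels = []
    for c in config.cohorts:
        eaf = eafs[c.name].to_numpy()
        b = beta[c.disease]
        # calibrate the intercept on a dedicated pool
        pool = (_simulate_haplotypes(5000, eaf, blocks,
                                     config.ld_copy_prob, rng)
                + _simulate_haplotypes(5000, eaf, blocks,
                                       config.ld_copy_prob, rng))
        intercept = _solve_intercept(pool @ b, prev[c.disease])

        need_ca, need_co = c.n_cases, c.n_controls
        geno_ca, geno_co = [], []
        p_case_mean = prev[c.disease]
        while need_ca > 0 or need_co > 0:
            batch = int(min(200_000, max(
                2000, need_ca / max(p_case_mean, 1e-4),
                need_co / max(1 - p_case_mean, 1e-4)) * 1.3))
            g = (_simulate_haplotypes(batch, eaf, blocks,
                                      config.ld_copy_prob, rng)
                 + _simulate_haplotypes(batch, eaf, blocks,
                                        config.ld_copy_prob, rng))
            case = rng.random(batch) < expit(intercept + g @ b)
            if need_ca > 0:
                take = g[case][:need_ca]
                geno_ca.append(take)
                need_ca -= len(take)
            if need_co > 0:
                take = g[~case][:need_co]
                geno_co.append(take)
                need_co -= len(take)
        g_all = np.vstack(geno_ca + geno_co).astype(float)
        pheno = np.array([c.disease] * c.n_cases
                         + ["control"] * c.n_controls, dtype=object)
        order = rng.permutation(len(pheno))
        panels.append(GenotypePanel(
            sample_ids=np.array([f"{c.name}_{k:05d}"
                                 for k in range(len(pheno))]),
            phenotype=pheno[order],
            dosages=g_all[order],
            variants=truth[["SNP", "CHR", "POS", "EA", "OA"]].copy(),
            sex=rng.integers(1, 3, size=len(pheno)),
        ))
    return panels, SimTruth(table=truth, cohort_eaf=eafs)


def simulate_retrospective(config: SimulationConfig):
    """Per-variant retrospective (case-control) genotype simulation.

    Complements :func:`simulate_cohorts` for harnesses that need many
    *mutually independent* associated variants in one panel: each variant is
    simulated as if it were the sole causal variant — case genotypes drawn
    from ``P(g | case) ∝ P(g) * expit(a + beta g)`` and controls from the
    complement, with the intercept ``a`` solved so the population prevalence
    matches the configuration.  Case-control ascertainment only shifts the
    logistic intercept, so the per-variant log odds ratios recovered by
    association models equal the generating betas.  LD blocks are ignored
    (every variant independent); use :func:`simulate_cohorts` when LD or a
    joint polygenic liability matters.
    """
    rng = np.random.default_rng(config.seed)
    truth = _truth_table(config, rng)
    eafs = _cohort_eafs(truth, config, rng)
    beta = {"AD": truth["BETA_AD"].to_numpy(),
            "PSO": truth["BETA_PSO"].to_numpy()}
    prev = {"AD": config.prevalence_ad, "PSO": config.prevalence_pso}

    panels = []
    for c in config.cohorts:
        eaf = eafs[c.name].to_numpy()
        b = beta[c.disease]
        n = c.n_cases + c.n_controls
        geno = np.empty((n, len(eaf)))
        for j in range(len(eaf)):
            p = eaf[j]
            gp = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
            lin = b[j] * np.arange(3)
            a = optimize.brentq(
                lambda a_: (gp * expit(a_ + lin)).sum() - prev[c.disease],
                -30, 10, xtol=1e-10)
            risk = expit(a + lin)
            p_case = gp * risk / (gp * risk).sum()
            p_ctrl = gp * (1 - risk) / (gp * (1 - risk)).sum()
            geno[:c.n_cases, j] = np.searchsorted(
                np.cumsum(p_case), rng.random(c.n_cases), side="right")
            geno[c.n_cases:, j] = np.searchsorted(
                np.cumsum(p_ctrl), rng.random(c.n_controls), side="right")
        pheno = np.array([c.disease] * c.n_cases
                         + ["control"] * c.n_controls, dtype=object)
        panels.append(GenotypePanel(
            sample_ids=np.array([f"{c.name}_{k:05d}" for k in range(n)]),
            phenotype=pheno, dosages=geno,
            variants=truth[["SNP", "CHR", "POS", "EA", "OA"]].copy(),
            sex=rng.integers(1, 3, size=n)))
    return panels, SimTruth(table=truth, cohort_eaf=eafs)


def summary_se(eaf: np.ndarray, n_cases: int, n_controls: int) -> np.ndarray:
    """Log-odds standard error from the 2x2 allele-count approximation."""
    pq = eaf * (1 - eaf)
    return np.sqrt(1.0 / (2 * n_cases * pq) + 1.0 / (2 * n_controls * pq))


def simulate_summary_stats(config: SimulationConfig):
    """Fast path: draw per-study summary statistics directly.

    For each cohort and variant, ``beta_hat ~ N(true beta, se^2)`` with
    ``se`` from :func:`summary_se` at the cohort's allele frequency and
    sample sizes.  Returns ``(studies, truth)`` with one
    :class:`StudySummary` per cohort, alleles already harmonized.
    """
    rng = np.random.default_rng(config.seed)
    truth = _truth_table(config, rng)
    eafs = _cohort_eafs(truth, config, rng)
    beta = {"AD": truth["BETA_AD"].to_numpy(),
            "PSO": truth["BETA_PSO"].to_numpy()}
    studies = []
    for c in config.cohorts:
        eaf = eafs[c.name].to_numpy()
        se = summary_se(eaf, c.n_cases, c.n_controls)
        bhat = rng.normal(beta[c.disease], se)
        z = bhat / se
        table = truth[["SNP", "CHR", "POS", "EA", "OA"]].copy()
        table["EAF"] = eaf
        table["BETA"] = bhat
        table["SE"] = se
        table["P"] = np.clip(2 * norm.sf(np.abs(z)), 1e-300, 1.0)
        table["N_CASES"] = c.n_cases
        table["N_CONTROLS"] = c.n_controls
        table["INFO"] = np.nan
        studies.append(StudySummary(
            study_id=c.name, disease=c.disease, table=table,
            subphenotype=c.subphenotype, ancestry_label=c.name))
    return studies, SimTruth(table=truth, cohort_eaf=eafs)


def pool_panels(panels, add_study_indicators: bool = False) -> GenotypePanel:
    """Concatenate cohort panels sample-wise for pooled multinomial fits.

    All panels must carry identical variant tables.  ``add_study_indicators``
    adds one 0/1 covariate column per non-reference cohort; leave it off
    when every cohort contributes cases of a single disease — the indicator
    then perfectly predicts the absence of the other disease and the
    multinomial likelihood is quasi-separated.  Ancestry-style covariates
    (MDS principal components) are the preferred adjustment in that design.
    """
    ref = panels[0].variants
    for p in panels[1:]:
        if not ref["SNP"].equals(p.variants["SNP"]):
            raise ValueError("panels must share an identical variant table")
    n_tot = sum(p.n_samples for p in panels)
    covs = {}
    if add_study_indicators:
        start = 0
        for i, p in enumerate(panels):
            if i > 0:
                col = np.zeros(n_tot)
                col[start:start + p.n_samples] = 1.0
                covs[f"study_{i}"] = col
            start += p.n_samples
    existing = [p.covariates for p in panels]
    if all(e is not None for e in existing):
        joined = pd.concat([e.reset_index(drop=True) for e in existing],
                           ignore_index=True)
        for c in joined.columns:
            covs[c] = joined[c].to_numpy()
    return GenotypePanel(
        sample_ids=np.concatenate([p.sample_ids for p in panels]),
        phenotype=np.concatenate([p.phenotype for p in panels]),
        dosages=np.vstack([p.dosages for p in panels]),
        variants=ref.copy(),
        sex=(np.concatenate([np.asarray(p.sex) for p in panels])
             if all(p.sex is not None for p in panels) else None),
        covariates=pd.DataFrame(covs) if covs else None,
    )
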