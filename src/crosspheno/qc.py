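"""Variant- and sample-level quality control.

Implements the exact Hardy-Weinberg test (conditional distribution of the
heterozygote count given allele counts), threshold-based variant filtering,
PLINK-style method-of-moments relatedness (PI_HAT), classical
multidimensional scaling of the identity-by-state matrix, and the genomic
control inflation factor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    MISSING_DOSAGE,
    GenotypePanel,
    QCThresholds,
    StudySummary,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test


def hwe_het_distribution(n: int, n_a: int) -> tuple[np.ndarray, np.ndarray]:
    """Conditional pmf of the heterozygote count given allele counts.

    Parameters
    ----------
    n
        Number of diploid genotypes.
    n_a
        Count of the rarer allele (0 <= n_a <= n; 2n - n_a copies of the
        other allele).

    Returns ``(het_values, probabilities)`` where ``het_values`` runs over
    the attainable heterozygote counts (same parity as ``n_a``).  Uses the
    stable ratio recurrence
    ``P(h+2)/P(h) = (na-h)(nb-h) / ((h+2)(h+1))`` with
    ``na, nb`` the two allele counts, normalised at the end.
    """
    n_b = 2 * n - n_a
    if n_a > n_b:
        n_a, n_b = n_b, n_a
    h_min = n_a % 2
    hets = np.arange(h_min, n_a + 1, 2)
    logp = np.zeros(len(hets))
    for i in range(1, len(hets)):
        h = hets[i - 1]
        ratio = (n_a - h) * (n_b - h) / ((h + 2.0) * (h + 1.0))
        logp[i] = logp[i - 1] + np.log(ratio)
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    return hets, p


def hwe_exact_p(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Two-sided exact Hardy-Weinberg p-value.

    Sums the conditional probabilities of all heterozygote configurations no
    more probable than the observed one, given the allele counts.
    Monomorphic variants return 1.0 by convention.
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValueError("no genotypes")
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    rare = min(n_a, n_b)
    if rare == 0:
        return 1.0
    hets, probs = hwe_het_distribution(n, rare)
    p_obs = probs[np.searchsorted(hets, n_ab)]
    # tolerance guards against ties lost to floating-point rounding
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# Variant filtering


def _genotype_counts(dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Hard-call genotype counts per variant, ignoring missing entries."""
    obs = dosages != MISSING_DOSAGE
    g = np.rint(dosages)
    n_bb = ((g == 0) & obs).sum(axis=0)   # homozygous other
    n_ab = ((g == 1) & obs).sum(axis=0)
    n_aa = ((g == 2) & obs).sum(axis=0)   # homozygous effect
    return n_aa, n_ab, n_bb


def filter_variants(data, thresholds: QCThresholds | None = None):
    """Apply per-variant QC thresholds to a panel or a summary table.

    For a :class:`GenotypePanel`: missingness, MAF and exact HWE are
    evaluated from the dosage matrix.  For a :class:`StudySummary`: MAF from
    ``EAF`` and the imputation-info rule from ``INFO`` apply (missingness and
    HWE need individual-level data).  All rule boundaries are strict in the
    failing direction, e.g. info 0.39 fails but 0.40 passes.

    Returns ``(retained_ids, reasons)`` where ``reasons`` maps a removed
    variant id to the list of all rule codes it violated
    (``"missing" | "maf" | "hwe" | "info"``).
    """
    thresholds = thresholds or QCThresholds()
    reasons: dict[str, list[str]] = {}

    if isinstance(data, GenotypePanel):
        ids = data.variants["SNP"].tolist()
        miss = (data.dosages == MISSING_DOSAGE).mean(axis=0)
        n_aa, n_ab, n_bb = _genotype_counts(data.dosages)
        n_obs = n_aa + n_ab + n_bb
        with np.errstate(invalid="ignore", divide="ignore"):
            eaf = np.where(n_obs > 0, (2 * n_aa + n_ab) / (2 * n_obs), 0.0)
        maf = np.minimum(eaf, 1 - eaf)
        hwe_p = np.array([
            hwe_exact_p(int(a), int(b), int(c)) if nt > 0 else 1.0
            for a, b, c, nt in zip(n_aa, n_ab, n_bb, n_obs)])
        for i, vid in enumerate(ids):
            r = []
            if miss[i] > thresholds.max_variant_missing:
                r.append("missing")
            if maf[i] < thresholds.min_maf:
                r.append("maf")
            if hwe_p[i] < thresholds.min_hwe_p:
                r.append("hwe")
            if r:
                reasons[vid] = r
    elif isinstance(data, StudySummary):
        t = data.table
        ids = t["SNP"].tolist()
        maf = np.minimum(t["EAF"], 1 - t["EAF"]).to_numpy()
        info = t["INFO"].to_numpy(dtype=float)
        for i, vid in enumerate(ids):
            r = []
            if maf[i] < thresholds.min_maf:
                r.append("maf")
            if np.isfinite(info[i]) and info[i] < thresholds.min_info:
                r.append("info")
            if r:
                reasons[vid] = r
    else:
        raise TypeError("expected GenotypePanel or StudySummary")

    retained = [v for v in ids if v not in reasons]
    return retained, reasons


# ---------------------------------------------------------------------------
# Relatedness


@dataclass
class RelatednessEstimate:
    sample_pair: tuple
    ibs0: int
    ibs1: int
    ibs2: int
    pihat: float


def _moment(x: np.ndarray, t: np.ndarray, a: int, b: int) -> np.ndarray:
    """Unbiased estimate of ``p^a * q^b`` from ``x`` of ``t`` allele draws.

    Uses falling-factorial moments of the hypergeometric-style counts,
    which removes the small-sample bias that plagues plug-in powers of the
    estimated frequency (the correction the PLINK moments estimator
    applies).  With exact frequencies supplied, callers bypass this and use
    plain products.
    """
    num = np.ones_like(x, dtype=float)
    for k in range(a):
        num *= x - k
    for k in range(b):
        num *= (t - x) - k
    den = np.ones_like(x, dtype=float)
    for k in range(a + b):
        den *= t - k
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.clip(num / den, 0.0, 1.0)


def estimate_relatedness(panel: GenotypePanel, pair,
                         allele_freqs=None) -> RelatednessEstimate:
    """PLINK-style method-of-moments PI_HAT for one sample pair.

    Counts IBS sharing over jointly non-missing hard-called variants, forms
    the expected IBS composition under IBD states 0/1/2 from allele
    frequencies, solves for the IBD-state proportions and returns
    ``PI_HAT = P(IBD=1)/2 + P(IBD=2)`` clipped to [0, 1].

    With ``allele_freqs=None`` (default) the frequency products entering
    the expectations are estimated without bias from the panel's allele
    counts via factorial moments; pass known frequencies to use exact
    plug-in products instead.
    """
    i, j = pair
    ids = list(panel.sample_ids)
    a, b = ids.index(i), ids.index(j)
    ga = np.rint(panel.dosages[a])
    gb = np.rint(panel.dosages[b])
    ok = (panel.dosages[a] != MISSING_DOSAGE) & (panel.dosages[b] != MISSING_DOSAGE)

    if allele_freqs is None:
        obs = panel.dosages != MISSING_DOSAGE
        g = np.where(obs, np.rint(panel.dosages), 0.0)
        x = g.sum(axis=0)                    # effect-allele count
        t = 2.0 * obs.sum(axis=0)            # total alleles observed
        ok &= (x > 0) & (x < t) & (t >= 4)
        x, t = x, t
        use_counts = True
    else:
        p_in = np.asarray(allele_freqs, dtype=float)
        ok &= np.isfinite(p_in) & (p_in > 0) & (p_in < 1)
        use_counts = False
    if ok.sum() == 0:
        raise ValueError("no jointly observed polymorphic variants for pair")
    if ok.sum() < 100:
        logger.warning("relatedness estimate from only %d variants", ok.sum())
    ga, gb = ga[ok], gb[ok]

    diff = np.abs(ga - gb)
    ibs2 = int((diff == 0).sum())
    ibs1 = int((diff == 1).sum())
    ibs0 = int((diff == 2).sum())

    if use_counts:
        x, t = x[ok], t[ok]
        p2q2 = _moment(x, t, 2, 2)
        e0_ibs0 = 2 * p2q2
        e0_ibs1 = 4 * _moment(x, t, 3, 1) + 4 * _moment(x, t, 1, 3)
        e1_ibs1 = 2 * _moment(x, t, 2, 1) + 2 * _moment(x, t, 1, 2)
        e0_ibs2 = _moment(x, t, 4, 0) + _moment(x, t, 0, 4) + 4 * p2q2
        e1_ibs2 = _moment(x, t, 2, 0) + _moment(x, t, 0, 2)
    else:
        p = p_in[ok]
        q = 1 - p
        e0_ibs0 = 2 * p**2 * q**2
        e0_ibs1 = 4 * p**3 * q + 4 * p * q**3
        e1_ibs1 = 2 * p**2 * q + 2 * p * q**2
        e0_ibs2 = p**4 + q**4 + 4 * p**2 * q**2
        e1_ibs2 = p**2 + q**2

    z0 = ibs0 / e0_ibs0.sum()
    z1 = (ibs1 - z0 * e0_ibs1.sum()) / e1_ibs1.sum()
    z2 = (ibs2 - z0 * e0_ibs2.sum() - z1 * e1_ibs2.sum()) / len(ga)
    z0, z1, z2 = np.clip([z0, z1, z2], 0, 1)
    s = z0 + z1 + z2
    if s > 0:
        z0, z1, z2 = z0 / s, z1 / s, z2 / s
    pihat = float(np.clip(z1 / 2 + z2, 0, 1))
    return RelatednessEstimate((i, j), ibs0, ibs1, ibs2, pihat)


# ---------------------------------------------------------------------------
# IBS / MDS


def ibs_matrix(panel: GenotypePanel) -> np.ndarray:
    """Pairwise proportion of alleles shared identical-by-state."""
    d = panel.dosages
    obs = d != MISSING_DOSAGE
    g = np.where(obs, np.rint(d), 0.0)
    n = panel.n_samples
    sim = np.zeros((n, n))
    counts = obs.astype(float) @ obs.T.astype(float)
    for a in range(n):
        diff = np.abs(g[a] - g)                # (n, m)
        diff[~(obs[a] & obs)] = 0.0
        sim[a] = 2 * counts[a] - diff.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(counts > 0, sim / (2 * counts), 1.0)


def mds_of_ibs(panel: GenotypePanel, k: int = 4) -> np.ndarray:
    """Classical (Torgerson) MDS of the IBS distance matrix.

    Distance = 1 - IBS similarity.  Returns an ``(n_samples, k)`` coordinate
    matrix ordered by decreasing eigenvalue; axes are deterministic up to
    sign.  If fewer than ``k`` positive eigenvalues exist, the trailing axes
    are zero-padded with a warning.
    """
    if panel.n_samples < k + 1:
        raise ValueError("need at least k+1 samples")
    dist = 1.0 - ibs_matrix(panel)
    d2 = dist**2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > max(vals.max(), 0) * 1e-12
    n_pos = int(pos[:k].sum())
    if n_pos < k:
        logger.warning("IBS matrix supports only %d of %d MDS axes", n_pos, k)
    coords = np.zeros((n, k))
    coords[:, :n_pos] = vecs[:, :n_pos] * np.sqrt(vals[:n_pos])
    return coords


# ---------------------------------------------------------------------------
# Sample-level QC


def sample_qc(panel: GenotypePanel,
              thresholds: QCThresholds | None = None) -> pd.DataFrame:
    """Per-sample missingness and heterozygosity report with exclusion flags.

    A sample fails on missingness above ``max_sample_missing`` or on a
    heterozygosity rate beyond ``het_sd`` standard deviations from the panel
    mean (excess heterozygosity suggests contamination, excess homozygosity
    inbreeding or genotyping failure).
    """
    thresholds = thresholds or QCThresholds()
    obs = panel.dosages != MISSING_DOSAGE
    miss = 1 - obs.mean(axis=1)
    het = np.where(obs, np.rint(panel.dosages) == 1, False).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        het_rate = np.where(obs.sum(axis=1) > 0, het / obs.sum(axis=1), np.nan)
    mu, sd = np.nanmean(het_rate), np.nanstd(het_rate)
    het_out = (np.abs(het_rate - mu) > thresholds.het_sd * sd) if sd > 0 \
        else np.zeros(len(het_rate), bool)
    return pd.DataFrame({
        "SAMPLE_ID": panel.sample_ids,
        "MISSING_RATE": miss,
        "HET_RATE": het_rate,
        "FAIL_MISSING": miss > thresholds.max_sample_missing,
        "FAIL_HET": het_out,
    })


def ld_prune(panel: GenotypePanel, max_r2: float = 0.2,
             window: int = 50) -> np.ndarray:
    """Greedy window-based LD pruning; returns indices of retained variants.

    Within a sliding window of ``window`` variants, a variant is dropped
    when its squared dosage correlation with any already-retained variant in
    the window reaches ``max_r2``.  Used to thin markers before
    identity-by-descent estimation, where dense LD would double-count
    information.
    """
    d = panel.dosages
    obs = d != MISSING_DOSAGE
    keep: list[int] = []
    for j in range(panel.n_variants):
        ok = True
        for k in reversed(keep):
            if j - k > window:
                break
            both = obs[:, j] & obs[:, k]
            a, b = d[both, j], d[both, k]
            if len(a) < 2 or a.std() == 0 or b.std() == 0:
                continue
            if np.corrcoef(a, b)[0, 1] ** 2 >= max_r2:
                ok = False
                break
        if ok:
            keep.append(j)
    return np.asarray(keep, dtype=int)


def flag_related_samples(panel: GenotypePanel,
                         thresholds: QCThresholds | None = None,
                         prune: bool = True):
    """All-pairs PI_HAT screen; returns samples to drop and the estimates.

    Markers are LD-pruned (r² < 0.2 in a sliding window) before estimation.
    For each pair above ``max_pihat`` the member with the higher missing
    rate is flagged for removal.
    """
    thresholds = thresholds or QCThresholds()
    if prune:
        panel = panel.subset_variants(ld_prune(panel))
    obs = panel.dosages != MISSING_DOSAGE
    miss = 1 - obs.mean(axis=1)
    drop, estimates = set(), []
    ids = list(panel.sample_ids)
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            est = estimate_relatedness(panel, (ids[a], ids[b]))
            estimates.append(est)
            if est.pihat > thresholds.max_pihat:
                drop.add(ids[a] if miss[a] >= miss[b] else ids[b])
    return drop, estimates


# ---------------------------------------------------------------------------
# Genomic control


@dataclass
class InflationEstimate:
    lambda_gc: float
    n_variants: int


def lambda_gc(p_values) -> InflationEstimate:
    """Genomic-control inflation factor.

    The median of the 1-df chi-square statistics implied by the p-values,
    divided by the theoretical null median (~0.456).
    """
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p) & (p > 0) & (p <= 1)]
    if len(p) < 100:
        logger.warning("lambda_gc from only %d p-values", len(p))
    chi2 = stats.chi2.isf(p, df=1)
    null_median = stats.chi2.ppf(0.5, df=1)
    return InflationEstimate(float(np.median(chi2) / null_median), len(p))
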