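"""Per-study logistic association and per-disease fixed-effects meta-analysis.

The cross-phenotype statistics downstream consume one signed z-score per
disease per variant: ``T1`` from the meta-analysis of the atopic-dermatitis
studies and ``T2`` from the psoriasis studies, both oriented to a common
effect allele.  Two pooling schemes are provided: inverse-variance weighting
of (beta, se) — the default — and the sample-size-weighted z-score scheme.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .datatypes import MISSING_DOSAGE, GenotypePanel, StudySummary

logger = logging.getLogger(__name__)


class SeparationError(RuntimeError):
    """Logistic fit did not converge (typically quasi-complete separation)."""


def study_logistic_assoc(panel: GenotypePanel, variant_id: str,
                         case_label: str, covariate_cols=None,
                         maxiter: int = 50):
    """Single-variant logistic regression of case status on dosage.

    Cases are samples with ``phenotype == case_label``; controls are
    ``"control"`` samples.  Covariates (columns of ``panel.covariates``, plus
    sex when present) enter additively; samples missing the dosage are
    dropped.  Returns ``(beta, se, p)`` for the dosage term.
    """
    is_case = panel.phenotype == case_label
    is_ctrl = panel.phenotype == "control"
    use = is_case | is_ctrl
    dose = panel.dosage_of(variant_id)
    use &= dose != MISSING_DOSAGE
    y = is_case[use].astype(float)
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("both phenotype classes must be present")

    cols = [np.ones(use.sum()), dose[use]]
    if panel.sex is not None:
        cols.append(np.asarray(panel.sex, dtype=float)[use])
    if covariate_cols and panel.covariates is not None:
        for c in covariate_cols:
            cols.append(panel.covariates[c].to_numpy(dtype=float)[use])
    x = np.column_stack(cols)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("covariate matrix is rank deficient")

    try:
        fit = sm.Logit(y, x).fit(method="newton", disp=0, maxiter=maxiter)
    except Exception as exc:  # pragma: no cover - statsmodels raises variously
        raise SeparationError(str(exc)) from exc
    if not fit.mle_retvals.get("converged", True) or abs(fit.params[1]) > 15:
        raise SeparationError(
            f"{variant_id}: non-converged or separated logistic fit")
    beta = float(fit.params[1])
    se = float(fit.bse[1])
    p = float(2 * stats.norm.sf(abs(beta / se)))
    return beta, se, p


def fixed_effects_meta(effects) -> dict:
    """Inverse-variance fixed-effects pooling of per-study (beta, se).

    Returns a dict with ``pooled_beta``, ``pooled_se``, ``z``, ``p``,
    ``n_studies`` and Cochran's ``heterogeneity_q``.
    """
    effects = list(effects)
    if not effects:
        raise ValueError("need at least one study")
    beta = np.array([e[0] for e in effects], dtype=float)
    se = np.array([e[1] for e in effects], dtype=float)
    if (se <= 0).any():
        raise ValueError("all standard errors must be positive")
    w = 1.0 / se**2
    pooled_beta = float((w * beta).sum() / w.sum())
    pooled_se = float(w.sum() ** -0.5)
    z = pooled_beta / pooled_se
    q = float((w * (beta - pooled_beta) ** 2).sum())
    return {
        "pooled_beta": pooled_beta,
        "pooled_se": pooled_se,
        "z": float(z),
        "p": float(2 * stats.norm.sf(abs(z))),
        "n_studies": len(effects),
        "heterogeneity_q": q,
    }


def sample_size_meta(z_and_n) -> float:
    """Sample-size-weighted z-score pooling: z = Σ√n_i·z_i / √Σn_i."""
    z_and_n = list(z_and_n)
    z = np.array([t[0] for t in z_and_n], dtype=float)
    n = np.array([t[1] for t in z_and_n], dtype=float)
    if (n <= 0).any():
        raise ValueError("all sample sizes must be positive")
    return float((np.sqrt(n) * z).sum() / np.sqrt(n.sum()))


def effective_sample_size(n_cases: int, n_controls: int) -> float:
    """METAL-style effective n for case-control studies: 4/(1/nca+1/nco)."""
    return 4.0 / (1.0 / n_cases + 1.0 / n_controls)


def meta_analyze_studies(studies, *, scheme: str = "ivw") -> pd.DataFrame:
    """Meta-analyse harmonized studies of one disease over shared variants.

    Variants are matched on ``SNP``; only variants present in every study
    enter.  Returns a frame with columns
    ``SNP CHR POS EA OA BETA SE Z P N_STUDIES Q`` (``BETA``/``SE`` are NaN
    under the sample-size scheme, which pools z-scores only).
    """
    if scheme not in ("ivw", "samplesize"):
        raise ValueError("scheme must be 'ivw' or 'samplesize'")
    studies = list(studies)
    if not studies:
        raise ValueError("no studies")
    diseases = {s.disease for s in studies}
    if len(diseases) > 1:
        raise ValueError(f"mixed diseases in one meta-analysis: {diseases}")
    common = set(studies[0].table["SNP"])
    for s in studies[1:]:
        common &= set(s.table["SNP"])
    order = sorted(common)
    tables = [s.table.set_index("SNP").loc[order] for s in studies]

    ea = np.column_stack([t["EA"].to_numpy() for t in tables])
    same_ea = (ea == ea[:, :1]).all(axis=1)
    for snp in np.asarray(order)[~same_ea][:20]:
        logger.warning("skipping %s: unharmonized effect alleles", snp)

    beta = np.column_stack([t["BETA"].to_numpy(float) for t in tables])
    se = np.column_stack([t["SE"].to_numpy(float) for t in tables])
    k = len(tables)
    if scheme == "ivw":
        w = 1.0 / se**2
        pooled_beta = (w * beta).sum(axis=1) / w.sum(axis=1)
        pooled_se = w.sum(axis=1) ** -0.5
        z = pooled_beta / pooled_se
        q = (w * (beta - pooled_beta[:, None]) ** 2).sum(axis=1)
    else:
        n_eff = np.column_stack([
            effective_sample_size(t["N_CASES"].to_numpy(float),
                                  t["N_CONTROLS"].to_numpy(float))
            for t in tables])
        z = (np.sqrt(n_eff) * beta / se).sum(axis=1) / np.sqrt(
            n_eff.sum(axis=1))
        pooled_beta = pooled_se = q = np.full(len(order), np.nan)

    base = tables[0]
    out = pd.DataFrame({
        "SNP": order, "CHR": base["CHR"].to_numpy(),
        "POS": base["POS"].to_numpy(), "EA": base["EA"].to_numpy(),
        "OA": base["OA"].to_numpy(), "BETA": pooled_beta, "SE": pooled_se,
        "Z": z, "P": 2 * stats.norm.sf(np.abs(z)),
        "N_STUDIES": k, "Q": q})
    return out[same_ea].reset_index(drop=True)
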