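"""Multinomial case-case-control modelling with Wald linear contrasts.

Controls form the baseline outcome category and the two diseases are
modelled jointly:

    P(outcome = d | x) = exp(x' beta_d) / (1 + sum_d' exp(x' beta_d')),

with ``beta_control = 0``.  For each variant the dosage coefficients
``beta_AD`` and ``beta_PSO`` (log odds versus control) and their joint
covariance feed five Wald tests: the 2-df overall test of
``(beta_PSO, beta_AD) = (0, 0)`` and four 1-df contrasts — per-disease
(``beta_PSO = 0``, ``beta_AD = 0``), shared (``beta_PSO + beta_AD = 0``) and
opposing (``beta_PSO - beta_AD = 0``).  The variant is categorized by the
smallest of the four 1-df p-values (``p_MNM``): a single-disease test is
most powerful for a disease-specific allele, the sum contrast for a
same-direction effect, and the difference contrast for an antagonistic one.

Stepwise conditional analysis dissects multi-signal regions (epidermal
differentiation complex, MHC): known causal carriers (e.g. FLG-null
mutations, the LCE3B-LCE3C deletion) enter as conditioning covariates, the
most significant remaining variant is added, and the scan repeats until no
variant clears the stop threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .datatypes import MISSING_DOSAGE, GenotypePanel

logger = logging.getLogger(__name__)

CATEGORIES = ("AD", "PSO", "shared", "opposing")

#: Default stop threshold for the stepwise scan (the "suggestive" level).
DEFAULT_STOP_P = 1e-5

#: Conditioning columns above this r² with the existing set are skipped.
COLLINEARITY_R2 = 0.95


@dataclass
class MnmResult:
    """One variant's multinomial fit and the five Wald tests."""

    beta_ad: float
    se_ad: float
    beta_pso: float
    se_pso: float
    cov: np.ndarray                       # 2x2, order (PSO, AD)
    p_overall: float
    p_ad: float
    p_pso: float
    p_shared: float
    p_opposing: float
    p_mnm: float
    category: str
    converged: bool = True
    n_samples: int = 0

    @property
    def or_ad(self) -> float:
        return float(np.exp(self.beta_ad))

    @property
    def or_pso(self) -> float:
        return float(np.exp(self.beta_pso))

    def ci_ad(self, z: float = 1.959963984540054) -> tuple[float, float]:
        return (float(np.exp(self.beta_ad - z * self.se_ad)),
                float(np.exp(self.beta_ad + z * self.se_ad)))

    def ci_pso(self, z: float = 1.959963984540054) -> tuple[float, float]:
        return (float(np.exp(self.beta_pso - z * self.se_pso)),
                float(np.exp(self.beta_pso + z * self.se_pso)))


class MnmFitError(RuntimeError):
    """The multinomial likelihood could not be maximized reliably."""


_PHENO_CODE = {"control": 0, "AD": 1, "PSO": 2}


def _design(panel: GenotypePanel, dose: np.ndarray, covariate_cols,
            extra: dict | None):
    """Assemble outcome codes and design matrix; drops missing-dosage rows."""
    use = dose != MISSING_DOSAGE
    if extra:
        for v in extra.values():
            use &= np.asarray(v) != MISSING_DOSAGE
    y = np.array([_PHENO_CODE[p] for p in panel.phenotype])[use]
    cols = [np.ones(use.sum()), dose[use]]
    names = ["const", "dosage"]
    if panel.sex is not None:
        cols.append(np.asarray(panel.sex, dtype=float)[use])
        names.append("sex")
    if covariate_cols and panel.covariates is not None:
        for c in covariate_cols:
            cols.append(panel.covariates[c].to_numpy(dtype=float)[use])
            names.append(c)
    if extra:
        for name, v in extra.items():
            cols.append(np.asarray(v, dtype=float)[use])
            names.append(name)
    return y, np.column_stack(cols), names


def fit_multinomial(panel: GenotypePanel, variant_id: str,
                    covariate_cols=None, extra_covariates: dict | None = None,
                    maxiter: int = 100) -> MnmResult:
    """Fit the three-category model for one variant and run the Wald tests.

    ``covariate_cols`` names columns of ``panel.covariates`` (typically the
    first four principal-component scores); sex is included automatically
    when present.  ``extra_covariates`` maps names to per-sample dosage
    vectors used for conditioning.
    """
    dose = panel.dosage_of(variant_id)
    y, x, names = _design(panel, dose, covariate_cols, extra_covariates)
    present = set(np.unique(y))
    if present != {0, 1, 2}:
        raise MnmFitError(
            f"{variant_id}: all three outcome categories required, "
            f"found codes {sorted(present)}")
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise MnmFitError(f"{variant_id}: design matrix rank deficient")
    try:
        fit = sm.MNLogit(y, x).fit(method="newton", disp=0, maxiter=maxiter)
    except Exception as exc:
        raise MnmFitError(f"{variant_id}: {exc}") from exc
    converged = bool(fit.mle_retvals.get("converged", True))

    k = x.shape[1]
    d_idx = names.index("dosage")
    params = np.asarray(fit.params)          # (k, 2): col 0 = AD, col 1 = PSO
    beta_ad = float(params[d_idx, 0])
    beta_pso = float(params[d_idx, 1])
    full_cov = np.asarray(fit.cov_params())  # (2k, 2k), equation-major
    i_ad, i_pso = d_idx, k + d_idx
    cov = np.array([[full_cov[i_pso, i_pso], full_cov[i_pso, i_ad]],
                    [full_cov[i_ad, i_pso], full_cov[i_ad, i_ad]]])
    if not np.all(np.isfinite(params)) or not np.all(np.isfinite(cov)):
        raise MnmFitError(f"{variant_id}: divergent multinomial fit "
                          "(non-finite estimates; check for separation)")
    if not converged or max(abs(beta_ad), abs(beta_pso)) > 15:
        raise MnmFitError(f"{variant_id}: non-converged multinomial fit")

    tests = wald_tests(beta_pso, beta_ad, cov)
    category, p_mnm = classify_mnm(tests)
    return MnmResult(
        beta_ad=beta_ad, se_ad=float(np.sqrt(cov[1, 1])),
        beta_pso=beta_pso, se_pso=float(np.sqrt(cov[0, 0])),
        cov=cov, converged=converged, n_samples=len(y),
        category=category, p_mnm=p_mnm, **tests)


def wald_tests(beta_pso: float, beta_ad: float, cov: np.ndarray) -> dict:
    """The five Wald p-values for one (beta_PSO, beta_AD, covariance) triple.

    ``cov`` is the 2x2 covariance of (beta_PSO, beta_AD).  The four 1-df
    statistics are ``(c'b)^2 / (c' cov c)`` for contrasts (1,0), (0,1),
    (1,1) and (1,-1) on chi-square(1); the overall statistic is the 2-df
    quadratic form ``b' cov^{-1} b`` on chi-square(2) (equivalent to testing
    the sum and difference jointly, since that contrast matrix is
    invertible).
    """
    b = np.array([beta_pso, beta_ad], dtype=float)
    cov = np.asarray(cov, dtype=float)
    if cov.shape != (2, 2):
        raise ValueError("cov must be 2x2")
    if not np.allclose(cov, cov.T) or np.linalg.eigvalsh(cov).min() <= 0:
        raise ValueError("cov must be symmetric positive definite")

    def one_df(c):
        c = np.asarray(c, dtype=float)
        stat = float((c @ b) ** 2 / (c @ cov @ c))
        return float(stats.chi2.sf(stat, df=1))

    overall = float(b @ np.linalg.solve(cov, b))
    return {
        "p_overall": float(stats.chi2.sf(overall, df=2)),
        "p_pso": one_df((1, 0)),
        "p_ad": one_df((0, 1)),
        "p_shared": one_df((1, 1)),
        "p_opposing": one_df((1, -1)),
    }


def classify_mnm(p_values: dict) -> tuple[str, float]:
    """Effect category by the smallest 1-df p-value.

    Ties break in the fixed order AD, PSO, shared, opposing.
    """
    ordered = [p_values["p_ad"], p_values["p_pso"], p_values["p_shared"],
               p_values["p_opposing"]]
    for p in ordered:
        if not 0 <= p <= 1:
            raise ValueError("p-values must lie in [0, 1]")
    idx = int(np.argmin(ordered))
    return CATEGORIES[idx], float(ordered[idx])


@dataclass
class StepwiseSignal:
    variant_id: str
    result: MnmResult
    conditioned_on: list


@dataclass
class StepwiseResult:
    signals: list = field(default_factory=list)
    full_model: dict = field(default_factory=dict)   # variant_id -> MnmResult


def _r2(a: np.ndarray, b: np.ndarray) -> float:
    ok = (a != MISSING_DOSAGE) & (b != MISSING_DOSAGE)
    a, b = a[ok], b[ok]
    if len(a) < 2 or a.std() == 0 or b.std() == 0:
        return 1.0
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def stepwise_conditional(panel: GenotypePanel, region_variant_ids,
                         preconditioned: dict | None = None,
                         stop_p: float = DEFAULT_STOP_P,
                         covariate_cols=None,
                         max_signals: int = 20) -> StepwiseResult:
    """Forward stepwise conditional dissection of a region.

    Starting from the ``preconditioned`` covariates (name -> dosage vector,
    e.g. known-mutation carrier counts), every region variant is refit with
    the current conditioning set; the variant with the smallest ``p_MNM`` is
    added as a new conditioning covariate if ``p_MNM < stop_p``, and the scan
    repeats.  Variants nearly collinear with the conditioning set
    (r² > 0.95) are skipped with a warning.  Ends with a joint "full model"
    fit of all selected variants.
    """
    conditioning = dict(preconditioned or {})
    region = list(region_variant_ids)
    result = StepwiseResult()
    selected: list[str] = []
    while len(selected) < max_signals:
        best = None
        for vid in region:
            if vid in selected:
                continue
            dose = panel.dosage_of(vid)
            if any(_r2(dose, np.asarray(v)) > COLLINEARITY_R2
                   for v in conditioning.values()):
                logger.warning("skipping %s: collinear with conditioning set",
                               vid)
                continue
            try:
                res = fit_multinomial(panel, vid, covariate_cols,
                                      extra_covariates=conditioning or None)
            except MnmFitError as exc:
                logger.warning("stepwise skip: %s", exc)
                continue
            if best is None or res.p_mnm < best[1].p_mnm:
                best = (vid, res)
        if best is None or not best[1].p_mnm < stop_p:
            break
        vid, res = best
        result.signals.append(StepwiseSignal(
            variant_id=vid, result=res,
            conditioned_on=list(conditioning.keys())))
        conditioning[vid] = panel.dosage_of(vid)
        selected.append(vid)

    # joint fit of all selected signals plus the original conditioning set
    if selected:
        base = dict(preconditioned or {})
        for vid in selected:
            extra = dict(base)
            for other in selected:
                if other != vid:
                    extra[other] = panel.dosage_of(other)
            try:
                result.full_model[vid] = fit_multinomial(
                    panel, vid, covariate_cols,
                    extra_covariates=extra or None)
            except MnmFitError as exc:
                logger.warning("full-model refit failed for %s: %s", vid, exc)
    return result
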