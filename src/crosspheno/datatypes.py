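"""Core domain types shared across the package.

Conventions used throughout:

* positions are 1-based base pairs (hg19-style coordinates); interval logic
  uses closed intervals;
* effect sizes (``beta``) are log odds ratios oriented to the effect allele;
* dosages live in [0, 2] counts of the effect allele; a missing dosage is
  encoded by the sentinel :data:`MISSING_DOSAGE` (outside the valid range) and
  every downstream operation must mask it explicitly;
* the two diseases are labelled ``"AD"`` (atopic dermatitis) and ``"PSO"``
  (psoriasis); controls are the common baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel for a missing dosage; deliberately outside [0, 2].
MISSING_DOSAGE: float = -1.0

#: Canonical summary-statistic column order.
SUMMARY_COLUMNS = [
    "SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P",
    "N_CASES", "N_CONTROLS", "INFO",
]

DISEASES = ("AD", "PSO")
SUBPHENOTYPES = ("general", "childhood")
PHENOTYPE_LEVELS = ("control", "AD", "PSO")

_VALID_BASES = set("ACGT")


def _is_valid_allele(a: str) -> bool:
    """Alleles are non-empty A/C/G/T strings or indel tokens (I/D/<...>)."""
    if not a:
        return False
    if set(a) <= _VALID_BASES:
        return True
    return a in ("I", "D", "-") or (a.startswith("<") and a.endswith(">"))


@dataclass(frozen=True)
class VariantKey:
    """Identity of one bi-allelic variant, oriented to an effect allele."""

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"effect and other allele identical: {self.effect_allele}")
        for a in (self.effect_allele, self.other_allele):
            if not _is_valid_allele(a):
                raise ValueError(f"invalid allele {a!r}")

    @property
    def allele_set(self) -> frozenset:
        return frozenset((self.effect_allele, self.other_allele))

    def is_palindromic(self) -> bool:
        """A/T or C/G pairs: strand orientation cannot be resolved from alleles."""
        return self.allele_set in (frozenset("AT"), frozenset("CG"))


@dataclass
class StudySummary:
    """Per-variant association evidence for one case-control study.

    ``table`` carries one row per variant with columns
    ``SNP, CHR, POS, EA, OA, EAF, BETA, SE, P, N_CASES, N_CONTROLS, INFO``
    (``INFO`` may be NaN for genotyped variants).
    """

    study_id: str
    disease: str
    table: pd.DataFrame
    subphenotype: str = "general"
    ancestry_label: str = ""

    def __post_init__(self) -> None:
        if self.disease not in DISEASES:
            raise ValueError(f"disease must be one of {DISEASES}, got {self.disease!r}")
        if self.subphenotype not in SUBPHENOTYPES:
            raise ValueError(f"subphenotype must be one of {SUBPHENOTYPES}")
        t = self.table
        missing = [c for c in SUMMARY_COLUMNS if c != "INFO" and c not in t.columns]
        if missing:
            raise ValueError(f"summary table missing columns: {missing}")
        if "INFO" not in t.columns:
            t = t.copy()
            t["INFO"] = np.nan
        self.table = t.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        t = self.table
        if t["SNP"].duplicated().any():
            dup = t.loc[t["SNP"].duplicated(), "SNP"].iloc[0]
            raise ValueError(f"duplicate variant_id within study: {dup}")
        if not (t["SE"] > 0).all():
            raise ValueError("all SE must be > 0")
        if not ((t["P"] > 0) & (t["P"] <= 1)).all():
            raise ValueError("all P must be in (0, 1]")
        if not ((t["EAF"] >= 0) & (t["EAF"] <= 1)).all():
            raise ValueError("all EAF must be in [0, 1]")
        info = t["INFO"].dropna()
        if len(info) and not ((info >= 0) & (info <= 1)).all():
            raise ValueError("INFO must be in [0, 1] where present")

    def __len__(self) -> int:
        return len(self.table)

    def variant_keys(self) -> list[VariantKey]:
        return [
            VariantKey(r.SNP, str(r.CHR), int(r.POS), r.EA, r.OA)
            for r in self.table.itertuples()
        ]


@dataclass
class GenotypePanel:
    """Individual-level dosage data with phenotype and covariates.

    ``dosages`` is a ``(n_samples, n_variants)`` float array of effect-allele
    counts in [0, 2]; missing entries hold :data:`MISSING_DOSAGE`.
    ``variants`` is a DataFrame with columns ``SNP, CHR, POS, EA, OA``.
    """

    sample_ids: np.ndarray
    phenotype: np.ndarray          # values in PHENOTYPE_LEVELS
    dosages: np.ndarray
    variants: pd.DataFrame
    sex: np.ndarray | None = None  # 1 = male, 2 = female convention
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids)
        self.phenotype = np.asarray(self.phenotype)
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if len(self.sample_ids) != n or len(self.phenotype) != n:
            raise ValueError("sample dimension mismatch")
        if len(self.variants) != m:
            raise ValueError("variant dimension mismatch")
        bad = set(np.unique(self.phenotype)) - set(PHENOTYPE_LEVELS)
        if bad:
            raise ValueError(f"unknown phenotype levels: {bad}")
        obs = self.dosages[self.dosages != MISSING_DOSAGE]
        if obs.size and ((obs < 0) | (obs > 2)).any():
            raise ValueError("non-missing dosages must lie in [0, 2]")
        if self.covariates is not None and len(self.covariates) != n:
            raise ValueError("covariate rows must match samples")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING_DOSAGE

    def dosage_of(self, variant_id: str) -> np.ndarray:
        idx = self.variants.index[self.variants["SNP"] == variant_id]
        if len(idx) == 0:
            raise KeyError(variant_id)
        return self.dosages[:, idx[0]]

    def subset_samples(self, mask: np.ndarray) -> "GenotypePanel":
        return GenotypePanel(
            sample_ids=self.sample_ids[mask],
            phenotype=self.phenotype[mask],
            dosages=self.dosages[mask],
            variants=self.variants,
            sex=None if self.sex is None else np.asarray(self.sex)[mask],
            covariates=None if self.covariates is None
            else self.covariates.loc[mask].reset_index(drop=True),
        )

    def subset_variants(self, idx: np.ndarray) -> "GenotypePanel":
        idx = np.asarray(idx)
        return GenotypePanel(
            sample_ids=self.sample_ids,
            phenotype=self.phenotype,
            dosages=self.dosages[:, idx],
            variants=self.variants.iloc[idx].reset_index(drop=True),
            sex=self.sex,
            covariates=self.covariates,
        )


@dataclass
class HlaCallTable:
    """Probabilistic classical-allele calls.

    ``probabilities`` has shape ``(n_samples, n_alleles, 3)``: for each sample
    and classical allele, the probabilities of carrying 0, 1 or 2 copies.
    """

    sample_ids: np.ndarray
    alleles: list
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        n, a, c = self.probabilities.shape
        if n != len(self.sample_ids) or a != len(self.alleles) or c != 3:
            raise ValueError("probability array shape mismatch")
        if (self.probabilities < 0).any():
            raise ValueError("negative probabilities")
        if (self.probabilities.sum(axis=2) > 1 + 1e-6).any():
            raise ValueError("copy-number probabilities sum above 1")


@dataclass
class QCThresholds:
    """Variant- and sample-level QC cutoffs.

    Defaults follow common ImmunoChip/GWAS practice for this design:
    missingness > 5%, MAF < 5%, HWE p < 1e-8 and imputation info < 0.4
    remove a variant; samples fail above 5% missingness or PI_HAT > 0.1875
    (halfway between second- and third-degree relative expectation).
    """

    max_variant_missing: float = 0.05
    min_maf: float = 0.05
    min_hwe_p: float = 1e-8
    min_info: float = 0.4
    min_call_rate: float = 0.95
    max_pihat: float = 0.1875
    max_sample_missing: float = 0.05
    het_sd: float = 3.0

    def __post_init__(self) -> None:
        for name in ("max_variant_missing", "min_maf", "min_hwe_p",
                     "min_call_rate", "max_sample_missing"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class MetaResult:
    """Fixed-effects meta-analysis result for one variant."""

    key: VariantKey
    pooled_beta: float
    pooled_se: float
    z: float
    p: float
    n_studies: int
    heterogeneity_q: float = field(default=np.nan)
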