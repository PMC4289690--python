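"""Allele harmonization across studies and HLA dosage hardening.

Meta-analysis of signed z-scores is only meaningful when every study reports
its effect for the same allele of each variant.  :func:`harmonize_alleles`
reorients each study onto a reference study's effect allele, flipping the
sign of beta and complementing the effect-allele frequency where the
orientation is reversed, and resolving strand flips by base complementing.
Palindromic variants (A/T, C/G) with minor-allele frequency above a cutoff
are dropped: their strand cannot be resolved from allele labels and their
frequency is too close to 0.5 to resolve it from frequency either.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import (
    MISSING_DOSAGE,
    GenotypePanel,
    HlaCallTable,
    StudySummary,
)

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Palindromic variants with MAF above this are dropped during harmonization.
PALINDROME_MAF_LIMIT = 0.4


def _complement(allele: str) -> str:
    if set(allele) <= set("ACGT"):
        return allele.translate(_COMPLEMENT)
    return allele


def _match_key(row, on: str):
    if on == "variant_id":
        return row.SNP
    return (str(row.CHR), int(row.POS))


def harmonize_alleles(studies, reference: StudySummary, *,
                      match_on: str = "position",
                      drop_ambiguous_palindromes: bool = True):
    """Orient every study's effects to the reference study's effect alleles.

    Parameters
    ----------
    studies
        Iterable of :class:`StudySummary` to harmonize (the reference itself
        may be among them; it passes through unchanged).
    match_on
        ``"position"`` (default) matches variants on (chrom, pos) and
        requires the allele sets to agree up to orientation/strand;
        ``"variant_id"`` matches on the SNP id.

    Returns the list of harmonized copies.  Variants that cannot be
    reconciled (different allele sets after flip and complement) or that are
    ambiguous palindromes are dropped from the non-reference studies and
    logged.
    """
    if match_on not in ("position", "variant_id"):
        raise ValueError("match_on must be 'position' or 'variant_id'")
    ref_idx = {}
    for row in reference.table.itertuples():
        ref_idx[_match_key(row, match_on)] = (row.EA, row.OA)

    out = []
    for study in studies:
        t = study.table.copy()
        keep = np.ones(len(t), dtype=bool)
        flip = np.zeros(len(t), dtype=bool)
        new_ea = t["EA"].to_numpy(dtype=object)
        new_oa = t["OA"].to_numpy(dtype=object)
        for i, row in enumerate(t.itertuples()):
            key = _match_key(row, match_on)
            if key not in ref_idx:
                continue  # study-private variant: left as-is
            ref_ea, ref_oa = ref_idx[key]
            ea, oa = row.EA, row.OA
            if drop_ambiguous_palindromes and {ea, oa} in (
                    {"A", "T"}, {"C", "G"}):
                maf = min(row.EAF, 1 - row.EAF)
                if maf > PALINDROME_MAF_LIMIT:
                    keep[i] = False
                    logger.warning("%s: dropped ambiguous palindrome %s "
                                   "(MAF %.3f)", study.study_id, row.SNP, maf)
                    continue
            resolved = False
            for cand_ea, cand_oa, flipped in (
                    (ea, oa, False),
                    (oa, ea, True),
                    (_complement(ea), _complement(oa), False),
                    (_complement(oa), _complement(ea), True)):
                if (cand_ea, cand_oa) == (ref_ea, ref_oa):
                    flip[i] = flipped
                    new_ea[i], new_oa[i] = ref_ea, ref_oa
                    resolved = True
                    break
            if not resolved:
                keep[i] = False
                logger.warning("%s: irreconcilable alleles for %s "
                               "(%s/%s vs reference %s/%s)", study.study_id,
                               row.SNP, ea, oa, ref_ea, ref_oa)
        t["EA"] = new_ea
        t["OA"] = new_oa
        t.loc[flip, "BETA"] = -t.loc[flip, "BETA"]
        t.loc[flip, "EAF"] = 1 - t.loc[flip, "EAF"]
        t = t[keep].reset_index(drop=True)
        out.append(StudySummary(study_id=study.study_id,
                                disease=study.disease, table=t,
                                subphenotype=study.subphenotype,
                                ancestry_label=study.ancestry_label))
    return out


def harden_hla_dosages(table: HlaCallTable,
                       threshold: float = 0.9) -> GenotypePanel:
    """Convert probabilistic classical-allele calls to best-guess dosages.

    For each sample and allele the dosage is the copy number whose posterior
    probability strictly exceeds ``threshold`` (default 0.9); if no copy
    number does, the call is missing.  The comparison is strict, so a
    threshold of 1.0 marks everything missing even for certain calls.
    """
    if not 0.5 < threshold <= 1.0:
        raise ValueError("threshold must be in (0.5, 1]")
    probs = table.probabilities
    best = probs.argmax(axis=2).astype(float)
    best_p = probs.max(axis=2)
    best[best_p <= threshold] = MISSING_DOSAGE

    variants = pd.DataFrame({
        "SNP": [str(a) for a in table.alleles],
        "CHR": "6",
        "POS": np.arange(1, len(table.alleles) + 1),
        "EA": "<PRESENT>",
        "OA": "<ABSENT>",
    })
    return GenotypePanel(
        sample_ids=table.sample_ids,
        phenotype=np.full(len(table.sample_ids), "control", dtype=object),
        dosages=best,
        variants=variants,
    )
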