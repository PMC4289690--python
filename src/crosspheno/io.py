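"""Readers and writers for summary statistics and genotype panels.

Summary statistics travel as (optionally gzipped) TSV with header columns
``SNP CHR POS EA OA EAF BETA SE P N_CASES N_CONTROLS [INFO]``; a
``column_map`` translates foreign headers onto this layout.  Genotypes are
read from VCF (GT or DS FORMAT fields, via cyvcf2) or from a plain TSV
dosage matrix (rows = samples, columns = variants), with phenotype, sex and
covariates in a sidecar TSV keyed by sample id.
"""

from __future__ import annotations

import gzip
import logging
import os

import numpy as np
import pandas as pd

from .datatypes import (
    MISSING_DOSAGE,
    SUMMARY_COLUMNS,
    GenotypePanel,
    StudySummary,
)

logger = logging.getLogger(__name__)

_MANDATORY = [c for c in SUMMARY_COLUMNS if c != "INFO"]

#: Fraction of malformed rows above which a read aborts instead of warning.
MAX_BAD_ROW_FRACTION = 0.01


class SummaryFormatError(ValueError):
    """A summary-statistics file cannot be interpreted."""


def read_summary(path, column_map=None, *, study_id=None, disease="AD",
                 subphenotype="general", ancestry_label="") -> StudySummary:
    """Read a per-study summary-statistics TSV into a :class:`StudySummary`.

    Parameters
    ----------
    column_map
        Optional mapping from file header names to canonical names, e.g.
        ``{"rsid": "SNP", "freq": "EAF"}``.  Unmapped canonical names must be
        present verbatim.

    Rows with non-numeric or invariant-violating fields (``SE <= 0``,
    ``P`` outside (0, 1], ``EAF`` outside [0, 1]) are dropped with a logged
    warning carrying the 1-based data line number; if more than
    ``MAX_BAD_ROW_FRACTION`` of rows fail, the read aborts.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, sep="\t", dtype=str)
    if column_map:
        raw = raw.rename(columns=dict(column_map))
    missing = [c for c in _MANDATORY if c not in raw.columns]
    if missing:
        raise SummaryFormatError(f"{path}: missing mandatory columns {missing}")
    if "INFO" not in raw.columns:
        raw["INFO"] = np.nan
    raw = raw[SUMMARY_COLUMNS]

    numeric = ["POS", "EAF", "BETA", "SE", "P", "N_CASES", "N_CONTROLS", "INFO"]
    conv = raw.copy()
    for c in numeric:
        conv[c] = pd.to_numeric(conv[c], errors="coerce")

    bad = conv[numeric[:-1]].isna().any(axis=1)
    bad |= ~(conv["SE"] > 0)
    bad |= ~((conv["P"] > 0) & (conv["P"] <= 1))
    bad |= ~((conv["EAF"] >= 0) & (conv["EAF"] <= 1))
    if bad.any():
        for i in conv.index[bad][:20]:
            logger.warning("%s: rejected malformed row at data line %d (%s)",
                           path, i + 1, raw.loc[i, "SNP"])
        if bad.mean() > MAX_BAD_ROW_FRACTION:
            raise SummaryFormatError(
                f"{path}: {int(bad.sum())}/{len(conv)} rows malformed "
                f"(> {MAX_BAD_ROW_FRACTION:.0%}); aborting")
        conv = conv[~bad]

    conv["POS"] = conv["POS"].astype(int)
    conv["N_CASES"] = conv["N_CASES"].astype(int)
    conv["N_CONTROLS"] = conv["N_CONTROLS"].astype(int)
    conv["CHR"] = conv["CHR"].astype(str)
    if study_id is None:
        study_id = os.path.basename(str(path)).split(".")[0]
    return StudySummary(study_id=study_id, disease=disease,
                        subphenotype=subphenotype,
                        ancestry_label=ancestry_label,
                        table=conv.reset_index(drop=True))


def write_summary(study: StudySummary, path) -> None:
    """Write a :class:`StudySummary` back to canonical TSV (gzip by suffix)."""
    study.table[SUMMARY_COLUMNS].to_csv(path, sep="\t", index=False,
                                        na_rep="NA")


def read_genotype_matrix(dosage_path, sidecar_path=None) -> GenotypePanel:
    """Read the plain-text dosage dialect.

    ``dosage_path``: TSV, first column ``SAMPLE_ID``, remaining columns one
    per variant named ``SNP:CHR:POS:EA:OA``; cells are dosages in [0, 2] or
    ``NA``.  ``sidecar_path``: TSV with columns ``SAMPLE_ID, PHENOTYPE, SEX``
    plus any number of covariate columns.
    """
    mat = pd.read_csv(dosage_path, sep="\t")
    sample_ids = mat.iloc[:, 0].astype(str).to_numpy()
    var_cols = list(mat.columns[1:])
    parts = [c.split(":") for c in var_cols]
    if any(len(p) != 5 for p in parts):
        raise SummaryFormatError(
            "dosage matrix columns must be named SNP:CHR:POS:EA:OA")
    variants = pd.DataFrame(parts, columns=["SNP", "CHR", "POS", "EA", "OA"])
    variants["POS"] = variants["POS"].astype(int)
    dosages = mat.iloc[:, 1:].to_numpy(dtype=float)
    dosages[np.isnan(dosages)] = MISSING_DOSAGE

    phenotype = np.full(len(sample_ids), "control", dtype=object)
    sex = None
    covariates = None
    if sidecar_path is not None:
        side = pd.read_csv(sidecar_path, sep="\t")
        side = side.set_index(side["SAMPLE_ID"].astype(str)).loc[sample_ids]
        phenotype = side["PHENOTYPE"].to_numpy()
        if "SEX" in side.columns:
            sex = side["SEX"].to_numpy()
        covar_cols = [c for c in side.columns
                      if c not in ("SAMPLE_ID", "PHENOTYPE", "SEX")]
        if covar_cols:
            covariates = side[covar_cols].reset_index(drop=True)
    return GenotypePanel(sample_ids=sample_ids, phenotype=phenotype,
                         dosages=dosages, variants=variants, sex=sex,
                         covariates=covariates)


def write_genotype_matrix(panel: GenotypePanel, dosage_path,
                          sidecar_path=None) -> None:
    v = panel.variants
    cols = [f"{r.SNP}:{r.CHR}:{r.POS}:{r.EA}:{r.OA}" for r in v.itertuples()]
    d = panel.dosages.copy()
    d[d == MISSING_DOSAGE] = np.nan
    out = pd.DataFrame(d, columns=cols)
    out.insert(0, "SAMPLE_ID", panel.sample_ids)
    out.to_csv(dosage_path, sep="\t", index=False, na_rep="NA")
    if sidecar_path is not None:
        side = pd.DataFrame({"SAMPLE_ID": panel.sample_ids,
                             "PHENOTYPE": panel.phenotype})
        if panel.sex is not None:
            side["SEX"] = panel.sex
        if panel.covariates is not None:
            side = pd.concat(
                [side, panel.covariates.reset_index(drop=True)], axis=1)
        side.to_csv(sidecar_path, sep="\t", index=False)


def read_vcf(path, sidecar_path=None, *, prefer_dosage=True) -> GenotypePanel:
    """Read genotypes from a VCF into a :class:`GenotypePanel`.

    The effect allele is the VCF ALT allele.  Dosages come from the ``DS``
    FORMAT field when present and ``prefer_dosage`` is true, else from hard
    ``GT`` calls; missing genotypes become :data:`MISSING_DOSAGE`.
    Multi-allelic sites are expanded into one record per ALT allele, treated
    as distinct bi-allelic variants.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = np.asarray(vcf.samples)
    rows, columns = [], []
    for rec in vcf:
        try:
            ds = rec.format("DS") if prefer_dosage else None
        except KeyError:
            ds = None
        for ai, alt in enumerate(rec.ALT):
            vid = rec.ID or f"{rec.CHROM}:{rec.POS}:{rec.REF}:{alt}"
            if len(rec.ALT) > 1:
                vid = f"{vid}_alt{ai + 1}"
            rows.append((vid, str(rec.CHROM), int(rec.POS), alt, rec.REF))
            if ds is not None and ai == 0 and len(rec.ALT) == 1:
                col = np.asarray(ds, dtype=float).reshape(-1)
                col[~np.isfinite(col)] = MISSING_DOSAGE
            else:
                gt = np.asarray(rec.genotype.array())[:, :2]
                col = (gt == ai + 1).sum(axis=1).astype(float)
                col[(gt < 0).any(axis=1)] = MISSING_DOSAGE
            columns.append(col)
    variants = pd.DataFrame(rows, columns=["SNP", "CHR", "POS", "EA", "OA"])
    dosages = (np.column_stack(columns) if columns
               else np.empty((len(sample_ids), 0)))

    phenotype = np.full(len(sample_ids), "control", dtype=object)
    sex = covariates = None
    if sidecar_path is not None:
        side = pd.read_csv(sidecar_path, sep="\t")
        side = side.set_index(side["SAMPLE_ID"].astype(str)).loc[sample_ids]
        phenotype = side["PHENOTYPE"].to_numpy()
        if "SEX" in side.columns:
            sex = side["SEX"].to_numpy()
        covar_cols = [c for c in side.columns
                      if c not in ("SAMPLE_ID", "PHENOTYPE", "SEX")]
        if covar_cols:
            covariates = side[covar_cols].reset_index(drop=True)
    return GenotypePanel(sample_ids=sample_ids, phenotype=phenotype,
                         dosages=dosages, variants=variants, sex=sex,
                         covariates=covariates)


def write_vcf(panel: GenotypePanel, path) -> None:
    """Write hard-called genotypes as a minimal VCFv4.2 text file.

    Dosages are rounded to the nearest integer copy number for the GT field;
    missing dosages become ``./.``.  Intended for round-tripping synthetic
    panels, not for annotating real call sets.
    """
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, panel.sample_ids)) + "\n")
        for j in range(len(panel.variants)):
            r = panel.variants.iloc[j]
            calls = []
            for d in panel.dosages[:, j]:
                if d == MISSING_DOSAGE:
                    calls.append("./.")
                else:
                    k = int(round(d))
                    calls.append(["0/0", "0/1", "1/1"][min(max(k, 0), 2)])
            fh.write(f"{r.CHR}\t{r.POS}\t{r.SNP}\t{r.OA}\t{r.EA}\t.\tPASS\t.\tGT\t"
                     + "\t".join(calls) + "\n")
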