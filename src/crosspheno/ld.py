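"""Genotype-based LD, greedy clumping, and locus/region definitions.

LD between two variants is the squared Pearson correlation of their dosage
vectors (composite LD, no phasing required).  Association results condense
to loci by greedy clumping: the best remaining variant above the statistic
threshold becomes a lead and absorbs every variant within 250 kb with
r² >= 0.5 (both parameters configurable).  A *locus* is the lead variant
plus companions with r² strictly > 0.5; a *shared region* is a 2 Mb window
holding signals for both diseases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import MISSING_DOSAGE, GenotypePanel

logger = logging.getLogger(__name__)

DEFAULT_MAX_DIST = 250_000
DEFAULT_MIN_R2 = 0.5
SHARED_REGION_SPAN = 2_000_000


def genotype_r2(a, b) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Missing entries (sentinel) are excluded pairwise; NaN is returned when
    fewer than two jointly observed samples remain or either vector is
    constant.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ok = (a != MISSING_DOSAGE) & (b != MISSING_DOSAGE)
    a, b = a[ok], b[ok]
    if len(a) < 2 or a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1] ** 2)


@dataclass
class LocusClump:
    lead: str
    lead_stat: float
    chrom: str
    members: list          # (variant_id, r2 with lead)
    min_pos: int
    max_pos: int


def _ld_source(panel: GenotypePanel, controls_only: bool) -> GenotypePanel:
    if controls_only and (panel.phenotype == "control").any():
        return panel.subset_samples(panel.phenotype == "control")
    return panel


def clump(results: pd.DataFrame, panel: GenotypePanel, *,
          stat_col: str = "TMAX", max_dist: int = DEFAULT_MAX_DIST,
          min_r2: float = DEFAULT_MIN_R2, stat_threshold: float = 0.0,
          controls_only: bool = True) -> list[LocusClump]:
    """Greedy LD clumping of an association table.

    ``results`` needs columns ``SNP CHR POS`` and ``stat_col`` (larger =
    more significant).  Repeatedly the best variant above
    ``stat_threshold`` becomes a lead and absorbs all remaining variants on
    the same chromosome within ``max_dist`` base pairs (closed interval,
    lead to member) and with r² >= ``min_r2``; clumps are therefore
    disjoint.  Equal statistics break toward the smaller position.  Variants
    missing from the panel stay unclumped with a warning.  LD is computed
    from control samples by default.
    """
    src = _ld_source(panel, controls_only)
    have = set(src.variants["SNP"])
    t = results[results[stat_col] >= stat_threshold].copy()
    missing = t.loc[~t["SNP"].isin(have), "SNP"]
    for vid in missing:
        logger.warning("clump: %s absent from genotype panel, left unclumped",
                       vid)
    t = t[t["SNP"].isin(have)]
    # best statistic first; ties -> smaller position
    t = t.sort_values([stat_col, "POS"],
                      ascending=[False, True]).reset_index(drop=True)

    unassigned = t.to_dict("records")
    clumps: list[LocusClump] = []
    while unassigned:
        lead = unassigned.pop(0)
        lead_dose = src.dosage_of(lead["SNP"])
        members = [(lead["SNP"], 1.0)]
        rest = []
        positions = [int(lead["POS"])]
        for row in unassigned:
            if (str(row["CHR"]) == str(lead["CHR"])
                    and abs(int(row["POS"]) - int(lead["POS"])) <= max_dist):
                r2 = genotype_r2(lead_dose, src.dosage_of(row["SNP"]))
                if np.isfinite(r2) and r2 >= min_r2:
                    members.append((row["SNP"], r2))
                    positions.append(int(row["POS"]))
                    continue
            rest.append(row)
        unassigned = rest
        clumps.append(LocusClump(
            lead=lead["SNP"], lead_stat=float(lead[stat_col]),
            chrom=str(lead["CHR"]), members=members,
            min_pos=min(positions), max_pos=max(positions)))
    return clumps


def define_locus(lead_id: str, candidate_ids, panel: GenotypePanel, *,
                 min_r2: float = DEFAULT_MIN_R2,
                 controls_only: bool = True) -> LocusClump:
    """A genetic locus: the lead variant plus all candidates with r² > 0.5.

    Note the strict inequality — a candidate at exactly r² = 0.5 is outside
    the locus, although :func:`clump` (r² >= 0.5) would absorb it.
    """
    src = _ld_source(panel, controls_only)
    lead_dose = src.dosage_of(lead_id)
    lead_row = src.variants.set_index("SNP").loc[lead_id]
    members = [(lead_id, 1.0)]
    positions = [int(lead_row["POS"])]
    vtab = src.variants.set_index("SNP")
    for vid in candidate_ids:
        if vid == lead_id:
            continue
        r2 = genotype_r2(lead_dose, src.dosage_of(vid))
        if np.isfinite(r2) and r2 > min_r2:
            members.append((vid, r2))
            positions.append(int(vtab.loc[vid, "POS"]))
    return LocusClump(lead=lead_id, lead_stat=float("nan"),
                      chrom=str(lead_row["CHR"]), members=members,
                      min_pos=min(positions), max_pos=max(positions))


def shared_regions(ad_clumps, pso_clumps,
                   span: int = SHARED_REGION_SPAN) -> list[dict]:
    """Windows of ``span`` base pairs containing clumps for both diseases.

    Each AD/PSO clump pair on the same chromosome whose leads lie within
    ``span`` of each other defines a shared region; overlapping pairs are
    merged per chromosome.
    """
    regions = []
    for a in ad_clumps:
        for p in pso_clumps:
            if a.chrom != p.chrom:
                continue
            lo = min(a.min_pos, p.min_pos)
            hi = max(a.max_pos, p.max_pos)
            if hi - lo <= span:
                regions.append({"chrom": a.chrom, "start": lo, "end": hi,
                                "ad_lead": a.lead, "pso_lead": p.lead})
    merged: list[dict] = []
    for r in sorted(regions, key=lambda r: (r["chrom"], r["start"])):
        if merged and merged[-1]["chrom"] == r["chrom"] \
                and r["start"] <= merged[-1]["end"]:
            merged[-1]["end"] = max(merged[-1]["end"], r["end"])
            merged[-1].setdefault("pairs", []).append(
                (r["ad_lead"], r["pso_lead"]))
        else:
            r = dict(r)
            r["pairs"] = [(r.pop("ad_lead"), r.pop("pso_lead"))]
            merged.append(r)
    return merged
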