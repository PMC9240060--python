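"""Somatic LOH assignment and inheritance-model genotype encoding.

LOH is assigned to gene-sample pairs from copy-number segments (or, when
segments are unavailable, from the tumor/normal allele-frequency shift of
the rare variant itself), with an exclusion for variants whose allele
frequency dropped in the tumor.  Carrier matrices are then encoded under
dominant, additive and recessive inheritance; the recessive model excludes
monoallelic carriers rather than scoring them 0.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

EXCLUDED = -1  # sentinel for recessive-model excluded samples

LOH_SEGMENT_CLASSES = {"LOH", "DUP-LOH", "LOHgain", "cnLOH"}


def _vaf_exclusion(vaf_t, vaf_n):
    """Drop the LOH call when the variant frequency is lower in the tumor,
    unless both tissue frequencies exceed 0.8."""
    lower_in_tumor = vaf_t < vaf_n
    both_high = (vaf_t > 0.8) & (vaf_n > 0.8)
    return lower_in_tumor & ~both_high


def assign_loh(
    variants: pd.DataFrame,
    segments: pd.DataFrame | None = None,
    mode: str = "segment",
    minor_allele_ploidy: pd.DataFrame | None = None,
    vaf_diff_min: float = 0.25,
    vaf_tumor_min: float = 0.8,
    map_threshold: float = 0.4,
) -> pd.DataFrame:
    """Assign putative LOH to gene-sample pairs carrying rare variants.

    Modes:

    * ``segment``: LOH when a qualifying segment covers the gene in that
      sample, excluded when the variant's tumor VAF is below its normal VAF
      and the two VAFs are not both above 0.8;
    * ``vaf_fallback`` (no segments): LOH when tumor-normal VAF difference
      exceeds 0.25 and the tumor VAF exceeds 0.8;
    * ``minor_allele_ploidy``: LOH when the minor allele ploidy is below
      0.4, with the same VAF exclusion as segment mode.

    ``variants`` must carry sample, gene, vaf_tumor, vaf_normal.  Returns
    one call per gene-sample with its source.
    """
    v = variants[["sample", "gene", "vaf_tumor", "vaf_normal"]].copy()
    calls = []

    if mode == "segment":
        if segments is None:
            raise ValueError("segment mode requires segments")
        seg = segments[segments["class"].isin(LOH_SEGMENT_CLASSES)]
        seg_pairs = set(zip(seg["sample"], seg["gene"]))
        for (s, g), grp in v.groupby(["sample", "gene"]):
            if (s, g) not in seg_pairs:
                continue
            vt = grp["vaf_tumor"].to_numpy()
            vn = grp["vaf_normal"].to_numpy()
            if bool(_vaf_exclusion(vt, vn).all()):
                continue
            calls.append((g, s, "segment", float(np.nanmax(vt)),
                          float(np.nanmax(vn))))
    elif mode == "vaf_fallback":
        for (s, g), grp in v.groupby(["sample", "gene"]):
            vt = grp["vaf_tumor"].to_numpy()
            vn = grp["vaf_normal"].to_numpy()
            missing = np.isnan(vt)
            if missing.all():
                log.info("no tumor VAF for %s/%s in fallback mode", s, g)
                continue
            hit = (vt - vn > vaf_diff_min) & (vt > vaf_tumor_min)
            if np.any(hit & ~missing):
                calls.append((g, s, "vaf_fallback", float(np.nanmax(vt)),
                              float(np.nanmax(vn))))
    elif mode == "minor_allele_ploidy":
        if minor_allele_ploidy is None:
            raise ValueError(
                "minor_allele_ploidy mode requires a ploidy table")
        mp = minor_allele_ploidy.set_index(["sample", "gene"])[
            "minor_allele_ploidy"]
        for (s, g), grp in v.groupby(["sample", "gene"]):
            if mp.get((s, g), np.inf) >= map_threshold:
                continue
            vt = grp["vaf_tumor"].to_numpy()
            vn = grp["vaf_normal"].to_numpy()
            if bool(_vaf_exclusion(vt, vn).all()):
                continue
            calls.append((g, s, "minor_allele_ploidy",
                          float(np.nanmax(vt)), float(np.nanmax(vn))))
    else:
        raise ValueError(f"unknown LOH mode {mode!r}")

    return pd.DataFrame(
        calls, columns=["gene", "sample", "source", "vaf_tumor",
                        "vaf_normal"]).drop_duplicates(["gene", "sample"])


def encode(
    carriers: pd.DataFrame,
    loh: pd.DataFrame,
    model: str,
) -> pd.DataFrame:
    """Encode gene x sample genotypes under an inheritance model.

    ``carriers`` is the gene x sample count of qualifying variants;
    ``loh`` the LOH call table.  Encodings: dominant 1 for any carrier;
    additive 2 for carrier+LOH or biallelic carriers, 1 for monoallelic
    carriers, 0 otherwise; recessive 1 for the biallelic state, EXCLUDED
    (-1) for monoallelic carriers without LOH, 0 for non-carriers.
    """
    if model not in {"dominant", "additive", "recessive"}:
        raise ValueError(f"unknown inheritance model {model!r}")
    C = carriers.to_numpy()
    has_var = C >= 1
    biallelic_var = C >= 2

    has_loh = np.zeros_like(has_var)
    n_orphan = 0
    gidx = {g: i for i, g in enumerate(carriers.index)}
    sidx = {s: j for j, s in enumerate(carriers.columns)}
    for _, row in loh.iterrows():
        i, j = gidx.get(row["gene"]), sidx.get(row["sample"])
        if i is None or j is None:
            continue
        if not has_var[i, j]:
            n_orphan += 1
            continue
        has_loh[i, j] = True
    if n_orphan:
        log.info("%d LOH calls without a carrier variant ignored", n_orphan)

    biallelic = (has_var & has_loh) | biallelic_var
    if model == "dominant":
        E = has_var.astype(int)
    elif model == "additive":
        E = has_var.astype(int) + biallelic.astype(int)
    else:  # recessive
        E = np.where(biallelic, 1,
                     np.where(has_var, EXCLUDED, 0))
    return pd.DataFrame(E, index=carriers.index, columns=carriers.columns)
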