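"""Somatic feature registry.

65 named per-sample features are computed; 9 raw count features (total SNVs,
total indels, and the seven single-substitution class counts) are excluded
before component extraction because the signature exposures already represent
them, leaving 56 features for the input matrix.
"""

from __future__ import annotations

SUB6 = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]

# seven substitution classes used as counts and as the WES-mode regression
# covariate: C>T is split at CpG sites
SUB7 = ["C>A", "C>G", "C>T_CpG", "C>T_nonCpG", "T>A", "T>C", "T>G"]

SNV_COUNT_FEATURES = [
    "snv_total",
    "count_C>A",
    "count_C>G",
    "count_C>T_CpG",
    "count_C>T_nonCpG",
    "count_T>A",
    "count_T>C",
    "count_T>G",
]

MITO_FEATURE = "mito_snv"

REF_SIGS = [
    "RefSig1", "RefSig2", "RefSig3", "RefSig4", "RefSig5", "RefSig7",
    "RefSig8", "RefSig11", "RefSig13", "RefSig17", "RefSig18", "RefSig19",
    "RefSig22", "RefSig30", "RefSig33", "RefSigMMR1", "RefSigMMR2",
]

TX_BIAS_FEATURES = [f"txbias_{s}" for s in SUB6]

REP_BIAS_FEATURE = "repbias"
X_HYPERMUT_FEATURE = "x_hypermut"
CTCF_FEATURE = "ctcf_ratio"

REGRESSION_FEATURES = ["enr_rt", "enr_dnase", "enr_expr", "enr_h3k36me3"]

DBS_SIGS = ["DBS1", "DBS2", "DBS4", "DBS9"]

INDEL_FEATURES = [
    "indel_total",
    "indel_1bp_ms",
    "indel_1bp_nonms",
    "indel_2_5bp_ms",
    "indel_2_5bp_nonms",
    "indel_6_10bp",
    "del_ge10bp",
    "del_mh_1bp",
    "del_mh_gt1bp",
]

ID_SIGS = ["ID2", "ID3", "ID4", "ID8"]

CNA_FEATURES = [
    "amp_1_10kb",
    "amp_10_100kb",
    "amp_100_1000kb",
    "amp_gt1000kb",
    "del_1_10kb",
    "del_10_100kb",
    "del_gt100kb",
    "ploidy",
    "wgd",
]

ALL_FEATURES = (
    SNV_COUNT_FEATURES
    + [MITO_FEATURE]
    + REF_SIGS
    + TX_BIAS_FEATURES
    + [REP_BIAS_FEATURE, X_HYPERMUT_FEATURE, CTCF_FEATURE]
    + REGRESSION_FEATURES
    + DBS_SIGS
    + INDEL_FEATURES
    + ID_SIGS
    + CNA_FEATURES
)

# excluded before component extraction: raw totals already represented by the
# NMF-derived signature exposures
EXCLUDED_FEATURES = ["snv_total", "indel_total"] + [f"count_{s}" for s in SUB7]

RETAINED_FEATURES = [f for f in ALL_FEATURES if f not in EXCLUDED_FEATURES]

assert len(ALL_FEATURES) == 65
assert len(EXCLUDED_FEATURES) == 9
assert len(RETAINED_FEATURES) == 56
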