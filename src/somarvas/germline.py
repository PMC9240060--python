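"""Rare pLoF variant set construction and cohort quality control.

Applies call-quality, population-rarity, PEXT-expression and terminal-exon
rules to annotated germline variants; builds the five rare pLoF variant
sets (PTV-only through constrained-missense) as gene x sample carrier
matrices; and performs sample-level QC on common variants (variant-count
and heterozygosity outliers, Hardy-Weinberg and LD filters, relatedness by
method-of-moments IBD, ancestry PCA with trimmed clustering).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

log = logging.getLogger(__name__)

PTV_CLASSES = {
    "frameshift_del", "frameshift_ins", "stoploss", "stopgain",
    "startloss", "splicing",
}

CONSEQUENCE_VOCAB = PTV_CLASSES | {"missense", "synonymous"}


# ---------------------------------------------------------------------------
# quality and rarity filtering
# ---------------------------------------------------------------------------

def quality_and_rarity_filter(
    variants: pd.DataFrame,
    cohort_size: int,
    gnomad_af_max: float = 0.001,
    cohort_freq_max: float = 0.01,
    require_tumor: bool = True,
) -> pd.DataFrame:
    """Filter germline variants by call quality and population rarity.

    Keep rules, applied in sequence:

    * filter PASS, or LowGQX with GQX >= 10;
    * present in gnomAD (PASS) with GQX >= 10, or absent from gnomAD with
      GQX >= 20;
    * gnomAD allele frequency < 0.1% overall and in every subpopulation
      (absent variants pass);
    * within-cohort frequency < 1% (per variant site);
    * present in the matched tumor sample when tumor calls exist.
    """
    v = variants.copy()
    bad_vocab = set(v["consequence"]) - CONSEQUENCE_VOCAB
    if bad_vocab:
        raise ValueError(f"unknown consequence class(es): {sorted(bad_vocab)}")

    low = v["filter"] == "LowGQX"
    missing_gqx = low & v["gqx"].isna()
    if missing_gqx.any():
        log.warning("%d LowGQX records lack GQX and are rejected",
                    int(missing_gqx.sum()))
    keep = (v["filter"] == "PASS") | (low & (v["gqx"] >= 10))
    v = v[keep.fillna(False)]

    in_g = v["in_gnomad"].fillna(False).astype(bool)
    keep = (in_g & (v["gqx"] >= 10)) | (~in_g & (v["gqx"] >= 20))
    v = v[keep]
    in_g = v["in_gnomad"].fillna(False).astype(bool)

    sub_cols = [c for c in v.columns if c.startswith("gnomad_af_sub")]
    af_ok = (v["gnomad_af"] < gnomad_af_max)
    for c in sub_cols:
        af_ok &= v[c] < gnomad_af_max
    v = v[~in_g | af_ok.fillna(False)]

    site = v["chrom"].astype(str) + ":" + v["pos"].astype(str) + \
        v["ref"] + ">" + v["alt"]
    counts = site.map(site.value_counts())
    v = v[counts / cohort_size < cohort_freq_max]

    if require_tumor and "present_in_tumor" in v.columns:
        has_info = v["present_in_tumor"].notna()
        v = v[~has_info | v["present_in_tumor"].fillna(False).astype(bool)]
    return v


# ---------------------------------------------------------------------------
# variant sets I-V and carrier matrices
# ---------------------------------------------------------------------------

@dataclass
class VariantSetConfig:
    """Thresholds of the five rare pLoF definitions."""

    cadd_strict: float = 25.0  # set II
    cadd_lenient: float = 15.0  # set III
    mtr_percentile_max: float = 25.0  # set IV
    ccr_percentile_min: float = 90.0  # set V
    spliceai_min: float = 0.8
    pext_min: float = 0.1
    set_ids: tuple = ("I", "II", "III", "IV", "V")


def is_ptv(variants: pd.DataFrame, cfg: VariantSetConfig) -> pd.Series:
    """Protein-truncating status: the six truncating classes, where
    splicing covers canonical splice annotation or SpliceAI donor/acceptor
    loss above 0.8."""
    splice_pred = (variants["spliceai_dl"] > cfg.spliceai_min) | \
        (variants["spliceai_al"] > cfg.spliceai_min)
    return variants["consequence"].isin(PTV_CLASSES) | splice_pred


def classify_and_build_sets(
    variants: pd.DataFrame,
    cfg: VariantSetConfig | None = None,
    tissue_map: dict | None = None,
    cancer_type_of_sample: pd.Series | None = None,
    gene_universe: list[str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Assign variants to the five pLoF sets and emit carrier matrices.

    Sets: I PTV only; II PTV + missense CADD >= 25; III PTV + missense
    CADD >= 15; IV missense with MTR <= 25th percentile; V missense with
    CCR >= 90th percentile.  All sets then pass the PEXT expression filter
    (matched GTEx-like tissue, mean PEXT when unmatched; skipped for
    splicing variants) and the terminal-exon exclusion, excepted for
    variants with CADD >= 15 or a predicted splicing effect.
    """
    if cfg is None:
        cfg = VariantSetConfig()
    v = variants.copy()
    ptv = is_ptv(v, cfg)
    splice_effect = (v["consequence"] == "splicing") | \
        (v["spliceai_dl"] > cfg.spliceai_min) | \
        (v["spliceai_al"] > cfg.spliceai_min)
    miss = v["consequence"] == "missense"

    membership = {
        "I": ptv,
        "II": ptv | (miss & (v["cadd"] >= cfg.cadd_strict)),
        "III": ptv | (miss & (v["cadd"] >= cfg.cadd_lenient)),
        "IV": miss & (v["mtr_pct"] <= cfg.mtr_percentile_max),
        "V": miss & (v["ccr_pct"] >= cfg.ccr_percentile_min),
    }

    # PEXT: matched-tissue value, mean as fallback; splicing variants skip
    if tissue_map is not None and cancer_type_of_sample is not None:
        tissue = v["sample"].map(cancer_type_of_sample).map(tissue_map)
        pext = pd.Series(np.nan, index=v.index)
        for t in tissue.dropna().unique():
            col = f"pext_{t}"
            if col in v.columns:
                pext[tissue == t] = v.loc[tissue == t, col]
        need_mean = pext.isna()
        if need_mean.any():
            if "pext_mean" not in v.columns:
                raise ValueError(
                    "unmatched tissue and no mean PEXT available")
            pext[need_mean] = v.loc[need_mean, "pext_mean"]
    else:
        if "pext_mean" not in v.columns:
            raise ValueError("no tissue map and no mean PEXT available")
        pext = v["pext_mean"]
    pext_ok = splice_effect | (pext > cfg.pext_min)

    terminal_ok = (~v["terminal_exon"].astype(bool)) | \
        (v["cadd"] >= cfg.cadd_lenient) | splice_effect

    common = pext_ok & terminal_ok
    out = {}
    for set_id, memb in membership.items():
        sel = v[memb & common]
        mat = (sel.groupby(["gene", "sample"]).size()
               .unstack(fill_value=0))
        if gene_universe is not None:
            mat = mat[mat.index.isin(gene_universe)]
        out[set_id] = mat
    return out


def carrier_matrix_full(mat: pd.DataFrame, genes: list[str],
                        samples: list[str]) -> pd.DataFrame:
    """Reindex a carrier matrix onto the full gene x sample grid."""
    return mat.reindex(index=genes, columns=samples, fill_value=0).fillna(0) \
        .astype(int)


# ---------------------------------------------------------------------------
# cohort QC: outliers, relatedness, ancestry
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    excluded: pd.DataFrame  # sample, reason
    n_variants_used: int
    pcs: pd.DataFrame | None = None
    cluster_labels: pd.Series | None = None
    details: dict = field(default_factory=dict)


def ld_prune(G: np.ndarray, window: int = 50, step: int = 5,
             r2_max: float = 0.2) -> np.ndarray:
    """Window-based LD pruning; returns indices of retained variants.

    Slides a window of ``window`` variants with the given step and removes
    one of each pair with squared correlation above ``r2_max``.
    """
    m = G.shape[1]
    removed = np.zeros(m, dtype=bool)
    for start in range(0, m, step):
        idx = [j for j in range(start, min(start + window, m))
               if not removed[j]]
        if len(idx) < 2:
            continue
        sub = G[:, idx].astype(float)
        sd = sub.std(axis=0)
        sd[sd == 0] = 1.0
        Z = (sub - sub.mean(axis=0)) / sd
        R2 = (Z.T @ Z / len(Z)) ** 2
        for a in range(len(idx)):
            if removed[idx[a]]:
                continue
            for b in range(a + 1, len(idx)):
                if removed[idx[b]]:
                    continue
                if R2[a, b] > r2_max:
                    removed[idx[b]] = True
        if start + window >= m:
            break
    return np.where(~removed)[0]


def hwe_pvalues(G: np.ndarray) -> np.ndarray:
    """Chi-square Hardy-Weinberg test p-value per variant column."""
    n = G.shape[0]
    n_aa = (G == 0).sum(axis=0)
    n_ab = (G == 1).sum(axis=0)
    n_bb = (G == 2).sum(axis=0)
    p = (2 * n_bb + n_ab) / (2 * n)
    q = 1 - p
    exp = np.stack([q ** 2, 2 * p * q, p ** 2], axis=1) * n
    obs = np.stack([n_aa, n_ab, n_bb], axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(exp > 0, (obs - exp) ** 2 / exp, 0.0).sum(axis=1)
    return stats.chi2.sf(chi2, df=1)


def ibd_pihat(G: np.ndarray) -> np.ndarray:
    """Method-of-moments PI-hat for all sample pairs.

    Allele-frequency-standardized genotype products give a moment estimate
    of twice the kinship coefficient, which equals the expected genome
    fraction shared identical by descent: ~1 for duplicates, ~0.5 for
    first-degree relatives, ~0 for unrelated pairs.
    """
    n, m = G.shape
    p = G.mean(axis=0) / 2.0
    ok = (p > 0) & (p < 1)
    Gs = G[:, ok].astype(float)
    p = p[ok]
    # standardized genotype correlation estimator of kinship
    Z = (Gs - 2 * p) / np.sqrt(2 * p * (1 - p))
    K = Z @ Z.T / Z.shape[1]  # ~2*kinship; 1 on diagonal, 1 for duplicates
    pihat = np.clip(K, 0.0, None)
    np.fill_diagonal(pihat, 1.0)
    return pihat


def cohort_qc(
    common: pd.DataFrame,
    anchor_labels: pd.Series | None = None,
    count_sd: float = 1.5,
    het_sd: float = 3.0,
    maf_min: float = 0.05,
    hwe_p_min: float = 1e-6,
    pihat_max: float = 0.185,
    n_pcs: int = 6,
    n_clusters: int = 10,
    trim: float = 0.01,
    min_pruned: int = 50,
    seed: int = 0,
) -> QCReport:
    """Sample-level QC and ancestry PCA on a common-variant matrix.

    Sequence: variant-count outliers (mean +/- 1.5 SD), MAF re-filter,
    heterozygosity outliers (+/- 3 SD), Hardy-Weinberg exclusion
    (p < 1e-6), LD pruning (window 50 variants, step 5, r^2 > 0.2), pairwise
    method-of-moments IBD with removal of one of each pair above
    PI-hat 0.185, PCA, trimmed k-means (k=10, 1% trim) ancestry clustering
    anchored by labeled samples, and a final PCA within the selected
    cluster returning the first 6 PCs.
    """
    rng = np.random.default_rng(seed)
    excluded = []
    G = common.to_numpy().astype(np.int8)
    samples = np.array(common.index)

    counts = (G > 0).sum(axis=1)
    mu, sd = counts.mean(), counts.std()
    bad = np.abs(counts - mu) > count_sd * sd
    for s in samples[bad]:
        excluded.append((s, "variant_count_outlier"))
    G, samples = G[~bad], samples[~bad]

    maf = np.minimum(G.mean(axis=0) / 2.0, 1 - G.mean(axis=0) / 2.0)
    G = G[:, maf > maf_min]

    het = (G == 1).mean(axis=1)
    mu, sd = het.mean(), het.std()
    bad = np.abs(het - mu) > het_sd * sd
    for s in samples[bad]:
        excluded.append((s, "heterozygosity_outlier"))
    G, samples = G[~bad], samples[~bad]

    hwe = hwe_pvalues(G)
    G = G[:, hwe >= hwe_p_min]

    keep_idx = ld_prune(G)
    if len(keep_idx) < min_pruned:
        raise ValueError(
            f"only {len(keep_idx)} variants after pruning; IBD unreliable")
    Gp = G[:, keep_idx]

    pihat = ibd_pihat(Gp)
    iu = np.triu_indices(len(samples), k=1)
    related = pihat[iu] > pihat_max
    to_drop = set()
    for a, b in zip(iu[0][related], iu[1][related]):
        if a not in to_drop and b not in to_drop:
            to_drop.add(b)
    bad = np.zeros(len(samples), dtype=bool)
    bad[list(to_drop)] = True
    for s in samples[bad]:
        excluded.append((s, "related"))
    Gp, samples = Gp[~bad], samples[~bad]

    pca = PCA(n_components=min(10, Gp.shape[1], len(samples) - 1),
              random_state=seed)
    pcs10 = pca.fit_transform(Gp.astype(float))

    # trimmed k-means: iterate plain k-means, dropping the trim fraction of
    # points farthest from their centroid
    mask = np.ones(len(samples), dtype=bool)
    labels = np.zeros(len(samples), dtype=int)
    k = min(n_clusters, max(2, len(samples) // 5))
    for _ in range(5):
        km = KMeans(n_clusters=k, n_init=4, random_state=seed)
        lab = km.fit_predict(pcs10[mask])
        d = np.linalg.norm(pcs10[mask] - km.cluster_centers_[lab], axis=1)
        cut = np.quantile(d, 1 - trim)
        inner = d <= cut
        new_mask = mask.copy()
        new_mask[np.where(mask)[0][~inner]] = False
        labels[np.where(mask)[0]] = lab
        if new_mask.sum() == mask.sum():
            break
        mask = new_mask
    labels = pd.Series(labels, index=samples)

    # select ancestry clusters dominated by anchor-labeled samples
    if anchor_labels is not None:
        anchors = anchor_labels.reindex(samples).fillna(False).astype(bool)
    else:
        anchors = pd.Series(True, index=samples)
    if anchors.any():
        frac = anchors.groupby(labels).mean()
        targets = frac[frac >= 0.5].index
        if len(targets) == 0:
            targets = [labels[anchors.to_numpy()].mode().iloc[0]]
    else:
        targets = [labels.value_counts().idxmax()]
    in_cluster = labels.isin(targets).to_numpy() & mask
    for s in samples[~in_cluster]:
        excluded.append((s, "ancestry"))

    Gc = Gp[in_cluster]
    pca2 = PCA(n_components=min(n_pcs, Gc.shape[1], in_cluster.sum() - 1),
               random_state=seed)
    pcs = pca2.fit_transform(Gc.astype(float))
    pcs_df = pd.DataFrame(
        pcs, index=samples[in_cluster],
        columns=[f"PC{i + 1}" for i in range(pcs.shape[1])])

    return QCReport(
        excluded=pd.DataFrame(excluded, columns=["sample", "reason"]),
        n_variants_used=Gp.shape[1],
        pcs=pcs_df,
        cluster_labels=labels,
        details={"pihat_max_observed": float(pihat[iu].max())
                 if len(iu[0]) else 0.0},
    )
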