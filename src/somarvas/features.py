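"""Per-sample somatic mutational feature extraction.

Computes the 65-feature catalog per tumor sample from somatic event tables
and genome annotation tracks: substitution-class counts, mitochondrial SNVs,
signature exposures fitted by bootstrapped non-negative least squares,
transcriptional and replicative strand-bias ratios, X-chromosome
hypermutation, CTCF-site enrichment, negative-binomial regional mutation
enrichment coefficients, indel spectra and copy-number features.

Count-derived features are log2(x + 1); features whose minimum-count rule
fails are missing (NaN), never zero.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .registry import (
    ALL_FEATURES, SUB6, SUB7, REF_SIGS, DBS_SIGS, ID_SIGS,
)
from .syndata import TrackBundle, REPLICATIVE_FOCAL, complement_sub

log = logging.getLogger(__name__)

_VALID_SUBS = set(SUB6)


def log2p1(x):
    return np.log2(np.asarray(x, dtype=float) + 1.0)


# ---------------------------------------------------------------------------
# basic counts
# ---------------------------------------------------------------------------

def count_basic_features(events: pd.DataFrame,
                         mito: pd.DataFrame | None = None,
                         mito_coverage_ok: bool = True,
                         mito_min_vaf: float = 0.03) -> pd.Series:
    """Eight substitution-class count features plus the mitochondrial count.

    C>T is split at CpG sites (3' flanking G on the pyrimidine strand).
    The mitochondrial count requires sufficient mitochondrial coverage and
    drops variants below 3% allele frequency.
    """
    out = {}
    subs = events.loc[events["class"] == "SNV", ["sub6", "cpg"]]
    bad = set(subs["sub6"]) - _VALID_SUBS
    if bad:
        raise ValueError(f"unknown substitution class(es): {sorted(bad)}")
    out["snv_total"] = log2p1(len(subs))
    for s7 in SUB7:
        if s7.startswith("C>T"):
            want_cpg = s7.endswith("CpG") and not s7.endswith("nonCpG")
            n = int(((subs["sub6"] == "C>T") & (subs["cpg"] == want_cpg)).sum())
        else:
            n = int((subs["sub6"] == s7).sum())
        out[f"count_{s7}"] = log2p1(n)
    if mito_coverage_ok and mito is not None:
        n_mito = int((mito["vaf"] >= mito_min_vaf).sum())
        out["mito_snv"] = log2p1(n_mito)
    else:
        out["mito_snv"] = np.nan
    return pd.Series(out)


# ---------------------------------------------------------------------------
# signature fitting
# ---------------------------------------------------------------------------

def fit_signatures(channel_counts: np.ndarray,
                   catalog: pd.DataFrame,
                   conversion: pd.DataFrame | None = None,
                   n_bootstrap: int = 100,
                   alpha: float = 0.05,
                   min_fraction: float = 0.05,
                   rng: np.random.Generator | None = None) -> pd.Series:
    """Bootstrapped non-negative least-squares signature exposures.

    A signature keeps its exposure only when its fitted fraction of the
    total mutation count exceeds ``min_fraction`` in at least ``1 - alpha``
    of multinomial bootstrap refits; otherwise it is set to 0.  Exposures
    are converted to the reference signature set via the conversion matrix.
    Values returned are raw (pre-log) exposures.
    """
    counts = np.asarray(channel_counts, dtype=float)
    if counts.shape[0] != catalog.shape[0]:
        raise ValueError(
            f"channel mismatch: counts has {counts.shape[0]} channels, "
            f"catalog has {catalog.shape[0]}")
    sigs = catalog.columns
    total = counts.sum()
    if total == 0:
        expo = np.zeros(len(sigs))
    else:
        A = catalog.to_numpy()
        expo, _ = nnls(A, counts)
        if n_bootstrap > 0:
            if rng is None:
                rng = np.random.default_rng(0)
            p = counts / total
            n_int = int(round(total))
            support = np.zeros(len(sigs))
            for _ in range(n_bootstrap):
                bc = rng.multinomial(n_int, p).astype(float)
                e_b, _ = nnls(A, bc)
                support += (e_b / max(bc.sum(), 1.0)) > min_fraction
            keep = support >= (1.0 - alpha) * n_bootstrap
            expo = np.where(keep, expo, 0.0)
    res = pd.Series(expo, index=sigs)
    if conversion is not None:
        res = pd.Series(res.to_numpy() @ conversion.to_numpy(),
                        index=conversion.columns)
    return res


# ---------------------------------------------------------------------------
# strand ratios
# ---------------------------------------------------------------------------

def strand_ratios(events: pd.DataFrame,
                  min_replicative: int = 20) -> pd.Series:
    """Transcriptional (6) and replicative (1) strand-bias log2 ratios.

    Transcriptional: per substitution class, log2((untranscribed + 1) /
    (transcribed + 1)).  Replicative: restricted to the two highest and two
    lowest fork-polarity deciles, counting the four focal reference-strand
    substitution types (T>C, T>G, G>A, C>A) on leading versus lagging
    strands; requires at least ``min_replicative`` qualifying substitutions.
    """
    out = {}
    snv = events[events["class"] == "SNV"]
    if "tx" not in snv.columns:
        log.warning("events lack strand annotation; transcriptional "
                    "ratios computed from 0 events")
        snv = snv.assign(tx="none")
    for s in SUB6:
        sel = snv[snv["sub6"] == s]
        u = int((sel["tx"] == "U").sum())
        t = int((sel["tx"] == "T").sum())
        out[f"txbias_{s}"] = np.log2((u + 1) / (t + 1))

    dec = snv["fork_decile"]
    extreme = snv[(dec <= 2) | (dec >= 9)].copy()
    ref_sub = extreme["ref_sub"]
    is_ref_focal = ref_sub.isin(REPLICATIVE_FOCAL)
    comp = ref_sub.map(complement_sub)
    is_opp_focal = comp.isin(REPLICATIVE_FOCAL)
    qual = extreme[is_ref_focal | is_opp_focal]
    ref_focal = is_ref_focal[is_ref_focal | is_opp_focal]
    top = qual["fork_decile"] >= 9  # reference strand replicated as leading
    leading = (top & ref_focal) | (~top & ~ref_focal)
    n_lead = int(leading.sum())
    n_lag = int(len(qual) - n_lead)
    if len(qual) >= min_replicative:
        out["repbias"] = np.log2((n_lead + 1) / (n_lag + 1))
    else:
        out["repbias"] = np.nan
    return pd.Series(out)


# ---------------------------------------------------------------------------
# region ratios
# ---------------------------------------------------------------------------

def region_ratio_features(events: pd.DataFrame, tracks: TrackBundle,
                          min_ctcf: int = 10) -> pd.Series:
    """X-chromosome hypermutation and CTCF-site mutation ratios.

    X: log2((X SNVs/Mb + 0.1) / (mean autosomal SNVs/Mb + 0.1)).
    CTCF: log2((core + 1) / (flank + 1)) from raw counts; missing below
    ``min_ctcf`` SNVs across core and flank combined.
    """
    snv = events[events["class"] == "SNV"]
    autosomes = [c for c in tracks.chrom_lengths
                 if c not in ("chrX", "chrM")]
    if not autosomes or sum(tracks.chrom_lengths[c] for c in autosomes) == 0:
        raise ValueError("zero autosomal coverage")
    rates = []
    for c in autosomes:
        mb = tracks.chrom_lengths[c] / 1e6
        rates.append((snv["chrom"] == c).sum() / mb)
    auto_mean = float(np.mean(rates))
    x_mb = tracks.chrom_lengths.get("chrX", 0) / 1e6
    x_rate = (snv["chrom"] == "chrX").sum() / x_mb if x_mb else 0.0
    out = {"x_hypermut": np.log2((x_rate + 0.1) / (auto_mean + 0.1))}

    from .syndata import _in_intervals
    core_iv = tracks.ctcf[tracks.ctcf["kind"] == "core"]
    flank_iv = tracks.ctcf[tracks.ctcf["kind"] == "flank"]
    chrom = snv["chrom"].to_numpy()
    pos = snv["pos"].to_numpy()
    n_core = int(_in_intervals(chrom, pos, core_iv).sum())
    n_flank = int(_in_intervals(chrom, pos, flank_iv).sum())
    if n_core + n_flank >= min_ctcf:
        out["ctcf_ratio"] = np.log2((n_core + 1) / (n_flank + 1))
    else:
        out["ctcf_ratio"] = np.nan
    return pd.Series(out)


# ---------------------------------------------------------------------------
# negative binomial regional enrichment
# ---------------------------------------------------------------------------

def _merge_bins(win: pd.DataFrame) -> pd.DataFrame:
    """Exome-style small-bin merging: RT 1+2, H3K36me3 1+2, Expr 0+1,
    DNase 1+2."""
    win = win.copy()
    win["rt_bin"] = win["rt_bin"].replace({1: 2})
    win["h3k_bin"] = win["h3k_bin"].replace({1: 2})
    win["expr_bin"] = win["expr_bin"].replace({0: 1})
    win["dnase_bin"] = win["dnase_bin"].replace({1: 2})
    return win


def _nb_fit(counts, design, offset):
    """MASS-style NB fit (ML dispersion); Poisson fallback on failure."""
    import statsmodels.api as sm
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = sm.NegativeBinomial(counts, design, offset=offset)
            res = model.fit(disp=False, maxiter=200)
            if np.isfinite(res.params).all() and res.mle_retvals.get(
                    "converged", True):
                return res.params[:-1], res.bse[:-1], False
        except Exception:
            pass
        res = sm.GLM(counts, design, offset=offset,
                     family=sm.families.Poisson()).fit()
        return res.params, res.bse, True


def regional_enrichment(events: pd.DataFrame, tracks: TrackBundle,
                        channel_mode: str = "7-class",
                        merged_bins: bool = False,
                        min_snvs: int = 30,
                        max_se: float = 100.0) -> pd.Series:
    """Regional mutation-enrichment coefficients from NB regression.

    Four regressions of binned mutation counts on genomic-state bins with a
    mutation-type covariate and a log-bp offset; the coefficient of the top
    bin against the reference bin (latest replication timing, zero signal)
    is the feature.  Coefficients with SE above ``max_se`` and samples with
    fewer than ``min_snvs`` SNVs are missing.
    """
    out = {f: np.nan for f in
           ["enr_rt", "enr_dnase", "enr_expr", "enr_h3k36me3"]}
    snv = events[events["class"] == "SNV"].copy()
    if len(snv) < min_snvs:
        return pd.Series(out)

    win = tracks.windows
    if merged_bins:
        win = _merge_bins(win)
    widx = tracks.window_index(snv["chrom"].to_numpy(), snv["pos"].to_numpy())
    snv = snv[widx >= 0]
    widx = widx[widx >= 0]
    for col in ["rt_bin", "expr_bin", "h3k_bin", "dnase_bin"]:
        snv[col] = win[col].to_numpy()[widx]
    if channel_mode == "96-channel":
        snv["mtype"] = snv["channel96"]
    else:
        snv["mtype"] = np.where(
            snv["sub6"] == "C>T",
            np.where(snv["cpg"], "C>T_CpG", "C>T_nonCpG"), snv["sub6"])

    bp = tracks.window_size
    specs = [
        ("enr_rt", ["rt_bin"], "rt_bin", max),
        ("enr_dnase", ["rt_bin", "dnase_bin"], "dnase_bin", max),
        ("enr_expr", ["rt_bin", "expr_bin"], "expr_bin", max),
        ("enr_h3k36me3", ["rt_bin", "h3k_bin"], "h3k_bin", max),
    ]
    for feat, bin_cols, target_col, _ in specs:
        size = win.groupby(bin_cols).size() * bp
        counts = snv.groupby(bin_cols + ["mtype"]).size()
        mtypes = sorted(snv["mtype"].unique())
        rows = []
        for combo, n_bp in size.items():
            combo_t = combo if isinstance(combo, tuple) else (combo,)
            for mt in mtypes:
                key = combo_t + (mt,)
                c = counts.get(key, 0)
                rows.append(combo_t + (mt, c, n_bp))
        df = pd.DataFrame(rows, columns=bin_cols + ["mtype", "count", "bp"])
        # reference levels: lowest label of each bin column, first mtype
        X_parts = [pd.Series(1.0, index=df.index, name="const")]
        coef_name = None
        for bc in bin_cols:
            levels = sorted(df[bc].unique())
            for lv in levels[1:]:
                name = f"{bc}_{lv}"
                X_parts.append((df[bc] == lv).astype(float).rename(name))
                if bc == target_col and lv == levels[-1]:
                    coef_name = name
        for mt in mtypes[1:]:
            X_parts.append((df["mtype"] == mt).astype(float)
                           .rename(f"mt_{mt}"))
        X = pd.concat(X_parts, axis=1)
        if coef_name is None:  # target column collapsed to one level
            continue
        try:
            params, bse, _pois = _nb_fit(
                df["count"].to_numpy(dtype=float), X.to_numpy(),
                np.log(df["bp"].to_numpy(dtype=float)))
        except Exception as exc:  # pragma: no cover - non-convergence path
            log.warning("regression for %s failed: %s", feat, exc)
            continue
        j = list(X.columns).index(coef_name)
        if bse[j] <= max_se and np.isfinite(params[j]):
            out[feat] = float(params[j])
    return pd.Series(out)


# ---------------------------------------------------------------------------
# indel and CNA features
# ---------------------------------------------------------------------------

def indel_cna_features(indels: pd.DataFrame,
                       cna_segments: pd.DataFrame,
                       ploidy: float) -> pd.Series:
    """Nine indel features and nine copy-number features.

    Indels are split by length, microsatellite context and flanking
    microhomology; CNAs by event size.  Whole-genome-duplication count is
    floor(ploidy / 2) with a 0.1 pseudocount; ploidy itself is log2 with no
    pseudocount.
    """
    if ploidy <= 0:
        raise ValueError("ploidy must be positive")
    out = {}
    L = indels["length"]
    ms = indels["in_ms"].astype(bool)
    is_del = indels["class"] == "DEL"
    out["indel_total"] = log2p1(len(indels))
    out["indel_1bp_ms"] = log2p1(((L == 1) & ms).sum())
    out["indel_1bp_nonms"] = log2p1(((L == 1) & ~ms).sum())
    out["indel_2_5bp_ms"] = log2p1((L.between(2, 5) & ms).sum())
    out["indel_2_5bp_nonms"] = log2p1((L.between(2, 5) & ~ms).sum())
    out["indel_6_10bp"] = log2p1(L.between(6, 10).sum())
    out["del_ge10bp"] = log2p1((is_del & (L >= 10)).sum())
    out["del_mh_1bp"] = log2p1((is_del & (indels["mh_len"] == 1)).sum())
    out["del_mh_gt1bp"] = log2p1((is_del & (indels["mh_len"] > 1)).sum())

    size = cna_segments["size_kb"]
    amp = cna_segments["type"] == "amp"
    dele = cna_segments["type"] == "del"
    out["amp_1_10kb"] = log2p1((amp & (size > 1) & (size <= 10)).sum())
    out["amp_10_100kb"] = log2p1((amp & (size > 10) & (size <= 100)).sum())
    out["amp_100_1000kb"] = log2p1((amp & (size > 100) & (size <= 1000)).sum())
    out["amp_gt1000kb"] = log2p1((amp & (size > 1000)).sum())
    out["del_1_10kb"] = log2p1((dele & (size > 1) & (size <= 10)).sum())
    out["del_10_100kb"] = log2p1((dele & (size > 10) & (size <= 100)).sum())
    out["del_gt100kb"] = log2p1((dele & (size > 100)).sum())
    out["ploidy"] = np.log2(ploidy)
    out["wgd"] = np.log2(int(ploidy // 2) + 0.1)
    return pd.Series(out)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def extract_features(catalog: dict, tracks: TrackBundle,
                     signature_catalogs: dict,
                     mode: str = "wgs",
                     n_bootstrap: int = 25,
                     seed: int = 0) -> pd.DataFrame:
    """Compute the full samples x 65 feature matrix from an event catalog.

    ``mode`` selects the regression channel encoding and bin merging:
    "wes" uses 7 substitution classes with merged small bins, "wgs" the
    96-channel encoding with unmerged bins.
    """
    rng = np.random.default_rng(seed)
    samples = catalog["samples"]
    events = catalog["events"]
    indels = catalog["indels"]
    dbs = catalog["dbs"]
    mito = catalog["mito"]
    ploidy = catalog["ploidy"].set_index("sample")["ploidy"]
    cna = catalog["cna_segments"]

    channel_mode = "96-channel" if mode == "wgs" else "7-class"
    merged = mode == "wes"
    conv = signature_catalogs.get("conversion")

    rows = {}
    for s in samples:
        ev = events[events["sample"] == s]
        ind = indels[indels["sample"] == s]
        db = dbs[dbs["sample"] == s]
        mt = mito[mito["sample"] == s]
        parts = [count_basic_features(ev, mt)]

        c96 = np.bincount(ev.loc[ev["class"] == "SNV", "channel96"],
                          minlength=96)
        sbs_expo = fit_signatures(c96, signature_catalogs["SBS"],
                                  conversion=conv, n_bootstrap=n_bootstrap,
                                  rng=rng)
        parts.append(pd.Series(log2p1(sbs_expo.to_numpy()),
                               index=list(sbs_expo.index)))
        parts.append(strand_ratios(ev))
        parts.append(region_ratio_features(ev, tracks))
        parts.append(regional_enrichment(ev, tracks,
                                         channel_mode=channel_mode,
                                         merged_bins=merged))
        c78 = np.bincount(db["channel78"], minlength=78)
        dbs_expo = fit_signatures(c78, signature_catalogs["DBS"],
                                  n_bootstrap=n_bootstrap, rng=rng)
        parts.append(pd.Series(log2p1(dbs_expo.to_numpy()), index=DBS_SIGS))
        c83 = np.bincount(ind["channel83"], minlength=83)
        id_expo = fit_signatures(c83, signature_catalogs["ID"],
                                 n_bootstrap=n_bootstrap, rng=rng)
        parts.append(pd.Series(log2p1(id_expo.to_numpy()), index=ID_SIGS))
        parts.append(indel_cna_features(
            ind, cna[cna["sample"] == s], float(ploidy[s])))
        rows[s] = pd.concat(parts)

    feat = pd.DataFrame(rows).T
    return feat.reindex(columns=ALL_FEATURES)
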