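"""Gene-based rare-variant association testing with SKAT-O.

The optimal unified test combines a burden statistic Q_B and a variance
(SKAT) statistic Q_S as Q_rho = rho*Q_B + (1-rho)*Q_S over a grid of 10
mixing values; rho = 1 reduces to the burden test, rho = 0 to SKAT.
Per-rho p-values come from moment-matched mixtures of chi-square variables
on the kernel eigenvalues; the omnibus p combines the grid through the
minimum-p statistic with one-dimensional numerical integration.  A
permutation mode (residual permutation with empirical per-rho p-values)
serves as the model-free oracle.

The module also provides burden effect directions, scenario-level inflation
QC, the randomization-based empirical FDR, the random-gene-set FDR,
discovery-to-validation replication, total-variance-explained estimation,
and validation subsampling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

EXCLUDED = -1

RHO_GRID = np.linspace(0.0, 1.0, 10)

CHI2_MEDIAN_1DF = 0.4549364231195724  # median of the 1-df chi-square


# ---------------------------------------------------------------------------
# null model
# ---------------------------------------------------------------------------

@dataclass
class NullModel:
    design: np.ndarray  # n x p, full rank, includes intercept
    residuals: np.ndarray
    sigma2: float
    samples: pd.Index
    coef: np.ndarray
    columns: list


def build_design(covariates: pd.DataFrame,
                 pcs: pd.DataFrame | None = None,
                 include_cancer_type: bool = True) -> pd.DataFrame:
    """Covariate design: age (median-imputed), sex, cancer-type dummies
    (reference level: lexicographically first) and ancestry PCs."""
    parts = [pd.Series(1.0, index=covariates.index, name="intercept")]
    if "age" in covariates:
        age = covariates["age"].astype(float)
        age = age.fillna(age.median())
        parts.append(age.rename("age"))
    if "sex" in covariates:
        parts.append((covariates["sex"] == "M").astype(float).rename("sex_M"))
    if include_cancer_type and "cancer_type" in covariates:
        levels = sorted(covariates["cancer_type"].unique())
        for lv in levels[1:]:
            parts.append((covariates["cancer_type"] == lv)
                         .astype(float).rename(f"ct_{lv}"))
    df = pd.concat(parts, axis=1)
    if pcs is not None:
        df = df.join(pcs.reindex(df.index).fillna(0.0))
    return df


def fit_null(phenotype: pd.Series, design: pd.DataFrame) -> NullModel:
    """OLS null fit of a component score on the covariate design."""
    y = phenotype.to_numpy(dtype=float)
    if np.std(y) == 0:
        raise ValueError("zero-variance phenotype")
    X = design.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, R = np.linalg.qr(X)
        aliased = [design.columns[j] for j in range(X.shape[1])
                   if abs(R[j, j]) < 1e-8]
        raise ValueError(f"rank-deficient design; aliased columns: {aliased}")
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ coef
    dof = max(len(y) - X.shape[1], 1)
    return NullModel(design=X, residuals=r, sigma2=float(r @ r / dof),
                     samples=design.index, coef=coef,
                     columns=list(design.columns))


# ---------------------------------------------------------------------------
# mixture-of-chi-square tail probabilities (Liu moment matching)
# ---------------------------------------------------------------------------

def _liu_params(lams: np.ndarray) -> dict:
    c1 = lams.sum()
    c2 = (lams ** 2).sum()
    c3 = (lams ** 3).sum()
    c4 = (lams ** 4).sum()
    s1 = c3 / c2 ** 1.5
    s2 = c4 / c2 ** 2
    if s1 ** 2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1 ** 2 - s2))
        d = s1 * a ** 3 - a ** 2
        l = a ** 2 - 2 * d
    else:
        l = 1.0 / s2
        a = np.sqrt(l)
        d = 0.0
    return {"muQ": c1, "sigmaQ": np.sqrt(2 * c2), "l": l, "d": d,
            "muX": l + d, "sigmaX": np.sqrt(2 * (l + 2 * d))}


def liu_sf(q: float, lams: np.ndarray) -> float:
    """Upper-tail probability of sum(lambda_k * chi2_1) at q."""
    lams = lams[lams > 1e-12]
    if len(lams) == 0:
        return 1.0
    pr = _liu_params(lams)
    t = (q - pr["muQ"]) / pr["sigmaQ"] * pr["sigmaX"] + pr["muX"]
    if pr["d"] > 0:
        return float(stats.ncx2.sf(t, pr["l"], pr["d"]))
    return float(stats.chi2.sf(t, pr["l"]))


def liu_quantile(p_upper: float, lams: np.ndarray) -> float:
    """Value whose upper-tail probability under the mixture equals
    ``p_upper``."""
    lams = lams[lams > 1e-12]
    if len(lams) == 0:
        return 0.0
    pr = _liu_params(lams)
    if pr["d"] > 0:
        t = stats.ncx2.isf(p_upper, pr["l"], pr["d"])
    else:
        t = stats.chi2.isf(p_upper, pr["l"])
    return float((t - pr["muX"]) / pr["sigmaX"] * pr["sigmaQ"] + pr["muQ"])


def _rho_sqrt(m: int, rho: float) -> np.ndarray:
    """Matrix square root of R_rho = (1-rho) I + rho 11' (m x m)."""
    a = np.sqrt(1.0 - rho)
    lam1 = 1.0 - rho + rho * m
    b = (np.sqrt(lam1) - a) / m
    return a * np.eye(m) + b * np.ones((m, m))


# ---------------------------------------------------------------------------
# SKAT-O
# ---------------------------------------------------------------------------

@dataclass
class SkatOResult:
    p: float
    rho_star: float
    p_grid: np.ndarray
    q_grid: np.ndarray
    n_carriers: int
    method: str


def _project(G: np.ndarray, X: np.ndarray) -> np.ndarray:
    beta = np.linalg.lstsq(X, G, rcond=None)[0]
    return G - X @ beta


def skat_o_test(
    G: np.ndarray,
    null: NullModel,
    weights: np.ndarray | None = None,
    rho_grid: np.ndarray = RHO_GRID,
    method: str = "analytic",
    n_perm: int = 2000,
    rng: np.random.Generator | None = None,
) -> SkatOResult:
    """SKAT-O test of a gene's variant matrix against the null residuals.

    ``G`` is samples x variants under the chosen inheritance encoding
    (values >= 0; excluded samples must be removed before calling).
    Default weights are flat — variants are pre-filtered to putative LoF,
    so no frequency up-weighting is imposed; Beta(MAF; 1, 25) weights can
    be supplied instead.
    """
    G = np.asarray(G, dtype=float)
    if G.ndim == 1:
        G = G[:, None]
    n, m = G.shape
    if weights is None:
        weights = np.ones(m)
    Gw = G * weights
    if np.all(Gw.std(axis=0) == 0):
        raise ValueError("all genotype columns constant; not testable")
    n_carriers = int((G.sum(axis=1) > 0).sum())

    A = _project(Gw, null.design)
    s = A.T @ null.residuals
    sig2 = null.sigma2
    Q_S = float(s @ s / sig2)
    Q_B = float(s.sum() ** 2 / sig2)
    q_grid = np.array([r * Q_B + (1 - r) * Q_S for r in rho_grid])
    B = A.T @ A

    if method == "permutation":
        if rng is None:
            rng = np.random.default_rng(0)
        R = rng.permuted(
            np.broadcast_to(null.residuals, (n_perm, n)), axis=1).T
        S = A.T @ R  # m x n_perm
        QSp = (S ** 2).sum(axis=0) / sig2
        QBp = S.sum(axis=0) ** 2 / sig2
        all_q = np.empty((len(rho_grid), n_perm + 1))
        for i, r in enumerate(rho_grid):
            all_q[i, 0] = q_grid[i]
            all_q[i, 1:] = r * QBp + (1 - r) * QSp
        # empirical per-rho p by descending rank within the pooled draws
        N1 = n_perm + 1
        p_all = np.empty_like(all_q)
        for i in range(len(rho_grid)):
            # per-rho empirical p: count of draws >= each value
            srt = np.sort(all_q[i])
            ge = N1 - np.searchsorted(srt, all_q[i], side="left")
            p_all[i] = ge / N1
        minp = p_all.min(axis=0)
        p = float((1 + (minp[1:] <= minp[0]).sum()) / (1 + n_perm))
        p_grid = p_all[:, 0]
        rho_star = float(rho_grid[int(np.argmin(p_grid))])
        return SkatOResult(p=p, rho_star=rho_star, p_grid=p_grid,
                           q_grid=q_grid, n_carriers=n_carriers,
                           method="permutation")

    # analytic per-rho p
    p_grid = np.empty(len(rho_grid))
    lam_grid = []
    for i, r in enumerate(rho_grid):
        Rh = _rho_sqrt(m, r)
        lam = np.linalg.eigvalsh(Rh @ B @ Rh)
        lam_grid.append(lam)
        p_grid[i] = liu_sf(q_grid[i], lam)
    rho_star = float(rho_grid[int(np.argmin(p_grid))])
    T = float(p_grid.min())

    if m == 1:
        return SkatOResult(p=T, rho_star=rho_star, p_grid=p_grid,
                           q_grid=q_grid, n_carriers=n_carriers,
                           method="analytic")

    # omnibus combination over the grid (minimum-p, 1-D integration)
    zbar = A.mean(axis=1)
    denom = float(zbar @ zbar)
    if denom < 1e-12:
        return SkatOResult(p=T, rho_star=rho_star, p_grid=p_grid,
                           q_grid=q_grid, n_carriers=n_carriers,
                           method="analytic")
    cof = (zbar @ A) / denom
    A2 = A - np.outer(zbar, cof)
    B2 = A2.T @ A2
    lam2 = np.linalg.eigvalsh(B2)
    lam2 = lam2[lam2 > 1e-10]
    if len(lam2) == 0:
        return SkatOResult(p=T, rho_star=rho_star, p_grid=p_grid,
                           q_grid=q_grid, n_carriers=n_carriers,
                           method="analytic")
    muQ = lam2.sum()
    varQ = 2 * (lam2 ** 2).sum() + 4 * denom * float(cof @ B2 @ cof)
    df_k = (lam2 ** 2).sum() ** 2 / (lam2 ** 4).sum()
    tau = np.array([(m ** 2 * r + (1 - r) * (cof ** 2).sum()) * denom
                    for r in rho_grid])
    rho_cap = np.minimum(rho_grid, 0.999)
    q_at_T = np.array([liu_quantile(T, lam_grid[i])
                       for i in range(len(rho_grid))])

    # integrate over the 1-df chi-square mixing variable; substituting
    # x = u^2 (u half-normal) removes the density singularity at 0
    u = np.linspace(1e-8, np.sqrt(40.0), 800)
    x = u ** 2
    vals = (q_at_T[:, None] - tau[:, None] * x[None, :]) \
        / (1 - rho_cap[:, None])
    v = vals.min(axis=0)
    t = (v - muQ) / np.sqrt(varQ) * np.sqrt(2 * df_k) + df_k
    F = np.where(v > 0, stats.chi2.cdf(np.clip(t, 0, None), df_k), 0.0)
    integral = np.trapezoid(F * 2 * stats.norm.pdf(u), u)
    p = 1.0 - integral
    p = float(np.clip(p, T, min(1.0, T * len(rho_grid))))
    return SkatOResult(p=p, rho_star=rho_star, p_grid=p_grid,
                       q_grid=q_grid, n_carriers=n_carriers,
                       method="analytic")


# ---------------------------------------------------------------------------
# burden effect direction
# ---------------------------------------------------------------------------

def burden_effect(gene_indicator: np.ndarray, phenotype: np.ndarray,
                  design: np.ndarray) -> tuple[float, float, int]:
    """OLS coefficient of a binary gene indicator with covariates.

    Returns (beta, standard error, direction sign)."""
    X = np.column_stack([design, gene_indicator.astype(float)])
    coef, _, _, _ = np.linalg.lstsq(X, phenotype, rcond=None)
    r = phenotype - X @ coef
    dof = max(len(phenotype) - X.shape[1], 1)
    s2 = r @ r / dof
    XtX_inv = np.linalg.pinv(X.T @ X)
    se = float(np.sqrt(s2 * XtX_inv[-1, -1]))
    beta = float(coef[-1])
    return beta, se, int(np.sign(beta))


# ---------------------------------------------------------------------------
# scenario-level inflation QC
# ---------------------------------------------------------------------------

def inflation_lambda(pvals: np.ndarray) -> float:
    """Genomic inflation: median chi-square statistic of the p-values over
    the expected 1-df chi-square median."""
    pvals = np.asarray(pvals, dtype=float)
    chi = stats.chi2.isf(np.clip(pvals, 1e-300, 1.0), df=1)
    return float(np.median(chi) / CHI2_MEDIAN_1DF)


def scenario_qc(results: pd.DataFrame,
                scenario_cols: list[str] | None = None,
                min_genes: int = 100,
                lambda_max: float = 1.5) -> pd.DataFrame:
    """Per-scenario inflation factors with the exclusion rule: a scenario
    is excluded when at least ``min_genes`` genes were tested and its
    inflation factor is at or above ``lambda_max``."""
    if scenario_cols is None:
        scenario_cols = [c for c in
                         ["stratum", "component", "model", "variant_set"]
                         if c in results.columns]
    rows = []
    for key, grp in results.groupby(scenario_cols):
        key = key if isinstance(key, tuple) else (key,)
        lam = inflation_lambda(grp["p"].to_numpy())
        n = len(grp)
        rows.append(key + (n, lam, n >= min_genes and lam >= lambda_max))
    return pd.DataFrame(
        rows, columns=scenario_cols + ["n_genes", "lambda", "excluded"])


# ---------------------------------------------------------------------------
# empirical FDR via within-stratum shuffling
# ---------------------------------------------------------------------------

@dataclass
class FdrCalibration:
    thresholds: pd.DataFrame  # stratum x level -> p threshold
    randomized_p: pd.DataFrame  # stratum, p
    levels: tuple = (0.01, 0.02)
    unstable: list = field(default_factory=list)


def shuffle_scores_within_strata(scores: pd.DataFrame,
                                 cancer_types: pd.Series,
                                 rng: np.random.Generator) -> pd.DataFrame:
    """Permute whole score rows within each cancer type: breaks the
    sample-component link but conserves inter-component correlation."""
    out = scores.copy()
    ct = cancer_types.reindex(scores.index)
    for t in ct.unique():
        idx = np.where((ct == t).to_numpy())[0]
        out.iloc[idx] = scores.iloc[idx[rng.permutation(len(idx))]].to_numpy()
    return out


def empirical_fdr(
    observed: pd.DataFrame,
    run_fn,
    scores: pd.DataFrame,
    cancer_types: pd.Series,
    n_shuffles: int = 1,
    levels: tuple = (0.01, 0.02),
    seed: int = 0,
    min_randomized: int = 100,
) -> tuple[FdrCalibration, pd.DataFrame]:
    """Randomization-based empirical FDR thresholds and hit calls.

    ``run_fn(shuffled_scores)`` must re-run the full testing on a shuffled
    score matrix and return a frame with ``stratum`` and ``p`` columns.
    Per stratum, the threshold at a level is that level's quantile of the
    randomized p distribution; observed tests at or below the threshold are
    hits.
    """
    rng = np.random.default_rng(seed)
    rand_frames = []
    for _ in range(n_shuffles):
        shuffled = shuffle_scores_within_strata(scores, cancer_types, rng)
        rand_frames.append(run_fn(shuffled)[["stratum", "p"]])
    randomized = pd.concat(rand_frames, ignore_index=True)

    unstable = []
    thr_rows = []
    for stratum, grp in randomized.groupby("stratum"):
        ps = grp["p"].to_numpy()
        if len(ps) < min_randomized:
            log.warning("stratum %s: only %d randomized p-values; "
                        "threshold unstable", stratum, len(ps))
            unstable.append(stratum)
        thr_rows.append((stratum,) + tuple(
            float(np.quantile(ps, lv)) for lv in levels))
    thresholds = pd.DataFrame(
        thr_rows, columns=["stratum"] + [f"t_{lv:g}" for lv in levels]
    ).set_index("stratum")

    hits = observed.merge(thresholds, left_on="stratum", right_index=True,
                          how="left")
    for lv in levels:
        hits[f"hit_{lv:g}"] = hits["p"] <= hits[f"t_{lv:g}"]
    cal = FdrCalibration(thresholds=thresholds, randomized_p=randomized,
                         levels=levels, unstable=unstable)
    return cal, hits


def random_geneset_fdr(hits_candidate: int, hits_random: int) -> float:
    """FDR estimate: hits from the random gene list over hits from the
    candidate list, as a percentage (NaN when no candidate hits)."""
    if hits_candidate == 0:
        return float("nan")
    return 100.0 * hits_random / hits_candidate


# ---------------------------------------------------------------------------
# replication
# ---------------------------------------------------------------------------

def replicate(
    discovery_hits: pd.DataFrame,
    validation_results: pd.DataFrame,
    validation_thresholds: pd.DataFrame,
    stratum_map: dict | None = None,
    levels: tuple = (0.01, 0.02),
    min_carriers: int = 2,
) -> pd.DataFrame:
    """Replication calls for discovery hits in the validation cohort.

    A hit replicates when its matching-stratum validation test reaches the
    validation empirical FDR (at either level) with the same burden effect
    direction.  Hits with fewer than ``min_carriers`` validation carriers
    are not re-testable; hits whose stratum has no mapping are unmappable.
    """
    keys = ["gene", "component", "model", "variant_set"]
    keys = [k for k in keys if k in discovery_hits.columns
            and k in validation_results.columns]
    val = validation_results.set_index(keys + ["stratum"])
    out_rows = []
    for _, h in discovery_hits.iterrows():
        stratum = h["stratum"]
        v_stratum = (stratum_map or {}).get(stratum, stratum)
        if stratum_map is not None and stratum not in stratum_map:
            status = "unmappable"
            out_rows.append({**h, "status": status})
            continue
        key = tuple(h[k] for k in keys) + (v_stratum,)
        if key not in val.index:
            out_rows.append({**h, "status": "not_testable"})
            continue
        v = val.loc[key]
        if isinstance(v, pd.DataFrame):
            v = v.iloc[0]
        if v.get("n_carriers", min_carriers) < min_carriers:
            out_rows.append({**h, "status": "not_testable"})
            continue
        if v_stratum not in validation_thresholds.index:
            out_rows.append({**h, "status": "not_testable"})
            continue
        thr = validation_thresholds.loc[v_stratum]
        sig = any(v["p"] <= thr[f"t_{lv:g}"] for lv in levels)
        same_dir = np.sign(v.get("direction", 0)) == np.sign(
            h.get("direction", 0))
        status = "replicated" if (sig and same_dir) else "not_replicated"
        out_rows.append({**h, "status": status,
                         "validation_p": float(v["p"])})
    if not out_rows:
        return pd.DataFrame(
            columns=list(discovery_hits.columns) + ["status",
                                                    "validation_p"])
    return pd.DataFrame(out_rows)


# ---------------------------------------------------------------------------
# total variance explained
# ---------------------------------------------------------------------------

def estimate_tve(phenotype: np.ndarray, design: np.ndarray,
                 variant_genotypes: np.ndarray) -> float:
    """Two-stage lower bound on variance explained by a gene's variants.

    Stage 1 regresses the phenotype on covariates; stage 2 regresses the
    residuals on all per-variant indicator columns; the stage-2 R^2 is
    returned.
    """
    V = np.asarray(variant_genotypes, dtype=float)
    if V.ndim == 1:
        V = V[:, None]
    if V.shape[1] >= len(phenotype):
        raise ValueError("more variant columns than samples")
    coef, _, _, _ = np.linalg.lstsq(design, phenotype, rcond=None)
    r = phenotype - design @ coef
    Vc = np.column_stack([np.ones(len(r)), V])
    coef2, _, _, _ = np.linalg.lstsq(Vc, r, rcond=None)
    fitted = Vc @ coef2
    ss_res = ((r - fitted) ** 2).sum()
    ss_tot = ((r - r.mean()) ** 2).sum()
    if ss_tot == 0:
        return 0.0
    return float(1.0 - ss_res / ss_tot)


# ---------------------------------------------------------------------------
# subsampling
# ---------------------------------------------------------------------------

def subsample_validation(
    run_validation_fn,
    discovery_hits: pd.DataFrame,
    validation_samples: list,
    fractions: tuple = (0.95, 0.90, 0.80),
    reps: int = 3,
    seed: int = 0,
    **replicate_kwargs,
) -> pd.DataFrame:
    """Replication counts when the validation cohort is randomly subsampled.

    ``run_validation_fn(samples)`` must return (validation results,
    validation thresholds) computed on the given sample subset, with
    thresholds re-derived on that subset.
    """
    rng = np.random.default_rng(seed)
    rows = []
    samples = np.asarray(validation_samples)
    for frac in fractions:
        for rep in range(reps):
            keep = rng.choice(len(samples), size=int(round(frac *
                                                           len(samples))),
                              replace=False)
            res, thr = run_validation_fn(samples[np.sort(keep)])
            rep_df = replicate(discovery_hits, res, thr, **replicate_kwargs)
            n_rep = int((rep_df["status"] == "replicated").sum())
            rows.append((frac, rep, n_rep))
    return pd.DataFrame(rows, columns=["fraction", "rep", "n_replicated"])


# ---------------------------------------------------------------------------
# cohort-level scan
# ---------------------------------------------------------------------------

def association_scan(
    scores: pd.DataFrame,
    encoded: pd.DataFrame,
    covariates: pd.DataFrame,
    pcs: pd.DataFrame | None = None,
    strata: list | None = None,
    model: str = "dominant",
    variant_set: str = "III",
    min_carriers: int = 2,
    method: str = "analytic",
    n_perm: int = 1000,
    min_snvs: pd.Series | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Test every gene x component x stratum combination.

    ``encoded`` is genes x samples with values {0, 1, 2} or -1 for
    recessive-excluded samples.  ``strata`` lists cancer types to test
    separately; "pan" tests all samples jointly with cancer-type dummies.
    Genes are testable with at least ``min_carriers`` carriers in the
    stratum (excluded samples removed per gene).
    """
    rng = np.random.default_rng(seed)
    samples = scores.index.intersection(covariates.index)
    if min_snvs is not None:
        samples = samples[min_snvs.reindex(samples).fillna(0) >= 10]
    scores = scores.loc[samples]
    cov = covariates.loc[samples]
    if strata is None:
        strata = ["pan"]

    rows = []
    for stratum in strata:
        if stratum == "pan":
            mask = pd.Series(True, index=samples)
            pan = True
        else:
            mask = cov["cancer_type"] == stratum
            pan = False
        sub = samples[mask]
        if len(sub) < 10:
            continue
        design = build_design(cov.loc[sub], pcs=pcs,
                              include_cancer_type=pan)
        for comp in scores.columns:
            null = fit_null(scores.loc[sub, comp], design)
            y = scores.loc[sub, comp].to_numpy()
            for gene in encoded.index:
                g = encoded.loc[gene, sub].to_numpy()
                keep = g != EXCLUDED
                gk = g[keep]
                n_carr = int((gk > 0).sum())
                if n_carr < min_carriers or gk.std() == 0:
                    continue
                if keep.all():
                    nm, Xk, yk = null, design.to_numpy(), y
                else:
                    dsub = design.loc[sub[keep]]
                    nm = fit_null(scores.loc[sub[keep], comp], dsub)
                    Xk, yk = dsub.to_numpy(), y[keep]
                res = skat_o_test(gk[:, None], nm, method=method,
                                  n_perm=n_perm, rng=rng)
                beta, se, direction = burden_effect(
                    (gk > 0).astype(float), yk, Xk)
                rows.append((gene, stratum, comp, model, variant_set,
                             res.p, res.rho_star, n_carr, beta, direction))
    return pd.DataFrame(rows, columns=[
        "gene", "stratum", "component", "model", "variant_set",
        "p", "rho", "n_carriers", "beta", "direction"])
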