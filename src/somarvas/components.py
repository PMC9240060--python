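"""Latent mutational-component extraction.

Assembles the standardized somatic-feature input matrix, extracts
independent components with a stability-clustering procedure (repeated
FastICA runs pooled and clustered by k-medoids; mirrored sign-flip pairs
deduplicated), trains a warm-started variational autoencoder as an
alternative non-linear extraction, and summarizes components by feature
correlations and tissue enrichments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import FastICA
from sklearn.metrics import silhouette_samples

from .registry import EXCLUDED_FEATURES, RETAINED_FEATURES

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# input matrix
# ---------------------------------------------------------------------------

def assemble_input(cohort_features: dict[str, pd.DataFrame],
                   max_missing_frac: float = 0.20) -> tuple[pd.DataFrame,
                                                            pd.Series]:
    """Build the standardized input matrix from per-cohort feature tables.

    Drops the 9 excluded count features, removes samples missing more than
    20% of features, imputes remaining missing values with the per-cohort
    column median, z-scores per cohort, and concatenates cohorts.

    Returns (matrix, cohort label per sample).
    """
    blocks, labels = [], []
    for name, feat in cohort_features.items():
        if len(feat) < 2:
            raise ValueError(f"cohort {name!r} has fewer than 2 samples")
        sub = feat.drop(columns=[c for c in EXCLUDED_FEATURES
                                 if c in feat.columns])
        sub = sub.reindex(columns=RETAINED_FEATURES)
        miss = sub.isna().mean(axis=1)
        sub = sub[miss <= max_missing_frac]
        sub = sub.fillna(sub.median())
        sd = sub.std(ddof=0)
        zero = sd[sd == 0].index.tolist()
        if zero:
            raise ValueError(
                f"constant feature column(s) in cohort {name!r}: {zero}")
        sub = (sub - sub.mean()) / sd
        blocks.append(sub)
        labels.extend([name] * len(sub))
    X = pd.concat(blocks, axis=0)
    return X, pd.Series(labels, index=X.index, name="cohort")


# ---------------------------------------------------------------------------
# k-medoids (PAM-style) on a precomputed distance matrix
# ---------------------------------------------------------------------------

def kmedoids(D: np.ndarray, k: int, rng: np.random.Generator,
             max_iter: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Alternating k-medoids on a precomputed distance matrix.

    Medoids are initialized k-medoids++-style; returns (medoid indices,
    labels).
    """
    n = D.shape[0]
    medoids = [int(rng.integers(n))]
    for _ in range(k - 1):
        d = D[:, medoids].min(axis=1)
        probs = d ** 2
        if probs.sum() == 0:
            probs = np.ones(n)
        probs = probs / probs.sum()
        medoids.append(int(rng.choice(n, p=probs)))
    medoids = np.array(medoids)
    for _ in range(max_iter):
        labels = np.argmin(D[:, medoids], axis=1)
        new = medoids.copy()
        for j in range(k):
            members = np.where(labels == j)[0]
            if len(members) == 0:
                continue
            within = D[np.ix_(members, members)].sum(axis=1)
            new[j] = members[int(np.argmin(within))]
        if np.array_equal(np.sort(new), np.sort(medoids)):
            break
        medoids = new
    labels = np.argmin(D[:, medoids], axis=1)
    return medoids, labels


def _cluster_silhouettes(D, labels):
    """(mean of per-cluster mean silhouettes, lowest, second lowest)."""
    s = silhouette_samples(D, labels, metric="precomputed")
    per_cluster = pd.Series(s).groupby(labels).mean().to_numpy()
    srt = np.sort(per_cluster)
    second = srt[1] if len(srt) > 1 else srt[0]
    return float(per_cluster.mean()), float(srt[0]), float(second)


# ---------------------------------------------------------------------------
# ICA with stability clustering
# ---------------------------------------------------------------------------

@dataclass
class ComponentModel:
    method: str
    scores: pd.DataFrame  # samples x k
    loadings: pd.DataFrame | None = None  # features x k (ICA)
    contributions: pd.DataFrame | None = None  # features x k (ICA)
    feature_correlations: pd.DataFrame | None = None


@dataclass
class ICAStabilityResult:
    silhouette_table: pd.DataFrame  # n_components, k, mean/lowest/second
    selected_n_components: int
    medoid_loadings: np.ndarray  # pre-dedup, 2*n_comp x features
    mirror_correlations: list  # per retained component, its mirror corr


def run_ica_stability(
    X: pd.DataFrame,
    n_comp_grid: list[int] | None = None,
    n_runs: int = 200,
    k_grid: range | None = None,
    n_components: int | None = None,
    mean_sil_min: float = 0.8,
    second_sil_min: float = 0.5,
    mirror_corr_max: float = -0.95,
    max_nonconverged_frac: float = 0.10,
    tol: float = 1e-4,
    max_iter: int = 1000,
    seed: int = 0,
) -> tuple[ICAStabilityResult, ComponentModel]:
    """Stability-clustered FastICA decomposition of the input matrix.

    For each candidate component number, FastICA (negentropy-based, with
    whitening) is rerun ``n_runs`` times under distinct seeds, the pooled
    unit-norm loading vectors are clustered by k-medoids, and cluster
    silhouettes are recorded.  Because component signs flip randomly across
    runs, each component appears as a mirrored pair of clusters, so the
    informative cluster number is twice the component number.  Cluster
    medoids become loadings; mirrored pairs are deduplicated keeping the
    member whose largest-|loading| feature is positive.  Contributions are
    squared loadings normalized to sum to 1 per component, and scores are
    the least-squares projection of the input on the loadings.
    """
    rng = np.random.default_rng(seed)
    Xv = X.to_numpy()
    if n_comp_grid is None:
        n_comp_grid = [n_components] if n_components else list(range(2, 11))

    pooled: dict[int, np.ndarray] = {}
    sil_rows = []
    for nc in n_comp_grid:
        vecs = []
        n_fail = 0
        for r in range(n_runs):
            import warnings as _w
            with _w.catch_warnings(record=True) as wlog:
                _w.simplefilter("always")
                ica = FastICA(n_components=nc, whiten="unit-variance",
                              fun="logcosh", tol=tol, max_iter=max_iter,
                              random_state=int(rng.integers(2 ** 31)))
                S = ica.fit_transform(Xv)
                if any("did not converge" in str(w.message) for w in wlog):
                    n_fail += 1
                    continue
            A = ica.mixing_  # features x nc
            A = A / np.linalg.norm(A, axis=0, keepdims=True)
            vecs.append(A.T)
        if n_fail > max_nonconverged_frac * n_runs:
            raise RuntimeError(
                f"{n_fail}/{n_runs} FastICA runs failed to converge "
                f"at {nc} components")
        if n_fail:
            log.info("%d/%d non-convergent ICA runs excluded at %d "
                     "components", n_fail, n_runs, nc)
        P = np.vstack(vecs)
        pooled[nc] = P
        C = np.corrcoef(P)
        D = 1.0 - C
        np.fill_diagonal(D, 0.0)
        D = np.clip((D + D.T) / 2, 0.0, None)
        ks = k_grid if k_grid is not None else range(2, 51)
        for k in ks:
            if k >= len(P):
                continue
            _, labels = kmedoids(D, k, rng)
            if len(np.unique(labels)) < 2:
                continue
            mean_s, low, second = _cluster_silhouettes(D, labels)
            sil_rows.append((nc, k, mean_s, low, second))
    sil = pd.DataFrame(
        sil_rows,
        columns=["n_components", "k", "mean_sil", "lowest_sil", "second_sil"])

    if n_components is None:
        ok = sil[(sil["k"] == 2 * sil["n_components"])
                 & (sil["mean_sil"] > mean_sil_min)
                 & (sil["second_sil"] > second_sil_min)]
        if len(ok):
            n_components = int(ok["n_components"].max())
        else:
            at2 = sil[sil["k"] == 2 * sil["n_components"]]
            n_components = int(
                at2.loc[at2["mean_sil"].idxmax(), "n_components"])

    P = pooled[n_components]
    C = np.corrcoef(P)
    D = np.clip(1.0 - (C + C.T) / 2, 0.0, None)
    np.fill_diagonal(D, 0.0)
    med_idx, labels = kmedoids(D, 2 * n_components, rng)
    medoids = P[med_idx]  # 2*nc x features

    # mirror-pair dedup: greedy disjoint matching on most-negative
    # correlations, so the retained count is always clusters/2; the kept
    # member is the one whose largest-|loading| feature is positive
    mc = np.corrcoef(medoids)
    n_med = len(medoids)
    cand_pairs = sorted(
        ((mc[i, j], i, j) for i in range(n_med) for j in range(i + 1, n_med)),
        key=lambda t: t[0])
    keep, used, mirror_corr = [], set(), []
    for corr, i, j in cand_pairs:
        if i in used or j in used:
            continue
        used.update((i, j))
        if corr > mirror_corr_max:
            log.warning("mirror pair correlation %.3f above %.2f; "
                        "clusters may be unstable", corr, mirror_corr_max)
        pair = [medoids[i], medoids[j]]
        signs = [v[int(np.argmax(np.abs(v)))] > 0 for v in pair]
        keep.append(pair[0] if signs[0] else pair[1])
        mirror_corr.append(float(corr))
    for i in range(n_med):  # odd leftover (odd cluster count only)
        if i not in used:
            v = medoids[i]
            if v[int(np.argmax(np.abs(v)))] < 0:
                v = -v
            keep.append(v)
            mirror_corr.append(float(np.nan))
    L = np.array(keep).T  # features x n_kept

    contrib = L ** 2
    contrib = contrib / contrib.sum(axis=0, keepdims=True)
    # scores: least squares of X ~ S L^T
    S = np.linalg.lstsq(L, Xv.T, rcond=None)[0].T
    names = [f"IC{i + 1}" for i in range(L.shape[1])]
    model = ComponentModel(
        method="ICA",
        scores=pd.DataFrame(S, index=X.index, columns=names),
        loadings=pd.DataFrame(L, index=X.columns, columns=names),
        contributions=pd.DataFrame(contrib, index=X.columns, columns=names),
    )
    model.feature_correlations = feature_score_correlations(X, model.scores)
    result = ICAStabilityResult(
        silhouette_table=sil,
        selected_n_components=n_components,
        medoid_loadings=medoids,
        mirror_correlations=mirror_corr,
    )
    return result, model


# ---------------------------------------------------------------------------
# variational autoencoder (numpy, manual gradients)
# ---------------------------------------------------------------------------

@dataclass
class VAEConfig:
    """Hyperparameters of the warm-started VAE.

    ``beta`` starts at ``beta0`` (0 = pure reconstruction) and grows by
    ``kappa`` per epoch up to 1, so the KL term is phased in gradually.
    """

    latent_dim: int = 14
    beta0: float = 0.0
    kappa: float = 0.001
    hidden_layer: bool = False  # extra layer of width 2 x latent_dim
    epochs: int = 100
    batch_size: int = 64
    learning_rate: float = 2e-3
    val_fraction: float = 0.10
    n_restarts: int = 1
    seed: int = 0


def _glorot(rng, n_in, n_out):
    lim = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-lim, lim, size=(n_in, n_out))


class _VAE:
    """Minimal VAE: dense encoder heads with batch-norm + ReLU, tanh
    decoder, MSE + beta*KL loss, Adam."""

    def __init__(self, n_features, cfg: VAEConfig, rng):
        self.cfg = cfg
        d, h = n_features, 2 * cfg.latent_dim
        self.hidden = cfg.hidden_layer
        self.params = {}
        p = self.params
        enc_in = d
        if self.hidden:
            p["W0"] = _glorot(rng, d, h)
            p["b0"] = np.zeros(h)
            p["g0"] = np.ones(h)
            p["be0"] = np.zeros(h)
            enc_in = h
        for head in ("m", "v"):
            p[f"W{head}"] = _glorot(rng, enc_in, cfg.latent_dim)
            p[f"b{head}"] = np.zeros(cfg.latent_dim)
            p[f"g{head}"] = np.ones(cfg.latent_dim)
            p[f"be{head}"] = np.zeros(cfg.latent_dim)
        p["Wd"] = _glorot(rng, cfg.latent_dim, d)
        p["bd"] = np.zeros(d)
        self.running = {k: (np.zeros_like(p[f"g{k}"]),
                            np.ones_like(p[f"g{k}"]))
                        for k in (["0"] if self.hidden else [])
                        + ["m", "v"]}
        self.adam_m = {k: np.zeros_like(v) for k, v in p.items()}
        self.adam_v = {k: np.zeros_like(v) for k, v in p.items()}
        self.t = 0

    @staticmethod
    def _bn_fwd(x, g, b, eps=1e-5):
        mu = x.mean(axis=0)
        var = x.var(axis=0)
        xh = (x - mu) / np.sqrt(var + eps)
        return g * xh + b, (xh, var, g, eps)

    @staticmethod
    def _bn_bwd(dout, cache):
        xh, var, g, eps = cache
        n = xh.shape[0]
        dg = (dout * xh).sum(axis=0)
        db = dout.sum(axis=0)
        dxh = dout * g
        dx = (dxh - dxh.mean(axis=0) - xh * (dxh * xh).mean(axis=0)) \
            / np.sqrt(var + eps)
        return dx, dg, db

    def _encode_train(self, x, rng):
        p = self.params
        cache = {"x": x}
        h = x
        if self.hidden:
            a0 = h @ p["W0"] + p["b0"]
            bn0, c0 = self._bn_fwd(a0, p["g0"], p["be0"])
            h0 = np.maximum(bn0, 0.0)
            cache.update(a0=a0, c0=c0, bn0=bn0, h0=h0)
            h = h0
        am = h @ p["Wm"] + p["bm"]
        bnm, cm = self._bn_fwd(am, p["gm"], p["bem"])
        mu = np.maximum(bnm, 0.0)
        av = h @ p["Wv"] + p["bv"]
        bnv, cv = self._bn_fwd(av, p["gv"], p["bev"])
        logvar = np.maximum(bnv, 0.0)
        eps = rng.standard_normal(mu.shape)
        z = mu + np.exp(0.5 * logvar) * eps
        cache.update(h=h, cm=cm, bnm=bnm, mu=mu, cv=cv, bnv=bnv,
                     logvar=logvar, eps=eps, z=z)
        return cache

    def encode(self, x):
        """Deterministic encoding (latent means) with running BN stats."""
        p = self.params
        h = x

        def bn_inf(a, key):
            mu, var = self.running[key]
            return p[f"g{key}"] * (a - mu) / np.sqrt(var + 1e-5) \
                + p[f"be{key}"]

        if self.hidden:
            h = np.maximum(bn_inf(h @ p["W0"] + p["b0"], "0"), 0.0)
        return np.maximum(bn_inf(h @ p["Wm"] + p["bm"], "m"), 0.0)

    def decode(self, z):
        p = self.params
        return np.tanh(z @ p["Wd"] + p["bd"])

    def reconstruct(self, x):
        return self.decode(self.encode(x))

    def _update_running(self, cache):
        mom = 0.9
        p = self.params
        acts = {"m": cache["h"] @ p["Wm"] + p["bm"],
                "v": cache["h"] @ p["Wv"] + p["bv"]}
        if self.hidden:
            acts["0"] = cache["x"] @ p["W0"] + p["b0"]
        for key, a in acts.items():
            rm, rv = self.running[key]
            self.running[key] = (mom * rm + (1 - mom) * a.mean(axis=0),
                                 mom * rv + (1 - mom) * a.var(axis=0))

    def step(self, x, beta, lr, rng):
        """One minibatch gradient step; returns (recon loss, KL)."""
        p = self.params
        n, d = x.shape
        cache = self._encode_train(x, rng)
        z = cache["z"]
        a_d = z @ p["Wd"] + p["bd"]
        xhat = np.tanh(a_d)
        diff = xhat - x
        # reconstruction summed over features, averaged over the batch
        recon = float((diff ** 2).sum(axis=1).mean())
        mu, logvar = cache["mu"], cache["logvar"]
        kl = float(-0.5 * (1 + logvar - mu ** 2 - np.exp(logvar))
                   .sum(axis=1).mean())

        grads = {}
        dxhat = 2.0 * diff / n
        da_d = dxhat * (1 - xhat ** 2)
        grads["Wd"] = z.T @ da_d
        grads["bd"] = da_d.sum(axis=0)
        dz = da_d @ p["Wd"].T
        dmu = dz + beta * mu / n
        sd = np.exp(0.5 * logvar)
        dlogvar = dz * cache["eps"] * 0.5 * sd \
            + beta * 0.5 * (np.exp(logvar) - 1) / n
        # back through relu + BN for each head
        dbnm = dmu * (cache["bnm"] > 0)
        dam, grads["gm"], grads["bem"] = self._bn_bwd(dbnm, cache["cm"])
        dbnv = dlogvar * (cache["bnv"] > 0)
        dav, grads["gv"], grads["bev"] = self._bn_bwd(dbnv, cache["cv"])
        h = cache["h"]
        grads["Wm"] = h.T @ dam
        grads["bm"] = dam.sum(axis=0)
        grads["Wv"] = h.T @ dav
        grads["bv"] = dav.sum(axis=0)
        if self.hidden:
            dh = dam @ p["Wm"].T + dav @ p["Wv"].T
            dbn0 = dh * (cache["bn0"] > 0)
            da0, grads["g0"], grads["be0"] = self._bn_bwd(dbn0, cache["c0"])
            grads["W0"] = cache["x"].T @ da0
            grads["b0"] = da0.sum(axis=0)

        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for k, g in grads.items():
            self.adam_m[k] = b1 * self.adam_m[k] + (1 - b1) * g
            self.adam_v[k] = b2 * self.adam_v[k] + (1 - b2) * g ** 2
            mhat = self.adam_m[k] / (1 - b1 ** self.t)
            vhat = self.adam_v[k] / (1 - b2 ** self.t)
            p[k] -= lr * mhat / (np.sqrt(vhat) + eps)
        self._update_running(cache)
        if not np.isfinite(recon):
            raise FloatingPointError(
                f"NaN/inf loss at step {self.t} (recon={recon}, kl={kl})")
        return recon, kl


def scale_to_unit_interval(X: pd.DataFrame) -> pd.DataFrame:
    """Min-max scale each feature to [-1, 1] (tanh decoder range)."""
    lo, hi = X.min(), X.max()
    span = (hi - lo).replace(0, 1.0)
    return 2.0 * (X - lo) / span - 1.0


def _stratified_split(strata: pd.Series, val_fraction: float, rng):
    val_idx = []
    for _, grp in strata.groupby(strata):
        idx = grp.index.to_numpy()
        rng.shuffle(idx)
        n_val = max(1, int(round(val_fraction * len(idx)))) \
            if len(idx) > 1 else 0
        val_idx.extend(idx[:n_val])
    val = strata.index.isin(val_idx)
    return ~val, val


def train_vae(
    X: pd.DataFrame,
    cfg: VAEConfig,
    strata: pd.Series | None = None,
    reference_components: pd.DataFrame | None = None,
) -> tuple[ComponentModel, dict]:
    """Train the warm-started VAE and report its selection metrics.

    ``X`` must be scaled to [-1, 1].  ``strata`` (e.g. sex x cancer type)
    drives the 90/10 train/validation split.  Metrics: mean Pearson r of
    reconstructed vs input validation rows, and — when reference component
    scores are supplied — the mean over reference components of the max |r|
    with any latent dimension.
    """
    if np.nanmax(np.abs(X.to_numpy())) > 1.0 + 1e-9:
        raise ValueError("VAE input must be scaled to [-1, 1]")
    rng = np.random.default_rng(cfg.seed)
    if strata is None:
        strata = pd.Series("all", index=X.index)
    train_m, val_m = _stratified_split(strata, cfg.val_fraction, rng)
    Xt = X.loc[train_m].to_numpy()
    Xv = X.loc[val_m].to_numpy()

    best = None
    for restart in range(cfg.n_restarts):
        vae = _VAE(X.shape[1], cfg, rng)
        beta = cfg.beta0
        for epoch in range(cfg.epochs):
            order = rng.permutation(len(Xt))
            for i in range(0, len(Xt), cfg.batch_size):
                batch = Xt[order[i:i + cfg.batch_size]]
                if len(batch) < 2:
                    continue
                vae.step(batch, beta, cfg.learning_rate, rng)
            beta = min(1.0, beta + cfg.kappa)
        rec = vae.reconstruct(Xv)
        rs = [stats.pearsonr(rec[i], Xv[i])[0] for i in range(len(Xv))]
        mean_r = float(np.nanmean(rs)) if len(rs) else np.nan
        if best is None or mean_r > best[0]:
            best = (mean_r, vae)
    mean_r, vae = best

    Z = vae.encode(X.to_numpy())
    names = [f"VAE{i + 1}" for i in range(cfg.latent_dim)]
    scores = pd.DataFrame(Z, index=X.index, columns=names)
    metrics = {"val_reconstruction_r": mean_r,
               "final_beta": min(1.0, cfg.beta0 + cfg.kappa * cfg.epochs)}
    if reference_components is not None:
        ref_rs = []
        for c in reference_components.columns:
            ref = reference_components[c].to_numpy()
            rs = [abs(stats.pearsonr(ref, Z[:, j])[0])
                  if Z[:, j].std() > 0 else 0.0
                  for j in range(Z.shape[1])]
            ref_rs.append(max(rs))
        metrics["reference_component_r"] = float(np.mean(ref_rs))
    model = ComponentModel(method="VAE", scores=scores)
    model.feature_correlations = feature_score_correlations(X, scores)
    return model, metrics


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def feature_score_correlations(features: pd.DataFrame,
                               scores: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of each input feature with each component."""
    F = features.to_numpy()
    S = scores.to_numpy()
    Fz = (F - F.mean(axis=0)) / np.where(F.std(axis=0) == 0, 1, F.std(axis=0))
    Sz = (S - S.mean(axis=0)) / np.where(S.std(axis=0) == 0, 1, S.std(axis=0))
    R = Fz.T @ Sz / len(F)
    return pd.DataFrame(R, index=features.columns, columns=scores.columns)


def cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    nx, ny = len(x), len(y)
    sp = np.sqrt(((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1))
                 / (nx + ny - 2))
    if sp == 0:
        return 0.0
    return float((x.mean() - y.mean()) / sp)


def component_summaries(
    scores: pd.DataFrame,
    features: pd.DataFrame,
    cancer_types: pd.Series,
    tissue_map: dict | None = None,
    min_group: int = 3,
) -> dict:
    """Feature-score correlations and per-cancer-type tissue enrichments.

    For each component x cancer type, a two-sided Welch t-test of that
    type's scores against all others plus Cohen's d; when a tissue map is
    given, per-tissue mean d is also reported.
    """
    corr = feature_score_correlations(features.loc[scores.index], scores)
    rows = []
    for comp in scores.columns:
        v = scores[comp]
        for ct in sorted(cancer_types.unique()):
            a = v[cancer_types == ct].to_numpy()
            b = v[cancer_types != ct].to_numpy()
            if len(a) < min_group or len(b) < min_group:
                rows.append((comp, ct, np.nan, np.nan))
                continue
            t, p = stats.ttest_ind(a, b, equal_var=False)
            rows.append((comp, ct, float(p), cohens_d(a, b)))
    enrich = pd.DataFrame(
        rows, columns=["component", "cancer_type", "welch_p", "cohens_d"])
    out = {"correlations": corr, "enrichments": enrich}
    if tissue_map is not None:
        enrich = enrich.assign(
            tissue=enrich["cancer_type"].map(tissue_map))
        out["tissue_mean_d"] = (
            enrich.groupby(["component", "tissue"])["cohens_d"]
            .mean().reset_index())
    return out
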