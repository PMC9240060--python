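"""SKAT-O association machinery: null model, test statistics, inflation,
empirical FDR, replication, TVE and subsampling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from somarvas import assoc


@pytest.fixture(scope="module")
def null_setup():
    rng = np.random.default_rng(1)
    n = 500
    cov = pd.DataFrame({
        "age": rng.normal(60, 10, n),
        "sex": rng.choice(["F", "M"], n),
        "cancer_type": rng.choice(list("AB"), n),
    }, index=[f"S{i}" for i in range(n)])
    design = assoc.build_design(cov)
    y = pd.Series(rng.normal(size=n), index=cov.index)
    return cov, design, y, rng


class TestNullModel:
    def test_zero_variance_phenotype_raises(self, null_setup):
        cov, design, y, _ = null_setup
        with pytest.raises(ValueError, match="zero-variance"):
            assoc.fit_null(y * 0, design)

    def test_rank_deficient_design_names_columns(self, null_setup):
        cov, design, y, _ = null_setup
        bad = design.copy()
        bad["dup"] = bad["age"]
        with pytest.raises(ValueError, match="aliased"):
            assoc.fit_null(y, bad)

    def test_orthogonal_covariates_residuals_centered(self):
        n = 200
        rng = np.random.default_rng(2)
        y = pd.Series(rng.normal(size=n))
        X = pd.DataFrame({"intercept": np.ones(n)})
        null = assoc.fit_null(y, X)
        assert np.allclose(null.residuals, y - y.mean())

    def test_planted_age_effect_recovered(self):
        rng = np.random.default_rng(3)
        n = 2000
        age = rng.normal(60, 12, n)
        y = pd.Series(0.05 * age + rng.normal(size=n))  # 0.5 per decade
        X = pd.DataFrame({"intercept": np.ones(n), "age": age})
        null = assoc.fit_null(y, X)
        se = 1.0 / (np.sqrt(n) * age.std())
        assert abs(null.coef[1] - 0.05) < 2 * se


class TestSkatO:
    def test_rho_endpoints_reduce_to_burden_and_skat(self, null_setup):
        _, design, y, _ = null_setup
        rng = np.random.default_rng(4)
        null = assoc.fit_null(y, design)
        G = (rng.random((len(y), 3)) < 0.02).astype(float)
        res = assoc.skat_o_test(G, null)
        # Q_rho = rho*Q_B + (1-rho)*Q_S reproduced on the grid
        qb, qs = res.q_grid[-1], res.q_grid[0]
        for r, q in zip(assoc.RHO_GRID, res.q_grid):
            assert q == pytest.approx(r * qb + (1 - r) * qs, rel=1e-9)

    def test_single_variant_equals_score_test(self, null_setup):
        _, design, y, _ = null_setup
        rng = np.random.default_rng(5)
        null = assoc.fit_null(y, design)
        g = (rng.random(len(y)) < 0.01).astype(float)
        res = assoc.skat_o_test(g, null)
        # closed-form score test for a single variant
        X = design.to_numpy()
        gp = g - X @ np.linalg.lstsq(X, g, rcond=None)[0]
        s = gp @ null.residuals
        chi = s ** 2 / (null.sigma2 * (gp @ gp))
        p_oracle = stats.chi2.sf(chi, 1)
        assert res.p == pytest.approx(p_oracle, rel=1e-6)
        assert np.allclose(res.p_grid, res.p_grid[0])

    def test_sandwich_property(self, null_setup):
        _, design, y, _ = null_setup
        rng = np.random.default_rng(6)
        null = assoc.fit_null(y, design)
        for _ in range(20):
            G = (rng.random((len(y), rng.integers(2, 5))) < 0.02) \
                .astype(float)
            if (G.std(axis=0) == 0).any():
                continue
            res = assoc.skat_o_test(G, null)
            T = res.p_grid.min()
            assert T - 1e-12 <= res.p <= min(1.0, T * len(assoc.RHO_GRID)) \
                + 1e-12

    def test_analytic_agrees_with_permutation_oracle(self, null_setup):
        _, design, y, _ = null_setup
        rng = np.random.default_rng(7)
        null = assoc.fit_null(y, design)
        pa, pp = [], []
        for _ in range(60):
            G = (rng.random((len(y), rng.integers(1, 4))) < 0.02) \
                .astype(float)
            if (G.std(axis=0) == 0).any():
                continue
            pa.append(assoc.skat_o_test(G, null).p)
            pp.append(assoc.skat_o_test(G, null, method="permutation",
                                        n_perm=1000, rng=rng).p)
        r = stats.spearmanr(pa, pp).statistic
        assert r > 0.95

    def test_constant_genotypes_not_testable(self, null_setup):
        _, design, y, _ = null_setup
        null = assoc.fit_null(y, design)
        with pytest.raises(ValueError, match="not testable"):
            assoc.skat_o_test(np.ones(len(y)), null)


class TestBurden:
    def test_flipping_phenotype_flips_direction(self, null_setup):
        _, design, y, _ = null_setup
        rng = np.random.default_rng(8)
        g = (rng.random(len(y)) < 0.05).astype(float)
        yy = y.to_numpy() + 0.8 * g
        X = design.to_numpy()
        b1, _, d1 = assoc.burden_effect(g, yy, X)
        b2, _, d2 = assoc.burden_effect(g, -yy, X)
        assert b1 == pytest.approx(-b2)
        assert d1 == -d2

    def test_planted_positive_shift_direction(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 1000
            g = np.zeros(n)
            g[:40] = 1
            y = rng.normal(size=n) + 1.0 * g
            X = np.ones((n, 1))
            _, _, d = assoc.burden_effect(g, y, X)
            hits += d > 0
        assert hits >= 19

    def test_independent_gene_ci_covers_zero(self):
        rng = np.random.default_rng(9)
        n = 2000
        g = (rng.random(n) < 0.05).astype(float)
        y = rng.normal(size=n)
        beta, se, _ = assoc.burden_effect(g, y, np.ones((n, 1)))
        assert abs(beta) < 2.5 * se


class TestInflation:
    def test_all_half_pvalues_lambda_one(self):
        assert assoc.inflation_lambda(np.full(100, 0.5)) \
            == pytest.approx(1.0, abs=1e-6)

    def test_uniform_pvalues_lambda_near_one(self):
        rng = np.random.default_rng(10)
        lam = assoc.inflation_lambda(rng.random(10_000))
        assert lam == pytest.approx(1.0, abs=0.05)

    def test_exclusion_rule(self):
        rng = np.random.default_rng(11)
        # inflated scenario: 120 genes with chi2 scaled by 1.6
        chi = stats.chi2.rvs(1, size=120, random_state=11) * 1.6
        p_inf = stats.chi2.sf(chi, 1)
        res = pd.DataFrame({
            "stratum": ["pan"] * 120 + ["A"] * 50,
            "component": "c1", "model": "dominant", "variant_set": "III",
            "p": np.concatenate([p_inf, rng.random(50)])})
        qc = assoc.scenario_qc(res)
        pan = qc[qc["stratum"] == "pan"].iloc[0]
        small = qc[qc["stratum"] == "A"].iloc[0]
        assert pan["lambda"] > 1.5 and pan["excluded"]
        assert not small["excluded"]  # fewer than 100 genes


class TestEmpiricalFdr:
    def test_uniform_randomized_threshold_near_level(self):
        rng = np.random.default_rng(12)
        obs = pd.DataFrame({"stratum": "pan", "p": rng.random(500)})
        scores = pd.DataFrame(rng.normal(size=(100, 2)))
        ct = pd.Series(["A"] * 100, index=scores.index)

        def run_fn(shuffled):
            return pd.DataFrame({"stratum": "pan",
                                 "p": rng.random(5000)})

        cal, hits = assoc.empirical_fdr(obs, run_fn, scores, ct,
                                        n_shuffles=1, seed=0)
        t1 = cal.thresholds.loc["pan", "t_0.01"]
        se = np.sqrt(0.01 * 0.99 / 5000)
        assert abs(t1 - 0.01) < 4 * se
        assert cal.thresholds.loc["pan", "t_0.01"] \
            <= cal.thresholds.loc["pan", "t_0.02"]

    def test_observed_equal_to_randomized_hits_one_percent(self):
        rng = np.random.default_rng(13)
        ps = rng.random(10_000)
        obs = pd.DataFrame({"stratum": "pan", "p": ps})
        scores = pd.DataFrame(rng.normal(size=(10, 2)))
        ct = pd.Series(["A"] * 10, index=scores.index)
        cal, hits = assoc.empirical_fdr(
            obs, lambda s: pd.DataFrame({"stratum": "pan", "p": ps}),
            scores, ct, n_shuffles=1, seed=0)
        frac = hits["hit_0.01"].mean()
        assert frac == pytest.approx(0.01, abs=2e-3)

    def test_shuffle_preserves_component_correlation(self):
        rng = np.random.default_rng(14)
        z = rng.normal(size=(400, 1))
        scores = pd.DataFrame(np.hstack([z, z + 0.1 * rng.normal(
            size=(400, 1))]), columns=["c1", "c2"])
        ct = pd.Series(rng.choice(["A", "B"], 400), index=scores.index)
        sh = assoc.shuffle_scores_within_strata(scores, ct, rng)
        r_orig = np.corrcoef(scores["c1"], scores["c2"])[0, 1]
        r_shuf = np.corrcoef(sh["c1"], sh["c2"])[0, 1]
        assert r_shuf == pytest.approx(r_orig, abs=1e-9)
        # but the sample-component link is broken
        assert abs(np.corrcoef(scores["c1"], sh["c1"])[0, 1]) < 0.2
        # and rows stay within their cancer type
        for t in ["A", "B"]:
            idx = ct[ct == t].index
            orig_rows = {tuple(r) for r in scores.loc[idx].to_numpy()}
            shuf_rows = {tuple(r) for r in sh.loc[idx].to_numpy()}
            assert orig_rows == shuf_rows


class TestRandomGenesetFdr:
    def test_worked_example(self):
        assert assoc.random_geneset_fdr(207, 44) == pytest.approx(21.0,
                                                                  abs=0.5)

    def test_zero_random_hits(self):
        assert assoc.random_geneset_fdr(207, 0) == 0.0

    def test_equal_counts(self):
        assert assoc.random_geneset_fdr(50, 50) == 100.0

    def test_no_candidate_hits_nan(self):
        assert np.isnan(assoc.random_geneset_fdr(0, 5))


class TestReplication:
    def _thr(self):
        return pd.DataFrame({"t_0.01": [0.001], "t_0.02": [0.005]},
                            index=pd.Index(["pan"], name="stratum"))

    def _hit(self, **kw):
        base = dict(gene="G1", stratum="pan", component="c1",
                    model="dominant", variant_set="III", p=1e-5,
                    direction=1)
        base.update(kw)
        return pd.DataFrame([base])

    def _val(self, p=1e-4, direction=1, n_carriers=5):
        return pd.DataFrame([dict(gene="G1", stratum="pan", component="c1",
                                  model="dominant", variant_set="III",
                                  p=p, direction=direction,
                                  n_carriers=n_carriers)])

    def test_significant_same_sign_replicates(self):
        out = assoc.replicate(self._hit(), self._val(), self._thr())
        assert out["status"].iloc[0] == "replicated"

    def test_opposite_sign_fails(self):
        out = assoc.replicate(self._hit(), self._val(direction=-1),
                              self._thr())
        assert out["status"].iloc[0] == "not_replicated"

    def test_single_carrier_not_testable(self):
        out = assoc.replicate(self._hit(), self._val(n_carriers=1),
                              self._thr())
        assert out["status"].iloc[0] == "not_testable"

    def test_unmapped_stratum(self):
        out = assoc.replicate(self._hit(stratum="X"), self._val(),
                              self._thr(), stratum_map={"pan": "pan"})
        assert out["status"].iloc[0] == "unmappable"


class TestTve:
    def test_single_variant_explaining_everything(self):
        n = 100
        g = np.zeros(n)
        g[:50] = 1
        y = 2.0 * g
        r2 = assoc.estimate_tve(y, np.ones((n, 1)), g)
        assert r2 == pytest.approx(1.0)

    def test_null_r2_near_k_over_n(self):
        rng = np.random.default_rng(15)
        n, k = 2000, 20
        V = rng.binomial(1, 0.05, (n, k)).astype(float)
        y = rng.normal(size=n)
        r2 = assoc.estimate_tve(y, np.ones((n, 1)), V)
        assert abs(r2 - k / n) < 3 * np.sqrt(2 * k) / n

    def test_planted_tve_two_percent(self):
        vals = []
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            n = 2000
            V = rng.binomial(1, 0.01, (n, 5)).astype(float)
            beta = np.sqrt(0.02 / max((V.sum(0) > 0).sum(), 1))
            y = V @ np.full(5, 1.4) + rng.normal(size=n) * np.sqrt(0.98)
            y = V @ np.full(5, np.sqrt(0.02 / (0.01 * 5))) \
                + rng.normal(size=n)
            r2 = assoc.estimate_tve(y, np.ones((n, 1)), V)
            vals.append(r2)
        assert all(0.01 <= v <= 0.04 for v in vals)

    def test_more_variants_than_samples_raises(self):
        with pytest.raises(ValueError):
            assoc.estimate_tve(np.ones(5), np.ones((5, 1)), np.ones((5, 6)))


class TestSubsampling:
    def test_fraction_one_equals_full_run(self):
        hits = pd.DataFrame([dict(gene="G1", stratum="pan", component="c1",
                                  model="dominant", variant_set="III",
                                  p=1e-5, direction=1)])
        val = pd.DataFrame([dict(gene="G1", stratum="pan", component="c1",
                                 model="dominant", variant_set="III",
                                 p=1e-4, direction=1, n_carriers=5)])
        thr = pd.DataFrame({"t_0.01": [0.001], "t_0.02": [0.005]},
                           index=pd.Index(["pan"], name="stratum"))

        calls = []

        def run_val(samples):
            calls.append(tuple(samples))
            return val, thr

        out = assoc.subsample_validation(
            run_val, hits, [f"S{i}" for i in range(100)],
            fractions=(1.0,), reps=2, seed=0)
        assert (out["n_replicated"] == 1).all()
        assert calls[0] == tuple(f"S{i}" for i in range(100))

    def test_fixed_seed_identical_subsets(self):
        seen = []

        def run_val(samples):
            seen.append(tuple(samples))
            return (pd.DataFrame(columns=["gene", "stratum", "component",
                                          "model", "variant_set", "p",
                                          "direction", "n_carriers"]),
                    pd.DataFrame({"t_0.01": [], "t_0.02": []}))

        hits = pd.DataFrame(columns=["gene", "stratum", "component",
                                     "model", "variant_set", "p",
                                     "direction"])
        samples = [f"S{i}" for i in range(50)]
        assoc.subsample_validation(run_val, hits, samples,
                                   fractions=(0.8,), reps=1, seed=3)
        first = list(seen)
        seen.clear()
        assoc.subsample_validation(run_val, hits, samples,
                                   fractions=(0.8,), reps=1, seed=3)
        assert seen == first
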