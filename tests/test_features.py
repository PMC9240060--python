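"""Somatic feature extraction: counting rules, minimum-count missingness,
signature fitting and regression recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import nnls

from somarvas import features, syndata
from somarvas.registry import (ALL_FEATURES, EXCLUDED_FEATURES,
                               RETAINED_FEATURES)


def _snv(sub6, cpg=False, n=1, **kw):
    base = dict(sample="S", chrom="chr1", pos=100, ref=sub6[0], alt=sub6[2],
                **{"class": "SNV"}, sub6=sub6, cpg=cpg, channel96=0,
                tx="none", fork_decile=5, ref_sub=sub6, pyr_on_ref=True)
    base.update(kw)
    return pd.DataFrame({k: [v] * n for k, v in base.items()})


def test_registry_counts():
    assert len(ALL_FEATURES) == 65
    assert len(EXCLUDED_FEATURES) == 9
    assert len(RETAINED_FEATURES) == 56


class TestBasicCounts:
    def test_zero_events_all_zero(self):
        ev = _snv("C>A", n=0)
        out = features.count_basic_features(ev, mito=None,
                                            mito_coverage_ok=False)
        for s7 in ["C>A", "C>G", "T>A"]:
            assert out[f"count_{s7}"] == 0.0
        assert out["snv_total"] == 0.0
        assert np.isnan(out["mito_snv"])

    def test_seven_events_log2_eight(self):
        out = features.count_basic_features(_snv("C>A", n=7))
        assert out["count_C>A"] == pytest.approx(3.0)

    def test_cpg_split(self):
        ev = pd.concat([_snv("C>T", cpg=True, n=3),
                        _snv("C>T", cpg=False, n=1)])
        out = features.count_basic_features(ev)
        assert out["count_C>T_CpG"] == pytest.approx(2.0)
        assert out["count_C>T_nonCpG"] == pytest.approx(1.0)

    def test_mito_low_vaf_excluded(self):
        mito = pd.DataFrame({"sample": ["S"] * 2, "chrom": "chrM",
                             "pos": [5, 6], "vaf": [0.02, 0.5]})
        out = features.count_basic_features(_snv("C>A", n=0), mito=mito)
        assert out["mito_snv"] == pytest.approx(1.0)  # log2(1+1)

    def test_unknown_class_raises(self):
        ev = _snv("C>A")
        ev.loc[0, "sub6"] = "A>X"
        with pytest.raises(ValueError, match="A>X"):
            features.count_basic_features(ev)


class TestSignatureFitting:
    def test_exact_single_signature(self, catalogs):
        cat = catalogs["SBS"]
        counts = 100 * cat.iloc[:, 3].to_numpy()
        expo = features.fit_signatures(counts, cat, n_bootstrap=0)
        assert expo.iloc[3] == pytest.approx(100, rel=1e-6)
        assert np.all(expo.drop(expo.index[3]).to_numpy() < 1e-6)

    def test_zero_counts_zero_exposures(self, catalogs):
        expo = features.fit_signatures(np.zeros(96), catalogs["SBS"],
                                       n_bootstrap=50)
        assert (expo == 0).all()

    def test_channel_mismatch_raises(self, catalogs):
        with pytest.raises(ValueError, match="channel mismatch"):
            features.fit_signatures(np.zeros(78), catalogs["SBS"])

    def test_equal_mixture_recovered_vs_grid_oracle(self):
        # two signatures with orthogonal support; oracle = exhaustive grid
        rng = np.random.default_rng(0)
        A = np.zeros((20, 2))
        A[:10, 0] = rng.dirichlet(np.ones(10))
        A[10:, 1] = rng.dirichlet(np.ones(10))
        cat = pd.DataFrame(A, columns=["s1", "s2"])
        truth = 5000 * A[:, 0] + 5000 * A[:, 1]
        counts = rng.poisson(truth)
        expo = features.fit_signatures(counts, cat, n_bootstrap=50,
                                       rng=rng)
        total = counts.sum()
        # grid-search oracle over the mixing fraction
        fracs = np.linspace(0, 1, 201)
        errs = [np.sum((counts - total * (f * A[:, 0] + (1 - f) * A[:, 1]))
                       ** 2) for f in fracs]
        f_star = fracs[int(np.argmin(errs))]
        assert abs(expo["s1"] / total - f_star) < 0.05
        assert abs(expo["s1"] - 0.5 * total) < 0.05 * total
        assert abs(expo["s2"] - 0.5 * total) < 0.05 * total
        # and NNLS direct oracle agrees
        direct, _ = nnls(A, counts.astype(float))
        assert expo.to_numpy() == pytest.approx(direct, rel=0.05)


class TestStrandRatios:
    def test_symmetric_counts_zero(self):
        ev = pd.concat([_snv("T>C", tx="U", n=5), _snv("T>C", tx="T", n=5)])
        out = features.strand_ratios(ev)
        assert out["txbias_T>C"] == 0.0

    def test_replicative_below_minimum_missing(self):
        ev = _snv("T>C", n=19, fork_decile=10)
        out = features.strand_ratios(ev)
        assert np.isnan(out["repbias"])

    def test_replicative_planted_factor_two(self, tracks, catalogs):
        spec = syndata.SyntheticCohortSpec(n_samples=1, seed=7)
        cat = syndata.generate_event_catalog(
            spec, tracks, catalogs, n_snv_per_sample=10_000,
            rep_strand_bias=2.0, rng=np.random.default_rng(7))
        out = features.strand_ratios(cat["events"])
        assert out["repbias"] == pytest.approx(1.0, abs=0.15)

    def test_counting_oracle_on_annotated_events(self):
        # 30 focal events leading, 10 lagging, by direct construction
        lead = _snv("T>C", n=30, fork_decile=10)  # ref leading, ref focal
        lag = _snv("C>T", n=10, fork_decile=10, ref_sub="C>T",
                   pyr_on_ref=True)  # comp G>A focal -> opposite strand
        out = features.strand_ratios(pd.concat([lead, lag]))
        assert out["repbias"] == pytest.approx(np.log2(31 / 11))


class TestRegionRatios:
    @staticmethod
    def _events_at_rate(tracks, per_mb):
        rows = []
        for c, l in tracks.chrom_lengths.items():
            if c == "chrM":
                continue
            rate = per_mb(c)
            n = int(round(l / 1e6 * rate))
            for i in range(n):
                rows.append(dict(sample="S", chrom=c, pos=1000 + i,
                                 **{"class": "SNV"}, sub6="C>A"))
        return pd.DataFrame(rows)

    def test_symmetry_zero(self, tracks):
        ev = self._events_at_rate(tracks, lambda c: 100)
        out = features.region_ratio_features(ev, tracks)
        assert out["x_hypermut"] == pytest.approx(0.0, abs=0.02)

    def test_formula_two_vs_one_per_mb(self):
        # 2 per Mb on X, 1 per Mb on autosomes -> log2(2.1/1.1) ~ 0.933
        big = syndata.generate_genome_tracks(1, genome_length=50_000_000)
        ev = self._events_at_rate(big, lambda c: 2 if c == "chrX" else 1)
        out = features.region_ratio_features(ev, big)
        assert out["x_hypermut"] == pytest.approx(np.log2(2.1 / 1.1),
                                                  abs=1e-9)

    def test_ctcf_below_minimum_missing(self, tracks):
        core = tracks.ctcf[tracks.ctcf["kind"] == "core"].iloc[0]
        ev = pd.DataFrame([dict(sample="S", chrom=core["chrom"],
                                pos=core["start"] + 1, **{"class": "SNV"},
                                sub6="C>A")] * 9)
        out = features.region_ratio_features(ev, tracks)
        assert np.isnan(out["ctcf_ratio"])

    def test_ctcf_ratio_counts(self, tracks):
        core = tracks.ctcf[tracks.ctcf["kind"] == "core"].iloc[0]
        flank = tracks.ctcf[(tracks.ctcf["kind"] == "flank")
                            & (tracks.ctcf["chrom"] == core["chrom"])
                            & (tracks.ctcf["end"] == core["start"])].iloc[0]
        ev = pd.DataFrame(
            [dict(sample="S", chrom=core["chrom"], pos=core["start"] + 1,
                  **{"class": "SNV"}, sub6="C>A")] * 7
            + [dict(sample="S", chrom=flank["chrom"], pos=flank["start"] + 1,
                    **{"class": "SNV"}, sub6="C>A")] * 3)
        out = features.region_ratio_features(ev, tracks)
        assert out["ctcf_ratio"] == pytest.approx(np.log2(8 / 4))


class TestRegionalEnrichment:
    def test_below_30_snvs_missing(self, tracks):
        ev = _snv("C>A", n=29, chrom="chr1", pos=100)
        out = features.regional_enrichment(ev, tracks)
        assert out.isna().all()

    def test_planted_rate_recovered_poisson_oracle(self, tracks, catalogs):
        spec = syndata.SyntheticCohortSpec(n_samples=1, seed=7)
        cat = syndata.generate_event_catalog(
            spec, tracks, catalogs, n_snv_per_sample=50_000,
            rt_rate_multipliers=[1, 1, 1, 1, 1, 2],
            rng=np.random.default_rng(7))
        ev = cat["events"]
        out = features.regional_enrichment(ev, tracks,
                                           channel_mode="7-class")
        assert out["enr_rt"] == pytest.approx(np.log(2), abs=0.05)
        # Poisson closed form on aggregate counts as the oracle
        win = tracks.windows
        widx = tracks.window_index(ev["chrom"].to_numpy(),
                                   ev["pos"].to_numpy())
        rt = win["rt_bin"].to_numpy()[widx[widx >= 0]]
        n6 = (rt == 6).sum() / (win["rt_bin"] == 6).sum()
        n1 = (rt == 1).sum() / (win["rt_bin"] == 1).sum()
        oracle = np.log(n6 / n1)
        assert out["enr_rt"] == pytest.approx(oracle, abs=0.02)

    def test_merged_bins_mode_runs(self, tracks, event_catalog):
        ev = event_catalog["events"]
        s = ev[ev["sample"] == ev["sample"].iloc[0]]
        out = features.regional_enrichment(s, tracks, merged_bins=True)
        assert set(out.index) == {"enr_rt", "enr_dnase", "enr_expr",
                                  "enr_h3k36me3"}


class TestIndelCna:
    def _indels(self, rows):
        return pd.DataFrame(rows, columns=["class", "length", "mh_len",
                                           "in_ms"])

    def _cna(self, rows):
        return pd.DataFrame(rows, columns=["type", "size_kb"])

    def test_wgd_integer_division(self):
        out = features.indel_cna_features(
            self._indels([]), self._cna([]), ploidy=3.8)
        assert out["wgd"] == pytest.approx(np.log2(1.1))
        assert out["ploidy"] == pytest.approx(np.log2(3.8))

    def test_diploid_ploidy_feature_is_one(self):
        out = features.indel_cna_features(
            self._indels([]), self._cna([]), ploidy=2.0)
        assert out["ploidy"] == 1.0

    def test_ms_deletions_counted(self):
        ind = self._indels([("DEL", 4, 0, True)] * 3)
        out = features.indel_cna_features(ind, self._cna([]), 2.0)
        assert out["indel_2_5bp_ms"] == pytest.approx(2.0)

    def test_microhomology_split(self):
        ind = self._indels([("DEL", 12, 1, False), ("DEL", 15, 3, False),
                            ("INS", 2, 0, False)])
        out = features.indel_cna_features(ind, self._cna([]), 2.0)
        assert out["del_mh_1bp"] == pytest.approx(1.0)
        assert out["del_mh_gt1bp"] == pytest.approx(1.0)
        assert out["del_ge10bp"] == pytest.approx(np.log2(3))

    def test_cna_size_bins(self):
        cna = self._cna([("amp", 5), ("amp", 50), ("amp", 500),
                         ("amp", 5000), ("del", 5), ("del", 50),
                         ("del", 500)])
        out = features.indel_cna_features(self._indels([]), cna, 2.0)
        for f in ["amp_1_10kb", "amp_10_100kb", "amp_100_1000kb",
                  "amp_gt1000kb", "del_1_10kb", "del_10_100kb",
                  "del_gt100kb"]:
            assert out[f] == pytest.approx(1.0)

    def test_nonpositive_ploidy_raises(self):
        with pytest.raises(ValueError):
            features.indel_cna_features(self._indels([]), self._cna([]), 0.0)


def test_extract_features_full_matrix(tracks, catalogs, event_catalog):
    feat = features.extract_features(event_catalog, tracks, catalogs,
                                     mode="wgs", n_bootstrap=5, seed=0)
    assert list(feat.columns) == ALL_FEATURES
    assert len(feat) == 6
    # minimum-count rules produce missing, never zero, where violated:
    # every present value of a count feature is a finite float
    assert feat["snv_total"].notna().all()
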