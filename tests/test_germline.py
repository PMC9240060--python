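"""Variant quality/rarity filters, pLoF set construction and cohort QC."""

import numpy as np
import pandas as pd
import pytest

from somarvas import germline, syndata


def _variant(**kw):
    base = dict(sample="S0", gene="G1", chrom="chr1", pos=100, ref="C",
                alt="T", filter="PASS", gqx=60.0, in_gnomad=False,
                gnomad_af=np.nan, gnomad_af_sub1=np.nan,
                gnomad_af_sub2=np.nan, consequence="missense", cadd=20.0,
                mtr_pct=50.0, ccr_pct=50.0, spliceai_dl=0.0,
                spliceai_al=0.0, exon_idx=1, terminal_exon=False,
                pext_mean=0.9, vaf_tumor=0.5, vaf_normal=0.5,
                present_in_tumor=True)
    base.update(kw)
    return base


def _vdf(rows):
    return pd.DataFrame([_variant(**r) for r in rows])


class TestQualityRarityFilter:
    def test_gqx_threshold_for_gnomad_absent(self):
        v = _vdf([dict(gqx=19.0, pos=1), dict(gqx=20.0, pos=2)])
        out = germline.quality_and_rarity_filter(v, cohort_size=1000)
        assert list(out["pos"]) == [2]

    def test_gnomad_present_needs_gqx_10(self):
        v = _vdf([dict(in_gnomad=True, gnomad_af=1e-4, gnomad_af_sub1=1e-4,
                       gnomad_af_sub2=1e-4, gqx=9.0, pos=1),
                  dict(in_gnomad=True, gnomad_af=1e-4, gnomad_af_sub1=1e-4,
                       gnomad_af_sub2=1e-4, gqx=10.0, pos=2)])
        out = germline.quality_and_rarity_filter(v, cohort_size=1000)
        assert list(out["pos"]) == [2]

    def test_subpopulation_af_fails_overall_pass(self):
        v = _vdf([dict(in_gnomad=True, gnomad_af=5e-4, gnomad_af_sub1=2e-3,
                       gnomad_af_sub2=1e-4, pos=1),
                  dict(in_gnomad=True, gnomad_af=5e-4, gnomad_af_sub1=5e-4,
                       gnomad_af_sub2=5e-4, pos=2)])
        out = germline.quality_and_rarity_filter(v, cohort_size=1000)
        assert list(out["pos"]) == [2]

    def test_cohort_frequency_one_percent(self):
        rows = [dict(sample=f"S{i}", pos=7) for i in range(10)]
        rows += [dict(sample="S0", pos=8)]
        out = germline.quality_and_rarity_filter(_vdf(rows),
                                                 cohort_size=1000)
        assert (out["pos"] == 7).sum() == 0
        assert (out["pos"] == 8).sum() == 1

    def test_lowgqx_kept_with_gqx_10(self):
        gn = dict(in_gnomad=True, gnomad_af=1e-4, gnomad_af_sub1=1e-4,
                  gnomad_af_sub2=1e-4)
        v = _vdf([dict(filter="LowGQX", gqx=10.0, pos=1, **gn),
                  dict(filter="LowGQX", gqx=9.0, pos=2, **gn),
                  dict(filter="FAIL", gqx=99.0, pos=3, **gn)])
        out = germline.quality_and_rarity_filter(v, cohort_size=1000)
        assert list(out["pos"]) == [1]

    def test_absent_from_tumor_dropped(self):
        v = _vdf([dict(present_in_tumor=False, pos=1),
                  dict(present_in_tumor=True, pos=2),
                  dict(present_in_tumor=None, pos=3)])
        out = germline.quality_and_rarity_filter(v, cohort_size=1000)
        assert sorted(out["pos"]) == [2, 3]


class TestVariantSets:
    def _sets(self, rows):
        v = germline.quality_and_rarity_filter(_vdf(rows), cohort_size=1000)
        return germline.classify_and_build_sets(v)

    def test_stopgain_internal_exon_in_sets_i_to_iii(self):
        sets = self._sets([dict(consequence="stopgain", cadd=10.0)])
        for sid in ["I", "II", "III"]:
            assert sets[sid].loc["G1", "S0"] == 1
        for sid in ["IV", "V"]:
            assert sets[sid].empty or sets[sid].get("S0") is None

    def test_missense_cadd_threshold_set_iii(self):
        sets = self._sets([dict(consequence="missense", cadd=14.0, pos=1),
                           dict(consequence="missense", cadd=15.0, pos=2)])
        assert sets["III"].loc["G1", "S0"] == 1  # only the CADD 15 variant
        sets2 = self._sets([dict(consequence="missense", cadd=14.0)])
        assert sets2["III"].empty

    def test_missense_cadd25_set_ii(self):
        sets = self._sets([dict(consequence="missense", cadd=25.0)])
        assert sets["II"].loc["G1", "S0"] == 1
        assert sets["I"].empty

    def test_terminal_exon_exceptions(self):
        # stopgain in terminal exon, CADD 10, no splice effect -> excluded
        sets = self._sets([dict(consequence="stopgain", cadd=10.0,
                                terminal_exon=True)])
        assert sets["I"].empty
        # CADD 16 -> retained
        sets = self._sets([dict(consequence="stopgain", cadd=16.0,
                                terminal_exon=True)])
        assert sets["I"].loc["G1", "S0"] == 1
        # splice effect -> retained
        sets = self._sets([dict(consequence="stopgain", cadd=5.0,
                                terminal_exon=True, spliceai_dl=0.9)])
        assert sets["I"].loc["G1", "S0"] == 1

    def test_pext_filter_skips_splicing(self):
        sets = self._sets([dict(consequence="stopgain", pext_mean=0.05,
                                pos=1),
                           dict(consequence="splicing", pext_mean=0.05,
                                pos=2)])
        assert sets["I"].loc["G1", "S0"] == 1  # only the splicing variant

    def test_spliceai_makes_ptv(self):
        sets = self._sets([dict(consequence="missense", cadd=5.0,
                                spliceai_al=0.85)])
        assert sets["I"].loc["G1", "S0"] == 1

    def test_mtr_ccr_sets(self):
        sets = self._sets([dict(consequence="missense", mtr_pct=20.0,
                                ccr_pct=95.0, cadd=5.0)])
        assert sets["IV"].loc["G1", "S0"] == 1
        assert sets["V"].loc["G1", "S0"] == 1
        assert sets["I"].empty

    def test_set_nesting_on_synthetic_cohort(self, small_cohort):
        spec, germ = small_cohort
        cov = germ["covariates"].set_index("sample")
        filt = germline.quality_and_rarity_filter(
            germ["variants"], cohort_size=spec.n_samples)
        sets = germline.classify_and_build_sets(
            filt, tissue_map=germ["tissue_map"],
            cancer_type_of_sample=cov["cancer_type"])
        genes = germ["gene_universe"]
        samples = list(cov.index)
        mats = {k: germline.carrier_matrix_full(v, genes, samples)
                for k, v in sets.items()}
        assert (mats["I"].to_numpy() <= mats["II"].to_numpy()).all()
        assert (mats["II"].to_numpy() <= mats["III"].to_numpy()).all()

    def test_filter_order_stability(self, small_cohort):
        spec, germ = small_cohort
        cov = germ["covariates"].set_index("sample")
        v = germ["variants"]
        a = germline.classify_and_build_sets(
            germline.quality_and_rarity_filter(v, spec.n_samples),
            tissue_map=germ["tissue_map"],
            cancer_type_of_sample=cov["cancer_type"])
        # quality filter applied after set rules gives identical carriers
        b_all = germline.classify_and_build_sets(
            v, tissue_map=germ["tissue_map"],
            cancer_type_of_sample=cov["cancer_type"])
        for sid in a:
            sel = germline.quality_and_rarity_filter(v, spec.n_samples)
            again = germline.classify_and_build_sets(
                sel, tissue_map=germ["tissue_map"],
                cancer_type_of_sample=cov["cancer_type"])[sid]
            pd.testing.assert_frame_equal(a[sid], again)


class TestCohortQC:
    def test_duplicate_pair_detected_and_removed(self, small_cohort):
        _, germ = small_cohort
        qc = germline.cohort_qc(
            germ["common_genotypes"],
            anchor_labels=(germ["covariates"].set_index("sample")
                           ["ancestry_cluster"] == 0), seed=0)
        assert qc.details["pihat_max_observed"] > 0.9
        excluded = set(qc.excluded["sample"])
        for a, b in germ["duplicate_pairs"] + germ["related_pairs"]:
            assert (a in excluded) or (b in excluded)
        assert qc.pcs.shape[1] == 6

    def test_null_cohort_minimal_removals(self):
        spec = syndata.SyntheticCohortSpec(n_samples=150, seed=21)
        germ = syndata.generate_germline_cohort(
            spec, n_duplicate_pairs=0, n_related_pairs=0,
            rng=np.random.default_rng(21))
        qc = germline.cohort_qc(germ["common_genotypes"], seed=0)
        reasons = qc.excluded["reason"].value_counts()
        assert reasons.get("related", 0) == 0
        assert reasons.get("heterozygosity_outlier", 0) <= 2
        # the +/-1.5 SD count rule trims ~13% of a clean Gaussian cohort
        assert reasons.get("variant_count_outlier", 0) <= 0.16 * 150

    def test_hwe_exact_case(self):
        G = np.concatenate([np.zeros((500, 1)), 2 * np.ones((500, 1))],
                           axis=0).astype(int)
        p = germline.hwe_pvalues(G)
        assert p[0] < 1e-6

    def test_ld_prune_removes_duplicate_column(self):
        rng = np.random.default_rng(0)
        x = rng.binomial(2, 0.3, (100, 1))
        G = np.hstack([x, x, rng.binomial(2, 0.4, (100, 8))])
        keep = germline.ld_prune(G)
        assert 0 in keep and 1 not in keep

    def test_too_few_pruned_variants_raises(self):
        rng = np.random.default_rng(1)
        G = pd.DataFrame(rng.binomial(2, 0.3, (50, 30)),
                         index=[f"S{i}" for i in range(50)])
        with pytest.raises(ValueError, match="IBD unreliable"):
            germline.cohort_qc(G, seed=0)

    def test_unknown_consequence_rejected(self):
        v = _vdf([dict(consequence="weird")])
        with pytest.raises(ValueError, match="consequence"):
            germline.quality_and_rarity_filter(v, cohort_size=10)
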