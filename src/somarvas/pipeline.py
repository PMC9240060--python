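"""End-to-end pipeline orchestration on synthetic two-cohort studies.

Runs simulate -> features -> components -> germline/QC -> encoding ->
association (discovery and validation) -> empirical FDR -> replication ->
network -> prevalence, writing each stage's outputs under the run
directory.  Stages are stamped with a hash of the configuration; rerunning
with an unchanged configuration skips completed stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc, components, germline, inheritance, network, prevalence
from . import features as somfeat
from . import syndata

log = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "seed": 0,
    "n_samples_discovery": 600,
    "n_samples_validation": 600,
    "n_genes": 120,
    "n_causal_genes": 8,
    "carrier_freq": 0.03,
    "effect_shift": 1.2,
    "loh_rate": 0.5,
    "n_latent_processes": 3,
    "noise_sd": 0.5,
    "fdr_levels": [0.01, 0.02],
    "n_shuffles": 1,
    "ica_runs": 30,
    "method": "analytic",
    "feature_mode": "wgs",
    "n_feature_samples": 12,  # event-level feature extraction subset
    "network_enrichment": 6.0,
    "variant_set": "III",
    "inheritance_models": ["dominant", "additive", "recessive"],
}


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


def _stage_done(stage_dir: Path, h: str) -> bool:
    stamp = stage_dir / "stamp.json"
    if not stamp.exists():
        return False
    try:
        return json.loads(stamp.read_text()).get("config_hash") == h
    except json.JSONDecodeError:
        return False


def _stamp(stage_dir: Path, h: str) -> None:
    stage_dir.mkdir(parents=True, exist_ok=True)
    (stage_dir / "stamp.json").write_text(json.dumps({"config_hash": h}))


def _make_cohort(cfg: dict, seed: int, n_samples: int,
                 mixing: np.ndarray | None = None):
    spec = syndata.SyntheticCohortSpec(
        n_samples=n_samples,
        mixing_loadings=mixing,
        n_latent_processes=cfg["n_latent_processes"],
        noise_sd=cfg["noise_sd"],
        n_genes=cfg["n_genes"],
        n_causal_genes=cfg["n_causal_genes"],
        carrier_freq=cfg["carrier_freq"],
        effect_sizes={
            f"GENE{i:04d}": (i % cfg["n_latent_processes"],
                             cfg["effect_shift"])
            for i in range(cfg["n_causal_genes"])},
        loh_rate=cfg["loh_rate"],
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    germ = syndata.generate_germline_cohort(spec, rng=rng)
    return spec, germ


def run_pipeline(cfg: dict | None = None, out_dir: str | Path = "run",
                 force: bool = False) -> dict:
    """Execute the full synthetic study; returns the summary report."""
    config = dict(DEFAULT_CONFIG)
    if cfg:
        config.update(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = config_hash(config)
    (out / "config.json").write_text(json.dumps(config, indent=2))
    seed = config["seed"]
    rng = np.random.default_rng(seed)

    # ---- simulate ---------------------------------------------------------
    # both cohorts share the process->feature mixing (the same biology
    # observed in two patient sets); samples and noise differ
    sim_dir = out / "simulate"
    k = config["n_latent_processes"]
    W = np.random.default_rng(seed + 3).normal(size=(k, 56))
    W *= np.random.default_rng(seed + 4).random((k, 56)) < 0.4
    spec_d, germ_d = _make_cohort(config, seed,
                                  config["n_samples_discovery"], mixing=W)
    spec_v, germ_v = _make_cohort(config, seed + 1,
                                  config["n_samples_validation"], mixing=W)
    # distinct sample ids per cohort
    for germ, tag in ((germ_d, "D"), (germ_v, "V")):
        ren = {s: f"{tag}{s}" for s in germ["truth"].sample_ids}
        germ["variants"]["sample"] = germ["variants"]["sample"].map(ren)
        germ["covariates"]["sample"] = germ["covariates"]["sample"].map(ren)
        germ["common_genotypes"].index = [
            ren[s] for s in germ["common_genotypes"].index]
        germ["truth"].sample_ids = [ren[s] for s in germ["truth"].sample_ids]
        germ["truth"].carrier_samples = {
            g: [ren[s] for s in ss]
            for g, ss in germ["truth"].carrier_samples.items()}
        germ["truth"].loh_samples = {
            g: [ren[s] for s in ss]
            for g, ss in germ["truth"].loh_samples.items()}
    net_edges = syndata.generate_network(
        spec_d, germ_d["truth"],
        enrichment_factor=config["network_enrichment"], rng=rng)
    if force or not _stage_done(sim_dir, h):
        sim_dir.mkdir(parents=True, exist_ok=True)
        net_edges.to_csv(sim_dir / "network_edges.tsv", sep="\t",
                         index=False)
        germ_d["truth"].to_json(sim_dir / "truth_discovery.json")
        _stamp(sim_dir, h)

    # ---- event-level feature extraction (demonstration subset) -----------
    feat_dir = out / "features"
    if force or not _stage_done(feat_dir, h):
        tracks = syndata.generate_genome_tracks(seed, genome_length=3_000_000)
        catalogs = syndata.synthetic_catalogs(seed)
        small = syndata.SyntheticCohortSpec(
            n_samples=config["n_feature_samples"], seed=seed)
        catalog = syndata.generate_event_catalog(small, tracks, catalogs,
                                                 n_snv_per_sample=800)
        feat = somfeat.extract_features(catalog, tracks, catalogs,
                                        mode=config["feature_mode"],
                                        n_bootstrap=10, seed=seed)
        feat_dir.mkdir(parents=True, exist_ok=True)
        feat.to_csv(feat_dir / "features.tsv", sep="\t")
        _stamp(feat_dir, h)

    # ---- components: ICA on the merged standardized matrix ----------------
    feat_d = syndata.mix_features(germ_d["truth"], config["noise_sd"], rng)
    feat_v = syndata.mix_features(germ_v["truth"], config["noise_sd"], rng)
    X, cohorts = components.assemble_input(
        {"discovery": feat_d.reindex(columns=somfeat.ALL_FEATURES),
         "validation": feat_v.reindex(columns=somfeat.ALL_FEATURES)})
    k = config["n_latent_processes"]
    ica_res, ica_model = components.run_ica_stability(
        X, n_comp_grid=[k], n_runs=config["ica_runs"],
        k_grid=range(2 * k, 2 * k + 1), n_components=k, seed=seed)
    comp_dir = out / "components"
    if force or not _stage_done(comp_dir, h):
        comp_dir.mkdir(parents=True, exist_ok=True)
        ica_model.scores.to_csv(comp_dir / "components_ica.tsv", sep="\t")
        ica_model.loadings.to_csv(comp_dir / "loadings.tsv", sep="\t")
        ica_model.contributions.to_csv(comp_dir / "contributions.tsv",
                                       sep="\t")
        _stamp(comp_dir, h)

    # ---- germline filtering, carrier sets, QC, encoding -------------------
    results = {}
    thresholds = {}
    lam_tables = {}
    genes = germ_d["gene_universe"]
    for tag, germ, spec in (("discovery", germ_d, spec_d),
                            ("validation", germ_v, spec_v)):
        cov = germ["covariates"].set_index("sample")
        ct = cov["cancer_type"]
        filt = germline.quality_and_rarity_filter(
            germ["variants"], cohort_size=spec.n_samples)
        sets = germline.classify_and_build_sets(
            filt, tissue_map=germ["tissue_map"], cancer_type_of_sample=ct,
            gene_universe=genes)
        carriers = germline.carrier_matrix_full(
            sets[config["variant_set"]], genes, list(cov.index))
        loh = inheritance.assign_loh(filt, mode="vaf_fallback")
        qc = germline.cohort_qc(germ["common_genotypes"],
                                anchor_labels=(cov["ancestry_cluster"] == 0),
                                seed=seed)
        kept = qc.pcs.index
        scores = ica_model.scores.loc[
            ica_model.scores.index.intersection(
                [s for s in cov.index if s in kept])]

        cohort_results = []
        for model in config["inheritance_models"]:
            enc = inheritance.encode(carriers, loh, model)
            res = assoc.association_scan(
                scores, enc[scores.index.intersection(enc.columns)],
                cov.loc[scores.index], pcs=qc.pcs,
                strata=["pan"], model=model,
                variant_set=config["variant_set"],
                method=config["method"], seed=seed)
            cohort_results.append(res)
        res = pd.concat(cohort_results, ignore_index=True)
        lam_tables[tag] = assoc.scenario_qc(res)

        def run_fn(shuffled, _scores=scores, _cov=cov, _qc=qc,
                   _carriers=carriers, _loh=loh):
            frames = []
            for model in config["inheritance_models"]:
                enc = inheritance.encode(_carriers, _loh, model)
                frames.append(assoc.association_scan(
                    shuffled, enc[shuffled.index.intersection(enc.columns)],
                    _cov.loc[shuffled.index], pcs=_qc.pcs, strata=["pan"],
                    model=model, variant_set=config["variant_set"],
                    method=config["method"], seed=seed))
            return pd.concat(frames, ignore_index=True)

        cal, hits = assoc.empirical_fdr(
            res, run_fn, scores, ct.loc[scores.index],
            n_shuffles=config["n_shuffles"],
            levels=tuple(config["fdr_levels"]), seed=seed + 17)
        results[tag] = {"results": res, "hits": hits, "cal": cal,
                        "carriers": carriers, "filtered": filt,
                        "qc": qc}
        thresholds[tag] = cal.thresholds

    assoc_dir = out / "assoc"
    if force or not _stage_done(assoc_dir, h):
        assoc_dir.mkdir(parents=True, exist_ok=True)
        for tag in results:
            results[tag]["results"].to_csv(
                assoc_dir / f"results_{tag}.tsv", sep="\t", index=False)
            thresholds[tag].to_csv(assoc_dir / f"thresholds_{tag}.tsv",
                                   sep="\t")
        _stamp(assoc_dir, h)

    # ---- replication -------------------------------------------------------
    lv = config["fdr_levels"][0]
    disc_hits = results["discovery"]["hits"]
    disc_hits = disc_hits[disc_hits[f"hit_{lv:g}"]]
    rep = assoc.replicate(
        disc_hits, results["validation"]["results"],
        thresholds["validation"], levels=tuple(config["fdr_levels"]))
    replicated_genes = sorted(
        rep.loc[rep["status"] == "replicated", "gene"].unique()) \
        if len(rep) else []

    # ---- network ----------------------------------------------------------
    graph = network.InteractionGraph(net_edges, universe=genes)
    causal = list(germ_d["truth"].causal_map)
    hit_genes = replicated_genes if len(replicated_genes) >= 3 else causal
    net_res = network.internal_connectivity_test(
        hit_genes, genes, graph, n_bins=5, n_rand=500, seed=seed)

    # ---- prevalence --------------------------------------------------------
    lengths = pd.Series(
        np.random.default_rng(seed + 5).integers(2, 10, len(genes)),
        index=genes, dtype=float)
    carr_d = results["discovery"]["carriers"]
    prev = prevalence.carrier_frequency(causal, carr_d)
    ctrl = prevalence.length_matched_controls(causal, lengths, carr_d,
                                              seed=seed)

    report = {
        "config_hash": h,
        "seed": seed,
        "n_tested": {t: int(len(results[t]["results"])) for t in results},
        "n_hits_discovery": int(len(disc_hits)),
        "n_replicated": int((rep["status"] == "replicated").sum())
        if len(rep) else 0,
        "replicated_genes": replicated_genes,
        "causal_genes": causal,
        "lambda": {t: lam_tables[t]["lambda"].round(3).tolist()
                   for t in lam_tables},
        "network_p": net_res.p,
        "network_observed_edges": net_res.observed,
        "carrier_freq_causal": prev,
        "carrier_freq_controls_median":
            prevalence.summarize_control_draws(ctrl)["median"],
    }
    (out / "report.json").write_text(json.dumps(report, indent=2,
                                                sort_keys=True))
    return report
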