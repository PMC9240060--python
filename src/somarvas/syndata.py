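"""Synthetic cohort generation with planted ground truth.

Generates every input the analysis consumes — genome annotation tracks,
somatic event catalogs, germline cohorts with rare pLoF carriers, common
variant matrices for QC, and gene interaction networks — from a single
seeded random generator, together with the generative parameters, so that
each downstream stage can be tested against known truth.

The causal picture mirrors the study design: latent mutational processes
mix linearly into somatic features; rare deleterious germline variants in
causal genes shift the score of one latent process in carriers; somatic LOH
amplifies the carrier state; causal genes cluster in the interaction
network.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .registry import SUB6, REF_SIGS, DBS_SIGS, ID_SIGS, ALL_FEATURES

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
PYRIMIDINE_SUBS = SUB6
# reference-strand substitution types entering the replicative strand bias
REPLICATIVE_FOCAL = {"T>C", "T>G", "G>A", "C>A"}

SBS96_CHANNELS = [
    f"{l}[{sub}]{r}"
    for sub in SUB6
    for l in "ACGT"
    for r in "ACGT"
]
DBS78_CHANNELS = [f"DBS_ch{i:02d}" for i in range(78)]
ID83_CHANNELS = [f"ID_ch{i:02d}" for i in range(83)]


def complement_sub(sub: str) -> str:
    a, b = sub.split(">")
    return f"{COMPLEMENT[a]}>{COMPLEMENT[b]}"


# ---------------------------------------------------------------------------
# cohort specification and truth
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohortSpec:
    """Generative parameters of a synthetic cohort.

    ``carrier_freq`` is the per-gene carrier fraction; carriers are spread
    over ``n_variant_sites_per_gene`` distinct variant sites so each site
    stays below the 1% within-cohort frequency filter.
    """

    n_samples: int = 500
    cancer_type_props: dict = field(
        default_factory=lambda: {"A": 0.5, "B": 0.3, "C": 0.2}
    )
    n_latent_processes: int = 3
    mixing_loadings: np.ndarray | None = None  # processes x features (56)
    noise_sd: float = 0.5
    n_genes: int = 300
    n_causal_genes: int = 10
    carrier_freq: float = 0.02
    n_variant_sites_per_gene: int = 8
    effect_sizes: dict | None = None  # gene -> (component index, shift in SD)
    loh_rate: float = 0.5
    covariate_effects: dict = field(
        default_factory=lambda: {"age_per_decade": 0.1, "sex": 0.2}
    )
    seed: int = 0

    def validate(self) -> None:
        props = np.array(list(self.cancer_type_props.values()), dtype=float)
        if np.any(props < 0) or np.any(props > 1):
            raise ValueError("cancer_type_props must lie in [0, 1]")
        if not np.isclose(props.sum(), 1.0):
            raise ValueError("cancer_type_props must sum to 1")
        if not 0 <= self.carrier_freq <= 1:
            raise ValueError("carrier_freq must lie in [0, 1]")
        if not 0 <= self.loh_rate <= 1:
            raise ValueError("loh_rate must lie in [0, 1]")
        if self.n_causal_genes > self.n_genes:
            raise ValueError("n_causal_genes cannot exceed n_genes")
        per_site = self.carrier_freq / self.n_variant_sites_per_gene
        if per_site >= 0.01:
            raise ValueError(
                "per-site cohort frequency %.4f would not survive the 1%% "
                "cohort-frequency filter; increase n_variant_sites_per_gene"
                % per_site
            )


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generator, serializable as JSON."""

    causal_map: dict  # gene -> {"component": int, "shift": float}
    planted_loadings: np.ndarray  # processes x features
    latent_scores: np.ndarray  # samples x processes (before mixing)
    carrier_samples: dict  # gene -> list of sample ids
    loh_samples: dict  # gene -> list of sample ids with planted LOH
    network_module: list  # genes forming the enriched module
    sample_ids: list

    def to_json(self, path: str | Path) -> None:
        obj = {
            "causal_map": self.causal_map,
            "planted_loadings": self.planted_loadings.tolist(),
            "latent_scores": self.latent_scores.tolist(),
            "carrier_samples": self.carrier_samples,
            "loh_samples": self.loh_samples,
            "network_module": self.network_module,
            "sample_ids": self.sample_ids,
        }
        Path(path).write_text(json.dumps(obj))


# ---------------------------------------------------------------------------
# genome tracks
# ---------------------------------------------------------------------------

@dataclass
class TrackBundle:
    chrom_lengths: dict
    windows: pd.DataFrame  # 10kb tiling with bin labels and fork polarity
    ctcf: pd.DataFrame  # chrom,start,end,kind in {core,flank}
    microsat: pd.DataFrame  # chrom,start,end
    mask: pd.DataFrame  # coverage mask intervals
    genes: pd.DataFrame  # gene,chrom,start,end,strand,n_exons
    exons: pd.DataFrame  # gene,exon_idx,start,end,terminal
    window_size: int = 10_000

    def window_index(self, chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
        """Map positions to row indices of ``windows`` (-1 when unmapped)."""
        out = np.full(len(pos), -1, dtype=np.int64)
        for c, sub in self.windows.groupby("chrom", sort=False):
            m = chrom == c
            if not m.any():
                continue
            starts = sub["start"].to_numpy()
            idx = np.searchsorted(starts, pos[m], side="right") - 1
            ends = sub["end"].to_numpy()
            valid = (idx >= 0) & (pos[m] < ends[np.clip(idx, 0, None)])
            rows = sub.index.to_numpy()[np.clip(idx, 0, None)]
            res = np.where(valid, rows, -1)
            out[np.where(m)[0]] = res
        return out


def _in_intervals(chrom, pos, intervals: pd.DataFrame) -> np.ndarray:
    """Boolean membership of 0-based positions in a BED-style interval set."""
    hit = np.zeros(len(pos), dtype=bool)
    for c, sub in intervals.groupby("chrom", sort=False):
        m = chrom == c
        if not m.any():
            continue
        starts = np.sort(sub["start"].to_numpy())
        ends = sub.sort_values("start")["end"].to_numpy()
        idx = np.searchsorted(starts, pos[m], side="right") - 1
        ok = (idx >= 0) & (pos[m] < ends[np.clip(idx, 0, None)])
        hit[np.where(m)[0]] = ok
    return hit


def generate_genome_tracks(seed: int, genome_length: int = 10_000_000,
                           window: int = 10_000) -> TrackBundle:
    """Build a toy multi-chromosome genome with all annotation tracks.

    Four autosomes plus chrX tile the requested length; chrM is a fixed
    16.6 kb contig.  Each 10 kb window receives replication-timing,
    expression, H3K36me3 and DNase bin labels, plus a smooth fork-polarity
    value whose deciles define the replicative-strand bins.
    """
    if genome_length < 1_000_000:
        raise ValueError("genome_length must be at least 1 Mb")
    rng = np.random.default_rng(seed)

    auto_len = int(genome_length * 0.24) // window * window
    x_len = int(genome_length * 0.04) // window * window
    chrom_lengths = {f"chr{i}": auto_len for i in range(1, 5)}
    chrom_lengths["chrX"] = x_len
    chrom_lengths["chrM"] = 16_600

    n_windows = sum(
        l // window for c, l in chrom_lengths.items() if c != "chrM"
    )
    if n_windows < 60:
        raise ValueError("genome too short to host at least one region per bin")

    rows = []
    for c, l in chrom_lengths.items():
        if c == "chrM":
            continue
        for s in range(0, l, window):
            rows.append((c, s, s + window))
    win = pd.DataFrame(rows, columns=["chrom", "start", "end"])

    n = len(win)
    # replication timing: smooth signal -> 6 equal-count bins, bin 1 latest
    rt_signal = np.cumsum(rng.normal(size=n))
    win["rt_bin"] = pd.qcut(rt_signal, 6, labels=False) + 1
    # expression / H3K36me3 / DNase: zero-signal bin 0 + 5 signal bins
    for col in ["expr_bin", "h3k_bin", "dnase_bin"]:
        signal = rng.gamma(1.0, 1.0, size=n)
        zero = rng.random(n) < 0.25
        signal[zero] = 0.0
        lab = np.zeros(n, dtype=int)
        nz = ~zero
        lab[nz] = pd.qcut(signal[nz], 5, labels=False, duplicates="drop") + 1
        win[col] = lab
    # fork polarity: signed derivative of the replication timing signal
    fp = np.gradient(rt_signal)
    win["fork_pol"] = fp
    win["fork_decile"] = pd.qcut(fp, 10, labels=False) + 1

    # CTCF cores with abutting +/-500bp flanks, away from chrom edges
    core_rows, flank_rows = [], []
    for c, l in chrom_lengths.items():
        if c in ("chrM", "chrX"):
            continue
        n_sites = max(3, l // 400_000)
        centers = rng.integers(2_000, l - 2_000, size=n_sites)
        for m in np.sort(centers):
            core_rows.append((c, int(m - 20), int(m + 20)))
            flank_rows.append((c, int(m - 520), int(m - 20)))
            flank_rows.append((c, int(m + 20), int(m + 520)))
    ctcf = pd.concat([
        pd.DataFrame(core_rows, columns=["chrom", "start", "end"]).assign(kind="core"),
        pd.DataFrame(flank_rows, columns=["chrom", "start", "end"]).assign(kind="flank"),
    ], ignore_index=True)

    ms_rows = []
    for c, l in chrom_lengths.items():
        if c == "chrM":
            continue
        n_sites = max(5, l // 200_000)
        starts = np.sort(rng.integers(0, l - 200, size=n_sites))
        for s in starts:
            ms_rows.append((c, int(s), int(s + rng.integers(20, 120))))
    microsat = pd.DataFrame(ms_rows, columns=["chrom", "start", "end"])

    # coverage mask: whole chroms minus a small excluded stripe per chrom
    mask_rows = []
    for c, l in chrom_lengths.items():
        gap_start = l // 2
        gap_end = min(l, gap_start + window)
        mask_rows.append((c, 0, gap_start))
        if gap_end < l:
            mask_rows.append((c, gap_end, l))
    mask = pd.DataFrame(mask_rows, columns=["chrom", "start", "end"])

    # toy gene models with exons; terminal exon flagged; strand random
    gene_rows, exon_rows = [], []
    gi = 0
    for c, l in chrom_lengths.items():
        if c == "chrM":
            continue
        n_genes = max(4, l // 150_000)
        starts = np.sort(rng.integers(0, l - 30_000, size=n_genes))
        for s in starts:
            gene = f"G{gi:04d}"
            strand = "+" if rng.random() < 0.5 else "-"
            n_ex = int(rng.integers(2, 6))
            length = int(rng.integers(10_000, 28_000))
            gene_rows.append((gene, c, int(s), int(s + length), strand, n_ex))
            bounds = np.sort(rng.choice(
                np.arange(s + 100, s + length - 100), size=2 * n_ex, replace=False))
            for e in range(n_ex):
                exon_rows.append((
                    gene, e, int(bounds[2 * e]), int(bounds[2 * e + 1]),
                    e == n_ex - 1 if strand == "+" else e == 0,
                ))
            gi += 1
    genes = pd.DataFrame(
        gene_rows, columns=["gene", "chrom", "start", "end", "strand", "n_exons"])
    exons = pd.DataFrame(
        exon_rows, columns=["gene", "exon_idx", "start", "end", "terminal"])

    return TrackBundle(
        chrom_lengths=chrom_lengths, windows=win, ctcf=ctcf,
        microsat=microsat, mask=mask, genes=genes, exons=exons,
        window_size=window,
    )


# ---------------------------------------------------------------------------
# signature catalogs
# ---------------------------------------------------------------------------

def synthetic_catalogs(seed: int = 0) -> dict:
    """Sparse synthetic signature catalogs for SBS-96, DBS-78 and ID-83.

    Each signature column is a Dirichlet draw concentrated on a random
    channel subset and sums to 1; the conversion matrix to the reference
    signature set is the identity (the synthetic catalogs *are* the
    reference set).
    """
    rng = np.random.default_rng(seed)

    def make(channels, names):
        mat = np.zeros((len(channels), len(names)))
        for j in range(len(names)):
            support = rng.choice(len(channels), size=max(4, len(channels) // 6),
                                 replace=False)
            w = rng.dirichlet(np.ones(len(support)) * 0.5)
            mat[support, j] = w
        return pd.DataFrame(mat, index=channels, columns=names)

    sbs = make(SBS96_CHANNELS, REF_SIGS)
    dbs = make(DBS78_CHANNELS, DBS_SIGS)
    idc = make(ID83_CHANNELS, ID_SIGS)
    conv = pd.DataFrame(np.eye(len(REF_SIGS)), index=REF_SIGS, columns=REF_SIGS)
    return {"SBS": sbs, "DBS": dbs, "ID": idc, "conversion": conv}


def channel_annotations() -> pd.DataFrame:
    """Per SBS-96 channel: pyrimidine substitution class and CpG status."""
    rows = []
    for i, ch in enumerate(SBS96_CHANNELS):
        sub = ch[2:5]
        right = ch[-1]
        cpg = sub == "C>T" and right == "G"
        rows.append((i, ch, sub, cpg))
    return pd.DataFrame(rows, columns=["channel", "name", "sub6", "cpg"])


# ---------------------------------------------------------------------------
# somatic event catalog
# ---------------------------------------------------------------------------

def generate_event_catalog(
    spec: SyntheticCohortSpec,
    tracks: TrackBundle,
    catalogs: dict | None = None,
    n_snv_per_sample: float = 2000.0,
    rt_rate_multipliers: np.ndarray | None = None,
    tx_strand_bias: float = 1.0,
    rep_strand_bias: float = 1.0,
    signature_mixture: np.ndarray | None = None,
    n_dbs_per_sample: float = 30.0,
    n_indel_per_sample: float = 150.0,
    n_cna_per_sample: float = 40.0,
    rng: np.random.Generator | None = None,
) -> dict:
    """Sample somatic SNVs, DBSs, indels, CNA segments and ploidy.

    Returns a dict with ``events`` (per-variant table), ``cna_segments``,
    ``ploidy``, ``mito`` and the true generative ``params`` for recovery
    tests.  SNV placement follows per-replication-timing-bin rate
    multipliers; strand assignment follows the transcriptional and
    replicative bias factors; channels follow the signature mixture.
    """
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if catalogs is None:
        catalogs = synthetic_catalogs(spec.seed)
    if rt_rate_multipliers is None:
        rt_rate_multipliers = np.ones(6)
    rt_rate_multipliers = np.asarray(rt_rate_multipliers, dtype=float)
    n_sigs = catalogs["SBS"].shape[1]
    per_sample_mixture = signature_mixture is None
    if not per_sample_mixture:
        signature_mixture = np.asarray(signature_mixture, dtype=float)
    if n_snv_per_sample < 1:
        warnings.warn("expected SNV count below 1 per sample")

    chan = channel_annotations()

    def _chan_probs(mix):
        p = catalogs["SBS"].to_numpy() @ mix
        return p / p.sum()

    win = tracks.windows
    win_w = rt_rate_multipliers[win["rt_bin"].to_numpy() - 1]
    win_p = win_w / win_w.sum()
    samples = [f"S{i:04d}" for i in range(spec.n_samples)]

    gene_int = tracks.genes
    ev_frames = []
    sample_mixtures = {}
    for s in samples:
        if per_sample_mixture:
            mix = rng.dirichlet(np.full(n_sigs, 0.5))
        else:
            mix = signature_mixture
        sample_mixtures[s] = mix
        chan_probs = _chan_probs(mix)
        n = rng.poisson(n_snv_per_sample)
        widx = rng.choice(len(win), size=n, p=win_p)
        offset = rng.integers(0, tracks.window_size, size=n)
        pos = win["start"].to_numpy()[widx] + offset
        chrom = win["chrom"].to_numpy()[widx]
        ch = rng.choice(96, size=n, p=chan_probs)
        sub6 = chan["sub6"].to_numpy()[ch]
        cpg = chan["cpg"].to_numpy()[ch]
        df = pd.DataFrame({
            "sample": s, "chrom": chrom, "pos": pos, "class": "SNV",
            "channel96": ch, "sub6": sub6, "cpg": cpg,
        })
        df["fork_decile"] = win["fork_decile"].to_numpy()[widx]
        ev_frames.append(df)
    events = pd.concat(ev_frames, ignore_index=True)
    events["ref"] = [s[0] for s in events["sub6"]]
    events["alt"] = [s[2] for s in events["sub6"]]

    # gene membership and strand for transcriptional bias
    events["gene_strand"] = None
    for _, g in gene_int.iterrows():
        m = (
            (events["chrom"] == g["chrom"])
            & (events["pos"] >= g["start"])
            & (events["pos"] < g["end"])
        )
        events.loc[m, "gene_strand"] = g["strand"]

    # orientation: is the pyrimidine of the pair the reference-strand base?
    # transcriptional bias factor f means untranscribed/transcribed = f
    p_untx = tx_strand_bias / (1.0 + tx_strand_bias)
    in_gene = events["gene_strand"].notna().to_numpy()
    u = rng.random(len(events))
    untx = u < p_untx  # genic events: mutation on untranscribed strand
    plus = (events["gene_strand"] == "+").to_numpy()
    pyr_on_ref = np.where(in_gene, untx == plus, rng.random(len(events)) < 0.5)
    events["pyr_on_ref"] = pyr_on_ref
    events["tx"] = np.where(~in_gene, "none", np.where(untx, "U", "T"))

    # replicative bias: re-orient focal-pair events in the extreme deciles
    comp = {s: complement_sub(s) for s in SUB6}
    focal_pyr = {s for s in SUB6
                 if s in REPLICATIVE_FOCAL or comp[s] in REPLICATIVE_FOCAL}
    if rep_strand_bias != 1.0:
        p_lead = rep_strand_bias / (1.0 + rep_strand_bias)
        dec = events["fork_decile"].to_numpy()
        extreme = (dec <= 2) | (dec >= 9)
        cand = extreme & events["sub6"].isin(focal_pyr).to_numpy()
        lead = rng.random(len(events)) < p_lead
        # ref strand is leading in top deciles: a ref-strand focal sub counts
        # leading there; orientation sets whether the focal type sits on ref
        ref_is_lead = dec >= 9
        want_ref = lead == ref_is_lead  # focal type should sit on ref strand
        pyr_is_focal = events["sub6"].isin(REPLICATIVE_FOCAL).to_numpy()
        # ref_sub is focal iff (pyrimidine class focal AND pyr on ref) or
        # (complement focal AND pyr not on ref); set orientation accordingly
        new_pyr = np.where(cand,
                           np.where(pyr_is_focal, want_ref, ~want_ref),
                           events["pyr_on_ref"].to_numpy())
        events["pyr_on_ref"] = new_pyr.astype(bool)

    # reference-strand substitution (pyrimidine class or its complement)
    events["ref_sub"] = np.where(
        events["pyr_on_ref"], events["sub6"],
        events["sub6"].map(comp),
    )

    # mito SNVs with VAFs
    mito_rows = []
    for s in samples:
        nm = rng.poisson(5)
        for _ in range(nm):
            mito_rows.append((s, "chrM", int(rng.integers(0, 16_600)),
                              float(rng.beta(2, 6))))
    mito = pd.DataFrame(mito_rows, columns=["sample", "chrom", "pos", "vaf"])

    # DBS events: channel only (features need channel counts); per-sample
    # signature mixtures, as for SBS
    dbs_cat = catalogs["DBS"].to_numpy()
    dbs_rows = []
    for s in samples:
        dbs_p = dbs_cat @ rng.dirichlet(np.full(dbs_cat.shape[1], 0.5))
        dbs_p /= dbs_p.sum()
        n = rng.poisson(n_dbs_per_sample)
        for ch in rng.choice(len(dbs_p), size=n, p=dbs_p):
            dbs_rows.append((s, int(ch)))
    dbs = pd.DataFrame(dbs_rows, columns=["sample", "channel78"])

    # indels: length, MS membership, microhomology; ID signature channel
    id_cat = catalogs["ID"].to_numpy()
    ind_frames = []
    ms = tracks.microsat.reset_index(drop=True)
    for s in samples:
        id_p = id_cat @ rng.dirichlet(np.full(id_cat.shape[1], 0.5))
        id_p /= id_p.sum()
        n = rng.poisson(n_indel_per_sample)
        length = rng.choice(
            [1, 2, 3, 4, 5, 6, 8, 10, 15, 25], size=n,
            p=[0.45, 0.12, 0.08, 0.06, 0.05, 0.05, 0.05, 0.05, 0.05, 0.04])
        is_del = rng.random(n) < 0.55
        widx = rng.choice(len(win), size=n)
        pos = win["start"].to_numpy()[widx] + rng.integers(
            0, tracks.window_size, size=n)
        chrom = win["chrom"].to_numpy()[widx]
        # replication slippage concentrates short indels in microsatellites
        in_ms_draw = (length <= 5) & (rng.random(n) < 0.3)
        if in_ms_draw.any() and len(ms):
            mi = rng.integers(0, len(ms), size=int(in_ms_draw.sum()))
            pos = pos.copy()
            pos[in_ms_draw] = ms["start"].to_numpy()[mi] + 1
            chrom = chrom.copy()
            chrom[in_ms_draw] = ms["chrom"].to_numpy()[mi]
        mh = np.where(is_del, rng.choice([0, 1, 2, 3], size=n,
                                         p=[0.55, 0.25, 0.12, 0.08]), 0)
        ind_frames.append(pd.DataFrame({
            "sample": s, "chrom": chrom, "pos": pos,
            "class": np.where(is_del, "DEL", "INS"),
            "length": length, "mh_len": mh,
            "channel83": rng.choice(len(id_p), size=n, p=id_p),
        }))
    indels = pd.concat(ind_frames, ignore_index=True)
    indels["in_ms"] = _in_intervals(
        indels["chrom"].to_numpy(), indels["pos"].to_numpy(), tracks.microsat)

    # CNA segments and ploidy
    cna_rows, ploidy_rows = [], []
    for s in samples:
        ploidy = float(np.clip(rng.normal(2.4, 0.8), 1.2, 6.0))
        ploidy_rows.append((s, ploidy))
        n = rng.poisson(n_cna_per_sample)
        for _ in range(n):
            kind = "amp" if rng.random() < 0.5 else "del"
            size_kb = float(10 ** rng.uniform(0.1, 3.5))
            c = rng.choice([f"chr{i}" for i in range(1, 5)])
            start = int(rng.integers(0, tracks.chrom_lengths[c] - 1000))
            cna_rows.append((s, c, start, start + int(size_kb * 1000), kind,
                             size_kb))
    cna = pd.DataFrame(
        cna_rows, columns=["sample", "chrom", "start", "end", "type", "size_kb"])
    ploidy = pd.DataFrame(ploidy_rows, columns=["sample", "ploidy"])

    params = {
        "rt_rate_multipliers": rt_rate_multipliers.tolist(),
        "tx_strand_bias": tx_strand_bias,
        "rep_strand_bias": rep_strand_bias,
        "signature_mixtures": {s: m.tolist()
                               for s, m in sample_mixtures.items()},
    }
    return {
        "events": events, "indels": indels, "dbs": dbs, "mito": mito,
        "cna_segments": cna, "ploidy": ploidy, "params": params,
        "samples": samples,
    }


# ---------------------------------------------------------------------------
# germline cohort
# ---------------------------------------------------------------------------

def _gene_universe(spec: SyntheticCohortSpec) -> list[str]:
    return [f"GENE{i:04d}" for i in range(spec.n_genes)]


def generate_germline_cohort(
    spec: SyntheticCohortSpec,
    tracks: TrackBundle | None = None,
    n_background_variants: int = 2000,
    n_common_variants: int = 800,
    n_related_pairs: int = 1,
    n_duplicate_pairs: int = 1,
    rng: np.random.Generator | None = None,
) -> dict:
    """Generate the germline side of a cohort with planted causal carriers.

    Returns annotated rare variants, a common-variant genotype matrix with
    planted duplicate/related pairs and ancestry clusters, per-sample
    covariates, latent process scores shifted in carriers, planted LOH
    assignments and the :class:`SyntheticTruth`.
    """
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(spec.seed)

    n = spec.n_samples
    samples = [f"S{i:04d}" for i in range(n)]
    genes = _gene_universe(spec)
    causal_genes = genes[: spec.n_causal_genes]

    types = list(spec.cancer_type_props)
    probs = np.array(list(spec.cancer_type_props.values()))
    cancer_type = rng.choice(types, size=n, p=probs)
    age = np.clip(rng.normal(60, 12, size=n), 20, 90)
    sex = rng.choice(["F", "M"], size=n)

    # latent scores: non-Gaussian (Laplace) sources + covariate structure
    k = spec.n_latent_processes
    Z = rng.laplace(0.0, 1.0 / np.sqrt(2.0), size=(n, k))
    a_eff = spec.covariate_effects.get("age_per_decade", 0.0)
    s_eff = spec.covariate_effects.get("sex", 0.0)
    Z[:, 0] += a_eff * (age - 60.0) / 10.0
    Z[:, 0] += s_eff * (sex == "M")

    # effect map: causal genes cycle over components
    if spec.effect_sizes is None:
        effect_sizes = {
            g: (i % k, 1.0) for i, g in enumerate(causal_genes)
        }
    else:
        effect_sizes = dict(spec.effect_sizes)

    ncarr = int(round(spec.carrier_freq * n))
    carrier_samples: dict[str, list[str]] = {}
    loh_samples: dict[str, list[str]] = {}
    var_rows = []
    tissues = {t: f"tissue_{t}" for t in types}
    tissue_cols = sorted(set(tissues.values()))

    def tissue_of(sample_idx):
        return tissues[cancer_type[sample_idx]]

    vid = 0
    for g_i, g in enumerate(causal_genes):
        if ncarr < 2:
            warnings.warn(
                f"gene {g}: fewer than 2 planted carriers; untestable by design")
        comp, shift = effect_sizes.get(g, (0, 0.0))
        idx = rng.choice(n, size=ncarr, replace=False)
        Z[idx, comp] += shift
        carrier_samples[g] = [samples[i] for i in idx]
        loh = rng.random(ncarr) < spec.loh_rate
        loh_samples[g] = [samples[i] for i, l in zip(idx, loh) if l]
        sites = rng.integers(1_000, 1_000_000, size=spec.n_variant_sites_per_gene)
        site_of = rng.integers(0, spec.n_variant_sites_per_gene, size=ncarr)
        for j, i in enumerate(idx):
            has_loh = bool(loh[j])
            vaf_n = float(np.clip(rng.normal(0.5, 0.05), 0.05, 0.95))
            vaf_t = (float(np.clip(rng.normal(0.9, 0.04), 0.6, 1.0))
                     if has_loh else
                     float(np.clip(rng.normal(0.5, 0.06), 0.05, 0.8)))
            row = {
                "sample": samples[i], "gene": g, "chrom": "chr1",
                "pos": int(sites[site_of[j]]) + g_i * 2_000_000,
                "ref": "C", "alt": "T", "filter": "PASS",
                "gqx": float(rng.integers(50, 99)),
                "in_gnomad": bool(rng.random() < 0.5),
                "gnomad_af": float(10 ** rng.uniform(-6, -4)),
                "consequence": "stopgain", "cadd": float(rng.uniform(30, 45)),
                "mtr_pct": float(rng.uniform(0, 100)),
                "ccr_pct": float(rng.uniform(0, 100)),
                "spliceai_dl": 0.0, "spliceai_al": 0.0,
                "exon_idx": 1, "terminal_exon": False,
                "pext_mean": float(rng.uniform(0.5, 1.0)),
                "vaf_tumor": vaf_t, "vaf_normal": vaf_n,
                "present_in_tumor": True, "causal": True,
            }
            for tc in tissue_cols:
                row[f"pext_{tc}"] = float(rng.uniform(0.5, 1.0))
            var_rows.append(row)
            vid += 1

    # background variants: mixture of consequences across non-causal genes
    bg_genes = genes[spec.n_causal_genes:]
    conseqs = ["missense", "stopgain", "frameshift_del", "frameshift_ins",
               "splicing", "stoploss", "startloss", "synonymous"]
    cprobs = [0.62, 0.08, 0.06, 0.05, 0.05, 0.04, 0.03, 0.07]
    for _ in range(n_background_variants):
        g = bg_genes[int(rng.integers(len(bg_genes)))]
        i = int(rng.integers(n))
        cq = rng.choice(conseqs, p=cprobs)
        terminal = bool(rng.random() < 0.15)
        has_loh = bool(rng.random() < spec.loh_rate * 0.5)
        vaf_n = float(np.clip(rng.normal(0.5, 0.05), 0.05, 0.95))
        vaf_t = (float(np.clip(rng.normal(0.9, 0.05), 0.5, 1.0))
                 if has_loh else
                 float(np.clip(rng.normal(0.5, 0.08), 0.05, 0.85)))
        in_gnomad = bool(rng.random() < 0.6)
        row = {
            "sample": samples[i], "gene": g, "chrom": "chr2",
            "pos": int(rng.integers(1, 90_000_000)),
            "ref": "G", "alt": "A",
            "filter": "PASS" if rng.random() < 0.9 else "LowGQX",
            "gqx": float(rng.integers(5, 99)),
            "in_gnomad": in_gnomad,
            "gnomad_af": float(10 ** rng.uniform(-6, -3.2)) if in_gnomad else np.nan,
            "consequence": cq, "cadd": float(rng.uniform(0, 45)),
            "mtr_pct": float(rng.uniform(0, 100)),
            "ccr_pct": float(rng.uniform(0, 100)),
            "spliceai_dl": float(rng.beta(0.3, 4)),
            "spliceai_al": float(rng.beta(0.3, 4)),
            "exon_idx": int(rng.integers(0, 5)), "terminal_exon": terminal,
            "pext_mean": float(rng.beta(3, 1.2)),
            "vaf_tumor": vaf_t, "vaf_normal": vaf_n,
            "present_in_tumor": bool(rng.random() < 0.95), "causal": False,
        }
        for tc in tissue_cols:
            row[f"pext_{tc}"] = float(rng.beta(3, 1.2))
        var_rows.append(row)
    variants = pd.DataFrame(var_rows)

    # gnomAD subpopulation AFs: Dirichlet perturbations of the overall AF
    af = variants["gnomad_af"].to_numpy()
    for j in range(3):
        mult = rng.gamma(20.0, 1 / 20.0, size=len(variants))
        variants[f"gnomad_af_sub{j + 1}"] = af * mult
    variants.loc[~variants["in_gnomad"],
                 [c for c in variants if c.startswith("gnomad_af")]] = np.nan

    # common-variant genotype matrix with ancestry clusters
    afs = rng.uniform(0.08, 0.5, size=n_common_variants)
    cluster = rng.choice([0, 1], size=n, p=[0.85, 0.15])  # planted ancestry
    shift = rng.normal(0, 0.08, size=n_common_variants)
    G = np.zeros((n, n_common_variants), dtype=np.int8)
    for c in (0, 1):
        m = cluster == c
        p = np.clip(afs + (shift if c == 1 else 0.0), 0.02, 0.98)
        G[m] = rng.binomial(2, p, size=(m.sum(), n_common_variants))
    # planted duplicates / first-degree relatives for relatedness QC
    dup_pairs, rel_pairs = [], []
    free = list(range(n))
    for _ in range(n_duplicate_pairs):
        a, b = free.pop(0), free.pop(0)
        G[b] = G[a]
        dup_pairs.append((samples[a], samples[b]))
    for _ in range(n_related_pairs):
        a, b = free.pop(0), free.pop(0)
        share = rng.random(n_common_variants) < 0.5
        G[b, share] = G[a, share]
        rel_pairs.append((samples[a], samples[b]))

    covariates = pd.DataFrame({
        "sample": samples, "age": age, "sex": sex,
        "cancer_type": cancer_type, "ancestry_cluster": cluster,
    })

    # mixing loadings: processes x 56 retained features
    n_feat = 56
    if spec.mixing_loadings is None:
        W = rng.normal(0.0, 1.0, size=(k, n_feat))
        W *= rng.random((k, n_feat)) < 0.4  # sparse support, O(1) weights
    else:
        W = np.asarray(spec.mixing_loadings, dtype=float)

    truth = SyntheticTruth(
        causal_map={g: {"component": int(c), "shift": float(s)}
                    for g, (c, s) in effect_sizes.items()},
        planted_loadings=W,
        latent_scores=Z,
        carrier_samples=carrier_samples,
        loh_samples=loh_samples,
        network_module=causal_genes,
        sample_ids=samples,
    )
    return {
        "variants": variants,
        "common_genotypes": pd.DataFrame(G, index=samples),
        "covariates": covariates,
        "latent_scores": Z,
        "truth": truth,
        "duplicate_pairs": dup_pairs,
        "related_pairs": rel_pairs,
        "tissue_map": tissues,
        "gene_universe": genes,
    }


def mix_features(truth: SyntheticTruth, noise_sd: float,
                 rng: np.random.Generator,
                 feature_names: list[str] | None = None) -> pd.DataFrame:
    """Linearly mix latent scores into a samples x features matrix + noise."""
    from .registry import RETAINED_FEATURES

    if feature_names is None:
        feature_names = RETAINED_FEATURES
    Z = truth.latent_scores
    W = truth.planted_loadings
    X = Z @ W + rng.normal(0.0, noise_sd, size=(Z.shape[0], W.shape[1]))
    return pd.DataFrame(X, index=truth.sample_ids,
                        columns=feature_names[: W.shape[1]])


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

def generate_network(
    spec: SyntheticCohortSpec,
    truth: SyntheticTruth,
    p_background: float = 0.02,
    enrichment_factor: float = 1.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Erdos-Renyi background network with an enriched causal-gene module.

    Edge weights are combined-confidence-like values in [0, 1]; module
    edges receive high weights.  Returns an edge list (gene_a, gene_b,
    weight) without self-loops or duplicates.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    genes = _gene_universe(spec)
    module = set(truth.network_module)
    rows = []
    for i, j in itertools.combinations(range(len(genes)), 2):
        a, b = genes[i], genes[j]
        if a in module and b in module:
            p = min(1.0, p_background * enrichment_factor)
            w_lo, w_hi = 0.8, 1.0
        else:
            p = p_background
            w_lo, w_hi = 0.0, 1.0
        if rng.random() < p:
            rows.append((a, b, float(rng.uniform(w_lo, w_hi))))
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "weight"])


# ---------------------------------------------------------------------------
# output writers
# ---------------------------------------------------------------------------

def write_cohort(out_dir: str | Path, catalog: dict, germ: dict,
                 network: pd.DataFrame, truth: SyntheticTruth) -> None:
    """Write the synthetic cohort to the standard TSV/JSON files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    catalog["events"].to_csv(out / "events.tsv", sep="\t", index=False)
    catalog["cna_segments"].to_csv(out / "cna_segments.tsv", sep="\t", index=False)
    germ["variants"].to_csv(out / "germline_variants.tsv", sep="\t", index=False)
    germ["common_genotypes"].to_csv(out / "common_genotypes.tsv", sep="\t")
    germ["covariates"].to_csv(out / "covariates.tsv", sep="\t", index=False)
    network.to_csv(out / "network_edges.tsv", sep="\t", index=False)
    truth.to_json(out / "truth.json")
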