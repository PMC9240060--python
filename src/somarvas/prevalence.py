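"""Carrier-prevalence comparisons.

Compares the fraction of individuals carrying qualifying rare pLoF
variants in an associated gene set against length-matched random control
genes, and against carrier frequencies implied by summing control-population
allele frequencies of the cohort-observed variants.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


def carrier_frequency(gene_set: list[str], carriers: pd.DataFrame,
                      n_samples: int | None = None) -> float:
    """Fraction of samples carrying at least one qualifying variant in any
    gene of the set."""
    if len(gene_set) == 0:
        raise ValueError("empty gene set")
    missing = set(gene_set) - set(carriers.index)
    if missing:
        raise ValueError(f"genes not in carrier matrix: {sorted(missing)}")
    if n_samples is None:
        n_samples = carriers.shape[1]
    any_carrier = (carriers.loc[gene_set] > 0).any(axis=0)
    return float(any_carrier.sum() / n_samples)


def length_matched_controls(
    gene_set: list[str],
    lengths: pd.Series,
    carriers: pd.DataFrame,
    n_draws: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Carrier frequencies of random control sets matched on covered
    exonic length.

    Each set gene is matched, per draw, to a pool gene with the same
    integer-kb covered length (nearest-kb fallback within 1 kb, logged);
    control genes never include set genes, and a gene is never its own
    control.  Returns one row per draw with the control carrier frequency.
    """
    rng = np.random.default_rng(seed)
    pool = lengths.drop(index=[g for g in gene_set if g in lengths.index])
    pool = pool[pool.index.isin(carriers.index)]
    pool_kb = pool.round(0).astype(int)
    rows = []
    for draw in range(n_draws):
        controls = []
        for g in gene_set:
            kb = int(round(lengths[g]))
            exact = pool_kb[pool_kb == kb].index.difference(controls)
            if len(exact):
                controls.append(rng.choice(exact))
                continue
            near = pool_kb[(pool_kb - kb).abs() <= 1].index.difference(
                controls)
            if len(near) == 0:
                raise ValueError(
                    f"no control gene within 1 kb of {g} ({kb} kb)")
            log.info("nearest-kb fallback for gene %s", g)
            controls.append(rng.choice(near))
        freq = carrier_frequency(controls, carriers)
        rows.append((draw, freq, tuple(controls)))
    out = pd.DataFrame(rows, columns=["draw", "carrier_freq", "controls"])
    return out


def summarize_control_draws(draws: pd.DataFrame) -> dict:
    f = draws["carrier_freq"]
    return {"median": float(f.median()),
            "q25": float(f.quantile(0.25)),
            "q75": float(f.quantile(0.75))}


def control_population_frequency(
    cohort_variants: pd.DataFrame,
    gene_set: list[str],
    af_column: str = "gnomad_af",
) -> float:
    """Summed control-population allele frequency of the cohort-observed
    qualifying variants in the gene set.

    Only variants present in the control database count (cohort-only
    singletons are dropped); frequencies are summed under the assumption
    that a rare pLoF variant occurs at most once per individual.
    """
    v = cohort_variants[cohort_variants["gene"].isin(gene_set)]
    v = v[v["in_gnomad"].fillna(False).astype(bool)]
    v = v.drop_duplicates(subset=["chrom", "pos", "ref", "alt"])
    total = float(v[af_column].fillna(0.0).sum())
    if total > 1:
        import warnings
        warnings.warn("summed allele frequency exceeds 1; the one-variant-"
                      "per-individual assumption is strained")
    return total
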