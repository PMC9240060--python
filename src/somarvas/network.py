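"""Degree-controlled network permutation tests and gene prioritization.

Tests whether associated genes interact with each other (or with a
higher-confidence tier) more than degree-matched random gene sets drawn
from the candidate universe, and prioritizes individual genes by their
strongest interaction with known repair-pathway proteins or with their
neighborhood, against degree-matched randomization nulls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

KNOWN_SETS = {
    "dHR": ["BRCA1", "BRCA2", "PALB2", "RAD51C"],
    "dMMR": ["MLH1", "MSH2", "MSH6", "PMS2"],
}


@dataclass
class RandomizationResult:
    observed: float
    null: np.ndarray
    p: float
    median_difference: float
    n_randomizations: int


class InteractionGraph:
    """Simple undirected weighted graph over a gene universe."""

    def __init__(self, edges: pd.DataFrame, universe: list[str] | None = None,
                 score_floor: float | None = None):
        e = edges[["gene_a", "gene_b", "weight"]].copy()
        e = e[e["gene_a"] != e["gene_b"]]
        if score_floor is not None:
            e = e[e["weight"] >= score_floor]
        if universe is None:
            universe = sorted(set(e["gene_a"]) | set(e["gene_b"]))
        self.genes = list(universe)
        self.index = {g: i for i, g in enumerate(self.genes)}
        n = len(self.genes)
        self.W = np.zeros((n, n))
        for a, b, w in e.itertuples(index=False):
            if a in self.index and b in self.index:
                i, j = self.index[a], self.index[b]
                self.W[i, j] = self.W[j, i] = max(self.W[i, j], float(w))
        self.adj = self.W > 0

    def degree(self, genes=None) -> np.ndarray:
        d = self.adj.sum(axis=1)
        if genes is None:
            return d
        return np.array([d[self.index[g]] for g in genes])

    def edges_within(self, genes: list[str]) -> int:
        idx = [self.index[g] for g in genes if g in self.index]
        sub = self.adj[np.ix_(idx, idx)]
        return int(sub.sum() // 2)

    def n_with_neighbor_in(self, genes_a: list[str],
                           genes_b: list[str]) -> int:
        ia = [self.index[g] for g in genes_a if g in self.index]
        ib = [self.index[g] for g in genes_b if g in self.index]
        if not ia or not ib:
            return 0
        return int(self.adj[np.ix_(ia, ib)].any(axis=1).sum())


def _degree_bins(hit_degrees: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-count degree bin edges from the hit set's degrees (stable
    tie-break by order)."""
    qs = np.quantile(hit_degrees, np.linspace(0, 1, n_bins + 1))
    qs[0] = -np.inf
    qs[-1] = np.inf
    return qs


def _binned_null_draws(graph: InteractionGraph, hit_set: list[str],
                       universe: list[str], n_bins: int, n_rand: int,
                       rng: np.random.Generator):
    """Yield degree-matched random gene sets preserving per-bin counts."""
    hit_deg = graph.degree(hit_set)
    edges = _degree_bins(hit_deg, n_bins)
    hit_bins = np.searchsorted(edges, hit_deg, side="left") - 1
    hit_bins = np.clip(hit_bins, 0, n_bins - 1)
    uni_deg = graph.degree(universe)
    uni_bins = np.clip(np.searchsorted(edges, uni_deg, side="left") - 1,
                       0, n_bins - 1)
    need = np.bincount(hit_bins, minlength=n_bins)
    pools = [np.array([universe[i] for i in np.where(uni_bins == b)[0]])
             for b in range(n_bins)]
    for b in range(n_bins):
        if need[b] > len(pools[b]):
            raise ValueError(
                f"degree bin {b} has {len(pools[b])} candidates for "
                f"{need[b]} draws; use fewer bins")
    for _ in range(n_rand):
        draw = []
        for b in range(n_bins):
            if need[b] == 0:
                continue
            draw.extend(rng.choice(pools[b], size=need[b], replace=False))
        yield draw, need


def internal_connectivity_test(
    hit_set: list[str],
    universe: list[str],
    graph: InteractionGraph,
    n_bins: int = 10,
    n_rand: int = 1000,
    exclude: list[str] | None = None,
    seed: int = 0,
) -> RandomizationResult:
    """Are edges among hit genes enriched over degree-matched random sets?

    The observed statistic is the number of graph edges with both endpoints
    in the hit set; null sets are drawn preserving the per-degree-bin
    composition of the hit set.  One-sided p with a +1 pseudo-count.
    """
    rng = np.random.default_rng(seed)
    if exclude:
        hit_set = [g for g in hit_set if g not in exclude]
        universe = [g for g in universe if g not in exclude]
    missing = set(hit_set) - set(universe)
    if missing:
        raise ValueError(f"hit genes outside universe: {sorted(missing)}")
    obs = graph.edges_within(hit_set)
    null = np.empty(n_rand)
    for i, (draw, need) in enumerate(_binned_null_draws(
            graph, hit_set, universe, n_bins, n_rand, rng)):
        assert len(draw) == need.sum()
        null[i] = graph.edges_within(list(draw))
    p = (1 + (null >= obs).sum()) / (1 + n_rand)
    return RandomizationResult(
        observed=float(obs), null=null, p=float(p),
        median_difference=float(obs - np.median(null)),
        n_randomizations=n_rand)


def cross_tier_connectivity_test(
    tier2_only: list[str],
    tier1: list[str],
    universe: list[str],
    graph: InteractionGraph,
    n_bins: int = 10,
    n_rand: int = 1000,
    seed: int = 0,
) -> RandomizationResult:
    """How many lower-tier genes touch at least one top-tier gene, versus
    degree-matched random sets standing in for the lower tier."""
    if set(tier2_only) & set(tier1):
        raise ValueError("tiers must be disjoint")
    rng = np.random.default_rng(seed)
    obs = graph.n_with_neighbor_in(tier2_only, tier1)
    null = np.empty(n_rand)
    for i, (draw, _) in enumerate(_binned_null_draws(
            graph, tier2_only, universe, n_bins, n_rand, rng)):
        null[i] = graph.n_with_neighbor_in(list(draw), tier1)
    p = (1 + (null >= obs).sum()) / (1 + n_rand)
    return RandomizationResult(
        observed=float(obs), null=null, p=float(p),
        median_difference=float(obs - np.median(null)),
        n_randomizations=n_rand)


def prioritize_gene(
    gene: str,
    graph: InteractionGraph,
    universe: list[str],
    known_sets: dict | None = None,
    mode: str = "known",
    hit_network_genes: list[str] | None = None,
    n_rand: int = 10_000,
    degree_tolerance: float = 0.5,
    seed: int = 0,
) -> RandomizationResult:
    """Prioritize a gene by its strongest interaction weight.

    ``known`` mode: observed = max edge weight from the gene to any known
    repair-pathway protein; the null takes the same statistic for
    degree-matched non-known genes of the universe.  ``neighbors`` mode:
    observed = max edge weight to any neighbor within the hit network; the
    null redraws degree-matched networks of the same size and records the
    gene's best weight (0 when isolated).
    """
    rng = np.random.default_rng(seed)
    if known_sets is None:
        known_sets = KNOWN_SETS
    if gene not in graph.index:
        raise ValueError(f"gene {gene!r} not in graph universe")
    gi = graph.index[gene]

    if mode == "known":
        known = [g for s in known_sets.values() for g in s
                 if g in graph.index]
        ki = [graph.index[g] for g in known]
        obs = float(graph.W[gi, ki].max()) if ki else 0.0
        deg = graph.degree()
        gdeg = deg[gi]
        lo, hi = gdeg * (1 - degree_tolerance), gdeg * (1 + degree_tolerance)
        pool = [g for g in universe
                if g not in known and g != gene and g in graph.index
                and (lo <= deg[graph.index[g]] <= hi or gdeg == 0)]
        if not pool:
            pool = [g for g in universe if g not in known and g != gene
                    and g in graph.index]
        null = np.array([
            graph.W[graph.index[g], ki].max() if ki else 0.0
            for g in rng.choice(pool, size=min(n_rand, 10 * len(pool)))])
    elif mode == "neighbors":
        if hit_network_genes is None:
            raise ValueError("neighbors mode requires hit_network_genes")
        hi_idx = [graph.index[g] for g in hit_network_genes
                  if g in graph.index and g != gene]
        obs = float(graph.W[gi, hi_idx].max()) if hi_idx else 0.0
        k = len(hi_idx)
        pool = [g for g in universe if g != gene and g in graph.index]
        null = np.empty(n_rand)
        for b in range(n_rand):
            draw = rng.choice(pool, size=min(k, len(pool)), replace=False)
            di = [graph.index[g] for g in draw]
            null[b] = graph.W[gi, di].max() if di else 0.0
    else:
        raise ValueError(f"unknown mode {mode!r}")

    p = (1 + (null >= obs).sum()) / (1 + len(null))
    return RandomizationResult(
        observed=obs, null=null, p=float(p),
        median_difference=float(obs - np.median(null)),
        n_randomizations=len(null))
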