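"""Proximity of second-hit genes to dysregulated genes in a weighted network.

The input is a probabilistic gene-interaction edge list; edges with
probability weight > 2.0 are retained and traversed with path weight
1/probability, so high-confidence interactions are short. For each
offspring, the observed quantity is the mean Dijkstra distance over all
(second-hit gene, expression-change gene) pairs; significance comes
from node-relabel permutations that keep the topology fixed and
randomly reassign genes to nodes, with a one-tailed z against the
permuted distribution (smaller observed distance = stronger
connectivity) plus an empirical p.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

from .expression_stats import bh_fdr

DEFAULT_EDGE_THRESHOLD = 2.0
DEFAULT_N_PERMUTATIONS = 100


def build_network(
    edges: list[tuple[str, str, float]],
    threshold: float = DEFAULT_EDGE_THRESHOLD,
) -> nx.Graph:
    """Thresholded undirected network with inverse-probability path weights.

    Edges with probability <= ``threshold`` are dropped, duplicates keep
    the maximum probability, self-loops are removed.
    """
    g = nx.Graph()
    for u, v, prob in edges:
        if prob <= 0:
            raise ValueError(f"non-positive edge probability on ({u}, {v})")
        if u == v or prob <= threshold:
            continue
        if g.has_edge(u, v) and g[u][v]["probability"] >= prob:
            continue
        g.add_edge(u, v, probability=prob, weight=1.0 / prob)
    return g


def avg_min_distance(
    network: nx.Graph, set_a: set[str], set_b: set[str]
) -> tuple[float, int, int]:
    """Mean shortest weighted distance over connected (a, b) pairs, a != b.

    Genes absent from the network are dropped; returns (mean distance,
    number of connected pairs used, number of pairs dropped as
    disconnected or absent).
    """
    a_nodes = sorted(set_a & set(network.nodes))
    b_nodes = sorted(set_b & set(network.nodes))
    n_absent_pairs = len(set_a) * len(set_b) - len(a_nodes) * len(b_nodes)
    dists = []
    dropped = n_absent_pairs
    for a in a_nodes:
        lengths = nx.single_source_dijkstra_path_length(network, a, weight="weight")
        for b in b_nodes:
            if a == b:
                continue
            if b in lengths:
                dists.append(lengths[b])
            else:
                dropped += 1
    if not dists:
        raise ValueError("no connected (a, b) pair in the network")
    return float(np.mean(dists)), len(dists), dropped


@dataclass
class ProximityResult:
    offspring_id: str
    observed: float
    permuted_mean: float
    permuted_sd: float
    z: float  # positive = observed closer than permuted
    pvalue: float  # one-tailed normal, observed-smaller alternative
    empirical_p: float
    n_permutations: int
    n_pairs: int
    fdr: float = field(default=np.nan)


def permutation_test(
    network: nx.Graph,
    set_a: set[str],
    set_b: set[str],
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int | np.random.Generator = 0,
    offspring_id: str = "",
) -> ProximityResult:
    """Node-relabel permutation test of set proximity.

    Each replicate permutes the gene->node assignment over all nodes
    (topology and weights untouched) and recomputes the mean shortest
    distance. z = (permuted mean - observed) / permuted SD; one-tailed
    p = Phi(-z) for the "observed smaller" alternative; the add-one
    empirical p is also returned.
    """
    if not set_a or not set_b:
        raise ValueError("both gene sets must be non-empty")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    observed, n_pairs, _ = avg_min_distance(network, set_a, set_b)
    nodes = sorted(network.nodes)
    perm_means = []
    for _ in range(n_permutations):
        relabel = dict(zip(nodes, rng.permutation(nodes)))
        pa = {relabel[g] for g in set_a if g in relabel}
        pb = {relabel[g] for g in set_b if g in relabel}
        try:
            d, _, _ = avg_min_distance(network, pa, pb)
        except ValueError:
            continue
        perm_means.append(d)
    perm_means_arr = np.array(perm_means)
    pm, ps = float(perm_means_arr.mean()), float(perm_means_arr.std(ddof=1))
    if ps == 0.0:
        warnings.warn("permuted SD is zero; p undefined")
        z, p = np.nan, np.nan
    else:
        z = (pm - observed) / ps
        p = float(stats.norm.sf(z))
    emp = float((np.sum(perm_means_arr <= observed) + 1) / (len(perm_means_arr) + 1))
    return ProximityResult(
        offspring_id=offspring_id,
        observed=observed,
        permuted_mean=pm,
        permuted_sd=ps,
        z=float(z),
        pvalue=p,
        empirical_p=emp,
        n_permutations=len(perm_means),
        n_pairs=n_pairs,
    )


def fdr_across_offspring(results: list[ProximityResult]) -> list[ProximityResult]:
    ps = [r.pvalue for r in results]
    if any(np.isnan(p) for p in ps):
        return results
    qs = bh_fdr(ps)
    for r, q in zip(results, qs):
        r.fdr = float(q)
    return results


def cohort_proximity_test(results: list[ProximityResult]) -> tuple[float, float]:
    """Paired two-sided Wilcoxon signed-rank of observed vs permuted means."""
    if len(results) < 5:
        raise ValueError("need at least five offspring")
    obs = [r.observed for r in results]
    perm = [r.permuted_mean for r in results]
    diffs = np.array(obs) - np.array(perm)
    if np.all(diffs == 0):
        warnings.warn("all paired differences are zero")
        return 0.0, 1.0
    method = "exact" if len(diffs) <= 25 and np.all(diffs != 0) else "approx"
    res = stats.wilcoxon(obs, perm, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
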