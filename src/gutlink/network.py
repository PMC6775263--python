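"""Genus co-occurrence networks with checkerboard null-model testing.

The procedure, stage by stage:

1. prevalence filter — keep taxa present (nonzero) in strictly more than
   half of the samples;
2. segregation test — the checkerboard score (C-score), the mean over
   unordered taxon pairs (i, j) of (R_i - S_ij)(R_j - S_ij) with R_i the
   occupancy of taxon i and S_ij the shared occupancy, tested against a
   fixed-fixed (SIM9) null model that randomizes the presence matrix by
   checkerboard 2x2 swaps preserving both row and column totals;
3. edges — Spearman rank correlations between filtered taxa; an edge is
   kept when |rho| > 0.7 (strictly) and p < 0.05 (exact permutation p for
   n <= 9 samples);
4. network properties (V, E, density, clustering, modularity, path
   length), compared against an ensemble of Erdos-Renyi G(n, M) random
   graphs with the same node and edge counts.

Networks are plain ``networkx.Graph`` objects: nodes are taxa with
optional "category" / "module" attributes, edges carry "weight" (rho) and
"sign" attributes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import igraph as ig
import networkx as nx
import numpy as np
from networkx.algorithms import community as nx_community
from scipy import stats

from .correlation import EXACT_MAX_N, spearman
from .diffabund import ResponseCategory
from .tables import AbundanceTable, CountTable, PresenceMatrix, to_relative_abundance

__all__ = [
    "NullModelResult",
    "NetworkProperties",
    "prevalence_filter",
    "c_score",
    "sim9_swap_chain",
    "cscore_null_test",
    "spearman_edges",
    "build_network",
    "network_properties",
    "sample_gnm",
    "er_ensemble_compare",
    "annotate_nodes",
    "CATEGORY_COLORS",
]

logger = logging.getLogger(__name__)

# Node colors used in figure exports: taxa elevated under stress (and
# behavior-linked) red, reversed-by-drug green, drug-responsive blue.
CATEGORY_COLORS = {
    "stress_only": "red",
    "restored": "green",
    "drug_only": "blue",
    "unchanged": "grey",
    "neutral": "grey",
}


@dataclass
class NullModelResult:
    observed: float
    null_mean: float
    null_sd: float
    ses: float | None
    p_value: float
    n_null: int
    seed: int | None = None
    burn_in: int = 0
    thin: int = 1
    vacuous: bool = False


@dataclass
class NetworkProperties:
    V: int
    E: int
    density: float | None = None
    mean_degree: float | None = None
    clustering: float | None = None
    modularity: float | None = None
    n_modules: int | None = None
    mean_path_length: float | None = None

    def as_dict(self) -> dict:
        return {
            "V": self.V, "E": self.E, "density": self.density,
            "mean_degree": self.mean_degree, "clustering": self.clustering,
            "modularity": self.modularity, "n_modules": self.n_modules,
            "mean_path_length": self.mean_path_length,
        }


# ---------------------------------------------------------------------------
# Prevalence filter
# ---------------------------------------------------------------------------


def prevalence_filter(t: CountTable) -> CountTable:
    """Keep taxa with nonzero counts in strictly more than half the samples."""
    n = len(t.sample_ids)
    occupancy = (t.counts > 0).sum(axis=1)
    keep = np.flatnonzero(occupancy > n / 2)
    if keep.size == 0:
        raise ValueError(
            "no taxon occurs in more than half of the samples; "
            "review the prevalence threshold or the input table"
        )
    taxa = [t.taxon_ids[i] for i in keep]
    taxonomy = {k: t.taxonomy[k] for k in taxa} if t.taxonomy else None
    return CountTable(taxa, list(t.sample_ids), t.counts[keep], taxonomy=taxonomy)


# ---------------------------------------------------------------------------
# C-score and the SIM9 fixed-fixed null model
# ---------------------------------------------------------------------------


def c_score(p: PresenceMatrix) -> float:
    """Checkerboard score: mean over taxon pairs of (R_i - S_ij)(R_j - S_ij)."""
    m = p.matrix
    t = m.shape[0]
    if t < 2:
        raise ValueError("C-score needs at least 2 taxa")
    s = m @ m.T
    r = m.sum(axis=1)
    units = (r[:, None] - s) * (r[None, :] - s)
    iu = np.triu_indices(t, k=1)
    total = int(units[iu].sum())
    return total / (t * (t - 1) // 2)


def _sim9_inplace(m: np.ndarray, n_steps: int, rng: np.random.Generator) -> None:
    """Run ``n_steps`` swap attempts of the sequential SIM9 chain in place.

    Each attempt draws a random 2x2 submatrix; if it is a checkerboard its
    two columns are exchanged within those rows, preserving all margins.
    """
    t, s = m.shape
    if t < 2 or s < 2:
        return
    chunk = 1 << 15
    done = 0
    while done < n_steps:
        k = min(chunk, n_steps - done)
        rows = rng.integers(0, t, size=(k, 2)).tolist()
        cols = rng.integers(0, s, size=(k, 2)).tolist()
        for (r1, r2), (c1, c2) in zip(rows, cols):
            if r1 == r2 or c1 == c2:
                continue
            a = m[r1, c1]
            if a == m[r2, c2] and a != m[r1, c2] and m[r1, c2] == m[r2, c1]:
                m[r1, c1] = m[r2, c2] = 1 - a
                m[r1, c2] = m[r2, c1] = a
        done += k


def sim9_swap_chain(p: PresenceMatrix, n_steps: int,
                    seed: int | np.random.Generator | None = None) -> PresenceMatrix:
    """Return a margin-preserving randomization of ``p`` after ``n_steps``
    checkerboard-swap attempts (fixed-fixed / SIM9 null model)."""
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m = p.matrix.copy()
    _sim9_inplace(m, n_steps, rng)
    return PresenceMatrix(list(p.taxon_ids), list(p.sample_ids), m)


def _has_checkerboard(m: np.ndarray) -> bool:
    s = m @ m.T
    r = m.sum(axis=1)
    units = (r[:, None] - s) * (r[None, :] - s)
    np.fill_diagonal(units, 0)
    return bool((units > 0).any())


def cscore_null_test(p: PresenceMatrix, n_null: int = 1000,
                     burn_in: int | None = None, thin: int | None = None,
                     seed: int | None = None) -> NullModelResult:
    """Upper-tail (segregation) C-score test under the SIM9 null model.

    The null distribution is sampled along one swap chain: ``burn_in``
    attempts first (default 10x the number of presences), then one sample
    every ``thin`` attempts (default 1x the number of presences).
    p = (#{null >= observed} + 1) / (n_null + 1).
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    observed = c_score(p)
    nnz = int(p.matrix.sum())
    if burn_in is None:
        burn_in = 10 * nnz
    if thin is None:
        thin = max(1, nnz)
    if not _has_checkerboard(p.matrix):
        # no pair can segregate: the chain cannot move and the test is vacuous
        logger.warning("C-score null test is vacuous: matrix admits no checkerboard")
        return NullModelResult(observed, observed, 0.0, None, 1.0, n_null,
                               seed, burn_in, thin, vacuous=True)
    rng = np.random.default_rng(seed)
    m = p.matrix.copy()
    _sim9_inplace(m, burn_in, rng)
    tmp = PresenceMatrix(list(p.taxon_ids), list(p.sample_ids), m)
    null = np.empty(n_null)
    for k in range(n_null):
        _sim9_inplace(m, thin, rng)
        tmp.matrix = m
        null[k] = c_score(tmp)
    mean = float(null.mean())
    sd = float(null.std(ddof=1)) if n_null > 1 else 0.0
    ses = (observed - mean) / sd if sd > 0 else None
    p_value = (int((null >= observed - 1e-12).sum()) + 1) / (n_null + 1)
    return NullModelResult(observed, mean, sd, ses, p_value, n_null,
                           seed, burn_in, thin)


# ---------------------------------------------------------------------------
# Spearman edges and the network
# ---------------------------------------------------------------------------


def spearman_edges(t: AbundanceTable | CountTable, rho_threshold: float = 0.7,
                   alpha: float = 0.05) -> list[tuple[str, str, float, float]]:
    """Robust-correlation edge list: pairs with |rho| strictly > threshold
    and p < alpha.

    Ranks are scale-invariant, so counts and relative abundances give
    identical rho.  Constant taxa carry no rank information and are
    excluded (logged).  Exact permutation p-values are used for n <= 9.
    """
    if isinstance(t, CountTable):
        t = to_relative_abundance(t)
    n = len(t.sample_ids)
    if n < 4:
        raise ValueError("need at least 4 samples for correlation edges")
    ranks = np.apply_along_axis(stats.rankdata, 1, t.values)
    sd = ranks.std(axis=1)
    usable = np.flatnonzero(sd > 0)
    for i in np.flatnonzero(sd == 0):
        logger.warning("taxon %s is constant across samples; excluded from edges",
                       t.taxon_ids[i])
    z = ranks[usable] - ranks[usable].mean(axis=1, keepdims=True)
    z /= np.linalg.norm(z, axis=1, keepdims=True)
    rho = np.clip(z @ z.T, -1.0, 1.0)
    edges = []
    method = "exact" if n <= EXACT_MAX_N else "approx"
    for a in range(len(usable)):
        for b in range(a + 1, len(usable)):
            r = float(rho[a, b])
            if abs(r) > rho_threshold:
                i, j = usable[a], usable[b]
                r_chk, p = spearman(t.values[i], t.values[j], method=method)
                if p < alpha:
                    edges.append((t.taxon_ids[i], t.taxon_ids[j], r_chk, p))
    return edges


def build_network(edges, all_taxa=None) -> nx.Graph:
    """Assemble the co-occurrence network from a robust edge list.

    Nodes are the taxa incident to at least one edge (isolated taxa are
    dropped, so V varies with the data).  ``all_taxa`` is the optional
    universe used to validate edge endpoints.
    """
    g = nx.Graph()
    seen = set()
    universe = set(all_taxa) if all_taxa is not None else None
    for u, v, rho, p in edges:
        if u == v:
            raise ValueError(f"self-loop edge on taxon {u!r}")
        key = frozenset((u, v))
        if key in seen:
            raise ValueError(f"duplicate edge between {u!r} and {v!r}")
        seen.add(key)
        if universe is not None and (u not in universe or v not in universe):
            raise ValueError(f"edge endpoint outside the taxon universe: {u!r}-{v!r}")
        g.add_edge(u, v, weight=float(rho), sign=int(np.sign(rho)), p=float(p))
    return g


def network_properties(n: nx.Graph) -> NetworkProperties:
    """Summary properties of a co-occurrence network (V, E, density,
    clustering, greedy modularity, mean shortest path on the largest
    component)."""
    v = n.number_of_nodes()
    e = n.number_of_edges()
    if v == 0:
        return NetworkProperties(0, 0)
    density = 2 * e / (v * (v - 1)) if v > 1 else 0.0
    mean_degree = 2 * e / v
    clustering = nx.transitivity(n)
    modularity = None
    n_modules = None
    if e > 0:
        comms = list(nx_community.greedy_modularity_communities(n, weight=None))
        modularity = nx_community.modularity(n, comms, weight=None)
        n_modules = len(comms)
    mean_path = None
    if v > 1:
        giant = n.subgraph(max(nx.connected_components(n), key=len))
        if giant.number_of_nodes() > 1:
            mean_path = nx.average_shortest_path_length(giant)
    return NetworkProperties(v, e, density, mean_degree, clustering,
                             modularity, n_modules, mean_path)


# ---------------------------------------------------------------------------
# Erdos-Renyi G(n, M) ensemble
# ---------------------------------------------------------------------------


def sample_gnm(v: int, e: int, rng: np.random.Generator) -> np.ndarray:
    """One uniform draw from G(n=v, M=e): an (e, 2) array of edges."""
    max_e = v * (v - 1) // 2
    if v < 2:
        raise ValueError("need at least 2 nodes")
    if not 0 <= e <= max_e:
        raise ValueError(f"edge count {e} outside [0, {max_e}]")
    iu, ju = np.triu_indices(v, k=1)
    idx = rng.choice(max_e, size=e, replace=False)
    return np.column_stack((iu[idx], ju[idx]))


def _ig_properties(v: int, edges: np.ndarray) -> tuple[float, float, float]:
    g = ig.Graph(n=v, edges=edges.tolist())
    clustering = g.transitivity_undirected(mode="zero")
    comps = g.connected_components()
    giant = comps.giant()
    path = giant.average_path_length() if giant.vcount() > 1 else np.nan
    if g.ecount() > 0:
        modularity = g.community_fastgreedy().as_clustering().modularity
    else:
        modularity = np.nan
    return clustering, path, modularity


def _empirical_two_tailed(null: np.ndarray, observed: float) -> float:
    null = null[~np.isnan(null)]
    n = null.size
    if n == 0:
        return 1.0
    ge = int((null >= observed - 1e-12).sum()) + 1
    le = int((null <= observed + 1e-12).sum()) + 1
    return min(1.0, 2 * min(ge, le) / (n + 1))


def er_ensemble_compare(props: NetworkProperties, n_random: int = 10000,
                        seed: int | None = None) -> dict[str, NullModelResult]:
    """Compare observed network properties against G(V, E) random graphs.

    Draws ``n_random`` Erdos-Renyi graphs with the same node and edge
    counts, computes clustering, mean path length (largest component) and
    greedy modularity for each, and reports SES and a two-tailed empirical
    p per property.
    """
    v, e = props.V, props.E
    if v < 2:
        raise ValueError("need at least 2 nodes for an ER comparison")
    if not 0 <= e <= v * (v - 1) // 2:
        raise ValueError("edge count exceeds the simple-graph maximum")
    rng = np.random.default_rng(seed)
    draws = np.empty((n_random, 3))
    for k in range(n_random):
        draws[k] = _ig_properties(v, sample_gnm(v, e, rng))
    names = ("clustering", "mean_path_length", "modularity")
    observed = (props.clustering, props.mean_path_length, props.modularity)
    out = {}
    for col, (name, obs) in enumerate(zip(names, observed)):
        null = draws[:, col]
        valid = null[~np.isnan(null)]
        mean = float(valid.mean()) if valid.size else np.nan
        sd = float(valid.std(ddof=1)) if valid.size > 1 else 0.0
        if obs is None or np.isnan(mean):
            out[name] = NullModelResult(np.nan, mean, sd, None, 1.0,
                                        n_random, seed)
            continue
        ses = (obs - mean) / sd if sd > 0 else None
        out[name] = NullModelResult(float(obs), mean, sd, ses,
                                    _empirical_two_tailed(valid, obs),
                                    n_random, seed)
    return out


# ---------------------------------------------------------------------------
# Node annotation
# ---------------------------------------------------------------------------


def annotate_nodes(n: nx.Graph, categories: list[ResponseCategory]) -> nx.Graph:
    """Set each node's "category" and "color" attributes from response
    categories; taxa without a category become "neutral".  Categories for
    taxa absent from the network are ignored with a notice."""
    nx.set_node_attributes(n, "neutral", "category")
    for cat in categories:
        if cat.taxon_id not in n:
            logger.info("category for %s ignored: taxon not in network",
                        cat.taxon_id)
            continue
        n.nodes[cat.taxon_id]["category"] = cat.category
    for node, data in n.nodes(data=True):
        data["color"] = CATEGORY_COLORS.get(data["category"], "grey")
    return n
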