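"""One-mode projection of the infection matrix onto hosts, and the
pairwise / neighborhood statistics defined on it.

In the projection, phage-permissive bacteria are nodes and two hosts are
linked iff at least one phage infects both; the edge weight w(u, v) counts
the phages that do. Shared-phage means are taken over *all* host pairs
H(H-1)/2, with zero-weight pairs contributing zero, and standard deviations
use the n-1 denominator. These conventions matter: they are what make the
pair means comparable across strata of different connectance.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Sequence

import networkx as nx
import numpy as np
from scipy import stats as sps

from .matrix_core import HostRecord, IncidenceMatrix, align_metadata

__all__ = [
    "project",
    "pair_shared_stats",
    "neighbor_stats",
    "species_network",
    "RankSumResult",
    "rank_sum_test",
]


def project(
    m: IncidenceMatrix, hosts: Sequence[HostRecord] | None = None
) -> nx.Graph:
    """Weighted one-mode host graph from an incidence matrix.

    The caller is expected to restrict the matrix to phage-permissive hosts
    first (see :func:`phagenet.matrix_core.drop_uninfected_hosts`). Isolated
    hosts remain as nodes. Graph-level attributes record the pair count
    H(H-1)/2, the number of connected pairs, the projection connectance and
    the number of phages that link at least one host pair.
    """
    a = m.entries.astype(np.int64)
    w = a @ a.T
    h = m.n_hosts
    g = nx.Graph()
    if hosts is not None:
        index = align_metadata(m, hosts, "host")
        g.add_nodes_from((hid, {"record": index[hid]}) for hid in m.host_ids)
    else:
        g.add_nodes_from(m.host_ids)
    iu, ju = np.triu_indices(h, k=1)
    linked = w[iu, ju] > 0
    g.add_weighted_edges_from(
        (m.host_ids[i], m.host_ids[j], int(w[i, j]))
        for i, j in zip(iu[linked], ju[linked])
    )
    n_pairs = h * (h - 1) // 2
    n_interactions = int(linked.sum())
    g.graph["H"] = h
    g.graph["n_pairs"] = n_pairs
    g.graph["n_interactions"] = n_interactions
    g.graph["connectance"] = n_interactions / n_pairs if n_pairs else float("nan")
    g.graph["n_linking_phages"] = int((m.phage_degrees() >= 2).sum())
    return g


def _weight(g: nx.Graph, u: str, v: str) -> int:
    data = g.get_edge_data(u, v)
    return int(data["weight"]) if data else 0


def _record(g: nx.Graph, u: str) -> HostRecord:
    rec = g.nodes[u].get("record")
    if rec is None:
        raise ValueError(f"node {u!r} carries no HostRecord metadata")
    return rec


def _stats(values: list[int]) -> dict:
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        return {"mean": float("nan"), "sd": float("nan"), "n": 0, "max": None}
    return {
        "mean": float(arr.mean()),
        "sd": float(arr.std(ddof=1)) if arr.size > 1 else float("nan"),
        "n": int(arr.size),
        "max": int(arr.max()),
    }


def pair_shared_stats(g: nx.Graph, grouping: str = "overall") -> dict:
    """Shared-phage statistics over all host pairs, stratified.

    ``grouping`` is one of ``overall``, ``species``, ``species_group``,
    ``biome`` or ``resistance_pairing``. Every stratum reports mean, n-1 sd,
    n and max (with the attaining pair under ``max_pair`` for the overall
    stratum). Strata of a disjoint grouping partition the H(H-1)/2 pairs.

    ``resistance_pairing`` buckets pairs as both-susceptible, both-resistant
    (pooling resistant and MDR) or mixed.
    """
    nodes = list(g.nodes)
    strata: dict[str, list[int]] = {}
    max_pair = (None, -1)
    for u, v in combinations(nodes, 2):
        w = _weight(g, u, v)
        if w > max_pair[1]:
            max_pair = ((u, v), w)
        if grouping == "overall":
            keys = ["overall"]
        elif grouping == "species":
            ru, rv = _record(g, u), _record(g, v)
            keys = ["same_species" if ru.species == rv.species else "different_species"]
        elif grouping == "species_group":
            ru, rv = _record(g, u), _record(g, v)
            keys = [
                "same_species_group"
                if ru.species_group == rv.species_group
                else "different_species_group"
            ]
        elif grouping == "biome":
            ru, rv = _record(g, u), _record(g, v)
            same = ru.biome == rv.biome
            keys = ["same_biome" if same else "different_biome"]
            keys.append("+".join(sorted((ru.biome, rv.biome))))
        elif grouping == "resistance_pairing":
            ru, rv = _record(g, u), _record(g, v)
            drug = [r.resistance in ("resistant", "MDR") for r in (ru, rv)]
            if not any(drug):
                keys = ["both_susceptible"]
            elif all(drug):
                keys = ["both_resistant"]
            else:
                keys = ["mixed"]
        else:
            raise ValueError(f"unknown grouping {grouping!r}")
        for key in keys:
            strata.setdefault(key, []).append(w)
    out = {key: _stats(vals) for key, vals in strata.items()}
    if grouping == "overall":
        out["overall"]["max_pair"] = max_pair[0]
    return out


def neighbor_stats(
    g: nx.Graph,
    neighbor_filter: Callable[[HostRecord, HostRecord], bool] | None = None,
    focal_filter: Callable[[HostRecord], bool] | None = None,
    mode: str = "strains",
) -> dict:
    """Per-host neighbor counts and their aggregate mean +- sd.

    ``mode="strains"`` counts direct neighbors (nodes joined by an edge);
    ``mode="species"`` counts distinct species among them. ``neighbor_filter``
    restricts which neighbors count, given the focal and neighbor records
    (e.g. neighbors from another biome, or drug-susceptible neighbors);
    ``focal_filter`` restricts which hosts are reported (e.g. drug-resistant
    focal hosts only).
    """
    if mode not in ("strains", "species"):
        raise ValueError(f"unknown mode {mode!r}")
    per_host: dict[str, int] = {}
    for u in g.nodes:
        if focal_filter is not None and not focal_filter(_record(g, u)):
            continue
        neigh = list(g.neighbors(u))
        if neighbor_filter is not None:
            ru = _record(g, u)
            neigh = [v for v in neigh if neighbor_filter(ru, _record(g, v))]
        if mode == "strains":
            per_host[u] = len(neigh)
        else:
            per_host[u] = len({_record(g, v).species for v in neigh})
    agg = _stats(list(per_host.values()))
    if per_host:
        agg["argmax"] = max(per_host, key=per_host.get)
    return {"per_host": per_host, **agg}


def species_network(
    g: nx.Graph,
    m: IncidenceMatrix,
    hosts: Sequence[HostRecord],
    threshold: int = 20,
    strain_pair_weights: bool = False,
) -> nx.Graph:
    """Collapse the host projection to a species-level weighted graph.

    Edge weight between species S and T is the number of *distinct* phages
    infecting at least one strain of each (or, with
    ``strain_pair_weights=True``, the sum of strain-pair shared counts).
    Node attribute ``mean_neighbors`` is the average strain-neighbor count
    over the species' strains; edges above ``threshold`` shared phages carry
    ``flagged=True``.
    """
    index = align_metadata(m, hosts, "host")
    species = sorted({index[h].species for h in m.host_ids})
    species_rows = {
        s: np.array([i for i, h in enumerate(m.host_ids) if index[h].species == s])
        for s in species
    }
    per_host_neigh = neighbor_stats(g)["per_host"]
    sg = nx.Graph()
    for s in species:
        strains = [m.host_ids[i] for i in species_rows[s]]
        counts = [per_host_neigh.get(h, 0) for h in strains]
        sg.add_node(
            s,
            n_strains=len(strains),
            mean_neighbors=float(np.mean(counts)) if counts else 0.0,
        )
    a = m.entries
    for s, t in combinations(species, 2):
        hits_s = a[species_rows[s], :].any(axis=0)
        hits_t = a[species_rows[t], :].any(axis=0)
        if strain_pair_weights:
            w = int(
                (a[species_rows[s], :].astype(np.int64) @ a[species_rows[t], :].T).sum()
            )
        else:
            w = int((hits_s & hits_t).sum())
        if w > 0:
            sg.add_edge(s, t, weight=w, flagged=w > threshold)
    return sg


@dataclass(frozen=True)
class RankSumResult:
    W: float  # rank sum of sample 1 minus n1(n1+1)/2 (Mann-Whitney U1)
    p: float
    method: str  # "exact" or "normal_approximation"
    degenerate: bool = False


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test.

    W is the sum of midranks of ``x`` in the pooled sample minus
    n1(n1+1)/2, so 0 <= W <= n1*n2. The p-value comes from the exact
    conditional distribution when it is cheap to have: the tie-free exact
    distribution for samples below 50 observations each, or full
    enumeration of rank assignments (midranks, so ties are handled) for
    pooled sizes up to 12. Larger samples use the normal approximation with
    tie-corrected variance and a 0.5 continuity correction. When every
    pooled value is identical the variance is degenerate and p = 1 is
    returned flagged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    w = float(ranks[: x.size].sum() - x.size * (x.size + 1) / 2)
    if np.unique(pooled).size == 1:
        return RankSumResult(W=w, p=1.0, method="degenerate", degenerate=True)
    has_ties = np.unique(pooled).size < pooled.size
    if not has_ties and x.size < 50 and y.size < 50:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return RankSumResult(W=w, p=float(res.pvalue), method="exact")
    if pooled.size <= 12:
        # exact conditional permutation distribution under ties
        offset = x.size * (x.size + 1) / 2
        null = np.array(
            [
                ranks[list(idx)].sum() - offset
                for idx in combinations(range(pooled.size), x.size)
            ]
        )
        lower = float((null <= w).mean())
        upper = float((null >= w).mean())
        return RankSumResult(W=w, p=min(1.0, 2 * min(lower, upper)), method="exact")
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return RankSumResult(W=w, p=float(res.pvalue), method="normal_approximation")
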