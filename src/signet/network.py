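"""Network layer: differential-protein calling, transcription-factor-rooted
sub-network extraction, network-based pathway over-representation with
regulator attribution, pathway overlap coefficients, and the seed-gene
proximity test with an empirical null.

Sub-network extraction follows the rule: for every target reachable from a
transcription factor in the directed signaling network, keep a minimum-length
directed path, and among all minimum-length paths choose the one passing
through the largest number of differentially expressed intermediate nodes
(exact maximization by dynamic programming over the shortest-path DAG, ties
broken by lexicographically smallest node sequence).  The sub-network is the
union of the chosen paths.

The proximity test measures the shortest-path distance from a seed gene (the
disease gene) to the nearest member of a pathway in an undirected
physical-interaction network, and compares it with the same statistic for
randomly sampled network genes; the empirical p is the plain proportion of
random genes at least as close as the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .covariates import bh_adjust
from .io_formats import ExpressionDataset, GeneSetCollection, InteractionNetwork

logger = logging.getLogger("signet")


@dataclass
class SubNetwork:
    regulator: str
    nodes: set[str]
    edges: set[tuple[str, str]]
    paths: dict[str, tuple[str, ...]]  # target -> chosen path (tf ... target)
    unreachable: list[str]
    n_de_nodes: int


@dataclass
class ProximityResult:
    seed_gene: str
    pathway_name: str
    observed_distance: float
    null_distances: np.ndarray
    p_value: float
    seed: int


# ---------------------------------------------------------------------------
# Differential proteins
# ---------------------------------------------------------------------------


def differential_proteins(
    dataset: ExpressionDataset, alpha: float = 0.05
) -> tuple[set[str], pd.DataFrame]:
    """Welch t-test on log2 values per protein, BH across the whole assay.

    Returns the differentially expressed gene symbols (mapped symbols of
    proteins with q < alpha) and the per-protein table.  Constant proteins
    get p = 1 (logged).
    """
    ctrl = np.log2(dataset.values[dataset.class_mask("control")])
    aff = np.log2(dataset.values[dataset.class_mask("affected")])
    if len(ctrl) == 0 or len(aff) == 0:
        raise ValueError("both classes must be present")
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(aff, ctrl, axis=0, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    n_degenerate = int(np.isnan(p).sum())
    if n_degenerate:
        logger.info("%d protein(s) with degenerate variance set to p = 1", n_degenerate)
    p = np.where(np.isnan(p), 1.0, p)
    q = bh_adjust(p)
    table = pd.DataFrame(
        {
            "protein_id": dataset.protein_ids,
            "log2_fc": aff.mean(axis=0) - ctrl.mean(axis=0),
            "p_value": p,
            "q_value": q,
        }
    )
    de_ids = [pid for pid, qq in zip(dataset.protein_ids, q) if qq < alpha]
    return set(dataset.genes_for(de_ids)), table


# ---------------------------------------------------------------------------
# TF-rooted sub-networks
# ---------------------------------------------------------------------------


def tf_subnetwork(
    network: InteractionNetwork,
    tf: str,
    targets,
    de_set,
) -> SubNetwork:
    """Union over targets of the DE-preferring minimum-length path from a TF."""
    tf = str(tf).upper()
    if tf not in network.nodes:
        raise ValueError(f"transcription factor {tf!r} absent from network")
    if not network.directed:
        raise ValueError("tf_subnetwork requires a directed signaling network")
    g = network.to_networkx()
    de = {str(d).upper() for d in de_set}
    targets = [str(t).upper() for t in targets]

    dist = nx.single_source_shortest_path_length(g, tf)
    # dynamic programming over the shortest-path DAG, processed by BFS layer:
    # score[v] = max DE nodes strictly between tf and v; path[v] = the
    # lexicographically smallest max-score path
    score: dict[str, int] = {tf: 0}
    path: dict[str, tuple[str, ...]] = {tf: (tf,)}
    by_layer: dict[int, list[str]] = {}
    for v, d in dist.items():
        by_layer.setdefault(d, []).append(v)
    for d in sorted(by_layer):
        if d == 0:
            continue
        for v in sorted(by_layer[d]):
            best: tuple[int, tuple[str, ...]] | None = None
            for u in g.predecessors(v):
                if dist.get(u, -1) != d - 1:
                    continue
                cand_score = score[u] + (1 if (u != tf and u in de) else 0)
                cand_path = path[u] + (v,)
                if best is None or (cand_score, _neg_lex(cand_path)) > (best[0], _neg_lex(best[1])):
                    best = (cand_score, cand_path)
            score[v], path[v] = best[0], best[1]

    nodes: set[str] = set()
    edges: set[tuple[str, str]] = set()
    chosen: dict[str, tuple[str, ...]] = {}
    unreachable: list[str] = []
    for t in targets:
        if t == tf:
            continue
        if t not in dist:
            unreachable.append(t)
            continue
        p = path[t]
        chosen[t] = p
        nodes.update(p)
        edges.update(zip(p[:-1], p[1:]))
    if unreachable:
        logger.info("TF %s: %d unreachable target(s)", tf, len(unreachable))
    return SubNetwork(
        regulator=tf,
        nodes=nodes,
        edges=edges,
        paths=chosen,
        unreachable=unreachable,
        n_de_nodes=len(nodes & de),
    )


class _neg_lex:
    """Order-reversing wrapper so that max() picks the lexicographically
    smallest path among equal scores."""

    __slots__ = ("t",)

    def __init__(self, t: tuple[str, ...]) -> None:
        self.t = t

    def __lt__(self, other: "_neg_lex") -> bool:
        return self.t > other.t

    def __gt__(self, other: "_neg_lex") -> bool:
        return self.t < other.t

    def __eq__(self, other: object) -> bool:
        return isinstance(other, _neg_lex) and self.t == other.t


# ---------------------------------------------------------------------------
# Regulator ranking (network-based pathway over-representation)
# ---------------------------------------------------------------------------


def rank_regulators(
    network: InteractionNetwork,
    tf_list,
    targets,
    de_set,
    collection: GeneSetCollection,
    background=None,
) -> pd.DataFrame:
    """Attribute each BH-significant pathway to its most significant regulator.

    Each TF's sub-network gene set is tested against each pathway with a
    one-sided Fisher exact test over the network gene universe; BH is applied
    across all (TF, pathway) tests; every pathway with q < 0.05 is reported
    once, attributed to the TF with the smallest raw p (ties by TF name).
    Rows are sorted by p.  The output is invariant to the order of tf_list
    and of the collection.
    """
    tf_list = sorted({str(t).upper() for t in tf_list})
    if not tf_list:
        raise ValueError("tf_list is empty")
    background = set(
        str(g).upper() for g in (background if background is not None else network.nodes)
    )
    subnets: dict[str, SubNetwork] = {}
    for tf in tf_list:
        try:
            sn = tf_subnetwork(network, tf, targets, de_set)
        except ValueError:
            logger.warning("TF %s absent from network; skipped", tf)
            continue
        if sn.nodes:
            subnets[tf] = sn
    if not subnets:
        raise ValueError("no transcription factor reaches any target")

    tests = []
    N = len(background)
    for tf, sn in sorted(subnets.items()):
        genes = sn.nodes & background
        n = len(genes)
        for name in sorted(collection.names()):
            members = collection[name] & background
            K = len(members)
            if K == 0:
                continue
            overlap = sorted(genes & members)
            k = len(overlap)
            p = float(stats.hypergeom.sf(k - 1, N, K, n))
            tests.append(
                {
                    "regulator": tf,
                    "subnetwork_size": len(sn.nodes),
                    "pathway": name,
                    "overlap": k,
                    "overlap_genes": ",".join(overlap),
                    "p_value": p,
                }
            )
    df = pd.DataFrame(tests)
    if df.empty:
        return pd.DataFrame(
            columns=["regulator", "subnetwork_size", "pathway", "overlap", "overlap_genes", "p_value", "q_value"]
        )
    df["q_value"] = bh_adjust(df["p_value"].to_numpy())
    rows = []
    for name, grp in df.groupby("pathway"):
        if grp["q_value"].min() >= 0.05:
            continue
        best = grp.sort_values(["p_value", "regulator"], kind="stable").iloc[0]
        rows.append(best)
    if not rows:
        return df.iloc[0:0]
    out = pd.DataFrame(rows).sort_values(["p_value", "pathway"], kind="stable").reset_index(drop=True)
    return out


def pathway_overlap_coefficient(set_a, set_b) -> tuple[float, int]:
    """Overlap coefficient |A & B| / min(|A|, |B|) and the shared-gene count."""
    a = {str(g).upper() for g in set_a}
    b = {str(g).upper() for g in set_b}
    if not a or not b:
        raise ValueError("overlap coefficient of an empty set is undefined")
    shared = len(a & b)
    return shared / min(len(a), len(b)), shared


# ---------------------------------------------------------------------------
# Seed-gene proximity with empirical null
# ---------------------------------------------------------------------------


def proximity_empirical_p(
    ppi: InteractionNetwork,
    seed_gene: str,
    pathway_genes,
    n_random: int = 1000,
    rng_seed: int = 0,
    pathway_name: str = "",
    exclude_pathway: bool = False,
    plus_one: bool = False,
) -> ProximityResult:
    """Minimal shortest-path distance from a seed gene to a pathway, with an
    empirical null from uniformly sampled network genes.

    d_obs = min over in-network pathway genes of the unweighted shortest-path
    length from the seed; the null repeats the statistic for ``n_random``
    genes sampled without replacement from the network nodes excluding the
    seed (and optionally the pathway).  Unreachable genes get distance
    +infinity.  p = #{null <= d_obs} / n_random (a +1 correction is optional).
    """
    if ppi.directed:
        raise ValueError("proximity analysis requires an undirected network")
    seed_gene = str(seed_gene).upper()
    if seed_gene not in ppi.nodes:
        raise ValueError(f"seed gene {seed_gene!r} absent from network")
    pathway = {str(g).upper() for g in pathway_genes} & ppi.nodes
    if not pathway:
        raise ValueError("no pathway gene present in the network")
    g = ppi.to_networkx()
    # one multi-source BFS from the pathway gives every node's distance to it
    dist = nx.multi_source_dijkstra_path_length(g, pathway, weight=None)
    d_obs = float(dist.get(seed_gene, np.inf))

    candidates = sorted(ppi.nodes - {seed_gene} - (pathway if exclude_pathway else set()))
    rng = np.random.default_rng(rng_seed)
    size = min(n_random, len(candidates))
    sampled = rng.choice(len(candidates), size=size, replace=False)
    null = np.array([float(dist.get(candidates[i], np.inf)) for i in sampled])
    hits = float((null <= d_obs).sum())
    p = (hits + 1.0) / (size + 1.0) if plus_one else hits / size
    return ProximityResult(
        seed_gene=seed_gene,
        pathway_name=pathway_name,
        observed_distance=d_obs,
        null_distances=null,
        p_value=float(p),
        seed=rng_seed,
    )
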