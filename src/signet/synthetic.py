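"""Synthetic cohorts, networks, gene sets and tissue tables with ground truth.

The generators emulate the statistical structure of an aptamer-based
case/control serum-proteomics study: ~1100 log-normal analytes measured in two
age-matched groups, a planted subset of differentially abundant proteins, an
age-dependent decline present in affected subjects only, and a treated
subgroup effect.  Every generator is deterministic under a fixed seed and
returns (or updates) a :class:`SyntheticTruth` record so that downstream
recovery can be tested without any external data.

Model for the abundance of protein *j* in subject *i* (log2 scale)::

    log2 y_ij = b_j                                  # per-protein baseline
              + affected_i * e_j                     # planted class effect
              + affected_i * s_j * (age_i - mid)     # age decline, cases only
              + treated_i  * t_j                     # steroid-like shift
              + N(0, sd_j)                           # residual noise

Six "strong" markers carry non-overlapping class distributions (|e_j| at
least six within-group standard deviations) and are placed at rank-extreme
baselines — three far above and three far below the 8–12 log2 band of the
other proteins — emulating muscle-leakage analytes (creatine-kinase-like)
whose serum levels in cases dwarf everything else on the panel.  That
placement is what makes per-subject rank signatures of length two sufficient
for classification, mirroring the six-protein panel the classifier is
expected to find.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np

from .io_formats import (
    ExpressionDataset,
    GeneSetCollection,
    InteractionNetwork,
    TissueExpressionTable,
)

logger = logging.getLogger("signet")


@dataclass
class CohortConfig:
    """Parameters of the synthetic case/control cohort.

    Defaults reproduce the study design the pipeline targets: 42 affected and
    28 control subjects, 1128 analytes, 52 planted differential proteins of
    which 6 are "strong", 31 age-associated markers (two increasing with age,
    the rest declining), and 32 treatment-associated markers among the 28
    treated affected subjects.
    """

    n_control: int = 28
    n_affected: int = 42
    n_proteins: int = 1128
    n_markers: int = 52
    effect_sizes: tuple[float, float] = (1.0, 2.5)  # |log2 shift| range
    n_strong_markers: int = 6
    baseline_mean_log2: tuple[float, float] = (8.0, 12.0)
    baseline_sd_log2: tuple[float, float] = (0.3, 0.8)
    age_range_years: tuple[float, float] = (4.0, 15.0)
    n_age_markers: int = 31
    age_slope_log2_per_year: tuple[float, float] = (-0.30, -0.08)
    treated_fraction_of_affected: float = 28 / 42
    n_treatment_markers: int = 32
    treatment_shift_log2: tuple[float, float] = (0.6, 1.5)
    seed: int = 0

    def validate(self) -> None:
        if not (self.n_strong_markers <= self.n_markers <= self.n_proteins):
            raise ValueError("need n_strong_markers <= n_markers <= n_proteins")
        if self.n_age_markers > self.n_markers:
            raise ValueError("n_age_markers exceeds n_markers")
        if self.n_treatment_markers > self.n_markers:
            raise ValueError("n_treatment_markers exceeds n_markers")
        if not 0.0 <= self.treated_fraction_of_affected <= 1.0:
            raise ValueError("treated_fraction_of_affected outside [0, 1]")
        if min(self.n_control, self.n_affected) < 1:
            raise ValueError("both classes need at least one subject")


@dataclass
class SyntheticTruth:
    """Ground-truth record of everything the generators planted."""

    marker_ids: list[str] = field(default_factory=list)
    strong_marker_ids: list[str] = field(default_factory=list)
    effects: dict[str, float] = field(default_factory=dict)  # assay id -> signed log2 shift
    age_marker_ids: list[str] = field(default_factory=list)
    age_slopes: dict[str, float] = field(default_factory=dict)
    treatment_marker_ids: list[str] = field(default_factory=list)
    treatment_shifts: dict[str, float] = field(default_factory=dict)
    marker_genes: list[str] = field(default_factory=list)
    strong_marker_genes: list[str] = field(default_factory=list)
    planted_regulator_tf: str | None = None
    planted_pathway_name: str | None = None
    planted_pathway_genes: list[str] = field(default_factory=list)
    planted_seed_gene: str | None = None
    planted_seed_distance: int | None = None
    de_intermediate_genes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "marker_ids": self.marker_ids,
            "strong_marker_ids": self.strong_marker_ids,
            "effects": self.effects,
            "age_marker_ids": self.age_marker_ids,
            "age_slopes": self.age_slopes,
            "treatment_marker_ids": self.treatment_marker_ids,
            "treatment_shifts": self.treatment_shifts,
            "marker_genes": self.marker_genes,
            "strong_marker_genes": self.strong_marker_genes,
            "planted_regulator_tf": self.planted_regulator_tf,
            "planted_pathway_name": self.planted_pathway_name,
            "planted_pathway_genes": self.planted_pathway_genes,
            "planted_seed_gene": self.planted_seed_gene,
            "planted_seed_distance": self.planted_seed_distance,
            "de_intermediate_genes": self.de_intermediate_genes,
        }


# Rank-extreme placement of the strong markers: (baseline log2, effect sign).
# Two high-baseline decliners alternate as the control top-of-ranking, one
# high riser tops every case ranking, two low-baseline risers alternate as the
# control bottom, one low decliner bottoms every case ranking.
_STRONG_TEMPLATE: tuple[tuple[float, int], ...] = (
    (16.0, -1),
    (15.75, -1),
    (15.0, +1),
    (3.75, +1),
    (4.0, +1),
    (5.5, -1),
)
_STRONG_SD = 0.3


def generate_cohort(config: CohortConfig) -> tuple[ExpressionDataset, SyntheticTruth]:
    """Generate a cohort per :class:`CohortConfig` and its ground-truth record.

    Ages are drawn identically for both classes (age-matched design) and the
    age contribution is centred at the midpoint of the age range, so the
    planted class effect equals the expected class-mean difference of log2
    levels (up to the treated-subgroup contribution recorded in the truth).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_sub = config.n_control + config.n_affected
    n_prot = config.n_proteins

    protein_ids = [f"A{j + 1:04d}" for j in range(n_prot)]
    gene_symbols = [f"G{j + 1:04d}" for j in range(n_prot)]

    # --- marker layout ---------------------------------------------------
    marker_idx = np.sort(rng.choice(n_prot, size=config.n_markers, replace=False))
    strong_idx = np.sort(rng.choice(marker_idx, size=config.n_strong_markers, replace=False))
    regular_idx = np.array([j for j in marker_idx if j not in set(strong_idx)], dtype=int)

    # Age/treatment markers live among the regular markers so that the strong
    # markers keep their non-overlapping class supports.
    age_pool = regular_idx if len(regular_idx) >= config.n_age_markers else marker_idx
    age_idx = np.sort(rng.choice(age_pool, size=config.n_age_markers, replace=False))
    trt_pool = regular_idx if len(regular_idx) >= config.n_treatment_markers else marker_idx
    trt_idx = np.sort(rng.choice(trt_pool, size=config.n_treatment_markers, replace=False))

    # --- per-protein parameters ------------------------------------------
    baseline = rng.uniform(*config.baseline_mean_log2, size=n_prot)
    sd = rng.uniform(*config.baseline_sd_log2, size=n_prot)
    effect = np.zeros(n_prot)
    lo, hi = config.effect_sizes
    effect[regular_idx] = rng.uniform(lo, hi, size=len(regular_idx)) * rng.choice(
        [-1.0, 1.0], size=len(regular_idx)
    )
    for i, j in enumerate(strong_idx):
        base, sign = _STRONG_TEMPLATE[i % len(_STRONG_TEMPLATE)]
        baseline[j] = base + 0.1 * (i // len(_STRONG_TEMPLATE))
        sd[j] = _STRONG_SD
        effect[j] = sign * max(hi, 6.0 * _STRONG_SD)

    slope = np.zeros(n_prot)
    s_lo, s_hi = config.age_slope_log2_per_year
    slope[age_idx] = rng.uniform(s_lo, s_hi, size=len(age_idx))
    if len(age_idx) > 2:
        # with two exceptions the age-associated proteins decline with age
        exceptions = rng.choice(age_idx, size=2, replace=False)
        slope[exceptions] = -slope[exceptions]

    shift = np.zeros(n_prot)
    t_lo, t_hi = config.treatment_shift_log2
    shift[trt_idx] = rng.uniform(t_lo, t_hi, size=len(trt_idx)) * rng.choice(
        [-1.0, 1.0], size=len(trt_idx)
    )

    # --- subjects ---------------------------------------------------------
    labels = np.array(
        ["control"] * config.n_control + ["affected"] * config.n_affected, dtype=object
    )
    ages = rng.uniform(*config.age_range_years, size=n_sub)
    age_mid = 0.5 * (config.age_range_years[0] + config.age_range_years[1])
    affected = (labels == "affected").astype(float)
    n_treated = int(round(config.treated_fraction_of_affected * config.n_affected))
    treated = np.zeros(n_sub, dtype=bool)
    aff_positions = np.flatnonzero(labels == "affected")
    treated[rng.choice(aff_positions, size=n_treated, replace=False)] = True

    log2_vals = (
        baseline[None, :]
        + affected[:, None] * effect[None, :]
        + (affected * (ages - age_mid))[:, None] * slope[None, :]
        + treated.astype(float)[:, None] * shift[None, :]
        + rng.normal(0.0, 1.0, size=(n_sub, n_prot)) * sd[None, :]
    )
    values = np.exp2(log2_vals)

    # Structural quirks of real aptamer panels, planted among non-markers:
    # two multi-gene analytes and one analyte with no annotation.
    gene_map = {pid: [gene_symbols[j]] for j, pid in enumerate(protein_ids)}
    non_marker = [j for j in range(n_prot) if j not in set(marker_idx)]
    if len(non_marker) >= 3:
        m1, m2, unmapped = non_marker[0], non_marker[1], non_marker[2]
        gene_map[protein_ids[m1]] = [gene_symbols[m1], gene_symbols[m1] + "B"]
        gene_map[protein_ids[m2]] = [gene_symbols[m2], gene_symbols[m2] + "B"]
        gene_map[protein_ids[unmapped]] = []

    dataset = ExpressionDataset(
        subject_ids=[f"S{i + 1:03d}" for i in range(n_sub)],
        protein_ids=protein_ids,
        values=values,
        gene_map=gene_map,
        class_labels=labels,
        ages=ages,
        treated=treated,
    )
    truth = SyntheticTruth(
        marker_ids=[protein_ids[j] for j in marker_idx],
        strong_marker_ids=[protein_ids[j] for j in strong_idx],
        effects={protein_ids[j]: float(effect[j]) for j in marker_idx},
        age_marker_ids=[protein_ids[j] for j in age_idx],
        age_slopes={protein_ids[j]: float(slope[j]) for j in age_idx},
        treatment_marker_ids=[protein_ids[j] for j in trt_idx],
        treatment_shifts={protein_ids[j]: float(shift[j]) for j in trt_idx},
        marker_genes=[gene_symbols[j] for j in marker_idx],
        strong_marker_genes=[gene_symbols[j] for j in strong_idx],
    )
    return dataset, truth


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------


def generate_network(
    n_nodes: int = 500,
    n_tfs: int = 20,
    mean_degree: float = 4.0,
    truth_markers: Sequence[str] = (),
    n_de_intermediates: int = 12,
    seed: int = 0,
    truth: SyntheticTruth | None = None,
    universe: Sequence[str] | None = None,
    seed_gene: str = "DMD",
    pathway_size: int = 15,
) -> tuple[InteractionNetwork, InteractionNetwork, SyntheticTruth]:
    """Generate a directed signaling network and an undirected physical copy.

    The topology is preferential-attachment (heavy-tailed, connected); edges
    of the directed copy are oriented from lower to higher attachment index so
    that early hubs act as upstream regulators.  One designated transcription
    factor (the planted regulator) is wired to every truth marker through
    length-2 paths whose intermediates are flagged differentially expressed,
    alongside decoy length-2 paths through non-DE nodes.  The undirected copy
    additionally plants a seed gene whose shortest distance to a designated
    pathway is recorded in the truth.

    Returns ``(signaling, physical, truth)``; the truth record is updated in
    place when one is passed in.
    """
    if n_tfs >= n_nodes:
        raise ValueError("n_tfs must be smaller than n_nodes")
    m = int(round(mean_degree / 2.0))
    if m < 1 or m >= n_nodes:
        raise ValueError(f"infeasible degree/size combination: mean_degree={mean_degree}, n_nodes={n_nodes}")
    truth = truth if truth is not None else SyntheticTruth()
    rng = np.random.default_rng(seed)

    markers = [str(g).upper() for g in truth_markers]
    if universe is not None:
        pool = [str(g).upper() for g in universe if str(g).upper() not in set(markers)]
    else:
        pool = [f"N{i + 1:04d}" for i in range(n_nodes)]
    if len(markers) > n_nodes:
        raise ValueError("more truth markers than network nodes")
    n_fill = n_nodes - len(markers)
    if len(pool) < n_fill:
        raise ValueError("node universe too small for requested n_nodes")

    g_ba = nx.barabasi_albert_graph(n_nodes, m, seed=int(rng.integers(2**31 - 1)))
    # name assignment: index 0 is the main hub -> the planted regulator TF;
    # markers go to late (peripheral) indices, fillers everywhere else.
    names: dict[int, str] = {}
    tf_name = "TF_REG1"
    names[0] = tf_name
    marker_positions = list(range(n_nodes - len(markers), n_nodes))
    for pos, gene in zip(marker_positions, markers):
        names[pos] = gene
    fill_iter = iter(pool)
    for i in range(n_nodes):
        if i not in names:
            names[i] = next(fill_iter)

    edges: set[tuple[str, str]] = set()
    for u, v in g_ba.edges():
        a, b = (u, v) if u < v else (v, u)
        edges.add((names[a], names[b]))

    # drop any direct TF->marker edge, then wire TF -> intermediate -> marker
    edges = {(u, v) for u, v in edges if not (u == tf_name and v in set(markers))}
    interm_candidates = [
        names[i] for i in range(1, n_nodes) if names[i] not in set(markers)
    ]
    if n_de_intermediates < 1 or n_de_intermediates > len(interm_candidates) - 1:
        raise ValueError("infeasible n_de_intermediates for this network size")
    chosen = rng.choice(len(interm_candidates), size=n_de_intermediates + 1, replace=False)
    de_intermediates = [interm_candidates[i] for i in chosen[:-1]]
    decoy = interm_candidates[chosen[-1]]  # a non-DE decoy intermediate
    for k, gene in enumerate(markers):
        x = de_intermediates[k % len(de_intermediates)]
        edges.add((tf_name, x))
        edges.add((x, gene))
        edges.add((tf_name, decoy))
        edges.add((decoy, gene))

    # TF flags: planted regulator plus random non-marker nodes
    other_tf_pool = [
        names[i]
        for i in range(1, n_nodes)
        if names[i] not in set(markers)
        and names[i] not in set(de_intermediates)
        and names[i] != decoy
    ]
    extra = rng.choice(len(other_tf_pool), size=n_tfs - 1, replace=False)
    tfs = {tf_name} | {other_tf_pool[i] for i in extra}
    de_flags = set(markers) | set(de_intermediates)

    signaling = InteractionNetwork(
        nodes={names[i] for i in range(n_nodes)},
        edges=edges,
        directed=True,
        is_tf=tfs,
        is_de=de_flags,
    )

    # --- undirected physical copy with a planted seed gene ----------------
    und_edges = {tuple(sorted(e)) for e in edges}
    all_nodes = {names[i] for i in range(n_nodes)}
    # the planted pathway overlaps the planted regulator's sub-network
    # (markers plus DE intermediates) so that the network layer can recover it
    pathway_pool = sorted(set(markers) | set(de_intermediates))
    if not pathway_pool:
        pathway_pool = sorted(all_nodes - tfs - {seed_gene})
    pw_idx = rng.choice(len(pathway_pool), size=min(pathway_size, len(pathway_pool)), replace=False)
    pathway_genes = sorted(pathway_pool[i] for i in pw_idx)
    # anchor the seed one step away from a neighbour of a pathway member
    g_und = nx.Graph()
    g_und.add_edges_from(und_edges)
    anchor = None
    for p in pathway_genes:
        for nb in sorted(g_und.neighbors(p)):
            if nb not in pathway_genes and nb != seed_gene:
                anchor = nb
                break
        if anchor:
            break
    if anchor is None:  # degenerate tiny graph: attach to the first pathway gene
        anchor = pathway_genes[0]
    seed_gene = str(seed_gene).upper()
    und_edges.add(tuple(sorted((seed_gene, anchor))))
    g_und.add_edge(seed_gene, anchor)
    dist = nx.single_source_shortest_path_length(g_und, seed_gene)
    planted_distance = min(dist[p] for p in pathway_genes if p in dist)

    physical = InteractionNetwork(
        nodes=all_nodes | {seed_gene},
        edges=und_edges,
        directed=False,
        is_tf=tfs,
        is_de=de_flags,
    )

    truth.planted_regulator_tf = tf_name
    truth.planted_pathway_genes = pathway_genes
    truth.planted_seed_gene = seed_gene
    truth.planted_seed_distance = int(planted_distance)
    truth.de_intermediate_genes = de_intermediates
    return signaling, physical, truth


# ---------------------------------------------------------------------------
# Gene sets
# ---------------------------------------------------------------------------


def generate_genesets(
    n_sets: int,
    set_size_range: tuple[int, int],
    universe: Sequence[str],
    planted_set: Sequence[str],
    seed: int = 0,
    planted_name: str = "PLANTED_PATHWAY",
    n_pad: int = 5,
) -> GeneSetCollection:
    """Uniform-random gene sets plus one set containing the planted symbols.

    The planted set is the planted symbols padded with ``n_pad`` random
    universe members not already planted.
    """
    universe = [str(g).upper() for g in universe]
    planted = [str(g).upper() for g in planted_set]
    if not set(planted).issubset(universe):
        raise ValueError("planted_set must be a subset of the universe")
    lo, hi = set_size_range
    if hi > len(universe):
        raise ValueError("set size exceeds universe size")
    rng = np.random.default_rng(seed)
    sets: dict[str, frozenset[str]] = {}
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(universe), size=size, replace=False)
        sets[f"SET_{i + 1:04d}"] = frozenset(universe[j] for j in members)
    rest = [g for g in universe if g not in set(planted)]
    pad = rng.choice(len(rest), size=min(n_pad, len(rest)), replace=False)
    sets[planted_name] = frozenset(planted) | {rest[j] for j in pad}
    return GeneSetCollection(sets=sets, source="synthetic")


# ---------------------------------------------------------------------------
# Tissue table
# ---------------------------------------------------------------------------

_CATEGORIES = (
    "tissue_enriched",
    "group_enriched",
    "tissue_enhanced",
    "expressed_in_all",
    "not_detected",
    "mixed",
)


def generate_tissue_table(
    n_genes: int,
    tissues: Sequence[str],
    category_quota: dict[str, int],
    seed: int = 0,
    detection_threshold: float = 1.0,
) -> tuple[TissueExpressionTable, dict[str, str]]:
    """Plant genes satisfying each tissue-specificity category with >=10% margin.

    ``category_quota`` maps category name to the number of genes to plant;
    remaining genes are filled with 'mixed'-profile genes.  Returns the table
    and the planted category per gene.
    """
    tissues = [str(t) for t in tissues]
    T = len(tissues)
    if T < 2:
        raise ValueError("need at least 2 tissues")
    unknown = set(category_quota) - set(_CATEGORIES)
    if unknown:
        raise ValueError(f"unknown categories in quota: {sorted(unknown)}")
    total = sum(category_quota.values())
    if total > n_genes:
        raise ValueError("category quotas exceed n_genes")
    if category_quota.get("group_enriched", 0) > 0 and T < 3:
        raise ValueError("group_enriched requires at least 3 tissues")
    if category_quota.get("tissue_enhanced", 0) > 0 and T < 8:
        raise ValueError("tissue_enhanced construction requires at least 8 tissues")

    rng = np.random.default_rng(seed)
    thr = float(detection_threshold)
    rows: list[np.ndarray] = []
    planted: dict[str, str] = {}
    genes: list[str] = []
    counter = 0

    def low_values(size: int) -> np.ndarray:
        return rng.uniform(2.0 * thr, 4.0 * thr, size=size)

    def mixed_row() -> np.ndarray:
        # detected in a subset, undetected tissues kept just under threshold
        # so the detected group is never 5x above them (not group enriched)
        row = rng.uniform(1.5 * thr, 2.5 * thr, size=T)
        off = rng.choice(T, size=max(1, T // 2), replace=False)
        row[off] = rng.uniform(0.6 * thr, 0.85 * thr, size=len(off))
        return row

    order = [c for c in _CATEGORIES if category_quota.get(c, 0) > 0]
    for cat in order:
        for _ in range(category_quota[cat]):
            counter += 1
            gene = f"TG{counter:04d}"
            row = np.zeros(T)
            if cat == "tissue_enriched":
                t = int(rng.integers(T))
                peak = rng.uniform(45.0, 60.0)
                row[:] = rng.uniform(0.0, peak / 5.5, size=T)
                row[t] = peak
            elif cat == "group_enriched":
                g = int(rng.integers(2, min(7, T - 1) + 1))
                grp = rng.choice(T, size=g, replace=False)
                vals = rng.uniform(40.0, 60.0, size=g)
                row[:] = rng.uniform(0.0, vals.min() / 5.5, size=T)
                row[grp] = vals
            elif cat == "tissue_enhanced":
                # one tissue >= 5x the all-tissue mean (with margin) while a
                # runner-up tissue keeps the single-tissue 5x rule unsatisfied
                # and the remaining tissues stay low enough that no 2..7 group
                # qualifies either
                t = int(rng.integers(T))
                runner = (t + 1) % T
                rest = [i for i in range(T) if i not in (t, runner)]
                row[:] = 0.0
                row[rest] = rng.uniform(1.1 * thr, 2.0 * thr, size=len(rest))
                row[rest[0]] = 2.5 * thr
                s_rest = row.sum()
                # x >= 1.1 * 5 * mean with runner = x/4.6 folded in
                x = 1.02 * 5.5 * s_rest / (T - 5.5 * (1.0 + 1.0 / 4.6))
                row[t] = x
                row[runner] = x / 4.6
            elif cat == "expressed_in_all":
                row[:] = low_values(T)
            elif cat == "not_detected":
                row[:] = rng.uniform(0.0, 0.5 * thr, size=T)
            else:  # mixed
                row = mixed_row()
            rows.append(row)
            planted[gene] = cat
            genes.append(gene)

    for _ in range(n_genes - total):
        counter += 1
        gene = f"TG{counter:04d}"
        rows.append(mixed_row())
        genes.append(gene)

    table = TissueExpressionTable(
        genes=genes,
        tissues=tissues,
        values=np.vstack(rows) if rows else np.zeros((0, T)),
        detection_threshold=thr,
    )
    return table, planted
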