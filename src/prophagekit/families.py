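"""Protein families, marker collections, core/variable genes, variable loci.

Prophage-encoded proteins are clustered into families by Markov
Clustering (MCL) of an all-against-all similarity graph whose edge
weights are capped negative-log e-values, ``min(ceil(-log10 e), 200)``.
Within a cluster of related phages, a family present in more than 80% of
members is core and one present in at most 30% is variable; runs of
non-core genes that contain variable genes and sit between two core
genes form the variable locus — the accessory-gene hotspot.  Defense
content of a locus is flagged from annotation labels (toxin/antitoxin
adjacency or external defense-tool labels).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .params import MCLParams, EPS

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# similarity graph
# ---------------------------------------------------------------------------

def build_similarity_graph(
    hits: Sequence[tuple[str, str, float]], params: MCLParams | None = None
) -> nx.Graph:
    """Undirected weighted protein-similarity graph from hit triples.

    Weight = min(ceil(-log10 evalue), 200); reciprocal hits collapse to
    the maximum weight; self-hits are dropped (MCL adds its own loops);
    e-values <= 0 (reported as 0 by search tools at underflow) take the
    cap weight.
    """
    params = params or MCLParams()
    g = nx.Graph()
    for a, b, evalue in hits:
        g.add_node(a)
        g.add_node(b)
        if a == b:
            continue
        if evalue <= 0:
            w = params.weight_cap
        else:
            w = min(math.ceil(-math.log10(evalue)), params.weight_cap)
        if w <= 0:
            continue
        if g.has_edge(a, b):
            g[a][b]["weight"] = max(g[a][b]["weight"], w)
        else:
            g.add_edge(a, b, weight=w)
    return g


# ---------------------------------------------------------------------------
# Markov Clustering
# ---------------------------------------------------------------------------

@dataclass
class GeneFamily:
    family_id: str
    members: list[str]


def mcl_cluster(
    graph: nx.Graph, params: MCLParams | None = None
) -> list[GeneFamily]:
    """Canonical Markov Clustering of a weighted graph.

    Self-loops are added with each node's maximum incident edge weight
    (1 for isolated nodes), columns are normalized to a stochastic
    matrix, then expansion (matrix square) alternates with inflation
    (elementwise power, column renormalization) and pruning of entries
    below the prune threshold, until the matrix change falls below the
    tolerance.  Clusters are the connected components of the converged
    matrix support.  Deterministic: nodes are processed in sorted order.
    """
    params = params or MCLParams()
    nodes = sorted(graph.nodes)
    if not nodes:
        return []
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    m = np.zeros((n, n))
    for a, b, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        m[index[a], index[b]] = w
        m[index[b], index[a]] = w
    loop = m.max(axis=0)
    loop[loop == 0] = 1.0
    np.fill_diagonal(m, loop)
    m /= m.sum(axis=0, keepdims=True)

    converged = False
    for _ in range(params.max_iter):
        prev = m
        m = m @ m                         # expansion
        m = np.power(m, params.inflation)  # inflation
        m[m < params.prune] = 0.0
        colsum = m.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        m /= colsum
        if prev.shape == m.shape and np.abs(m - prev).max() < params.tol:
            converged = True
            break
    if not converged:
        logger.warning("MCL did not converge in %d iterations", params.max_iter)

    support = nx.Graph()
    support.add_nodes_from(range(n))
    rows, cols = np.nonzero(m > params.prune)
    support.add_edges_from(zip(rows.tolist(), cols.tolist()))
    components = sorted(
        (sorted(comp) for comp in nx.connected_components(support)),
        key=lambda c: c[0],
    )
    return [
        GeneFamily(f"family_{i:04d}", [nodes[j] for j in comp])
        for i, comp in enumerate(components)
    ]


# ---------------------------------------------------------------------------
# marker collections
# ---------------------------------------------------------------------------

def collect_marker_families(
    families: Sequence[GeneFamily], seeds: dict[str, str]
) -> tuple[dict[str, list[str]], list[str]]:
    """Per-realm marker collections by family co-membership with seeds.

    ``seeds`` maps seed protein id -> realm.  Every member of a family
    containing at least one seed of realm R joins R's collection; a
    family seeded by two realms is a conflict and joins none.
    """
    collections: dict[str, list[str]] = {}
    conflicts: list[str] = []
    for fam in families:
        realms = {seeds[m] for m in fam.members if m in seeds}
        if len(realms) > 1:
            conflicts.append(fam.family_id)
        elif len(realms) == 1:
            collections.setdefault(realms.pop(), []).extend(fam.members)
    return {r: sorted(ms) for r, ms in collections.items()}, conflicts


# ---------------------------------------------------------------------------
# core / variable classification
# ---------------------------------------------------------------------------

@dataclass
class PhageCluster:
    cluster_id: str
    members: list[str]                        # prophage ids
    family_frequency: dict[str, float] = field(default_factory=dict)
    family_class: dict[str, str] = field(default_factory=dict)  # core|variable|intermediate


@dataclass
class VariableLocus:
    cluster_id: str
    prophage_id: str
    left_core: str
    right_core: str
    gene_index_span: tuple[int, int]  # inclusive indices of first/last variable gene
    member_genes: list[str]


def family_frequencies(
    cluster_id: str,
    member_gene_families: dict[str, Sequence[str]],
    params: MCLParams | None = None,
) -> PhageCluster:
    """Family frequencies within a phage cluster and their classes.

    Frequency = fraction of member genomes carrying at least one gene of
    the family; core strictly above 0.8, variable at or below 0.3,
    intermediate otherwise.
    """
    params = params or MCLParams()
    members = sorted(member_gene_families)
    size = len(members)
    if size == 0:
        raise ValueError("empty cluster")
    counts: dict[str, int] = {}
    for genome in members:
        for fam in set(member_gene_families[genome]):
            counts[fam] = counts.get(fam, 0) + 1
    freq = {f: c / size for f, c in counts.items()}
    classes = {}
    for f, q in freq.items():
        if q > params.core_threshold + EPS:
            classes[f] = "core"
        elif q <= params.variable_threshold + EPS:
            classes[f] = "variable"
        else:
            classes[f] = "intermediate"
    return PhageCluster(cluster_id, members, freq, classes)


def extract_variable_loci(
    cluster: PhageCluster,
    ordered_genes: dict[str, Sequence[tuple[str, str]]],
    params: MCLParams | None = None,
) -> list[VariableLocus]:
    """Variable loci per genome: runs of non-core genes containing at
    least one variable gene, enclosed by core-family genes on both sides.

    ``ordered_genes`` maps prophage id -> genes as (gene_id, family) in
    genomic order.  Clusters with fewer than 5 members yield no loci.
    The locus spans the first to the last variable gene of the run.
    """
    params = params or MCLParams()
    if len(cluster.members) < params.min_cluster_members:
        return []
    loci: list[VariableLocus] = []
    for genome in cluster.members:
        genes = list(ordered_genes.get(genome, ()))
        classes = [cluster.family_class.get(fam, "variable") for _, fam in genes]
        i = 0
        while i < len(genes):
            if classes[i] == "core":
                i += 1
                continue
            j = i
            while j < len(genes) and classes[j] != "core":
                j += 1
            # run [i, j): needs core flank both sides and >=1 variable gene
            if i > 0 and j < len(genes):
                var_idx = [k for k in range(i, j) if classes[k] == "variable"]
                if var_idx:
                    lo, hi = var_idx[0], var_idx[-1]
                    loci.append(
                        VariableLocus(
                            cluster_id=cluster.cluster_id,
                            prophage_id=genome,
                            left_core=genes[i - 1][1],
                            right_core=genes[j][1],
                            gene_index_span=(lo, hi),
                            member_genes=[genes[k][0] for k in range(lo, hi + 1)],
                        )
                    )
            i = j
    return loci


def cluster_prophages_by_ani(
    pair_table: pd.DataFrame, ids: Sequence[str], min_ani: float = 80.0
) -> list[PhageCluster]:
    """Single-linkage phage clusters from a pairwise ANI table.

    Stands in for fine-grained cluster assignments when none are supplied:
    prophages joined whenever their ANI is at least ``min_ani``.
    ``pair_table`` needs columns id_a, id_b, ani.
    """
    g = nx.Graph()
    g.add_nodes_from(ids)
    for row in pair_table.itertuples(index=False):
        if row.ani >= min_ani - EPS:
            g.add_edge(row.id_a, row.id_b)
    comps = sorted((sorted(c) for c in nx.connected_components(g)), key=lambda c: c[0])
    return [PhageCluster(f"VGC_{i:03d}", comp) for i, comp in enumerate(comps)]


# ---------------------------------------------------------------------------
# defense flagging
# ---------------------------------------------------------------------------

DEFENSE_TERMS = ("abortive infection", "toxin", "antitoxin", "restriction", "retron")


def _is_toxin(label: str) -> bool:
    low = label.lower()
    return "toxin" in low and "antitoxin" not in low and "anti-toxin" not in low


def _is_antitoxin(label: str) -> bool:
    low = label.lower()
    return "antitoxin" in low or "anti-toxin" in low


def flag_defense(
    locus_genes: Sequence[tuple[str, Sequence[str]]],
    external_complete: bool = False,
) -> tuple[str, list[str]]:
    """Defense classification of a variable locus from annotation labels.

    ``locus_genes`` lists (gene_id, labels) in genomic order.  The locus
    is a complete system if an external defense tool reported one
    (``external_complete``) or adjacent genes carry toxin and antitoxin
    labels; an incomplete system if any defense-related label occurs
    without completeness; otherwise "other".
    """
    systems: list[str] = []
    if external_complete:
        systems.append("external_tool")

    gene_labels = [" ; ".join(labels).lower() for _, labels in locus_genes]
    toxin_flags = [_is_toxin(t) for t in gene_labels]
    antitoxin_flags = [_is_antitoxin(t) for t in gene_labels]
    for i in range(len(gene_labels) - 1):
        if (toxin_flags[i] and antitoxin_flags[i + 1]) or (
            antitoxin_flags[i] and toxin_flags[i + 1]
        ):
            systems.append("toxin-antitoxin")
            break
    if systems:
        return "complete_system", systems

    if any(term in t for t in gene_labels for term in DEFENSE_TERMS):
        return "incomplete_system", []
    return "other", []
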