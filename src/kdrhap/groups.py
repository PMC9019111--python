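"""Haplotype grouping: pairwise distances, hierarchical clusters,
median-joining networks and concordance between the two groupings.

Haplotypes swept to high frequency by selection on a resistance allele are
near-identical over the gene, so they collapse into tight clusters of an
agglomerative tree and into connected components of a median-joining
network pruned at a small maximum edge distance.  Both routes are
implemented and their agreement is measured by a maximum-agreement label
matching.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import squareform

from .genemodel import CodonEffect
from .hapmatrix import HaplotypeMatrix

__all__ = [
    "pairwise_hamming",
    "hierarchical_groups",
    "median_joining_network",
    "HaplotypeNetwork",
    "network_groups",
    "annotate_nonsynonymous_edges",
    "concordance",
    "label_clusters",
    "group_frequency_table",
]

WILDTYPE = "wt"
OTHER_RESISTANT = "OR"


# ------------------------------------------------------------- distances


def pairwise_hamming(
    haps: HaplotypeMatrix,
    window: tuple[int, int] | None = None,
    biallelic_only: bool = True,
) -> np.ndarray:
    """Integer Hamming distance matrix between all haplotype pairs.

    ``window`` is (start, end), 1-based end-exclusive; None uses all
    sites.  With ``biallelic_only`` sites with more than one alternate
    allele are excluded.
    """
    if window is None:
        rows = np.arange(haps.n_sites)
    else:
        rows = haps.site_index_in(*window)
    if biallelic_only:
        mask = haps.biallelic_mask()
        rows = rows[mask[rows]]
    sub = haps.codes[rows]
    n = haps.n_haplotypes
    dist = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        diffs = (sub[:, i + 1 :] != sub[:, i : i + 1]).sum(axis=0)
        dist[i, i + 1 :] = diffs
        dist[i + 1 :, i] = diffs
    return dist


# ------------------------------------------------------------- labelling


def label_clusters(
    cluster_ids: np.ndarray,
    focal_carriage: dict[str, np.ndarray],
    min_group_size: int = 1,
) -> list[str]:
    """Assign field-style group labels to clustered haplotypes.

    ``focal_carriage`` maps a label base to a boolean carrier vector over
    haplotypes; single-letter bases (e.g. ``F``, ``S``) are numbered by
    decreasing cluster size (F1 = largest cluster of carriers), longer
    bases (e.g. ``L1``, ``L2``) name a single group — the largest
    qualifying cluster — directly.  A cluster's base is the focal allele
    carried by the majority of its members.  Haplotypes that carry a focal
    allele but fall outside any labelled group are ``OR`` (other
    resistant); everything else is ``wt``.
    """
    n = len(cluster_ids)
    for base, carr in focal_carriage.items():
        if len(carr) != n:
            raise ValueError(f"carrier vector for {base} has wrong length")
    clusters: dict[int, np.ndarray] = {
        cid: np.nonzero(cluster_ids == cid)[0] for cid in np.unique(cluster_ids)
    }
    # majority focal base per cluster
    cluster_base: dict[int, str | None] = {}
    for cid, members in clusters.items():
        counts = {
            base: int(np.count_nonzero(carr[members]))
            for base, carr in focal_carriage.items()
        }
        counts[""] = len(members) - max(counts.values(), default=0)
        best_base, best_count = "", 0
        for base in sorted(counts):
            if counts[base] > best_count:
                best_base, best_count = base, counts[base]
        # require a strict majority of members to carry the focal allele
        if best_base and counts[best_base] * 2 > len(members):
            cluster_base[cid] = best_base
        else:
            cluster_base[cid] = None

    cluster_label: dict[int, str | None] = {cid: None for cid in clusters}
    for base in focal_carriage:
        eligible = [
            cid
            for cid, members in clusters.items()
            if cluster_base[cid] == base and len(members) >= min_group_size
        ]
        # decreasing size; ties by cluster id for determinism
        eligible.sort(key=lambda cid: (-len(clusters[cid]), cid))
        if len(base) == 1:
            for rank, cid in enumerate(eligible, 1):
                cluster_label[cid] = f"{base}{rank}"
        elif eligible:
            cluster_label[eligible[0]] = base

    any_focal = np.zeros(n, dtype=bool)
    for carr in focal_carriage.values():
        any_focal |= np.asarray(carr, dtype=bool)

    labels = []
    for h in range(n):
        cid = cluster_ids[h]
        lab = cluster_label[cid]
        base = cluster_base[cid]
        if lab is not None and base is not None and focal_carriage[base][h]:
            labels.append(lab)
        elif any_focal[h]:
            labels.append(OTHER_RESISTANT)
        else:
            labels.append(WILDTYPE)
    return labels


def hierarchical_groups(
    dist: np.ndarray,
    focal_carriage: dict[str, np.ndarray],
    method: str = "average",
    cut_height: float = 5.0,
    min_group_size: int = 3,
) -> list[str]:
    """Agglomerative clustering of the distance matrix into labelled groups.

    The tree is cut at ``cut_height`` (in SNP differences); clusters of
    near-identical haplotypes below the cut become groups, labelled via
    :func:`label_clusters`; clusters smaller than ``min_group_size``
    dissolve into OR/wt according to focal-allele carriage.
    """
    if cut_height < 0:
        raise ValueError("cut_height must be non-negative")
    if dist.shape[0] == 1:
        return label_clusters(np.array([1]), focal_carriage, min_group_size)
    condensed = squareform(dist, checks=False).astype(float)
    Z = linkage(condensed, method=method)
    cluster_ids = fcluster(Z, t=cut_height, criterion="distance")
    return label_clusters(cluster_ids, focal_carriage, min_group_size)


# ------------------------------------------------- median-joining network


@dataclass
class HaplotypeNetwork:
    """Median-joining network over binary haplotype strings.

    ``graph`` is an undirected networkx graph; nodes are haplotype tuples
    with attributes ``observed`` (bool), ``multiplicity``,
    ``haplotype_indices`` (matrix columns collapsing to the node) and
    ``populations`` (Counter).  Edges carry ``distance`` and
    ``diff_sites`` (window site indices at which the endpoints differ).
    """

    graph: nx.Graph
    window_rows: np.ndarray  # matrix row index per window site
    positions: np.ndarray  # genomic position per window site
    node_of_haplotype: dict[int, tuple]  # matrix column -> node key
    max_edge_dist: int | float = 2
    epsilon: int = 0
    components: list[set] = field(default_factory=list)

    def component_ids(self) -> np.ndarray:
        """Component index per observed haplotype column (dense ids)."""
        comp_of_node: dict[tuple, int] = {}
        for k, comp in enumerate(self.components):
            for node in comp:
                comp_of_node[node] = k
        n = max(self.node_of_haplotype) + 1
        out = np.full(n, -1, dtype=int)
        for h, node in self.node_of_haplotype.items():
            out[h] = comp_of_node[node]
        return out

    def observed_nodes(self) -> list[tuple]:
        return [n for n, d in self.graph.nodes(data=True) if d["observed"]]

    def total_edge_length(self) -> int:
        return sum(d["distance"] for _, _, d in self.graph.edges(data=True))


def _hamming(a: tuple, b: tuple) -> int:
    return sum(x != y for x, y in zip(a, b))


def _msn_edges(nodes: list[tuple], epsilon: int) -> list[tuple[tuple, tuple, int]]:
    """Epsilon-relaxed minimum spanning network over the node set.

    An edge of weight w is retained when its endpoints are not already
    connected using only edges of weight <= w - 1 - epsilon; at epsilon=0
    this is the classic minimum spanning network (all co-minimal edges of
    every merging step kept).
    """
    if len(nodes) < 2:
        return []
    arr = np.asarray(nodes, dtype=np.int8)
    dmat = np.count_nonzero(arr[:, None, :] != arr[None, :, :], axis=2)
    iu, ju = np.triu_indices(len(nodes), k=1)
    pairs = sorted(
        (int(dmat[i, j]), nodes[i], nodes[j]) for i, j in zip(iu, ju)
    )
    parent: dict[tuple, tuple] = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    # components snapshot after processing all edges of weight <= t
    edges: list[tuple[tuple, tuple, int]] = []
    comp_at: dict[int, dict[tuple, tuple]] = {}
    weights = sorted({w for w, _, _ in pairs})
    k = 0
    for w in weights:
        comp_at[w - 1] = {n: find(n) for n in nodes}
        while k < len(pairs) and pairs[k][0] == w:
            _, u, v = pairs[k]
            k += 1
            threshold = w - 1 - epsilon
            snap_keys = [t for t in comp_at if t <= threshold]
            if snap_keys:
                snap = comp_at[max(snap_keys)]
                connected = snap[u] == snap[v]
            else:
                connected = False
            if not connected:
                edges.append((u, v, w))
        for u, v, w2 in edges:
            if w2 == w:
                ru, rv = find(u), find(v)
                if ru != rv:
                    parent[ru] = rv
    return edges


def _median_vector(u: tuple, v: tuple, w: tuple) -> tuple:
    """Per-site majority consensus of three binary haplotypes."""
    return tuple(1 if (a + b + c) >= 2 else 0 for a, b, c in zip(u, v, w))


def median_joining_network(
    haps: HaplotypeMatrix,
    window: tuple[int, int] | None = None,
    hap_subset: np.ndarray | None = None,
    epsilon: int = 0,
    max_edge_dist: int | float = 2,
    max_iter: int = 50,
) -> HaplotypeNetwork:
    """Median-joining network over binary haplotype strings in a window.

    The construction iterates: build the epsilon-relaxed minimum spanning
    network over the current node set; for every mutually connected node
    triple, form the per-site majority-consensus median and add it as an
    inferred node when the star through it is shorter than connecting the
    triple directly; repeat to fixation.  Unused (degree <= 1) median
    nodes are then removed and edges longer than ``max_edge_dist`` pruned;
    connected components are recorded afterwards.  Non-binary sites in the
    window are an error — filter to biallelic sites first.
    """
    if window is None:
        rows = np.arange(haps.n_sites)
    else:
        rows = haps.site_index_in(*window)
    bad = [int(r) for r in rows if len(haps.sites[r].alts) != 1]
    if bad:
        raise ValueError(
            f"window contains non-biallelic sites at rows {bad[:5]}; "
            "restrict to biallelic sites before building the network"
        )
    cols = np.arange(haps.n_haplotypes) if hap_subset is None else np.asarray(hap_subset)
    if cols.size < 1:
        raise ValueError("need at least one haplotype")
    sub = haps.codes[np.ix_(rows, cols)]

    node_of_haplotype: dict[int, tuple] = {}
    observed: dict[tuple, list[int]] = {}
    for j, h in enumerate(cols):
        key = tuple(int(x) for x in sub[:, j])
        observed.setdefault(key, []).append(int(h))
        node_of_haplotype[int(h)] = key

    nodes: set[tuple] = set(observed)
    for _ in range(max_iter):
        edges = _msn_edges(sorted(nodes), epsilon)
        adj: dict[tuple, set] = {n: set() for n in nodes}
        dist_lookup: dict[frozenset, int] = {}
        for u, v, w in edges:
            adj[u].add(v)
            adj[v].add(u)
            dist_lookup[frozenset((u, v))] = w
        new_medians: set[tuple] = set()
        for u in sorted(nodes):
            for v, w in combinations(sorted(adj[u]), 2):
                if v not in adj[w]:
                    continue
                m = _median_vector(u, v, w)
                if m in nodes or m in new_medians:
                    continue
                star = _hamming(m, u) + _hamming(m, v) + _hamming(m, w)
                d_uv = dist_lookup[frozenset((u, v))]
                d_uw = dist_lookup[frozenset((u, w))]
                d_vw = _hamming(v, w)
                direct = sum(sorted((d_uv, d_uw, d_vw))[:2])
                if star < direct:
                    new_medians.add(m)
        if not new_medians:
            break
        nodes |= new_medians

    # final network; iteratively drop median nodes of degree <= 1
    while True:
        edges = _msn_edges(sorted(nodes), epsilon)
        degree = Counter()
        for u, v, _ in edges:
            degree[u] += 1
            degree[v] += 1
        drop = {n for n in nodes if n not in observed and degree[n] <= 1}
        if not drop:
            break
        nodes -= drop

    graph = nx.Graph()
    pop_series = haps.meta["population"]
    for n in sorted(nodes):
        members = observed.get(n, [])
        graph.add_node(
            n,
            observed=n in observed,
            multiplicity=len(members),
            haplotype_indices=members,
            populations=Counter(pop_series.iloc[h] for h in members),
        )
    for u, v, w in edges:
        if w <= max_edge_dist:
            diff = tuple(i for i, (a, b) in enumerate(zip(u, v)) if a != b)
            graph.add_edge(u, v, distance=w, diff_sites=diff, nonsynonymous=False, labels=())
    components = [set(c) for c in nx.connected_components(graph)]
    components.sort(key=lambda c: (-sum(graph.nodes[n]["multiplicity"] for n in c), min(c)))
    return HaplotypeNetwork(
        graph=graph,
        window_rows=rows,
        positions=haps.positions[rows],
        node_of_haplotype=node_of_haplotype,
        max_edge_dist=max_edge_dist,
        epsilon=epsilon,
        components=components,
    )


def annotate_nonsynonymous_edges(
    net: HaplotypeNetwork,
    effects: dict[int, CodonEffect | str],
) -> HaplotypeNetwork:
    """Flag network edges whose distinguishing sites include a missense SNP.

    ``effects`` maps matrix site index -> CodonEffect.  Flagged edges get
    the codon-change label(s); the stored edge direction
    (``direction_to``) points at the endpoint carrying the derived
    (non-reference) allele at the first missense distinguishing site.
    """
    for u, v, data in net.graph.edges(data=True):
        labels = []
        head = None
        for widx in data["diff_sites"]:
            row = int(net.window_rows[widx])
            eff = effects.get(row)
            if eff is None or isinstance(eff, str):
                continue
            if eff.effect_class in ("missense", "nonsense"):
                labels.append(eff.label)
                if head is None:
                    head = v if v[widx] == 1 else u
        data["nonsynonymous"] = bool(labels)
        data["labels"] = tuple(labels)
        if head is not None:
            data["direction_to"] = head
    return net


def network_groups(
    net: HaplotypeNetwork,
    focal_carriage: dict[str, np.ndarray],
    min_group_size: int = 3,
) -> list[str]:
    """Group labels from network components, mirroring the cluster labels."""
    comp = net.component_ids()
    return label_clusters(comp + 1, focal_carriage, min_group_size)


# ------------------------------------------------------------ concordance


def concordance(a: list[str], b: list[str]) -> float:
    """Fraction of haplotypes identically assigned under the best
    one-to-one matching between the two label sets."""
    if len(a) != len(b):
        raise ValueError("assignments cover different haplotype sets")
    if not a:
        return 1.0
    labels_a = sorted(set(a))
    labels_b = sorted(set(b))
    table = np.zeros((len(labels_a), len(labels_b)), dtype=np.int64)
    ia = {lab: i for i, lab in enumerate(labels_a)}
    ib = {lab: i for i, lab in enumerate(labels_b)}
    for x, y in zip(a, b):
        table[ia[x], ib[y]] += 1
    rows, cols = linear_sum_assignment(table, maximize=True)
    return float(table[rows, cols].sum() / len(a))


# --------------------------------------------------------- group tables


def group_frequency_table(
    haps: HaplotypeMatrix, assignment: list[str]
) -> pd.DataFrame:
    """Population x group frequency table (rows sum to 1 per population)."""
    df = pd.DataFrame(
        {"population": haps.meta["population"].to_numpy(), "group": assignment}
    )
    counts = df.groupby(["population", "group"]).size().unstack(fill_value=0)
    return counts.div(counts.sum(axis=1), axis=0)


def export_network(net: HaplotypeNetwork, dot_path=None, gml_path=None) -> None:
    """GraphViz DOT / GML export with display attributes."""
    g = nx.Graph()
    for i, (n, d) in enumerate(net.graph.nodes(data=True)):
        g.add_node(
            i,
            label="".join(map(str, n)) if len(n) <= 20 else f"n{i}",
            observed=str(d["observed"]),
            multiplicity=d["multiplicity"],
            width=max(0.2, 0.1 * np.sqrt(d["multiplicity"])),
        )
    index = {n: i for i, n in enumerate(net.graph.nodes)}
    for u, v, d in net.graph.edges(data=True):
        g.add_edge(
            index[u],
            index[v],
            distance=d["distance"],
            label=",".join(d.get("labels", ())),
            color="red" if d.get("nonsynonymous") else "black",
        )
    if dot_path is not None:
        nx.nx_pydot.write_dot(g, dot_path) if _has_pydot() else _write_dot_fallback(g, dot_path)
    if gml_path is not None:
        nx.write_gml(g, gml_path)


def _has_pydot() -> bool:
    try:
        import pydot  # noqa: F401

        return True
    except ImportError:
        return False


def _write_dot_fallback(g: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        fh.write("graph haplotype_network {\n")
        for n, d in g.nodes(data=True):
            fh.write(f'  {n} [label="{d["label"]}", width={d["width"]:.2f}];\n')
        for u, v, d in g.edges(data=True):
            fh.write(
                f'  {u} -- {v} [label="{d["label"]}", color={d["color"]}, '
                f"len={d['distance']}];\n"
            )
        fh.write("}\n")
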