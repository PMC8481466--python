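"""Gene-sharing viral clustering into pseudogenera (viral clusters, VCs).

Contigs sharing protein families are connected into a weighted graph;
connected components of two or more contigs become clusters, isolated
contigs stay unclustered, and articulation points — contigs bridging
otherwise-separate parts of a component — are flagged ambiguous.  The
abundance stage treats ambiguous and unclustered contigs as singletons.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd


def shared_gene_graph(
    annotations: pd.DataFrame,
    contig_ids: list[str] | None = None,
    min_shared: int = 2,
    category: str = "pVOG",
) -> nx.Graph:
    """Build the gene-sharing graph.

    An edge connects two contigs iff they share at least ``min_shared``
    protein families (annotation rows of the given category, identified by
    their ``label``); edge weight is the shared-family count.  Contigs with
    no annotated proteins are isolated nodes.
    """
    rows = annotations[annotations["category"] == category]
    fams: dict[str, set[str]] = {
        cid: set(grp["label"]) for cid, grp in rows.groupby("contig_id", sort=False)
    }
    if contig_ids is None:
        contig_ids = sorted(fams)
    graph = nx.Graph()
    graph.add_nodes_from(contig_ids)
    ids = list(contig_ids)
    for i, a in enumerate(ids):
        fa = fams.get(a)
        if not fa:
            continue
        for b in ids[i + 1 :]:
            fb = fams.get(b)
            if not fb:
                continue
            shared = len(fa & fb)
            if shared >= min_shared:
                graph.add_edge(a, b, weight=shared)
    return graph


def cluster_graph(graph: nx.Graph) -> pd.DataFrame:
    """Assign every contig a status: ``cluster:<k>``, ``ambiguous`` or
    ``unclustered``.

    Connected components of size >= 2 become clusters (numbered by their
    lexicographically smallest member, for input-order invariance);
    articulation points within a component are flagged ambiguous.
    """
    status: dict[str, str] = {}
    components = sorted(nx.connected_components(graph), key=min)
    k = 0
    for comp in components:
        if len(comp) == 1:
            status[next(iter(comp))] = "unclustered"
            continue
        k += 1
        arts = set(nx.articulation_points(graph.subgraph(comp)))
        for node in comp:
            status[node] = "ambiguous" if node in arts else f"cluster:{k}"
    out = pd.DataFrame(sorted(status.items()), columns=["contig_id", "status"])
    return out


def cluster_contigs(
    annotations: pd.DataFrame,
    contig_ids: list[str] | None = None,
    min_shared: int = 2,
) -> pd.DataFrame:
    """Convenience wrapper: graph construction followed by clustering."""
    return cluster_graph(shared_gene_graph(annotations, contig_ids, min_shared))
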