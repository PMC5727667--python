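"""Kinome and integrated interaction networks, with community detection.

Two graphs are built from the differential calls:

* the kinome network: kinases with at least one regulated substrate, their
  regulated substrates, curated kinase-substrate edges labeled with the
  site and direction, plus high-confidence protein-protein interaction
  edges among the included nodes;
* the integrated network: protein-protein interaction edges whose *both*
  endpoints are regulated phosphoproteins or significantly enriched
  transcription factors (an ``include_bridging`` flag relaxes to
  one-endpoint eligibility).

Communities are extracted by greedy modularity maximization
(Clauset-Newman-Moore) with lexicographic tie-breaking — a deterministic
stand-in for plugin-based community clustering.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .datamodel import ValidationError
from .diffreg import STATUS_DOWN, STATUS_UP, RegulationCall


@dataclass
class Community:
    partition: dict[str, int]
    modularity: float


def filter_high_confidence(interactions: pd.DataFrame,
                           conf_min: float = 0.7) -> pd.DataFrame:
    """Keep interaction edges with confidence >= conf_min."""
    if not (0.0 <= conf_min <= 1.0):
        raise ValidationError(f"conf_min={conf_min} outside [0,1]")
    return (interactions[interactions["confidence"] >= conf_min]
            .reset_index(drop=True))


def _direction_by_gene(calls: Sequence[RegulationCall]) -> dict[str, str]:
    """Gene -> up/down/none; a gene with both directions is marked 'both'."""
    out: dict[str, str] = {}
    for c in calls:
        if c.status not in (STATUS_UP, STATUS_DOWN):
            continue
        prev = out.get(c.gene)
        if prev is None:
            out[c.gene] = c.status
        elif prev != c.status:
            out[c.gene] = "both"
    return out


def build_kinome_network(calls: Sequence[RegulationCall],
                         ksr: pd.DataFrame,
                         interactions: pd.DataFrame | None = None,
                         source: str = "curated") -> nx.Graph:
    """Kinases with >= 1 regulated substrate plus those substrates.

    Kinase-substrate edges carry provenance 'ksr', the substrate site label,
    and the site's direction; interaction edges among included nodes are
    added with provenance 'ppi'. Kinases and substrates are identified by
    gene symbol.
    """
    ksr = ksr[ksr["source"] == source]
    reg_by_site: dict[tuple[str, int], RegulationCall] = {}
    for c in calls:
        if c.status in (STATUS_UP, STATUS_DOWN):
            pid, pos, _ = c.unit_key
            # keep the most regulated multiplicity form for the edge label
            prev = reg_by_site.get((pid, pos))
            if prev is None or abs(c.mean_log2fc) > abs(prev.mean_log2fc):
                reg_by_site[(pid, pos)] = c
    g = nx.Graph()
    for kinase, pid, pos in ksr[["kinase", "substrate_protein",
                                 "substrate_position"]
                                ].drop_duplicates().itertuples(index=False):
        call = reg_by_site.get((pid, int(pos)))
        if call is None:
            continue
        sub = call.gene
        if kinase not in g:
            g.add_node(kinase, is_kinase=True, regulated_phospho="none",
                       tf_status="none")
        if sub not in g:
            g.add_node(sub, is_kinase=False,
                       regulated_phospho=call.status, tf_status="none")
        g.add_edge(kinase, sub, provenance="ksr",
                   site=f"{pid}:{pos}", direction=call.status)
    if interactions is not None:
        for a, b, conf in interactions[["node_a", "node_b", "confidence"]
                                       ].itertuples(index=False):
            if a in g and b in g and a != b and not g.has_edge(a, b):
                g.add_edge(a, b, provenance="ppi", confidence=float(conf))
    return g


def build_integrated_network(calls: Sequence[RegulationCall],
                             significant_tfs: Iterable[str],
                             interactions: pd.DataFrame,
                             tf_direction: dict[str, str] | None = None,
                             include_bridging: bool = False,
                             drop_isolated: bool = True) -> nx.Graph:
    """Interaction network restricted to regulated phosphoproteins and
    significant TFs.

    An edge is retained when both endpoints are eligible (or at least one,
    with ``include_bridging``). A node may carry both the regulated-phospho
    and the TF flag. Eligible nodes left without any retained edge are
    dropped by default.
    """
    phos_dir = _direction_by_gene(calls)
    tfs = set(significant_tfs)
    tf_direction = tf_direction or {}
    eligible = set(phos_dir) | tfs

    g = nx.Graph()
    for node in sorted(eligible):
        g.add_node(node,
                   is_kinase=False,
                   regulated_phospho=phos_dir.get(node, "none"),
                   tf_status=tf_direction.get(node,
                                              "sig" if node in tfs
                                              else "none"))
    kept = 0
    for a, b, conf in interactions[["node_a", "node_b", "confidence"]
                                   ].itertuples(index=False):
        if a == b:
            continue
        ok = ((a in eligible and b in eligible) if not include_bridging
              else (a in eligible or b in eligible))
        if not ok:
            continue
        for n in (a, b):
            if n not in g:
                g.add_node(n, is_kinase=False, regulated_phospho="none",
                           tf_status="none")
        g.add_edge(a, b, provenance="ppi", confidence=float(conf))
        kept += 1
    if drop_isolated:
        g.remove_nodes_from([n for n in list(g) if g.degree(n) == 0])
    if kept == 0:
        warnings.warn("no interaction edge connects eligible nodes; "
                      "integrated network is empty")
    return g


def detect_communities(graph: nx.Graph, seed: int = 0) -> Community:
    """Greedy modularity (CNM) partition with deterministic labeling.

    Communities are numbered by (size desc, lexicographically smallest
    member); ``seed`` is accepted for interface stability — the algorithm
    itself is deterministic.
    """
    if graph.number_of_nodes() == 0:
        raise ValidationError("cannot partition an empty network")
    comms = nx.community.greedy_modularity_communities(graph)
    comms = sorted((sorted(c) for c in comms),
                   key=lambda c: (-len(c), c[0]))
    partition = {node: i for i, members in enumerate(comms)
                 for node in members}
    mod = nx.community.modularity(graph, [set(c) for c in comms]) \
        if graph.number_of_edges() else 0.0
    return Community(partition=partition, modularity=float(mod))


def network_stats(graph: nx.Graph) -> dict:
    """Deterministic JSON-serializable summary of an annotated network."""
    up = sum(1 for _, d in graph.nodes(data=True)
             if d.get("regulated_phospho") == STATUS_UP)
    down = sum(1 for _, d in graph.nodes(data=True)
               if d.get("regulated_phospho") == STATUS_DOWN)
    both = sum(1 for _, d in graph.nodes(data=True)
               if d.get("regulated_phospho") == "both")
    kin = sum(1 for _, d in graph.nodes(data=True) if d.get("is_kinase"))
    tf = sum(1 for _, d in graph.nodes(data=True)
             if d.get("tf_status", "none") != "none")
    degrees = sorted((deg for _, deg in graph.degree()), reverse=True)
    return {
        "n_nodes": graph.number_of_nodes(),
        "n_edges": graph.number_of_edges(),
        "n_phospho_up": up,
        "n_phospho_down": down,
        "n_phospho_both": both,
        "n_kinases": kin,
        "n_tfs": tf,
        "degree_max": degrees[0] if degrees else 0,
        "degree_mean": (sum(degrees) / len(degrees)) if degrees else 0.0,
    }


def nodes_frame(graph: nx.Graph) -> pd.DataFrame:
    rows = [{"node": n,
             "is_kinase": bool(d.get("is_kinase", False)),
             "regulated_phospho": d.get("regulated_phospho", "none"),
             "tf_status": d.get("tf_status", "none")}
            for n, d in sorted(graph.nodes(data=True))]
    return pd.DataFrame(rows, columns=["node", "is_kinase",
                                       "regulated_phospho", "tf_status"])


def edges_frame(graph: nx.Graph) -> pd.DataFrame:
    rows = []
    for u, v, d in graph.edges(data=True):
        a, b = sorted((u, v))
        rows.append({"node_a": a, "node_b": b,
                     "provenance": d.get("provenance", ""),
                     "site": d.get("site", ""),
                     "direction": d.get("direction", ""),
                     "confidence": d.get("confidence", "")})
    rows.sort(key=lambda r: (r["node_a"], r["node_b"]))
    return pd.DataFrame(rows, columns=["node_a", "node_b", "provenance",
                                       "site", "direction", "confidence"])


def communities_frame(community: Community) -> pd.DataFrame:
    rows = [{"node": n, "community": c}
            for n, c in sorted(community.partition.items())]
    return pd.DataFrame(rows, columns=["node", "community"])


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)


def stats_to_json(stats: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(stats, fh, indent=2, sort_keys=True)
        fh.write("\n")
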