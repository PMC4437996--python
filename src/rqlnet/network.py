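"""Network assembly, topology diagnostics and export.

Rule sets become graphs: one edge per 1–1 rule, and one edge per LHS member
for n–1 rules (star expansion, the flat-edge-list convention of Cytoscape;
the shared rule id lets the hyperedge be reconstructed).  The topology
panel reports the metrics commonly used to compare inferred regulatory
networks, including the scale-free criterion: the fit of log P(k) against
log k, whose squared correlation r² and absolute slope γ diagnose a
power-law degree distribution P(k) ~ k^−γ.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import InsufficientDegreesError
from .rules import Rule, RuleSet
from .tables import Dataset

UNDEFINED = float("nan")


@dataclass(frozen=True)
class Edge:
    source: str
    target: str
    support: float
    confidence: float
    lift: float
    leverage: float
    query_id: str
    rule_id: str


@dataclass
class Network:
    """Graph assembled from rule sets."""
    nodes: set[str]
    edges: list[Edge]
    directed: bool = True

    def graph(self) -> nx.Graph:
        """Undirected simple-graph view (parallel edges merged, used by all
        topology metrics)."""
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            if e.source != e.target:
                g.add_edge(e.source, e.target)
        return g

    def digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(e.source, e.target)
        return g


@dataclass
class TopologyReport:
    scale_free_r2: float
    gamma: float
    n_nodes: int
    n_edges: int
    avg_neighbors: float
    n_components: int
    density: float
    avg_clustering: float
    centralization: float
    heterogeneity: float
    char_path_length: float

    def to_frame(self) -> pd.DataFrame:
        rows = [("Scale-free r2", self.scale_free_r2),
                ("Absolute scaling exponent gamma", self.gamma),
                ("no. of nodes", self.n_nodes),
                ("no. of edges", self.n_edges),
                ("Avg. no. of neighbours", self.avg_neighbors),
                ("Connected components", self.n_components),
                ("Network density", self.density),
                ("Avg. clustering coefficient", self.avg_clustering),
                ("Network centralization", self.centralization),
                ("Network heterogeneity", self.heterogeneity),
                ("Characteristic path length", self.char_path_length)]
        return pd.DataFrame(rows, columns=["metric", "value"])


def _rule_id(rs: RuleSet, rule: Rule) -> str:
    left = ",".join(sorted(rule.lhs)) if rule.lhs else "-"
    prefix = f"{rs.query_id}:" if rs.query_id else ""
    return f"{prefix}{left}=>{rule.rhs}"


def build_network(rulesets: Sequence[RuleSet], collapse_labels: bool = False,
                  directed: bool = True) -> Network:
    """Assemble one network from one or more rule sets.

    ``collapse_labels`` merges the labeled variants of an attribute
    (``A_high``/``A_low`` → ``A``); parallel edges keep the metrics of the
    best-confidence rule.  In undirected mode reciprocal edges merge the
    same way.  Empty-LHS rules carry no edge (their consequent still
    becomes a node).
    """
    if not rulesets:
        raise ValueError("need at least one rule set")
    raw: list[Edge] = []
    nodes: set[str] = set()
    for rs in rulesets:
        for rule in rs.rules:
            rid = _rule_id(rs, rule)
            tgt = rule.rhs
            nodes.add(tgt)
            nodes.update(rule.lhs)
            for src in sorted(rule.lhs):
                raw.append(Edge(src, tgt, rule.support, rule.confidence,
                                rule.lift, rule.leverage, rs.query_id, rid))
    if collapse_labels:
        nodes = {_strip_label(n) for n in nodes}
        raw = [Edge(_strip_label(e.source), _strip_label(e.target),
                    e.support, e.confidence, e.lift, e.leverage,
                    e.query_id, e.rule_id) for e in raw]

    best: dict[tuple, Edge] = {}
    for e in raw:
        key = (e.source, e.target) if directed else \
            tuple(sorted((e.source, e.target)))
        cur = best.get(key)
        if cur is None or e.confidence > cur.confidence:
            best[key] = e
    edges = sorted(best.values(), key=lambda e: (e.source, e.target))
    return Network(nodes, edges, directed)


def _strip_label(name: str) -> str:
    """Collapse ``attr_label`` back to ``attr`` (last underscore group)."""
    return name.rsplit("_", 1)[0] if "_" in name else name


# ---------------------------------------------------------------------------
# Topology metrics
# ---------------------------------------------------------------------------

def scale_free_fit(net: Network | nx.Graph) -> tuple[float, float]:
    """Least-squares fit of log P(k) vs log k over observed degrees k ≥ 1.

    Returns (r², |slope|).  Unbinned: every observed positive degree
    contributes one point, P(k) = fraction of positive-degree nodes with
    degree k.  Needs ≥ 3 distinct positive degrees.
    """
    g = net.graph() if isinstance(net, Network) else net
    degrees = np.array([d for _, d in g.degree() if d >= 1])
    ks, counts = np.unique(degrees, return_counts=True)
    if len(ks) < 3:
        raise InsufficientDegreesError(
            f"scale-free fit needs ≥ 3 distinct positive degrees, "
            f"got {len(ks)}")
    x = np.log(ks.astype(float))
    y = np.log(counts / counts.sum())
    slope, _ = np.polyfit(x, y, 1)
    r2 = float(np.corrcoef(x, y)[0, 1] ** 2)
    return r2, float(abs(slope))


def topology(net: Network) -> TopologyReport:
    """The standard topology panel, computed on the undirected view.

    density = 2E/(n(n−1)); avg_neighbors = 2E/n; centralization =
    n/(n−2)·(max_degree/(n−1) − density); heterogeneity = coefficient of
    variation of the degree sequence; clustering averages local
    coefficients with 0 assigned below degree 2; characteristic path
    length averages shortest paths over connected node pairs.  Metrics
    needing n ≥ 3 are NaN for smaller graphs.
    """
    g = net.graph()
    n, e = g.number_of_nodes(), g.number_of_edges()
    degrees = np.array([d for _, d in g.degree()], dtype=float)
    density = 2 * e / (n * (n - 1)) if n >= 2 else UNDEFINED
    avg_neigh = 2 * e / n if n else UNDEFINED
    if n >= 3:
        centralization = (n / (n - 2)) * (degrees.max() / (n - 1) - density)
    else:
        centralization = UNDEFINED
    mean_deg = degrees.mean() if n else UNDEFINED
    heterogeneity = (degrees.std(ddof=0) / mean_deg
                     if n and mean_deg > 0 else UNDEFINED)
    avg_clust = (float(np.mean(list(nx.clustering(g).values())))
                 if n else UNDEFINED)
    cpl = _char_path_length(g)
    try:
        r2, gamma = scale_free_fit(g)
    except InsufficientDegreesError:
        r2, gamma = UNDEFINED, UNDEFINED
    return TopologyReport(
        scale_free_r2=r2, gamma=gamma, n_nodes=n, n_edges=e,
        avg_neighbors=avg_neigh,
        n_components=nx.number_connected_components(g) if n else 0,
        density=density, avg_clustering=avg_clust,
        centralization=centralization, heterogeneity=heterogeneity,
        char_path_length=cpl)


def _char_path_length(g: nx.Graph) -> float:
    """Mean shortest-path length over all connected ordered pairs."""
    total, pairs = 0, 0
    for src, dists in nx.all_pairs_shortest_path_length(g):
        for dst, d in dists.items():
            if dst != src:
                total += d
                pairs += 1
    return total / pairs if pairs else UNDEFINED


# ---------------------------------------------------------------------------
# Correlation baseline
# ---------------------------------------------------------------------------

def pearson_baseline(ds: Dataset, attrs: Sequence[str] | None = None,
                     cutoff: float = 0.8) -> Network:
    """Correlation network: undirected edge where |Pearson r| ≥ cutoff.

    The standard comparator for rule-based networks.  Constant attributes
    are excluded (correlation undefined) with a warning.
    """
    import warnings

    if attrs is None:
        attrs = [a.name for a in ds.attributes if a.kind == "quantitative"]
    if ds.n_samples < 3:
        raise ValueError("pearson_baseline needs at least 3 samples")
    cols = []
    kept = []
    for a in attrs:
        v = ds.frame[a].astype(float).to_numpy()
        if np.nanstd(v) == 0 or np.isnan(v).all():
            warnings.warn(f"excluding constant attribute {a!r} from "
                          f"correlation network")
            continue
        cols.append(v)
        kept.append(a)
    edges = []
    nodes = set(kept)
    if len(kept) >= 2:
        r = np.corrcoef(np.vstack(cols))
        for i in range(len(kept)):
            for j in range(i + 1, len(kept)):
                rij = r[i, j]
                if np.isfinite(rij) and abs(rij) >= cutoff:
                    a, b = sorted((kept[i], kept[j]))
                    edges.append(Edge(a, b, UNDEFINED, UNDEFINED, UNDEFINED,
                                      abs(float(rij)), "pearson",
                                      f"pearson:{a}=>{b}"))
    edges.sort(key=lambda e: (e.source, e.target))
    return Network(nodes, edges, directed=False)


# ---------------------------------------------------------------------------
# Export / import
# ---------------------------------------------------------------------------

_EXPORT_COLUMNS = ["source", "interaction", "target", "support",
                   "confidence", "lift", "leverage", "query_id"]


def export_cytoscape(net: Network, path) -> None:
    """Tab-delimited edge table loadable by Cytoscape 3.x."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_EXPORT_COLUMNS)
        for e in sorted(net.edges, key=lambda e: (e.source, e.target)):
            w.writerow([e.source, "rule", e.target,
                        _fmt(e.support), _fmt(e.confidence),
                        _fmt(e.lift), _fmt(e.leverage), e.query_id])


def import_cytoscape(path, directed: bool = True) -> Network:
    """Re-read an exported edge table (round-trip partner of export)."""
    edges, nodes = [], set()
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if header != _EXPORT_COLUMNS:
            raise ValueError(f"unexpected header {header}")
        for row in reader:
            src, _, tgt, sup, conf, lft, lev, qid = row
            nodes.update((src, tgt))
            edges.append(Edge(src, tgt, _parse(sup), _parse(conf),
                              _parse(lft), _parse(lev), qid,
                              f"{qid}:{src}=>{tgt}"))
    return Network(nodes, edges, directed)


def export_sif(net: Network, path) -> None:
    """Minimal SIF: source, "rule", target."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for e in sorted(net.edges, key=lambda e: (e.source, e.target)):
            fh.write(f"{e.source}\trule\t{e.target}\n")


def _fmt(v: float) -> str:
    return "NA" if v != v else repr(float(v))


def _parse(s: str) -> float:
    return UNDEFINED if s == "NA" else float(s)
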