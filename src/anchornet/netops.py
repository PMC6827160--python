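"""Subnetwork extraction, signature enrichment, and key-regulator
identification on a consensus network.

Enrichment is the one-sided hypergeometric tail P(X >= k) of the overlap k
between a signature (K genes in the universe) and a node set of size n out
of a universe of N genes, with fold enrichment (k/K)/(n/N). Key regulators
are nodes whose l-step subnetwork is significantly enriched for a
signature, selected greedily with nested candidates excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

from .bn import ConsensusNetwork, is_cnv_node
from .cis import bh_adjust

__all__ = [
    "Subnetwork",
    "EnrichmentResult",
    "KeyRegulator",
    "extract_subnetwork",
    "enrich",
    "key_regulators",
    "signature_subnetwork",
    "chromosome_enrichment",
]


def _as_digraph(net) -> nx.DiGraph:
    if isinstance(net, ConsensusNetwork):
        return net.to_networkx()
    if isinstance(net, nx.DiGraph):
        return net
    raise TypeError(f"expected ConsensusNetwork or DiGraph, got {type(net)!r}")


@dataclass
class Subnetwork:
    """Nodes within l steps of the seeds plus the edges induced among them."""

    nodes: frozenset
    edges: frozenset
    seeds: frozenset
    radius: int
    mode: str

    def __len__(self) -> int:
        return len(self.nodes)


@dataclass
class EnrichmentResult:
    """One-sided hypergeometric enrichment of an overlap."""

    overlap: int          # k
    signature_size: int   # K (signature genes in the universe)
    subnet_size: int      # n
    universe: int         # N
    pvalue: float
    fold: float

    def __post_init__(self):
        if self.overlap > min(self.signature_size, self.subnet_size):
            raise ValueError("overlap exceeds signature or subnetwork size")
        if not (0.0 < self.pvalue <= 1.0):
            raise ValueError("p-value out of (0, 1]")
        if self.fold < 0:
            raise ValueError("fold enrichment must be >= 0")


@dataclass
class KeyRegulator:
    node: str
    pvalue: float
    adj_pvalue: float
    overlap: int
    subnetwork_nodes: frozenset
    excluded: tuple = field(default_factory=tuple)  # candidates it absorbed


def extract_subnetwork(net, seeds, l: int, mode: str = "downstream") -> Subnetwork:
    """Breadth-first expansion of the seeds to depth ``l`` (``downstream``
    follows edge direction; ``undirected`` ignores it), then the induced
    edge set."""
    g = _as_digraph(net)
    if l < 0:
        raise ValueError("l must be >= 0")
    if mode not in ("downstream", "undirected"):
        raise ValueError(f"unknown mode {mode!r}")
    seeds = [str(s) for s in seeds]
    unknown = [s for s in seeds if s not in g]
    if unknown:
        raise KeyError(f"unknown seed node(s): {unknown[:5]}")
    search = g if mode == "downstream" else g.to_undirected(as_view=True)
    nodes = set(seeds)
    frontier = set(seeds)
    for _ in range(l):
        nxt = set()
        for u in frontier:
            nxt.update(search.neighbors(u))
        frontier = nxt - nodes
        nodes |= frontier
        if not frontier:
            break
    edges = frozenset((u, v) for u, v in g.edges if u in nodes and v in nodes)
    return Subnetwork(nodes=frozenset(nodes), edges=edges,
                      seeds=frozenset(seeds), radius=l, mode=mode)


def enrich(signature_in_universe: int, subnet_size: int, overlap: int,
           universe: int) -> EnrichmentResult:
    """One-sided (enrichment) hypergeometric test P(X >= overlap) for
    drawing ``subnet_size`` genes from a universe of ``universe`` genes of
    which ``signature_in_universe`` carry the signature."""
    K, n, k, N = signature_in_universe, subnet_size, overlap, universe
    if N <= 0:
        raise ValueError("universe must be positive")
    if not (0 <= k <= min(K, n) <= N):
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    fold = (k / K) / (n / N) if K > 0 and n > 0 else 0.0
    return EnrichmentResult(overlap=k, signature_size=K, subnet_size=n,
                            universe=N, pvalue=p, fold=fold)


def _gene_nodes(g: nx.DiGraph) -> list:
    return sorted(n for n in g.nodes if not is_cnv_node(n))


def key_regulators(net, signature, l: int = 2, alpha: float = 0.05,
                   mode: str = "downstream", universe: int = None):
    """Greedy key-regulator selection for a signature.

    Every gene node's l-step subnetwork is tested for signature enrichment;
    candidates are nodes with BH-adjusted p < ``alpha``. The best candidate
    (smallest p, then largest overlap, then node id) is selected and all
    candidates inside its subnetwork are excluded; the scan repeats down the
    sorted list. Returns ``(regulators, unmapped_signature_genes)``.
    """
    g = _as_digraph(net)
    genes = _gene_nodes(g)
    n_universe = universe if universe is not None else len(genes)
    sig_genes = {str(x) for x in signature.genes}
    mapped = sig_genes & set(genes)
    unmapped = sorted(sig_genes - mapped)
    if not mapped:
        return [], unmapped
    rows = []
    for node in genes:
        sub = extract_subnetwork(g, [node], l, mode=mode)
        sub_genes = {x for x in sub.nodes if not is_cnv_node(x)}
        k = len(sub_genes & mapped)
        res = enrich(len(mapped), len(sub_genes), k, n_universe)
        rows.append((node, res.pvalue, k, frozenset(sub_genes)))
    pvals = bh_adjust([r[1] for r in rows])
    cands = [
        KeyRegulator(node=node, pvalue=p, adj_pvalue=ap, overlap=k,
                     subnetwork_nodes=subn)
        for (node, p, k, subn), ap in zip(rows, pvals)
        if ap < alpha
    ]
    cands.sort(key=lambda c: (c.pvalue, -c.overlap, c.node))
    selected = []
    available = {c.node for c in cands}
    for c in cands:
        if c.node not in available:
            continue
        absorbed = tuple(sorted(
            x for x in available if x != c.node and x in c.subnetwork_nodes))
        for x in absorbed:
            available.discard(x)
        available.discard(c.node)
        selected.append(KeyRegulator(
            node=c.node, pvalue=c.pvalue, adj_pvalue=c.adj_pvalue,
            overlap=c.overlap, subnetwork_nodes=c.subnetwork_nodes,
            excluded=absorbed))
    return selected, unmapped


def signature_subnetwork(net, signature, l: int = 1, universe: int = None):
    """Expand the signature's mapped genes by ``l`` undirected steps, induce
    the edges, and return the largest weakly-connected component along with
    its signature enrichment."""
    g = _as_digraph(net)
    genes = set(_gene_nodes(g))
    mapped = sorted({str(x) for x in signature.genes} & genes)
    if not mapped:
        empty = Subnetwork(frozenset(), frozenset(), frozenset(), l, "undirected")
        return empty, None
    sub = extract_subnetwork(g, mapped, l, mode="undirected")
    h = nx.DiGraph()
    h.add_nodes_from(sub.nodes)
    h.add_edges_from(sub.edges)
    comps = sorted(nx.weakly_connected_components(h),
                   key=lambda c: (-len(c), min(c)))
    comp = comps[0]
    comp_edges = frozenset((u, v) for u, v in sub.edges if u in comp and v in comp)
    component = Subnetwork(nodes=frozenset(comp), edges=comp_edges,
                           seeds=sub.seeds, radius=l, mode="undirected")
    comp_genes = {x for x in comp if not is_cnv_node(x)}
    n_universe = universe if universe is not None else len(genes)
    res = enrich(len(mapped), len(comp_genes), len(comp_genes & set(mapped)),
                 n_universe)
    return component, res


def chromosome_enrichment(signature, ann, universe_ann=None) -> dict:
    """Per-chromosome hypergeometric enrichment of the signature genes
    against the annotated universe. Unannotated signature genes are dropped
    (their count is returned under the ``"unannotated"`` key)."""
    universe_chrom = (universe_ann or ann).chrom_of()
    universe_genes = list(universe_chrom)
    sig = {str(x) for x in signature.genes}
    annotated = sorted(sig & set(universe_chrom))
    n_unannotated = len(sig) - len(annotated)
    N = len(universe_genes)
    out = {"unannotated": n_unannotated}
    chroms = sorted({universe_chrom[g] for g in universe_genes})
    for chrom in chroms:
        on_chrom = [g for g in universe_genes if universe_chrom[g] == chrom]
        k = len([g for g in annotated if universe_chrom[g] == chrom])
        out[chrom] = enrich(len(annotated), len(on_chrom), k, N)
    return out
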