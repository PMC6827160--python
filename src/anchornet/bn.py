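"""Consensus causal network learning over discretized profiles with
cis-CNV anchor nodes.

Pipeline: informative-gene filtering -> 3-state discretization (k-means
guided) -> mutual-information candidate-parent pruning (with each gene's
cis-CNV node as a mandatory candidate) -> Metropolis-Hastings structure
search under a BDeu score -> consensus over independent runs (edge
frequency > threshold) -> weakest-link loop removal.

CNV anchor nodes (ids prefixed ``CNV:``) never have parents and can only
parent their own cis gene; they break the Markov equivalence of X->Y and
Y->X, orienting edges that observational expression data alone cannot.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.special import gammaln
from sklearn.cluster import KMeans

__all__ = [
    "CNV_PREFIX",
    "DiscreteMatrix",
    "CandidateSet",
    "DagSample",
    "ConsensusNetwork",
    "select_informative_genes",
    "discretize",
    "discretize_matrix",
    "mutual_information",
    "build_candidates",
    "FamilyScoreCache",
    "score_structure",
    "mcmc_search",
    "learn_consensus",
    "consensus",
    "remove_loops",
]

CNV_PREFIX = "CNV:"
N_STATES = 3


def is_cnv_node(node_id: str) -> bool:
    return node_id.startswith(CNV_PREFIX)


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------

@dataclass
class DiscreteMatrix:
    """Node x sample matrix of states in {0=low, 1=normal, 2=high} with the
    per-node discretization cutpoints."""

    node_ids: list
    states: np.ndarray
    cutpoints: dict

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.states.shape[0] != len(self.node_ids):
            raise ValueError("states shape does not match node list")
        if not np.isin(self.states, [0, 1, 2]).all():
            raise ValueError("states must be in {0, 1, 2}")
        for node, cuts in self.cutpoints.items():
            if any(b <= a for a, b in zip(cuts, cuts[1:])):
                raise ValueError(f"cutpoints for {node} not strictly increasing")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_samples(self) -> int:
        return self.states.shape[1]

    def index_of(self, node_id: str) -> int:
        return self.node_ids.index(node_id)


@dataclass
class CandidateSet:
    """Allowed parents per node. CNV nodes have no candidate parents and
    appear only as the candidate parent of their own cis gene."""

    parents: dict                 # node_id -> tuple of candidate parent ids
    mi: dict = field(default_factory=dict)  # node_id -> {parent_id: MI}

    def __post_init__(self):
        for node, cands in self.parents.items():
            if node in cands:
                raise ValueError(f"node {node} is its own candidate parent")
            for c in cands:
                if is_cnv_node(c) and c != CNV_PREFIX + node:
                    raise ValueError(
                        f"CNV node {c} can only parent its cis gene, not {node}")
            if is_cnv_node(node) and cands:
                raise ValueError(f"CNV node {node} cannot have parents")


@dataclass(frozen=True)
class DagSample:
    """One structure from a search run."""

    edges: frozenset              # of (parent_id, child_id)
    log_score: float
    seed: int


@dataclass
class ConsensusNetwork:
    """Directed edges with across-run frequencies f in (0, 1]."""

    edges: dict                   # (src, dst) -> frequency
    threshold: float
    n_runs: int
    seeds: tuple = ()

    @property
    def nodes(self) -> list:
        out = set()
        for u, v in self.edges:
            out.update((u, v))
        return sorted(out)

    @property
    def gene_nodes(self) -> list:
        return [n for n in self.nodes if not is_cnv_node(n)]

    def gene_edges(self) -> dict:
        return {e: f for e, f in self.edges.items()
                if not (is_cnv_node(e[0]) or is_cnv_node(e[1]))}

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for n in self.nodes:
            g.add_node(n)
        for (u, v), f in sorted(self.edges.items()):
            g.add_edge(u, v, frequency=f)
        return g

    def is_acyclic(self) -> bool:
        return nx.is_directed_acyclic_graph(self.to_networkx())


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------

def select_informative_genes(expr, mean_min: float = 4.8, var_min: float = 0.4) -> list:
    """Genes with mean expression strictly > ``mean_min`` and variance
    strictly > ``var_min`` across samples."""
    means = np.nanmean(expr.values, axis=1)
    variances = np.nanvar(expr.values, axis=1, ddof=0)
    pass_mean = means > mean_min
    pass_var = variances > var_min
    keep = pass_mean & pass_var
    if not keep.any():
        raise ValueError(
            f"no informative genes: {int(pass_mean.sum())} pass mean > {mean_min}, "
            f"{int(pass_var.sum())} pass variance > {var_min}")
    return [g for g, k in zip(expr.gene_ids, keep) if k]


def discretize(values, min_frac: float = 0.05, seed: int = 0):
    """Discretize one profile into {0=low, 1=normal, 2=high}.

    k-means (k=3) clusters the values; clusters are ordered by centroid and
    the cutpoints are midpoints between adjacent centroids. A cluster
    holding fewer than ``min_frac`` of the samples is collapsed: a sparse
    outer cluster is absorbed into the middle state, a sparse middle
    cluster is split to the nearer outer centroid (a deterministic 2-state
    fallback). Fewer than 3 distinct values -> everything "normal".
    """
    v = np.asarray(values, dtype=float)
    finite = v[~np.isnan(v)]
    if np.unique(finite).size < 3:
        warnings.warn("fewer than 3 distinct values: all states set to normal")
        return np.ones(v.size, dtype=np.int8), ()
    km = KMeans(n_clusters=3, n_init=10, random_state=seed).fit(finite.reshape(-1, 1))
    order = np.argsort(km.cluster_centers_[:, 0])
    rank_of = np.empty(3, dtype=int)
    rank_of[order] = np.arange(3)
    centers = np.sort(km.cluster_centers_[:, 0])
    cuts = tuple((centers[:-1] + centers[1:]) / 2.0)
    states = np.ones(v.size, dtype=np.int8)
    states[~np.isnan(v)] = rank_of[km.labels_]
    counts = np.bincount(states[~np.isnan(v)], minlength=3)
    n = finite.size
    min_count = min_frac * n
    if counts[1] < min_count and counts[0] >= min_count and counts[2] >= min_count:
        mid = states == 1
        nearer_low = np.abs(v - centers[0]) <= np.abs(v - centers[2])
        states[mid & nearer_low] = 0
        states[mid & ~nearer_low] = 2
    else:
        for outer in (0, 2):
            if counts[outer] < min_count:
                states[states == outer] = 1
    return states, cuts


def discretize_matrix(expr, cnv=None, cis_genes=None, min_frac: float = 0.05,
                      seed: int = 0):
    """Discretize an expression matrix, optionally appending a CNV anchor
    node (``CNV:<gene>``) for every cis gene present in ``cnv``.

    Returns ``(DiscreteMatrix, cis_map)`` where cis_map maps each anchored
    gene id to its CNV node id. Sample order follows ``expr``; ``cnv`` must
    cover those samples.
    """
    node_ids, rows, cutpoints = [], [], {}
    for i, g in enumerate(expr.gene_ids):
        states, cuts = discretize(expr.values[i], min_frac=min_frac, seed=seed)
        node_ids.append(g)
        rows.append(states)
        cutpoints[g] = cuts
    cis_map = {}
    if cnv is not None and cis_genes:
        cnv_aligned = cnv.subset(samples=expr.sample_ids)
        for g in cis_genes:
            if g not in expr.gene_ids or g not in cnv_aligned.gene_ids:
                continue
            node = CNV_PREFIX + g
            states, cuts = discretize(cnv_aligned.row(g), min_frac=min_frac, seed=seed)
            node_ids.append(node)
            rows.append(states)
            cutpoints[node] = cuts
            cis_map[g] = node
    return DiscreteMatrix(node_ids, np.vstack(rows), cutpoints), cis_map


# ---------------------------------------------------------------------------
# mutual information and candidate pruning
# ---------------------------------------------------------------------------

def mutual_information(a, b) -> float:
    """Plug-in mutual information (nats) of two 3-state vectors."""
    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    if a.shape != b.shape:
        raise ValueError("state vectors must have equal length")
    n = a.size
    counts = np.bincount(N_STATES * a + b, minlength=N_STATES ** 2).reshape(3, 3)
    pij = counts / n
    pi = pij.sum(axis=1, keepdims=True)
    pj = pij.sum(axis=0, keepdims=True)
    nz = pij > 0
    return float((pij[nz] * np.log(pij[nz] / (pi @ pj)[nz])).sum())


def _mi_matrix(states: np.ndarray) -> np.ndarray:
    """Pairwise MI between all rows of a 3-state matrix (vectorized)."""
    n_nodes, m = states.shape
    onehot = [(states == k).astype(float) for k in range(N_STATES)]
    marg = np.stack([x.sum(axis=1) for x in onehot]) / m  # (3, n_nodes)
    mi = np.zeros((n_nodes, n_nodes))
    for k in range(N_STATES):
        for l_ in range(N_STATES):
            joint = (onehot[k] @ onehot[l_].T) / m
            denom = np.outer(marg[k], marg[l_])
            with np.errstate(divide="ignore", invalid="ignore"):
                term = joint * np.log(joint / denom)
            mi += np.where(joint > 0, term, 0.0)
    np.fill_diagonal(mi, 0.0)
    return mi


def build_candidates(disc: DiscreteMatrix, cis_map=None, exclude_frac: float = 0.2,
                     max_candidates=None) -> CandidateSet:
    """Sparse-candidate pruning: for each gene, rank the other genes by MI,
    drop the bottom ``exclude_frac`` fraction, cap at ``max_candidates``
    (highest MI first, node-id tie break), and add the gene's cis-CNV node
    (when present) as a mandatory candidate."""
    if not 0.0 <= exclude_frac < 1.0:
        raise ValueError("exclude_frac must be in [0, 1)")
    cis_map = dict(cis_map or {})
    gene_nodes = [n for n in disc.node_ids if not is_cnv_node(n)]
    gene_idx = [disc.node_ids.index(n) for n in gene_nodes]
    mi = _mi_matrix(disc.states[gene_idx])
    parents, mi_out = {}, {}
    for gi, g in enumerate(gene_nodes):
        others = [(mi[gi, gj], gene_nodes[gj]) for gj in range(len(gene_nodes))
                  if gj != gi]
        others.sort(key=lambda t: (t[0], t[1]))
        n_drop = int(np.floor(exclude_frac * len(others)))
        kept = others[n_drop:]
        kept.sort(key=lambda t: (-t[0], t[1]))
        if max_candidates is not None:
            kept = kept[:max_candidates]
        cand = [name for _v, name in kept]
        if g in cis_map:
            cand.append(cis_map[g])
        parents[g] = tuple(cand)
        mi_out[g] = {name: v for v, name in kept}
    for node in disc.node_ids:
        if is_cnv_node(node):
            parents[node] = ()
    return CandidateSet(parents=parents, mi=mi_out)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

class FamilyScoreCache:
    """Memoized BDeu family scores over a DiscreteMatrix.

    Family score = BDeu marginal likelihood (equivalent sample size ``ess``)
    plus a structure prior of ``-lam * |parents|``; the total structure
    score decomposes as the sum of family scores, so single-edge moves
    rescore only the affected families.
    """

    def __init__(self, disc: DiscreteMatrix, ess: float = 1.0, lam: float = 1.0):
        self.states = disc.states.astype(np.int64)
        self.ess = float(ess)
        self.lam = float(lam)
        self._cache = {}

    def family_score(self, child: int, parents: tuple) -> float:
        key = (child, parents)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        r = N_STATES
        q = r ** len(parents)
        # encode parent configuration * r + child state
        pcode = np.zeros_like(self.states[child])
        mult = 1
        for p in parents:
            pcode += mult * self.states[p]
            mult *= r
        flat = pcode * r + self.states[child]
        counts = np.bincount(flat, minlength=q * r).reshape(q, r)
        a_jk = self.ess / (q * r)
        a_j = self.ess / q
        n_j = counts.sum(axis=1)
        score = float(
            (gammaln(a_j) - gammaln(a_j + n_j)).sum()
            + (gammaln(a_jk + counts) - gammaln(a_jk)).sum()
        ) - self.lam * len(parents)
        self._cache[key] = score
        return score


def score_structure(parents_map, disc: DiscreteMatrix, ess: float = 1.0,
                    lam: float = 1.0, cache: FamilyScoreCache = None) -> float:
    """Total log score of a DAG given as {child_id: iterable of parent_ids}.
    Nodes absent from the map are scored with no parents."""
    cache = cache or FamilyScoreCache(disc, ess=ess, lam=lam)
    idx = {n: i for i, n in enumerate(disc.node_ids)}
    total = 0.0
    for node in disc.node_ids:
        ps = tuple(sorted(idx[p] for p in parents_map.get(node, ())))
        total += cache.family_score(idx[node], ps)
    return total


# ---------------------------------------------------------------------------
# MCMC structure search
# ---------------------------------------------------------------------------

def _has_path(children: dict, src: int, dst: int, skip_edge=None) -> bool:
    """Directed reachability src -> dst, optionally ignoring one edge."""
    if src == dst:
        return True
    stack = [src]
    seen = {src}
    while stack:
        u = stack.pop()
        for v in children[u]:
            if skip_edge is not None and (u, v) == skip_edge:
                continue
            if v == dst:
                return True
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return False


class _EdgeList:
    """Uniform-sampling edge container with O(1) add/remove."""

    def __init__(self):
        self.items = []
        self.pos = {}

    def add(self, e):
        self.pos[e] = len(self.items)
        self.items.append(e)

    def remove(self, e):
        i = self.pos.pop(e)
        last = self.items.pop()
        if i < len(self.items):
            self.items[i] = last
            self.pos[last] = i

    def __len__(self):
        return len(self.items)


def mcmc_search(disc: DiscreteMatrix, candidates: CandidateSet, seed: int,
                n_iter: int = 2000, max_parents: int = 3, ess: float = 1.0,
                lam: float = 1.0, temperature: float = 1.0,
                cache: FamilyScoreCache = None) -> DagSample:
    """Metropolis-Hastings over candidate-respecting DAGs.

    Proposals add, delete, or reverse one edge chosen uniformly within the
    move type; acyclicity and parent caps are enforced at proposal time. The
    best-scoring structure visited is returned. Fully deterministic given
    the seed (and a shared score cache does not change the trajectory).
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    idx = {n: i for i, n in enumerate(disc.node_ids)}
    names = disc.node_ids
    cand_parents = {
        idx[n]: tuple(sorted(idx[p] for p in candidates.parents.get(n, ())))
        for n in names
    }
    cand_pairs = [(p, idx[n]) for n in names
                  for p in cand_parents[idx[n]]]
    cand_parent_sets = {c: set(ps) for c, ps in cand_parents.items()}
    cache = cache or FamilyScoreCache(disc, ess=ess, lam=lam)

    parents = {i: [] for i in range(len(names))}
    children = {i: set() for i in range(len(names))}
    fam = {i: cache.family_score(i, ()) for i in range(len(names))}
    total = sum(fam.values())
    edges = _EdgeList()
    best_score = total
    best_edges = frozenset()
    inv_t = 1.0 / float(temperature)

    def fam_with(child, plist):
        return cache.family_score(child, tuple(sorted(plist)))

    for _ in range(n_iter):
        move = rng.integers(3)
        delta = None
        if move == 0 and cand_pairs:  # add
            p, c = cand_pairs[rng.integers(len(cand_pairs))]
            if (p in children and c not in children[p]
                    and len(parents[c]) < max_parents
                    and p not in parents[c]
                    and not _has_path(children, c, p)):
                new_fam_c = fam_with(c, parents[c] + [p])
                delta = new_fam_c - fam[c]
                action = ("add", p, c, new_fam_c)
            else:
                continue
        elif move == 1 and len(edges):  # delete
            p, c = edges.items[rng.integers(len(edges))]
            new_fam_c = fam_with(c, [x for x in parents[c] if x != p])
            delta = new_fam_c - fam[c]
            action = ("del", p, c, new_fam_c)
        elif move == 2 and len(edges):  # reverse
            p, c = edges.items[rng.integers(len(edges))]
            if (c in cand_parent_sets.get(p, ())
                    and len(parents[p]) < max_parents
                    and not _has_path(children, p, c, skip_edge=(p, c))):
                new_fam_c = fam_with(c, [x for x in parents[c] if x != p])
                new_fam_p = fam_with(p, parents[p] + [c])
                delta = (new_fam_c - fam[c]) + (new_fam_p - fam[p])
                action = ("rev", p, c, (new_fam_c, new_fam_p))
            else:
                continue
        else:
            continue

        if delta < 0 and rng.random() >= np.exp(delta * inv_t):
            continue
        kind, p, c, newscores = action
        if kind == "add":
            parents[c].append(p)
            children[p].add(c)
            edges.add((p, c))
            fam[c] = newscores
        elif kind == "del":
            parents[c].remove(p)
            children[p].discard(c)
            edges.remove((p, c))
            fam[c] = newscores
        else:
            parents[c].remove(p)
            children[p].discard(c)
            edges.remove((p, c))
            parents[p].append(c)
            children[c].add(p)
            edges.add((c, p))
            fam[c], fam[p] = newscores
        total += delta
        if total > best_score + 1e-12:
            best_score = total
            best_edges = frozenset((names[u], names[v]) for u, v in edges.items)
    return DagSample(edges=best_edges, log_score=float(best_score), seed=int(seed))


def learn_consensus(disc: DiscreteMatrix, candidates: CandidateSet,
                    n_runs: int = 50, n_iter: int = 2000, seed_base: int = 1,
                    max_parents: int = 3, ess: float = 1.0, lam: float = 1.0,
                    threshold: float = 0.3):
    """Run ``n_runs`` independent searches (seeds seed_base..seed_base+n-1,
    one shared score cache) and build the consensus network."""
    cache = FamilyScoreCache(disc, ess=ess, lam=lam)
    samples = [
        mcmc_search(disc, candidates, seed=seed_base + k, n_iter=n_iter,
                    max_parents=max_parents, cache=cache)
        for k in range(n_runs)
    ]
    return consensus(samples, threshold=threshold), samples


# ---------------------------------------------------------------------------
# consensus and loop removal
# ---------------------------------------------------------------------------

def consensus(samples, threshold: float = 0.3) -> ConsensusNetwork:
    """Edge frequency across run structures; keep edges with frequency
    strictly > ``threshold``, then remove loops."""
    if not samples:
        raise ValueError("need at least one structure sample")
    counts = Counter()
    for s in samples:
        counts.update(s.edges)
    n = len(samples)
    edges = {e: c / n for e, c in counts.items() if c / n > threshold}
    net = ConsensusNetwork(edges=edges, threshold=threshold, n_runs=n,
                           seeds=tuple(s.seed for s in samples))
    return remove_loops(net)


def _find_cycle(g: nx.DiGraph):
    """Deterministically locate one directed cycle: take the cyclic
    strongly-connected component containing the smallest node id, start at
    that node, and BFS (sorted adjacency) back to it."""
    cyclic = []
    for scc in nx.strongly_connected_components(g):
        if len(scc) > 1 or any(g.has_edge(n, n) for n in scc):
            cyclic.append(scc)
    if not cyclic:
        return None
    scc = min(cyclic, key=lambda s: min(s))
    start = min(scc)
    if g.has_edge(start, start):
        return [(start, start)]
    sub = {n: sorted(v for v in g.successors(n) if v in scc) for n in scc}
    # BFS from start's successors back to start
    first = sub[start][0]
    pred = {first: start}
    queue = [first]
    while queue:
        u = queue.pop(0)
        for v in sub[u]:
            if v == start:
                path = [(u, start)]
                while u != start:
                    path.append((pred[u], u))
                    u = pred[u]
                return list(reversed(path))
            if v not in pred:
                pred[v] = u
                queue.append(v)
    raise AssertionError("SCC without a cycle back to start")  # pragma: no cover


def remove_loops(net: ConsensusNetwork) -> ConsensusNetwork:
    """Delete the weakest (minimum-frequency) edge of each directed cycle
    until the network is acyclic. Cycle choice is deterministic (smallest
    node id first); frequency ties break on the lexicographically smallest
    edge."""
    edges = dict(net.edges)
    g = nx.DiGraph()
    for (u, v) in sorted(edges):
        g.add_edge(u, v)
    while True:
        cycle = _find_cycle(g)
        if cycle is None:
            break
        weakest = min(cycle, key=lambda e: (edges[e], e))
        del edges[weakest]
        g.remove_edge(*weakest)
    return ConsensusNetwork(edges=edges, threshold=net.threshold,
                            n_runs=net.n_runs, seeds=net.seeds)
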