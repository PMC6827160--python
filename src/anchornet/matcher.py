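"""Detection and correction of sample-labeling errors between paired
expression and CNV layers, plus metadata inference (sex, immunoglobulin
isotype, hyperdiploidy) used to attribute which layer was mislabeled.

Scheme
------
1. Select "cis genes": genes whose expression is significantly correlated
   (Spearman, BH FDR) with their own gene-level CNV across currently paired
   samples.
2. Rank-transform the cis-gene profiles per gene and compute the similarity
   S(i, j) = Pearson correlation between the expression ranks of sample i
   and the CNV ranks of sample j (equivalent to a Spearman similarity).
3. A pair is self-matched when S(i, i) is both the row and the column
   maximum and stands z > z_threshold above the empirical off-diagonal
   background. Non-self-matched samples are searched for mutually maximal,
   significant cross matches.
4. Corrections are applied and the procedure iterates until a fixed point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans

from .cis import bh_adjust
from .simulate import HYPERDIPLOID_CHROMS

__all__ = [
    "SimilarityMatrix",
    "MatchReport",
    "select_cis_genes",
    "similarity_matrix",
    "classify_matches",
    "iterate_matching",
    "infer_sex",
    "infer_isotype",
    "infer_hyperdiploidy",
    "attribute_error_layer",
]


@dataclass
class SimilarityMatrix:
    """S(i, j): similarity of expression sample i to CNV sample j, computed
    over the cis-gene list; pairing is positional (expr_samples[k] is
    currently labeled as the same sample as cnv_samples[k])."""

    expr_samples: list
    cnv_samples: list
    values: np.ndarray
    cis_genes: list
    iteration: int = 0

    def __post_init__(self):
        n = len(self.expr_samples)
        if self.values.shape != (n, len(self.cnv_samples)):
            raise ValueError("similarity matrix shape mismatch")


@dataclass
class MatchReport:
    self_matched: list
    cross_matched: list          # [(expr_sample, cnv_sample, z), ...]
    unmatched: list
    corrected_pairing: dict      # expr_sample -> cnv_sample (partial bijection)
    cis_counts: list = field(default_factory=list)
    iterations: int = 1
    converged: bool = True
    error_layers: dict = field(default_factory=dict)

    def __post_init__(self):
        vals = list(self.corrected_pairing.values())
        if len(vals) != len(set(vals)):
            raise ValueError("corrected pairing is not a partial bijection")


def _paired_arrays(expr, cnv, expr_samples, cnv_samples, genes=None):
    shared = [g for g in expr.gene_ids if g in set(cnv.gene_ids)]
    if genes is not None:
        shared = [g for g in shared if g in set(genes)]
    e = expr.subset(genes=shared, samples=list(expr_samples))
    c = cnv.subset(genes=shared, samples=list(cnv_samples))
    return shared, e.values, c.values


def select_cis_genes(expr, cnv, fdr: float = 0.01, pairing=None) -> list:
    """Genes whose expression-vs-own-CNV Spearman correlation passes
    BH FDR < ``fdr`` across the currently paired samples.

    ``pairing`` is an (expr_samples, cnv_samples) pair of equal-length
    lists; position k pairs the two profiles. Defaults to the identity
    pairing on shared sample ids. Genes with a constant profile are
    excluded (undefined correlation).
    """
    if pairing is None:
        shared_samples = [s for s in expr.sample_ids if s in set(cnv.sample_ids)]
        pairing = (shared_samples, shared_samples)
    expr_samples, cnv_samples = pairing
    if len(expr_samples) != len(cnv_samples):
        raise ValueError("pairing lists must have equal length")
    if len(expr_samples) < 10:
        raise ValueError("need at least 10 paired samples for stable correlations")
    genes, E, C = _paired_arrays(expr, cnv, expr_samples, cnv_samples)
    if not genes:
        raise ValueError("expression and CNV share no genes")
    ok = ~(np.isnan(E).any(axis=1) | np.isnan(C).any(axis=1))
    ok &= (np.ptp(E, axis=1) > 0) & (np.ptp(C, axis=1) > 0)
    if not ok.any():
        return []
    re = stats.rankdata(E[ok], axis=1)
    rc = stats.rankdata(C[ok], axis=1)
    re = re - re.mean(axis=1, keepdims=True)
    rc = rc - rc.mean(axis=1, keepdims=True)
    denom = np.sqrt((re ** 2).sum(axis=1) * (rc ** 2).sum(axis=1))
    rho = (re * rc).sum(axis=1) / denom
    n = E.shape[1]
    # t approximation, matching scipy.stats.spearmanr
    rho_c = np.clip(rho, -0.9999999999, 0.9999999999)
    t = rho_c * np.sqrt((n - 2) / (1 - rho_c ** 2))
    p = 2 * stats.t.sf(np.abs(t), n - 2)
    adj = bh_adjust(p)
    kept = np.asarray(genes)[ok][adj < fdr]
    return [str(g) for g in kept]


def similarity_matrix(expr, cnv, cis_genes, pairing=None, iteration: int = 0) -> SimilarityMatrix:
    """Compute S(i, j) over the cis genes after per-gene rank transforms."""
    if not cis_genes:
        raise ValueError("cis gene list is empty")
    if len(cis_genes) < 20:
        warnings.warn(f"only {len(cis_genes)} cis genes: low discriminative power")
    if pairing is None:
        shared_samples = [s for s in expr.sample_ids if s in set(cnv.sample_ids)]
        pairing = (shared_samples, shared_samples)
    expr_samples, cnv_samples = pairing
    genes, E, C = _paired_arrays(expr, cnv, expr_samples, cnv_samples, genes=cis_genes)
    re = stats.rankdata(E, axis=1)
    rc = stats.rankdata(C, axis=1)
    ze = _zscore_columns(re)
    zc = _zscore_columns(rc)
    S = (ze.T @ zc) / ze.shape[0]
    return SimilarityMatrix(list(expr_samples), list(cnv_samples),
                            np.clip(S, -1.0, 1.0), list(genes), iteration)


def _zscore_columns(a: np.ndarray) -> np.ndarray:
    mu = a.mean(axis=0, keepdims=True)
    sd = a.std(axis=0, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    return (a - mu) / sd


def _background_z(S: np.ndarray, i: int, j: int) -> float:
    """z of S[i, j] against the pooled off-diagonal entries of row i and
    column j (excluding position (i, j) itself)."""
    n = S.shape[0]
    row = np.delete(S[i, :], j)
    col = np.delete(S[:, j], i)
    pool = np.concatenate([row, col])
    sd = pool.std(ddof=0)
    if sd == 0:
        return 0.0
    return float((S[i, j] - pool.mean()) / sd)


def classify_matches(S: SimilarityMatrix, z_threshold: float = 3.0) -> MatchReport:
    """Classify every labeled pair as self-matched, cross-matched, or
    unmatched.

    Self-matched: S(i, i) is the maximum of row i and of column i, and lies
    z > ``z_threshold`` above the row/column background. Cross matches must
    be mutually maximal (row AND column argmax) and significant; mutual
    maximality prevents correction chains.
    """
    M = S.values
    n = M.shape[0]
    if M.shape[0] != M.shape[1]:
        raise ValueError("similarity matrix must be square for classification")
    self_matched, cross, used_rows, used_cols = [], [], set(), set()
    for i in range(n):
        if (np.argmax(M[i, :]) == i and np.argmax(M[:, i]) == i
                and _background_z(M, i, i) > z_threshold):
            self_matched.append(i)
            used_rows.add(i)
            used_cols.add(i)
    for i in range(n):
        if i in used_rows:
            continue
        j = int(np.argmax(M[i, :]))
        if (j not in used_cols and j != i and int(np.argmax(M[:, j])) == i
                and _background_z(M, i, j) > z_threshold):
            cross.append((i, j, _background_z(M, i, j)))
            used_rows.add(i)
            used_cols.add(j)
    unmatched = [i for i in range(n) if i not in used_rows]
    pairing = {S.expr_samples[i]: S.cnv_samples[i] for i in self_matched}
    for i, j, _z in cross:
        pairing[S.expr_samples[i]] = S.cnv_samples[j]
    return MatchReport(
        self_matched=[S.expr_samples[i] for i in self_matched],
        cross_matched=[(S.expr_samples[i], S.cnv_samples[j], z) for i, j, z in cross],
        unmatched=[S.expr_samples[i] for i in unmatched],
        corrected_pairing=pairing,
    )


def iterate_matching(expr, cnv, fdr: float = 0.01, max_iter: int = 10,
                     z_threshold: float = 3.0) -> MatchReport:
    """Alternate cis-gene refinement and match classification until no
    pairing update occurs (fixed point) or ``max_iter`` is reached.

    The returned report reflects the final corrected pairing; cross_matched
    accumulates every correction applied across iterations, and cis_counts
    records the cis-gene count of each iteration.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    expr_samples = [s for s in expr.sample_ids if s in set(cnv.sample_ids)]
    cnv_order = list(expr_samples)
    cis_counts, corrections = [], []
    converged = False
    report = None
    for it in range(1, max_iter + 1):
        cis = select_cis_genes(expr, cnv, fdr=fdr, pairing=(expr_samples, cnv_order))
        cis_counts.append(len(cis))
        if not cis:
            warnings.warn("no cis genes selected; matching cannot proceed")
            report = MatchReport([], [], list(expr_samples), {},
                                 cis_counts=cis_counts, iterations=it, converged=True)
            return report
        S = similarity_matrix(expr, cnv, cis, pairing=(expr_samples, cnv_order),
                              iteration=it)
        report = classify_matches(S, z_threshold=z_threshold)
        if not report.cross_matched:
            converged = True
            break
        # apply corrections as transpositions so the pairing stays a bijection
        pos_of = {s: k for k, s in enumerate(expr_samples)}
        new_order = list(cnv_order)
        for e_s, c_s, z in sorted(report.cross_matched):
            i = pos_of[e_s]
            j = new_order.index(c_s)
            new_order[i], new_order[j] = new_order[j], new_order[i]
            corrections.append((e_s, c_s, z))
        cnv_order = new_order
    return MatchReport(
        self_matched=report.self_matched,
        cross_matched=corrections,
        unmatched=report.unmatched,
        corrected_pairing=report.corrected_pairing,
        cis_counts=cis_counts,
        iterations=len(cis_counts),
        converged=converged,
    )


# ---------------------------------------------------------------------------
# metadata inference
# ---------------------------------------------------------------------------

def infer_sex(expr, markers=("XIST", "RPS4Y1"), seed: int = 0) -> dict:
    """Per-sample sex call from k-means (k=3) on the two marker genes.

    Clusters with high XIST / low RPS4Y1 are Female, low/high Male, and
    low/low NoCall (X or Y loss in tumor cells makes both markers dark).
    """
    x_marker, y_marker = markers
    for mk in markers:
        if mk not in expr.gene_ids:
            warnings.warn(f"marker gene {mk!r} missing: all samples NoCall")
            return {s: "NoCall" for s in expr.sample_ids}
    pts = np.column_stack([expr.row(x_marker), expr.row(y_marker)])
    if np.unique(pts, axis=0).shape[0] < 3:
        return {s: "NoCall" for s in expr.sample_ids}
    km = KMeans(n_clusters=3, n_init=10, random_state=seed).fit(pts)
    cx, cy = km.cluster_centers_[:, 0], km.cluster_centers_[:, 1]
    x_hi = cx > (cx.min() + cx.max()) / 2
    y_hi = cy > (cy.min() + cy.max()) / 2
    labels = []
    for hx, hy in zip(x_hi, y_hi):
        if hx and not hy:
            labels.append("Female")
        elif hy and not hx:
            labels.append("Male")
        else:
            labels.append("NoCall")
    return {s: labels[k] for s, k in zip(expr.sample_ids, km.labels_)}


def infer_isotype(expr, marker_sets: dict, margin: float = 1.0) -> dict:
    """Per-sample isotype call: argmax of mean marker-set expression;
    a winning margin below ``margin`` yields NoCall."""
    if not marker_sets or any(not genes for genes in marker_sets.values()):
        raise ValueError("every isotype needs a non-empty marker gene list")
    means = {}
    for iso, genes in marker_sets.items():
        present = [g for g in genes if g in expr.gene_ids]
        if not present:
            raise ValueError(f"no marker genes of isotype {iso!r} in the matrix")
        rows = np.vstack([expr.row(g) for g in present])
        means[iso] = rows.mean(axis=0)
    isotypes = sorted(means)
    mat = np.vstack([means[i] for i in isotypes])
    calls = {}
    for j, s in enumerate(expr.sample_ids):
        order = np.argsort(mat[:, j])[::-1]
        if len(isotypes) > 1 and mat[order[0], j] - mat[order[1], j] < margin:
            calls[s] = "NoCall"
        else:
            calls[s] = isotypes[order[0]]
    return calls


def infer_hyperdiploidy(cnv, ann, chroms=HYPERDIPLOID_CHROMS,
                        gain_threshold: float = 0.2, min_gained: int = 2) -> dict:
    """Per-sample hyperdiploidy call from gene-level CNV.

    A chromosome is "gained" when the median gene logR exceeds
    ``gain_threshold``; a sample is hyperdiploid when at least
    ``min_gained`` of the listed chromosomes are gained.
    """
    chrom_of = ann.chrom_of()
    gained_counts = np.zeros(cnv.n_samples, dtype=int)
    for chrom in chroms:
        rows = [i for i, g in enumerate(cnv.gene_ids)
                if chrom_of.get(g) == str(chrom)]
        if not rows:
            warnings.warn(f"no genes on chromosome {chrom}; skipped")
            continue
        med = np.nanmedian(cnv.values[rows], axis=0)
        gained_counts += (med > gain_threshold).astype(int)
    return {s: bool(gained_counts[j] >= min_gained)
            for j, s in enumerate(cnv.sample_ids)}


def attribute_error_layer(pair, inferred_expr_meta, inferred_cnv_meta,
                          annotated_meta) -> str:
    """Decide which layer of a cross-matched pair was mislabeled.

    For each metadata field, the profile-derived call of each layer (keyed
    by the label it carries) is compared against the clinical annotation of
    that label; the layer accumulating more disagreements is called
    mislabeled by majority vote. Returns "expression", "cnv", or "unknown".
    """
    a, b = pair
    votes = {"expression": 0, "cnv": 0}
    for layer, inferred in (("expression", inferred_expr_meta),
                            ("cnv", inferred_cnv_meta)):
        for s in (a, b):
            calls = inferred.get(s, {})
            annot = annotated_meta.get(s, {})
            for fieldname, value in calls.items():
                truth = annot.get(fieldname)
                if truth is None or value in (None, "NoCall"):
                    continue
                if value != truth:
                    votes[layer] += 1
    if votes["expression"] > votes["cnv"]:
        return "expression"
    if votes["cnv"] > votes["expression"]:
        return "cnv"
    return "unknown"
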