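"""Cis-association testing between expression and gene-level CNV, and
CNV-conditioned association between gene pairs.

Correlations use Spearman rank statistics for robustness; conditioning is
implemented as partial correlation via linear residualization.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["cis_test_all", "conditional_association", "bh_adjust"]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    return stats.false_discovery_control(p, method="bh")


def cis_test_all(expr, cnv, threshold: float = 0.01) -> pd.DataFrame:
    """Spearman test of each shared gene's expression against its own
    gene-level CNV, BH-corrected across all tested genes.

    Returns a table with one row per shared gene: ``statistic``, ``pvalue``,
    ``adj_pvalue``, ``is_cis`` (adjusted p < threshold) and ``tested``
    (False for genes with a constant profile or too few complete pairs,
    which are excluded from testing and from the BH correction).
    """
    shared_genes = [g for g in expr.gene_ids if g in set(cnv.gene_ids)]
    shared_samples = [s for s in expr.sample_ids if s in set(cnv.sample_ids)]
    if not shared_genes or not shared_samples:
        raise ValueError("expression and CNV share no genes or no samples")
    e = expr.subset(genes=shared_genes, samples=shared_samples)
    c = cnv.subset(genes=shared_genes, samples=shared_samples)

    rows = []
    for i, g in enumerate(shared_genes):
        x, y = e.values[i], c.values[i]
        ok = ~(np.isnan(x) | np.isnan(y))
        if ok.sum() < 3 or np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
            rows.append((g, np.nan, np.nan, False))
            continue
        rho, p = stats.spearmanr(x[ok], y[ok])
        rows.append((g, rho, p, True))
    table = pd.DataFrame(rows, columns=["gene_id", "statistic", "pvalue", "tested"])
    table["adj_pvalue"] = np.nan
    tested = table["tested"].to_numpy()
    if tested.any():
        table.loc[tested, "adj_pvalue"] = bh_adjust(table.loc[tested, "pvalue"])
    table["is_cis"] = table["adj_pvalue"] < threshold
    return table


def _pearson_p(r: float, n: int, n_conditioned: int = 0) -> float:
    """Two-sided p for a (partial) Pearson correlation on n observations."""
    df = n - 2 - n_conditioned
    if df <= 0:
        return float("nan")
    r = min(max(r, -1.0), 1.0)
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df))


def conditional_association(x, y, c):
    """Association of (x, y) before and after conditioning on c.

    Raw p comes from a Pearson correlation test of (x, y). The conditioned
    p is the partial correlation: Pearson on the residuals of x and y after
    linear regression on c, with the degree of freedom reduced by one for
    the conditioning variable.

    Returns ``(raw_p, conditioned_p, constant_c)``; when c is constant the
    conditioned p equals the raw p and ``constant_c`` is True.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    c = np.asarray(c, dtype=float)
    if not (len(x) == len(y) == len(c)):
        raise ValueError("x, y, c must have equal lengths")
    if len(x) < 10:
        raise ValueError("need at least 10 observations")
    r_raw = float(np.corrcoef(x, y)[0, 1])
    raw_p = _pearson_p(r_raw, len(x))
    if np.ptp(c) == 0:
        return raw_p, raw_p, True
    design = np.column_stack([np.ones_like(c), c])
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return raw_p, 1.0, False
    r_cond = float(np.corrcoef(rx, ry)[0, 1])
    cond_p = _pearson_p(r_cond, len(x), n_conditioned=1)
    return raw_p, cond_p, False
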