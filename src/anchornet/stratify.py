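"""Risk stratification of a cohort from a gene set, and survival comparison
between the resulting groups.

Samples are clustered with k-means (k=3) on per-gene z-scored expression of
the signature genes; clusters are labeled High / Medium / Low risk by
decreasing observed event rate (events per unit follow-up time), then
compared by a 3-group log-rank test, pairwise proportional-hazards ratios,
and Kaplan-Meier estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from sklearn.cluster import KMeans

from .io import validate_survival

__all__ = [
    "RiskStratification",
    "SurvivalComparison",
    "zscore_by_gene",
    "cluster_patients",
    "compare_survival",
    "evaluate_signatures",
]

RISK_LABELS = ("High", "Medium", "Low")


@dataclass
class RiskStratification:
    groups: dict                  # sample_id -> "High" | "Medium" | "Low"
    method: str
    seed: int
    genes: tuple
    degenerate: bool = False

    @property
    def group_sizes(self) -> dict:
        sizes = {lab: 0 for lab in RISK_LABELS}
        for lab in self.groups.values():
            sizes[lab] += 1
        return sizes


@dataclass
class SurvivalComparison:
    endpoint: str
    logrank_p: float              # 3-group log-rank test
    hazard_ratios: dict           # ("High","Low") -> (HR, lo95, hi95)
    km_curves: dict = field(default_factory=dict)  # label -> DataFrame
    group_sizes: dict = field(default_factory=dict)
    unstable: tuple = ()


def zscore_by_gene(expr, genes):
    """Center/scale each requested gene row across samples.

    Returns ``(matrix, kept_genes)``; requested genes that are absent or
    have zero variance are dropped with a warning.
    """
    present = [g for g in genes if g in set(expr.gene_ids)]
    missing = sorted(set(map(str, genes)) - set(present))
    if missing:
        warnings.warn(f"{len(missing)} signature genes not in matrix: {missing[:5]}")
    if not present:
        raise ValueError("no signature genes present in the expression matrix")
    sub = expr.subset(genes=present)
    sd = np.nanstd(sub.values, axis=1, ddof=0)
    flat = sd == 0
    if flat.any():
        dropped = [g for g, f in zip(present, flat) if f]
        warnings.warn(f"dropping zero-variance genes: {dropped[:5]}")
        present = [g for g, f in zip(present, flat) if not f]
        if not present:
            raise ValueError("all signature genes have zero variance")
        sub = expr.subset(genes=present)
        sd = np.nanstd(sub.values, axis=1, ddof=0)
    mu = np.nanmean(sub.values, axis=1)
    z = (sub.values - mu[:, None]) / sd[:, None]
    return type(expr)(present, list(expr.sample_ids), z), present


def _event_rate(surv: pd.DataFrame, sample_ids) -> float:
    rows = surv[surv["sample_id"].isin(set(sample_ids))]
    if rows.empty or rows["time"].sum() == 0:
        return 0.0
    return float(rows["event"].sum() / rows["time"].sum())


def cluster_patients(z, surv: pd.DataFrame, k: int = 3, seed: int = 0,
                     n_init: int = 50, max_restarts: int = 5) -> RiskStratification:
    """k-means over sample vectors (samples x signature genes), labeled by
    decreasing observed event rate. Degenerate partitions (an empty or
    singleton-only split, or k == n) are flagged."""
    surv = validate_survival(surv)
    if z.n_samples < k:
        raise ValueError("need at least k samples")
    X = z.values.T
    labels = None
    for attempt in range(max_restarts):
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed + attempt).fit(X)
        if len(set(km.labels_)) == k:
            labels = km.labels_
            break
    degenerate = labels is None or z.n_samples == k
    if labels is None:
        labels = km.labels_
    clusters = {c: [z.sample_ids[i] for i in np.flatnonzero(labels == c)]
                for c in sorted(set(labels))}
    rates = {c: _event_rate(surv, members) for c, members in clusters.items()}
    ordered = sorted(clusters, key=lambda c: (-rates[c], c))
    if k == 3:
        names = dict(zip(ordered, RISK_LABELS))
    else:
        names = {c: f"G{rank}" for rank, c in enumerate(ordered)}
        degenerate = True
    groups = {s: names[c] for c, members in clusters.items() for s in members}
    return RiskStratification(groups=groups, method=f"kmeans(k={k})", seed=seed,
                              genes=tuple(z.gene_ids), degenerate=degenerate)


def _pairwise_hr(surv: pd.DataFrame, groups: dict, a: str, b: str):
    """HR of group a relative to group b from a two-group Cox fit."""
    rows = surv[surv["sample_id"].isin({s for s, g in groups.items()
                                        if g in (a, b)})].copy()
    rows["x"] = [1.0 if groups[s] == a else 0.0 for s in rows["sample_id"]]
    if rows[rows["x"] == 1]["event"].sum() == 0 or rows[rows["x"] == 0]["event"].sum() == 0:
        return None
    cph = CoxPHFitter()
    cph.fit(rows[["time", "event", "x"]], duration_col="time", event_col="event")
    hr = float(np.exp(cph.params_["x"]))
    lo, hi = np.exp(cph.confidence_intervals_.loc["x"]).to_numpy()
    return hr, float(lo), float(hi)


def compare_survival(strat: RiskStratification, surv: pd.DataFrame,
                     endpoint: str = None) -> SurvivalComparison:
    """3-group log-rank p, pairwise hazard ratios, and KM curves."""
    surv = validate_survival(surv)
    if endpoint is not None:
        surv = surv[surv["endpoint"] == endpoint].reset_index(drop=True)
    else:
        endpoint = surv["endpoint"].iloc[0] if len(surv) else "OS"
    surv = surv[surv["sample_id"].isin(strat.groups)].reset_index(drop=True)
    labels = pd.Series([strat.groups[s] for s in surv["sample_id"]])
    present = sorted(set(labels))
    if len(present) < 2:
        raise ValueError("need at least 2 groups for survival comparison")
    with_events = [g for g in present
                   if surv.loc[(labels == g).to_numpy(), "event"].sum() > 0]
    if len(with_events) < 2:
        raise ValueError("need at least 2 groups with at least one event")
    res = multivariate_logrank_test(surv["time"], labels, surv["event"])
    hrs, unstable = {}, []
    for a, b in (("High", "Low"), ("High", "Medium"), ("Medium", "Low")):
        if a not in present or b not in present:
            continue
        fit = _pairwise_hr(surv, strat.groups, a, b)
        if fit is None:
            unstable.append((a, b))
        else:
            hrs[(a, b)] = fit
    km = {}
    for g in present:
        mask = (labels == g).to_numpy()
        fitter = KaplanMeierFitter()
        fitter.fit(surv.loc[mask, "time"], surv.loc[mask, "event"], label=g)
        table = fitter.event_table
        km[g] = pd.DataFrame({
            "time": fitter.survival_function_.index.to_numpy(),
            "survival": fitter.survival_function_[g].to_numpy(),
            "at_risk": table["at_risk"].reindex(
                fitter.survival_function_.index).to_numpy(),
        })
    sizes = {g: int((labels == g).sum()) for g in present}
    return SurvivalComparison(endpoint=endpoint, logrank_p=float(res.p_value),
                              hazard_ratios=hrs, km_curves=km,
                              group_sizes=sizes, unstable=tuple(unstable))


def evaluate_signatures(expr, surv: pd.DataFrame, signatures, k: int = 3,
                        seed: int = 0) -> pd.DataFrame:
    """Run zscore -> cluster -> compare for each signature and endpoint;
    emit one row per (signature, endpoint) with the log-rank p and the three
    pairwise HRs. Signatures with fewer than 2 mapped genes are skipped."""
    surv = validate_survival(surv)
    rows = []
    for sig in signatures:
        mapped = [g for g in sorted(sig.genes) if g in set(expr.gene_ids)]
        if len(mapped) < 2:
            warnings.warn(f"signature {sig.name!r}: <2 mapped genes, skipped")
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            z, _ = zscore_by_gene(expr, mapped)
        for endpoint in sorted(surv["endpoint"].unique()):
            sub = surv[surv["endpoint"] == endpoint]
            strat = cluster_patients(z, sub, k=k, seed=seed)
            comp = compare_survival(strat, sub, endpoint=endpoint)

            def _hr(pair):
                v = comp.hazard_ratios.get(pair)
                return v[0] if v else np.nan

            rows.append({
                "signature": sig.name,
                "endpoint": endpoint,
                "n_genes": len(mapped),
                "logrank_p": comp.logrank_p,
                "hr_high_low": _hr(("High", "Low")),
                "hr_high_med": _hr(("High", "Medium")),
                "hr_med_low": _hr(("Medium", "Low")),
                "degenerate": strat.degenerate,
            })
    return pd.DataFrame(rows, columns=[
        "signature", "endpoint", "n_genes", "logrank_p",
        "hr_high_low", "hr_high_med", "hr_med_low", "degenerate",
    ])
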