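"""Cohort-level and screening statistics used around the splicing results.

Spearman correlation (tumor expression vs isoform levels), Kaplan-Meier
stratification of survival at an expression cutoff with a log-rank test,
relative qPCR quantification by the delta-delta-Ct method, CRISPR
gene-effect essentiality filtering, gene co-dependency correlation, and
hypergeometric over-representation with BH FDR.
"""
from __future__ import annotations

import itertools
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

from .stats_util import bh_fdr

__all__ = [
    "spearman",
    "km_estimate",
    "logrank",
    "stratify_by_cutoff",
    "ddct",
    "essential_gene_filter",
    "codependency",
    "hypergeom_enrichment",
    "bh_fdr",
]


def spearman(x, y, exact_below: int = 10) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    Pairs with a missing value are deleted.  Ties receive mid-ranks.  For
    n >= ``exact_below`` the p-value uses the t approximation
    ``t = rho * sqrt((n-2)/(1-rho^2))``; below that, all n! pairings are
    enumerated for an exact permutation p.  A constant vector leaves rho
    undefined (NaN, NaN).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValueError(f"need >=3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan, np.nan

    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n >= exact_below:
        res = stats.spearmanr(x, y)
        return rho, float(res.pvalue)
    # exact permutation over all pairings of the ranks
    perms = np.array(list(itertools.permutations(range(n))))
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = math.sqrt(float((rxc**2).sum() * (ryc**2).sum()))
    rhos = (rxc[perms] @ ryc) / denom
    p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    return rho, p


def km_estimate(table: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Kaplan-Meier product-limit survival curves per group.

    ``table`` needs columns time (> 0), event (1 = occurred, 0 =
    censored) and group.  Returns group -> DataFrame(time, survival),
    each curve starting at S(0) = 1 and non-increasing.  Ties between an
    event and a censoring at the same time follow the standard convention
    (censoring after events).
    """
    _check_survival(table)
    out: dict[str, pd.DataFrame] = {}
    for group, sub in table.groupby("group", sort=True):
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], event_observed=sub["event"])
        sf = kmf.survival_function_
        out[str(group)] = pd.DataFrame(
            {"time": sf.index.to_numpy(dtype=float),
             "survival": sf.iloc[:, 0].to_numpy(dtype=float)}
        )
    return out


def logrank(table: pd.DataFrame) -> tuple[float, float, int]:
    """Two-group log-rank test; returns (chi-square statistic, p, df=1)."""
    _check_survival(table)
    groups = sorted(table["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"log-rank needs exactly 2 groups, got {groups}")
    a = table[table["group"] == groups[0]]
    b = table[table["group"] == groups[1]]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("one group is empty")
    if table["event"].sum() == 0:
        raise ValueError("log-rank needs at least one event")
    res = logrank_test(a["time"], b["time"], a["event"], b["event"])
    return float(res.test_statistic), float(res.p_value), 1


def _check_survival(table: pd.DataFrame) -> None:
    for col in ("time", "event", "group"):
        if col not in table.columns:
            raise ValueError(f"survival table missing column {col!r}")
    if (table["time"] <= 0).any():
        raise ValueError("survival times must be positive")
    if not table["event"].isin([0, 1]).all():
        raise ValueError("event indicator must be 0/1")


def stratify_by_cutoff(values, cutoff: float) -> np.ndarray:
    """Binary 'high'/'low' labels at an expression cutoff (high iff > cutoff)."""
    values = np.asarray(values, dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("expression values must be finite")
    return np.where(values > cutoff, "high", "low")


def ddct(table: pd.DataFrame, control_group: str) -> pd.DataFrame:
    """Relative expression 2^(-ddCt) per sample from a Ct table.

    ``table`` columns: sample, group, target_ct, reference_ct; replicate
    wells are rows and are averaged per sample.  dCt = mean target Ct -
    mean reference Ct; ddCt subtracts the control-group mean dCt, so the
    control group's mean ddCt is 0 exactly (geometric-mean expression 1).
    """
    for col in ("sample", "group", "target_ct", "reference_ct"):
        if col not in table.columns:
            raise ValueError(f"Ct table missing column {col!r}")
    missing = table[table["reference_ct"].isna()]
    if not missing.empty:
        raise ValueError(
            f"missing reference Ct for sample(s) {sorted(missing['sample'].unique())}"
        )
    per_sample = (
        table.groupby(["sample", "group"], sort=False)[["target_ct", "reference_ct"]]
        .mean()
        .reset_index()
    )
    per_sample["dct"] = per_sample["target_ct"] - per_sample["reference_ct"]
    control = per_sample[per_sample["group"] == control_group]
    if control.empty:
        raise ValueError(f"control group {control_group!r} has no samples")
    baseline = control["dct"].mean()
    per_sample["ddct"] = per_sample["dct"] - baseline
    per_sample["relative_expression"] = 2.0 ** (-per_sample["ddct"])
    return per_sample[["sample", "group", "dct", "ddct", "relative_expression"]]


def essential_gene_filter(effects: pd.DataFrame, threshold: float = -0.4) -> pd.DataFrame:
    """Genes whose mean dependency score falls strictly below ``threshold``.

    ``effects`` is genes x cell lines; missing values are ignored in the
    mean.  More negative scores mean stronger essentiality, so the result
    is sorted ascending by mean (most essential first).
    """
    means = effects.mean(axis=1, skipna=True)
    hits = means[means < threshold].sort_values()
    return pd.DataFrame({"gene_id": hits.index, "mean_score": hits.to_numpy()})


def codependency(
    effects: pd.DataFrame,
    query: str,
    method: str = "spearman",
    min_overlap: int = 10,
) -> pd.DataFrame:
    """Correlation of every gene's effect profile with the query gene's.

    Pairwise-complete over cell lines; pairs with fewer than
    ``min_overlap`` shared observations are skipped (reported with NaN
    rho and their overlap count).  Returns a table sorted by rho
    descending with BH FDR over the tested pairs.  Works equally for a
    metabolite-abundance vector appended as a row of ``effects``.
    """
    if query not in effects.index:
        raise KeyError(f"query gene {query!r} not in effect matrix")
    if method not in ("spearman", "pearson"):
        raise ValueError("method must be 'spearman' or 'pearson'")
    qv = effects.loc[query].to_numpy(dtype=float)

    rows = []
    for gene in effects.index:
        gv = effects.loc[gene].to_numpy(dtype=float)
        keep = ~(np.isnan(qv) | np.isnan(gv))
        n = int(keep.sum())
        if n < min_overlap:
            rows.append({"gene_id": gene, "rho": np.nan, "p_value": np.nan, "n": n})
            continue
        if gene == query:
            rows.append({"gene_id": gene, "rho": 1.0, "p_value": 0.0, "n": n})
            continue
        if method == "spearman":
            rho, p = spearman(qv[keep], gv[keep])
        else:
            if np.ptp(qv[keep]) == 0 or np.ptp(gv[keep]) == 0:
                rho, p = np.nan, np.nan
            else:
                res = stats.pearsonr(qv[keep], gv[keep])
                rho, p = float(res.statistic), float(res.pvalue)
        rows.append({"gene_id": gene, "rho": rho, "p_value": p, "n": n})

    df = pd.DataFrame(rows)
    df["fdr"] = bh_fdr(df["p_value"].to_numpy())
    return df.sort_values("rho", ascending=False, na_position="last").reset_index(drop=True)


def hypergeom_enrichment(
    hits: set[str],
    background: set[str],
    annotation: Mapping[str, str] | Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation per category.

    ``annotation`` maps gene -> category (or list of categories).  Every
    hit must be in the background.  Returns per category the overlap, the
    expected overlap, the upper-tail p and BH FDR.
    """
    hits = set(hits)
    background = set(background)
    outside = hits - background
    if outside:
        raise ValueError(f"hits outside background: {sorted(outside)[:5]}")

    cat_members: dict[str, set[str]] = {}
    for gene, cats in annotation.items():
        if gene not in background:
            continue
        if isinstance(cats, str):
            cats = [cats]
        for c in cats:
            cat_members.setdefault(c, set()).add(gene)

    m_total = len(background)
    n_hits = len(hits)
    rows = []
    for cat in sorted(cat_members):
        members = cat_members[cat]
        k = len(hits & members)
        expected = n_hits * len(members) / m_total
        p = float(stats.hypergeom.sf(k - 1, m_total, len(members), n_hits))
        rows.append(
            {"category": cat, "overlap": k, "category_size": len(members),
             "expected": expected, "p_value": p}
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        df["fdr"] = bh_fdr(df["p_value"].to_numpy())
    return df
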