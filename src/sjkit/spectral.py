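"""Spectral-count interactome enrichment via the G-test.

Spectral counts from IP-MS reflect relative protein abundance within a
sample once protein size is normalized out; the two-sample G-test (a
likelihood-ratio goodness-of-fit against an equal-split null) yields a
per-protein p-value for bait-vs-control enrichment.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .stats_util import bh_fdr


def size_normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Length-normalize spectral counts, preserving per-sample totals.

    ``table`` needs columns protein_id, length, then one count column per
    sample.  Each protein's counts are divided by its length (amino
    acids) and the column rescaled so the normalized values sum to the
    sample's raw total, keeping count magnitudes meaningful for the
    G-test.  Zero lengths are an error; equal lengths make this the
    identity.
    """
    _check_table(table)
    if (table["length"] <= 0).any():
        raise ValueError("protein lengths must be positive")
    samples = _sample_columns(table)
    out = table.copy()
    for s in samples:
        raw = table[s].to_numpy(dtype=float)
        rate = raw / table["length"].to_numpy(dtype=float)
        total = rate.sum()
        out[s] = rate * (raw.sum() / total) if total > 0 else rate
    return out


def g_test(a: float, b: float, pseudocount: float = 0.5) -> tuple[float, float]:
    """Two-sample G-test against an equal-abundance null.

    With a' = a + pseudocount, b' = b + pseudocount and expected
    e = (a' + b')/2::

        G = 2 * (a' ln(a'/e) + b' ln(b'/e))

    p is the upper chi-square(1) tail at G.  A zero cell with
    pseudocount 0 uses the 0*ln(0) := 0 convention.  Both inputs zero
    (after pseudocount) is untested -> (NaN, NaN).
    """
    if a < 0 or b < 0:
        raise ValueError("spectral counts must be non-negative")
    ap = a + pseudocount
    bp = b + pseudocount
    if ap + bp == 0:
        return np.nan, np.nan
    e = (ap + bp) / 2.0
    g = 0.0
    for v in (ap, bp):
        if v > 0:
            g += v * np.log(v / e)
    g *= 2.0
    g = max(g, 0.0)
    return float(g), float(stats.chi2.sf(g, df=1))


def interactome_contrast(
    table: pd.DataFrame,
    bait_sample: str,
    control_sample: str,
    fdr_alpha: float = 0.05,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-protein enrichment of the bait IP over the control IP.

    Size-normalizes the counts, applies the G-test per protein and BH
    FDR over tested proteins; a protein is 'enriched' when FDR <
    ``fdr_alpha`` and its normalized bait count exceeds control.
    Proteins with zero counts in both samples are untested.
    """
    _check_table(table)
    for s in (bait_sample, control_sample):
        if s not in table.columns:
            raise ValueError(f"sample {s!r} not in spectral count table")
    norm = size_normalize(table)
    bait = norm[bait_sample].to_numpy(dtype=float)
    ctrl = norm[control_sample].to_numpy(dtype=float)

    g = np.full(len(norm), np.nan)
    p = np.full(len(norm), np.nan)
    for i, (x, y) in enumerate(zip(bait, ctrl)):
        if x == 0 and y == 0:
            continue
        g[i], p[i] = g_test(x, y, pseudocount=pseudocount)
    fdr = bh_fdr(p)
    out = pd.DataFrame(
        {
            "protein_id": table["protein_id"],
            "bait_normalized": bait,
            "control_normalized": ctrl,
            "G": g,
            "p_value": p,
            "fdr": fdr,
        }
    )
    out["enriched"] = (out["fdr"] < fdr_alpha) & (bait > ctrl)
    out["enriched"] = out["enriched"].fillna(False)
    return out


def _sample_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in ("protein_id", "length")]


def _check_table(table: pd.DataFrame) -> None:
    for col in ("protein_id", "length"):
        if col not in table.columns:
            raise ValueError(f"spectral count table missing column {col!r}")
    if table["protein_id"].duplicated().any():
        raise ValueError("duplicate protein ids")
    samples = _sample_columns(table)
    if not samples:
        raise ValueError("no sample count columns")
    if (table[samples].to_numpy() < 0).any():
        raise ValueError("negative spectral counts")
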