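"""Between-sample normalization of the junction count matrix.

Scaling factors are computed with the trimmed mean of M-values (TMM)
method: log ratios (M) and log average abundances (A) against a
reference sample are doubly trimmed, and the factor is ``2**`` the
precision-weighted mean of the surviving M values, with all factors
rescaled to geometric mean 1.  The downstream working scale is log2
counts-per-million with a prior count, using TMM-effective library
sizes.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .models import JunctionCountMatrix, SampleDesign, conditions_in_order

logger = logging.getLogger(__name__)


@dataclass
class NormFactors:
    """Per-sample library sizes and TMM scaling factors.

    ``effective_sizes`` (library size x factor) is what log-CPM divides
    by.  Factors always have geometric mean 1.
    """

    samples: list[str]
    library_sizes: np.ndarray
    tmm_factors: np.ndarray

    def __post_init__(self) -> None:
        self.library_sizes = np.asarray(self.library_sizes, dtype=np.int64)
        self.tmm_factors = np.asarray(self.tmm_factors, dtype=float)
        if (self.tmm_factors <= 0).any():
            raise ValueError("TMM factors must be positive")
        log_gm = float(np.mean(np.log(self.tmm_factors)))
        if abs(log_gm) > 1e-10:
            raise ValueError(f"TMM factors do not have geometric mean 1 (log gm {log_gm:g})")

    @property
    def effective_sizes(self) -> np.ndarray:
        return self.library_sizes * self.tmm_factors

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.samples,
                "library_size": self.library_sizes,
                "tmm_factor": self.tmm_factors,
            }
        )


def _as_counts(matrix: JunctionCountMatrix | np.ndarray) -> tuple[np.ndarray, list[str]]:
    if isinstance(matrix, JunctionCountMatrix):
        return matrix.counts, matrix.samples
    counts = np.asarray(matrix)
    return counts, [f"s{i}" for i in range(counts.shape[1])]


def library_sizes(matrix: JunctionCountMatrix | np.ndarray) -> np.ndarray:
    """Column sums of unique-read counts; an all-zero sample is an error."""
    counts, samples = _as_counts(matrix)
    sizes = counts.sum(axis=0)
    zero = np.nonzero(sizes == 0)[0]
    if zero.size:
        raise ValueError(f"sample(s) with zero total counts: {[samples[i] for i in zero]}")
    return sizes


def tmm_factors(
    matrix: JunctionCountMatrix | np.ndarray,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> NormFactors:
    """TMM scaling factors for each sample of the count matrix.

    The reference sample is the one whose 75th-percentile CPM (over rows
    nonzero in that sample) is closest to the across-sample mean of that
    quantity (ties -> lowest index).  For every other sample k, over rows
    with positive counts in both k and the reference r::

        M = log2((y_k/N_k) / (y_r/N_r))
        A = 0.5 * log2((y_k/N_k) * (y_r/N_r))

    ``trim_m``/``trim_a`` of each tail of M and A are trimmed (double
    trimming), and the factor is ``2**`` the weighted mean of the kept M
    with inverse-asymptotic-variance weights
    ``1/w = (N_k - y_k)/(N_k y_k) + (N_r - y_r)/(N_r y_r)``.
    Degenerate trims (<10 surviving rows) fall back to the untrimmed
    weighted mean; a sample sharing no nonzero rows with the reference
    gets factor 1.  Finally all factors are rescaled to geometric mean 1.
    """
    counts, samples = _as_counts(matrix)
    if counts.ndim != 2 or counts.shape[1] < 2:
        raise ValueError("TMM needs a 2-D matrix with >=2 samples")
    sizes = library_sizes(counts)
    counts = counts.astype(float)

    cpm = counts / sizes * 1e6
    f75 = np.array(
        [np.percentile(cpm[counts[:, k] > 0, k], 75) for k in range(counts.shape[1])]
    )
    ref = int(np.argmin(np.abs(f75 - f75.mean())))

    factors = np.ones(counts.shape[1])
    yr_all = counts[:, ref]
    nr = float(sizes[ref])
    for k in range(counts.shape[1]):
        if k == ref:
            continue
        yk_all = counts[:, k]
        nk = float(sizes[k])
        mask = (yk_all > 0) & (yr_all > 0)
        if not mask.any():
            logger.warning(
                "sample %s shares no nonzero junctions with reference %s; factor 1",
                samples[k],
                samples[ref],
            )
            continue
        yk = yk_all[mask]
        yr = yr_all[mask]
        pk = yk / nk
        pr = yr / nr
        m = np.log2(pk / pr)
        a = 0.5 * np.log2(pk * pr)
        w = 1.0 / ((nk - yk) / (nk * yk) + (nr - yr) / (nr * yr))

        n = m.size
        rank_m = rankdata(m)
        rank_a = rankdata(a)
        lo_m = math.floor(n * trim_m) + 1
        hi_m = n + 1 - lo_m
        lo_a = math.floor(n * trim_a) + 1
        hi_a = n + 1 - lo_a
        keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if keep.sum() < 10:
            logger.warning(
                "sample %s: only %d junctions survive trimming; using untrimmed mean",
                samples[k],
                int(keep.sum()),
            )
            keep = np.ones(n, dtype=bool)
        factors[k] = 2.0 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep]))

    factors = factors / np.exp(np.mean(np.log(factors)))
    return NormFactors(list(samples), sizes, factors)


def log_cpm(
    matrix: JunctionCountMatrix | np.ndarray,
    factors: NormFactors,
    prior_count: float = 0.5,
) -> np.ndarray:
    """log2 counts-per-million on TMM-effective library sizes.

    value = log2((count + prior) / (effective_size + 2*prior) * 1e6).
    Finite everywhere for prior_count > 0 and strictly increasing in the
    underlying count.
    """
    counts, samples = _as_counts(matrix)
    if counts.shape[1] != len(factors.samples):
        raise ValueError(
            f"matrix has {counts.shape[1]} samples but factors have {len(factors.samples)}"
        )
    if isinstance(matrix, JunctionCountMatrix) and matrix.samples != factors.samples:
        raise ValueError("sample order mismatch between matrix and factors")
    eff = factors.effective_sizes
    return np.log2((counts + prior_count) / (eff + 2.0 * prior_count) * 1e6)


def condition_means(
    logmat: np.ndarray, design: Sequence[SampleDesign], conditions: Sequence[str] | None = None
) -> pd.DataFrame:
    """Arithmetic mean of log-CPM within each condition (genotype averaging).

    Returns a DataFrame with one column per condition, rows aligned to the
    matrix's junction order.
    """
    if conditions is None:
        conditions = conditions_in_order(design)
    cols = {}
    for cond in conditions:
        mask = np.array([d.condition == cond for d in design])
        if not mask.any():
            raise ValueError(f"condition {cond!r} absent from design")
        cols[cond] = logmat[:, mask].mean(axis=1)
    return pd.DataFrame(cols)
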