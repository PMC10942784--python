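"""Differential splicing from the unified junction matrix.

The central idea: a gene's overall expression change is estimated from
the canonical junctions of its most abundant isoform, and a junction
whose fold change *deviates* from that gene-level change is flagged as
differentially spliced.  The deviation is tested with a moderated t
statistic on the junction-minus-gene residual (empirical-Bayes variance
shrinkage, BH FDR).  The module also classifies junction-graph events
(SE / A5SS / A3SS / MXE) with per-sample PSI and permutation tests, and
calls two-isoform switches of the glutaminase GAC/KGA type from
isoform-diagnostic junction counts.
"""
from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .junctions import (
    AMBIGUOUS,
    UNASSIGNED,
    diagnostic_junctions,
    gene_junctions,
    transcript_junctions,
)
from .models import GeneModel, Junction, JunctionCountMatrix, SampleDesign, resolve_contrast
from .stats_util import bh_fdr

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Gene-level expression from canonical junctions
# ---------------------------------------------------------------------------

@dataclass
class GeneExpressionEstimate:
    """Gene expression summarized from its most abundant isoform's junctions."""

    gene_id: str
    transcript_id: str
    junctions: list[Junction]
    per_sample: np.ndarray
    condition_means: dict[str, float]
    log2fc: float


def estimate_gene_expression(
    matrix: JunctionCountMatrix,
    logmat: np.ndarray,
    models: Sequence[GeneModel],
    conditions: tuple[str, str] | None = None,
) -> dict[str, GeneExpressionEstimate]:
    """Per-gene expression from the canonical junctions of the most
    abundant isoform.

    The most abundant isoform is the transcript maximizing the mean
    log-CPM over its matrix-present junctions, averaged over *all*
    samples (so the gene baseline is fixed across the contrast); ties go
    to the lexicographically smallest transcript_id.  Gene expression per
    sample is the mean log-CPM over the chosen transcript's junctions and
    the gene log2 fold change is condition B minus condition A.

    Genes with no matrix-present annotated junction are skipped with a
    logged warning.
    """
    cond_a, cond_b = resolve_contrast(matrix.design, conditions)
    mask_a = matrix.sample_mask(cond_a)
    mask_b = matrix.sample_mask(cond_b)

    out: dict[str, GeneExpressionEstimate] = {}
    for model in models:
        per_tx = transcript_junctions(model)
        proxies: list[tuple[float, str, list[Junction]]] = []
        for tid in sorted(per_tx):
            present = [j for j in per_tx[tid] if j in matrix]
            if not present:
                continue
            rows = np.array([matrix.index_of(j) for j in present])
            proxies.append((float(logmat[rows].mean()), tid, present))
        if not proxies:
            logger.warning(
                "gene %s has no junctions present in the matrix; skipped",
                model.gene_id,
            )
            continue
        # argmax on abundance proxy; tie -> lexicographically smallest tid
        _, tid, present = sorted(proxies, key=lambda t: (-t[0], t[1]))[0]
        rows = np.array([matrix.index_of(j) for j in present])
        per_sample = logmat[rows].mean(axis=0)
        means = {
            cond_a: float(per_sample[mask_a].mean()),
            cond_b: float(per_sample[mask_b].mean()),
        }
        out[model.gene_id] = GeneExpressionEstimate(
            gene_id=model.gene_id,
            transcript_id=tid,
            junctions=present,
            per_sample=per_sample,
            condition_means=means,
            log2fc=means[cond_b] - means[cond_a],
        )
    return out


# ---------------------------------------------------------------------------
# Junction-vs-gene deviation test
# ---------------------------------------------------------------------------

def junction_deviation_test(
    matrix: JunctionCountMatrix,
    logmat: np.ndarray,
    estimates: Mapping[str, GeneExpressionEstimate],
    assignment: Mapping[Junction, str],
    d0: float = 4.0,
    alpha: float = 0.05,
    delta_min: float = 1.0,
    min_count: int = 5,
    conditions: tuple[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Moderated-t deviation calls for every gene-assigned junction.

    For junction j of gene g the per-sample residual is
    ``r_{j,s} = logCPM_{j,s} - geneExpr_{g,s}``; the deviation
    ``delta_j`` is the difference of condition means of r, algebraically
    identical to (junction log2FC - gene log2FC).  The pooled
    within-condition variance of r (df = n_A + n_B - 2) is shrunk toward
    ``s0^2`` (the median residual variance across tested junctions) with
    prior df ``d0``; the statistic is t with ``d0 + df`` degrees of
    freedom and BH FDR across all tested junctions.  A junction is called
    iff FDR < alpha and \\|delta\\| >= delta_min.

    Junctions are tested only when expressed (count >= ``min_count`` in at
    least min(n_A, n_B) samples).  With a single replicate per condition
    the variance is undefined: only delta is reported (p, FDR = NaN).

    Returns ``(calls, unassigned)``: the calls table and a sidecar of
    junctions excluded because they map to no gene or to several genes.
    """
    cond_a, cond_b = resolve_contrast(matrix.design, conditions)
    mask_a = matrix.sample_mask(cond_a)
    mask_b = matrix.sample_mask(cond_b)
    n_a, n_b = int(mask_a.sum()), int(mask_b.sum())
    df_resid = n_a + n_b - 2
    min_samples = min(n_a, n_b)

    rows: list[dict] = []
    side: list[dict] = []
    for i, j in enumerate(matrix.junctions):
        gene = assignment.get(j, UNASSIGNED)
        if gene in (UNASSIGNED, AMBIGUOUS):
            side.append(
                {"chrom": j.chrom, "start": j.start, "end": j.end, "strand": j.strand,
                 "reason": "ambiguous" if gene == AMBIGUOUS else "unassigned"}
            )
            continue
        est = estimates.get(gene)
        if est is None:
            side.append(
                {"chrom": j.chrom, "start": j.start, "end": j.end, "strand": j.strand,
                 "reason": "gene_not_estimated"}
            )
            continue
        if int((matrix.counts[i] >= min_count).sum()) < min_samples:
            continue
        x = logmat[i]
        fc_junction = float(x[mask_b].mean() - x[mask_a].mean())
        fc_gene = est.log2fc
        delta = fc_junction - fc_gene
        r = x - est.per_sample
        if min(n_a, n_b) >= 2:
            ss = float(((r[mask_a] - r[mask_a].mean()) ** 2).sum()
                       + ((r[mask_b] - r[mask_b].mean()) ** 2).sum())
            s2 = ss / df_resid
        else:
            s2 = np.nan
        rows.append(
            {
                "chrom": j.chrom, "start": j.start, "end": j.end, "strand": j.strand,
                "gene_id": gene,
                "log2fc_junction": fc_junction,
                "log2fc_gene": fc_gene,
                "delta": delta,
                "s2": s2,
            }
        )

    calls = pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "strand", "gene_id",
                 "log2fc_junction", "log2fc_gene", "delta", "s2"],
    )
    side_df = pd.DataFrame(side, columns=["chrom", "start", "end", "strand", "reason"])

    if calls.empty:
        for col in ("moderated_t", "df_total", "p_value", "fdr"):
            calls[col] = pd.Series(dtype=float)
        calls["is_called"] = pd.Series(dtype=bool)
        return calls, side_df

    if df_resid >= 2 and calls["s2"].notna().any():
        s0_sq = float(np.nanmedian(calls["s2"]))
        s2_mod = (d0 * s0_sq + df_resid * calls["s2"]) / (d0 + df_resid)
        se = np.sqrt(s2_mod * (1.0 / n_a + 1.0 / n_b))
        t = calls["delta"] / se
        df_total = d0 + df_resid
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
        calls["moderated_t"] = t
        calls["df_total"] = float(df_total)
        calls["p_value"] = p
        calls["fdr"] = bh_fdr(p)
        calls["is_called"] = (calls["fdr"] < alpha) & (calls["delta"].abs() >= delta_min)
    else:
        calls["moderated_t"] = np.nan
        calls["df_total"] = np.nan
        calls["p_value"] = np.nan
        calls["fdr"] = np.nan
        calls["is_called"] = False
    return calls, side_df


# ---------------------------------------------------------------------------
# Splice graph and event classification
# ---------------------------------------------------------------------------

@dataclass
class SpliceGraph:
    """Donor/acceptor adjacency over one gene's junctions.

    Nodes are the distinct donor (intron start) and acceptor (intron end)
    coordinates; edges are the junctions themselves with their total
    unique-read support.
    """

    junctions: tuple[Junction, ...]
    donors: dict[int, tuple[Junction, ...]]
    acceptors: dict[int, tuple[Junction, ...]]
    support: dict[Junction, int]

    @property
    def n_nodes(self) -> int:
        return len(self.donors) + len(self.acceptors)


def build_splice_graph(
    junctions: Sequence[Junction],
    support: Mapping[Junction, int] | None = None,
) -> SpliceGraph:
    if not junctions:
        raise ValueError("cannot build a splice graph from zero junctions")
    js = tuple(sorted(set(junctions)))
    donors: dict[int, list[Junction]] = {}
    acceptors: dict[int, list[Junction]] = {}
    for j in js:
        donors.setdefault(j.start, []).append(j)
        acceptors.setdefault(j.end, []).append(j)
    return SpliceGraph(
        junctions=js,
        donors={k: tuple(v) for k, v in donors.items()},
        acceptors={k: tuple(v) for k, v in acceptors.items()},
        support={j: int(support.get(j, 0)) if support else 0 for j in js},
    )


@dataclass
class SpliceEvent:
    """A classified alternative-splicing event.

    ``inclusion``/``exclusion`` are the junctions supporting the two
    forms.  For SE the skipped exon is recorded; for MXE the two mutually
    exclusive exons, ordered by coordinate.
    """

    event_type: str  # SE | A5SS | A3SS | MXE
    gene_id: str
    inclusion: tuple[Junction, ...]
    exclusion: tuple[Junction, ...]
    exons: tuple[tuple[int, int], ...] = ()
    psi: np.ndarray | None = None
    delta_psi: float = np.nan
    p_value: float = np.nan
    fdr: float = np.nan
    significant: bool = False

    def key(self) -> tuple:
        return (self.event_type, self.inclusion, self.exclusion)


def _se_paths(graph: SpliceGraph, exon_set: set[tuple[int, int]]):
    """All (j1, j2, exon) inclusion paths: j1 -> annotated exon -> j2."""
    paths = []
    for j1 in graph.junctions:
        for j2 in graph.junctions:
            if j2.start <= j1.end + 1:
                continue
            exon = (j1.end + 1, j2.start - 1)
            if exon in exon_set:
                paths.append((j1, j2, exon))
    return paths


def detect_events(graph: SpliceGraph, model: GeneModel) -> list[SpliceEvent]:
    """Classify SE, A5SS, A3SS and MXE events from the junction graph.

    * SE: junctions (J1: d0->a1, J2: d1->a2) flanking an annotated exon
      (a1+1, d1-1), plus the skipping junction J3: d0->a2.
    * A5SS: two junctions sharing the acceptor coordinate but differing
      in donor; the shorter intron (longer exonic form) is 'inclusion'.
    * A3SS: two junctions sharing the donor, differing in acceptor.
    * MXE: two inclusion paths between the same outer donor/acceptor
      through two annotated exons that co-occur in no annotated
      transcript; the path through the left-most exon is 'inclusion'.

    Events are deduplicated and reported in canonical coordinate order.
    """
    exon_set: set[tuple[int, int]] = set()
    for exons in model.transcripts.values():
        exon_set.update(exons)

    events: dict[tuple, SpliceEvent] = {}

    def add(ev: SpliceEvent) -> None:
        events.setdefault(ev.key(), ev)

    # SE -------------------------------------------------------------
    paths = _se_paths(graph, exon_set)
    jset = set(graph.junctions)
    for j1, j2, exon in paths:
        skip = Junction(model.chrom, j1.start, j2.end, j1.strand)
        if skip in jset:
            add(
                SpliceEvent(
                    "SE", model.gene_id,
                    inclusion=(j1, j2), exclusion=(skip,), exons=(exon,),
                )
            )

    # A5SS / A3SS -----------------------------------------------------
    for end, js in graph.acceptors.items():
        for ja, jb in itertools.combinations(sorted(js), 2):
            # shared acceptor, different donors; shorter intron = inclusion
            incl, excl = (ja, jb) if ja.intron_length < jb.intron_length else (jb, ja)
            add(SpliceEvent("A5SS", model.gene_id, (incl,), (excl,)))
    for start, js in graph.donors.items():
        for ja, jb in itertools.combinations(sorted(js), 2):
            incl, excl = (ja, jb) if ja.intron_length < jb.intron_length else (jb, ja)
            add(SpliceEvent("A3SS", model.gene_id, (incl,), (excl,)))

    # MXE -------------------------------------------------------------
    by_outer: dict[tuple[int, int], list[tuple[Junction, Junction, tuple[int, int]]]] = {}
    for j1, j2, exon in paths:
        by_outer.setdefault((j1.start, j2.end), []).append((j1, j2, exon))
    tx_exon_sets = [set(ex) for ex in model.transcripts.values()]
    for outer, plist in by_outer.items():
        for pa, pb in itertools.combinations(sorted(plist, key=lambda p: p[2]), 2):
            ex_a, ex_b = pa[2], pb[2]
            if ex_a == ex_b:
                continue
            if any(ex_a in txs and ex_b in txs for txs in tx_exon_sets):
                continue  # exons co-occur in an annotated isoform
            add(
                SpliceEvent(
                    "MXE", model.gene_id,
                    inclusion=(pa[0], pa[1]), exclusion=(pb[0], pb[1]),
                    exons=(ex_a, ex_b),
                )
            )

    return sorted(
        events.values(),
        key=lambda e: (e.event_type, e.inclusion, e.exclusion),
    )


# ---------------------------------------------------------------------------
# PSI and permutation tests
# ---------------------------------------------------------------------------

def psi(event: SpliceEvent, matrix: JunctionCountMatrix) -> np.ndarray:
    """Per-sample percent-spliced-in for one event (NaN when unsupported).

    SE uses (I1 + I2) / (I1 + I2 + 2 S): the inclusion form is crossed by
    two junctions, the skipping form by one, so skip reads are doubled to
    balance the junction counts.  Other event types use I / (I + S).
    """
    incl = np.zeros(matrix.n_samples, dtype=float)
    excl = np.zeros(matrix.n_samples, dtype=float)
    for j in event.inclusion:
        if j in matrix:
            incl += matrix.row(j)
    for j in event.exclusion:
        if j in matrix:
            excl += matrix.row(j)
    if event.event_type == "SE":
        denom = incl + 2.0 * excl
    else:
        denom = incl + excl
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(denom > 0, incl / denom, np.nan)
    return values


def _mean_diff(values: np.ndarray, mask_b: np.ndarray) -> float:
    with np.errstate(invalid="ignore"):
        a = values[~mask_b]
        b = values[mask_b]
        a = a[~np.isnan(a)]
        b = b[~np.isnan(b)]
        if a.size == 0 or b.size == 0:
            return np.nan
        return float(b.mean() - a.mean())


def permutation_pvalue(
    values: np.ndarray,
    mask_b: np.ndarray,
    n_perm: int = 1000,
    seed: int | None = None,
    max_exact: int = 1000,
) -> tuple[float, float]:
    """Two-sided label-permutation p for a difference of group means.

    Group sizes are preserved.  All C(n, n_B) distinct label assignments
    are enumerated when there are at most ``max_exact``; otherwise
    ``n_perm`` Monte Carlo draws are taken with the given seed (required
    in that case) and the p-value uses the (1 + exceed)/(1 + n_perm)
    convention.  Returns ``(p, observed_delta)``.
    """
    values = np.asarray(values, dtype=float)
    mask_b = np.asarray(mask_b, dtype=bool)
    n = values.size
    n_b = int(mask_b.sum())
    obs = _mean_diff(values, mask_b)
    if np.isnan(obs):
        return np.nan, obs
    n_splits = math.comb(n, n_b)
    tol = 1e-12
    if n_splits <= max_exact:
        exceed = 0
        for idx in itertools.combinations(range(n), n_b):
            m = np.zeros(n, dtype=bool)
            m[list(idx)] = True
            d = _mean_diff(values, m)
            if not np.isnan(d) and abs(d) >= abs(obs) - tol:
                exceed += 1
        return exceed / n_splits, obs
    if seed is None:
        raise ValueError("Monte Carlo permutation requires a seed")
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        m = np.zeros(n, dtype=bool)
        m[perm[:n_b]] = True
        d = _mean_diff(values, m)
        if not np.isnan(d) and abs(d) >= abs(obs) - tol:
            exceed += 1
    return (1 + exceed) / (1 + n_perm), obs


def delta_psi_test(
    events: Sequence[SpliceEvent],
    matrix: JunctionCountMatrix,
    seed: int,
    n_perm: int = 1000,
    fdr_alpha: float = 0.05,
    min_abs_delta: float = 0.1,
    conditions: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Permutation test of the PSI difference for each event.

    delta_psi = mean PSI(B) - mean PSI(A); the p-value permutes condition
    labels over samples (exact enumeration when feasible); significance
    requires BH FDR < ``fdr_alpha`` and \\|delta_psi\\| > ``min_abs_delta``.
    Events with PSI defined in fewer than 2 samples of either condition
    are reported untested (NaN p).  Events are annotated in place and a
    summary table is returned.
    """
    cond_a, cond_b = resolve_contrast(matrix.design, conditions)
    mask_b = matrix.sample_mask(cond_b)
    mask_a = matrix.sample_mask(cond_a)

    for k, ev in enumerate(events):
        values = psi(ev, matrix)
        ev.psi = values
        ok_a = int((~np.isnan(values[mask_a])).sum())
        ok_b = int((~np.isnan(values[mask_b])).sum())
        if ok_a < 2 or ok_b < 2:
            ev.delta_psi = _mean_diff(values, mask_b)
            ev.p_value = np.nan
            continue
        p, obs = permutation_pvalue(
            values, mask_b, n_perm=n_perm, seed=seed + k
        )
        ev.delta_psi = obs
        ev.p_value = p

    tested = [ev for ev in events if not np.isnan(ev.p_value)]
    if tested:
        q = bh_fdr(np.array([ev.p_value for ev in tested]))
        for ev, fdr in zip(tested, q):
            ev.fdr = float(fdr)
            ev.significant = bool(fdr < fdr_alpha and abs(ev.delta_psi) > min_abs_delta)

    return events_to_frame(events)


def events_to_frame(events: Sequence[SpliceEvent]) -> pd.DataFrame:
    def _jstr(js: tuple[Junction, ...]) -> str:
        return ";".join(f"{j.start}-{j.end}" for j in js)

    return pd.DataFrame(
        {
            "event_type": [e.event_type for e in events],
            "gene_id": [e.gene_id for e in events],
            "inclusion": [_jstr(e.inclusion) for e in events],
            "exclusion": [_jstr(e.exclusion) for e in events],
            "delta_psi": [e.delta_psi for e in events],
            "p_value": [e.p_value for e in events],
            "fdr": [e.fdr for e in events],
            "significant": [e.significant for e in events],
        }
    )


# ---------------------------------------------------------------------------
# Two-isoform switch calls (GAC/KGA pattern)
# ---------------------------------------------------------------------------

@dataclass
class IsoformSwitch:
    """A two-isoform switch call from diagnostic junction counts.

    ``proportion_a`` maps condition -> pooled share of isoform_a's
    diagnostic counts; ``direction`` reads "<a>-><b>" when isoform_a
    loses share in condition B.
    """

    gene_id: str
    isoform_a: str
    isoform_b: str
    proportion_a: dict[str, float]
    delta_proportion: float
    p_value: float
    direction: str


def isoform_switch_call(
    model: GeneModel,
    matrix: JunctionCountMatrix,
    seed: int,
    n_perm: int = 1000,
    conditions: tuple[str, str] | None = None,
) -> IsoformSwitch:
    """Call an isoform switch for a gene with exactly two diagnosable isoforms.

    Per condition, isoform a's proportion is
    sum(diag_a counts) / (sum(diag_a) + sum(diag_b)) pooled over that
    condition's samples.  delta_proportion is condition B minus A; the
    p-value permutes condition labels over per-sample proportions.  A
    condition with zero total diagnostic counts leaves the call untested.
    """
    diag = diagnostic_junctions(model)
    nonempty = {tid: js for tid, js in diag.items() if js}
    if len(nonempty) > 2:
        raise ValueError(
            f"gene {model.gene_id} has {len(nonempty)} isoforms with diagnostic "
            "junctions; call isoforms pairwise instead"
        )
    if len(nonempty) < 2:
        raise ValueError(
            f"gene {model.gene_id} needs two isoforms with nonempty diagnostic "
            "junction sets"
        )
    iso_a, iso_b = sorted(nonempty)
    cond_a, cond_b = resolve_contrast(matrix.design, conditions)

    def sample_sums(js) -> np.ndarray:
        total = np.zeros(matrix.n_samples, dtype=float)
        for j in sorted(js):
            if j in matrix:
                total += matrix.row(j)
        return total

    counts_a = sample_sums(nonempty[iso_a])
    counts_b = sample_sums(nonempty[iso_b])
    mask_b = matrix.sample_mask(cond_b)
    mask_a = matrix.sample_mask(cond_a)

    pooled: dict[str, float] = {}
    for cond, mask in ((cond_a, mask_a), (cond_b, mask_b)):
        denom = counts_a[mask].sum() + counts_b[mask].sum()
        pooled[cond] = float(counts_a[mask].sum() / denom) if denom > 0 else np.nan

    if any(np.isnan(v) for v in pooled.values()):
        return IsoformSwitch(
            model.gene_id, iso_a, iso_b, pooled, np.nan, np.nan, "untested"
        )

    delta = pooled[cond_b] - pooled[cond_a]
    denom = counts_a + counts_b
    with np.errstate(invalid="ignore", divide="ignore"):
        per_sample = np.where(denom > 0, counts_a / denom, np.nan)
    p, _ = permutation_pvalue(per_sample, mask_b, n_perm=n_perm, seed=seed)

    if delta < 0:
        direction = f"{iso_a}->{iso_b}"
    elif delta > 0:
        direction = f"{iso_b}->{iso_a}"
    else:
        direction = "none"
    return IsoformSwitch(model.gene_id, iso_a, iso_b, pooled, float(delta), p, direction)
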