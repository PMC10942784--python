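"""Synthetic study generator for every input the pipeline consumes.

The junction simulator emulates the count structure the pipeline
assumes: per-condition isoform mixtures over a toy annotation, expected
junction counts proportional to summed isoform proportions, negative
binomial sampling (variance m + phi*m^2) with variable library sizes,
and planted isoform switches and differentially expressed genes whose
ground truth is returned for parameter-recovery tests.  Companion
generators produce spectral-count tables, survival cohorts and CRISPR
gene-effect matrices.

Everything is a deterministic function of (config, seed): the same
configuration yields byte-identical output files.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from . import io
from .junctions import build_matrix, gene_junctions, transcript_junctions
from .models import GeneModel, Junction, JunctionCountMatrix, SampleDesign, SJRecord


@dataclass
class SimConfig:
    """Study conditions for the junction-count simulator.

    ``exon_range`` applies to single-isoform genes; multi-isoform genes
    draw from ``multi_exon_range`` so that a cassette or alternative
    terminal structure always leaves shared flanking junctions on which
    the gene-level baseline can rest.  ``dispersion`` is the NB phi in
    Var = m + phi*m^2.  ``switch_delta`` bounds the planted proportion
    change of switch genes (drawn only from 2-isoform genes).
    """

    seed: int
    n_genes: int = 200
    isoform_probs: tuple[float, float, float] = (0.5, 0.4, 0.1)
    exon_range: tuple[int, int] = (3, 10)
    multi_exon_range: tuple[int, int] = (6, 10)
    n_switch: int = 20
    switch_delta: tuple[float, float] = (0.3, 0.6)
    n_de: int = 20
    de_fold: tuple[float, float] = (2.0, 4.0)
    dispersion: float = 0.1
    library_size: float = 1e6
    library_sigma: float = 0.3
    n_replicates: int = 3
    conditions: tuple[str, str] = ("control", "knockdown")
    junction_cv: float = 0.0
    overlap: bool = False

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is required")
        if abs(sum(self.isoform_probs) - 1.0) > 1e-9:
            raise ValueError("isoform_probs must sum to 1")
        if self.dispersion < 0 or self.library_size <= 0 or self.n_replicates < 1:
            raise ValueError("invalid simulation parameters")


@dataclass
class SimTruth:
    """Ground truth of one simulated study.

    genes: per-gene base weight, DE factor (applied in condition B),
    switch flag and planted proportion change.
    proportions: per (gene, transcript, condition) isoform proportion.
    junctions: per junction its gene and role ('shared' or the transcript
    it is diagnostic for).
    expected: per junction the expected (mean) count per sample.
    """

    genes: pd.DataFrame
    proportions: pd.DataFrame
    junctions: pd.DataFrame
    expected: pd.DataFrame

    def switch_gene_ids(self) -> list[str]:
        return sorted(self.genes.loc[self.genes["is_switch"], "gene_id"])

    def diagnostic_junctions_of_switch_genes(self) -> pd.DataFrame:
        switch = set(self.switch_gene_ids())
        j = self.junctions
        return j[(j["gene_id"].isin(switch)) & (j["role"] != "shared")]


@dataclass
class SimResult:
    config: SimConfig
    models: list[GeneModel]
    design: list[SampleDesign]
    matrix: JunctionCountMatrix
    truth: SimTruth
    records_by_sample: dict[str, list[SJRecord]]


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def make_annotation(config: SimConfig) -> list[GeneModel]:
    """Generate a toy single-chromosome annotation.

    Genes are tiled with 10 kb gaps (deliberately overlapped every tenth
    gene when ``overlap`` is set, to exercise the 'ambiguous' assignment
    path).  Two-isoform genes are either a cassette exon (inclusion vs
    skipping transcript) or an alternative-terminal-exon pair mirroring
    the glutaminase GAC/KGA structure (shared 5' exons, then one terminal
    exon vs a distinct run of terminal exons).  Three-isoform genes are a
    full transcript plus two distinct single-exon skips.
    """
    rng = np.random.default_rng(config.seed)
    models: list[GeneModel] = []
    cursor = 10_000
    prev_span: tuple[int, int] | None = None
    for i in range(config.n_genes):
        gid = f"G{i:04d}"
        n_iso = int(rng.choice([1, 2, 3], p=config.isoform_probs))
        lo, hi = config.exon_range if n_iso == 1 else config.multi_exon_range
        n_ex = int(rng.integers(lo, hi + 1))
        pattern = "single"
        extra = 0
        if n_iso == 2:
            pattern = "cassette" if rng.random() < 0.5 else "terminal"
            if pattern == "terminal":
                extra = 2  # terminal exon A plus two KGA-like exons
        elif n_iso == 3:
            pattern = "double_cassette"

        start = cursor
        if config.overlap and prev_span is not None and i % 10 == 9:
            start = (prev_span[0] + prev_span[1]) // 2  # overlap previous gene
        exon_lens = rng.integers(100, 301, size=n_ex + extra)
        intron_lens = rng.integers(500, 2001, size=n_ex + extra)
        exons: list[tuple[int, int]] = []
        pos = start
        for k in range(n_ex + extra):
            exons.append((pos, pos + int(exon_lens[k]) - 1))
            pos = exons[-1][1] + 1 + int(intron_lens[k])
        strand = "+" if rng.random() < 0.5 else "-"

        if n_iso == 1:
            transcripts = {f"{gid}.t1": exons}
        elif pattern == "cassette":
            skip = int(rng.integers(1, n_ex - 1))
            transcripts = {
                f"{gid}.t1": exons,
                f"{gid}.t2": [e for k, e in enumerate(exons) if k != skip],
            }
        elif pattern == "terminal":
            shared = exons[: n_ex - 1]
            term_a = exons[n_ex - 1]
            term_b = exons[n_ex:]
            transcripts = {
                f"{gid}.t1": shared + [term_a],
                f"{gid}.t2": shared + list(term_b),
            }
        else:  # double cassette
            s1, s2 = sorted(rng.choice(np.arange(1, n_ex - 1), size=2, replace=False))
            transcripts = {
                f"{gid}.t1": exons,
                f"{gid}.t2": [e for k, e in enumerate(exons) if k != int(s1)],
                f"{gid}.t3": [e for k, e in enumerate(exons) if k != int(s2)],
            }

        span = (min(s for ex in transcripts.values() for s, _ in ex),
                max(e for ex in transcripts.values() for _, e in ex))
        models.append(GeneModel(gid, "chrS", strand, span, transcripts))
        prev_span = span
        cursor = span[1] + 10_000
    return models


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """NB with Var = m + phi*m^2 (Poisson when phi == 0)."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if phi == 0:
        out[pos] = rng.poisson(mean[pos])
        return out
    size = 1.0 / phi
    p = size / (size + mean[pos])
    out[pos] = rng.negative_binomial(size, p)
    return out


def simulate_counts(
    models: Sequence[GeneModel],
    config: SimConfig,
    outdir: str | os.PathLike | None = None,
) -> SimResult:
    """Simulate per-sample junction tables with planted truth.

    Expected count of junction j in sample s:
    ``libsize_s * w_g * DE_g(cond) * sum_{iso containing j} prop_iso(cond)
    * share_j / Z`` with uniform junction share within a transcript
    (log-normal jitter when ``junction_cv`` > 0).  Realized counts are NB
    with dispersion phi.  Switch genes flip a symmetric isoform
    proportion pair (0.5 +/- delta/2) between conditions.  Files are
    written in the exact SJ.out.tab dialect when ``outdir`` is given.
    """
    rng = np.random.default_rng([config.seed, 1])
    cond_a, cond_b = config.conditions

    two_iso = sorted(g.gene_id for g in models if len(g.transcripts) == 2)
    if config.n_switch > len(two_iso):
        raise ValueError(
            f"cannot plant {config.n_switch} switches: only {len(two_iso)} "
            "two-isoform genes"
        )
    switch_ids = set(
        rng.choice(two_iso, size=config.n_switch, replace=False)
    ) if config.n_switch else set()
    non_switch = sorted(g.gene_id for g in models if g.gene_id not in switch_ids)
    if config.n_de > len(non_switch):
        raise ValueError("not enough genes to plant DE on")
    de_ids = set(
        rng.choice(non_switch, size=config.n_de, replace=False)
    ) if config.n_de else set()

    gene_rows = []
    prop_rows = []
    junction_rows = []

    # per-gene parameters
    props: dict[str, dict[str, dict[str, float]]] = {}  # gene -> cond -> tid -> p
    base_w: dict[str, float] = {}
    de_factor: dict[str, float] = {}
    for g in models:
        tids = g.transcript_ids
        k = len(tids)
        base_w[g.gene_id] = float(rng.lognormal(0.0, 1.0))
        delta = 0.0
        if g.gene_id in switch_ids:
            delta = float(rng.uniform(*config.switch_delta))
            major_first = bool(rng.random() < 0.5)
            hi_p, lo_p = 0.5 + delta / 2.0, 0.5 - delta / 2.0
            pa = {tids[0]: hi_p if major_first else lo_p,
                  tids[1]: lo_p if major_first else hi_p}
            pb = {tids[0]: pa[tids[1]], tids[1]: pa[tids[0]]}
        else:
            p = rng.dirichlet([5.0] * k)
            pa = dict(zip(tids, map(float, p)))
            pb = dict(pa)
        props[g.gene_id] = {cond_a: pa, cond_b: pb}
        if g.gene_id in de_ids:
            fold = float(rng.uniform(*config.de_fold))
            de_factor[g.gene_id] = fold if rng.random() < 0.5 else 1.0 / fold
        else:
            de_factor[g.gene_id] = 1.0
        gene_rows.append(
            {"gene_id": g.gene_id, "n_isoforms": k, "base_weight": base_w[g.gene_id],
             "de_factor": de_factor[g.gene_id], "is_switch": g.gene_id in switch_ids,
             "switch_delta": delta}
        )
        for cond in (cond_a, cond_b):
            for tid in tids:
                prop_rows.append(
                    {"gene_id": g.gene_id, "transcript_id": tid, "condition": cond,
                     "proportion": props[g.gene_id][cond][tid]}
                )

    # per-junction inclusion weights and roles
    all_junctions: list[tuple[Junction, str]] = []  # (junction, gene)
    incl: dict[Junction, dict[str, float]] = {}
    jitter: dict[Junction, float] = {}
    for g in models:
        per_tx = transcript_junctions(g)
        union = sorted(gene_junctions(g))
        for j in union:
            containing = [tid for tid, js in per_tx.items() if j in js]
            role = "shared" if len(containing) == len(per_tx) or len(containing) > 1 \
                else containing[0]
            if len(per_tx) == 1:
                role = "shared"
            junction_rows.append(
                {"chrom": j.chrom, "start": j.start, "end": j.end, "strand": j.strand,
                 "gene_id": g.gene_id, "role": role}
            )
            incl[j] = {
                cond: sum(props[g.gene_id][cond][tid] for tid in containing)
                for cond in (cond_a, cond_b)
            }
            jitter[j] = float(rng.lognormal(0.0, config.junction_cv)) \
                if config.junction_cv > 0 else 1.0
            all_junctions.append((j, g.gene_id))

    # normalizer so expected library totals track the configured size
    z = sum(
        base_w[gid] * incl[j][cond_a] * jitter[j] for j, gid in all_junctions
    )

    samples: list[SampleDesign] = []
    for cond in (cond_a, cond_b):
        for r in range(1, config.n_replicates + 1):
            samples.append(SampleDesign(f"{cond}_{r}", cond))
    lib = rng.lognormal(np.log(config.library_size), config.library_sigma,
                        size=len(samples))

    mu = np.zeros((len(all_junctions), len(samples)))
    for row, (j, gid) in enumerate(all_junctions):
        base = base_w[gid] * jitter[j] / z
        for col, d in enumerate(samples):
            fac = de_factor[gid] if d.condition == cond_b else 1.0
            mu[row, col] = lib[col] * base * fac * incl[j][d.condition]

    counts = np.zeros(mu.shape, dtype=np.int64)
    for col in range(mu.shape[1]):
        counts[:, col] = _nb_draw(rng, mu[:, col], config.dispersion)

    records_by_sample: dict[str, list[SJRecord]] = {}
    for col, d in enumerate(samples):
        recs = []
        order = sorted(range(len(all_junctions)), key=lambda r: all_junctions[r][0])
        for row in order:
            c = int(counts[row, col])
            if c == 0:
                continue
            j = all_junctions[row][0]
            recs.append(
                SJRecord(junction=j, unique_reads=c, multimapped_reads=0,
                         motif_code=0, annotated_flag=1, max_overhang=50)
            )
        records_by_sample[d.sample_id] = recs

    matrix = build_matrix(records_by_sample, samples)

    expected = pd.DataFrame(
        {"chrom": [j.chrom for j, _ in all_junctions],
         "start": [j.start for j, _ in all_junctions],
         "end": [j.end for j, _ in all_junctions],
         "strand": [j.strand for j, _ in all_junctions],
         "gene_id": [gid for _, gid in all_junctions]}
    )
    for col, d in enumerate(samples):
        expected[d.sample_id] = mu[:, col]

    truth = SimTruth(
        genes=pd.DataFrame(gene_rows),
        proportions=pd.DataFrame(prop_rows),
        junctions=pd.DataFrame(junction_rows),
        expected=expected,
    )
    result = SimResult(config, list(models), samples, matrix, truth, records_by_sample)
    if outdir is not None:
        write_study(result, outdir)
    return result


def simulate_study(config: SimConfig, outdir: str | os.PathLike | None = None) -> SimResult:
    """Convenience: annotation + counts in one call."""
    models = make_annotation(config)
    return simulate_counts(models, config, outdir=outdir)


def write_study(result: SimResult, outdir: str | os.PathLike) -> None:
    """Write annotation, design, per-sample SJ.out.tab files, truth, config."""
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    io.write_gtf(result.models, os.path.join(outdir, "annotation.gtf"))
    design_with_paths = [
        SampleDesign(d.sample_id, d.condition, f"{d.sample_id}.SJ.out.tab")
        for d in result.design
    ]
    io.write_design_table(design_with_paths, os.path.join(outdir, "design.tsv"))
    for d in result.design:
        io.write_sj_table(
            result.records_by_sample[d.sample_id],
            os.path.join(outdir, f"{d.sample_id}.SJ.out.tab"),
        )
    result.truth.genes.to_csv(os.path.join(outdir, "truth_genes.tsv"),
                              sep="\t", index=False)
    result.truth.proportions.to_csv(os.path.join(outdir, "truth_proportions.tsv"),
                                    sep="\t", index=False)
    result.truth.junctions.to_csv(os.path.join(outdir, "truth_junctions.tsv"),
                                  sep="\t", index=False)
    with open(os.path.join(outdir, "config.txt"), "w") as fh:
        for key, value in asdict(result.config).items():
            fh.write(f"{key}={value}\n")


# ---------------------------------------------------------------------------
# GLS-like packaged fixture
# ---------------------------------------------------------------------------

def gls_like_fixture(
    seed: int = 0,
    n_replicates: int = 3,
    control_gac: float = 0.75,
    knockdown_gac: float = 0.30,
    depth: float = 1000.0,
    dispersion: float = 0.05,
) -> tuple[GeneModel, JunctionCountMatrix, list[SampleDesign]]:
    """A glutaminase-structured fixture with a planted GAC-to-KGA switch.

    The gene has 19 exons; the GAC transcript uses exons 1-15 and the KGA
    transcript exons 1-14 plus 16-19, so the two isoforms share the first
    13 junctions and diverge at the exon-14 donor.  Under knockdown the
    GAC share drops from ``control_gac`` to ``knockdown_gac`` — the
    direction observed when the splicing regulator is lost.
    """
    base = 190_880_000
    exons = [(base + k * 2000, base + k * 2000 + 199) for k in range(19)]
    gac = exons[:15]
    kga = exons[:14] + exons[15:]
    model = GeneModel(
        "GLS", "chr2", "+",
        (exons[0][0], exons[-1][1]),
        {"GLS.GAC": gac, "GLS.KGA": kga},
    )
    per_tx = transcript_junctions(model)
    rng = np.random.default_rng(seed)
    design = [
        SampleDesign(f"{cond}_{r}", cond)
        for cond in ("control", "knockdown")
        for r in range(1, n_replicates + 1)
    ]
    records: dict[str, list[SJRecord]] = {}
    for d in design:
        gac_p = control_gac if d.condition == "control" else knockdown_gac
        prop = {"GLS.GAC": gac_p, "GLS.KGA": 1.0 - gac_p}
        recs = []
        for j in sorted(gene_junctions(model)):
            weight = sum(p for tid, p in prop.items() if j in per_tx[tid])
            c = int(_nb_draw(rng, np.array([depth * weight]), dispersion)[0])
            if c > 0:
                recs.append(SJRecord(j, unique_reads=c, motif_code=0,
                                     annotated_flag=1, max_overhang=50))
        records[d.sample_id] = recs
    matrix = build_matrix(records, design)
    return model, matrix, design


# ---------------------------------------------------------------------------
# Companion generators
# ---------------------------------------------------------------------------

def simulate_spectral(
    n_proteins: int = 20,
    n_enriched: int = 3,
    fold: float = 5.0,
    seed: int = 0,
    mean_count: float = 30.0,
) -> tuple[pd.DataFrame, list[str]]:
    """Poisson spectral counts with length-proportional baselines.

    Returns (table, enriched protein ids); enriched proteins have their
    bait-sample mean multiplied by ``fold``.
    """
    if fold <= 0:
        raise ValueError("fold must be positive")
    rng = np.random.default_rng(seed)
    lengths = rng.integers(100, 1001, size=n_proteins)
    ids = [f"P{i:03d}" for i in range(n_proteins)]
    enriched = sorted(rng.choice(ids, size=n_enriched, replace=False)) if n_enriched else []
    baseline = mean_count * lengths / lengths.mean()
    bait_mean = baseline * np.where(np.isin(ids, enriched), fold, 1.0)
    table = pd.DataFrame(
        {"protein_id": ids, "length": lengths,
         "bait": rng.poisson(bait_mean), "control": rng.poisson(baseline)}
    )
    return table, list(enriched)


def simulate_survival(
    n: int, hazard_ratio: float, censor_rate: float, seed: int
) -> pd.DataFrame:
    """Two-group exponential survival with independent exponential censoring."""
    if hazard_ratio <= 0 or censor_rate < 0:
        raise ValueError("hazard_ratio must be > 0 and censor_rate >= 0")
    rng = np.random.default_rng(seed)
    n0 = n // 2
    n1 = n - n0
    t = np.concatenate([rng.exponential(1.0, n0),
                        rng.exponential(1.0 / hazard_ratio, n1)])
    group = np.array(["low"] * n0 + ["high"] * n1)
    if censor_rate > 0:
        c = rng.exponential(1.0 / censor_rate, n)
    else:
        c = np.full(n, np.inf)
    time = np.minimum(t, c)
    event = (t <= c).astype(int)
    return pd.DataFrame({"time": time, "event": event, "group": group})


def simulate_effect_matrix(
    n_genes: int,
    n_lines: int,
    seed: int,
    query: str = "QUERY",
    planted: str = "PARTNER",
    latent_loading: float = 0.8,
) -> pd.DataFrame:
    """Standard-normal gene-effect matrix with one planted co-dependency.

    The query gene and the planted partner share a latent factor with the
    given loading; all other genes are independent noise.
    """
    rng = np.random.default_rng(seed)
    data = rng.standard_normal((n_genes, n_lines))
    index = [f"G{i:04d}" for i in range(n_genes)]
    latent = rng.standard_normal(n_lines)
    resid = np.sqrt(1.0 - latent_loading**2)
    qv = latent_loading * latent + resid * rng.standard_normal(n_lines)
    pv = latent_loading * latent + resid * rng.standard_normal(n_lines)
    df = pd.DataFrame(data, index=index,
                      columns=[f"line{j:02d}" for j in range(n_lines)])
    df.loc[query] = qv
    df.loc[planted] = pv
    return df
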