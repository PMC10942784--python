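"""Junction derivation, the unified junction matrix, and gene assignment.

The unified matrix is built over the union of unique junction positions
across all samples, one column per sample, counting unique-mapping reads
only; a junction absent from a sample's table contributes 0 in that
column.
"""
from __future__ import annotations

import logging
from collections import defaultdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import io
from .models import GeneModel, Junction, JunctionCountMatrix, SampleDesign, SJRecord

logger = logging.getLogger(__name__)

#: Assignment sentinels for junctions matching >=2 genes / no gene.
AMBIGUOUS = "__ambiguous__"
UNASSIGNED = "__unassigned__"


def derive_junctions(
    exons: Sequence[tuple[int, int]], chrom: str, strand: str
) -> list[Junction]:
    """Junctions of a transcript: the gaps between consecutive exons.

    For exons ``(s_i, t_i)`` the i-th junction spans intronic bases
    ``t_i + 1 .. s_{i+1} - 1``.  Adjacent exons with no gap are an error
    (they would describe a zero-length intron).
    """
    exons = sorted(exons)
    out: list[Junction] = []
    for (s0, e0), (s1, e1) in zip(exons, exons[1:]):
        if e0 + 1 > s1 - 1:
            raise ValueError(
                f"exons ({s0},{e0}) and ({s1},{e1}) leave no intronic gap"
            )
        out.append(Junction(chrom, e0 + 1, s1 - 1, strand))
    return out


def transcript_junctions(model: GeneModel) -> dict[str, list[Junction]]:
    """Per-transcript canonical junction lists for one gene."""
    return {
        tid: derive_junctions(exons, model.chrom, model.strand)
        for tid, exons in model.transcripts.items()
    }


def gene_junctions(model: GeneModel) -> set[Junction]:
    """Union of canonical junctions over the gene's transcripts."""
    out: set[Junction] = set()
    for js in transcript_junctions(model).values():
        out.update(js)
    return out


def diagnostic_junctions(model: GeneModel) -> dict[str, frozenset[Junction]]:
    """Per-isoform junction sets unique to that isoform within the gene.

    A junction is diagnostic for a transcript when no other transcript of
    the same gene contains it; sets may be empty (e.g. two transcripts
    with identical junction chains).
    """
    if len(model.transcripts) < 2:
        raise ValueError(
            f"gene {model.gene_id} needs >=2 transcripts for diagnostic junctions"
        )
    per_tx = transcript_junctions(model)
    out: dict[str, frozenset[Junction]] = {}
    for tid, js in per_tx.items():
        others: set[Junction] = set()
        for other_tid, other_js in per_tx.items():
            if other_tid != tid:
                others.update(other_js)
        out[tid] = frozenset(set(js) - others)
    return out


# ---------------------------------------------------------------------------
# Unified matrix
# ---------------------------------------------------------------------------

def build_matrix(
    records_by_sample: Mapping[str, Sequence[SJRecord]],
    design: Sequence[SampleDesign],
) -> JunctionCountMatrix:
    """Assemble the unified junction count matrix from per-sample records.

    The junction set is the union over samples, rows sorted
    lexicographically by (chrom, start, end, strand).  Duplicate junction
    keys within one sample are an error.
    """
    if not records_by_sample:
        raise ValueError("no samples to unify")
    samples = [d.sample_id for d in design]
    missing = [s for s in samples if s not in records_by_sample]
    if missing:
        raise ValueError(f"design samples without junction tables: {missing}")

    per_sample: dict[str, dict[Junction, int]] = {}
    for sample in samples:
        counts: dict[Junction, int] = {}
        for rec in records_by_sample[sample]:
            if rec.junction in counts:
                raise ValueError(
                    f"duplicate junction {rec.junction} in sample {sample}"
                )
            counts[rec.junction] = rec.unique_reads
        per_sample[sample] = counts

    union: set[Junction] = set()
    for counts in per_sample.values():
        union.update(counts)
    junctions = sorted(union)

    mat = np.zeros((len(junctions), len(samples)), dtype=np.int64)
    for col, sample in enumerate(samples):
        counts = per_sample[sample]
        for row, j in enumerate(junctions):
            c = counts.get(j)
            if c is not None:
                mat[row, col] = c
    return JunctionCountMatrix(junctions, samples, mat, design)


def unify_junctions(design: Sequence[SampleDesign]) -> JunctionCountMatrix:
    """Read each design sample's ``SJ.out.tab`` and build the unified matrix."""
    if not design:
        raise ValueError("empty design")
    records = {}
    for d in design:
        if d.path is None:
            raise ValueError(f"sample {d.sample_id} has no junction table path")
        records[d.sample_id] = io.read_sj_table(d.path)
    return build_matrix(records, design)


# ---------------------------------------------------------------------------
# Gene assignment
# ---------------------------------------------------------------------------

def assign_junctions_to_genes(
    matrix: JunctionCountMatrix | Sequence[Junction],
    models: Sequence[GeneModel],
) -> dict[Junction, str]:
    """Map each junction to a gene_id, ``AMBIGUOUS`` or ``UNASSIGNED``.

    Priority: a junction equal to an annotated (transcript-derived)
    junction of exactly one gene takes that gene; otherwise a junction
    falling strictly inside exactly one strand-compatible gene span is
    assigned by containment (strand 'unknown' is compatible with either).
    Two or more candidate genes at either stage -> ``AMBIGUOUS``.
    """
    if not models:
        raise ValueError("no gene models")
    junctions = matrix.junctions if isinstance(matrix, JunctionCountMatrix) else list(matrix)

    # strand-'unknown' junctions are assignable by span containment only
    annotated: dict[Junction, set[str]] = defaultdict(set)
    for g in models:
        for j in gene_junctions(g):
            annotated[j].add(g.gene_id)

    by_chrom: dict[str, list[GeneModel]] = defaultdict(list)
    for g in models:
        by_chrom[g.chrom].append(g)

    out: dict[Junction, str] = {}
    for j in junctions:
        hits = annotated.get(j, set())
        if len(hits) == 1:
            out[j] = next(iter(hits))
            continue
        if len(hits) > 1:
            out[j] = AMBIGUOUS
            continue
        spans = [
            g.gene_id
            for g in by_chrom.get(j.chrom, [])
            if g.span[0] < j.start and j.end < g.span[1]
            and (j.strand == "unknown" or j.strand == g.strand)
        ]
        if len(spans) == 1:
            out[j] = spans[0]
        elif len(spans) > 1:
            out[j] = AMBIGUOUS
        else:
            out[j] = UNASSIGNED
    return out


def summarize_gene_junctions(
    matrix: JunctionCountMatrix,
    models: Sequence[GeneModel],
    gene_id: str,
    assignment: Mapping[Junction, str] | None = None,
) -> pd.DataFrame:
    """Per-junction per-sample count table for one gene.

    Rows are the gene's annotated junctions (in coordinate order) followed
    by unannotated junctions assigned to the gene; columns are samples.
    Annotated junctions absent from the matrix appear as all-zero rows.
    """
    model = next((g for g in models if g.gene_id == gene_id), None)
    if model is None:
        raise KeyError(f"unknown gene_id {gene_id!r}")
    if assignment is None:
        assignment = assign_junctions_to_genes(matrix, models)

    ann = sorted(gene_junctions(model))
    ann_set = set(ann)
    unann = sorted(
        j
        for j, g in assignment.items()
        if g == gene_id and j not in ann_set and j in matrix
    )

    rows = []
    labels = []
    flags = []
    for j in ann + unann:
        labels.append(str(j))
        flags.append("annotated" if j in ann_set else "unannotated")
        rows.append(matrix.row(j) if j in matrix else np.zeros(matrix.n_samples, dtype=np.int64))
    df = pd.DataFrame(rows, index=labels, columns=matrix.samples)
    df.insert(0, "status", flags)
    return df
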