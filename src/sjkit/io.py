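"""Readers and writers for the pipeline's tabular formats.

Formats handled here:

* STAR ``SJ.out.tab`` — 9 tab-separated columns: chrom, intron start,
  intron end, strand code (0/1/2), intron motif code, annotated flag,
  unique-mapping reads, multimapping reads, maximum spliced overhang.
* GTF subset — gene/transcript/exon feature lines with ``gene_id`` and
  ``transcript_id`` attributes; both ``key "value";`` and ``key=value``
  attribute dialects are accepted (tolerant reader, strict writer).
* Design table — 3-column TSV: sample_id, condition, path.
* Junction matrix TSV — 4 key columns (chrom, start, end, strand) then
  one count column per sample.
* BED6 export of junctions (0-based half-open conversion at this
  boundary only).
"""
from __future__ import annotations

import os
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .models import (
    CODE_TO_STRAND,
    STRAND_TO_CODE,
    GeneModel,
    Junction,
    JunctionCountMatrix,
    SampleDesign,
    SJRecord,
)


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


# ---------------------------------------------------------------------------
# SJ.out.tab
# ---------------------------------------------------------------------------

def read_sj_table(path: str | os.PathLike) -> list[SJRecord]:
    """Parse a STAR ``SJ.out.tab`` file into :class:`SJRecord` objects.

    Line order is preserved.  Strand codes map 0 -> 'unknown', 1 -> '+',
    2 -> '-'.  Any malformed line raises :class:`ParseError` naming the
    1-based line number.
    """
    records: list[SJRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) == 1:  # tolerate space-separated input
                fields = line.split()
            if len(fields) != 9:
                raise ParseError(
                    f"{path}: line {lineno}: expected 9 columns, got {len(fields)}"
                )
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                strand_code = int(fields[3])
                motif = int(fields[4])
                annotated = int(fields[5])
                unique = int(fields[6])
                multi = int(fields[7])
                overhang = int(fields[8])
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer field ({exc})"
                ) from None
            if strand_code not in CODE_TO_STRAND:
                raise ParseError(
                    f"{path}: line {lineno}: strand code {strand_code} not in {{0,1,2}}"
                )
            try:
                records.append(
                    SJRecord(
                        junction=Junction(chrom, start, end, CODE_TO_STRAND[strand_code]),
                        unique_reads=unique,
                        multimapped_reads=multi,
                        motif_code=motif,
                        annotated_flag=annotated,
                        max_overhang=overhang,
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
    return records


def write_sj_table(records: Iterable[SJRecord], path: str | os.PathLike) -> None:
    """Write records in the exact 9-column ``SJ.out.tab`` dialect."""
    with open(path, "w") as fh:
        for r in records:
            j = r.junction
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        j.chrom,
                        j.start,
                        j.end,
                        STRAND_TO_CODE[j.strand],
                        r.motif_code,
                        r.annotated_flag,
                        r.unique_reads,
                        r.multimapped_reads,
                        r.max_overhang,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Design table
# ---------------------------------------------------------------------------

def read_design_table(path: str | os.PathLike) -> list[SampleDesign]:
    """Read a 3-column TSV (sample_id, condition, path); '#' lines skipped."""
    design: list[SampleDesign] = []
    base = os.path.dirname(os.fspath(path))
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(
                    f"{path}: line {lineno}: expected >=2 tab-separated columns"
                )
            sample, condition = fields[0], fields[1]
            p = fields[2] if len(fields) > 2 and fields[2] else None
            if p is not None and not os.path.isabs(p):
                p = os.path.join(base, p)
            design.append(SampleDesign(sample, condition, p))
    ids = [d.sample_id for d in design]
    if len(set(ids)) != len(ids):
        raise ParseError(f"{path}: duplicate sample ids")
    return design


def write_design_table(design: Sequence[SampleDesign], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for d in design:
            fh.write(f"{d.sample_id}\t{d.condition}\t{d.path or ''}\n")


# ---------------------------------------------------------------------------
# GTF subset
# ---------------------------------------------------------------------------

def _parse_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in text.strip().rstrip(";").split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part and '"' not in part:
            key, value = part.split("=", 1)
        else:
            bits = part.split(None, 1)
            if len(bits) != 2:
                continue
            key, value = bits
        attrs[key.strip()] = value.strip().strip('"')
    return attrs


def read_gene_models(path: str | os.PathLike) -> list[GeneModel]:
    """Read gene models from a GTF-subset annotation file.

    Uses gene/transcript/exon feature lines; other features are ignored.
    An exon lacking a ``transcript_id`` is an error, as are overlapping
    exons within one transcript (reported by :class:`GeneModel`
    validation, naming the transcript).
    """
    gene_meta: dict[str, dict] = {}
    tx_gene: dict[str, str] = {}
    tx_exons: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ParseError(
                    f"{path}: line {lineno}: expected 9 GTF columns, got {len(fields)}"
                )
            chrom, _source, feature, start, end, _score, strand, _frame, attr = fields
            if feature not in ("gene", "transcript", "exon"):
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise ParseError(f"{path}: line {lineno}: non-integer coordinates") from None
            attrs = _parse_attributes(attr)
            gid = attrs.get("gene_id")
            if gid is None:
                raise ParseError(f"{path}: line {lineno}: missing gene_id attribute")
            if gid not in gene_meta:
                gene_meta[gid] = {"chrom": chrom, "strand": strand, "span": None}
                order.append(gid)
            if feature == "gene":
                gene_meta[gid]["span"] = (start_i, end_i)
                gene_meta[gid]["chrom"] = chrom
                gene_meta[gid]["strand"] = strand
            elif feature == "exon":
                tid = attrs.get("transcript_id")
                if tid is None:
                    raise ParseError(
                        f"{path}: line {lineno}: exon lacks transcript_id attribute"
                    )
                tx_gene[tid] = gid
                tx_exons.setdefault(tid, []).append((start_i, end_i))
            else:  # transcript line: record membership only
                tid = attrs.get("transcript_id")
                if tid is not None:
                    tx_gene[tid] = gid

    models: list[GeneModel] = []
    for gid in order:
        meta = gene_meta[gid]
        tids = sorted(t for t, g in tx_gene.items() if g == gid and t in tx_exons)
        if not tids:
            continue  # gene line without exon evidence
        transcripts = {tid: sorted(tx_exons[tid]) for tid in tids}
        span = meta["span"]
        if span is None:
            lo = min(s for ex in transcripts.values() for s, _ in ex)
            hi = max(e for ex in transcripts.values() for _, e in ex)
            span = (lo, hi)
        models.append(
            GeneModel(
                gene_id=gid,
                chrom=meta["chrom"],
                strand=meta["strand"],
                span=span,
                transcripts=transcripts,
            )
        )
    return models


def write_gtf(models: Sequence[GeneModel], path: str | os.PathLike) -> None:
    """Write gene models in the strict ``key "value";`` GTF dialect."""
    with open(path, "w") as fh:
        for g in models:
            lo, hi = g.span
            fh.write(
                f"{g.chrom}\ttoy\tgene\t{lo}\t{hi}\t.\t{g.strand}\t.\t"
                f'gene_id "{g.gene_id}";\n'
            )
            for tid in g.transcript_ids:
                exons = g.transcripts[tid]
                fh.write(
                    f"{g.chrom}\ttoy\ttranscript\t{exons[0][0]}\t{exons[-1][1]}\t.\t"
                    f'{g.strand}\t.\tgene_id "{g.gene_id}"; transcript_id "{tid}";\n'
                )
                for s, e in exons:
                    fh.write(
                        f"{g.chrom}\ttoy\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                        f'gene_id "{g.gene_id}"; transcript_id "{tid}";\n'
                    )


# ---------------------------------------------------------------------------
# Junction matrix TSV / BED
# ---------------------------------------------------------------------------

def write_matrix_tsv(matrix: JunctionCountMatrix, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tstrand\t" + "\t".join(matrix.samples) + "\n")
        for i, j in enumerate(matrix.junctions):
            row = "\t".join(str(c) for c in matrix.counts[i])
            fh.write(f"{j.chrom}\t{j.start}\t{j.end}\t{j.strand}\t{row}\n")


def read_matrix_tsv(
    path: str | os.PathLike, design: Sequence[SampleDesign] | None = None
) -> JunctionCountMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "strand": str})
    key_cols = ["chrom", "start", "end", "strand"]
    samples = [c for c in df.columns if c not in key_cols]
    junctions = [
        Junction(r.chrom, int(r.start), int(r.end), r.strand)
        for r in df.itertuples()
    ]
    if design is None:
        design = [SampleDesign(s, "all") for s in samples]
    return JunctionCountMatrix(
        junctions, samples, df[samples].to_numpy(dtype=np.int64), design
    )


def write_bed6(
    matrix: JunctionCountMatrix,
    assignment: Mapping[Junction, str],
    path: str | os.PathLike,
) -> None:
    """Export junctions as BED6: score = total unique reads capped at 1000,
    name = gene assignment.  BED is 0-based half-open, so the interval is
    ``[start-1, end)`` of the intron."""
    totals = matrix.counts.sum(axis=1)
    with open(path, "w") as fh:
        for i, j in enumerate(matrix.junctions):
            strand = j.strand if j.strand in ("+", "-") else "."
            name = assignment.get(j, "unassigned")
            score = int(min(totals[i], 1000))
            fh.write(f"{j.chrom}\t{j.start - 1}\t{j.end}\t{name}\t{score}\t{strand}\n")
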