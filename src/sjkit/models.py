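"""Core domain types for junction-level splicing analysis.

Coordinate convention
---------------------
All positions are 1-based and closed, following the STAR ``SJ.out.tab``
dialect: a :class:`Junction` is keyed by the first and last *intronic*
bases of the intron it spans.  Conversion to other conventions (e.g.
0-based half-open BED) happens only at the I/O boundary.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

#: Allowed strand labels.  STAR encodes these as 0 (undefined), 1 (+), 2 (-).
STRANDS = ("+", "-", "unknown")
CODE_TO_STRAND = {0: "unknown", 1: "+", 2: "-"}
STRAND_TO_CODE = {"unknown": 0, "+": 1, "-": 2}


@dataclass(frozen=True, order=True, slots=True)
class Junction:
    """A splice junction keyed by its intron's first/last bases.

    Equality, hashing and ordering are exactly the 4-tuple
    ``(chrom, start, end, strand)``; ordering is the deterministic output
    order used throughout the package.
    """

    chrom: str
    start: int
    end: int
    strand: str = "unknown"

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"junction start must be >= 1, got {self.start}")
        if self.start > self.end:
            raise ValueError(
                f"junction start {self.start} exceeds end {self.end} on {self.chrom}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def intron_length(self) -> int:
        return self.end - self.start + 1

    def __str__(self) -> str:  # used in tabular output
        return f"{self.chrom}:{self.start}-{self.end}({self.strand})"


@dataclass(frozen=True, slots=True)
class SJRecord:
    """One line of a STAR ``SJ.out.tab`` file.

    Only ``unique_reads`` enters any statistic downstream; multimapping
    reads are parsed and carried for diagnostics but never counted.
    """

    junction: Junction
    unique_reads: int
    multimapped_reads: int = 0
    motif_code: int = 0
    annotated_flag: int = 1
    max_overhang: int = 0

    def __post_init__(self) -> None:
        if self.unique_reads < 0 or self.multimapped_reads < 0:
            raise ValueError("read counts must be non-negative")
        if not 0 <= self.motif_code <= 6:
            raise ValueError(f"motif code must be in [0, 6], got {self.motif_code}")
        if self.annotated_flag not in (0, 1):
            raise ValueError(f"annotated flag must be 0/1, got {self.annotated_flag}")
        if self.max_overhang < 0:
            raise ValueError("max overhang must be non-negative")


@dataclass(frozen=True, slots=True)
class SampleDesign:
    """One sample of the study design: id, condition label, input path."""

    sample_id: str
    condition: str
    path: str | None = None


def conditions_in_order(design: Sequence[SampleDesign]) -> list[str]:
    """Condition labels in order of first appearance (the contrast order:
    the first label is the reference/baseline condition A)."""
    seen: list[str] = []
    for d in design:
        if d.condition not in seen:
            seen.append(d.condition)
    return seen


def resolve_contrast(
    design: Sequence[SampleDesign], conditions: tuple[str, str] | None = None
) -> tuple[str, str]:
    """Return ``(condition_a, condition_b)`` for a two-condition contrast.

    Fold changes are always reported as B minus A.  When ``conditions`` is
    None the order of first appearance in the design is used.
    """
    present = conditions_in_order(design)
    if conditions is None:
        if len(present) != 2:
            raise ValueError(
                f"contrast needs exactly 2 conditions, design has {present}"
            )
        return present[0], present[1]
    a, b = conditions
    for c in (a, b):
        if c not in present:
            raise ValueError(f"condition {c!r} absent from design (has {present})")
    return a, b


@dataclass
class GeneModel:
    """A gene with its transcripts and exon lists.

    ``transcripts`` maps transcript_id -> list of 1-based closed exon
    intervals, sorted ascending and pairwise disjoint within a transcript.
    """

    gene_id: str
    chrom: str
    strand: str
    span: tuple[int, int]
    transcripts: dict[str, list[tuple[int, int]]]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene strand must be +/-, got {self.strand!r}")
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id} has no transcripts")
        lo, hi = self.span
        for tid, exons in self.transcripts.items():
            if not exons:
                raise ValueError(f"transcript {tid} has no exons")
            exons.sort()
            prev_end = None
            for s, e in exons:
                if s > e:
                    raise ValueError(f"transcript {tid}: exon ({s},{e}) inverted")
                if not (lo <= s and e <= hi):
                    raise ValueError(
                        f"transcript {tid}: exon ({s},{e}) outside gene span {self.span}"
                    )
                if prev_end is not None and s <= prev_end:
                    raise ValueError(
                        f"overlapping exons in transcript {tid} of gene {self.gene_id}"
                    )
                prev_end = e

    @property
    def transcript_ids(self) -> list[str]:
        return sorted(self.transcripts)

    def exons(self, transcript_id: str) -> list[tuple[int, int]]:
        return self.transcripts[transcript_id]


class JunctionCountMatrix:
    """Samples x junctions unique-read count matrix over the junction union.

    Rows are :class:`Junction` keys in deterministic lexicographic order;
    columns follow the design's sample order.  A junction absent from a
    sample's table has count 0.
    """

    def __init__(
        self,
        junctions: Sequence[Junction],
        samples: Sequence[str],
        counts: np.ndarray,
        design: Sequence[SampleDesign],
    ) -> None:
        counts = np.asarray(counts, dtype=np.int64)
        if counts.shape != (len(junctions), len(samples)):
            raise ValueError(
                f"count matrix shape {counts.shape} does not match "
                f"{len(junctions)} junctions x {len(samples)} samples"
            )
        if (counts < 0).any():
            raise ValueError("negative counts in junction matrix")
        if len(set(junctions)) != len(junctions):
            raise ValueError("duplicate junction keys in matrix")
        if len(set(samples)) != len(samples):
            raise ValueError("duplicate sample ids in matrix")
        by_id = {d.sample_id: d for d in design}
        missing = [s for s in samples if s not in by_id]
        if missing:
            raise ValueError(f"samples missing from design: {missing}")
        self.junctions = list(junctions)
        self.samples = list(samples)
        self.counts = counts
        self.design = [by_id[s] for s in samples]
        self._index = {j: i for i, j in enumerate(self.junctions)}

    # -- lookup ---------------------------------------------------------
    def __contains__(self, junction: Junction) -> bool:
        return junction in self._index

    def index_of(self, junction: Junction) -> int:
        return self._index[junction]

    def row(self, junction: Junction) -> np.ndarray:
        return self.counts[self._index[junction]]

    @property
    def n_junctions(self) -> int:
        return len(self.junctions)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def conditions(self) -> list[str]:
        return conditions_in_order(self.design)

    def sample_mask(self, condition: str) -> np.ndarray:
        mask = np.array([d.condition == condition for d in self.design])
        if not mask.any():
            raise ValueError(f"condition {condition!r} has no samples")
        return mask

    # -- views ----------------------------------------------------------
    def to_frame(self):
        """Counts as a pandas DataFrame indexed by junction string keys."""
        import pandas as pd

        return pd.DataFrame(
            self.counts,
            index=[str(j) for j in self.junctions],
            columns=self.samples,
        )
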