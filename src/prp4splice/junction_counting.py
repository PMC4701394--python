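"""Split/unsplit read counting at intron 5' exon/intron junctions.

A read is SPLIT when its alignment skips the intron exactly at the 5'
junction (an N gap in the CIGAR whose transcript-5' boundary equals the
junction) with at least ``window`` aligned bases on each side of the gap,
and UNSPLIT when it aligns contiguously across the junction covering the
last ``window`` exon bases and the first ``window`` intron bases.  Each read
contributes at most one count to exactly one category per intron.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam

from prp4splice.annotation_io import IntronIndex, IntronRecord

DEFAULT_WINDOW = 3

SPLIT = "SPLIT"
UNSPLIT = "UNSPLIT"
NONE = "NONE"

# CIGAR operation codes (pysam numeric)
_M, _I, _D, _N, _S, _H, _EQ, _X = 0, 1, 2, 3, 4, 5, 7, 8
_ALIGNED_OPS = {_M, _EQ, _X}
_SUPPORTED_OPS = {_M, _I, _D, _N, _S, _H, _EQ, _X}


class UnsupportedCigarError(ValueError):
    """Read alignment uses a CIGAR operation the counter cannot interpret."""


@dataclass(frozen=True)
class JunctionCounts:
    """Split (S) and unsplit (U) read counts for one intron in one sample."""

    intron_id: str
    sample_id: str
    split: int
    unsplit: int

    @property
    def total(self) -> int:
        return self.split + self.unsplit


def _gaps_and_blocks(
    read: pysam.AlignedSegment,
) -> tuple[list[tuple[int, int, int, int]], list[tuple[int, int]]]:
    """Decompose a CIGAR into N gaps and gapless aligned blocks.

    Gaps are ``(gap_start, gap_end, left_run, right_run)`` where the runs
    are the lengths of uninterrupted aligned (M/=/X) stretches immediately
    flanking the gap.  Blocks are maximal reference intervals of aligned
    bases not interrupted by N, D or I (soft clips never extend a block).
    """
    cigar = read.cigartuples or []
    for op, _ in cigar:
        if op not in _SUPPORTED_OPS:
            raise UnsupportedCigarError(
                f"read {read.query_name!r}: unsupported CIGAR op code {op}"
            )
    ref = read.reference_start
    blocks: list[tuple[int, int]] = []
    runs: list[tuple[int, int]] = []  # aligned runs as reference intervals
    gaps: list[tuple[int, int]] = []
    cur_start: int | None = None
    for op, length in cigar:
        if op in _ALIGNED_OPS:
            if cur_start is None:
                cur_start = ref
            ref += length
        else:
            if cur_start is not None:
                runs.append((cur_start, ref))
                blocks.append((cur_start, ref))
                cur_start = None
            if op == _N:
                gaps.append((ref, ref + length))
                ref += length
            elif op == _D:
                ref += length
            # I, S, H consume no reference
    if cur_start is not None:
        runs.append((cur_start, ref))
        blocks.append((cur_start, ref))

    annotated = []
    for gs, ge in gaps:
        left = next((e - s for s, e in runs if e == gs), 0)
        right = next((e - s for s, e in runs if s == ge), 0)
        annotated.append((gs, ge, left, right))
    return annotated, blocks


def classify_read_at_junction(
    read: pysam.AlignedSegment,
    intron: IntronRecord,
    window: int = DEFAULT_WINDOW,
    stranded: bool = True,
    require_both_boundaries: bool = False,
) -> str:
    """Classify one aligned read at one intron's 5' junction.

    Returns ``"SPLIT"``, ``"UNSPLIT"`` or ``"NONE"``.  With ``stranded``
    (the default), reads antisense to the annotated transcript are NONE.
    """
    if read.is_unmapped or read.reference_name != intron.chrom:
        return NONE
    if stranded and read.is_reverse != (intron.strand == "-"):
        return NONE

    j = intron.junction
    gaps, blocks = _gaps_and_blocks(read)

    for gs, ge, left, right in gaps:
        if left < window or right < window:
            continue
        if require_both_boundaries and (gs, ge) != (intron.start, intron.end):
            continue
        boundary_ok = (gs == intron.start) if intron.strand == "+" else (ge == intron.end)
        if boundary_ok:
            return SPLIT

    # Unsplit: one gapless block covers the full 2*window junction span.
    for bs_, be in blocks:
        if bs_ <= j - window and be >= j + window:
            return UNSPLIT
    return NONE


def _is_countable(read: pysam.AlignedSegment, min_mapq: int) -> bool:
    return not (
        read.is_unmapped
        or read.is_secondary
        or read.is_supplementary
        or read.mapping_quality < min_mapq
    )


def count_junctions(
    alignments: str | Path | Iterable[pysam.AlignedSegment],
    introns: Sequence[IntronRecord],
    sample_id: str,
    window: int = DEFAULT_WINDOW,
    stranded: bool = True,
    min_mapq: int = 1,
    require_both_boundaries: bool = False,
) -> list[JunctionCounts]:
    """Count split/unsplit reads per intron for one sample.

    ``alignments`` may be a SAM/BAM path or an iterable of pysam records;
    the stream is scanned once, so no index is required.  Secondary and
    supplementary alignments and reads below ``min_mapq`` (multimappers)
    are excluded.  Every intron appears in the output, with S = U = 0 when
    no read overlaps its junction.
    """
    close_me = None
    if isinstance(alignments, (str, Path)):
        close_me = pysam.AlignmentFile(str(alignments), check_sq=False)
        stream: Iterable[pysam.AlignedSegment] = close_me
    else:
        stream = alignments

    index = IntronIndex(introns)
    split_counts = {r.intron_id: 0 for r in introns}
    unsplit_counts = {r.intron_id: 0 for r in introns}
    any_read = False
    try:
        for read in stream:
            if not _is_countable(read, min_mapq) or read.reference_end is None:
                continue
            any_read = True
            candidates = index.overlapping_junctions(
                read.reference_name, read.reference_start, read.reference_end, window
            )
            # Long split reads skip far past the junction window; also offer
            # introns whose junction lies anywhere under the alignment span.
            for intron in candidates:
                call = classify_read_at_junction(
                    read, intron, window, stranded, require_both_boundaries
                )
                if call == SPLIT:
                    split_counts[intron.intron_id] += 1
                elif call == UNSPLIT:
                    unsplit_counts[intron.intron_id] += 1
    finally:
        if close_me is not None:
            close_me.close()

    if not any_read:
        import warnings

        warnings.warn(
            f"sample {sample_id!r}: no countable reads on any annotated "
            "chromosome",
            stacklevel=2,
        )
    return [
        JunctionCounts(
            intron_id=r.intron_id,
            sample_id=sample_id,
            split=split_counts[r.intron_id],
            unsplit=unsplit_counts[r.intron_id],
        )
        for r in introns
    ]


def counts_to_frame(counts: Iterable[JunctionCounts]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "intron_id": c.intron_id,
                "sample_id": c.sample_id,
                "split": c.split,
                "unsplit": c.unsplit,
                "total": c.total,
            }
            for c in counts
        ],
        columns=["intron_id", "sample_id", "split", "unsplit", "total"],
    )


def write_counts_tsv(counts: Iterable[JunctionCounts], path: str | Path) -> None:
    counts_to_frame(counts).to_csv(path, sep="\t", index=False)
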