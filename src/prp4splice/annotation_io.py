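"""Intron extraction from genome FASTA plus GFF3/BED12 annotation.

Coordinates are 0-based half-open internally; GFF3 (1-based inclusive) and
BED (already 0-based half-open) are converted at the boundary.  All context
strings are stored in the RNA alphabet (T -> U), read 5'->3' in transcript
orientation, so that minus-strand introns are reverse-complemented once at
extraction time and every downstream pairing computation is strand-free.
"""

from __future__ import annotations

import bisect
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from pyfaidx import Fasta

MIN_INTRON_LENGTH = 12

# Branch-sequence consensus 1.C/U 2.U 3.N 4.A 5.C/U as a position weight
# matrix; the branch adenosine at position 4 is a hard requirement.
BS_PWM: tuple[dict[str, float], ...] = (
    {"C": 0.5, "U": 0.5},
    {"U": 1.0},
    {"A": 0.25, "C": 0.25, "G": 0.25, "U": 0.25},
    {"A": 1.0},
    {"C": 0.5, "U": 0.5},
)
# Search window: branch A between 5 and 50 nt upstream of the intron 3' end.
BS_MIN_OFFSET = 5
BS_MAX_OFFSET = 50

_COMPLEMENT = str.maketrans("ACGTUacgtu", "TGCAATGCAA")


class AnnotationError(ValueError):
    """Malformed or inconsistent annotation input."""


class MissingChromosomeError(AnnotationError):
    """Annotation references a sequence absent from the genome FASTA."""


class ExonOverlapError(AnnotationError):
    """Exons within one transcript overlap; intron gaps are undefined."""


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA or RNA string (returns DNA alphabet)."""
    return seq.translate(_COMPLEMENT)[::-1]


def to_rna(seq: str) -> str:
    """Uppercase and transcribe a DNA string to the RNA alphabet."""
    return seq.upper().replace("T", "U")


@dataclass(frozen=True)
class IntronRecord:
    """One annotated intron with its splice-site context sequences.

    ``start``/``end`` are genomic, 0-based half-open.  ``ordinal`` counts
    introns 5'->3' within the gene starting at 1 (reported as Roman numerals
    elsewhere).  Context strings (RNA alphabet, transcript orientation):

    - ``exon1_ctx``: the last three exon-1 nucleotides, positions -3..-1
    - ``ss5``: the first six intron nucleotides, positions +1..+6
    - ``bs``: the 5-nt branch sequence (position 4 = branch adenosine), or
      ``None`` when no candidate window contains an A at position 4
    - ``bs_offset``: nucleotides from the branch adenosine to the 3' intron
      end (0 would mean the branch A is the last intron base)
    - ``ss3_ctx``: the last three intron nucleotides
    """

    intron_id: str
    gene_id: str
    ordinal: int
    chrom: str
    start: int
    end: int
    strand: str
    exon1_ctx: str
    ss5: str
    ss3_ctx: str
    bs: str | None = None
    bs_offset: int | None = None
    too_short: bool = field(default=False, compare=False)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def junction(self) -> int:
        """Genomic coordinate of the 5' exon/intron junction.

        For a plus-strand intron this is ``start`` (the first intron base);
        for a minus-strand intron it is ``end`` (one past the last genomic
        base, which is the first intron base in transcript orientation).
        """
        return self.start if self.strand == "+" else self.end

    @property
    def roman(self) -> str:
        return _to_roman(self.ordinal)


def _to_roman(n: int) -> str:
    vals = (
        (1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"),
        (90, "XC"), (50, "L"), (40, "XL"), (10, "X"), (9, "IX"),
        (5, "V"), (4, "IV"), (1, "I"),
    )
    out = []
    for v, s in vals:
        while n >= v:
            out.append(s)
            n -= v
    return "".join(out)


def locate_branch_sequence(intron_seq: str) -> tuple[str | None, int | None]:
    """Find the branch sequence in an intron sequence (RNA, 5'->3').

    Scans all 5-mer windows whose position 4 is the branch adenosine and
    whose branch A lies 5-50 nt upstream of the intron 3' end, scores each
    by the sum of consensus position weights, and returns the best window
    with ties broken in favour of the window closest to the 3' end.

    Returns ``(None, None)`` when no window has an A at position 4.
    """
    seq = to_rna(intron_seq)
    n = len(seq)
    best: tuple[float, int] | None = None  # (score, -offset) maximized
    best_window: tuple[str, int] | None = None
    # branch A at 0-based index i; offset = n - 1 - i
    for i in range(n - 2, 2, -1):
        offset = n - 1 - i
        if offset < BS_MIN_OFFSET or offset > BS_MAX_OFFSET:
            continue
        if seq[i] != "A":
            continue
        window = seq[i - 3 : i + 2]
        if len(window) != 5:
            continue
        score = sum(BS_PWM[j].get(window[j], 0.0) for j in range(5))
        key = (score, -offset)
        if best is None or key > best:
            best = key
            best_window = (window, offset)
    if best_window is None:
        return None, None
    return best_window


def _parse_gff3_exons(path: Path) -> dict[str, list[tuple[str, int, int, str, str]]]:
    """Return exons grouped by transcript: {tx: [(chrom,start,end,strand,gene)]}."""
    tx_exons: dict[str, list[tuple[str, int, int, str, str]]] = {}
    tx_gene: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise AnnotationError(f"malformed GFF3 line: {line.rstrip()!r}")
            chrom, _, ftype, start, end, _, strand, _, attrs = fields[:9]
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if ftype in {"mRNA", "transcript"}:
                tid = attr.get("ID")
                if tid:
                    tx_gene[tid] = attr.get("Parent", tid)
            if ftype != "exon":
                continue
            parent = attr.get("Parent")
            if parent is None:
                raise AnnotationError(
                    f"exon without Parent attribute: {line.rstrip()!r}"
                )
            for tid in parent.split(","):
                tx_exons.setdefault(tid, []).append(
                    (chrom, int(start) - 1, int(end), strand, "")
                )
    # resolve gene ids
    resolved = {}
    for tid, exons in tx_exons.items():
        gene = tx_gene.get(tid, tid)
        resolved[tid] = [(c, s, e, st, gene) for c, s, e, st, _ in exons]
    return resolved


def _parse_bed12_exons(path: Path) -> dict[str, list[tuple[str, int, int, str, str]]]:
    tx_exons: dict[str, list[tuple[str, int, int, str, str]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise AnnotationError(
                    f"BED12 requires 12 columns, got {len(f)}: {line.rstrip()!r}"
                )
            chrom, chrom_start, name, strand = f[0], int(f[1]), f[3], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = [
                (chrom, chrom_start + st, chrom_start + st + sz, strand, name)
                for st, sz in zip(starts, sizes)
            ]
            tx_exons[name] = exons
    return tx_exons


def read_annotation(
    annotation_file: str | Path,
    genome: str | Path,
    min_length: int = MIN_INTRON_LENGTH,
) -> list[IntronRecord]:
    """Extract one IntronRecord per inter-exon gap of each transcript.

    Accepts GFF3 (``.gff``/``.gff3``) or BED12 (``.bed``) annotation.
    Introns shared between isoforms are deduplicated on
    ``(chrom, start, end, strand)``; introns shorter than ``min_length``
    are kept but flagged ``too_short`` with a warning.
    """
    annotation_file = Path(annotation_file)
    if annotation_file.suffix.lower() == ".bed":
        tx_exons = _parse_bed12_exons(annotation_file)
    else:
        tx_exons = _parse_gff3_exons(annotation_file)

    fasta = Fasta(str(genome), sequence_always_upper=True)
    seen: set[tuple[str, int, int, str]] = set()
    per_gene: dict[str, list[IntronRecord]] = {}

    for tid in sorted(tx_exons):
        exons = sorted(tx_exons[tid], key=lambda x: x[1])
        chrom, strand, gene = exons[0][0], exons[0][3], exons[0][4] or tid
        for (_, s1, e1, *_), (_, s2, e2, *_) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ExonOverlapError(
                    f"overlapping exons in transcript {tid!r}: "
                    f"[{s1},{e1}) and [{s2},{e2})"
                )
        if chrom not in fasta:
            raise MissingChromosomeError(
                f"chromosome {chrom!r} (transcript {tid!r}) not in FASTA"
            )
        for (_, _, e1, *_), (_, s2, _, *_) in zip(exons, exons[1:]):
            key = (chrom, e1, s2, strand)
            if key in seen:
                continue
            seen.add(key)
            rec = _extract_intron(fasta, chrom, e1, s2, strand, gene)
            if rec.too_short:
                warnings.warn(
                    f"intron {chrom}:{e1}-{s2} ({gene}) is shorter than "
                    f"{min_length} nt; context strings may overlap",
                    stacklevel=2,
                )
            per_gene.setdefault(gene, []).append(rec)

    records: list[IntronRecord] = []
    for gene in sorted(per_gene):
        introns = sorted(per_gene[gene], key=lambda r: r.start)
        if introns[0].strand == "-":
            introns = introns[::-1]  # 5'->3' in transcript orientation
        for ordinal, rec in enumerate(introns, start=1):
            records.append(
                replace(
                    rec,
                    ordinal=ordinal,
                    intron_id=f"{gene}.intron{ordinal}",
                )
            )
    return records


def _extract_intron(
    fasta: Fasta, chrom: str, start: int, end: int, strand: str, gene: str
) -> IntronRecord:
    length = end - start
    intron_dna = fasta[chrom][start:end].seq
    if strand == "+":
        exon1_dna = fasta[chrom][max(0, start - 3) : start].seq
        intron_tx = intron_dna
    else:
        exon1_dna = reverse_complement(fasta[chrom][end : end + 3].seq)
        intron_tx = reverse_complement(intron_dna)
    intron_rna = to_rna(intron_tx)
    bs, bs_offset = (
        locate_branch_sequence(intron_rna)
        if length >= MIN_INTRON_LENGTH
        else (None, None)
    )
    return IntronRecord(
        intron_id="",
        gene_id=gene,
        ordinal=0,
        chrom=chrom,
        start=start,
        end=end,
        strand=strand,
        exon1_ctx=to_rna(exon1_dna),
        ss5=intron_rna[:6],
        ss3_ctx=intron_rna[-3:],
        bs=bs,
        bs_offset=bs_offset,
        too_short=length < MIN_INTRON_LENGTH,
    )


# ---------------------------------------------------------------------------
# TSV / BED interchange

_TSV_COLUMNS = [
    "intron_id", "gene_id", "ordinal", "chrom", "start", "end", "strand",
    "length", "exon1_ctx", "ss5", "bs", "bs_offset", "ss3_ctx", "too_short",
]


def introns_to_frame(introns: Iterable[IntronRecord]) -> pd.DataFrame:
    rows = [
        {
            "intron_id": r.intron_id,
            "gene_id": r.gene_id,
            "ordinal": r.ordinal,
            "chrom": r.chrom,
            "start": r.start,
            "end": r.end,
            "strand": r.strand,
            "length": r.length,
            "exon1_ctx": r.exon1_ctx,
            "ss5": r.ss5,
            "bs": r.bs if r.bs is not None else "not_found",
            "bs_offset": r.bs_offset if r.bs_offset is not None else -1,
            "ss3_ctx": r.ss3_ctx,
            "too_short": r.too_short,
        }
        for r in introns
    ]
    return pd.DataFrame(rows, columns=_TSV_COLUMNS)


def write_introns_tsv(introns: Iterable[IntronRecord], path: str | Path) -> None:
    introns_to_frame(introns).to_csv(path, sep="\t", index=False)


def read_introns_tsv(path: str | Path) -> list[IntronRecord]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    records = []
    for row in df.itertuples(index=False):
        records.append(
            IntronRecord(
                intron_id=str(row.intron_id),
                gene_id=str(row.gene_id),
                ordinal=int(row.ordinal),
                chrom=str(row.chrom),
                start=int(row.start),
                end=int(row.end),
                strand=str(row.strand),
                exon1_ctx=str(row.exon1_ctx),
                ss5=str(row.ss5),
                ss3_ctx=str(row.ss3_ctx),
                bs=None if row.bs == "not_found" else str(row.bs),
                bs_offset=None if int(row.bs_offset) < 0 else int(row.bs_offset),
                too_short=bool(row.too_short),
            )
        )
    return records


def write_introns_bed(introns: Iterable[IntronRecord], path: str | Path) -> None:
    """Write introns as BED6 (name = intron_id, score = length)."""
    with open(path, "w") as fh:
        for r in introns:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.intron_id}\t{r.length}\t{r.strand}\n"
            )


class IntronIndex:
    """Per-chromosome sorted index over intron 5' junctions for read lookup."""

    def __init__(self, introns: Sequence[IntronRecord]):
        self._by_chrom: dict[str, tuple[list[int], list[IntronRecord]]] = {}
        for chrom in {r.chrom for r in introns}:
            recs = sorted(
                (r for r in introns if r.chrom == chrom), key=lambda r: r.junction
            )
            self._by_chrom[chrom] = ([r.junction for r in recs], recs)

    def overlapping_junctions(
        self, chrom: str, ref_start: int, ref_end: int, window: int
    ) -> list[IntronRecord]:
        """Introns whose junction window [j-window, j+window) meets [ref_start, ref_end)."""
        if chrom not in self._by_chrom:
            return []
        positions, recs = self._by_chrom[chrom]
        lo = bisect.bisect_left(positions, ref_start - window + 1)
        hi = bisect.bisect_right(positions, ref_end + window - 1)
        return recs[lo:hi]
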