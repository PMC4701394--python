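"""Shared fixtures: toy genomes, in-memory reads, brute-force oracles."""

from __future__ import annotations

import pandas as pd
import pysam
import pytest

from prp4splice import annotation_io as aio
from prp4splice import junction_counting as jc
from prp4splice import rsei_analysis as ra
from prp4splice import synthetic_data as sd

SIM_HEADER = {
    "HD": {"VN": "1.6"},
    "SQ": [{"SN": "chr1", "LN": 100000}],
}


def make_read(
    name: str,
    pos: int,
    cigar: str,
    flag: int = 0,
    mapq: int = 60,
    chrom: str = "chr1",
    header: dict | None = None,
) -> pysam.AlignedSegment:
    """Build an in-memory aligned read with a placeholder sequence."""
    hdr = pysam.AlignmentHeader.from_dict(header or SIM_HEADER)
    rec = pysam.AlignedSegment(hdr)
    rec.query_name = name
    rec.flag = flag
    rec.reference_id = [sq["SN"] for sq in (header or SIM_HEADER)["SQ"]].index(chrom)
    rec.reference_start = pos
    rec.mapping_quality = mapq
    rec.cigarstring = cigar
    qlen = rec.infer_query_length()
    rec.query_sequence = "A" * qlen
    rec.query_qualities = pysam.qualitystring_to_array("I" * qlen)
    return rec


def brute_force_classify(
    read: pysam.AlignedSegment,
    intron: aio.IntronRecord,
    window: int = 3,
    stranded: bool = True,
) -> str:
    """Per-base enumeration oracle for junction classification.

    Walks the CIGAR assigning every aligned reference position a segment
    id (segments break at N, D and I), then checks the split/unsplit
    definitions positionally, independent of the implementation's
    run-length bookkeeping.
    """
    if read.reference_name != intron.chrom:
        return "NONE"
    if stranded and read.is_reverse != (intron.strand == "-"):
        return "NONE"
    seg: dict[int, int] = {}
    gaps: list[tuple[int, int]] = []
    ref = read.reference_start
    sid = 0
    for op, ln in read.cigartuples:
        if op in (0, 7, 8):
            for p in range(ref, ref + ln):
                seg[p] = sid
            ref += ln
        elif op == 3:
            gaps.append((ref, ref + ln))
            ref += ln
            sid += 1
        elif op == 2:
            ref += ln
            sid += 1
        elif op in (1, 4, 5):
            sid += 1
        else:
            raise ValueError(f"op {op}")

    def one_segment(positions: list[int]) -> bool:
        return all(p in seg for p in positions) and len(
            {seg[p] for p in positions}
        ) == 1

    for gs, ge in gaps:
        boundary = gs == intron.start if intron.strand == "+" else ge == intron.end
        left = [gs - 1 - k for k in range(window)]
        right = [ge + k for k in range(window)]
        if boundary and one_segment(left) and one_segment(right):
            return "SPLIT"
    j = intron.junction
    if one_segment(list(range(j - window, j + window))):
        return "UNSPLIT"
    return "NONE"


def brute_force_counts(reads, introns, sample_id, window=3, stranded=True):
    split = {r.intron_id: 0 for r in introns}
    unsplit = {r.intron_id: 0 for r in introns}
    for read in reads:
        if (
            read.is_unmapped
            or read.is_secondary
            or read.is_supplementary
            or read.mapping_quality < 1
        ):
            continue
        for intron in introns:
            call = brute_force_classify(read, intron, window, stranded)
            if call == "SPLIT":
                split[intron.intron_id] += 1
            elif call == "UNSPLIT":
                unsplit[intron.intron_id] += 1
    return {
        iid: (split[iid], unsplit[iid]) for iid in split
    }


def toy_intron(
    start: int = 1000,
    end: int = 1100,
    strand: str = "+",
    intron_id: str = "gX.intron1",
    chrom: str = "chr1",
) -> aio.IntronRecord:
    return aio.IntronRecord(
        intron_id=intron_id,
        gene_id="gX",
        ordinal=1,
        chrom=chrom,
        start=start,
        end=end,
        strand=strand,
        exon1_ctx="AAG",
        ss5="GUAAGU",
        ss3_ctx="UAG",
        bs="CUAAC",
        bs_offset=20,
    )


def run_pipeline(config: sd.SimConfig, workdir):
    """Simulate, extract, count and classify; return all intermediates."""
    fasta, gff, truth = sd.generate_genome(config, workdir)
    sam_paths, ledger = sd.simulate_reads(fasta, truth, config, workdir)
    introns = aio.read_annotation(gff, fasta)
    counts = pd.concat(
        [
            jc.counts_to_frame(jc.count_junctions(path, introns, sample))
            for sample, path in sam_paths.items()
        ],
        ignore_index=True,
    )
    manifest = pd.DataFrame(
        {"sample_id": list(sam_paths), "condition": list(sam_paths)}
    )
    rsei = ra.rsei_table(counts, manifest)
    report = sd.recovery_report(truth, rsei)
    return {
        "config": config,
        "fasta": fasta,
        "gff": gff,
        "truth": truth,
        "sam_paths": sam_paths,
        "ledger": ledger,
        "introns": introns,
        "counts": counts,
        "rsei": rsei,
        "report": report,
    }


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """30 single-intron genes at modest depth; shared across test modules."""
    cfg = sd.SimConfig(n_genes=30, depth=100.0, seed=7)
    return run_pipeline(cfg, tmp_path_factory.mktemp("small_sim"))


@pytest.fixture(scope="session")
def study_sim(tmp_path_factory):
    """The desk-scale study conditions: 200 introns, depth 500, f=0.3."""
    cfg = sd.SimConfig(seed=11)
    return run_pipeline(cfg, tmp_path_factory.mktemp("study_sim"))
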