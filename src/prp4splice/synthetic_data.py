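"""Synthetic genomes, annotations and aligned junction reads.

The generator emulates the three-sample design of an acute kinase-
inhibition experiment: one untreated sample and two inhibitor timepoints
(30 and 60 min).  Each intron carries a true splicing efficiency theta per
condition; kinase-dependent introns have theta multiplied by an inhibition
effect delta under treatment, independent introns keep theta.  Junction
reads are emitted pre-aligned (SAM) -- a Poisson number of reads per
intron per sample, each spliced with probability theta (an N-gap CIGAR
skipping the intron exactly) or unspliced (a contiguous match spanning
the junction) -- so every downstream stage can be tested against the
generator's own bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import pysam

from prp4splice.annotation_io import reverse_complement
from prp4splice.rsei_analysis import DEPENDENT, INDEPENDENT, UNCLASSIFIED

SAMPLES = ("untreated", "inh30", "inh60")
CONDITIONS: Mapping[str, str] = {s: s for s in SAMPLES}

_RNA_TO_DNA = str.maketrans("U", "T")


class GeometryError(ValueError):
    """Requested gene/read geometry is infeasible."""


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the simulated inhibition experiment.

    Defaults are the desk-scale conditions used throughout the test suite:
    200 single-intron genes, intron lengths 40-120 nt (centred near the
    83 nt fission-yeast average), 30% kinase-dependent introns, untreated
    splicing efficiency theta ~ Beta(9, 1) (splicing is efficient for
    nearly all introns in untreated cells), a multiplicative inhibition
    effect delta = 0.05 on dependent introns, and a mean junction depth of
    500 reads per intron per sample.
    """

    n_genes: int = 200
    introns_per_gene: int = 1
    intron_length_range: tuple[int, int] = (40, 120)
    exon_length: int = 80
    dependent_fraction: float = 0.3
    theta_alpha: float = 9.0
    theta_beta: float = 1.0
    inhibition_effect: float = 0.05
    depth: float = 500.0
    read_length: int = 50
    window: int = 3
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.dependent_fraction <= 1:
            raise ValueError("dependent_fraction must be in [0, 1]")
        if not 0 <= self.inhibition_effect:
            raise ValueError("inhibition_effect must be non-negative")
        lo, hi = self.intron_length_range
        if lo < 12 or hi < lo:
            raise GeometryError("intron length range must be >= 12 nt")
        if self.exon_length < self.read_length:
            raise GeometryError(
                "exons must be at least one read length long"
            )
        if self.read_length < 2 * self.window:
            raise GeometryError(
                f"read length {self.read_length} too short for "
                f"2 x window ({self.window})"
            )


# 5'SS positions +3..+6 drawn from a consensus-like distribution (the +1/+2
# GU dinucleotide is invariant); branch sequence from the C/U, U, N, A, C/U
# consensus.
_SS5_TAIL_FREQS = (
    ("A", 0.60, "U", 0.25, "C", 0.10, "G", 0.05),  # +3
    ("A", 0.50, "U", 0.30, "G", 0.10, "C", 0.10),  # +4
    ("G", 0.80, "A", 0.10, "U", 0.05, "C", 0.05),  # +5
    ("U", 0.80, "G", 0.10, "A", 0.05, "C", 0.05),  # +6
)
_BS_FREQS = (
    ("C", 0.6, "U", 0.4),
    ("U", 1.0),
    ("A", 0.5, "G", 0.2, "U", 0.2, "C", 0.1),
    ("A", 1.0),
    ("C", 0.6, "U", 0.4),
)


def _draw(freq_row: tuple, rng: np.random.Generator) -> str:
    letters = freq_row[0::2]
    probs = np.asarray(freq_row[1::2], dtype=float)
    return str(rng.choice(list(letters), p=probs / probs.sum()))


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def _intron_dna(rng: np.random.Generator, length: int) -> str:
    """Intron sequence (DNA) with consensus 5'SS, planted bs and 3' AG."""
    ss5 = "GT" + "".join(
        _draw(row, rng) for row in _SS5_TAIL_FREQS
    ).translate(_RNA_TO_DNA)
    bs = "".join(_draw(row, rng) for row in _BS_FREQS).translate(_RNA_TO_DNA)
    ss3 = _draw(("T", 0.6, "C", 0.4), rng).translate(_RNA_TO_DNA) + "AG"
    # branch A 10-30 nt from the 3' end (within the 5-50 search window)
    bs_offset = int(rng.integers(10, min(31, length - 11)))
    # layout: ss5(6) | mid | bs(5) | tail | ss3(3); branch A (bs position 4)
    # then sits tail_len + 4 nt from the 3' end
    tail_len = bs_offset - 4
    mid_len = length - 6 - 5 - tail_len - 3
    if mid_len < 0 or tail_len < 0:
        raise GeometryError(f"intron length {length} too short for layout")
    # avoid accidental AG-rich / A-at-branch decoys in fillers: exclude A
    mid = "".join(rng.choice(list("CGT"), size=mid_len))
    tail = "".join(rng.choice(list("CGT"), size=tail_len))
    return ss5 + mid + bs + tail + ss3


def generate_genome(
    config: SimConfig, outdir: str | Path
) -> tuple[Path, Path, pd.DataFrame]:
    """Write a toy genome (FASTA), annotation (GFF3) and truth table.

    Every gene has ``introns_per_gene + 1`` exons of ``exon_length`` nt
    separated by introns with consensus-like splice sites; genes alternate
    deterministically between strands.  The truth table lists, per intron,
    the dependency class and the true splicing efficiency theta for each
    condition.  Output is byte-identical for a fixed seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta_path = outdir / "genome.fa"
    gff_path = outdir / "annotation.gff3"
    truth_path = outdir / "truth.tsv"

    n_introns = (
        config.n_genes * config.introns_per_gene
        if isinstance(config.introns_per_gene, int)
        else None
    )
    lo, hi = config.intron_length_range
    chrom = "chrSIM"
    spacer = 50
    seq_parts: list[str] = []
    gff_lines = ["##gff-version 3"]
    truth_rows = []
    cursor = 0

    for g in range(config.n_genes):
        gene_id = f"g{g + 1:04d}"
        strand = "+" if g % 2 == 0 else "-"
        dependent = bool(rng.random() < config.dependent_fraction)
        theta_u = float(rng.beta(config.theta_alpha, config.theta_beta))
        if dependent:
            theta_t = min(1.0, theta_u * config.inhibition_effect)
        else:
            theta_t = theta_u

        spacer_seq = _random_dna(rng, spacer)
        seq_parts.append(spacer_seq)
        cursor += spacer
        gene_start = cursor

        exon_coords = []
        intron_coords = []
        n_exons = config.introns_per_gene + 1
        for e in range(n_exons):
            exon_seq = _random_dna(rng, config.exon_length)
            seq_parts.append(exon_seq)
            exon_coords.append((cursor, cursor + config.exon_length))
            cursor += config.exon_length
            if e < n_exons - 1:
                ilen = int(rng.integers(lo, hi + 1))
                intron_seq = _intron_dna(rng, ilen)
                if strand == "-":
                    intron_seq = reverse_complement(intron_seq)
                seq_parts.append(intron_seq)
                intron_coords.append((cursor, cursor + ilen))
                cursor += ilen
        gene_end = cursor

        # transcript-orientation ordinals
        ordered = intron_coords if strand == "+" else intron_coords[::-1]
        for ordinal, (istart, iend) in enumerate(ordered, start=1):
            truth_rows.append(
                {
                    "intron_id": f"{gene_id}.intron{ordinal}",
                    "gene_id": gene_id,
                    "chrom": chrom,
                    "start": istart,
                    "end": iend,
                    "strand": strand,
                    "dependent": dependent,
                    "theta_untreated": theta_u,
                    "theta_inh30": theta_t,
                    "theta_inh60": theta_t,
                }
            )

        tid = f"{gene_id}.1"
        gff_lines.append(
            f"{chrom}\t.\tgene\t{gene_start + 1}\t{gene_end}\t.\t{strand}\t.\tID={gene_id}"
        )
        gff_lines.append(
            f"{chrom}\t.\tmRNA\t{gene_start + 1}\t{gene_end}\t.\t{strand}\t.\t"
            f"ID={tid};Parent={gene_id}"
        )
        for es, ee in exon_coords:
            gff_lines.append(
                f"{chrom}\t.\texon\t{es + 1}\t{ee}\t.\t{strand}\t.\tParent={tid}"
            )

    genome_seq = "".join(seq_parts)
    with open(fasta_path, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(genome_seq), 70):
            fh.write(genome_seq[i : i + 70] + "\n")
    with open(gff_path, "w") as fh:
        fh.write("\n".join(gff_lines) + "\n")
    truth = pd.DataFrame(truth_rows)
    truth.to_csv(truth_path, sep="\t", index=False)
    assert n_introns is None or len(truth) == n_introns
    return fasta_path, gff_path, truth


def simulate_reads(
    genome_fasta: str | Path,
    truth: pd.DataFrame,
    config: SimConfig,
    outdir: str | Path,
) -> tuple[dict[str, Path], pd.DataFrame]:
    """Emit per-sample SAM files of junction reads with known composition.

    Returns the SAM path per sample and an emission ledger with the exact
    split/unsplit read numbers per intron per sample (the oracle for
    junction-counting tests).  All reads are primary, mapping quality 60,
    on the transcript strand, coordinate-sorted.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    from pyfaidx import Fasta

    genome = Fasta(str(genome_fasta), sequence_always_upper=True)
    chrom_lengths = {name: len(genome[name]) for name in genome.keys()}
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": n, "LN": ln} for n, ln in chrom_lengths.items()],
    }

    rl, w = config.read_length, config.window
    chrom_seqs = {name: genome[name][:].seq for name in genome.keys()}
    sam_paths: dict[str, Path] = {}
    ledger_rows = []
    for sample in SAMPLES:
        theta_col = f"theta_{sample}"
        reads = []  # (pos, name, flag, cigar, seq)
        serial = 0
        for row in truth.itertuples(index=False):
            theta = getattr(row, theta_col)
            n = int(rng.poisson(config.depth))
            n_split = int(rng.binomial(n, theta)) if n else 0
            n_unsplit = n - n_split
            chrom, istart, iend = row.chrom, int(row.start), int(row.end)
            ilen = iend - istart
            junction = istart if row.strand == "+" else iend
            flag = 0 if row.strand == "+" else 16
            chrom_seq = chrom_seqs[chrom]

            for _ in range(n_split):
                a = int(rng.integers(w, rl - w + 1))  # exon bases before gap
                b = rl - a
                pos = istart - a
                cigar = f"{a}M{ilen}N{b}M"
                seq = chrom_seq[pos : pos + a] + chrom_seq[iend : iend + b]
                serial += 1
                reads.append(
                    (pos, f"{sample}.r{serial}", flag, cigar, seq)
                )
            for _ in range(n_unsplit):
                a = int(rng.integers(w, rl - w + 1))  # bases before junction
                pos = junction - a
                cigar = f"{rl}M"
                seq = chrom_seq[pos : pos + rl]
                serial += 1
                reads.append(
                    (pos, f"{sample}.r{serial}", flag, cigar, seq)
                )
            ledger_rows.append(
                {
                    "intron_id": row.intron_id,
                    "sample_id": sample,
                    "split": n_split,
                    "unsplit": n_unsplit,
                }
            )

        reads.sort(key=lambda r: (r[0], r[1]))
        path = outdir / f"{sample}.sam"
        with pysam.AlignmentFile(str(path), "wh", header=header) as out:
            for pos, name, flag, cigar, seq in reads:
                rec = pysam.AlignedSegment(out.header)
                rec.query_name = name
                rec.flag = flag
                rec.reference_id = 0
                rec.reference_start = pos
                rec.mapping_quality = 60
                rec.cigarstring = cigar
                rec.query_sequence = seq
                rec.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
                out.write(rec)
        sam_paths[sample] = path
    return sam_paths, pd.DataFrame(ledger_rows)


def recovery_report(
    truth: pd.DataFrame, rsei: pd.DataFrame
) -> dict[str, object]:
    """Compare pipeline output against the simulation truth.

    Returns the dependency-class confusion matrix, sensitivity (fraction of
    true dependent introns called DEPENDENT among those passing the
    coverage filter; UNCLASSIFIED counts as a miss), specificity (fraction
    of true independent introns called INDEPENDENT), and the mean RSEI bias
    -- estimate minus log2(theta/(1-theta)) -- per sample over introns with
    finite estimates and theta strictly inside (0, 1).
    """
    merged = truth.merge(rsei, on="intron_id", how="inner")
    filtered = merged[merged["passed_filter"]]
    if filtered.empty:
        return {
            "confusion": pd.DataFrame(),
            "sensitivity": float("nan"),
            "specificity": float("nan"),
            "rsei_bias": pd.DataFrame(),
            "n_classified": 0,
        }
    truth_cls = np.where(filtered["dependent"], DEPENDENT, INDEPENDENT)
    confusion = pd.crosstab(
        pd.Series(truth_cls, name="truth"),
        filtered["dependency_class"].rename("predicted"),
    )
    dep = filtered[filtered["dependent"]]
    indep = filtered[~filtered["dependent"]]
    sensitivity = (
        float((dep["dependency_class"] == DEPENDENT).mean())
        if len(dep)
        else float("nan")
    )
    specificity = (
        float((indep["dependency_class"] == INDEPENDENT).mean())
        if len(indep)
        else float("nan")
    )

    bias_rows = []
    for sample in SAMPLES:
        col, tcol = f"rsei_{sample}", f"theta_{sample}"
        if col not in merged.columns:
            continue
        sub = merged[
            np.isfinite(merged[col])
            & (merged[tcol] > 0)
            & (merged[tcol] < 1)
        ]
        expected = np.log2(sub[tcol] / (1.0 - sub[tcol]))
        resid = sub[col] - expected
        bias_rows.append(
            {
                "sample_id": sample,
                "n": int(len(sub)),
                "mean_bias": float(resid.mean()),
                "sd": float(resid.std(ddof=1)) if len(sub) > 1 else float("nan"),
            }
        )
    return {
        "confusion": confusion,
        "sensitivity": sensitivity,
        "specificity": specificity,
        "rsei_bias": pd.DataFrame(bias_rows),
        "n_classified": int((filtered["dependency_class"] != UNCLASSIFIED).sum()),
    }
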