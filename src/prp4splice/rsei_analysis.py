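"""Relative Splicing Efficiency Index (RSEI) and dependency classification.

RSEI = log2(S / U) where S and U are the split and unsplit read counts at
an intron's 5' exon junction.  A positive RSEI means the intron is mostly
spliced out; a negative RSEI means unspliced pre-mRNA dominates.  An intron
is called kinase-DEPENDENT when its RSEI is positive without inhibitor but
negative under kinase inhibition, and INDEPENDENT when it stays positive
throughout.  Only introns with more than ``min_reads`` junction reads in
every sample are classified.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

INDEPENDENT = "INDEPENDENT"
DEPENDENT = "DEPENDENT"
UNCLASSIFIED = "UNCLASSIFIED"

DEFAULT_MIN_READS = 10
DEFAULT_BIN = 0.05

RNA_ALPHABET = ("A", "C", "G", "U")


class ZeroCoverageError(ValueError):
    """RSEI requested for an intron with no junction reads at all."""


class MissingSampleError(KeyError):
    """A required sample is absent from the junction-count table."""


class EmptyTreatedError(ValueError):
    """Dependency classification needs at least one treated sample."""


@dataclass(frozen=True)
class RseiRecord:
    intron_id: str
    rsei_by_sample: Mapping[str, float]
    passed_filter: bool
    dependency_class: str


def compute_rsei(split: int, unsplit: int, pseudocount: float = 0.0) -> float:
    """log2((S + c) / (U + c)); +/-inf sentinels when a count is 0 and c = 0."""
    if split < 0 or unsplit < 0:
        raise ValueError("counts must be non-negative")
    s = split + pseudocount
    u = unsplit + pseudocount
    if s == 0 and u == 0:
        raise ZeroCoverageError(
            "RSEI undefined for S = U = 0 with pseudocount 0; "
            "apply the coverage filter first"
        )
    if u == 0:
        return math.inf
    if s == 0:
        return -math.inf
    return math.log2(s / u)


def apply_coverage_filter(
    totals_by_sample: Mapping[str, int],
    min_reads: int = DEFAULT_MIN_READS,
    required_samples: Sequence[str] | None = None,
) -> bool:
    """True iff total junction reads exceed ``min_reads`` in every sample.

    The threshold is strict: a sample with exactly ``min_reads`` fails.
    """
    if required_samples is not None:
        missing = [s for s in required_samples if s not in totals_by_sample]
        if missing:
            raise MissingSampleError(
                f"missing sample(s) in count table: {', '.join(missing)}"
            )
    if not totals_by_sample:
        return False
    return all(t > min_reads for t in totals_by_sample.values())


def classify_dependency(
    rsei_untreated: float,
    rsei_treated: Sequence[float],
    mode: str = "any",
) -> str:
    """Classify an intron from untreated and inhibitor-treated RSEI values.

    INDEPENDENT: positive RSEI with and without inhibitor.
    DEPENDENT: positive untreated RSEI, negative under inhibition -- at any
    treated timepoint (``mode="any"``, default) or at all of them
    (``mode="all"``).
    UNCLASSIFIED: everything else (non-positive untreated RSEI, or treated
    values that are zero without any being negative).
    """
    if len(rsei_treated) == 0:
        raise EmptyTreatedError("at least one treated RSEI value is required")
    if mode not in {"any", "all"}:
        raise ValueError(f"mode must be 'any' or 'all', got {mode!r}")
    if not rsei_untreated > 0:
        return UNCLASSIFIED
    negative = [r < 0 for r in rsei_treated]
    if (any(negative) if mode == "any" else all(negative)):
        return DEPENDENT
    if all(r > 0 for r in rsei_treated):
        return INDEPENDENT
    return UNCLASSIFIED


def rsei_table(
    counts: pd.DataFrame,
    manifest: pd.DataFrame,
    min_reads: int = DEFAULT_MIN_READS,
    pseudocount: float = 0.0,
    mode: str = "any",
) -> pd.DataFrame:
    """Per-intron RSEI across samples, coverage filter and dependency class.

    ``counts`` has columns intron_id, sample_id, split, unsplit;
    ``manifest`` has columns sample_id, condition with conditions drawn from
    {untreated, inh30, inh60, ...}; exactly one untreated sample is required
    for classification.
    """
    required = {"intron_id", "sample_id", "split", "unsplit"}
    if not required.issubset(counts.columns):
        raise ValueError(f"count table must have columns {sorted(required)}")
    conditions = dict(zip(manifest["sample_id"], manifest["condition"]))
    untreated = [s for s, c in conditions.items() if c == "untreated"]
    if len(untreated) != 1:
        raise MissingSampleError(
            f"exactly one untreated sample required, found {len(untreated)}"
        )
    untreated_sample = untreated[0]
    treated_samples = [s for s in conditions if s != untreated_sample]
    samples = [untreated_sample] + treated_samples

    wide_split = counts.pivot_table(
        index="intron_id", columns="sample_id", values="split", aggfunc="sum"
    )
    wide_unsplit = counts.pivot_table(
        index="intron_id", columns="sample_id", values="unsplit", aggfunc="sum"
    )
    missing = [s for s in samples if s not in wide_split.columns]
    if missing:
        raise MissingSampleError(
            f"missing sample(s) in count table: {', '.join(missing)}"
        )

    rows = []
    for intron_id in wide_split.index:
        totals = {
            s: int(wide_split.loc[intron_id, s]) + int(wide_unsplit.loc[intron_id, s])
            for s in samples
        }
        passed = apply_coverage_filter(totals, min_reads=min_reads)
        rsei = {}
        for s in samples:
            sp = int(wide_split.loc[intron_id, s])
            un = int(wide_unsplit.loc[intron_id, s])
            if sp == 0 and un == 0 and pseudocount == 0:
                rsei[s] = math.nan
            else:
                rsei[s] = compute_rsei(sp, un, pseudocount)
        if passed:
            cls = classify_dependency(
                rsei[untreated_sample],
                [rsei[s] for s in treated_samples],
                mode=mode,
            )
        else:
            cls = UNCLASSIFIED
        row = {"intron_id": intron_id, "passed_filter": passed,
               "dependency_class": cls}
        for s in samples:
            row[f"rsei_{s}"] = rsei[s]
            row[f"total_{s}"] = totals[s]
        rows.append(row)
    return pd.DataFrame(rows)


def rsei_histogram(
    values: Iterable[float], bin_size: float = DEFAULT_BIN
) -> pd.DataFrame:
    """Bin RSEI values into half-open bins [k*bin, (k+1)*bin).

    Infinite sentinel values go to ``+inf`` / ``-inf`` overflow bins; NaN
    values are dropped.  Frequencies sum to the number of finite and
    infinite inputs.
    """
    if bin_size <= 0:
        raise ValueError(f"bin size must be positive, got {bin_size}")
    vals = np.asarray(list(values), dtype=float)
    vals = vals[~np.isnan(vals)]
    finite = vals[np.isfinite(vals)]
    n_neg_inf = int(np.sum(vals == -math.inf))
    n_pos_inf = int(np.sum(vals == math.inf))
    counts: dict[float, int] = {}
    for v in finite:
        k = math.floor(v / bin_size)
        left = k * bin_size
        counts[left] = counts.get(left, 0) + 1
    rows = []
    if n_neg_inf:
        rows.append({"bin_left": -math.inf, "bin_right": -math.inf,
                     "count": n_neg_inf})
    for left in sorted(counts):
        rows.append({"bin_left": left, "bin_right": left + bin_size,
                     "count": counts[left]})
    if n_pos_inf:
        rows.append({"bin_left": math.inf, "bin_right": math.inf,
                     "count": n_pos_inf})
    return pd.DataFrame(rows, columns=["bin_left", "bin_right", "count"])


def summarize_sizes(
    lengths_by_class: Mapping[str, Sequence[int]],
) -> pd.DataFrame:
    """Descriptive length quantiles per dependency class (no testing)."""
    rows = []
    for cls, lengths in lengths_by_class.items():
        arr = np.asarray(list(lengths), dtype=float)
        if arr.size == 0:
            rows.append({"class": cls, "n": 0, "min": math.nan,
                         "q25": math.nan, "median": math.nan,
                         "q75": math.nan, "max": math.nan})
        else:
            rows.append({
                "class": cls,
                "n": int(arr.size),
                "min": float(arr.min()),
                "q25": float(np.quantile(arr, 0.25)),
                "median": float(np.median(arr)),
                "q75": float(np.quantile(arr, 0.75)),
                "max": float(arr.max()),
            })
    return pd.DataFrame(rows)


def position_frequency_matrix(sequences: Sequence[str]) -> pd.DataFrame:
    """4 x L position frequency matrix over the RNA alphabet.

    Rows are A, C, G, U; columns are 0-based positions; every column sums
    to 1.  All sequences must have equal length and contain only ACGU.
    """
    if not sequences:
        raise ValueError("no sequences given")
    length = len(sequences[0])
    counts = np.zeros((4, length), dtype=float)
    idx = {b: i for i, b in enumerate(RNA_ALPHABET)}
    for seq in sequences:
        if len(seq) != length:
            raise ValueError(
                f"sequences of unequal length: {length} vs {len(seq)}"
            )
        for pos, base in enumerate(seq):
            if base not in idx:
                raise ValueError(
                    f"non-ACGU character {base!r} in sequence {seq!r}"
                )
            counts[idx[base], pos] += 1
    freqs = counts / counts.sum(axis=0, keepdims=True)
    return pd.DataFrame(freqs, index=list(RNA_ALPHABET),
                        columns=list(range(length)))
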