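# Methods

## Junction counting and the RSEI

For every annotated intron the statistic of interest is measured at the 5'
exon/intron junction only. A read is **split** when its alignment contains
an N gap whose transcript-5' boundary coincides exactly with the junction
and at least `window` (default 3) aligned bases flank the gap on each side;
it is **unsplit** when a single gapless aligned block covers the last
`window` exon bases and the first `window` intron bases. "Three bases
around the junction" is applied two-sidedly for both calls — the symmetric
reading, standard for junction quantification. A split read is not required
to match the intron's 3' boundary (the statistic is defined at the 5'
junction); `--require-both-boundaries` tightens this. Soft-clipped bases
never count toward the window, and insertions, deletions and skips all
interrupt contiguity for the unsplit call. Secondary and supplementary
alignments and reads with mapping quality below 1 are excluded as
multimappers; with a stranded library (default) antisense reads are
ignored. Mates of a pair are counted as independent reads.

RSEI = log2((S + c)/(U + c)) with pseudocount c = 0 by default, matching
the plain log-ratio definition; S = 0 or U = 0 then yield ∓∞ sentinels,
which the histogram routine places in overflow bins. The coverage filter
is strict: an intron is classifiable only when S + U > `min_reads`
(default 10) in **every** sample. Classification against one untreated
and ≥ 1 treated sample: INDEPENDENT iff all RSEI are positive; DEPENDENT
iff the untreated RSEI is positive and a treated one is negative — at any
treated timepoint by default (`--mode all` requires all timepoints, since
the verbal definition "negative in the presence of inhibitor" admits both
readings); everything else, including exact zeros, is UNCLASSIFIED. Ties
at zero are practically impossible with real counts.

## Intron extraction and branch-sequence search

Coordinates are 0-based half-open internally (GFF3 converted at the
boundary; reports 1-based). Context strings are extracted in transcript
orientation and transcribed to RNA (T→U) once, so all pairing logic
downstream is strand-free: `exon1_ctx` (−3..−1), `ss5` (+1..+6), `bs`
(5 nt, position 4 = branch adenosine), `ss3_ctx` (last 3 intron nt).
Introns shared by isoforms are deduplicated on (chrom, start, end,
strand); ordinals are numbered 5'→3' per gene and reported as Roman
numerals. Introns shorter than 12 nt cannot hold the three elements
without overlap and are flagged rather than dropped.

The branch sequence is found with a position-weight matrix built from the
fungal consensus (position 1: C/U; 2: U; 3: any; 4: A, required; 5: C/U),
scored as the **sum** of per-position weights so that a single
off-consensus position does not veto a window, with the branch adenosine
constrained to lie 5–50 nt upstream of the intron's 3' end — the
conventional fungal range; the genome-wide search convention used for the
original counts is not recoverable. Ties break toward the 3' end, the
position the spliceosome favours for branch points close to the 3' splice
site. No valid window (no A at position 4 in range) is reported as
"not found" and the intron flagged.

## Pairing registers, hydrogen bonds and the dependency rules

U1 5' end is fixed as residues 1..9 = A, C, Ψ, U, A, C, C, U, G, pairing
antiparallel with +6..+1, −1..−3 (residue 3 = Ψ opposite +4); it is a
constructor argument for other species. The U2 register pairs branch
positions 1, 2, 3, 5 against G, A, Ψ, G with position 4 bulged and never
scored. Pair types are a pure function of the two bases: Watson–Crick,
G·U wobble, Ψ-stable (Ψ against A or G), or none (including Ψ–C/Ψ–U,
consistent with Ψ pairing most stably with A and G). Hydrogen bonds:
G–C 3; A–U, G·U, Ψ–A, Ψ–G 2; else 0. This table is the simplest integral
scoring under which the two strengthened reporter alleles gain a minimum
of exactly 4 bonds over the weak wild-type register while a Ψ–U contact
contributes nothing.

The classifier reduces a U1 register to features: e = number of
Watson–Crick pairs at −1/−2; s3, s5, s6 = Watson–Crick at +3/+5/+6;
s4 = Ψ-stable at +4. Rules, in order:

1. +1/+2 ≠ GU → NOT_RECOGNIZED (the invariant dinucleotide).
2. s3 + s4 = 0 and (s6 = 0 or e ≤ 1) → NOT_RECOGNIZED (three
   intermittent pairs are insufficient for recognition).
3. Otherwise INDEPENDENT iff s5 = 1, e ≥ 1, and the 5'SS core holds
   (s3 = 1, or s3 + s4 = 2, or s4 = 1 with e = 2); else DEPENDENT.

Branch-sequence rules layer on top (a NOT_RECOGNIZED 5'SS dominates):
position 2 ≠ U → NOT_RECOGNIZED; branch A destroyed → NOT_RECOGNIZED on a
weak 5'SS, barely-spliced DEPENDENT on a strong one; position 3 not
Ψ-stabilized → DEPENDENT; an unpaired flank (1 or 5) costs efficiency
only (REDUCED on a strong 5'SS, SEVERE on a weak one).

These rules are the minimal decision system consistent with every allele
in the shipped panel; exhaustive enumeration of all 4^9 exon1/5'SS
sequences confirms internal consistency, and registers whose outcome
rests on pair states the panel never probes (G·U wobbles at −2 or +3) are
flagged `extrapolated`. Efficiency is a coarse three-level label; the
prediction that independence carried by a single anchor is REDUCED
over-calls one panel allele whose splicing is described as fully
efficient, so efficiency agreement is reported alongside, but separately
from, class concordance.

### The allele panel

41 fixtures encode the mutant reporter series, the two-intron wild-type
gene used as a natural test of the exon rules, and two intron-transplant
constructs. Where a figure shows a mutated position only as a pair state,
the fixture stores `N` plus an explicit override rather than a guessed
nucleotide; the two transplant fixtures are synthetic pattern-based
registers (flanking sequences were never printed) and are labelled as
such in their source column. The allele numbering attaches the +3-only,
+4-only and +1/+2-control constructs to otherwise unnumbered figure
panels; one allele number is omitted entirely because no phenotype is
stated for it anywhere in the text.

## Synthetic data

The generator emulates the three-sample acute-inhibition design. Defaults
(chosen once as the study conditions for the test suite): 200
single-intron genes on alternating strands, 80 nt exons, intron lengths
uniform 40–120 nt around the 83 nt fission-yeast average, 30% dependent
introns, θ_untreated ~ Beta(9, 1) — untreated splicing is efficient for
nearly all introns, matching a strongly positive untreated RSEI
distribution — and θ_treated = δ·θ_untreated with δ = 0.05 for dependent
introns (both timepoints; independents keep θ). Depth is Poisson with
mean λ = 500 junction reads per intron per sample; reads (50 nt) are
emitted pre-aligned with exact N-gap CIGARs for spliced molecules and
contiguous matches for unspliced ones, placement uniform subject to the
3-base window, all primary, mapq 60, on the transcript strand,
coordinate-sorted. Output is byte-identical under a fixed seed.

What this emulates — two intron classes, binomial split/unsplit sampling,
Poisson depth, both strands — and what it does not: alignment error,
multimappers, soft-clipping, paired-end structure, expression confounding
(depth is independent of class), or 3'SS/branch decoys beyond the planted
elements. Passing recovery tests therefore demonstrates correctness of
the counting and classification machinery, not robustness to alignment
artefacts.

`recovery_report` defines sensitivity as the fraction of true dependent
introns (passing the coverage filter) called DEPENDENT — UNCLASSIFIED
counts as a miss — and specificity as the fraction of true independents
called INDEPENDENT. RSEI bias is the mean of estimate − log2(θ/(1−θ))
over introns with finite estimates and θ ∈ (0, 1), per sample. At the
study conditions the acceptance suite requires sensitivity and
specificity ≥ 0.95 and a mean untreated-sample bias within three standard
errors of zero; the first-order bias of the binomial log-odds at depth
500 (~0.01–0.02 log2 units) sits well inside that band. Estimator
consistency is checked separately at depths 50/500/5000 with a moderate
θ distribution (Beta(4, 2)) so the true log-odds stay away from the
infinite-sentinel region at low depth.

## Problem sizes and runtime

The shipped tests and the acceptance script run the full pipeline at 200
introns × 3 samples × ~500 reads (≈ 300k alignments, a few seconds) and
exhaustive rule enumeration at 4^9 registers; these sizes make every
check reproducible on a laptop. Genome-scale analyses (thousands of
introns from real alignments against a specific annotation release) use
the same code paths via the CLI but depend on the chosen annotation
version, which is why no genome-wide intron counts are asserted anywhere
in the package.

## Known limitations

- No thermodynamic (nearest-neighbour) duplex model: hydrogen-bond
  counting is deliberately coarse, and kinetic effects are out of scope.
- The rule system is fit to a finite allele panel; outside the probed
  pair-state space predictions are literal extrapolations and flagged.
- Junction counting treats read mates independently and performs no
  duplicate marking.
- The branch-point search reports one window per intron; genuinely
  ambiguous or multiple branch points are not modelled.
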