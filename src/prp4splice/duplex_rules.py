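"""Base-pairing registers between pre-mRNA and the U1/U2 snRNA 5' regions.

The 5' splice-site register pairs nine pre-mRNA positions -- the last three
exon-1 nucleotides (-3..-1) and the first six intron nucleotides (+1..+6)
-- against the nine 5'-terminal residues of fission-yeast U1 snRNA.  U1
residue 3 is a pseudouridine (psi) and sits opposite intron position +4;
psi pairs most stably with A or G.  The branch-sequence register pairs the
5-nt branch sequence against U2 snRNA with the branch adenosine (position
4) bulged out of the duplex and branch position 3 opposite the U2
pseudouridine (residue 39).

A rule system over these registers predicts whether an intron is not
recognized at all, spliced only with active Prp4 kinase (DEPENDENT), or
spliced regardless of kinase activity (INDEPENDENT).  The rules were fit
to, and are shipped with, a curated panel of mutant reporter alleles whose
splicing phenotypes are known.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

PSI = "Ψ"

# Pair types
WC = "WC"
WOBBLE_GU = "WOBBLE_GU"
PSI_STABLE = "PSI_STABLE"
NONE_PAIR = "NONE"
BULGED = "BULGED"

# Classes / efficiency
NOT_RECOGNIZED = "NOT_RECOGNIZED"
DEPENDENT = "DEPENDENT"
INDEPENDENT = "INDEPENDENT"
NORMAL = "NORMAL"
REDUCED = "REDUCED"
SEVERE = "SEVERE"

# U1 snRNA 5'-terminal residues 1..9 (residue 3 is pseudouridine).  The
# register runs antiparallel: U1 residue 1 pairs intron +6, residue 9 pairs
# exon position -3.
U1_5PRIME: tuple[str, ...] = ("A", "C", PSI, "U", "A", "C", "C", "U", "G")

U1_POSITION_LABELS: tuple[str, ...] = (
    "-3", "-2", "-1", "+1", "+2", "+3", "+4", "+5", "+6"
)
# pre-mRNA label -> U1 residue number (1-based)
_U1_PARTNER_INDEX: dict[str, int] = {
    "+6": 1, "+5": 2, "+4": 3, "+3": 4, "+2": 5,
    "+1": 6, "-1": 7, "-2": 8, "-3": 9,
}

# U2 partners for branch-sequence positions 1,2,3,5 (complementary to the
# CUA_C consensus); position 4 is the bulged branch adenosine.
_U2_PARTNERS: dict[int, str] = {1: "G", 2: "A", 3: PSI, 5: "G"}

_WC_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE_PAIRS = {("G", "U"), ("U", "G")}


class RegisterError(ValueError):
    """Register construction failed (bad length or unresolved base)."""


class FixtureError(ValueError):
    """An allele fixture lacks both sequences and pairing overrides."""


def pair_type(pre_base: str, partner_base: str) -> str:
    """Pair type of one pre-mRNA base against one snRNA residue.

    Pseudouridine is treated as stabilizing only opposite A or G; psi-C and
    psi-U contacts are scored as unpaired, as are all non-Watson-Crick,
    non-G.U combinations.
    """
    if partner_base == PSI:
        return PSI_STABLE if pre_base in ("A", "G") else NONE_PAIR
    duo = (pre_base, partner_base)
    if duo in _WC_PAIRS:
        return WC
    if duo in _WOBBLE_PAIRS:
        return WOBBLE_GU
    return NONE_PAIR


def pair_hbonds(ptype: str, partner_base: str) -> int:
    """Hydrogen bonds contributed by one register position.

    G-C Watson-Crick pairs contribute 3 bonds; A-U, G.U wobble and
    stabilizing psi pairs contribute 2; everything else 0.  The partner
    base determines the 3-vs-2 split for Watson-Crick pairs, so positions
    whose pre-mRNA identity is known only as a pair state still score.
    """
    if ptype == WC:
        return 3 if partner_base in ("G", "C") else 2
    if ptype in (WOBBLE_GU, PSI_STABLE):
        return 2
    return 0


@dataclass(frozen=True)
class RegisterPosition:
    label: str
    pre_base: str  # RNA letter or "N" when only the pair state is known
    partner_base: str  # RNA letter or psi
    pair_type: str

    @property
    def hbonds(self) -> int:
        return pair_hbonds(self.pair_type, self.partner_base)


@dataclass(frozen=True)
class PairingRegister:
    """An ordered pre-mRNA/snRNA duplex with a pair type per position."""

    region: str  # "U1" or "U2"
    positions: tuple[RegisterPosition, ...]

    @property
    def hbonds(self) -> int:
        return sum(p.hbonds for p in self.positions)

    def __getitem__(self, label: str) -> RegisterPosition:
        for p in self.positions:
            if p.label == label:
                return p
        raise KeyError(label)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "position": p.label,
                    "pre_mRNA": p.pre_base,
                    "snRNA": p.partner_base,
                    "pair": p.pair_type,
                    "hbonds": p.hbonds,
                }
                for p in self.positions
            ]
        )


def _parse_overrides(spec: str | None) -> dict[str, str]:
    if not spec or (isinstance(spec, float) and math.isnan(spec)):
        return {}
    out = {}
    for item in str(spec).split(","):
        item = item.strip()
        if not item:
            continue
        label, state = item.split(":")
        out[label.strip()] = state.strip()
    return out


def build_u1_register(
    exon1: str,
    ss5: str,
    overrides: Mapping[str, str] | None = None,
) -> PairingRegister:
    """Build the 9-position exon1/5'SS-U1 register.

    ``exon1`` is the 3-mer at exon positions -3..-1 and ``ss5`` the 6-mer
    at intron positions +1..+6, both RNA.  ``N`` marks a base whose
    identity is unknown; each such position must have its pair state
    supplied in ``overrides`` (label -> pair type), as used by the curated
    allele panel for nucleotides not printed in the source figures.
    """
    exon1, ss5 = exon1.upper(), ss5.upper()
    if len(exon1) != 3:
        raise RegisterError(f"exon1 context must be 3 nt, got {exon1!r}")
    if len(ss5) != 6:
        raise RegisterError(f"5'SS must be 6 nt, got {ss5!r}")
    overrides = dict(overrides or {})
    pre = dict(zip(("-3", "-2", "-1"), exon1))
    pre.update(zip(("+1", "+2", "+3", "+4", "+5", "+6"), ss5))
    positions = []
    for label in U1_POSITION_LABELS:
        base = pre[label]
        partner = U1_5PRIME[_U1_PARTNER_INDEX[label] - 1]
        if label in overrides:
            ptype = overrides[label]
        elif base == "N":
            raise RegisterError(
                f"position {label} is N but has no pairing override"
            )
        else:
            if base not in "ACGU":
                raise RegisterError(
                    f"invalid base {base!r} at position {label}"
                )
            ptype = pair_type(base, partner)
        positions.append(RegisterPosition(label, base, partner, ptype))
    return PairingRegister(region="U1", positions=tuple(positions))


def build_u2_register(
    bs: str,
    overrides: Mapping[str, str] | None = None,
) -> PairingRegister:
    """Build the 5-position branch-sequence-U2 register.

    Position 4 carries the branch adenosine, bulged out of the duplex: its
    identity is recorded but it never pairs or contributes hydrogen bonds.
    """
    bs = bs.upper()
    if len(bs) != 5:
        raise RegisterError(f"branch sequence must be 5 nt, got {bs!r}")
    overrides = dict(overrides or {})
    positions = []
    for i, base in enumerate(bs, start=1):
        label = str(i)
        if i == 4:
            positions.append(RegisterPosition(label, base, "-", BULGED))
            continue
        partner = _U2_PARTNERS[i]
        if label in overrides:
            ptype = overrides[label]
        elif base == "N":
            raise RegisterError(
                f"branch position {i} is N but has no pairing override"
            )
        else:
            if base not in "ACGU":
                raise RegisterError(f"invalid base {base!r} at bs position {i}")
            ptype = pair_type(base, partner)
        positions.append(RegisterPosition(label, base, partner, ptype))
    return PairingRegister(region="U2", positions=tuple(positions))


def hbond_score(register: PairingRegister) -> int:
    """Total hydrogen bonds over the register (bulged positions excluded)."""
    return register.hbonds


@dataclass(frozen=True)
class Prediction:
    dependency_class: str
    efficiency: str
    extrapolated: bool = False


def _u1_features(u1: PairingRegister) -> dict[str, int | bool]:
    plus1 = u1["+1"]
    plus2 = u1["+2"]
    # +1/+2 must be the invariant GU dinucleotide; an unknown base whose
    # override says WC implies the invariant identity (partner C resp. A).
    plus1_ok = plus1.pre_base == "G" or (plus1.pre_base == "N" and plus1.pair_type == WC)
    plus2_ok = plus2.pre_base == "U" or (plus2.pre_base == "N" and plus2.pair_type == WC)
    e = sum(1 for lab in ("-1", "-2") if u1[lab].pair_type == WC)
    return {
        "gu_ok": plus1_ok and plus2_ok,
        "e": e,
        "s3": int(u1["+3"].pair_type == WC),
        "s4": int(u1["+4"].pair_type == PSI_STABLE),
        "s5": int(u1["+5"].pair_type == WC),
        "s6": int(u1["+6"].pair_type == WC),
    }


def classify_5ss(u1: PairingRegister) -> Prediction:
    """Dependency class of an intron from its exon1/5'SS-U1 register alone.

    Rules (each supported by the shipped allele panel):

    - Broken GU at +1/+2: never recognized (res1'-6/-14, ppk8'-1).
    - No contact at both +3 and +4, and either no contact at +6 or at most
      one exon Watson-Crick pair: not recognized -- three intermittent
      pairs are insufficient (res1'-8, ppk8'-3).
    - Otherwise INDEPENDENT requires a Watson-Crick pair at +5, at least
      one exon WC pair at -1/-2, and a stable 5'SS core: both +3 and +4
      paired, or +3 alone, or +4 alone backed by both exon pairs
      (res1'-2/-3/-4, ppk8'-2, mrp17-II); anything weaker is DEPENDENT.

    Independence carried by a single 5'SS pair or a single exon pair is
    flagged REDUCED.  Registers with a G.U wobble at -2 or +3 are flagged
    extrapolated: the panel never probes wobbles at those positions (only
    the wobble at -3 is covered), so treating them as non-contributing is
    the rules' literal reading rather than an observed outcome.
    """
    f = _u1_features(u1)
    extrapolated = any(
        u1[lab].pair_type == WOBBLE_GU for lab in ("-2", "+3")
    )
    if not f["gu_ok"]:
        return Prediction(NOT_RECOGNIZED, SEVERE, extrapolated)
    if f["s3"] + f["s4"] == 0 and (f["s6"] == 0 or f["e"] <= 1):
        return Prediction(NOT_RECOGNIZED, SEVERE, extrapolated)
    independent = (
        f["s5"] == 1
        and f["e"] >= 1
        and (
            f["s3"] + f["s4"] == 2
            or f["s3"] == 1
            or (f["s4"] == 1 and f["e"] == 2)
        )
    )
    if independent:
        eff = REDUCED if (f["s3"] + f["s4"] == 1 or f["e"] == 1) else NORMAL
        return Prediction(INDEPENDENT, eff, extrapolated)
    return Prediction(DEPENDENT, NORMAL, extrapolated)


def classify_intron(
    u1: PairingRegister, u2: PairingRegister | None
) -> Prediction:
    """Combined dependency class from the U1 and U2 registers.

    Branch-sequence rules layered over the 5'SS class (a 5'SS that is not
    recognized always dominates):

    - bs position 2 not U (the invariant uridine): not recognized.
    - bs position 4 not A (branch point destroyed): not recognized on a
      weak 5'SS; barely spliced (DEPENDENT, SEVERE) on a strong one.
    - bs position 3 not stabilized by the U2 pseudouridine (not A/G):
      DEPENDENT; SEVERE when the 5'SS was already weak.
    - bs position 1 or 5 unpaired: tolerated on a strong 5'SS with a mild
      cost (INDEPENDENT, REDUCED); SEVERE on a weak one.
    """
    ss = classify_5ss(u1)
    if u2 is None or ss.dependency_class == NOT_RECOGNIZED:
        return ss
    pos2, pos3, pos4 = u2["2"], u2["3"], u2["4"]
    pos2_is_u = pos2.pre_base == "U" or (
        pos2.pre_base == "N" and pos2.pair_type == WC
    )
    if not pos2_is_u:
        return Prediction(NOT_RECOGNIZED, SEVERE, ss.extrapolated)
    pos4_is_a = pos4.pre_base == "A"
    if pos4.pre_base == "N":
        raise RegisterError("branch position 4 identity is required")
    if not pos4_is_a:
        if ss.dependency_class == DEPENDENT:
            return Prediction(NOT_RECOGNIZED, SEVERE, ss.extrapolated)
        return Prediction(DEPENDENT, SEVERE, ss.extrapolated)
    if pos3.pair_type != PSI_STABLE:
        eff = SEVERE if ss.dependency_class == DEPENDENT else NORMAL
        return Prediction(DEPENDENT, eff, ss.extrapolated)
    flank_unpaired = any(
        u2[lab].pair_type == NONE_PAIR for lab in ("1", "5")
    )
    if flank_unpaired:
        if ss.dependency_class == INDEPENDENT:
            return Prediction(INDEPENDENT, REDUCED, ss.extrapolated)
        return Prediction(DEPENDENT, SEVERE, ss.extrapolated)
    return ss


def predict_from_sequences(
    exon1: str,
    ss5: str,
    bs: str | None = None,
    u1_overrides: Mapping[str, str] | None = None,
    u2_overrides: Mapping[str, str] | None = None,
) -> tuple[Prediction, PairingRegister, PairingRegister | None]:
    """Convenience wrapper: build registers and classify in one call."""
    u1 = build_u1_register(exon1, ss5, u1_overrides)
    u2 = build_u2_register(bs, u2_overrides) if bs else None
    return classify_intron(u1, u2), u1, u2


# ---------------------------------------------------------------------------
# Curated allele panel


@dataclass(frozen=True)
class AlleleFixture:
    """One curated mutant reporter allele with its observed phenotype.

    Bases printed only as pair states in the source figures are encoded as
    ``N`` with an explicit override; ``bs`` is empty when the allele's
    branch sequence is unknown (prediction then uses the U1 register only).
    """

    name: str
    exon1: str
    ss5: str
    bs: str | None
    u1_overrides: Mapping[str, str] = field(default_factory=dict)
    u2_overrides: Mapping[str, str] = field(default_factory=dict)
    observed_class: str = DEPENDENT
    observed_efficiency: str = NORMAL
    source: str = ""


def load_allele_panel(path: str | Path | None = None) -> list[AlleleFixture]:
    """Load the packaged mutant-allele panel (or a user TSV of same shape)."""
    if path is None:
        ref = resources.files("prp4splice").joinpath("data/allele_panel.tsv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t", dtype=str, keep_default_na=False)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    fixtures = []
    for row in df.itertuples(index=False):
        u1_ov = _parse_overrides(row.u1_overrides)
        u2_ov = _parse_overrides(row.u2_overrides)
        exon1, ss5, bs = row.exon1, row.ss5, row.bs or None
        if ("N" in exon1 + ss5 and not u1_ov) or (bs and "N" in bs and not u2_ov):
            raise FixtureError(
                f"fixture {row.name!r} has unknown bases but no overrides"
            )
        fixtures.append(
            AlleleFixture(
                name=row.name,
                exon1=exon1,
                ss5=ss5,
                bs=bs,
                u1_overrides=u1_ov,
                u2_overrides=u2_ov,
                observed_class=row.observed_class,
                observed_efficiency=row.efficiency,
                source=row.source,
            )
        )
    return fixtures


def evaluate_panel(
    panel: Sequence[AlleleFixture] | None = None,
) -> tuple[pd.DataFrame, float]:
    """Predicted vs observed class for every allele, plus concordance.

    Returns ``(table, concordance)`` where concordance is the fraction of
    alleles whose predicted dependency class matches the observed one
    (NaN for an empty panel).  Efficiency agreement is reported in the
    table but not folded into the concordance.
    """
    if panel is None:
        panel = load_allele_panel()
    rows = []
    for fx in panel:
        pred, u1, u2 = predict_from_sequences(
            fx.exon1, fx.ss5, fx.bs, fx.u1_overrides, fx.u2_overrides
        )
        rows.append(
            {
                "allele": fx.name,
                "predicted": pred.dependency_class,
                "observed": fx.observed_class,
                "match": pred.dependency_class == fx.observed_class,
                "predicted_efficiency": pred.efficiency,
                "observed_efficiency": fx.observed_efficiency,
                "hbonds_u1": u1.hbonds,
                "extrapolated": pred.extrapolated,
                "source": fx.source,
            }
        )
    table = pd.DataFrame(rows)
    concordance = float(table["match"].mean()) if len(table) else math.nan
    return table, concordance
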