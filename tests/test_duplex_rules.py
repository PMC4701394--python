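"""U1/U2 pairing registers, hydrogen-bond scores and the dependency rules."""

from __future__ import annotations

import itertools
import math

import pytest

from prp4splice import duplex_rules as dr


def u1(exon1, ss5, overrides=None):
    return dr.build_u1_register(exon1, ss5, overrides)


class TestU1Register:
    def test_consensus_fully_paired(self):
        reg = u1("CAG", "GUAAGU")
        types = {p.label: p.pair_type for p in reg.positions}
        assert types["+4"] == dr.PSI_STABLE  # psi-A at the U1 pseudouridine
        assert all(
            t == dr.WC for lab, t in types.items() if lab != "+4"
        )

    def test_weak_exon_with_wobble(self):
        # UAA against U1 ...UG: WC at -2, G.U wobble at -3, psi-U at +4 unpaired
        reg = u1("UAA", "GUAUGU")
        assert reg["-2"].pair_type == dr.WC
        assert reg["-3"].pair_type == dr.WOBBLE_GU
        assert reg["-1"].pair_type == dr.NONE_PAIR
        assert reg["+4"].pair_type == dr.NONE_PAIR

    def test_weak_5ss_core(self):
        reg = u1("AAG", "GUUUGU")
        assert reg["+3"].pair_type == dr.NONE_PAIR
        assert reg["+4"].pair_type == dr.NONE_PAIR
        assert reg["-1"].pair_type == dr.WC
        assert reg["-2"].pair_type == dr.WC

    def test_register_order_and_length(self):
        reg = u1("CAG", "GUAAGU")
        assert [p.label for p in reg.positions] == list(dr.U1_POSITION_LABELS)

    @pytest.mark.parametrize("exon1,ss5", [("CA", "GUAAGU"), ("CAG", "GUAAG")])
    def test_wrong_length_raises(self, exon1, ss5):
        with pytest.raises(dr.RegisterError):
            u1(exon1, ss5)

    def test_unknown_base_needs_override(self):
        with pytest.raises(dr.RegisterError, match="-3"):
            u1("NAG", "GUAAGU")
        reg = u1("NAG", "GUAAGU", {"-3": dr.WC})
        assert reg["-3"].pair_type == dr.WC


class TestHbondScore:
    @pytest.mark.parametrize(
        "exon1,ss5,score",
        [("CAG", "GUAAGU", 22), ("AAG", "GUUUGU", 15), ("AAG", "GUAAGU", 19)],
    )
    def test_worked_examples(self, exon1, ss5, score):
        assert dr.hbond_score(u1(exon1, ss5)) == score

    def test_minimum_gain_of_strengthened_alleles_is_four(self):
        """The weakest of the two strengthened reporter alleles gains 4 bonds."""
        panel = {fx.name: fx for fx in dr.load_allele_panel()}
        wt = dr.hbond_score(u1(panel["res1'"].exon1, panel["res1'"].ss5))
        gains = []
        for name in ("res1'-1", "res1'-2"):
            fx = panel[name]
            gains.append(
                dr.hbond_score(u1(fx.exon1, fx.ss5, fx.u1_overrides)) - wt
            )
        assert min(gains) == 4
        assert all(g >= 4 for g in gains)

    def test_consensus_is_maximal_under_single_substitutions(self):
        best = dr.hbond_score(u1("CAG", "GUAAGU"))
        seq = "CAGGUAAGU"
        for i, alt in itertools.product(range(9), "ACGU"):
            if seq[i] == alt:
                continue
            mut = seq[:i] + alt + seq[i + 1 :]
            assert dr.hbond_score(u1(mut[:3], mut[3:])) <= best


class TestClassify5ss:
    @pytest.mark.parametrize(
        "exon1,ss5,expected",
        [
            ("AAG", "GUUUGU", dr.DEPENDENT),
            ("AAG", "GUAAGU", dr.INDEPENDENT),
            ("AAG", "GUAUGU", dr.INDEPENDENT),  # +3 contact alone suffices
            ("AAG", "GUUAGU", dr.INDEPENDENT),  # psi-A at +4 with strong exon
            ("AAG", "GUAAAU", dr.DEPENDENT),  # +5 broken
            ("AAG", "CUUUGU", dr.NOT_RECOGNIZED),  # +1 not G
            ("AAG", "GAUUGU", dr.NOT_RECOGNIZED),  # +2 not U
            ("CCA", "GUAAGU", dr.DEPENDENT),  # exon WC only at -3
            ("UAA", "GUAUGU", dr.INDEPENDENT),  # WC at -2, wobble at -3
        ],
    )
    def test_text_described_alleles(self, exon1, ss5, expected):
        assert dr.classify_5ss(u1(exon1, ss5)).dependency_class == expected

    def test_three_intermittent_pairs_not_recognized(self):
        # no contacts at +3/+4/+6 on a strong exon
        reg = u1("AAG", "GUUUGN", {"+6": dr.NONE_PAIR})
        assert dr.classify_5ss(reg).dependency_class == dr.NOT_RECOGNIZED
        # same 5'SS core with a single exon pair is also not recognized
        reg2 = u1("NNG", "GUUUGU", {"-3": dr.NONE_PAIR, "-2": dr.NONE_PAIR})
        assert dr.classify_5ss(reg2).dependency_class == dr.NOT_RECOGNIZED

    def test_reduced_efficiency_on_single_anchors(self):
        single_exon = u1("NNG", "GUAAGU",
                         {"-3": dr.NONE_PAIR, "-2": dr.NONE_PAIR})
        pred = dr.classify_5ss(single_exon)
        assert pred.dependency_class == dr.INDEPENDENT
        assert pred.efficiency == dr.REDUCED

    def test_wobble_at_unprobed_positions_flagged_extrapolated(self):
        # G.U wobble opposite the U1 U at +3: never probed by the panel
        reg = u1("AAG", "GUGAGU")
        assert reg["+3"].pair_type == dr.WOBBLE_GU
        assert dr.classify_5ss(reg).extrapolated
        # exon -2 wobble (G against U1 U) likewise
        reg2 = u1("AGG", "GUAAGU")
        assert reg2["-2"].pair_type == dr.WOBBLE_GU
        assert dr.classify_5ss(reg2).extrapolated
        # the -3 wobble is probed by the panel: not extrapolated
        reg3 = u1("UAA", "GUAUGU")
        assert not dr.classify_5ss(reg3).extrapolated

    def test_exhaustive_enumeration_consistency(self):
        """Every 9-mer maps to exactly one class, consistent with its features.

        Independently recomputes the pair-state features from sequence
        (complements of the fixed U1 9-mer) and checks the class against
        the rule definitions for all 4^9 sequences.
        """
        partner = {"-3": "G", "-2": "U", "-1": "C", "+1": "C", "+2": "A",
                   "+3": "U", "+4": None, "+5": "C", "+6": "A"}
        wc = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
        labels = list(dr.U1_POSITION_LABELS)
        classes = {dr.NOT_RECOGNIZED, dr.DEPENDENT, dr.INDEPENDENT}
        for seq in itertools.product("ACGU", repeat=9):
            exon1, ss5 = "".join(seq[:3]), "".join(seq[3:])
            pred = dr.classify_5ss(u1(exon1, ss5))
            assert pred.dependency_class in classes
            base = dict(zip(labels, seq))
            e = sum((base[l], partner[l]) in wc for l in ("-1", "-2"))
            s3 = (base["+3"], "U") in wc
            s4 = base["+4"] in "AG"
            s5 = (base["+5"], "C") in wc
            s6 = (base["+6"], "A") in wc
            gu = base["+1"] == "G" and base["+2"] == "U"
            if pred.dependency_class == dr.NOT_RECOGNIZED:
                assert (not gu) or (not s3 and not s4 and (not s6 or e <= 1))
            elif pred.dependency_class == dr.INDEPENDENT:
                assert gu and s5 and e >= 1 and (s3 or (s4 and e == 2))

    def test_adding_exon_pair_never_breaks_recognition(self):
        """Strengthening the exon duplex can only help a dependent intron."""
        for seq in itertools.product("ACGU", repeat=9):
            exon1, ss5 = "".join(seq[:3]), "".join(seq[3:])
            if not ss5.startswith("GU"):
                continue
            reg = u1(exon1, ss5)
            if dr.classify_5ss(reg).dependency_class != dr.DEPENDENT:
                continue
            for lab, strong in (("-1", "G"), ("-2", "A")):
                idx = {"-3": 0, "-2": 1, "-1": 2}[lab]
                mut = exon1[:idx] + strong + exon1[idx + 1 :]
                cls = dr.classify_5ss(u1(mut, ss5)).dependency_class
                assert cls in (dr.DEPENDENT, dr.INDEPENDENT)


class TestU2Register:
    def test_consensus_branch_sequence(self):
        reg = dr.build_u2_register("CUAAC")
        assert reg["1"].pair_type == dr.WC
        assert reg["2"].pair_type == dr.WC
        assert reg["3"].pair_type == dr.PSI_STABLE
        assert reg["4"].pair_type == dr.BULGED
        assert reg["5"].pair_type == dr.WC
        # the bulged branch adenosine never contributes hydrogen bonds
        assert reg["4"].hbonds == 0

    def test_psi_u_contact_is_unstable(self):
        assert dr.build_u2_register("CUUAC")["3"].pair_type == dr.NONE_PAIR

    def test_position2_mismatch(self):
        assert dr.build_u2_register("CGAAC")["2"].pair_type == dr.NONE_PAIR

    def test_wrong_length(self):
        with pytest.raises(dr.RegisterError):
            dr.build_u2_register("CUAA")


class TestClassifyIntron:
    def test_consensus_is_independent_normal(self):
        pred, *_ = dr.predict_from_sequences("CAG", "GUAAGU", "CUAAC")
        assert pred.dependency_class == dr.INDEPENDENT
        assert pred.efficiency == dr.NORMAL

    @pytest.mark.parametrize(
        "exon1,ss5,bs,expected_class,expected_eff",
        [
            # bs3 A->U converts the strong 5'SS to kinase dependence
            ("AAG", "GUAAGU", "CUUAC", dr.DEPENDENT, dr.NORMAL),
            # branch point destroyed on the weak 5'SS: never recognized
            ("AAG", "GUUUGU", "CUAUC", dr.NOT_RECOGNIZED, dr.SEVERE),
            # branch point destroyed on the strong 5'SS: barely spliced
            ("AAG", "GUAAGU", "CUAUC", dr.DEPENDENT, dr.SEVERE),
            # invariant bs2 broken: never recognized either way
            ("AAG", "GUAAGU", "CGAAC", dr.NOT_RECOGNIZED, dr.SEVERE),
            ("AAG", "GUUUGU", "CGAAC", dr.NOT_RECOGNIZED, dr.SEVERE),
            # bs flank mutations: mild on a strong 5'SS, severe on a weak one
            ("AAG", "GUAAGU", "GUAAC", dr.INDEPENDENT, dr.REDUCED),
            ("AAG", "GUUUGU", "GUAAC", dr.DEPENDENT, dr.SEVERE),
            ("AAG", "GUAAGU", "CUAAG", dr.INDEPENDENT, dr.REDUCED),
        ],
    )
    def test_branch_sequence_rules(self, exon1, ss5, bs, expected_class,
                                   expected_eff):
        pred, *_ = dr.predict_from_sequences(exon1, ss5, bs)
        assert pred.dependency_class == expected_class
        assert pred.efficiency == expected_eff

    def test_unrecognized_5ss_dominates_branch_sequence(self):
        pred, *_ = dr.predict_from_sequences("AAG", "CUUUGU", "CUAAC")
        assert pred.dependency_class == dr.NOT_RECOGNIZED

    def test_without_branch_sequence_falls_back_to_u1(self):
        pred, _, u2reg = dr.predict_from_sequences("AAG", "GUAAGU", None)
        assert u2reg is None and pred.dependency_class == dr.INDEPENDENT


class TestAllelePanel:
    def test_panel_loads_with_expected_size(self):
        panel = dr.load_allele_panel()
        assert len(panel) == 41
        names = {fx.name for fx in panel}
        assert {"res1'", "res1'-2", "ppk8'", "mrp17-I", "mrp17-II"} <= names

    def test_full_panel_concordance(self):
        table, concordance = dr.evaluate_panel()
        assert concordance == 1.0
        assert table["match"].all()

    def test_not_recognized_subset(self):
        panel = [
            fx for fx in dr.load_allele_panel()
            if fx.observed_class == dr.NOT_RECOGNIZED
        ]
        assert len(panel) >= 6
        table, concordance = dr.evaluate_panel(panel)
        assert (table["predicted"] == dr.NOT_RECOGNIZED).all()
        assert concordance == 1.0

    def test_empty_panel_concordance_undefined(self):
        table, concordance = dr.evaluate_panel([])
        assert table.empty and math.isnan(concordance)

    def test_fixture_without_overrides_rejected(self, tmp_path):
        bad = tmp_path / "bad.tsv"
        bad.write_text(
            "name\texon1\tss5\tbs\tu1_overrides\tu2_overrides\t"
            "observed_class\tefficiency\tsource\n"
            "broken\tNNN\tGUAAGU\t\t\t\tDEPENDENT\tNORMAL\tnone\n"
        )
        with pytest.raises(dr.FixtureError, match="broken"):
            dr.load_allele_panel(bad)
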