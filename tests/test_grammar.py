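from itertools import permutations

import pytest

from msseqsim.grammar import (
    LINE_LABELS,
    GrammarError,
    GrammarRules,
    SequenceSpec,
    enumerate_sequences,
    is_valid_switch,
    parse_sequence_label,
    sequences_to_frame,
    validate_sequence,
)
from msseqsim.parameters import DMTDefinition, EfficacyEstimate, Measure


def _dmt(name, moa, lines):
    eff = EfficacyEstimate.certain(0.5, Measure.IRR_ARR)
    cdp = EfficacyEstimate.certain(0.6, Measure.RR_CDP)
    return DMTDefinition(
        name=name,
        moa_class=moa,
        eligible_lines=frozenset(lines),
        efficacy_arr=eff,
        efficacy_cdp=cdp,
        annual_cost_first_year=1000,
        annual_cost_subsequent=1000,
    )


def brute_force_sequences(anchor, anchor_line, dmts, rules):
    """Independent oracle: filter all orderings through is_valid_switch."""
    by_name = {d.name: d for d in dmts}
    out = set()
    for r in range(1, min(len(dmts), 5) + 1):
        for perm in permutations(dmts, r):
            opener = perm[0]
            if "1a" not in opener.eligible_lines:
                continue
            with_1b = (
                rules.line1b_enabled
                and opener.name in rules.first_line_escalation_set
            )
            slots = (
                rules.line_labels
                if with_1b
                else ("1a",) + tuple(l for l in rules.line_labels if l not in ("1a", "1b"))
            )
            if r > len(slots) or r < 2:
                continue
            labels = slots[:r]
            if anchor_line not in labels:
                continue
            ok = True
            for i in range(1, r):
                prevs = [perm[i - 1]]
                if with_1b and labels[i] == "2":
                    prevs = [perm[0], perm[1]]
                if not all(is_valid_switch(p, perm[i], rules, labels[i]) for p in prevs):
                    ok = False
                    break
            if not ok:
                continue
            if not any(d.name == anchor and labels[i] == anchor_line for i, d in enumerate(perm)):
                continue
            if any(d.name == anchor and labels[i] != anchor_line for i, d in enumerate(perm)):
                continue
            # maximality: no unused drug may validly extend the sequence
            if r < len(slots):
                nxt = slots[r]
                used = {d.name for d in perm}
                prevs = [perm[-1]]
                if with_1b and nxt == "2":
                    prevs = [perm[0], perm[1]]
                extendable = any(
                    d.name not in used
                    and d.name != anchor
                    and all(is_valid_switch(p, d, rules, nxt) for p in prevs)
                    for d in dmts
                )
                if extendable:
                    continue
            out.add(tuple(d.name for d in perm))
    return out


@pytest.fixture()
def cd20_first_line_universe():
    """An anti-CD20 opener with only high-efficacy follow-ons, last-resort
    anti-CD52 drug restricted to the final line."""
    dmts = [
        _dmt("OCR", "anti-CD20", {"1a", "2"}),
        _dmt("OFA", "anti-CD20", {"1a", "2"}),
        _dmt("CLA", "purine-analogue", {"2", "3", "4"}),
        _dmt("NAT", "integrin-antagonist", {"2", "3", "4"}),
        _dmt("ALE", "anti-CD52", {"4"}),
    ]
    rules = GrammarRules(
        first_line_highefficacy_set=frozenset({"OCR", "OFA"}),
        last_resort_only=frozenset({"ALE"}),
    )
    return dmts, rules


class TestIsValidSwitch:
    def test_same_moa_forbidden(self, cd20_first_line_universe):
        dmts, rules = cd20_first_line_universe
        by = {d.name: d for d in dmts}
        assert not is_valid_switch(by["OCR"], by["OFA"], rules, "2")

    def test_plausible_escalation_allowed(self, cd20_first_line_universe):
        dmts, rules = cd20_first_line_universe
        by = {d.name: d for d in dmts}
        assert is_valid_switch(by["OCR"], by["CLA"], rules, "2")

    def test_last_resort_only_final_line(self, cd20_first_line_universe):
        dmts, rules = cd20_first_line_universe
        by = {d.name: d for d in dmts}
        assert not is_valid_switch(by["CLA"], by["ALE"], rules, "3")
        assert is_valid_switch(by["CLA"], by["ALE"], rules, "4")

    def test_eligibility_respected(self, cd20_first_line_universe):
        dmts, rules = cd20_first_line_universe
        by = {d.name: d for d in dmts}
        # anti-CD20s are first/second-line drugs here, never third-line
        assert not is_valid_switch(by["CLA"], by["OCR"], rules, "3")


class TestEnumeration:
    def test_two_orderings_per_high_efficacy_opener(self, cd20_first_line_universe):
        """A high-efficacy opener followed by {CLA, NAT} with a last-resort
        closer admits exactly the two printed orderings."""
        dmts, rules = cd20_first_line_universe
        for anchor in ("OCR", "OFA"):
            seqs = enumerate_sequences(anchor, "1a", dmts, rules)
            assert [s.lines for s in seqs] == [
                (anchor, "CLA", "NAT", "ALE"),
                (anchor, "NAT", "CLA", "ALE"),
            ]
            assert all(not s.has_line1b for s in seqs)

    def test_two_drug_universe_single_sequence(self):
        dmts = [_dmt("A", "x", {"1a"}), _dmt("B", "y", {"2"})]
        seqs = enumerate_sequences("A", "1a", dmts, GrammarRules())
        assert [s.lines for s in seqs] == [("A", "B")]

    def test_matches_brute_force_with_same_class_pair(self):
        dmts = [
            _dmt("A", "x", {"1a", "2"}),
            _dmt("B", "x", {"1a", "2", "3"}),
            _dmt("C", "y", {"2", "3", "4"}),
            _dmt("D", "z", {"3", "4"}),
        ]
        rules = GrammarRules()
        for anchor, line in [("A", "1a"), ("C", "2"), ("D", "3")]:
            got = {s.lines for s in enumerate_sequences(anchor, line, dmts, rules)}
            assert got == brute_force_sequences(anchor, line, dmts, rules)

    def test_matches_brute_force_with_line1b(self):
        dmts = [
            _dmt("E1", "p", {"1a", "1b"}),
            _dmt("E2", "q", {"1a", "1b"}),
            _dmt("E3", "p", {"1a", "1b"}),
            _dmt("H1", "r", {"2", "3"}),
            _dmt("H2", "s", {"2", "3"}),
            _dmt("L", "t", {"4"}),
        ]
        rules = GrammarRules(
            first_line_escalation_set=frozenset({"E1", "E2", "E3"}),
            last_resort_only=frozenset({"L"}),
        )
        for anchor, line in [("H1", "2"), ("E1", "1a")]:
            got = {s.lines for s in enumerate_sequences(anchor, line, dmts, rules)}
            assert got == brute_force_sequences(anchor, line, dmts, rules)
            assert got  # non-degenerate check

    def test_every_emitted_sequence_is_self_consistent(self, default_params):
        seqs = enumerate_sequences("OFA", "2", default_params.dmts, default_params.grammar)
        assert seqs
        for s in seqs:
            validate_sequence(s, default_params.dmts, default_params.grammar)

    def test_default_ruleset_second_line_count(self, default_params):
        """The shipped rule set is a reconstruction: 7 escalation openers in
        1a/1b (one multi-drug class) x 4 high-efficacy closures = 144
        second-line sequences per anti-CD20 drug."""
        seqs = enumerate_sequences("OCR", "2", default_params.dmts, default_params.grammar)
        assert len(seqs) == 144
        assert all(s.has_line1b for s in seqs)

    def test_ineligible_anchor_raises(self, cd20_first_line_universe):
        dmts, rules = cd20_first_line_universe
        with pytest.raises(GrammarError, match="not eligible"):
            enumerate_sequences("ALE", "1a", dmts, rules)


class TestSequenceSpec:
    def test_labels_with_and_without_1b(self):
        s = SequenceSpec(lines=("A", "B", "C"), has_line1b=True)
        assert s.line_labels() == ("1a", "1b", "2")
        s2 = SequenceSpec(lines=("A", "B", "C"))
        assert s2.line_labels() == ("1a", "2", "3")

    def test_parse_label_infers_1b_from_opener(self, default_params):
        s = parse_sequence_label("INFB-GLA-OCR-CLA-ALE", default_params)
        assert s.has_line1b and s.line_labels() == LINE_LABELS
        s2 = parse_sequence_label("OCR-CLA-NAT-ALE", default_params)
        assert not s2.has_line1b

    def test_parse_label_unknown_drug(self, default_params):
        with pytest.raises(GrammarError, match="XYZ"):
            parse_sequence_label("OCR-XYZ", default_params)

    def test_export_frame_columns(self, cd20_first_line_universe):
        dmts, rules = cd20_first_line_universe
        seqs = enumerate_sequences("OCR", "1a", dmts, rules)
        frame = sequences_to_frame(seqs)
        assert list(frame.columns) == ["label", "line1a", "line1b", "line2", "line3", "line4"]
        assert frame.loc[0, "line1a"] == "OCR"
        assert (frame["line1b"] == "").all()
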