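"""Enumeration and validation of clinically plausible DMT sequences.

Sequences occupy labelled treatment lines.  In an escalation setting the
first line splits into line 1a and line 1b: line 1b is the alternative
first-line slot entered only when the patient leaves line 1a because of
adverse events, so a sequence with a 1b entry is a depth-1 tree, not a
longer chain.  When a high-efficacy drug opens the sequence the 1b branch
is dropped.  Escalated lines are labelled 2, 3 and 4.

Constraints: every drug must be eligible for the line it occupies,
consecutive drugs must differ in mode of action (so e.g. one anti-CD20 mAb
never follows another), and last-resort drugs (alemtuzumab) may only occupy
the final line label.  Enumeration emits maximal sequences only — a
sequence that could still be validly extended is not a terminal treatment
plan.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Sequence

if TYPE_CHECKING:  # pragma: no cover
    from .parameters import DMTDefinition, ModelParameters

__all__ = [
    "GrammarRules",
    "SequenceSpec",
    "GrammarError",
    "LINE_LABELS",
    "is_valid_switch",
    "enumerate_sequences",
    "validate_sequence",
    "parse_sequence_label",
    "sequences_to_frame",
]

LINE_LABELS = ("1a", "1b", "2", "3", "4")


class GrammarError(ValueError):
    """A sequence or enumeration request violates the grammar rules."""


@dataclass(frozen=True)
class GrammarRules:
    first_line_escalation_set: frozenset = frozenset()
    first_line_highefficacy_set: frozenset = frozenset()
    forbid_same_moa_consecutive: bool = True
    last_resort_only: frozenset = frozenset()
    max_lines: int = 5
    line1b_enabled: bool = True

    @property
    def line_labels(self) -> tuple:
        return LINE_LABELS[: self.max_lines]

    @property
    def final_line(self) -> str:
        return self.line_labels[-1]


@dataclass(frozen=True)
class SequenceSpec:
    """An ordered treatment sequence; ``lines[1]`` is the 1b branch when
    ``has_line1b`` is set."""

    lines: tuple
    has_line1b: bool = False
    label: str = ""

    def __post_init__(self) -> None:
        if not self.label:
            object.__setattr__(self, "label", "-".join(self.lines))

    def line_labels(self) -> tuple:
        labels = LINE_LABELS if self.has_line1b else ("1a",) + LINE_LABELS[2:]
        return labels[: len(self.lines)]

    def line_label(self, index: int) -> str:
        return self.line_labels()[index]

    def __len__(self) -> int:
        return len(self.lines)


def _lookup(dmts, name: str):
    for d in dmts:
        if d.name == name:
            return d
    raise KeyError(f"unknown DMT {name!r}")


def is_valid_switch(from_dmt, to_dmt, rules: GrammarRules, position: str) -> bool:
    """May ``to_dmt`` follow ``from_dmt`` at line label ``position``?

    False when the modes of action coincide (if forbidden), when the target
    drug is not eligible at that line, or when a last-resort drug would be
    placed before the final line.
    """
    if position not in LINE_LABELS:
        raise GrammarError(f"unknown line label {position!r}")
    if rules.forbid_same_moa_consecutive and from_dmt.moa_class == to_dmt.moa_class:
        return False
    if position not in to_dmt.eligible_lines:
        return False
    if to_dmt.name in rules.last_resort_only and position != rules.final_line:
        return False
    return True


def _opener_slots(opener, rules: GrammarRules) -> tuple:
    """The line labels a sequence opened by ``opener`` walks through."""
    if rules.line1b_enabled and opener.name in rules.first_line_escalation_set:
        return rules.line_labels  # includes 1b
    labels = ("1a",) + tuple(l for l in rules.line_labels if l in ("2", "3", "4"))
    return labels


def _candidates_at(slot_idx: int, slots, chosen, dmts, rules: GrammarRules):
    """Valid drugs for the next slot, given drugs chosen so far.

    A patient reaches line 2 from either 1a or 1b, so a candidate at slot
    '2' in a 1b-carrying sequence must be a valid switch from both.
    """
    slot = slots[slot_idx]
    used = {d.name for d in chosen}
    prev = [chosen[-1]]
    if slot == "2" and len(chosen) >= 2 and slots[1] == "1b":
        prev = [chosen[0], chosen[1]]
    out = []
    for d in dmts:
        if d.name in used:
            continue
        if all(is_valid_switch(p, d, rules, slot) for p in prev):
            out.append(d)
    return sorted(out, key=lambda d: d.name)


def enumerate_sequences(
    anchor_dmt: str,
    anchor_line: str,
    dmts: Sequence,
    rules: GrammarRules,
) -> list:
    """All maximal valid sequences holding ``anchor_dmt`` at ``anchor_line``.

    Deterministic lexicographic order (by drug name slot by slot).  Raises
    :class:`GrammarError` when the anchor drug is not eligible at the anchor
    line.
    """
    anchor = _lookup(dmts, anchor_dmt)
    if anchor_line not in anchor.eligible_lines:
        raise GrammarError(
            f"{anchor_dmt} is not eligible at line {anchor_line!r} "
            f"(eligible: {sorted(anchor.eligible_lines)})"
        )

    results = []

    def extend(chosen, slots):
        idx = len(chosen)
        if idx >= len(slots):
            results.append((chosen, slots))
            return
        slot = slots[idx]
        cands = _candidates_at(idx, slots, chosen, dmts, rules)
        if slot == anchor_line:
            cands = [d for d in cands if d.name == anchor_dmt]
        else:
            cands = [d for d in cands if d.name != anchor_dmt]
        if not cands:
            # maximal: no valid continuation
            if any(d.name == anchor_dmt for d in chosen) and len(chosen) >= 2:
                results.append((chosen, slots))
            return
        # anchor not yet placed and its slot would be skipped -> dead branch
        for d in cands:
            extend(chosen + [d], slots)

    openers = sorted(
        (d for d in dmts if "1a" in d.eligible_lines), key=lambda d: d.name
    )
    if anchor_line == "1a":
        openers = [d for d in openers if d.name == anchor_dmt]
    else:
        openers = [d for d in openers if d.name != anchor_dmt]
    for opener in openers:
        slots = _opener_slots(opener, rules)
        if anchor_line not in slots:
            continue
        extend([opener], slots)

    out = []
    seen = set()
    for chosen, slots in results:
        names = tuple(d.name for d in chosen)
        if names in seen:
            continue
        seen.add(names)
        out.append(SequenceSpec(lines=names, has_line1b=(len(slots) == 5 and slots[1] == "1b")))
    out.sort(key=lambda s: s.lines)
    return out


def validate_sequence(seq: SequenceSpec, dmts: Sequence, rules: GrammarRules) -> None:
    """Raise :class:`GrammarError` unless every junction of ``seq`` is valid."""
    if not (2 <= len(seq.lines) <= 5):
        raise GrammarError(f"sequence {seq.label}: length must be 2..5")
    drugs = [_lookup(dmts, n) for n in seq.lines]
    labels = seq.line_labels()
    if labels[0] not in drugs[0].eligible_lines:
        raise GrammarError(f"{drugs[0].name} not eligible at line {labels[0]}")
    for i in range(1, len(drugs)):
        prevs = [drugs[i - 1]]
        if seq.has_line1b and labels[i] == "2":
            prevs = [drugs[0], drugs[1]]
        for p in prevs:
            if not is_valid_switch(p, drugs[i], rules, labels[i]):
                raise GrammarError(
                    f"sequence {seq.label}: invalid switch {p.name} -> "
                    f"{drugs[i].name} at line {labels[i]}"
                )


def parse_sequence_label(label: str, params: "ModelParameters") -> SequenceSpec:
    """Turn a label like ``OCR-CLA-NAT-ALE`` into a :class:`SequenceSpec`.

    Whether the second entry is a 1b branch follows from the opener: an
    escalation opener (with 1b enabled) carries a 1b slot.
    """
    names = tuple(label.split("-"))
    known = set(params.dmt_names())
    unknown = [n for n in names if n not in known]
    if unknown:
        raise GrammarError(f"unknown DMT name(s) {unknown}; known: {sorted(known)}")
    rules = params.grammar
    has_1b = (
        rules.line1b_enabled
        and names[0] in rules.first_line_escalation_set
        and len(names) >= 2
    )
    return SequenceSpec(lines=names, has_line1b=has_1b)


def sequences_to_frame(seqs: Iterable[SequenceSpec]):
    """Delimited-table view (label, line1a, line1b, line2, line3, line4)."""
    import pandas as pd

    rows = []
    for s in seqs:
        cells = dict.fromkeys(("line1a", "line1b", "line2", "line3", "line4"), "")
        for name, lab in zip(s.lines, s.line_labels()):
            cells[f"line{lab}"] = name
        rows.append({"label": s.label, **cells})
    return pd.DataFrame(rows)
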