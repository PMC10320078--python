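"""Nomenclature normalisation of alignment-derived variant calls.

Sequence aligners left-align insertions and deletions, but mitochondrial
phylogenetic trees name indels at their rightmost equivalent position
(e.g. the C insertion in the 303-315 homopolymer stretch is written
315.1C, never 303.1C).  Two passes run before classification:

1. :func:`right_align_indels` -- generic shift of every indel to the
   rightmost position at which the edited sequence is unchanged;
2. :func:`apply_rules` -- a tree-package-specific table of rewrite rules
   covering residual special cases the generic shift cannot express.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional

from .variants import (
    DELETION,
    SUBSTITUTION,
    Variant,
    VariantError,
    parse_tokens,
)


@dataclass(frozen=True)
class NomenclatureRule:
    """Rewrite rule: when ALL source variants are present in a profile,
    remove them and add the target variants."""

    source: tuple[Variant, ...]
    target: tuple[Variant, ...]
    id: str

    def __post_init__(self) -> None:
        if not self.source:
            raise VariantError(f"rule {self.id}: empty source")


class RuleParseError(ValueError):
    """Malformed rule file line."""


def parse_rules(text: str) -> list[NomenclatureRule]:
    """Parse a rule table: ``source-variants<TAB>target-variants`` per
    line, variants space-separated, ``#`` starts a comment."""
    rules: list[NomenclatureRule] = []
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].rstrip()
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) > 2:
            raise RuleParseError(f"line {lineno}: expected source<TAB>target")
        try:
            source = tuple(parse_tokens(parts[0].split()))
            target = tuple(
                parse_tokens(parts[1].split()) if len(parts) == 2 else ()
            )
        except VariantError as exc:
            raise RuleParseError(f"line {lineno}: {exc}") from exc
        if not source:
            raise RuleParseError(f"line {lineno}: empty source")
        rules.append(
            NomenclatureRule(source=source, target=target, id=f"rule-{lineno}")
        )
    return rules


def apply_rules(
    variants: Iterable[Variant],
    rules: Iterable[NomenclatureRule],
    log: Optional[list[str]] = None,
) -> frozenset[Variant]:
    """Apply rules in order; each fires at most once, only when every
    source variant is present.  Fired rule ids are appended to ``log``."""
    current = set(variants)
    for rule in rules:
        if all(v in current for v in rule.source):
            current.difference_update(rule.source)
            current.update(rule.target)
            if log is not None:
                log.append(rule.id)
    return frozenset(current)


def right_align_indels(
    variants: Iterable[Variant], reference: str
) -> frozenset[Variant]:
    """Shift every insertion/deletion to its rightmost equivalent
    position; the implied sample sequence is unchanged.  Substitutions
    pass through untouched.

    A single-base deletion slides right through a homopolymer run; an
    insertion slides right while its first base matches the next
    reference base, rotating the inserted string as it goes (which also
    normalises insertions inside dinucleotide repeats).
    """
    length = len(reference)
    out: list[Variant] = []
    shifted_insertions: list[tuple[tuple[int, int], Variant]] = []
    for v in variants:
        if v.kind == SUBSTITUTION:
            out.append(v)
            continue
        if v.position > length:
            raise VariantError(
                f"indel position {v.position} outside reference (L={length})"
            )
        if v.kind == DELETION:
            pos = v.position
            while pos < length and reference[pos - 1] == reference[pos]:
                pos += 1
            out.append(replace(v, position=pos))
        else:  # insertion: anchor a means "inserted after position a"
            anchor, alt = v.position, v.alt
            while anchor < length and reference[anchor] == alt[0]:
                alt = alt[1:] + alt[0]
                anchor += 1
            shifted_insertions.append(((v.position, v.insertion_index), replace(v, position=anchor, alt=alt)))

    # Insertions that converge on one anchor get consecutive indices in
    # their original left-to-right order.
    by_anchor: dict[int, list[tuple[tuple[int, int], Variant]]] = {}
    for orig_key, ins in shifted_insertions:
        by_anchor.setdefault(ins.position, []).append((orig_key, ins))
    for anchor, group in by_anchor.items():
        group.sort(key=lambda item: item[0])
        for idx, (_, ins) in enumerate(group, start=1):
            out.append(replace(ins, insertion_index=idx))
    return frozenset(out)


def apply_variants(reference: str, variants: Iterable[Variant]) -> str:
    """Build the sample sequence implied by a variant set.

    Used by the synthetic-data generator to emit FASTA and by tests to
    verify that indel right-alignment preserves the edited sequence.
    """
    length = len(reference)
    subs: dict[int, str] = {}
    dels: set[int] = set()
    ins: dict[int, list[Variant]] = {}
    for v in variants:
        if v.back_mutation:
            continue
        if v.position > length:
            raise VariantError(
                f"variant position {v.position} outside reference (L={length})"
            )
        if v.kind == SUBSTITUTION:
            subs[v.position] = v.alt
        elif v.kind == DELETION:
            dels.add(v.position)
        else:
            ins.setdefault(v.position, []).append(v)
    pieces: list[str] = []
    # anchor 0 would mean "before position 1"; not representable in the
    # nomenclature, so insertions start at anchor 1.
    for pos in range(1, length + 1):
        if pos not in dels:
            pieces.append(subs.get(pos, reference[pos - 1]))
        if pos in ins:
            for v in sorted(ins[pos], key=lambda x: x.insertion_index):
                pieces.append(v.alt)
    return "".join(pieces)
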