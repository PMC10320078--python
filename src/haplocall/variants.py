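"""Mitochondrial variant nomenclature and circular-genome ranges.

Variants follow the Phylotree naming convention relative to a linear
reference with 1-based coordinates:

* substitutions:  ``263G`` (position + alternate base), ``152C!`` for a
  back mutation (reversion of an ancestral variant);
* insertions:     ``309.1C`` -- one base inserted after position 309; the
  ``.1`` counts consecutive insertions at the same anchor;
* deletions:      ``249d`` -- the reference base at 249 is deleted; a span
  such as ``8281-8289d`` expands to nine single-position deletions.

Ranges are unions of inclusive 1-based intervals on the circular genome;
an interval whose start exceeds its end wraps the origin, which is how the
mtDNA control region (16024-576 on the rCRS) is written.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional

SUBSTITUTION = "substitution"
INSERTION = "insertion"
DELETION = "deletion"

_IUPAC = "ACGTUNRYSWKMBDHV"

_SUB_RE = re.compile(rf"^([{_IUPAC}])?(\d+)([{_IUPAC}]+)(!?)$", re.IGNORECASE)
_INS_RE = re.compile(rf"^(\d+)\.(\d+)([{_IUPAC}]+)(!?)$", re.IGNORECASE)
_DEL_RE = re.compile(r"^(\d+)(?:-(\d+))?(?:d|D|del)(!?)$")


class VariantError(ValueError):
    """Raised for malformed variant strings or invalid variant fields."""


@dataclass(frozen=True, order=True)
class Variant:
    """One mitochondrial polymorphism in Phylotree nomenclature.

    ``heteroplasmy_level`` (variant allele fraction in ``[0, 1]``) is
    carried as metadata and deliberately excluded from equality and
    hashing so that observed and haplogroup-defining variants compare by
    identity of the event, not by its cellular dosage.
    """

    position: int
    kind: str
    alt: str = ""
    insertion_index: int = 0
    back_mutation: bool = False
    heteroplasmy_level: Optional[float] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.position < 1:
            raise VariantError(f"position must be >= 1, got {self.position}")
        if self.kind not in (SUBSTITUTION, INSERTION, DELETION):
            raise VariantError(f"unknown variant kind {self.kind!r}")
        if (self.kind == INSERTION) != (self.insertion_index > 0):
            raise VariantError("insertion_index > 0 iff kind is insertion")
        if self.kind == DELETION and self.alt:
            raise VariantError("deletion must have empty alt")
        if self.kind != DELETION and not self.alt:
            raise VariantError(f"{self.kind} requires a non-empty alt")
        if self.heteroplasmy_level is not None and not (
            0.0 <= self.heteroplasmy_level <= 1.0
        ):
            raise VariantError("heteroplasmy_level must lie in [0, 1]")

    @property
    def key(self) -> tuple[int, str, int]:
        """Identity used for back-mutation matching: a ``!`` event cancels
        any variant at the same position/kind/index regardless of alt."""
        return (self.position, self.kind, self.insertion_index)

    def render(self) -> str:
        """Canonical string form; ``parse_variant`` round-trips it."""
        bang = "!" if self.back_mutation else ""
        if self.kind == INSERTION:
            return f"{self.position}.{self.insertion_index}{self.alt}{bang}"
        if self.kind == DELETION:
            return f"{self.position}d{bang}"
        return f"{self.position}{self.alt}{bang}"

    def canonical(self) -> str:
        """Rendering without the back-mutation flag; the lookup key used
        for weight and hotspot tables."""
        return replace(self, back_mutation=False).render()

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


def parse_variant(token: str) -> Variant:
    """Parse a single variant token; raises :class:`VariantError` on
    malformed input or on span deletions (use :func:`parse_tokens`)."""
    tok = token.strip()
    if not tok:
        raise VariantError("empty variant token")
    m = _INS_RE.match(tok)
    if m:
        return Variant(
            position=int(m.group(1)),
            kind=INSERTION,
            alt=m.group(3).upper(),
            insertion_index=int(m.group(2)),
            back_mutation=bool(m.group(4)),
        )
    m = _DEL_RE.match(tok)
    if m:
        if m.group(2) is not None:
            raise VariantError(
                f"span deletion {tok!r} expands to several variants; "
                "use parse_tokens"
            )
        return Variant(
            position=int(m.group(1)),
            kind=DELETION,
            back_mutation=bool(m.group(3)),
        )
    m = _SUB_RE.match(tok)
    if m:
        alt = m.group(3).upper()
        if len(alt) != 1:
            raise VariantError(f"substitution alt must be one base: {tok!r}")
        return Variant(
            position=int(m.group(2)),
            kind=SUBSTITUTION,
            alt=alt,
            back_mutation=bool(m.group(4)),
        )
    raise VariantError(f"unrecognised variant token {token!r}")


def parse_tokens(tokens: Iterable[str]) -> list[Variant]:
    """Parse tokens, expanding span deletions like ``8281-8289d``."""
    out: list[Variant] = []
    for tok in tokens:
        tok = tok.strip()
        if not tok:
            continue
        m = _DEL_RE.match(tok)
        if m and m.group(2) is not None:
            start, end = int(m.group(1)), int(m.group(2))
            if end < start:
                raise VariantError(f"inverted deletion span {tok!r}")
            bang = bool(m.group(3))
            out.extend(
                Variant(position=p, kind=DELETION, back_mutation=bang)
                for p in range(start, end + 1)
            )
        else:
            out.append(parse_variant(tok))
    return out


@dataclass(frozen=True)
class Range:
    """Union of inclusive 1-based intervals on the circular genome.

    An interval with ``start > end`` wraps the origin: ``(16024, 576)``
    covers 16024..L plus 1..576.
    """

    intervals: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.intervals:
            raise VariantError("range must contain at least one interval")
        for start, end in self.intervals:
            if start < 1 or end < 1:
                raise VariantError(f"interval bounds must be >= 1: {start}-{end}")

    @classmethod
    def full(cls, length: int) -> "Range":
        return cls(((1, length),))

    @classmethod
    def parse(cls, text: str) -> "Range":
        """Parse ``"16024-16569;1-576"`` / ``"16024-576"`` / ``"73"``."""
        intervals = []
        for part in re.split(r"[;,]", text.strip()):
            part = part.strip()
            if not part:
                continue
            if "-" in part:
                a, b = part.split("-", 1)
                intervals.append((int(a), int(b)))
            else:
                p = int(part)
                intervals.append((p, p))
        return cls(tuple(intervals))

    @classmethod
    def from_positions(cls, positions: Iterable[int]) -> "Range":
        """Minimal range covering exactly the given positions, adjacent
        positions merged into one interval."""
        pos = sorted(set(positions))
        if not pos:
            raise VariantError("cannot build a range from zero positions")
        intervals: list[tuple[int, int]] = []
        start = prev = pos[0]
        for p in pos[1:]:
            if p == prev + 1:
                prev = p
            else:
                intervals.append((start, prev))
                start = prev = p
        intervals.append((start, prev))
        return cls(tuple(intervals))

    def contains(self, position: int) -> bool:
        for start, end in self.intervals:
            if start <= end:
                if start <= position <= end:
                    return True
            elif position >= start or position <= end:
                return True
        return False

    def __contains__(self, position: int) -> bool:
        return self.contains(position)

    def positions(self, length: int) -> Iterator[int]:
        """All member positions in 1..length, ascending, deduplicated."""
        seen: set[int] = set()
        for start, end in self.intervals:
            if start <= end:
                seen.update(range(start, min(end, length) + 1))
            else:
                seen.update(range(start, length + 1))
                seen.update(range(1, end + 1))
        return iter(sorted(seen))

    def covers_full(self, length: int) -> bool:
        covered = set(self.positions(length))
        return len(covered) == length

    def render(self) -> str:
        return ";".join(
            f"{s}-{e}" if s != e else str(s) for s, e in self.intervals
        )

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


def restrict_to_range(variants: Iterable[Variant], rng: Range) -> frozenset[Variant]:
    """Subset of variants whose anchor position lies inside the range."""
    return frozenset(v for v in variants if rng.contains(v.position))
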