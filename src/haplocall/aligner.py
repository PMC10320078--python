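"""Pairwise alignment of sample sequences against the tree reference.

FASTA input is turned into a variant profile by aligning each record to
the reference and reading substitutions and indels off the alignment
path.  The aligner is pluggable: anything with an
``align(query, reference)`` method returning an :class:`Alignment` can be
substituted.  The built-in :class:`EdlibAligner` performs edit-distance
alignment in infix mode, so partial sequences (e.g. a control-region-only
record) align to their sub-span of the reference without end-gap
penalties.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Protocol

import edlib

from .rules import right_align_indels
from .variants import DELETION, INSERTION, SUBSTITUTION, Range, Variant

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass(frozen=True)
class Alignment:
    """Alignment of a query against the reference.

    ``start`` is the 0-based reference offset of the first aligned
    column; ``cigar`` is a list of (length, op) with ops ``=`` match,
    ``X`` mismatch, ``I`` insertion in the query, ``D`` deletion from the
    query; ``identity`` is matches over alignment columns.
    """

    start: int
    cigar: tuple[tuple[int, str], ...]
    identity: float


class Aligner(Protocol):  # pragma: no cover - structural type
    def align(self, query: str, reference: str) -> Alignment: ...


class EdlibAligner:
    """Edit-distance alignment with path reconstruction (infix mode)."""

    def align(self, query: str, reference: str) -> Alignment:
        res = edlib.align(query.upper(), reference.upper(), mode="HW", task="path")
        cigar = tuple(
            (int(n), op) for n, op in _CIGAR_RE.findall(res["cigar"] or "")
        )
        columns = sum(n for n, _ in cigar)
        matches = sum(n for n, op in cigar if op == "=")
        start = res["locations"][0][0]
        return Alignment(
            start=start,
            cigar=cigar,
            identity=matches / columns if columns else 0.0,
        )


def call_variants(
    query: str, reference: str, aligner: Aligner | None = None
) -> tuple[frozenset[Variant], Range, float]:
    """Align a sequence to the reference and emit its variant profile.

    Returns ``(variants, covered_range, identity)``.  Indels are
    right-aligned to match tree nomenclature.  Reference positions whose
    query base is N are dropped from the covered range and never called.
    """
    query = query.upper()
    aln = (aligner or EdlibAligner()).align(query, reference)
    ref_pos = aln.start  # 0-based, next reference base to consume
    q_pos = 0
    raw: list[Variant] = []
    excluded: set[int] = set()
    for length, op in aln.cigar:
        if op == "=":
            for i in range(length):
                if query[q_pos + i] == "N":
                    excluded.add(ref_pos + i + 1)
            ref_pos += length
            q_pos += length
        elif op in ("X", "M"):
            for i in range(length):
                qbase = query[q_pos + i]
                pos = ref_pos + i + 1
                if qbase == "N":
                    excluded.add(pos)
                elif qbase != reference[ref_pos + i]:
                    raw.append(Variant(position=pos, kind=SUBSTITUTION, alt=qbase))
            ref_pos += length
            q_pos += length
        elif op == "I":
            inserted = query[q_pos : q_pos + length]
            if ref_pos >= 1 and "N" not in inserted:
                raw.append(
                    Variant(
                        position=ref_pos,
                        kind=INSERTION,
                        alt=inserted,
                        insertion_index=1,
                    )
                )
            q_pos += length
        elif op == "D":
            raw.extend(
                Variant(position=ref_pos + i + 1, kind=DELETION)
                for i in range(length)
            )
            ref_pos += length
    covered = set(range(aln.start + 1, ref_pos + 1)) - excluded
    rng = Range.from_positions(covered) if covered else Range(((1, 1),))
    return right_align_indels(raw, reference), rng, aln.identity
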