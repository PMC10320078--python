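"""Variant-level annotation joins.

Tree packages may ship annotation tables (population frequencies,
pathogenicity predictions, ...) as TSV files keyed by position and
alternate allele.  Annotation is pure decoration: it attaches per-table
lookup results to a classification result and never alters qualities,
ordering or variant partitions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import pandas as pd

from .classify import ClassificationResult
from .variants import DELETION, Variant


class AnnotationError(ValueError):
    """Malformed annotation table."""


@dataclass
class AnnotationTable:
    """TSV-backed table indexed by (POS, ALT)."""

    name: str
    version: str
    frame: pd.DataFrame  # indexed by (POS, ALT)

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    def lookup(self, position: int, alt: str) -> dict:
        try:
            row = self.frame.loc[(position, alt)]
        except KeyError:
            return {}
        return row.to_dict()

    def lookup_variant(self, variant: Variant) -> dict:
        return self.lookup(variant.position, annotation_alt(variant))


def annotation_alt(variant: Variant) -> str:
    """ALT key used in annotation tables: the alternate allele string,
    ``-`` for deletions."""
    return "-" if variant.kind == DELETION else variant.alt


def load_annotation_table(
    path: str | Path, name: str | None = None, version: str = "0"
) -> AnnotationTable:
    """Load a TSV with POS and ALT key columns plus at least one data
    column; duplicate keys are an error naming the offending key."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype={"ALT": str})
    for col in ("POS", "ALT"):
        if col not in frame.columns:
            raise AnnotationError(f"{path}: missing required column {col!r}")
    if len(frame.columns) < 3:
        raise AnnotationError(f"{path}: no data columns beside POS/ALT")
    dup = frame.duplicated(subset=["POS", "ALT"], keep=False)
    if dup.any():
        first = frame.loc[dup, ["POS", "ALT"]].iloc[0]
        raise AnnotationError(
            f"{path}: duplicate key POS={int(first['POS'])} ALT={first['ALT']}"
        )
    indexed = frame.set_index(["POS", "ALT"]).sort_index()
    return AnnotationTable(
        name=name or path.stem, version=version, frame=indexed
    )


def annotate_result(
    result: ClassificationResult, tables: list[AnnotationTable]
) -> ClassificationResult:
    """Return a copy of the result whose ``annotations`` maps each
    variant of the hit partitions to per-table lookup rows."""
    if not tables:
        return result
    annotations: dict[str, dict[str, dict]] = {}
    seen: set[Variant] = set()
    for hit in result.hits:
        seen.update(hit.found, hit.expected_missing, hit.remaining)
    for variant in seen:
        annotations[variant.render()] = {
            table.name: table.lookup_variant(variant) for table in tables
        }
    return replace(result, annotations=annotations)
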