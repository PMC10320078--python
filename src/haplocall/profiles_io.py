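"""Readers and writers for sample data: hsd, VCF and FASTA in;
tab-delimited result and QC reports out.

The hsd format is the field's plain-text profile exchange format: one
tab-delimited line per sample holding the sample ID, the analysed range,
an (ignored) haplogroup column and then one variant token per column.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

from cyvcf2 import VCF
from Bio import SeqIO

from .aligner import Aligner, call_variants
from .rules import right_align_indels
from .variants import (
    DELETION,
    INSERTION,
    SUBSTITUTION,
    Range,
    Variant,
    VariantError,
    parse_tokens,
)

MIN_FASTA_IDENTITY = 0.70

HET_FIELDS = ("AF", "HF", "VAF")


class ProfileParseError(ValueError):
    """Fatal sample-input problem (duplicates, bad contig, no samples)."""


@dataclass
class SampleProfile:
    """One sample: its analysed range on the circular genome and its
    observed variant set."""

    id: str
    range: Range
    variants: frozenset[Variant]
    source: str = "hsd"
    warnings: list[str] = field(default_factory=list)
    flagged: bool = False


@dataclass(frozen=True)
class VcfOptions:
    """VCF interpretation switches.

    ``mode="array"`` restricts the search range to the genotyped sites so
    expected variants at untyped positions are not penalised.  Variants
    whose heteroplasmy fraction falls below ``het_threshold`` are dropped
    (``het_handling="drop"``) or kept with the fraction recorded
    (``"keep"``).
    """

    mode: str = "sequencing"
    het_threshold: float = 0.9
    het_handling: str = "drop"

    def __post_init__(self) -> None:
        if self.mode not in ("sequencing", "array"):
            raise ValueError(f"unknown VCF mode {self.mode!r}")
        if not (0.0 <= self.het_threshold <= 1.0):
            raise ValueError("het_threshold must lie in [0, 1]")
        if self.het_handling not in ("drop", "keep"):
            raise ValueError(f"unknown het_handling {self.het_handling!r}")


@dataclass(frozen=True)
class SiteRecord:
    """One VCF site retained for pre-classification QC."""

    position: int
    ref: str
    alts: tuple[str, ...]
    calls: tuple[Optional[tuple[int, ...]], ...]  # per sample; None = missing


@dataclass
class VcfBatch:
    """Parsed VCF: per-sample profiles plus the site-level records QC
    needs (REF/ALT and the raw genotype calls)."""

    samples: list[str]
    profiles: list[SampleProfile]
    sites: list[SiteRecord]


# -- hsd --------------------------------------------------------------------


def parse_hsd(stream: io.TextIOBase | str) -> list[SampleProfile]:
    """Parse hsd text into profiles.

    Malformed variant tokens become per-sample warnings, not errors;
    duplicate sample IDs are fatal.
    """
    text = stream if isinstance(stream, str) else stream.read()
    profiles: list[SampleProfile] = []
    seen: dict[str, int] = {}
    for raw in text.splitlines():
        if not raw.strip():
            continue
        cols = raw.rstrip("\n").split("\t")
        if cols[0].strip().lower() in ("sampleid", "id", "sample"):
            continue  # optional header
        if len(cols) < 2:
            continue
        sample_id = cols[0].strip()
        seen[sample_id] = seen.get(sample_id, 0) + 1
        try:
            rng = Range.parse(cols[1])
        except (VariantError, ValueError):
            rng = None
        warnings: list[str] = []
        if rng is None:
            warnings.append(f"unparseable range {cols[1]!r}; assuming full")
            rng = Range.parse("1-16569")
        variants: set[Variant] = set()
        tokens = [t for col in cols[3:] for t in col.split() if t.strip()]
        for tok in tokens:
            try:
                variants.update(parse_tokens([tok]))
            except VariantError as exc:
                warnings.append(f"skipped variant token {tok!r}: {exc}")
        profiles.append(
            SampleProfile(
                id=sample_id,
                range=rng,
                variants=frozenset(variants),
                source="hsd",
                warnings=warnings,
            )
        )
    dupes = [s for s, n in seen.items() if n > 1]
    if dupes:
        raise ProfileParseError(f"duplicate sample IDs: {', '.join(sorted(dupes))}")
    return profiles


def write_hsd(profiles: Iterable[SampleProfile]) -> str:
    lines = ["SampleID\tRange\tHaplogroup\tPolymorphisms"]
    for p in profiles:
        variants = "\t".join(v.render() for v in sorted(p.variants))
        lines.append(f"{p.id}\t{p.range.render()}\t?\t{variants}".rstrip("\t"))
    return "\n".join(lines) + "\n"


# -- VCF --------------------------------------------------------------------


def derive_chip_range(positions: Sequence[int]) -> Range:
    """Range of exactly the genotyped positions (adjacent sites merged),
    so array data is only judged on positions the chip covers."""
    if not positions:
        raise ProfileParseError("cannot derive a chip range from zero sites")
    return Range.from_positions(positions)


def _decompose(pos: int, ref: str, alt: str) -> list[Variant]:
    """Decompose one REF/ALT pair into atomic variants (anchored VCF
    convention); indels come out left-anchored and are right-aligned by
    the caller."""
    ref, alt = ref.upper(), alt.upper()
    # trim shared suffix, then shared prefix
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    k = 0
    while k < min(len(ref), len(alt)) and ref[k] == alt[k]:
        k += 1
    out: list[Variant] = []
    r, a = ref[k:], alt[k:]
    start = pos + k
    if len(r) == len(a):
        out.extend(
            Variant(position=start + i, kind=SUBSTITUTION, alt=a[i])
            for i in range(len(r))
            if r[i] != a[i]
        )
    elif not r:  # pure insertion after the last shared base
        out.append(
            Variant(position=start - 1, kind=INSERTION, alt=a, insertion_index=1)
        )
    elif not a:  # pure deletion
        out.extend(
            Variant(position=start + i, kind=DELETION) for i in range(len(r))
        )
    else:  # complex: substitutions over the overlap + indel remainder
        n = min(len(r), len(a))
        out.extend(
            Variant(position=start + i, kind=SUBSTITUTION, alt=a[i])
            for i in range(n)
            if r[i] != a[i]
        )
        if len(r) > n:
            out.extend(
                Variant(position=start + i, kind=DELETION)
                for i in range(n, len(r))
            )
        else:
            out.append(
                Variant(
                    position=start + n - 1,
                    kind=INSERTION,
                    alt=a[n:],
                    insertion_index=1,
                )
            )
    return out


def read_vcf(
    path: str | Path,
    options: VcfOptions | None = None,
    reference: str = "",
) -> VcfBatch:
    """Read a single-contig mtDNA VCF into per-sample profiles plus the
    site records kept for QC."""
    options = options or VcfOptions()
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise ProfileParseError(f"{path}: VCF contains no samples")

    if reference:
        declared = dict(zip(vcf.seqnames, vcf.seqlens or []))
        for contig, length in declared.items():
            if length and length != len(reference):
                raise ProfileParseError(
                    f"{path}: contig {contig!r} has length {length}, "
                    f"reference has {len(reference)}"
                )

    sites: list[SiteRecord] = []
    per_sample: list[set[Variant]] = [set() for _ in samples]
    contigs: set[str] = set()
    for rec in vcf:
        contigs.add(rec.CHROM)
        if len(contigs) > 1:
            raise ProfileParseError(
                f"{path}: expected one mtDNA contig, found {sorted(contigs)}"
            )
        if reference and rec.POS > len(reference):
            raise ProfileParseError(
                f"{path}: position {rec.POS} beyond reference "
                f"(contig {rec.CHROM!r}, L={len(reference)})"
            )
        het = None
        for name in HET_FIELDS:
            try:
                het = rec.format(name)
            except KeyError:
                het = None
            if het is not None:
                break
        calls: list[Optional[tuple[int, ...]]] = []
        for si, gt in enumerate(rec.genotypes):
            alleles = tuple(a for a in gt[:-1] if a != -1)
            missing = len(alleles) == 0
            calls.append(None if missing else alleles)
            for ai in set(a for a in alleles if a > 0):
                fraction = None
                if het is not None:
                    row = het[si]
                    try:
                        fraction = float(row[ai - 1] if len(row) > 1 else row[0])
                    except (TypeError, IndexError):
                        fraction = None
                if fraction is not None and fraction < options.het_threshold:
                    if options.het_handling == "drop":
                        continue
                variants = _decompose(rec.POS, rec.REF, rec.ALT[ai - 1])
                if fraction is not None:
                    variants = [
                        replace(v, heteroplasmy_level=round(fraction, 6))
                        for v in variants
                    ]
                per_sample[si].update(variants)
        sites.append(
            SiteRecord(
                position=rec.POS,
                ref=rec.REF.upper(),
                alts=tuple(a.upper() for a in rec.ALT),
                calls=tuple(calls),
            )
        )
    if not sites:
        raise ProfileParseError(f"{path}: VCF contains no records")

    if options.mode == "array":
        rng = derive_chip_range([s.position for s in sites])
    else:
        rng = Range.full(len(reference)) if reference else Range.full(16569)

    profiles = []
    for name, variants in zip(samples, per_sample):
        if reference:
            variants = right_align_indels(variants, reference)
        profiles.append(
            SampleProfile(
                id=name,
                range=rng,
                variants=frozenset(variants),
                source="vcf",
            )
        )
    return VcfBatch(samples=samples, profiles=profiles, sites=sites)


def parse_vcf(
    path: str | Path,
    options: VcfOptions | None = None,
    reference: str = "",
) -> list[SampleProfile]:
    return read_vcf(path, options, reference).profiles


# -- FASTA ------------------------------------------------------------------


def parse_fasta(
    path: str | Path,
    reference: str,
    aligner: Aligner | None = None,
) -> list[SampleProfile]:
    """Align FASTA records to the reference and call their variants.

    Partial sequences get a range restricted to the reference span the
    alignment covers.  Records aligning below 70% identity are flagged
    and left unclassified; empty records are skipped with a warning.
    """
    profiles: list[SampleProfile] = []
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).strip("*").upper()
        if not seq:
            profiles.append(
                SampleProfile(
                    id=record.id,
                    range=Range.full(len(reference)),
                    variants=frozenset(),
                    source="fasta",
                    warnings=["empty sequence; skipped"],
                    flagged=True,
                )
            )
            continue
        variants, rng, identity = call_variants(seq, reference, aligner)
        warnings = []
        flagged = False
        if identity < MIN_FASTA_IDENTITY:
            warnings.append(
                f"alignment identity {identity:.2f} below "
                f"{MIN_FASTA_IDENTITY:.2f}; sample not classified"
            )
            flagged = True
        profiles.append(
            SampleProfile(
                id=record.id,
                range=rng,
                variants=variants,
                source="fasta",
                warnings=warnings,
                flagged=flagged,
            )
        )
    return profiles


# -- format autodetection ---------------------------------------------------


def detect_format(path: str | Path) -> str:
    """Guess hsd / vcf / fasta from the extension, then the content."""
    suffix = Path(path).suffix.lower()
    if suffix in (".vcf",):
        return "vcf"
    if suffix in (".fasta", ".fa", ".fna", ".fas"):
        return "fasta"
    if suffix in (".hsd",):
        return "hsd"
    with open(path) as fh:
        head = fh.read(4096)
    if head.startswith("##fileformat"):
        return "vcf"
    if head.lstrip().startswith(">"):
        return "fasta"
    return "hsd"


# -- exports ----------------------------------------------------------------

RESULT_COLUMNS = [
    "SampleID",
    "Range",
    "Haplogroup",
    "Quality",
    "Cluster",
    "Expected",
    "Found",
    "Remaining",
    "Status",
]


def write_results_tsv(results: Iterable, tree=None) -> str:
    """One row per sample: top haplogroup, quality, cluster and the
    expected / found / remaining variant counts of the top hit."""
    from .cluster import assign_cluster

    lines = ["\t".join(RESULT_COLUMNS)]
    for res in results:
        if not res.hits:
            lines.append(
                "\t".join([res.sample_id, res.range.render()] + [""] * 7)
            )
            continue
        top = res.hits[0]
        cluster = ""
        if tree is not None and tree.clusters:
            cluster = assign_cluster(tree, top.haplogroup)
        lines.append(
            "\t".join(
                [
                    res.sample_id,
                    res.range.render(),
                    top.haplogroup,
                    f"{top.quality:.4f}",
                    cluster,
                    str(len(top.found) + len(top.expected_missing)),
                    str(len(top.found)),
                    str(len(top.remaining)),
                    top.status,
                ]
            )
        )
    return "\n".join(lines) + "\n"


QC_COLUMNS = ["Scope", "ID", "Check", "Value", "Status", "Detail"]


def write_qc_tsv(report) -> str:
    """QC report: one row per check per scope."""
    lines = ["\t".join(QC_COLUMNS)]
    for flag in report.flags:
        lines.append(
            "\t".join(
                [
                    flag.scope,
                    flag.id,
                    flag.check,
                    f"{flag.value:.4f}" if isinstance(flag.value, float) else str(flag.value),
                    flag.status,
                    flag.detail,
                ]
            )
        )
    return "\n".join(lines) + "\n"
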