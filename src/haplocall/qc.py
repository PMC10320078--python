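"""Pre-classification quality control for VCF batches.

Genotype data reaching a classifier from heterogeneous sources (arrays,
WGS, long reads) often carries systematic problems — strand flips,
reference mismatches, missing calls — that silently depress haplogroup
quality or cause outright misclassification.  This module computes
file-, sample- and variant-level statistics before classification and
maps them to pass / warn / fail flags; QC annotates samples, it never
silently drops them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .phylotree import PhyloTree
from .profiles_io import VcfBatch
from .variants import SUBSTITUTION

SAMPLE_CALL_RATE_WARN = 0.9
SAMPLE_CALL_RATE_FAIL = 0.5
TREE_OVERLAP_WARN = 0.5  # array data legitimately covers a modest fraction

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class QCFlag:
    scope: str  # file | sample | variant
    id: str
    check: str
    value: object
    status: str  # pass | warn | fail
    detail: str = ""


@dataclass
class QCReport:
    n_samples: int = 0
    n_sites: int = 0
    tree_overlap: float = 0.0
    n_monomorphic: int = 0
    n_reference_mismatch: int = 0
    n_strand_flip_suspects: int = 0
    sample_call_rates: dict[str, float] = field(default_factory=dict)
    variant_call_rates: dict[int, float] = field(default_factory=dict)
    flags: list[QCFlag] = field(default_factory=list)

    @property
    def failed(self) -> bool:
        return any(f.status == "fail" for f in self.flags)

    @property
    def blocked(self) -> bool:
        return self.n_sites == 0


def run_vcf_qc(
    batch: VcfBatch,
    tree: PhyloTree,
    sample_warn: float = SAMPLE_CALL_RATE_WARN,
    sample_fail: float = SAMPLE_CALL_RATE_FAIL,
    overlap_warn: float = TREE_OVERLAP_WARN,
) -> QCReport:
    """Compute the pre-classification QC report for a parsed VCF batch.

    Checks: sample/site counts; the fraction of sites at positions the
    tree's edge variants use (overlap); monomorphic sites (every called
    genotype identical); sites whose VCF REF disagrees with the tree
    reference (fail — wrong reference build); among those, strand-flip
    suspects where REF/ALT equal the complements of the reference base
    and a tree-known alternate; sample and variant call rates.
    """
    report = QCReport(n_samples=len(batch.samples), n_sites=len(batch.sites))
    flags = report.flags
    if not batch.sites:
        flags.append(
            QCFlag("file", "-", "site count", 0, "fail", "VCF contains no sites")
        )
        return report

    tree_positions: set[int] = set()
    tree_alts: dict[int, set[str]] = {}
    for node in tree.nodes.values():
        for v in node.edge_variants:
            tree_positions.add(v.position)
            if v.kind == SUBSTITUTION:
                tree_alts.setdefault(v.position, set()).add(v.alt)

    report.tree_overlap = sum(
        1 for s in batch.sites if s.position in tree_positions
    ) / len(batch.sites)

    for site in batch.sites:
        called = [c for c in site.calls if c is not None]
        if len(set(called)) <= 1:
            report.n_monomorphic += 1
        ref_base = (
            tree.reference[site.position - 1]
            if site.position <= len(tree.reference)
            else "?"
        )
        if site.ref[0] != ref_base:
            report.n_reference_mismatch += 1
            flip = len(site.ref) == 1 and site.ref == _COMPLEMENT.get(
                ref_base, "?"
            ) and any(
                len(alt) == 1 and alt == _COMPLEMENT.get(talt)
                for alt in site.alts
                for talt in tree_alts.get(site.position, ())
            )
            if flip:
                report.n_strand_flip_suspects += 1
            flags.append(
                QCFlag(
                    "variant",
                    str(site.position),
                    "reference match",
                    site.ref,
                    "fail",
                    (
                        "REF/ALT match the strand-flipped reference/tree alleles"
                        if flip
                        else f"VCF REF {site.ref!r} != reference base {ref_base!r}"
                    ),
                )
            )
        rate = len(called) / len(site.calls)
        report.variant_call_rates[site.position] = rate
        if rate < sample_warn:
            flags.append(
                QCFlag(
                    "variant",
                    str(site.position),
                    "call rate",
                    rate,
                    "warn" if rate >= sample_fail else "fail",
                    f"{len(called)}/{len(site.calls)} genotypes called",
                )
            )

    for si, name in enumerate(batch.samples):
        called = sum(1 for s in batch.sites if s.calls[si] is not None)
        rate = called / len(batch.sites)
        report.sample_call_rates[name] = rate
        status = (
            "pass"
            if rate >= sample_warn
            else ("warn" if rate >= sample_fail else "fail")
        )
        flags.append(
            QCFlag(
                "sample",
                name,
                "call rate",
                rate,
                status,
                "" if status == "pass" else f"{called}/{len(batch.sites)} sites called",
            )
        )

    flags.insert(
        0, QCFlag("file", "-", "sample count", report.n_samples, "pass", "")
    )
    flags.insert(
        1, QCFlag("file", "-", "site count", report.n_sites, "pass", "")
    )
    flags.insert(
        2,
        QCFlag(
            "file",
            "-",
            "tree overlap",
            report.tree_overlap,
            "pass" if report.tree_overlap >= overlap_warn else "warn",
            f"{report.tree_overlap:.2%} of sites at tree-variant positions",
        ),
    )
    flags.insert(
        3,
        QCFlag(
            "file",
            "-",
            "monomorphic sites",
            report.n_monomorphic,
            "pass",
            "",
        ),
    )
    flags.insert(
        4,
        QCFlag(
            "file",
            "-",
            "reference mismatches",
            report.n_reference_mismatch,
            "pass" if report.n_reference_mismatch == 0 else "fail",
            (
                ""
                if report.n_reference_mismatch == 0
                else f"{report.n_strand_flip_suspects} look like strand flips"
            ),
        ),
    )
    return report
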