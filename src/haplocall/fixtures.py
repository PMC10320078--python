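"""Synthetic tree packages and sample batches.

Real tree packages and genotype batches are external downloads; this
module generates structurally equivalent synthetic ones so every other
module is testable end to end.  Trees are random rooted topologies whose
edges carry unique substitution/indel variants (plus deliberate back
mutations); samples are planted at known nodes with Poisson-distributed
private variants, and are emitted consistently as hsd, VCF and FASTA
together with a ground-truth table.

All randomness flows from ``SimulationSpec.seed`` through explicit
``random.Random`` instances, so identical specs produce byte-identical
output on any platform.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, replace
from pathlib import Path

from .phylotree import Node, PhyloTree, write_tree_package
from .rules import apply_variants, parse_rules, right_align_indels
from .variants import (
    DELETION,
    INSERTION,
    SUBSTITUTION,
    Range,
    Variant,
)

_BASES = "ACGT"


class SimulationError(ValueError):
    """Infeasible simulation parameters."""


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one synthetic study.

    Defaults describe a small but structurally realistic mtDNA-like
    setting: a 16,569 bp reference (the rCRS length), 40 haplogroups of
    depth up to 6 with 1-3 defining variants per branch, occasional back
    mutations, and samples carrying on average half a private variant.
    """

    n_haplogroups: int = 40
    max_depth: int = 6
    variants_per_edge: tuple[int, int] = (1, 3)
    back_mutation_rate: float = 0.05
    indel_rate: float = 0.1
    n_clusters: int = 4
    n_samples: int = 20
    extra_variant_rate: float = 0.5
    missing_rate: float = 0.0
    seed: int = 0
    reference_length: int = 16569

    def __post_init__(self) -> None:
        for name in ("back_mutation_rate", "indel_rate", "missing_rate"):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise SimulationError(f"{name} must lie in [0, 1], got {value}")
        if self.n_haplogroups < 1 or self.n_samples < 0:
            raise SimulationError("counts must be positive")
        if self.extra_variant_rate < 0:
            raise SimulationError("extra_variant_rate must be >= 0")


def _poisson(rng: random.Random, lam: float) -> int:
    # Knuth's method; lam is small here.
    if lam <= 0:
        return 0
    limit, k, p = pow(2.718281828459045, -lam), 0, 1.0
    while True:
        p *= rng.random()
        if p <= limit:
            return k
        k += 1


def build_tree(spec: SimulationSpec) -> PhyloTree:
    """Generate a random tree package in memory (see module docstring)."""
    rng = random.Random(f"tree:{spec.seed}")
    length = spec.reference_length
    max_needed = spec.n_haplogroups * spec.variants_per_edge[1] + 64
    if max_needed > length // 2:
        raise SimulationError(
            f"{spec.n_haplogroups} haplogroups x up to "
            f"{spec.variants_per_edge[1]} variants need more positions than "
            f"a {length} bp reference offers"
        )
    reference = "".join(rng.choice(_BASES) for _ in range(length))
    # keep position 1 and the last positions free so indel encoding in
    # VCF always has an anchor base on its left
    free_positions = list(range(2, length))
    rng.shuffle(free_positions)

    used_positions: set[int] = set()

    def draw_variant(occupied_keys: set) -> Variant:
        while True:
            pos = free_positions.pop()
            roll = rng.random()
            if roll < spec.indel_rate / 2:
                v = Variant(position=pos, kind=DELETION)
            elif roll < spec.indel_rate:
                v = Variant(
                    position=pos,
                    kind=INSERTION,
                    alt=rng.choice(_BASES),
                    insertion_index=1,
                )
            else:
                ref_base = reference[pos - 1]
                alt = rng.choice([b for b in _BASES if b != ref_base])
                v = Variant(position=pos, kind=SUBSTITUTION, alt=alt)
            # indels are stored right-aligned, matching tree nomenclature
            (v,) = right_align_indels([v], reference)
            if v.key not in occupied_keys and v.position not in used_positions:
                used_positions.add(v.position)
                return v

    nodes: dict[str, Node] = {"ROOT": Node("ROOT", None, ())}
    depths = {"ROOT": 0}
    profiles: dict[str, dict] = {"ROOT": {}}
    used_keys: set = set()
    for i in range(1, spec.n_haplogroups):
        if i <= spec.n_clusters:
            parent = "ROOT"
        else:
            parent = rng.choice(
                [n for n in nodes if depths[n] < spec.max_depth]
            )
        name = f"H{i}"
        n_vars = rng.randint(*spec.variants_per_edge)
        parent_profile = dict(profiles[parent])
        edge: list[Variant] = []
        for _ in range(n_vars):
            candidates = [
                v
                for k, v in parent_profile.items()
                if k not in {e.key for e in edge}
            ]
            if candidates and rng.random() < spec.back_mutation_rate:
                target = rng.choice(sorted(candidates, key=lambda v: v.key))
                ev = replace(target, back_mutation=True)
            else:
                ev = draw_variant(used_keys | {e.key for e in edge})
                used_keys.add(ev.key)
            edge.append(ev)
        state = dict(parent_profile)
        for ev in edge:
            if ev.back_mutation:
                state.pop(ev.key, None)
            else:
                state[ev.key] = ev
        nodes[name] = Node(name, parent, tuple(edge))
        nodes[parent].children.append(name)
        depths[name] = depths[parent] + 1
        profiles[name] = state

    clusters = sorted(nodes["ROOT"].children)

    weights: dict[str, float] = {}
    all_edge_variants = [v for n in nodes.values() for v in n.edge_variants]
    for v in all_edge_variants:
        if rng.random() < 0.8:  # the rest exercise the default weight
            weights[v.canonical()] = float(rng.randint(1, 20))

    hotspot_tokens = []
    for _ in range(5):
        pos = free_positions.pop()
        ref_base = reference[pos - 1]
        hotspot_tokens.append(f"{pos}{rng.choice([b for b in _BASES if b != ref_base])}")

    # one residual rewrite rule on positions the tree never uses
    p1, p2 = free_positions.pop(), free_positions.pop()
    rules = parse_rules(f"{p1}.1C\t{p2}.1C\n")

    return PhyloTree(
        nodes=nodes,
        root="ROOT",
        reference=reference,
        weights=weights,
        hotspots=frozenset(hotspot_tokens),
        rules=rules,
        clusters=clusters,
        name=f"synthetic-{spec.seed}",
        version="1.0.0",
    )


def make_tree_package(spec: SimulationSpec, directory: str | Path) -> Path:
    """Generate a tree and write it in the package layout."""
    return write_tree_package(build_tree(spec), directory)


@dataclass
class SampleBatch:
    """A simulated batch with its ground truth and on-disk renderings."""

    truth: dict[str, str]  # sample id -> planted haplogroup
    profiles: dict[str, frozenset[Variant]]
    hsd_path: Path
    vcf_path: Path
    fasta_path: Path
    truth_path: Path


def simulate_profiles(
    tree: PhyloTree, spec: SimulationSpec
) -> tuple[dict[str, str], dict[str, frozenset[Variant]]]:
    """Plant each sample at a random non-root node and add Poisson
    private substitution variants at positions the tree does not use."""
    rng = random.Random(f"samples:{spec.seed}")
    node_names = sorted(n for n in tree.nodes if n != tree.root) or [tree.root]
    used = {
        v.position for n in tree.nodes.values() for v in n.edge_variants
    } | {v.position for v in _hotspot_variants(tree)}
    free = sorted(set(range(2, tree.reference_length)) - used)
    rng.shuffle(free)
    truth: dict[str, str] = {}
    profiles: dict[str, frozenset[Variant]] = {}
    for i in range(spec.n_samples):
        sid = f"S{i + 1:03d}"
        node = rng.choice(node_names)
        variants = set(tree.expected_profile(node))
        for _ in range(_poisson(rng, spec.extra_variant_rate)):
            pos = free.pop()
            ref_base = tree.reference[pos - 1]
            variants.add(
                Variant(
                    position=pos,
                    kind=SUBSTITUTION,
                    alt=rng.choice([b for b in _BASES if b != ref_base]),
                )
            )
        truth[sid] = node
        profiles[sid] = frozenset(variants)
    return truth, profiles


def _hotspot_variants(tree: PhyloTree):
    from .variants import parse_tokens

    return parse_tokens(tree.hotspots)


def _vcf_record(variant: Variant, reference: str) -> tuple[int, str, str]:
    """Anchored VCF encoding of one variant."""
    pos, base = variant.position, None
    if variant.kind == SUBSTITUTION:
        return pos, reference[pos - 1], variant.alt
    if variant.kind == INSERTION:
        anchor = reference[pos - 1]
        return pos, anchor, anchor + variant.alt
    anchor = reference[pos - 2]
    return pos - 1, anchor + reference[pos - 1], anchor


def write_vcf(
    profiles: dict[str, frozenset[Variant]],
    reference: str,
    path: Path,
    rng: random.Random | None = None,
    missing_rate: float = 0.0,
    contig: str = "chrM",
) -> None:
    """Emit a plain-text multi-sample VCF of the given profiles; one
    record per distinct variant, haploid genotypes, optional random
    genotype masking."""
    samples = sorted(profiles)
    events = sorted(
        {v for vs in profiles.values() for v in vs},
        key=lambda v: (v.position, v.kind, v.alt, v.insertion_index),
    )
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={contig},length={len(reference)}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples),
    ]
    rows = []
    for v in events:
        pos, ref, alt = _vcf_record(v, reference)
        gts = []
        for s in samples:
            if rng is not None and missing_rate > 0 and rng.random() < missing_rate:
                gts.append(".")
            else:
                gts.append("1" if v in profiles[s] else "0")
        rows.append(
            (pos, f"{contig}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t" + "\t".join(gts))
        )
    rows.sort(key=lambda r: r[0])
    lines.extend(r[1] for r in rows)
    path.write_text("\n".join(lines) + "\n")


def make_samples(
    tree: PhyloTree, spec: SimulationSpec, directory: str | Path
) -> SampleBatch:
    """Simulate a batch and write consistent hsd, VCF and FASTA
    renderings plus a ground-truth table."""
    from .profiles_io import SampleProfile, write_hsd

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    truth, profiles = simulate_profiles(tree, spec)
    full = Range.full(tree.reference_length)

    hsd_path = directory / "samples.hsd"
    hsd_path.write_text(
        write_hsd(
            SampleProfile(id=s, range=full, variants=profiles[s])
            for s in sorted(profiles)
        )
    )

    vcf_path = directory / "samples.vcf"
    write_vcf(
        profiles,
        tree.reference,
        vcf_path,
        rng=random.Random(f"mask:{spec.seed}"),
        missing_rate=spec.missing_rate,
    )

    fasta_path = directory / "samples.fasta"
    with open(fasta_path, "w") as fh:
        for s in sorted(profiles):
            seq = apply_variants(tree.reference, profiles[s])
            fh.write(f">{s}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")

    truth_path = directory / "truth.tsv"
    truth_path.write_text(
        "SampleID\tHaplogroup\n"
        + "".join(f"{s}\t{truth[s]}\n" for s in sorted(truth))
    )
    return SampleBatch(
        truth=truth,
        profiles=profiles,
        hsd_path=hsd_path,
        vcf_path=vcf_path,
        fasta_path=fasta_path,
        truth_path=truth_path,
    )
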