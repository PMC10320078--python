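"""Phylogenetic tree packages: data model, loader and tree queries.

A tree package is a directory decoupling the classification engine from
any particular phylogeny:

* ``tree.xml`` (or ``tree.tsv``) -- the rooted haplogroup tree; each edge
  carries the variants that define the branch, possibly back mutations;
* ``weights.txt`` -- per-variant phylogenetic weights used by the
  classification metric (tab-delimited: variant, weight);
* ``hotspots.txt`` -- hypervariable positions excluded from phylogenetic
  interpretation (one variant per line);
* ``rules.txt`` -- optional nomenclature rewrite rules (see ``rules``);
* ``reference.fasta`` -- the reference sequence (e.g. the 16,569 bp rCRS);
* ``clusters.txt`` -- haplogroup names designated top-level clusters;
* ``metadata.yaml`` -- tree name, version, optional annotation tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import yaml
from Bio import SeqIO
from lxml import etree

from .variants import Range, Variant, parse_tokens, restrict_to_range

DEFAULT_WEIGHT = 10.0


class TreeLoadError(Exception):
    """Fatal problem while loading a tree package."""


class UnknownHaplogroupError(KeyError):
    """Lookup of a haplogroup name absent from the tree."""

    def __init__(self, name: str, candidates: Iterable[str]):
        self.name = name
        self.candidates = sorted(candidates)[:5]
        super().__init__(
            f"unknown haplogroup {name!r}; nearest names: "
            + ", ".join(self.candidates)
        )


@dataclass
class Node:
    name: str
    parent: Optional[str]
    edge_variants: tuple[Variant, ...]
    children: list[str] = field(default_factory=list)


@dataclass
class PhyloTree:
    """Rooted labelled tree whose edges carry defining variants, plus the
    weights, hotspots, rules, reference and cluster labels of its package."""

    nodes: dict[str, Node]
    root: str
    reference: str
    weights: dict[str, float] = field(default_factory=dict)
    hotspots: frozenset[str] = frozenset()
    rules: list = field(default_factory=list)
    clusters: list[str] = field(default_factory=list)
    name: str = "unnamed"
    version: str = "0"
    annotation_files: list[str] = field(default_factory=list)
    default_weight: float = DEFAULT_WEIGHT
    _profiles: dict[str, frozenset[Variant]] = field(
        default_factory=dict, repr=False
    )

    # -- structure ---------------------------------------------------------

    def __post_init__(self) -> None:
        self._validate()

    def _validate(self) -> None:
        roots = [n for n in self.nodes.values() if n.parent is None]
        if len(roots) != 1:
            raise TreeLoadError(f"tree must have exactly one root, found {len(roots)}")
        if roots[0].name != self.root:
            raise TreeLoadError("declared root does not match parentless node")
        for name in self.clusters:
            if name not in self.nodes:
                raise TreeLoadError(f"cluster label {name!r} is not a tree node")
        for node in self.nodes.values():
            seen, cur = {node.name}, node.parent
            while cur is not None:
                if cur in seen:
                    raise TreeLoadError(f"cycle through {cur!r}")
                seen.add(cur)
                cur = self.nodes[cur].parent

    @property
    def reference_length(self) -> int:
        return len(self.reference)

    def node(self, name: str) -> Node:
        try:
            return self.nodes[name]
        except KeyError:
            raise UnknownHaplogroupError(name, self.nodes) from None

    def ancestors(self, name: str) -> list[str]:
        """Path root -> ``name`` inclusive."""
        path = [self.node(name).name]
        while (parent := self.nodes[path[-1]].parent) is not None:
            path.append(parent)
        return path[::-1]

    # -- weights and hotspots ---------------------------------------------

    def weight_of(self, variant: Variant) -> float:
        return self.weights.get(variant.canonical(), self.default_weight)

    def is_hotspot(self, variant: Variant) -> bool:
        return variant.canonical() in self.hotspots

    def drop_hotspots(self, variants: Iterable[Variant]) -> frozenset[Variant]:
        return frozenset(v for v in variants if not self.is_hotspot(v))

    # -- queries -----------------------------------------------------------

    def expected_profile(self, haplogroup: str) -> frozenset[Variant]:
        """Variants defining a haplogroup relative to the reference.

        Edge events are replayed along the root-to-node path: a plain
        variant is added; a back mutation (``!``) removes the variant at
        the same position/kind/index, whatever its alt allele, and is
        itself excluded; a later re-occurrence re-adds it.  The result
        never contains back-mutation-flagged entries.
        """
        if haplogroup in self._profiles:
            return self._profiles[haplogroup]
        node = self.node(haplogroup)
        if node.parent is None:
            profile: frozenset[Variant] = frozenset()
        else:
            state = {v.key: v for v in self.expected_profile(node.parent)}
            for ev in node.edge_variants:
                if ev.back_mutation:
                    state.pop(ev.key, None)
                else:
                    state[ev.key] = ev
            profile = frozenset(state.values())
        self._profiles[haplogroup] = profile
        return profile

    def tree_distance(self, hg1: str, hg2: str) -> int:
        """Phylogenetic distance between two haplogroups: the number of
        non-hotspot variants separating their expected profiles (the
        symmetric difference after back-mutation resolution along the
        connecting path).  Symmetric; zero iff the profiles coincide."""
        p1 = self.drop_hotspots(self.expected_profile(hg1))
        p2 = self.drop_hotspots(self.expected_profile(hg2))
        return len(p1 ^ p2)

    def restrict_to_range(
        self, variants: Iterable[Variant], rng: Range
    ) -> frozenset[Variant]:
        return restrict_to_range(variants, rng)


# -- loading ----------------------------------------------------------------


def _parse_variant_field(text: str, context: str) -> tuple[Variant, ...]:
    try:
        return tuple(parse_tokens(text.replace(",", " ").split()))
    except Exception as exc:
        raise TreeLoadError(f"{context}: bad variant list {text!r}: {exc}") from exc


def _load_tree_xml(path: Path) -> tuple[dict[str, Node], str]:
    try:
        doc = etree.parse(str(path))
    except (etree.XMLSyntaxError, OSError) as exc:
        raise TreeLoadError(f"cannot parse {path}: {exc}") from exc
    nodes: dict[str, Node] = {}

    def walk(elem: etree._Element, parent: Optional[str]) -> None:
        name = elem.get("name")
        if not name:
            raise TreeLoadError(f"{path}: haplogroup element without name")
        if name in nodes:
            raise TreeLoadError(f"{path}: duplicate haplogroup {name!r}")
        variants = _parse_variant_field(elem.get("variants", ""), f"{path}:{name}")
        nodes[name] = Node(name=name, parent=parent, edge_variants=variants)
        if parent is not None:
            nodes[parent].children.append(name)
        for child in elem.iterchildren("haplogroup"):
            walk(child, name)

    root_elems = doc.getroot().findall("haplogroup")
    if doc.getroot().tag == "haplogroup":
        root_elems = [doc.getroot()]
    if len(root_elems) != 1:
        raise TreeLoadError(f"{path}: expected exactly one root haplogroup")
    walk(root_elems[0], None)
    return nodes, root_elems[0].get("name")


def _load_tree_tsv(path: Path) -> tuple[dict[str, Node], str]:
    """Flat alternative: ``id<TAB>parent-id<TAB>variant-list`` per line,
    empty parent for the root."""
    rows: list[tuple[str, str, str]] = []
    for i, line in enumerate(path.read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise TreeLoadError(f"{path}:{i}: expected id<TAB>parent[<TAB>variants]")
        rows.append((parts[0], parts[1], parts[2] if len(parts) > 2 else ""))
    nodes: dict[str, Node] = {}
    root = None
    for name, parent, vtext in rows:
        if name in nodes:
            raise TreeLoadError(f"{path}: duplicate haplogroup {name!r}")
        variants = _parse_variant_field(vtext, f"{path}:{name}")
        parent_or_none = parent or None
        if parent_or_none is None:
            root = name
        nodes[name] = Node(name=name, parent=parent_or_none, edge_variants=variants)
    if root is None:
        raise TreeLoadError(f"{path}: no root row (empty parent column)")
    for node in nodes.values():
        if node.parent is not None:
            if node.parent not in nodes:
                raise TreeLoadError(
                    f"{path}: {node.name!r} references unknown parent {node.parent!r}"
                )
            nodes[node.parent].children.append(node.name)
    return nodes, root


def _load_weights(path: Path) -> dict[str, float]:
    weights: dict[str, float] = {}
    for i, line in enumerate(path.read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise TreeLoadError(f"{path}:{i}: expected variant<TAB>weight")
        try:
            key = parse_tokens([parts[0]])
            weight = float(parts[1])
        except Exception as exc:
            raise TreeLoadError(f"{path}:{i}: {exc}") from exc
        if weight <= 0:
            raise TreeLoadError(f"{path}:{i}: weight must be positive")
        for v in key:
            weights[v.canonical()] = weight
    return weights


def load_tree_package(directory: str | Path) -> PhyloTree:
    """Load a tree package directory into a fully linked :class:`PhyloTree`.

    ``tree.xml``/``tree.tsv``, ``reference.fasta`` are required; weights,
    hotspots, rules, clusters and metadata are optional with sensible
    fallbacks (variants missing a weight entry receive the default weight).
    """
    from .rules import parse_rules  # local import to avoid a cycle

    directory = Path(directory)
    if not directory.is_dir():
        raise TreeLoadError(f"tree package {directory} is not a directory")

    xml = directory / "tree.xml"
    tsv = directory / "tree.tsv"
    if xml.exists():
        nodes, root = _load_tree_xml(xml)
    elif tsv.exists():
        nodes, root = _load_tree_tsv(tsv)
    else:
        raise TreeLoadError(f"{directory}: neither tree.xml nor tree.tsv found")

    ref_path = directory / "reference.fasta"
    if not ref_path.exists():
        raise TreeLoadError(f"{directory}: reference.fasta missing")
    records = list(SeqIO.parse(str(ref_path), "fasta"))
    if not records:
        raise TreeLoadError(f"{ref_path}: no FASTA record")
    reference = str(records[0].seq).upper()

    weights_path = directory / "weights.txt"
    weights = _load_weights(weights_path) if weights_path.exists() else {}

    hotspots_path = directory / "hotspots.txt"
    hotspots: frozenset[str] = frozenset()
    if hotspots_path.exists():
        hotspots = frozenset(
            v.canonical()
            for v in parse_tokens(
                line
                for line in hotspots_path.read_text().splitlines()
                if line.strip() and not line.startswith("#")
            )
        )

    rules_path = directory / "rules.txt"
    rules = parse_rules(rules_path.read_text()) if rules_path.exists() else []

    clusters_path = directory / "clusters.txt"
    clusters = (
        [
            line.strip()
            for line in clusters_path.read_text().splitlines()
            if line.strip() and not line.startswith("#")
        ]
        if clusters_path.exists()
        else []
    )

    meta = {}
    meta_path = directory / "metadata.yaml"
    if meta_path.exists():
        meta = yaml.safe_load(meta_path.read_text()) or {}

    return PhyloTree(
        nodes=nodes,
        root=root,
        reference=reference,
        weights=weights,
        hotspots=hotspots,
        rules=rules,
        clusters=clusters,
        name=str(meta.get("name", directory.name)),
        version=str(meta.get("version", "0")),
        annotation_files=list(meta.get("annotations", [])),
    )


def write_tree_package(tree: PhyloTree, directory: str | Path) -> Path:
    """Serialize a tree back into the package layout (XML form)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    def elem_for(name: str) -> etree._Element:
        node = tree.nodes[name]
        e = etree.Element("haplogroup", name=name)
        if node.edge_variants:
            e.set("variants", " ".join(v.render() for v in node.edge_variants))
        for child in node.children:
            e.append(elem_for(child))
        return e

    root_elem = etree.Element("phylotree", name=tree.name, version=tree.version)
    root_elem.append(elem_for(tree.root))
    (directory / "tree.xml").write_bytes(
        etree.tostring(root_elem, pretty_print=True, xml_declaration=True)
    )
    (directory / "reference.fasta").write_text(
        f">{tree.name}\n"
        + "\n".join(
            tree.reference[i : i + 70] for i in range(0, len(tree.reference), 70)
        )
        + "\n"
    )
    (directory / "weights.txt").write_text(
        "".join(f"{k}\t{w:g}\n" for k, w in sorted(tree.weights.items()))
    )
    (directory / "hotspots.txt").write_text(
        "".join(f"{h}\n" for h in sorted(tree.hotspots))
    )
    (directory / "clusters.txt").write_text(
        "".join(f"{c}\n" for c in tree.clusters)
    )
    (directory / "rules.txt").write_text(
        "".join(
            " ".join(v.render() for v in r.source)
            + "\t"
            + " ".join(v.render() for v in r.target)
            + "\n"
            for r in tree.rules
        )
    )
    (directory / "metadata.yaml").write_text(
        yaml.safe_dump(
            {
                "name": tree.name,
                "version": tree.version,
                "annotations": tree.annotation_files,
            },
            sort_keys=True,
        )
    )
    return directory
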