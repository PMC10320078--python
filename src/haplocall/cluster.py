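"""Top-level haplogroup clustering and batch summaries.

A tree package designates some haplogroups as top-level clusters
(macrohaplogroup labels).  Every haplogroup is assigned to the cluster at
minimal phylogenetic distance; classified batches are then summarised by
cluster for dashboard-style overviews.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .classify import ClassificationResult
from .phylotree import PhyloTree


class ClusterError(ValueError):
    """Tree carries no cluster labels."""


def assign_cluster(tree: PhyloTree, haplogroup: str) -> str:
    """Cluster with minimal tree distance to the haplogroup.

    Ties prefer a cluster that is an ancestor of the haplogroup, then the
    lexicographically smallest name, so assignment is deterministic.
    """
    if not tree.clusters:
        raise ClusterError("tree package defines no clusters")
    tree.node(haplogroup)  # raises on unknown name
    ancestry = set(tree.ancestors(haplogroup))
    best = min(
        tree.clusters,
        key=lambda c: (tree.tree_distance(haplogroup, c), c not in ancestry, c),
    )
    return best


@dataclass
class ClusterSummary:
    """Per-cluster sample counts, member haplogroups and warning tallies."""

    counts: dict[str, int] = field(default_factory=dict)
    members: dict[str, list[str]] = field(default_factory=dict)
    ok_counts: dict[str, int] = field(default_factory=dict)
    warning_counts: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def to_tsv(self) -> str:
        lines = ["Cluster\tSamples\tOK\tWarnings\tHaplogroups"]
        for cluster in sorted(self.counts):
            lines.append(
                "\t".join(
                    [
                        cluster,
                        str(self.counts[cluster]),
                        str(self.ok_counts.get(cluster, 0)),
                        str(self.warning_counts.get(cluster, 0)),
                        ",".join(sorted(set(self.members.get(cluster, [])))),
                    ]
                )
            )
        return "\n".join(lines) + "\n"


def summarize_clusters(
    results: Iterable[ClassificationResult], tree: PhyloTree
) -> ClusterSummary:
    """Tally each sample once under its top hit's cluster."""
    summary = ClusterSummary()
    for res in results:
        if not res.hits:
            continue
        top = res.hits[0]
        cluster = assign_cluster(tree, top.haplogroup)
        summary.counts[cluster] = summary.counts.get(cluster, 0) + 1
        summary.members.setdefault(cluster, []).append(top.haplogroup)
        bucket = summary.ok_counts if top.status == "ok" else summary.warning_counts
        bucket[cluster] = bucket.get(cluster, 0) + 1
    return summary
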