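"""Haplogroup classification: weighted set-similarity metrics and ranked
assignment of sample profiles to tree haplogroups.

A sample's observed variants and a haplogroup's expected variants are
compared as weighted sets after two filters: both sides are restricted to
the sample's analysed range, and hotspot variants (hypervariable
positions carrying no phylogenetic signal) are removed.  The default
quality score is the weighted Kulczynski measure

    S = 1/2 * (W_shared / W_expected + W_shared / W_observed)

where ``W_x`` sums the phylogenetic weights of the variants in each set.
Every haplogroup in the tree is scored and the hits are returned sorted
by quality, ties broken by name for determinism.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

from .phylotree import PhyloTree
from .profiles_io import SampleProfile
from .variants import Variant, restrict_to_range

DEFAULT_TOP_N = 20
QUALITY_WARNING_THRESHOLD = 0.9
REMAINING_WARNING_COUNT = 5

WeightedSet = Mapping[Variant, float]


class MetricError(ValueError):
    """Invalid metric input (non-positive weight, unknown metric name)."""


def _check_weights(*sets: WeightedSet) -> None:
    for ws in sets:
        for v, w in ws.items():
            if w <= 0:
                raise MetricError(f"non-positive weight {w} for {v.render()}")


def kulczynski_quality(observed: WeightedSet, expected: WeightedSet) -> float:
    """Weighted Kulczynski similarity in [0, 1].

    Each term measures the shared mass as a fraction of one side's total
    mass, with the shared mass counted in that side's own weights (the
    two coincide when both sets are weighted by the same tree).  An
    empty side contributes a full term; both empty -> 1.
    """
    _check_weights(observed, expected)
    inter = expected.keys() & observed.keys()

    # build each denominator from the shared partial sum so that a side
    # fully contained in the intersection scores exactly 1.0
    def term(side: WeightedSet) -> float:
        shared = sum(side[v] for v in inter)
        only = sum(side[v] for v in side.keys() - inter)
        total = shared + only
        return 1.0 if total == 0 else shared / total

    return 0.5 * (term(expected) + term(observed))


def jaccard_quality(observed: WeightedSet, expected: WeightedSet) -> float:
    """Weighted Jaccard: shared mass over union mass (min/max over the
    intersection when per-side weights differ); 0/0 -> 1."""
    _check_weights(observed, expected)
    inter = observed.keys() & expected.keys()
    shared = sum(min(observed[v], expected[v]) for v in inter)
    slack = (
        sum(max(observed[v], expected[v]) - min(observed[v], expected[v]) for v in inter)
        + sum(observed[v] for v in observed.keys() - inter)
        + sum(expected[v] for v in expected.keys() - inter)
    )
    union = shared + slack
    return 1.0 if union == 0 else shared / union


def hamming_quality(observed: WeightedSet, expected: WeightedSet) -> float:
    """Hamming-derived quality: 1 minus the symmetric-difference mass
    over the total mass of both sets; 0/0 -> 1."""
    _check_weights(observed, expected)
    inter = observed.keys() & expected.keys()
    shared = sum(min(observed[v], expected[v]) for v in inter)
    symdiff = (
        sum(max(observed[v], expected[v]) - min(observed[v], expected[v]) for v in inter)
        + sum(observed[v] for v in observed.keys() - inter)
        + sum(expected[v] for v in expected.keys() - inter)
    )
    total = 2.0 * shared + symdiff
    return 1.0 if total == 0 else 1.0 - symdiff / total


METRICS = {
    "kulczynski": kulczynski_quality,
    "jaccard": jaccard_quality,
    "hamming": hamming_quality,
}


@dataclass(frozen=True)
class Hit:
    """One ranked haplogroup candidate with its variant partitions."""

    haplogroup: str
    quality: float
    found: frozenset[Variant]
    expected_missing: frozenset[Variant]
    remaining: frozenset[Variant]
    status: str = "ok"
    triggered_rules: tuple[str, ...] = ()


@dataclass
class ClassificationResult:
    sample_id: str
    hits: list[Hit]
    range: "object"
    warnings: list[str] = field(default_factory=list)
    annotations: dict = field(default_factory=dict)

    @property
    def top_hit(self) -> Hit:
        return self.hits[0]


def quality_flag(
    hit: Hit,
    *,
    full_range: bool,
    quality_threshold: float = QUALITY_WARNING_THRESHOLD,
    remaining_threshold: int = REMAINING_WARNING_COUNT,
) -> tuple[str, tuple[str, ...]]:
    """Rule-based status of a hit: ``warning`` on low quality, on
    expected variants missing from a fully covered range, or on too many
    remaining (private) variants; otherwise ``ok``."""
    triggered: list[str] = []
    if hit.quality < quality_threshold:
        triggered.append("low quality")
    if full_range and hit.expected_missing:
        triggered.append("expected variants missing")
    if len(hit.remaining) >= remaining_threshold:
        triggered.append("many remaining variants")
    return ("warning" if triggered else "ok"), tuple(triggered)


def _weighted(tree: PhyloTree, variants: Iterable[Variant]) -> dict[Variant, float]:
    return {v: tree.weight_of(v) for v in variants}


def classify_sample(
    tree: PhyloTree,
    profile: SampleProfile,
    metric: str = "kulczynski",
    top_n: int = DEFAULT_TOP_N,
    quality_threshold: float = QUALITY_WARNING_THRESHOLD,
    remaining_threshold: int = REMAINING_WARNING_COUNT,
) -> ClassificationResult:
    """Score a sample against every haplogroup of the tree and return the
    ``top_n`` hits sorted by quality (ties by name).

    Both the observed set and each expected profile are restricted to the
    sample's range and cleansed of hotspots before scoring.  A sample
    with no variants on a fully covered range matches the reference
    haplotype: it classifies to the root with a warning attached.
    """
    if metric not in METRICS:
        raise MetricError(
            f"unknown metric {metric!r}; available: {', '.join(sorted(METRICS))}"
        )
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    metric_fn = METRICS[metric]

    rng = profile.range
    observed = tree.drop_hotspots(restrict_to_range(profile.variants, rng))
    observed_w = _weighted(tree, observed)
    full = rng.covers_full(tree.reference_length)

    scored: list[Hit] = []
    for name in tree.nodes:
        expected = tree.drop_hotspots(
            restrict_to_range(tree.expected_profile(name), rng)
        )
        found = expected & observed
        missing = expected - observed
        remaining = observed - expected
        quality = metric_fn(observed_w, _weighted(tree, expected))
        scored.append(
            Hit(
                haplogroup=name,
                quality=quality,
                found=found,
                expected_missing=missing,
                remaining=remaining,
            )
        )
    scored.sort(key=lambda h: (-h.quality, h.haplogroup))
    hits = []
    for hit in scored[:top_n]:
        status, triggered = quality_flag(
            hit,
            full_range=full,
            quality_threshold=quality_threshold,
            remaining_threshold=remaining_threshold,
        )
        hits.append(replace(hit, status=status, triggered_rules=triggered))

    warnings = list(profile.warnings)
    if not observed and full:
        warnings.append(
            "sample carries no variants relative to the reference; "
            "classified to the reference haplotype"
        )
    if hits and hits[0].status == "warning":
        warnings.extend(hits[0].triggered_rules)
    return ClassificationResult(
        sample_id=profile.id, hits=hits, range=rng, warnings=warnings
    )
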