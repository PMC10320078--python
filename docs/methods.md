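# Methods

## Model and procedure

Haplogroup classification treats a phylogenetic tree as a catalogue of
variant sets. Each node (haplogroup) `h` has an expected profile
`E(h)`, obtained by replaying the edge events on the root-to-`h` path:
a plain variant adds itself; a back mutation (suffix `!`) removes the
variant with the same position, kind and insertion index — whatever its
alternate allele, matching the position-level semantics of the `!`
notation — and a later re-occurrence re-adds it. Profiles therefore
never contain back-mutation-flagged entries.

A sample contributes an observed set `O` and an analysed range `R` (a
union of inclusive 1-based intervals on the circular genome; an
interval with start > end wraps the origin, as the control region
16024–576 does). Scoring compares `O` and `E(h)` after restricting both
to `R` and removing hotspot variants, using one of three weighted
set-similarity measures with per-variant weights `w(v)` from the tree
package (default weight 10 where the table has no entry, so an
unweighted package degrades to plain counting):

* Kulczynski (default): `½·(W(O∩E)/W(E) + W(O∩E)/W(O))`; an empty side
  contributes a full term, both sides empty give 1.
* Jaccard: shared over union mass.
* Hamming-derived: `1 − W(OΔE)/(W(O)+W(E))`, 0/0 → 1.

Each score is assembled from the same partial sums for numerator and
denominator, so a profile identical to its haplogroup scores exactly
1.0 in floating point, not 1−ε. When the two sides ever carry different
weights for the same variant (possible only when callers supply their
own weighted sets), shared mass is counted per side (Kulczynski) or via
min/max (Jaccard/Hamming), which keeps every score in [0, 1]; with a
single tree supplying both sides these reduce to the formulas above.

Every haplogroup in the tree is scored (exhaustive scan; at the scale
of mtDNA trees this is cheap and avoids the correctness risks of a
pruned descent), hits are sorted by quality with lexicographic
tie-breaks, and the top 20 (configurable) are reported. A rule-based
flag marks a hit `warning` when quality < 0.9, when expected variants
are missing although the range covers the whole reference, or when ≥ 5
non-hotspot private variants remain; thresholds are configurable.

Tree distance between two haplogroups is the size of the symmetric
difference of their hotspot-filtered expected profiles — equivalently,
the number of surviving edge events on the connecting path after back
mutations cancel. It is symmetric, satisfies the triangle inequality,
and is 0 exactly for profile-identical nodes (which a back-mutating
edge can produce for distinct nodes; cluster assignment is unaffected
because it only consumes distances). Top-level cluster assignment picks
the cluster label at minimal distance, preferring an ancestor and then
the lexicographically smallest name on ties.

## Input handling

**hsd** lines are `SampleID<TAB>Range<TAB>Haplogroup<TAB>variant...`;
malformed variant tokens become per-sample warnings rather than
errors, duplicate IDs are fatal. **VCF** parsing (cyvcf2) splits
multi-allelic records, decomposes REF/ALT pairs into atomic
substitutions/insertions/deletions, and right-aligns indels against
the tree reference. Heteroplasmy fractions are read from the first
per-genotype field among AF, HF, VAF; fractions below the threshold
(default 0.9) are dropped by default or kept with the fraction
recorded (`het_handling="keep"`). Missing genotypes (`./.`) never
produce variants; they feed the QC call rates. In array mode the
analysed range is exactly the genotyped positions (adjacent sites
merged), so untyped expected variants are not penalised. **FASTA**
records are aligned with edlib in infix mode — partial sequences such
as control-region-only records align to their sub-span without end-gap
penalties — and variants are read off the alignment path; reference
positions matched by query Ns are excluded from the range, and records
below 70% alignment identity are flagged and not classified. Wrapping
of reads across the circular origin is not modelled.

## Indel normalisation

Aligners and VCF convention left-align indels; tree nomenclature
expects them right-aligned. A generic pass shifts every single-base
deletion to the end of its homopolymer run and every insertion
rightward while its first base matches the next reference base,
rotating the inserted string (which also normalises insertions in
dinucleotide repeats); the edited sequence is provably unchanged, and
tests verify maximality against brute-force enumeration of equivalent
placements. A tree-supplied rewrite-rule table
(`source-variants<TAB>target-variants`, applied in file order, a rule
firing only when all its sources are present) covers residual special
cases the positional shift cannot express. Rules run after the generic
pass, are context-free, and rule application is idempotent for
non-cyclic tables.

## VCF quality control

Computed before classification, reported per file / sample / variant,
never silently dropping samples: sample and site counts; the fraction
of sites at positions used by any tree edge variant (< 0.5 warns —
array data legitimately has modest overlap); monomorphic sites (≤ 1
distinct called genotype); sites whose REF disagrees with the tree
reference base (fail — wrong build), and among those, strand-flip
suspects where REF and ALT equal the complements of the reference base
and a tree-known alternate; per-sample and per-variant call rates
(< 0.9 warn, < 0.5 fail). A zero-site file blocks classification.

## Synthetic data

The generator emulates the structure of mtDNA phylogeny packages, not
human mutation-rate realism: random rooted topologies (default 40
nodes, depth ≤ 6) over a random reference of rCRS length (16,569 bp),
1–3 defining variants per edge drawn without position collisions (10%
indels, right-aligned at birth), back mutations of ancestral variants
at rate 0.05, clusters = the root's children, random integer weights
for 80% of variants (the rest exercise the default), five hotspot
positions and one rewrite rule on otherwise unused positions. Samples
are planted at random non-root nodes with Poisson(0.5) private
substitutions at unused positions and emitted consistently as hsd, VCF
(one record per distinct variant, haploid genotypes, optional random
masking) and FASTA (the actual mutated sequence, so the
alignment/variant-calling path is exercised end to end), plus a ground
truth table. All randomness derives from the spec seed through explicit
`random.Random` streams, making packages byte-identical across
platforms. Because planted profiles are exact subsets of tree profiles
and private variants avoid tree positions, recovery tests certify the
engine's bookkeeping, not its robustness to the correlated noise,
contamination or mapping artefacts of real sequencing data.

Where an acceptance-style check states its own scale (100-node tree,
500 random indels, 50 cross-format samples, 1,000 random weighted
sets), the tests and `scripts/acceptance.py` use that scale; other
fixtures use smaller trees (15–50 nodes, 1.5–4 kb references) chosen
to keep the default suite fast while still containing every structural
feature (back mutations, indels, hotspots, default weights).

## Design choices and limitations

* Tree package schema (nested-XML with a flat-TSV alternative, file
  names, rule syntax) is defined by this package; published trees use
  other schemas and would need conversion.
* A sample with zero variants on a full range is classified to the
  reference (root) haplotype with an explicit warning rather than
  rejected; reference-identical samples are genuinely ambiguous.
* Hotspots are excluded from tree distance as well as from scoring,
  keeping the two consistent.
* `quality_flag` takes an explicit `full_range` argument because a hit
  alone cannot know the sample's coverage.
* Annotation is a generic TSV join keyed by (POS, ALT) — `-` for
  deletions — and is pure decoration; it never changes qualities or
  orderings.
* The CLI `server` subcommand is a stub: the artifact is the engine
  and its library API, not a web application.
* Heteroplasmy metadata is excluded from variant identity, so observed
  and expected variants compare as events; levels survive on the
  profile for reporting.
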