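"""Sample input parsing (hsd, VCF, FASTA) and TSV exports."""

import random

import pytest

from haplocall.classify import classify_sample
from haplocall.fixtures import SimulationSpec, build_tree, make_samples
from haplocall.profiles_io import (
    ProfileParseError,
    SampleProfile,
    VcfOptions,
    derive_chip_range,
    detect_format,
    parse_fasta,
    parse_hsd,
    parse_vcf,
    write_hsd,
    write_results_tsv,
)
from haplocall.variants import Range, Variant, SUBSTITUTION


class TestHsd:
    def test_canonical_line(self):
        (p,) = parse_hsd("S1\t1-16569\t?\t263G\t8860G\n")
        assert p.id == "S1"
        assert p.range == Range.parse("1-16569")
        assert {v.render() for v in p.variants} == {"263G", "8860G"}

    def test_control_region_multi_interval(self):
        (p,) = parse_hsd("S2\t16024-16569;1-576\t?\t16189C\n")
        assert len(p.range.intervals) == 2
        assert p.range.contains(100) and not p.range.contains(1000)

    def test_header_is_optional(self):
        text = "SampleID\tRange\tHaplogroup\tPolymorphisms\nS1\t1-100\t?\t73G\n"
        assert [p.id for p in parse_hsd(text)] == ["S1"]

    def test_malformed_token_is_warning_not_error(self):
        (p,) = parse_hsd("S1\t1-16569\t?\t263G\tBOGUS\n")
        assert {v.render() for v in p.variants} == {"263G"}
        assert any("BOGUS" in w for w in p.warnings)

    def test_duplicate_ids_fatal(self):
        with pytest.raises(ProfileParseError, match="S1"):
            parse_hsd("S1\t1-100\t?\t73G\nS1\t1-100\t?\t73G\n")

    def test_empty_input_gives_empty_batch(self):
        assert parse_hsd("") == []

    def test_round_trip_identity_on_random_profiles(self):
        """write_hsd(parse_hsd(x)) re-parsed equals the originals."""
        rng = random.Random(3)
        profiles = []
        for i in range(100):
            variants = frozenset(
                Variant(
                    position=rng.randint(1, 16569),
                    kind=SUBSTITUTION,
                    alt=rng.choice("ACGT"),
                )
                for _ in range(rng.randint(0, 8))
            )
            profiles.append(
                SampleProfile(
                    id=f"R{i}", range=Range.parse("1-16569"), variants=variants
                )
            )
        reparsed = parse_hsd(write_hsd(profiles))
        assert len(reparsed) == len(profiles)
        for a, b in zip(profiles, reparsed):
            assert (a.id, a.range, a.variants) == (b.id, b.range, b.variants)


class TestChipRange:
    def test_adjacency_merge(self):
        assert derive_chip_range([263, 264, 750]).intervals == (
            (263, 264),
            (750, 750),
        )

    def test_singleton(self):
        assert derive_chip_range([73]).intervals == ((73, 73),)

    def test_empty_errors(self):
        with pytest.raises(ProfileParseError):
            derive_chip_range([])

    def test_membership_matches_site_list(self):
        rng = random.Random(11)
        sites = rng.sample(range(1, 16570), 500)
        chip = derive_chip_range(sites)
        site_set = set(sites)
        for pos in list(site_set)[:100] + rng.sample(range(1, 16570), 200):
            assert chip.contains(pos) == (pos in site_set)


VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "##contig=<ID=chrM,length={length}>\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    '##FORMAT=<ID=AF,Number=1,Type=Float,Description="Allele fraction">\n'
)


def write_vcf_text(tmp_path, body, length=16569, samples=("S1",)):
    path = tmp_path / "in.vcf"
    header = VCF_HEADER.format(length=length)
    header += (
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples)
        + "\n"
    )
    path.write_text(header + body)
    return path


class TestVcf:
    def test_plain_substitutions(self, tmp_path):
        path = write_vcf_text(
            tmp_path,
            "chrM\t263\t.\tA\tG\t.\tPASS\t.\tGT\t1\n"
            "chrM\t8860\t.\tA\tG\t.\tPASS\t.\tGT\t1\n",
        )
        (p,) = parse_vcf(path, VcfOptions(), "A" * 16569)
        assert {v.render() for v in p.variants} == {"263G", "8860G"}
        assert p.range.covers_full(16569)

    def test_heteroplasmy_below_threshold_dropped(self, tmp_path):
        path = write_vcf_text(
            tmp_path, "chrM\t263\t.\tA\tG\t.\tPASS\t.\tGT:AF\t1:0.3\n"
        )
        (p,) = parse_vcf(
            path, VcfOptions(het_threshold=0.9, het_handling="drop"), "A" * 16569
        )
        assert p.variants == frozenset()

    def test_heteroplasmy_keep_records_level(self, tmp_path):
        path = write_vcf_text(
            tmp_path, "chrM\t263\t.\tA\tG\t.\tPASS\t.\tGT:AF\t1:0.3\n"
        )
        (p,) = parse_vcf(
            path, VcfOptions(het_threshold=0.9, het_handling="keep"), "A" * 16569
        )
        (v,) = p.variants
        assert v.render() == "263G"
        assert v.heteroplasmy_level == pytest.approx(0.3)

    def test_missing_genotype_not_a_variant(self, tmp_path):
        path = write_vcf_text(
            tmp_path,
            "chrM\t263\t.\tA\tG\t.\tPASS\t.\tGT\t.\t1\n",
            samples=("S1", "S2"),
        )
        a, b = parse_vcf(path, VcfOptions(), "A" * 16569)
        assert a.variants == frozenset()
        assert {v.render() for v in b.variants} == {"263G"}

    def test_contig_length_mismatch_fatal(self, tmp_path):
        path = write_vcf_text(
            tmp_path, "chrM\t263\t.\tA\tG\t.\tPASS\t.\tGT\t1\n", length=999
        )
        with pytest.raises(ProfileParseError, match="chrM"):
            parse_vcf(path, VcfOptions(), "A" * 16569)

    def test_array_mode_range_is_typed_sites_only(self, tmp_path):
        path = write_vcf_text(
            tmp_path,
            "chrM\t263\t.\tA\tG\t.\tPASS\t.\tGT\t1\n"
            "chrM\t750\t.\tA\tG\t.\tPASS\t.\tGT\t0\n",
        )
        (p,) = parse_vcf(path, VcfOptions(mode="array"), "A" * 16569)
        assert p.range.contains(263) and p.range.contains(750)
        assert not p.range.contains(264)

    def test_generator_round_trip(self, tmp_path):
        """A VCF generated from known profiles parses back to them."""
        spec = SimulationSpec(
            n_haplogroups=20, n_samples=20, reference_length=3000, seed=13
        )
        tree = build_tree(spec)
        batch = make_samples(tree, spec, tmp_path)
        parsed = parse_vcf(batch.vcf_path, VcfOptions(), tree.reference)
        assert len(parsed) == 20
        for p in parsed:
            assert p.variants == batch.profiles[p.id]

    def test_record_order_irrelevant(self, tmp_path):
        body = [
            "chrM\t263\t.\tA\tG\t.\tPASS\t.\tGT\t1\n",
            "chrM\t8860\t.\tA\tG\t.\tPASS\t.\tGT\t1\n",
        ]
        p1 = parse_vcf(
            write_vcf_text(tmp_path, "".join(body)), VcfOptions(), "A" * 16569
        )
        p2 = parse_vcf(
            write_vcf_text(tmp_path, "".join(body[::-1])),
            VcfOptions(),
            "A" * 16569,
        )
        assert p1[0].variants == p2[0].variants


class TestFasta:
    def test_identity_sequence_has_no_variants(self, synthetic_tree, tmp_path):
        ref = synthetic_tree.reference
        path = tmp_path / "in.fasta"
        path.write_text(f">S1\n{ref}\n")
        (p,) = parse_fasta(path, ref)
        assert p.variants == frozenset()
        assert p.range.covers_full(len(ref))

    def test_single_substitution_called(self, synthetic_tree, tmp_path):
        ref = synthetic_tree.reference
        alt = "G" if ref[262] != "G" else "A"
        seq = ref[:262] + alt + ref[263:]
        path = tmp_path / "in.fasta"
        path.write_text(f">S1\n{seq}\n")
        (p,) = parse_fasta(path, ref)
        assert {v.render() for v in p.variants} == {f"263{alt}"}

    def test_partial_sequence_range_is_covered_span(self, synthetic_tree, tmp_path):
        ref = synthetic_tree.reference
        seq = ref[1000:1545]  # 545 bp slice, positions 1001..1545
        path = tmp_path / "in.fasta"
        path.write_text(f">S1\n{seq}\n")
        (p,) = parse_fasta(path, ref)
        assert p.variants == frozenset()
        assert p.range.contains(1001) and p.range.contains(1545)
        assert not p.range.contains(900) and not p.range.contains(1700)

    def test_low_identity_flagged(self, synthetic_tree, tmp_path):
        rng = random.Random(1)
        junk = "".join(rng.choice("ACGT") for _ in range(300))
        path = tmp_path / "in.fasta"
        path.write_text(f">S1\n{junk}\n")
        (p,) = parse_fasta(path, synthetic_tree.reference)
        assert p.flagged

    def test_n_positions_excluded_from_range(self, synthetic_tree, tmp_path):
        ref = synthetic_tree.reference
        seq = ref[:499] + "N" + ref[500:]
        path = tmp_path / "in.fasta"
        path.write_text(f">S1\n{seq}\n")
        (p,) = parse_fasta(path, ref)
        assert not p.range.contains(500)
        assert p.variants == frozenset()


class TestExports:
    def test_perfect_match_row(self, synthetic_tree):
        node = sorted(synthetic_tree.nodes)[5]
        profile = SampleProfile(
            id="P1",
            range=Range.full(synthetic_tree.reference_length),
            variants=synthetic_tree.expected_profile(node),
        )
        result = classify_sample(synthetic_tree, profile)
        text = write_results_tsv([result], synthetic_tree)
        header, row = text.strip().split("\n")
        fields = dict(zip(header.split("\t"), row.split("\t")))
        assert fields["Quality"] == "1.0000"
        assert fields["Remaining"] == "0"
        assert fields["Haplogroup"] == node

    def test_empty_batch_header_only(self):
        assert write_results_tsv([]).strip().count("\n") == 0

    def test_constant_column_count(self, synthetic_tree, sample_batch):
        profiles = parse_hsd(sample_batch.hsd_path.read_text())
        results = [classify_sample(synthetic_tree, p) for p in profiles]
        lines = write_results_tsv(results, synthetic_tree).strip().split("\n")
        widths = {len(line.split("\t")) for line in lines}
        assert widths == {9}


def test_format_autodetection(tmp_path, sample_batch):
    assert detect_format(sample_batch.vcf_path) == "vcf"
    assert detect_format(sample_batch.fasta_path) == "fasta"
    assert detect_format(sample_batch.hsd_path) == "hsd"
    sniffed = tmp_path / "data.txt"
    sniffed.write_text("##fileformat=VCFv4.2\n")
    assert detect_format(sniffed) == "vcf"
    sniffed.write_text(">rec\nACGT\n")
    assert detect_format(sniffed) == "fasta"
    sniffed.write_text("S1\t1-100\t?\t73G\n")
    assert detect_format(sniffed) == "hsd"
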