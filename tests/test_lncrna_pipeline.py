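"""lncRNA catalog filtering, ORF scoring, TE annotation and conservation."""

import numpy as np
import pytest

from teconsex.errors import UndefinedStatisticError, ValidationError
from teconsex.lncrna_pipeline import (
    LncTranscript,
    TargetReads,
    annotate_te_overlap,
    build_lncrna_catalog,
    contribution_stats,
    lncrna_conservation,
    orf_coding_score,
    percent_of,
    read_transcripts_gtf,
    reference_overlap,
    write_catalog_gtf,
)
from teconsex.orthology_lift import Chain, ChainBlock
from conftest import make_instance


def tx(tid, exons, biotype=None, cp=None, seq=None, chrom="chr1", strand="+"):
    return LncTranscript(
        transcript_id=tid, chrom=chrom, strand=strand, exons=list(exons),
        biotype=biotype, coding_potential=cp, sequence=seq,
    )


class TestOrfCodingScore:
    def test_no_atg_scores_zero(self):
        assert orf_coding_score("CCCCCCCCTAACCC") == 0.0

    def test_full_orf_scores_one(self):
        assert orf_coding_score("ATGAAATAA") == 1.0

    def test_start_without_stop_does_not_count(self):
        assert orf_coding_score("ATGAAAAAA") == 0.0

    def test_empty_and_bad_alphabet(self):
        with pytest.raises(ValidationError):
            orf_coding_score("")
        with pytest.raises(ValidationError):
            orf_coding_score("ATGXXX")

    def test_matches_exhaustive_scan(self, rng):
        """Independent oracle: enumerate every (ATG, in-frame stop) pair."""

        def oracle(seq):
            stops = ("TAA", "TAG", "TGA")
            best = 0
            for i in range(len(seq) - 2):
                if seq[i : i + 3] != "ATG":
                    continue
                for k in range(i + 3, len(seq) - 2, 3):
                    if seq[k : k + 3] in stops:
                        best = max(best, k + 3 - i)
                        break
            return best / len(seq)

        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=300))
            assert orf_coding_score(seq) == pytest.approx(oracle(seq))


class TestCatalogCascade:
    def build_fixture(self):
        """10 transcripts: 3 coding-biotype, 2 mono-exonic, 1 high potential."""
        return [
            tx("c1", [(0, 100), (200, 300)], biotype="protein_coding"),
            tx("c2", [(400, 500), (600, 700)], biotype="protein_coding"),
            tx("c3", [(800, 900), (1000, 1100)], biotype="processed_pseudogene"),
            tx("m1", [(1200, 1500)]),
            tx("m2", [(1600, 1900)], cp=0.0),
            tx("h1", [(2000, 2100), (2200, 2300)], cp=0.9),
            tx("k1", [(2400, 2500), (2600, 2700)], cp=0.1),
            tx("k2", [(2800, 2900), (3000, 3100)], cp=0.0),
            tx("k3", [(3200, 3300), (3400, 3500)], seq="CCCTAACCCTAA" * 20),
            tx("k4", [(3600, 3700), (3800, 3900)], cp=0.3),
        ]

    def test_retains_four_and_counts_sum(self):
        result = build_lncrna_catalog(self.build_fixture(), coding_potential_cutoff=0.5)
        assert sorted(t.transcript_id for t in result.catalog) == ["k1", "k2", "k3", "k4"]
        c = result.counts
        assert c["retained"] == 4
        removed = (
            c["removed_biotype"] + c["removed_mono_exonic"]
            + c["removed_coding_potential"] + c["removed_unscoreable"]
        )
        assert c["input"] - removed == c["retained"]
        assert (c["removed_biotype"], c["removed_mono_exonic"],
                c["removed_coding_potential"]) == (3, 2, 1)

    def test_mono_exonic_removed_even_with_zero_potential(self):
        result = build_lncrna_catalog([tx("m", [(0, 300)], cp=0.0)])
        assert result.catalog == [] and result.counts["removed_mono_exonic"] == 1

    def test_unscoreable_removed_with_warning(self):
        result = build_lncrna_catalog([tx("u", [(0, 100), (200, 300)])])
        assert result.counts["removed_unscoreable"] == 1

    def test_cutoff_boundary_inclusive(self):
        result = build_lncrna_catalog(
            [tx("b", [(0, 100), (200, 300)], cp=0.364)], coding_potential_cutoff=0.364
        )
        assert result.catalog == []


class TestTEOverlapAnnotation:
    def test_ten_percent_boundary(self):
        catalog = [tx("t", [(0, 100)])]
        counted = annotate_te_overlap(catalog, [make_instance(start=90, end=300)])
        assert counted[0].has_te  # 10 bp of a 100 bp exon: boundary counts
        missed = annotate_te_overlap(catalog, [make_instance(start=91, end=300)])
        assert not missed[0].has_te  # 9 bp: below the threshold

    def test_dominant_is_largest_total_overlap(self):
        catalog = [tx("t", [(0, 500)])]
        tes = [
            make_instance("teA", start=0, end=120, family="FamA"),
            make_instance("teB", start=200, end=280, family="FamB"),
        ]
        ann = annotate_te_overlap(catalog, tes)[0]
        assert ann.dominant_instance == "teA" and ann.dominant_family == "FamA"

    def test_zero_fraction_equals_any_overlap_oracle(self, rng):
        exons = []
        p = 0
        for _ in range(5):
            p += int(rng.integers(50, 200))
            q = p + int(rng.integers(50, 300))
            exons.append((p, q))
            p = q
        catalog = [tx("t", exons)]
        tes = []
        for i in range(30):
            a = int(rng.integers(0, p))
            tes.append(make_instance(f"te{i}", start=a, end=a + int(rng.integers(10, 400))))
        ann = annotate_te_overlap(catalog, tes, min_exon_fraction=0.0)[0]
        got = {(o.te_instance_id, o.exon_index) for o in ann.overlaps}
        expected = {
            (te.instance_id, k)
            for te in tes
            for k, (es, ee) in enumerate(exons)
            if te.start < ee and te.end > es
        }
        assert got == expected


class TestContribution:
    def test_class_proportion(self):
        catalog = [tx("t", [(0, 1000)])]
        te = make_instance("te1", start=100, end=500, te_class="LTR", family="FamL")
        ann = annotate_te_overlap(catalog, [te])
        stats = contribution_stats(ann, catalog, [te], genome_length=100_000)
        row = stats.class_table.set_index("te_class").loc["LTR"]
        assert row["lncrna_proportion"] == pytest.approx(0.4)

    def test_normalized_contribution(self):
        # family occupies 1% of the genome and 2% of lncRNA exonic bp
        catalog = [tx("t", [(0, 1000)])]
        te = make_instance("te1", start=0, end=20, te_class="DNA", family="FamD",
                           length_bp=100)
        ann = annotate_te_overlap(catalog, [te], min_exon_fraction=0.0)
        stats = contribution_stats(ann, catalog, [te], genome_length=10_000)
        row = stats.family_table.set_index("family").loc["FamD"]
        assert row["normalized_contribution"] == pytest.approx(
            (20 / 1000) / (100 / 10_000)
        )

    def test_overlapping_annotations_not_double_counted(self):
        catalog = [tx("t", [(0, 1000)])]
        tes = [
            make_instance("a", start=0, end=400, te_class="LTR", family="F1"),
            make_instance("b", start=200, end=600, te_class="LTR", family="F2"),
        ]
        ann = annotate_te_overlap(catalog, tes)
        stats = contribution_stats(ann, catalog, tes, genome_length=10_000)
        assert stats.class_table.set_index("te_class").loc["LTR", "lncrna_bp"] == 600
        raw = contribution_stats(ann, catalog, tes, genome_length=10_000,
                                 allow_double_count=True)
        assert raw.class_table.set_index("te_class").loc["LTR", "lncrna_bp"] == 800

    def test_class_proportions_sum_below_one(self, small_dataset):
        from teconsex import repeat_catalog as rc
        from Bio import SeqIO

        sp = small_dataset.species[0]
        seqs = {r.id: str(r.seq) for r in SeqIO.parse(small_dataset.files["fasta"][sp], "fasta")}
        transcripts = read_transcripts_gtf(small_dataset.files["gtf"][sp], seqs)
        catalog = build_lncrna_catalog(transcripts).catalog
        tes = rc.join_nested_repeats(
            rc.parse_repeatmasker_out(small_dataset.files["repeats"][sp])
        )
        ann = annotate_te_overlap(catalog, tes)
        stats = contribution_stats(ann, catalog, tes,
                                   small_dataset.config.genome_length)
        assert stats.class_table["lncrna_proportion"].sum() <= 1.0 + 1e-12

    def test_no_overlapping_transcripts_is_undefined(self):
        catalog = [tx("t", [(0, 100), (200, 300)])]
        ann = annotate_te_overlap(catalog, [])
        with pytest.raises(UndefinedStatisticError):
            contribution_stats(ann, catalog, [], genome_length=1000)


class TestReferenceOverlap:
    def test_trivial_cases(self):
        cat = [tx("a", [(0, 100), (200, 300)])]
        assert reference_overlap(cat, cat) == 1.0
        far = [tx("r", [(10_000, 10_100), (10_200, 10_300)])]
        assert reference_overlap(cat, far) == 0.0
        with pytest.raises(UndefinedStatisticError):
            reference_overlap([], cat)

    def test_strand_aware_and_planted_fraction(self):
        catalog = [
            tx(f"t{i}", [(1000 * i, 1000 * i + 100), (1000 * i + 200, 1000 * i + 300)])
            for i in range(10)
        ]
        # reference hits 9 of 10 on the same strand; the last only antisense
        reference = [
            tx(f"r{i}", [(1000 * i + 50, 1000 * i + 80)]) for i in range(9)
        ] + [tx("r9", [(9000, 9100)], strand="-")]
        assert reference_overlap(catalog, reference) == pytest.approx(0.9)


def test_percent_formatting_matches_published_lift_table():
    """Published lifted/TE/expressed counts reproduce the printed percentages."""
    assert percent_of(5175, 7479) == 69.19
    assert percent_of(2103, 7479) == 28.12
    assert percent_of(2086, 6709) == 31.09
    assert percent_of(70, 100) == 70.0


def test_gtf_round_trip(tmp_path):
    catalog = [
        tx("t1", [(100, 250), (400, 600)]),
        tx("t2", [(1000, 1100), (1300, 1500), (1700, 1800)]),
    ]
    path = tmp_path / "cat.gtf"
    write_catalog_gtf(catalog, path)
    back = read_transcripts_gtf(path)
    assert [(t.transcript_id, t.exons) for t in back] == [
        ("t1", [(100, 250), (400, 600)]),
        ("t2", [(1000, 1100), (1300, 1500), (1700, 1800)]),
    ]
    assert all(t.biotype == "lncRNA" for t in back)


class TestLncrnaConservation:
    def make_world(self):
        """Two transcripts on an identity chain; one expressed in the target."""
        catalog = [
            tx("expr", [(100, 250), (400, 600)]),
            tx("silent", [(2000, 2150), (2300, 2500)]),
        ]
        chain = Chain(
            chain_id=1, score=10_000, source_chrom="chr1", source_size=10_000,
            source_start=0, source_end=10_000, target_chrom="chr1",
            target_size=10_000, target_strand="+", target_start=0,
            target_end=10_000, blocks=[ChainBlock(10_000)],
        )
        reads = [("chr1", 100 + i, 200 + i) for i in range(50)]
        treads = TargetReads(reads_per_replicate=[reads], library_sizes=[10_000])
        tes = [make_instance("te1", start=90, end=300, family="FamA")]
        return catalog, {"sp2": [chain]}, {"sp2": treads}, {"sp2": tes}

    def test_counts_percentages_and_tiers(self):
        catalog, chains, reads, tes = self.make_world()
        table, tiers = lncrna_conservation(catalog, chains, reads, tes)
        row = table.iloc[0]
        assert row["n_lifted"] == 2
        assert row["n_lifted_te"] == 1  # only "expr" overlaps the TE
        assert row["n_lifted_expressed"] == 1
        assert row["pct_lifted_expressed"] == 50.0
        assert tiers == {"expr": "all_species", "silent": "query_only"}

    def test_tier_partition(self, small_dataset, tmp_path):
        from teconsex.pipeline import config_from_dataset, run_pipeline

        pc = config_from_dataset(small_dataset, tmp_path / "out")
        result = run_pipeline(pc)
        tiers = result.tiers
        assert len(tiers) == len(result.catalog_result.catalog)
        assert set(tiers.values()) <= {"all_species", "some_nhp", "query_only"}
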