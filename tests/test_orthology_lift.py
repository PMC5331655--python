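"""Chain parsing and interval lifting, including the per-base brute-force oracle."""

import io

import numpy as np
import pytest

from teconsex.errors import ParseError, UndefinedStatisticError, ValidationError
from teconsex.orthology_lift import (
    Chain,
    ChainBlock,
    LiftStatus,
    classify_conservation,
    lift_interval,
    parse_chain,
    reannotation_concordance,
    write_chains,
)
from conftest import make_instance


def identity_chain(size=1000, chain_id=1, score=1000):
    return Chain(
        chain_id=chain_id,
        score=score,
        source_chrom="chr1",
        source_size=size,
        source_start=0,
        source_end=size,
        target_chrom="chr1",
        target_size=size,
        target_strand="+",
        target_start=0,
        target_end=size,
        blocks=[ChainBlock(size)],
    )


def make_chain(blocks, source_start=0, target_start=0, strand="+", chain_id=1,
               score=100, source_chrom="chr1", target_chrom="chrT", extra=500):
    aligned = sum(b.size for b in blocks)
    sgap = sum(b.source_gap for b in blocks)
    tgap = sum(b.target_gap for b in blocks)
    source_end = source_start + aligned + sgap
    target_end = target_start + aligned + tgap
    return Chain(
        chain_id=chain_id,
        score=score,
        source_chrom=source_chrom,
        source_size=source_end + extra,
        source_start=source_start,
        source_end=source_end,
        target_chrom=target_chrom,
        target_size=target_end + extra,
        target_strand=strand,
        target_start=target_start,
        target_end=target_end,
        blocks=blocks,
    )


def base_map(chain):
    """Brute-force per-base coordinate map by enumerating aligned base pairs."""
    mapping = {}
    s, t = chain.source_start, chain.target_start
    for b in chain.blocks:
        for k in range(b.size):
            mapping[s + k] = t + k
        s += b.size + b.source_gap
        t += b.size + b.target_gap
    return mapping


def oracle_lift(chain, start, end):
    """Mapped base count and chain-orientation first/last target positions."""
    mapping = base_map(chain)
    hits = [mapping[p] for p in range(start, end) if p in mapping]
    if not hits:
        return 0, None, None
    return len(hits), min(hits), max(hits)


class TestParseChain:
    def test_single_block_identity(self, tmp_path):
        text = "chain 1000 chr1 1000 + 0 1000 chr1 1000 + 0 1000 1\n1000\n"
        chains = parse_chain(io.StringIO(text))
        assert len(chains) == 1
        assert chains[0].blocks == [ChainBlock(1000)]

    def test_interior_gap_sums_verified(self):
        text = "chain 900 chr1 2000 + 0 1050 chrT 2000 + 100 1100 7\n500 50 0\n500\n"
        chain = parse_chain(io.StringIO(text))[0]
        assert chain.chain_id == 7
        assert sum(b.size for b in chain.blocks) == 1000

    def test_block_sum_mismatch_names_chain(self):
        text = "chain 900 chr1 2000 + 0 1000 chrT 2000 + 0 1000 9\n500 50 0\n500\n"
        with pytest.raises(ParseError, match="chain 9"):
            parse_chain(io.StringIO(text))

    def test_empty_file(self):
        assert parse_chain(io.StringIO("")) == []

    def test_round_trip(self, tmp_path):
        chain = make_chain([ChainBlock(50, 10, 0), ChainBlock(40, 0, 25), ChainBlock(60)],
                           source_start=30, target_start=70, strand="-")
        path = tmp_path / "t.chain"
        write_chains([chain], path)
        back = parse_chain(path)[0]
        assert back.blocks == chain.blocks
        assert (back.target_strand, back.target_start, back.target_end) == (
            "-", chain.target_start, chain.target_end
        )


class TestLiftInterval:
    def test_identity(self):
        res = lift_interval(("chr1", 100, 200), [identity_chain()])
        assert res.status is LiftStatus.MAPPED
        assert (res.target_start, res.target_end) == (100, 200)
        assert res.mapped_ratio == 1.0

    def test_below_min_match(self):
        # only [195, 200) of the interval is inside an aligned block
        chain = make_chain([ChainBlock(100)], source_start=195, target_start=0)
        res = lift_interval(("chr1", 100, 200), [chain], min_match=0.1)
        assert res.status is LiftStatus.UNMAPPED_BELOW_MINMATCH
        assert res.mapped_bases == 5
        assert res.mapped_ratio == pytest.approx(0.05)

    def test_target_gap_stretches_interval(self):
        # [100,150) then a 30 bp target gap then [150,200): lifted length 130
        chain = make_chain(
            [ChainBlock(50, 0, 30), ChainBlock(50)], source_start=100, target_start=500
        )
        res = lift_interval(("chr1", 100, 200), [chain])
        assert res.mapped
        assert res.mapped_bases == 100
        assert res.target_end - res.target_start == 130
        assert (res.target_start, res.target_end) == (500, 630)

    def test_negative_strand_forward_coordinates(self):
        # one block of 100 at chain-orientation target [40, 140) on '-' of a
        # 1000 bp chromosome: forward coords are [1000-140, 1000-40)
        chain = make_chain([ChainBlock(100)], source_start=200, target_start=40,
                           strand="-", extra=860)
        res = lift_interval(("chr1", 200, 300), [chain])
        assert res.mapped and res.target_strand == "-"
        size = chain.target_size
        assert (res.target_start, res.target_end) == (size - 140, size - 40)

    def test_no_chain_and_zero_length(self):
        assert (
            lift_interval(("chrX", 0, 10), [identity_chain()]).status
            is LiftStatus.UNMAPPED_NO_CHAIN
        )
        with pytest.raises(ValidationError):
            lift_interval(("chr1", 5, 5), [identity_chain()])

    def test_best_chain_by_mapped_bases_then_score(self):
        big = make_chain([ChainBlock(1000)], chain_id=1, score=10, target_chrom="chrA")
        small = make_chain([ChainBlock(50)], source_start=100, chain_id=2, score=99,
                           target_chrom="chrB")
        res = lift_interval(("chr1", 100, 200), [small, big])
        assert res.chain_id == 1 and res.target_chrom == "chrA"

    def test_tied_chains_to_different_loci_are_ambiguous(self):
        c1 = make_chain([ChainBlock(1000)], chain_id=1, score=50, target_start=0)
        c2 = make_chain([ChainBlock(1000)], chain_id=2, score=50, target_start=5000)
        res = lift_interval(("chr1", 100, 200), [c1, c2])
        assert res.status is LiftStatus.AMBIGUOUS

    def test_min_match_monotonicity(self):
        chain = make_chain([ChainBlock(30, 40, 0), ChainBlock(30)], source_start=100)
        interval = ("chr1", 100, 200)
        statuses = [
            lift_interval(interval, [chain], m).status for m in (0.9, 0.6, 0.3, 0.1, 0.01)
        ]
        seen_mapped = False
        for status in statuses:  # decreasing minMatch can only unlock mapping
            if status is LiftStatus.MAPPED:
                seen_mapped = True
            else:
                assert not seen_mapped
        assert statuses[-1] is LiftStatus.MAPPED


def random_chain(rng, n_blocks=None, strand=None):
    n = int(n_blocks if n_blocks is not None else rng.integers(1, 40))
    blocks = []
    for i in range(n):
        size = int(rng.integers(1, 60))
        if i == n - 1:
            blocks.append(ChainBlock(size))
        else:
            blocks.append(ChainBlock(size, int(rng.integers(0, 30)), int(rng.integers(0, 30))))
    return make_chain(
        blocks,
        source_start=int(rng.integers(0, 500)),
        target_start=int(rng.integers(0, 500)),
        strand=strand if strand is not None else ("+" if rng.random() < 0.5 else "-"),
    )


def test_lift_matches_per_base_oracle(rng):
    """Randomized chains: mapped bases and target span equal the brute-force map."""
    for _ in range(60):
        chain = random_chain(rng)
        start = int(rng.integers(0, chain.source_end + 20))
        end = start + int(rng.integers(1, 300))
        res = lift_interval(("chr1", start, end), [chain], min_match=1e-9)
        mapped, t_first, t_last = oracle_lift(chain, start, end)
        if mapped == 0:
            assert res.status is LiftStatus.UNMAPPED_NO_CHAIN
            continue
        assert res.mapped_bases == mapped
        if chain.target_strand == "-":
            expected = (chain.target_size - (t_last + 1), chain.target_size - t_first)
        else:
            expected = (t_first, t_last + 1)
        assert (res.target_start, res.target_end) == expected


class TestConservationRecords:
    def test_planted_retained_and_lost(self):
        query = [
            make_instance("q1", start=100, end=300, family="FamA"),
            make_instance("q2", start=2000, end=2200, family="FamA"),
        ]
        # chain aligns [0, 1000) only: q1 lifts, q2 has no chain coverage
        chain = make_chain([ChainBlock(1000)], target_chrom="chr1")
        target = [make_instance("t1", start=100, end=300, family="FamA")]
        records = classify_conservation(query, [chain], target)
        by_id = {r.instance_id: r for r in records}
        assert by_id["q1"].lifted and by_id["q1"].te_annotated_in_target
        assert by_id["q1"].same_family_in_target
        assert not by_id["q2"].lifted

    def test_annotated_but_different_family(self):
        query = [make_instance("q1", start=100, end=300, family="FamA")]
        chain = make_chain([ChainBlock(1000)], target_chrom="chr1")
        target = [make_instance("t1", start=150, end=400, family="FamB")]
        rec = classify_conservation(query, [chain], target)[0]
        assert rec.te_annotated_in_target and not rec.same_family_in_target

    def test_concordance_fraction_and_undefined(self):
        query = [
            make_instance(f"q{k}", start=1000 * k, end=1000 * k + 100, family="FamA")
            for k in range(1, 11)
        ]
        chain = make_chain([ChainBlock(20000)], target_chrom="chr1")
        target = [
            make_instance(
                f"t{k}", start=1000 * k, end=1000 * k + 100,
                family="FamA" if k > 1 else "Other",
            )
            for k in range(1, 11)
        ]
        records = classify_conservation(query, [chain], target)
        assert reannotation_concordance("FamA", records) == pytest.approx(0.9)
        with pytest.raises(UndefinedStatisticError):
            reannotation_concordance("Absent", records)


def test_flag_implications_on_synthetic_data(small_dataset):
    """teAnnotated implies lifted; sameFamily implies teAnnotated — on a full run."""
    from teconsex import repeat_catalog as rc
    from teconsex.orthology_lift import parse_chain as pc

    target = small_dataset.species[1]
    q = rc.join_nested_repeats(
        rc.parse_repeatmasker_out(small_dataset.files["repeats"][small_dataset.species[0]])
    )
    t = rc.join_nested_repeats(
        rc.parse_repeatmasker_out(small_dataset.files["repeats"][target])
    )
    chains = pc(small_dataset.files["chains"][target])
    records = classify_conservation(q, chains, t)
    for rec in records:
        assert rec.lifted or not rec.te_annotated_in_target
        assert rec.te_annotated_in_target or not rec.same_family_in_target


def test_lifted_fraction_matches_planted_loss(rng):
    """Family with per-branch loss 0.1 lifts ~90% of instances (3 binomial SE)."""
    import tempfile

    from teconsex.synthetic_data import FamilySpec, SimConfig, simulate_dataset
    from teconsex import repeat_catalog as rc

    config = SimConfig(
        seed=5,
        n_species=2,
        genome_length=1_500_000,
        families=[FamilySpec("Fam", "LTR", 400, 10.0, 0.1, 0.3, 0.5)],
        n_reads_per_replicate=0,
        replicates_per_species=[1, 1],
        lncrna_count=0,
        coding_gene_count=0,
        coding_overlap_fraction=0.0,
        te_overlap_fraction=0.0,
    )
    with tempfile.TemporaryDirectory() as tmp:
        ds = simulate_dataset(config, tmp)
        q = rc.join_nested_repeats(
            rc.parse_repeatmasker_out(ds.files["repeats"]["species1"])
        )
        t = rc.join_nested_repeats(
            rc.parse_repeatmasker_out(ds.files["repeats"]["species2"])
        )
        chains = parse_chain(ds.files["chains"]["species2"])
        records = classify_conservation(q, chains, t)
    frac = sum(r.lifted for r in records) / len(records)
    se = np.sqrt(0.9 * 0.1 / 400)
    assert abs(frac - 0.9) <= 3 * se
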