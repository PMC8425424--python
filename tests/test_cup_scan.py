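"""Round-trip classification and the genome scan (both modes)."""

import pytest

import cupscan as cs
from cupscan.cup_scan import (
    CupCategory,
    classify_position,
    merge_category_regions,
    scan_genome,
)
from cupscan.regions import RegionSet
from conftest import assert_scans_equal, mixed_script


def test_identity_chains_give_stable_everywhere(identity_realization):
    r = identity_realization
    for pos in (0, 1, 500, 999):
        assert classify_position(r.fwd, r.rev, "chrA", pos) is CupCategory.STABLE
    res = scan_genome(r.fwd, r.rev, r.source_sizes, mode="interval")
    assert res.regions[CupCategory.STABLE].total_bp == 1000
    assert res.fractions[CupCategory.STABLE] == 1.0


def test_single_deletion_is_reject1_rest_stable():
    r = cs.realize(cs.RearrangementScript({"chr1": 1000}, (cs.Delete("chr1", 100, 150),)))
    res = scan_genome(r.fwd, r.rev, r.source_sizes, mode="per_base")
    assert res.regions[CupCategory.REJECT_1].intervals("chr1") == [(100, 150)]
    assert res.regions[CupCategory.STABLE].total_bp == 950


def test_translocation_to_other_chromosome_is_chr_jump1():
    r = cs.realize(
        cs.RearrangementScript(
            {"chr1": 1000, "chr2": 1000}, (cs.Translocate("chr1", 200, 300, "chr2", 500),)
        )
    )
    assert classify_position(r.fwd, r.rev, "chr1", 250) is CupCategory.CHR_JUMP_1
    assert classify_position(r.fwd, r.rev, "chr1", 150) is CupCategory.STABLE


def test_chr_jump2_takes_precedence_over_pos_jump():
    # back-map goes to another chromosome *and* another offset; the wrong
    # chromosome is what gets counted
    r = cs.realize(
        cs.RearrangementScript(
            {"chr1": 1000, "chr2": 1000},
            (cs.AsymmetricBackmap("chr1", 100, 150, "chr2", 600),),
        )
    )
    assert classify_position(r.fwd, r.rev, "chr1", 120) is CupCategory.CHR_JUMP_2


def test_dest_outside_scanned_set_counts_as_chromosome_jump():
    # forward chain sends chr1 to an alternate contig not in the scan set
    import io
    from cupscan.chain_io import parse_chain_file

    fwd = parse_chain_file(
        io.StringIO("chain 100 chr1 100 + 0 100 chr1_alt 500 + 0 100 1\n100\n")
    )
    rev = parse_chain_file(
        io.StringIO("chain 100 chr1_alt 500 + 0 100 chr1 100 + 0 100 1\n100\n")
    )
    cat = classify_position(fwd, rev, "chr1", 10, scanned_chroms={"chr1"})
    assert cat is CupCategory.CHR_JUMP_1
    # without a scan set, only the name comparison applies
    assert classify_position(fwd, rev, "chr1", 10) is CupCategory.CHR_JUMP_1  # name differs too


def test_chromosome_without_chains_is_wholly_reject1(identity_realization):
    r = identity_realization
    res = scan_genome(r.fwd, r.rev, {"chrA": 1000, "chrM": 600}, mode="interval")
    assert res.regions[CupCategory.REJECT_1].intervals("chrM") == [(0, 600)]


def test_scan_modes_agree_and_match_truth(mixed_realization):
    r = mixed_realization
    pb = scan_genome(r.fwd, r.rev, r.source_sizes, mode="per_base")
    iv = scan_genome(r.fwd, r.rev, r.source_sizes, mode="interval")
    assert_scans_equal(pb, iv)
    for cat in CupCategory:
        assert iv.regions[cat] == r.truth[cat], cat
    # every category is exercised by the mixed script
    for cat in CupCategory:
        assert r.truth[cat].total_bp > 0, cat


def test_scan_partitions_genome(mixed_realization):
    r = mixed_realization
    res = scan_genome(r.fwd, r.rev, r.source_sizes, mode="interval")
    assert res.total_bp == sum(r.source_sizes.values())
    union = RegionSet()
    for cat in CupCategory:
        assert union.intersection(res.regions[cat]).total_bp == 0
        union = union.union(res.regions[cat])
    assert union == RegionSet.whole_genome(r.source_sizes)


def test_rescanning_stable_set_finds_no_new_cups(mixed_realization):
    r = mixed_realization
    res = scan_genome(r.fwd, r.rev, r.source_sizes, mode="interval")
    stable = res.regions[CupCategory.STABLE]
    again = scan_genome(r.fwd, r.rev, r.source_sizes, mode="interval", restrict=stable)
    assert again.cups().total_bp == 0
    assert again.regions[CupCategory.STABLE] == stable


def test_stable_lift_is_bijective_roundtrip(mixed_realization):
    """On the stable set, rev(fwd(x)) == x and fwd is injective."""
    from cupscan.lift_engine import lift_position

    r = mixed_realization
    res = scan_genome(r.fwd, r.rev, r.source_sizes, mode="interval")
    seen = set()
    for chrom, s, e in res.regions[CupCategory.STABLE]:
        for pos in range(s, e):
            f = lift_position(r.fwd, chrom, pos)
            assert f.mapped
            key = (f.dest_chrom, f.dest_pos)
            assert key not in seen
            seen.add(key)
            b = lift_position(r.rev, f.dest_chrom, f.dest_pos)
            assert (b.dest_chrom, b.dest_pos) == (chrom, pos)


def test_merge_category_regions_examples():
    assert merge_category_regions([("c", 5, 6), ("c", 6, 7), ("c", 7, 8)]).intervals("c") == [(5, 8)]
    assert merge_category_regions([("c", 5, 6), ("c", 7, 8)]).intervals("c") == [(5, 6), (7, 8)]


def test_merge_conserves_bp_on_random_single_base_entries():
    import random

    rng = random.Random(0)
    entries = [("c", p, p + 1) for p in (rng.randrange(10_000) for _ in range(10_000))]
    merged = merge_category_regions(entries)
    assert merged.total_bp == len({s for _, s, _ in entries})


def test_summary_frame_and_outputs(tmp_path, mixed_realization):
    r = mixed_realization
    res = scan_genome(r.fwd, r.rev, r.source_sizes, mode="interval")
    df = res.summary_frame()
    assert list(df["category"]) == [c.value for c in cs.cup_scan.SCAN_ORDER]
    assert df["bp"].sum() == res.total_bp
    assert df["pct_of_build"].sum() == pytest.approx(100.0)
    res.write_outputs(tmp_path)
    reread = RegionSet.from_bed(tmp_path / "Stable.bed")
    assert reread == res.regions[CupCategory.STABLE]


def test_invalid_mode_rejected(identity_realization):
    r = identity_realization
    with pytest.raises(ValueError):
        scan_genome(r.fwd, r.rev, r.source_sizes, mode="bogus")
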