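"""VCF SNV conversion: extraction, the two reference-allele dialects,
round-trip classification against positional truth, pre-exclusion and
discordance metrics."""

import pytest

import cupscan as cs
from cupscan.cup_scan import CupCategory, classify_position, scan_genome
from cupscan.regions import RegionSet
from cupscan.synthetic_builds import simulate_variants, write_vcf
from cupscan.vcf_convert import (
    Dialect,
    Snv,
    VcfCategory,
    convert_variant,
    discordance,
    extract_biallelic_snvs,
    filter_at_cups,
    roundtrip_classify_vcf,
    seq_lookup,
    write_vcf as write_snv_vcf,
)


# ------------------------------------------------------------- extraction


VCF_MIXED = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=chr1,length=5000>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1
chr1\t10\t.\tA\tG\t.\t.\t.\tGT\t0/1
chr1\t20\t.\tA\tAT\t.\t.\t.\tGT\t0/1
chr1\t30\t.\tA\tG,T\t.\t.\t.\tGT\t1/2
chr1\t40\t.\tAT\tA\t.\t.\t.\tGT\t0/1
chr1\t50\t.\tC\t<DEL>\t.\t.\t.\tGT\t0/1
chr1\t60\t.\tG\tC\t.\t.\t.\tGT\t1|0
"""


def is_biallelic_snv(ref, alts):
    return len(alts) == 1 and ref in "ACGT" and len(ref) == 1 and alts[0] in "ACGT"


def test_extract_biallelic_snvs_matches_independent_predicate(tmp_path):
    p = tmp_path / "mixed.vcf"
    p.write_text(VCF_MIXED)
    stats = {}
    kept = extract_biallelic_snvs(p, stats=stats)
    # independent pass over the raw rows
    rows = [l.split("\t") for l in VCF_MIXED.splitlines() if not l.startswith("#")]
    expect = [r for r in rows if is_biallelic_snv(r[3], r[4].split(","))]
    assert [(v.chrom, v.pos, v.ref, v.alt) for v in kept] == [
        (r[0], int(r[1]), r[3], r[4]) for r in expect
    ]
    assert stats["kept"] == 2 and stats["dropped_non_snv"] == 4
    assert kept[1].genotype == "1|0"


def test_extract_order_preserved_on_simulated_vcf(tmp_path, mixed_realization):
    r = mixed_realization
    vs = simulate_variants(r.source_seqs, 100, seed=5)
    path = tmp_path / "sim.vcf"
    write_vcf(vs, r.source_sizes, path)
    kept = extract_biallelic_snvs(path)
    assert [(v.chrom, v.pos) for v in kept] == [(v.chrom, v.pos) for v in vs]


# ---------------------------------------------------------------- dialects


@pytest.fixture(scope="module")
def identity_pair():
    return cs.realize(cs.RearrangementScript({"chrA": 100}))


def dialect_cases(ref, alt):
    third = next(b for b in "ACGT" if b not in (ref, alt))
    # (target base, expected reject_on_mismatch, expected update_ref)
    return [
        (ref, "converted", "converted"),
        (alt, "mismatch", "mismatch"),  # alt equals updated ref
        (third, "mismatch", "converted"),  # ref flipped to third allele
        ("N", "mismatch", "mismatch"),  # IUPAC ambiguity
        ("R", "mismatch", "mismatch"),
    ]


def test_dialect_truth_table(identity_pair):
    r = identity_pair
    ref = r.source_seqs["chrA"][10]
    alt = next(b for b in "ACGT" if b != ref)
    v = Snv("chrA", 11, ".", ref, alt, "0/1")
    for tbase, want_rej, want_upd in dialect_cases(ref, alt):
        got_rej = convert_variant(v, r.fwd, lambda c, p: tbase, Dialect.REJECT_ON_MISMATCH)
        got_upd = convert_variant(v, r.fwd, lambda c, p: tbase, Dialect.UPDATE_REF)
        assert got_rej.status == want_rej, tbase
        assert got_upd.status == want_upd, tbase
        if got_rej.status == "converted":
            assert got_rej.variant.ref == ref  # never rewritten in this dialect
        if got_upd.status == "converted":
            assert got_upd.variant.ref == tbase
            assert got_upd.variant.alt == alt


def test_dialect_containment(identity_pair):
    """Whatever fails reject_on_mismatch either fails update_ref or had its
    ref updated to the target base."""
    r = identity_pair
    ref = r.source_seqs["chrA"][10]
    alt = next(b for b in "ACGT" if b != ref)
    v = Snv("chrA", 11, ".", ref, alt, "0/1")
    for tbase in "ACGTN":
        rej = convert_variant(v, r.fwd, lambda c, p: tbase, Dialect.REJECT_ON_MISMATCH)
        upd = convert_variant(v, r.fwd, lambda c, p: tbase, Dialect.UPDATE_REF)
        if rej.status == "mismatch" and upd.status == "converted":
            assert upd.variant.ref == tbase != ref


def test_lift_failure_maps_to_reject(identity_pair):
    r = cs.realize(cs.RearrangementScript({"chrA": 100}, (cs.Delete("chrA", 40, 60),)))
    v = Snv("chrA", 51, ".", r.source_seqs["chrA"][50], "A", "0/1")
    step = convert_variant(v, r.fwd, seq_lookup(r.dest_seqs), Dialect.REJECT_ON_MISMATCH)
    assert step.status == "reject"


def test_alleles_reverse_complemented_on_minus_strand_chain():
    r = cs.realize(cs.RearrangementScript({"chrA": 200}, (cs.Invert("chrA", 50, 100),)))
    ref = r.source_seqs["chrA"][70]
    alt = next(b for b in "ACGT" if b != ref)
    v = Snv("chrA", 71, ".", ref, alt, "0/1")
    step = convert_variant(v, r.fwd, seq_lookup(r.dest_seqs), Dialect.REJECT_ON_MISMATCH)
    assert step.status == "converted" and step.dest_strand == "-"
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    assert step.variant.ref == comp[ref] and step.variant.alt == comp[alt]
    # and the full round trip restores the original alleles
    res = roundtrip_classify_vcf(
        [v], r.fwd, r.rev, seq_lookup(r.source_seqs), seq_lookup(r.dest_seqs)
    )
    assert res.counts[VcfCategory.STABLE] == 1


# -------------------------------------------------------------- round trip


def stratified_vcf(real, per_cat=6):
    variants = []
    for i, cat in enumerate(CupCategory):
        reg = real.truth[cat]
        n = min(per_cat, reg.total_bp)
        if n:
            variants += simulate_variants(real.source_seqs, n, seed=100 + i, within=reg)
    variants.sort(key=lambda v: (v.chrom, v.pos))
    return [Snv(v.chrom, v.pos, ".", v.ref, v.alt, v.genotype) for v in variants]


@pytest.mark.parametrize("dialect", list(Dialect))
def test_roundtrip_counts_conserved_and_match_positional_truth(mixed_realization, dialect):
    r = mixed_realization
    snvs = stratified_vcf(r)
    res = roundtrip_classify_vcf(
        snvs, r.fwd, r.rev, seq_lookup(r.source_seqs), seq_lookup(r.dest_seqs),
        dialect, scanned_chroms=r.source_sizes,
    )
    assert res.total == len(snvs)
    for cat, recs in res.categories.items():
        if cat.is_mismatch:
            continue
        for v in recs:
            pc = classify_position(r.fwd, r.rev, v.chrom, v.pos0, scanned_chroms=r.source_sizes)
            assert cat.as_cup_category() == pc, (cat, v)


def test_all_stable_vcf_roundtrips_byte_identical(mixed_realization, tmp_path):
    r = mixed_realization
    stable = r.truth[CupCategory.STABLE]
    vs = simulate_variants(r.source_seqs, 50, seed=9, within=stable)
    path = tmp_path / "stable.vcf"
    write_vcf(vs, r.source_sizes, path)
    snvs = extract_biallelic_snvs(path)
    res = roundtrip_classify_vcf(
        snvs, r.fwd, r.rev, seq_lookup(r.source_seqs), seq_lookup(r.dest_seqs),
        scanned_chroms=r.source_sizes,
    )
    assert res.counts[VcfCategory.STABLE] == 50
    assert sorted(res.stable(), key=lambda v: (v.chrom, v.pos)) == snvs


def test_mismatch_category_when_target_base_disagrees(mixed_realization):
    r = mixed_realization
    stable = r.truth[CupCategory.STABLE]
    vs = simulate_variants(r.source_seqs, 5, seed=13, within=stable)
    snvs = [Snv(v.chrom, v.pos, ".", v.ref, v.alt, v.genotype) for v in vs]

    def always_n(chrom, pos):
        return "N"

    res = roundtrip_classify_vcf(
        snvs, r.fwd, r.rev, seq_lookup(r.source_seqs), always_n, scanned_chroms=r.source_sizes
    )
    assert res.counts[VcfCategory.MISMATCH_1] == 5

    res2 = roundtrip_classify_vcf(
        snvs, r.fwd, r.rev, always_n, seq_lookup(r.dest_seqs), scanned_chroms=r.source_sizes
    )
    assert res2.counts[VcfCategory.MISMATCH_2] == 5


# ------------------------------------------------------------ pre-exclude


def test_filter_at_cups_edges(mixed_realization):
    r = mixed_realization
    snvs = stratified_vcf(r)
    kept, excluded = filter_at_cups(snvs, RegionSet())
    assert kept == snvs and excluded == []
    all_cover = RegionSet.whole_genome(r.source_sizes)
    kept, excluded = filter_at_cups(snvs, all_cover)
    assert kept == [] and excluded == snvs


def test_pre_exclusion_gives_same_stable_set(mixed_realization):
    r = mixed_realization
    snvs = stratified_vcf(r)
    scan = scan_genome(r.fwd, r.rev, r.source_sizes, mode="interval")
    res_orig = roundtrip_classify_vcf(
        snvs, r.fwd, r.rev, seq_lookup(r.source_seqs), seq_lookup(r.dest_seqs),
        scanned_chroms=r.source_sizes,
    )
    kept, excluded = filter_at_cups(snvs, scan.novel_cups())
    res_filt = roundtrip_classify_vcf(
        kept, r.fwd, r.rev, seq_lookup(r.source_seqs), seq_lookup(r.dest_seqs),
        scanned_chroms=r.source_sizes,
    )
    assert res_filt.stable_loci() == res_orig.stable_loci()
    assert res_filt.counts[VcfCategory.STABLE] == res_orig.counts[VcfCategory.STABLE]
    # filtered data contain no novel-CUP variants at all
    for cat in (VcfCategory.CHR_JUMP_1, VcfCategory.REJECT_2, VcfCategory.CHR_JUMP_2, VcfCategory.POS_JUMP):
        assert res_filt.counts[cat] == 0


# ------------------------------------------------------------ discordance


def test_discordance_identical_and_disjoint():
    a = [Snv("c", i, ".", "A", "G", "0/1") for i in range(1, 6)]
    rep = discordance(a, list(a))
    assert rep.position_discordance == 0.0 and rep.genotype_discordance == 0.0
    b = [Snv("c", i + 100, ".", "A", "G", "0/1") for i in range(1, 6)]
    rep = discordance(a, b)
    assert rep.position_discordance == 1.0 and rep.genotype_discordance is None
    rep = discordance([], a)
    assert rep.position_discordance is None and rep.n_converted == 0


def test_discordance_hand_counted_example():
    conv = [Snv("c", i, ".", "A", "G", "0/1") for i in range(1, 11)]
    alig = [Snv("c", i, ".", "A", "G", "0/1") for i in range(1, 9)]  # 2 position misses
    alig[3] = Snv("c", 4, ".", "A", "G", "1/1")  # 1 genotype flip among 8 matches
    rep = discordance(conv, alig)
    assert rep.position_discordance == pytest.approx(0.2)
    assert rep.genotype_discordance == pytest.approx(0.125)
    assert (rep.n_position_matched, rep.n_genotype_discordant) == (8, 1)


def test_genotype_comparison_ignores_phase():
    a = [Snv("c", 1, ".", "A", "G", "0/1")]
    b = [Snv("c", 1, ".", "A", "G", "1|0")]
    assert discordance(a, b).genotype_discordance == 0.0


def test_written_vcf_reparses(tmp_path):
    snvs = [Snv("chr1", 5, "rs1", "A", "G", "0/1"), Snv("chr1", 9, ".", "C", "T", "1|1")]
    p = tmp_path / "out.vcf"
    write_snv_vcf(snvs, {"chr1": 100}, p)
    again = extract_biallelic_snvs(p)
    assert [(v.chrom, v.pos, v.ref, v.alt, v.genotype) for v in again] == [
        (v.chrom, v.pos, v.ref, v.alt, v.genotype) for v in snvs
    ]
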