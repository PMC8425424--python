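"""Round-trip build conversion of VCF SNVs with reference-allele checking.

The genome scan classifies bare positions; variants add one wrinkle: after
lifting, the reference allele must agree with the target build's base.
Real tools handle disagreement in two dialects, both implemented here:

* ``reject_on_mismatch`` — drop any variant whose (strand-adjusted) ref
  differs from the target base (the Picard LiftoverVcf behaviour);
* ``update_ref`` — replace the ref with the target base and fail only if
  the source alt equals the updated ref (the CrossMap behaviour).

In both dialects a target base that is an IUPAC ambiguity code is a
mismatch. This yields two extra failure categories on top of the
round-trip ones: MISMATCH_1 (first conversion) and MISMATCH_2 (second).
At each conversion the order of checks is: lift failure (Reject), then
reference check (Mismatch), then chromosome comparison (CHR_Jump) — a
mismatched variant is dropped by the conversion tool before any
chromosome bookkeeping can see it.

Genotypes ride along opaquely; discordance metrics compare unphased
allele multisets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Callable, Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pysam

from .chain_io import ChainSet
from .cup_scan import CupCategory
from .lift_engine import lift_position, normalize_chrom
from .regions import RegionSet

BASES = frozenset("ACGT")
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

BaseLookup = Callable[[str, int], str]  # (chrom, 0-based pos) -> base


class VcfCategory(Enum):
    STABLE = "Stable"
    REJECT_1 = "Reject_1"
    CHR_JUMP_1 = "CHR_Jump_1"
    REJECT_2 = "Reject_2"
    CHR_JUMP_2 = "CHR_Jump_2"
    POS_JUMP = "POS_Jump"
    MISMATCH_1 = "Mismatch_1"
    MISMATCH_2 = "Mismatch_2"

    @property
    def is_mismatch(self) -> bool:
        return self in (VcfCategory.MISMATCH_1, VcfCategory.MISMATCH_2)

    def as_cup_category(self) -> Optional[CupCategory]:
        """The positional category this corresponds to; None for mismatches."""
        if self.is_mismatch:
            return None
        return CupCategory[self.name]


class Dialect(Enum):
    REJECT_ON_MISMATCH = "reject_on_mismatch"  # LiftoverVcf-style
    UPDATE_REF = "update_ref"  # CrossMap-style


@dataclass(frozen=True)
class Snv:
    """A biallelic SNV; pos is 1-based (VCF convention)."""

    chrom: str
    pos: int
    id: str
    ref: str
    alt: str
    genotype: str = "./."

    @property
    def pos0(self) -> int:
        return self.pos - 1

    def gt_bases(self) -> Tuple[str, ...]:
        """Unphased multiset (sorted tuple) of called allele bases."""
        alleles = (self.ref, self.alt)
        out = []
        for tok in self.genotype.replace("|", "/").split("/"):
            if tok == ".":
                out.append(".")
            else:
                out.append(alleles[int(tok)])
        return tuple(sorted(out))


def seq_lookup(seqs: Mapping[str, str]) -> BaseLookup:
    def lookup(chrom: str, pos: int) -> str:
        return seqs[chrom][pos].upper()

    return lookup


def fasta_lookup(path) -> BaseLookup:
    from pyfaidx import Fasta

    fa = Fasta(str(path))

    def lookup(chrom: str, pos: int) -> str:
        return str(fa[chrom][pos]).upper()

    return lookup


# ---------------------------------------------------------------- extract


def _gt_string(rec: "pysam.VariantRecord") -> str:
    if not rec.samples:
        return "./."
    sample = rec.samples[0]
    gt = sample.get("GT")
    if gt is None or all(a is None for a in gt):
        return "./."
    sep = "|" if sample.phased else "/"
    return sep.join("." if a is None else str(a) for a in gt)


def extract_biallelic_snvs(source, stats: Optional[Dict[str, int]] = None) -> List[Snv]:
    """Keep only biallelic SNVs (single-base ACGT ref and alt, exactly one
    alt); indels, multiallelic and symbolic records are dropped and
    counted. Input order is preserved."""
    vf = pysam.VariantFile(str(source)) if isinstance(source, (str, Path)) else source
    kept: List[Snv] = []
    dropped = malformed = 0
    for rec in vf:
        try:
            ref = (rec.ref or "").upper()
            alts = rec.alts or ()
        except Exception:  # pragma: no cover - defensive
            malformed += 1
            continue
        if len(alts) == 1 and ref in BASES and len(alts[0]) == 1 and alts[0].upper() in BASES:
            kept.append(
                Snv(rec.chrom, rec.pos, rec.id or ".", ref, alts[0].upper(), _gt_string(rec))
            )
        else:
            dropped += 1
    if stats is not None:
        stats.update({"kept": len(kept), "dropped_non_snv": dropped, "malformed": malformed})
    return kept


# ---------------------------------------------------------------- convert


@dataclass(frozen=True)
class ConversionStep:
    """Outcome of converting one variant across one direction."""

    status: str  # 'converted' | 'reject' | 'mismatch'
    variant: Optional[Snv] = None
    dest_strand: Optional[str] = None


def convert_variant(
    snv: Snv,
    chains: ChainSet,
    target_base_lookup: BaseLookup,
    dialect: Dialect,
) -> ConversionStep:
    """Lift one SNV and apply the dialect's reference-allele rule.

    On a '-'-strand chain the alleles are reverse-complemented before the
    target-base comparison. An ambiguous lift counts as a reject, like the
    tools' refusal of multi-mapped features.
    """
    lr = lift_position(chains, snv.chrom, snv.pos0)
    if not lr.mapped:
        return ConversionStep("reject")
    ref, alt = snv.ref, snv.alt
    if lr.dest_strand == "-":
        ref, alt = _COMP[ref], _COMP[alt]
    tbase = target_base_lookup(lr.dest_chrom, lr.dest_pos).upper()
    if tbase not in BASES:
        return ConversionStep("mismatch")  # IUPAC ambiguity code
    if dialect is Dialect.REJECT_ON_MISMATCH:
        if tbase != ref:
            return ConversionStep("mismatch")
        new_ref = ref
    else:  # UPDATE_REF
        if tbase != ref and alt == tbase:
            return ConversionStep("mismatch")
        new_ref = tbase
    out = replace(snv, chrom=lr.dest_chrom, pos=lr.dest_pos + 1, ref=new_ref, alt=alt)
    return ConversionStep("converted", out, lr.dest_strand)


# ------------------------------------------------------------- round trip


@dataclass
class VcfScanResult:
    """Per-category variants; for STABLE, the first-leg converted record
    is kept alongside the original."""

    categories: Dict[VcfCategory, List[Snv]] = field(default_factory=dict)
    converted: Dict[Tuple[str, int], Snv] = field(default_factory=dict)  # stable: locus -> converted

    @property
    def counts(self) -> Dict[VcfCategory, int]:
        return {c: len(self.categories.get(c, [])) for c in VcfCategory}

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def stable(self) -> List[Snv]:
        return list(self.categories.get(VcfCategory.STABLE, []))

    def stable_loci(self) -> set:
        return {(v.chrom, v.pos) for v in self.stable()}


def roundtrip_classify_vcf(
    snvs: Iterable[Snv],
    fwd: ChainSet,
    rev: ChainSet,
    src_base_lookup: BaseLookup,
    tgt_base_lookup: BaseLookup,
    dialect: Dialect = Dialect.REJECT_ON_MISMATCH,
    scanned_chroms: Optional[Iterable[str]] = None,
) -> VcfScanResult:
    """Round-trip every SNV and assign exactly one VcfCategory.

    Variants failing the first conversion (Reject_1/Mismatch_1) or landing
    on another chromosome (CHR_Jump_1) take no part in the second
    conversion. Counts are conserved: category totals sum to the input.
    """
    scanned = {normalize_chrom(c) for c in scanned_chroms} if scanned_chroms is not None else None
    res = VcfScanResult(categories={c: [] for c in VcfCategory})
    for snv in snvs:
        res.categories[_classify_one(snv, fwd, rev, src_base_lookup, tgt_base_lookup, dialect, scanned, res)].append(snv)
    return res


def _classify_one(snv, fwd, rev, src_lookup, tgt_lookup, dialect, scanned, res) -> VcfCategory:
    step1 = convert_variant(snv, fwd, tgt_lookup, dialect)
    if step1.status == "reject":
        return VcfCategory.REJECT_1
    if step1.status == "mismatch":
        return VcfCategory.MISMATCH_1
    conv = step1.variant
    nd = normalize_chrom(conv.chrom)
    if nd != normalize_chrom(snv.chrom) or (scanned is not None and nd not in scanned):
        return VcfCategory.CHR_JUMP_1

    step2 = convert_variant(conv, rev, src_lookup, dialect)
    if step2.status == "reject":
        return VcfCategory.REJECT_2
    if step2.status == "mismatch":
        return VcfCategory.MISMATCH_2
    back = step2.variant
    if normalize_chrom(back.chrom) != normalize_chrom(snv.chrom):
        return VcfCategory.CHR_JUMP_2
    if back.pos != snv.pos:
        return VcfCategory.POS_JUMP
    res.converted[(snv.chrom, snv.pos)] = conv
    return VcfCategory.STABLE


# ------------------------------------------------------------ pre-exclude


def filter_at_cups(snvs: Iterable[Snv], cup_regions: RegionSet) -> Tuple[List[Snv], List[Snv]]:
    """Partition variants by whether their (0-based) position lies inside
    the unstable-position regions; kept + excluded = input."""
    kept: List[Snv] = []
    excluded: List[Snv] = []
    for snv in snvs:
        (excluded if cup_regions.contains(snv.chrom, snv.pos0) else kept).append(snv)
    return kept, excluded


# ------------------------------------------------------------ discordance


@dataclass(frozen=True)
class DiscordanceReport:
    position_discordance: Optional[float]  # None when no converted variants
    genotype_discordance: Optional[float]  # None when no position matches
    n_converted: int
    n_position_matched: int
    n_genotype_discordant: int


def discordance(converted: Sequence[Snv], aligned: Sequence[Snv]) -> DiscordanceReport:
    """Compare converted variants against natively aligned calls.

    Position discordance: fraction of converted variants with no aligned
    variant at the same (chrom, pos). Genotype discordance: among
    position matches, fraction whose unphased allele multisets differ.
    """
    n_conv = len(converted)
    if n_conv == 0:
        return DiscordanceReport(None, None, 0, 0, 0)
    by_locus = {(v.chrom, v.pos): v for v in aligned}
    matched = gt_bad = 0
    for v in converted:
        other = by_locus.get((v.chrom, v.pos))
        if other is None:
            continue
        matched += 1
        if v.gt_bases() != other.gt_bases():
            gt_bad += 1
    pos_disc = (n_conv - matched) / n_conv
    gt_disc = gt_bad / matched if matched else None
    return DiscordanceReport(pos_disc, gt_disc, n_conv, matched, gt_bad)


# ------------------------------------------------------------------- I/O


def write_vcf(
    snvs: Sequence[Snv],
    chrom_sizes: Optional[Mapping[str, int]],
    path,
    sample: str = "SAMPLE",
    extra_header: Sequence[str] = (),
) -> None:
    """Write SNVs as VCFv4.2 text, with target-build contig lines when
    chromosome sizes are available."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if chrom_sizes:
            for chrom, size in chrom_sizes.items():
                fh.write(f"##contig=<ID={chrom},length={size}>\n")
        for line in extra_header:
            fh.write(line.rstrip("\n") + "\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample + "\n")
        for v in snvs:
            fh.write(f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref}\t{v.alt}\t.\t.\t.\tGT\t{v.genotype}\n")
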