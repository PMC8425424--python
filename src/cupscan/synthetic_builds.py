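"""Paired toy genome builds with exact chain files and per-base truth labels.

A :class:`RearrangementScript` declares how a destination build differs
from a source build: deletions, insertions, inversions, translocations,
duplications — the kinds of change real assembly updates introduce (gap
closing, contig replacement, relocated duplicated sequence) — plus a
deliberately asymmetric back-mapping that manufactures round-trip
failures. :func:`realize` turns a script into source/dest sequences, the
two direction chain files, and the analytically known conversion-stability
category of every source base, so the genome scanner and the VCF workflow
can be tested against ground truth with no external downloads.

Truth rules (all intervals half-open on source coordinates):

* ``delete``                       -> REJECT_1 (no chain covers the bases)
* ``duplicate(score_tie=True)``    -> REJECT_1 (ambiguous between equal-score chains)
* ``translocate`` to another chrom -> CHR_JUMP_1 (same chrom: STABLE)
* ``asymmetric_backmap(alt=None)`` -> REJECT_2 (block absent from reverse chains)
* ``asymmetric_backmap`` to another chrom -> CHR_JUMP_2
* ``asymmetric_backmap`` same chrom, shifted -> POS_JUMP
* everything else (inversions, inserts, plain duplications, untouched) -> STABLE
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

from .chain_io import AlignmentBlock, Chain, ChainHeader, ChainSet
from .cup_scan import CupCategory
from .regions import RegionSet

_BASES = "ACGT"
_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ------------------------------------------------------------- script ops


@dataclass(frozen=True)
class Delete:
    chrom: str
    start: int
    end: int


@dataclass(frozen=True)
class Insert:
    chrom: str
    pos: int
    length: int


@dataclass(frozen=True)
class Invert:
    chrom: str
    start: int
    end: int


@dataclass(frozen=True)
class Translocate:
    chrom: str
    start: int
    end: int
    dest_chrom: str
    dest_pos: int


@dataclass(frozen=True)
class Duplicate:
    chrom: str
    start: int
    end: int
    dest_chrom: str
    dest_pos: int
    score_tie: bool = False


@dataclass(frozen=True)
class AsymmetricBackmap:
    """Forward chain is normal; the reverse chain maps the block's dest
    image to alt_source (or nowhere, when alt_source is None)."""

    chrom: str
    start: int
    end: int
    alt_chrom: Optional[str] = None
    alt_start: Optional[int] = None  # None together with alt_chrom => dropped

    @property
    def dropped(self) -> bool:
        return self.alt_chrom is None


Operation = Union[Delete, Insert, Invert, Translocate, Duplicate, AsymmetricBackmap]

_INTERVAL_OPS = (Delete, Invert, Translocate, Duplicate, AsymmetricBackmap)


class ScriptError(ValueError):
    """A rearrangement script with invalid or overlapping operations."""


@dataclass(frozen=True)
class RearrangementScript:
    chrom_sizes: Mapping[str, int]
    ops: Tuple[Operation, ...] = ()
    seed: int = 0

    def validate(self) -> None:
        sizes = dict(self.chrom_sizes)
        used: Dict[str, List[Tuple[int, int]]] = {c: [] for c in sizes}
        points: List[Tuple[str, int]] = []

        def check_interval(chrom, s, e, what):
            if chrom not in sizes:
                raise ScriptError(f"{what}: unknown chromosome {chrom!r}")
            if not 0 <= s < e <= sizes[chrom]:
                raise ScriptError(f"{what}: interval [{s},{e}) out of bounds on {chrom}")

        for op in self.ops:
            if isinstance(op, _INTERVAL_OPS):
                check_interval(op.chrom, op.start, op.end, type(op).__name__)
                used[op.chrom].append((op.start, op.end))
            if isinstance(op, Insert):
                if op.chrom not in sizes or not 0 <= op.pos <= sizes[op.chrom]:
                    raise ScriptError(f"Insert: position {op.pos} out of bounds on {op.chrom}")
                if op.length <= 0:
                    raise ScriptError("Insert: non-positive length")
                points.append((op.chrom, op.pos))
            if isinstance(op, (Translocate, Duplicate)):
                if op.dest_chrom not in sizes or not 0 <= op.dest_pos <= sizes[op.dest_chrom]:
                    raise ScriptError(
                        f"{type(op).__name__}: destination {op.dest_chrom}:{op.dest_pos} out of bounds"
                    )
                points.append((op.dest_chrom, op.dest_pos))
            if isinstance(op, Duplicate) and op.end - op.start < 2:
                raise ScriptError("Duplicate: interval must be at least 2 bp (score separation)")
            if isinstance(op, AsymmetricBackmap) and not op.dropped:
                if op.alt_start is None:
                    raise ScriptError("AsymmetricBackmap: alt_chrom without alt_start")
                check_interval(op.alt_chrom, op.alt_start, op.alt_start + (op.end - op.start),
                               "AsymmetricBackmap alt target")
                if op.alt_chrom == op.chrom and op.alt_start == op.start:
                    raise ScriptError("AsymmetricBackmap: alt target equals source (would be stable)")

        for chrom, ivs in used.items():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ScriptError(f"overlapping operations on {chrom}: [{s1},{e1}) and [{s2},{e2})")
        for chrom, pos in points:
            for s, e in used.get(chrom, []):
                if s < pos < e:
                    raise ScriptError(
                        f"insertion/destination point {chrom}:{pos} falls inside operation interval [{s},{e})"
                    )


# ------------------------------------------------------------- realization


@dataclass
class _Seg:
    origin_chrom: Optional[str]  # None for novel inserted sequence
    start: int
    end: int
    strand: str = "+"
    kind: str = "normal"  # normal | dup_original | dup_copy | asym | novel
    tie: bool = False
    backmap: Optional[Tuple[str, int]] = None  # asym only; None => dropped
    novel_seq: str = ""

    def __len__(self) -> int:
        return self.end - self.start


def _find_split(layouts: Dict[str, List[_Seg]], chrom: str, pos: int) -> Tuple[str, int]:
    """Return (layout chrom, index) such that inserting at that index places
    material at source coordinate ``pos`` of ``chrom``; splits a pristine
    segment when pos is interior."""
    for lay_chrom, segs in layouts.items():
        for i, seg in enumerate(segs):
            if seg.origin_chrom != chrom or seg.kind != "normal" or seg.strand != "+":
                continue
            if seg.start < pos < seg.end:
                right = replace(seg, start=pos)
                seg.end = pos
                segs.insert(i + 1, right)
                return lay_chrom, i + 1
            if pos == seg.start:
                return lay_chrom, i
            if pos == seg.end:
                return lay_chrom, i + 1
    raise ScriptError(f"cannot locate source coordinate {chrom}:{pos} in any pristine segment")


def _extract(layouts: Dict[str, List[_Seg]], chrom: str, start: int, end: int) -> Tuple[str, int, _Seg]:
    _find_split(layouts, chrom, start)
    _find_split(layouts, chrom, end)
    for lay_chrom, segs in layouts.items():
        for i, seg in enumerate(segs):
            if (
                seg.origin_chrom == chrom
                and seg.kind == "normal"
                and seg.start == start
                and seg.end == end
            ):
                return lay_chrom, i, segs.pop(i)
    raise ScriptError(f"interval {chrom}:[{start},{end}) is not a pristine segment")


@dataclass
class Realization:
    script: RearrangementScript
    source_seqs: Dict[str, str]
    dest_seqs: Dict[str, str]
    source_sizes: Dict[str, int]
    dest_sizes: Dict[str, int]
    fwd: ChainSet
    rev: ChainSet
    truth: Dict[CupCategory, RegionSet] = field(default_factory=dict)

    def truth_region(self, cat: CupCategory) -> RegionSet:
        return self.truth.get(cat, RegionSet())


def _random_seq(rng: random.Random, n: int) -> str:
    return "".join(rng.choice(_BASES) for _ in range(n))


def realize(script: RearrangementScript) -> Realization:
    """Materialize a script: sequences, both chain sets, truth labels."""
    script.validate()
    sizes = dict(script.chrom_sizes)
    rng = random.Random(f"realize/{script.seed}")
    seq_bufs = {
        c: bytearray(_random_seq(random.Random(f"seq/{script.seed}/{c}"), n), "ascii")
        for c, n in sizes.items()
    }
    # Asymmetric back-map targets receive a copy of the source interval's
    # sequence: real chromosome/position jumps arise in homologous
    # (duplicated) sequence, so back-mapped reference-allele checks should
    # compare equal bases. Overlapping self-targets are left as-is.
    for op in script.ops:
        if isinstance(op, AsymmetricBackmap) and not op.dropped:
            n = op.end - op.start
            overlaps = op.alt_chrom == op.chrom and not (
                op.alt_start + n <= op.start or op.end <= op.alt_start
            )
            if not overlaps:
                seq_bufs[op.alt_chrom][op.alt_start : op.alt_start + n] = seq_bufs[op.chrom][
                    op.start : op.end
                ]
    source_seqs = {c: buf.decode("ascii") for c, buf in seq_bufs.items()}

    layouts: Dict[str, List[_Seg]] = {c: [_Seg(c, 0, n)] for c, n in sizes.items()}
    truth_acc: Dict[CupCategory, List[Tuple[str, int, int]]] = {c: [] for c in CupCategory}

    for op in script.ops:
        if isinstance(op, Delete):
            _extract(layouts, op.chrom, op.start, op.end)
            truth_acc[CupCategory.REJECT_1].append((op.chrom, op.start, op.end))
        elif isinstance(op, Invert):
            lay, i, seg = _extract(layouts, op.chrom, op.start, op.end)
            seg.strand = "-"
            layouts[lay].insert(i, seg)
        elif isinstance(op, Translocate):
            _extract(layouts, op.chrom, op.start, op.end)
            lay, i = _find_split(layouts, op.dest_chrom, op.dest_pos)
            layouts[lay].insert(i, _Seg(op.chrom, op.start, op.end))
            if op.dest_chrom != op.chrom:
                truth_acc[CupCategory.CHR_JUMP_1].append((op.chrom, op.start, op.end))
        elif isinstance(op, Duplicate):
            lay, i, seg = _extract(layouts, op.chrom, op.start, op.end)
            seg.kind, seg.tie = "dup_original", op.score_tie
            layouts[lay].insert(i, seg)
            lay2, j = _find_split(layouts, op.dest_chrom, op.dest_pos)
            layouts[lay2].insert(j, _Seg(op.chrom, op.start, op.end, kind="dup_copy", tie=op.score_tie))
            if op.score_tie:
                truth_acc[CupCategory.REJECT_1].append((op.chrom, op.start, op.end))
        elif isinstance(op, AsymmetricBackmap):
            lay, i, seg = _extract(layouts, op.chrom, op.start, op.end)
            seg.kind = "asym"
            seg.backmap = None if op.dropped else (op.alt_chrom, op.alt_start)
            layouts[lay].insert(i, seg)
            iv = (op.chrom, op.start, op.end)
            if op.dropped:
                truth_acc[CupCategory.REJECT_2].append(iv)
            elif op.alt_chrom != op.chrom:
                truth_acc[CupCategory.CHR_JUMP_2].append(iv)
            else:
                truth_acc[CupCategory.POS_JUMP].append(iv)
        elif isinstance(op, Insert):
            lay, i = _find_split(layouts, op.chrom, op.pos)
            layouts[lay].insert(
                i, _Seg(None, 0, op.length, kind="novel", novel_seq=_random_seq(rng, op.length))
            )
        else:  # pragma: no cover
            raise ScriptError(f"unknown operation {op!r}")

    # destination sequences and per-segment dest offsets
    dest_seqs: Dict[str, str] = {}
    dest_sizes: Dict[str, int] = {}
    offsets: Dict[int, int] = {}  # id(segment) -> dest start
    for chrom, segs in layouts.items():
        parts: List[str] = []
        off = 0
        for seg in segs:
            offsets[id(seg)] = off
            if seg.kind == "novel":
                parts.append(seg.novel_seq)
            else:
                piece = source_seqs[seg.origin_chrom][seg.start:seg.end]
                parts.append(revcomp(piece) if seg.strand == "-" else piece)
            off += len(seg)
        dest_seqs[chrom] = "".join(parts)
        dest_sizes[chrom] = off

    fwd = ChainSet(_forward_chains(layouts, sizes, dest_sizes, offsets), direction_label="source->dest")
    rev = ChainSet(_reverse_chains(layouts, sizes, dest_sizes, offsets), direction_label="dest->source")

    truth: Dict[CupCategory, RegionSet] = {
        c: RegionSet.from_pairs(v) for c, v in truth_acc.items() if v
    }
    non_stable = RegionSet()
    for c, rs in truth.items():
        non_stable = non_stable.union(rs)
    truth[CupCategory.STABLE] = non_stable.complement(sizes)
    for c in CupCategory:
        truth.setdefault(c, RegionSet())

    return Realization(script, source_seqs, dest_seqs, sizes, dest_sizes, fwd, rev, truth)


def _forward_chains(layouts, src_sizes, dest_sizes, offsets) -> List[Chain]:
    """One chain per maximal colinear run of forward segments; deletions
    become source-side gaps, novel insertions dest-side gaps. Duplicate
    originals/copies and inversions get dedicated chains (score control,
    strand)."""
    chains: List[Chain] = []
    next_id = [1]

    def emit(src_chrom, dest_chrom, run, score=None):
        # run: list of (seg, dest_off) colinear '+' segments
        blocks: List[AlignmentBlock] = []
        for k, (seg, doff) in enumerate(run):
            if k + 1 < len(run):
                nxt_seg, nxt_doff = run[k + 1]
                gap_s = nxt_seg.start - seg.end
                gap_d = nxt_doff - (doff + len(seg))
                blocks.append(AlignmentBlock(len(seg), gap_s, gap_d))
            else:
                blocks.append(AlignmentBlock(len(seg)))
        t0, t1 = run[0][0].start, run[-1][0].end
        d0 = run[0][1]
        d1 = run[-1][1] + len(run[-1][0])
        header = ChainHeader(
            score=score if score is not None else sum(b.size for b in blocks),
            source_name=src_chrom,
            source_size=src_sizes[src_chrom],
            source_strand="+",
            source_start=t0,
            source_end=t1,
            dest_name=dest_chrom,
            dest_size=dest_sizes[dest_chrom],
            dest_strand="+",
            dest_start=d0,
            dest_end=d1,
            chain_id=str(next_id[0]),
        )
        next_id[0] += 1
        chains.append(Chain(header, tuple(blocks)))

    for dest_chrom, segs in layouts.items():
        run: List[Tuple[_Seg, int]] = []
        run_chrom: Optional[str] = None
        for seg in segs:
            doff = offsets[id(seg)]
            if seg.kind == "novel":
                continue  # contributes dest gap inside a run; never breaks colinearity check
            plain = seg.kind in ("normal", "asym") and seg.strand == "+"
            colinear = (
                plain
                and run
                and seg.origin_chrom == run_chrom
                and seg.start >= run[-1][0].end
            )
            if colinear:
                run.append((seg, doff))
                continue
            if run:
                emit(run_chrom, dest_chrom, run)
                run = []
            if plain:
                run, run_chrom = [(seg, doff)], seg.origin_chrom
            elif seg.kind in ("dup_original", "dup_copy"):
                n = len(seg)
                score = n if (seg.kind == "dup_original" or seg.tie) else max(1, n // 2)
                emit(seg.origin_chrom, dest_chrom, [(seg, doff)], score=score)
            elif seg.strand == "-":
                # single-block reverse-orientation chain
                n = len(seg)
                qsize = dest_sizes[dest_chrom]
                header = ChainHeader(
                    score=n,
                    source_name=seg.origin_chrom,
                    source_size=src_sizes[seg.origin_chrom],
                    source_strand="+",
                    source_start=seg.start,
                    source_end=seg.end,
                    dest_name=dest_chrom,
                    dest_size=qsize,
                    dest_strand="-",
                    dest_start=qsize - (doff + n),
                    dest_end=qsize - doff,
                    chain_id=str(next_id[0]),
                )
                next_id[0] += 1
                chains.append(Chain(header, (AlignmentBlock(n),)))

        if run:
            emit(run_chrom, dest_chrom, run)
    return chains


def _reverse_chains(layouts, src_sizes, dest_sizes, offsets) -> List[Chain]:
    """One single-block chain per mappable destination segment."""
    chains: List[Chain] = []
    next_id = [1]
    for dest_chrom, segs in layouts.items():
        for seg in segs:
            if seg.kind == "novel":
                continue
            if seg.kind == "asym" and seg.backmap is None:
                continue  # deliberately absent from the reverse direction
            doff = offsets[id(seg)]
            n = len(seg)
            if seg.kind == "asym":
                q_chrom, q_start = seg.backmap
                q_strand = "+"
            else:
                q_chrom, q_start, q_strand = seg.origin_chrom, seg.start, seg.strand
            qsize = src_sizes[q_chrom]
            if q_strand == "+":
                qs, qe = q_start, q_start + n
            else:
                qs, qe = qsize - (q_start + n), qsize - q_start
            header = ChainHeader(
                score=n,
                source_name=dest_chrom,
                source_size=dest_sizes[dest_chrom],
                source_strand="+",
                source_start=doff,
                source_end=doff + n,
                dest_name=q_chrom,
                dest_size=qsize,
                dest_strand=q_strand,
                dest_start=qs,
                dest_end=qe,
                chain_id=str(next_id[0]),
            )
            next_id[0] += 1
            chains.append(Chain(header, (AlignmentBlock(n),)))
    return chains


# --------------------------------------------------------------- variants


@dataclass(frozen=True)
class SimVariant:
    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    genotype: str  # e.g. "0/1"


def simulate_variants(
    source_seqs: Mapping[str, str],
    n: int,
    seed: int,
    within: Optional[RegionSet] = None,
) -> List[SimVariant]:
    """n distinct biallelic SNVs with ref matching the source sequence.

    ``within`` restricts placement to the given regions (used to stratify
    across truth categories). Deterministic per seed; sorted by locus.
    """
    rng = random.Random(f"variants/{seed}")
    space: List[Tuple[str, int]] = []
    if within is None:
        for chrom, seq in sorted(source_seqs.items()):
            space.extend((chrom, i) for i in range(len(seq)))
    else:
        for chrom, s, e in within:
            space.extend((chrom, i) for i in range(s, e))
    if n > len(space):
        raise ValueError(f"cannot place {n} distinct variants in {len(space)} bp")
    chosen = rng.sample(space, n)
    out = []
    for chrom, pos0 in sorted(chosen):
        ref = source_seqs[chrom][pos0]
        alt = rng.choice([b for b in _BASES if b != ref])
        gt = rng.choice(["0/1", "1/1", "0/1"])
        out.append(SimVariant(chrom, pos0 + 1, ref, alt, gt))
    return out


def write_vcf(variants: Sequence[SimVariant], chrom_sizes: Mapping[str, int], path, sample="SAMPLE") -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom, size in chrom_sizes.items():
            fh.write(f"##contig=<ID={chrom},length={size}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample + "\n")
        for v in variants:
            fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t.\t.\tGT\t{v.genotype}\n")


def write_fasta(seqs: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(seqs):
            fh.write(f">{chrom}\n")
            s = seqs[chrom]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


# ---------------------------------------------------------- random scripts


def random_script(seed: int, n_chroms: int = 2, chrom_len: int = 5000) -> RearrangementScript:
    """A seeded, always-valid random script mixing every operation kind.

    Operation intervals are sampled disjoint with a 1-bp margin; insertion
    and destination points avoid other operations' intervals.
    """
    rng = random.Random(f"script/{seed}")
    chroms = [f"chr{i + 1}" for i in range(n_chroms)]
    sizes = {c: chrom_len + rng.randrange(0, chrom_len // 2) for c in chroms}

    used: Dict[str, List[Tuple[int, int]]] = {c: [] for c in chroms}
    points: Dict[str, List[int]] = {c: [] for c in chroms}

    def free_interval(chrom, lo_len=20, hi_len=200, tries=50):
        for _ in range(tries):
            n = rng.randrange(lo_len, hi_len)
            s = rng.randrange(0, sizes[chrom] - n)
            clear = all(e2 <= s - 1 or s + n + 1 <= s2 for s2, e2 in used[chrom])
            clear = clear and all(not (s - 1 < p < s + n + 1) for p in points[chrom])
            if clear:
                used[chrom].append((s, s + n))
                return s, s + n
        return None

    def free_point(chrom):
        for _ in range(50):
            p = rng.randrange(1, sizes[chrom])
            if all(p <= s - 1 or p >= e + 1 for s, e in used[chrom]):
                points[chrom].append(p)
                return p
        points[chrom].append(0)
        return 0

    ops: List[Operation] = []
    kinds = ["delete", "insert", "invert", "translocate", "duplicate", "dup_tie",
             "asym_drop", "asym_chrom", "asym_pos"]
    n_ops = rng.randrange(4, 9)
    for _ in range(n_ops):
        kind = rng.choice(kinds)
        chrom = rng.choice(chroms)
        iv = free_interval(chrom)
        if iv is None:
            continue
        s, e = iv
        if kind == "delete":
            ops.append(Delete(chrom, s, e))
        elif kind == "insert":
            used[chrom].remove((s, e))
            ops.append(Insert(chrom, free_point(chrom), rng.randrange(10, 100)))
        elif kind == "invert":
            ops.append(Invert(chrom, s, e))
        elif kind == "translocate":
            dchrom = rng.choice(chroms)
            ops.append(Translocate(chrom, s, e, dchrom, free_point(dchrom)))
        elif kind in ("duplicate", "dup_tie"):
            dchrom = rng.choice(chroms)
            ops.append(Duplicate(chrom, s, e, dchrom, free_point(dchrom), score_tie=kind == "dup_tie"))
        elif kind == "asym_drop":
            ops.append(AsymmetricBackmap(chrom, s, e))
        elif kind == "asym_chrom":
            alt_chrom = rng.choice([c for c in chroms if c != chrom] or [chrom])
            if alt_chrom == chrom:
                ops.append(AsymmetricBackmap(chrom, s, e))
            else:
                alt_start = rng.randrange(0, sizes[alt_chrom] - (e - s))
                ops.append(AsymmetricBackmap(chrom, s, e, alt_chrom, alt_start))
        else:  # asym_pos
            n = e - s
            alt_start = None
            for _ in range(50):
                cand = rng.randrange(0, sizes[chrom] - n)
                if cand + n <= s or e <= cand:  # disjoint from own interval
                    alt_start = cand
                    break
            if alt_start is None:
                continue
            ops.append(AsymmetricBackmap(chrom, s, e, chrom, alt_start))
    script = RearrangementScript(sizes, tuple(ops), seed=seed)
    script.validate()
    return script
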