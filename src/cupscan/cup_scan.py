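"""Round-trip conversion-stability scan: classify every base of a build.

Each source-build position is converted to the target build and back.
The outcome is one of six mutually exclusive categories, tested in a fixed
decision order:

1. ``REJECT_1``   — the first conversion fails (no chain, chain gap, or an
                    unresolvable tie between chains);
2. ``CHR_JUMP_1`` — the first conversion lands on a different chromosome
                    (any destination outside the scanned chromosome set,
                    including unlocalized/unplaced/alternate contigs,
                    counts as different);
3. ``REJECT_2``   — the back-conversion of the mapped point fails;
4. ``CHR_JUMP_2`` — the back-conversion returns to the wrong chromosome;
5. ``POS_JUMP``   — the back-conversion returns to the wrong position;
6. ``STABLE``     — the round trip is the identity.

Everything except STABLE is a conversion-unstable position (CUP);
categories 2-5 are the "novel" CUPs a conversion tool does not itself
report. Positions failing at step 1 or 2 take no part in the second
conversion.

Two scan modes exist: ``per_base`` applies the classifier to every single
position (the reference semantics, feasible on toy genomes) and
``interval`` computes the identical partition by exact piecewise-affine
interval algebra over the chain blocks. The two are extensionally equal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import pandas as pd

from .chain_io import ChainSet
from .lift_engine import MapPiece, lift_position, normalize_chrom, piecewise_map
from .regions import RegionSet


class CupCategory(Enum):
    STABLE = "Stable"
    REJECT_1 = "Reject_1"
    CHR_JUMP_1 = "CHR_Jump_1"
    REJECT_2 = "Reject_2"
    CHR_JUMP_2 = "CHR_Jump_2"
    POS_JUMP = "POS_Jump"

    @property
    def is_cup(self) -> bool:
        return self is not CupCategory.STABLE

    @property
    def is_novel_cup(self) -> bool:
        return self in _NOVEL


_NOVEL = {
    CupCategory.CHR_JUMP_1,
    CupCategory.REJECT_2,
    CupCategory.CHR_JUMP_2,
    CupCategory.POS_JUMP,
}

SCAN_ORDER = [
    CupCategory.STABLE,
    CupCategory.REJECT_1,
    CupCategory.CHR_JUMP_1,
    CupCategory.REJECT_2,
    CupCategory.CHR_JUMP_2,
    CupCategory.POS_JUMP,
]


@dataclass
class ScanResult:
    """Per-category region sets on source-build coordinates."""

    regions: Dict[CupCategory, RegionSet]
    chrom_sizes: Dict[str, int] = field(default_factory=dict)

    @property
    def counts(self) -> Dict[CupCategory, int]:
        return {c: self.regions[c].total_bp for c in SCAN_ORDER}

    @property
    def total_bp(self) -> int:
        return sum(self.counts.values())

    @property
    def fractions(self) -> Dict[CupCategory, float]:
        tot = self.total_bp
        return {c: (n / tot if tot else 0.0) for c, n in self.counts.items()}

    def novel_cups(self) -> RegionSet:
        out = RegionSet()
        for c in _NOVEL:
            out = out.union(self.regions[c])
        return out

    def cups(self) -> RegionSet:
        return self.novel_cups().union(self.regions[CupCategory.REJECT_1])

    def summary_frame(self) -> pd.DataFrame:
        tot = self.total_bp
        rows = [
            {
                "category": c.value,
                "bp": self.regions[c].total_bp,
                "pct_of_build": 100.0 * self.regions[c].total_bp / tot if tot else 0.0,
            }
            for c in SCAN_ORDER
        ]
        return pd.DataFrame(rows)

    def write_outputs(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for c in SCAN_ORDER:
            self.regions[c].to_bed(out / f"{c.value}.bed", label=c.value)
        self.summary_frame().to_csv(out / "summary.tsv", sep="\t", index=False)


def classify_position(
    fwd: ChainSet,
    rev: ChainSet,
    chrom: str,
    pos: int,
    scanned_chroms: Optional[Iterable[str]] = None,
) -> CupCategory:
    """Classify one source position through the round trip (decision order
    Reject_1, CHR_Jump_1, Reject_2, CHR_Jump_2, POS_Jump, else Stable)."""
    scanned = {normalize_chrom(c) for c in scanned_chroms} if scanned_chroms is not None else None

    first = lift_position(fwd, chrom, pos)
    if not first.mapped:
        return CupCategory.REJECT_1
    if _different_chrom(first.dest_chrom, chrom, scanned):
        return CupCategory.CHR_JUMP_1

    second = lift_position(rev, first.dest_chrom, first.dest_pos)
    if not second.mapped:
        return CupCategory.REJECT_2
    if normalize_chrom(second.dest_chrom) != normalize_chrom(chrom):
        return CupCategory.CHR_JUMP_2
    if second.dest_pos != pos:
        return CupCategory.POS_JUMP
    return CupCategory.STABLE


def _different_chrom(dest: str, src: str, scanned: Optional[set]) -> bool:
    nd = normalize_chrom(dest)
    if nd != normalize_chrom(src):
        return True
    return scanned is not None and nd not in scanned


def merge_category_regions(positions: Iterable[Tuple[str, int, int]]) -> RegionSet:
    """Collapse sorted-or-sortable single-base entries (or sub-intervals)
    into merged regions; book-ended intervals fuse, total bp is conserved."""
    return RegionSet.from_pairs(positions)


def scan_genome(
    fwd: ChainSet,
    rev: ChainSet,
    chrom_sizes: Mapping[str, int],
    mode: str = "interval",
    restrict: Optional[RegionSet] = None,
) -> ScanResult:
    """Scan (a subset of) the source build and partition it by category.

    chrom_sizes lists exactly the chromosomes to scan; a chromosome with no
    chain coverage is wholly REJECT_1 (it cannot convert). ``restrict``
    limits the scan to the given source regions (used e.g. to re-scan the
    stable set when checking idempotence).
    """
    if mode not in ("interval", "per_base"):
        raise ValueError(f"unknown scan mode {mode!r}")
    acc: Dict[CupCategory, List[Tuple[str, int, int]]] = {c: [] for c in SCAN_ORDER}
    scanned = set(chrom_sizes)
    for chrom, size in chrom_sizes.items():
        spans = [(0, size)]
        if restrict is not None:
            spans = restrict.intersection(RegionSet({chrom: [(0, size)]})).intervals(chrom)
        if not spans:
            continue
        if mode == "per_base":
            _scan_chrom_per_base(fwd, rev, chrom, spans, scanned, acc)
        else:
            _scan_chrom_interval(fwd, rev, chrom, spans, scanned, acc)
    return ScanResult(
        regions={c: RegionSet.from_pairs(acc[c]) for c in SCAN_ORDER},
        chrom_sizes=dict(chrom_sizes),
    )


def _scan_chrom_per_base(fwd, rev, chrom, spans, scanned, acc) -> None:
    for s, e in spans:
        for pos in range(s, e):
            cat = classify_position(fwd, rev, chrom, pos, scanned_chroms=scanned)
            acc[cat].append((chrom, pos, pos + 1))


def _scan_chrom_interval(fwd, rev, chrom, spans, scanned, acc) -> None:
    pieces = piecewise_map(fwd, chrom)
    rev_cache: Dict[str, List[MapPiece]] = {}
    norm_scanned = {normalize_chrom(c) for c in scanned}
    for lo, hi in spans:
        covered: List[Tuple[int, int]] = []
        for p in pieces:
            a, b = max(p.start, lo), min(p.end, hi)
            if a >= b:
                continue
            covered.append((a, b))
            if p.kind == "ambiguous":
                acc[CupCategory.REJECT_1].append((chrom, a, b))
                continue
            if _different_chrom(p.dest_chrom, chrom, norm_scanned):
                acc[CupCategory.CHR_JUMP_1].append((chrom, a, b))
                continue
            _second_leg(rev, rev_cache, chrom, MapPiece(a, b, "mapped", p.dest_chrom, p.slope, p.intercept), acc)
        # anything not covered by any piece failed the first conversion
        gap_set = RegionSet({chrom: [(lo, hi)]}).difference(RegionSet({chrom: covered}))
        for c, s, e in gap_set:
            acc[CupCategory.REJECT_1].append((c, s, e))


def _second_leg(rev, rev_cache, chrom, piece: MapPiece, acc) -> None:
    """Push a first-leg-mapped source piece through the back-conversion."""
    dest_chrom = piece.dest_chrom
    if dest_chrom not in rev_cache:
        rev_cache[dest_chrom] = piecewise_map(rev, dest_chrom)
    u0, v0 = piece.image()
    covered: List[Tuple[int, int]] = []
    for rp in rev_cache[dest_chrom]:
        u, v = max(rp.start, u0), min(rp.end, v0)
        if u >= v:
            continue
        covered.append((u, v))
        src_lo, src_hi = piece.back(u, v)
        if rp.kind == "ambiguous":
            acc[CupCategory.REJECT_2].append((chrom, src_lo, src_hi))
            continue
        if normalize_chrom(rp.dest_chrom) != normalize_chrom(chrom):
            acc[CupCategory.CHR_JUMP_2].append((chrom, src_lo, src_hi))
            continue
        # compose: back(x) = s2*(s1*x + i1) + i2 ; identity iff s1*s2 == 1, s2*i1 + i2 == 0
        s1, i1 = piece.slope, piece.intercept
        s2, i2 = rp.slope, rp.intercept
        if s1 * s2 == 1 and s2 * i1 + i2 == 0:
            acc[CupCategory.STABLE].append((chrom, src_lo, src_hi))
        else:
            acc[CupCategory.POS_JUMP].append((chrom, src_lo, src_hi))
    gap_set = RegionSet({dest_chrom: [(u0, v0)]}).difference(RegionSet({dest_chrom: covered}))
    for _, u, v in gap_set:
        src_lo, src_hi = piece.back(u, v)
        acc[CupCategory.REJECT_2].append((chrom, src_lo, src_hi))
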