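"""Single-base liftover between builds via a ChainSet.

Two routes to the same mapping are provided:

* :func:`lift_position` — per-base lookup through the chain interval index
  (the reference semantics; used by the per-base genome scan and by VCF
  conversion).
* :func:`piecewise_map` — the full source chromosome resolved into maximal
  intervals on which the lift is a single affine map (slope +/-1). This is
  the exact interval-algebra route used by the fast genome scan; the two
  routes are extensionally equal and tests hold them to that.

Ambiguity policy: when aligned blocks of several chains cover a base and
disagree on the destination, the highest-scoring chain wins; an exact score
tie between disagreeing chains is reported as ``ambiguous`` (downstream,
a conversion failure).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Literal, Optional, Tuple

from .chain_io import Chain, ChainSet

Status = Literal["mapped", "unmapped", "ambiguous"]

REASON_GAP = "gap"
REASON_NO_CHAIN = "no_chain"
REASON_AMBIGUOUS = "ambiguous"
REASON_INVALID_WIDTH = "invalid_width"


@dataclass(frozen=True)
class LiftResult:
    status: Status
    dest_chrom: Optional[str] = None
    dest_pos: Optional[int] = None  # 0-based, forward strand
    dest_strand: Optional[str] = None
    chain_ordinal: Optional[int] = None
    reason: Optional[str] = None

    @property
    def mapped(self) -> bool:
        return self.status == "mapped"


def normalize_chrom(name: str) -> str:
    """Case-fold and strip a 'chr' prefix for cross-build name comparison."""
    n = name.lower()
    return n[3:] if n.startswith("chr") else n


def lift_position(chains: ChainSet, chrom: str, pos: int) -> LiftResult:
    """Map one 0-based source position to the destination build.

    Unknown chromosomes and positions outside every chain are unmapped,
    not errors.
    """
    if pos < 0:
        raise ValueError(f"negative position {pos}")
    hits = chains.lookup(chrom, pos)
    if not hits:
        return LiftResult("unmapped", reason=REASON_NO_CHAIN)

    # candidates: (dest_chrom, dest_pos, strand, score, ordinal)
    candidates: List[Tuple[str, int, str, float, int]] = []
    in_gap = False
    for ordinal, ch in hits:
        fwd = ch.map_forward(pos)
        if fwd is None:
            in_gap = True
            continue
        h = ch.header
        candidates.append((h.dest_name, fwd, h.dest_strand, h.score, ordinal))

    if not candidates:
        return LiftResult("unmapped", reason=REASON_GAP if in_gap else REASON_NO_CHAIN)

    destinations = {(c[0], c[1]) for c in candidates}
    if len(destinations) == 1:
        best = max(candidates, key=lambda c: (c[3], -c[4]))
        return LiftResult("mapped", best[0], best[1], best[2], best[4])

    top = max(c[3] for c in candidates)
    leaders = [c for c in candidates if c[3] == top]
    if len({(c[0], c[1]) for c in leaders}) > 1:
        return LiftResult("ambiguous", reason=REASON_AMBIGUOUS)
    best = min(leaders, key=lambda c: c[4])
    return LiftResult("mapped", best[0], best[1], best[2], best[4])


# ------------------------------------------------------------- BED records


@dataclass(frozen=True)
class BedRecord:
    chrom: str
    start: int
    end: int
    label: str


def lift_bed_records(
    chains: ChainSet, records: Iterable[BedRecord]
) -> Tuple[List[BedRecord], List[Tuple[BedRecord, str]]]:
    """Partition 1-bp BED records into (mapped, rejected-with-reason).

    Mapped records keep their labels and carry destination coordinates.
    Records wider than 1 bp are rejected per-record with reason
    ``invalid_width`` (multi-base conversion is out of scope), so
    |input| = |mapped| + |rejected| always holds.
    """
    mapped: List[BedRecord] = []
    rejected: List[Tuple[BedRecord, str]] = []
    for rec in records:
        if rec.end != rec.start + 1:
            rejected.append((rec, REASON_INVALID_WIDTH))
            continue
        res = lift_position(chains, rec.chrom, rec.start)
        if res.mapped:
            mapped.append(BedRecord(res.dest_chrom, res.dest_pos, res.dest_pos + 1, rec.label))
        else:
            rejected.append((rec, res.reason or res.status))
    return mapped, rejected


def parse_bed_line(line: str) -> BedRecord:
    f = line.rstrip("\n").split("\t")
    label = f[3] if len(f) > 3 else f"{f[0]}:{f[1]}"
    return BedRecord(f[0], int(f[1]), int(f[2]), label)


# --------------------------------------------------------- piecewise route


@dataclass(frozen=True)
class MapPiece:
    """A maximal source interval with a single resolved lift outcome.

    For ``kind == 'mapped'``: dest(x) = slope * x + intercept (forward
    strand), with slope in {+1, -1}. ``kind == 'ambiguous'`` marks a
    score-tied conflict. Uncovered source intervals emit no piece.
    """

    start: int
    end: int
    kind: Literal["mapped", "ambiguous"]
    dest_chrom: Optional[str] = None
    slope: int = 0
    intercept: int = 0

    def image(self) -> Tuple[int, int]:
        """Forward-strand dest interval (half-open) of a mapped piece."""
        if self.slope == 1:
            return self.start + self.intercept, self.end + self.intercept
        return self.intercept - self.end + 1, self.intercept - self.start + 1

    def back(self, u: int, v: int) -> Tuple[int, int]:
        """Source interval whose image is dest interval [u, v)."""
        if self.slope == 1:
            return u - self.intercept, v - self.intercept
        return self.intercept - v + 1, self.intercept - u + 1


def _chain_affines(chains: ChainSet, chrom: str):
    """Yield (src_start, src_end, dest_chrom, slope, intercept, score, ordinal)
    for every aligned block on chrom, in forward-strand dest coordinates."""
    for ordinal, ch in chains.chains_on(chrom):
        h = ch.header
        for s0, s1, d0 in ch.block_spans():
            if h.dest_strand == "+":
                # fwd = pos + (d0 - s0)
                yield s0, s1, h.dest_name, 1, d0 - s0, h.score, ordinal
            else:
                # fwd = dest_size - 1 - (d0 + pos - s0)
                yield s0, s1, h.dest_name, -1, h.dest_size - 1 - d0 + s0, h.score, ordinal


def piecewise_map(chains: ChainSet, chrom: str) -> List[MapPiece]:
    """Resolve a whole source chromosome into maximal affine map pieces.

    Overlapping blocks from different chains are resolved with the same
    policy as :func:`lift_position`, piecewise: distinct affine maps on an
    elementary interval are ranked by chain score, exact ties between
    disagreeing maps become ``ambiguous`` pieces.
    """
    blocks = list(_chain_affines(chains, chrom))
    if not blocks:
        return []
    bounds = sorted({b[0] for b in blocks} | {b[1] for b in blocks})
    # active-block sweep over elementary intervals
    pieces: List[MapPiece] = []
    events: List[Tuple[int, int, int]] = []  # (coord, +1/-1 via sort, block idx)
    for i, b in enumerate(blocks):
        events.append((b[0], 1, i))
        events.append((b[1], 0, i))
    events.sort(key=lambda t: (t[0], t[1]))
    active: set = set()
    ei = 0
    for k in range(len(bounds) - 1):
        lo, hi = bounds[k], bounds[k + 1]
        while ei < len(events) and events[ei][0] <= lo:
            coord, kind, idx = events[ei]
            if kind == 1 and coord == lo:
                active.add(idx)
            elif kind == 0 and coord <= lo:
                active.discard(idx)
            ei += 1
        if not active:
            continue
        cand = [blocks[i] for i in sorted(active)]
        maps = {}
        for s0, s1, dc, sl, ic, score, ordinal in cand:
            key = (dc, sl, ic)
            if key not in maps or score > maps[key]:
                maps[key] = score
        if len(maps) == 1:
            (dc, sl, ic), _ = next(iter(maps.items()))
            pieces.append(MapPiece(lo, hi, "mapped", dc, sl, ic))
        else:
            top = max(maps.values())
            leaders = [k for k, v in maps.items() if v == top]
            if len(leaders) > 1:
                pieces.append(MapPiece(lo, hi, "ambiguous"))
            else:
                dc, sl, ic = leaders[0]
                pieces.append(MapPiece(lo, hi, "mapped", dc, sl, ic))
    # coalesce adjacent pieces with identical outcome
    out: List[MapPiece] = []
    for p in pieces:
        if (
            out
            and out[-1].end == p.start
            and out[-1].kind == p.kind
            and out[-1].dest_chrom == p.dest_chrom
            and out[-1].slope == p.slope
            and out[-1].intercept == p.intercept
        ):
            out[-1] = MapPiece(out[-1].start, p.end, p.kind, p.dest_chrom, p.slope, p.intercept)
        else:
            out.append(p)
    return out
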