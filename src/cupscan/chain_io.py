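"""UCSC chain-file parsing, validation, indexing and serialization.

A chain describes a scored, gapped pairwise alignment between a source
("target"/t in UCSC terms) and a destination ("query"/q) sequence as a run
of ungapped blocks separated by gaps on either side. All coordinates are
0-based half-open as written in the file; destination coordinates on a
'-'-strand chain are kept raw (reverse-strand) here and converted to
forward-strand coordinates at the lifting layer.
"""

from __future__ import annotations

import gzip
import io
import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, TextIO, Tuple

from intervaltree import IntervalTree

logger = logging.getLogger(__name__)


class ChainParseError(ValueError):
    """Malformed chain text (bad header or body line)."""


class ChainValidationError(ValueError):
    """Structurally parseable chain whose arithmetic invariants fail."""


@dataclass(frozen=True)
class ChainHeader:
    score: float
    source_name: str
    source_size: int
    source_strand: str
    source_start: int
    source_end: int
    dest_name: str
    dest_size: int
    dest_strand: str
    dest_start: int
    dest_end: int
    chain_id: str

    def validate(self) -> None:
        if self.source_strand != "+":
            raise ChainValidationError(
                f"chain {self.chain_id}: source strand must be '+', got {self.source_strand!r}"
            )
        if self.dest_strand not in "+-":
            raise ChainValidationError(f"chain {self.chain_id}: bad dest strand {self.dest_strand!r}")
        if not 0 <= self.source_start < self.source_end <= self.source_size:
            raise ChainValidationError(f"chain {self.chain_id}: source span out of bounds")
        if not 0 <= self.dest_start < self.dest_end <= self.dest_size:
            raise ChainValidationError(f"chain {self.chain_id}: dest span out of bounds")
        if self.score < 0:
            raise ChainValidationError(f"chain {self.chain_id}: negative score")


@dataclass(frozen=True)
class AlignmentBlock:
    size: int
    gap_source: int = 0  # bp skipped on source after this block (UCSC dt)
    gap_dest: int = 0  # bp skipped on dest after this block (UCSC dq)


@dataclass
class Chain:
    header: ChainHeader
    blocks: Tuple[AlignmentBlock, ...]
    # absolute block start coordinates, precomputed for bisection
    _src_starts: List[int] = field(default_factory=list, repr=False)
    _dst_starts: List[int] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        self.header.validate()
        if not self.blocks:
            raise ChainValidationError(f"chain {self.header.chain_id}: no blocks")
        s, d = self.header.source_start, self.header.dest_start
        src_sum = dst_sum = 0
        self._src_starts, self._dst_starts = [], []
        for i, b in enumerate(self.blocks):
            if b.size <= 0 or b.gap_source < 0 or b.gap_dest < 0:
                raise ChainValidationError(
                    f"chain {self.header.chain_id}: bad block {i} ({b.size},{b.gap_source},{b.gap_dest})"
                )
            self._src_starts.append(s)
            self._dst_starts.append(d)
            s += b.size + b.gap_source
            d += b.size + b.gap_dest
            src_sum += b.size + b.gap_source
            dst_sum += b.size + b.gap_dest
        last = self.blocks[-1]
        if last.gap_source or last.gap_dest:
            raise ChainValidationError(f"chain {self.header.chain_id}: final block has trailing gaps")
        if src_sum != self.header.source_end - self.header.source_start:
            raise ChainValidationError(
                f"chain {self.header.chain_id}: source block sum {src_sum} != span "
                f"{self.header.source_end - self.header.source_start}"
            )
        if dst_sum != self.header.dest_end - self.header.dest_start:
            raise ChainValidationError(
                f"chain {self.header.chain_id}: dest block sum {dst_sum} != span "
                f"{self.header.dest_end - self.header.dest_start}"
            )

    def block_spans(self) -> Iterable[Tuple[int, int, int]]:
        """Yield (src_start, src_end, dest_start_raw) per ungapped block.

        dest_start_raw is on the strand the header declares (i.e. as
        written in the file), not necessarily forward.
        """
        for b, s0, d0 in zip(self.blocks, self._src_starts, self._dst_starts):
            yield s0, s0 + b.size, d0

    def map_raw(self, pos: int) -> Optional[int]:
        """Map a source position to the raw (file-strand) dest coordinate.

        Returns None when pos is in an inter-block gap or outside the chain.
        """
        if not self.header.source_start <= pos < self.header.source_end:
            return None
        i = bisect_right(self._src_starts, pos) - 1
        if i < 0:
            return None
        off = pos - self._src_starts[i]
        if off >= self.blocks[i].size:
            return None  # gap
        return self._dst_starts[i] + off

    def map_forward(self, pos: int) -> Optional[int]:
        """Map a source position to a forward-strand dest coordinate."""
        raw = self.map_raw(pos)
        if raw is None:
            return None
        if self.header.dest_strand == "-":
            return self.header.dest_size - raw - 1
        return raw


class ChainSet:
    """A collection of chains with an interval index over source coordinates.

    ``lookup(chrom, pos)`` returns every chain whose overall source span
    (aligned blocks *or* internal gaps) covers pos, as (ordinal, chain).
    """

    def __init__(self, chains: Sequence[Chain], direction_label: str = ""):
        self.chains: List[Chain] = list(chains)
        self.direction_label = direction_label
        self._index: Dict[str, IntervalTree] = {}
        seen_ids: Dict[str, int] = {}
        for ordinal, ch in enumerate(self.chains):
            h = ch.header
            seen_ids[h.chain_id] = seen_ids.get(h.chain_id, 0) + 1
            self._index.setdefault(h.source_name, IntervalTree()).addi(
                h.source_start, h.source_end, ordinal
            )
        dups = [cid for cid, n in seen_ids.items() if n > 1]
        if dups:
            logger.warning(
                "%s: duplicate chain ids %s; chains are keyed by ordinal",
                direction_label or "chain set",
                dups[:5],
            )
        self._unknown_chroms: set = set()

    def __len__(self) -> int:
        return len(self.chains)

    def source_chroms(self) -> List[str]:
        return sorted(self._index)

    def lookup(self, chrom: str, pos: int) -> List[Tuple[int, Chain]]:
        tree = self._index.get(chrom)
        if tree is None:
            if chrom not in self._unknown_chroms:
                self._unknown_chroms.add(chrom)
                logger.info("no chains for chromosome %r", chrom)
            return []
        return sorted((iv.data, self.chains[iv.data]) for iv in tree.at(pos))

    def chains_on(self, chrom: str) -> List[Tuple[int, Chain]]:
        tree = self._index.get(chrom)
        if tree is None:
            return []
        return sorted((iv.data, self.chains[iv.data]) for iv in tree)


# ---------------------------------------------------------------- parsing


def _open_text(source) -> TextIO:
    if isinstance(source, (str, Path)):
        p = str(source)
        if p.endswith(".gz"):
            return io.TextIOWrapper(gzip.open(p, "rb"))
        return open(p)
    return source


def parse_chain_file(source, direction_label: str = "") -> ChainSet:
    """Parse chain-format text from a path or text stream into a ChainSet.

    Raises ChainParseError (with line number) on malformed lines and
    ChainValidationError (naming the chain id) when block sums disagree
    with the header spans.
    """
    fh = _open_text(source)
    close = isinstance(source, (str, Path))
    chains: List[Chain] = []
    header: Optional[ChainHeader] = None
    blocks: List[AlignmentBlock] = []
    try:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("chain"):
                if header is not None:
                    raise ChainParseError(
                        f"line {lineno}: new chain begins before chain "
                        f"{header.chain_id} was terminated"
                    )
                f = line.split()
                if len(f) != 13:
                    raise ChainParseError(f"line {lineno}: header has {len(f)} fields, expected 13")
                try:
                    header = ChainHeader(
                        score=float(f[1]),
                        source_name=f[2],
                        source_size=int(f[3]),
                        source_strand=f[4],
                        source_start=int(f[5]),
                        source_end=int(f[6]),
                        dest_name=f[7],
                        dest_size=int(f[8]),
                        dest_strand=f[9],
                        dest_start=int(f[10]),
                        dest_end=int(f[11]),
                        chain_id=f[12],
                    )
                except ValueError as exc:
                    raise ChainParseError(f"line {lineno}: {exc}") from None
                blocks = []
            else:
                if header is None:
                    raise ChainParseError(f"line {lineno}: alignment data outside any chain")
                f = line.split()
                try:
                    if len(f) == 3:
                        blocks.append(AlignmentBlock(int(f[0]), int(f[1]), int(f[2])))
                    elif len(f) == 1:
                        blocks.append(AlignmentBlock(int(f[0])))
                        chains.append(Chain(header, tuple(blocks)))
                        header, blocks = None, []
                    else:
                        raise ChainParseError(
                            f"line {lineno}: body line has {len(f)} fields, expected 1 or 3"
                        )
                except ChainValidationError:
                    raise
                except ValueError as exc:
                    raise ChainParseError(f"line {lineno}: {exc}") from None
        if header is not None:
            raise ChainParseError(f"chain {header.chain_id}: file ended before final block line")
    finally:
        if close:
            fh.close()
    return ChainSet(chains, direction_label=direction_label)


def write_chain_file(chain_set: ChainSet, dest) -> None:
    """Serialize a ChainSet; output re-parses to an equal structure."""
    fh = open(dest, "w") if isinstance(dest, (str, Path)) else dest
    try:
        for ch in chain_set.chains:
            h = ch.header
            score = int(h.score) if float(h.score).is_integer() else h.score
            fh.write(
                f"chain {score} {h.source_name} {h.source_size} {h.source_strand} "
                f"{h.source_start} {h.source_end} {h.dest_name} {h.dest_size} "
                f"{h.dest_strand} {h.dest_start} {h.dest_end} {h.chain_id}\n"
            )
            for b in ch.blocks[:-1]:
                fh.write(f"{b.size} {b.gap_source} {b.gap_dest}\n")
            fh.write(f"{ch.blocks[-1].size}\n\n")
    finally:
        if isinstance(dest, (str, Path)):
            fh.close()


def read_chrom_sizes(source) -> Dict[str, int]:
    """Two-column TSV (name, length) -> ordered dict of sizes."""
    fh = _open_text(source)
    close = isinstance(source, (str, Path))
    sizes: Dict[str, int] = {}
    try:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, length = line.split()[:2]
            sizes[name] = int(length)
    finally:
        if close:
            fh.close()
    return sizes
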