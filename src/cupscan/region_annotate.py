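"""Overlap statistics between CUP categories and assembly annotation sets.

The question asked here: what fraction of each unstable-position category
is explained by known assembly annotation — gaps in the build, contig
updates between builds, segmental duplications? The headline statistic is
the overlap proportion |A n B| / |A| for a CUP category A and an
annotation set B, with the three annotation sets additionally partitioned
into exclusive ("gap only", ...), "multiple" (in strictly more than one
set) and "other" (in none) components.

The GRCh37 gap track contains the centromeres (they were not part of that
assembly); for a like-for-like comparison with builds whose gap track does
not, centromere rows can be removed from the gap set before comparison and
re-attributed separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Tuple

import pandas as pd

from .regions import RegionSet


def intersect_bp(a: RegionSet, b: RegionSet) -> int:
    """Exact bp of overlap between two region sets (commutative)."""
    return a.intersection(b).total_bp


def overlap_proportion(a: RegionSet, b: RegionSet) -> Optional[float]:
    """|A n B| / |A|; None (not-applicable, never 0) when A is empty."""
    denom = a.total_bp
    if denom == 0:
        return None
    return intersect_bp(a, b) / denom


@dataclass
class AnnotationPartition:
    """Exclusive decomposition of three annotation sets over a genome."""

    gap_only: RegionSet
    contigdiff_only: RegionSet
    segdup_only: RegionSet
    multiple: RegionSet  # in strictly more than one input set
    other: RegionSet  # in none of them

    def as_dict(self) -> Dict[str, RegionSet]:
        return {
            "gap_only": self.gap_only,
            "contigdiff_only": self.contigdiff_only,
            "segdup_only": self.segdup_only,
            "multiple": self.multiple,
            "other": self.other,
        }


def partition_annotations(
    gap: RegionSet,
    contigdiff: RegionSet,
    segdup: RegionSet,
    chrom_sizes: Mapping[str, int],
) -> AnnotationPartition:
    """Split the genome into {gap,contigdiff,segdup}-exclusive, multiple
    and other components. The five sets are pairwise disjoint and cover
    the genome; the first four union to the union of the inputs."""
    pairwise = (
        gap.intersection(contigdiff)
        .union(gap.intersection(segdup))
        .union(contigdiff.intersection(segdup))
    )
    union = gap.union(contigdiff).union(segdup)
    return AnnotationPartition(
        gap_only=gap.difference(contigdiff).difference(segdup),
        contigdiff_only=contigdiff.difference(gap).difference(segdup),
        segdup_only=segdup.difference(gap).difference(contigdiff),
        multiple=pairwise,
        other=union.complement(chrom_sizes),
    )


def load_ucsc_table(
    path,
    column_map: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Read a UCSC Table Browser TSV dump (header line may start with '#').

    column_map renames source columns to the canonical
    chrom/chromStart/chromEnd(/type) names when a table uses different ones.
    """
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lstrip("#") for c in df.columns]
    if column_map:
        df = df.rename(columns=dict(column_map))
    for col in ("chrom", "chromStart", "chromEnd"):
        if col not in df.columns:
            raise ValueError(f"UCSC table {path}: missing column {col!r}")
    return df


def table_regions(df: pd.DataFrame) -> RegionSet:
    """Region set of a UCSC table (0-based half-open, as distributed)."""
    return RegionSet.from_pairs(
        zip(df["chrom"].astype(str), df["chromStart"].astype(int), df["chromEnd"].astype(int))
    )


def remove_centromeres(gap_table: pd.DataFrame) -> Tuple[RegionSet, RegionSet]:
    """Split a UCSC gap table into (non-centromere gaps, centromeres).

    The removed centromere regions are returned separately so their
    contribution to a CUP category can be re-attributed after the main
    comparison. Requires the gap-track ``type`` column.
    """
    if "type" not in gap_table.columns:
        raise ValueError("gap table has no 'type' column; cannot identify centromeres")
    is_cen = gap_table["type"].astype(str).str.lower() == "centromere"
    return table_regions(gap_table[~is_cen]), table_regions(gap_table[is_cen])


def overlap_report(
    cup_regions: Mapping[str, RegionSet],
    annotation_sets: Mapping[str, RegionSet],
) -> pd.DataFrame:
    """Long-format table of bp overlap and proportion per (category, set).

    Proportions are additionally rounded to 0.1% in a display column;
    raw bp counts are always present.
    """
    rows = []
    for cat, a in cup_regions.items():
        for name, b in annotation_sets.items():
            prop = overlap_proportion(a, b)
            rows.append(
                {
                    "category": cat,
                    "annotation": name,
                    "category_bp": a.total_bp,
                    "overlap_bp": intersect_bp(a, b),
                    "proportion": prop,
                    "proportion_pct": None if prop is None else round(100.0 * prop, 1),
                }
            )
    return pd.DataFrame(rows)
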