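"""Genome-architecture accounting on the circular genome.

Spacer/overlap bookkeeping between genomically adjacent features (the
origin-spanning pair included), strand tallies, and per-category totals —
the numbers that characterize how tightly a mitogenome is packed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .model_io import MitogenomeAnnotation, gene_length

_STRAND_OUT = {"+": "F", "-": "R", None: "-"}


@dataclass(frozen=True)
class SpacerRecord:
    """Gap between two adjacent features; negative = overlap, 0 = abutting."""

    upstream: str
    downstream: str
    spacer: int
    wraps_origin: bool = False


def pairwise_spacers(ann: MitogenomeAnnotation) -> list[SpacerRecord]:
    """One spacer per adjacent feature pair, in genomic order.

    spacer = downstream.start - upstream.end - 1, wrapped across the origin
    for the last/first pair on a circular genome.
    """
    recs = ann.records
    if len(recs) < 2:
        raise ValueError("need at least 2 records to compute spacers")
    out = []
    for up, down in zip(recs, recs[1:]):
        out.append(SpacerRecord(up.name, down.name, down.start - up.end - 1))
    if ann.circular:
        last, first = recs[-1], recs[0]
        if last.end < last.start:
            # the last record wraps the origin; it may overlap the first
            wrap = first.start - last.end - 1
        else:
            wrap = (first.start - last.end - 1) % ann.genome_length
        out.append(SpacerRecord(last.name, first.name, wrap, wraps_origin=True))
    return out


def overlap_summary(ann: MitogenomeAnnotation) -> tuple[int, int, Optional[tuple[str, str, int]]]:
    """(number of overlapping pairs, total overlap bp, longest pair).

    Only genomically adjacent pairs are considered, so a triple overlap is
    counted once per adjacency and never double-counted.
    """
    overlaps = [s for s in pairwise_spacers(ann) if s.spacer < 0]
    if not overlaps:
        return 0, 0, None
    longest = max(overlaps, key=lambda s: -s.spacer)
    return (len(overlaps), sum(-s.spacer for s in overlaps),
            (longest.upstream, longest.downstream, -longest.spacer))


def intergenic_summary(ann: MitogenomeAnnotation,
                       include_origin: bool = False) -> tuple[int, int, int]:
    """(number of intergenic regions, total intergenic bp, longest region).

    Counts positive spacers only.  The unannotated stretch at the origin
    (between the last and first feature) is excluded by default, matching
    how published tables leave the first gene's intergenic cell empty.
    """
    spacers = [s for s in pairwise_spacers(ann)
               if s.spacer > 0 and (include_origin or not s.wraps_origin)]
    if not spacers:
        return 0, 0, 0
    return len(spacers), sum(s.spacer for s in spacers), max(s.spacer for s in spacers)


def strand_tally(ann: MitogenomeAnnotation) -> tuple[int, int]:
    """(plus count, minus count) over all stranded records.

    The control region carries no strand and is excluded.
    """
    plus = sum(1 for r in ann.records if r.strand == "+")
    minus = sum(1 for r in ann.records if r.strand == "-")
    return plus, minus


def category_totals(ann: MitogenomeAnnotation) -> pd.DataFrame:
    """Per category (PCG/tRNA/rRNA/CR): record count and summed coordinate-
    derived length in bp."""
    rows = []
    for cat in ("PCG", "tRNA", "rRNA", "CR"):
        members = [r for r in ann.records if r.category == cat]
        rows.append({
            "category": cat,
            "count": len(members),
            "total_bp": sum(gene_length(r, ann.genome_length, ann.circular)
                            for r in members),
        })
    return pd.DataFrame(rows)


def architecture_report(ann: MitogenomeAnnotation) -> pd.DataFrame:
    """Per-gene table: coordinates, coordinate length, strand, spacer to the
    next feature."""
    spacers = {s.upstream: s for s in pairwise_spacers(ann)}
    rows = []
    for r in ann.records:
        s = spacers.get(r.name)
        rows.append({
            "gene": r.name, "start": r.start, "end": r.end,
            "length": gene_length(r, ann.genome_length, ann.circular),
            "strand": _STRAND_OUT[r.strand],
            "spacer_to_next": s.spacer if s else pd.NA,
            "wraps_origin": bool(s.wraps_origin) if s else False,
        })
    return pd.DataFrame(rows)
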