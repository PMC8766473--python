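"""Gene-junction ledger: overlaps, intergenic spacers and strand tallies.

For consecutive features (in start order) the signed gap is::

    gap = start(downstream) - end(upstream) - 1

Negative gaps are overlaps, positive gaps are spacers, zero means the genes
abut.  The circle is closed with one wrapping junction from the last feature
back to the first, for which the downstream start is shifted by the genome
length.  Zero-gap junctions count as neither overlap nor spacer.  The strand
tally excludes the control region, which carries no strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .annotation_io import MitogenomeRecord
from .errors import ValidationError


@dataclass(frozen=True)
class JunctionRecord:
    upstream_gene: str
    downstream_gene: str
    gap: int
    wraps_origin: bool = False


@dataclass
class ArchitectureReport:
    junctions: list[JunctionRecord]
    n_overlaps: int
    total_overlap_bp: int
    longest_overlap: Optional[tuple[tuple[str, str], int]]
    n_spacers: int
    total_spacer_bp: int
    longest_spacer: Optional[tuple[tuple[str, str], int]]
    n_plus_strand: int
    n_minus_strand: int
    class_totals: dict[str, int] = field(default_factory=dict)
    genome_length: int = 0


def junction_ledger(record: MitogenomeRecord) -> list[JunctionRecord]:
    """One junction per consecutive feature pair, plus the wrap-around."""
    feats = record.features
    if len(feats) < 2:
        raise ValidationError("need at least 2 features for a junction ledger")
    length = record.genome_length
    junctions = []
    for up, down in zip(feats, feats[1:]):
        junctions.append(JunctionRecord(up.name, down.name,
                                        down.start - up.end - 1))
    first, last = feats[0], feats[-1]
    junctions.append(JunctionRecord(
        last.name, first.name, (first.start + length) - last.end - 1,
        wraps_origin=True))
    return junctions


def architecture_report(record: MitogenomeRecord) -> ArchitectureReport:
    junctions = junction_ledger(record)
    overlaps = [j for j in junctions if j.gap < 0]
    spacers = [j for j in junctions if j.gap > 0]

    def _extreme(js, key):
        if not js:
            return None
        best = max(js, key=key)
        return ((best.upstream_gene, best.downstream_gene), abs(best.gap))

    class_totals: dict[str, int] = {}
    for f in record.features:
        class_totals[f.gene_class] = class_totals.get(f.gene_class, 0) + f.size

    stranded = [f for f in record.features if f.gene_class != "control_region"]
    return ArchitectureReport(
        junctions=junctions,
        n_overlaps=len(overlaps),
        total_overlap_bp=sum(-j.gap for j in overlaps),
        longest_overlap=_extreme(overlaps, key=lambda j: -j.gap),
        n_spacers=len(spacers),
        total_spacer_bp=sum(j.gap for j in spacers),
        longest_spacer=_extreme(spacers, key=lambda j: j.gap),
        n_plus_strand=sum(1 for f in stranded if f.strand == "+"),
        n_minus_strand=sum(1 for f in stranded if f.strand == "-"),
        class_totals=class_totals,
        genome_length=record.genome_length,
    )


def pcg_fraction(record: MitogenomeRecord) -> float:
    """Percentage of the genome occupied by protein-coding genes.

    Full precision is returned; round to 2 decimals for display.
    """
    pcgs = record.by_class("PCG")
    if not pcgs:
        raise ValidationError("record has no protein-coding genes")
    length = record.genome_length
    if length == 0:
        raise ValidationError("genome length is zero")
    return 100.0 * sum(f.size for f in pcgs) / length
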