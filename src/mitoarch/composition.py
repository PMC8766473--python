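"""Base composition and strand skews per region class.

Skews are computed on raw counts::

    at_skew = (A - T) / (A + T)        gc_skew = (G - C) / (G + C)

and reported as ``None`` (not 0) when the denominator is zero.  N bases are
excluded from all denominators.

Per-class profiles concatenate feature subsequences in genomic order on the
reference (plus) strand for every feature, minus-strand genes included: the
whole-genome and per-class skews are mutually consistent only under a
single-strand convention.  Overlapping bases are counted once per feature
they belong to (concatenation semantics), so per-class totals match the
annotation's summed gene sizes, not the union of covered positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .annotation_io import MitogenomeRecord
from .errors import ValidationError

#: region-class label used in profiles for each feature class
_CLASS_LABELS = (("PCG", "PCG"), ("tRNA", "tRNA"),
                 ("rRNA", "rRNA"), ("control_region", "CR"))


@dataclass
class CompositionProfile:
    region_class: str
    length_bp: int
    counts: dict[str, int]
    pct_A: float
    pct_T: float
    pct_G: float
    pct_C: float
    gc_content: float
    at_skew: Optional[float]
    gc_skew: Optional[float]

    def rounded(self, ndigits: int = 2) -> dict:
        """Display form: percentages and skews rounded half-even."""
        rnd = lambda v: None if v is None else round(v, ndigits)
        return {
            "region_class": self.region_class,
            "length_bp": self.length_bp,
            "pct_A": rnd(self.pct_A), "pct_T": rnd(self.pct_T),
            "pct_G": rnd(self.pct_G), "pct_C": rnd(self.pct_C),
            "gc_content": rnd(self.gc_content),
            "at_skew": rnd(self.at_skew), "gc_skew": rnd(self.gc_skew),
        }


def composition_profile(sequence: str, region_class: str = "genome") -> CompositionProfile:
    """Profile one sequence; length includes N, percentages exclude N."""
    if not sequence:
        raise ValidationError("empty sequence")
    seq = sequence.upper()
    counts = {b: seq.count(b) for b in "ACGT"}
    total = sum(counts.values())
    if total == 0:
        raise ValidationError("sequence contains no A/C/G/T bases")
    a, c, g, t = counts["A"], counts["C"], counts["G"], counts["T"]
    at_skew = (a - t) / (a + t) if a + t else None
    gc_skew = (g - c) / (g + c) if g + c else None
    pct = lambda n: 100.0 * n / total
    return CompositionProfile(
        region_class=region_class,
        length_bp=len(seq),
        counts=counts,
        pct_A=pct(a), pct_T=pct(t), pct_G=pct(g), pct_C=pct(c),
        gc_content=pct(g + c),
        at_skew=at_skew, gc_skew=gc_skew,
    )


def region_profiles(record: MitogenomeRecord) -> list[CompositionProfile]:
    """Whole-genome profile plus one per gene class present in the record."""
    if record.sequence is None:
        raise ValidationError("record has no sequence")
    seq = record.sequence
    for f in record.features:
        if f.end > len(seq):
            raise ValidationError(f"{f.name} exceeds sequence bounds")
    profiles = [composition_profile(seq, "genome")]
    for gene_class, label in _CLASS_LABELS:
        feats = record.by_class(gene_class)
        if not feats:
            continue
        concat = "".join(seq[f.start - 1:f.end] for f in feats)
        profiles.append(composition_profile(concat, label))
    return profiles
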