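"""Uncorrected p-distance and variable-site counting on aligned sequences.

Defaults follow common practice for reporting "genetic distance" on rRNA
alignments: uncorrected p-distance with pairwise deletion of gap/N sites.
A Jukes-Cantor corrected mode is available behind ``model="jc"`` but is not
the default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from Bio import SeqIO

from .errors import ValidationError

_MISSING = set("-N")
_VALID = set("ACGTN-")


@dataclass
class AlignedSet:
    labels: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValidationError("empty alignment")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValidationError(f"unequal sequence lengths: {sorted(lengths)}")
        self.sequences = [s.upper() for s in self.sequences]
        for label, seq in zip(self.labels, self.sequences):
            bad = set(seq) - _VALID
            if bad:
                raise ValidationError(f"{label}: invalid characters {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    @classmethod
    def from_fasta(cls, path) -> "AlignedSet":
        records = list(SeqIO.parse(path, "fasta"))
        return cls(labels=[r.id for r in records],
                   sequences=[str(r.seq) for r in records])


def p_distance(a: str, b: str, deletion_mode: str = "pairwise",
               model: str = "p") -> float:
    """Proportion of differing sites between two aligned sequences.

    Sites with a gap or N in either sequence are excluded (pairwise
    deletion; ``complete-set`` deletion is applied at the matrix level by
    :func:`distance_matrix` and is equivalent to pairwise for two
    sequences).  ``model="jc"`` applies the Jukes-Cantor correction.
    """
    if deletion_mode not in ("pairwise", "complete-set"):
        raise ValidationError(f"unknown deletion mode {deletion_mode!r}")
    if len(a) != len(b):
        raise ValidationError("sequences have different lengths")
    a, b = a.upper(), b.upper()
    compared = diffs = 0
    for x, y in zip(a, b):
        if x in _MISSING or y in _MISSING:
            continue
        compared += 1
        if x != y:
            diffs += 1
    if compared == 0:
        raise ValidationError("no comparable sites")
    p = diffs / compared
    if model == "jc":
        if p >= 0.75:
            raise ValidationError("p-distance saturated; JC undefined")
        return -0.75 * math.log1p(-4.0 * p / 3.0)
    return p


def distance_matrix(aligned: AlignedSet, deletion_mode: str = "pairwise",
                    model: str = "p") -> pd.DataFrame:
    """Symmetric distance matrix over all sequence pairs."""
    seqs = aligned.sequences
    if deletion_mode == "complete-set":
        keep = [i for i in range(aligned.length)
                if not any(s[i] in _MISSING for s in seqs)]
        if not keep:
            raise ValidationError("complete-set deletion removed every site")
        seqs = ["".join(s[i] for i in keep) for s in seqs]
    n = len(seqs)
    mat = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            d = p_distance(seqs[i], seqs[j], model=model)
            mat[i][j] = mat[j][i] = d
    return pd.DataFrame(mat, index=aligned.labels, columns=aligned.labels)


def variable_sites(aligned: AlignedSet) -> int:
    """Number of columns with >= 2 distinct non-gap, non-N states."""
    if len(aligned.sequences) < 2:
        raise ValidationError("need at least 2 sequences")
    count = 0
    for i in range(aligned.length):
        states = {s[i] for s in aligned.sequences} - _MISSING
        if len(states) >= 2:
            count += 1
    return count
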