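"""Codon extraction, codon-usage tabulation, RSCU and amino-acid abundance.

The default genetic code is the vertebrate mitochondrial code (NCBI table 2),
under which AGA/AGG are stops and ATA encodes Met.  Synonymous-family
degeneracies are always derived from the active code table, never hard-coded.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping, Optional, Union

from Bio.Data import CodonTable as _BioCodonTable
from Bio.SeqUtils import seq3

from .annotation_io import MitogenomeRecord
from .errors import ValidationError
from .sequtils import reverse_complement

_CODE_IDS = {
    "vert-mito": 2,
    "vertebrate-mitochondrial": 2,
    "standard": 1,
}

ALL_CODONS = tuple("".join(p) for p in product("TCAG", repeat=3))


class CodonTable:
    """A genetic code: codon->amino-acid map, stop set, synonymous families."""

    def __init__(self, code_id: str = "vert-mito"):
        try:
            ncbi_id = _CODE_IDS.get(code_id) or int(code_id)
        except ValueError:
            raise ValidationError(f"unknown genetic code {code_id!r}") from None
        table = _BioCodonTable.unambiguous_dna_by_id[ncbi_id]
        self.code_id = code_id
        self.ncbi_id = ncbi_id
        self.stops = frozenset(table.stop_codons)
        self.forward = dict(table.forward_table)  # sense codons only
        self.sense_codons = tuple(c for c in ALL_CODONS if c not in self.stops)
        families: dict[str, list[str]] = {}
        for codon in self.sense_codons:
            families.setdefault(self.forward[codon], []).append(codon)
        self.families = {aa: tuple(cs) for aa, cs in families.items()}

    def aa(self, codon: str) -> Optional[str]:
        """One-letter amino acid, or None for a stop codon."""
        return self.forward.get(codon)

    def is_stop(self, codon: str) -> bool:
        return codon in self.stops

    def degeneracy(self, codon: str) -> int:
        return len(self.families[self.forward[codon]])


VERTEBRATE_MITO = CodonTable("vert-mito")


@dataclass
class CodonExtraction:
    gene: str
    start_codon: str
    stop_codon: Optional[str]
    codons: list[str]
    warnings: list[str] = field(default_factory=list)


def extract_codons(record: MitogenomeRecord, gene: str,
                   code: CodonTable = VERTEBRATE_MITO) -> CodonExtraction:
    """In-frame codons of one PCG, minus the terminal stop.

    Minus-strand genes are reverse-complemented before reading the frame.
    A trailing 1-2 nt remainder is reported as an incomplete stop token in
    the style ``T(AA)`` and excluded from the codon list.  Internal stop
    codons produce warnings, not errors (they stay in the list).
    """
    feat = record.feature(gene)
    if feat.gene_class != "PCG":
        raise ValidationError(f"{gene} is not a protein-coding gene")
    if record.sequence is None:
        raise ValidationError("record has no sequence")
    cds = record.sequence[feat.start - 1:feat.end]
    if feat.strand == "-":
        cds = reverse_complement(cds)
    if len(cds) < 6:
        raise ValidationError(f"{gene}: CDS shorter than 6 nt")

    n_full = len(cds) // 3
    codons = [cds[3 * i:3 * i + 3] for i in range(n_full)]
    remainder = cds[3 * n_full:]
    warnings: list[str] = []
    if remainder:
        stop = f"{remainder}({'A' * (3 - len(remainder))})"
    elif code.is_stop(codons[-1]):
        stop = codons.pop()
    else:
        stop = None
        warnings.append(f"{gene}: no terminal stop codon (last codon {codons[-1]})")
    for i, c in enumerate(codons):
        if code.is_stop(c):
            warnings.append(f"{gene}: internal stop {c} at codon {i + 1}")
    return CodonExtraction(gene=gene, start_codon=codons[0], stop_codon=stop,
                           codons=codons, warnings=warnings)


def count_codons(source: Union[Iterable[str], Mapping[str, int]]) -> Counter:
    if isinstance(source, Mapping):
        return Counter(source)
    return Counter(source)


@dataclass(frozen=True)
class RSCURow:
    codon: str
    amino_acid: str
    count: int
    degeneracy: int
    rscu: Optional[float]


@dataclass
class RSCUTable:
    code_id: str
    rows: list[RSCURow]

    def __getitem__(self, codon: str) -> RSCURow:
        for row in self.rows:
            if row.codon == codon:
                return row
        raise KeyError(codon)


def rscu(counts: Union[Iterable[str], Mapping[str, int]],
         code: CodonTable = VERTEBRATE_MITO) -> RSCUTable:
    """Relative synonymous codon usage over all sense codons of the code.

    ``rscu(c) = degeneracy * count(c) / family_total``; undefined (None)
    for codons of a family never observed.  Stop codons are ignored.
    """
    tab = count_codons(counts)
    observed = {c: n for c, n in tab.items() if c in code.forward}
    if not any(observed.values()):
        raise ValidationError("no sense codons counted")
    rows = []
    for aa_sym, family in sorted(code.families.items()):
        fam_total = sum(observed.get(c, 0) for c in family)
        for codon in family:
            n = observed.get(codon, 0)
            value = len(family) * n / fam_total if fam_total else None
            rows.append(RSCURow(codon=codon, amino_acid=aa_sym, count=n,
                                degeneracy=len(family), rscu=value))
    return RSCUTable(code_id=code.code_id, rows=rows)


def aa_abundance(counts: Union[Iterable[str], Mapping[str, int]],
                 code: CodonTable = VERTEBRATE_MITO) -> dict[str, float]:
    """Relative amino-acid frequencies (three-letter names, sum to 1)."""
    tab = count_codons(counts)
    aa_counts: Counter = Counter()
    for codon, n in tab.items():
        aa_sym = code.aa(codon)
        if aa_sym is not None:
            aa_counts[seq3(aa_sym)] += n
    total = sum(aa_counts.values())
    if total == 0:
        raise ValidationError("no sense codons counted")
    return {aa_name: n / total for aa_name, n in sorted(aa_counts.items())}


def genome_codon_counts(record: MitogenomeRecord,
                        code: CodonTable = VERTEBRATE_MITO,
                        genes: Optional[list[str]] = None) -> Counter:
    """Codon counts concatenated over PCGs (stops and incomplete tails excluded)."""
    targets = genes or [f.name for f in record.by_class("PCG")]
    total: Counter = Counter()
    for gene in targets:
        ext = extract_codons(record, gene, code=code)
        total.update(c for c in ext.codons if not code.is_stop(c))
    return total
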