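"""Read and write annotated mitogenomes.

Supported inputs are GenBank flat files and a FASTA + gene-table TSV pair.
Coordinates are 1-based inclusive everywhere; origin-spanning features are
rejected (none occur in the packaged reference annotation).

The gene-table TSV dialect is UTF-8, tab-separated, with header::

    gene  strand  start  end  size  anticodon  start_codon  stop_codon

and ``.`` for absent values.  The ``size`` column is optional on input and
derived from the coordinates when missing.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Optional

from Bio import SeqIO

from .errors import LengthError, ParseError, UnsupportedFeatureError, ValidationError

GENE_CLASSES = ("PCG", "tRNA", "rRNA", "control_region")

#: vertebrate-mitochondrial stop triplets, used only for GenBank codon capture
_MITO_STOPS = frozenset({"TAA", "TAG", "AGA", "AGG"})

_INCOMPLETE_STOP_RE = re.compile(r"^([ACGT]{1,2})\(([ACGT]{1,2})\)$")

_TSV_COLUMNS = ("gene", "strand", "start", "end", "size",
                "anticodon", "start_codon", "stop_codon")


@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene (a single row of a gene table)."""

    name: str
    gene_class: str
    strand: Optional[str]  # "+", "-" or None (control region has no strand)
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive, start <= end
    anticodon: Optional[str] = None
    start_codon: Optional[str] = None
    stop_codon: Optional[str] = None

    @property
    def size(self) -> int:
        return self.end - self.start + 1

    @property
    def has_incomplete_stop(self) -> bool:
        tok = self.stop_codon
        if tok is None:
            return False
        return len(tok) < 3 or bool(_INCOMPLETE_STOP_RE.match(tok))

    def validate(self) -> None:
        if self.gene_class not in GENE_CLASSES:
            raise ValidationError(f"{self.name}: unknown gene class {self.gene_class!r}")
        if self.start < 1 or self.end < self.start:
            raise ValidationError(
                f"{self.name}: bad coordinates {self.start}..{self.end} "
                "(origin-spanning features are not supported)")
        if self.strand not in ("+", "-", None):
            raise ValidationError(f"{self.name}: bad strand {self.strand!r}")
        if (self.anticodon is not None) != (self.gene_class == "tRNA"):
            raise ValidationError(
                f"{self.name}: anticodon present iff gene class is tRNA")


@dataclass
class MitogenomeRecord:
    """A circular mitogenome: sequence plus ordered feature list."""

    accession: str = ""
    species: str = ""
    sequence: Optional[str] = None
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        # canonical order: by start, ties broken by end descending
        self.features = sorted(self.features, key=lambda f: (f.start, -f.end))
        if self.sequence is not None:
            self.sequence = self.sequence.upper()

    @property
    def genome_length(self) -> int:
        if self.sequence is not None:
            return len(self.sequence)
        return max((f.end for f in self.features), default=0)

    def feature(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def by_class(self, gene_class: str) -> list[GeneFeature]:
        return [f for f in self.features if f.gene_class == gene_class]

    def validate(self) -> None:
        if not self.features:
            raise ValidationError("record has no features")
        for f in self.features:
            f.validate()
        if self.sequence is not None:
            bad = [f.name for f in self.features if f.end > len(self.sequence)]
            if bad:
                raise LengthError(
                    f"features exceed sequence length {len(self.sequence)}: "
                    + ", ".join(bad))


def classify_gene_name(name: str) -> str:
    """Infer the gene class of a gene-table row from its symbol."""
    low = name.strip().lower()
    if low.startswith("trn"):
        return "tRNA"
    if low.startswith("rrn") or low in ("12s", "16s"):
        return "rRNA"
    if low in ("cr", "d-loop", "dloop", "d_loop", "control_region", "control region"):
        return "control_region"
    return "PCG"


def _cell(value: Optional[str]) -> Optional[str]:
    if value is None:
        return None
    value = value.strip()
    # tolerate the unicode minus occasionally produced by table exports
    value = value.replace("−", "-")
    return value if value not in (".", "", "-") else value if value == "-" else None


def read_gene_table(tsv, fasta=None) -> MitogenomeRecord:
    """Load a gene-table TSV (path or file object), optionally with a FASTA.

    The ``size`` column, when present, is cross-checked against the
    coordinates; all offending rows are reported at once.
    """
    close = False
    if isinstance(tsv, (str, bytes)) or hasattr(tsv, "__fspath__"):
        handle = open(tsv, "r", encoding="utf-8", newline="")
        close = True
    else:
        handle = tsv
    try:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None:
            raise ValidationError("empty gene table (no header row)")
        missing = {"gene", "strand", "start", "end"} - set(reader.fieldnames)
        if missing:
            raise ValidationError(f"gene table missing columns: {sorted(missing)}")
        features: list[GeneFeature] = []
        size_errors: list[str] = []
        for i, row in enumerate(reader, start=2):
            name = (row.get("gene") or "").strip()
            if not name:
                raise ValidationError(f"line {i}: empty gene name")
            try:
                start = int(row["start"])
                end = int(row["end"])
            except (TypeError, ValueError) as exc:
                raise ValidationError(f"line {i}: bad coordinates: {exc}") from exc
            strand = _cell(row.get("strand"))
            anticodon = _cell(row.get("anticodon"))
            size_cell = _cell(row.get("size"))
            if size_cell is not None and int(size_cell) != end - start + 1:
                size_errors.append(
                    f"line {i} ({name}): size {size_cell} != {end - start + 1}")
            gene_class = classify_gene_name(name)
            if gene_class == "PCG" and anticodon is not None:
                gene_class = "tRNA"  # unknown name but clearly a tRNA row
            feat = GeneFeature(
                name=name,
                gene_class=gene_class,
                strand=strand,
                start=start,
                end=end,
                anticodon=anticodon,
                start_codon=_cell(row.get("start_codon")),
                stop_codon=_cell(row.get("stop_codon")),
            )
            feat.validate()
            features.append(feat)
        if size_errors:
            raise ValidationError("size column contradicts coordinates:\n  "
                                  + "\n  ".join(size_errors))
        if not features:
            raise ValidationError("empty gene table (no data rows)")
    finally:
        if close:
            handle.close()

    sequence = None
    accession = species = ""
    if fasta is not None:
        seqrec = SeqIO.read(fasta, "fasta")
        sequence = str(seqrec.seq).upper()
        accession = seqrec.id
        species = seqrec.description
        max_end = max(f.end for f in features)
        if len(sequence) < max_end:
            raise LengthError(
                f"FASTA length {len(sequence)} < max feature end {max_end}")
    record = MitogenomeRecord(accession=accession, species=species,
                              sequence=sequence, features=features)
    record.validate()
    return record


def write_gene_table(record: MitogenomeRecord) -> str:
    """Serialize features to the canonical TSV dialect (deterministic)."""
    if not record.features:
        raise ValidationError("record has no features to write")
    out = io.StringIO()
    writer = csv.writer(out, delimiter="\t", lineterminator="\n")
    writer.writerow(_TSV_COLUMNS)
    for f in record.features:
        writer.writerow([
            f.name,
            f.strand if f.strand is not None else ".",
            f.start,
            f.end,
            f.size,
            f.anticodon or ".",
            f.start_codon or ".",
            f.stop_codon or ".",
        ])
    return out.getvalue()


def read_genbank(path) -> MitogenomeRecord:
    """Parse a GenBank flat file into a :class:`MitogenomeRecord`.

    CDS features map to class PCG, tRNA/rRNA to their classes and
    D-loop/misc_feature to ``control_region`` (named ``CR``).  Features on
    the complement strand get strand ``-``.  Compound (origin-spanning)
    locations raise :class:`UnsupportedFeatureError`.
    """
    try:
        seqrec = SeqIO.read(path, "genbank")
    except ValueError as exc:
        raise ParseError(f"malformed GenBank file {path!r}: {exc}") from exc
    sequence = str(seqrec.seq).upper() if len(seqrec.seq) else None

    class_by_key = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA",
                    "D-loop": "control_region", "misc_feature": "control_region"}
    features: list[GeneFeature] = []
    for feat in seqrec.features:
        gene_class = class_by_key.get(feat.type)
        if gene_class is None:
            continue
        if len(feat.location.parts) > 1:
            raise UnsupportedFeatureError(
                f"feature {feat.type} at {feat.location} has a compound "
                "location (origin-spanning features are not supported)")
        start = int(feat.location.start) + 1
        end = int(feat.location.end)
        strand = "-" if feat.location.strand == -1 else "+"
        if gene_class == "control_region":
            name, strand = "CR", None
        else:
            quals = feat.qualifiers
            name = (quals.get("gene", quals.get("product", [feat.type])))[0]
        anticodon = None
        if gene_class == "tRNA":
            acq = feat.qualifiers.get("anticodon") or feat.qualifiers.get("note")
            if acq:
                m = re.search(r"\b([ACGTUacgtu]{3})\b", acq[0])
                anticodon = m.group(1).upper().replace("U", "T") if m else None
            if anticodon is None:
                anticodon = "NNN"  # placeholder satisfying the class invariant
        start_codon = stop_codon = None
        if gene_class == "PCG" and sequence is not None:
            cds = sequence[start - 1:end]
            if strand == "-":
                from .sequtils import reverse_complement
                cds = reverse_complement(cds)
            if len(cds) >= 3:
                start_codon = cds[:3]
                rem = len(cds) % 3
                if rem:
                    tail = cds[-rem:]
                    stop_codon = f"{tail}({'A' * (3 - rem)})"
                elif cds[-3:] in _MITO_STOPS:
                    stop_codon = cds[-3:]
        features.append(GeneFeature(
            name=name, gene_class=gene_class, strand=strand,
            start=start, end=end, anticodon=anticodon,
            start_codon=start_codon, stop_codon=stop_codon))
    record = MitogenomeRecord(
        accession=seqrec.id or seqrec.name,
        species=seqrec.annotations.get("organism", ""),
        sequence=sequence,
        features=features,
    )
    record.validate()
    return record


def load_reference_table(fasta=None) -> MitogenomeRecord:
    """Load the packaged reference gene table (GenBank MW751815 annotation)."""
    ref = resources.files("mitoarch.data").joinpath("mw751815_genes.tsv")
    with ref.open("r", encoding="utf-8") as handle:
        record = read_gene_table(handle, fasta=fasta)
    record.accession = record.accession or "MW751815"
    record.species = record.species or "Tupaia nicobarica"
    return record


def write_fasta(record: MitogenomeRecord, path, line_width: int = 70) -> None:
    if record.sequence is None:
        raise ValidationError("record has no sequence")
    with open(path, "w", encoding="utf-8") as fh:
        header = record.accession or "genome"
        if record.species:
            header += f" {record.species}"
        fh.write(f">{header}\n")
        seq = record.sequence
        for i in range(0, len(seq), line_width):
            fh.write(seq[i:i + line_width] + "\n")
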