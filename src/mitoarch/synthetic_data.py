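"""Seeded synthetic mitogenomes and divergent genome pairs.

``generate_genome`` writes a full circular genome over a gene table (by
default the packaged 38-feature reference layout): protein-coding genes are
in-frame codon strings with the annotated start/stop (incomplete stops are
written as their 1-2 nt tail), RNA genes and the control region are sampled
from per-class base probabilities, and minus-strand genes are written
reverse-complemented on the reference strand.  Features are written in
genomic order, so where two genes overlap the downstream gene's bases win
and the upstream gene's tail (typically its stop codon) is overwritten --
exactly the compromise a real overlapping annotation forces.  The returned
ground-truth ledger therefore records *realized* per-gene codons and
per-class base counts re-read from the final sequence, plus the planted
repeat location.

``diverge_pair`` applies an exact number of synonymous and nonsynonymous
single-nucleotide codon changes (at most one per codon, never creating a
stop, never inside a region shared with another protein-coding gene) and
returns the mutated record with a per-change ground-truth list.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .annotation_io import GeneFeature, MitogenomeRecord, load_reference_table
from .codon_usage import CodonTable, VERTEBRATE_MITO
from .errors import InfeasibleSpecError, ValidationError
from .sequtils import complement_base, reverse_complement

_INCOMPLETE_RE = re.compile(r"^([ACGT]{1,2})\([ACGT]{1,2}\)$")

#: AT-biased defaults in the style of a treeshrew mitogenome
DEFAULT_BASE_PROBS = {
    "background": {"A": 0.33, "C": 0.27, "G": 0.14, "T": 0.26},
    "tRNA": {"A": 0.34, "C": 0.22, "G": 0.17, "T": 0.27},
    "rRNA": {"A": 0.36, "C": 0.23, "G": 0.18, "T": 0.23},
    "control_region": {"A": 0.33, "C": 0.27, "G": 0.14, "T": 0.26},
}


@dataclass
class GenomeSpec:
    seed: int = 7
    gene_table: Optional[list[GeneFeature]] = None  # None -> packaged layout
    length: Optional[int] = None                    # None -> max feature end
    base_probs: Optional[dict[str, dict[str, float]]] = None
    pcg_codon_usage: Optional[dict[str, float]] = None  # None -> uniform sense
    planted_repeat: Optional[tuple[str, float, int]] = None  # motif, copies, CR offset
    accession: str = "SIM000001"
    species: str = "synthetic mitogenome"


@dataclass
class DivergenceSpec:
    seed: int = 1
    n_syn_substitutions: int = 0
    n_nonsyn_substitutions: int = 0
    genes: Optional[list[str]] = None  # None -> all PCGs


def _written_stop(token: Optional[str], gene: str) -> str:
    """Nucleotides actually written for a stop token ('T(AA)' -> 'T')."""
    if token is None:
        return "TAA"
    m = _INCOMPLETE_RE.match(token)
    if m:
        return m.group(1)
    if len(token) in (1, 2):
        return token
    if len(token) == 3:
        return token
    raise InfeasibleSpecError(f"{gene}: unparseable stop token {token!r}")


def _check_probs(probs: dict[str, float], label: str) -> tuple[list[str], list[float]]:
    bases = sorted(probs)
    vals = [probs[b] for b in bases]
    if set(bases) != set("ACGT") or abs(sum(vals) - 1.0) > 1e-9 or min(vals) < 0:
        raise ValidationError(f"base probabilities for {label} must be a "
                              "distribution over A/C/G/T")
    return bases, vals


def _sample_bases(rng: np.random.Generator, n: int,
                  probs: dict[str, float], label: str) -> str:
    bases, vals = _check_probs(probs, label)
    return "".join(rng.choice(list(bases), size=n, p=vals)) if n else ""


def generate_genome(spec: GenomeSpec) -> tuple[MitogenomeRecord, dict]:
    """Deterministically generate a genome for ``spec``; returns (record, ledger)."""
    rng = np.random.default_rng(spec.seed)
    if spec.gene_table is None:
        features = list(load_reference_table().features)
    else:
        features = sorted(spec.gene_table, key=lambda f: (f.start, -f.end))
        for f in features:
            f.validate()
    length = spec.length or max((f.end for f in features), default=0)
    if length <= 0:
        raise InfeasibleSpecError("genome length must be positive")
    if features and max(f.end for f in features) > length:
        raise InfeasibleSpecError("a feature extends past the requested length")
    base_probs = {**DEFAULT_BASE_PROBS, **(spec.base_probs or {})}

    code = VERTEBRATE_MITO
    if spec.pcg_codon_usage is None:
        codon_pool = list(code.sense_codons)
        codon_p = [1.0 / len(codon_pool)] * len(codon_pool)
    else:
        codon_pool = sorted(spec.pcg_codon_usage)
        bad = [c for c in codon_pool if c not in code.forward]
        if bad:
            raise ValidationError(f"codon weights include non-sense codons: {bad}")
        total = float(sum(spec.pcg_codon_usage.values()))
        codon_p = [spec.pcg_codon_usage[c] / total for c in codon_pool]

    seq = list(_sample_bases(rng, length, base_probs["background"], "background"))

    for feat in features:
        if feat.gene_class == "PCG":
            start = feat.start_codon or "ATG"
            stop = _written_stop(feat.stop_codon, feat.name)
            n_body = feat.size - len(start) - len(stop)
            if n_body < 0 or n_body % 3:
                raise InfeasibleSpecError(
                    f"{feat.name}: size {feat.size} incompatible with start "
                    f"{start!r} and stop {feat.stop_codon!r}")
            body = "".join(rng.choice(codon_pool, size=n_body // 3, p=codon_p))
            coding = start + body + stop
        else:
            probs = base_probs.get(feat.gene_class, base_probs["background"])
            coding = _sample_bases(rng, feat.size, probs, feat.gene_class)
        if feat.strand == "-":
            coding = reverse_complement(coding)
        seq[feat.start - 1:feat.end] = coding

    repeat_truth = None
    if spec.planted_repeat is not None:
        motif, copies, offset = spec.planted_repeat
        crs = [f for f in features if f.gene_class == "control_region"]
        if not crs:
            raise InfeasibleSpecError("planted repeat requires a control region")
        cr = crs[0]
        array_len = int(round(copies * len(motif)))
        start0 = cr.start - 1 + offset
        if offset < 0 or start0 + array_len > cr.end:
            raise InfeasibleSpecError(
                f"planted repeat ({array_len} bp at CR offset {offset}) does "
                f"not fit inside {cr.name}")
        array = (motif * (array_len // len(motif) + 2))[:array_len]
        seq[start0:start0 + array_len] = array
        repeat_truth = {"motif": motif, "period": len(motif),
                        "copies": array_len / len(motif),
                        "start": start0 + 1, "end": start0 + array_len}

    sequence = "".join(seq)
    record = MitogenomeRecord(accession=spec.accession, species=spec.species,
                              sequence=sequence, features=features)

    # ground truth re-read from the final sequence (realized, post-overlap)
    class_counts: dict[str, dict[str, int]] = {}
    for gene_class in ("PCG", "tRNA", "rRNA", "control_region"):
        feats = [f for f in features if f.gene_class == gene_class]
        if not feats:
            continue
        concat = "".join(sequence[f.start - 1:f.end] for f in feats)
        class_counts[gene_class] = {b: concat.count(b) for b in "ACGT"}

    codon_counts: dict[str, dict[str, int]] = {}
    for feat in features:
        if feat.gene_class != "PCG":
            continue
        cds = sequence[feat.start - 1:feat.end]
        if feat.strand == "-":
            cds = reverse_complement(cds)
        n_full = len(cds) // 3
        codons = [cds[3 * i:3 * i + 3] for i in range(n_full)]
        if len(cds) % 3 == 0 and codons and code.is_stop(codons[-1]):
            codons.pop()
        counts: dict[str, int] = {}
        for c in codons:
            counts[c] = counts.get(c, 0) + 1
        codon_counts[feat.name] = counts

    ledger = {
        "seed": spec.seed,
        "length": length,
        "class_base_counts": class_counts,
        "genome_base_counts": {b: sequence.count(b) for b in "ACGT"},
        "codon_counts": codon_counts,
        "planted_repeat": repeat_truth,
    }
    return record, ledger


def _pcg_overlap_positions(record: MitogenomeRecord) -> set[int]:
    """0-based reference positions covered by more than one PCG."""
    seen: set[int] = set()
    shared: set[int] = set()
    for f in record.by_class("PCG"):
        span = set(range(f.start - 1, f.end))
        shared |= seen & span
        seen |= span
    return shared


def diverge_pair(record: MitogenomeRecord, spec: DivergenceSpec,
                 code: CodonTable = VERTEBRATE_MITO
                 ) -> tuple[MitogenomeRecord, list[dict]]:
    """Apply exact counts of synonymous/nonsynonymous changes to a copy.

    At most one substitution per codon; substitutions never create a stop
    codon and never touch a position shared by two protein-coding genes (so
    every change is attributable to exactly one gene and one category).
    """
    if record.sequence is None:
        raise ValidationError("record has no sequence")
    rng = np.random.default_rng(spec.seed)
    targets = spec.genes or [f.name for f in record.by_class("PCG")]
    feats = []
    for name in targets:
        f = record.feature(name)
        if f.gene_class != "PCG":
            raise ValidationError(f"{name} is not a protein-coding gene")
        feats.append(f)
    shared = _pcg_overlap_positions(record)
    seq = list(record.sequence)

    # candidate codons: (gene, codon_index, ref positions coding-order)
    candidates: list[tuple[str, int, tuple[int, int, int]]] = []
    for f in feats:
        cds_len = (f.end - f.start + 1) // 3 * 3
        n_codons = cds_len // 3
        for idx in range(n_codons):
            if f.strand == "-":
                refs = tuple(f.end - 1 - (3 * idx + k) for k in range(3))
            else:
                refs = tuple(f.start - 1 + 3 * idx + k for k in range(3))
            if any(r in shared for r in refs):
                continue
            candidates.append((f.name, idx, refs))
    order = rng.permutation(len(candidates))

    def codon_at(refs, strand) -> str:
        bases = [seq[r] for r in refs]
        if strand == "-":
            bases = [complement_base(b) for b in bases]
        return "".join(bases)

    truth: list[dict] = []
    wanted = [("synonymous", spec.n_syn_substitutions),
              ("nonsynonymous", spec.n_nonsyn_substitutions)]
    cursor = 0
    for kind, n_wanted in wanted:
        placed = 0
        while placed < n_wanted:
            if cursor >= len(order):
                raise InfeasibleSpecError(
                    f"could not place {n_wanted} {kind} substitutions "
                    f"(placed {placed}) in genes {targets}")
            gene, idx, refs = candidates[order[cursor]]
            cursor += 1
            strand = record.feature(gene).strand
            codon = codon_at(refs, strand)
            if codon not in code.forward:
                continue
            variants = []
            for pos in range(3):
                for base in "ACGT":
                    if base == codon[pos]:
                        continue
                    alt = codon[:pos] + base + codon[pos + 1:]
                    if code.is_stop(alt):
                        continue
                    syn = code.aa(alt) == code.aa(codon)
                    if (kind == "synonymous") == syn:
                        variants.append((pos, alt))
            if not variants:
                continue
            pos, alt = variants[rng.integers(len(variants))]
            new_base = alt[pos]
            ref = refs[pos]
            seq[ref] = complement_base(new_base) if strand == "-" else new_base
            truth.append({"gene": gene, "codon_index": idx,
                          "position_in_codon": pos, "ref_position": ref + 1,
                          "from_codon": codon, "to_codon": alt, "kind": kind})
            placed += 1

    record_b = MitogenomeRecord(
        accession=record.accession + "_div", species=record.species,
        sequence="".join(seq),
        features=[replace(f) for f in record.features])
    return record_b, truth
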