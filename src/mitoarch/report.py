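"""Comparative pipeline over one or more annotated genomes.

Orchestrates the per-genome analyses (architecture, composition, codon
usage) and the cross-genome comparisons (gene-order identity, per-class
length ranges, pairwise Ka/Ks, control-region repeat summaries) and writes
deterministic TSV/JSON outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .annotation_io import MitogenomeRecord, read_gene_table
from .architecture import ArchitectureReport, architecture_report, pcg_fraction
from .codon_usage import VERTEBRATE_MITO, genome_codon_counts, rscu
from .composition import CompositionProfile, region_profiles
from .errors import MitoarchError, ValidationError
from .repeats import find_tandem_repeats
from .selection import KaKsResult, kaks_for_gene

logger = logging.getLogger("mitoarch")


def _load_synonyms() -> dict[str, str]:
    ref = resources.files("mitoarch.data").joinpath("gene_synonyms.yaml")
    with ref.open("r", encoding="utf-8") as fh:
        table = yaml.safe_load(fh)
    reverse: dict[str, str] = {}
    for canonical, aliases in table.items():
        reverse[canonical.lower()] = canonical
        for alias in aliases:
            reverse[str(alias).lower()] = canonical
    return reverse


_SYNONYMS = _load_synonyms()


def normalize_gene_name(name: str) -> str:
    """Map a gene symbol to its canonical form; unknown names pass through."""
    key = name.strip().lower()
    if key in _SYNONYMS:
        return _SYNONYMS[key]
    logger.debug("unknown gene name %r passed through", name)
    return name.strip()


@dataclass
class GeneOrderResult:
    identical: bool
    first_divergence: Optional[int] = None  # index into genomic order
    detail: str = ""


def gene_order_identical(records: list[MitogenomeRecord]) -> GeneOrderResult:
    """Compare normalized (name, strand) sequences in genomic order."""
    if len(records) < 2:
        raise ValidationError("need at least 2 records to compare gene order")
    orders = [[(normalize_gene_name(f.name), f.strand) for f in r.features]
              for r in records]
    reference = orders[0]
    for r_i, order in enumerate(orders[1:], start=1):
        limit = min(len(reference), len(order))
        for i in range(limit):
            if reference[i] != order[i]:
                return GeneOrderResult(
                    False, i,
                    f"record {r_i} diverges at index {i}: "
                    f"{reference[i]} vs {order[i]}")
        if len(reference) != len(order):
            return GeneOrderResult(False, limit,
                                   f"record {r_i} has {len(order)} features, "
                                   f"expected {len(reference)}")
    return GeneOrderResult(True)


@dataclass
class ComparativeReport:
    architectures: dict[str, ArchitectureReport]
    compositions: dict[str, list[CompositionProfile]]
    rscu_tables: dict[str, object]
    gene_order: Optional[GeneOrderResult]
    class_ranges: dict[str, tuple[int, int]]
    kaks_results: dict[tuple[str, str], list[KaKsResult]]
    repeat_summaries: dict[str, list]
    pcg_fractions: dict[str, float] = field(default_factory=dict)


def _digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def load_genomes_config(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def run_pipeline(config: dict, out_dir=None) -> ComparativeReport:
    """Run every applicable analysis for each configured genome.

    ``config["genomes"]`` is a list of ``{label, table, fasta}`` mappings
    (``fasta`` optional; sequence-dependent analyses are skipped without it).
    """
    entries = config.get("genomes") or []
    if not entries:
        raise ValidationError("config lists no genomes")
    records: dict[str, MitogenomeRecord] = {}
    for entry in entries:
        label = entry["label"]
        try:
            rec = read_gene_table(entry["table"], fasta=entry.get("fasta"))
        except MitoarchError as exc:
            raise type(exc)(f"genome {label!r}: {exc}") from exc
        records[label] = rec
        logger.info("loaded %s: %d features, table digest %s", label,
                    len(rec.features), _digest(entry["table"]))

    architectures = {}
    compositions = {}
    rscu_tables = {}
    repeat_summaries = {}
    fractions = {}
    for label, rec in records.items():
        try:
            architectures[label] = architecture_report(rec)
            fractions[label] = pcg_fraction(rec)
            if rec.sequence is not None:
                compositions[label] = region_profiles(rec)
                rscu_tables[label] = rscu(genome_codon_counts(rec))
                crs = rec.by_class("control_region")
                if crs:
                    cr_seq = rec.sequence[crs[0].start - 1:crs[0].end]
                    repeat_summaries[label] = find_tandem_repeats(cr_seq)
        except MitoarchError as exc:
            raise type(exc)(f"genome {label!r}: {exc}") from exc

    class_ranges: dict[str, tuple[int, int]] = {}
    for gene_class in ("PCG", "tRNA", "rRNA", "control_region"):
        totals = [rep.class_totals[gene_class]
                  for rep in architectures.values()
                  if gene_class in rep.class_totals]
        if totals:
            class_ranges[gene_class] = (min(totals), max(totals))

    gene_order = None
    if len(records) >= 2:
        gene_order = gene_order_identical(list(records.values()))

    kaks_results: dict[tuple[str, str], list[KaKsResult]] = {}
    if config.get("kaks", True):
        labels = [l for l, r in records.items() if r.sequence is not None]
        for i, la in enumerate(labels):
            for lb in labels[i + 1:]:
                results = []
                shared = ({normalize_gene_name(f.name)
                           for f in records[la].by_class("PCG")}
                          & {normalize_gene_name(f.name)
                             for f in records[lb].by_class("PCG")})
                for gene in sorted(shared):
                    try:
                        results.append(kaks_for_gene(records[la], records[lb], gene))
                    except MitoarchError as exc:
                        logger.warning("kaks %s/%s %s skipped: %s",
                                       la, lb, gene, exc)
                if results:
                    kaks_results[(la, lb)] = results

    report = ComparativeReport(
        architectures=architectures, compositions=compositions,
        rscu_tables=rscu_tables, gene_order=gene_order,
        class_ranges=class_ranges, kaks_results=kaks_results,
        repeat_summaries=repeat_summaries, pcg_fractions=fractions)
    if out_dir is not None:
        write_report(report, out_dir)
    return report


def architecture_table(rep: ArchitectureReport) -> pd.DataFrame:
    rows = [{"upstream": j.upstream_gene, "downstream": j.downstream_gene,
             "gap": j.gap, "wraps_origin": j.wraps_origin}
            for j in rep.junctions]
    return pd.DataFrame(rows)


def composition_table(profiles: list[CompositionProfile]) -> pd.DataFrame:
    return pd.DataFrame([p.rounded() for p in profiles])


def write_report(report: ComparativeReport, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary = {
        "version": __version__,
        "pcg_fraction_pct": {k: round(v, 2)
                             for k, v in report.pcg_fractions.items()},
        "class_ranges_bp": {k: list(v) for k, v in report.class_ranges.items()},
        "gene_order_identical": (report.gene_order.identical
                                 if report.gene_order else None),
    }
    for label, rep in report.architectures.items():
        architecture_table(rep).to_csv(out / f"{label}.architecture.tsv",
                                       sep="\t", index=False)
        summary.setdefault("architecture", {})[label] = {
            "n_overlaps": rep.n_overlaps,
            "total_overlap_bp": rep.total_overlap_bp,
            "n_spacers": rep.n_spacers,
            "total_spacer_bp": rep.total_spacer_bp,
            "n_minus_strand": rep.n_minus_strand,
            "genome_length": rep.genome_length,
        }
    for label, profiles in report.compositions.items():
        composition_table(profiles).to_csv(out / f"{label}.composition.tsv",
                                           sep="\t", index=False)
    for label, table in report.rscu_tables.items():
        pd.DataFrame([{"codon": r.codon, "aa": r.amino_acid, "count": r.count,
                       "rscu": None if r.rscu is None else round(r.rscu, 4)}
                      for r in table.rows]).to_csv(
            out / f"{label}.rscu.tsv", sep="\t", index=False)
    for (la, lb), results in report.kaks_results.items():
        pd.DataFrame([{"gene": r.gene, "S": round(r.S_sites, 4),
                       "N": round(r.N_sites, 4), "Sd": round(r.Sd, 4),
                       "Nd": round(r.Nd, 4),
                       "Ks": None if r.Ks is None else round(r.Ks, 6),
                       "Ka": None if r.Ka is None else round(r.Ka, 6),
                       "ratio": None if r.ratio is None else round(r.ratio, 6),
                       "flags": ";".join(r.flags)}
                      for r in results]).to_csv(
            out / f"{la}__{lb}.kaks.tsv", sep="\t", index=False)
    for label, reps in report.repeat_summaries.items():
        pd.DataFrame([{"start": r.start, "end": r.end, "period": r.period,
                       "copy_number": r.copy_number_display,
                       "consensus": r.consensus,
                       "identity": round(r.identity, 4)}
                      for r in reps]).to_csv(
            out / f"{label}.repeats.tsv", sep="\t", index=False)
    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")


def configure_logging(log_file=None, level=logging.INFO) -> None:
    handlers = [logging.StreamHandler(sys.stderr)]
    if log_file:
        handlers.append(logging.FileHandler(log_file))
    logging.basicConfig(level=level, handlers=handlers, force=True,
                        format="%(asctime)s %(name)s %(levelname)s %(message)s")
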