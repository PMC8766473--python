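"""Pairwise Ka/Ks by Nei-Gojobori (1986) pathway counting with Jukes-Cantor
correction.

Sites: at each codon position the synonymous fraction is the number of the
three possible single-nucleotide changes that are synonymous divided by the
number of changes that do not create a stop codon (changes to stops are
excluded from numerator and denominator); n = 3 - s per codon.

Differences: codon pairs differing at k positions are resolved by averaging
the synonymous/nonsynonymous step classification over all k! orderings of
single-nucleotide steps, excluding pathways that pass through a stop codon.
If every pathway is blocked, blocked pathways are included and the result
is flagged.

Distances: p = d/sites per category, JC-corrected as
``d = -(3/4) * ln(1 - 4p/3)``; p >= 3/4 is reported as saturated (None).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import permutations
from typing import Optional

from .codon_usage import CodonTable, VERTEBRATE_MITO
from .errors import ValidationError

_BASES = "ACGT"


@dataclass
class KaKsResult:
    gene: str
    n_codons_compared: int
    S_sites: float
    N_sites: float
    Sd: float
    Nd: float
    ps: Optional[float]
    pn: Optional[float]
    Ks: Optional[float]
    Ka: Optional[float]
    ratio: Optional[float]
    flags: list[str] = field(default_factory=list)


@lru_cache(maxsize=4096)
def _count_sites_cached(codon: str, ncbi_id: int, code_id: str) -> tuple[float, float]:
    code = CodonTable(code_id)
    s = 0.0
    aa0 = code.aa(codon)
    for pos in range(3):
        syn = 0
        non_stop = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1:]
            if code.is_stop(alt):
                continue
            non_stop += 1
            if code.aa(alt) == aa0:
                syn += 1
        if non_stop:
            s += syn / non_stop
    return s, 3.0 - s


def count_sites(codon: str, code: CodonTable = VERTEBRATE_MITO) -> tuple[float, float]:
    """Fractional (synonymous, nonsynonymous) sites of one sense codon."""
    codon = codon.upper()
    if code.is_stop(codon):
        raise ValidationError(f"stop codon {codon} has no site decomposition")
    if codon not in code.forward:
        raise ValidationError(f"not an unambiguous codon: {codon!r}")
    return _count_sites_cached(codon, code.ncbi_id, code.code_id)


def _pathways(codon_a: str, codon_b: str, code: CodonTable):
    """Yield (sd, nd, blocked) for every ordering of the differing positions."""
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    for order in permutations(diff):
        current = codon_a
        sd = nd = 0
        blocked = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1:]
            if code.is_stop(nxt):
                blocked = True
            aa_from = code.aa(current)
            aa_to = code.aa(nxt)
            if aa_from is not None and aa_to is not None and aa_from == aa_to:
                sd += 1
            else:
                nd += 1
            current = nxt
        yield sd, nd, blocked


def count_differences(codon_a: str, codon_b: str,
                      code: CodonTable = VERTEBRATE_MITO) -> tuple[float, float]:
    """(sd, nd) for one codon pair; see :func:`count_differences_detail`."""
    sd, nd, _ = count_differences_detail(codon_a, codon_b, code)
    return sd, nd


def count_differences_detail(codon_a: str, codon_b: str,
                             code: CodonTable = VERTEBRATE_MITO
                             ) -> tuple[float, float, bool]:
    """(sd, nd, used_blocked_fallback) by equal-weight pathway averaging."""
    codon_a, codon_b = codon_a.upper(), codon_b.upper()
    for c in (codon_a, codon_b):
        if code.is_stop(c) or c not in code.forward:
            raise ValidationError(f"not a sense codon: {c!r}")
    if codon_a == codon_b:
        return 0.0, 0.0, False
    paths = list(_pathways(codon_a, codon_b, code))
    open_paths = [(sd, nd) for sd, nd, blocked in paths if not blocked]
    fallback = not open_paths
    if fallback:
        open_paths = [(sd, nd) for sd, nd, _ in paths]
    sd = sum(p[0] for p in open_paths) / len(open_paths)
    nd = sum(p[1] for p in open_paths) / len(open_paths)
    return sd, nd, fallback


def _jc(p: float) -> Optional[float]:
    if p >= 0.75:
        return None
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def _comparable(codon: str, code: CodonTable) -> bool:
    return codon in code.forward


def kaks(gene_a: list[str], gene_b: list[str],
         code: CodonTable = VERTEBRATE_MITO, gene: str = "") -> KaKsResult:
    """Nei-Gojobori Ka/Ks over two aligned, equal-length codon lists.

    Codon pairs where either codon contains a gap/N or is a stop codon are
    dropped pairwise.  ``ratio`` is None when Ks is 0 or either distance is
    saturated.
    """
    if len(gene_a) != len(gene_b):
        raise ValidationError(
            f"codon list length mismatch: {len(gene_a)} vs {len(gene_b)}")
    pairs = [(a.upper(), b.upper()) for a, b in zip(gene_a, gene_b)
             if _comparable(a.upper(), code) and _comparable(b.upper(), code)]
    if not pairs:
        raise ValidationError("no comparable codon pairs")

    flags: list[str] = []
    s_a = s_b = 0.0
    sd = nd = 0.0
    for a, b in pairs:
        sa, _ = count_sites(a, code)
        sb, _ = count_sites(b, code)
        s_a += sa
        s_b += sb
        d_s, d_n, fb = count_differences_detail(a, b, code)
        sd += d_s
        nd += d_n
        if fb and "blocked_pathway_fallback" not in flags:
            flags.append("blocked_pathway_fallback")

    n_codons = len(pairs)
    S = (s_a + s_b) / 2.0
    N = 3.0 * n_codons - S
    ps = sd / S if S > 0 else None
    pn = nd / N if N > 0 else None
    Ks = _jc(ps) if ps is not None else None
    Ka = _jc(pn) if pn is not None else None
    if (ps is not None and ps >= 0.75) or (pn is not None and pn >= 0.75):
        flags.append("saturated")
    ratio = None
    if Ks is not None and Ka is not None and Ks > 0:
        ratio = Ka / Ks
    return KaKsResult(gene=gene, n_codons_compared=n_codons,
                      S_sites=S, N_sites=N, Sd=sd, Nd=nd,
                      ps=ps, pn=pn, Ks=Ks, Ka=Ka, ratio=ratio, flags=flags)


def kaks_for_gene(record_a, record_b, gene: str,
                  code: CodonTable = VERTEBRATE_MITO) -> KaKsResult:
    """Convenience wrapper: extract codons from two records and compare.

    Performs trivial equal-length pairing only; genes of different length
    are rejected (alignment is the caller's responsibility).
    """
    from .codon_usage import extract_codons
    ext_a = extract_codons(record_a, gene, code=code)
    ext_b = extract_codons(record_b, gene, code=code)
    return kaks(ext_a.codons, ext_b.codons, code=code, gene=gene)
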