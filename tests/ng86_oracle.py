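"""Independent brute-force reference for pathway-counting Ka/Ks primitives.

Implemented directly on Biopython's code tables with recursive pathway
enumeration, on purpose sharing no code with mitoarch.selection.
"""

from Bio.Data.CodonTable import unambiguous_dna_by_id

BASES = "ACGT"


def oracle_sites(codon, table_id=2):
    table = unambiguous_dna_by_id[table_id]
    stops = set(table.stop_codons)
    s = 0.0
    for pos in range(3):
        neighbours = [codon[:pos] + b + codon[pos + 1:]
                      for b in BASES if b != codon[pos]]
        neighbours = [n for n in neighbours if n not in stops]
        if not neighbours:
            continue
        syn = sum(table.forward_table[n] == table.forward_table[codon]
                  for n in neighbours)
        s += syn / len(neighbours)
    return s, 3.0 - s


def oracle_differences(codon_a, codon_b, table_id=2):
    table = unambiguous_dna_by_id[table_id]
    stops = set(table.stop_codons)
    paths = []

    def walk(current, sd, nd, through_stop):
        if current == codon_b:
            paths.append((sd, nd, through_stop))
            return
        for pos in range(3):
            if current[pos] == codon_b[pos]:
                continue
            nxt = current[:pos] + codon_b[pos] + current[pos + 1:]
            step_is_stop = nxt in stops
            synonymous = (not step_is_stop and current not in stops
                          and table.forward_table[nxt] == table.forward_table[current])
            walk(nxt, sd + (1 if synonymous else 0),
                 nd + (0 if synonymous else 1),
                 through_stop or step_is_stop)

    walk(codon_a, 0, 0, False)
    usable = [(sd, nd) for sd, nd, blocked in paths if not blocked]
    if not usable:
        usable = [(sd, nd) for sd, nd, _ in paths]
    return (sum(p[0] for p in usable) / len(usable),
            sum(p[1] for p in usable) / len(usable))
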