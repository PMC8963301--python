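"""Codon-level utilities: genetic code access, Nei–Gojobori mutational-opportunity
site counting, and classification of nucleotide changes as synonymous or
nonsynonymous.

Site counting follows the mutational-opportunity convention: each of the three
positions of a codon contributes (number of synonymous single-base changes at
that position)/3 to the synonymous site count L_S, and the complement to the
nonsynonymous count L_N, so every fully resolved codon contributes exactly
three sites in total. Changes between codons differing at more than one
position are classified along the pathway that minimises the number of
nonsynonymous steps, skipping pathways through stop codons when any
stop-free pathway exists.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import permutations

from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"

_STANDARD = CodonTable.unambiguous_dna_by_id[1]


@lru_cache(maxsize=None)
def genetic_code(table_id: int = 1) -> dict[str, str]:
    """Return a codon -> amino-acid map; stop codons map to '*'."""
    table = CodonTable.unambiguous_dna_by_id[table_id]
    code = dict(table.forward_table)
    for stop in table.stop_codons:
        code[stop] = "*"
    return code


def is_valid_codon(codon: str) -> bool:
    return len(codon) == 3 and all(b in NUCLEOTIDES for b in codon)


def is_stop(codon: str, table_id: int = 1) -> bool:
    return genetic_code(table_id).get(codon) == "*"


@lru_cache(maxsize=None)
def codon_site_counts(codon: str, table_id: int = 1) -> tuple[float, float]:
    """Nei–Gojobori (L_N, L_S) contribution of a single codon.

    Each position contributes f/3 synonymous sites, where f is the fraction of
    the three possible single-base changes at that position that preserve the
    amino acid. Changes creating stop codons count as nonsynonymous
    opportunities. Stop codons themselves contribute no sites (they are
    masked upstream).
    """
    code = genetic_code(table_id)
    if not is_valid_codon(codon) or code[codon] == "*":
        return (0.0, 0.0)
    aa = code[codon]
    l_s = 0.0
    for pos in range(3):
        syn = 0
        for base in NUCLEOTIDES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if code[mutant] == aa:
                syn += 1
        l_s += syn / 3.0
    return (3.0 - l_s, l_s)


@lru_cache(maxsize=None)
def classify_path(codon_a: str, codon_b: str, table_id: int = 1) -> tuple[int, int]:
    """Count (nonsynonymous, synonymous) single-base steps between two codons.

    For codons differing at k positions, all k! orderings of the substitutions
    are enumerated; pathways passing through a stop codon are discarded unless
    no stop-free pathway exists. Among admissible pathways the one with the
    minimum number of nonsynonymous steps is used.
    """
    code = genetic_code(table_id)
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return (0, 0)
    best: tuple[int, int] | None = None
    best_with_stop: tuple[int, int] | None = None
    for order in permutations(diff):
        cur = codon_a
        n_non = n_syn = 0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if code[cur] == code[nxt]:
                n_syn += 1
            else:
                n_non += 1
            if code[nxt] == "*":
                through_stop = True
            cur = nxt
        step = (n_non, n_syn)
        if through_stop:
            if best_with_stop is None or step < best_with_stop:
                best_with_stop = step
        elif best is None or step < best:
            best = step
    return best if best is not None else best_with_stop  # type: ignore[return-value]


def classify_single_change(codon_from: str, codon_to: str, table_id: int = 1) -> str:
    """Classify a codon change at exactly one position as 'syn' or 'nonsyn'."""
    code = genetic_code(table_id)
    return "syn" if code[codon_from] == code[codon_to] else "nonsyn"
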