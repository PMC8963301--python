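"""Per-gene codon alignments and the statistics computed from them.

A :class:`CodonAlignment` holds the aligned coding sequence of 2n ingroup
haplotypes (two per diploid individual) plus one or two outgroup sequences.
From a masked alignment the module derives Nei–Gojobori site counts, the
McDonald–Kreitman count table (P_N, P_S, D_N, D_S), pairwise diversity
(π_A, π_S) and divergence (K_A, K_S, optionally Jukes–Cantor corrected).

Conventions
-----------
* Coordinates are 0-based half-open; codon index = position // 3.
* A codon column is *countable* when every ingroup haplotype and the primary
  outgroup carry a fully resolved (ACGT) non-stop codon there.
* Sites that are both polymorphic and divergent count as polymorphism only.
* Segregating changes are classified against the ingroup major-allele codon
  context; fixed differences between codons differing at several positions
  are classified along the minimum-nonsynonymous pathway.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np

from .codon import classify_path, codon_site_counts, genetic_code, is_valid_codon

GAP_CHARS = set("-N")


class NoCountableSitesError(ValueError):
    """Raised when an alignment retains no countable codon after masking."""


@dataclass
class SiteCounts:
    """Mutational-opportunity site counts (Nei–Gojobori units)."""

    L_N: float
    L_S: float

    def __post_init__(self) -> None:
        if self.L_N < 0 or self.L_S < 0:
            raise ValueError("site counts must be nonnegative")


@dataclass
class MKTable:
    """Per-gene McDonald–Kreitman counts with site opportunities."""

    gene_id: str
    P_N: int
    P_S: int
    D_N: int
    D_S: int
    L_N: float
    L_S: float
    class_label: str = "control"

    def __post_init__(self) -> None:
        for name in ("P_N", "P_S", "D_N", "D_S"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a nonnegative integer")


@dataclass
class DiversityStats:
    pi_A: float | None = None
    pi_S: float | None = None
    K_A: float | None = None
    K_S: float | None = None
    K_A_jc: float | None = None
    K_S_jc: float | None = None
    pi_within: float | None = None
    pi_total: float | None = None
    paralog_flag: bool = False


@dataclass
class CodonAlignment:
    """Codon alignment of ingroup haplotypes plus outgroup sequence(s)."""

    gene_id: str
    ingroup_haplotypes: list[str]
    outgroup1: str
    outgroup2: str | None = None
    deme_of_haplotype: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ingroup_haplotypes = [s.upper() for s in self.ingroup_haplotypes]
        self.outgroup1 = self.outgroup1.upper()
        if self.outgroup2 is not None:
            self.outgroup2 = self.outgroup2.upper()
        if len(self.ingroup_haplotypes) < 2:
            raise ValueError("need at least 2 ingroup haplotypes")
        length = len(self.outgroup1)
        for seq in self.all_sequences():
            if len(seq) != length:
                raise ValueError("all sequences must have equal length")
        if length % 3 != 0:
            raise ValueError("alignment length must be divisible by 3")
        if not self.deme_of_haplotype:
            # default: haplotype pairs (2i, 2i+1) belong to individual/deme i
            self.deme_of_haplotype = [
                f"deme{i // 2}" for i in range(len(self.ingroup_haplotypes))
            ]
        if len(self.deme_of_haplotype) != len(self.ingroup_haplotypes):
            raise ValueError("deme list length must equal haplotype count")

    # -- basic accessors ---------------------------------------------------
    def all_sequences(self) -> list[str]:
        seqs = list(self.ingroup_haplotypes) + [self.outgroup1]
        if self.outgroup2 is not None:
            seqs.append(self.outgroup2)
        return seqs

    @property
    def n_haplotypes(self) -> int:
        return len(self.ingroup_haplotypes)

    @property
    def n_codons(self) -> int:
        return len(self.outgroup1) // 3

    def ingroup_codon(self, hap: int, codon_idx: int) -> str:
        return self.ingroup_haplotypes[hap][3 * codon_idx : 3 * codon_idx + 3]

    def codon_column(self, codon_idx: int) -> list[str]:
        return [self.ingroup_codon(h, codon_idx) for h in range(self.n_haplotypes)]

    def outgroup_codon(self, codon_idx: int, which: int = 1) -> str | None:
        seq = self.outgroup1 if which == 1 else self.outgroup2
        if seq is None:
            return None
        return seq[3 * codon_idx : 3 * codon_idx + 3]

    def countable_codons(self, table_id: int = 1) -> list[int]:
        """Codon columns fully resolved and non-stop in all ingroup haplotypes
        and in outgroup1."""
        code = genetic_code(table_id)
        out: list[int] = []
        for c in range(self.n_codons):
            cods = self.codon_column(c) + [self.outgroup_codon(c)]
            if all(is_valid_codon(x) and code[x] != "*" for x in cods):
                out.append(c)
        return out

    def major_codon(self, codon_idx: int) -> str:
        """Most common ingroup codon; ties broken lexicographically."""
        counts = Counter(self.codon_column(codon_idx))
        # deterministic: highest count, then lexicographically smallest
        top = max(counts.values())
        return min(c for c, k in counts.items() if k == top)


# ---------------------------------------------------------------------------
# masking
# ---------------------------------------------------------------------------

def _mask_codons(aln: CodonAlignment, codon_idxs: set[int]) -> CodonAlignment:
    if not codon_idxs:
        return aln

    def mask_seq(seq: str) -> str:
        chars = list(seq)
        for c in codon_idxs:
            chars[3 * c : 3 * c + 3] = "NNN"
        return "".join(chars)

    return replace(
        aln,
        ingroup_haplotypes=[mask_seq(s) for s in aln.ingroup_haplotypes],
        outgroup1=mask_seq(aln.outgroup1),
        outgroup2=mask_seq(aln.outgroup2) if aln.outgroup2 is not None else None,
    )


def mask_alignment(
    aln: CodonAlignment,
    window_codons: int = 10,
    k_threshold: float = 0.5,
    table_id: int = 1,
) -> CodonAlignment:
    """QC-mask an alignment, replacing failing codons by N (coordinates kept).

    Masks, in order: codon columns containing a stop codon in any sequence;
    codon columns containing an alignment gap in any sequence (unalignable
    positions); and sliding windows of ``window_codons`` codons whose raw
    total divergence K or nonsynonymous divergence K_A against the primary
    outgroup exceeds ``k_threshold`` (poorly aligned regions).
    """
    code = genetic_code(table_id)
    to_mask: set[int] = set()
    for c in range(aln.n_codons):
        for seq_codon in (
            aln.codon_column(c)
            + [aln.outgroup_codon(c)]
            + ([aln.outgroup_codon(c, 2)] if aln.outgroup2 is not None else [])
        ):
            assert seq_codon is not None
            if any(ch in GAP_CHARS for ch in seq_codon):
                if "-" in seq_codon:
                    to_mask.add(c)
                continue
            if is_valid_codon(seq_codon) and code[seq_codon] == "*":
                to_mask.add(c)
    masked = _mask_codons(aln, to_mask)

    # sliding-window divergence filter against outgroup1
    window_mask: set[int] = set()
    countable = set(masked.countable_codons(table_id))
    for start in range(0, masked.n_codons - window_codons + 1):
        window = [c for c in range(start, start + window_codons) if c in countable]
        if not window:
            continue
        n_diff = n_nonsyn = 0
        l_n = l_s = 0.0
        for c in window:
            major = masked.major_codon(c)
            out = masked.outgroup_codon(c)
            assert out is not None
            ln_c, ls_c = codon_site_counts(major, table_id)
            l_n += ln_c
            l_s += ls_c
            if major != out:
                nn, ns = classify_path(major, out, table_id)
                n_nonsyn += nn
                n_diff += nn + ns
        k_tot = n_diff / (l_n + l_s) if l_n + l_s > 0 else 0.0
        k_a = n_nonsyn / l_n if l_n > 0 else 0.0
        if k_tot > k_threshold or k_a > k_threshold:
            window_mask.update(range(start, start + window_codons))
    return _mask_codons(masked, window_mask)


# ---------------------------------------------------------------------------
# site counting
# ---------------------------------------------------------------------------

def count_sites(aln: CodonAlignment, table_id: int = 1) -> SiteCounts:
    """Nei–Gojobori site counts averaged over ingroup haplotypes.

    Raises :class:`NoCountableSitesError` when no codon column is countable
    after masking.
    """
    countable = aln.countable_codons(table_id)
    if not countable:
        raise NoCountableSitesError(f"{aln.gene_id}: no countable sites")
    l_n = l_s = 0.0
    for c in countable:
        col = aln.codon_column(c)
        per_hap = [codon_site_counts(cod, table_id) for cod in col]
        l_n += sum(p[0] for p in per_hap) / len(per_hap)
        l_s += sum(p[1] for p in per_hap) / len(per_hap)
    return SiteCounts(L_N=l_n, L_S=l_s)


# ---------------------------------------------------------------------------
# polymorphism / divergence classification per codon column
# ---------------------------------------------------------------------------

def _column_changes(
    aln: CodonAlignment, codon_idx: int, table_id: int = 1
) -> tuple[int, int, int, int]:
    """(p_n, p_s, d_n, d_s) contribution of one countable codon column."""
    code = genetic_code(table_id)
    col = aln.codon_column(codon_idx)
    major = aln.major_codon(codon_idx)
    out = aln.outgroup_codon(codon_idx)
    assert out is not None
    p_n = p_s = 0
    poly_positions: set[int] = set()
    for pos in range(3):
        alleles = sorted({cod[pos] for cod in col})
        if len(alleles) > 1:
            poly_positions.add(pos)
            for b in alleles:
                if b == major[pos]:
                    continue
                variant = major[:pos] + b + major[pos + 1 :]
                if code[variant] == code[major]:
                    p_s += 1
                else:
                    p_n += 1
    # divergence at positions monomorphic in the ingroup
    out_eff = "".join(
        major[pos] if pos in poly_positions else out[pos] for pos in range(3)
    )
    d_n = d_s = 0
    if out_eff != major:
        d_n, d_s = classify_path(major, out_eff, table_id)
    return p_n, p_s, d_n, d_s


def build_mk_table(
    aln: CodonAlignment, class_label: str = "control", table_id: int = 1
) -> MKTable:
    """Build the per-gene MK count table from a masked alignment."""
    sites = count_sites(aln, table_id)
    P_N = P_S = D_N = D_S = 0
    for c in aln.countable_codons(table_id):
        p_n, p_s, d_n, d_s = _column_changes(aln, c, table_id)
        P_N += p_n
        P_S += p_s
        D_N += d_n
        D_S += d_s
    return MKTable(
        gene_id=aln.gene_id,
        P_N=P_N,
        P_S=P_S,
        D_N=D_N,
        D_S=D_S,
        L_N=sites.L_N,
        L_S=sites.L_S,
        class_label=class_label,
    )


# ---------------------------------------------------------------------------
# diversity and divergence
# ---------------------------------------------------------------------------

def _site_heterozygosity(bases: list[str]) -> float:
    """Unbiased per-site heterozygosity sum_alleles 2p(1-p) * n/(n-1)."""
    n = len(bases)
    counts = Counter(bases)
    h = 1.0 - sum((k / n) ** 2 for k in counts.values())
    return h * n / (n - 1)


def pairwise_pi(
    aln: CodonAlignment, site_class: str, table_id: int = 1
) -> float | None:
    """Per-site pairwise diversity for 'synonymous' or 'nonsynonymous' sites.

    Returns ``None`` (missing) when the relevant site opportunity is zero.
    """
    if site_class not in ("synonymous", "nonsynonymous"):
        raise ValueError("site_class must be 'synonymous' or 'nonsynonymous'")
    sites = count_sites(aln, table_id)
    L = sites.L_S if site_class == "synonymous" else sites.L_N
    if L <= 0:
        return None
    code = genetic_code(table_id)
    total = 0.0
    for c in aln.countable_codons(table_id):
        col = aln.codon_column(c)
        major = aln.major_codon(c)
        for pos in range(3):
            bases = [cod[pos] for cod in col]
            if len(set(bases)) < 2:
                continue
            # classify the segregating site by its changes in major context;
            # a site whose alternative alleles are all synonymous belongs to
            # the synonymous class, otherwise nonsynonymous
            classes = set()
            for b in set(bases):
                if b == major[pos]:
                    continue
                variant = major[:pos] + b + major[pos + 1 :]
                classes.add("syn" if code[variant] == code[major] else "nonsyn")
            cls = "synonymous" if classes == {"syn"} else "nonsynonymous"
            if cls == site_class:
                total += _site_heterozygosity(bases)
    return total / L


def divergence(
    aln: CodonAlignment,
    corrected: bool = True,
    paralog_ks: float = 0.6,
    table_id: int = 1,
) -> DiversityStats:
    """Raw (and optionally Jukes–Cantor corrected) K_A and K_S vs outgroup1.

    The Jukes–Cantor transform is -(3/4)ln(1 - 4K/3); it is undefined for
    raw K >= 0.75, in which case only the raw value is reported. Genes with
    K_S above ``paralog_ks`` are flagged as putative paralogs.
    """
    sites = count_sites(aln, table_id)
    D_N = D_S = 0
    for c in aln.countable_codons(table_id):
        _, _, d_n, d_s = _column_changes(aln, c, table_id)
        D_N += d_n
        D_S += d_s
    k_a = D_N / sites.L_N if sites.L_N > 0 else None
    k_s = D_S / sites.L_S if sites.L_S > 0 else None

    def jc(k: float | None) -> float | None:
        if k is None or not corrected or k >= 0.75:
            return None
        return -0.75 * math.log1p(-4.0 * k / 3.0)

    k_a_jc = jc(k_a)
    k_s_jc = jc(k_s)
    k_s_for_flag = k_s_jc if k_s_jc is not None else k_s
    return DiversityStats(
        K_A=k_a,
        K_S=k_s,
        K_A_jc=k_a_jc,
        K_S_jc=k_s_jc,
        paralog_flag=bool(k_s_for_flag is not None and k_s_for_flag > paralog_ks),
    )


# ---------------------------------------------------------------------------
# haplotype matrix extraction (feeds SFS construction)
# ---------------------------------------------------------------------------

def segregating_sites(
    aln: CodonAlignment, table_id: int = 1
) -> list[dict]:
    """Enumerate biallelic-or-more segregating sites in countable codons.

    Each record holds the alignment position, site class ('synonymous' when
    every alternative allele is synonymous in major context), ingroup allele
    counts, and the outgroup alleles at that position.
    """
    code = genetic_code(table_id)
    records: list[dict] = []
    for c in aln.countable_codons(table_id):
        col = aln.codon_column(c)
        major = aln.major_codon(c)
        for pos in range(3):
            bases = [cod[pos] for cod in col]
            counts = Counter(bases)
            if len(counts) < 2:
                continue
            classes = set()
            for b in counts:
                if b == major[pos]:
                    continue
                variant = major[:pos] + b + major[pos + 1 :]
                classes.add("syn" if code[variant] == code[major] else "nonsyn")
            out1 = aln.outgroup_codon(c)
            out2 = aln.outgroup_codon(c, 2)
            records.append(
                {
                    "position": 3 * c + pos,
                    "site_class": "synonymous" if classes == {"syn"} else "nonsynonymous",
                    "allele_counts": dict(counts),
                    "outgroup1": out1[pos] if out1 is not None else None,
                    "outgroup2": out2[pos] if out2 is not None else None,
                }
            )
    return records


# ---------------------------------------------------------------------------
# FASTA input
# ---------------------------------------------------------------------------

def read_codon_alignment(
    path,
    gene_id: str | None = None,
    outgroup_names: tuple[str, ...] = ("outgroup1", "outgroup2"),
) -> CodonAlignment:
    """Read a per-gene FASTA codon alignment.

    Ingroup haplotype ids are suffixed ``_1``/``_2`` per diploid individual;
    the individual id doubles as the deme label. Records named in
    ``outgroup_names`` are taken as the outgroup sequences, in order.
    """
    from Bio import SeqIO

    ingroup: list[tuple[str, str]] = []
    outgroups: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in outgroup_names:
            outgroups[rec.id] = str(rec.seq)
        else:
            ingroup.append((rec.id, str(rec.seq)))
    if outgroup_names[0] not in outgroups:
        raise ValueError(f"{path}: missing primary outgroup '{outgroup_names[0]}'")
    demes = [name.rsplit("_", 1)[0] for name, _ in ingroup]
    return CodonAlignment(
        gene_id=gene_id or str(path),
        ingroup_haplotypes=[s for _, s in ingroup],
        outgroup1=outgroups[outgroup_names[0]],
        outgroup2=outgroups.get(outgroup_names[1]) if len(outgroup_names) > 1 else None,
        deme_of_haplotype=demes,
    )


def haplotype_matrix(aln: CodonAlignment) -> np.ndarray:
    """Ingroup haplotypes as a (n_haplotypes, length) byte matrix."""
    return np.frombuffer(
        "".join(aln.ingroup_haplotypes).encode(), dtype="S1"
    ).reshape(aln.n_haplotypes, -1)
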