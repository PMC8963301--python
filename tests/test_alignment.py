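"""Codon-alignment QC, MK tables, diversity and divergence."""

import math

import pytest

from parthenopop.alignment import (
    CodonAlignment, NoCountableSitesError, build_mk_table, count_sites,
    divergence, mask_alignment, pairwise_pi, read_codon_alignment,
    segregating_sites,
)


def brute_force_pi(aln: CodonAlignment, site_class: str) -> float:
    """Oracle: average pairwise per-site differences over all haplotype
    pairs at sites of the class, divided by the class site opportunity."""
    from parthenopop.codon import genetic_code

    code = genetic_code()
    sites = count_sites(aln)
    L = sites.L_S if site_class == "synonymous" else sites.L_N
    n = aln.n_haplotypes
    total = 0.0
    for c in aln.countable_codons():
        col = aln.codon_column(c)
        major = aln.major_codon(c)
        for pos in range(3):
            bases = [cod[pos] for cod in col]
            if len(set(bases)) < 2:
                continue
            classes = set()
            for b in set(bases):
                if b == major[pos]:
                    continue
                var = major[:pos] + b + major[pos + 1 :]
                classes.add("syn" if code[var] == code[major] else "nonsyn")
            cls = "synonymous" if classes == {"syn"} else "nonsynonymous"
            if cls != site_class:
                continue
            # mean pairwise discordance equals 2p(1-p) * n/(n-1) directly
            diffs = sum(
                1 for i in range(n) for j in range(i + 1, n) if bases[i] != bases[j]
            )
            total += diffs / (n * (n - 1) / 2)
    return total / L


class TestMKTable:
    def test_toy_alignment_counts(self, toy_alignment):
        t = build_mk_table(toy_alignment)
        assert (t.P_N, t.P_S, t.D_N, t.D_S) == (0, 1, 1, 0)

    def test_fixed_synonymous_difference_only(self):
        aln = CodonAlignment(
            "g", ["CCAATG", "CCAATG"], outgroup1="CCGATG"
        )
        t = build_mk_table(aln)
        assert (t.P_N, t.P_S, t.D_N, t.D_S) == (0, 0, 0, 1)

    def test_single_nonsynonymous_polymorphism(self):
        # one haplotype carries Lys->Arg; outgroup matches the major allele
        aln = CodonAlignment(
            "g", ["AAAATG", "AAAATG", "AAAATG", "AGAATG"], outgroup1="AAAATG"
        )
        t = build_mk_table(aln)
        assert (t.P_N, t.P_S, t.D_N, t.D_S) == (1, 0, 0, 0)

    def test_polymorphic_and_divergent_site_counts_once_as_polymorphism(self):
        # site segregates A/G in ingroup and outgroup carries G: polymorphism only
        aln = CodonAlignment(
            "g", ["CCAATG", "CCGATG"], outgroup1="CCGATG"
        )
        t = build_mk_table(aln)
        assert (t.P_S, t.D_S) == (1, 0)

    @pytest.mark.parametrize("seed", range(6))
    def test_brute_force_small_alignment_oracle(self, random_alignment_factory, seed):
        """On small random alignments the table equals exhaustive per-site
        enumeration of segregating and fixed changes."""
        from parthenopop.codon import classify_path, genetic_code

        aln = random_alignment_factory(n_codons=5, n_haps=4, seed=seed, mut_rate=0.15, div_rate=0.15)
        code = genetic_code()
        P_N = P_S = D_N = D_S = 0
        for c in aln.countable_codons():
            col = aln.codon_column(c)
            major = aln.major_codon(c)
            out = aln.outgroup_codon(c)
            poly = set()
            for pos in range(3):
                alleles = {cod[pos] for cod in col}
                if len(alleles) > 1:
                    poly.add(pos)
                    for b in sorted(alleles):
                        if b == major[pos]:
                            continue
                        var = major[:pos] + b + major[pos + 1 :]
                        if code[var] == code[major]:
                            P_S += 1
                        else:
                            P_N += 1
            out_eff = "".join(major[p] if p in poly else out[p] for p in range(3))
            nn, ns = classify_path(major, out_eff)
            D_N += nn
            D_S += ns
        t = build_mk_table(aln)
        assert (t.P_N, t.P_S, t.D_N, t.D_S) == (P_N, P_S, D_N, D_S)


class TestSiteCounts:
    def test_site_conservation_on_random_alignments(self, random_alignment_factory):
        aln = random_alignment_factory(n_codons=30, n_haps=4, seed=5)
        sc = count_sites(aln)
        assert sc.L_N + sc.L_S == pytest.approx(3 * len(aln.countable_codons()), abs=1e-9)

    def test_no_countable_sites_error(self):
        aln = CodonAlignment("g", ["NNNNNN", "NNNNNN"], outgroup1="NNNNNN")
        with pytest.raises(NoCountableSitesError):
            count_sites(aln)


class TestMasking:
    def test_stop_codon_column_masked(self):
        # internal TAA in the outgroup masks the codon column everywhere
        aln = CodonAlignment("g", ["CCAATGAAA", "CCAATGAAA"], outgroup1="CCATAAAAA")
        masked = mask_alignment(aln)
        assert masked.outgroup1[3:6] == "NNN"
        assert masked.ingroup_haplotypes[0][3:6] == "NNN"

    def test_identical_sequences_unchanged(self):
        aln = CodonAlignment("g", ["CCAATG", "CCAATG"], outgroup1="CCAATG")
        masked = mask_alignment(aln)
        assert masked.ingroup_haplotypes == aln.ingroup_haplotypes
        assert masked.outgroup1 == aln.outgroup1

    def test_high_divergence_window_masked(self):
        """A 10-codon window with K_A above threshold is masked entirely."""
        # ingroup all Lys (AAA); outgroup Gly (GGA) at 8 of 10 codons:
        # 16 nonsynonymous steps over L_N ~ 27.3 gives window K_A ~ 0.59
        ingroup = "AAA" * 10
        out = "GGA" * 8 + "AAA" * 2
        aln = CodonAlignment("g", [ingroup, ingroup], outgroup1=out)
        masked = mask_alignment(aln, window_codons=10, k_threshold=0.5)
        assert len(masked.countable_codons()) == 0
        # below threshold: untouched
        out_low = "GGA" * 2 + "AAA" * 8
        aln2 = CodonAlignment("g", [ingroup, ingroup], outgroup1=out_low)
        masked2 = mask_alignment(aln2, window_codons=10, k_threshold=0.5)
        assert len(masked2.countable_codons()) == 10

    def test_gap_codon_masked(self):
        aln = CodonAlignment("g", ["CCA---ATG", "CCAATGATG"], outgroup1="CCAATGATG")
        masked = mask_alignment(aln)
        assert masked.ingroup_haplotypes[1][3:6] == "NNN"


class TestDiversity:
    def test_identical_haplotypes_zero_pi(self):
        aln = CodonAlignment("g", ["CCAATG", "CCAATG"], outgroup1="CCAATG")
        assert pairwise_pi(aln, "synonymous") == 0.0

    def test_two_haplotypes_single_synonymous_difference(self):
        aln = CodonAlignment("g", ["CCA" * 50, "CCG" + "CCA" * 49], outgroup1="CCA" * 50)
        pi = pairwise_pi(aln, "synonymous")
        sc = count_sites(aln)
        assert pi == pytest.approx(1.0 / sc.L_S)

    def test_pi_matches_pairwise_difference_oracle(self, random_alignment_factory):
        for seed in range(4):
            aln = random_alignment_factory(n_codons=15, n_haps=6, seed=seed, mut_rate=0.1)
            for cls in ("synonymous", "nonsynonymous"):
                got = pairwise_pi(aln, cls)
                want = brute_force_pi(aln, cls)
                assert got == pytest.approx(want, abs=1e-12)

    def test_folded_count_weighting(self, toy_alignment):
        # 2/2 split at a synonymous site: heterozygosity 2*0.5*0.5*4/3
        pi = pairwise_pi(toy_alignment, "synonymous")
        sc = count_sites(toy_alignment)
        assert pi == pytest.approx((2 * 0.25 * 4 / 3) / sc.L_S)


class TestDivergence:
    def test_identical_zero(self):
        aln = CodonAlignment("g", ["CCAATG", "CCAATG"], outgroup1="CCAATG")
        d = divergence(aln)
        assert d.K_A == 0 and d.K_S == 0 and not d.paralog_flag

    def test_jukes_cantor_transform(self):
        raw = 0.06
        jc = -0.75 * math.log1p(-4 * raw / 3)
        assert jc == pytest.approx(0.0625, abs=2e-4)
        assert jc > raw  # JC >= raw below saturation

    def test_paralog_flag_threshold(self, random_alignment_factory):
        aln = random_alignment_factory(n_codons=40, n_haps=2, seed=3, mut_rate=0.0, div_rate=0.9)
        d = divergence(aln, corrected=True)
        if d.K_S_jc is not None and d.K_S_jc > 0.6:
            assert d.paralog_flag


class TestFastaIO:
    def test_roundtrip(self, tmp_path, toy_alignment):
        p = tmp_path / "toy.fasta"
        with open(p, "w") as fh:
            for i, seq in enumerate(toy_alignment.ingroup_haplotypes):
                fh.write(f">ind{i // 2}_{i % 2 + 1}\n{seq}\n")
            fh.write(f">outgroup1\n{toy_alignment.outgroup1}\n")
            fh.write(f">outgroup2\n{toy_alignment.outgroup2}\n")
        aln = read_codon_alignment(p, gene_id="toy")
        assert aln.ingroup_haplotypes == toy_alignment.ingroup_haplotypes
        assert aln.outgroup1 == toy_alignment.outgroup1
        assert aln.deme_of_haplotype == ["ind0", "ind0", "ind1", "ind1"]


def test_segregating_site_records(toy_alignment):
    recs = segregating_sites(toy_alignment)
    assert len(recs) == 1
    assert recs[0]["site_class"] == "synonymous"
    assert recs[0]["allele_counts"] == {"A": 2, "G": 2}
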