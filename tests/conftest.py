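import numpy as np
import pytest

from parthenopop.alignment import CodonAlignment


@pytest.fixture
def toy_alignment() -> CodonAlignment:
    """4 ingroup haplotypes, 3 codons.

    Codon 0: CCA/CCG segregating 2:2 at third position (both Pro; synonymous).
    Codon 1: ingroup AAA (Lys) fixed, outgroup AGA (Arg): nonsynonymous
    divergence. Codon 2: invariant ATG.
    """
    return CodonAlignment(
        gene_id="toy",
        ingroup_haplotypes=[
            "CCAAAAATG",
            "CCAAAAATG",
            "CCGAAAATG",
            "CCGAAAATG",
        ],
        outgroup1="CCAAGAATG",
        outgroup2="CCAAGAATG",
        deme_of_haplotype=["d0", "d0", "d1", "d1"],
    )


@pytest.fixture
def random_alignment_factory():
    """Random stop-free codon alignments with controlled divergence."""

    def make(n_codons=20, n_haps=6, seed=0, mut_rate=0.05, div_rate=0.05):
        from parthenopop.codon import genetic_code

        code = genetic_code()
        safe = [c for c, aa in code.items() if aa != "*"]
        rng = np.random.default_rng(seed)

        def no_stop_mutate(seq, rate):
            s = list(seq)
            for i in rng.choice(len(s), max(1, int(rate * len(s))), replace=False):
                cod_i = i // 3
                for base in rng.permutation(list("ACGT")):
                    cand = s[:]
                    cand[i] = base
                    codon = "".join(cand[3 * cod_i : 3 * cod_i + 3])
                    if code.get(codon) not in ("*", None):
                        s = cand
                        break
            return "".join(s)

        ancestor = "".join(rng.choice(safe, n_codons))
        haps = [no_stop_mutate(ancestor, mut_rate) for _ in range(n_haps)]
        out = no_stop_mutate(ancestor, div_rate)
        return CodonAlignment(
            gene_id=f"rand{seed}",
            ingroup_haplotypes=haps,
            outgroup1=out,
        )

    return make
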