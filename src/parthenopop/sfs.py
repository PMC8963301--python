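"""Site frequency spectra: construction, folding, and polarization.

An unfolded SFS indexes segregating sites by derived-allele count 1..n-1; a
folded SFS indexes by minor-allele count 1..floor(n/2). Polarization assigns
ancestral/derived states from one or two outgroups; sites that cannot be
polarized contribute to folded spectra only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class PolarizationResult:
    position: int
    ancestral: str | None
    derived: str | None
    confidence: float
    usable: bool


@dataclass
class SFS:
    """Allele-frequency spectrum for one site class at haploid sample size n."""

    n: int
    counts: np.ndarray
    folded: bool = False
    site_class: str = "synonymous"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        expected = self.n // 2 if self.folded else self.n - 1
        if len(self.counts) != expected:
            raise ValueError(
                f"counts length {len(self.counts)} does not match n={self.n} "
                f"({'folded' if self.folded else 'unfolded'}; expected {expected})"
            )
        if np.any(self.counts < 0):
            raise ValueError("SFS counts must be nonnegative")

    @property
    def n_sites(self) -> float:
        return float(self.counts.sum())

    def fold(self) -> "SFS":
        """Fold the spectrum (idempotent); total site count is preserved."""
        if self.folded:
            return SFS(self.n, self.counts.copy(), True, self.site_class)
        half = self.n // 2
        folded = np.zeros(half)
        for i in range(1, self.n):
            folded[min(i, self.n - i) - 1] += self.counts[i - 1]
        return SFS(self.n, folded, True, self.site_class)

    def to_dataframe(self):
        import pandas as pd

        idx = np.arange(1, len(self.counts) + 1)
        label = "minor_allele_count" if self.folded else "derived_allele_count"
        return pd.DataFrame({label: idx, "n_sites": self.counts})


def polarize(
    position: int,
    ingroup_counts: dict[str, int],
    outgroup1: str | None,
    outgroup2: str | None = None,
    epsilon: float = 0.1,
) -> PolarizationResult:
    """Assign the ancestral allele of a biallelic ingroup site from outgroups.

    Both outgroups agreeing on an ingroup allele gives confidence 1; a single
    informative outgroup (second absent, disagreeing, or uninformative) gives
    confidence 1 - epsilon, where epsilon is the ancestral-misidentification
    weight. Sites where no outgroup allele matches the ingroup, and sites with
    more than two ingroup alleles, are unusable (folded spectra only).
    """
    alleles = sorted(a for a, c in ingroup_counts.items() if c > 0)
    if len(alleles) != 2:
        return PolarizationResult(position, None, None, 0.0, False)
    a, b = alleles

    def other(x: str) -> str:
        return b if x == a else a

    if outgroup1 in alleles and outgroup2 is not None and outgroup2 == outgroup1:
        return PolarizationResult(position, outgroup1, other(outgroup1), 1.0, True)
    if outgroup1 in alleles:
        return PolarizationResult(position, outgroup1, other(outgroup1), 1.0 - epsilon, True)
    if outgroup2 in alleles:
        return PolarizationResult(position, outgroup2, other(outgroup2), 1.0 - epsilon, True)
    return PolarizationResult(position, None, None, 0.0, False)


def sfs_from_haplotype_matrix(
    genotypes: np.ndarray,
    folded: bool = False,
    site_class: str = "synonymous",
    ancestral_is_zero: bool = True,
) -> SFS:
    """Build an SFS from a (haplotypes, sites) 0/1 matrix.

    With ``ancestral_is_zero`` the 1-allele is derived (unfolded spectra);
    otherwise only folding is meaningful. Monomorphic columns are ignored.
    """
    g = np.asarray(genotypes)
    n = g.shape[0]
    dac = g.sum(axis=0).astype(int)
    dac = dac[(dac > 0) & (dac < n)]
    counts = np.bincount(dac, minlength=n)[1:n].astype(float)
    spec = SFS(n=n, counts=counts, folded=False, site_class=site_class)
    return spec.fold() if folded else spec


def build_sfs(
    site_records: list[dict],
    n: int,
    site_class: str,
    folded: bool = False,
    epsilon: float = 0.1,
) -> SFS:
    """Build an SFS for one site class from segregating-site records.

    ``site_records`` are the dictionaries produced by
    :func:`parthenopop.alignment.segregating_sites` (possibly pooled over
    genes). Sites whose total allele count differs from ``n`` (missing data)
    are excluded. Unfolded spectra use :func:`polarize`; unusable sites are
    dropped from unfolded spectra but retained in folded ones.
    """
    unfolded = np.zeros(n - 1)
    half = n // 2
    folded_counts = np.zeros(half)
    for rec in site_records:
        if rec["site_class"] != site_class:
            continue
        counts = rec["allele_counts"]
        if sum(counts.values()) != n:
            continue
        if len(counts) == 2 and not folded:
            pol = polarize(
                rec["position"], counts, rec.get("outgroup1"), rec.get("outgroup2"), epsilon
            )
            if pol.usable and pol.derived is not None:
                d = counts[pol.derived]
                if 0 < d < n:
                    unfolded[d - 1] += 1
                continue
            # unusable: excluded from the unfolded spectrum
        if folded and len(counts) == 2:
            minor = min(counts.values())
            if 0 < minor:
                folded_counts[min(minor, n - minor) - 1] += 1
    if folded:
        return SFS(n=n, counts=folded_counts, folded=True, site_class=site_class)
    return SFS(n=n, counts=unfolded, folded=False, site_class=site_class)
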