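"""Population summary statistics derived from diversity values."""

from __future__ import annotations


def fst_from_pi(pi_within: float, pi_total: float) -> float | None:
    """F_ST from mean within-deme and pooled total diversity.

    Computed with the conventional sign, (pi_total - pi_within) / pi_total,
    and clipped to [-1, 1]. Returns ``None`` when pi_total is zero (undefined).
    The statistic is invariant to a common rescaling of both inputs.
    """
    if pi_total == 0:
        return None
    if pi_within < 0 or pi_total < 0:
        raise ValueError("diversities must be nonnegative")
    fst = (pi_total - pi_within) / pi_total
    return max(-1.0, min(1.0, fst))


def ne_from_pi(pi_neutral: float, mu: float) -> float:
    """Effective population size from neutral diversity, Ne = pi / (4 mu)."""
    if mu <= 0:
        raise ValueError("mutation rate must be positive")
    if pi_neutral < 0:
        raise ValueError("diversity must be nonnegative")
    return pi_neutral / (4.0 * mu)
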