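# Methods

`parthenopop` estimates the proportion (α) and per-site rate (ω_a) of
adaptive amino-acid substitution in a species that is cyclically
parthenogenetic and strongly geographically structured, and provides a
forward simulator of exactly that population model so the estimators can be
audited on data whose truth is known. This note records the models, the
parameter choices, the numerical decisions, and the known limits of each
component.

## Scaling convention

One convention is used everywhere: the scaled selection coefficient is

    S = 2 · N_e · s,   S < 0 deleterious,

with semidominant fitness (1, 1 + s/2, 1 + s). The Kimura relative fixation
rate under this convention is R(S) = S / (1 − e^(−S)), with R(0) = 1. The
discretized DFE is reported over N_e·s = |S|/2 in the conventional bins
[0, 1), [1, 10), [10, 100), [100, ∞). Simulator DFE defaults are stated in
|S| units (gamma mean 2000, i.e. mean N_e·s of 1000).

## MK framework

Per-gene tables (P_N, P_S, D_N, D_S) are built from masked codon
alignments. Nei–Gojobori mutational-opportunity counting assigns each codon
position the fraction of its three single-base changes that are synonymous;
per-codon opportunities are averaged over ingroup haplotypes. Segregating
changes are classified against the ingroup major-allele codon; fixed
differences between codons differing at more than one position follow the
pathway minimizing nonsynonymous steps (stop-free pathways preferred).
Sites both polymorphic and divergent count as polymorphism only. Masking
replaces by N: codon columns containing stop codons or alignment gaps, and
sliding windows (default 10 codons) whose raw K or K_A against the primary
outgroup exceeds 0.5. Genes with (Jukes–Cantor) K_S > 0.6 are flagged as
putative paralogs and excluded by the pipeline.

Estimators, in increasing sophistication:

* **naive**: α = 1 − (D_S P_N)/(D_N P_S) on pooled counts; undefined (and
  reported as missing) when D_N = 0 or P_S = 0.
* **per-gene exact tests**: two-sided Fisher tests with Benjamini–Hochberg
  FDR; a margin-zero table is p = 1 by convention.
* **multigene ML**: per gene i, Poisson counts with means θ_i L_S,
  f_i θ_i L_N, T θ_i L_S and f_i T θ_i L_N/(1 − α_c). The per-gene nuisance
  parameters (θ_i, and f_i when gene-specific) have closed-form profile
  MLEs, so the numeric search is only over (log T, α…). The divergence
  scale T is shared across genes — per-gene divergence variation is
  absorbed by θ_i — which keeps the richest supported structure (every gene
  its own θ and f) identifiable. Model structures {α ≡ 0, single α,
  per-class α} × {f per-gene, per-class} are compared by AIC and Akaike
  weights; α is bounded to (−5, 0.999) because strongly negative estimates
  are a real outcome in this system. Bootstrap intervals resample genes
  within classes (percentile, default B = 1000).
* **asymptotic MK**: polymorphism is pooled into 20 derived-allele-frequency
  slices of 5%; per slice α(x) = 1 − (D_S/D_N)(P_N(x)/P_S(x)); a saturating
  exponential a + b·e^(−cx) is fitted over slice midpoints and read out at
  x = 1. Slices without synonymous polymorphism are dropped; a straight
  line is the fallback when the exponential fit fails or turns
  anti-saturating (c < 0). In the diffusion limit α(x) → α as x → 1, but
  with a broad weak-effect DFE the approach to the asymptote is steeper
  than the exponential family can represent, leaving a residual downward
  bias of roughly 0.05–0.1 at realistic sample sizes; the simulation tests
  exercise this directionally rather than asserting unbiasedness.
* **SnIPRE-like GLMM**: the four counts per gene are Poisson with log-mean
  built from fixed effects for nonsynonymous state, divergence state, their
  interaction (the genome-wide selection effect), class-specific N and N:D
  interactions, and centered log gene length; per-gene 4-dimensional random
  effects carry an unstructured covariance Σ. Sampling is
  Metropolis-within-Gibbs: vectorized per-gene random-effect updates,
  coordinate-wise adaptive random-walk updates for the fixed effects, and a
  conjugate inverse-Wishart(ν = 5 + G, I + ΣU U′) draw for Σ (prior
  IW(ν = 5, I); improper flat priors on fixed effects). Convergence is
  summarized by split-chain R̂ of the selection effect; runs with R̂ > 1.1
  are flagged unreliable.

## SFS machinery and DFE inference

Polarization uses two outgroups: agreement on an ingroup allele gives
confidence 1; a single informative outgroup gives 1 − ε (ε default 0.1,
configurable) — the misidentification weight is recorded per site, and
unusable sites contribute only to folded spectra.

Expected spectra come from discretized Wright–Fisher transition matrices at
a reduced reference size (N_ref = 100 diploids by default; convergence was
checked at doubled and quadrupled sizes, where the O(1/N_ref) discretization
error at the neutral spectrum falls below 1%). A mutation enters at count 1;
the expected sojourn times solve a linear system in the transient states;
sample spectra follow by binomial sampling; folding is linear. For
|S| > 150 (where the reference-size fitness would saturate) the spectrum is
the capped solution scaled by 150/|S| — the mutation–selection-balance
scaling of the strong-selection limit, which is singleton-dominated. The
step-change demography (N2/N1, time t2 in units of 2·N2 generations) is
fitted to the neutral spectrum by multinomial ML over a coarse log-grid
with Nelder–Mead polish; if no size change improves on equilibrium by 2
log-units the equilibrium model is returned flagged.

The deleterious DFE (gamma by default; lognormal, 1–6-spike and 1–5-step
mixtures available) is fitted to the selected spectrum conditional on that
demography, by Poisson likelihood over frequency classes with the DFE
integrated over a log-spaced |S| grid (81 points, 10^−4…10^6). When the
selected-class mutational influx θ_N is supplied — normally calibrated from
the synonymous spectrum as θ̂_site · L_N — the absolute deficit of selected
polymorphism enters the likelihood; this constraint is what identifies the
DFE mean, and without it only the spectrum shape is used. Beneficial mass
is not fitted from the SFS; adaptive substitution is estimated afterwards:
E[nonadaptive D_N] = D_S (L_N/L_S) E[R(S)] over the fitted DFE, and
α = 1 − E[nonadaptive D_N]/D_N, ω_a = α (D_N/L_N)/(D_S/L_S). Bootstrap
intervals resample spectra and divergence counts as Poisson draws
(site-level bootstrap; sites are independent after the upstream filters).
Class contrasts use likelihood-ratio tests with two degrees of freedom (the
two gamma parameters freed, demography shared).

## Island-model simulator

The population is a finite island model: d = 36 demes of N = 500 diploids,
symmetric migration at per-individual rate m per generation, soft selection
(fitness-proportional parent choice within demes), and migration realized
as offspring drawing their parents from a uniformly random other deme with
probability m — one consistent convention, pinned by the F_ST checks below.
The chromosome carries ten 5-kb coding loci; within coding sequence 24% of
mutations are unconstrained and 76% selected, of which 0.022% are
beneficial at S = +250 and the rest deleterious with S ~ −gamma(mean 2000,
shape 0.3); all effects are semidominant and multiplicative across sites.
The noncoding spacers are widened to 45 kb so that ten coding loci tile the
stated 500-kb chromosome exactly; since all rates are per site, no compound
parameter depends on this choice. Scaled defaults (μ = 1.53 × 10⁻⁷,
r = 4.52 × 10⁻⁶) reproduce local π_S = 4Ndμ ≈ 0.011. The life cycle is
cyclically parthenogenetic: every k-th generation (k ∈ {1, 8, 80}) is fully
sexual; in the intervening generations 99% of offspring are clonal copies
of a single parent (both haplotypes, no recombination) and 1% sexual.
Sexual gametes recombine with Poisson(r·L) crossovers.

Burn-in uses a stationarity rule (two successive π_S windows within 5%)
with a hard floor of 8·(2dN) generations; fixations are logged only after
burn-in, and divergence for simulated MK tables is the post-burn-in
fixation count (no outgroup branch is simulated). The true adaptive
proportion is the beneficial fraction of selected-class fixations.
Sampling strategies: one diploid per deme, 36 diploids from one deme, or
360 diploids spread evenly.

**Rescaling.** Selection is parameterized in scaled units, so
`rescale_config(factor)` (N → N/factor, μ, r, m → ×factor,
generations → /factor) preserves 4N_Tμ, 4N_Tr, S and N·m exactly. The
equilibrium F_ST of the island model, however, depends on m beyond first
order: 1/(1 + 4Nm(d/(d−1))²) is the m → 0 limit of the exact two-lineage
recursion (implemented in `expected_fst_exact`), and naively multiplying m
by the factor weakens differentiation measurably in the high-migration
regime (exact F_ST 0.0435 vs. 0.0493 at factor 10). The `match_fst` option
therefore solves the rescaled m so the exact full-scale F_ST is preserved;
calibration runs use it.

**Two engines.** For unlinked neutral sites the haplotype engine's marginal
allele-frequency process is exactly a per-site Wright–Fisher island model,
so neutral calibration (π, F_ST) runs on a frequency-based engine
(`neutral_fst_calibration`) that tracks per-deme allele counts of
segregating sites only — about two orders of magnitude faster, enabling
ten-replicate calibrations at all three study migration rates on one CPU in
minutes. Everything involving selection, linkage, recombination or clonal
structure runs on the haplotype engine. Calibration burn-in is 5× the mean
pairwise coalescence time 2Nd + (d−1)/(2m), followed by 12 π snapshots
spaced N/2 generations; F_ST is the ratio of averages.

**Fast generator.** `fast_tables` Poisson-samples per-gene MK tables and
pooled spectra directly from the expected-SFS machinery with a known true
α (D_N ~ Poisson(T·L_N·E[R]/(1 − α))). It shares the expected-SFS code with
the fitter, so recovery tests on it validate the inference logic and the
Poisson noise model, not the Wright–Fisher discretization itself — the
discretization is validated separately against diffusion-integral oracles,
and end-to-end behavior against the haplotype simulator.

## Problem sizes for desk-scale runs

Calibration targets use rescale factor 10 (N = 50 per deme), 10 replicates
per migration rate and 400–800 unlinked neutral sites; replicate-level
standard errors of F_ST are then 0.0003–0.002, and the closed-form F_ST is
checked against simulation within 3 SE plus its own exactly-known small-m
truncation. DFE recovery uses the fast generator at n = 72 haplotypes and
~2.3 × 10⁵ selected sites (shape estimates then scatter by about ±0.02
around the generating value). The structured-sampling experiment runs the
haplotype engine at rescale factor 25 (N = 20) on a 20-kb chromosome with
ten 1-kb coding loci, k = 8 clonal cycling and intermediate migration — it
reproduces the directional pattern (naive α negative, DFE-corrected α
positive and somewhat high, asymptotic α positive and low, against a true
α ≈ 0.3) rather than full-scale magnitudes.

## What the synthetic data do and do not capture

The generators emulate: island-model structure and its doubleton excess
under one-per-deme sampling, clonal interference from rare sex, a
gamma-distributed deleterious DFE with rare strong beneficials, and
Poisson count noise. They do not emulate: local adaptation or balancing
selection (deliberately absent, as the simulation design isolates
structure/asexuality effects), gene conversion, variable mutation or
recombination rates along the genome, alignment error beyond the masking
model, or ancestral-state misidentification beyond the ε weight. Passing
tests therefore demonstrate correctness of the estimators under the stated
population model, not robustness to every property of real data.

## Numerical details and edge cases

* Multi-hit codons: minimum-nonsynonymous pathway, stop-free paths
  preferred; ties broken deterministically.
* Ingroup major-allele ties: lexicographically smallest codon.
* Jukes–Cantor correction is undefined at K ≥ 0.75; raw K is reported with
  the corrected field empty.
* F_ST from diversity uses the conventional sign (π_T − π_W)/π_T, clipped
  to [−1, 1]; undefined (missing) at π_T = 0.
* Gamma-DFE fits launch Nelder–Mead from six spread starting points; a
  shape collapsing below 10⁻³ is flagged as boundary convergence.
* All stochastic code takes explicit seeds (numpy Generator); identical
  seeds give bit-identical outputs, including the MCMC and both simulation
  engines.
* Fitness underflow (mean fitness ≤ 0 in a deme) raises an error advising
  a smaller |s| or a larger rescale factor.

## Known limitations

* The Welch-style divergence scale T is shared across genes; true per-gene
  divergence-time variation loads onto θ_i.
* The strong-selection 1/|S| cap makes spectra for |S| > 150 exact only in
  the singleton-dominated limit; DFE fits are internally consistent, but
  tail shape beyond the cap is approximate.
* Two-epoch spectra re-equilibrate strongly selected classes through the
  transition matrices; for extreme expansions (ratio > 5) runtime grows
  quadratically with the epoch-2 size and the demography search is bounded
  accordingly.
* The SnIPRE-like sampler is a straightforward MCMC, adequate for the gene
  counts used here (tens to hundreds); thousands of genes would warrant a
  gradient-based sampler.
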