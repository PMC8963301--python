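# parthenopop

Adaptive protein evolution in structured, cyclically parthenogenetic
populations: McDonald–Kreitman (MK) statistics, SFS-based inference of the
distribution of deleterious fitness effects (DFE), four estimators of the
adaptive proportion α and rate ω_a, and a forward island-model simulator
with a clonal/sexual life cycle for auditing those estimators.

## Who this is for

Population geneticists analyzing per-gene codon alignments of a diploid
species sampled across a structured range (the motivating system is a
cyclically asexual freshwater crustacean sampled one diploid per pond, with
two outgroup species), and anyone who wants to test how population
structure, structured sampling, and rare sex bias MK-framework estimators.

## The statistics

With nonsynonymous/synonymous polymorphism counts P_N, P_S, fixed
differences D_N, D_S and site opportunities L_N, L_S (Nei–Gojobori
mutational-opportunity counting):

* naive estimator: α = 1 − (D_S P_N)/(D_N P_S),
  ω_a = α (D_N/L_N)/(D_S/L_S)
* per-gene two-sided Fisher exact tests with Benjamini–Hochberg FDR
* multigene maximum likelihood: Poisson model with gene-wise mutation
  parameters θ_i and constraints f_i, shared divergence scale T, and α
  fixed at zero / shared / free per gene class; AIC + Akaike weights;
  within-class gene bootstrap
* asymptotic MK: α(x) = 1 − (D_S/D_N)·(P_N(x)/P_S(x)) in 20 derived-allele
  frequency slices of 5%, extrapolated to x = 1 with a + b·e^(−cx)
* DFE-based correction: a gamma (or lognormal/spike/step) DFE over
  S = 2·N_e·s fitted to the selected SFS under a step-change demography
  fitted to the neutral SFS; then
  α = 1 − D_S (L_N/L_S) E[R(S)] / D_N with R(S) = S/(1 − e^(−S))
* a SnIPRE-like Bayesian Poisson mixed model over the four count
  categories with gene-level random effects

The simulator implements a finite island model (36 demes × 500 diploids,
symmetric migration) of a 500-kb chromosome with ten coding loci, 24%
unconstrained coding mutations, gamma-deleterious (mean |2Ns| = 2000,
shape 0.3) plus rare beneficial (|2Ns| = 250, 0.022%) selection, and
cyclical parthenogenesis (every k-th generation sexual, 99% clonal
otherwise). Configurations rescale to desk size preserving 4Nμ, 4Nr,
2Ns, N·m and (optionally, exactly) F_ST. See `docs/methods.md`.

## Worked example

Generate MK tables and spectra with a known truth (no adaptive
substitution, abundant weakly deleterious variation), then watch the naive
estimator go negative and the DFE correction recover the truth:

```python
from parthenopop import (DFEModel, DemographyModel, naive_alpha,
                         fast_tables, fit_dfe, alpha_from_dfe)
from parthenopop.dfe import estimate_theta_site

dfe = DFEModel("gamma", {"mean": 50.0, "shape": 0.5})   # |2 Ne s|
tables, sfs_N, sfs_S = fast_tables(
    dfe, alpha_true=0.0, n_genes=150, theta_site=0.01, T=0.3, n=20, seed=6)

print("naive alpha:", round(naive_alpha(tables).alpha, 3))

dem = DemographyModel()                   # equilibrium
L_N, L_S = 750.0 * 150, 250.0 * 150
theta = estimate_theta_site(sfs_S, L_S, dem)
fit = fit_dfe(sfs_N, dem, "gamma", theta_N=theta * L_N)
D_N = sum(t.D_N for t in tables); D_S = sum(t.D_S for t in tables)
alpha, omega_a = alpha_from_dfe(fit, D_N, D_S, L_N, L_S)
print("DFE-corrected alpha:", round(alpha, 3))
print("DFE bins [0,1) [1,10) [10,100) [100,inf):",
      [round(b, 2) for b in fit.bin_proportions])
```

prints

```
naive alpha: -1.506
DFE-corrected alpha: 0.108
DFE bins [0,1) [1,10) [10,100) [100,inf): [0.14, 0.35, 0.49, 0.02]
```

The naive estimate is pulled far below zero by segregating weakly
deleterious amino-acid variants (they inflate P_N but rarely fix); the
fitted DFE — whose bin proportions closely track the generating gamma
(0.15/0.34/0.49/0.02) — quantifies how many nonadaptive fixations those
effects predict, and the corrected α returns close to 0, the simulated
truth.

The same machinery runs from the shell: `parthenopop mk
naive|fisher|welch|asymptotic|snipre`, `parthenopop fit-dfe`,
`parthenopop simulate`, `parthenopop run --config run.yaml`, and
`parthenopop validate` for the simulation-based estimator-bias grid.

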