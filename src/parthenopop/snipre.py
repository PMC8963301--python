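"""SnIPRE-like Bayesian Poisson mixed model over MK count categories.

The MK test is recast as a generalized linear mixed model: for each gene the
four counts (P_S, P_N, D_S, D_N) are Poisson with log mean built from fixed
effects for the nonsynonymous state, the divergence state, and their
interaction (the genome-wide "selection effect"), class-specific
nonsynonymous and nonsynonymous:divergence interaction terms, a gene-length
coefficient, and a 4-dimensional gene-level random effect with an
unstructured covariance.

Sampling is Metropolis-within-Gibbs: random-walk Metropolis for the fixed
effects and (vectorized, per-gene independent) random effects, and a
conjugate inverse-Wishart update for the random-effect covariance
(prior IW(nu = 5, identity scale); fixed effects carry an improper flat
prior). Convergence is summarized by the split-chain Gelman-Rubin statistic
of the selection effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .alignment import MKTable

CATEGORIES = ("P_S", "P_N", "D_S", "D_N")


@dataclass
class SnipreModel:
    classes: list[str]
    fixed_effect_names: list[str]
    beta_samples: np.ndarray          # (draws, n_fixed)
    Sigma_samples: np.ndarray         # (draws, 4, 4)
    selection_effect: dict            # class -> posterior mean of gamma + gamma_class
    selection_samples: dict           # class -> posterior draws
    significance: dict                # class -> min tail fraction (<=0 vs >=0)
    length_coefficient: float
    r_hat: float
    reliable: bool
    seed: int
    n_iter: int
    n_chains: int
    extras: dict = field(default_factory=dict)


def _design(tables: list[MKTable], classes: list[str], labels: list[str]):
    """Fixed-effect design per gene per category.

    Columns: intercept, N, D, N:D, then per non-reference class (N_class,
    N:D_class), then log-length (centered).
    """
    G = len(tables)
    extra = [c for c in classes if c != classes[0]]
    names = ["intercept", "N", "D", "N:D"]
    for c in extra:
        names += [f"N:{c}", f"N:D:{c}"]
    names.append("log_length")
    P = len(names)
    X = np.zeros((G, 4, P))
    lens = np.array([t.L_N + t.L_S for t in tables], float)
    loglen = np.log(lens) - np.log(lens).mean()
    is_N = np.array([0.0, 1.0, 0.0, 1.0])   # P_S, P_N, D_S, D_N
    is_D = np.array([0.0, 0.0, 1.0, 1.0])
    for g in range(G):
        X[g, :, 0] = 1.0
        X[g, :, 1] = is_N
        X[g, :, 2] = is_D
        X[g, :, 3] = is_N * is_D
        col = 4
        for c in extra:
            if labels[g] == c:
                X[g, :, col] = is_N
                X[g, :, col + 1] = is_N * is_D
            col += 2
        X[g, :, -1] = loglen[g]
    Y = np.array([[t.P_S, t.P_N, t.D_S, t.D_N] for t in tables], float)
    return X, Y, names


def _loglik_by_gene(X, Y, beta, U):
    eta = X @ beta + U
    eta = np.clip(eta, -30, 30)
    mu = np.exp(eta)
    return (Y * eta - mu).sum(axis=1)


def snipre_fit(
    tables: list[MKTable],
    class_partition: dict[str, str] | None = None,
    chains: int = 2,
    iterations: int = 3000,
    burn_in: int | None = None,
    seed: int = 0,
    nu0: float = 5.0,
) -> SnipreModel:
    """Fit the Poisson mixed model by MCMC and summarize selection effects.

    The selection effect of the reference (first) class is the genome-wide
    N:D interaction gamma; for other classes it is gamma plus the class
    interaction. ``significance`` reports, per class, the smaller posterior
    tail fraction (mass <= 0 or >= 0). Results are flagged unreliable when
    the split-chain R-hat of the genome-wide gamma exceeds 1.1.
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 genes")
    labels = [
        class_partition.get(t.gene_id, t.class_label) if class_partition else t.class_label
        for t in tables
    ]
    classes = sorted(set(labels), key=lambda c: (c != "control", c))
    X, Y, names = _design(tables, classes, labels)
    G, _, P = X.shape
    burn = burn_in if burn_in is not None else iterations // 3

    all_beta = []
    all_Sigma = []
    chain_gamma = []

    for chain in range(chains):
        rng = np.random.default_rng((seed, chain))
        beta = np.zeros(P)
        # crude initialization from marginal means
        beta[0] = np.log(np.maximum(Y[:, 0].mean(), 0.5))
        beta[1] = np.log(np.maximum(Y[:, 1].mean(), 0.5)) - beta[0]
        beta[2] = np.log(np.maximum(Y[:, 2].mean(), 0.5)) - beta[0]
        beta[3] = np.log(np.maximum(Y[:, 3].mean(), 0.5)) - beta[0] - beta[1] - beta[2]
        U = np.zeros((G, 4))
        Sigma = np.eye(4) * 0.2
        Sigma_inv = np.linalg.inv(Sigma)
        step_beta = np.full(P, 0.05)
        step_u = 0.2
        acc_b = np.zeros(P)
        n_b = 0
        acc_u = n_u = 0

        beta_draws = np.empty((iterations - burn, P))
        Sigma_draws = np.empty((iterations - burn, 4, 4))

        for it in range(iterations):
            # --- random effects: vectorized per-gene Metropolis ----------
            prop = U + rng.normal(0, step_u, (G, 4))
            ll0 = _loglik_by_gene(X, Y, beta, U)
            ll1 = _loglik_by_gene(X, Y, beta, prop)
            pr0 = -0.5 * np.einsum("gi,ij,gj->g", U, Sigma_inv, U)
            pr1 = -0.5 * np.einsum("gi,ij,gj->g", prop, Sigma_inv, prop)
            accept = np.log(rng.random(G)) < (ll1 + pr1 - ll0 - pr0)
            U[accept] = prop[accept]
            acc_u += accept.mean()
            n_u += 1

            # --- fixed effects: coordinate-wise random-walk Metropolis ---
            ll_cur = _loglik_by_gene(X, Y, beta, U).sum()
            for j in range(P):
                prop_b = beta.copy()
                prop_b[j] += rng.normal(0, step_beta[j])
                ll_prop = _loglik_by_gene(X, Y, prop_b, U).sum()
                if np.log(rng.random()) < ll_prop - ll_cur:
                    beta = prop_b
                    ll_cur = ll_prop
                    acc_b[j] += 1
            n_b += 1

            # --- covariance: conjugate inverse-Wishart --------------------
            scale = np.eye(4) + U.T @ U
            Sigma = stats.invwishart.rvs(df=nu0 + G, scale=scale, random_state=rng)
            Sigma_inv = np.linalg.inv(Sigma)

            # --- adapt during burn-in -------------------------------------
            if it < burn and (it + 1) % 100 == 0:
                if acc_u / n_u < 0.2:
                    step_u *= 0.7
                elif acc_u / n_u > 0.5:
                    step_u *= 1.3
                rate = acc_b / n_b
                step_beta[rate < 0.25] *= 0.7
                step_beta[rate > 0.5] *= 1.4
                acc_b = np.zeros(P)
                acc_u = n_b = n_u = 0

            if it >= burn:
                beta_draws[it - burn] = beta
                Sigma_draws[it - burn] = Sigma

        all_beta.append(beta_draws)
        all_Sigma.append(Sigma_draws)
        chain_gamma.append(beta_draws[:, 3])

    beta_samples = np.concatenate(all_beta)
    Sigma_samples = np.concatenate(all_Sigma)

    # split-chain R-hat on gamma
    halves = []
    for g in chain_gamma:
        half = len(g) // 2
        halves += [g[:half], g[half : 2 * half]]
    halves_arr = np.array(halves)
    W = halves_arr.var(axis=1, ddof=1).mean()
    B = halves_arr.mean(axis=1).var(ddof=1) * halves_arr.shape[1]
    n_half = halves_arr.shape[1]
    r_hat = float(np.sqrt(((n_half - 1) / n_half * W + B / n_half) / W)) if W > 0 else 1.0

    sel_samples: dict[str, np.ndarray] = {}
    sel_mean: dict[str, float] = {}
    signif: dict[str, float] = {}
    for c in classes:
        draws = beta_samples[:, 3].copy()
        if c != classes[0]:
            j = names.index(f"N:D:{c}")
            draws = draws + beta_samples[:, j]
        sel_samples[c] = draws
        sel_mean[c] = float(draws.mean())
        tail = min(float((draws <= 0).mean()), float((draws >= 0).mean()))
        signif[c] = tail

    return SnipreModel(
        classes=classes,
        fixed_effect_names=names,
        beta_samples=beta_samples,
        Sigma_samples=Sigma_samples,
        selection_effect=sel_mean,
        selection_samples=sel_samples,
        significance=signif,
        length_coefficient=float(beta_samples[:, -1].mean()),
        r_hat=r_hat,
        reliable=bool(r_hat <= 1.1),
        seed=seed,
        n_iter=iterations,
        n_chains=chains,
    )
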