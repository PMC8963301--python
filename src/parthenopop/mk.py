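"""McDonald–Kreitman framework estimators of adaptive protein evolution.

Given per-gene count tables (P_N, P_S, D_N, D_S with site opportunities
L_N, L_S) this module provides:

* the naive pooled estimator  alpha = 1 - (D_S P_N) / (D_N P_S)  and the
  per-site adaptive rate  omega_a = alpha * (D_N/L_N) / (D_S/L_S);
* per-gene Fisher exact tests with Benjamini–Hochberg FDR correction;
* a maximum-likelihood multigene model with gene-specific mutation
  parameters theta_i and constraints f_i, a shared divergence scale T, and
  alpha either fixed at zero, shared, or free per gene class, compared by
  AIC/Akaike weights, with class-resampling bootstrap intervals;
* the asymptotic-MK estimator: alpha(x) computed in 20 derived-allele
  frequency slices of 5% and extrapolated to x = 1 with a saturating
  exponential a + b*exp(-c*x).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .alignment import MKTable
from .sfs import SFS

logger = logging.getLogger(__name__)

ALPHA_LOWER, ALPHA_UPPER = -5.0, 0.999


@dataclass
class EstimatorResult:
    alpha: float | None
    omega_a: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    method: str = ""
    seed: int | None = None
    n_bootstrap: int = 0
    adaptive_count: float | None = None
    reason: str | None = None
    extras: dict = field(default_factory=dict)


def _pool(tables: list[MKTable]) -> tuple[int, int, int, int, float, float]:
    P_N = sum(t.P_N for t in tables)
    P_S = sum(t.P_S for t in tables)
    D_N = sum(t.D_N for t in tables)
    D_S = sum(t.D_S for t in tables)
    L_N = sum(t.L_N for t in tables)
    L_S = sum(t.L_S for t in tables)
    return P_N, P_S, D_N, D_S, L_N, L_S


# ---------------------------------------------------------------------------
# naive estimator
# ---------------------------------------------------------------------------

def naive_alpha_from_counts(
    P_N: float, P_S: float, D_N: float, D_S: float,
    L_N: float | None = None, L_S: float | None = None,
) -> EstimatorResult:
    if D_N == 0 or P_S == 0:
        return EstimatorResult(
            alpha=None, method="naive",
            reason="undefined: D_N = 0" if D_N == 0 else "undefined: P_S = 0",
        )
    alpha = 1.0 - (D_S * P_N) / (D_N * P_S)
    adaptive = D_N - D_S * (P_N / P_S)
    omega_a = None
    if L_N and L_S and D_S > 0:
        omega_a = alpha * (D_N / L_N) / (D_S / L_S)
    return EstimatorResult(
        alpha=alpha, omega_a=omega_a, adaptive_count=adaptive, method="naive"
    )


def naive_alpha(tables: list[MKTable]) -> EstimatorResult:
    """Pooled naive alpha/omega_a over a set of gene tables."""
    P_N, P_S, D_N, D_S, L_N, L_S = _pool(tables)
    return naive_alpha_from_counts(P_N, P_S, D_N, D_S, L_N, L_S)


# ---------------------------------------------------------------------------
# per-gene exact tests with FDR
# ---------------------------------------------------------------------------

def gene_mk_test(table: MKTable) -> float:
    """Two-sided Fisher exact p for one gene's 2x2 MK table.

    By convention p = 1 when any margin of the table is zero (the test
    carries no information).
    """
    tab = np.array([[table.P_N, table.P_S], [table.D_N, table.D_S]])
    if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
        return 1.0
    return float(stats.fisher_exact(tab, alternative="two-sided")[1])


def fdr_correct(p_values) -> np.ndarray:
    """Benjamini–Hochberg q-values."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def significant_positive_genes(
    tables: list[MKTable], q_threshold: float = 0.05
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(p, q, flag) per gene; flag = q < threshold and per-gene naive alpha > 0."""
    p = np.array([gene_mk_test(t) for t in tables])
    q = fdr_correct(p)
    flags = np.zeros(len(tables), dtype=bool)
    for i, t in enumerate(tables):
        res = naive_alpha_from_counts(t.P_N, t.P_S, t.D_N, t.D_S)
        flags[i] = q[i] < q_threshold and res.alpha is not None and res.alpha > 0
    return p, q, flags


# ---------------------------------------------------------------------------
# maximum-likelihood multigene model
# ---------------------------------------------------------------------------

@dataclass
class WelchModel:
    """Fitted multigene Poisson model.

    Expected counts per gene i in class c(i):
        E[P_S] = theta_i L_S,   E[P_N] = f_i theta_i L_N,
        E[D_S] = T theta_i L_S, E[D_N] = f_i T theta_i L_N / (1 - alpha_c).
    """

    alpha_structure: str  # 'zero' | 'single' | 'per-class'
    f_structure: str      # 'per-gene' | 'per-class'
    alpha: dict           # class label (or '*') -> alpha
    T: float
    theta: np.ndarray
    f: np.ndarray
    logL: float
    n_params: int
    AIC: float
    converged: bool
    akaike_weight: float | None = None
    classes: list[str] | None = None


def _table_arrays(tables: list[MKTable]):
    PS = np.array([t.P_S for t in tables], float)
    PN = np.array([t.P_N for t in tables], float)
    DS = np.array([t.D_S for t in tables], float)
    DN = np.array([t.D_N for t in tables], float)
    LS = np.array([t.L_S for t in tables], float)
    LN = np.array([t.L_N for t in tables], float)
    return PS, PN, DS, DN, LS, LN


def _poisson_loglik(y: np.ndarray, mu: np.ndarray) -> float:
    mu = np.maximum(mu, 1e-300)
    return float(np.sum(stats.poisson.logpmf(y, mu)))


def _profile_loglik(
    tables_arr, alpha_per_gene: np.ndarray, T: float,
    f_per_gene: np.ndarray | None,
):
    """Log-likelihood with per-gene theta (and, when ``f_per_gene`` is None,
    per-gene f) profiled out analytically."""
    PS, PN, DS, DN, LS, LN = tables_arr
    one_minus_a = 1.0 - alpha_per_gene
    if f_per_gene is None:
        # theta_hat = (PS+DS)/(LS(1+T)); f_hat = (PN+DN)/(theta LN (1+T/(1-a)))
        theta = (PS + DS) / np.maximum(LS * (1.0 + T), 1e-12)
        denom = theta * LN * (1.0 + T / one_minus_a)
        f = np.where(denom > 0, (PN + DN) / np.maximum(denom, 1e-12), 0.0)
    else:
        f = f_per_gene
        denom = LS * (1.0 + T) + f * LN * (1.0 + T / one_minus_a)
        theta = (PS + PN + DS + DN) / np.maximum(denom, 1e-12)
    mu_PS = theta * LS
    mu_PN = f * theta * LN
    mu_DS = T * theta * LS
    mu_DN = f * T * theta * LN / one_minus_a
    ll = (
        _poisson_loglik(PS, mu_PS)
        + _poisson_loglik(PN, mu_PN)
        + _poisson_loglik(DS, mu_DS)
        + _poisson_loglik(DN, mu_DN)
    )
    return ll, theta, f


def welch_ml_fit(
    tables: list[MKTable],
    class_partition: dict[str, str] | None = None,
    alpha_structure: str = "single",
    f_structure: str = "per-gene",
    n_starts: int = 4,
) -> WelchModel:
    """Fit one multigene model structure by profile maximum likelihood.

    ``class_partition`` maps gene_id -> class label (defaults to each table's
    own label). The divergence scale T is shared across genes; per-gene
    nuisance parameters are profiled analytically, so the numeric search is
    only over (log T, alphas[, log f per class]).
    """
    if len(tables) < 1:
        raise ValueError("need at least one gene table")
    arr = _table_arrays(tables)
    labels = [
        class_partition.get(t.gene_id, t.class_label) if class_partition else t.class_label
        for t in tables
    ]
    classes = sorted(set(labels))
    class_idx = np.array([classes.index(c) for c in labels])
    G = len(tables)

    n_alpha = {"zero": 0, "single": 1, "per-class": len(classes)}[alpha_structure]
    n_fc = len(classes) if f_structure == "per-class" else 0

    def unpack(x):
        T = np.exp(x[0])
        if alpha_structure == "zero":
            a_gene = np.zeros(G)
            a_out = {"*": 0.0}
        elif alpha_structure == "single":
            a_gene = np.full(G, x[1])
            a_out = {"*": float(x[1])}
        else:
            a_gene = np.asarray(x[1 : 1 + n_alpha])[class_idx]
            a_out = {c: float(x[1 + i]) for i, c in enumerate(classes)}
        f_gene = None
        if f_structure == "per-class":
            f_gene = np.exp(np.asarray(x[1 + n_alpha :]))[class_idx]
        return T, a_gene, a_out, f_gene

    def negloglik(x):
        T, a_gene, _, f_gene = unpack(x)
        ll, _, _ = _profile_loglik(arr, a_gene, T, f_gene)
        return -ll

    bounds = [(-8.0, 8.0)] + [(ALPHA_LOWER, ALPHA_UPPER)] * n_alpha + [(-8.0, 4.0)] * n_fc
    rng = np.random.default_rng(0)
    best = None
    starts = [np.zeros(1 + n_alpha + n_fc)]
    for _ in range(max(0, n_starts - 1)):
        x0 = np.zeros(1 + n_alpha + n_fc)
        x0[0] = rng.normal(0, 1.5)
        x0[1 : 1 + n_alpha] = rng.uniform(-0.8, 0.8, n_alpha)
        x0[1 + n_alpha :] = rng.normal(-1, 1, n_fc)
        starts.append(x0)
    converged = False
    for x0 in starts:
        res = optimize.minimize(negloglik, x0, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
            converged = bool(res.success)
    assert best is not None
    T, a_gene, a_out, f_gene = unpack(best.x)
    ll, theta, f = _profile_loglik(arr, a_gene, T, f_gene)
    # parameter count: theta per gene + f (per gene or per class) + T + alphas
    n_params = G + (len(classes) if f_structure == "per-class" else G) + 1 + n_alpha
    aic = 2.0 * n_params - 2.0 * ll
    return WelchModel(
        alpha_structure=alpha_structure,
        f_structure=f_structure,
        alpha=a_out,
        T=float(T),
        theta=theta,
        f=f,
        logL=float(ll),
        n_params=n_params,
        AIC=float(aic),
        converged=converged,
        classes=classes,
    )


def welch_model_selection(
    tables: list[MKTable],
    class_partition: dict[str, str] | None = None,
    alpha_structures: tuple[str, ...] = ("zero", "single", "per-class"),
    f_structures: tuple[str, ...] = ("per-gene", "per-class"),
) -> list[WelchModel]:
    """Fit the model set and attach Akaike weights (sorted best first)."""
    models = [
        welch_ml_fit(tables, class_partition, a, f)
        for a in alpha_structures
        for f in f_structures
    ]
    aics = np.array([m.AIC for m in models])
    rel = np.exp(-0.5 * (aics - aics.min()))
    weights = rel / rel.sum()
    for m, w in zip(models, weights):
        m.akaike_weight = float(w)
    return sorted(models, key=lambda m: m.AIC)


def bootstrap_welch(
    tables: list[MKTable],
    class_partition: dict[str, str] | None = None,
    alpha_structure: str = "per-class",
    f_structure: str = "per-gene",
    B: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> dict[str, tuple[float, float]]:
    """Percentile bootstrap intervals for class alphas.

    Genes are resampled with replacement within each class. Degenerate
    resamples (all-zero counts in a class) are redrawn and logged. Classes
    with a single gene collapse to the point estimate with a warning.
    """
    rng = np.random.default_rng(seed)
    labels = [
        class_partition.get(t.gene_id, t.class_label) if class_partition else t.class_label
        for t in tables
    ]
    by_class: dict[str, list[MKTable]] = {}
    for t, lab in zip(tables, labels):
        by_class.setdefault(lab, []).append(t)
    for lab, members in by_class.items():
        if len(members) == 1:
            warnings.warn(
                f"class '{lab}' has a single gene; its bootstrap interval "
                "collapses to the point estimate"
            )
    draws: dict[str, list[float]] = {lab: [] for lab in by_class}
    for _ in range(B):
        sample: list[MKTable] = []
        for lab, members in by_class.items():
            for _attempt in range(100):
                idx = rng.integers(0, len(members), len(members))
                res = [members[i] for i in idx]
                if sum(t.P_S + t.P_N + t.D_S + t.D_N for t in res) > 0:
                    break
                logger.info("degenerate resample in class %s redrawn", lab)
            sample.extend(res)
        part = {t.gene_id: lab for t, lab in zip(tables, labels)}
        # gene ids may repeat in the resample; rebuild labels positionally
        labs = []
        for t in sample:
            labs.append(part.get(t.gene_id, t.class_label))
        model = welch_ml_fit(
            sample,
            {t.gene_id: lab for t, lab in zip(sample, labs)},
            alpha_structure,
            f_structure,
            n_starts=1,
        )
        for lab in by_class:
            key = lab if alpha_structure == "per-class" else "*"
            if key in model.alpha:
                draws[lab].append(model.alpha[key])
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    return {
        lab: (float(np.quantile(v, lo_q)), float(np.quantile(v, hi_q)))
        for lab, v in draws.items()
        if v
    }


def permutation_test_omega_a(
    tables_a: list[MKTable],
    tables_b: list[MKTable],
    B: int = 1000,
    seed: int = 0,
) -> dict:
    """Label-permutation test for a difference in pooled omega_a.

    The statistic is the difference of pooled naive omega_a between the two
    gene sets; gene labels are permuted B times. This is an interpretive
    test (the underlying contrast is not otherwise specified) and the
    two-sided permutation p-value is reported as such.
    """
    rng = np.random.default_rng(seed)

    def omega(tables: list[MKTable]) -> float | None:
        r = naive_alpha(tables)
        return r.omega_a

    obs_a, obs_b = omega(tables_a), omega(tables_b)
    if obs_a is None or obs_b is None:
        return {"statistic": None, "p_value": None, "reason": "undefined omega_a"}
    observed = obs_a - obs_b
    pool = list(tables_a) + list(tables_b)
    n_a = len(tables_a)
    hits = 0
    used = 0
    for _ in range(B):
        idx = rng.permutation(len(pool))
        pa = [pool[i] for i in idx[:n_a]]
        pb = [pool[i] for i in idx[n_a:]]
        oa, ob = omega(pa), omega(pb)
        if oa is None or ob is None:
            continue
        used += 1
        if abs(oa - ob) >= abs(observed) - 1e-15:
            hits += 1
    p = (hits + 1) / (used + 1) if used else None
    return {"statistic": observed, "p_value": p, "B_used": used, "seed": seed,
            "interpretive": True}


# ---------------------------------------------------------------------------
# asymptotic MK
# ---------------------------------------------------------------------------

@dataclass
class AsymptoticFit:
    bin_mid: np.ndarray
    alpha_x: np.ndarray
    a: float
    b: float
    c: float
    alpha_asymptotic: float
    fallback_linear: bool
    n_bins_used: int
    residual: float


def asymptotic_mk(
    sfs_N: SFS,
    sfs_S: SFS,
    D_N: float,
    D_S: float,
    n_bins: int = 20,
) -> AsymptoticFit:
    """Asymptotic-MK fit over derived-allele-frequency slices.

    Polymorphism is pooled into ``n_bins`` slices with equal (5% by default)
    frequency boundaries; per slice, alpha(x) = 1 - (D_S/D_N)(P_N(x)/P_S(x));
    a saturating exponential a + b*exp(-c*x) is fitted over slice midpoints
    and evaluated at x = 1. Slices with no synonymous polymorphism are
    dropped. A straight-line fit is the fallback when the exponential fit
    fails to converge or returns c < 0.
    """
    if sfs_N.folded or sfs_S.folded:
        raise ValueError("asymptotic MK requires unfolded spectra")
    if sfs_N.n != sfs_S.n:
        raise ValueError("spectra must share the haploid sample size")
    if D_N <= 0 or D_S <= 0:
        raise ValueError("divergence counts must be positive")
    n = sfs_N.n
    freqs = np.arange(1, n) / n
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    # assign frequency i/n to bin floor(x * n_bins), clamped
    which = np.clip(np.floor(freqs * n_bins).astype(int), 0, n_bins - 1)
    P_N = np.bincount(which, weights=sfs_N.counts, minlength=n_bins)
    P_S = np.bincount(which, weights=sfs_S.counts, minlength=n_bins)
    mid = 0.5 * (edges[:-1] + edges[1:])
    use = P_S > 0
    if use.sum() < 3:
        raise ValueError("too few informative frequency slices")
    if (~use).any():
        logger.info("dropping %d empty synonymous slices", int((~use).sum()))
    x = mid[use]
    alpha_x = 1.0 - (D_S / D_N) * (P_N[use] / P_S[use])

    def expo(xv, a, b, c):
        return a + b * np.exp(-c * xv)

    fallback = False
    a = b = c = np.nan
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = optimize.curve_fit(
                expo, x, alpha_x,
                p0=(alpha_x[-1], alpha_x[0] - alpha_x[-1], 1.0),
                maxfev=10000,
            )
        a, b, c = popt
        if not np.isfinite([a, b, c]).all() or c < 0:
            fallback = True
    except RuntimeError:
        fallback = True
    if fallback:
        slope, intercept = np.polyfit(x, alpha_x, 1)
        alpha_inf = float(intercept + slope * 1.0)
        resid = float(np.sum((np.polyval([slope, intercept], x) - alpha_x) ** 2))
        return AsymptoticFit(
            bin_mid=x, alpha_x=alpha_x, a=float(intercept), b=float(slope),
            c=np.nan, alpha_asymptotic=alpha_inf, fallback_linear=True,
            n_bins_used=int(use.sum()), residual=resid,
        )
    alpha_inf = float(expo(1.0, a, b, c))
    resid = float(np.sum((expo(x, a, b, c) - alpha_x) ** 2))
    return AsymptoticFit(
        bin_mid=x, alpha_x=alpha_x, a=float(a), b=float(b), c=float(c),
        alpha_asymptotic=alpha_inf, fallback_linear=False,
        n_bins_used=int(use.sum()), residual=resid,
    )
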