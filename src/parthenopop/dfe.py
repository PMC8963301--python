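"""SFS-based inference of the distribution of deleterious fitness effects.

The machinery follows the two-step architecture of SFS-based DFE estimators:
a step-change demography is first fitted to the putatively neutral
(synonymous) spectrum, then a deleterious DFE is fitted to the selected
(nonsynonymous) spectrum conditional on that demography, and finally the
fitted DFE converts divergence counts into an estimate of the adaptive
proportion alpha and rate omega_a.

Expected spectra are computed from discretized Wright–Fisher transition
matrices at a reduced reference size (default 100 diploids) with the scaled
selection coefficient preserved. Selection is semidominant throughout.

Scaling convention (used consistently everywhere in this package):
    S = 2 * N_e * s,  negative for deleterious mutations.
The relative fixation rate of a semidominant mutation is the Kimura form
    R(S) = S / (1 - exp(-S)),  with R(0) = 1.
DFE families are parameterized over the magnitude |S|; the discretized DFE
is reported over N_e s = |S|/2 in the bins [0,1), [1,10), [10,100), [100,inf).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats

from .sfs import SFS

logger = logging.getLogger(__name__)

NE_S_BIN_EDGES = (0.0, 1.0, 10.0, 100.0, math.inf)  # in units of Ne*s

#: |S| above which Wright-Fisher matrices are replaced by the 1/|S|
#: mutation-selection-balance scaling of the strong-selection limit.
S_CAP = 150.0


def fixation_rate_ratio(S) -> np.ndarray | float:
    """Kimura semidominant relative fixation rate R(S) = S/(1 - e^-S)."""
    scalar = np.isscalar(S) or np.ndim(S) == 0
    S = np.atleast_1d(np.asarray(S, dtype=float))
    out = np.ones_like(S)
    nz = S != 0
    with np.errstate(over="ignore", divide="ignore"):
        out[nz] = S[nz] / -np.expm1(-S[nz])
    # large negative S underflows to 0; large positive S -> S
    out = np.where(S < -700, 0.0, out)
    return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class DemographyModel:
    """Two-epoch step-change demography.

    ``ratio`` is N2/N1 (1 = equilibrium); ``t2`` is the time since the size
    change in units of 2*N2 generations; ``N_ref`` the reduced reference
    size used to discretize the Wright-Fisher process.
    """

    ratio: float = 1.0
    t2: float = 0.0
    N_ref: int = 100
    equilibrium_flag: bool = False

    def __post_init__(self) -> None:
        if self.ratio <= 0:
            raise ValueError("N2/N1 must be positive")
        if self.t2 < 0:
            raise ValueError("t2 must be nonnegative")

    @property
    def is_equilibrium(self) -> bool:
        return self.t2 == 0 or abs(self.ratio - 1.0) < 1e-9


@dataclass
class DFEModel:
    """A deleterious-DFE family over the scaled effect magnitude |S| = |2 Ne s|.

    families:
      * ``gamma``:     params (mean, shape) of |S|
      * ``lognormal``: params (mu, sigma) of log|S|
      * ``spike``:     params (s_values tuple, weights tuple) point masses
      * ``step``:      params (edges tuple len k+1, weights tuple len k)
                       uniform segments on |S|
    ``neutral_mass`` is an optional extra point mass exactly at S = 0.
    """

    family: str
    params: dict
    neutral_mass: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in ("gamma", "lognormal", "spike", "step"):
            raise ValueError(f"unknown DFE family {self.family!r}")
        if not 0 <= self.neutral_mass <= 1:
            raise ValueError("neutral_mass must be in [0, 1]")
        if self.family == "spike":
            w = np.asarray(self.params["weights"], float)
            if np.any(w < 0) or not math.isclose(w.sum() + self.neutral_mass, 1.0, abs_tol=1e-9):
                raise ValueError("spike weights must be nonnegative and sum to 1")
        if self.family == "step":
            w = np.asarray(self.params["weights"], float)
            if np.any(w < 0) or not math.isclose(w.sum() + self.neutral_mass, 1.0, abs_tol=1e-9):
                raise ValueError("step weights must be nonnegative and sum to 1")

    # -- probability over |S| ---------------------------------------------
    def _dist(self):
        if self.family == "gamma":
            mean, shape = self.params["mean"], self.params["shape"]
            return stats.gamma(a=shape, scale=mean / shape)
        if self.family == "lognormal":
            return stats.lognorm(s=self.params["sigma"], scale=math.exp(self.params["mu"]))
        return None

    def cdf(self, s_abs) -> np.ndarray:
        """CDF of |S| including any neutral point mass at 0."""
        s_abs = np.asarray(s_abs, dtype=float)
        cont = 1.0 - self.neutral_mass
        dist = self._dist()
        if dist is not None:
            base = dist.cdf(s_abs)
        elif self.family == "spike":
            vals = np.asarray(self.params["s_values"], float)
            w = np.asarray(self.params["weights"], float)
            base = (w[None, :] * (vals[None, :] <= s_abs.reshape(-1, 1))).sum(axis=1)
            base = base.reshape(s_abs.shape) / max(cont, 1e-300)
        else:  # step
            edges = np.asarray(self.params["edges"], float)
            w = np.asarray(self.params["weights"], float)
            base = np.zeros_like(s_abs, dtype=float)
            for lo, hi, wk in zip(edges[:-1], edges[1:], w):
                frac = np.clip((s_abs - lo) / (hi - lo), 0.0, 1.0)
                base = base + wk * frac
            base = base / max(cont, 1e-300)
        return self.neutral_mass + cont * np.clip(base, 0.0, 1.0)

    def mass_between(self, lo: float, hi: float) -> float:
        """P(lo < |S| <= hi); lo < 0 starts below the neutral atom at 0."""
        lo_c = 0.0 if lo < 0 else float(self.cdf(np.array(lo)))
        hi_c = float(self.cdf(np.array(hi))) if np.isfinite(hi) else 1.0
        return hi_c - lo_c

    def grid_weights(self, grid: np.ndarray) -> tuple[np.ndarray, float]:
        """(weights over grid points, neutral weight).

        Continuous families are discretized by assigning the probability mass
        between geometric midpoints of the |S| grid to each grid point; point
        masses go to the nearest grid point (or the neutral atom at 0).
        """
        grid = np.asarray(grid, float)
        edges = np.concatenate(([0.0], np.sqrt(grid[1:] * grid[:-1]), [np.inf]))
        if self.family in ("gamma", "lognormal", "step"):
            cdf_vals = np.concatenate((self.cdf(edges[:-1]), [1.0]))
            w = np.diff(cdf_vals)
            neutral = self.neutral_mass
            # mass assigned below the first midpoint includes the neutral atom
            w[0] -= neutral
            w = np.maximum(w, 0.0)
            return w, neutral
        # spike family
        w = np.zeros_like(grid)
        for sv, wk in zip(self.params["s_values"], self.params["weights"]):
            if sv <= grid[0]:  # effectively neutral below grid resolution
                continue
            idx = int(np.argmin(np.abs(np.log(grid) - np.log(sv))))
            w[idx] += wk
        neutral = self.neutral_mass + sum(
            wk for sv, wk in zip(self.params["s_values"], self.params["weights"])
            if sv <= grid[0]
        )
        return w, neutral

    def mean_fixation_ratio(self) -> float:
        """E[R(-|S|)] over the DFE: the expected non-adaptive dN/dS."""
        grid = default_s_grid()
        w, neutral = self.grid_weights(grid)
        return float(neutral + np.sum(w * fixation_rate_ratio(-grid)))


@dataclass
class DFEFit:
    model: DFEModel
    demography: DemographyModel
    logL: float
    n_params: int
    AIC: float
    theta_scale: float
    converged: bool
    boundary_flag: bool = False
    bin_proportions: tuple[float, ...] | None = None
    alpha: float | None = None
    omega_a: float | None = None
    alpha_ci: tuple[float, float] | None = None
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Wright-Fisher expected-SFS engine
# ---------------------------------------------------------------------------

def _wf_transition_matrix(two_N: int, s: float) -> np.ndarray:
    """Row-stochastic WF transition matrix with semidominant selection.

    Genotype fitnesses are 1, 1+s/2, 1+s; after deterministic selection the
    next generation is a binomial sample of 2N allele copies.
    """
    x = np.arange(two_N + 1) / two_N
    w_bar = 1.0 + s * x  # additive marginal fitness: mean fitness 1 + s*x
    with np.errstate(invalid="ignore", divide="ignore"):
        p_sel = (x * (1.0 + s / 2.0) + (x ** 2) * (s / 2.0)) / np.maximum(w_bar, 1e-12)
    p_sel = np.clip(p_sel, 0.0, 1.0)
    k = np.arange(two_N + 1)
    return stats.binom.pmf(k[None, :], two_N, p_sel[:, None])


def _equilibrium_sojourn(two_N: int, s: float) -> np.ndarray:
    """Expected sojourn time at each transient count 1..2N-1 for a mutation
    entering at count 1 (unit influx): the equilibrium frequency density."""
    T = _wf_transition_matrix(two_N, s)
    Q = T[1:-1, 1:-1]
    rhs = np.zeros(two_N - 1)
    rhs[0] = 1.0
    return np.linalg.solve(np.eye(two_N - 1) - Q.T, rhs)


class ExpectedSFSEngine:
    """Expected sample spectra under a two-epoch demography, cached per |S|.

    All spectra are on a common scale: the neutral spectrum is normalized so
    that multiplying by theta (=4*Ne*mu*L of the site class) gives expected
    segregating-site counts E[xi_i] ~= theta/i at equilibrium.
    """

    def __init__(self, demography: DemographyModel, n: int):
        self.demography = demography
        self.n = n
        N1 = demography.N_ref
        if n > 2 * N1:
            raise ValueError(
                f"sample size n={n} exceeds 2*N_ref={2 * N1}; increase the "
                "reference discretization size"
            )
        self._cache: dict[float, np.ndarray] = {}
        self._grid_cache: dict[tuple, np.ndarray] = {}
        self._prepare()

    def _prepare(self) -> None:
        d = self.demography
        self.two_N1 = 2 * d.N_ref
        self.N2 = max(4, int(round(d.N_ref * d.ratio)))
        self.two_N2 = 2 * self.N2
        self.t_gen = int(round(d.t2 * self.two_N2)) if not d.is_equilibrium else 0
        # calibration: unit-influx neutral sojourn ~ c/x; theta-scale factor
        u0 = self._population_density(0.0)
        raw = self._sample_sfs_from_density(u0)
        harmonic = np.sum(1.0 / np.arange(1, self.n))
        self._scale = harmonic / raw.sum()

    # -- population frequency density -------------------------------------
    def _population_density(self, S: float) -> np.ndarray:
        """Transient-count density (length 2N-1 of the final epoch)."""
        s1 = S / self.two_N1
        u1 = _equilibrium_sojourn(self.two_N1, s1)
        if self.t_gen == 0 and self.two_N2 == self.two_N1:
            return u1
        if self.t_gen == 0:
            # size label changed but no time elapsed: treat as equilibrium
            return u1
        s2 = S / self.two_N2
        # map epoch-1 density through one generation at the new size
        x = np.arange(1, self.two_N1) / self.two_N1
        w_bar = 1.0 + s2 * x
        p_sel = np.clip((x * (1 + s2 / 2) + x ** 2 * (s2 / 2)) / np.maximum(w_bar, 1e-12), 0, 1)
        k = np.arange(self.two_N2 + 1)
        map_T = stats.binom.pmf(k[None, :], self.two_N2, p_sel[:, None])
        v = u1 @ map_T
        T2 = _wf_transition_matrix(self.two_N2, s2)
        Q2 = T2[1:-1, 1:-1]
        v = v[1:-1]
        influx = np.zeros(self.two_N2 - 1)
        influx[0] = self.N2 / self.demography.N_ref  # mutational influx scales with N
        for _ in range(self.t_gen - 1):
            v = v @ Q2 + influx
        return v

    def _sample_sfs_from_density(self, u: np.ndarray) -> np.ndarray:
        two_N = len(u) + 1
        x = np.arange(1, two_N) / two_N
        i = np.arange(1, self.n)
        # E[xi_i] = sum_j u_j * Binom(i; n, x_j), polymorphic classes only
        pmf = stats.binom.pmf(i[None, :], self.n, x[:, None])
        return u @ pmf

    def sfs_for_S(self, S: float) -> np.ndarray:
        """Expected unfolded spectrum (classes 1..n-1) per unit theta."""
        S = float(S)
        if S in self._cache:
            return self._cache[S]
        if S < -S_CAP:
            base = self.sfs_for_S(-S_CAP)
            out = base * (S_CAP / abs(S))
        elif S > S_CAP:
            out = self.sfs_for_S(S_CAP)
        else:
            u = self._population_density(S)
            out = self._sample_sfs_from_density(u) * self._scale
        self._cache[S] = out
        return out

    def sfs_for_model(self, model: DFEModel, grid: np.ndarray | None = None) -> np.ndarray:
        """Expected deleterious-DFE spectrum per unit theta."""
        if grid is None:
            grid = default_s_grid()
        w, neutral = model.grid_weights(grid)
        out = neutral * self.sfs_for_S(0.0)
        for wk, sk in zip(w, grid):
            if wk > 0:
                out = out + wk * self.sfs_for_S(-sk)
        return out

    def grid_matrix(self, grid: np.ndarray, folded: bool = False) -> np.ndarray:
        """(len(grid)+1, classes) matrix of spectra: row 0 neutral, then -grid."""
        key = (folded, len(grid), float(grid[0]), float(grid[-1]))
        if key in self._grid_cache:
            return self._grid_cache[key]
        rows = [self.sfs_for_S(0.0)]
        rows += [self.sfs_for_S(-sk) for sk in grid]
        M = np.vstack(rows)
        if folded:
            M = np.vstack([SFS(n=self.n, counts=r).fold().counts for r in M])
        self._grid_cache[key] = M
        return M


def default_s_grid() -> np.ndarray:
    """Log-spaced |S| grid spanning effectively neutral to lethal effects."""
    return np.logspace(-4, 6, 81)


_ENGINE_CACHE: dict[tuple, "ExpectedSFSEngine"] = {}


def get_engine(demography: DemographyModel, n: int) -> "ExpectedSFSEngine":
    """Process-wide cache of engines keyed by (demography, n).

    Spectra grids are expensive to rebuild; repeated fits under the same
    demography (bootstrap replicates, simulation studies) reuse one engine.
    """
    key = (round(demography.ratio, 6), round(demography.t2, 6), demography.N_ref, n)
    if key not in _ENGINE_CACHE:
        if len(_ENGINE_CACHE) > 32:
            _ENGINE_CACHE.clear()
        _ENGINE_CACHE[key] = ExpectedSFSEngine(demography, n)
    return _ENGINE_CACHE[key]


def expected_sfs(
    demography: DemographyModel,
    n: int,
    effect: float | DFEModel,
    folded: bool = False,
    theta: float = 1.0,
) -> np.ndarray:
    """Expected SFS counts (up to the theta scale) for one scaled effect or a DFE.

    ``effect`` is either a scaled selection value S = 2*Ne*s (negative =
    deleterious) or a :class:`DFEModel` integrated over its grid weights.
    """
    if n < 4:
        raise ValueError("n must be at least 4")
    engine = ExpectedSFSEngine(demography, n)
    if isinstance(effect, DFEModel):
        vec = engine.sfs_for_model(effect)
    else:
        vec = engine.sfs_for_S(float(effect))
    vec = theta * vec
    if folded:
        return SFS(n=n, counts=np.maximum(vec, 0), folded=False).fold().counts
    return vec


# ---------------------------------------------------------------------------
# demography fitting (neutral spectrum)
# ---------------------------------------------------------------------------

def fit_demography(
    sfs_S: SFS,
    N_ref: int = 100,
    ratio_bounds: tuple[float, float] = (0.1, 10.0),
    t2_bounds: tuple[float, float] = (0.02, 2.0),
    grid_points: int = 5,
) -> DemographyModel:
    """ML step-change demography from the neutral spectrum shape.

    Maximizes the multinomial likelihood of the spectrum shape (theta
    profiles out). A coarse log-grid over (N2/N1, t2) seeds a Nelder-Mead
    polish. When no model improves measurably on equilibrium (flat
    likelihood), the equilibrium model is returned flagged.
    """
    obs = np.asarray(sfs_S.counts, float)
    if obs.sum() <= 0:
        return DemographyModel(N_ref=N_ref, equilibrium_flag=True)

    def shape_of(dem: DemographyModel) -> np.ndarray:
        eng = ExpectedSFSEngine(dem, sfs_S.n)
        vec = eng.sfs_for_S(0.0)
        if sfs_S.folded:
            vec = SFS(n=sfs_S.n, counts=vec).fold().counts
        return vec / vec.sum()

    def negloglik(params) -> float:
        r, t = math.exp(params[0]), math.exp(params[1])
        r = min(max(r, ratio_bounds[0]), ratio_bounds[1])
        t = min(max(t, t2_bounds[0]), t2_bounds[1])
        p = shape_of(DemographyModel(ratio=r, t2=t, N_ref=N_ref))
        return -float(np.sum(obs * np.log(np.maximum(p, 1e-300))))

    ll_eq = -negloglik([0.0, math.log(t2_bounds[0])])  # ratio 1 ~ equilibrium
    rs = np.linspace(math.log(ratio_bounds[0]), math.log(ratio_bounds[1]), grid_points)
    ts = np.linspace(math.log(t2_bounds[0]), math.log(t2_bounds[1]), grid_points - 1)
    best_x, best_nll = None, -ll_eq
    for lr in rs:
        for lt in ts:
            nll = negloglik([lr, lt])
            if nll < best_nll - 1e-9:
                best_nll, best_x = nll, [lr, lt]
    if best_x is None:
        return DemographyModel(N_ref=N_ref, equilibrium_flag=True)
    res = optimize.minimize(
        negloglik, best_x, method="Nelder-Mead",
        options={"xatol": 1e-3, "fatol": 1e-4, "maxiter": 60},
    )
    r = min(max(math.exp(res.x[0]), ratio_bounds[0]), ratio_bounds[1])
    t = min(max(math.exp(res.x[1]), t2_bounds[0]), t2_bounds[1])
    if -res.fun - ll_eq < 2.0:  # no real signal for a size change
        return DemographyModel(N_ref=N_ref, equilibrium_flag=True)
    return DemographyModel(ratio=r, t2=t, N_ref=N_ref)


# ---------------------------------------------------------------------------
# DFE fitting (selected spectrum)
# ---------------------------------------------------------------------------

def _model_from_x(family: str, x: np.ndarray) -> DFEModel:
    if family == "gamma":
        return DFEModel("gamma", {"mean": math.exp(x[0]), "shape": math.exp(x[1])})
    if family == "lognormal":
        return DFEModel("lognormal", {"mu": x[0], "sigma": math.exp(x[1])})
    if family.startswith("spike"):
        k = int(family.split(":")[1])
        vals = np.exp(x[:k])
        w = _softmax(x[k : 2 * k - 1])
        return DFEModel("spike", {"s_values": tuple(vals), "weights": tuple(w)})
    if family.startswith("step"):
        k = int(family.split(":")[1])
        # increasing edges from cumulative exp increments, starting at 0
        edges = np.concatenate(([0.0], np.cumsum(np.exp(x[:k]))))
        w = _softmax(x[k : 2 * k - 1])
        return DFEModel("step", {"edges": tuple(edges), "weights": tuple(w)})
    raise ValueError(f"unknown family {family!r}")


def _softmax(z: np.ndarray) -> np.ndarray:
    z = np.concatenate((np.asarray(z, float), [0.0]))
    e = np.exp(z - z.max())
    return e / e.sum()


def _family_dims(family: str) -> int:
    if family in ("gamma", "lognormal"):
        return 2
    k = int(family.split(":")[1])
    return 2 * k - 1


def _family_x0(family: str) -> list[np.ndarray]:
    if family == "gamma":
        return [np.array([math.log(m), math.log(s)])
                for m in (10.0, 500.0, 4000.0) for s in (0.2, 0.6)]
    if family == "lognormal":
        return [np.array([mu, math.log(sig)]) for mu in (1.0, 4.0) for sig in (1.0, 3.0)]
    k = int(family.split(":")[1])
    outs = []
    for scale in (1.0, 3.0):
        vals = np.linspace(0.0, scale * 2, k) + np.log(5.0)
        outs.append(np.concatenate((vals, np.zeros(k - 1))))
    return outs


def estimate_theta_site(sfs_S: SFS, L_S: float, demography: DemographyModel) -> float:
    """Per-site theta (4 Ne mu) from the neutral spectrum under a demography."""
    engine = get_engine(demography, sfs_S.n)
    vec = engine.sfs_for_S(0.0)
    if sfs_S.folded:
        vec = SFS(n=sfs_S.n, counts=vec).fold().counts
    return float(np.asarray(sfs_S.counts).sum() / (L_S * vec.sum()))


def fit_dfe(
    sfs_N: SFS,
    demography: DemographyModel,
    family: str = "gamma",
    grid: np.ndarray | None = None,
    theta_N: float | None = None,
    starts: list[np.ndarray] | None = None,
    maxiter: int = 2000,
) -> DFEFit:
    """ML fit of a deleterious DFE to the selected spectrum.

    The likelihood is Poisson over frequency classes. When ``theta_N`` (the
    expected mutational influx theta_site * L_N, normally calibrated from
    the neutral spectrum via :func:`estimate_theta_site`) is given, the
    absolute deficit of selected polymorphism informs the fit; otherwise the
    scale is profiled analytically and only the spectrum shape is used.
    Folded and unfolded input are both supported. A fit that converges to
    the shape boundary is flagged. The returned fit carries the discretized
    bin proportions; alpha and omega_a are attached by
    :func:`alpha_from_dfe`.
    """
    if grid is None:
        grid = default_s_grid()
    engine = get_engine(demography, sfs_N.n)
    M = engine.grid_matrix(grid, folded=sfs_N.folded)
    obs = np.asarray(sfs_N.counts, float)

    def expected_shape(model: DFEModel) -> np.ndarray:
        w, neutral = model.grid_weights(grid)
        return np.concatenate(([neutral], w)) @ M

    def negloglik(x) -> float:
        try:
            model = _model_from_x(family, x)
        except (ValueError, OverflowError):
            return 1e12
        e = expected_shape(model)
        tot = e.sum()
        if not np.isfinite(tot) or tot <= 0:
            return 1e12
        theta = theta_N if theta_N is not None else obs.sum() / tot
        mu = np.maximum(theta * e, 1e-300)
        return float(np.sum(mu - obs * np.log(mu)))

    best = None
    for x0 in (starts if starts is not None else _family_x0(family)):
        res = optimize.minimize(
            negloglik, x0, method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": maxiter,
                     "maxfev": 2 * maxiter},
        )
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    model = _model_from_x(family, best.x)
    e = expected_shape(model)
    theta = theta_N if theta_N is not None else obs.sum() / e.sum()
    mu = np.maximum(theta * e, 1e-300)
    ll = float(np.sum(stats.poisson.logpmf(np.round(obs), mu)))
    n_params = _family_dims(family) + 1  # + theta
    boundary = False
    if family == "gamma" and model.params["shape"] < 1e-3:
        boundary = True
    fit = DFEFit(
        model=model,
        demography=demography,
        logL=ll,
        n_params=n_params,
        AIC=2.0 * n_params - 2.0 * ll,
        theta_scale=float(theta),
        converged=bool(best.success),
        boundary_flag=boundary,
        bin_proportions=discretize_dfe(model),
        extras={"x_opt": np.asarray(best.x)},
    )
    return fit


def discretize_dfe(model: DFEModel) -> tuple[float, float, float, float]:
    """DFE mass in the Ne*s bins [0,1), [1,10), [10,100), [100,inf).

    Computed from the family CDF over |S| = 2*Ne*s (point masses included in
    their containing bin); the proportions sum to 1.
    """
    props = []
    for lo, hi in zip(NE_S_BIN_EDGES[:-1], NE_S_BIN_EDGES[1:]):
        # half-open [lo, hi) bins: nudge both edges below the boundary so a
        # point mass exactly on an edge lands in the upper bin
        lo_s = 2.0 * lo - 1e-9 if lo > 0 else -1.0
        hi_s = 2.0 * hi - 1e-9 if np.isfinite(hi) else math.inf
        props.append(model.mass_between(lo_s, hi_s))
    total = sum(props)
    return tuple(p / total for p in props)  # type: ignore[return-value]


def alpha_from_dfe(
    fit: DFEFit | DFEModel,
    D_N: float,
    D_S: float,
    L_N: float,
    L_S: float,
) -> tuple[float, float]:
    """DFE-corrected (alpha, omega_a) from divergence counts.

    The expected non-adaptive nonsynonymous divergence is
    D_S * (L_N/L_S) * E[R(S)] with R the semidominant fixation-rate ratio
    integrated over the fitted deleterious DFE; alpha is the complement of
    its share of the observed D_N.
    """
    if D_S <= 0:
        raise ValueError("alpha undefined for D_S = 0")
    if D_N <= 0:
        raise ValueError("alpha undefined for D_N = 0")
    model = fit.model if isinstance(fit, DFEFit) else fit
    mean_R = model.mean_fixation_ratio()
    expected_nonadaptive = D_S * (L_N / L_S) * mean_R
    alpha = 1.0 - expected_nonadaptive / D_N
    omega_a = alpha * (D_N / L_N) / (D_S / L_S)
    if isinstance(fit, DFEFit):
        fit.alpha, fit.omega_a = float(alpha), float(omega_a)
    return float(alpha), float(omega_a)


# ---------------------------------------------------------------------------
# class contrasts and bootstrap
# ---------------------------------------------------------------------------

def class_lrt(fit_joint: DFEFit, fit_control: DFEFit, fit_class: DFEFit, df: int = 2):
    """Likelihood-ratio test for a class-specific DFE.

    The null fits control and class genes as a single group (``fit_joint``);
    the alternative fits each separately. Two degrees of freedom (the two
    gamma parameters freed). Fits must share family and demography.
    """
    for f in (fit_control, fit_class):
        if f.model.family != fit_joint.model.family:
            raise ValueError("LRT requires nested fits of the same DFE family")
        if (f.demography.ratio, f.demography.t2) != (
            fit_joint.demography.ratio, fit_joint.demography.t2,
        ):
            raise ValueError("LRT requires a shared demography")
    chi2 = 2.0 * (fit_control.logL + fit_class.logL - fit_joint.logL)
    chi2 = max(chi2, 0.0)
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def bootstrap_dfe(
    sfs_N: SFS,
    sfs_S: SFS | None,
    demography: DemographyModel,
    D_N: float,
    D_S: float,
    L_N: float,
    L_S: float,
    family: str = "gamma",
    B: int = 200,
    seed: int = 0,
    refit_demography: bool = False,
    level: float = 0.95,
) -> dict:
    """Percentile bootstrap intervals for DFE bin proportions, alpha, omega_a.

    Sites are independent after the upstream filters, so each replicate
    resamples the spectra (both selected and neutral — the neutral side
    propagates uncertainty in the theta calibration) and the divergence
    counts as Poisson draws around the observed values, then refits from a
    warm start at the point estimate. With B = 1 the interval degenerates
    to the point estimate.
    """
    rng = np.random.default_rng(seed)
    theta0 = (
        estimate_theta_site(sfs_S, L_S, demography) * L_N
        if sfs_S is not None else None
    )
    fit0 = fit_dfe(sfs_N, demography, family, theta_N=theta0)
    alpha0, omega0 = alpha_from_dfe(fit0, D_N, D_S, L_N, L_S)
    warm = [np.asarray(fit0.extras["x_opt"])]
    alphas, omegas, bins = [], [], []
    for _ in range(B):
        counts = rng.poisson(np.maximum(sfs_N.counts, 0.0))
        rep_sfs = SFS(sfs_N.n, counts.astype(float), sfs_N.folded, sfs_N.site_class)
        dn = max(int(rng.poisson(D_N)), 1)
        ds = max(int(rng.poisson(D_S)), 1)
        dem = demography
        theta_rep = None
        if sfs_S is not None:
            s_counts = rng.poisson(np.maximum(sfs_S.counts, 0.0)).astype(float)
            rep_syn = SFS(sfs_S.n, s_counts, sfs_S.folded, sfs_S.site_class)
            if refit_demography:
                dem = fit_demography(rep_syn)
            theta_rep = estimate_theta_site(rep_syn, L_S, dem) * L_N
        fit = fit_dfe(rep_sfs, dem, family, theta_N=theta_rep,
                      starts=warm, maxiter=600)
        a, w = alpha_from_dfe(fit, dn, ds, L_N, L_S)
        alphas.append(a)
        omegas.append(w)
        bins.append(fit.bin_proportions)
    lo, hi = (1 - level) / 2, 1 - (1 - level) / 2
    if B == 1:
        alpha_ci = (alphas[0], alphas[0])
        omega_ci = (omegas[0], omegas[0])
    else:
        alpha_ci = (float(np.quantile(alphas, lo)), float(np.quantile(alphas, hi)))
        omega_ci = (float(np.quantile(omegas, lo)), float(np.quantile(omegas, hi)))
    bins_arr = np.asarray(bins)
    fit0.alpha_ci = alpha_ci
    return {
        "fit": fit0,
        "alpha": alpha0,
        "omega_a": omega0,
        "alpha_ci": alpha_ci,
        "omega_a_ci": omega_ci,
        "bin_ci": [
            (float(np.quantile(bins_arr[:, j], lo)), float(np.quantile(bins_arr[:, j], hi)))
            for j in range(bins_arr.shape[1])
        ],
        "seed": seed,
        "B": B,
    }
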