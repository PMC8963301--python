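"""Forward simulation of a finite island model with cyclical parthenogenesis.

Two engines share the same population model (d demes of N diploids,
symmetric migration at per-individual rate m, Wright-Fisher reproduction
with soft selection within demes):

* :func:`simulate` — the full haplotype engine: a chromosome of alternating
  coding and noncoding blocks, semidominant selection with a gamma DFE and
  rare fixed-effect beneficials, recombination, and a sexual/clonal life
  cycle (every k-th generation fully sexual; otherwise 99% of offspring
  clonal). It logs post-burn-in fixations and returns sampled haplotypes,
  spectra, and MK-style count tables.
* :func:`neutral_fst_calibration` — a per-site allele-frequency engine for
  unconstrained, unlinked sites. For neutral unlinked sites the marginal
  allele-frequency process of the haplotype engine is exactly this
  frequency process, so equilibrium diversity and F_ST can be calibrated at
  a fraction of the cost.

Selection is parameterized in scaled units S = 2*N_T*s (N_T = d*N total
diploids), so configurations can be rescaled to desk size while preserving
4*N_T*mu, 4*N_T*r, S, and N*m exactly.

:func:`fast_tables` sidesteps forward simulation entirely: it draws per-gene
MK tables and SFS pairs by Poisson sampling around the expected-SFS
machinery, for estimator tests with known truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .dfe import DemographyModel, DFEModel, get_engine
from .sfs import SFS

# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Island-model configuration; defaults are the full-scale study design."""

    d: int = 36                      # demes
    N: int = 500                     # diploids per deme
    m: float = 0.00142               # per-individual migration probability
    L: int = 500_000                 # chromosome length (bp)
    n_coding_loci: int = 10
    coding_bp: int = 5_000
    spacer_bp: int = 45_000
    mu: float = 1.53e-7              # per-site per-generation (scaled)
    r: float = 4.52e-6               # per-site per-generation (scaled)
    frac_unconstrained: float = 0.24 # of coding mutations
    del_mean_S: float = 2000.0       # |2 N_T s| gamma mean, deleterious
    del_shape: float = 0.3
    ben_S: float = 250.0             # 2 N_T s, beneficial
    ben_prob: float = 0.00022        # among selected coding mutations
    sex_period: int = 8              # k: every k-th generation fully sexual
    clonal_fraction: float = 0.99    # clonal offspring in asexual generations
    generations: int = 1_000_000
    burn_in: int | None = None       # None = stationarity rule with hard floor
    seed: int = 0
    rescale_factor: float = 1.0

    def __post_init__(self) -> None:
        for p in (self.m, self.frac_unconstrained, self.ben_prob, self.clonal_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.d < 2 and self.m > 0:
            raise ValueError("migration requires at least 2 demes")
        layout = self.n_coding_loci * (self.coding_bp + self.spacer_bp)
        if layout != self.L:
            raise ValueError(
                f"locus layout ({self.n_coding_loci} x ({self.coding_bp} + "
                f"{self.spacer_bp}) = {layout}) must tile L = {self.L} exactly"
            )

    @property
    def N_total(self) -> int:
        return self.d * self.N

    @property
    def coding_length(self) -> int:
        return self.n_coding_loci * self.coding_bp

    def is_coding(self, positions: np.ndarray) -> np.ndarray:
        period = self.coding_bp + self.spacer_bp
        return (positions % period) < self.coding_bp

    # compound (scale-invariant) parameters
    @property
    def theta_total(self) -> float:
        return 4.0 * self.N_total * self.mu

    @property
    def rho_total(self) -> float:
        return 4.0 * self.N_total * self.r


def rescale_config(config: SimConfig, factor: float, match_fst: bool = False) -> SimConfig:
    """Rescale to a smaller population preserving 4*N_T*mu, 4*N_T*r, S, N*m.

    N -> N/factor; mu, r, m -> x factor; generations -> /factor. Selection is
    stored in scaled units so S = 2*N_T*s is preserved by construction.

    Multiplying m by the factor preserves N*m exactly, but because the
    island-model F_ST depends on m beyond first order, a large rescaled m
    slightly weakens equilibrium differentiation. With ``match_fst`` the
    rescaled migration rate is instead solved so the exact two-lineage
    equilibrium F_ST of the original configuration is preserved.
    """
    if factor <= 0:
        raise ValueError("rescale factor must be positive")
    new_N = config.N / factor
    if new_N < 10:
        raise ValueError(
            f"rescale factor {factor} gives N = {new_N:.1f} < 10 per deme; "
            "drift discretization unsafe"
        )
    if abs(new_N - round(new_N)) > 0.005 * new_N:
        raise ValueError(f"rescale factor {factor} must (nearly) divide N = {config.N}")
    new_N_int = int(round(new_N))
    new_m = min(config.m * factor, 1.0)
    if match_fst and config.m > 0 and config.d > 1:
        from scipy.optimize import brentq

        target = expected_fst_exact(config)
        def gap(mm: float) -> float:
            probe = replace(config, N=new_N_int, m=mm)
            return expected_fst_exact(probe) - target
        new_m = float(brentq(gap, 1e-8, 0.999))
    return replace(
        config,
        N=new_N_int,
        mu=config.mu * factor,
        r=config.r * factor,
        m=new_m,
        generations=max(1, int(round(config.generations / factor))),
        burn_in=None if config.burn_in is None else max(1, int(round(config.burn_in / factor))),
        rescale_factor=config.rescale_factor * factor,
    )


def expected_fst(config: SimConfig) -> float:
    """Finite-island-model equilibrium F_ST: 1/(1 + 4 N m (d/(d-1))^2)."""
    dd = config.d / (config.d - 1)
    return 1.0 / (1.0 + 4.0 * config.N * config.m * dd * dd)


def expected_fst_exact(config: SimConfig) -> float:
    """Exact equilibrium F_ST = 1 - T_within/T_bar from the two-lineage
    coalescent recursion of the finite island model (backward migration,
    then coalescence at 1/2N within a deme); reduces to the closed form
    1/(1 + 4Nm(d/(d-1))^2) as m -> 0."""
    N, d, m = config.N, config.d, config.m
    if d < 2 or m <= 0:
        raise ValueError("exact F_ST requires migration between >= 2 demes")
    two_N = 2 * N
    pSS = (1 - m) ** 2 + m ** 2 / (d - 1)
    pDS = 2 * m * (1 - m) / (d - 1) + m ** 2 * (d - 2) / (d - 1) ** 2
    c = 1.0 / two_N
    M = np.array([[1.0 - pSS * (1 - c), -(1.0 - pSS)],
                  [-pDS * (1 - c), 1.0 - (1.0 - pDS)]])
    T_S, T_D = np.linalg.solve(M, np.ones(2))
    T_bar = ((two_N - 1) * T_S + two_N * (d - 1) * T_D) / (two_N * d - 1)
    return float(1.0 - T_S / T_bar)


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

@dataclass
class SampleSpec:
    strategy: str = "one-per-deme"   # | 'single-deme-36' | 'spread-360'
    seed: int = 0

    def __post_init__(self) -> None:
        if self.strategy not in ("one-per-deme", "single-deme-36", "spread-360"):
            raise ValueError(f"unknown sampling strategy {self.strategy!r}")


def sample_individual_indices(config: SimConfig, spec: SampleSpec) -> np.ndarray:
    """Deterministic (seeded) diploid indices for a sampling strategy."""
    rng = np.random.default_rng(spec.seed)
    d, N = config.d, config.N
    if spec.strategy == "one-per-deme":
        return np.array([deme * N + rng.integers(N) for deme in range(d)])
    if spec.strategy == "single-deme-36":
        if N < 36:
            raise ValueError("single-deme-36 requires at least 36 diploids per deme")
        deme = int(rng.integers(d))
        return deme * N + rng.choice(N, size=36, replace=False)
    per_deme = 360 // d
    if per_deme < 1 or N < per_deme:
        raise ValueError("spread-360 requires N >= 360/d diploids per deme")
    return np.concatenate(
        [deme * N + rng.choice(N, size=per_deme, replace=False) for deme in range(d)]
    )


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass
class FixationRecord:
    position: int
    site_class: str            # 'neutral' | 'selected'
    s: float                   # scaled S = 2 N_T s
    origin_generation: int
    fixation_generation: int
    beneficial: bool
    coding: bool


@dataclass
class SimResult:
    config: SimConfig
    samples: dict               # strategy -> dict(haplotypes, demes, positions, ...)
    fixations: list[FixationRecord]
    burn_in_generation: int
    pi_S_local: float
    pi_S_total: float
    fst_neutral: float | None
    generations_run: int

    def true_alpha(self) -> float | None:
        return true_alpha(self.fixations)

    def mk_table(self, strategy: str = "one-per-deme", gene_id: str = "sim"):
        """MK-style count table: polymorphism from the sampled haplotypes
        (coding sites), divergence from the post-burn-in fixation log."""
        from .alignment import MKTable

        sample = self.samples[strategy]
        coding = sample["coding"]
        sel = sample["selected"]
        H = sample["haplotypes"]
        n = H.shape[0]
        seg = (H.sum(axis=0) > 0) & (H.sum(axis=0) < n)
        P_N = int((seg & coding & sel).sum())
        P_S = int((seg & coding & ~sel).sum())
        D_N, D_S = self.divergence_counts(coding_only=True)
        cfg = self.config
        L_N = (1.0 - cfg.frac_unconstrained) * cfg.coding_length
        L_S = cfg.frac_unconstrained * cfg.coding_length
        return MKTable(gene_id, P_N, P_S, D_N, D_S, L_N, L_S, "control")

    def divergence_counts(self, coding_only: bool = True) -> tuple[int, int]:
        """(D_N, D_S): post-burn-in selected and neutral fixation counts."""
        D_N = sum(1 for f in self.fixations if f.site_class == "selected")
        D_S = sum(
            1 for f in self.fixations
            if f.site_class == "neutral" and (f.coding or not coding_only)
        )
        return D_N, D_S


def true_alpha(fixations: list[FixationRecord]) -> float | None:
    """Fraction of selected-class fixations that were beneficial."""
    selected = [f for f in fixations if f.site_class == "selected"]
    if not selected:
        return None
    return sum(f.beneficial for f in selected) / len(selected)


# ---------------------------------------------------------------------------
# haplotype engine
# ---------------------------------------------------------------------------

class _SitePool:
    """Fixed-capacity pool of segregating-site columns, compacted on the fly."""

    def __init__(self, n_hap: int, capacity: int):
        self.G = np.zeros((n_hap, capacity), dtype=np.uint8)
        self.pos = np.zeros(capacity, dtype=np.int64)
        self.S_scaled = np.zeros(capacity)          # scaled effect 2 N_T s
        self.log_het = np.zeros(capacity)           # log fitness of heterozygote
        self.log_hom = np.zeros(capacity)           # log fitness of homozygote
        self.selected = np.zeros(capacity, dtype=bool)
        self.beneficial = np.zeros(capacity, dtype=bool)
        self.coding = np.zeros(capacity, dtype=bool)
        self.origin = np.zeros(capacity, dtype=np.int64)
        self.n_active = 0

    def grow(self) -> None:
        cap = self.G.shape[1]
        new_cap = int(cap * 1.6) + 64
        for name in ("pos", "S_scaled", "log_het", "log_hom",
                     "selected", "beneficial", "coding", "origin"):
            arr = getattr(self, name)
            new = np.zeros(new_cap, dtype=arr.dtype)
            new[:cap] = arr
            setattr(self, name, new)
        G_new = np.zeros((self.G.shape[0], new_cap), dtype=np.uint8)
        G_new[:, :cap] = self.G
        self.G = G_new

    def add_sites(self, k: int) -> np.ndarray:
        while self.n_active + k > self.G.shape[1]:
            self.grow()
        idx = np.arange(self.n_active, self.n_active + k)
        self.n_active += k
        self.G[:, idx] = 0
        return idx

    def drop(self, cols: np.ndarray) -> None:
        """Remove columns, compacting the active block."""
        if len(cols) == 0:
            return
        n = self.n_active
        mask = np.ones(n, dtype=bool)
        mask[cols] = False
        idx = np.flatnonzero(mask)
        k = len(idx)
        self.G[:, :k] = self.G[:, idx]
        for name in ("pos", "S_scaled", "log_het", "log_hom",
                     "selected", "beneficial", "coding", "origin"):
            arr = getattr(self, name)
            arr[:k] = arr[idx]
        self.n_active = k


def _draw_effects(config: SimConfig, coding: np.ndarray, rng) -> tuple[np.ndarray, ...]:
    """Classify new mutations and draw their scaled effects."""
    k = len(coding)
    selected = coding & (rng.random(k) >= config.frac_unconstrained)
    beneficial = selected & (rng.random(k) < config.ben_prob)
    S = np.zeros(k)
    n_del = int((selected & ~beneficial).sum())
    if n_del:
        S[selected & ~beneficial] = -rng.gamma(
            config.del_shape, config.del_mean_S / config.del_shape, n_del
        )
    S[beneficial] = config.ben_S
    return selected, beneficial, S


def _log_fitness_terms(S: np.ndarray, two_NT: int) -> tuple[np.ndarray, np.ndarray]:
    s = S / two_NT  # S = 2 N_T s
    het = np.where(1.0 + s / 2.0 > 1e-9, np.log(np.maximum(1.0 + s / 2.0, 1e-9)), -1e9)
    hom = np.where(1.0 + s > 1e-9, np.log(np.maximum(1.0 + s, 1e-9)), -1e9)
    return het, hom


def simulate(
    config: SimConfig,
    sample_specs: tuple[SampleSpec, ...] = (SampleSpec("one-per-deme"),),
    post_burn_in: int | None = None,
    pi_check_every: int = 500,
    gc_every: int = 4,
) -> SimResult:
    """Run the forward haplotype engine and return samples plus fixation log.

    Each generation, offspring in every deme are produced by
    fitness-proportional parent choice (soft selection); with probability m
    an offspring's parents come from a uniformly random other deme. In a
    sexual generation (every ``sex_period``-th, or a 1% background fraction
    otherwise) an offspring is formed from two parental gametes with
    Poisson-recombined crossovers at rate r per site; clonal offspring copy
    both haplotypes of a single parent. Mutations arise at mu per site per
    haplotype with the coding/noncoding and 24/76 neutral/selected split.

    Burn-in follows the stationarity rule (two successive pi_S windows within
    5%) with a hard floor of 8*(2*d*N) generations, unless ``config.burn_in``
    pins it; ``post_burn_in`` limits the number of generations simulated
    after burn-in (defaults to the remainder of ``config.generations``).
    Fixations are logged only after burn-in.
    """
    rng = np.random.default_rng(config.seed)
    d, N = config.d, config.N
    n_ind = config.N_total
    n_hap = 2 * n_ind
    two_NT = n_hap

    pool = _SitePool(n_hap, max(1024, int(0.2 * config.mu * config.L * two_NT * 20)))
    mean_new = 2.0 * config.N_total * config.mu * config.L

    deme_of_ind = np.repeat(np.arange(d), N)
    deme_offsets = np.arange(d) * N

    fixations: list[FixationRecord] = []
    burn_in_gen: int | None = config.burn_in
    hard_floor = 8 * 2 * d * N
    pi_history: list[float] = []
    pi_samples_total: list[float] = []
    pi_samples_within: list[float] = []

    neutral_L = config.L - int(
        round((1.0 - config.frac_unconstrained) * config.coding_length)
    )

    def population_pi() -> tuple[float, float]:
        """(local mean within-deme pi_S, total pi_S) at neutral sites."""
        S = pool.n_active
        if S == 0:
            return 0.0, 0.0
        neut = ~pool.selected[:S]
        cols = np.flatnonzero(neut)
        if cols.size == 0:
            return 0.0, 0.0
        counts = pool.G[:, cols].sum(axis=0).astype(float)
        p = counts / two_NT
        pi_tot = float(np.sum(2 * p * (1 - p)) * two_NT / (two_NT - 1)) / neutral_L
        # within-deme
        within = 0.0
        two_N = 2 * N
        for deme in range(d):
            rows = slice(2 * deme * N, 2 * (deme + 1) * N)
            cd = pool.G[rows, :][:, cols].sum(axis=0).astype(float)
            pd_ = cd / two_N
            within += float(np.sum(2 * pd_ * (1 - pd_)) * two_N / (two_N - 1))
        return within / d / neutral_L, pi_tot

    gens_run = 0
    post_gens = 0
    max_gens = config.generations

    while gens_run < max_gens:
        gen = gens_run
        sexual_generation = (config.sex_period <= 1) or (gen % config.sex_period == 0)

        S = pool.n_active
        # --- fitness -----------------------------------------------------
        if S and pool.selected[:S].any():
            sel_cols = np.flatnonzero(pool.selected[:S])
            dosage = (
                pool.G[0::2, sel_cols].astype(np.int16)
                + pool.G[1::2, sel_cols].astype(np.int16)
            )
            logw = (dosage == 1) @ pool.log_het[sel_cols] + (dosage == 2) @ pool.log_hom[sel_cols]
            logw -= logw.max()
            w = np.exp(np.maximum(logw, -700))
        else:
            w = np.ones(n_ind)
        if not np.isfinite(w).all() or w.sum() <= 0:
            raise FloatingPointError(
                "mean fitness underflow; use a smaller |s| or a larger rescale factor"
            )

        # --- parent deme (migration as offspring origin) ------------------
        parent_deme = deme_of_ind.copy()
        if config.m > 0 and d > 1:
            mig = rng.random(n_ind) < config.m
            k = int(mig.sum())
            if k:
                shift = rng.integers(1, d, k)
                parent_deme[mig] = (parent_deme[mig] + shift) % d

        # per-deme fitness cumsums
        cum_by_deme = []
        for deme in range(d):
            wd = w[deme * N : (deme + 1) * N]
            tot = wd.sum()
            if tot <= 0:
                raise FloatingPointError(
                    "deme mean fitness underflow; use a smaller |s| or rescale"
                )
            cum_by_deme.append(np.cumsum(wd) / tot)

        def choose_parents(pd: np.ndarray) -> np.ndarray:
            out = np.empty(len(pd), dtype=np.int64)
            u = rng.random(len(pd))
            for deme in range(d):
                mask = pd == deme
                if mask.any():
                    out[mask] = deme_offsets[deme] + np.searchsorted(
                        cum_by_deme[deme], u[mask]
                    )
            return out

        if sexual_generation:
            is_sexual = np.ones(n_ind, dtype=bool)
        else:
            is_sexual = rng.random(n_ind) < (1.0 - config.clonal_fraction)

        p1 = choose_parents(parent_deme)
        p2 = choose_parents(parent_deme)  # only used for sexual offspring

        # --- gametes -------------------------------------------------------
        # source row for each offspring haplotype in the no-crossover case
        src = np.empty(n_hap, dtype=np.int64)
        hap_choice_1 = rng.integers(0, 2, n_ind)
        hap_choice_2 = rng.integers(0, 2, n_ind)
        # clonal: copy both parental haplotypes; sexual: one gamete per parent
        clonal = ~is_sexual
        src[0::2] = np.where(clonal, 2 * p1, 2 * p1 + hap_choice_1)
        src[1::2] = np.where(clonal, 2 * p1 + 1, 2 * p2 + hap_choice_2)

        mosaic_target_rows = None
        mosaic_gametes = None
        if S and config.r > 0:
            sex_idx = np.flatnonzero(is_sexual)
            if sex_idx.size:
                n_cross = rng.poisson(config.r * config.L, (len(sex_idx), 2))
                gj, gw = np.nonzero(n_cross)  # gametes needing a mosaic
                if gj.size:
                    ncx = n_cross[gj, gw]
                    b_max = int(ncx.max())
                    # padded break matrix; pad value L never toggles a site
                    breaks = np.full((gj.size, b_max), config.L + 1, dtype=np.int64)
                    flat = rng.integers(0, config.L, int(ncx.sum()))
                    offs = np.concatenate(([0], np.cumsum(ncx)))
                    for gi in range(gj.size):
                        breaks[gi, : ncx[gi]] = flat[offs[gi] : offs[gi + 1]]
                    pos_row = pool.pos[:S][None, None, :]
                    parity = (breaks[:, :, None] <= pos_row[0]).sum(axis=1) % 2
                    inds = sex_idx[gj]
                    pars = np.where(gw == 0, p1[inds], p2[inds])
                    start = rng.integers(0, 2, gj.size)
                    hapA = pool.G[2 * pars, :S]
                    hapB = pool.G[2 * pars + 1, :S]
                    pick_A = (parity == 0) == (start[:, None] == 0)
                    mosaic_gametes = np.where(pick_A, hapA, hapB)
                    mosaic_target_rows = 2 * inds + gw

        new_G = pool.G[src, :S] if S else pool.G[:, :0]
        pool.G[:, :S] = new_G
        if mosaic_target_rows is not None:
            pool.G[mosaic_target_rows, :S] = mosaic_gametes

        # --- mutation ------------------------------------------------------
        n_new = rng.poisson(mean_new)
        if n_new:
            positions = rng.integers(0, config.L, n_new)
            coding = config.is_coding(positions)
            selected, beneficial, S_eff = _draw_effects(config, coding, rng)
            het, hom = _log_fitness_terms(S_eff, two_NT)
            idx = pool.add_sites(n_new)
            pool.pos[idx] = positions
            pool.S_scaled[idx] = S_eff
            pool.log_het[idx] = het
            pool.log_hom[idx] = hom
            pool.selected[idx] = selected
            pool.beneficial[idx] = beneficial
            pool.coding[idx] = coding
            pool.origin[idx] = gen
            rows = rng.integers(0, n_hap, n_new)
            pool.G[rows, idx] = 1

        gens_run += 1

        # --- fixation / loss bookkeeping ----------------------------------
        if gens_run % gc_every == 0 or gens_run == max_gens:
            Sa = pool.n_active
            if Sa:
                totals = pool.G[:, :Sa].sum(axis=0)
                lost = np.flatnonzero(totals == 0)
                fixed = np.flatnonzero(totals == n_hap)
                if burn_in_gen is not None and gens_run > burn_in_gen:
                    for c in fixed:
                        fixations.append(
                            FixationRecord(
                                position=int(pool.pos[c]),
                                site_class="selected" if pool.selected[c] else "neutral",
                                s=float(pool.S_scaled[c]),
                                origin_generation=int(pool.origin[c]),
                                fixation_generation=gens_run,
                                beneficial=bool(pool.beneficial[c]),
                                coding=bool(pool.coding[c]),
                            )
                        )
                pool.drop(np.concatenate((lost, fixed)))

        # --- burn-in detection --------------------------------------------
        if burn_in_gen is None and gens_run % pi_check_every == 0:
            _, pi_tot = population_pi()
            pi_history.append(pi_tot)
            if (
                gens_run >= hard_floor
                and len(pi_history) >= 2
                and pi_history[-2] > 0
                and abs(pi_history[-1] - pi_history[-2]) / pi_history[-2] < 0.05
            ):
                burn_in_gen = gens_run
                if post_burn_in is not None:
                    max_gens = min(max_gens, gens_run + post_burn_in)
        elif burn_in_gen is not None and gens_run == burn_in_gen and post_burn_in is not None:
            max_gens = min(max_gens, gens_run + post_burn_in)

        if burn_in_gen is not None and gens_run > burn_in_gen:
            post_gens += 1
            if gens_run % pi_check_every == 0:
                wi, tot = population_pi()
                pi_samples_within.append(wi)
                pi_samples_total.append(tot)

    if burn_in_gen is None:
        burn_in_gen = gens_run  # never equilibrated within budget
    if not pi_samples_total:
        wi, tot = population_pi()
        pi_samples_within.append(wi)
        pi_samples_total.append(tot)

    pi_w = float(np.mean(pi_samples_within))
    pi_t = float(np.mean(pi_samples_total))
    fst = None
    if pi_t > 0 and d > 1 and config.m > 0:
        fst = (pi_t - pi_w) / pi_t

    # --- samples ----------------------------------------------------------
    samples = {}
    Sa = pool.n_active
    order = np.argsort(pool.pos[:Sa], kind="stable")
    for spec in sample_specs:
        ind_idx = sample_individual_indices(config, spec)
        rows = np.empty(2 * len(ind_idx), dtype=np.int64)
        rows[0::2] = 2 * ind_idx
        rows[1::2] = 2 * ind_idx + 1
        H = pool.G[rows][:, order]
        seg = (H.sum(axis=0) > 0) & (H.sum(axis=0) < len(rows))
        samples[spec.strategy] = {
            "haplotypes": H[:, seg],
            "positions": pool.pos[:Sa][order][seg].copy(),
            "selected": pool.selected[:Sa][order][seg].copy(),
            "coding": pool.coding[:Sa][order][seg].copy(),
            "deme_of_haplotype": np.repeat(deme_of_ind[ind_idx], 2),
            "individuals": ind_idx,
        }

    return SimResult(
        config=config,
        samples=samples,
        fixations=fixations,
        burn_in_generation=int(burn_in_gen),
        pi_S_local=pi_w,
        pi_S_total=pi_t,
        fst_neutral=fst,
        generations_run=gens_run,
    )


def sample_sfs(sample: dict, site_class: str = "neutral", coding_only: bool = True) -> SFS:
    """SFS of a simulate() sample for 'neutral' or 'selected' coding sites."""
    H = sample["haplotypes"]
    sel = sample["selected"]
    cod = sample["coding"]
    if site_class == "selected":
        mask = sel
    else:
        mask = ~sel & (cod if coding_only else np.ones_like(sel))
    n = H.shape[0]
    dac = H[:, mask].sum(axis=0).astype(int)
    dac = dac[(dac > 0) & (dac < n)]
    counts = np.bincount(dac, minlength=n)[1:n].astype(float)
    label = "nonsynonymous" if site_class == "selected" else "synonymous"
    return SFS(n=n, counts=counts, folded=False, site_class=label)


# ---------------------------------------------------------------------------
# neutral frequency engine (F_ST calibration)
# ---------------------------------------------------------------------------

def neutral_fst_calibration(
    config: SimConfig,
    n_sites: int = 1500,
    seed: int = 0,
    burn_in: int | None = None,
    n_time_samples: int = 12,
    sample_spacing: int | None = None,
    burn_in_multiplier: float = 5.0,
) -> dict:
    """Equilibrium neutral diversity and F_ST by per-site forward simulation.

    Simulates ``n_sites`` unlinked neutral sites (infinite-sites influx at
    theta = 4*N_T*mu per site) through the island-model Wright-Fisher
    process. Burn-in defaults to 3.5x the mean pairwise coalescence time
    2*N*d + (d-1)/(2m); pi is then averaged over ``n_time_samples`` spaced
    snapshots. F_ST is the ratio-of-averages (pi_T - pi_W)/pi_T.
    """
    rng = np.random.default_rng(seed)
    d, N, m, mu = config.d, config.N, config.m, config.mu
    two_N = 2 * N
    two_NT = 2 * config.N_total
    t_bar = 2.0 * N * d + ((d - 1) / (2.0 * m) if m > 0 and d > 1 else 0.0)
    if burn_in is None:
        burn_in = int(math.ceil(burn_in_multiplier * t_bar))
    if sample_spacing is None:
        sample_spacing = max(1, int(0.5 * N))
    influx = two_NT * mu * n_sites  # new mutations per generation

    cap = 4096
    counts = np.zeros((d, cap), dtype=np.int32)
    n_active = 0

    pi_w_samples: list[float] = []
    pi_t_samples: list[float] = []
    total_gens = burn_in + n_time_samples * sample_spacing
    next_sample = burn_in

    for gen in range(total_gens):
        if n_active:
            p = counts[:, :n_active] / two_N
            if m > 0 and d > 1:
                pbar_others = (p.sum(axis=0, keepdims=True) - p) / (d - 1)
                p = (1.0 - m) * p + m * pbar_others
            counts[:, :n_active] = rng.binomial(two_N, p)
            totals = counts[:, :n_active].sum(axis=0)
            dead = (totals == 0) | (totals == two_NT)
            if dead.any():
                keep = np.flatnonzero(~dead)
                k = len(keep)
                counts[:, :k] = counts[:, keep]
                counts[:, k:n_active] = 0
                n_active = k
        n_new = rng.poisson(influx)
        if n_new:
            while n_active + n_new > counts.shape[1]:
                grown = np.zeros((d, counts.shape[1] * 2), dtype=np.int32)
                grown[:, : counts.shape[1]] = counts
                counts = grown
            counts[:, n_active : n_active + n_new] = 0
            demes = rng.integers(0, d, n_new)
            for j, deme in enumerate(demes):
                counts[deme, n_active + j] = 1
            n_active += n_new

        if gen + 1 >= next_sample and len(pi_t_samples) < n_time_samples:
            next_sample += sample_spacing
            if n_active == 0:
                pi_w_samples.append(0.0)
                pi_t_samples.append(0.0)
                continue
            c = counts[:, :n_active].astype(float)
            p_tot = c.sum(axis=0) / two_NT
            pi_t = float(np.sum(2 * p_tot * (1 - p_tot)) * two_NT / (two_NT - 1)) / n_sites
            p_d = c / two_N
            pi_w = float(
                np.mean(np.sum(2 * p_d * (1 - p_d), axis=1)) * two_N / (two_N - 1)
            ) / n_sites
            pi_w_samples.append(pi_w)
            pi_t_samples.append(pi_t)

    pi_w = float(np.mean(pi_w_samples))
    pi_t = float(np.mean(pi_t_samples))
    return {
        "pi_within": pi_w,
        "pi_total": pi_t,
        "fst": (pi_t - pi_w) / pi_t if pi_t > 0 else None,
        "expected_pi_local": 4.0 * config.N_total * mu,
        "expected_fst": expected_fst(config),
        "burn_in": burn_in,
        "n_sites": n_sites,
        "seed": seed,
    }


# ---------------------------------------------------------------------------
# fast direct generator of MK tables and SFS pairs
# ---------------------------------------------------------------------------

def fast_tables(
    dfe: DFEModel,
    alpha_true: float,
    n_genes: int,
    theta_site: float,
    T: float,
    n: int,
    seed: int = 0,
    L_N: float = 750.0,
    L_S: float = 250.0,
    demography: DemographyModel | None = None,
):
    """Poisson-sample per-gene MK tables and pooled SFS pairs with known truth.

    Synonymous spectra are Poisson around theta_S times the neutral expected
    SFS; nonsynonymous spectra around theta_N times the DFE expectation.
    Divergence: D_S ~ Poisson(T * L_S); D_N ~ Poisson(T * L_N * E[R] /
    (1 - alpha_true)), so ``alpha_true`` is the exact adaptive proportion by
    construction. theta_site is 4*Ne*mu per site; T is the expected neutral
    substitutions per site on the divergence branch.
    """
    from .alignment import MKTable

    if not 0.0 <= alpha_true < 1.0:
        raise ValueError("alpha_true must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    dem = demography or DemographyModel()
    engine = get_engine(dem, n)
    neutral_shape = engine.sfs_for_S(0.0)
    sel_shape = engine.sfs_for_model(dfe)
    mean_R = dfe.mean_fixation_ratio()

    tables = []
    sfs_S_total = np.zeros(n - 1)
    sfs_N_total = np.zeros(n - 1)
    for g in range(n_genes):
        e_S = theta_site * L_S * neutral_shape
        e_N = theta_site * L_N * sel_shape
        xs = rng.poisson(e_S)
        xn = rng.poisson(e_N)
        sfs_S_total += xs
        sfs_N_total += xn
        D_S = int(rng.poisson(T * L_S))
        D_N = int(rng.poisson(T * L_N * mean_R / (1.0 - alpha_true)))
        tables.append(
            MKTable(
                gene_id=f"gene{g:04d}",
                P_N=int(xn.sum()),
                P_S=int(xs.sum()),
                D_N=D_N,
                D_S=D_S,
                L_N=L_N,
                L_S=L_S,
            )
        )
    sfs_S = SFS(n=n, counts=sfs_S_total, folded=False, site_class="synonymous")
    sfs_N = SFS(n=n, counts=sfs_N_total, folded=False, site_class="nonsynonymous")
    return tables, sfs_N, sfs_S
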