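"""End-to-end orchestration: alignments -> tables -> estimators -> reports.

``run_analysis`` drives a full config-described analysis of per-gene codon
alignments; ``run_validation`` runs the simulation-based estimator-bias
experiment over a migration x sex-schedule x sampling grid;
``class_contrast_report`` summarizes gene-class contrasts. All outputs are
TSV/JSON, reproducible byte-for-byte from (inputs, config, seeds), and a
manifest records every stage with its seed and wall time.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .alignment import (
    MKTable, build_mk_table, divergence, mask_alignment,
    pairwise_pi, read_codon_alignment, segregating_sites,
)
from .dfe import DemographyModel, alpha_from_dfe, fit_demography, fit_dfe
from .io import read_class_labels, write_mk_tables, write_sfs
from .mk import (
    asymptotic_mk, bootstrap_welch, fdr_correct, gene_mk_test, naive_alpha,
    welch_model_selection,
)
from .sfs import SFS, build_sfs
from .sim import (
    SampleSpec, SimConfig, neutral_fst_calibration, rescale_config, sample_sfs,
    simulate, true_alpha,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    alignment_dir: str
    out_dir: str
    class_labels: str | None = None
    outgroup_names: tuple[str, ...] = ("outgroup1", "outgroup2")
    paralog_ks: float = 0.6
    mask_window_codons: int = 10
    mask_k_threshold: float = 0.5
    epsilon: float = 0.1
    estimators: tuple[str, ...] = ("naive", "fisher", "welch")
    bootstrap_B: int = 200
    seed: int = 0
    dfe_family: str = "gamma"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "outgroup_names" in raw:
            raw["outgroup_names"] = tuple(raw["outgroup_names"])
        if "estimators" in raw:
            raw["estimators"] = tuple(raw["estimators"])
        return cls(**raw)


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    return obj


def run_analysis(config: RunConfig) -> dict:
    """Run the full per-gene pipeline; returns the manifest dictionary.

    Stages: read + mask alignments, paralog filter (K_S threshold), MK
    tables, pooled spectra, then the requested estimators. Partial outputs
    are kept on stage failure and the manifest marks the failure point.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    labels = read_class_labels(config.class_labels) if config.class_labels else {}
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": _jsonify(config.__dict__),
        "stages": [],
    }
    log_path = out / "run_log.jsonl"
    log_fh = open(log_path, "w")

    def stage(name):
        def wrap(fn):
            t0 = time.time()
            try:
                result = fn()
                entry = {"stage": name, "status": "ok", "seconds": round(time.time() - t0, 3)}
                manifest["stages"].append(entry)
                log_fh.write(json.dumps(entry) + "\n")
                return result
            except Exception as exc:  # keep partial outputs, mark failure
                entry = {
                    "stage": name, "status": "failed", "error": str(exc),
                    "seconds": round(time.time() - t0, 3),
                }
                manifest["stages"].append(entry)
                log_fh.write(json.dumps(entry) + "\n")
                manifest["failed_at"] = name
                raise
        return wrap

    try:
        fasta_paths = sorted(Path(config.alignment_dir).glob("*.fasta")) + sorted(
            Path(config.alignment_dir).glob("*.fa")
        )

        def load_and_mask():
            alns = []
            for p in fasta_paths:
                aln = read_codon_alignment(p, gene_id=p.stem, outgroup_names=config.outgroup_names)
                alns.append(
                    mask_alignment(aln, config.mask_window_codons, config.mask_k_threshold)
                )
            return alns

        alignments = stage("load_and_mask")(load_and_mask)

        def filter_and_tabulate():
            tables, extras, records, excluded = [], {}, [], []
            for aln in alignments:
                div = divergence(aln, corrected=True, paralog_ks=config.paralog_ks)
                if div.paralog_flag:
                    excluded.append(aln.gene_id)
                    logger.warning("gene %s excluded: K_S exceeds paralog threshold", aln.gene_id)
                    continue
                label = labels.get(aln.gene_id, "control")
                t = build_mk_table(aln, class_label=label)
                tables.append(t)
                extras[aln.gene_id] = {
                    "pi_A": pairwise_pi(aln, "nonsynonymous"),
                    "pi_S": pairwise_pi(aln, "synonymous"),
                    "K_A": div.K_A, "K_S": div.K_S,
                    "paralog_flag": div.paralog_flag,
                }
                records.extend(segregating_sites(aln))
            write_mk_tables(tables, out / "mk_tables.tsv", extras)
            with open(out / "excluded_genes.json", "w") as fh:
                json.dump({"paralog_filter": excluded}, fh)
            return tables, records, excluded

        tables, site_records, excluded = stage("tables")(filter_and_tabulate)
        manifest["n_genes"] = len(tables)
        manifest["excluded"] = excluded

        def spectra():
            n = len(alignments[0].ingroup_haplotypes) if alignments else 0
            out_sfs = {}
            for cls in ("synonymous", "nonsynonymous"):
                for folded in (True, False):
                    s = build_sfs(site_records, n, cls, folded=folded, epsilon=config.epsilon)
                    tag = f"{cls}_{'folded' if folded else 'unfolded'}"
                    write_sfs(s, out / f"sfs_{tag}.tsv")
                    out_sfs[tag] = s
            return out_sfs

        spectra_by_class = stage("spectra")(spectra) if tables else {}

        results: dict = {}
        if "naive" in config.estimators and tables:
            def naive():
                r = naive_alpha(tables)
                results["naive"] = {"alpha": r.alpha, "omega_a": r.omega_a,
                                    "adaptive_count": r.adaptive_count, "reason": r.reason}
                return r
            stage("naive")(naive)
        if "fisher" in config.estimators and tables:
            def fisher():
                p = np.array([gene_mk_test(t) for t in tables])
                q = fdr_correct(p)
                df = pd.DataFrame({
                    "gene_id": [t.gene_id for t in tables], "p": p, "q": q,
                })
                df.to_csv(out / "gene_mk_tests.tsv", sep="\t", index=False)
                results["fisher"] = {"n_significant_q05": int((q < 0.05).sum())}
            stage("fisher")(fisher)
        if "welch" in config.estimators and len(tables) >= 2:
            def welch():
                models = welch_model_selection(tables)
                best = models[0]
                cis = bootstrap_welch(
                    tables, alpha_structure=best.alpha_structure,
                    f_structure=best.f_structure, B=config.bootstrap_B,
                    seed=config.seed,
                ) if config.bootstrap_B > 0 else {}
                results["welch"] = {
                    "best_structure": (best.alpha_structure, best.f_structure),
                    "alpha": best.alpha, "T": best.T, "AIC": best.AIC,
                    "akaike_weights": {
                        f"{m.alpha_structure}/{m.f_structure}": m.akaike_weight for m in models
                    },
                    "bootstrap_ci": cis,
                }
            stage("welch")(welch)
        if "asymptotic" in config.estimators and tables:
            def asym():
                sN = spectra_by_class["nonsynonymous_unfolded"]
                sS = spectra_by_class["synonymous_unfolded"]
                D_N = sum(t.D_N for t in tables)
                D_S = sum(t.D_S for t in tables)
                fit = asymptotic_mk(sN, sS, D_N, D_S)
                results["asymptotic"] = {
                    "alpha_asymptotic": fit.alpha_asymptotic,
                    "a": fit.a, "b": fit.b, "c": fit.c,
                    "fallback_linear": fit.fallback_linear,
                }
                pd.DataFrame({"x": fit.bin_mid, "alpha_x": fit.alpha_x}).to_csv(
                    out / "asymptotic_alpha_x.tsv", sep="\t", index=False
                )
            stage("asymptotic")(asym)
        if "dfe" in config.estimators and tables:
            def dfe_stage():
                sS = spectra_by_class["synonymous_folded"]
                sN = spectra_by_class["nonsynonymous_folded"]
                dem = fit_demography(sS)
                fit = fit_dfe(sN, dem, family=config.dfe_family)
                D_N = sum(t.D_N for t in tables)
                D_S = sum(t.D_S for t in tables)
                L_N = sum(t.L_N for t in tables)
                L_S = sum(t.L_S for t in tables)
                if D_N > 0 and D_S > 0:
                    alpha_from_dfe(fit, D_N, D_S, L_N, L_S)
                results["dfe"] = {
                    "family": fit.model.family, "params": fit.model.params,
                    "demography": {"ratio": dem.ratio, "t2": dem.t2},
                    "bin_proportions": fit.bin_proportions,
                    "alpha": fit.alpha, "omega_a": fit.omega_a,
                }
            stage("dfe_stage")(dfe_stage)
        if "snipre" in config.estimators and len(tables) >= 20:
            def snipre_stage():
                from .snipre import snipre_fit

                model = snipre_fit(tables, seed=config.seed)
                results["snipre"] = {
                    "selection_effect": model.selection_effect,
                    "significance": model.significance,
                    "length_coefficient": model.length_coefficient,
                    "r_hat": model.r_hat, "reliable": model.reliable,
                }
            stage("snipre_stage")(snipre_stage)

        if len({t.class_label for t in tables}) >= 2:
            def contrasts():
                df = class_contrast_report(tables, site_records=site_records)
                df.to_csv(out / "class_contrasts.tsv", sep="\t", index=False)
            stage("class_contrasts")(contrasts)

        with open(out / "results.json", "w") as fh:
            json.dump(_jsonify(results), fh, indent=2, sort_keys=True)
    finally:
        with open(out / "manifest.json", "w") as fh:
            json.dump(_jsonify(manifest), fh, indent=2, sort_keys=True)
        log_fh.close()
    return manifest


# ---------------------------------------------------------------------------
# gene-class contrasts
# ---------------------------------------------------------------------------

def class_contrast_report(
    tables: list[MKTable],
    site_records: list[dict] | None = None,
    q_method: str = "fdr_bh",
) -> pd.DataFrame:
    """Per-class summary with pooled ratios, naive alpha, and rank tests.

    The rank-based test of per-gene pi/K ratios against the control class is
    an interpretation (the underlying statistic is a Mann-Whitney U) and is
    labeled as such in the column name. Classes left empty after filtering
    are dropped with a warning. BH correction is applied within each test
    family.
    """
    from scipy.stats import mannwhitneyu

    by_class: dict[str, list[MKTable]] = {}
    for t in tables:
        by_class.setdefault(t.class_label, []).append(t)
    control = by_class.get("control", [])
    rows = []
    p_rank = {}
    for cls, members in sorted(by_class.items()):
        if not members:
            logger.warning("class %s empty after filters; dropped", cls)
            continue
        P_N = sum(t.P_N for t in members); P_S = sum(t.P_S for t in members)
        D_N = sum(t.D_N for t in members); D_S = sum(t.D_S for t in members)
        L_N = sum(t.L_N for t in members); L_S = sum(t.L_S for t in members)
        res = naive_alpha(members)
        row = {
            "class": cls, "n_genes": len(members),
            "P_N": P_N, "P_S": P_S, "D_N": D_N, "D_S": D_S,
            "pN_pS_ratio": (P_N / L_N) / (P_S / L_S) if P_S > 0 and L_S > 0 else np.nan,
            "dN_dS_ratio": (D_N / L_N) / (D_S / L_S) if D_S > 0 and L_S > 0 else np.nan,
            "alpha_naive": res.alpha,
            "omega_a_naive": res.omega_a,
            "small_class_flag": len(members) < 10,
        }
        if control and cls != "control" and len(members) >= 2:
            ratios_c = [
                (t.P_N / t.L_N) / max(t.P_S / t.L_S, 1e-12) for t in control if t.P_S > 0
            ]
            ratios_m = [
                (t.P_N / t.L_N) / max(t.P_S / t.L_S, 1e-12) for t in members if t.P_S > 0
            ]
            if len(ratios_c) >= 2 and len(ratios_m) >= 2:
                p_rank[cls] = mannwhitneyu(ratios_m, ratios_c).pvalue
        rows.append(row)
    df = pd.DataFrame(rows).sort_values("class").reset_index(drop=True)
    if p_rank:
        q = fdr_correct(list(p_rank.values()))
        qmap = dict(zip(p_rank.keys(), q))
        df["p_rank_vs_control_interpretive"] = df["class"].map(p_rank)
        df["q_rank_vs_control_interpretive"] = df["class"].map(qmap)
    return df


# ---------------------------------------------------------------------------
# simulation-based validation grid
# ---------------------------------------------------------------------------

@dataclass
class ValidationGrid:
    migration_rates: tuple[float, ...] = (0.00898, 0.00142, 0.000158)
    sex_periods: tuple[int, ...] = (1, 8, 80)
    strategies: tuple[str, ...] = ("one-per-deme", "single-deme-36", "spread-360")
    replicates: int = 1


def run_validation(
    grid: ValidationGrid,
    base_config: SimConfig | None = None,
    rescale: float = 10.0,
    post_burn_in: int | None = None,
    seed: int = 0,
    dfe_family: str = "gamma",
) -> pd.DataFrame:
    """Estimator-bias experiment over the migration x sex x sampling grid.

    Each cell runs ``grid.replicates`` forward simulations (pooled across
    replicates before estimation), then computes true alpha from the
    fixation log and the naive and DFE-corrected estimates per sampling
    strategy. Cells without selected fixations report missing alpha bias.
    """
    base = base_config or SimConfig()
    rows = []
    for m in grid.migration_rates:
        for k in grid.sex_periods:
            cfg0 = replace(base, m=m, sex_period=k)
            cfg = rescale_config(cfg0, rescale) if rescale != 1.0 else cfg0
            fixations = []
            pooled = {s: [] for s in grid.strategies}
            for rep in range(grid.replicates):
                cfg_r = replace(cfg, seed=hash((seed, m, k, rep)) % (2**31))
                res = simulate(
                    cfg_r,
                    sample_specs=tuple(SampleSpec(s, seed=seed) for s in grid.strategies),
                    post_burn_in=post_burn_in,
                )
                fixations.extend(res.fixations)
                for s in grid.strategies:
                    pooled[s].append(res)
            t_alpha = true_alpha(fixations)
            D_N = sum(1 for f in fixations if f.site_class == "selected")
            D_S = sum(1 for f in fixations if f.site_class == "neutral" and f.coding)
            for s in grid.strategies:
                sfs_n = None
                sfs_s = None
                for res in pooled[s]:
                    sn = sample_sfs(res.samples[s], "selected")
                    ss = sample_sfs(res.samples[s], "neutral")
                    sfs_n = sn if sfs_n is None else SFS(sn.n, sfs_n.counts + sn.counts, False, sn.site_class)
                    sfs_s = ss if sfs_s is None else SFS(ss.n, sfs_s.counts + ss.counts, False, ss.site_class)
                row = {
                    "m": m, "sex_period": k, "strategy": s,
                    "true_alpha": t_alpha, "D_N": D_N, "D_S": D_S,
                    "expected_fst": expected_fst_for(cfg),
                }
                if D_N > 0 and D_S > 0 and sfs_n is not None and sfs_n.n_sites > 0:
                    P_N, P_S = sfs_n.n_sites, sfs_s.n_sites
                    from .mk import naive_alpha_from_counts

                    res_naive = naive_alpha_from_counts(P_N, P_S, D_N, D_S)
                    row["alpha_naive"] = res_naive.alpha
                    L_N = (1 - cfg.frac_unconstrained) * cfg.coding_length
                    L_S = cfg.frac_unconstrained * cfg.coding_length
                    dem = DemographyModel()
                    fit = fit_dfe(sfs_n.fold(), dem, family=dfe_family)
                    a_dfe, w_dfe = alpha_from_dfe(fit, D_N, D_S, L_N, L_S)
                    row["alpha_dfe"] = a_dfe
                    row["omega_a_dfe"] = w_dfe
                    if t_alpha is not None:
                        row["bias_naive"] = (row["alpha_naive"] - t_alpha
                                             if row["alpha_naive"] is not None else None)
                        row["bias_dfe"] = a_dfe - t_alpha
                rows.append(row)
    return pd.DataFrame(rows)


def expected_fst_for(cfg: SimConfig) -> float:
    from .sim import expected_fst

    return expected_fst(cfg)


def fst_calibration_study(
    migration_rates: tuple[float, ...] = (0.00898, 0.00142, 0.000158),
    rescale: float = 10.0,
    replicates: int = 10,
    seed: int = 0,
    n_sites: dict[float, int] | int = 800,
) -> pd.DataFrame:
    """Neutral island-model F_ST calibration at the study migration rates.

    For each migration rate, the full-scale configuration (36 demes of 500
    diploids) is rescaled to desk size preserving the exact equilibrium
    F_ST, simulated with the unlinked-site neutral engine for ``replicates``
    independent runs, and summarized by the ratio-of-averages F_ST with its
    replicate standard error, next to the closed-form island-model value and
    the exact two-lineage expectation.
    """
    from .sim import expected_fst, expected_fst_exact, neutral_fst_calibration

    ss = np.random.SeedSequence(seed)
    rows = []
    for m in migration_rates:
        full = SimConfig(m=m)
        cfg = rescale_config(full, rescale, match_fst=True)
        k = n_sites[m] if isinstance(n_sites, dict) else n_sites
        pw, pt, per_rep = [], [], []
        for child in ss.spawn(replicates):
            rep_seed = int(child.generate_state(1)[0] % (2**31))
            out = neutral_fst_calibration(cfg, n_sites=k, seed=rep_seed)
            pw.append(out["pi_within"])
            pt.append(out["pi_total"])
            per_rep.append(out["fst"])
        fst = (np.mean(pt) - np.mean(pw)) / np.mean(pt)
        rows.append({
            "m": m,
            "fst_sim": float(fst),
            "fst_se": float(np.std(per_rep, ddof=1) / np.sqrt(len(per_rep))),
            "fst_formula": expected_fst(full),
            "fst_exact": expected_fst_exact(full),
            "pi_within": float(np.mean(pw)),
            "pi_total": float(np.mean(pt)),
            "expected_pi_local": 4.0 * full.N_total * full.mu,
            "replicates": replicates,
            "n_sites": k,
        })
    return pd.DataFrame(rows)
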