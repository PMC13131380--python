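"""Config-driven end-to-end experiment runner.

For each replicate: simulate a population, fit the benchmark ssGBLUP
(training + candidate genotypes), fit the reduced ssGBLUP (training
genotypes only), back-solve SNP effects, compute indirect predictions
under each genotyping-error scenario, and evaluate against the benchmark
GEBV. Replicates are aggregated as mean ± SE.

Seed discipline: replicate ``i`` simulates with seed ``master_seed + i``;
error injection draws from an independent stream, so every scenario
within a replicate evaluates the identical candidates.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as ipio
from . import kinship
from .indirect import ErrorSpec, compute_ip, inject_errors, run_scenarios, scenario_label
from .kinship import GenotypeMatrix
from .metrics import EvalReport, ReplicateSummary, aggregate_replicates, evaluate, \
    predictions_long, render_tables
from .popsim import Population, SimConfig, TraitModel, simulate_population
from .ssgblup import SingleStepGBLUP

logger = logging.getLogger("ipsim")

__all__ = ["ExperimentConfig", "ReplicateResult", "ExperimentResult",
           "run_replicate", "run_experiment", "desk_profile", "full_scale_profile"]


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to reproduce an experiment bitwise."""

    sim: SimConfig = field(default_factory=SimConfig)
    h2: float = 0.25
    rpg_fraction: float = 0.05
    sigma2_p: float = 1.0
    alpha: float = 0.05
    tuning: str = "mean"
    error_rates: tuple = (0.05, 0.10, 0.20)
    error_target: str = "validation"     # 'validation' | 'training'
    shared_loci: bool = False
    n_replicates: int = 5
    master_seed: int = 2024
    solver_method: str = "auto"
    solver_tol: float = 1e-10
    solver_maxiter: int = 20000
    apy_enabled: bool = False
    apy_core_size: int | None = None
    apy_seed: int = 0
    # allele frequencies used for centering Z and for k:
    # 'training' = observed training-set frequencies (production pipelines
    # recompute frequencies from the data they ingest; IP are then
    # referenced to the training mean); 'founder' = base-population
    # (generation 0) frequencies, which keep the genetic trend in both
    # GEBV and IP on the pedigree base.
    centering: str = "training"
    # side experiment: errors in TRAINING genotypes, correct candidates
    side_training_error_rate: float | None = None

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if list(self.error_rates) != sorted(self.error_rates):
            raise ValueError("error_rates must be sorted ascending")
        if self.error_target not in ("validation", "training"):
            raise ValueError("error_target must be 'validation' or 'training'")

    @property
    def trait(self) -> TraitModel:
        return TraitModel(h2=self.h2, rpg_fraction=self.rpg_fraction,
                          sigma2_p=self.sigma2_p)


@dataclass
class ReplicateResult:
    replicate: int
    seed: int
    reports: dict                 # scenario -> EvalReport
    gebv_validation: np.ndarray
    validation_ids: np.ndarray
    ips: dict                     # scenario -> IpResult
    side_report: EvalReport | None = None
    apy_ip_correlation: float | None = None
    timings: dict = field(default_factory=dict)


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    summary: ReplicateSummary
    replicates: list
    manifest: dict

    def tables(self):
        return render_tables(self.summary)


def _fit_reduced(phen, ped, gm_train, cfg, pre):
    model = SingleStepGBLUP(phen, ped, genotypes=gm_train, sigma2_a=cfg.h2 * cfg.sigma2_p,
                            sigma2_e=(1 - cfg.h2) * cfg.sigma2_p, alpha=cfg.alpha,
                            tuning=cfg.tuning, precomputed=pre)
    return model.fit(method=cfg.solver_method, tol=cfg.solver_tol,
                     maxiter=cfg.solver_maxiter)


def run_replicate(cfg: ExperimentConfig, replicate: int,
                  outdir: Path | None = None) -> ReplicateResult:
    """One replicate of the full pipeline; see module docstring."""
    t0 = time.perf_counter()
    seed = cfg.master_seed + replicate
    popn = simulate_population(cfg.sim, cfg.trait, seed)
    trait = popn.trait
    rng_err = np.random.default_rng(np.random.SeedSequence([cfg.master_seed, replicate, 7919]))
    rng_side = np.random.default_rng(np.random.SeedSequence([cfg.master_seed, replicate, 104729]))
    t_sim = time.perf_counter()

    train_ids = popn.ids_of_generation(list(cfg.sim.training_generations))
    val_ids = popn.ids_of_generation(cfg.sim.validation_generation)
    snp_mask = popn.genome.snp_mask
    codes_train = popn.genotypes(train_ids)[:, snp_mask]
    codes_val = popn.genotypes(val_ids)[:, snp_mask]
    if cfg.centering == "founder":
        founder_ids = popn.ids_of_generation(0)
        freqs = popn.genotypes(founder_ids)[:, snp_mask].mean(axis=0) / 2.0
    else:
        freqs = codes_train.mean(axis=0) / 2.0
    nt = train_ids.size
    all_ids = np.concatenate([train_ids, val_ids])
    gm_all = GenotypeMatrix(np.vstack([codes_train, codes_val]), all_ids, freqs)
    gm_train = GenotypeMatrix(codes_train, train_ids, freqs)

    ped = popn.pedigree_frame()
    a_inv, _ = kinship.build_A_inverse(ped, F=popn.inbreeding)
    a22_all = kinship.build_A22(ped, all_ids, method="solve", a_inverse=a_inv)
    g_all = kinship.build_G_raw(gm_all)
    mask = ~np.isin(popn.id, val_ids)
    phen = pd.Series(popn.phenotype[mask], index=popn.id[mask])
    pre_common = {"a_inverse": a_inv, "inbreeding": popn.inbreeding}
    t_kin = time.perf_counter()

    bench_model = SingleStepGBLUP(phen, ped, genotypes=gm_all,
                                  sigma2_a=trait.sigma2_a, sigma2_e=trait.sigma2_e,
                                  alpha=cfg.alpha, tuning=cfg.tuning,
                                  precomputed={**pre_common, "a22": a22_all,
                                               "g_raw": g_all})
    bench = bench_model.fit(method=cfg.solver_method, tol=cfg.solver_tol,
                            maxiter=cfg.solver_maxiter)
    t_bench = time.perf_counter()

    pre_red = {**pre_common, "a22": a22_all[:nt, :nt], "g_raw": g_all[:nt, :nt]}
    reduced = _fit_reduced(phen, ped, gm_train, cfg, pre_red)
    effects = reduced.backsolve_snp_effects()
    t_red = time.perf_counter()

    gebv_val = bench.gebv_for(val_ids)
    if cfg.error_target == "validation":
        ips = run_scenarios(codes_val, effects, cfg.error_rates, rng_err,
                            animal_ids=val_ids, shared_loci=cfg.shared_loci)
    else:
        # error scenarios in the TRAINING genotypes; candidates stay correct
        ips = {"correct": compute_ip(codes_val, effects, animal_ids=val_ids)}
        for rate in cfg.error_rates:
            label = scenario_label(rate)
            eff_err = _training_error_effects(cfg, phen, ped, popn, codes_train,
                                              train_ids, rate, rng_err, freqs)
            ips[label] = compute_ip(codes_val, eff_err, animal_ids=val_ids,
                                    scenario=label)
    reports = {lab: evaluate(gebv_val, res, sigma2_a=trait.sigma2_a)
               for lab, res in ips.items()}

    side_report = None
    if cfg.side_training_error_rate:
        eff_err = _training_error_effects(cfg, phen, ped, popn, codes_train,
                                          train_ids, cfg.side_training_error_rate,
                                          rng_side, freqs)
        ip_side = compute_ip(codes_val, eff_err, animal_ids=val_ids,
                             scenario=f"train_{scenario_label(cfg.side_training_error_rate)}")
        side_report = evaluate(gebv_val, ip_side, sigma2_a=trait.sigma2_a)

    apy_corr = None
    if cfg.apy_enabled:
        rng_apy = np.random.default_rng(cfg.apy_seed)
        core_size = cfg.apy_core_size or max(2, nt // 2)
        core = rng_apy.choice(nt, size=min(core_size, nt), replace=False)
        g_apy_inv = kinship.apy_inverse(reduced.model.g_star, core)
        from .indirect import backsolve_snp_effects

        eff_apy = backsolve_snp_effects(reduced.gebv_for(train_ids), gm_train.Z,
                                        g_apy_inv, reduced.model.blend, gm_train.k,
                                        freqs=freqs)
        ip_apy = compute_ip(codes_val, eff_apy, animal_ids=val_ids)
        apy_corr = float(np.corrcoef(ips["correct"].ip, ip_apy.ip)[0, 1])

    t_end = time.perf_counter()
    timings = {"simulate": t_sim - t0, "kinship": t_kin - t_sim,
               "benchmark": t_bench - t_kin, "reduced_backsolve": t_red - t_bench,
               "scenarios": t_end - t_red, "total": t_end - t0}
    logger.info("replicate %d done in %.1fs (sim %.1f, kinship %.1f, bench %.1f)",
                replicate, timings["total"], timings["simulate"], timings["kinship"],
                timings["benchmark"])

    result = ReplicateResult(replicate=replicate, seed=seed, reports=reports,
                             gebv_validation=gebv_val, validation_ids=val_ids,
                             ips=ips, side_report=side_report,
                             apy_ip_correlation=apy_corr, timings=timings)
    if outdir is not None:
        _write_replicate(outdir, cfg, popn, train_ids, val_ids, bench, reduced,
                         effects, result)
    return result


def _training_error_effects(cfg, phen, ped, popn, codes_train, train_ids, rate,
                            rng, freqs=None):
    """Re-run the reduced evaluation with substitution errors in the
    training genotypes and back-solve effects from it.

    Under 'founder' centering the frequencies are unaffected by the
    errors; under 'training' centering the erroneous set defines its own
    frequencies, exactly as a production pipeline ingesting bad genotypes
    would."""
    spec = ErrorSpec(rate=rate, target="training", shared_loci=cfg.shared_loci)
    codes_err = inject_errors(codes_train, spec, rng)
    gm_err = GenotypeMatrix(codes_err, train_ids,
                            freqs if cfg.centering == "founder" else None)
    reduced_err = _fit_reduced(phen, ped, gm_err, cfg, {})
    return reduced_err.backsolve_snp_effects()


def run_experiment(cfg: ExperimentConfig, output_dir=None) -> ExperimentResult:
    """All replicates plus aggregation; optionally writes the artifact tree."""
    outdir = Path(output_dir) if output_dir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    replicates = []
    for i in range(cfg.n_replicates):
        rep_dir = outdir / f"replicate_{i}" if outdir else None
        replicates.append(run_replicate(cfg, i, rep_dir))
    scen_order = list(replicates[0].reports.keys())
    reports = {s: [r.reports[s] for r in replicates] for s in scen_order}
    summary = aggregate_replicates(reports)
    manifest = {
        "config": _clean(cfg),
        "replicate_seeds": [r.seed for r in replicates],
        "versions": _versions(),
        "timings": [r.timings for r in replicates],
    }
    result = ExperimentResult(cfg, summary, replicates, manifest)
    if outdir:
        summary.to_csv(outdir / "summary.csv")
        frames = [predictions_long(r.gebv_validation, r.ips, r.validation_ids,
                                   r.replicate) for r in replicates]
        pd.concat(frames, ignore_index=True).to_csv(outdir / "predictions.csv",
                                                    index=False)
        _, _, text = render_tables(summary)
        (outdir / "tables.txt").write_text(text + "\n")
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    return result


def _write_replicate(outdir, cfg, popn, train_ids, val_ids, bench, reduced,
                     effects, result):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ipio.export_population(popn, outdir, training_ids=train_ids,
                           validation_ids=val_ids)
    bench.to_csv(outdir / "solutions.csv")
    chroms, pos = popn.genome.snp_table()
    effects.to_frame(chroms, pos).to_csv(outdir / "snp_effects.csv", index=False)
    for lab, res in result.ips.items():
        pd.DataFrame({"id": res.animal_ids, "scenario": lab, "ip": res.ip}).to_csv(
            outdir / f"ip_{lab}.csv", index=False
        )


def _clean(obj):
    if dataclasses.is_dataclass(obj):
        return {f.name: _clean(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, (list, tuple)):
        return [_clean(x) for x in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def _versions():
    import scipy

    from . import __version__

    return {"ipsim": __version__, "numpy": np.__version__,
            "scipy": scipy.__version__, "pandas": pd.__version__}


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------

def desk_profile(master_seed: int = 2024, n_replicates: int = 5) -> ExperimentConfig:
    """Desk-scale study profile: same design, reduced sizes.

    ~3,200 training and ~800 validation genotyped animals, 5,000 SNPs and
    200 QTL on the full 29-chromosome map, shortened historical phase
    (150 + 150 generations, 300→60→30) targeting the same qualitative
    drift/LD structure, five replicates. Includes the 20%-training-error
    side experiment.
    """
    sim = SimConfig(
        historical_schedule=((300, 60, 150), (60, 30, 150)),
        n_sires=30,
        n_dams=120,
        max_dams=160,
        n_snps=5000,
        n_qtl=200,
        pool_multiplier=8.0,
    )
    return ExperimentConfig(sim=sim, master_seed=master_seed,
                            n_replicates=n_replicates,
                            side_training_error_rate=0.20)


def full_scale_profile(master_seed: int = 2024) -> ExperimentConfig:
    """Full-scale study profile (compute-heavy; not desk-sized)."""
    return ExperimentConfig(sim=SimConfig(), master_seed=master_seed,
                            side_training_error_rate=0.20)
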