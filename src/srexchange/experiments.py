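"""Config-driven experiment runner.

Each experiment reproduces the quantitative content of one in-silico
analysis — a trade-off scan, a degradation time course, a dose scan, the
redistribution decomposition, the three-receptor hierarchy, the
architecture comparison, the exchange-assay calibration, or a noisy
parameter-recovery table — from a small YAML document and writes tidy
TSV tables with unit-annotated headers plus a provenance record.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .architecture import compare_architectures
from .calibration import ExchangeSetup, estimate_kca_prime, observed_exchange_rate
from .degradation import (
    cand1_dose_response,
    hierarchy_experiment,
    redistribution_analysis,
    run_degradation,
)
from .equilibrium import solve_equilibrium, tradeoff_scan
from .parameters import KineticParameters, PoolTotals, SubstrateParameters
from .simulate import SolverSettings
from .synthetic import parameter_recovery_suite

__all__ = ["ExperimentConfig", "run_experiment", "EXPERIMENTS", "load_config"]

EXPERIMENTS = (
    "consistency", "tradeoff", "degrade", "dose_scan", "redistribute",
    "hierarchy", "compare_arch", "calibrate", "recover",
)

_ALLOWED_KEYS = {"experiment", "seed", "solver", "params", "totals",
                 "substrate", "options"}


@dataclass
class ExperimentConfig:
    """One experiment: name, parameter overrides, solver settings, seed."""

    experiment: str
    seed: int = 0
    solver: SolverSettings = field(default_factory=SolverSettings)
    params: KineticParameters = field(default_factory=KineticParameters)
    totals: PoolTotals | None = None
    substrate: SubstrateParameters | None = None
    options: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(
                f"unknown experiment {self.experiment!r}; "
                f"choose from {', '.join(EXPERIMENTS)}"
            )

    def digest(self) -> str:
        payload = {
            "experiment": self.experiment,
            "seed": self.seed,
            "solver": asdict(self.solver),
            "params": asdict(self.params),
            "totals": asdict(self.totals) if self.totals else None,
            "substrate": asdict(self.substrate) if self.substrate else None,
            "options": self.options,
        }
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(source: str | Path | dict) -> ExperimentConfig:
    """Build an :class:`ExperimentConfig` from a YAML file or mapping."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = dict(source)
    if not isinstance(raw, dict) or "experiment" not in raw:
        raise ValueError("config must be a mapping with an 'experiment' key")
    unknown = set(raw) - _ALLOWED_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")

    def build(cls, mapping, **defaults):
        if mapping is None:
            return None
        valid = set(cls.__dataclass_fields__)
        bad = set(mapping) - valid
        if bad:
            raise ValueError(f"unknown {cls.__name__} keys: {sorted(bad)}")
        merged = {**defaults, **mapping}
        if cls is PoolTotals:
            merged["sr_totals"] = tuple(merged.get("sr_totals", ()))
            merged["substrate_totals"] = tuple(merged.get("substrate_totals", ()))
        return cls(**merged)

    return ExperimentConfig(
        experiment=raw["experiment"],
        seed=int(raw.get("seed", 0)),
        solver=build(SolverSettings, raw.get("solver")) or SolverSettings(),
        params=build(KineticParameters, raw.get("params")) or KineticParameters(),
        totals=build(PoolTotals, raw.get("totals")),
        substrate=build(SubstrateParameters, raw.get("substrate")),
        options=dict(raw.get("options", {})),
    )


def _default_totals(cfg: ExperimentConfig, sr=(30.0, 630.0),
                    cand1=100.0, substrate=(300.0,)) -> PoolTotals:
    if cfg.totals is not None:
        return cfg.totals
    return PoolTotals(300.0, cand1, sr, substrate)


def _default_substrate(cfg: ExperimentConfig) -> SubstrateParameters:
    return cfg.substrate or SubstrateParameters()


# -- individual experiments -------------------------------------------------

def _exp_consistency(cfg: ExperimentConfig):
    p = cfg.params
    summary = {
        "eta": p.eta,
        "alpha": p.alpha,
        "beta": p.beta,
        "Kca_from_cycle_nM": p.eta * p.Ksr,
        "detailed_balance_residual": p.detailed_balance_residual(),
    }
    return {"summary": pd.DataFrame([summary])}, summary


def _exp_tradeoff(cfg: ExperimentConfig):
    totals = _default_totals(cfg, sr=(100.0, 560.0), cand1=390.0, substrate=())
    etas = tuple(cfg.options.get("eta_values", (cfg.params.eta,)))
    grid = cfg.options.get("cand1_grid")
    curves = tradeoff_scan(cfg.params, replace(totals, substrate_totals=()),
                           cand1_grid=None if grid is None else np.asarray(grid),
                           eta_values=etas)
    frames = []
    for c in curves:
        frames.append(pd.DataFrame({
            "eta": c.eta,
            "cand1_total_nM": c.cand1_grid,
            "occupancy_nM": c.occupancy,
            "exchange_rate_per_s": c.exchange_rate,
            "tau_s_s": c.tau_s,
        }))
    table = pd.concat(frames, ignore_index=True)
    ss = solve_equilibrium(cfg.params,
                           replace(totals, cand1_total=390.0,
                                   substrate_totals=()))
    summary = {"occupancy_at_cellular_cand1_nM": ss.occupancy("Cul1.SR1"),
               "exchange_rate_at_cellular_cand1_per_s": ss.exchange_rate}
    return {"tradeoff": table}, summary


def _exp_degrade(cfg: ExperimentConfig):
    totals = _default_totals(cfg)
    run = run_degradation(cfg.params, totals, _default_substrate(cfg),
                          settings=cfg.solver,
                          t_max=cfg.options.get("t_max", 1e5))
    tidy = run.timecourse.to_frame()
    summary = {"cand1_total_nM": totals.cand1_total,
               "t_half_min": run.t_half, "censored": run.censored}
    summary_df = pd.DataFrame([summary])
    return {"timecourse": tidy, "summary": summary_df}, summary


def _exp_dose_scan(cfg: ExperimentConfig):
    totals = _default_totals(cfg)
    grid = cfg.options.get("cand1_grid")
    resp = cand1_dose_response(
        cfg.params, totals, _default_substrate(cfg),
        cand1_grid=None if grid is None else np.asarray(grid, float),
        settings=cfg.solver, t_max=cfg.options.get("t_max", 1e5))
    table = pd.DataFrame({
        "cand1_total_nM": resp.cand1_grid,
        "t_half_min": resp.t_half,
        "censored": resp.censored,
    })
    summary = {"optimal_cand1_nM": resp.optimal_cand1,
               "optimal_t_half_min": resp.optimal_t_half,
               "monotone_increasing": resp.monotone_increasing}
    return {"dose_response": table}, summary


def _exp_redistribute(cfg: ExperimentConfig):
    totals = _default_totals(cfg)
    run = run_degradation(cfg.params, totals, _default_substrate(cfg),
                          settings=cfg.solver,
                          t_max=cfg.options.get("t_max", 3e4))
    decomp = redistribution_analysis(run)
    table = pd.DataFrame({"time_s": decomp.t,
                          "engaged_increase_nM": decomp.engaged_increase,
                          "free_cul1_delta_nM": decomp.free_cul1_delta,
                          **{f"delta_{k}_nM": v for k, v in decomp.delta.items()}})
    summary = {"peak_fold_increase": decomp.peak_fold_increase,
               "dominant_contributor": decomp.dominant_contributor,
               "closure_error": decomp.closure_error()}
    return {"redistribution": table}, summary


def _exp_hierarchy(cfg: ExperimentConfig):
    variant = cfg.options.get("variant", "affinity_substrate")
    res = hierarchy_experiment(variant, cfg.params, settings=cfg.solver,
                               **{k: v for k, v in cfg.options.items()
                                  if k in ("sr1_total", "sr2_total",
                                           "cand1_total", "t_max")})
    occ = pd.DataFrame({"time_s": res.t,
                        **{f"engaged_fraction_{k}": v
                           for k, v in res.occupancy_fraction.items()}})
    summary = {"variant": variant,
               "t_half_S1_min": res.t_half[0],
               "t_half_S2_min": res.t_half[1]}
    return {"occupancy_fractions": occ}, summary


def _exp_compare_arch(cfg: ExperimentConfig):
    mode = cfg.options.get("mode", "sequential")
    res = compare_architectures(cfg.params, cfg.totals, cfg.substrate,
                                mode=mode, settings=cfg.solver)
    summary = {"mode": mode, "gamma": res.gamma,
               "t_half_with_cand1_min": res.t_half_with_cand1,
               "t_half_without_cand1_min": res.t_half_without_cand1,
               "fold_ratio": res.fold_ratio, "verdict": res.verdict,
               "occupancy_with_nM": res.occupancy_with,
               "occupancy_without_nM": res.occupancy_without}
    return {"summary": pd.DataFrame([summary])}, summary


def _exp_calibrate(cfg: ExperimentConfig):
    target = float(cfg.options.get("target_kobs", 0.07))
    setup = ExchangeSetup(**cfg.options.get("setup", {}))
    kca_prime, beta = estimate_kca_prime(target, cfg.params, setup)
    fit = observed_exchange_rate(replace(cfg.params, kca_prime=kca_prime),
                                 setup)
    summary = {"target_kobs_per_s": target, "kca_prime_per_s": kca_prime,
               "beta": beta, "k_obs_fit_per_s": fit.k_obs}
    return {"summary": pd.DataFrame([summary])}, summary


def _exp_recover(cfg: ExperimentConfig):
    table = parameter_recovery_suite(
        true_kca_prime=float(cfg.options.get("true_kca_prime", 0.04)),
        sigma_relative=float(cfg.options.get("sigma_relative", 0.02)),
        n_replicates=int(cfg.options.get("n_replicates", 20)),
        seed=cfg.seed, params=cfg.params)
    return {"recovery": table}, dict(table.attrs["summary"])


_RUNNERS = {
    "consistency": _exp_consistency,
    "tradeoff": _exp_tradeoff,
    "degrade": _exp_degrade,
    "dose_scan": _exp_dose_scan,
    "redistribute": _exp_redistribute,
    "hierarchy": _exp_hierarchy,
    "compare_arch": _exp_compare_arch,
    "calibrate": _exp_calibrate,
    "recover": _exp_recover,
}


def run_experiment(
    config: ExperimentConfig | str | Path | dict,
    out_dir: str | Path | None = None,
) -> dict[str, Any]:
    """Dispatch a configured experiment; optionally write TSV outputs.

    Returns ``{"tables": {name: DataFrame}, "summary": dict,
    "provenance": dict}``.  With ``out_dir`` each table is written as
    ``<experiment>_<name>.tsv`` along with a ``provenance.json``.
    """
    cfg = config if isinstance(config, ExperimentConfig) else load_config(config)
    tables, summary = _RUNNERS[cfg.experiment](cfg)
    provenance = {"experiment": cfg.experiment, "seed": cfg.seed,
                  "config_digest": cfg.digest(),
                  "package_version": __version__}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(out / f"{cfg.experiment}_{name}.tsv", sep="\t",
                      index=False)
        with open(out / "provenance.json", "w") as fh:
            json.dump({**provenance, "summary": _jsonable(summary)}, fh,
                      indent=2)
    return {"tables": tables, "summary": summary, "provenance": provenance}


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj
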