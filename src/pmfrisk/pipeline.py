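"""End-to-end orchestration: screen → factorize → errors → CPF/PSCF → risk.

A single structured configuration (YAML or dict) drives every stage; all
randomness flows from one seed, so a rerun with the same configuration
produces a byte-identical JSON summary.  Each stage persists its artifacts
(CSV/JSON) under the run directory before the next stage starts, so a
failing stage aborts with its name while earlier outputs survive.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from pmfrisk import receptor, pmf, trajectory, risk as risk_mod
from pmfrisk import synthetic

logger = logging.getLogger("pmfrisk")

__all__ = ["RunConfig", "run_all", "simulate_bundle"]

_SECTION_KEYS = {
    "inputs": {"concentrations", "mdl", "wind", "tdump", "toxicity", "run_dir"},
    "screening": {"snr_cutoff", "bdl_policy", "outlier_z"},
    "pmf": {"q", "q_range", "n_starts", "robust", "tol", "max_iter", "include_total"},
    "errors": {"n_boot", "block_size", "map_r_threshold", "dqmax_levels",
               "disp_species"},
    "cpf": {"quantile", "n_sectors", "calm_cutoff"},
    "pscf": {"quantile", "cell", "n_avg_mode"},
    "risk": {"et", "ef", "ed", "statistic", "cr_hex_fraction", "target",
             "hq_convention"},
}


@dataclass
class RunConfig:
    """Validated pipeline configuration; unknown keys are rejected."""

    seed: int
    inputs: dict = field(default_factory=dict)
    screening: dict = field(default_factory=dict)
    pmf: dict = field(default_factory=dict)
    errors: dict = field(default_factory=dict)
    cpf: dict = field(default_factory=dict)
    pscf: dict = field(default_factory=dict)
    risk: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        self.seed = int(self.seed)
        for section, allowed in _SECTION_KEYS.items():
            given = getattr(self, section)
            unknown = set(given) - allowed
            if unknown:
                raise ValueError(f"unknown keys in [{section}]: {sorted(unknown)}")
        for section in ("cpf", "pscf"):
            qv = getattr(self, section).get("quantile")
            if qv is not None and not 0 < qv < 1:
                raise ValueError(f"[{section}] quantile must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {"seed"} | set(_SECTION_KEYS)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
        return cls(seed=raw.get("seed"), **{k: raw.get(k, {}) for k in _SECTION_KEYS})


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (pd.Series,)):
        return o.to_dict()
    raise TypeError(type(o))


def _write_json(path, obj):
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True,
                                     default=_json_default) + "\n")


def simulate_bundle(out_dir, seed: int = 1, n_days: int = 200) -> dict:
    """Emit a complete synthetic input bundle (concentration CSV, MDL CSV,
    wind CSV, tdump file, truth JSON) to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds, truth, winds, trajs = synthetic.default_scenario(
        n_days=n_days, seed=seed, with_met=True)
    ds.data.to_csv(out / "concentrations.csv", index_label="date")
    ds.mdl.rename_axis("species").to_csv(out / "mdl.csv")
    winds.to_csv(out / "wind.csv", index_label="timestamp")
    trajectory.write_tdump(trajs, out / "trajectories.tdump")
    _write_json(out / "truth.json", {
        "seed": seed,
        "factors": truth.factors,
        "planted_factor": truth.planted_factor,
        "planted_sector_deg": truth.planted_sector_deg,
        "planted_cell": list(truth.planted_cell) if truth.planted_cell else None,
        "F_true": {f: truth.F_true.loc[f].to_dict() for f in truth.factors},
        "mass_shares_pct": truth.mass_shares().to_dict(),
    })
    return {
        "concentrations": str(out / "concentrations.csv"),
        "mdl": str(out / "mdl.csv"),
        "wind": str(out / "wind.csv"),
        "tdump": str(out / "trajectories.tdump"),
    }


def run_all(config: RunConfig, run_dir=None) -> dict:
    """Run every stage and return the JSON-ready summary dictionary.

    Stages: load+screen, PMF fit (with optional factor-count scan),
    bootstrap, DISP, CPF and PSCF per factor, source-resolved risk, summary.
    """
    t0 = time.time()
    run_dir = Path(run_dir or config.inputs.get("run_dir", "pmfrisk_run"))
    run_dir.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        # ---- load ---------------------------------------------------------
        conc = receptor.read_concentration_csv(config.inputs["concentrations"])
        mdl = receptor.read_mdl_csv(config.inputs["mdl"])
        ds = receptor.build_dataset(conc, mdl)
        logger.info("loaded %d samples × %d species", *ds.data.shape)

        # ---- screening ----------------------------------------------------
        stage = "screening"
        t = time.time()
        sc = config.screening
        ds = receptor.screen_dataset(
            ds,
            snr_cutoff=sc.get("snr_cutoff", receptor.DEFAULT_SNR_CUTOFF),
            bdl_policy=sc.get("bdl_policy", "substitute"),
            outlier_z=sc.get("outlier_z"),
        )
        for rem in ds.screening_report["removed_species"]:
            logger.warning("screened out species %(species)s: %(reason)s", rem)
        ds.to_csv(run_dir / "screened_conc.csv", run_dir / "screened_sigma.csv",
                  run_dir / "screening_report.json")
        logger.info("screening done in %.1fs", time.time() - t)

        # ---- PMF fit ------------------------------------------------------
        stage = "pmf"
        t = time.time()
        pc = dict(config.pmf)
        q_range = pc.pop("q_range", None)
        q = pc.pop("q", None)
        n_starts = pc.pop("n_starts", pmf.DEFAULT_N_STARTS)
        scan_table = None
        if q_range:
            scan_table = pmf.scan_factors(ds, q_range, n_starts=n_starts,
                                          seed=config.seed, **pc)
            scan_table.to_csv(run_dir / "factor_scan.csv")
            if q is None:
                ratio = (scan_table["Q_true_over_expected"] - 1.0).abs()
                q = int(ratio.idxmin())
        if q is None:
            raise ValueError("config must set pmf.q or pmf.q_range")
        model = pmf.PMFModel(ds, q, **{k: v for k, v in pc.items()
                                       if k in ("robust", "tol", "max_iter",
                                                "include_total")})
        results = model.fit(n_starts=n_starts, seed=config.seed)
        results.contributions.to_csv(run_dir / "contributions.csv", index_label="date")
        results.profiles.to_csv(run_dir / "profiles.csv", index_label="factor")
        pd.DataFrame(results.scaled_residuals,
                     index=ds.data.index, columns=results.species
                     ).to_csv(run_dir / "scaled_residuals.csv", index_label="date")
        apport = pmf.apportion_mass(results)
        logger.info("PMF fit (q=%d) done in %.1fs; Q=%.1f", q,
                    time.time() - t, results.Q_true)

        # ---- error estimation --------------------------------------------
        stage = "errors"
        t = time.time()
        ec = config.errors
        bs = results.bootstrap(
            n_boot=ec.get("n_boot", 50),
            block_size=ec.get("block_size", 3),
            r_threshold=ec.get("map_r_threshold", 0.6),
            seed=config.seed + 1,
        )
        bs.summary().to_csv(run_dir / "bootstrap.csv", index_label="factor")
        disp_species = ec.get("disp_species")
        if disp_species is None:
            # one dominant (marker) species per factor keeps DISP desk-scale
            disp_species = sorted({results.profiles.loc[f].drop(
                labels=[ds.total_species], errors="ignore").idxmax()
                for f in results.factor_names})
        dr = results.disp(species_subset=disp_species,
                          dqmax_levels=tuple(ec.get("dqmax_levels", (4, 8, 16, 32))))
        dr.table.to_csv(run_dir / "disp.csv", index=False)
        logger.info("BS+DISP done in %.1fs", time.time() - t)

        # ---- CPF / PSCF ---------------------------------------------------
        cpf_results, pscf_results = {}, {}
        if config.inputs.get("wind"):
            stage = "cpf"
            wind = pd.read_csv(config.inputs["wind"], index_col=0, parse_dates=True)
            for f in results.factor_names:
                r = trajectory.cpf(
                    results.contributions[f], wind,
                    quantile=config.cpf.get("quantile", 0.75),
                    n_sectors=config.cpf.get("n_sectors", 16),
                    calm_cutoff=config.cpf.get("calm_cutoff", 0.5),
                )
                r.sectors.to_csv(run_dir / f"cpf_{f}.csv")
                cpf_results[f] = r
        if config.inputs.get("tdump"):
            stage = "pscf"
            trajs = trajectory.read_tdump(config.inputs["tdump"])
            for f in results.factor_names:
                g = trajectory.pscf(
                    trajs, results.contributions[f],
                    quantile=config.pscf.get("quantile", 0.70),
                )
                g = trajectory.wpscf(g, config.pscf.get("n_avg_mode", "nonzero"))
                g.to_frame().to_csv(run_dir / f"pscf_{f}.csv", index=False)
                pscf_results[f] = g

        # ---- risk ---------------------------------------------------------
        stage = "risk"
        rc = config.risk
        tox = (risk_mod.ToxicityTable.from_csv(config.inputs["toxicity"])
               if config.inputs.get("toxicity") else risk_mod.ToxicityTable.default())
        params = risk_mod.ExposureParams(
            et=rc.get("et", 24.0), ef=rc.get("ef", 365.0), ed=rc.get("ed", 30.0))
        elements = [s for s in results.species
                    if s in set(risk_mod.CARCINOGENS) | {"Cr"}]
        apportioned = results.apportion_species()
        matrix = risk_mod.source_risk_matrix(
            apportioned, tox, params,
            statistic=rc.get("statistic", "median"),
            cr_hex_fraction=rc.get("cr_hex_fraction", risk_mod.DEFAULT_CR_HEX_FRACTION),
            elements=elements,
        )
        matrix.to_csv(run_dir / "risk_matrix.csv")
        target = rc.get("target", 1e-6)
        reductions = {
            el: risk_mod.required_reduction(v, target)
            for el, v in matrix.col_sums.items() if v > target
        }

        # ---- summary ------------------------------------------------------
        stage = "summary"
        summary = {
            "seed": config.seed,
            "n_samples": int(ds.data.shape[0]),
            "n_species_fitted": len(results.species),
            "n_factors": int(results.n_factors),
            "Q_true": round(results.Q_true, 6),
            "Q_robust": round(results.Q_robust, 6),
            "Q_expected": results.Q_expected,
            "converged": bool(results.converged),
            "mass_shares_pct": {k: round(v, 6) for k, v in
                                apport["shares_pct"].to_dict().items()},
            "pm25_r2": round(apport["r2"], 6),
            "bootstrap_mapping_rate": {f: round(v, 6) for f, v in zip(
                results.factor_names, bs.mapping_rate)},
            "disp_any_swap": bool(dr.any_swap),
            "cpf_argmax_sector_deg": {f: r.argmax_sector()
                                      for f, r in cpf_results.items()},
            "pscf_argmax_cell": {f: list(g.argmax_cell())
                                 for f, g in pscf_results.items()},
            "risk": {k: (round(v, 12) if isinstance(v, float) else v)
                     for k, v in matrix.to_dict().items()
                     if k not in ("row_sums", "col_sums", "row_shares_pct",
                                  "col_shares_pct")},
            "grand_total_ilcr": matrix.grand_total,
            "ilcr_by_element": matrix.col_sums.to_dict(),
            "ilcr_by_source": matrix.row_sums.to_dict(),
            "source_shares_pct": matrix.row_shares.to_dict(),
            "element_shares_pct": matrix.col_shares.to_dict(),
            "required_reductions": reductions,
            "risk_target": target,
        }
        _write_json(run_dir / "summary.json", summary)
        logger.info("pipeline complete in %.1fs", time.time() - t0)
        return summary
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
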