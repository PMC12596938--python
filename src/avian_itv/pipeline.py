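"""End-to-end orchestration: filter -> CV model -> covariates -> regressions.

``run_pipeline`` takes a configuration (dict or YAML path) naming the input
files and stage settings, executes every stage for each requested trait, and
writes a report: one JSON file with all effects, convergence gates, seeds
and a config hash, plus CSV tables per stage.  A failed convergence gate
marks downstream results as not converged but does not halt the run; a
stage that raises is recorded and later stages for that trait are skipped,
earlier outputs are preserved.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from pathlib import Path

import pandas as pd
import yaml

from . import among_model, covariates, cv_model, filters, within_model
from .diagnostics import McmcConfig
from .synth import load_dataset_dir

__all__ = ["run_pipeline", "default_config"]

log = logging.getLogger("avian_itv")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)


def default_config(data_dir: str, out_dir: str, seed: int = 0) -> dict:
    """A complete pipeline configuration with conservative defaults."""
    return {
        "data_dir": data_dir,
        "out_dir": out_dir,
        "traits": ["mass", "wing"],
        "seed": seed,
        "crs": "planar_km",
        "buffer_km": 10.0,
        "radius_km": 10.0,
        "filter": {},
        "mcmc_cv": {"chains": 4, "iterations": 50_000, "warmup": 20_000, "thin": 20},
        "mcmc_within": {"chains": 4, "iterations": 5000, "warmup": 2500, "thin": 1},
        "mcmc_among": {"chains": 4, "iterations": 5000, "warmup": 2500, "thin": 1},
    }


def _mcmc(cfg: dict, key: str, seed_offset: int) -> McmcConfig:
    d = dict(cfg.get(key, {}))
    d.setdefault("chains", 4)
    d["seed"] = (int(cfg.get("seed", 0)) + seed_offset) % (2**31)
    return McmcConfig(**d)


def run_pipeline(config: dict | str | Path) -> dict:
    """Run every stage; return (and write) the report dictionary."""
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    data_dir = Path(config["data_dir"])
    out_dir = Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)

    required = ["captures.csv", "stations.csv", "raster.csv", "traits.csv",
                "tree.nwk", "ranges.geojson"]
    missing = [f for f in required if not (data_dir / f).exists()]
    if missing:
        raise FileNotFoundError(f"missing pipeline inputs in {data_dir}: {missing}")

    data = load_dataset_dir(data_dir)
    fcfg = filters.FilterConfig(**config.get("filter", {}))
    report: dict = {
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": int(config.get("seed", 0)),
        "traits": {},
    }

    for trait in config.get("traits", ["mass"]):
        t0 = time.time()
        tr: dict = {"stages": {}}
        report["traits"][trait] = tr
        try:
            filtered, filter_report = filters.apply_filters(
                data["captures"], fcfg, trait=trait
            )
            filtered.to_csv(out_dir / f"filtered_{trait}.csv", index=False)
            tr["stages"]["filter"] = {
                "n_in": filter_report["n_raw"],
                "n_out": filter_report["n_final"],
                "n_species": filter_report["n_species_final"],
            }
            log.info("[%s] filter: %d -> %d records", trait, len(data["captures"]), len(filtered))

            obs = cv_model.TraitObservationSet.from_captures(filtered, trait)
            post = cv_model.fit_cv_model(
                obs, _mcmc(config, "mcmc_cv", 1), trait=trait
            )
            group_cvs = cv_model.derive_all_group_cvs(post)
            species_cvs = cv_model.derive_all_species_cvs(post)
            group_cvs.assign(
                rhat_max=post.draws.gate["rhat_max_observed"],
                ess_min=post.draws.gate["ess_min_observed"],
            ).to_csv(out_dir / f"group_cv_{trait}.csv", index=False)
            species_cvs.to_csv(out_dir / f"species_cv_{trait}.csv", index=False)
            tr["stages"]["cv_model"] = {"gate": post.draws.gate, "n_groups": len(group_cvs)}
            log.info("[%s] cv model: %d groups, converged=%s", trait, len(group_cvs), post.converged)

            design = covariates.assemble_within_design(
                group_cvs,
                data["stations"],
                data["raster"],
                data["ranges"],
                buffer_km=config.get("buffer_km", 10.0),
                radius_km=config.get("radius_km", 10.0),
                crs=config.get("crs", "planar_km"),
            )
            design.to_csv(out_dir / f"within_design_{trait}.csv", index=False)
            vifs = covariates.vif(design[covariates.WITHIN_COVARIATES])
            tr["stages"]["covariates"] = {
                "vif": dict(zip(covariates.WITHIN_COVARIATES, map(float, vifs)))
            }

            wpost = within_model.fit_within_model(
                design, _mcmc(config, "mcmc_within", 2)
            )
            wtab = within_model.effects_table(wpost)
            wtab.to_csv(out_dir / f"within_effects_{trait}.csv", index=False)
            tr["stages"]["within_model"] = {
                "gate": wpost.draws.gate,
                "effects": wtab.to_dict(orient="records"),
            }
            log.info("[%s] within model converged=%s", trait, wpost.converged)

            profiles = covariates.build_species_profiles(
                species_cvs[["species", "cvsp_hat", "tausp_hat"]], data["traits"]
            )
            P = among_model.phylo_correlation(data["tree"], profiles["species"].tolist())
            apost = among_model.fit_among_model(
                profiles, P, _mcmc(config, "mcmc_among", 3)
            )
            atab = among_model.among_effects_table(apost)
            atab.to_csv(out_dir / f"among_effects_{trait}.csv", index=False)
            tr["stages"]["among_model"] = {
                "gate": apost.draws.gate,
                "effects": atab.to_dict(orient="records"),
            }
            log.info("[%s] among model converged=%s", trait, apost.converged)
        except Exception as exc:  # record and continue with the next trait
            tr["error"] = f"{type(exc).__name__}: {exc}"
            log.error("[%s] stage failed: %s", trait, exc)
        tr["runtime_s"] = round(time.time() - t0, 2)

    (out_dir / "report.json").write_text(json.dumps(report, indent=1, default=str))
    return report
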