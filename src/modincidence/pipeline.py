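"""Pipeline runner: execute generate -> fit -> transition -> genetics from
one YAML configuration, stamping every artifact with the config hash and
seed so runs are self-documenting and reproducible."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import genetics, simulate, transition
from .fit import FitConfig, IncidenceModel
from .io import IncidenceTable, read_incidence_csv, write_incidence_csv, write_locus_csv
from .params import HomogenizedParams

logger = logging.getLogger("modincidence")

__all__ = ["run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def _stamp(path: Path, payload: dict, config_hash: str, seed: int) -> None:
    payload = dict(payload)
    payload["config_hash"] = config_hash
    payload["seed"] = seed
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))


def _params_from(cfg: dict) -> HomogenizedParams:
    return HomogenizedParams(
        N=int(cfg["N"]), tau=float(cfg["tau"]), T=float(cfg["T"]), Phi=float(cfg["Phi"])
    )


def run_pipeline(config: dict, outdir) -> Path:
    """Execute the configured stages; returns the artifact directory.

    Recognized top-level keys: ``seed`` (global; each stage derives its own
    substream), ``registry``, ``fit``, ``transition``, ``genetics``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    chash = _config_hash(config)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(config.get("log_level", "INFO"))
    # stage seeds are fixed offsets of the global seed (named substreams)
    stage_seed = {"registry": seed, "fit": seed + 1, "genetics": seed + 2}
    table = None
    stage = "setup"
    try:
        logger.info("pipeline start: config hash %s, seed %d", chash, seed)
        if "registry" in config:
            stage = "registry"
            cfg = config["registry"]
            rc = simulate.RegistryConfig(
                params=_params_from(cfg["params"]),
                bin_width=float(cfg.get("bin_width", 5.0)),
                max_age=float(cfg.get("max_age", 90.0)),
                person_years=float(cfg.get("person_years", 5e6)),
                seed=stage_seed["registry"],
                noise=cfg.get("noise", "none"),
            )
            table = simulate.generate_registry(rc)
            write_incidence_csv(table, outdir / "registry.csv")
            logger.info("registry: %d bins written", len(table))
        if "fit" in config:
            stage = "fit"
            cfg = config["fit"]
            if table is None:
                if "table" not in cfg:
                    raise PipelineError(stage, "no registry stage and no table path")
                table = read_incidence_csv(cfg["table"])
            fc = FitConfig(
                N_grid=tuple(cfg.get("N_grid", [12])),
                fix_tau=cfg.get("fix_tau"),
                n_starts=int(cfg.get("n_starts", 32)),
                seed=stage_seed["fit"],
                loss=cfg.get("loss", "unweighted_ls"),
            )
            result = IncidenceModel(table).fit(fc)
            _stamp(outdir / "fit.json", result.to_dict(), chash, seed)
            logger.info("fit: %s", result.summary().replace("\n", " | "))
        if "transition" in config:
            stage = "transition"
            cfg = config["transition"]
            scenario = transition.TransitionScenario(
                base=_params_from(cfg["base"]),
                phi_after=float(cfg["phi_after"]),
                T_star=float(cfg["T_star"]),
                t50=float(cfg.get("t50", 0.0)),
                transition_width=float(cfg.get("transition_width", 10.0)),
                era=tuple(cfg.get("era", (0.0, 40.0))),
                destabilize=cfg.get("destabilize", "all"),
            )
            curves = transition.secular_curves(scenario)
            curves.to_dataframe().to_csv(outdir / "secular_curves.csv", index=False)
            curves.annual_dataframe().to_csv(outdir / "annual_series.csv", index=False)
            logger.info("transition: %d decade curves written", curves.curves.shape[0])
        if "genetics" in config:
            stage = "genetics"
            cfg = config["genetics"]
            phi = float(cfg.get("phi", 0.63))
            nu = genetics.OrDistribution.lognormal(
                mode=float(cfg.get("or_mode", 1.1)), sigma=float(cfg.get("or_sigma", 0.15))
            )
            rho = genetics.RafDistribution.beta(
                float(cfg.get("raf_a", 2.0)), float(cfg.get("raf_b", 2.0))
            )
            records = simulate.generate_locus_catalogue(
                int(cfg.get("n_loci", 140)), nu, rho, phi, seed=stage_seed["genetics"]
            )
            write_locus_csv(records, outdir / "loci.csv")
            grid = np.linspace(0.05, min(0.95, phi / 0.67), int(cfg.get("grid_size", 101)))
            g = genetics.mdp_density(nu, rho, phi, grid)
            np.savetxt(
                outdir / "mdp_density.csv",
                np.column_stack([g.grid, g.density]),
                delimiter=",",
                header="mdp,density",
                comments="",
            )
            logger.info("genetics: %d loci and MDP density written", len(records))
        _stamp(outdir / "manifest.json", {"stages": [k for k in
                ("registry", "fit", "transition", "genetics") if k in config]}, chash, seed)
        logger.info("pipeline complete")
    except PipelineError:
        raise
    except Exception as exc:  # annotate failures with the stage name
        logger.error("stage %s failed: %s", stage, exc)
        raise PipelineError(stage, str(exc)) from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
    return outdir


def load_pipeline_config(path) -> dict:
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: pipeline config must be a YAML mapping")
    return data
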