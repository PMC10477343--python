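"""Pipeline configuration and stage orchestration.

Each stage reads its inputs from disk (or from an earlier in-run stage),
computes with the library modules, and writes CSV artifacts prefixed with a
provenance header (config hash, seed, stage).  A single global seed is
split into independent per-stage substreams, so adding or rerunning one
stage never shifts another stage's random draws.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import datasets, fitting, optimize, pmm, validation
from .params import (StrainModel, design_inputs, input_region, load_model,
                     model_to_dict, ta1415_model, ta2445_model)
from .simulate import simulate

STAGES = ("generate", "simulate", "fit", "validate", "optimize", "pmm-sweep")
# fixed substream index per stage, so stage seeds are independent of which
# stages actually run
_STAGE_STREAM = {name: i for i, name in enumerate(STAGES)}


@dataclass
class PipelineConfig:
    """Settings for a full pipeline run on one strain."""

    strain: str = "TA1415"
    out_dir: Path = Path("results")
    seed: int = 0
    param_file: Optional[Path] = None      # defaults to the published values
    dataset_file: Optional[Path] = None    # defaults to <out_dir>/flasks_<strain>.csv
    noise: datasets.NoiseSpec = field(default_factory=datasets.NoiseSpec)
    n_replicates: int = 3
    n_starts: int = 4
    fit_rtol: float = fitting.FIT_RTOL
    sweep_points: Optional[int] = None
    pmm_ratios: Sequence[float] = pmm.RATIO_GRID_DEFAULT

    def model(self) -> StrainModel:
        if self.param_file is not None:
            return load_model(self.param_file)
        return ta1415_model() if self.strain == "TA1415" else ta2445_model()

    def stage_seed(self, stage: str) -> int:
        child = np.random.SeedSequence(self.seed).spawn(len(STAGES))
        return int(child[_STAGE_STREAM[stage]].generate_state(1)[0] % (2 ** 31))

    def digest(self) -> str:
        # output location is not part of the scientific configuration
        payload = {k: str(v) for k, v in self.__dict__.items()
                   if k != "out_dir"}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def _write_csv(df: pd.DataFrame, path: Path, config: PipelineConfig,
               stage: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    header = (f"# hisicc stage={stage} strain={config.strain} "
              f"seed={config.seed} config={config.digest()}\n")
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def run_pipeline(config: PipelineConfig, stages: Sequence[str] = STAGES) -> dict:
    """Run an ordered subset of stages; returns {stage: artifact path}.

    Stage dependencies (fit needs a dataset; validate needs a dataset and
    benefits from a fit warm start; pmm-sweep needs the optimized input)
    are satisfied either by an earlier in-run stage or by artifacts already
    on disk; a missing dependency names the stage to run first.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model = config.model()
    strain = config.strain
    artifacts: dict = {}
    flasks = None
    fit_result = None
    optimum = None

    dataset_path = (Path(config.dataset_file) if config.dataset_file
                    else out / f"flasks_{strain}.csv")
    fitted_param_path = out / f"fitted_params_{strain}.yaml"

    def need_flasks():
        nonlocal flasks
        if flasks is None:
            if not dataset_path.exists():
                raise FileNotFoundError(
                    f"{dataset_path} missing: run the 'generate' stage first")
            flasks = datasets.load_flasks(dataset_path)
        return flasks

    for stage in stages:
        if stage == "generate":
            flasks = datasets.generate_flasks(
                model, design_inputs(strain), n_replicates=config.n_replicates,
                noise=config.noise, seed=config.stage_seed(stage))
            _write_csv(datasets.flasks_to_frame(flasks), dataset_path,
                       config, stage)
            artifacts[stage] = dataset_path

        elif stage == "simulate":
            frames = []
            for cond in design_inputs(strain):
                traj = simulate(model, cond)
                df = traj.to_frame()
                df.insert(0, "input_value", cond.value)
                frames.append(df)
            path = out / f"trajectories_{strain}.csv"
            _write_csv(pd.concat(frames, ignore_index=True), path, config, stage)
            artifacts[stage] = path

        elif stage == "fit":
            fit_result = fitting.fit_parameters(
                need_flasks(), model, n_starts=config.n_starts,
                seed=config.stage_seed(stage), rtol=config.fit_rtol)
            d = model_to_dict(fit_result.model)
            d["_meta"] = {"cost": fit_result.cost, "nfev": fit_result.nfev,
                          "success": fit_result.success,
                          "n_starts": fit_result.n_starts,
                          "seed": config.stage_seed(stage),
                          "config": config.digest()}
            fitted_param_path.write_text(yaml.safe_dump(d, sort_keys=False))
            artifacts[stage] = fitted_param_path

        elif stage == "validate":
            warm = None
            if fit_result is not None:
                warm = fit_result.theta
            elif fitted_param_path.exists():
                fitted = yaml.safe_load(fitted_param_path.read_text())
                warm = {k: fitted[k] for k in fitting.FREE_DEFAULT[strain]}
            rounds = validation.holdout_validate(
                need_flasks(), model, warm_start=warm,
                n_starts=1 if warm else config.n_starts,
                seed=config.stage_seed(stage), rtol=config.fit_rtol)
            path = out / f"validation_{strain}.csv"
            _write_csv(validation.rounds_to_frame(rounds), path, config, stage)
            artifacts[stage] = path

        elif stage == "optimize":
            optimum = optimize.optimize_input(model, n_points=config.sweep_points)
            path = out / f"input_sweep_{strain}.csv"
            _write_csv(optimum.sweep, path, config, stage)
            opt_path = out / f"optimum_{strain}.json"
            opt_path.write_text(json.dumps(
                {"strain": strain, "u_opt": optimum.u_opt,
                 "yield_opt": optimum.yield_opt,
                 "region": list(input_region(strain))}, indent=2))
            artifacts[stage] = opt_path

        elif stage == "pmm-sweep":
            if optimum is None:
                opt_path = out / f"optimum_{strain}.json"
                if not opt_path.exists():
                    raise FileNotFoundError(
                        f"{opt_path} missing: run the 'optimize' stage first")
                u_opt = json.loads(opt_path.read_text())["u_opt"]
            else:
                u_opt = optimum.u_opt
            surface = pmm.pmm_surface(model, u_opt,
                                      ratios_k1=config.pmm_ratios,
                                      ratios_k2=config.pmm_ratios)
            path = out / f"pmm_surface_{strain}.csv"
            _write_csv(surface.to_frame(), path, config, stage)
            artifacts[stage] = path

        else:
            raise ValueError(f"unknown stage {stage!r}")

    return artifacts
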