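"""Synthetic flask timecourses and promoter dose-response grids.

The generators reproduce the structure of the study's experiments so that
estimation and validation can be exercised without the deposited data:
five IPTG input conditions per strain, three flasks each, OD600 and IPA
sampled on a regular grid; plus a (AHL, IPTG) dose-response grid of the
shared promoter, as measured with a GFP reporter strain.

Noise model: mean-one lognormal multiplicative noise (coefficient of
variation per channel) plus an additive Gaussian floor, then clipping at 0.
The floor mimics the detection limits of OD and HPLC readings; neither the
noise law nor its levels come from the study, which reports no error model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dynamics import promoter_response
from .params import (TA2445, InputCondition, QuorumParams, StrainModel,
                     design_inputs)
from .simulate import RTOL_DEFAULT, simulate

MEASUREMENT_INTERVAL_H = 3.0   # default sampling interval


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise specification for flask data.

    cv_od600 / cv_ipa : multiplicative coefficient of variation per channel.
    floor_od600 / floor_ipa : SD of the additive zero-mean Gaussian floor
    (OD600 units / mM).
    """

    cv_od600: float = 0.05
    cv_ipa: float = 0.05
    floor_od600: float = 0.01
    floor_ipa: float = 0.02

    def __post_init__(self) -> None:
        for name in ("cv_od600", "cv_ipa", "floor_od600", "floor_ipa"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


NOISELESS = NoiseSpec(0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class FlaskDataset:
    """One flask's measured timecourse and its input condition."""

    flask_id: str
    condition: InputCondition
    data: pd.DataFrame = field(repr=False)  # columns: time_h, od600, ipa_mM

    @property
    def strain(self) -> str:
        return self.condition.strain

    @property
    def times(self) -> np.ndarray:
        return self.data["time_h"].to_numpy()

    @property
    def od600(self) -> np.ndarray:
        return self.data["od600"].to_numpy()

    @property
    def ipa(self) -> np.ndarray:
        return self.data["ipa_mM"].to_numpy()


@dataclass(frozen=True)
class PromoterDataset:
    """Dose-response measurements of the shared promoter.

    ``data`` columns: ahl_nM, iptg_mM, response (normalized, dimensionless).
    """

    data: pd.DataFrame = field(repr=False)


def default_measurement_grid(duration: float,
                             interval: float = MEASUREMENT_INTERVAL_H) -> np.ndarray:
    """Sampling times: every `interval` hours plus the endpoint."""
    grid = np.arange(0.0, duration, interval)
    return np.append(grid, duration)


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-one lognormal multiplier with the requested CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv ** 2)
    return rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=size)


def generate_flasks(model: StrainModel,
                    inputs: Optional[Sequence[InputCondition]] = None,
                    n_replicates: int = 3,
                    noise: NoiseSpec = NoiseSpec(),
                    seed: Optional[int] = None,
                    rng: Optional[np.random.Generator] = None,
                    times: Optional[np.ndarray] = None,
                    rtol: float = RTOL_DEFAULT) -> list:
    """Simulate ground truth and sample noisy flask datasets.

    Defaults emulate the study design: the strain's five input conditions,
    three flasks each, measurements every 3 h plus the culture endpoint.
    Fully reproducible given ``seed`` (or an explicit ``rng``).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if inputs is None:
        inputs = design_inputs(model.strain)
    if rng is None:
        rng = np.random.default_rng(seed)
    if times is None:
        times = default_measurement_grid(model.duration)

    flasks = []
    for j, cond in enumerate(inputs):
        traj = simulate(model, cond, times=times, rtol=rtol)
        for r in range(n_replicates):
            od = traj.od600 * _lognormal_factor(rng, noise.cv_od600, times.size)
            od = od + rng.normal(0.0, noise.floor_od600, times.size) if noise.floor_od600 else od
            ipa = traj.ipa_mM * _lognormal_factor(rng, noise.cv_ipa, times.size)
            ipa = ipa + rng.normal(0.0, noise.floor_ipa, times.size) if noise.floor_ipa else ipa
            df = pd.DataFrame({
                "time_h": times,
                "od600": np.clip(od, 0.0, None),
                "ipa_mM": np.clip(ipa, 0.0, None),
            })
            flasks.append(FlaskDataset(
                flask_id=f"{model.strain}-c{j + 1}-r{r + 1}",
                condition=cond, data=df))
    return flasks


def generate_promoter_grid(q: QuorumParams,
                           ahl_levels: Optional[Sequence[float]] = None,
                           iptg_levels: Optional[Sequence[float]] = None,
                           noise_cv: float = 0.0,
                           seed: Optional[int] = None,
                           rng: Optional[np.random.Generator] = None) -> PromoterDataset:
    """Dose-response grid of the promoter over (AHL, IPTG) levels.

    Default levels span 1.5 decades either side of each dissociation
    constant (9 points per axis, log-spaced).  Responses are the Hill
    product times a (1 + cv*N(0,1)) factor, clipped at 0.
    """
    if ahl_levels is None:
        ahl_levels = q.K_A * np.logspace(-1.5, 1.5, 9)
    if iptg_levels is None:
        iptg_levels = q.K_u * np.logspace(-1.5, 1.5, 9)
    if rng is None:
        rng = np.random.default_rng(seed)
    A, U = np.meshgrid(np.asarray(ahl_levels, float),
                       np.asarray(iptg_levels, float), indexing="ij")
    z = promoter_response(A.ravel(), U.ravel(), q)
    if noise_cv:
        z = np.clip(z * (1.0 + noise_cv * rng.standard_normal(z.size)), 0.0, None)
    return PromoterDataset(data=pd.DataFrame({
        "ahl_nM": A.ravel(), "iptg_mM": U.ravel(), "response": z}))


# ---------------------------------------------------------------------------
# CSV round-trip (also the reader contract for reshaped experimental data)

def flasks_to_frame(flasks: Sequence[FlaskDataset]) -> pd.DataFrame:
    rows = []
    for f in flasks:
        df = f.data.copy()
        df.insert(0, "flask_id", f.flask_id)
        df.insert(1, "strain", f.strain)
        df.insert(2, "input_value", f.condition.value)
        rows.append(df)
    return pd.concat(rows, ignore_index=True)


def save_flasks(flasks: Sequence[FlaskDataset], path) -> None:
    flasks_to_frame(flasks).to_csv(path, index=False)


def load_flasks(path) -> list:
    df = pd.read_csv(Path(path), comment="#")
    flasks = []
    for (fid, strain, val), grp in df.groupby(["flask_id", "strain", "input_value"],
                                              sort=False):
        cond = (InputCondition(strain, u_conc=float(val)) if strain == TA2445
                else InputCondition(strain, t_add=float(val)))
        flasks.append(FlaskDataset(
            flask_id=str(fid), condition=cond,
            data=grp[["time_h", "od600", "ipa_mM"]].reset_index(drop=True)))
    return flasks


def save_promoter(ds: PromoterDataset, path) -> None:
    ds.data.to_csv(path, index=False)


def load_promoter(path) -> PromoterDataset:
    return PromoterDataset(data=pd.read_csv(Path(path), comment="#"))
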