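"""Hold-out validation of the fitted strain models.

One flask at a time is held out, the model is refitted on the remaining
flasks, and the held-out timecourse is scored with the coefficient of
determination R² per output channel.  Following the study design, only
flasks under the three middle input conditions are eligible for hold-out
(the extreme conditions always stay in training), giving 9 rounds per
strain and 18 R² values (9 flasks × 2 channels).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datasets import FlaskDataset
from .fitting import FIT_RTOL, FitResult, fit_parameters
from .params import StrainModel
from .simulate import simulate


def r_squared(measured, predicted) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot.

    Can be negative for predictions worse than the measured mean; raises
    when the measured series has zero variance (R² undefined).
    """
    y = np.asarray(measured, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.size < 2:
        raise ValueError("R² needs at least two measured points")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("measured series has zero variance; R² undefined")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot


@dataclass
class ValidationRound:
    """One hold-out round: refit without one flask, score that flask."""

    flask_id: str
    input_value: float
    r2_od600: float
    r2_ipa: float
    fit: FitResult

    @property
    def converged(self) -> bool:
        return self.fit.success


def middle_condition_flasks(datasets: Sequence[FlaskDataset]) -> list:
    """Flask ids under the middle input conditions (extremes excluded)."""
    values = sorted({f.condition.value for f in datasets})
    middle = set(values[1:-1])
    return [f.flask_id for f in datasets if f.condition.value in middle]


def holdout_validate(datasets: Sequence[FlaskDataset],
                     template: StrainModel,
                     holdout_ids: Optional[Sequence[str]] = None,
                     warm_start: Optional[dict] = None,
                     n_starts: int = 1,
                     seed: Optional[int] = None,
                     rtol: float = FIT_RTOL,
                     **fit_kwargs) -> list:
    """Run leave-one-flask-out validation.

    Parameters
    ----------
    holdout_ids
        Flasks to hold out, one round each; defaults to every flask under
        the middle input conditions.
    warm_start
        Start point for each refit, typically the parameters fitted on all
        data; when omitted each round multi-starts from scratch.

    Returns a list of ValidationRound with per-channel R² on the held-out
    flask.
    """
    if holdout_ids is None:
        holdout_ids = middle_condition_flasks(datasets)
    by_id = {f.flask_id: f for f in datasets}
    rounds = []
    for fid in holdout_ids:
        held = by_id[fid]
        train = [f for f in datasets if f.flask_id != fid]
        fit = fit_parameters(train, template, start=warm_start,
                             n_starts=n_starts, seed=seed, rtol=rtol,
                             **fit_kwargs)
        traj = simulate(fit.model, held.condition, times=held.times, rtol=rtol)
        rounds.append(ValidationRound(
            flask_id=fid,
            input_value=held.condition.value,
            r2_od600=r_squared(held.od600, traj.od600),
            r2_ipa=r_squared(held.ipa, traj.ipa_mM),
            fit=fit))
    return rounds


def rounds_to_frame(rounds: Sequence[ValidationRound]) -> pd.DataFrame:
    """Tidy per-round, per-channel table: flask_id, channel, r_squared, converged."""
    rows = []
    for r in rounds:
        for channel, r2 in (("od600", r.r2_od600), ("ipa", r.r2_ipa)):
            rows.append({"flask_id": r.flask_id, "input_value": r.input_value,
                         "channel": channel, "r_squared": r2,
                         "converged": r.converged})
    return pd.DataFrame(rows)
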