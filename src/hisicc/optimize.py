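"""Model-based optimization of the scalar IPTG input.

The in silico feedforward controller picks the input value (IPTG addition
time for TA1415, constant IPTG concentration for TA2445) that maximizes
the predicted IPA concentration at the end of the culture.  An exhaustive
sweep over the feasible region visualizes the yield tradeoff; the optimum
is refined from the best grid point with a bounded scalar search, which is
derivative-free and therefore indifferent to the step-input discontinuity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .params import TA1415, InputCondition, StrainModel, input_region
from .simulate import RTOL_DEFAULT, final_yield

SWEEP_POINTS_DEFAULT = {"TA1415": 150, "TA2445": 100}
INPUT_XATOL = 1e-4   # refinement tolerance on the input (h or mM)


def _condition(model: StrainModel, value: float) -> InputCondition:
    if model.strain == TA1415:
        return InputCondition(TA1415, t_add=float(value))
    return InputCondition(model.strain, u_conc=float(value))


def sweep_inputs(model: StrainModel,
                 region: Optional[tuple] = None,
                 n_points: Optional[int] = None,
                 spacing: Optional[str] = None,
                 rtol: float = RTOL_DEFAULT) -> pd.DataFrame:
    """Evaluate the final IPA yield on a grid of input values.

    Linear spacing by default for TA1415 (addition time), logarithmic for
    TA2445 (concentration, spanning two decades).  Returns a table with
    columns ``input_value`` and ``final_ipa_mM``.
    """
    if region is None:
        region = input_region(model.strain)
    lo, hi = region
    if hi < lo:
        raise ValueError("empty input region")
    if n_points is None:
        n_points = SWEEP_POINTS_DEFAULT[model.strain] if lo < hi else 1
    if spacing is None:
        spacing = "linear" if model.strain == TA1415 else "log"
    if n_points == 1 or lo == hi:
        grid = np.array([lo])
    elif spacing == "log":
        grid = np.logspace(np.log10(lo), np.log10(hi), n_points)
    else:
        grid = np.linspace(lo, hi, n_points)
    yields = [final_yield(model, _condition(model, v), rtol=rtol) for v in grid]
    return pd.DataFrame({"input_value": grid, "final_ipa_mM": yields})


def count_interior_maxima(sweep: pd.DataFrame) -> int:
    """Number of strict interior local maxima of the sweep curve."""
    y = sweep["final_ipa_mM"].to_numpy()
    return int(np.sum((y[1:-1] > y[:-2]) & (y[1:-1] > y[2:])))


@dataclass
class InputOptimum:
    """The optimized input and its predicted yield, with the sweep table."""

    strain: str
    u_opt: float                  # h for TA1415, mM for TA2445
    yield_opt: float              # predicted final IPA, mM
    sweep: pd.DataFrame = field(repr=False)
    refined: bool = True          # False if the scalar refinement failed


def optimize_input(model: StrainModel,
                   region: Optional[tuple] = None,
                   n_points: Optional[int] = None,
                   spacing: Optional[str] = None,
                   xatol: float = INPUT_XATOL,
                   rtol: float = RTOL_DEFAULT) -> InputOptimum:
    """Maximize the predicted final IPA yield over the feasible input region.

    Coarse grid sweep followed by bounded scalar refinement in the bracket
    around the best grid point.  If the refinement fails or loses to the
    grid, the best grid point is returned with ``refined = False``.
    """
    if region is None:
        region = input_region(model.strain)
    sweep = sweep_inputs(model, region=region, n_points=n_points,
                         spacing=spacing, rtol=rtol)
    grid = sweep["input_value"].to_numpy()
    yields = sweep["final_ipa_mM"].to_numpy()
    i = int(np.argmax(yields))
    if grid.size == 1:
        return InputOptimum(model.strain, float(grid[0]), float(yields[0]),
                            sweep, refined=False)
    lo_b = grid[max(i - 1, 0)]
    hi_b = grid[min(i + 1, grid.size - 1)]
    try:
        res = minimize_scalar(
            lambda v: -final_yield(model, _condition(model, v), rtol=rtol),
            bounds=(lo_b, hi_b), method="bounded", options={"xatol": xatol})
        ok = bool(res.success) and -res.fun >= yields[i]
    except Exception:
        ok = False
    if not ok:
        return InputOptimum(model.strain, float(grid[i]), float(yields[i]),
                            sweep, refined=False)
    return InputOptimum(model.strain, float(res.x), float(-res.fun),
                        sweep, refined=True)
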