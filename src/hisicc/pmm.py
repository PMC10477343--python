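"""Process-model-mismatch (PMM) robustness analysis.

The controller model fixes the IPTG input at its optimum, then the "plant"
— the simulated true process — is given growth-rate parameters k1*, k2*
that deviate from the controller's k1, k2 by grid-point-specific ratios.
The final IPA yield over the ratio grid forms a yield surface; comparing
the two strains' normalized surfaces quantifies how much the quorum-sensing
in-cell feedback of TA2445 compensates for growth-rate prediction error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .optimize import _condition
from .params import StrainModel
from .simulate import RTOL_DEFAULT, SolverError, final_yield

RATIO_GRID_DEFAULT = tuple(np.round(np.linspace(0.5, 1.5, 11), 10))


@dataclass
class YieldSurface:
    """Final IPA yields over a grid of growth-parameter mismatch ratios.

    ``yields[i, j]`` is the plant yield with k1* = ratios_k1[i] * k1 and
    k2* = ratios_k2[j] * k2, under the fixed input ``u_opt`` optimized for
    the unperturbed controller model.  ``ipa_opt`` is the matched-model
    yield, i.e. the value at ratios (1, 1) when the grid contains it.
    """

    strain: str
    u_opt: float
    ipa_opt: float
    ratios_k1: np.ndarray
    ratios_k2: np.ndarray
    yields: np.ndarray = field(repr=False)

    @property
    def normalized(self) -> np.ndarray:
        return self.yields / self.ipa_opt

    def to_frame(self) -> pd.DataFrame:
        r1, r2 = np.meshgrid(self.ratios_k1, self.ratios_k2, indexing="ij")
        return pd.DataFrame({
            "ratio_k1": r1.ravel(),
            "ratio_k2": r2.ravel(),
            "final_ipa_mM": self.yields.ravel(),
            "normalized_yield": self.normalized.ravel(),
        })


def pmm_surface(model: StrainModel, u_opt: float,
                ratios_k1: Optional[Sequence[float]] = None,
                ratios_k2: Optional[Sequence[float]] = None,
                rtol: float = RTOL_DEFAULT) -> YieldSurface:
    """Simulate the plant under the fixed optimal input across mismatch ratios.

    Only k1 and k2 — the parameters that set the cell growth rate — are
    perturbed; everything else, including the input, stays at the
    controller-model values.  A ratio of exactly 1.0 reproduces the
    controller model bit-for-bit (same code path, same floats).  Failed
    integrations are recorded as NaN cells.
    """
    ratios_k1 = np.asarray(RATIO_GRID_DEFAULT if ratios_k1 is None else ratios_k1,
                           dtype=float)
    ratios_k2 = np.asarray(RATIO_GRID_DEFAULT if ratios_k2 is None else ratios_k2,
                           dtype=float)
    cond = _condition(model, u_opt)
    yields = np.full((ratios_k1.size, ratios_k2.size), np.nan)
    for i, r1 in enumerate(ratios_k1):
        for j, r2 in enumerate(ratios_k2):
            plant = model.with_shared(k1=r1 * model.shared.k1,
                                      k2=r2 * model.shared.k2)
            try:
                yields[i, j] = final_yield(plant, cond, rtol=rtol)
            except SolverError:
                pass
    ipa_opt = final_yield(model, cond, rtol=rtol)
    return YieldSurface(strain=model.strain, u_opt=u_opt, ipa_opt=ipa_opt,
                        ratios_k1=ratios_k1, ratios_k2=ratios_k2, yields=yields)


def compare_strains(surface_a: YieldSurface,
                    surface_b: YieldSurface) -> pd.DataFrame:
    """Pointwise comparison of two strains' normalized yield surfaces.

    Returns one row per ratio grid point with each strain's normalized
    yield and the difference (b - a).  Requires identical ratio grids.
    """
    if (not np.array_equal(surface_a.ratios_k1, surface_b.ratios_k1)
            or not np.array_equal(surface_a.ratios_k2, surface_b.ratios_k2)):
        raise ValueError("surfaces computed on different ratio grids")
    r1, r2 = np.meshgrid(surface_a.ratios_k1, surface_a.ratios_k2, indexing="ij")
    return pd.DataFrame({
        "ratio_k1": r1.ravel(),
        "ratio_k2": r2.ravel(),
        f"normalized_{surface_a.strain}": surface_a.normalized.ravel(),
        f"normalized_{surface_b.strain}": surface_b.normalized.ravel(),
        "difference": (surface_b.normalized - surface_a.normalized).ravel(),
    })


def quadrant_summary(comparison: pd.DataFrame,
                     strains: Sequence[str]) -> pd.DataFrame:
    """Mean normalized yield per strain in each mismatch quadrant."""
    c = comparison
    quadrants = {
        "faster_growth": (c.ratio_k1 > 1) & (c.ratio_k2 > 1),
        "slower_growth": (c.ratio_k1 < 1) & (c.ratio_k2 < 1),
        "matched": (c.ratio_k1 == 1) & (c.ratio_k2 == 1),
    }
    rows = []
    for name, mask in quadrants.items():
        row = {"quadrant": name, "n_points": int(mask.sum())}
        for s in strains:
            row[f"mean_normalized_{s}"] = float(c.loc[mask, f"normalized_{s}"].mean())
        rows.append(row)
    return pd.DataFrame(rows)
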