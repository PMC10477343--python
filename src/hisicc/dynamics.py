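"""Right-hand-side dynamics of the two strain models.

State ordering is (S, X_A, X_G, E, B) for TA1415 and (S, X_A, X_G, E, B, A)
for TA2445.  Three reactions drive both models:

    v1 = k1 * S * (X_A + X_G + E) * (1 - (1 - r_leak) * u)   (resource uptake)
    v2 = k2 * X_A * (X_G + E)                                 (maturation)
    v3 = k3 * E / (E + K_E) * X_G                             (IPA synthesis)

with u the toggle-switch activation: the normalized 0/1 IPTG input for
TA1415, and the quorum-sensing promoter output z(A, u) for TA2445.  The sum
S + X_A + X_G + E is conserved exactly (the first four derivatives cancel
algebraically).
"""

from __future__ import annotations

import numpy as np

from .params import QuorumParams, SharedParams


def _hill(x: np.ndarray, K: float, n: float) -> np.ndarray:
    """x^n / (x^n + K^n), with the continuous limit 0 at x = 0."""
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    pos = x > 0
    xn = np.power(x, n, where=pos, out=np.zeros_like(x))
    out[pos] = xn[pos] / (xn[pos] + K ** n)
    return out


def promoter_response(A, u, q: QuorumParams):
    """Output z of the shared sender/receiver promoter.

    Product of two Hill functions, one in AHL concentration ``A`` (nM) and
    one in IPTG concentration ``u`` (mM); z lies in [0, 1) and vanishes when
    either ligand is absent.  Accepts scalars or arrays.
    """
    A = np.asarray(A, dtype=float)
    u = np.asarray(u, dtype=float)
    if np.any(A < 0) or np.any(u < 0):
        raise ValueError("AHL and IPTG concentrations must be >= 0")
    z = _hill(A, q.K_A, q.n_A) * _hill(u, q.K_u, q.n_u)
    return z if z.ndim else float(z)


def reaction_rates(S: float, X_A: float, X_G: float, E: float,
                   u: float, p: SharedParams) -> tuple:
    """The three reaction rates (v1, v2, v3) at a given activation level u."""
    v1 = p.k1 * S * (X_A + X_G + E) * (1.0 - (1.0 - p.r_leak) * u)
    v2 = p.k2 * X_A * (X_G + E)
    v3 = p.k3 * E / (E + p.K_E) * X_G
    return v1, v2, v3


def rhs_ta1415(state, u: float, p: SharedParams) -> np.ndarray:
    """Time derivative of (S, X_A, X_G, E, B) under normalized input u ∈ {0, 1}."""
    S, X_A, X_G, E, _B = state
    v1, v2, v3 = reaction_rates(S, X_A, X_G, E, u, p)
    return np.array([-v1, v1 - v2, v2 * (1.0 - p.a_E * u), v2 * p.a_E * u, v3])


def rhs_ta2445(state, u: float, p: SharedParams, q: QuorumParams) -> np.ndarray:
    """Time derivative of (S, X_A, X_G, E, B, A) at IPTG concentration u (mM).

    The toggle activation is the promoter output z(A, u); AHL is produced in
    proportion to X_G * z (positive feedback, the sender device uses the same
    promoter) and degrades first-order.
    """
    S, X_A, X_G, E, _B, A = state
    z = promoter_response(max(A, 0.0), u, q)
    v1, v2, v3 = reaction_rates(S, X_A, X_G, E, z, p)
    return np.array([
        -v1,
        v1 - v2,
        v2 * (1.0 - p.a_E * z),
        v2 * p.a_E * z,
        v3,
        q.k_A * X_G * z - q.d_A * A,
    ])


def observe(state, p: SharedParams) -> tuple:
    """Map a state to the measured outputs (OD600, IPA mM).

    Cell density is proportional to the inactive compartment, y1 = N_m * X_G;
    IPA concentration is observed directly, y2 = B.
    """
    return p.N_m * state[2], state[4]
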