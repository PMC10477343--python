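"""Parameter sets and model definitions for the two IPA-producing strains.

Two engineered *E. coli* strains are modeled. TA1415 carries a metabolic
toggle switch (MTS) activated by adding IPTG to the medium at a chosen time;
TA2445 additionally carries a quorum-sensing circuit (AHL sender/receiver)
that activates the MTS autonomously once cell density is high enough, with
the constant IPTG concentration acting as a sensitivity reference.

Both strains share a three-compartment structured growth model (active
biomass ``X_A``, inactive biomass ``X_G``, IPA-pathway enzymes ``E``)
drawing on a dimensionless pool of extracellular resources ``S``; the
product isopropanol ``B`` is in mM.  TA2445 adds the extracellular AHL
concentration ``A`` (nM).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import yaml

TA1415 = "TA1415"
TA2445 = "TA2445"


@dataclass(frozen=True)
class SharedParams:
    """Kinetic parameters common to both strain models.

    k1 : 1/h
        Rate constant of Reaction 1 (S -> X_A via the TCA cycle).
    k2 : 1/h
        Rate constant of Reaction 2 (X_A -> X_G and E).
    k3 : mM/h
        Rate constant of Reaction 3 (IPA synthesis).
    r_leak : dimensionless, in [0, 1]
        Residual fraction of Reaction 1 that proceeds when the MTS is fully
        on (promoter leak).
    a_E : dimensionless, in [0, 1]
        Fraction of Reaction 2 flux allocated to enzyme synthesis when the
        MTS is on.
    K_E : dimensionless, > 0
        Saturation coefficient of the IPA production rate in E.
    X_A0 : dimensionless
        Initial active-compartment size (a fitted initial condition).
    N_m : OD600 units
        Proportionality between X_G and measured cell density.
    """

    k1: float
    k2: float
    k3: float
    r_leak: float
    a_E: float
    K_E: float
    X_A0: float
    N_m: float

    def __post_init__(self) -> None:
        for name in ("k1", "k2", "k3", "K_E", "X_A0", "N_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if not 0.0 <= self.r_leak <= 1.0:
            raise ValueError(f"r_leak must be in [0, 1], got {self.r_leak}")
        if not 0.0 <= self.a_E <= 1.0:
            raise ValueError(f"a_E must be in [0, 1], got {self.a_E}")

    def replace(self, **changes: float) -> "SharedParams":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class QuorumParams:
    """Quorum-sensing circuit parameters (TA2445 only).

    k_A : nM/h
        AHL production rate constant (per unit X_G at full promoter output).
    d_A : 1/h
        First-order AHL degradation rate.
    K_A : nM
        AHL dissociation constant of the shared promoter.
    K_u : mM
        IPTG dissociation constant of the shared promoter.
    n_A, n_u : dimensionless
        Hill coefficients for AHL and IPTG.
    """

    k_A: float
    d_A: float
    K_A: float
    K_u: float
    n_A: float
    n_u: float

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be > 0")

    def replace(self, **changes: float) -> "QuorumParams":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class InputCondition:
    """The scalar IPTG input of one culture.

    For TA1415 the input is the IPTG addition time ``t_add`` (h): the
    normalized input u steps from 0 to 1 at that moment.  For TA2445 the
    input is the constant IPTG concentration ``u_conc`` (mM) present from
    t = 0.
    """

    strain: str
    t_add: Optional[float] = None
    u_conc: Optional[float] = None

    def __post_init__(self) -> None:
        if self.strain == TA1415:
            if self.t_add is None or self.u_conc is not None:
                raise ValueError("TA1415 input must set t_add only")
            if self.t_add < 0:
                raise ValueError("t_add must be >= 0")
        elif self.strain == TA2445:
            if self.u_conc is None or self.t_add is not None:
                raise ValueError("TA2445 input must set u_conc only")
            if self.u_conc <= 0:
                raise ValueError("u_conc must be > 0")
        else:
            raise ValueError(f"unknown strain {self.strain!r}")

    @property
    def value(self) -> float:
        """The scalar input value (h for TA1415, mM for TA2445)."""
        return self.t_add if self.strain == TA1415 else self.u_conc  # type: ignore[return-value]


@dataclass(frozen=True)
class StrainModel:
    """A complete parameterized model of one strain.

    Bundles the kinetic parameters, the fixed initial conditions
    (X_G(0), and A(0) for TA2445) and the culture duration.  Initial
    S is 1 - X_A(0) - X_G(0); E and B start at 0.
    """

    strain: str
    shared: SharedParams
    quorum: Optional[QuorumParams] = None
    X_G0: float = 0.02
    A0: Optional[float] = None
    duration: float = 69.0

    def __post_init__(self) -> None:
        if self.strain == TA2445:
            if self.quorum is None or self.A0 is None:
                raise ValueError("TA2445 model requires quorum params and A0")
        elif self.strain == TA1415:
            if self.quorum is not None or self.A0 is not None:
                raise ValueError("TA1415 model takes no quorum params or A0")
        else:
            raise ValueError(f"unknown strain {self.strain!r}")
        if self.S0 <= 0:
            raise ValueError("initial S = 1 - X_A0 - X_G0 must be > 0")
        if self.duration < 0:
            raise ValueError("duration must be >= 0")

    @property
    def S0(self) -> float:
        return 1.0 - self.shared.X_A0 - self.X_G0

    @property
    def n_states(self) -> int:
        return 6 if self.strain == TA2445 else 5

    @property
    def state_names(self) -> tuple:
        base = ("S", "X_A", "X_G", "E", "B")
        return base + ("A",) if self.strain == TA2445 else base

    def initial_state(self) -> list:
        y0 = [self.S0, self.shared.X_A0, self.X_G0, 0.0, 0.0]
        if self.strain == TA2445:
            y0.append(self.A0)
        return y0

    def replace(self, **changes) -> "StrainModel":
        return dataclasses.replace(self, **changes)

    def with_shared(self, **changes: float) -> "StrainModel":
        return self.replace(shared=self.shared.replace(**changes))


def ta1415_model() -> StrainModel:
    """TA1415 model at the published fitted parameter values."""
    return StrainModel(
        strain=TA1415,
        shared=SharedParams(
            k1=0.4772, k2=0.9089, k3=1.2418, r_leak=0.2777,
            a_E=0.1508, K_E=0.0081, X_A0=0.0572, N_m=5.4651,
        ),
        X_G0=0.02,
        duration=69.0,
    )


def ta2445_model() -> StrainModel:
    """TA2445 model at the published fitted parameter values.

    The printed table runs the k2 and k3 cells of the two strains together;
    we read the TA2445 values as k2 = 1 /h and k3 = 2 mM/h (the reading
    that reproduces the published optimal inputs).  Both are plain config
    values, so the alternative parse (k2 = 0.9089.., k3 = 1.2418..) can be
    run by constructing the model with those numbers instead.
    """
    return StrainModel(
        strain=TA2445,
        shared=SharedParams(
            k1=0.4526, k2=1.0, k3=2.0, r_leak=0.0607,
            a_E=0.0190, K_E=0.0034, X_A0=0.0240, N_m=5.6799,
        ),
        quorum=QuorumParams(
            k_A=1913.7, d_A=0.1489, K_A=1.596, K_u=0.02268,
            n_A=1.752, n_u=1.597,
        ),
        X_G0=0.005,
        A0=0.01,
        duration=51.5,
    )


# The experimental design: five input conditions per strain, three flasks each.
TA1415_INPUT_TIMES = (0.0, 6.0, 9.0, 12.0, 15.0)       # h, 0.1 mM IPTG added
TA2445_INPUT_CONCS = (0.01, 0.03, 0.05, 0.1, 1.0)      # mM, present from t=0
N_REPLICATES = 3

# Feasible input regions for model-based optimization.
TA1415_INPUT_REGION = (0.0, 15.0)      # h
TA2445_INPUT_REGION = (0.01, 1.0)      # mM


def design_inputs(strain: str) -> list:
    """The five experimental input conditions for a strain."""
    if strain == TA1415:
        return [InputCondition(TA1415, t_add=t) for t in TA1415_INPUT_TIMES]
    return [InputCondition(TA2445, u_conc=u) for u in TA2445_INPUT_CONCS]


def input_region(strain: str) -> tuple:
    return TA1415_INPUT_REGION if strain == TA1415 else TA2445_INPUT_REGION


# ---------------------------------------------------------------------------
# Flat key:value serialization (YAML mapping, keys named as the symbols)

def model_to_dict(model: StrainModel) -> dict:
    d = {"strain": model.strain, "X_G0": model.X_G0, "duration": model.duration}
    d.update(dataclasses.asdict(model.shared))
    if model.strain == TA2445:
        d["A0"] = model.A0
        d.update(dataclasses.asdict(model.quorum))
    # numpy scalars (e.g. fitted values) are not plain-YAML representable
    return {k: float(v) if k != "strain" else v for k, v in d.items()}


def model_from_dict(d: dict) -> StrainModel:
    d = dict(d)
    strain = d.pop("strain")
    shared = SharedParams(**{f.name: float(d.pop(f.name))
                             for f in dataclasses.fields(SharedParams)})
    quorum = None
    a0 = None
    if strain == TA2445:
        quorum = QuorumParams(**{f.name: float(d.pop(f.name))
                                 for f in dataclasses.fields(QuorumParams)})
        a0 = float(d.pop("A0"))
    return StrainModel(strain=strain, shared=shared, quorum=quorum,
                       X_G0=float(d.pop("X_G0")), A0=a0,
                       duration=float(d.pop("duration")))


def save_model(model: StrainModel, path) -> None:
    """Write a model as a flat YAML mapping of symbol: value."""
    Path(path).write_text(yaml.safe_dump(model_to_dict(model), sort_keys=False))


def load_model(path) -> StrainModel:
    return model_from_dict(yaml.safe_load(Path(path).read_text()))
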