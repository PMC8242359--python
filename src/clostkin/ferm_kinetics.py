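"""Batch-fermentation kinetic model for acidogenic *Clostridium tyrobutyricum*.

The model couples four state variables over a batch run — biomass X (g/L dry
cell weight), glucose S (g/L), butyrate P_Ba (g/L) and acetate P_Aa (g/L) —
through:

* growth with Haldane substrate inhibition and a power-law product-inhibition
  factor,  mu = mu_m * S / (S + K_S + S^2/K_I) * (1 - P/P_d)^i,
  where P is the total acid concentration P_Ba + P_Aa by default;
* a first-order death term K_d acting on biomass at all times;
* Luedeking-Piret product formation, dP/dt = alpha * dX/dt + beta * X, with
  separate (alpha, beta) for butyrate and acetate and only the positive part
  of dX/dt contributing (product is not consumed when biomass decays);
* a substrate balance routing glucose to biomass, both acids and maintenance:
  -dS/dt = dX/dt/Y_X + dP_Ba/dt/Y_Ba + dP_Aa/dt/Y_Aa + m_S * X.

Units are hours and g/L throughout; yields are g/g.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.integrate import solve_ivp

__all__ = [
    "KineticParams",
    "FermentationState",
    "TimeCourse",
    "StoichiometricYields",
    "specific_growth_rate",
    "haldane_optimum",
    "ode_rhs",
    "simulate_batch",
    "stoichiometric_yields",
    "OD_TO_DCW_G_PER_L",
]

#: Dry-cell-weight equivalent of one OD600 unit (g/L DCW per OD unit).
OD_TO_DCW_G_PER_L = 0.412

# IUPAC 2021 standard atomic weights (abridged).
_ATOMIC_MASS = {"C": 12.011, "H": 1.008, "O": 15.999}

#: width (g/L) of the substrate boundary layer over which non-growth
#: production and maintenance ramp linearly to zero. Keeps the vector field
#: continuous at glucose exhaustion (stiff but solvable) instead of
#: discontinuous (step-size collapse); 1e-4 g/L is far below assay detection
#: and leaves the equations exact everywhere else.
_S_EXHAUST_LAYER = 1e-4


def _molar_mass(formula: dict[str, int]) -> float:
    return sum(_ATOMIC_MASS[el] * n for el, n in formula.items())


@dataclass(frozen=True)
class KineticParams:
    """Kinetic and stoichiometric parameter set of the batch model.

    Defaults are the fitted values for the high-producing mutant strain:
    mu_m = 0.48 1/h, K_S = 1.71 g/L, K_I = 383 g/L, P_d = 53.8 g/L,
    i = 5.32, K_d = 0.0027 1/h, alpha_Ba = 3.12, alpha_Aa = 0.83 g/g DCW,
    beta_Ba = 0.049 g/g DCW/h (beta_Aa unreported, taken as 0),
    Y_X = 0.812, Y_Ba = 0.973, Y_Aa = 0.997 g/g, m_S = 0.015 1/h.
    """

    mu_m: float = 0.48      #: maximum specific growth rate, 1/h
    K_S: float = 1.71       #: substrate saturation constant, g/L
    K_I: float = 383.0      #: substrate inhibition constant, g/L
    P_d: float = 53.8       #: critical total-acid concentration, g/L
    i: float = 5.32         #: product-inhibition exponent, dimensionless
    K_d: float = 0.0027     #: specific death rate, 1/h
    alpha_Ba: float = 3.12  #: growth-associated butyrate coefficient, g/g DCW
    alpha_Aa: float = 0.83  #: growth-associated acetate coefficient, g/g DCW
    beta_Ba: float = 0.049  #: non-growth butyrate coefficient, g/g DCW/h
    beta_Aa: float = 0.0    #: non-growth acetate coefficient, g/g DCW/h
    Y_X: float = 0.812      #: biomass yield on glucose, g/g
    Y_Ba: float = 0.973     #: butyrate yield factor, g/g
    Y_Aa: float = 0.997     #: acetate yield factor, g/g
    m_S: float = 0.015      #: maintenance coefficient, 1/h

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{f.name} must be finite and nonnegative, got {v}")
        for name in ("mu_m", "K_S", "K_I", "P_d"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    def replace(self, **updates: float) -> "KineticParams":
        """Return a copy with the given fields replaced."""
        d = asdict(self)
        d.update(updates)
        return KineticParams(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "KineticParams":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**{k: float(v) for k, v in raw.items()})


@dataclass(frozen=True)
class FermentationState:
    """Instantaneous state of a batch: time plus the four concentrations."""

    t: float        #: time, h
    X: float        #: biomass, g/L DCW
    S: float        #: glucose, g/L
    P_Ba: float     #: butyric acid, g/L
    P_Aa: float     #: acetic acid, g/L

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValueError("time must be nonnegative")
        for name in ("X", "S", "P_Ba", "P_Aa"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def total_acid(self) -> float:
        return self.P_Ba + self.P_Aa

    def as_vector(self) -> np.ndarray:
        return np.array([self.X, self.S, self.P_Ba, self.P_Aa])


@dataclass
class TimeCourse:
    """Sampled batch trajectory.

    `states` is ordered in time and starts at `initial`.
    """

    states: list[FermentationState]
    params_used: KineticParams
    initial: FermentationState

    def __post_init__(self) -> None:
        t = self.times
        if len(t) and not np.all(np.diff(t) > 0):
            raise ValueError("state times must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return np.array([s.t for s in self.states])

    def as_array(self) -> np.ndarray:
        """(n_times, 4) array of columns X, S, P_Ba, P_Aa."""
        return np.array([[s.X, s.S, s.P_Ba, s.P_Aa] for s in self.states])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_h": self.times,
                "X_gL": [s.X for s in self.states],
                "S_gL": [s.S for s in self.states],
                "butyrate_gL": [s.P_Ba for s in self.states],
                "acetate_gL": [s.P_Aa for s in self.states],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls, path: str | Path, params: KineticParams | None = None
    ) -> "TimeCourse":
        df = pd.read_csv(path)
        states = [
            FermentationState(
                t=row.t_h, X=row.X_gL, S=row.S_gL,
                P_Ba=row.butyrate_gL, P_Aa=row.acetate_gL,
            )
            for row in df.itertuples()
        ]
        return cls(states=states, params_used=params or KineticParams(),
                   initial=states[0])


def specific_growth_rate(
    params: KineticParams, S: float, P: float, *, include_product_inhibition: bool = True
) -> float:
    """Specific growth rate mu (1/h) at substrate S and inhibitory product P.

    Haldane kinetics in S with a (1 - P/P_d)^i product-inhibition factor.
    The inhibition base is clamped at zero before exponentiation: with a
    non-integer exponent a negative base is undefined, and physically growth
    is simply shut off once total acid reaches P_d.
    """
    if not (math.isfinite(S) and math.isfinite(P)) or S < 0 or P < 0:
        raise ValueError(f"S and P must be finite and nonnegative, got S={S}, P={P}")
    if S == 0.0:
        return 0.0
    haldane = params.mu_m * S / (S + params.K_S + S * S / params.K_I)
    if not include_product_inhibition:
        return haldane
    base = max(1.0 - P / params.P_d, 0.0)
    return haldane * base**params.i


def haldane_optimum(params: KineticParams) -> dict[str, float]:
    """Substrate level maximizing growth under Haldane kinetics.

    Returns S_opt = sqrt(K_S * K_I) and mu_opt = mu(S_opt) at zero product,
    with mu_opt = mu_m / (1 + 2*sqrt(K_S/K_I)) in closed form.
    """
    s_opt = math.sqrt(params.K_S * params.K_I)
    mu_opt = specific_growth_rate(params, s_opt, 0.0)
    return {"S_opt": s_opt, "mu_opt": mu_opt}


def ode_rhs(
    params: KineticParams,
    state: FermentationState,
    *,
    inhibition: str = "total",
) -> tuple[float, float, float, float]:
    """Time derivatives (dX/dt, dS/dt, dP_Ba/dt, dP_Aa/dt) at `state`.

    `inhibition` selects which product pool enters the growth-inhibition
    factor: "total" (default; P = P_Ba + P_Aa, the critical threshold P_d
    being a total-acid concentration) or "butyrate" (P = P_Ba only).

    Once glucose is exhausted (S = 0) all substrate-consuming fluxes stop:
    growth and both product-formation rates are zero and biomass only decays
    at rate K_d.
    """
    return _rhs(params, state.X, state.S, state.P_Ba, state.P_Aa, inhibition)


def _rhs(
    params: KineticParams,
    X: float, S: float, P_Ba: float, P_Aa: float,
    inhibition: str,
) -> tuple[float, float, float, float]:
    if inhibition not in ("total", "butyrate"):
        raise ValueError(f"unknown inhibition mode {inhibition!r}")
    X = max(X, 0.0)
    S = max(S, 0.0)
    P_Ba = max(P_Ba, 0.0)
    P_Aa = max(P_Aa, 0.0)
    if X == 0.0:
        return (0.0, 0.0, 0.0, 0.0)
    if S == 0.0:
        return (-params.K_d * X, 0.0, 0.0, 0.0)
    P = P_Ba + P_Aa if inhibition == "total" else P_Ba
    mu = specific_growth_rate(params, S, P)
    dX = (mu - params.K_d) * X
    growth = max(dX, 0.0)  # biomass decay neither makes product nor frees glucose
    # substrate-availability ramp: exactly 1 above the exhaustion layer
    avail = min(S / _S_EXHAUST_LAYER, 1.0)
    dP_Ba = params.alpha_Ba * growth + params.beta_Ba * X * avail
    dP_Aa = params.alpha_Aa * growth + params.beta_Aa * X * avail
    dS = -(growth / params.Y_X + dP_Ba / params.Y_Ba + dP_Aa / params.Y_Aa
           + params.m_S * X * avail)
    return (dX, dS, dP_Ba, dP_Aa)


class SimulationError(RuntimeError):
    """ODE integration failed; carries the last valid state."""

    def __init__(self, message: str, last_state: FermentationState | None = None):
        super().__init__(message)
        self.last_state = last_state


def simulate_batch(
    params: KineticParams,
    initial: FermentationState,
    t_end: float,
    t_eval: Sequence[float] | None = None,
    *,
    inhibition: str = "total",
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> TimeCourse:
    """Integrate the batch model from `initial` to `t_end` hours.

    Returns states at `t_eval` (default: 121 evenly spaced points including
    t=0). Nonnegativity of all state variables is preserved: fluxes shut off
    at zero substrate/biomass inside the right-hand side and output values
    are clipped of solver-level negative round-off (magnitude below atol).
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if t_eval is None:
        t_eval = np.linspace(0.0, t_end, 121)
    t_eval = np.asarray(t_eval, dtype=float)
    if t_eval[0] != initial.t:
        t_eval = np.concatenate([[initial.t], t_eval])

    def rhs(t: float, y: np.ndarray) -> list[float]:
        return list(_rhs(params, y[0], y[1], y[2], y[3], inhibition))

    sol = solve_ivp(
        rhs,
        (initial.t, t_end),
        initial.as_vector(),
        t_eval=t_eval,
        method=method,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        last = None
        if sol.y.size:
            yl = np.clip(sol.y[:, -1], 0.0, None)
            last = FermentationState(sol.t[-1], *yl)
        raise SimulationError(f"ODE solver failed: {sol.message}", last)
    y = np.clip(sol.y, 0.0, None)
    states = [
        FermentationState(t=float(t), X=float(x), S=float(s),
                          P_Ba=float(pb), P_Aa=float(pa))
        for t, x, s, pb, pa in zip(sol.t, y[0], y[1], y[2], y[3])
    ]
    return TimeCourse(states=states, params_used=params, initial=states[0])


@dataclass(frozen=True)
class StoichiometricYields:
    """Theoretical mass yields per gram glucose and molar gas yields.

    From the fermentation stoichiometry
    glucose -> butyrate + 2 H2 + 2 CO2 and
    glucose + 2 H2O -> 2 acetate + 4 H2 + 2 CO2.
    """

    butyrate_g_per_g: float
    acetate_g_per_g: float
    h2_mol_per_mol_butyrate_route: float = 2.0
    co2_mol_per_mol_butyrate_route: float = 2.0
    h2_mol_per_mol_acetate_route: float = 4.0
    co2_mol_per_mol_acetate_route: float = 2.0


def stoichiometric_yields() -> StoichiometricYields:
    """Theoretical maximum product yields from glucose, by molar mass.

    Butyrate: M(C4H8O2)/M(C6H12O6) ~= 0.489 g/g.
    Acetate: 2*M(C2H4O2)/M(C6H12O6) ~= 0.667 g/g.
    """
    m_glc = _molar_mass({"C": 6, "H": 12, "O": 6})
    m_but = _molar_mass({"C": 4, "H": 8, "O": 2})
    m_ace = _molar_mass({"C": 2, "H": 4, "O": 2})
    return StoichiometricYields(
        butyrate_g_per_g=m_but / m_glc,
        acetate_g_per_g=2.0 * m_ace / m_glc,
    )
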