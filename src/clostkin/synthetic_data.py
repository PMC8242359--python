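"""Synthetic-data generators and packaged reference fixtures.

The generators produce inputs with exactly the statistical structure the
analyses assume: binomial dead-colony counts under the logistic dose model,
and batch time courses from the kinetic ODE with multiplicative (or
additive) Gaussian observation noise. All randomness flows through explicit
integer seeds — there is no global RNG state.

`load_fixture` returns typed objects for the three packaged reference
tables: per-dose irradiation survival counts ("table2"), mutant screening
productivities ("table3"), and the fitted kinetic parameter set ("table4").
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .dose_response import LogisticParams, SurvivalRecord, SurvivalTable, lethality_prob
from .ferm_kinetics import FermentationState, KineticParams, TimeCourse, simulate_batch
from .mutant_screening import ScreeningRecord

__all__ = [
    "DoseDesign",
    "NoiseModel",
    "generate_survival_table",
    "generate_timecourse",
    "load_fixture",
    "FIXTURE_NAMES",
]

FIXTURE_NAMES = ("table2", "table3", "table4")

#: irradiation doses (Gy) of the reference survival design
_REFERENCE_DOSES = (50.0, 55.0, 60.0, 65.0, 70.0, 75.0, 80.0)
#: approximate colonies per dose in the reference design
_REFERENCE_N = 6000


@dataclass
class DoseDesign:
    """Design of a synthetic irradiation experiment.

    Defaults copy the reference survival study: seven doses from 50 to
    80 Gy with roughly 6,000 colonies per dose, so statistical power of
    downstream fits is realistic.
    """

    doses: Sequence[float] = _REFERENCE_DOSES
    n_per_dose: Sequence[int] | int = _REFERENCE_N
    true_params: LogisticParams = field(
        default_factory=lambda: LogisticParams(beta0=-50.0, beta1=28.0)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.doses):
            raise ValueError("doses must be positive")
        ns = self.counts
        if any(n < 1 for n in ns):
            raise ValueError("n_per_dose must be >= 1")

    @property
    def counts(self) -> list[int]:
        if isinstance(self.n_per_dose, int):
            return [self.n_per_dose] * len(self.doses)
        return list(self.n_per_dose)


@dataclass(frozen=True)
class NoiseModel:
    """Observation-noise layer for generated fermentation trajectories.

    kind "multiplicative-Gaussian": y_obs = y * (1 + sigma*eps);
    kind "additive-Gaussian": y_obs = y + sigma*eps; eps ~ N(0,1) i.i.d.
    per variable and time point. Values are clamped at zero. sigma = 0
    returns the exact simulation.
    """

    kind: str = "multiplicative-Gaussian"
    sigma: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        if self.kind not in ("multiplicative-Gaussian", "additive-Gaussian"):
            raise ValueError(f"unknown noise kind {self.kind!r}")


def generate_survival_table(design: DoseDesign, sample_id: str = "synthetic") -> SurvivalTable:
    """Draw binomial dead-colony counts under the logistic dose model.

    For each dose d, n_lethal ~ Binomial(n, p) with
    p = lethality_prob(true_params, log10 d). Deterministic under a fixed
    design seed.
    """
    rng = np.random.default_rng(design.seed)
    records = []
    for dose, n in zip(design.doses, design.counts):
        p = float(lethality_prob(design.true_params, np.log10(dose)))
        k = int(rng.binomial(n, p))
        records.append(SurvivalRecord(dose=float(dose), n_total=n, n_lethal=k))
    return SurvivalTable(sample_id=sample_id, records=records)


def generate_timecourse(
    params: KineticParams,
    initial: FermentationState,
    t_eval: Sequence[float],
    noise: NoiseModel,
    *,
    inhibition: str = "total",
) -> TimeCourse:
    """Simulate a batch and overlay observation noise.

    Noise is applied independently per variable and time point; the initial
    state is observed noisily too (its true value is known to the
    generator, not the analyst). Clamped at zero so concentrations stay
    physical.
    """
    t_eval = np.asarray(t_eval, dtype=float)
    clean = simulate_batch(
        params, initial, t_end=float(t_eval[-1]), t_eval=t_eval, inhibition=inhibition
    )
    if noise.sigma == 0:
        return clean
    rng = np.random.default_rng(noise.seed)
    y = clean.as_array()
    eps = rng.standard_normal(y.shape)
    if noise.kind == "multiplicative-Gaussian":
        y_obs = y * (1.0 + noise.sigma * eps)
    else:
        y_obs = y + noise.sigma * eps
    y_obs = np.clip(y_obs, 0.0, None)
    states = [
        FermentationState(t=float(t), X=float(r[0]), S=float(r[1]),
                          P_Ba=float(r[2]), P_Aa=float(r[3]))
        for t, r in zip(clean.times, y_obs)
    ]
    return TimeCourse(states=states, params_used=params, initial=states[0])


def _data_path(filename: str) -> Path:
    return Path(importlib.resources.files("clostkin") / "data" / filename)


def load_fixture(name: str):
    """Load a packaged reference table as typed, validated objects.

    * "table2" -> dict sample_id -> SurvivalTable (irradiation survival
      counts at 50-80 Gy for three samples). One transcription repair: the
      H51-8 / 55 Gy lethal count is stored as 2,070 (= 5,500 total minus
      the 3,430 survivors) because the source prints the survivor count in
      the lethal column, contradicting its own survival proportion 0.6236
      and dose-monotonicity; the printed proportion is retained in the
      printed_survival_prop column.
    * "table3" -> list[ScreeningRecord] plus footer counts in the list's
      `.counts`-free companion: returns (records, {"P": 24, "M": 81,
      "T": 409}). Printed delta ratios are transcribed verbatim, including
      rows whose ratio disagrees with their own productivities (see
      mutant_screening.delta_mismatch_log).
    * "table4" -> KineticParams (the fitted kinetic parameter set).
    """
    if name == "table2":
        return SurvivalTable.all_samples_from_csv(_data_path("table2_survival.csv"))
    if name == "table3":
        df = pd.read_csv(_data_path("table3_screening.csv"))
        records = [
            ScreeningRecord(
                sample_id=str(r.sample_id),
                r_butyric=float(r.r_butyric),
                r_butyric_sd=float(r.r_butyric_sd),
                r_acetic=float(r.r_acetic),
                r_acetic_sd=float(r.r_acetic_sd),
                printed_delta=float(r.printed_delta),
            )
            for r in df.itertuples()
        ]
        return records, {"P": 24, "M": 81, "T": 409}
    if name == "table4":
        raw = yaml.safe_load(_data_path("table4_params.yaml").read_text())
        return KineticParams(**{k: float(v) for k, v in raw.items()})
    raise ValueError(f"unknown fixture {name!r}; expected one of {FIXTURE_NAMES}")
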