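"""Binomial-logistic modeling of cell-strain lethality versus irradiation dose.

Colonies irradiated at dose d (Gy) die with probability p(x) where
x = log10(d) and logit(p) = beta0 + beta1 * x. Observed dead counts are
binomial per dose, so the model is an ordinary logistic regression on
grouped counts, fit here by direct maximization of the binomial
log-likelihood. Survival is 1 - p throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit
from scipy.stats import binom

from ._rounding import round_half_up

__all__ = [
    "SurvivalRecord",
    "SurvivalTable",
    "LogisticParams",
    "LogisticFit",
    "lethality_prob",
    "binomial_loglik",
    "fit_mle",
    "survival_summary",
    "pool_tables",
]


@dataclass(frozen=True)
class LogisticParams:
    """Logistic regression parameters on the logit scale.

    beta0 is the intercept; beta1 the slope per unit log10-dose
    (1 / log10 Gy).
    """

    beta0: float
    beta1: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.beta0) and math.isfinite(self.beta1)):
            raise ValueError("logistic parameters must be finite")


@dataclass(frozen=True)
class SurvivalRecord:
    """Binomial outcome of one irradiation test at a single dose."""

    dose: float      #: irradiation dose, Gy
    n_total: int     #: colonies irradiated
    n_lethal: int    #: colonies killed

    def __post_init__(self) -> None:
        if self.dose <= 0:
            raise ValueError("dose must be positive")
        if not 0 <= self.n_lethal <= self.n_total:
            raise ValueError("need 0 <= n_lethal <= n_total")
        if self.n_total <= 0:
            raise ValueError("n_total must be positive")

    @property
    def log_dose(self) -> float:
        """Base-10 log of the dose — the regression covariate."""
        return math.log10(self.dose)

    @property
    def survival_prop(self) -> float:
        return (self.n_total - self.n_lethal) / self.n_total


@dataclass
class SurvivalTable:
    """Ordered per-dose survival counts for one irradiated sample."""

    sample_id: str
    records: list[SurvivalRecord]

    def __post_init__(self) -> None:
        doses = [r.dose for r in self.records]
        if len(doses) >= 2 and not all(a < b for a, b in zip(doses, doses[1:])):
            raise ValueError("doses must be strictly increasing")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def doses(self) -> np.ndarray:
        return np.array([r.dose for r in self.records])

    @property
    def log_doses(self) -> np.ndarray:
        return np.array([r.log_dose for r in self.records])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_id,
                "dose_gy": [r.dose for r in self.records],
                "n_total": [r.n_total for r in self.records],
                "n_lethal": [r.n_lethal for r in self.records],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, sample_id: str | None = None) -> "SurvivalTable":
        """Read one sample's counts from `sample_id,dose_gy,n_total,n_lethal` CSV.

        Log-dose and survival proportions are always derived, never read.
        """
        df = pd.read_csv(path)
        if sample_id is not None:
            df = df[df["sample_id"] == sample_id]
            if df.empty:
                raise ValueError(f"sample {sample_id!r} not found in {path}")
        elif df["sample_id"].nunique() > 1:
            raise ValueError("multiple samples in file; pass sample_id")
        df = df.sort_values("dose_gy")
        records = [
            SurvivalRecord(dose=float(r.dose_gy), n_total=int(r.n_total),
                           n_lethal=int(r.n_lethal))
            for r in df.itertuples()
        ]
        return cls(sample_id=str(df["sample_id"].iloc[0]), records=records)

    @classmethod
    def all_samples_from_csv(cls, path: str | Path) -> dict[str, "SurvivalTable"]:
        df = pd.read_csv(path)
        return {
            sid: cls.from_csv(path, sample_id=sid)
            for sid in df["sample_id"].unique()
        }


def pool_tables(tables: list[SurvivalTable], sample_id: str = "pooled") -> SurvivalTable:
    """Merge counts across samples dose-by-dose (sum of totals and lethals)."""
    acc: dict[float, list[int]] = {}
    for t in tables:
        for r in t.records:
            tot, let = acc.setdefault(r.dose, [0, 0])
            acc[r.dose] = [tot + r.n_total, let + r.n_lethal]
    records = [
        SurvivalRecord(dose=d, n_total=tot, n_lethal=let)
        for d, (tot, let) in sorted(acc.items())
    ]
    return SurvivalTable(sample_id=sample_id, records=records)


def lethality_prob(params: LogisticParams, log_dose: float) -> float:
    """Lethality probability p = expit(beta0 + beta1 * log_dose), in (0,1)."""
    if not np.all(np.isfinite(log_dose)):
        raise ValueError("log_dose must be finite")
    return expit(params.beta0 + params.beta1 * np.asarray(log_dose, dtype=float))[()]


def binomial_loglik(
    params: LogisticParams,
    table: SurvivalTable,
    covariate: Literal["log10", "dose"] = "log10",
) -> float:
    """Binomial log-likelihood of the table under the logistic dose model.

    Sum over doses of log C(n,k) + k*log(p) + (n-k)*log(1-p); the binomial
    coefficient is included both here and in reported -2*loglik so the two
    are directly comparable. Returns -inf (never raises) when a fitted p
    of numerically 0 or 1 contradicts the observed counts.
    """
    x = table.log_doses if covariate == "log10" else table.doses
    n = np.array([r.n_total for r in table.records])
    k = np.array([r.n_lethal for r in table.records])
    p = expit(params.beta0 + params.beta1 * x)
    return float(np.sum(binom.logpmf(k, n, p)))


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit with diagnostics."""

    params: LogisticParams
    neg2_loglik: float
    converged: bool
    separation_flag: bool   #: data (near-)perfectly separated; estimates unstable
    n_records: int
    covariate: str
    table: SurvivalTable = field(repr=False)

    def lethality_at(self, dose: float) -> float:
        x = math.log10(dose) if self.covariate == "log10" else dose
        return float(lethality_prob(self.params, x))

    def survival_at(self, dose: float) -> float:
        return 1.0 - self.lethality_at(dose)

    def fitted_frame(self) -> pd.DataFrame:
        """Per-dose observed and fitted lethality/survival."""
        return pd.DataFrame(
            {
                "dose_gy": self.table.doses,
                "observed_survival": [r.survival_prop for r in self.table.records],
                "fitted_lethality": [self.lethality_at(d) for d in self.table.doses],
                "fitted_survival": [self.survival_at(d) for d in self.table.doses],
            }
        )


def _empirical_logit_start(
    table: SurvivalTable, x: np.ndarray
) -> tuple[float, float]:
    # OLS on empirical logits; 0.5 continuity correction keeps the all-die
    # and all-survive rows usable for initialization.
    n = np.array([r.n_total for r in table.records], dtype=float)
    k = np.array([r.n_lethal for r in table.records], dtype=float)
    p = (k + 0.5) / (n + 1.0)
    z = np.log(p / (1.0 - p))
    slope, intercept = np.polyfit(x, z, 1)
    return float(intercept), float(slope)


def fit_mle(
    table: SurvivalTable,
    covariate: Literal["log10", "dose"] = "log10",
) -> LogisticFit:
    """Fit the binomial-logistic dose model by maximum likelihood.

    Initialization is ordinary least squares on continuity-corrected
    empirical logits, refined by Nelder-Mead on the exact binomial
    log-likelihood (all rows retained, including 0% and 100% survival).
    Complete separation is flagged, not raised: the likelihood then has no
    interior maximum and the returned estimates are boundary-chasing.
    """
    if len({r.dose for r in table.records}) < 2:
        raise ValueError("need at least 2 distinct doses to fit")
    props = {r.n_lethal / r.n_total for r in table.records}
    if props <= {0.0} or props <= {1.0}:
        raise ValueError("degenerate table: identical all-survive/all-die outcome at every dose")

    x = table.log_doses if covariate == "log10" else table.doses
    b0, b1 = _empirical_logit_start(table, x)

    def nll(beta: np.ndarray) -> float:
        ll = binomial_loglik(LogisticParams(*beta), table, covariate)
        return -ll if math.isfinite(ll) else 1e300

    res = optimize.minimize(
        nll, x0=[b0, b1], method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 5000},
    )
    params = LogisticParams(*res.x)
    # Separation heuristic: fitted probabilities pinned to 0/1 at every dose.
    p_hat = expit(params.beta0 + params.beta1 * x)
    separated = bool(np.all((p_hat < 1e-8) | (p_hat > 1 - 1e-8)))
    return LogisticFit(
        params=params,
        neg2_loglik=2.0 * res.fun,
        converged=bool(res.success),
        separation_flag=separated,
        n_records=len(table),
        covariate=covariate,
        table=table,
    )


def survival_summary(table: SurvivalTable) -> pd.DataFrame:
    """Per-dose survival proportions, reported to 4 decimals (half-up).

    Returns a frame with raw and rounded proportions plus `min`/`max`
    attributes over the nonzero entries (in attrs: survival_range).
    """
    rows = []
    for r in table.records:
        raw = r.survival_prop
        rows.append(
            {
                "dose_gy": r.dose,
                "log_dose": round_half_up(r.log_dose, 4),
                "n_total": r.n_total,
                "n_lethal": r.n_lethal,
                "survival_prop": round_half_up(raw, 4),
                "survival_prop_raw": raw,
            }
        )
    df = pd.DataFrame(rows)
    nonzero = df.loc[df["survival_prop_raw"] > 0, "survival_prop_raw"]
    df.attrs["survival_range"] = (
        (float(nonzero.min()), float(nonzero.max())) if len(nonzero) else (0.0, 0.0)
    )
    return df
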