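"""Mutant screening arithmetic: acid-ratio classification and MTT survival.

After mutagenesis, colonies are screened by their butyric and acetic acid
specific productivities. The butyrate:acetate ratio delta = R_butyric /
R_acetic is compared against the wild-type baseline (3.05): a strictly
larger ratio calls the colony a "positive" (improved) mutant. Group-level
screening rates R_M/T and R_P/T are simple percentages of the colony
totals. The MTT viability assay's survival fraction is 2^(-T_delay /
T_doubling).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import pandas as pd

from ._rounding import round_half_up, truncate

__all__ = [
    "ScreeningRecord",
    "ScreeningSummary",
    "MttMeasurement",
    "WILD_TYPE_DELTA",
    "delta_ratio",
    "classify_mutant",
    "screening_rates",
    "mtt_survival_fraction",
    "delta_mismatch_log",
    "read_screening_csv",
]

#: wild-type butyrate:acetate productivity ratio used as the call threshold
WILD_TYPE_DELTA = 3.05


def delta_ratio(r_butyric: float, r_acetic: float) -> float:
    """Butyrate:acetate productivity ratio, reported to 2 decimals (half-up).

    Keep the raw quotient via ScreeningRecord.delta_raw when the unrounded
    value matters.
    """
    if r_acetic <= 0:
        raise ValueError("r_acetic must be positive")
    if r_butyric < 0:
        raise ValueError("r_butyric must be nonnegative")
    return round_half_up(r_butyric / r_acetic, 2)


def classify_mutant(
    delta: float, wild_type_delta: float = WILD_TYPE_DELTA
) -> Literal["positive", "negative"]:
    """Positive iff delta strictly exceeds the wild-type ratio; ties negative."""
    if delta <= 0 or wild_type_delta <= 0:
        raise ValueError("ratios must be positive")
    return "positive" if delta > wild_type_delta else "negative"


@dataclass(frozen=True)
class ScreeningRecord:
    """Productivities and derived call for one screened colony."""

    sample_id: str
    r_butyric: float            #: butyric acid specific productivity, g/L
    r_acetic: float             #: acetic acid specific productivity, g/L
    r_butyric_sd: float = 0.0
    r_acetic_sd: float = 0.0
    printed_delta: float | None = None  #: ratio as printed in the source table

    def __post_init__(self) -> None:
        if self.r_acetic <= 0:
            raise ValueError("r_acetic must be positive")
        if self.r_butyric < 0:
            raise ValueError("r_butyric must be nonnegative")

    @property
    def delta_raw(self) -> float:
        return self.r_butyric / self.r_acetic

    @property
    def delta(self) -> float:
        return delta_ratio(self.r_butyric, self.r_acetic)

    @property
    def call(self) -> str:
        return classify_mutant(self.delta)


@dataclass(frozen=True)
class MttMeasurement:
    """MTT assay timing: delay to reference absorbance and doubling time (h)."""

    t_delay: float
    t_doubling: float

    def __post_init__(self) -> None:
        if self.t_delay < 0:
            raise ValueError("t_delay must be nonnegative")
        if self.t_doubling <= 0:
            raise ValueError("t_doubling must be positive")


def mtt_survival_fraction(m: MttMeasurement) -> float:
    """Survival fraction 2^(-T_delay / T_doubling), in (0, 1]."""
    return 2.0 ** (-m.t_delay / m.t_doubling)


@dataclass(frozen=True)
class ScreeningSummary:
    """Group-level screening rates from colony totals."""

    n_total_T: int
    n_positive_subtotal_P: int
    n_subtotal_M: int
    rate_M_over_T: float    #: percent, reported rounding applied
    rate_P_over_T: float
    rate_M_over_T_raw: float
    rate_P_over_T_raw: float


def screening_rates(
    P: int, M: int, T: int, rounding: Literal["half_up", "truncate"] = "half_up"
) -> ScreeningSummary:
    """Percent rates R_M/T = 100*M/T and R_P/T = 100*P/T, 1 decimal.

    `rounding="truncate"` drops the second decimal instead of rounding;
    source tables occasionally print truncated rates (24/409 = 5.87%
    appearing as 5.8%), so both conventions are available and the raw
    percentages are always retained.
    """
    if T <= 0:
        raise ValueError("T must be positive")
    if not (0 <= P <= T and 0 <= M <= T):
        raise ValueError("need 0 <= P, M <= T")
    rm, rp = 100.0 * M / T, 100.0 * P / T
    rounder = round_half_up if rounding == "half_up" else truncate
    return ScreeningSummary(
        n_total_T=T, n_positive_subtotal_P=P, n_subtotal_M=M,
        rate_M_over_T=rounder(rm, 1), rate_P_over_T=rounder(rp, 1),
        rate_M_over_T_raw=rm, rate_P_over_T_raw=rp,
    )


def delta_mismatch_log(
    records: list[ScreeningRecord], tol: float = 0.03
) -> pd.DataFrame:
    """Compare recomputed ratios against printed ones; flag disagreements.

    Printed screening tables are not always self-consistent (a printed
    ratio can disagree with the quotient of its own row's productivities);
    mismatches beyond `tol` are reported rather than silently corrected.
    """
    rows = []
    for r in records:
        if r.printed_delta is None:
            continue
        recomputed = r.delta
        rows.append(
            {
                "sample_id": r.sample_id,
                "printed_delta": r.printed_delta,
                "recomputed_delta": recomputed,
                "abs_diff": abs(recomputed - r.printed_delta),
                "mismatch": abs(recomputed - r.printed_delta) > tol,
            }
        )
    return pd.DataFrame(rows)


def read_screening_csv(path: str | Path) -> list[ScreeningRecord]:
    """Read colonies from `sample_id,r_butyric,r_butyric_sd,r_acetic,r_acetic_sd`.

    An optional `printed_delta` column carries ratios transcribed from a
    source table for mismatch logging.
    """
    df = pd.read_csv(path)
    out = []
    for row in df.itertuples():
        printed = getattr(row, "printed_delta", None)
        if printed is not None and (isinstance(printed, float) and math.isnan(printed)):
            printed = None
        out.append(
            ScreeningRecord(
                sample_id=str(row.sample_id),
                r_butyric=float(row.r_butyric),
                r_acetic=float(row.r_acetic),
                r_butyric_sd=float(getattr(row, "r_butyric_sd", 0.0) or 0.0),
                r_acetic_sd=float(getattr(row, "r_acetic_sd", 0.0) or 0.0),
                printed_delta=None if printed is None else float(printed),
            )
        )
    return out
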