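"""Decile-based calibration of predicted against observed 5-year risk.

Persons are ranked by predicted risk and cut into ten near-equal groups.
Within each decile the mean predicted risk is compared with the observed
risk — the Kaplan-Meier cumulative incidence at the horizon — and the
calibration statistic is the observed:predicted ratio.  Its unweighted
arithmetic mean across the ten deciles is the headline measure of
under-prediction: a mean ratio of 1.3 means observed events ran 30% above
what the equation predicted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError
from .survival import km_curve, risk_at

N_DECILES = 10


def decile_assign(predicted: pd.Series | np.ndarray,
                  person_ids=None) -> np.ndarray:
    """Rank-based assignment into 10 near-equal groups (labels 1..10).

    Ties are broken by stable ordering on (risk, person_id) so the
    partition is reproducible; group sizes differ by at most one, with the
    earlier deciles taking the remainder.
    """
    risks = np.asarray(predicted, dtype=float)
    n = risks.size
    if n < N_DECILES:
        raise DataError(f"decile assignment needs at least {N_DECILES} persons, got {n}")
    if person_ids is None:
        person_ids = np.arange(n)
    ids = np.asarray(person_ids)
    order = np.lexsort((ids, risks))  # primary: risk, secondary: person_id
    sizes = np.full(N_DECILES, n // N_DECILES)
    sizes[: n % N_DECILES] += 1
    labels = np.empty(n, dtype=int)
    labels[order] = np.repeat(np.arange(1, N_DECILES + 1), sizes)
    return labels


@dataclass
class CalibrationTable:
    """Per-decile calibration rows plus the summary mean ratio.

    ``table`` columns: decile, n, mean_predicted, observed, lower, upper,
    ratio, zero_events.  A decile with no observed events keeps ratio 0 and
    is flagged rather than dropped.
    """

    table: pd.DataFrame
    horizon_years: float
    population: str = ""

    @property
    def mean_ratio(self) -> float:
        """Unweighted arithmetic mean of the 10 decile observed:predicted ratios."""
        return float(self.table["ratio"].mean())

    @property
    def person_weighted_ratio(self) -> float:
        """Person-weighted companion statistic (not the headline measure)."""
        w = self.table["n"].to_numpy(dtype=float)
        return float(np.average(self.table["ratio"], weights=w))


def calibration_table(
    predicted: pd.Series | np.ndarray,
    times: pd.Series | np.ndarray,
    events: pd.Series | np.ndarray,
    person_ids=None,
    horizon: float = 5.0,
    population: str = "",
) -> CalibrationTable:
    """Observed vs predicted risk in deciles of predicted risk.

    ``predicted``: per-person absolute risk at the horizon; ``times`` /
    ``events``: follow-up time in years and the CVD event indicator
    (censoring = False).  Observed risk per decile comes from the decile's
    own Kaplan-Meier curve evaluated at the horizon.
    """
    risks = np.asarray(predicted, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if not (risks.size == t.size == e.size):
        raise DataError("predicted, times and events must have equal length")
    labels = decile_assign(risks, person_ids)

    rows = []
    for d in range(1, N_DECILES + 1):
        mask = labels == d
        mean_pred = float(risks[mask].mean())
        curve = km_curve(t[mask], e[mask])
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")  # horizon beyond a decile's follow-up is expected
            observed, (lo, hi) = risk_at(curve, horizon)
        zero_events = not e[mask].any()
        ratio = 0.0 if observed <= 0 else observed / mean_pred
        rows.append(
            {
                "decile": d,
                "n": int(mask.sum()),
                "mean_predicted": mean_pred,
                "observed": observed,
                "lower": lo,
                "upper": hi,
                "ratio": ratio,
                "zero_events": zero_events,
            }
        )
    return CalibrationTable(
        table=pd.DataFrame(rows), horizon_years=horizon, population=population
    )


def mean_ratio(table: CalibrationTable) -> float:
    """Summary statistic: unweighted mean of the ten decile ratios."""
    return table.mean_ratio
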