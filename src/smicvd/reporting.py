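"""Descriptive tables stratified by sex and mental-health exposure group.

Strata follow the paper-style layout: within each sex, all persons with an
SMI history, the schizophrenia/bipolar (functional psychosis) subgroup,
and persons with no mental-health service history.  Percentages are
rounded half-up to one decimal; a categorical variable's counts always sum
to the stratum total (missing values get their own row where the variable
is nullable).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

BMI_BANDS = (
    ("BMI <25", lambda b: b < 25),
    ("BMI 25-29", lambda b: (b >= 25) & (b < 30)),
    ("BMI 30-34", lambda b: (b >= 30) & (b < 35)),
    ("BMI 35-39", lambda b: (b >= 35) & (b < 40)),
    ("BMI 40+", lambda b: b >= 40),
)

AGE_BANDS_DESCRIPTIVE = (("30-44", 30, 44), ("45-54", 45, 54),
                         ("55-64", 55, 64), ("65-74", 65, 74))

GROUPS = ("smi", "psychosis", "no_mh")


def percentage(numerator: float, denominator: float) -> float:
    """Percentage rounded half-up to one decimal; NaN when the denominator is zero."""
    if denominator == 0:
        return float("nan")
    pct = Decimal(numerator) / Decimal(denominator) * 100
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def elevated_bp(sbp, dbp):
    """Elevated blood pressure: SBP > 120 mmHg or DBP > 90 mmHg."""
    return (np.asarray(sbp, dtype=float) > 120) | (np.asarray(dbp, dtype=float) > 90)


@dataclass
class DescriptiveTable:
    """Tidy long table: one row per (sex, group, variable, statistic)."""

    table: pd.DataFrame

    def cell(self, sex: str, group: str, variable: str):
        rows = self.table[
            (self.table["sex"] == sex)
            & (self.table["group"] == group)
            & (self.table["variable"] == variable)
        ]
        return rows.iloc[0] if len(rows) else None


def _stratum_rows(df: pd.DataFrame, sex: str, group: str) -> list[dict]:
    total = len(df)

    def count_row(variable: str, mask) -> dict:
        n = int(np.asarray(mask).sum()) if total else 0
        return {
            "sex": sex, "group": group, "variable": variable,
            "n": n, "pct": percentage(n, total), "mean": np.nan, "sd": np.nan,
        }

    def mean_row(variable: str, values: pd.Series) -> dict:
        vals = pd.to_numeric(values, errors="coerce").dropna()
        return {
            "sex": sex, "group": group, "variable": variable,
            "n": int(len(vals)), "pct": np.nan,
            "mean": float(vals.mean()) if len(vals) else np.nan,
            "sd": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
        }

    rows = [
        {"sex": sex, "group": group, "variable": "Total", "n": total,
         "pct": np.nan, "mean": np.nan, "sd": np.nan}
    ]
    age = pd.to_numeric(df["age_at_index"], errors="coerce")
    for label, lo, hi in AGE_BANDS_DESCRIPTIVE:
        rows.append(count_row(f"Age {label}", (age >= lo) & (age <= hi)))
    for cat in ("maori", "pacific", "indian", "chinese_asian", "european_other"):
        rows.append(count_row(f"Ethnicity {cat}", df["ethnicity"] == cat))
    dep = pd.to_numeric(df["deprivation_quintile"], errors="coerce")
    for q in range(1, 6):
        rows.append(count_row(f"Deprivation quintile {q}", dep == q))
    for variable, col in (
        ("Family history of CVD", "family_history"),
        ("History of diabetes", "diabetes"),
        ("History of atrial fibrillation", "atrial_fibrillation"),
        ("Lipid lowering medication", "lipid_lowering"),
        ("BP lowering medication", "bp_lowering"),
        ("Antithrombotic medication", "antithrombotic"),
    ):
        rows.append(count_row(variable, df[col].astype(bool)))
    smoker = df["smoker_status"].astype("string")
    rows.append(count_row("Past smoker", smoker == "past"))
    rows.append(count_row("Current smoker", smoker == "current"))
    rows.append(count_row("Smoking status missing", smoker.isna() | (smoker == "")))

    bmi = pd.to_numeric(df["bmi"], errors="coerce")
    rows.append(mean_row("Mean BMI", bmi))
    for label, pred in BMI_BANDS:
        rows.append(count_row(label, pred(bmi)))  # NaN fails every band
    rows.append(count_row("BMI missing", bmi.isna()))

    tchdl = pd.to_numeric(df["tchdl"], errors="coerce")
    rows.append(mean_row("Mean TC:HDL", tchdl))
    rows.append(count_row("TC:HDL >4", tchdl > 4))
    rows.append(mean_row("Mean SBP", df["sbp"]))
    rows.append(mean_row("Mean DBP", df["dbp"]))
    rows.append(count_row("Elevated BP", elevated_bp(df["sbp"], df["dbp"])))
    if "event_type" in df.columns:
        rows.append(count_row("CVD events over follow up", df["event_type"] == "cvd"))
    return rows


def plot_calibration(table, path) -> None:
    """Save a calibration plot: observed (with CI bars) vs predicted risk by decile.

    ``table`` is a CalibrationTable; the diagonal marks perfect calibration
    (points above it mean the equation under-predicts).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = table.table
    fig, ax = plt.subplots(figsize=(5, 5))
    yerr = np.vstack([t["observed"] - t["lower"], t["upper"] - t["observed"]])
    ax.errorbar(100 * t["mean_predicted"], 100 * t["observed"],
                yerr=100 * np.clip(yerr, 0, None), fmt="o", capsize=3)
    lim = max(100 * t[["mean_predicted", "observed"]].to_numpy().max() * 1.1, 1.0)
    ax.plot([0, lim], [0, lim], color="tab:blue", lw=1)
    ax.set_xlabel("Mean predicted 5-year risk per decile (%)")
    ax.set_ylabel("Observed 5-year risk (%)")
    ax.set_title(table.population or "calibration")
    ax.set_xlim(0, lim)
    ax.set_ylim(0, lim)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def descriptive_table(eligible: pd.DataFrame) -> DescriptiveTable:
    """Build the stratified descriptive table from an eligible table with flags.

    Requires columns ``smi``/``psychosis`` (exposure flags) and
    ``ethnicity`` (prioritized), as produced by the cohort builder.  The
    psychosis stratum is a subset of the SMI stratum, mirroring the
    overlapping columns of the published layout.
    """
    rows: list[dict] = []
    for sex in ("F", "M"):
        sdf = eligible[eligible["sex"] == sex]
        strata = {
            "smi": sdf[sdf["smi"].astype(bool)],
            "psychosis": sdf[sdf["psychosis"].astype(bool)],
            "no_mh": sdf[~sdf["smi"].astype(bool)],
        }
        for group, gdf in strata.items():
            rows.extend(_stratum_rows(gdf, sex, group))
    return DescriptiveTable(table=pd.DataFrame(rows))
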