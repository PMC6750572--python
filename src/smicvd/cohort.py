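"""Cohort construction: eligibility cascade, exposure ascertainment, ethnicity.

Eligibility mirrors a primary-prevention risk-assessment cohort: ages 30-74
inclusive at the index assessment, no prior cardiovascular disease
(including heart failure) or renal failure, and non-missing smoking status
and TC:HDL ratio.  Persons failing several rules are counted once, at the
first rule in that order, so the flow accounting telescopes exactly.

Exposure (a history of severe mental illness, SMI) is ascertained from
service-contact records: any inpatient or face-to-face community contact
in the half-open five-year window [index - 5y, index) qualifies.  The
functional-psychosis subgroup additionally requires any contact, on any
date including after the index assessment, carrying an ICD-10 diagnosis in
the F20-F31 family.
"""

from __future__ import annotations

import logging
import re
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .errors import DataError, LinkageError

logger = logging.getLogger(__name__)

AGE_MIN = 30.0
AGE_MAX = 74.0

QUALIFYING_SETTINGS = frozenset({"inpatient", "community_face_to_face"})

#: Ethnicity categories in priority order (highest first).
ETHNICITY_PRIORITY = ("maori", "pacific", "indian", "chinese_asian", "european_other")

_ETHNICITY_ALIASES = {
    "maori": "maori",
    "pacific": "pacific",
    "indian": "indian",
    "chinese": "chinese_asian",
    "chinese_asian": "chinese_asian",
    "other_asian": "chinese_asian",
    "asian": "chinese_asian",
    "european": "european_other",
    "european_other": "european_other",
    "other": "european_other",
}

_ICD_F_CODE = re.compile(r"^F(\d{2})")


@dataclass
class CohortFlow:
    """Stage counts of the eligibility cascade; telescopes by construction."""

    assessed_total: int
    in_age_range: int
    excluded_prior_cvd_or_renal: int
    excluded_missing_smoking: int
    excluded_missing_cholesterol: int
    final_eligible: int

    def __post_init__(self) -> None:
        expected = (
            self.in_age_range
            - self.excluded_prior_cvd_or_renal
            - self.excluded_missing_smoking
            - self.excluded_missing_cholesterol
        )
        if self.final_eligible != expected or min(asdict(self).values()) < 0:
            raise DataError("cohort flow counts do not telescope")

    def to_dict(self) -> dict:
        return asdict(self)


def _require_non_null(persons: pd.DataFrame, column: str) -> None:
    null = persons[column].isna()
    if null.any():
        ids = persons.loc[null, "person_id"].astype(str).head(10).tolist()
        raise DataError(f"null {column} for persons {ids}")


def apply_exclusions(persons: pd.DataFrame) -> tuple[pd.DataFrame, CohortFlow]:
    """Apply the eligibility cascade and account for every exclusion.

    Order: age 30-74 inclusive, then prior CVD/renal failure, then missing
    smoking status, then missing TC:HDL.  Returns the eligible subset (a
    copy, original row order preserved) and the stage counts.
    """
    for col in ("age_at_index", "prior_cvd", "prior_renal_failure"):
        _require_non_null(persons, col)

    age = pd.to_numeric(persons["age_at_index"])
    in_age = (age >= AGE_MIN) & (age <= AGE_MAX)
    prior = persons["prior_cvd"].astype(bool) | persons["prior_renal_failure"].astype(bool)
    smoking_missing = persons["smoker_status"].isna() | (
        persons["smoker_status"].astype("string") == ""
    )
    chol_missing = pd.to_numeric(persons["tchdl"], errors="coerce").isna()

    # each person counted once, at the first failing rule
    stage2 = in_age & ~prior
    stage3 = stage2 & ~smoking_missing
    eligible_mask = stage3 & ~chol_missing

    flow = CohortFlow(
        assessed_total=len(persons),
        in_age_range=int(in_age.sum()),
        excluded_prior_cvd_or_renal=int((in_age & prior).sum()),
        excluded_missing_smoking=int((stage2 & smoking_missing).sum()),
        excluded_missing_cholesterol=int((stage3 & chol_missing).sum()),
        final_eligible=int(eligible_mask.sum()),
    )
    logger.info(
        "apply_exclusions: %d assessed -> %d eligible (%s)",
        flow.assessed_total, flow.final_eligible, flow.to_dict(),
    )
    return persons.loc[eligible_mask].copy(), flow


def _check_linkage(persons: pd.DataFrame, contacts: pd.DataFrame) -> None:
    known = set(persons["person_id"])
    unknown = set(contacts["person_id"]) - known
    if unknown:
        raise LinkageError(
            f"contacts reference unknown person ids: {sorted(map(str, unknown))[:10]}"
        )


def ascertain_smi(persons: pd.DataFrame, contacts: pd.DataFrame) -> pd.DataFrame:
    """Flag persons with a qualifying service contact in the 5-year lookback.

    A contact qualifies when its setting is inpatient or face-to-face
    community AND index - 5 calendar years <= contact_date < index (half-open:
    same-day contacts never qualify).  Returns a frame indexed by person_id
    with boolean columns smi, psychosis, smi_non_psychosis (the latter two
    all-False until :func:`ascertain_psychosis` runs).
    """
    _check_linkage(persons, contacts)
    index_dates = pd.to_datetime(persons.set_index("person_id")["index_date"])

    flags = pd.DataFrame(
        {"smi": False, "psychosis": False, "smi_non_psychosis": False},
        index=index_dates.index,
    )
    if len(contacts):
        c = contacts.loc[contacts["setting"].isin(QUALIFYING_SETTINGS)].copy()
        if len(c):
            c["contact_date"] = pd.to_datetime(c["contact_date"])
            idx = index_dates.loc[c["person_id"]].to_numpy()
            lower = pd.DatetimeIndex(idx) - pd.DateOffset(years=5)
            in_window = (c["contact_date"].to_numpy() >= lower.to_numpy()) & (
                c["contact_date"].to_numpy() < idx
            )
            exposed = pd.unique(c.loc[in_window.tolist(), "person_id"])
            flags.loc[exposed, "smi"] = True
    logger.info("ascertain_smi: %d of %d exposed", int(flags["smi"].sum()), len(flags))
    return flags


def _code_family(code) -> int | None:
    """Two-digit ICD-10 F family (e.g. 'F25.1' -> 25), or None if not parseable."""
    if code is None or (isinstance(code, float) and np.isnan(code)):
        return None
    m = _ICD_F_CODE.match(str(code).strip())
    return int(m.group(1)) if m else None


def is_psychosis_code(code) -> bool:
    """True for the functional-psychosis family F20-F31 inclusive (any sub-code)."""
    fam = _code_family(code)
    return fam is not None and 20 <= fam <= 31


def ascertain_psychosis(flags: pd.DataFrame, contacts: pd.DataFrame) -> pd.DataFrame:
    """Refine exposure flags with the functional-psychosis subgroup.

    psychosis = smi AND any contact (any date, any setting, including after
    the index assessment) whose diagnosis code falls in F20-F31.  Malformed
    codes are logged and treated as missing, never fatal.
    """
    flags = flags.copy()
    if len(contacts):
        codes = contacts["diagnosis_code"]
        non_null = codes.notna() & (codes.astype("string") != "")
        parsed = codes[non_null].map(_code_family)
        malformed = parsed.isna() & non_null[non_null]
        if malformed.any():
            logger.warning(
                "ascertain_psychosis: %d malformed diagnosis codes treated as missing",
                int(malformed.sum()),
            )
        psychotic_contacts = contacts.loc[non_null].loc[
            parsed.notna() & parsed.between(20, 31, inclusive="both")
        ]
        with_code = set(psychotic_contacts["person_id"]) & set(flags.index)
        flags.loc[sorted(with_code), "psychosis"] = flags.loc[
            sorted(with_code), "smi"
        ]
    flags["psychosis"] = flags["psychosis"] & flags["smi"]
    flags["smi_non_psychosis"] = flags["smi"] & ~flags["psychosis"]
    return flags


def ascertain_exposure(persons: pd.DataFrame, contacts: pd.DataFrame) -> pd.DataFrame:
    """Convenience: SMI lookback then psychosis refinement in one call."""
    return ascertain_psychosis(ascertain_smi(persons, contacts), contacts)


def prioritized_ethnicity(records) -> str:
    """Resolve multiple raw ethnicity records to one prioritized category.

    Priority (highest first): Maori > Pacific > Indian > Chinese/other
    Asian > European/other.  Order of the input records never matters.
    """
    if isinstance(records, str):
        records = [r for r in records.split("|") if r]
    records = list(records)
    if not records:
        raise DataError("empty ethnicity record list")
    cats = set()
    for raw in records:
        key = str(raw).strip().lower().replace(" ", "_").replace("/", "_")
        cats.add(_ETHNICITY_ALIASES.get(key, "european_other"))
    for cat in ETHNICITY_PRIORITY:
        if cat in cats:
            return cat
    return "european_other"


def build_eligible_table(
    persons: pd.DataFrame, contacts: pd.DataFrame
) -> tuple[pd.DataFrame, CohortFlow]:
    """Full build: exclusions, exposure flags, prioritized ethnicity.

    Returns the eligible table augmented with columns ``ethnicity``, ``smi``,
    ``psychosis``, ``smi_non_psychosis``, plus the flow accounting.
    """
    eligible, flow = apply_exclusions(persons)
    flags = ascertain_exposure(eligible, contacts[contacts["person_id"].isin(
        set(eligible["person_id"]))]) if len(eligible) else pd.DataFrame(
        columns=["smi", "psychosis", "smi_non_psychosis"])
    out = eligible.copy()
    if len(out):
        out["ethnicity"] = out["ethnicity_records"].map(prioritized_ethnicity)
        for col in ("smi", "psychosis", "smi_non_psychosis"):
            out[col] = out["person_id"].map(flags[col]).astype(bool)
    return out, flow
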