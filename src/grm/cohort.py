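"""EHR phenotyping: dementia case/control eligibility from encounter tables.

Patients are partitioned into cases, controls, and exclusions (each with the
first failing filter as its reason), following the record-quality and
age-eligibility rules used for biobank dementia studies: complete
demographics, at least two encounters after age 55, censoring at the last
encounter age of 90, onset strictly after 55 for cases, and for controls a
last visit at age 70 or later with at least 5 years of records averaging
one encounter per year.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Dementia ICD-10 code prefixes (Alzheimer's disease, unspecified dementia,
#: dementia in other diseases, vascular dementia, other degeneration of the
#: nervous system). Users supply their own full lists in production.
DEFAULT_DEMENTIA_CODES = frozenset({"G30", "F03", "F02", "F01", "G31.83"})

#: Dementia-adjacent exclusion phenotypes disqualifying controls (mild
#: cognitive impairment, amnesia, delirium). Configuration, not a clinical
#: standard.
DEFAULT_EXCLUSION_CODES = frozenset({"G31.84", "R41", "F05"})

_ICD10_RE = re.compile(r"^[A-Z]\d+[A-Z0-9]*(\.[A-Z0-9]+)?$")

DAYS_PER_YEAR = 365.25


class PhenotypingError(ValueError):
    pass


@dataclass
class CohortLabels:
    """Per-patient status with derived EHR features.

    ``table`` columns: patient_id, status (case/control/excluded),
    exclusion_reason, onset_age (cases only), span_years, n_encounters,
    encounters_per_year, age_last, sex.
    """

    table: pd.DataFrame

    @property
    def cases(self) -> list:
        return self.table.loc[self.table.status == "case", "patient_id"].tolist()

    @property
    def controls(self) -> list:
        return self.table.loc[self.table.status == "control", "patient_id"].tolist()

    def summary(self) -> dict:
        counts = self.table.status.value_counts().to_dict()
        reasons = (self.table.loc[self.table.status == "excluded",
                                  "exclusion_reason"].value_counts().to_dict())
        return {"n_case": counts.get("case", 0),
                "n_control": counts.get("control", 0),
                "n_excluded": counts.get("excluded", 0),
                "exclusion_reasons": reasons}


def _validate_codes(codes: pd.Series) -> None:
    bad = codes[~codes.astype(str).str.match(_ICD10_RE)]
    if len(bad):
        raise PhenotypingError(
            f"unparseable ICD-10 codes: {sorted(set(bad))[:5]}")


def _matches(codes: pd.Series, prefixes) -> pd.Series:
    """True where a code equals or refines (dot-extends) any prefix."""
    pref = tuple(prefixes)

    def hit(c: str) -> bool:
        return any(c == p or c.startswith(p + ".") for p in pref)

    return codes.astype(str).map(hit)


def derive_ehr_features(enc: pd.DataFrame) -> pd.DataFrame:
    """Per-patient record span, encounter count, rate, and ages.

    Span is years between first and last encounter; a single-encounter
    patient has span 0 and rate equal to the encounter count.
    """
    if enc.empty:
        raise PhenotypingError("encounter table is empty")
    e = enc.copy()
    e["encounter_date"] = pd.to_datetime(e["encounter_date"])
    e["birth_date"] = pd.to_datetime(e["birth_date"])
    g = e.groupby("patient_id")
    first = g["encounter_date"].min()
    last = g["encounter_date"].max()
    birth = g["birth_date"].first()
    n = g.size()
    span = (last - first) / np.timedelta64(1, "D") / DAYS_PER_YEAR
    rate = np.where(span > 0, n / span, n)
    out = pd.DataFrame({
        "patient_id": n.index,
        "span_years": span.to_numpy(),
        "n_encounters": n.to_numpy(),
        "encounters_per_year": rate,
        "age_first": ((first - birth) / np.timedelta64(1, "D")
                      / DAYS_PER_YEAR).to_numpy(),
        "age_last": ((last - birth) / np.timedelta64(1, "D")
                     / DAYS_PER_YEAR).to_numpy(),
    }).reset_index(drop=True)
    return out


def select_cohort(enc: pd.DataFrame,
                  dementia_codes=DEFAULT_DEMENTIA_CODES,
                  exclusion_codes=DEFAULT_EXCLUSION_CODES,
                  min_encounters_after: tuple[int, float] = (2, 55.0),
                  last_age_max: float = 90.0,
                  case_onset_min: float = 55.0,
                  control_last_age_min: float = 70.0,
                  control_min_span: float = 5.0,
                  control_min_rate: float = 1.0) -> CohortLabels:
    """Label every patient case / control / excluded, in pipeline order.

    Filters: (1) complete demographics; (2) at least
    ``min_encounters_after[0]`` encounters after age
    ``min_encounters_after[1]``; (3) age at last encounter <
    ``last_age_max``; (4) patients with a dementia code are cases iff the
    first dementia-coded encounter is strictly after ``case_onset_min``
    (else excluded, early_onset); (5) remaining patients are controls iff
    they carry no exclusion code, last age >= ``control_last_age_min``,
    span >= ``control_min_span`` and rate >= ``control_min_rate``.
    The exclusion reason is the first failing filter.
    """
    if not dementia_codes:
        raise PhenotypingError("dementia code set is empty")
    e = enc.copy()
    _validate_codes(e["icd10_code"])
    e["encounter_date"] = pd.to_datetime(e["encounter_date"])
    e["birth_date"] = pd.to_datetime(e["birth_date"])
    feats = derive_ehr_features(e)
    e["age_at_enc"] = (e["encounter_date"] - e["birth_date"]) \
        / np.timedelta64(1, "D") / DAYS_PER_YEAR
    e["is_dementia"] = _matches(e["icd10_code"], dementia_codes)
    e["is_exclusion"] = _matches(e["icd10_code"], exclusion_codes)

    min_n, min_age = min_encounters_after
    rows = []
    sex_by_pid = e.groupby("patient_id")["sex"].first()
    for _, f in feats.iterrows():
        pid = f.patient_id
        sub = e.loc[e.patient_id == pid]
        sex = sex_by_pid[pid]
        rec = {"patient_id": pid, "status": "excluded",
               "exclusion_reason": None, "onset_age": np.nan,
               "span_years": f.span_years, "n_encounters": f.n_encounters,
               "encounters_per_year": f.encounters_per_year,
               "age_last": f.age_last, "sex": sex}
        if pd.isna(sex) or sub["birth_date"].isna().any():
            rec["exclusion_reason"] = "incomplete_demographics"
        elif (sub["age_at_enc"] > min_age).sum() < min_n:
            rec["exclusion_reason"] = "insufficient_encounters_after_55"
        elif f.age_last >= last_age_max:
            rec["exclusion_reason"] = "over_age_censoring"
        elif sub["is_dementia"].any():
            onset = float(sub.loc[sub.is_dementia, "age_at_enc"].min())
            if onset > case_onset_min:
                rec.update(status="case", onset_age=onset)
            else:
                rec["exclusion_reason"] = "early_onset"
        elif sub["is_exclusion"].any():
            rec["exclusion_reason"] = "has_exclusion_code"
        elif f.age_last < control_last_age_min:
            rec["exclusion_reason"] = "control_too_young"
        elif f.span_years < control_min_span:
            rec["exclusion_reason"] = "short_span"
        elif f.encounters_per_year < control_min_rate:
            rec["exclusion_reason"] = "low_encounter_rate"
        else:
            rec["status"] = "control"
        rows.append(rec)
    return CohortLabels(pd.DataFrame(rows))
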