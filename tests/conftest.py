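"""Shared fixtures: small synthetic cohorts and the hand-traced EHR fixture."""

import numpy as np
import pandas as pd
import pytest

from grm import GenotypeMatrix, SimulationConfig, VariantRecord
from grm.synthetic import simulate_cohort


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_samples=400, n_blocks=4, snps_per_block=5,
                            block_r2=0.5, causal_snps=[(0, 0.6), (10, 0.5)],
                            seed=7, include_apoe=True, apoe_effect=0.8)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config, gwas_n=200_000, n_ref=300)


def make_geno(dosages, ids=None, chrom="1", positions=None, ref="A", alt="G"):
    """Convenience constructor for tiny genotype matrices."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    ids = ids or [f"v{j}" for j in range(m)]
    positions = positions or [100 * (j + 1) for j in range(m)]
    refs = [ref] * m if isinstance(ref, str) else ref
    alts = [alt] * m if isinstance(alt, str) else alt
    variants = [VariantRecord(ids[j], chrom, positions[j], refs[j], alts[j])
                for j in range(m)]
    return GenotypeMatrix(dosages, variants, [f"s{i}" for i in range(n)])


@pytest.fixture
def tiny_geno():
    return make_geno([[0, 1, 2], [2, 1, 0]])


def _enc_rows(pid, birth_year, sex, visits):
    """visits: list of (age_years, code)."""
    birth = pd.Timestamp(f"{birth_year}-01-01")
    rows = []
    for age, code in visits:
        rows.append({"patient_id": pid, "birth_date": birth, "sex": sex,
                     "encounter_date": birth +
                     pd.to_timedelta(age * 365.25, unit="D"),
                     "icd10_code": code})
    return rows


@pytest.fixture(scope="session")
def twelve_patient_encounters():
    """Hand-constructed encounter table covering every selection branch.

    Expected labels (traced by hand against the filter definitions):
      p01 case          (dementia onset 76, last visit 80 < 90)
      p02 early_onset   (first dementia code at age 54)
      p03 control       (no dementia, last 75, span 6 y, 12 encounters)
      p04 control_too_young   (clean, last visit at 69)
      p05 short_span    (clean, last 75, span 3 y)
      p06 low_encounter_rate  (clean, span 6 y, only 5 encounters)
      p07 over_age_censoring  (last visit at 91)
      p08 incomplete_demographics (missing sex)
      p09 insufficient_encounters_after_55 (one visit after 55)
      p10 has_exclusion_code  (carries R41.3)
      p11 early_onset   (dementia first coded at 54.9, boundary)
      p12 control       (last visit exactly at 70, span 8 y)
    """
    rows = []
    rows += _enc_rows("p01", 1944, "F",
                      [(70 + i, "I10") for i in range(6)] + [(76, "G30.9"),
                                                             (80, "E11.9")])
    rows += _enc_rows("p02", 1950, "M",
                      [(54, "F03.90")] + [(56 + i, "I10") for i in range(6)])
    rows += _enc_rows("p03", 1948, "F",
                      [(69 + 0.5 * i, "I10") for i in range(12)] + [(75, "Z00.00")])
    rows += _enc_rows("p04", 1958, "M",
                      [(60 + i, "I10") for i in range(10)])  # last 69
    rows += _enc_rows("p05", 1946, "F",
                      [(72 + 0.5 * i, "I10") for i in range(7)])  # span 3
    rows += _enc_rows("p06", 1947, "M",
                      [(70, "I10"), (71.5, "I10"), (73, "E11.9"),
                       (74.5, "I10"), (76, "I10")])  # 5 enc over 6 y
    rows += _enc_rows("p07", 1932, "F",
                      [(80 + i, "I10") for i in range(12)])  # last 91
    rows += _enc_rows("p08", 1945, None,
                      [(70 + i, "I10") for i in range(8)])
    rows += _enc_rows("p09", 1960, "M",
                      [(50, "I10"), (52, "I10"), (56, "I10")])
    rows += _enc_rows("p10", 1947, "F",
                      [(70 + i, "I10") for i in range(7)] + [(74, "R41.3")])
    rows += _enc_rows("p11", 1951, "M",
                      [(54.9, "G30.9")] + [(56 + i, "I10") for i in range(8)])
    rows += _enc_rows("p12", 1954, "F",
                      [(62.5 + i, "I10") for i in range(9)])  # 62.5..70.5
    return pd.DataFrame(rows)


TWELVE_PATIENT_EXPECTED = {
    "p01": ("case", None), "p02": ("excluded", "early_onset"),
    "p03": ("control", None), "p04": ("excluded", "control_too_young"),
    "p05": ("excluded", "short_span"),
    "p06": ("excluded", "low_encounter_rate"),
    "p07": ("excluded", "over_age_censoring"),
    "p08": ("excluded", "incomplete_demographics"),
    "p09": ("excluded", "insufficient_encounters_after_55"),
    "p10": ("excluded", "has_exclusion_code"),
    "p11": ("excluded", "early_onset"), "p12": ("control", None),
}
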