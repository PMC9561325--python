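"""Cohort data model, CSV readers/writers and cohort-cleaning/encoding rules.

A cohort is a set of patients, each with an ordered sequence of hospital
admissions ("visits").  Every visit carries a set of ICD-9 diagnosis codes, a
set of DRG codes (standing in for treatment/intervention), an admission type,
admission/discharge timestamps and an in-hospital death flag.  The cleaning
rules applied here mirror standard practice for MIMIC-III-style tables:
patients with fewer than 2 or more than 10 admissions are excluded, ICD-9
codes are truncated to their 3-character category, and the four raw admission
types are regrouped into emergency (EMERGENCY, URGENT) versus non-emergency
(ELECTIVE, NEWBORN).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EMERGENCY_TYPES = frozenset({"EMERGENCY", "URGENT"})
NON_EMERGENCY_TYPES = frozenset({"ELECTIVE", "NEWBORN"})
ADMISSION_TYPES = EMERGENCY_TYPES | NON_EMERGENCY_TYPES

#: admission-type weight m_t: the input gate is scaled by 1/m_t, so the
#: emergency group gets the heavier weight (m=1) and non-emergency m=2.
M_EMERGENCY = 1
M_NON_EMERGENCY = 2

MIN_VISITS = 2
MAX_VISITS = 10


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class RowError(ValueError):
    """A specific input row is malformed (named in the message)."""


@dataclass
class Visit:
    admit_time: datetime
    discharge_time: datetime
    admission_type_raw: str
    diagnosis_codes: set[str]
    drg_codes: set[str]
    died_in_hospital: bool = False
    hadm_id: str | None = None

    def __post_init__(self) -> None:
        if self.discharge_time < self.admit_time:
            raise ValueError(
                f"visit {self.hadm_id}: discharge_time precedes admit_time"
            )


@dataclass
class Patient:
    patient_id: str
    visits: list[Visit] = field(default_factory=list)

    @property
    def died(self) -> bool:
        return bool(self.visits) and self.visits[-1].died_in_hospital


@dataclass
class Cohort:
    patients: list[Patient] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self):
        return iter(self.patients)


@dataclass
class CodeVocabulary:
    """Deterministic (lexicographic) code <-> index bijection."""

    kind: str  # "diagnosis" | "drg"
    codes: list[str]
    index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.index = {c: i for i, c in enumerate(self.codes)}
        if len(self.index) != len(self.codes):
            raise ValueError("duplicate codes in vocabulary")

    def __len__(self) -> int:
        return len(self.codes)


@dataclass
class EncodedSequence:
    """Per-patient encoded visit sequence.

    x, p are multi-hot {0,1} matrices over the diagnosis/DRG vocabularies; m
    holds the admission-type weights; delta_prev the day gap to the previous
    discharge; delta_to_last the days from each admission to the final
    discharge; y the per-visit death labels.  admit_day/discharge_day are day
    offsets from the first admission, retained so that prefix-limited
    predictions can recompute time-to-last-discharge relative to any prefix.
    """

    patient_id: str
    x: np.ndarray            # (T, |D|)
    p: np.ndarray            # (T, |L|)
    m: np.ndarray            # (T,)
    delta_prev: np.ndarray   # (T,)
    delta_to_last: np.ndarray  # (T,)
    y: np.ndarray            # (T,)
    mask: np.ndarray         # (T,) bool
    admit_day: np.ndarray    # (T,)
    discharge_day: np.ndarray  # (T,)

    @property
    def n_visits(self) -> int:
        return int(self.mask.sum())


# ---------------------------------------------------------------------------
# elementary cleaning rules
# ---------------------------------------------------------------------------

def truncate_icd9(code: str, length: int = 3) -> str:
    """Truncate an ICD-9 code to its leading category characters.

    The default keeps the first 3 characters ("42831" -> "428"); V- and
    E-codes are truncated the same way.
    """
    if not code:
        raise ValueError("empty ICD-9 code")
    return code[:length]


def regroup_admission_type(raw_label: str) -> int:
    """Map a raw admission type to the m_t weight (emergency=1, else 2)."""
    label = raw_label.strip().upper()
    if label in EMERGENCY_TYPES:
        return M_EMERGENCY
    if label in NON_EMERGENCY_TYPES:
        return M_NON_EMERGENCY
    raise ValueError(
        f"unknown admission type {raw_label!r}; accepted: "
        + ", ".join(sorted(ADMISSION_TYPES))
    )


def _floor_days(later: datetime, earlier: datetime) -> float:
    return float((later - earlier).total_seconds() // 86400)


def compute_intervals(patient: Patient) -> tuple[np.ndarray, np.ndarray]:
    """Day gaps (delta_prev, delta_to_last) for a patient's ordered visits.

    delta_prev[t] is the (floored, non-negative) number of days between visit
    t's admission and visit t-1's discharge, with delta_prev[0] = 0 by
    convention; delta_to_last[t] counts days from visit t's admission to the
    final discharge.  Negative raw gaps (overlapping admissions) clamp to 0.
    """
    visits = patient.visits
    if any(
        visits[i].admit_time > visits[i + 1].admit_time
        for i in range(len(visits) - 1)
    ):
        raise ValueError(f"patient {patient.patient_id}: visits not ordered")
    T = len(visits)
    delta_prev = np.zeros(T)
    delta_to_last = np.zeros(T)
    last_discharge = visits[-1].discharge_time
    for t, v in enumerate(visits):
        if t > 0:
            delta_prev[t] = max(
                0.0, _floor_days(v.admit_time, visits[t - 1].discharge_time)
            )
        delta_to_last[t] = max(0.0, _floor_days(last_discharge, v.admit_time))
    return delta_prev, delta_to_last


def clean_cohort(cohort: Cohort, icd9_len: int | None = 3) -> Cohort:
    """Apply the cohort-cleaning rules, returning a new Cohort.

    Rules, in order: (1) ICD-9 codes truncated to ``icd9_len`` characters
    (None disables truncation); (2) visits with no diagnosis codes dropped;
    (3) visits after an in-hospital death dropped, so death can only mark the
    final visit; (4) patients retained only if they have 2..10 visits.
    Idempotent: cleaning a cleaned cohort changes nothing.
    """
    kept: list[Patient] = []
    n_codeless = n_truncated_tail = n_count = 0
    for patient in cohort:
        visits = sorted(patient.visits, key=lambda v: v.admit_time)
        new_visits: list[Visit] = []
        for v in visits:
            dx = {truncate_icd9(c, icd9_len) for c in v.diagnosis_codes} \
                if icd9_len else set(v.diagnosis_codes)
            if not dx:
                n_codeless += 1
                continue
            new_visits.append(
                Visit(
                    admit_time=v.admit_time,
                    discharge_time=v.discharge_time,
                    admission_type_raw=v.admission_type_raw,
                    diagnosis_codes=dx,
                    drg_codes=set(v.drg_codes),
                    died_in_hospital=v.died_in_hospital,
                    hadm_id=v.hadm_id,
                )
            )
        for i, v in enumerate(new_visits):
            if v.died_in_hospital and i < len(new_visits) - 1:
                n_truncated_tail += len(new_visits) - 1 - i
                new_visits = new_visits[: i + 1]
                break
        if MIN_VISITS <= len(new_visits) <= MAX_VISITS:
            kept.append(Patient(patient.patient_id, new_visits))
        else:
            n_count += 1
    logger.info(
        "clean_cohort: %d patients kept (%d removed by visit-count filter, "
        "%d codeless visits dropped, %d post-death visits dropped)",
        len(kept), n_count, n_codeless, n_truncated_tail,
    )
    if not kept:
        raise ValueError("no patients survive filters")
    return Cohort(kept)


# ---------------------------------------------------------------------------
# vocabulary and encoding
# ---------------------------------------------------------------------------

def build_vocab(cohort: Cohort, kind: str) -> CodeVocabulary:
    """Collect the sorted, deduplicated code set of one kind."""
    if kind not in ("diagnosis", "drg"):
        raise ValueError("kind must be 'diagnosis' or 'drg'")
    if not len(cohort):
        raise ValueError("cannot build a vocabulary from an empty cohort")
    codes: set[str] = set()
    for patient in cohort:
        for v in patient.visits:
            codes |= v.diagnosis_codes if kind == "diagnosis" else v.drg_codes
    return CodeVocabulary(kind=kind, codes=sorted(codes))


def encode_sequences(
    cohort: Cohort,
    vocab_dx: CodeVocabulary,
    vocab_drg: CodeVocabulary,
) -> list[EncodedSequence]:
    """Encode each patient into multi-hot matrices and scalar covariates.

    Out-of-vocabulary codes are dropped with a warning; a visit left without
    any in-vocabulary diagnosis code is an error (the model has no input for
    it).
    """
    out: list[EncodedSequence] = []
    n_oov = 0
    for patient in cohort:
        T = len(patient.visits)
        x = np.zeros((T, len(vocab_dx)))
        p = np.zeros((T, len(vocab_drg)))
        m = np.zeros(T)
        y = np.zeros(T)
        admit_day = np.zeros(T)
        discharge_day = np.zeros(T)
        t0 = patient.visits[0].admit_time
        for t, v in enumerate(patient.visits):
            dx_idx = [vocab_dx.index[c] for c in v.diagnosis_codes
                      if c in vocab_dx.index]
            n_oov += len(v.diagnosis_codes) - len(dx_idx)
            if not dx_idx:
                raise ValueError(
                    f"patient {patient.patient_id}, visit {t} "
                    f"({v.hadm_id}): no in-vocabulary diagnosis codes"
                )
            x[t, dx_idx] = 1.0
            drg_idx = [vocab_drg.index[c] for c in v.drg_codes
                       if c in vocab_drg.index]
            n_oov += len(v.drg_codes) - len(drg_idx)
            p[t, drg_idx] = 1.0
            m[t] = regroup_admission_type(v.admission_type_raw)
            y[t] = float(v.died_in_hospital)
            admit_day[t] = _floor_days(v.admit_time, t0)
            discharge_day[t] = _floor_days(v.discharge_time, t0)
        delta_prev, delta_to_last = compute_intervals(patient)
        out.append(
            EncodedSequence(
                patient_id=patient.patient_id,
                x=x, p=p, m=m,
                delta_prev=delta_prev, delta_to_last=delta_to_last,
                y=y, mask=np.ones(T, dtype=bool),
                admit_day=admit_day, discharge_day=discharge_day,
            )
        )
    if n_oov:
        logger.warning("encode_sequences: dropped %d out-of-vocabulary codes",
                       n_oov)
    return out


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

_ADMISSIONS_COLS = ["subject_id", "hadm_id", "admittime", "dischtime",
                    "admission_type", "hospital_expire_flag"]
_DIAGNOSES_COLS = ["hadm_id", "icd9_code"]
_DRG_COLS = ["hadm_id", "drg_code"]
_PATIENTS_COLS = ["subject_id", "dod"]


def _require_columns(df: pd.DataFrame, cols: list[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing required column(s) {missing}")


def _parse_dt(value, table: str, row: int) -> datetime:
    try:
        ts = pd.Timestamp(value)
        if pd.isna(ts):
            raise ValueError
        return ts.to_pydatetime()
    except Exception:
        raise RowError(
            f"{table} row {row}: unparsable datetime {value!r}"
        ) from None


def load_cohort_csv(
    admissions_path: str | Path,
    diagnoses_path: str | Path,
    drg_path: str | Path,
    patients_path: str | Path,
) -> Cohort:
    """Read the four-table CSV dialect into a Cohort.

    Visits are grouped by admission id, sorted by admission time, and the
    death flag of a visit is set when the patient's date of death (null for
    survivors) falls within that admission, or when the admission's
    hospital_expire_flag is set.
    """
    adm = pd.read_csv(admissions_path, dtype={"subject_id": str,
                                              "hadm_id": str})
    dx = pd.read_csv(diagnoses_path, dtype=str)
    drg = pd.read_csv(drg_path, dtype=str)
    pts = pd.read_csv(patients_path, dtype={"subject_id": str})
    _require_columns(adm, _ADMISSIONS_COLS, "admissions")
    _require_columns(dx, _DIAGNOSES_COLS, "diagnoses")
    _require_columns(drg, _DRG_COLS, "drg")
    _require_columns(pts, _PATIENTS_COLS, "patients")

    known_hadm = set(adm["hadm_id"])
    for table, df in (("diagnoses", dx), ("drg", drg)):
        bad = df.loc[~df["hadm_id"].isin(known_hadm)]
        if len(bad):
            raise RowError(
                f"{table} row {bad.index[0]}: unknown admission id "
                f"{bad.iloc[0]['hadm_id']!r}"
            )

    dx_by_hadm = dx.dropna(subset=["icd9_code"]).groupby("hadm_id")[
        "icd9_code"].apply(set).to_dict()
    drg_by_hadm = drg.dropna(subset=["drg_code"]).groupby("hadm_id")[
        "drg_code"].apply(set).to_dict()
    dod_by_subject: dict[str, datetime | None] = {}
    for i, row in pts.iterrows():
        dod = row["dod"]
        dod_by_subject[row["subject_id"]] = (
            None if pd.isna(dod) or str(dod).strip() == ""
            else _parse_dt(dod, "patients", i)
        )

    patients: dict[str, Patient] = {}
    for i, row in adm.iterrows():
        sid = row["subject_id"]
        admit = _parse_dt(row["admittime"], "admissions", i)
        disch = _parse_dt(row["dischtime"], "admissions", i)
        dod = dod_by_subject.get(sid)
        died = bool(int(row["hospital_expire_flag"])) or (
            dod is not None and admit <= dod <= disch
        )
        visit = Visit(
            admit_time=admit,
            discharge_time=disch,
            admission_type_raw=str(row["admission_type"]),
            diagnosis_codes=set(dx_by_hadm.get(row["hadm_id"], set())),
            drg_codes=set(drg_by_hadm.get(row["hadm_id"], set())),
            died_in_hospital=died,
            hadm_id=row["hadm_id"],
        )
        patients.setdefault(sid, Patient(sid)).visits.append(visit)
    for patient in patients.values():
        patient.visits.sort(key=lambda v: v.admit_time)
    return Cohort(sorted(patients.values(), key=lambda p: p.patient_id))


def write_cohort_csv(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write a cohort back to the four-table CSV dialect (round-trippable)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    adm_rows, dx_rows, drg_rows, pt_rows = [], [], [], []
    for patient in cohort:
        dod = ""
        for t, v in enumerate(patient.visits):
            hadm = v.hadm_id or f"{patient.patient_id}-{t}"
            adm_rows.append({
                "subject_id": patient.patient_id,
                "hadm_id": hadm,
                "admittime": v.admit_time.isoformat(sep=" "),
                "dischtime": v.discharge_time.isoformat(sep=" "),
                "admission_type": v.admission_type_raw,
                "hospital_expire_flag": int(v.died_in_hospital),
            })
            dx_rows.extend({"hadm_id": hadm, "icd9_code": c}
                           for c in sorted(v.diagnosis_codes))
            drg_rows.extend({"hadm_id": hadm, "drg_code": c}
                            for c in sorted(v.drg_codes))
            if v.died_in_hospital:
                dod = v.discharge_time.isoformat(sep=" ")
        pt_rows.append({"subject_id": patient.patient_id, "dod": dod})
    paths = {}
    for name, rows, cols in (
        ("admissions", adm_rows, _ADMISSIONS_COLS),
        ("diagnoses", dx_rows, _DIAGNOSES_COLS),
        ("drg", drg_rows, _DRG_COLS),
        ("patients", pt_rows, _PATIENTS_COLS),
    ):
        path = out_dir / f"{name}.csv"
        pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
        paths[name] = path
    return paths
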