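"""Synthetic longitudinal EHR cohorts with the structure the model assumes.

The generator emulates, with abstract code tokens, the statistical shape of a
cleaned ICU cohort: 2-10 visits per patient with mean ~2.57, ~13 diagnosis
codes and ~2.2 DRG codes per visit, comorbidity blocks of co-occurring
diagnosis codes, emergency/non-emergency admissions, long-tailed
(log-normal) inter-visit gaps, and an in-hospital death label on the final
visit driven by a small set of "lethal" diagnosis codes through a logistic
mechanism:

    P(death) = sigmoid(baseline_logit + lethal_effect * k)

where k is the number of distinct lethal codes across the patient's visits.
Lethal codes live inside the first comorbidity block and are drawn only as
within-block codes, modelling severe diagnoses that occur in the context of
their syndrome; this makes k nearly bimodal, so the mechanism is strongly
recoverable at lethal_effect=3 and exactly uninformative at lethal_effect=0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta

import numpy as np

from .ehr_data import Cohort, Patient, Visit

_VISIT_MIN, _VISIT_MAX = 2, 10


def _truncated_geometric_weights(target_mean: float) -> np.ndarray:
    """Weights of a geometric distribution truncated to [2, 10] whose mean
    equals target_mean (solved by bisection on the success probability)."""
    ks = np.arange(_VISIT_MIN, _VISIT_MAX + 1)
    if not (_VISIT_MIN < target_mean < _VISIT_MAX):
        raise ValueError("visit-count mean must lie strictly in (2, 10)")

    def mean_for(p: float) -> float:
        w = (1 - p) ** (ks - _VISIT_MIN) * p
        return float((ks * w).sum() / w.sum())

    lo, hi = 1e-9, 1 - 1e-9
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mean_for(mid) > target_mean:
            lo = mid
        else:
            hi = mid
    p = 0.5 * (lo + hi)
    w = (1 - p) ** (ks - _VISIT_MIN) * p
    return w / w.sum()


@dataclass
class SynthConfig:
    """Generator settings; defaults emulate a balanced cleaned ICU cohort."""

    n_patients: int = 2000
    visit_count_mean: float = 2.57
    n_dx_codes: int = 200
    n_drg_codes: int = 60
    #: comorbidity blocks as lists of diagnosis-code indices
    comorbidity_blocks: list[list[int]] = field(
        default_factory=lambda: [list(range(i * 12, (i + 1) * 12))
                                 for i in range(4)]
    )
    within_block_prob: float = 0.75
    codes_per_visit_mean: float = 13.0
    max_codes_per_visit: int = 39
    drg_per_visit_mean: float = 2.23
    max_drg_per_visit: int = 3
    lethal_codes: frozenset[int] = frozenset(range(5))
    baseline_logit: float = -4.0
    lethal_effect: float = 3.0
    gap_lognormal_params: tuple[float, float] = (3.0, 1.2)   # days between visits
    los_lognormal_params: tuple[float, float] = (1.6, 0.6)   # length of stay, days
    emergency_prob: float = 0.6
    seed: int = 0

    def validate(self) -> None:
        for name in ("within_block_prob", "emergency_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.codes_per_visit_mean > self.n_dx_codes:
            raise ValueError("codes_per_visit_mean exceeds vocabulary size")
        if any(c >= self.n_dx_codes for b in self.comorbidity_blocks for c in b):
            raise ValueError("comorbidity block index outside vocabulary")
        if any(c >= self.n_dx_codes for c in self.lethal_codes):
            raise ValueError("lethal code index outside vocabulary")


def _dx_name(i: int) -> str:
    # 3-character numeric codes: invariant under ICD-9 category truncation
    return f"{i:03d}"


def _drg_name(i: int) -> str:
    return f"G{i:03d}"


def generate_cohort(config: SynthConfig) -> Cohort:
    """Sample a cohort; byte-identical for a fixed config (incl. seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    visit_w = _truncated_geometric_weights(config.visit_count_mean)
    visit_support = np.arange(_VISIT_MIN, _VISIT_MAX + 1)
    lethal = set(config.lethal_codes)
    non_lethal = np.array(
        [c for c in range(config.n_dx_codes) if c not in lethal]
    )
    blocks = [np.array(b) for b in config.comorbidity_blocks]
    base_date = datetime(2140, 1, 1)
    mu_g, sd_g = config.gap_lognormal_params
    mu_l, sd_l = config.los_lognormal_params

    patients: list[Patient] = []
    for n in range(config.n_patients):
        T = int(rng.choice(visit_support, p=visit_w))
        visits: list[Visit] = []
        admit = base_date + timedelta(days=float(rng.integers(0, 3650)))
        patient_codes: set[int] = set()
        for t in range(T):
            block = blocks[int(rng.integers(len(blocks)))] if blocks else None
            n_codes = min(max(1, int(rng.poisson(config.codes_per_visit_mean))),
                          config.max_codes_per_visit)
            codes: set[int] = set()
            n_within = 0
            if block is not None:
                n_within = min(int(rng.binomial(n_codes,
                                                config.within_block_prob)),
                               len(block))
                codes |= {int(c) for c in rng.choice(block, size=n_within,
                                                     replace=False)}
            n_bg = min(n_codes - n_within, len(non_lethal))
            if n_bg > 0:
                codes |= {int(c) for c in rng.choice(non_lethal, size=n_bg,
                                                     replace=False)}
            patient_codes |= codes
            n_drg = min(max(1, int(rng.poisson(config.drg_per_visit_mean))),
                        config.max_drg_per_visit)
            drgs = {int(c) for c in
                    rng.choice(config.n_drg_codes, size=n_drg, replace=False)}
            emergency = rng.random() < config.emergency_prob
            adm_type = ("EMERGENCY" if rng.random() < 0.8 else "URGENT") \
                if emergency else \
                ("ELECTIVE" if rng.random() < 0.8 else "NEWBORN")
            los = max(1.0, float(rng.lognormal(mu_l, sd_l)) / 1.0)
            discharge = admit + timedelta(days=los)
            visits.append(
                Visit(
                    admit_time=admit,
                    discharge_time=discharge,
                    admission_type_raw=adm_type,
                    diagnosis_codes={_dx_name(c) for c in codes},
                    drg_codes={_drg_name(c) for c in drgs},
                    died_in_hospital=False,
                    hadm_id=f"H{n:05d}-{t}",
                )
            )
            gap = float(rng.lognormal(mu_g, sd_g))
            admit = discharge + timedelta(days=max(1.0, gap))
        k = len(patient_codes & lethal)
        logit = config.baseline_logit + config.lethal_effect * k
        died = rng.random() < 1.0 / (1.0 + np.exp(-logit))
        # death truncates the sequence: it can only mark the final visit
        visits[-1].died_in_hospital = bool(died)
        patients.append(Patient(patient_id=f"P{n:05d}", visits=visits))
    return Cohort(patients)


def make_fixture_cohort() -> Cohort:
    """Tiny deterministic hand-written cohort covering the cleaning edge
    cases: a 1-visit patient, an 11-visit patient, overlapping admissions,
    an unusually long code (vocabulary/truncation edge) and a death on the
    final visit."""

    def dt(day: int, hour: int = 0) -> datetime:
        return datetime(2100, 1, 1) + timedelta(days=day, hours=hour)

    def visit(day, los, kind, dx, drg, died=False, hadm=None):
        return Visit(
            admit_time=dt(day), discharge_time=dt(day + los),
            admission_type_raw=kind,
            diagnosis_codes=set(dx), drg_codes=set(drg),
            died_in_hospital=died, hadm_id=hadm,
        )

    patients = [
        # removed by cleaning: single visit
        Patient("F-single", [visit(0, 3, "EMERGENCY", {"42831"}, {"G001"})]),
        # removed by cleaning: 11 visits
        Patient("F-eleven", [
            visit(30 * t, 2, "ELECTIVE", {"496", "4019"}, {"G002"})
            for t in range(11)
        ]),
        # kept: 2 visits, overlapping admissions (negative gap -> clamp), dies
        Patient("F-overlap", [
            visit(0, 10, "URGENT", {"42831", "V1006"}, {"G003"}),
            visit(7, 5, "EMERGENCY", {"42831", "0389"}, {"G003", "G004"},
                  died=True),
        ]),
        # kept: 3 visits, survivor, includes an unusually long rare code
        Patient("F-survivor", [
            visit(0, 4, "ELECTIVE", {"25000", "4019"}, {"G005"}),
            visit(60, 3, "NEWBORN", {"25000"}, {"G005"}),
            visit(400, 6, "EMERGENCY", {"25000", "5849", "99591XX"}, {"G006"}),
        ]),
        # kept: exactly 10 visits
        Patient("F-ten", [
            visit(45 * t, 3, "EMERGENCY" if t % 2 else "ELECTIVE",
                  {"410" + str(t % 3)}, {"G007"})
            for t in range(10)
        ]),
    ]
    return Cohort(patients)
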