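"""Longitudinal population-PK data model and NONMEM-style CSV I/O.

The on-disk layout is a single comma-separated table with one row per
event: dose rows (``EVID=1``) carry the administered amount in mg/kg and
the route, observation rows (``EVID=0``) carry the measured blood
concentration in ng/mL or a censoring flag for samples below the lower
limit of quantification (BLQ).  Covariates (bodyweight, age, sex,
perioperative/anesthesia status, study label) are repeated on every row
of a subject, as is conventional for this format.

Units: time in hours, concentration in ng/mL, dose in mg/kg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "DoseEvent",
    "Observation",
    "SubjectRecord",
    "PKDataset",
    "ValidationReport",
    "read_dataset",
    "write_dataset",
    "validate_dataset",
    "MANDATORY_COLUMNS",
]

MANDATORY_COLUMNS = (
    "ID", "OCC", "TIME", "EVID", "AMT", "ROUTE", "DV", "CENS",
    "LLOQ", "WT", "AGE", "SEX", "ANEST", "STUDY",
)

#: route codes used on disk (1 = subcutaneous, 2 = intravenous)
ROUTE_CODES = {"SC": 1, "IV": 2}
ROUTE_NAMES = {1: "SC", 2: "IV"}


@dataclass(frozen=True)
class DoseEvent:
    """A single administration (IV bolus or SC dose) for one subject."""

    subject_id: int
    time: float          # hours within the occasion
    amount: float        # mg/kg
    route: str           # "SC" or "IV"
    occasion: int = 1

    def __post_init__(self):
        if self.amount <= 0:
            raise ValueError(f"dose amount must be positive, got {self.amount}")
        if self.time < 0:
            raise ValueError(f"dose time must be non-negative, got {self.time}")
        if self.route not in ROUTE_CODES:
            raise ValueError(f"route must be 'SC' or 'IV', got {self.route!r}")


@dataclass(frozen=True)
class Observation:
    """A blood-concentration sample, possibly censored at the LLOQ.

    A censored sample has no ``value``; it contributes the interval
    ``[0, lloq]`` to the likelihood (M3 convention).  Predose samples
    (time 0 within an occasion) are stored but flagged, and excluded
    from the likelihood by default: a washout of at least one week
    between occasions implies a true predose concentration of zero.
    """

    subject_id: int
    time: float          # hours since the first dose of the occasion
    value: Optional[float]
    censored: bool = False
    lloq: float = 3.0
    occasion: int = 1
    predose: bool = False

    def __post_init__(self):
        if self.time < 0:
            raise ValueError(f"observation time must be non-negative, got {self.time}")
        if self.lloq <= 0:
            raise ValueError(f"lloq must be positive, got {self.lloq}")
        if self.censored and self.value is not None:
            raise ValueError("censored observation must not carry a value")
        if not self.censored and not self.predose and self.value is None:
            raise ValueError("uncensored observation requires a value")


@dataclass(frozen=True)
class SubjectRecord:
    """Per-subject covariates."""

    subject_id: int
    weight0: float       # kg at first administration
    age: float           # years
    gender: str          # "F" or "M"
    anest: int = 0       # 1 = perioperative/anesthetized clinical subject
    study_label: str = ""

    def __post_init__(self):
        if self.weight0 <= 0:
            raise ValueError("weight0 must be positive")
        if self.age <= 0:
            raise ValueError("age must be positive")
        if self.gender not in ("F", "M"):
            raise ValueError(f"gender must be 'F' or 'M', got {self.gender!r}")
        if self.anest not in (0, 1):
            raise ValueError("anest must be 0 or 1")


@dataclass
class ValidationReport:
    errors: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


@dataclass
class PKDataset:
    """Container for the pooled longitudinal dataset."""

    subjects: list
    doses: list
    observations: list

    # ------------------------------------------------------------------
    def subject_map(self) -> dict:
        return {s.subject_id: s for s in self.subjects}

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_doses(self) -> int:
        return len(self.doses)

    def n_observations(self, include_predose: bool = True) -> int:
        if include_predose:
            return len(self.observations)
        return sum(1 for o in self.observations if not o.predose)

    def doses_for(self, subject_id: int) -> list:
        return [d for d in self.doses if d.subject_id == subject_id]

    def observations_for(self, subject_id: int) -> list:
        return [o for o in self.observations if o.subject_id == subject_id]

    # ------------------------------------------------------------------
    def iv_subset(self) -> "PKDataset":
        """Restrict to IV occasions of subjects with at least one IV dose.

        Occasions are renumbered consecutively from 1 per subject so the
        result is itself a valid dataset (used for the disposition-only
        first stage of sequential fitting).
        """
        iv_occ = {(d.subject_id, d.occasion) for d in self.doses if d.route == "IV"}
        keep_subjects = sorted({sid for sid, _ in iv_occ})
        # doses of a kept occasion must all be IV for a clean subset
        remap = {}
        for sid in keep_subjects:
            occs = sorted({occ for s, occ in iv_occ if s == sid})
            for new, old in enumerate(occs, start=1):
                remap[(sid, old)] = new
        doses = [replace(d, occasion=remap[(d.subject_id, d.occasion)])
                 for d in self.doses if (d.subject_id, d.occasion) in remap]
        obs = [replace(o, occasion=remap[(o.subject_id, o.occasion)])
               for o in self.observations if (o.subject_id, o.occasion) in remap]
        smap = self.subject_map()
        return PKDataset([smap[sid] for sid in keep_subjects], doses, obs)

    def subset_subjects(self, subject_ids: Iterable[int]) -> "PKDataset":
        keep = set(subject_ids)
        smap = self.subject_map()
        return PKDataset(
            [smap[sid] for sid in smap if sid in keep],
            [d for d in self.doses if d.subject_id in keep],
            [o for o in self.observations if o.subject_id in keep],
        )


# ----------------------------------------------------------------------
# CSV reading / writing
# ----------------------------------------------------------------------

class DatasetFormatError(ValueError):
    """Raised for structural problems in the on-disk table."""


def _parse_float(raw, column: str, line: int) -> Optional[float]:
    if raw is None:
        return None
    s = str(raw).strip()
    if s == "" or s.lower() == "nan":
        return None
    try:
        return float(s)
    except ValueError:
        raise DatasetFormatError(
            f"line {line}: non-numeric {column} value {raw!r}") from None


def read_dataset(path, dialect: Optional[dict] = None) -> PKDataset:
    """Read a NONMEM-style CSV file into a :class:`PKDataset`.

    Raises :class:`DatasetFormatError` for a missing mandatory column or
    a non-numeric ``TIME``/``AMT``/``DV`` cell (with the 1-based file
    line number), and a ``ValueError`` when an occasion contains an
    observation before any dose.
    """
    dialect = dialect or {}
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False, **dialect)
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise DatasetFormatError(f"missing mandatory column {col!r}")

    subjects: dict = {}
    doses: list = []
    observations: list = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # 1-based, after the header row
        sid = int(_parse_float(getattr(row, "ID"), "ID", line))
        occ = int(_parse_float(getattr(row, "OCC"), "OCC", line) or 1)
        time = _parse_float(getattr(row, "TIME"), "TIME", line)
        if time is None:
            raise DatasetFormatError(f"line {line}: empty TIME")
        evid = int(_parse_float(getattr(row, "EVID"), "EVID", line))
        if sid not in subjects:
            subjects[sid] = SubjectRecord(
                subject_id=sid,
                weight0=_parse_float(getattr(row, "WT"), "WT", line) or 0.0,
                age=_parse_float(getattr(row, "AGE"), "AGE", line) or 0.0,
                gender="M" if (_parse_float(getattr(row, "SEX"), "SEX", line) or 0) else "F",
                anest=int(_parse_float(getattr(row, "ANEST"), "ANEST", line) or 0),
                study_label=str(getattr(row, "STUDY")).strip(),
            )
        if evid == 1:
            amt = _parse_float(getattr(row, "AMT"), "AMT", line)
            if amt is None:
                raise DatasetFormatError(f"line {line}: dose row with empty AMT")
            route = ROUTE_NAMES.get(int(_parse_float(getattr(row, "ROUTE"), "ROUTE", line) or 0))
            if route is None:
                raise DatasetFormatError(f"line {line}: unknown ROUTE code")
            doses.append(DoseEvent(sid, time, amt, route, occ))
        else:
            cens = bool(int(_parse_float(getattr(row, "CENS"), "CENS", line) or 0))
            dv = _parse_float(getattr(row, "DV"), "DV", line)
            lloq = _parse_float(getattr(row, "LLOQ"), "LLOQ", line) or 3.0
            predose = time == 0.0
            observations.append(Observation(
                subject_id=sid, time=time,
                value=None if cens else dv,
                censored=cens, lloq=lloq, occasion=occ, predose=predose,
            ))

    ds = PKDataset(list(subjects.values()), doses, observations)
    _check_dose_precedence(ds)
    return ds


def _check_dose_precedence(ds: PKDataset) -> None:
    first_dose: dict = {}
    for d in ds.doses:
        key = (d.subject_id, d.occasion)
        first_dose[key] = min(first_dose.get(key, math.inf), d.time)
    for o in ds.observations:
        t0 = first_dose.get((o.subject_id, o.occasion))
        if t0 is None or o.time < t0:
            raise ValueError(
                f"subject {o.subject_id} occasion {o.occasion}: observation at "
                f"t={o.time} precedes any dose")


def _fmt(x: Optional[float]) -> str:
    if x is None:
        return ""
    return f"{x:.12g}"


def write_dataset(ds: PKDataset, path) -> None:
    """Write the CSV dialect described in the module docstring.

    Rows are ordered by (subject input order, occasion, time, EVID
    descending) so doses precede simultaneous observations.
    """
    order = {s.subject_id: i for i, s in enumerate(ds.subjects)}
    smap = ds.subject_map()
    rows = []
    for d in ds.doses:
        s = smap[d.subject_id]
        rows.append((order[d.subject_id], d.occasion, d.time, -1, {
            "ID": d.subject_id, "OCC": d.occasion, "TIME": _fmt(d.time),
            "EVID": 1, "AMT": _fmt(d.amount), "ROUTE": ROUTE_CODES[d.route],
            "DV": "", "CENS": 0, "LLOQ": "", "WT": _fmt(s.weight0),
            "AGE": _fmt(s.age), "SEX": 1 if s.gender == "M" else 0,
            "ANEST": s.anest, "STUDY": s.study_label,
        }))
    for o in ds.observations:
        s = smap[o.subject_id]
        rows.append((order[o.subject_id], o.occasion, o.time, 0, {
            "ID": o.subject_id, "OCC": o.occasion, "TIME": _fmt(o.time),
            "EVID": 0, "AMT": "", "ROUTE": "",
            "DV": _fmt(o.value), "CENS": 1 if o.censored else 0,
            "LLOQ": _fmt(o.lloq), "WT": _fmt(s.weight0),
            "AGE": _fmt(s.age), "SEX": 1 if s.gender == "M" else 0,
            "ANEST": s.anest, "STUDY": s.study_label,
        }))
    rows.sort(key=lambda r: (r[0], r[1], r[2], r[3]))
    df = pd.DataFrame([r[4] for r in rows], columns=list(MANDATORY_COLUMNS))
    df.to_csv(path, index=False)


# ----------------------------------------------------------------------
# Validation
# ----------------------------------------------------------------------

def validate_dataset(ds: PKDataset,
                     weight_window=(0.5, 15.0)) -> ValidationReport:
    """Structural and plausibility checks; errors are data, not exceptions."""
    rep = ValidationReport()
    ids = {s.subject_id for s in ds.subjects}
    if len(ids) != len(ds.subjects):
        rep.errors.append("duplicate subject ids")
    for s in ds.subjects:
        if not (weight_window[0] <= s.weight0 <= weight_window[1]):
            rep.warnings.append(
                f"subject {s.subject_id}: weight {s.weight0} kg outside "
                f"plausibility window {weight_window}")
    occs: dict = {}
    for d in ds.doses:
        if d.subject_id not in ids:
            rep.errors.append(f"dose references unknown subject {d.subject_id}")
        occs.setdefault(d.subject_id, set()).add(d.occasion)
    for sid, os_ in occs.items():
        if sorted(os_) != list(range(1, len(os_) + 1)):
            rep.errors.append(
                f"subject {sid}: occasions {sorted(os_)} not consecutive from 1")
    first_dose: dict = {}
    for d in ds.doses:
        key = (d.subject_id, d.occasion)
        first_dose[key] = min(first_dose.get(key, math.inf), d.time)
    for o in ds.observations:
        if o.subject_id not in ids:
            rep.errors.append(f"observation references unknown subject {o.subject_id}")
            continue
        t0 = first_dose.get((o.subject_id, o.occasion))
        if t0 is None:
            rep.errors.append(
                f"subject {o.subject_id} occasion {o.occasion}: observation "
                "without any dose")
        elif o.time < t0:
            rep.errors.append(
                f"subject {o.subject_id} occasion {o.occasion}: observation at "
                f"t={o.time} precedes the first dose")
        if (not o.censored and not o.predose and o.value is not None
                and o.value < o.lloq):
            rep.warnings.append(
                f"subject {o.subject_id} t={o.time}: uncensored value "
                f"{o.value} below LLOQ {o.lloq}")
    return rep
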