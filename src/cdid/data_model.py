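"""Patient-level data handling for the continuous difference-in-differences model.

Reads patient-year records, applies the registry exclusion rules, reduces the
kept records to clinic-year sufficient statistics, and assembles the clinic-level
design matrix and block covariance structure used by the regression on outcome
change.

The data are never matched at the patient level across years: every quantity the
model consumes is a clinic-year summary (count, mean, sample variance, covariate
counts), which is why the sampler operates on :class:`ClinicYearSummary` /
:class:`ClinicData` rather than raw rows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

OUTCOMES = ("a1c", "ldl", "sbp")

#: Design-matrix column labels understood by :func:`build_design_matrix`.
#: ``*_diff`` columns are (2012 value − 2009 value) clinic summaries.
DESIGN_COLUMNS = (
    "intercept",
    "cdiff",
    "comm_diff",
    "age_diff",
    "fem_diff",
    "ivd_diff",
    "wlth_diff",
    "inc_diff",
    "nhw_diff",
    "c2008",
)

#: Columns that are rebuilt from latent clinic-year covariate parameters when the
#: errors-in-covariates measurement model is active.  Neighborhood (ACS) columns
#: and the clinic scores are treated as fixed.
LATENT_CAPABLE = ("comm_diff", "age_diff", "fem_diff", "ivd_diff")

YEARS = (2009, 2012)

_REQUIRED_PATIENT_COLUMNS = (
    "system_id", "clinic_id", "year", "a1c", "ldl", "sbp", "dbp",
    "commercial", "age", "female", "ivd", "diabetes_type",
    "wlth", "inc", "nhw", "a1c_date_valid", "ldl_date_valid",
)

EXCLUSION_ORDER = ("invalid_date", "a1c_range", "ldl_range", "sbp_rule", "type1")


class SchemaError(ValueError):
    """The input file does not have the documented layout."""


@dataclass(frozen=True)
class PatientRecord:
    """One patient-year row of the outcome registry.

    Outcomes are A1c (%), LDL (mg/dL) and systolic/diastolic blood pressure
    (mmHg); ``wlth``/``inc``/``nhw`` are the patient's ZIP-code neighborhood
    scores.  Missing optional values are ``None`` (or NaN for floats read from
    file and normalised to ``None`` here).
    """

    system_id: str
    clinic_id: str
    year: int
    a1c: float | None = None
    ldl: float | None = None
    sbp: float | None = None
    dbp: float | None = None
    commercial: bool | None = None
    age: float | None = None
    female: bool | None = None
    ivd: bool | None = None
    diabetes_type: int | None = None
    wlth: float | None = None
    inc: float | None = None
    nhw: float | None = None
    a1c_date_valid: bool = True
    ldl_date_valid: bool = True


@dataclass(frozen=True)
class RowError:
    line: int
    message: str


@dataclass
class ParseResult:
    """Parsed records plus row-level problems (rows that could not be parsed)."""

    records: list[PatientRecord]
    errors: list[RowError] = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)


@dataclass
class ClinicYearSummary:
    """Sufficient statistics for one clinic-year.

    ``ybar``/``s2`` are per-outcome dictionaries keyed by ``a1c``/``ldl``/``sbp``;
    sample variances use the n−1 denominator and are ``nan`` when fewer than two
    patients contributed.  Covariate counts (``x_comm``, ``x_fem``, ``x_ivd``)
    are kept as counts, not proportions, because the measurement model treats
    them as binomial draws.
    """

    system_id: str
    clinic_id: str
    year: int
    n: int
    ybar: dict[str, float]
    s2: dict[str, float]
    x_comm: int
    x_fem: int
    x_ivd: int
    age_mean: float
    age_s2: float
    wlth_mean: float
    inc_mean: float
    nhw_mean: float


@dataclass(frozen=True)
class ClinicScore:
    """Clinic transformation-maturity scores for 2008 and 2011."""

    clinic_id: str
    c2008: float
    c2011: float

    @property
    def cdiff(self) -> float:
        return self.c2011 - self.c2008


@dataclass
class DesignMatrix:
    """Clinic-level design matrix, rows ordered by system then clinic.

    ``latent_columns`` maps a latent-capable column label to its column index so
    the sampler can rebuild those entries from the current draw of the
    clinic-year covariate parameters.
    """

    X: np.ndarray
    columns: list[str]
    clinic_ids: list[str]
    system_index: np.ndarray  # int codes 0..S-1, aligned with rows
    latent_columns: dict[str, int] = field(default_factory=dict)

    @property
    def n_clinics(self) -> int:
        return self.X.shape[0]

    def column(self, label: str) -> np.ndarray:
        return self.X[:, self.columns.index(label)]


@dataclass(frozen=True)
class BlockCovariance:
    """Exchangeable-within-system block covariance.

    Realised matrix has ``diagonal_variance`` on the diagonal,
    ``within_block_covariance`` on within-system off-diagonals and zero
    elsewhere.  For the change model these are τ²+ζ² and ζ²; for the baseline
    model λ²+ω² and ω².
    """

    diagonal_variance: float
    within_block_covariance: float
    block_sizes: tuple[int, ...]

    def to_dense(self) -> np.ndarray:
        n = sum(self.block_sizes)
        out = np.zeros((n, n))
        start = 0
        for b in self.block_sizes:
            out[start:start + b, start:start + b] = self.within_block_covariance
            start += b
        np.fill_diagonal(out, self.diagonal_variance)
        return out


def _none_if_nan(x):
    if x is None:
        return None
    if isinstance(x, float) and math.isnan(x):
        return None
    return x


def _as_bool(x):
    x = _none_if_nan(x)
    if x is None:
        return None
    if isinstance(x, str):
        s = x.strip().lower()
        if s in ("true", "t", "1", "yes"):
            return True
        if s in ("false", "f", "0", "no"):
            return False
        raise ValueError(f"cannot interpret {x!r} as a boolean")
    return bool(x)


def read_patient_records(path) -> ParseResult:
    """Read ``patients.csv`` into :class:`PatientRecord` objects.

    Raises :class:`SchemaError` when a mandatory column is missing.  Rows whose
    year is not 2009/2012 or whose fields cannot be parsed are collected as
    :class:`RowError` (1-based data line numbers, header = line 1) and the
    remaining rows are returned.
    """
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED_PATIENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s): {', '.join(missing)}")

    records: list[PatientRecord] = []
    errors: list[RowError] = []
    for pos, row in enumerate(df.itertuples(index=False)):
        line = pos + 2  # header occupies line 1
        try:
            year = int(row.year)
            if year not in YEARS:
                raise ValueError(f"year must be 2009 or 2012, got {year}")
            dt = _none_if_nan(row.diabetes_type)
            records.append(PatientRecord(
                system_id=str(row.system_id),
                clinic_id=str(row.clinic_id),
                year=year,
                a1c=_none_if_nan(float(row.a1c)) if _none_if_nan(row.a1c) is not None else None,
                ldl=_none_if_nan(float(row.ldl)) if _none_if_nan(row.ldl) is not None else None,
                sbp=_none_if_nan(float(row.sbp)) if _none_if_nan(row.sbp) is not None else None,
                dbp=_none_if_nan(float(row.dbp)) if _none_if_nan(row.dbp) is not None else None,
                commercial=_as_bool(row.commercial),
                age=_none_if_nan(float(row.age)) if _none_if_nan(row.age) is not None else None,
                female=_as_bool(row.female),
                ivd=_as_bool(row.ivd),
                diabetes_type=int(dt) if dt is not None else None,
                wlth=_none_if_nan(row.wlth),
                inc=_none_if_nan(row.inc),
                nhw=_none_if_nan(row.nhw),
                a1c_date_valid=bool(_as_bool(row.a1c_date_valid)),
                ldl_date_valid=bool(_as_bool(row.ldl_date_valid)),
            ))
        except (TypeError, ValueError) as exc:
            errors.append(RowError(line=line, message=str(exc)))
    return ParseResult(records=records, errors=errors)


def _first_violation(r: PatientRecord) -> str | None:
    """First failing exclusion rule in the fixed order, or None if kept.

    Rules (registry cleaning): invalid measurement date; A1c outside [3, 25]%;
    LDL outside [0, 1000] mg/dL; SBP < 50 mmHg or below DBP; Type 1 diabetes.
    Missing values never trigger a range rule (vacuous pass).
    """
    if not (r.a1c_date_valid and r.ldl_date_valid):
        return "invalid_date"
    if r.a1c is not None and not (3.0 <= r.a1c <= 25.0):
        return "a1c_range"
    if r.ldl is not None and not (0.0 <= r.ldl <= 1000.0):
        return "ldl_range"
    if r.sbp is not None and (r.sbp < 50.0 or (r.dbp is not None and r.sbp < r.dbp)):
        return "sbp_rule"
    if r.diabetes_type == 1:
        return "type1"
    return None


def apply_exclusion_filters(
    records: Iterable[PatientRecord],
) -> tuple[list[PatientRecord], dict[str, int]]:
    """Apply the patient-year exclusion rules.

    Returns the kept records and a count of exclusions by reason.  A record
    failing several rules is counted once, under the first failing rule in the
    fixed order ``invalid_date, a1c_range, ldl_range, sbp_rule, type1``, so the
    log is additive: kept + sum(log) == input.  Never raises on data values.
    """
    kept: list[PatientRecord] = []
    log: dict[str, int] = {reason: 0 for reason in EXCLUSION_ORDER}
    for r in records:
        reason = _first_violation(r)
        if reason is None:
            kept.append(r)
        else:
            log[reason] += 1
    return kept, log


def summarize_clinic_year(
    records: Sequence[PatientRecord],
    min_n: int = 30,
) -> tuple[list[ClinicYearSummary], list[str]]:
    """Reduce kept records to clinic-year sufficient statistics.

    Clinics must appear in both years with at least ``min_n`` patient-years in
    each; clinics failing either requirement are dropped entirely and their ids
    returned in the log.  Sample variances use the n−1 denominator.
    """
    groups: dict[tuple[str, str, int], list[PatientRecord]] = {}
    for r in records:
        groups.setdefault((r.system_id, r.clinic_id, r.year), []).append(r)

    by_clinic: dict[tuple[str, str], dict[int, list[PatientRecord]]] = {}
    for (sid, cid, year), rows in groups.items():
        by_clinic.setdefault((sid, cid), {})[year] = rows

    summaries: list[ClinicYearSummary] = []
    dropped: list[str] = []
    for (sid, cid) in sorted(by_clinic):
        yrs = by_clinic[(sid, cid)]
        if set(yrs) != set(YEARS) or any(len(yrs[y]) < min_n for y in YEARS):
            dropped.append(cid)
            continue
        for year in YEARS:
            rows = yrs[year]
            summaries.append(_summarize_one(sid, cid, year, rows))
    return summaries, dropped


def _mean_s2(values: list[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        return float("nan"), float("nan")
    m = float(arr.mean())
    s2 = float(arr.var(ddof=1)) if arr.size >= 2 else float("nan")
    return m, s2


def _summarize_one(sid, cid, year, rows) -> ClinicYearSummary:
    ybar, s2 = {}, {}
    for out in OUTCOMES:
        vals = [getattr(r, out) for r in rows if getattr(r, out) is not None]
        ybar[out], s2[out] = _mean_s2(vals)
    ages = [r.age for r in rows if r.age is not None]
    age_mean, age_s2 = _mean_s2(ages)
    return ClinicYearSummary(
        system_id=sid, clinic_id=cid, year=year, n=len(rows),
        ybar=ybar, s2=s2,
        x_comm=sum(1 for r in rows if r.commercial),
        x_fem=sum(1 for r in rows if r.female),
        x_ivd=sum(1 for r in rows if r.ivd),
        age_mean=age_mean, age_s2=age_s2,
        wlth_mean=float(np.mean([r.wlth for r in rows if r.wlth is not None] or [np.nan])),
        inc_mean=float(np.mean([r.inc for r in rows if r.inc is not None] or [np.nan])),
        nhw_mean=float(np.mean([r.nhw for r in rows if r.nhw is not None] or [np.nan])),
    )


def read_clinic_scores(path) -> list[ClinicScore]:
    """Read ``scores.csv`` (clinic_id, c2008, c2011)."""
    df = pd.read_csv(path)
    missing = [c for c in ("clinic_id", "c2008", "c2011") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
    return [ClinicScore(str(r.clinic_id), float(r.c2008), float(r.c2011))
            for r in df.itertuples(index=False)]


def _pair_summaries(summaries: Sequence[ClinicYearSummary]):
    """Group summaries into (s09, s12) pairs ordered by system then clinic."""
    by_clinic: dict[tuple[str, str], dict[int, ClinicYearSummary]] = {}
    for s in summaries:
        by_clinic.setdefault((s.system_id, s.clinic_id), {})[s.year] = s
    pairs = []
    for key in sorted(by_clinic):
        yrs = by_clinic[key]
        if set(yrs) != set(YEARS):
            raise ValueError(f"clinic {key[1]} does not have both-year summaries")
        pairs.append((yrs[2009], yrs[2012]))
    return pairs


def build_design_matrix(
    summaries: Sequence[ClinicYearSummary],
    scores: Sequence[ClinicScore],
    covariate_set: Sequence[str],
    latent_values: Mapping[str, np.ndarray] | None = None,
) -> DesignMatrix:
    """Assemble the clinic-level design matrix for the change regression.

    ``covariate_set`` is an ordered subset of :data:`DESIGN_COLUMNS`; the
    intercept and ``cdiff`` columns are always present (prepended if omitted).
    Diff columns are 2012 − 2009 clinic summaries.  Clinic scores and the
    neighborhood (ACS) means are always taken from the observed data; the
    patient-mix columns (``comm/age/fem/ivd``) come from observed summaries, or
    from ``latent_values[label]`` for labels supplied there (those columns are
    flagged in ``latent_columns`` for in-sampler rebuilds).
    """
    cols = list(covariate_set)
    for required in ("cdiff", "intercept"):
        if required not in cols:
            cols.insert(0, required)
    unknown = [c for c in cols if c not in DESIGN_COLUMNS]
    if unknown:
        raise ValueError(f"unknown design column(s): {unknown}")
    # canonical ordering: as listed in DESIGN_COLUMNS
    cols = [c for c in DESIGN_COLUMNS if c in cols]

    score_map = {s.clinic_id: s for s in scores}
    pairs = _pair_summaries(summaries)
    clinic_ids = [s09.clinic_id for s09, _ in pairs]
    for cid in clinic_ids:
        if cid not in score_map:
            raise ValueError(f"clinic {cid!r} has no clinic-score entry")

    sys_ids = [s09.system_id for s09, _ in pairs]
    sys_order = sorted(dict.fromkeys(sys_ids))
    sys_code = {sid: k for k, sid in enumerate(sys_order)}
    system_index = np.array([sys_code[s] for s in sys_ids], dtype=int)

    latent_values = latent_values or {}

    def observed(label, s09, s12):
        if label == "intercept":
            return 1.0
        if label == "cdiff":
            return score_map[s09.clinic_id].cdiff
        if label == "c2008":
            return score_map[s09.clinic_id].c2008
        if label == "comm_diff":
            return s12.x_comm / s12.n - s09.x_comm / s09.n
        if label == "age_diff":
            return s12.age_mean - s09.age_mean
        if label == "fem_diff":
            return s12.x_fem / s12.n - s09.x_fem / s09.n
        if label == "ivd_diff":
            return s12.x_ivd / s12.n - s09.x_ivd / s09.n
        if label == "wlth_diff":
            return s12.wlth_mean - s09.wlth_mean
        if label == "inc_diff":
            return s12.inc_mean - s09.inc_mean
        if label == "nhw_diff":
            return s12.nhw_mean - s09.nhw_mean
        raise AssertionError(label)

    X = np.empty((len(pairs), len(cols)))
    latent_columns: dict[str, int] = {}
    for k, label in enumerate(cols):
        if label in latent_values:
            if label not in LATENT_CAPABLE:
                raise ValueError(f"column {label!r} cannot be driven by latent values")
            X[:, k] = np.asarray(latent_values[label], dtype=float)
            latent_columns[label] = k
        else:
            X[:, k] = [observed(label, s09, s12) for s09, s12 in pairs]
    return DesignMatrix(X=X, columns=cols, clinic_ids=clinic_ids,
                        system_index=system_index, latent_columns=latent_columns)


def build_block_covariance(
    residual_variance: float,
    system_variance: float,
    block_sizes: Sequence[int],
) -> BlockCovariance:
    """Block covariance with residual variance on top of a shared system effect.

    Diagonal entries are ``residual_variance + system_variance``; within-system
    off-diagonals equal ``system_variance``.
    """
    if residual_variance <= 0:
        raise ValueError(f"residual_variance must be > 0, got {residual_variance}")
    if system_variance < 0:
        raise ValueError(f"system_variance must be >= 0, got {system_variance}")
    return BlockCovariance(
        diagonal_variance=residual_variance + system_variance,
        within_block_covariance=system_variance,
        block_sizes=tuple(int(b) for b in block_sizes),
    )
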