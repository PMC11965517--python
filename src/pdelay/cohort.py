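"""Cohort data model and I/O for long-format longitudinal visit data.

A :class:`Cohort` bundles three tables: per-individual covariates, long-format
visit measurements (individual, outcome, time since diagnosis in years, value)
and per-outcome metadata (:class:`OutcomeSpec`).  Times are signed years since
clinical diagnosis; negative times (pre-diagnosis visits) are allowed.

The module also implements outcome min-max normalization on the theoretical
scale ranges (with inversion for "higher is better" scales such as the MoCA),
the longitudinal inclusion filters, and tremor-dominant / PIGD motor-phenotype
classification from sub-score ratios.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SCALE_KINDS = ("continuous", "ordinal", "binary")

VISIT_COLUMNS = ["individual_id", "outcome", "time_years", "value"]
INDIVIDUAL_COLUMNS = ["individual_id", "age_at_diagnosis", "sex"]
OPTIONAL_INDIVIDUAL_COLUMNS = ["progression_subtype", "reported_time_to_diagnosis"]
SPEC_COLUMNS = ["outcome", "scale_kind", "min", "max", "invert", "domain", "in_ltjmm"]


class CohortError(ValueError):
    """Base class for cohort validation errors."""


class SchemaError(CohortError):
    """A mandatory column is missing or malformed."""


class ReferentialError(CohortError):
    """A measurement references an undeclared individual or outcome."""


class UniquenessError(CohortError):
    """Duplicate (individual, outcome, time) measurement rows."""


class RangeError(CohortError):
    """A value lies outside the declared theoretical range."""


class StateError(CohortError):
    """Operation applied to a cohort in the wrong state (e.g. re-normalizing)."""


class DegenerateDataError(CohortError):
    """Filtering removed all usable data."""


@dataclass(frozen=True)
class OutcomeSpec:
    """Metadata for one clinical outcome.

    Parameters
    ----------
    name
        Outcome identifier, e.g. ``"updrs3"``.
    scale_kind
        One of ``continuous``, ``ordinal``, ``binary``.
    theoretical_min, theoretical_max
        Theoretical range of the score used for min-max normalization.
    invert
        If True the scale runs "higher is better" (e.g. MoCA) and is flipped
        during normalization so disease progression has a positive slope.
    domain
        Symptom-domain label used as the meta-analysis unit, or ``None``.
    in_ltjmm
        Whether the outcome enters the joint latent-time fit (continuous only).
    """

    name: str
    scale_kind: str
    theoretical_min: float
    theoretical_max: float
    invert: bool = False
    domain: str | None = None
    in_ltjmm: bool = False

    def __post_init__(self) -> None:
        if self.scale_kind not in SCALE_KINDS:
            raise SchemaError(
                f"outcome {self.name!r}: unknown scale_kind {self.scale_kind!r}"
            )
        if self.scale_kind in ("continuous", "ordinal"):
            if not self.theoretical_max > self.theoretical_min:
                raise SchemaError(
                    f"outcome {self.name!r}: theoretical_max must exceed theoretical_min"
                )
        if self.in_ltjmm and self.scale_kind != "continuous":
            raise SchemaError(
                f"outcome {self.name!r}: only continuous outcomes may enter the LTJMM"
            )


@dataclass(frozen=True)
class IndividualRecord:
    id: str
    age_at_diagnosis: float
    sex: str
    progression_subtype: str | None = None
    patient_reported_time_to_diagnosis: float | None = None

    def __post_init__(self) -> None:
        if not self.age_at_diagnosis > 0:
            raise SchemaError(f"individual {self.id!r}: age_at_diagnosis must be > 0")
        if self.sex not in ("male", "female"):
            raise SchemaError(f"individual {self.id!r}: sex must be male/female")


@dataclass
class Cohort:
    """One study cohort: individuals, measurements and outcome specs.

    ``individuals`` is indexed by ``individual_id`` with columns
    ``age_at_diagnosis, sex, progression_subtype, reported_time_to_diagnosis``;
    ``measurements`` is long format with columns
    ``individual_id, outcome, time_years, value``.
    """

    name: str
    individuals: pd.DataFrame
    measurements: pd.DataFrame
    specs: dict[str, OutcomeSpec]
    normalized: bool = False
    filter_report: dict | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- accessors ---------------------------------------------------------

    @property
    def individual_ids(self) -> list[str]:
        return list(self.individuals.index)

    def spec(self, outcome: str) -> OutcomeSpec:
        try:
            return self.specs[outcome]
        except KeyError:
            raise ReferentialError(f"unknown outcome {outcome!r}") from None

    def ltjmm_outcomes(self) -> list[str]:
        return [k for k, s in self.specs.items() if s.in_ltjmm]

    def measurements_for(self, outcome: str) -> pd.DataFrame:
        self.spec(outcome)
        return self.measurements[self.measurements["outcome"] == outcome]

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        missing = [c for c in VISIT_COLUMNS if c not in self.measurements.columns]
        if missing:
            raise SchemaError(f"measurements table missing column(s) {missing}")
        for col in ("age_at_diagnosis", "sex"):
            if col not in self.individuals.columns:
                raise SchemaError(f"individuals table missing column {col!r}")
        if (self.individuals["age_at_diagnosis"] <= 0).any():
            bad = self.individuals.index[self.individuals["age_at_diagnosis"] <= 0]
            raise SchemaError(f"non-positive age_at_diagnosis for {list(bad)}")
        bad_sex = ~self.individuals["sex"].isin(["male", "female"])
        if bad_sex.any():
            raise SchemaError(
                f"invalid sex for {list(self.individuals.index[bad_sex])}"
            )

        m = self.measurements
        unknown_ind = set(m["individual_id"]) - set(self.individuals.index)
        if unknown_ind:
            raise ReferentialError(
                f"measurements reference unknown individual(s) {sorted(unknown_ind)[:5]}"
            )
        unknown_out = set(m["outcome"]) - set(self.specs)
        if unknown_out:
            raise ReferentialError(
                f"measurements reference unknown outcome(s) {sorted(unknown_out)[:5]}"
            )
        dup = m.duplicated(subset=["individual_id", "outcome", "time_years"])
        if dup.any():
            raise UniquenessError(
                f"{int(dup.sum())} duplicate (individual, outcome, time) rows, "
                f"first at index {m.index[dup][0]}"
            )
        # integer-valued categories within the declared range
        for k, spec in self.specs.items():
            if spec.scale_kind in ("ordinal", "binary"):
                vals = m.loc[m["outcome"] == k, "value"]
                if len(vals) == 0:
                    continue
                if not np.allclose(vals, np.round(vals)):
                    raise RangeError(f"outcome {k!r}: non-integer ordinal/binary values")
                lo, hi = spec.theoretical_min, spec.theoretical_max
                if spec.scale_kind == "binary":
                    lo, hi = 0, 1
                if (vals < lo).any() or (vals > hi).any():
                    raise RangeError(f"outcome {k!r}: values outside [{lo}, {hi}]")

    def copy(self) -> "Cohort":
        return Cohort(
            name=self.name,
            individuals=self.individuals.copy(),
            measurements=self.measurements.copy(),
            specs=dict(self.specs),
            normalized=self.normalized,
            filter_report=dict(self.filter_report) if self.filter_report else None,
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _specs_from_frame(df: pd.DataFrame) -> dict[str, OutcomeSpec]:
    missing = [c for c in SPEC_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"specs table missing column(s) {missing}")
    specs: dict[str, OutcomeSpec] = {}
    for row in df.itertuples(index=False):
        domain = None if pd.isna(row.domain) or row.domain == "" else str(row.domain)
        specs[str(row.outcome)] = OutcomeSpec(
            name=str(row.outcome),
            scale_kind=str(row.scale_kind),
            theoretical_min=float(row.min),
            theoretical_max=float(row.max),
            invert=_as_bool(row.invert),
            domain=domain,
            in_ltjmm=_as_bool(row.in_ltjmm),
        )
    return specs


def _as_bool(x) -> bool:
    if isinstance(x, str):
        return x.strip().lower() in ("true", "1", "yes")
    return bool(x)


def read_cohort(
    visits_path: str | Path,
    individuals_path: str | Path,
    specs_path: str | Path,
    name: str | None = None,
) -> Cohort:
    """Read a cohort from three delimited text files (see module docs).

    Rows with missing ``value`` are dropped (count logged).  Schema,
    referential and uniqueness violations raise the corresponding error.
    """
    visits = pd.read_csv(visits_path)
    missing = [c for c in VISIT_COLUMNS if c not in visits.columns]
    if missing:
        raise SchemaError(f"visits file missing column(s) {missing}")
    n_missing = int(visits["value"].isna().sum())
    if n_missing:
        logger.info("read_cohort: dropping %d rows with missing value", n_missing)
        visits = visits.dropna(subset=["value"])
    visits = visits.reset_index(drop=True)
    visits["individual_id"] = visits["individual_id"].astype(str)

    individuals = pd.read_csv(individuals_path)
    missing = [c for c in INDIVIDUAL_COLUMNS if c not in individuals.columns]
    if missing:
        raise SchemaError(f"individuals file missing column(s) {missing}")
    for col in OPTIONAL_INDIVIDUAL_COLUMNS:
        if col not in individuals.columns:
            individuals[col] = np.nan
    individuals["individual_id"] = individuals["individual_id"].astype(str)
    individuals = individuals.set_index("individual_id")

    specs = _specs_from_frame(pd.read_csv(specs_path))
    return Cohort(
        name=name or Path(visits_path).stem,
        individuals=individuals,
        measurements=visits,
        specs=specs,
    )


def write_cohort(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write a cohort to ``visits.csv``, ``individuals.csv``, ``specs.csv``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "visits": out / "visits.csv",
        "individuals": out / "individuals.csv",
        "specs": out / "specs.csv",
    }
    cohort.measurements.to_csv(paths["visits"], index=False)
    cohort.individuals.reset_index().to_csv(paths["individuals"], index=False)
    spec_rows = [
        {
            "outcome": s.name,
            "scale_kind": s.scale_kind,
            "min": s.theoretical_min,
            "max": s.theoretical_max,
            "invert": s.invert,
            "domain": s.domain if s.domain is not None else "",
            "in_ltjmm": s.in_ltjmm,
        }
        for s in cohort.specs.values()
    ]
    pd.DataFrame(spec_rows, columns=SPEC_COLUMNS).to_csv(paths["specs"], index=False)
    return paths


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def normalize_outcomes(cohort: Cohort) -> Cohort:
    """Min-max normalize continuous outcomes on their theoretical ranges.

    Non-inverted scales map ``v -> (v - min) / (max - min)``; inverted scales
    ("higher is better") map ``v -> (max - v) / (max - min)`` so progression
    has a positive slope everywhere.  Ordinal and binary values are unchanged.
    Raises :class:`StateError` if the cohort is already normalized and
    :class:`RangeError` for values outside the theoretical range.
    """
    if cohort.normalized:
        raise StateError(f"cohort {cohort.name!r} is already normalized")
    m = cohort.measurements.copy()
    for k, spec in cohort.specs.items():
        if spec.scale_kind != "continuous":
            continue
        lo, hi = spec.theoretical_min, spec.theoretical_max
        if not (np.isfinite(lo) and np.isfinite(hi)):
            raise RangeError(f"outcome {k!r}: non-finite theoretical range")
        mask = m["outcome"] == k
        vals = m.loc[mask, "value"]
        bad = (vals < lo) | (vals > hi)
        if bad.any():
            ind = m.loc[mask].loc[bad, "individual_id"].iloc[0]
            raise RangeError(
                f"outcome {k!r}: value outside [{lo}, {hi}] "
                f"(e.g. individual {ind!r})"
            )
        if spec.invert:
            m.loc[mask, "value"] = (hi - vals) / (hi - lo)
        else:
            m.loc[mask, "value"] = (vals - lo) / (hi - lo)
    new = cohort.copy()
    new.measurements = m
    new.normalized = True
    return new


# ---------------------------------------------------------------------------
# inclusion filters
# ---------------------------------------------------------------------------


def apply_inclusion_filters(
    cohort: Cohort,
    min_visits: int = 2,
    min_individuals_per_outcome: int = 30,
    min_measurements_per_individual_outcome: int = 2,
) -> Cohort:
    """Apply the longitudinal inclusion filters.

    In order: (1) individuals with fewer than ``min_visits`` distinct visit
    times are removed; (2) per outcome, individual series with fewer than
    ``min_measurements_per_individual_outcome`` measurements are removed;
    (3) outcomes retained by fewer than ``min_individuals_per_outcome``
    individuals are removed entirely.  The step-by-step removal counts are
    attached as ``filter_report``.
    """
    m = cohort.measurements
    report: dict[str, object] = {
        "n_measurements_in": int(len(m)),
        "n_individuals_in": int(len(cohort.individuals)),
    }

    visits_per_ind = m.groupby("individual_id")["time_years"].nunique()
    keep_ind = set(visits_per_ind.index[visits_per_ind >= min_visits])
    removed_individuals = [
        i for i in cohort.individuals.index if i not in keep_ind
    ]
    m = m[m["individual_id"].isin(keep_ind)]
    report["individuals_removed_min_visits"] = len(removed_individuals)

    series_len = m.groupby(["individual_id", "outcome"])["time_years"].transform("size")
    short = series_len < min_measurements_per_individual_outcome
    report["series_removed_short"] = int(
        m[short].groupby(["individual_id", "outcome"]).ngroups
    )
    m = m[~short]

    ind_per_outcome = m.groupby("outcome")["individual_id"].nunique()
    keep_out = set(ind_per_outcome.index[ind_per_outcome >= min_individuals_per_outcome])
    dropped_outcomes = sorted(set(m["outcome"]) - keep_out)
    m = m[m["outcome"].isin(keep_out)]
    report["outcomes_removed"] = dropped_outcomes
    report["n_measurements_out"] = int(len(m))

    if len(m) == 0:
        raise DegenerateDataError(
            f"cohort {cohort.name!r}: no measurements left after filtering"
        )

    new = cohort.copy()
    new.individuals = cohort.individuals.loc[
        [i for i in cohort.individuals.index if i in keep_ind]
    ]
    new.measurements = m.reset_index(drop=True)
    new.filter_report = report
    return new


# ---------------------------------------------------------------------------
# motor phenotype
# ---------------------------------------------------------------------------


def classify_motor_phenotype(
    cohort: Cohort,
    tremor_items: Sequence[str],
    pigd_items: Sequence[str],
    td_threshold: float = 1.15,
    pigd_threshold: float = 0.90,
) -> pd.Series:
    """Classify individuals as TD / PIGD / indeterminate from sub-score ratios.

    Uses the earliest visit at which all named items are available (baseline,
    least progression-confounded).  ratio = mean(tremor) / mean(pigd);
    ratio >= ``td_threshold`` -> TD, ratio <= ``pigd_threshold`` -> PIGD, else
    indeterminate.  A zero PIGD mean yields TD when the tremor mean is
    positive, else indeterminate.  Individuals without a complete baseline are
    labelled missing (NaN) and logged.
    """
    items = list(tremor_items) + list(pigd_items)
    for it in items:
        cohort.spec(it)
    m = cohort.measurements[cohort.measurements["outcome"].isin(items)]
    wide = m.pivot_table(
        index=["individual_id", "time_years"], columns="outcome", values="value"
    )
    labels: dict[str, object] = {}
    n_absent = 0
    for ind in cohort.individuals.index:
        try:
            sub = wide.loc[ind]
        except KeyError:
            sub = pd.DataFrame()
        complete = (
            sub.dropna(subset=[c for c in items if c in sub.columns])
            if not sub.empty and all(c in sub.columns for c in items)
            else pd.DataFrame()
        )
        if complete.empty:
            labels[ind] = np.nan
            n_absent += 1
            continue
        base = complete.sort_index().iloc[0]
        tremor_mean = float(base[list(tremor_items)].mean())
        pigd_mean = float(base[list(pigd_items)].mean())
        if pigd_mean == 0:
            labels[ind] = "TD" if tremor_mean > 0 else "indeterminate"
        else:
            ratio = tremor_mean / pigd_mean
            if ratio >= td_threshold:
                labels[ind] = "TD"
            elif ratio <= pigd_threshold:
                labels[ind] = "PIGD"
            else:
                labels[ind] = "indeterminate"
    if n_absent:
        logger.info(
            "classify_motor_phenotype: %d individuals without complete baseline items",
            n_absent,
        )
    return pd.Series(labels, name="motor_phenotype")
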