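"""Cohort stratification by sex, decade age class, prescription type and
diabetes status, plus sample-representativeness checks.

Age classes are decades starting at 15, upper-inclusive — (15,25],
(25,35], ..., (75,85] — with a terminal open-ended class (85,110].  The
first class additionally includes its lower bound so that age 15, the
youngest age seen in adult primary care, is assigned.  A record is
stratified by the patient's age *at the prescription date*, so one patient
may contribute to several age strata over a multi-year window; each
stratum's denominator counts the distinct patients contributing at least
one record to it.

Diabetes is a patient-level label: a patient is diabetic (D) iff at least
one of their Drug prescriptions carries an ICD-9 code in 250.00-250.99,
assessed over the patient's full record history and then applied uniformly
in every stratum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .records import MIN_AGE, RX_TYPES

AGE_CLASS_EDGES: tuple[int, ...] = (15, 25, 35, 45, 55, 65, 75, 85, 110)

AGE_CLASSES: tuple[str, ...] = tuple(
    f"({lo},{hi}]" for lo, hi in zip(AGE_CLASS_EDGES[:-1], AGE_CLASS_EDGES[1:])
)


def assign_age_class(age: int) -> str:
    """Decade age class of an integer age (upper-inclusive bounds).

    Ages above 85 all fall in the terminal class ``(85,110]``; ages below
    15 are out of scope (paediatric care) and raise ``ValueError``.
    """
    if age < MIN_AGE:
        raise ValueError(f"age {age} is below the adult primary-care minimum of {MIN_AGE}")
    for lo, hi in zip(AGE_CLASS_EDGES[:-2], AGE_CLASS_EDGES[1:-1]):
        if age <= hi:
            return f"({lo},{hi}]"
    return AGE_CLASSES[-1]


def assign_age_classes(ages: pd.Series) -> pd.Series:
    """Vectorised :func:`assign_age_class`."""
    if (ages < MIN_AGE).any():
        raise ValueError("ages below 15 cannot be assigned an adult age class")
    edges = list(AGE_CLASS_EDGES[:-1]) + [np.inf]
    cut = pd.cut(ages, bins=edges, right=True, labels=AGE_CLASSES, include_lowest=True)
    return cut.astype(object)


def diabetic_patient_ids(records: pd.DataFrame) -> set[str]:
    """IDs of patients with >=1 Drug prescription coded 250.00-250.99."""
    is_diab_rx = records["rx_type"].eq("Drug") & records["icd9_code"].str.match(
        r"^250(\.\d{1,2})?$"
    )
    return set(records.loc[is_diab_rx, "patient_id"].unique())


def classify_diabetes(patient_records: pd.DataFrame) -> str:
    """``'D'`` or ``'ND'`` for the records of a single patient.

    An empty record list is non-evidence and returns ``'ND'``.
    """
    if len(patient_records) and patient_records["patient_id"].nunique() > 1:
        raise ValueError("classify_diabetes expects the records of one patient")
    return "D" if diabetic_patient_ids(patient_records) else "ND"


@dataclass(frozen=True)
class StratumSpec:
    """A population slice: sex x age class x prescription type x diabetes."""

    sex: str = "all"          # M, F or all
    age_class: str = "all"    # one of AGE_CLASSES or all
    rx_type: str = "all"      # one of RX_TYPES or all
    diabetes: str = "all"     # D, ND or all

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F", "all"):
            raise ValueError(f"bad sex {self.sex!r}")
        if self.age_class != "all" and self.age_class not in AGE_CLASSES:
            raise ValueError(f"bad age class {self.age_class!r}")
        if self.rx_type != "all" and self.rx_type not in RX_TYPES:
            raise ValueError(f"bad rx_type {self.rx_type!r}")
        if self.diabetes not in ("D", "ND", "all"):
            raise ValueError(f"bad diabetes label {self.diabetes!r}")

    def label(self) -> str:
        return f"sex={self.sex},age={self.age_class},type={self.rx_type},diab={self.diabetes}"


@dataclass
class Stratum:
    """Records of one population slice plus its patient denominator."""

    spec: StratumSpec
    records: pd.DataFrame
    patient_ids: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.patient_ids = set(self.records["patient_id"].unique())

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)


def stratify(
    records: pd.DataFrame,
    specs: list[StratumSpec],
    diabetic_ids: set[str] | None = None,
) -> list[Stratum]:
    """Slice validated records into the requested strata.

    The diabetes label is computed globally from *all* records (or taken
    from ``diabetic_ids``) before slicing, so a patient carries the same
    label in every stratum.
    """
    if diabetic_ids is None:
        diabetic_ids = diabetic_patient_ids(records)
    age_class = assign_age_classes(records["age"])
    is_diab = records["patient_id"].isin(diabetic_ids)

    out = []
    for spec in specs:
        mask = pd.Series(True, index=records.index)
        if spec.sex != "all":
            mask &= records["sex"].eq(spec.sex)
        if spec.age_class != "all":
            mask &= age_class.eq(spec.age_class)
        if spec.rx_type != "all":
            mask &= records["rx_type"].eq(spec.rx_type)
        if spec.diabetes == "D":
            mask &= is_diab
        elif spec.diabetes == "ND":
            mask &= ~is_diab
        out.append(Stratum(spec=spec, records=records[mask]))
    return out


def age_strata(
    records: pd.DataFrame,
    sex: str = "all",
    rx_type: str = "all",
    diabetes: str = "all",
    diabetic_ids: set[str] | None = None,
) -> list[Stratum]:
    """Convenience: the full age-ordered partition for one sex/type/diabetes slice."""
    specs = [
        StratumSpec(sex=sex, age_class=ac, rx_type=rx_type, diabetes=diabetes)
        for ac in AGE_CLASSES
    ]
    return stratify(records, specs, diabetic_ids=diabetic_ids)


@dataclass(frozen=True)
class RepresentativenessResult:
    r_squared: float
    chi_square: float
    dof: int
    p_value: float


def representativeness(
    sample_hist: pd.DataFrame, reference_hist: pd.DataFrame
) -> dict[str, RepresentativenessResult]:
    """Compare a sample age distribution with a reference population.

    Both inputs are tables with columns ``age_class``, ``count`` and
    optionally ``sex``; results are computed per sex (or under the key
    ``'all'``).  ``r_squared`` is the squared Pearson correlation of the
    age-class percentages; the chi-square statistic is the goodness of fit
    of the sample counts against the reference proportions.  Note the two
    answer different questions: percentages can be strongly linearly
    related (r^2 near 1) while a large sample still rejects exact equality
    of the distributions.
    """
    for name, h in (("sample", sample_hist), ("reference", reference_hist)):
        if not {"age_class", "count"} <= set(h.columns):
            raise ValueError(f"{name} histogram needs age_class and count columns")

    def by_sex(h: pd.DataFrame) -> dict[str, pd.Series]:
        if "sex" in h.columns:
            return {
                s: g.set_index("age_class")["count"].astype(float)
                for s, g in h.groupby("sex")
            }
        return {"all": h.set_index("age_class")["count"].astype(float)}

    samples, refs = by_sex(sample_hist), by_sex(reference_hist)
    if set(samples) != set(refs):
        raise ValueError("sample and reference cover different sexes")

    out: dict[str, RepresentativenessResult] = {}
    for sex, s in samples.items():
        r = refs[sex]
        if set(s.index) != set(r.index):
            raise ValueError("sample and reference use different age classes")
        r = r.reindex(s.index)
        if (r <= 0).any():
            raise ValueError("reference counts must be positive")
        s_pct = 100 * s / s.sum()
        r_pct = 100 * r / r.sum()
        if len(s) > 1 and s_pct.std() > 0 and r_pct.std() > 0:
            r2 = float(np.corrcoef(s_pct, r_pct)[0, 1] ** 2)
        else:
            r2 = float("nan")
        expected = r / r.sum() * s.sum()
        chi2, p = scipy.stats.chisquare(f_obs=s, f_exp=expected)
        out[sex] = RepresentativenessResult(
            r_squared=r2, chi_square=float(chi2), dof=len(s) - 1, p_value=float(p)
        )
    return out
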