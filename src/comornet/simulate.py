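"""Synthetic GP-prescription cohort generator.

Emulates the statistical structure the downstream analysis assumes: an
adult (15+) population with configurable sex ratio, decade age mix and
diabetes prevalence; per-patient visit processes with age-dependent
inter-visit gaps (uniform within 20-70 days for non-diabetics, 17-40 days
for diabetics, who see their GP more often); and, at each visit, diagnosis
groups drawn from two mechanisms — independent per-group base draws and
coupled pair draws — whose second-order structure is exactly what the
comorbidity network measures.

Rates are parameterised per patient-year.  A group's base rate and a
pair's coupling rate are converted to per-visit probabilities by dividing
by the expected number of visits per year for the patient's current age
class and diabetes status, so an annual rate of r yields ~r events per
patient-year regardless of visit frequency.  In particular the expected
D/ND link-weight ratio of a pair equals its configured diabetic coupling
multiplier, which makes parameter-recovery experiments well-posed.

Every drawn group emits one prescription record with a representative
ICD-9-CM code of that chapter and a prescription type drawn from the
group's type mix.  Any record coded with stem 250 (diabetes) is emitted as
a Drug prescription, and only diabetic patients draw 250.xx codes, so the
generator's diabetes labels are recoverable from the records by the
standard rule (Drug prescriptions in 250.00-250.99).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import reference
from .cohort import AGE_CLASSES
from .icd9 import GROUPS
from .records import RX_TYPES, ObservationWindow

N_CLASSES = len(AGE_CLASSES)
N_GROUPS = len(GROUPS)
_GROUP_IDX = {g: i for i, g in enumerate(GROUPS)}
_CLASS_UPPER = np.array([25, 35, 45, 55, 65, 75, 85])  # searchsorted boundaries

#: Representative ICD-9-CM codes per chapter (the mapper's exercise codes).
CODE_POOLS: dict[str, tuple[str, ...]] = {
    "INFE": ("008.8", "038.9", "079.99"),
    "NEOP": ("174.9", "185", "162.9"),
    "META": ("272.0", "244.9", "274.9"),
    "BLD": ("280.9", "285.9"),
    "MENT": ("300.00", "311"),
    "NERV": ("331.0", "346.90"),
    "SENS": ("366.9", "389.10"),
    "CIRC": ("401.9", "414.00", "427.31"),
    "RESP": ("466.0", "493.90", "486"),
    "DIGE": ("530.81", "535.50", "564.0"),
    "GEN": ("592.0", "599.0", "600.00"),
    "PREG": ("650",),
    "SKIN": ("682.9", "692.9"),
    "MUSC": ("715.90", "724.2"),
    "CONG": ("745.5",),
    "NEWB": ("774.6",),
    "ILL": ("780.79", "786.50"),
    "INJ": ("845.00", "959.9"),
    "SUPP": ("V70.0", "V58.69"),
    "EXT": ("E849.0",),
}

#: Diabetes diagnosis codes; emitted only for diabetic patients, as Drug.
DIABETIC_META_CODES: tuple[str, ...] = ("250.00", "250.01", "250.40", "250.60")


@dataclass(frozen=True)
class PopulationConfig:
    """Synthetic population: size, sex ratio, age mix, diabetes prevalence."""

    n_patients: int
    sex_ratio: float = 0.48  # fraction male
    age_weights: tuple[float, ...] = (0.14, 0.16, 0.16, 0.15, 0.14, 0.12, 0.08, 0.05)
    diabetes_prevalence: float = 0.08
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be non-negative")
        if not 0 <= self.sex_ratio <= 1:
            raise ValueError("sex_ratio must lie in [0, 1]")
        if not 0 <= self.diabetes_prevalence <= 1:
            raise ValueError("diabetes_prevalence must lie in [0, 1]")
        w = np.asarray(self.age_weights, dtype=float)
        if len(w) != N_CLASSES or (w < 0).any() or not np.isclose(w.sum(), 1.0):
            raise ValueError("age_weights must be 8 non-negative weights summing to 1")

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationConfig":
        if "age_weights" in d:
            d = {**d, "age_weights": tuple(d["age_weights"])}
        return cls(**d)


@dataclass
class MorbidityModel:
    """Rates and couplings driving the prescription process.

    ``base_rates[c, g]`` is the expected annual number of base-draw
    prescriptions of group g for a patient in age class c;
    ``coupling[g, h] * coupling_age_scale[c]`` the expected annual number
    of coupled g-h co-prescription events.  Diabetic patients multiply
    rates by ``diabetes_rate_mult[g]`` and couplings by
    ``diabetes_coupling_mult[g, h]``, and visit on the 17-40 day rhythm of
    ``visit_gap_d`` instead of the 20-70 day ``visit_gap_nd``.
    """

    base_rates: np.ndarray                      # (n_classes, n_groups)
    coupling: np.ndarray                        # (n_groups, n_groups), sym, 0 diag
    coupling_age_scale: np.ndarray = field(
        default_factory=lambda: np.ones(N_CLASSES)
    )
    diabetes_rate_mult: np.ndarray = field(
        default_factory=lambda: np.ones(N_GROUPS)
    )
    diabetes_coupling_mult: np.ndarray = field(
        default_factory=lambda: np.ones((N_GROUPS, N_GROUPS))
    )
    visit_gap_nd: np.ndarray = field(
        default_factory=lambda: np.tile([20.0, 70.0], (N_CLASSES, 1))
    )
    visit_gap_d: np.ndarray = field(
        default_factory=lambda: np.tile([17.0, 40.0], (N_CLASSES, 1))
    )
    type_mix: np.ndarray | None = None          # (n_groups, 6), rows sum to 1
    code_pools: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(CODE_POOLS)
    )
    diabetic_meta_codes: tuple[str, ...] = DIABETIC_META_CODES
    diabetic_meta_prob: float = 0.8  # P(a diabetic's META record is a 250.xx Drug)

    def __post_init__(self) -> None:
        self.base_rates = np.asarray(self.base_rates, dtype=float)
        self.coupling = np.asarray(self.coupling, dtype=float)
        if self.base_rates.shape != (N_CLASSES, N_GROUPS):
            raise ValueError(f"base_rates must be ({N_CLASSES}, {N_GROUPS})")
        if (self.base_rates < 0).any():
            raise ValueError("base_rates must be non-negative")
        if self.coupling.shape != (N_GROUPS, N_GROUPS):
            raise ValueError(f"coupling must be ({N_GROUPS}, {N_GROUPS})")
        if not np.allclose(self.coupling, self.coupling.T):
            raise ValueError("coupling must be symmetric")
        if np.diagonal(self.coupling).any():
            raise ValueError("coupling diagonal must be zero")
        if (self.coupling < 0).any():
            raise ValueError("coupling must be non-negative")
        for name, gaps, lo, hi in (
            ("visit_gap_nd", self.visit_gap_nd, 20.0, 70.0),
            ("visit_gap_d", self.visit_gap_d, 17.0, 40.0),
        ):
            g = np.asarray(gaps, dtype=float)
            if g.shape != (N_CLASSES, 2) or (g[:, 0] > g[:, 1]).any():
                raise ValueError(f"{name} must be ({N_CLASSES}, 2) with lo <= hi")
            if (g < lo).any() or (g > hi).any():
                raise ValueError(f"{name} intervals must lie within [{lo}, {hi}] days")
        if self.type_mix is None:
            self.type_mix = default_type_mix()
        self.type_mix = np.asarray(self.type_mix, dtype=float)
        if self.type_mix.shape != (N_GROUPS, len(RX_TYPES)) or not np.allclose(
            self.type_mix.sum(axis=1), 1.0
        ):
            raise ValueError("type_mix rows must be probabilities summing to 1")

    def visits_per_year(self, class_idx: np.ndarray, diabetic: np.ndarray) -> np.ndarray:
        """Expected visit frequency for each (age class, diabetes status)."""
        mean_nd = self.visit_gap_nd.mean(axis=1)
        mean_d = self.visit_gap_d.mean(axis=1)
        mean_gap = np.where(diabetic, mean_d[class_idx], mean_nd[class_idx])
        return 365.0 / mean_gap

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
        d["code_pools"] = {g: list(p) for g, p in self.code_pools.items()}
        d["diabetic_meta_codes"] = list(self.diabetic_meta_codes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MorbidityModel":
        d = dict(d)
        for k in (
            "base_rates", "coupling", "coupling_age_scale", "diabetes_rate_mult",
            "diabetes_coupling_mult", "visit_gap_nd", "visit_gap_d", "type_mix",
        ):
            if k in d and d[k] is not None:
                d[k] = np.asarray(d[k], dtype=float)
        if "code_pools" in d:
            d["code_pools"] = {g: tuple(p) for g, p in d["code_pools"].items()}
        if "diabetic_meta_codes" in d:
            d["diabetic_meta_codes"] = tuple(d["diabetic_meta_codes"])
        return cls(**d)


def group_shares() -> np.ndarray:
    """Relative prescription volume per group, from the reference table
    (EXT, absent there, gets a token share)."""
    counts = np.array(
        [reference.GROUP_COUNTS.get(g, 500.0) for g in GROUPS], dtype=float
    )
    return counts / counts.sum()


def default_type_mix() -> np.ndarray:
    """Per-group prescription-type probabilities from the reference table."""
    mix = np.empty((N_GROUPS, len(RX_TYPES)))
    for i, g in enumerate(GROUPS):
        row = np.asarray(
            reference.GROUP_TYPE_PCT.get(g, reference.GROUP_TYPE_PCT["INJ"]),
            dtype=float,
        )
        mix[i] = row / row.sum()
    return mix


#: Relative morbidity by age class: rising through (75,85], lower again in
#: the open-ended 85+ class (the "survivor" dip seen in elderly cohorts).
DEFAULT_AGE_PROFILE = np.array([0.55, 0.70, 0.85, 1.00, 1.25, 1.55, 1.90, 1.30])


def default_morbidity_model(
    overall_rate: float = 10.5,
    coupling_scale: float = 6.0,
    age_profile: np.ndarray = DEFAULT_AGE_PROFILE,
) -> MorbidityModel:
    """Realistic defaults: group mix and type mix from the reference cohort,
    ~``overall_rate`` prescriptions per patient-year, morbidity and coupling
    rising with age, diabetics with elevated META/CIRC rates and a strongly
    enriched CIRC-META coupling."""
    shares = group_shares()
    coupling = coupling_scale * np.outer(shares, shares)
    np.fill_diagonal(coupling, 0.0)
    # coupled pair draws emit two records each; subtract their expected
    # annual record volume so the cohort total stays near overall_rate
    coupled_records = coupling.sum()
    base_total = max(overall_rate - coupled_records, 0.1 * overall_rate)
    base = base_total * np.outer(age_profile, shares)
    rate_mult = np.full(N_GROUPS, 1.3)
    rate_mult[_GROUP_IDX["META"]] = 3.0
    rate_mult[_GROUP_IDX["CIRC"]] = 2.0
    coup_mult = np.full((N_GROUPS, N_GROUPS), 2.0)
    i, j = _GROUP_IDX["CIRC"], _GROUP_IDX["META"]
    coup_mult[i, j] = coup_mult[j, i] = 10.0
    gaps_nd = np.column_stack([np.linspace(40, 20, N_CLASSES), np.linspace(70, 45, N_CLASSES)])
    return MorbidityModel(
        base_rates=base,
        coupling=coupling,
        coupling_age_scale=np.asarray(age_profile, dtype=float),
        diabetes_rate_mult=rate_mult,
        diabetes_coupling_mult=coup_mult,
        visit_gap_nd=gaps_nd,
    )


def coupling_recovery_model(
    enrichment: float = 15.0,
    coupling_nd: float = 0.06,
    meta_base_rate: float = 0.5,
    meta_diabetes_mult: float = 6.0,
) -> MorbidityModel:
    """Controlled configuration for coupling-recovery experiments.

    Only the CIRC-META coupling is active (``coupling_nd`` events per
    patient-year, multiplied by ``enrichment`` for diabetics) and CIRC has
    no base rate, so every CIRC-META co-prescription stems from the coupled
    mechanism and the expected D/ND link-weight ratio equals
    ``enrichment`` exactly.  META keeps a base rate so diabetic patients
    accumulate the 250.xx Drug prescriptions that identify them.
    """
    base = np.zeros((N_CLASSES, N_GROUPS))
    base[:, _GROUP_IDX["META"]] = meta_base_rate
    coupling = np.zeros((N_GROUPS, N_GROUPS))
    i, j = _GROUP_IDX["CIRC"], _GROUP_IDX["META"]
    coupling[i, j] = coupling[j, i] = coupling_nd
    rate_mult = np.ones(N_GROUPS)
    rate_mult[_GROUP_IDX["META"]] = meta_diabetes_mult
    coup_mult = np.ones((N_GROUPS, N_GROUPS))
    coup_mult[i, j] = coup_mult[j, i] = enrichment
    return MorbidityModel(
        base_rates=base,
        coupling=coupling,
        diabetes_rate_mult=rate_mult,
        diabetes_coupling_mult=coup_mult,
    )


# ---------------------------------------------------------------------------

def generate_population(
    cfg: PopulationConfig,
    window_start_year: int = 2002,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw a synthetic patient table (patient_id, sex, birth_year, diabetic).

    Ages at the window start are drawn by age class from ``age_weights``
    (uniform integer within the class, the open-ended 85+ class truncated
    at 95 for realism); ``birth_year = window_start_year - age``.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    n = cfg.n_patients
    if n == 0:
        return pd.DataFrame(columns=["patient_id", "sex", "birth_year", "diabetic"])
    cls = rng.choice(N_CLASSES, size=n, p=np.asarray(cfg.age_weights, dtype=float))
    lows = np.array([15, 26, 36, 46, 56, 66, 76, 86])
    highs = np.array([25, 35, 45, 55, 65, 75, 85, 95])
    age = rng.integers(lows[cls], highs[cls] + 1)
    sex = np.where(rng.random(n) < cfg.sex_ratio, "M", "F")
    diabetic = rng.random(n) < cfg.diabetes_prevalence
    return pd.DataFrame(
        {
            "patient_id": [f"P{i:06d}" for i in range(n)],
            "sex": sex,
            "birth_year": window_start_year - age,
            "diabetic": diabetic,
        }
    )


def _age_class_index(ages: np.ndarray) -> np.ndarray:
    """Index into AGE_CLASSES for integer ages >= 15 (upper-inclusive)."""
    return np.searchsorted(_CLASS_UPPER, ages, side="left")


def _draw_visits(
    patients: pd.DataFrame,
    model: MorbidityModel,
    window: ObservationWindow,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Visit times for all patients: (patient index, day offset) arrays.

    Each patient is a renewal process with gaps uniform in the interval of
    their *current* age class (ages advance during the window); the first
    visit lands uniformly within one initial gap.
    """
    n = len(patients)
    t_total = float(window.days)
    birth_year = patients["birth_year"].to_numpy()
    diabetic = patients["diabetic"].to_numpy(dtype=bool)
    start64 = np.datetime64(window.start)

    def gap_draw(t: np.ndarray, idx: np.ndarray) -> np.ndarray:
        dates = start64 + np.floor(t).astype("timedelta64[D]")
        years = dates.astype("datetime64[Y]").astype(int) + 1970
        age = np.maximum(years - birth_year[idx], 15)
        cls = _age_class_index(age)
        d = diabetic[idx]
        lo = np.where(d, model.visit_gap_d[cls, 0], model.visit_gap_nd[cls, 0])
        hi = np.where(d, model.visit_gap_d[cls, 1], model.visit_gap_nd[cls, 1])
        return lo + rng.random(len(idx)) * (hi - lo)

    idx = np.arange(n)
    t = rng.random(n) * gap_draw(np.zeros(n), idx)
    vis_p: list[np.ndarray] = []
    vis_t: list[np.ndarray] = []
    max_steps = int(t_total / 17.0) + 3
    for _ in range(max_steps):
        active = t < t_total
        idx, t = idx[active], t[active]
        if len(idx) == 0:
            break
        vis_p.append(idx)
        vis_t.append(t)
        t = t + gap_draw(t, idx)
    if not vis_p:
        return np.array([], dtype=int), np.array([], dtype=float)
    return np.concatenate(vis_p), np.concatenate(vis_t)


def generate_prescriptions(
    patients: pd.DataFrame,
    model: MorbidityModel,
    window: ObservationWindow = ObservationWindow(),
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate the full prescription record frame for a patient table.

    Deterministic given the random generator state; an empty patient table
    yields an empty (but well-formed) frame.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    cols = ["patient_id", "age", "sex", "date", "rx_type", "rx_code", "icd9_code"]
    if len(patients) == 0:
        return pd.DataFrame(columns=cols)

    vp, vt = _draw_visits(patients, model, window, rng)
    if len(vp) == 0:
        return pd.DataFrame(columns=cols)

    birth_year = patients["birth_year"].to_numpy()
    diabetic = patients["diabetic"].to_numpy(dtype=bool)
    start64 = np.datetime64(window.start)
    vdates = start64 + np.floor(vt).astype("timedelta64[D]")
    vyears = vdates.astype("datetime64[Y]").astype(int) + 1970
    vage = np.maximum(vyears - birth_year[vp], 15)
    vcls = _age_class_index(vage)
    vdiab = diabetic[vp]
    vpy = model.visits_per_year(vcls, vdiab)

    rec_visit: list[np.ndarray] = []
    rec_group: list[np.ndarray] = []

    # independent base draws, one Bernoulli per visit per active group
    dmult = model.diabetes_rate_mult
    for g in range(N_GROUPS):
        col = model.base_rates[:, g]
        if not col.any():
            continue
        p = col[vcls] * np.where(vdiab, dmult[g], 1.0) / vpy
        hit = np.flatnonzero(rng.random(len(vp)) < np.clip(p, 0.0, 0.95))
        if len(hit):
            rec_visit.append(hit)
            rec_group.append(np.full(len(hit), g, dtype=int))

    # coupled pair draws: one Bernoulli per visit per active pair; a hit
    # emits one record of each group of the pair at that visit
    cscale = model.coupling_age_scale
    cmult = model.diabetes_coupling_mult
    for gi in range(N_GROUPS):
        for gj in range(gi + 1, N_GROUPS):
            c = model.coupling[gi, gj]
            if c == 0:
                continue
            p = c * cscale[vcls] * np.where(vdiab, cmult[gi, gj], 1.0) / vpy
            hit = np.flatnonzero(rng.random(len(vp)) < np.clip(p, 0.0, 0.95))
            if len(hit):
                rec_visit.append(np.concatenate([hit, hit]))
                rec_group.append(
                    np.concatenate(
                        [np.full(len(hit), gi, dtype=int), np.full(len(hit), gj, dtype=int)]
                    )
                )

    if not rec_visit:
        return pd.DataFrame(columns=cols)
    rv = np.concatenate(rec_visit)
    rg = np.concatenate(rec_group)
    m = len(rv)

    # representative diagnosis codes per group
    code = np.empty(m, dtype=object)
    for g in range(N_GROUPS):
        sel = np.flatnonzero(rg == g)
        if not len(sel):
            continue
        pool = np.array(model.code_pools[GROUPS[g]], dtype=object)
        code[sel] = pool[rng.integers(0, len(pool), len(sel))]
    meta_idx = _GROUP_IDX["META"]
    diab_meta = np.flatnonzero((rg == meta_idx) & vdiab[rv])
    if len(diab_meta):
        take = diab_meta[rng.random(len(diab_meta)) < model.diabetic_meta_prob]
        pool = np.array(model.diabetic_meta_codes, dtype=object)
        code[take] = pool[rng.integers(0, len(pool), len(take))]

    # prescription type from the group's mix; diabetes codes are Drug therapy
    rx_type = np.empty(m, dtype=object)
    type_labels = np.array(RX_TYPES, dtype=object)
    for g in range(N_GROUPS):
        sel = np.flatnonzero(rg == g)
        if not len(sel):
            continue
        rx_type[sel] = type_labels[
            rng.choice(len(RX_TYPES), size=len(sel), p=model.type_mix[g])
        ]
    is_250 = np.array([c.startswith("250") for c in code], dtype=bool)
    rx_type[is_250] = "Drug"

    rx_code = "RX" + pd.Series(rng.integers(10000, 100000, m)).astype(str)

    pid = patients["patient_id"].to_numpy()
    sex = patients["sex"].to_numpy()
    df = pd.DataFrame(
        {
            "patient_id": pid[vp[rv]],
            "age": vage[rv].astype(int),
            "sex": sex[vp[rv]],
            "date": pd.to_datetime(vdates[rv]).astype("datetime64[ns]"),
            "rx_type": rx_type,
            "rx_code": rx_code.to_numpy(),
            "icd9_code": code,
        }
    )
    return df.sort_values(["patient_id", "date"], kind="stable").reset_index(drop=True)


def generate_dataset(
    cfg: PopulationConfig,
    model: MorbidityModel | None = None,
    window: ObservationWindow = ObservationWindow(),
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Population + prescriptions in one call, from a single seed."""
    rng = np.random.default_rng(seed if seed is not None else cfg.seed)
    model = model or default_morbidity_model()
    patients = generate_population(cfg, window_start_year=window.start.year, rng=rng)
    records = generate_prescriptions(patients, model, window, rng=rng)
    return patients, records
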