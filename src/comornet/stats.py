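"""Tabular and curve statistics for GP prescription cohorts.

Covers: prescription-type frequency summaries, per-group type mixes, the
clinical-group share of total prescription volume, age curves of morbidity
(prescriptions per patient) and comorbidity (network strength per
patient), META-anchored co-prescription profiles of diabetic (D) vs
non-diabetic (ND) patients, exact (Garwood) Poisson confidence intervals
and the D/ND rate ratio with an exact conditional-binomial interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import Stratum
from .icd9 import GROUPS, GroupMap
from .network import network_from_frame
from .records import RX_TYPES

__all__ = [
    "TypeSummary",
    "RatioEstimate",
    "summarize_by_type",
    "summarize_group_by_type",
    "selected_groups_share",
    "morbidity_curve",
    "comorbidity_curve",
    "meta_coprescription_profile",
    "poisson_ci",
    "dn_ratio",
]


@dataclass
class TypeSummary:
    """Prescription counts and shares by prescription type."""

    counts: dict[str, int]
    n_patients: int
    window_years: float

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def percents(self) -> dict[str, float]:
        tot = self.total
        return {t: (100.0 * c / tot if tot else 0.0) for t, c in self.counts.items()}

    @property
    def per_patient_per_year(self) -> dict[str, float]:
        denom = self.n_patients * self.window_years
        out = {t: c / denom for t, c in self.counts.items()}
        out["All"] = self.total / denom
        return out

    def to_frame(self) -> pd.DataFrame:
        """Full-precision table; round only when rendering."""
        ppy = self.per_patient_per_year
        rows = [("All", self.total, 100.0 if self.total else 0.0, ppy["All"])]
        rows += [
            (t, self.counts[t], self.percents[t], ppy[t]) for t in self.counts
        ]
        return pd.DataFrame(
            rows, columns=["rx_type", "count", "percent_of_total", "per_patient_per_year"]
        )


def summarize_by_type(
    records: pd.DataFrame | None = None,
    *,
    counts: dict[str, int] | None = None,
    n_patients: int,
    window_years: float,
) -> TypeSummary:
    """Type-frequency summary from a record frame or from printed counts.

    ``percent_of_total`` = 100 x type count / total; per-patient-per-year
    = count / (n_patients x window_years).
    """
    if (records is None) == (counts is None):
        raise ValueError("provide exactly one of records or counts")
    if window_years <= 0:
        raise ValueError("window_years must be positive")
    if counts is None:
        vc = records["rx_type"].value_counts()
        counts = {t: int(vc.get(t, 0)) for t in RX_TYPES}
    else:
        unknown = set(counts) - set(RX_TYPES)
        if unknown:
            raise ValueError(f"unknown prescription type(s): {sorted(unknown)}")
        counts = {t: int(counts.get(t, 0)) for t in RX_TYPES}
    if n_patients == 0 and sum(counts.values()) > 0:
        raise ValueError("n_patients must be >= 1 when prescriptions are present")
    return TypeSummary(counts=counts, n_patients=max(n_patients, 1), window_years=window_years)


def summarize_group_by_type(
    records: pd.DataFrame, gmap: GroupMap | None = None
) -> pd.DataFrame:
    """Per diagnosis group: total count and row-wise percent by type.

    One row per group present in the data, sorted by count descending;
    each row's percentages sum to 100.
    """
    from .icd9 import default_group_map

    if records.empty:
        return pd.DataFrame(
            columns=["group", "count"] + [f"{t} %" for t in RX_TYPES]
        )
    gmap = gmap or default_group_map()
    df = pd.DataFrame(
        {
            "group": gmap.map_codes(records["icd9_code"]).to_numpy(),
            "rx_type": records["rx_type"].to_numpy(),
        }
    )
    counts = df.groupby(["group", "rx_type"]).size().unstack(fill_value=0)
    counts = counts.reindex(columns=list(RX_TYPES), fill_value=0)
    total = counts.sum(axis=1)
    pct = counts.div(total, axis=0) * 100.0
    out = pd.DataFrame({"group": total.index, "count": total.to_numpy()})
    for t in RX_TYPES:
        out[f"{t} %"] = pct[t].to_numpy()
    return out.sort_values(["count", "group"], ascending=[False, True]).reset_index(drop=True)


def selected_groups_share(
    records: pd.DataFrame | None = None,
    groups: tuple[str, ...] | set[str] = (),
    *,
    counts: dict[str, int] | None = None,
    total: int | None = None,
) -> float:
    """Fraction of total prescriptions carried by the listed groups.

    Accepts either a record frame or a precomputed {group: count} mapping
    (e.g. a printed frequency table); ``total`` overrides the denominator
    when the mapping omits some residual groups.
    """
    from .icd9 import default_group_map

    unknown = set(groups) - set(GROUPS)
    if unknown:
        raise ValueError(f"unknown group label(s): {sorted(unknown)}")
    if (records is None) == (counts is None):
        raise ValueError("provide exactly one of records or counts")
    if counts is None:
        mapped = default_group_map().map_codes(records["icd9_code"])
        counts = mapped.value_counts().to_dict()
    total = total if total is not None else sum(counts.values())
    if total == 0:
        return 0.0
    return sum(c for g, c in counts.items() if g in set(groups)) / total


# ---- age curves ------------------------------------------------------------

def morbidity_curve(strata: list[Stratum]) -> pd.DataFrame:
    """Mean prescriptions per patient by age class (empty strata omitted)."""
    rows = [
        (s.spec.age_class, len(s.records) / s.n_patients)
        for s in strata
        if s.n_patients > 0
    ]
    return pd.DataFrame(rows, columns=["age_class", "value"])


def comorbidity_curve(
    strata: list[Stratum], gmap: GroupMap | None = None, cooccur: str = "visit"
) -> pd.DataFrame:
    """Total per-patient network strength by age class.

    The value for a class is the sum over nodes of the normalized node
    strengths of that class's comorbidity network, i.e. twice the total
    normalized link weight — the scalar comorbidity burden per patient.
    """
    rows = []
    for s in strata:
        if s.n_patients == 0:
            continue
        net = network_from_frame(s.records, s.n_patients, gmap=gmap, cooccur=cooccur)
        rows.append((s.spec.age_class, net.normalize().total_strength()))
    return pd.DataFrame(rows, columns=["age_class", "value"])


def meta_coprescription_profile(
    stratum_d: Stratum,
    stratum_nd: Stratum,
    gmap: GroupMap | None = None,
    groups: tuple[str, ...] | None = None,
    anchor: str = "META",
    cooccur: str = "visit",
) -> pd.DataFrame:
    """Anchor-group co-prescription counts and per-patient rates, D vs ND.

    For each group g, ``count_X`` is the raw link weight {g, anchor} in
    stratum X and ``rate_X`` = count_X / n_patients(X).  A missing anchor
    node simply yields zero counts.
    """
    nets = {}
    for label, s in (("D", stratum_d), ("ND", stratum_nd)):
        nets[label] = network_from_frame(
            s.records, max(s.n_patients, 1), gmap=gmap, cooccur=cooccur
        )
    if groups is None:
        groups = tuple(
            g
            for g in sorted(set(nets["D"].node_weight) | set(nets["ND"].node_weight))
            if g != anchor
        )
    rows = []
    for g in groups:
        pair = tuple(sorted((g, anchor)))
        c_d = nets["D"].link_weight.get(pair, 0.0)
        c_nd = nets["ND"].link_weight.get(pair, 0.0)
        rows.append(
            (
                g,
                c_d,
                c_nd,
                c_d / stratum_d.n_patients if stratum_d.n_patients else 0.0,
                c_nd / stratum_nd.n_patients if stratum_nd.n_patients else 0.0,
            )
        )
    return pd.DataFrame(rows, columns=["group", "count_D", "count_ND", "rate_D", "rate_ND"])


# ---- Poisson intervals and the D/ND ratio ----------------------------------

def poisson_ci(k: int, level: float = 0.95, method: str = "garwood") -> tuple[float, float]:
    """Confidence interval for a Poisson mean given an observed count.

    The default is the exact Garwood interval from gamma quantiles:
    ``lo = Gamma(k).ppf(alpha/2)`` (0 when k = 0) and
    ``hi = Gamma(k+1).ppf(1 - alpha/2)``.  ``method='normal'`` gives the
    k +/- z*sqrt(k) approximation for comparison.
    """
    if not float(k).is_integer() or k < 0:
        raise ValueError("k must be a non-negative integer")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    k = int(k)
    alpha = 1.0 - level
    if method == "garwood":
        lo = 0.0 if k == 0 else float(sps.gamma.ppf(alpha / 2, k))
        hi = float(sps.gamma.ppf(1 - alpha / 2, k + 1))
    elif method == "normal":
        z = float(sps.norm.ppf(1 - alpha / 2))
        half = z * math.sqrt(k)
        lo, hi = max(0.0, k - half), k + half
    else:
        raise ValueError(f"unknown method {method!r}")
    return lo, hi


@dataclass(frozen=True)
class RatioEstimate:
    """D/ND per-patient co-prescription rate ratio with exact 95%-style CI."""

    count_D: float
    n_D: int
    count_ND: float
    n_ND: int
    ratio: float
    ci: tuple[float, float]
    level: float
    group: str | None = None

    @property
    def rate_D(self) -> float:
        return self.count_D / self.n_D

    @property
    def rate_ND(self) -> float:
        return self.count_ND / self.n_ND


def dn_ratio(
    count_D: int,
    n_D: int,
    count_ND: int,
    n_ND: int,
    level: float = 0.95,
    group: str | None = None,
) -> RatioEstimate:
    """Ratio of per-patient co-prescription rates, diabetic vs non-diabetic.

    ``ratio = (count_D/n_D) / (count_ND/n_ND)``.  The interval propagates
    the Poisson uncertainty of both counts through the conditional-binomial
    construction: conditional on the total, ``count_D`` is binomial with
    success probability p, for which an exact Clopper-Pearson interval is
    computed and transformed to the rate-ratio scale via the odds times
    ``n_ND/n_D``.  With ``count_ND = 0`` the ratio is undefined (reported
    as ``inf``) and only the lower bound is informative.
    """
    if count_D < 0 or count_ND < 0:
        raise ValueError("counts must be non-negative")
    if n_D < 1 or n_ND < 1:
        raise ValueError("patient denominators must be >= 1")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    x, n = int(count_D), int(count_D) + int(count_ND)
    alpha = 1.0 - level
    factor = n_ND / n_D
    if n == 0:
        return RatioEstimate(count_D, n_D, count_ND, n_ND, math.nan,
                             (0.0, math.inf), level, group)
    p_lo = 0.0 if x == 0 else float(sps.beta.ppf(alpha / 2, x, n - x + 1))
    p_hi = 1.0 if x == n else float(sps.beta.ppf(1 - alpha / 2, x + 1, n - x))
    lo = factor * p_lo / (1.0 - p_lo) if p_lo < 1 else math.inf
    hi = factor * p_hi / (1.0 - p_hi) if p_hi < 1 else math.inf
    ratio = (count_D / n_D) / (count_ND / n_ND) if count_ND > 0 else math.inf
    return RatioEstimate(count_D, n_D, count_ND, n_ND, ratio, (lo, hi), level, group)
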