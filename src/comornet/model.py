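"""Model/results facade over the comorbidity-network pipeline.

:class:`ComorbidityNetworkModel` is built from a validated record frame;
``fit()`` runs classification, stratification, network construction and
the epidemiological statistics, returning a
:class:`ComorbidityNetworkResults` that carries the per-age-class
networks, the morbidity/comorbidity age curves for the whole population
and the diabetic (D) / non-diabetic (ND) subpopulations, and the D/ND
co-prescription rate ratios with exact confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .cohort import (
    AGE_CLASSES,
    Stratum,
    StratumSpec,
    age_strata,
    diabetic_patient_ids,
    stratify,
)
from .icd9 import GroupMap, default_group_map
from .network import ComorbidityNetwork, network_from_frame
from .records import DEFAULT_WINDOW, ObservationWindow, parse_records
from .stats import (
    RatioEstimate,
    TypeSummary,
    comorbidity_curve,
    dn_ratio,
    meta_coprescription_profile,
    morbidity_curve,
    summarize_by_type,
    summarize_group_by_type,
)

DEFAULT_RATIO_GROUPS = ("CIRC", "RESP", "DIGE", "GEN")


class ComorbidityNetworkModel:
    """Comorbidity-network analysis of a GP prescription cohort.

    Parameters
    ----------
    records : validated record frame (see :mod:`comornet.records`).
    group_map : ICD-9-CM chapter map; the bundled 20-chapter default if None.
    cooccur : co-prescription granularity, ``'visit'`` (same patient and
        date) or ``'patient'`` (whole history).
    window_years : effective observation span in years, used for
        per-patient-per-year rates; defaults to the window length.
    """

    def __init__(
        self,
        records: pd.DataFrame,
        group_map: GroupMap | None = None,
        cooccur: str = "visit",
        window: ObservationWindow = DEFAULT_WINDOW,
        window_years: float | None = None,
    ):
        self.records = records
        self.group_map = group_map or default_group_map()
        self.cooccur = cooccur
        self.window = window
        self.window_years = window_years if window_years is not None else window.years

    @classmethod
    def from_dataframe(cls, records: pd.DataFrame, **kwargs) -> "ComorbidityNetworkModel":
        return cls(records, **kwargs)

    @classmethod
    def from_csv(cls, path, window: ObservationWindow = DEFAULT_WINDOW, **kwargs):
        records, report = parse_records(path, window=window)
        model = cls(records, window=window, **kwargs)
        model.validation_report = report
        return model

    def fit(
        self,
        sex: str = "all",
        rx_type: str = "all",
        anchor: str = "META",
        ratio_groups: tuple[str, ...] = DEFAULT_RATIO_GROUPS,
        min_ratio_age_class: str = "(35,45]",
        ci_level: float = 0.95,
    ) -> "ComorbidityNetworkResults":
        """Run the full analysis for one sex/prescription-type slice."""
        recs = self.records
        diab_ids = diabetic_patient_ids(recs)
        n_patients = recs["patient_id"].nunique()

        type_summary = summarize_by_type(
            recs, n_patients=max(n_patients, 1), window_years=self.window_years
        )
        group_type = summarize_group_by_type(recs, gmap=self.group_map)

        strata = {
            pop: age_strata(recs, sex=sex, rx_type=rx_type, diabetes=pop, diabetic_ids=diab_ids)
            for pop in ("all", "D", "ND")
        }
        curves = []
        for pop, ss in strata.items():
            mo = morbidity_curve(ss).assign(population=pop, measure="morbidity")
            co = comorbidity_curve(ss, gmap=self.group_map, cooccur=self.cooccur).assign(
                population=pop, measure="comorbidity"
            )
            curves.append(mo)
            curves.append(co)
        curves_df = pd.concat(curves, ignore_index=True)[
            ["measure", "population", "age_class", "value"]
        ]

        networks = {
            s.spec.age_class: network_from_frame(
                s.records, s.n_patients, gmap=self.group_map, cooccur=self.cooccur
            )
            for s in strata["all"]
            if s.n_patients > 0
        }

        # pooled D vs ND anchor-group ratios over the adult classes from
        # min_ratio_age_class upward
        keep = AGE_CLASSES[AGE_CLASSES.index(min_ratio_age_class):]
        pooled = recs[recs["age"] > int(min_ratio_age_class.split(",")[0][1:])]
        if sex != "all":
            pooled = pooled[pooled["sex"] == sex]
        if rx_type != "all":
            pooled = pooled[pooled["rx_type"] == rx_type]
        d_mask = pooled["patient_id"].isin(diab_ids)
        strat_d = Stratum(
            spec=StratumSpec(sex=sex, rx_type=rx_type, diabetes="D"),
            records=pooled[d_mask],
        )
        strat_nd = Stratum(
            spec=StratumSpec(sex=sex, rx_type=rx_type, diabetes="ND"),
            records=pooled[~d_mask],
        )
        profile = meta_coprescription_profile(
            strat_d, strat_nd, gmap=self.group_map, groups=ratio_groups,
            anchor=anchor, cooccur=self.cooccur,
        )
        ratios = [
            dn_ratio(
                int(r.count_D), max(strat_d.n_patients, 1),
                int(r.count_ND), max(strat_nd.n_patients, 1),
                level=ci_level, group=r.group,
            )
            for r in profile.itertuples(index=False)
        ]
        return ComorbidityNetworkResults(
            model=self,
            n_patients=n_patients,
            n_diabetic=len(diab_ids & set(recs["patient_id"].unique())),
            type_summary=type_summary,
            group_type_summary=group_type,
            curves=curves_df,
            networks=networks,
            anchor=anchor,
            meta_profile=profile,
            ratio_estimates=ratios,
            ratio_age_classes=keep,
        )


@dataclass
class ComorbidityNetworkResults:
    """Fitted quantities of a :class:`ComorbidityNetworkModel`."""

    model: ComorbidityNetworkModel
    n_patients: int
    n_diabetic: int
    type_summary: TypeSummary
    group_type_summary: pd.DataFrame
    curves: pd.DataFrame
    networks: dict[str, ComorbidityNetwork]
    anchor: str
    meta_profile: pd.DataFrame
    ratio_estimates: list[RatioEstimate] = field(default_factory=list)
    ratio_age_classes: tuple[str, ...] = ()

    def ratio_table(self) -> pd.DataFrame:
        rows = [
            (
                r.group, r.count_D, r.n_D, r.count_ND, r.n_ND,
                r.rate_D, r.rate_ND, r.ratio, r.ci[0], r.ci[1],
            )
            for r in self.ratio_estimates
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "group", "count_D", "n_D", "count_ND", "n_ND",
                "rate_D", "rate_ND", "ratio", "ci_lo", "ci_hi",
            ],
        )

    def summary(self) -> str:
        """Human-readable report of the fitted quantities."""
        lines = [
            "Comorbidity network analysis",
            "=" * 60,
            f"patients: {self.n_patients}   diabetic: {self.n_diabetic} "
            f"({100 * self.n_diabetic / max(self.n_patients, 1):.1f}%)",
            f"prescriptions: {self.type_summary.total}   "
            f"per patient per year: {self.type_summary.per_patient_per_year['All']:.2f}",
            "",
            "Prescription types (% of total):",
        ]
        for t, pct in self.type_summary.percents.items():
            lines.append(f"  {t:<16s} {pct:5.1f}%")
        lines.append("")
        lines.append(f"D/ND co-prescription rate ratios with {self.anchor} "
                     f"(exact CI, pooled over {self.ratio_age_classes[0]}..):")
        for r in self.ratio_estimates:
            ratio = f"{r.ratio:.2f}" if r.ratio != float("inf") else "inf"
            lines.append(
                f"  {r.group:<5s} ratio {ratio:>7s}   "
                f"[{r.ci[0]:.2f}, {r.ci[1]:.2f}]   "
                f"(D {r.count_D:.0f}/{r.n_D}, ND {r.count_ND:.0f}/{r.n_ND})"
            )
        return "\n".join(lines)

    def plot_curves(self, ax=None):
        """Morbidity and comorbidity age curves, one panel per measure."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, axes = plt.subplots(1, 2, figsize=(10, 4), sharex=True)
        else:
            axes = ax
        for axis, measure in zip(axes, ("morbidity", "comorbidity")):
            sub = self.curves[self.curves["measure"] == measure]
            for pop, g in sub.groupby("population"):
                axis.plot(g["age_class"], g["value"], marker="o", label=pop)
            axis.set_title(measure)
            axis.set_xlabel("age class")
            axis.tick_params(axis="x", rotation=45)
            axis.legend()
        axes[0].set_ylabel("per patient")
        return axes
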