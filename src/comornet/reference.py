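"""Published reference frequencies from a decade-long Italian GP cohort.

These constants reproduce the prescription-type and diagnosis-group
frequency table of a 2002-2013 Italian general-practice prescription
registry (14,958 adult patients, 1,728,736 prescriptions).  They
serve two purposes: as printed input data for the tabular summary
statistics, and as realistic marginals for the synthetic record generator
(group mix, per-group prescription-type mix, overall prescription volume).

The per-patient-per-year figure printed alongside the table (10.51)
corresponds to an effective observation span of 11 years, which is why
``WINDOW_YEARS`` is 11.0 here; elsewhere in the package the observation
span is always an explicit input.
"""

from __future__ import annotations

TOTAL_PRESCRIPTIONS = 1_728_736
N_PATIENTS = 14_958
WINDOW_YEARS = 11.0

#: Prescription counts by type (whole cohort).
TYPE_COUNTS: dict[str, int] = {
    "Drug": 897_329,
    "Laboratory Test": 647_023,
    "Procedures": 105_126,
    "Rehab": 8_388,
    "Referral": 65_734,
    "Hospital": 5_136,
}

#: Prescription counts by diagnosis group (EXT omitted in the source table).
GROUP_COUNTS: dict[str, int] = {
    "CIRC": 451_765,
    "META": 231_541,
    "ILL": 219_664,
    "DIGE": 133_736,
    "MUSC": 122_718,
    "GEN": 112_029,
    "RESP": 110_587,
    "SUPP": 75_458,
    "NEOP": 72_708,
    "MENT": 45_328,
    "NERV": 28_969,
    "BLD": 28_406,
    "SENS": 26_879,
    "SKIN": 22_250,
    "INFE": 21_803,
    "INJ": 20_342,
    "PREG": 2_748,
    "CONG": 1_401,
    "NEWB": 404,
}

#: Row-wise percentage of each prescription type within a diagnosis group,
#: in the order (Drug, Laboratory Test, Procedures, Rehab, Referral, Hospital).
GROUP_TYPE_PCT: dict[str, tuple[float, float, float, float, float, float]] = {
    "CIRC": (69.2, 25.4, 3.5, 0.0, 1.8, 0.2),
    "META": (37.6, 56.6, 2.5, 0.0, 3.3, 0.1),
    "ILL": (26.7, 56.4, 10.7, 1.0, 4.8, 0.5),
    "DIGE": (72.6, 20.4, 4.8, 0.0, 1.9, 0.3),
    "MUSC": (57.4, 22.2, 11.8, 3.7, 4.6, 0.3),
    "GEN": (37.6, 51.6, 6.7, 0.0, 3.8, 0.3),
    "RESP": (87.1, 6.9, 3.2, 0.1, 2.5, 0.2),
    "SUPP": (13.0, 76.9, 6.5, 0.1, 3.3, 0.3),
    "NEOP": (15.2, 67.7, 12.2, 0.0, 4.0, 0.9),
    "MENT": (89.5, 4.9, 0.7, 0.0, 4.8, 0.1),
    "NERV": (69.0, 16.9, 7.3, 0.4, 5.8, 0.6),
    "BLD": (20.5, 75.6, 1.3, 0.0, 2.4, 0.2),
    "SENS": (57.1, 5.3, 14.0, 0.0, 22.0, 1.5),
    "SKIN": (44.3, 36.2, 3.7, 0.1, 15.4, 0.4),
    "INFE": (49.5, 33.1, 11.5, 0.1, 5.6, 0.2),
    "INJ": (40.1, 14.7, 21.7, 5.3, 17.5, 0.7),
    "PREG": (41.9, 48.2, 4.4, 0.0, 3.2, 2.2),
    "CONG": (24.1, 42.1, 18.6, 1.1, 10.5, 3.5),
    "NEWB": (66.6, 21.0, 2.0, 0.0, 8.9, 1.5),
}

#: The thirteen groups attached to specific clinical sectors, jointly
#: accounting for ~81% of the cohort's prescriptions.
CLINICAL_GROUPS_13: tuple[str, ...] = (
    "CIRC", "META", "DIGE", "MUSC", "GEN", "RESP", "NEOP", "MENT", "NERV",
    "BLD", "SENS", "SKIN", "INFE",
)
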