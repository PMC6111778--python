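"""Weighted comorbidity networks over ICD-9-CM diagnosis groups.

Nodes are diagnosis groups; a link between two distinct groups records
that they were co-prescribed on the same co-prescription occasion.  The
default occasion ("visit") is one patient on one calendar date; a
whole-history alternative ("patient") counts each pair at most once per
patient.  Node weight counts prescriptions, link weight counts occasions
on which both groups occur (once per occasion, regardless of how many
records of each group the occasion contains), and node strength is the sum
of incident link weights.  Networks have no self-loops, and all weights
can be normalized per patient (divided by the stratum's patient count) to
compare population slices of different size.
"""

from __future__ import annotations

import datetime as dt
import itertools
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .icd9 import GroupMap, default_group_map


@dataclass(frozen=True)
class CoPrescriptionEvent:
    """The multiset of diagnosis groups prescribed to one patient on one date."""

    patient_id: str
    date: dt.date
    groups: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("a co-prescription event carries at least one group")


@dataclass
class ComorbidityNetwork:
    """Weighted undirected group-group network with a patient denominator."""

    node_weight: dict[str, float]
    link_weight: dict[tuple[str, str], float]  # keys are sorted 2-tuples
    n_patients: int
    normalized: bool = False

    def __post_init__(self) -> None:
        for (a, b) in self.link_weight:
            if a == b:
                raise ValueError("self-loops are not allowed")
            if a > b:
                raise ValueError("link keys must be sorted pairs")

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(self.node_weight)

    def strength(self, group: str) -> float:
        """Sum of the weights of the links incident to *group*."""
        if group not in self.node_weight:
            raise KeyError(f"group {group!r} not in network")
        return sum(w for pair, w in self.link_weight.items() if group in pair)

    def strengths(self) -> dict[str, float]:
        s = {g: 0.0 for g in self.node_weight}
        for (a, b), w in self.link_weight.items():
            s[a] += w
            s[b] += w
        return s

    def total_strength(self) -> float:
        """Sum of strengths over all nodes (= twice the total link weight)."""
        return 2.0 * sum(self.link_weight.values())

    def normalize(self) -> "ComorbidityNetwork":
        """Per-patient network: every node and link weight divided by n_patients."""
        if self.normalized:
            raise ValueError("network is already normalized")
        if self.n_patients < 1:
            if self.node_weight or self.link_weight:
                raise ValueError("cannot normalize a non-empty network by 0 patients")
            return ComorbidityNetwork({}, {}, self.n_patients, normalized=True)
        n = float(self.n_patients)
        return ComorbidityNetwork(
            node_weight={g: w / n for g, w in self.node_weight.items()},
            link_weight={p: w / n for p, w in self.link_weight.items()},
            n_patients=self.n_patients,
            normalized=True,
        )

    # ---- reporting ----------------------------------------------------
    def summary(self) -> pd.DataFrame:
        """Per-node table (group, mean prescriptions per patient, strength),
        sorted by node weight descending.  Requires a normalized network."""
        if not self.normalized:
            raise ValueError("summary requires a normalized (per-patient) network")
        s = self.strengths()
        df = pd.DataFrame(
            {
                "group": list(self.node_weight),
                "prescriptions_per_patient": list(self.node_weight.values()),
                "strength": [s[g] for g in self.node_weight],
            }
        )
        return df.sort_values(
            ["prescriptions_per_patient", "group"], ascending=[False, True]
        ).reset_index(drop=True)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        strengths = self.strengths()
        for node, w in self.node_weight.items():
            g.add_node(node, weight=float(w), strength=float(strengths[node]))
        for (a, b), w in self.link_weight.items():
            g.add_edge(a, b, weight=float(w))
        g.graph["n_patients"] = self.n_patients
        g.graph["normalized"] = self.normalized
        return g

    def export(self, path, fmt: str = "graphml") -> None:
        """Write the network as GraphML or as an edge-list TSV
        (``group_a<TAB>group_b<TAB>weight``, 6 significant digits)."""
        if fmt == "graphml":
            nx.write_graphml(self.to_networkx(), path)
        elif fmt == "tsv":
            with open(path, "w", encoding="utf-8") as fh:
                fh.write("group_a\tgroup_b\tweight\n")
                for (a, b) in sorted(self.link_weight):
                    fh.write(f"{a}\t{b}\t{self.link_weight[a, b]:.6g}\n")
        else:
            raise ValueError(f"unknown export format {fmt!r}")


def group_events(
    records: pd.DataFrame,
    gmap: GroupMap | None = None,
    cooccur: str = "visit",
) -> list[CoPrescriptionEvent]:
    """Collapse records into co-prescription events.

    ``cooccur='visit'`` produces one event per (patient, date) carrying the
    multiset of that day's diagnosis groups; ``cooccur='patient'`` one event
    per patient over the whole window.
    """
    if cooccur not in ("visit", "patient"):
        raise ValueError("cooccur must be 'visit' or 'patient'")
    if records.empty:
        return []
    gmap = gmap or default_group_map()
    groups = gmap.map_codes(records["icd9_code"])
    df = pd.DataFrame(
        {
            "patient_id": records["patient_id"].to_numpy(),
            "date": pd.to_datetime(records["date"]).to_numpy(),
            "group": groups.to_numpy(),
        }
    )
    keys = ["patient_id", "date"] if cooccur == "visit" else ["patient_id"]
    events = []
    for key, sub in df.groupby(keys, sort=True):
        pid = key[0]
        date = pd.Timestamp(key[1]).date() if cooccur == "visit" else None
        events.append(
            CoPrescriptionEvent(
                patient_id=str(pid),
                date=date or pd.Timestamp(sub["date"].iloc[0]).date(),
                groups=tuple(sub["group"]),
            )
        )
    return events


def build_network(
    events: list[CoPrescriptionEvent],
    n_patients: int,
    patient_ids: set[str] | None = None,
) -> ComorbidityNetwork:
    """Raw-count network from co-prescription events.

    Node weight counts group occurrences (prescriptions); link weight
    counts, for each unordered pair of distinct groups, the events in which
    both appear (once per event).  ``patient_ids``, when given, is the
    stratum membership and events outside it are an error.
    """
    if events and n_patients < 1:
        raise ValueError("n_patients must be >= 1 when events are present")
    node_weight: dict[str, float] = {}
    link_weight: dict[tuple[str, str], float] = {}
    for ev in events:
        if patient_ids is not None and ev.patient_id not in patient_ids:
            raise ValueError(f"event patient {ev.patient_id!r} outside stratum")
        for g in ev.groups:
            node_weight[g] = node_weight.get(g, 0.0) + 1.0
        for a, b in itertools.combinations(sorted(set(ev.groups)), 2):
            link_weight[a, b] = link_weight.get((a, b), 0.0) + 1.0
    return ComorbidityNetwork(node_weight, link_weight, n_patients=n_patients)


def network_from_frame(
    records: pd.DataFrame,
    n_patients: int,
    gmap: GroupMap | None = None,
    cooccur: str = "visit",
) -> ComorbidityNetwork:
    """Vectorised equivalent of ``build_network(group_events(records), ...)``."""
    if cooccur not in ("visit", "patient"):
        raise ValueError("cooccur must be 'visit' or 'patient'")
    if records.empty:
        return ComorbidityNetwork({}, {}, n_patients=n_patients)
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1 when records are present")
    gmap = gmap or default_group_map()
    groups = gmap.map_codes(records["icd9_code"])
    node_weight = groups.value_counts().astype(float).to_dict()

    if cooccur == "visit":
        key = (
            records["patient_id"].astype(str)
            + "|"
            + pd.to_datetime(records["date"]).dt.strftime("%Y-%m-%d")
        )
    else:
        key = records["patient_id"].astype(str)
    ev = pd.DataFrame({"key": key.to_numpy(), "group": groups.to_numpy()})
    ev = ev.drop_duplicates()
    pairs = ev.merge(ev, on="key")
    pairs = pairs[pairs["group_x"] < pairs["group_y"]]
    link = pairs.groupby(["group_x", "group_y"]).size()
    link_weight = {(a, b): float(w) for (a, b), w in link.items()}
    return ComorbidityNetwork(node_weight, link_weight, n_patients=n_patients)


# ---- spec-style functional wrappers ----------------------------------------

def normalize_network(net: ComorbidityNetwork, n_patients: int | None = None) -> ComorbidityNetwork:
    if n_patients is not None and n_patients != net.n_patients:
        net = ComorbidityNetwork(
            dict(net.node_weight), dict(net.link_weight), n_patients, net.normalized
        )
    return net.normalize()


def node_strength(net: ComorbidityNetwork, group: str) -> float:
    return net.strength(group)


def network_summary(net: ComorbidityNetwork) -> pd.DataFrame:
    return net.summary()


def export_network(net: ComorbidityNetwork, path, fmt: str = "graphml") -> None:
    net.export(path, fmt=fmt)
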