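"""ICD-9-CM code handling and chapter grouping.

Individual ICD-9-CM diagnosis codes are pooled into the 20 top-level
chapters ("groups") used throughout the package: the 18 numeric chapters
(001-999), the V-code supplementary chapter (SUPP) and the E-code
external-cause chapter (EXT).  Sub-codes inherit the group of their
three-digit stem, e.g. ``250.42`` maps with ``250`` to META.
"""

from __future__ import annotations

import bisect
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

#: Regular expression accepted as a syntactically valid ICD-9-CM code.
ICD9_RE = re.compile(r"^(?:\d{3}(?:\.\d{1,2})?|V\d{2}(?:\.\d{1,2})?|E\d{3}(?:\.\d)?)$")

#: The 20 chapter labels.
GROUPS: tuple[str, ...] = (
    "INFE", "NEOP", "META", "BLD", "MENT", "NERV", "SENS", "CIRC", "RESP",
    "DIGE", "GEN", "PREG", "SKIN", "MUSC", "CONG", "NEWB", "ILL", "INJ",
    "SUPP", "EXT",
)

# Standard ICD-9-CM chapter boundaries on the 3-digit stem (inclusive).
_CHAPTER_RANGES: tuple[tuple[int, int, str], ...] = (
    (1, 139, "INFE"),    # infectious and parasitic
    (140, 239, "NEOP"),  # neoplasms
    (240, 279, "META"),  # endocrine, nutritional, metabolic, immunity
    (280, 289, "BLD"),   # blood and blood-forming organs
    (290, 319, "MENT"),  # mental disorders
    (320, 359, "NERV"),  # nervous system
    (360, 389, "SENS"),  # sense organs
    (390, 459, "CIRC"),  # circulatory system
    (460, 519, "RESP"),  # respiratory system
    (520, 579, "DIGE"),  # digestive system
    (580, 629, "GEN"),   # genitourinary system
    (630, 679, "PREG"),  # pregnancy, childbirth, puerperium
    (680, 709, "SKIN"),  # skin and subcutaneous tissue
    (710, 739, "MUSC"),  # musculoskeletal and connective tissue
    (740, 759, "CONG"),  # congenital anomalies
    (760, 779, "NEWB"),  # perinatal conditions
    (780, 799, "ILL"),   # symptoms, signs and ill-defined conditions
    (800, 999, "INJ"),   # injury and poisoning
)


class UnmappableCodeError(ValueError):
    """Raised when a code cannot be assigned to any chapter group."""


def is_valid_code(code: str) -> bool:
    """True if *code* is a syntactically valid ICD-9-CM code."""
    return bool(ICD9_RE.match(code))


@dataclass(frozen=True)
class GroupMap:
    """Mapping from ICD-9-CM codes to the 20 chapter groups.

    ``entries`` are inclusive ``(lo, hi, group)`` intervals on the numeric
    3-digit stem; ``v_group``/``e_group`` catch the V- and E-code prefixes.
    The intervals must be disjoint and jointly cover 001-999 so that every
    syntactically valid code maps to exactly one group.
    """

    entries: tuple[tuple[int, int, str], ...] = _CHAPTER_RANGES
    v_group: str = "SUPP"
    e_group: str = "EXT"

    def __post_init__(self) -> None:
        prev_hi = 0
        for lo, hi, group in self.entries:
            if lo != prev_hi + 1 or hi < lo:
                raise ValueError(
                    f"group map ranges must be disjoint and contiguous; "
                    f"got ({lo}, {hi}, {group}) after stem {prev_hi}"
                )
            prev_hi = hi
        if prev_hi != 999:
            raise ValueError("group map must cover stems 001-999")
        labels = {g for _, _, g in self.entries} | {self.v_group, self.e_group}
        if len(labels) != 20:
            raise ValueError(f"expected 20 distinct groups, got {len(labels)}")

    @property
    def groups(self) -> tuple[str, ...]:
        seen = [g for _, _, g in self.entries] + [self.v_group, self.e_group]
        return tuple(dict.fromkeys(seen))

    # cached boundaries for bisection
    @property
    def _lows(self) -> list[int]:
        return [lo for lo, _, _ in self.entries]

    def map_code(self, code: str) -> str:
        """Group label for one code; raises :class:`UnmappableCodeError`."""
        if not isinstance(code, str) or not is_valid_code(code):
            raise UnmappableCodeError(f"not a valid ICD-9-CM code: {code!r}")
        if code[0] == "V":
            return self.v_group
        if code[0] == "E":
            return self.e_group
        stem = int(code[:3])
        if stem == 0:
            raise UnmappableCodeError(f"stem 000 is outside the classification: {code!r}")
        i = bisect.bisect_right(self._lows, stem) - 1
        lo, hi, group = self.entries[i]
        assert lo <= stem <= hi
        return group

    def map_codes(self, codes: pd.Series) -> pd.Series:
        """Vectorised :meth:`map_code` over a Series of valid codes."""
        s = codes.astype(str)
        out = pd.Series(np.empty(len(s), dtype=object), index=s.index)
        first = s.str[0]
        out[first.eq("V").to_numpy()] = self.v_group
        out[first.eq("E").to_numpy()] = self.e_group
        numeric = ~first.isin(("V", "E")).to_numpy()
        if numeric.any():
            stems = pd.to_numeric(s[numeric].str.slice(0, 3), errors="coerce")
            if stems.isna().any() or (stems < 1).any():
                bad = s[numeric][stems.isna() | (stems < 1)].iloc[0]
                raise UnmappableCodeError(f"not a valid ICD-9-CM code: {bad!r}")
            lows = np.array(self._lows)
            labels = np.array([g for _, _, g in self.entries], dtype=object)
            idx = np.searchsorted(lows, stems.to_numpy(), side="right") - 1
            out[numeric] = labels[idx]
        return out

    # ---- serialisation ------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "ranges": [{"lo": lo, "hi": hi, "group": g} for lo, hi, g in self.entries],
            "v_group": self.v_group,
            "e_group": self.e_group,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroupMap":
        entries = tuple((r["lo"], r["hi"], r["group"]) for r in d["ranges"])
        return cls(entries=entries, v_group=d.get("v_group", "SUPP"),
                   e_group=d.get("e_group", "EXT"))

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GroupMap":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_group_map() -> GroupMap:
    """The bundled 20-chapter map (standard ICD-9-CM chapter boundaries)."""
    return GroupMap()


def map_code_to_group(code: str, gmap: GroupMap | None = None) -> str:
    """Group label for a single ICD-9-CM code (e.g. ``'401'`` -> ``'CIRC'``)."""
    return (gmap or default_group_map()).map_code(code)
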