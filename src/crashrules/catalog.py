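"""Factor catalog: the coding scheme for multi-fatality crash records.

Every crash record is encoded as a set of boolean sub-items ("factors")
drawn from a fixed catalog.  The catalog groups items three ways:

* **category** — the survey variable an item is a level of (severity,
  terrain, road segment, violation, ...); 18 categories in the default
  catalog;
* **construct** — the system-level grouping used for contribution and
  combination analyses: ``driver``, ``vehicle``, ``roadway``,
  ``environment``, ``crash``, plus ``context`` for items (time, severity)
  that belong to none of the four causal subsystems;
* **exclusive groups** — sets of items that are mutually exclusive within
  a single record (a crash is on plain *or* mountainous terrain, never
  both).

The default catalog ships with the package and reflects the coding of a
national in-depth investigation corpus of crashes with three or more
fatalities; the per-item counts are the published marginal frequencies of
that 1068-crash corpus and double as default Bernoulli marginals for the
synthetic generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

CONSTRUCTS = ("driver", "vehicle", "roadway", "environment", "crash", "context")

#: (category, item, published count out of 1068, construct)
#: Two cells of the published table are internally inconsistent
#: ("Passenger overload 30", "Angle 134 12.54"); printed counts are kept as-is.
_DEFAULT_ENTRIES: list[tuple[str, str, int, str]] = [
    ("Severity", "Severity: A", 691, "context"),
    ("Severity", "Severity: B", 377, "context"),
    ("Time", "Day: workday", 613, "context"),
    ("Time", "Day: weekend", 455, "context"),
    ("Time", "Time: 0:00-6:00", 220, "context"),
    ("Time", "Time: 7:00-12:00", 268, "context"),
    ("Time", "Time: 13:00-17:00", 316, "context"),
    ("Time", "Time: 18:00-23:00", 257, "context"),
    ("Terrain", "Terrain: plain", 575, "environment"),
    ("Terrain", "Terrain: mountainous", 493, "environment"),
    ("Vehicle number", "Veh num = 1", 236, "crash"),
    ("Vehicle number", "Veh num = 2", 583, "crash"),
    ("Vehicle number", "Veh num >= 3", 249, "crash"),
    ("Vehicle type", "Veh type: light-duty", 304, "vehicle"),
    ("Vehicle type", "Veh type: truck", 452, "vehicle"),
    ("Vehicle type", "Veh type: bus", 365, "vehicle"),
    ("Light condition", "Light: daylight", 580, "environment"),
    ("Light condition", "Light: dark", 228, "environment"),
    ("Light condition", "Light: dark without light", 260, "environment"),
    ("Road segment", "Curve", 126, "roadway"),
    ("Road segment", "Uphill", 44, "roadway"),
    ("Road segment", "Downhill", 118, "roadway"),
    ("Road segment", "Up-curve", 30, "roadway"),
    ("Road segment", "Down-curve", 205, "roadway"),
    ("Road segment", "Radius < 500 m", 175, "roadway"),
    ("Road segment", "Radius [500-1000] m", 158, "roadway"),
    ("Road segment", "Radius > 1000 m", 64, "roadway"),
    ("Road segment", "Grade >= 4%", 199, "roadway"),
    ("Road segment", "Grade [2%,4%]", 226, "roadway"),
    ("Road segment", "Straight segment", 545, "roadway"),
    ("Road segment", "Intersection", 121, "roadway"),
    ("Road segment", "Bridge/tunnel", 84, "roadway"),
    ("Road segment", "Ramp/interchange", 60, "roadway"),
    ("Crash type", "Crash: head-on", 353, "crash"),
    ("Crash type", "Crash: rear-end", 284, "crash"),
    ("Crash type", "Crash: angle", 134, "crash"),
    ("Crash type", "Crash: sideswipe", 21, "crash"),
    ("Crash type", "Crash: hit an object", 126, "crash"),
    ("Crash type", "Crash: skidding", 196, "crash"),
    ("Crash type", "Crash: rollover/overturn", 307, "crash"),
    ("Crash type", "Crash: falling/immersion", 147, "crash"),
    ("Lanes number", "Lanes num <= 2", 532, "roadway"),
    ("Lanes number", "Lanes num > 2", 536, "roadway"),
    ("Crash location", "Location: roadside", 335, "crash"),
    ("Crash location", "Location: roadway", 672, "crash"),
    ("Crash location", "Location: barrier/shoulder", 63, "crash"),
    ("Environmental condition", "Weather: rain", 233, "environment"),
    ("Environmental condition", "Weather: snow", 54, "environment"),
    ("Environmental condition", "Surf: wet/slippery", 303, "environment"),
    ("Deform", "Deform: disabled", 827, "vehicle"),
    ("Deform", "Deform: functional", 203, "vehicle"),
    ("Deform", "Deform: minor", 37, "vehicle"),
    ("Violation", "Unlicensed", 114, "driver"),
    ("Violation", "Alcohol", 138, "driver"),
    ("Violation", "Speeding", 331, "driver"),
    ("Violation", "Improper lane usage", 352, "driver"),
    ("Violation", "Insufficient distance", 251, "driver"),
    ("Violation", "Improper operations", 250, "driver"),
    ("Violation", "Illegal overtaking", 308, "driver"),
    ("Violation", "Dangerous driving", 194, "driver"),
    ("Violation", "Passenger overload", 30, "vehicle"),
    ("Violation", "Overspeed > 20%", 326, "vehicle"),
    ("Violation", "Overspeed < 20%", 193, "vehicle"),
    ("Violation", "Low speed", 19, "vehicle"),
    ("Limit speed", "Limit speed > 80 km/h", 423, "roadway"),
    ("Limit speed", "Limit speed [60-80] km/h", 375, "roadway"),
    ("Limit speed", "Limit speed < 60 km/h", 270, "roadway"),
    ("Driver condition", "Dr: fatigue/impaired", 272, "driver"),
    ("Driver condition", "Dr: unfamiliar", 192, "driver"),
    ("Driver condition", "Dr: normal", 604, "driver"),
    ("Road category", "Freeway", 307, "roadway"),
    ("Road category", "1st-class highway", 187, "roadway"),
    ("Road category", "2nd-class highway", 418, "roadway"),
    ("Road category", "Lower-level road", 125, "roadway"),
    ("Road category", "Urban road", 31, "roadway"),
    ("Vehicle condition", "Loss of control", 208, "vehicle"),
    ("Vehicle condition", "Tire/brake failure", 291, "vehicle"),
    ("Vehicle condition", "Fire occurrence", 75, "vehicle"),
    ("Vehicle condition", "Overweight", 275, "vehicle"),
    ("Vehicle condition", "Veh condition: unknown", 225, "vehicle"),
    ("Traffic condition", "Traffic: free flow", 309, "environment"),
    ("Traffic condition", "Traffic: stable flow", 217, "environment"),
    ("Traffic condition", "Traffic: congestion", 127, "environment"),
    ("Traffic condition", "Traffic: oversaturation", 107, "environment"),
    ("Traffic condition", "Traffic: unknown", 308, "environment"),
]

#: Categories whose levels are mutually exclusive within one record.  The
#: "Time" category holds two independent exclusive sub-groups (day type and
#: time band), so groups are itemised explicitly rather than per category.
_DEFAULT_EXCLUSIVE: list[list[str]] = [
    ["Severity: A", "Severity: B"],
    ["Day: workday", "Day: weekend"],
    ["Time: 0:00-6:00", "Time: 7:00-12:00", "Time: 13:00-17:00", "Time: 18:00-23:00"],
    ["Terrain: plain", "Terrain: mountainous"],
    ["Veh num = 1", "Veh num = 2", "Veh num >= 3"],
    ["Light: daylight", "Light: dark", "Light: dark without light"],
    ["Lanes num <= 2", "Lanes num > 2"],
    ["Location: roadside", "Location: roadway", "Location: barrier/shoulder"],
    ["Deform: disabled", "Deform: functional", "Deform: minor"],
    ["Limit speed > 80 km/h", "Limit speed [60-80] km/h", "Limit speed < 60 km/h"],
    ["Dr: fatigue/impaired", "Dr: unfamiliar", "Dr: normal"],
    ["Freeway", "1st-class highway", "2nd-class highway", "Lower-level road", "Urban road"],
    [
        "Traffic: free flow",
        "Traffic: stable flow",
        "Traffic: congestion",
        "Traffic: oversaturation",
        "Traffic: unknown",
    ],
]

_REFERENCE_N = 1068


@dataclass
class FactorCatalog:
    """Item universe with category, construct and exclusivity structure.

    Parameters
    ----------
    items
        Ordered item identifiers.
    category_of
        Item -> category name; every item maps to exactly one category.
    construct_of
        Item -> one of :data:`CONSTRUCTS`.
    exclusive_groups
        Pairwise-disjoint lists of items that are mutually exclusive
        within a record.
    marginal_count_of
        Optional item -> reference occurrence count (used as generator
        defaults); ``reference_n`` is the corresponding record total.
    """

    items: list[str]
    category_of: dict[str, str]
    construct_of: dict[str, str]
    exclusive_groups: list[list[str]] = field(default_factory=list)
    marginal_count_of: dict[str, int] = field(default_factory=dict)
    reference_n: int = _REFERENCE_N

    def __post_init__(self) -> None:
        if len(set(self.items)) != len(self.items):
            raise ValueError("duplicate item identifiers in catalog")
        missing = [i for i in self.items if i not in self.category_of]
        if missing:
            raise ValueError(f"items without a category: {missing}")
        bad = {i: c for i, c in self.construct_of.items() if c not in CONSTRUCTS}
        if bad:
            raise ValueError(f"unknown constructs: {bad}")
        seen: set[str] = set()
        for group in self.exclusive_groups:
            overlap = seen.intersection(group)
            if overlap:
                raise ValueError(f"exclusive groups are not disjoint: {sorted(overlap)}")
            seen.update(group)
            unknown = [i for i in group if i not in self.category_of]
            if unknown:
                raise ValueError(f"exclusive group references unknown items: {unknown}")

    @property
    def categories(self) -> list[str]:
        out: list[str] = []
        for item in self.items:
            cat = self.category_of[item]
            if cat not in out:
                out.append(cat)
        return out

    def items_of_category(self, category: str) -> list[str]:
        return [i for i in self.items if self.category_of[i] == category]

    def items_of_construct(self, construct: str) -> list[str]:
        return [i for i in self.items if self.construct_of.get(i) == construct]

    def marginal_probability(self, item: str) -> float:
        """Reference marginal frequency of *item*, count / reference N."""
        return self.marginal_count_of[item] / self.reference_n

    # -- serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "items": [
                {
                    "item": i,
                    "category": self.category_of[i],
                    "construct": self.construct_of.get(i, "context"),
                    **(
                        {"count": self.marginal_count_of[i]}
                        if i in self.marginal_count_of
                        else {}
                    ),
                }
                for i in self.items
            ],
            "exclusive_groups": [list(g) for g in self.exclusive_groups],
            "reference_n": self.reference_n,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "FactorCatalog":
        rows = data["items"]
        return cls(
            items=[r["item"] for r in rows],
            category_of={r["item"]: r["category"] for r in rows},
            construct_of={r["item"]: r.get("construct", "context") for r in rows},
            exclusive_groups=[list(g) for g in data.get("exclusive_groups", [])],
            marginal_count_of={r["item"]: r["count"] for r in rows if "count" in r},
            reference_n=data.get("reference_n", _REFERENCE_N),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False, allow_unicode=True)

    @classmethod
    def from_yaml(cls, path) -> "FactorCatalog":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_catalog() -> FactorCatalog:
    """The built-in multi-fatality crash catalog (18 categories)."""
    return FactorCatalog(
        items=[item for _, item, _, _ in _DEFAULT_ENTRIES],
        category_of={item: cat for cat, item, _, _ in _DEFAULT_ENTRIES},
        construct_of={item: cons for _, item, _, cons in _DEFAULT_ENTRIES},
        exclusive_groups=[list(g) for g in _DEFAULT_EXCLUSIVE],
        marginal_count_of={item: n for _, item, n, _ in _DEFAULT_ENTRIES},
        reference_n=_REFERENCE_N,
    )
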