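"""Anticoagulant treatment-pathway classification across the care transition.

Each patient exposed to an oral anticoagulant in primary care and/or during
the index stay receives exactly one label:

* ``continued`` — exposed in both settings (molecule switches count as
  continuation of anticoagulation; a molecule-level breakdown is available
  separately);
* ``discontinued_bleeding`` / ``discontinued_surgery`` /
  ``discontinued_other`` — exposed pre-hospital only, with reason precedence
  bleeding > surgery > other;
* ``initiated_in_hospital`` — exposed during the stay only;
* ``none`` — no anticoagulant exposure in either setting.
"""

from __future__ import annotations

import enum
from typing import Iterable, Mapping

import pandas as pd

from .ade import BleedingAdeResult
from .data_model import HospitalStay, Setting, StayType
from .exposure import ScreenResult, _pct


class PathwayCategory(str, enum.Enum):
    CONTINUED = "continued"
    DISCONTINUED_BLEEDING = "discontinued_bleeding"
    DISCONTINUED_SURGERY = "discontinued_surgery"
    DISCONTINUED_OTHER = "discontinued_other"
    INITIATED_IN_HOSPITAL = "initiated_in_hospital"
    NONE = "none"

    @property
    def is_discontinued(self) -> bool:
        return self.value.startswith("discontinued")


DISCONTINUED_CATEGORIES = (
    PathwayCategory.DISCONTINUED_BLEEDING,
    PathwayCategory.DISCONTINUED_SURGERY,
    PathwayCategory.DISCONTINUED_OTHER,
)


def classify_pathway(
    screen: ScreenResult,
    ade_result: BleedingAdeResult | None,
    stay: HospitalStay,
) -> PathwayCategory:
    """Deterministic pathway label for one patient (order-independent)."""
    pre = bool(screen.exposures[Setting.PRIMARY_CARE])
    hosp = bool(screen.exposures[Setting.HOSPITAL])
    if pre and hosp:
        return PathwayCategory.CONTINUED
    if pre:
        if ade_result is not None and ade_result.is_ade:
            return PathwayCategory.DISCONTINUED_BLEEDING
        if stay.stay_type is StayType.SURGERY:
            return PathwayCategory.DISCONTINUED_SURGERY
        return PathwayCategory.DISCONTINUED_OTHER
    if hosp:
        return PathwayCategory.INITIATED_IN_HOSPITAL
    return PathwayCategory.NONE


def classify_cohort(
    screens: Mapping[str, ScreenResult],
    ade_results: Mapping[str, BleedingAdeResult],
    index_stays: Mapping[str, HospitalStay],
) -> dict[str, PathwayCategory]:
    return {
        pid: classify_pathway(screen, ade_results.get(pid), index_stays[pid])
        for pid, screen in screens.items()
    }


def aggregate_flows(labels: Iterable[PathwayCategory]) -> pd.DataFrame:
    """Sankey-style flow counts and percentages per pathway category.

    Percentages of top-level categories (continued, discontinued,
    initiated_in_hospital, none) are over all labeled patients; the
    discontinued subcategory percentages are over the discontinued total, and
    subcategory counts sum to it.  An empty input yields an empty table.
    """
    labels = list(labels)
    rows = []
    n_total = len(labels)
    if n_total == 0:
        return pd.DataFrame(columns=["category", "count", "percent", "of"])
    counts = {cat: 0 for cat in PathwayCategory}
    for lab in labels:
        counts[lab] += 1
    n_disc = sum(counts[c] for c in DISCONTINUED_CATEGORIES)
    rows.append(
        {"category": "continued", "count": counts[PathwayCategory.CONTINUED],
         "percent": _pct(counts[PathwayCategory.CONTINUED], n_total), "of": "total"}
    )
    rows.append({"category": "discontinued", "count": n_disc,
                 "percent": _pct(n_disc, n_total), "of": "total"})
    for cat in DISCONTINUED_CATEGORIES:
        rows.append(
            {"category": cat.value, "count": counts[cat],
             "percent": _pct(counts[cat], n_disc), "of": "discontinued"}
        )
    for cat in (PathwayCategory.INITIATED_IN_HOSPITAL, PathwayCategory.NONE):
        rows.append(
            {"category": cat.value, "count": counts[cat],
             "percent": _pct(counts[cat], n_total), "of": "total"}
        )
    return pd.DataFrame(rows, columns=["category", "count", "percent", "of"])


def flow_edges(labels: Mapping[str, PathwayCategory]) -> pd.DataFrame:
    """(source, target, count) edge list consumable by Sankey renderers."""
    edges: dict[tuple[str, str], int] = {}
    for cat in labels.values():
        if cat is PathwayCategory.CONTINUED:
            key = ("primary_care", "hospital")
        elif cat.is_discontinued:
            key = ("primary_care", cat.value.replace("discontinued_", "stopped_"))
        elif cat is PathwayCategory.INITIATED_IN_HOSPITAL:
            key = ("no_prior_treatment", "hospital")
        else:
            key = ("no_prior_treatment", "no_treatment")
        edges[key] = edges.get(key, 0) + 1
    return pd.DataFrame(
        [{"source": s, "target": t, "count": c} for (s, t), c in sorted(edges.items())],
        columns=["source", "target", "count"],
    )
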