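"""The (co-)limitation taxonomy and cohort summaries.

A stream x response variable is classified from its response-ratio set
against two fixed effect-size thresholds.  For each registered contrast with
axes A and B (B is always a single element; A is a single element for
pairwise contrasts or a two-element block for three-element contrasts), with
``S_X := RR_X > theta_single``:

* both stimulated                         -> independent co-limitation
* one stimulated, extra combined response -> serial limitation (primary first)
* one stimulated, no extra response       -> single limitation
* neither, combined stimulated            -> simultaneous co-limitation
* neither, any ratio below -theta_single  -> negative response
* otherwise                               -> no response

The interaction class is super-additive when IRR > theta_interaction,
sub-additive when IRR < -theta_interaction, else additive.  Serial
limitation is deliberately *not* counted as co-limitation: the secondary
element follows Liebig expectations and only the primary is recorded as
limited.  Elements never supplied singly (Mo, Ni) are counted co-limiting
when their added-element response exceeds theta_single while the base
combination itself responded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .design import ELEMENT_ORDER, ExperimentDesign, Thresholds
from .ratios import Contrast, RatioValue, ResponseRatioSet

# taxonomy categories
NO_RESPONSE = "no_response"
NEGATIVE_RESPONSE = "negative_response"
SINGLE_LIMITATION = "single_limitation"
SERIAL_LIMITATION = "serial_limitation"
INDEPENDENT_COLIMITATION = "independent_colimitation"
SIMULTANEOUS_COLIMITATION = "simultaneous_colimitation"
CATEGORIES = (
    NO_RESPONSE,
    NEGATIVE_RESPONSE,
    SINGLE_LIMITATION,
    SERIAL_LIMITATION,
    INDEPENDENT_COLIMITATION,
    SIMULTANEOUS_COLIMITATION,
)
COLIMITATION_CATEGORIES = (INDEPENDENT_COLIMITATION, SIMULTANEOUS_COLIMITATION)

# interaction classes
ADDITIVE = "additive"
SUPER_ADDITIVE = "super_additive"
SUB_ADDITIVE = "sub_additive"
NOT_APPLICABLE = "not_applicable"

# element-level status
LIMITED = "limited_or_colimited"
SERIAL_SECONDARY = "serial_secondary_only"
NEGATIVE = "negative"
NONE = "none"


@dataclass(frozen=True)
class LimitationLabel:
    """Outcome of one classified contrast."""

    contrast: str
    category: str
    elements: tuple[str, ...]
    interaction_class: str = NOT_APPLICABLE
    primary: tuple[str, ...] = ()
    secondary: Optional[str] = None


def classify_combination(
    rr_a: float,
    rr_b: float,
    rr_combined: float,
    irr: Optional[float],
    thresholds: Thresholds = Thresholds(),
    *,
    a_elements: tuple[str, ...] = ("A",),
    b_elements: tuple[str, ...] = ("B",),
    contrast: str = "",
) -> LimitationLabel:
    """Classify one contrast; see the module docstring for the decision rules.

    ``irr=None`` (or NaN) marks a degenerate interaction ratio; a label is
    still produced with interaction class not-applicable.  Collapsed arms may
    be passed as ``-inf``.
    """
    th = thresholds.theta_single
    s_a = rr_a > th
    s_b = rr_b > th

    primary: tuple[str, ...] = ()
    secondary: Optional[str] = None
    if s_a and s_b:
        category = INDEPENDENT_COLIMITATION
        elements = a_elements + b_elements
    elif s_a or s_b:
        resp_rr, resp_el = (rr_a, a_elements) if s_a else (rr_b, b_elements)
        other_el = b_elements if s_a else a_elements
        if rr_combined - resp_rr > th:
            category = SERIAL_LIMITATION
            elements = resp_el + other_el
            primary = resp_el
            secondary = other_el[0] if len(other_el) == 1 else None
        else:
            category = SINGLE_LIMITATION
            elements = resp_el
    elif rr_combined > th:
        category = SIMULTANEOUS_COLIMITATION
        elements = a_elements + b_elements
    elif min(rr_a, rr_b, rr_combined) < -th:
        category = NEGATIVE_RESPONSE
        elements = tuple(
            el
            for rr, els in ((rr_a, a_elements), (rr_b, b_elements))
            if rr < -th
            for el in els
        )
    else:
        category = NO_RESPONSE
        elements = ()

    if irr is None or (isinstance(irr, float) and math.isnan(irr)):
        iclass = NOT_APPLICABLE
    elif irr > thresholds.theta_interaction:
        iclass = SUPER_ADDITIVE
    elif irr < -thresholds.theta_interaction:
        iclass = SUB_ADDITIVE
    else:
        iclass = ADDITIVE
    return LimitationLabel(contrast, category, elements, iclass, primary, secondary)


@dataclass(frozen=True)
class AddedResult:
    """Outcome of an added-element contrast (Mo/Ni over a base combination)."""

    contrast: str
    element: str
    base_elements: tuple[str, ...]
    added_rr: float
    base_rr: float
    colimited: bool


@dataclass
class StreamClassification:
    """Full taxonomy outcome for one stream x response variable."""

    stream_id: str
    response_var: str
    labels: tuple[LimitationLabel, ...]
    added: tuple[AddedResult, ...]
    element_status: dict
    single_rrs: dict  # element -> float RR of the single-supply arm
    thresholds: Thresholds
    analysable: bool = True
    reason: str = ""

    @property
    def limited_elements(self) -> tuple[str, ...]:
        return tuple(e for e in ELEMENT_ORDER if self.element_status.get(e) == LIMITED)

    @property
    def any_limited(self) -> bool:
        return any(v == LIMITED for v in self.element_status.values())

    @property
    def colimitation_combos(self) -> tuple[tuple[str, ...], ...]:
        """Element combinations with co-limitation evidence (labels + added)."""
        combos = {
            tuple(sorted(lab.elements, key=ELEMENT_ORDER.index))
            for lab in self.labels
            if lab.category in COLIMITATION_CATEGORIES
        }
        combos |= {
            tuple(sorted(ar.base_elements + (ar.element,), key=ELEMENT_ORDER.index))
            for ar in self.added
            if ar.colimited
        }
        return tuple(sorted(combos))


def roll_up_status(
    labels: Iterable[LimitationLabel],
    added: Iterable[AddedResult],
    single_rrs: dict,
    thresholds: Thresholds,
    elements: Iterable[str],
) -> dict:
    """Element-level status derived purely from contrast outcomes.

    Priority: limited_or_colimited > serial_secondary_only > negative > none.
    Serial secondaries never earn limited status from the serial label alone.
    """
    th = thresholds.theta_single
    limited: set[str] = set()
    serial_secondary: set[str] = set()
    for lab in labels:
        if lab.category == SINGLE_LIMITATION and len(lab.elements) == 1:
            limited.update(lab.elements)
        elif lab.category in COLIMITATION_CATEGORIES:
            limited.update(lab.elements)
        elif lab.category == SERIAL_LIMITATION:
            if len(lab.primary) == 1:
                limited.update(lab.primary)
            if lab.secondary is not None:
                serial_secondary.add(lab.secondary)
    for ar in added:
        if ar.colimited:
            limited.add(ar.element)
    # a single-supply arm above threshold is direct evidence of limitation,
    # covering elements that enter no pairwise contrast (Zn in the 2021 design)
    for el, rr in single_rrs.items():
        if rr is not None and rr > th:
            limited.add(el)

    status = {}
    for el in elements:
        if el in limited:
            status[el] = LIMITED
        elif el in serial_secondary:
            status[el] = SERIAL_SECONDARY
        elif el in single_rrs and single_rrs[el] is not None and single_rrs[el] < -th:
            status[el] = NEGATIVE
        else:
            status[el] = NONE
    return status


def _status_elements(design: ExperimentDesign) -> tuple[str, ...]:
    els = set()
    for t in design.treatments:
        els.update(t.slot_elements)  # Co is a passenger, never a status element
    return tuple(e for e in ELEMENT_ORDER if e in els)


def classify_stream(
    rs: ResponseRatioSet,
    thresholds: Thresholds = Thresholds(),
    design: Optional[ExperimentDesign] = None,
) -> StreamClassification:
    """Apply the taxonomy to one stream x response variable ratio set."""
    elements = tuple(
        e for e in ELEMENT_ORDER if e in rs.singles or e in ("Mo", "Ni")
    )
    if design is not None:
        elements = _status_elements(design)

    single_rrs = {
        el: (rv.value if rv.usable else None) for el, rv in rs.singles.items()
    }
    if not rs.analysable:
        return StreamClassification(
            rs.stream_id,
            rs.response_var,
            (),
            (),
            {el: NONE for el in elements},
            single_rrs,
            thresholds,
            analysable=False,
            reason=rs.reason or "not analysable",
        )

    labels: list[LimitationLabel] = []
    added: list[AddedResult] = []
    for c in rs.registry:
        irr = rs.interactions.get(c.name, RatioValue(math.nan, "undefined"))
        if c.kind == "added":
            base_rv = rs.treatment_rr.get(c.a_label)
            if base_rv is None or not base_rv.usable or not irr.usable:
                continue
            colim = irr.value > thresholds.theta_single and base_rv.value > thresholds.theta_single
            added.append(
                AddedResult(c.name, c.axis_b[0], c.axis_a, irr.value, base_rv.value, colim)
            )
            continue
        rr_a = rs.treatment_rr.get(c.a_label)
        rr_b = rs.treatment_rr.get(c.b_label)
        rr_comb = rs.treatment_rr.get(c.combined_label)
        if any(v is None or not v.usable for v in (rr_a, rr_b, rr_comb)):
            continue
        labels.append(
            classify_combination(
                rr_a.value,
                rr_b.value,
                rr_comb.value,
                irr.value if irr.ok else None,
                thresholds,
                a_elements=c.axis_a,
                b_elements=c.axis_b,
                contrast=c.name,
            )
        )

    status = roll_up_status(labels, added, single_rrs, thresholds, elements)
    return StreamClassification(
        rs.stream_id,
        rs.response_var,
        tuple(labels),
        tuple(added),
        status,
        single_rrs,
        thresholds,
    )


def classify_all(
    ratio_sets: dict,
    thresholds: Thresholds = Thresholds(),
    design: Optional[ExperimentDesign] = None,
) -> dict:
    """Classify every (stream, response_var) ratio set."""
    return {
        key: classify_stream(rs, thresholds, design) for key, rs in ratio_sets.items()
    }


def rr_to_percent(rr: float) -> float:
    """Convert a log response ratio to a percent biomass change: 100*(e^rr - 1)."""
    return 100.0 * math.expm1(rr)


@dataclass
class CohortSummary:
    """Per-element and per-combination summaries over a stream cohort."""

    response_var: str
    n_streams: int
    element_summary: pd.DataFrame
    combination_counts: pd.DataFrame
    interaction_class_distribution: pd.DataFrame
    pct_any_response: float


def summarize_cohort(
    classifications: Iterable[StreamClassification], response_var: Optional[str] = None
) -> CohortSummary:
    """Summarise one response variable's classifications across streams.

    Reports, per element: how many streams it (co-)limits and the percent,
    how many streams its single supply stimulated, and the median single-arm
    RR among streams where the element is limited.  Also counts co-limited
    element combinations and the interaction-class mix among co-limitation
    labels.
    """
    cls = [c for c in classifications if c.analysable]
    if response_var is not None:
        cls = [c for c in cls if c.response_var == response_var]
    else:
        rvars = {c.response_var for c in cls}
        if len(rvars) > 1:
            raise ValueError(
                "cohort mixes response variables; pass response_var explicitly"
            )
        response_var = rvars.pop() if rvars else ""
    if not cls:
        raise ValueError("no analysable classifications to summarise")

    n = len(cls)
    th = cls[0].thresholds.theta_single
    elements = sorted({e for c in cls for e in c.element_status}, key=ELEMENT_ORDER.index)

    rows = []
    for el in elements:
        limited = [c for c in cls if c.element_status.get(el) == LIMITED]
        stimulated = sum(
            1
            for c in cls
            if c.single_rrs.get(el) is not None and c.single_rrs[el] > th
        )
        med_rrs = [
            c.single_rrs[el]
            for c in limited
            if c.single_rrs.get(el) is not None and np.isfinite(c.single_rrs[el])
        ]
        rows.append(
            {
                "element": el,
                "n_limited": len(limited),
                "pct_limited": 100.0 * len(limited) / n,
                "n_single_stimulated": stimulated,
                "median_rr": float(np.median(med_rrs)) if med_rrs else np.nan,
            }
        )
    element_summary = pd.DataFrame(rows)

    combo_counts: dict[tuple[str, ...], int] = {}
    for c in cls:
        for combo in c.colimitation_combos:
            combo_counts[combo] = combo_counts.get(combo, 0) + 1
    combination_counts = pd.DataFrame(
        [
            {"combination": "+".join(combo), "n_streams": cnt}
            for combo, cnt in sorted(combo_counts.items(), key=lambda kv: (-kv[1], kv[0]))
        ],
        columns=["combination", "n_streams"],
    )

    iclasses = [
        lab.interaction_class
        for c in cls
        for lab in c.labels
        if lab.category in COLIMITATION_CATEGORIES
    ]
    idist = pd.DataFrame(
        [
            {
                "interaction_class": k,
                "n_labels": iclasses.count(k),
                "fraction": iclasses.count(k) / len(iclasses) if iclasses else np.nan,
            }
            for k in (SUPER_ADDITIVE, ADDITIVE, SUB_ADDITIVE, NOT_APPLICABLE)
        ]
    )

    pct_any = 100.0 * sum(1 for c in cls if c.any_limited) / n
    return CohortSummary(response_var, n, element_summary, combination_counts, idist, pct_any)


def classifications_to_frame(classifications: dict) -> pd.DataFrame:
    """Long-format export: one row per classified contrast."""
    rows = []
    for (stream, rvar), c in sorted(classifications.items()):
        if not c.analysable:
            rows.append((stream, rvar, "", "unclassifiable", "", "", c.reason))
            continue
        for lab in c.labels:
            rows.append(
                (stream, rvar, lab.contrast, lab.category, "+".join(lab.elements), lab.interaction_class, "")
            )
        for ar in c.added:
            rows.append(
                (
                    stream,
                    rvar,
                    ar.contrast,
                    "added_colimited" if ar.colimited else "added_no_response",
                    "+".join(ar.base_elements + (ar.element,)),
                    NOT_APPLICABLE,
                    "",
                )
            )
    return pd.DataFrame(
        rows,
        columns=["stream_id", "response_var", "contrast", "category", "elements", "interaction_class", "note"],
    )


def element_status_frame(classifications: dict, response_var: str = "chl_a") -> pd.DataFrame:
    """Wide per-element presence/absence of (co-)limitation, one row per stream.

    For a stream missing the requested response variable the first available
    other response variable stands in (the field-fluorometry fallback).
    """
    by_stream: dict[str, StreamClassification] = {}
    for (stream, rvar), c in sorted(classifications.items()):
        if not c.analysable:
            continue
        if rvar == response_var or stream not in by_stream:
            by_stream[stream] = c
    rows = []
    for stream, c in sorted(by_stream.items()):
        row = {"stream_id": stream, "response_var": c.response_var}
        for el, st in c.element_status.items():
            row[el] = int(st == LIMITED)
        rows.append(row)
    return pd.DataFrame(rows)
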