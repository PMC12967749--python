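"""Log response ratios and interaction response ratios.

The effect size of an enrichment treatment T is the log response ratio
``RR_T = ln(Ybar_T / Ybar_C)`` where ``Ybar`` are arithmetic means of
replicate biomass and C is the unamended control.  Non-additivity of a
combined treatment is measured by an interaction response ratio against the
additive expectation on the mean scale:

    IRR(A, B)   = ln( Ybar_AB  / (Ybar_A  + Ybar_B - Ybar_C) )
    IRR(AB, X)  = ln( Ybar_ABX / (Ybar_AB + Ybar_X - Ybar_C) )   (three-element)

For combinations whose extra element was never supplied singly (Mo, Ni) the
marginal response of adding X on top of the base pair is used instead:
``ln(Ybar_ABX / Ybar_AB)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .design import ELEMENT_ORDER, CONTROL_LABEL, ExperimentDesign, Thresholds
from .tables import BiomassTable

STATUS_OK = "ok"
STATUS_COLLAPSE = "collapse"  # treatment mean is zero with positive control
STATUS_UNDEFINED = "undefined"  # a required mean is non-positive/absent
STATUS_DEGENERATE = "degenerate"  # additive expectation <= 0


class UndefinedRatioError(ValueError):
    """A response ratio is undefined because an input mean is non-positive."""

    def __init__(self, side: str):
        self.side = side
        super().__init__(f"undefined ratio: non-positive {side} mean")


class DegenerateExpectationError(ValueError):
    """The additive expectation for an interaction ratio is non-positive."""


def log_rr(mean_treatment: float, mean_control: float) -> float:
    """ln(treatment mean / control mean)."""
    if not mean_control > 0:
        raise UndefinedRatioError("control")
    if not mean_treatment > 0:
        raise UndefinedRatioError("treatment")
    return math.log(mean_treatment / mean_control)


def interaction_rr_pair(mean_ab: float, mean_a: float, mean_b: float, mean_c: float) -> float:
    """IRR of a two-element treatment against the additive expectation."""
    for side, v in (("combined", mean_ab), ("A", mean_a), ("B", mean_b), ("control", mean_c)):
        if not v > 0:
            raise UndefinedRatioError(side)
    expectation = mean_a + mean_b - mean_c
    if not expectation > 0:
        raise DegenerateExpectationError(
            f"additive expectation {expectation:.4g} is non-positive"
        )
    return math.log(mean_ab / expectation)


def interaction_rr_triple(mean_abx: float, mean_ab: float, mean_x: float, mean_c: float) -> float:
    """IRR of a three-element treatment against (two-element block + single)."""
    return interaction_rr_pair(mean_abx, mean_ab, mean_x, mean_c)


def added_element_rr(mean_abx: float, mean_ab: float) -> float:
    """Marginal log response of adding element X on top of combination AB."""
    if not mean_ab > 0:
        raise UndefinedRatioError("base")
    if not mean_abx > 0:
        raise UndefinedRatioError("combined")
    return math.log(mean_abx / mean_ab)


@dataclass(frozen=True)
class RatioValue:
    """A ratio with a status; ``value`` is -inf for collapses, NaN when undefined."""

    value: float
    status: str = STATUS_OK

    @property
    def ok(self) -> bool:
        return self.status == STATUS_OK

    @property
    def usable(self) -> bool:
        """Usable for threshold comparisons (collapse compares as -inf)."""
        return self.status in (STATUS_OK, STATUS_COLLAPSE)


@dataclass(frozen=True)
class Contrast:
    """A registered interaction contrast.

    ``kind`` is ``pair`` (A x B singles), ``triple`` (two-element block AB x
    single X) or ``added`` (marginal response of X over base AB).  Labels are
    slot labels, so they resolve the 2021 Zn+Co arm to the Zn slot.
    """

    name: str
    kind: str
    axis_a: tuple[str, ...]
    axis_b: tuple[str, ...]
    a_label: str
    b_label: Optional[str]
    combined_label: str


def build_contrast_registry(design: ExperimentDesign) -> tuple[Contrast, ...]:
    """Enumerate the interaction contrasts a design supports.

    Pairwise contrasts need both single arms; a three-element treatment is
    decomposed as (block of first two elements) x (last element in canonical
    order).  If that last element has no single arm the contrast is the
    added-element form over the block; if the block arm is missing (the 2021
    design lacks N+Fe) the contrast cannot be formed and is skipped.
    """
    slots = design.by_slot
    contrasts: list[Contrast] = []
    for slot, t in sorted(slots.items(), key=lambda kv: _slot_sort_key(kv[1].slot_elements)):
        elems = t.slot_elements
        if len(elems) == 2:
            a, b = elems
            if a in slots and b in slots:
                contrasts.append(
                    Contrast(f"{a}x{b}", "pair", (a,), (b,), a, b, slot)
                )
        elif len(elems) == 3:
            *block, x = elems
            block_label = "+".join(block)
            if x in slots and block_label in slots:
                contrasts.append(
                    Contrast(f"({block_label})x{x}", "triple", tuple(block), (x,), block_label, x, slot)
                )
            elif x not in slots and block_label in slots:
                contrasts.append(
                    Contrast(f"{block_label}+{x}", "added", tuple(block), (x,), block_label, None, slot)
                )
            # else: no valid decomposition (e.g. N+Fe+Zn in 2021) -- skipped
    return tuple(contrasts)


def _slot_sort_key(elems: tuple[str, ...]):
    return (len(elems), tuple(ELEMENT_ORDER.index(e) for e in elems))


@dataclass
class ResponseRatioSet:
    """All ratios for one stream x response variable.

    ``singles`` maps slot elements of single-element arms to their RR;
    ``treatment_rr`` maps every non-control slot label to its RR;
    ``interactions`` maps contrast name to its IRR (or added-element RR).
    """

    stream_id: str
    response_var: str
    control_mean: float
    means: dict = field(default_factory=dict)  # slot label -> mean
    counts: dict = field(default_factory=dict)  # slot label -> n replicates
    singles: dict = field(default_factory=dict)  # element -> RatioValue
    treatment_rr: dict = field(default_factory=dict)  # slot label -> RatioValue
    interactions: dict = field(default_factory=dict)  # contrast name -> RatioValue
    registry: tuple = ()
    analysable: bool = True
    reason: str = ""

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for el, rv in self.singles.items():
            rows.append((self.stream_id, self.response_var, "single", el, rv.value, rv.status))
        for label, rv in self.treatment_rr.items():
            if len(label.split("+")) > 1:
                rows.append((self.stream_id, self.response_var, "treatment", label, rv.value, rv.status))
        for c in self.registry:
            rv = self.interactions.get(c.name)
            if rv is not None:
                kind = "added" if c.kind == "added" else "interaction"
                rows.append((self.stream_id, self.response_var, kind, c.name, rv.value, rv.status))
        return pd.DataFrame(
            rows, columns=["stream_id", "response_var", "contrast_type", "label", "value", "status"]
        )


def _rr_value(mean_t: Optional[float], mean_c: float) -> RatioValue:
    if mean_t is None:
        return RatioValue(math.nan, STATUS_UNDEFINED)
    if mean_t == 0:
        # conceptually RR = -inf: complete collapse under enrichment
        return RatioValue(-math.inf, STATUS_COLLAPSE)
    return RatioValue(log_rr(mean_t, mean_c))


def compute_ratio_set(
    means: dict, counts: dict, design: ExperimentDesign, stream_id: str = "", response_var: str = ""
) -> ResponseRatioSet:
    """Compute RRs and IRRs from per-slot-label treatment means.

    ``means`` keys are slot labels (``CTRL`` required).  The contrast
    registry is derived from the design; contrasts whose arms are missing
    from ``means`` are marked undefined rather than dropped.
    """
    registry = build_contrast_registry(design)
    ctrl = means.get(CONTROL_LABEL)
    rs = ResponseRatioSet(
        stream_id=stream_id,
        response_var=response_var,
        control_mean=ctrl if ctrl is not None else math.nan,
        means=dict(means),
        counts=dict(counts),
        registry=registry,
    )
    if ctrl is None or not ctrl > 0:
        rs.analysable = False
        rs.reason = "control mean is missing or non-positive"
        return rs

    for slot, t in design.by_slot.items():
        if t.is_control:
            continue
        rv = _rr_value(means.get(slot), ctrl)
        rs.treatment_rr[slot] = rv
        if len(t.slot_elements) == 1:
            rs.singles[t.slot_elements[0]] = rv

    for c in registry:
        rs.interactions[c.name] = _interaction_value(c, means, ctrl)
    return rs


def _interaction_value(c: Contrast, means: dict, ctrl: float) -> RatioValue:
    m_comb = means.get(c.combined_label)
    m_a = means.get(c.a_label)
    if c.kind == "added":
        if m_comb is None or m_a is None:
            return RatioValue(math.nan, STATUS_UNDEFINED)
        if m_a > 0 and m_comb == 0:
            return RatioValue(-math.inf, STATUS_COLLAPSE)
        try:
            return RatioValue(added_element_rr(m_comb, m_a))
        except UndefinedRatioError:
            return RatioValue(math.nan, STATUS_UNDEFINED)
    m_b = means.get(c.b_label)
    if m_comb is None or m_a is None or m_b is None:
        return RatioValue(math.nan, STATUS_UNDEFINED)
    try:
        return RatioValue(interaction_rr_pair(m_comb, m_a, m_b, ctrl))
    except DegenerateExpectationError:
        return RatioValue(math.nan, STATUS_DEGENERATE)
    except UndefinedRatioError:
        if m_comb == 0:
            expectation = m_a + m_b - ctrl
            if expectation > 0:
                return RatioValue(-math.inf, STATUS_COLLAPSE)
        return RatioValue(math.nan, STATUS_UNDEFINED)


def compute_all_ratios(table: BiomassTable, design: Optional[ExperimentDesign] = None) -> dict:
    """Ratio sets for every stream x response variable in a biomass table.

    Returns ``{(stream_id, response_var): ResponseRatioSet}``.  Non-analysable
    combinations yield a set with ``analysable=False`` and the audit reason.
    """
    design = design or table.design
    slot_of = {t.label: t.slot for t in design.treatments}
    df = table.data
    grouped = (
        df.groupby(["stream_id", "response_var", "treatment"])["biomass"]
        .agg(["mean", "count"])
        .reset_index()
    )
    grouped["slot"] = grouped["treatment"].map(slot_of)

    out: dict = {}
    for (stream, rvar), grp in grouped.groupby(["stream_id", "response_var"], sort=True):
        means = dict(zip(grp["slot"], grp["mean"]))
        counts = dict(zip(grp["slot"], grp["count"]))
        rs = compute_ratio_set(means, counts, design, stream, rvar)
        if not table.is_analysable(stream, rvar):
            rs.analysable = False
            mask = (table.analysability["stream_id"] == stream) & (
                table.analysability["response_var"] == rvar
            )
            reasons = table.analysability.loc[mask, "reason"]
            rs.reason = reasons.iloc[0] if len(reasons) else "not analysable"
        out[(stream, rvar)] = rs
    return out


def ratios_to_frame(ratio_sets: dict) -> pd.DataFrame:
    """Long-format export of many ratio sets."""
    frames = [rs.to_frame() for rs in ratio_sets.values() if rs.analysable]
    if not frames:
        return pd.DataFrame(
            columns=["stream_id", "response_var", "contrast_type", "label", "value", "status"]
        )
    return pd.concat(frames, ignore_index=True)
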