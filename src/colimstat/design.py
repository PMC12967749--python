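"""Treatment design bookkeeping for nutrient-diffusing-substrate (NDS) experiments.

An NDS deployment exposes stream biofilm to a factorial set of nutrient and
trace-metal enrichments: single elements (N, P, Fe, Zn), pairwise and
three-way combinations, plus an unamended control.  Two deployment variants
exist: the 2021 design pairs Co with Zn (the two metals substitute at the
active site of carbonic anhydrase, so Co rides along with Zn) and lacks the
N+Fe arm, which was added in 2022.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

#: Canonical element ordering used for treatment labels.
ELEMENT_ORDER = ("N", "P", "Fe", "Zn", "Co", "Mo", "Ni")
ELEMENTS = frozenset(ELEMENT_ORDER)

CONTROL_LABEL = "CTRL"

#: Biomass response variables: lab-extracted chlorophyll a plus the three
#: field-fluorometry pigment groups.
RESPONSE_VARS = ("chl_a", "diatom", "cyanobacteria", "chlorophyte")


class DesignError(ValueError):
    """Raised for invalid elements, treatment labels or design years."""


def _rank(element: str) -> int:
    return ELEMENT_ORDER.index(element)


def _canonical_order(elements: Iterable[str]) -> tuple[str, ...]:
    elems = list(elements)
    for e in elems:
        if e not in ELEMENTS:
            raise DesignError(f"unknown element {e!r}; valid: {ELEMENT_ORDER}")
    return tuple(sorted(set(elems), key=_rank))


@dataclass(frozen=True)
class Treatment:
    """An enrichment treatment identified by its element set (empty = control).

    Equality and hashing are by element set only, so e.g. ``Fe+N`` and
    ``N+Fe`` denote the same treatment.
    """

    elements: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "elements", frozenset(_canonical_order(self.elements)))
        if len(self.elements) > 3:
            raise DesignError(f"treatments combine at most 3 elements, got {sorted(self.elements)}")

    @property
    def label(self) -> str:
        if not self.elements:
            return CONTROL_LABEL
        return "+".join(_canonical_order(self.elements))

    @property
    def is_control(self) -> bool:
        return not self.elements

    @property
    def slot_elements(self) -> tuple[str, ...]:
        """Element set with the Co passenger dropped when it rides with Zn.

        The 2021 Zn treatment is physically Zn+Co; for cross-year comparison
        it occupies the Zn slot and Co is recorded as a passenger.
        """
        elems = set(self.elements)
        if "Co" in elems and "Zn" in elems:
            elems.discard("Co")
        return _canonical_order(elems)

    @property
    def slot(self) -> str:
        """Canonical slot label (``Zn+Co`` -> ``Zn``)."""
        if not self.elements:
            return CONTROL_LABEL
        return "+".join(self.slot_elements)

    @classmethod
    def from_label(cls, label: str) -> "Treatment":
        label = str(label).strip()
        if label == "" or label.upper() in (CONTROL_LABEL, "CONTROL"):
            return cls(frozenset())
        return cls(frozenset(part.strip() for part in label.split("+")))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


def treatment(*elements: str) -> Treatment:
    """Convenience constructor: ``treatment("N", "Fe")``."""
    return Treatment(frozenset(elements))


CONTROL = treatment()


@dataclass(frozen=True)
class Thresholds:
    """Effect-size cut-offs for the limitation classification.

    ``theta_single`` is the log response ratio above which a treatment is
    taken to stimulate growth (0.326, i.e. +38.5% biomass); ``theta_interaction``
    is the interaction response ratio above which a combined treatment is
    significantly non-additive (0.385).
    """

    theta_single: float = 0.326
    theta_interaction: float = 0.385

    def __post_init__(self) -> None:
        if not (self.theta_single > 0 and self.theta_interaction > 0):
            raise ValueError("thresholds must be positive")


@dataclass(frozen=True)
class ExperimentDesign:
    """The treatment set deployed in a given year, plus the replicate target."""

    year: int
    treatments: frozenset
    replicates_target: int = 5

    def __post_init__(self) -> None:
        if self.replicates_target < 1:
            raise DesignError("replicates_target must be positive")
        if CONTROL not in self.treatments:
            raise DesignError("design must include the control treatment")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(sorted(t.label for t in self.treatments))

    @property
    def by_label(self) -> dict:
        return {t.label: t for t in self.treatments}

    @property
    def by_slot(self) -> dict:
        """Treatments keyed by slot label (maps the 2021 Zn+Co arm to ``Zn``)."""
        return {t.slot: t for t in self.treatments}

    def contains_label(self, label: str) -> bool:
        try:
            return Treatment.from_label(label) in self.treatments
        except DesignError:
            return False

    @property
    def n_cups(self) -> int:
        """Cups per stream at the replicate target."""
        return len(self.treatments) * self.replicates_target


_COMMON = [
    treatment("N"),
    treatment("P"),
    treatment("Fe"),
    treatment("N", "P"),
    treatment("P", "Fe"),
    treatment("N", "P", "Fe"),
    treatment("N", "Fe", "Zn"),
    treatment("P", "Fe", "Ni"),
    treatment("P", "Fe", "Mo"),
]


def design_for_year(year: int, replicates_target: int = 5) -> ExperimentDesign:
    """Canonical NDS design for a deployment year.

    2022: control + 11 treatments (N, P, Fe, Zn, N+P, N+Fe, P+Fe, N+P+Fe,
    N+Fe+Zn, P+Fe+Ni, P+Fe+Mo).  2021: Zn is supplied as Zn+Co and the N+Fe
    arm is absent.
    """
    if year == 2022:
        extra = [treatment("Zn"), treatment("N", "Fe")]
    elif year == 2021:
        extra = [treatment("Zn", "Co")]
    else:
        raise DesignError(f"no NDS design defined for year {year}")
    treatments = frozenset([CONTROL, *_COMMON, *extra])
    return ExperimentDesign(year=year, treatments=treatments, replicates_target=replicates_target)
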