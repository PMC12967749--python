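"""Validated readers/writers for cup-level biomass and stream covariate tables.

Biomass CSVs are long format with one row per cup:
``stream_id, response_var, treatment, replicate, biomass`` (biomass in
micrograms per square centimetre; units are metadata only, every downstream
statistic is a ratio).  Covariate CSVs are long format:
``stream_id, variable_name, value, group`` with blank cells meaning missing.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Union

import numpy as np
import pandas as pd

from .design import (
    RESPONSE_VARS,
    DesignError,
    ExperimentDesign,
    Treatment,
)

BIOMASS_COLUMNS = ("stream_id", "response_var", "treatment", "replicate", "biomass")
COVARIATE_COLUMNS = ("stream_id", "variable_name", "value", "group")
COVARIATE_GROUPS = ("water_quality", "landscape", "soil_metal_decile")

#: Minimum fraction of a design's cups that must be recovered for a stream x
#: response variable to be analysable.
MIN_RECOVERY = 0.70
#: Minimum replicates per present treatment.
MIN_REPLICATES = 2


class SchemaError(ValueError):
    """Input file does not match the expected column schema."""


class ValidationError(ValueError):
    """Input values violate a domain constraint."""


@dataclass
class BiomassTable:
    """Replicate-level biomass per stream x treatment x response variable.

    ``data`` holds canonicalised treatment labels.  ``analysability`` flags
    each (stream_id, response_var) as analysable or not, with a reason; a
    combination is analysable when the control and every present treatment
    have at least :data:`MIN_REPLICATES` cups and at least
    :data:`MIN_RECOVERY` of the design's cups were recovered.
    """

    data: pd.DataFrame
    design: ExperimentDesign
    units: str = "ug/cm2"
    analysability: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        self.data = self.data.reset_index(drop=True)
        self.analysability = _assess_analysability(self.data, self.design)

    def is_analysable(self, stream_id: str, response_var: str) -> bool:
        mask = (self.analysability["stream_id"] == stream_id) & (
            self.analysability["response_var"] == response_var
        )
        sub = self.analysability.loc[mask, "analysable"]
        return bool(sub.iloc[0]) if len(sub) else False

    @property
    def streams(self) -> tuple[str, ...]:
        return tuple(pd.unique(self.data["stream_id"]))

    def subset(self, mask) -> "BiomassTable":
        return BiomassTable(self.data.loc[mask].copy(), self.design, self.units)


def _assess_analysability(df: pd.DataFrame, design: ExperimentDesign) -> pd.DataFrame:
    rows = []
    for (stream, rvar), grp in df.groupby(["stream_id", "response_var"], sort=True):
        counts = grp.groupby("treatment")["biomass"].count()
        reasons = []
        if "CTRL" not in counts.index:
            reasons.append("control treatment absent")
        short = counts[counts < MIN_REPLICATES]
        if len(short):
            reasons.append(
                "fewer than %d replicates for: %s" % (MIN_REPLICATES, ", ".join(short.index))
            )
        recovery = len(grp) / design.n_cups
        if recovery < MIN_RECOVERY:
            reasons.append(f"cup recovery {recovery:.2f} below {MIN_RECOVERY:.2f}")
        rows.append(
            {
                "stream_id": stream,
                "response_var": rvar,
                "analysable": not reasons,
                "reason": "; ".join(reasons),
            }
        )
    return pd.DataFrame(rows, columns=["stream_id", "response_var", "analysable", "reason"])


def _validate_biomass_frame(df: pd.DataFrame, design: ExperimentDesign) -> pd.DataFrame:
    missing = [c for c in BIOMASS_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"biomass table missing columns: {missing}")
    df = df.loc[:, list(BIOMASS_COLUMNS)].copy()

    bad_rv = set(df["response_var"]) - set(RESPONSE_VARS)
    if bad_rv:
        raise ValidationError(f"unknown response variables: {sorted(bad_rv)}")

    # Canonicalise treatment labels; unknown elements or labels outside the
    # design are rejected outright.
    canonical = {}
    for label in pd.unique(df["treatment"]):
        try:
            t = Treatment.from_label(label)
        except DesignError as exc:
            raise ValidationError(f"invalid treatment label {label!r}: {exc}") from exc
        if t not in design.treatments:
            raise ValidationError(
                f"treatment {t.label!r} is not part of the {design.year} design"
            )
        canonical[label] = t.label
    df["treatment"] = df["treatment"].map(canonical)

    df["biomass"] = pd.to_numeric(df["biomass"], errors="raise")
    if (df["biomass"] < 0).any():
        bad = df.loc[df["biomass"] < 0].iloc[0]
        raise ValidationError(
            f"negative biomass for stream {bad['stream_id']!r}, treatment {bad['treatment']!r}"
        )
    df["replicate"] = df["replicate"].astype(int)
    df["stream_id"] = df["stream_id"].astype(str)
    return df


def read_biomass(path, design: ExperimentDesign) -> BiomassTable:
    """Read and validate a biomass CSV against a design.

    Unknown treatment labels or negative biomass raise; streams with missing
    replicates are only *flagged* not-analysable, not rejected.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    return BiomassTable(_validate_biomass_frame(df, design), design)


def biomass_from_frame(df: pd.DataFrame, design: ExperimentDesign) -> BiomassTable:
    """Build a validated table from an in-memory frame (same checks as the reader)."""
    return BiomassTable(_validate_biomass_frame(df, design), design)


def write_biomass(table: BiomassTable, path) -> None:
    # %.17g round-trips every double exactly, so write-then-read is bit-exact
    table.data.to_csv(path, index=False, float_format="%.17g")


@dataclass
class CovariateTable:
    """Long-format stream covariates (water quality, landscape, soil-metal deciles)."""

    data: pd.DataFrame

    def missingness(self) -> pd.Series:
        """Fraction missing per variable."""
        return self.data.groupby("variable_name")["value"].apply(lambda s: s.isna().mean())

    @property
    def missing_fraction(self) -> float:
        return float(self.data["value"].isna().mean())

    def to_wide(self) -> pd.DataFrame:
        """Streams x variables matrix (NaN = missing)."""
        wide = self.data.pivot_table(
            index="stream_id", columns="variable_name", values="value", aggfunc="first", dropna=False
        )
        wide.columns.name = None
        return wide.sort_index()

    @property
    def groups(self) -> pd.Series:
        return self.data.drop_duplicates("variable_name").set_index("variable_name")["group"]


def _validate_covariate_frame(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COVARIATE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"covariate table missing columns: {missing}")
    df = df.loc[:, list(COVARIATE_COLUMNS)].copy()

    bad_groups = set(df["group"]) - set(COVARIATE_GROUPS)
    if bad_groups:
        raise ValidationError(f"unknown covariate groups: {sorted(bad_groups)}")

    def to_float(v):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return np.nan
        s = str(v).strip()
        if s == "":
            return np.nan
        try:
            return float(s)
        except ValueError:
            raise ValidationError(f"non-numeric covariate value {v!r}") from None

    df["value"] = df["value"].map(to_float)

    deciles = df.loc[df["group"] == "soil_metal_decile", "value"].dropna()
    if len(deciles) and ((deciles < 1) | (deciles > 10)).any():
        raise ValidationError("soil-metal decile values must lie in 1-10")
    df["stream_id"] = df["stream_id"].astype(str)
    return df


def read_covariates(path) -> CovariateTable:
    """Read a long-format covariate CSV; blank cells become missing values."""
    df = pd.read_csv(path, dtype={"value": str}, keep_default_na=False, na_values=[""])
    return CovariateTable(_validate_covariate_frame(df))


def covariates_from_frame(df: pd.DataFrame) -> CovariateTable:
    return CovariateTable(_validate_covariate_frame(df))


def write_covariates(table: CovariateTable, path) -> None:
    table.data.to_csv(path, index=False)
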