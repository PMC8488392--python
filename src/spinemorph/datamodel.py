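"""Domain model for dendritic-spine morphometry tables.

All measurements are carried in tidy :class:`pandas.DataFrame` tables with a
fixed column vocabulary, keyed by the anatomical hierarchy
strain → mouse → region → neuron → compartment → position → segment.
Lengths are in μm and areas in μm² throughout; files carry no unit columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Brain regions analysed: CA1 field of the dorsal hippocampus and
#: layer II/III of the prefrontal cortex.
REGIONS = ("hippocampus_CA1", "pfc_II_III")
#: Dendritic compartments of a pyramidal neuron.
COMPARTMENTS = ("apical", "basal")
#: Segment position relative to the soma (proximal: < 40 μm, distal: > 40 μm).
POSITIONS = ("proximal", "distal")

ANATOMY_KEYS = ["strain", "mouse_id", "region", "neuron_id"]
SEGMENT_KEYS = ANATOMY_KEYS + ["compartment", "position", "segment_id"]

SPINE_COLUMNS = SEGMENT_KEYS + ["length_um", "width_um", "branched"]
SEGMENT_COLUMNS = SEGMENT_KEYS + ["segment_length_um", "spine_count"]
SOMA_COLUMNS = ANATOMY_KEYS + ["perimeter_um", "area_um2"]

_SCHEMA_COLUMNS = {
    "spines": SPINE_COLUMNS,
    "segments": SEGMENT_COLUMNS,
    "somata": SOMA_COLUMNS,
}


class SchemaError(ValueError):
    """A table is structurally malformed (missing or unknown columns)."""


class ValidationError(ValueError):
    """A table violates a value-level invariant; message cites 1-based rows."""


def empty_table(schema: str) -> pd.DataFrame:
    """Return an empty table with the declared columns for *schema*."""
    return pd.DataFrame({c: pd.Series(dtype=_dtype(schema, c)) for c in _SCHEMA_COLUMNS[schema]})


def _dtype(schema: str, column: str) -> str:
    if column in ("length_um", "width_um", "segment_length_um", "perimeter_um", "area_um2"):
        return "float64"
    if column == "spine_count":
        return "int64"
    if column == "branched":
        return "bool"
    return "object"


def _bad_rows(mask: pd.Series) -> str:
    rows = (np.flatnonzero(mask.to_numpy()) + 1).tolist()
    shown = ", ".join(map(str, rows[:10]))
    more = "" if len(rows) <= 10 else f" (+{len(rows) - 10} more)"
    return shown + more


def validate_table(df: pd.DataFrame, schema: str) -> pd.DataFrame:
    """Validate one table against its schema, returning it with typed columns.

    Raises
    ------
    SchemaError
        if a mandatory column is missing.
    ValidationError
        if any row violates a type or range invariant; the message names the
        offending column and 1-based data-row numbers.
    """
    if schema not in _SCHEMA_COLUMNS:
        raise SchemaError(f"unknown schema {schema!r}; expected one of {sorted(_SCHEMA_COLUMNS)}")
    columns = _SCHEMA_COLUMNS[schema]
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{schema} table is missing mandatory column(s): {', '.join(missing)}")
    df = df[columns].copy()

    for col, allowed in (("region", REGIONS), ("compartment", COMPARTMENTS), ("position", POSITIONS)):
        if col not in columns:
            continue
        bad = ~df[col].astype(str).isin(allowed)
        if bad.any():
            tokens = sorted(set(df.loc[bad, col].astype(str)))
            raise ValidationError(
                f"{schema}: unknown {col} token(s) {tokens} in row(s) {_bad_rows(bad)}; "
                f"allowed: {list(allowed)}"
            )

    for col in columns:
        if col in ("branched",):
            df[col] = _parse_bool(df[col], schema, col)
        elif _dtype(schema, col) in ("float64", "int64"):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna()
            if bad.any():
                raise ValidationError(f"{schema}: non-numeric {col} in row(s) {_bad_rows(bad)}")
            # convert via numpy: correctly-rounded parsing (to_numeric is not)
            df[col] = df[col].to_numpy().astype(_dtype(schema, col))
        else:
            df[col] = df[col].astype(str)

    positive = {
        "spines": ["length_um", "width_um"],
        "segments": ["segment_length_um"],
        "somata": ["perimeter_um", "area_um2"],
    }[schema]
    for col in positive:
        bad = ~(df[col] > 0)
        if bad.any():
            raise ValidationError(f"{schema}: non-positive {col} in row(s) {_bad_rows(bad)}")
    if schema == "segments":
        bad = df["spine_count"] < 0
        if bad.any():
            raise ValidationError(f"segments: negative spine_count in row(s) {_bad_rows(bad)}")
    if schema == "somata":
        # isoperimetric inequality 4πA ≤ P² must hold for any simple outline
        bad = 4.0 * np.pi * df["area_um2"] > df["perimeter_um"] ** 2 * (1 + 1e-9)
        if bad.any():
            raise ValidationError(
                f"somata: area/perimeter pair violates the isoperimetric bound "
                f"4πA ≤ P² in row(s) {_bad_rows(bad)}"
            )
    return df.reset_index(drop=True)


_TRUE = {"true", "1", "t", "yes"}
_FALSE = {"false", "0", "f", "no"}


def _parse_bool(series: pd.Series, schema: str, col: str) -> pd.Series:
    if series.dtype == bool:
        return series
    tokens = series.astype(str).str.strip().str.lower()
    bad = ~tokens.isin(_TRUE | _FALSE)
    if bad.any():
        raise ValidationError(f"{schema}: non-boolean {col} in row(s) {_bad_rows(bad)}")
    return tokens.isin(_TRUE)


@dataclass
class Dataset:
    """A complete morphometry dataset: spines, segments and soma traces.

    Any of the three tables may be empty; ``provenance`` records where the
    data came from (a source file, or a generator preset and seed).
    """

    spines: pd.DataFrame = field(default_factory=lambda: empty_table("spines"))
    segments: pd.DataFrame = field(default_factory=lambda: empty_table("segments"))
    somata: pd.DataFrame = field(default_factory=lambda: empty_table("somata"))
    provenance: str = ""

    def validate(self) -> "Dataset":
        """Re-validate all tables and their cross-table consistency."""
        self.spines = validate_table(self.spines, "spines")
        self.segments = validate_table(self.segments, "segments")
        self.somata = validate_table(self.somata, "somata")
        if len(self.spines) and len(self.segments):
            # segments that carry per-spine measurements must agree on counts
            per_seg = self.spines.groupby(SEGMENT_KEYS, observed=True).size()
            seg = self.segments.set_index(SEGMENT_KEYS)["spine_count"]
            common = per_seg.index.intersection(seg.index)
            mismatch = per_seg.loc[common] != seg.loc[common]
            if mismatch.any():
                keys = list(per_seg.loc[common][mismatch].index[:5])
                raise ValidationError(
                    f"spine_count disagrees with per-spine rows for segment(s) {keys}"
                )
        return self

    @property
    def strains(self) -> list[str]:
        out: list[str] = []
        for df in (self.spines, self.segments, self.somata):
            for s in df["strain"].unique():
                if s not in out:
                    out.append(s)
        return out

    def subset(self, **filters: str) -> "Dataset":
        """Restrict all tables by equality filters on key columns.

        ``subset(region="hippocampus_CA1", compartment="apical")`` keeps only
        matching rows; a filter on a column a table lacks is ignored there.
        """
        def _apply(df: pd.DataFrame) -> pd.DataFrame:
            for col, val in filters.items():
                if col in df.columns:
                    df = df[df[col] == val]
            return df.reset_index(drop=True)

        return Dataset(
            spines=_apply(self.spines),
            segments=_apply(self.segments),
            somata=_apply(self.somata),
            provenance=self.provenance,
        )

    def equals(self, other: "Dataset") -> bool:
        return (
            self.spines.equals(other.spines)
            and self.segments.equals(other.segments)
            and self.somata.equals(other.somata)
        )
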