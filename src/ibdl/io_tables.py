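"""Tabular I/O, schema validation, and the calibrated index-model artifact.

All community, metadata and environmental tables enter the pipeline through
the readers in this module, which enforce the schema invariants up front so
that the computational modules (:mod:`ibdl.titan`, :mod:`ibdl.metrics`,
:mod:`ibdl.aggregation`) can assume clean inputs.

The canonical dialect is plain CSV (comma separator, "." decimal mark); a
``dialect="french"`` option accepts the ";" separator with "," decimals used
by French agency exports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "IBDLError",
    "SchemaError",
    "ParseError",
    "CalibrationError",
    "UnsupportedModelVersion",
    "VARIABLES",
    "SUBSTRATES",
    "METATYPES",
    "RIPARIAN_TYPES",
    "DIALECTS",
    "CountMatrix",
    "IndexModel",
    "read_counts",
    "write_counts",
    "read_sample_metadata",
    "write_sample_metadata",
    "read_lake_metadata",
    "write_lake_metadata",
    "read_env_table",
    "write_env_table",
    "validate_sample",
    "validate_samples",
    "read_model",
    "write_model",
]


class IBDLError(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(IBDLError):
    """An input table violates a structural invariant."""


class ParseError(SchemaError):
    """A cell could not be parsed; the message names the row and column."""


class CalibrationError(IBDLError):
    """Calibration cannot proceed (degenerate groups, empty reference pool...)."""


class UnsupportedModelVersion(IBDLError):
    """A model file declares a format version this build does not read."""


#: Environmental variables of the physico-chemical monitoring table.
VARIABLES = ("NKJ", "NH4", "BOD5", "Cond", "NO3", "NO2", "PO4", "O2", "PctO2", "SP", "Pt")
SUBSTRATES = ("mineral", "macrophyte")
METATYPES = ("LA", "MA", "HA", "unknown")
RIPARIAN_TYPES = (1, 2, 3, 4)

DIALECTS: Mapping[str, dict] = {
    "standard": {"sep": ",", "decimal": "."},
    "french": {"sep": ";", "decimal": ","},
}

#: Sample-validity thresholds (NF T90-354 compliance: at least 350 counted
#: valves, strictly more than half determined at species level; 400 valves is
#: the nominal counting target).
MIN_VALVES = 350
MIN_SPECIES_LEVEL_FRACTION = 0.5
NOMINAL_DEPTH = 400

MODEL_FORMAT_VERSION = 1


def _dialect_kwargs(dialect: str) -> dict:
    try:
        return DIALECTS[dialect]
    except KeyError:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {sorted(DIALECTS)}")


# ---------------------------------------------------------------------------
# Count matrix
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CountMatrix:
    """Samples x taxa table of raw valve counts.

    ``counts`` is indexed by sample id with one integer column per taxon
    code.  Relative abundances are always derived on demand from the counts
    (single source of truth); they are never persisted.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        df.index.name = "sample_id"
        df.columns.name = None
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()].unique().tolist()
            raise SchemaError(f"duplicate sample ids: {dup}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()].unique().tolist()
            raise SchemaError(f"duplicate taxon codes: {dup}")
        values = df.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            raise SchemaError("counts must be integers")
        if values.size and (values < 0).any():
            rows, cols = np.nonzero(values < 0)
            raise SchemaError(
                f"negative count at sample {df.index[rows[0]]!r}, taxon {df.columns[cols[0]]!r}"
            )

    @property
    def sample_ids(self) -> list:
        return list(self.counts.index)

    @property
    def taxon_codes(self) -> list:
        return list(self.counts.columns)

    @property
    def total_counts(self) -> pd.Series:
        """Valves counted per sample (row sums)."""
        return self.counts.sum(axis=1)

    def relative_abundance(self) -> pd.DataFrame:
        """Counts divided by the per-sample total; zero-total rows stay 0."""
        totals = self.total_counts.to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = self.counts.to_numpy(dtype=float) / totals[:, None]
        rel[totals == 0] = 0.0
        return pd.DataFrame(rel, index=self.counts.index, columns=self.counts.columns)

    def occurrence(self) -> pd.Series:
        """Number of samples in which each taxon has a nonzero count."""
        return (self.counts > 0).sum(axis=0)

    def subset_samples(self, sample_ids: Iterable) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(sample_ids)])


def read_counts(path, dialect: str = "standard") -> CountMatrix:
    """Read a samples x taxa count table (first column = sample id)."""
    path = Path(path)
    kw = _dialect_kwargs(dialect)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(kw["sep"])
    taxa = header[1:]
    seen, dups = set(), []
    for t in taxa:
        if t in seen:
            dups.append(t)
        seen.add(t)
    if dups:
        raise SchemaError(f"duplicate taxon columns in {path.name}: {sorted(set(dups))}")

    df = pd.read_csv(path, index_col=0, dtype=str, **kw)
    df.index = df.index.astype(str)
    numeric = df.apply(lambda col: pd.to_numeric(col.str.replace(kw["decimal"], ".", regex=False)
                                                 if kw["decimal"] != "." else col, errors="coerce"))
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.nonzero(bad.to_numpy())
        raise ParseError(
            f"malformed numeric cell at sample {df.index[r[0]]!r}, column {df.columns[c[0]]!r}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.nonzero(numeric.isna().to_numpy())
        raise ParseError(
            f"missing count at sample {df.index[r[0]]!r}, column {df.columns[c[0]]!r}"
        )
    values = numeric.to_numpy(dtype=float)
    if values.size and not np.allclose(values, np.round(values)):
        r, c = np.nonzero(~np.isclose(values, np.round(values)))
        raise SchemaError(
            f"non-integer count at sample {df.index[r[0]]!r}, column {df.columns[c[0]]!r}"
        )
    return CountMatrix(pd.DataFrame(values.astype(np.int64), index=df.index, columns=df.columns))


def write_counts(matrix: CountMatrix, path, dialect: str = "standard") -> None:
    kw = _dialect_kwargs(dialect)
    matrix.counts.to_csv(path, sep=kw["sep"], index_label="sample_id")


# ---------------------------------------------------------------------------
# Metadata tables
# ---------------------------------------------------------------------------

_SAMPLE_COLUMNS = ("sample_id", "lake_id", "ou_id", "substrate", "riparian_type",
                   "date", "species_level_fraction")


def read_sample_metadata(path, dialect: str = "standard") -> pd.DataFrame:
    """Read per-sample metadata; one row per sample of the count matrix."""
    df = pd.read_csv(path, **_dialect_kwargs(dialect))
    return validate_sample_metadata(df)


def validate_sample_metadata(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"sample metadata is missing columns {missing}")
    df = df.copy()
    df["sample_id"] = df["sample_id"].astype(str)
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise SchemaError(f"duplicate sample ids in metadata: {dup}")
    bad = ~df["substrate"].isin(SUBSTRATES)
    if bad.any():
        raise SchemaError(f"invalid substrate values: {sorted(df.loc[bad, 'substrate'].unique())}")
    df["riparian_type"] = pd.to_numeric(df["riparian_type"], errors="coerce")
    bad = ~df["riparian_type"].isin(RIPARIAN_TYPES)
    if bad.any():
        raise SchemaError("riparian_type must be one of 1, 2, 3, 4")
    df["riparian_type"] = df["riparian_type"].astype(int)
    frac = pd.to_numeric(df["species_level_fraction"], errors="coerce")
    out_of_range = frac.notna() & ((frac < 0) | (frac > 1))
    if out_of_range.any():
        raise SchemaError("species_level_fraction must lie in [0, 1]")
    df["species_level_fraction"] = frac
    return df


def write_sample_metadata(df: pd.DataFrame, path, dialect: str = "standard") -> None:
    df.to_csv(path, index=False, sep=_dialect_kwargs(dialect)["sep"])


_LAKE_COLUMNS = ("lake_id", "metatype", "pc_type_1", "pc_type_2", "pc_type_3",
                 "pc_type_4", "pct_artificial_landuse", "pct_agriculture")


def read_lake_metadata(path, dialect: str = "standard") -> pd.DataFrame:
    df = pd.read_csv(path, **_dialect_kwargs(dialect))
    return validate_lake_metadata(df)


def validate_lake_metadata(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _LAKE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"lake metadata is missing columns {missing}")
    df = df.copy()
    if df["lake_id"].duplicated().any():
        raise SchemaError("duplicate lake ids in lake metadata")
    bad = ~df["metatype"].isin(METATYPES)
    if bad.any():
        raise SchemaError(f"invalid metatype values: {sorted(df.loc[bad, 'metatype'].unique())}")
    pc = df[[f"pc_type_{t}" for t in RIPARIAN_TYPES]].astype(float)
    if (pc.to_numpy() < 0).any():
        raise SchemaError("pc_type percentages must be non-negative")
    sums = pc.sum(axis=1)
    off = ~np.isclose(sums, 1.0, atol=1e-6)
    if off.any():
        raise SchemaError(
            f"pc_type fractions must sum to 1 (lake {df.loc[off, 'lake_id'].iloc[0]!r})"
        )
    return df


def write_lake_metadata(df: pd.DataFrame, path, dialect: str = "standard") -> None:
    df.to_csv(path, index=False, sep=_dialect_kwargs(dialect)["sep"])


_ENV_COLUMNS = ("lake_id", "variable", "value", "year")


def read_env_table(path, dialect: str = "standard") -> pd.DataFrame:
    df = pd.read_csv(path, **_dialect_kwargs(dialect))
    return validate_env_table(df)


def validate_env_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _ENV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"environmental table is missing columns {missing}")
    df = df.copy()
    bad = ~df["variable"].isin(VARIABLES)
    if bad.any():
        raise SchemaError(f"unknown env variables: {sorted(df.loc[bad, 'variable'].unique())}")
    df["value"] = pd.to_numeric(df["value"], errors="coerce")
    if (df["value"].dropna() < 0).any():
        raise SchemaError("environmental values must be non-negative")
    if df.duplicated(subset=["lake_id", "variable", "year"]).any():
        raise SchemaError("at most one value per (lake, variable, year)")
    return df


def write_env_table(df: pd.DataFrame, path, dialect: str = "standard") -> None:
    df.to_csv(path, index=False, sep=_dialect_kwargs(dialect)["sep"])


# ---------------------------------------------------------------------------
# Sample validity
# ---------------------------------------------------------------------------

def validate_sample(total_count, species_level_fraction, policy: str = "strict"):
    """Apply the count-compliance rules to one sample.

    A sample is valid iff at least :data:`MIN_VALVES` valves were counted AND
    strictly more than half of them were determined at species level.  With
    ``policy="strict"`` a missing species-level fraction invalidates the
    sample; with ``policy="lenient"`` it only triggers a warning reason while
    the count rule alone decides.

    Returns ``(valid, reasons)`` where ``reasons`` is a tuple of
    machine-readable codes.
    """
    if policy not in ("strict", "lenient"):
        raise ValueError(f"unknown policy {policy!r}")
    reasons = []
    if total_count < MIN_VALVES:
        reasons.append("low_count")
    frac_missing = species_level_fraction is None or (
        isinstance(species_level_fraction, float) and np.isnan(species_level_fraction)
    )
    if frac_missing:
        if policy == "strict":
            reasons.append("missing_species_level_fraction")
        # lenient: count rule alone decides
    elif not species_level_fraction > MIN_SPECIES_LEVEL_FRACTION:
        reasons.append("low_species_level")
    return (len(reasons) == 0, tuple(reasons))


def validate_samples(matrix: CountMatrix, sample_meta: pd.DataFrame,
                     policy: str = "strict") -> pd.DataFrame:
    """Vectorized :func:`validate_sample` over a count matrix.

    Every sample of the matrix must have exactly one metadata row.
    """
    meta = sample_meta.set_index("sample_id")
    missing = [s for s in matrix.sample_ids if s not in meta.index]
    if missing:
        raise SchemaError(f"samples without metadata: {missing[:5]}")
    totals = matrix.total_counts
    rows = []
    for sid in matrix.sample_ids:
        valid, reasons = validate_sample(
            int(totals.loc[sid]), meta.at[sid, "species_level_fraction"], policy=policy
        )
        rows.append((sid, valid, ";".join(reasons)))
    return pd.DataFrame(rows, columns=["sample_id", "valid", "reasons"])


# ---------------------------------------------------------------------------
# Index-model artifact
# ---------------------------------------------------------------------------

def _group_key(substrate: str, metatype: str) -> str:
    return f"{substrate}|{metatype}"


@dataclass(frozen=True)
class IndexModel:
    """Calibrated index artifact.

    Holds everything needed to score new data without re-running TITAN:
    the index-taxa list, per-variable alert-taxa sets with directions,
    community shift thresholds, per-group metric statistics (mean/sd per
    substrate x alkalinity metatype, plus substrate-pooled fallbacks keyed
    ``"<substrate>|*"``), normalization bounds, reference expectations and
    the selected metric variables.
    """

    index_taxa: tuple
    alert_taxa: dict          # variable -> ((taxon_code, direction), ...)
    community_thresholds: dict  # variable -> {"plus": float|None, "minus": float|None}
    group_stats: dict         # variable -> {group_key: (mean, sd)}
    norm_bounds: dict         # variable -> (min, max)
    reference_values: dict    # variable -> SESnor expected under reference
    selected_metrics: tuple
    provenance: dict = field(default_factory=dict)
    format_version: int = MODEL_FORMAT_VERSION

    def validate(self) -> None:
        index = set(self.index_taxa)
        for var, taxa in self.alert_taxa.items():
            for code, direction in taxa:
                if code not in index:
                    raise SchemaError(f"alert taxon {code!r} ({var}) not among index taxa")
                if direction not in ("plus", "minus"):
                    raise SchemaError(f"invalid direction {direction!r} for {code!r}")
        for var, stats in self.group_stats.items():
            for key, (mean, sd) in stats.items():
                if not sd > 0:
                    raise SchemaError(f"sd_group must be > 0 (variable {var}, group {key})")
        for var, (lo, hi) in self.norm_bounds.items():
            if not lo < hi:
                raise SchemaError(f"normalization bounds must satisfy Min < Max ({var})")
        for var, ref in self.reference_values.items():
            if not 0 < ref <= 1:
                raise SchemaError(f"reference value must lie in (0, 1] ({var})")
        for var in self.selected_metrics:
            if var not in self.norm_bounds:
                raise SchemaError(f"selected metric {var!r} has no normalization bounds")

    def to_dict(self) -> dict:
        return {
            "format_version": self.format_version,
            "index_taxa": list(self.index_taxa),
            "alert_taxa": {v: [list(t) for t in taxa] for v, taxa in self.alert_taxa.items()},
            "community_thresholds": self.community_thresholds,
            "group_stats": {
                v: {k: list(ms) for k, ms in stats.items()}
                for v, stats in self.group_stats.items()
            },
            "norm_bounds": {v: list(b) for v, b in self.norm_bounds.items()},
            "reference_values": dict(self.reference_values),
            "selected_metrics": list(self.selected_metrics),
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "IndexModel":
        version = data.get("format_version")
        if version != MODEL_FORMAT_VERSION:
            raise UnsupportedModelVersion(
                f"model format_version {version!r} is not supported (expected {MODEL_FORMAT_VERSION})"
            )
        return cls(
            index_taxa=tuple(data["index_taxa"]),
            alert_taxa={v: tuple((c, d) for c, d in taxa)
                        for v, taxa in data["alert_taxa"].items()},
            community_thresholds={v: dict(t) for v, t in data["community_thresholds"].items()},
            group_stats={v: {k: tuple(ms) for k, ms in stats.items()}
                         for v, stats in data["group_stats"].items()},
            norm_bounds={v: tuple(b) for v, b in data["norm_bounds"].items()},
            reference_values=dict(data["reference_values"]),
            selected_metrics=tuple(data["selected_metrics"]),
            provenance=data.get("provenance", {}),
            format_version=version,
        )


def write_model(model: IndexModel, path) -> None:
    """Serialize a validated model to JSON (refuses invalid models)."""
    model.validate()
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_model(path) -> IndexModel:
    with open(path) as fh:
        data = json.load(fh)
    model = IndexModel.from_dict(data)
    model.validate()
    return model
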