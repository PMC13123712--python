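"""Domain tables and their invariants.

All tabular data flows through four light wrappers around pandas
DataFrames: integer count tables (samples x taxa), closed compositions,
CLR-transformed coordinates, and tidy immune-cell density records.
Validation happens at construction so downstream stages can assume the
invariants hold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Taxonomic ranks carried by a taxonomy table, coarsest first.
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")

COHORTS = frozenset({"pediatric", "adult"})
TIMEPOINTS = frozenset({"pre", "post", "none"})
INDICATIONS = frozenset({"elective", "non_elective", "pathological_phimosis", "none"})
ASPECTS = frozenset({"inner", "outer"})
LAYERS = frozenset({"epidermis", "dermis"})
#: Immune-cell surface markers quantified by fluorescence/histology.
MARKERS = ("CD3", "CD4", "CD56", "CD11c", "CD207", "CD68", "CD117", "tryptase")

_MARKER_CANON = {m.lower(): m for m in MARKERS}

METADATA_COLUMNS = (
    "sample_id",
    "cohort",
    "subject_id",
    "timepoint",
    "indication",
    "age_years",
    "ethnicity",
    "dna_conc",
    "is_negative_control",
)


def _check_unique(values, what: str) -> None:
    s = pd.Index(values)
    if s.has_duplicates:
        dups = s[s.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dups}")


@dataclass
class CountTable:
    """Sample x taxon matrix of nonnegative integer read counts.

    ``data`` is indexed by sample id with taxon ids as columns.
    ``taxonomy``, when present, maps every taxon id to an ordered rank
    lineage (kingdom ... genus) and is indexed by taxon id.
    """

    data: pd.DataFrame
    taxonomy: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        self.data = self.data.rename_axis(index="sample_id", columns="taxon_id")
        _check_unique(self.data.index, "sample_id")
        _check_unique(self.data.columns, "taxon_id")
        arr = self.data.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.isfinite(arr)) or np.any(arr != np.round(arr)):
                raise ValidationError("counts must be integers")
            self.data = self.data.astype(np.int64)
            arr = self.data.to_numpy()
        if arr.size and arr.min() < 0:
            i, j = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative count at sample {self.data.index[i]!r}, "
                f"taxon {self.data.columns[j]!r}"
            )
        if self.taxonomy is not None:
            missing = self.data.columns.difference(self.taxonomy.index)
            if len(missing):
                raise ValidationError(
                    f"taxonomy missing for taxa: {missing.tolist()}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    def depths(self) -> pd.Series:
        """Per-sample total read count."""
        return self.data.sum(axis=1)


@dataclass
class CompositionTable:
    """Per-sample proportions; every row closes to 1.

    ``totals`` carries the original per-sample read totals so zero
    replacement can derive each sample's detection limit.
    """

    data: pd.DataFrame
    totals: pd.Series | None = None

    def __post_init__(self) -> None:
        arr = self.data.to_numpy(dtype=float)
        if arr.size:
            if arr.min() < 0 or arr.max() > 1 + 1e-12:
                raise ValidationError("proportions must lie in [0, 1]")
            sums = arr.sum(axis=1)
            if np.any(np.abs(sums - 1.0) > 1e-9):
                bad = self.data.index[np.argmax(np.abs(sums - 1.0))]
                raise ValidationError(f"row {bad!r} does not sum to 1")
        if self.totals is not None:
            self.totals = self.totals.reindex(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class ClrTable:
    """Centered-log-ratio coordinates; every row sums to 0."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.data.to_numpy(dtype=float)
        if arr.size and np.any(np.abs(arr.sum(axis=1)) > 1e-8):
            bad = self.data.index[np.argmax(np.abs(arr.sum(axis=1)))]
            raise ValidationError(f"CLR row {bad!r} does not sum to 0")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class CellDensityTable:
    """Tidy immune-cell densities: participant x aspect x layer x marker.

    Densities are in cells per mm^2 of tissue. At most one record per
    (participant, aspect, layer, marker) combination.
    """

    data: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        required = {"participant_id", "aspect", "layer", "marker", "density"}
        if self.data.empty and not required.issubset(self.data.columns):
            self.data = pd.DataFrame(columns=sorted(required))
            return
        missing = required - set(self.data.columns)
        if missing:
            raise ValidationError(f"density table missing columns: {sorted(missing)}")
        df = self.data.copy()
        df["aspect"] = df["aspect"].astype(str).str.lower()
        df["layer"] = df["layer"].astype(str).str.lower()
        df["marker"] = df["marker"].astype(str).map(
            lambda m: _MARKER_CANON.get(m.lower(), m)
        )
        for col, allowed in (("aspect", ASPECTS), ("layer", LAYERS)):
            bad = set(df[col]) - allowed
            if bad:
                raise ValidationError(f"unknown {col} value(s): {sorted(bad)}")
        bad = set(df["marker"]) - set(MARKERS)
        if bad:
            raise ValidationError(f"unknown marker(s): {sorted(bad)}")
        if (df["density"] < 0).any():
            raise ValidationError("densities must be nonnegative")
        key = ["participant_id", "aspect", "layer", "marker"]
        if df.duplicated(subset=key).any():
            dup = df[df.duplicated(subset=key)].iloc[0]
            raise ValidationError(
                "duplicate density record for "
                f"{tuple(dup[k] for k in key)}"
            )
        self.data = df


def validate_metadata(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a sample-metadata frame.

    Enum columns are lower-cased; ``dna_conc`` may be missing (NA).
    Returns a fresh, normalized copy.
    """
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"metadata missing required column(s): {missing}")
    out = df.copy()
    _check_unique(out["sample_id"], "sample_id")
    for col, allowed in (
        ("cohort", COHORTS),
        ("timepoint", TIMEPOINTS),
        ("indication", INDICATIONS),
    ):
        out[col] = out[col].astype(str).str.strip().str.lower()
        bad = set(out[col]) - allowed
        if bad:
            raise ValidationError(f"unknown {col} value(s): {sorted(bad)}")
    out["age_years"] = pd.to_numeric(out["age_years"], errors="raise")
    if (out["age_years"].dropna() < 0).any():
        raise ValidationError("age_years must be nonnegative")
    out["dna_conc"] = pd.to_numeric(out["dna_conc"], errors="coerce")
    if (out["dna_conc"].dropna() <= 0).any():
        raise ValidationError("dna_conc must be positive when present")
    if out["is_negative_control"].dtype != bool:
        out["is_negative_control"] = (
            out["is_negative_control"].astype(str).str.strip().str.lower()
            .map({"true": True, "false": False, "1": True, "0": False})
        )
        if out["is_negative_control"].isna().any():
            raise ValidationError("is_negative_control must be boolean")
    neg = out[out["is_negative_control"]]
    if (neg["indication"] != "none").any():
        raise ValidationError("negative controls must have indication 'none'")
    return out.reset_index(drop=True)
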