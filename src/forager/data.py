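"""Data model, CSV I/O and validation for foraging observations.

Four tables make up a dataset:

``individuals``
    one row per forager: ``individual_id``, ``sex`` (female/male),
    ``age`` in years, and possibly-missing trait measurements
    ``height_obs`` (cm) and ``grip_obs`` (kgf).
``shellfish``
    one row per person-trip: ``individual_id``, ``trip_id``,
    ``returns_kg`` (> 0 by construction: only the positive part of the
    hurdle is modelled), ``duration_min``, ``tide_height`` (m).
``traps``
    one row per snare: ``trap_id``, ``installer_id``,
    ``exposure_days``, ``captures`` (non-negative count).
``knowledge``
    long-format binary item responses: ``individual_id``, ``item_id``,
    ``component`` (question / image / freelist), ``response``.

Missing trait values are explicit (empty CSV field -> NaN) and are never
dropped: the foraging model treats them as latent parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

SEX_LEVELS = ("female", "male")
KNOWLEDGE_COMPONENTS = ("question", "image", "freelist")

INDIVIDUAL_COLUMNS = ["individual_id", "sex", "age", "height_obs", "grip_obs"]
SHELLFISH_COLUMNS = ["individual_id", "trip_id", "returns_kg", "duration_min", "tide_height"]
TRAP_COLUMNS = ["trap_id", "installer_id", "exposure_days", "captures"]
KNOWLEDGE_COLUMNS = ["individual_id", "item_id", "component", "response"]

FILE_NAMES = {
    "individuals": "individuals.csv",
    "shellfish": "shellfish_obs.csv",
    "traps": "traps.csv",
    "knowledge": "knowledge_responses.csv",
}


class SchemaError(ValueError):
    """Raised when a table violates the dataset schema.

    Carries every located violation, not just the first, so that
    ingestion is all-or-nothing.
    """

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__(
            "dataset validation failed with %d error(s):\n  %s"
            % (len(self.errors), "\n  ".join(self.errors))
        )


@dataclass
class ForagingDataset:
    """Container for the four entity tables of one study dataset."""

    individuals: pd.DataFrame
    shellfish: pd.DataFrame = field(default_factory=lambda: _empty("shellfish"))
    traps: pd.DataFrame = field(default_factory=lambda: _empty("traps"))
    knowledge: pd.DataFrame = field(default_factory=lambda: _empty("knowledge"))

    def validate(self) -> "ForagingDataset":
        validate_dataset(self)
        return self

    def copy(self) -> "ForagingDataset":
        return ForagingDataset(
            self.individuals.copy(),
            self.shellfish.copy(),
            self.traps.copy(),
            self.knowledge.copy(),
        )


def _empty(kind: str) -> pd.DataFrame:
    cols = {
        "individuals": INDIVIDUAL_COLUMNS,
        "shellfish": SHELLFISH_COLUMNS,
        "traps": TRAP_COLUMNS,
        "knowledge": KNOWLEDGE_COLUMNS,
    }[kind]
    return pd.DataFrame({c: pd.Series(dtype=object) for c in cols})


def _check_columns(df: pd.DataFrame, required: list[str], table: str, errors: list[str]) -> bool:
    missing = [c for c in required if c not in df.columns]
    if missing:
        errors.append(f"{table}: missing column(s) {missing}")
        return False
    return True


def _rows(mask: pd.Series) -> str:
    idx = list(np.flatnonzero(np.asarray(mask)))
    shown = ", ".join(str(i) for i in idx[:5])
    more = "" if len(idx) <= 5 else f" (+{len(idx) - 5} more)"
    return f"row(s) {shown}{more}"


def validate_individuals(df: pd.DataFrame, errors: list[str]) -> None:
    if not _check_columns(df, INDIVIDUAL_COLUMNS, "individuals", errors):
        return
    dup = df["individual_id"].duplicated()
    if dup.any():
        errors.append(f"individuals: duplicate individual_id at {_rows(dup)}")
    bad_sex = ~df["sex"].isin(SEX_LEVELS)
    if bad_sex.any():
        errors.append(
            f"individuals: sex must be one of {SEX_LEVELS} at {_rows(bad_sex)}"
        )
    age = pd.to_numeric(df["age"], errors="coerce")
    bad = age.isna() | (age <= 0)
    if bad.any():
        errors.append(f"individuals: age must be a positive real at {_rows(bad)}")
    for col in ("height_obs", "grip_obs"):
        v = pd.to_numeric(df[col], errors="coerce")
        bad = df[col].notna() & (v.isna() | (v <= 0))
        if bad.any():
            errors.append(f"individuals: {col} must be positive when present at {_rows(bad)}")


def validate_shellfish(df: pd.DataFrame, individual_ids: set, errors: list[str]) -> None:
    if not _check_columns(df, SHELLFISH_COLUMNS, "shellfish", errors):
        return
    r = pd.to_numeric(df["returns_kg"], errors="coerce")
    bad = r.isna() | (r <= 0)
    if bad.any():
        n = int(bad.sum())
        errors.append(
            f"shellfish: returns_kg must be strictly positive "
            f"({n} violating row(s): {_rows(bad)}); zero returns are out of model scope"
        )
    d = pd.to_numeric(df["duration_min"], errors="coerce")
    bad = d.isna() | (d <= 0)
    if bad.any():
        errors.append(f"shellfish: duration_min must be positive at {_rows(bad)}")
    t = pd.to_numeric(df["tide_height"], errors="coerce")
    if t.isna().any():
        errors.append(f"shellfish: tide_height must be numeric at {_rows(t.isna())}")
    unknown = ~df["individual_id"].isin(individual_ids)
    if unknown.any():
        errors.append(f"shellfish: unknown individual_id at {_rows(unknown)}")
    # trip-level covariates must be constant within a trip
    if len(df):
        per_trip = df.groupby("trip_id")[["duration_min", "tide_height"]].nunique()
        bad_trips = per_trip[(per_trip > 1).any(axis=1)].index.tolist()
        if bad_trips:
            errors.append(
                f"shellfish: duration_min/tide_height differ within trip_id(s) {bad_trips[:5]}"
            )


def validate_traps(df: pd.DataFrame, individual_ids: set, errors: list[str]) -> None:
    if not _check_columns(df, TRAP_COLUMNS, "traps", errors):
        return
    dup = df["trap_id"].duplicated()
    if dup.any():
        errors.append(f"traps: duplicate trap_id at {_rows(dup)}")
    e = pd.to_numeric(df["exposure_days"], errors="coerce")
    bad = e.isna() | (e <= 0)
    if bad.any():
        errors.append(f"traps: exposure_days must be positive at {_rows(bad)}")
    c = pd.to_numeric(df["captures"], errors="coerce")
    bad = c.isna() | (c < 0) | (c != np.floor(c.fillna(-1)))
    if bad.any():
        errors.append(f"traps: captures must be a non-negative integer at {_rows(bad)}")
    unknown = ~df["installer_id"].isin(individual_ids)
    if unknown.any():
        errors.append(f"traps: unknown installer_id at {_rows(unknown)}")


def validate_knowledge(df: pd.DataFrame, individual_ids: set, errors: list[str]) -> None:
    if not _check_columns(df, KNOWLEDGE_COLUMNS, "knowledge", errors):
        return
    dup = df.duplicated(subset=["individual_id", "item_id"])
    if dup.any():
        errors.append(
            f"knowledge: duplicate (individual_id, item_id) response at {_rows(dup)}"
        )
    bad = ~df["component"].isin(KNOWLEDGE_COMPONENTS)
    if bad.any():
        errors.append(
            f"knowledge: component must be one of {KNOWLEDGE_COMPONENTS} at {_rows(bad)}"
        )
    r = pd.to_numeric(df["response"], errors="coerce")
    bad = ~r.isin([0, 1])
    if bad.any():
        errors.append(f"knowledge: response must be binary 0/1 at {_rows(bad)}")
    unknown = ~df["individual_id"].isin(individual_ids)
    if unknown.any():
        errors.append(f"knowledge: unknown individual_id at {_rows(unknown)}")


def validate_dataset(dataset: ForagingDataset) -> None:
    """Check every schema invariant; raise :class:`SchemaError` listing all violations."""
    errors: list[str] = []
    validate_individuals(dataset.individuals, errors)
    ids = set(dataset.individuals.get("individual_id", pd.Series(dtype=object)))
    validate_shellfish(dataset.shellfish, ids, errors)
    validate_traps(dataset.traps, ids, errors)
    validate_knowledge(dataset.knowledge, ids, errors)
    if errors:
        raise SchemaError(errors)


_NUMERIC = {
    "individuals": ["age", "height_obs", "grip_obs"],
    "shellfish": ["returns_kg", "duration_min", "tide_height"],
    "traps": ["exposure_days", "captures"],
    "knowledge": ["response"],
}


def _coerce(df: pd.DataFrame, kind: str) -> pd.DataFrame:
    df = df.copy()
    for col in _NUMERIC[kind]:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    if kind == "traps" and "captures" in df.columns and len(df):
        df["captures"] = df["captures"].astype(np.int64)
    if kind == "knowledge" and "response" in df.columns and len(df):
        df["response"] = df["response"].astype(np.int64)
    return df


def read_dataset(
    directory: str | Path,
    mapping: Mapping[str, Mapping[str, str]] | None = None,
    validate: bool = True,
) -> ForagingDataset:
    """Read the four CSV files from ``directory`` into a validated dataset.

    Parameters
    ----------
    directory:
        Folder holding ``individuals.csv``, ``shellfish_obs.csv``,
        ``traps.csv`` and ``knowledge_responses.csv``.  The two latter
        files are optional (empty tables are substituted).
    mapping:
        Optional per-table column-name map, ``{table: {source: canonical}}``,
        so externally deposited files with different headers can be
        loaded without editing them.
    validate:
        Run full schema validation after reading (default).
    """
    directory = Path(directory)
    tables = {}
    for kind, fname in FILE_NAMES.items():
        path = directory / fname
        if not path.exists():
            if kind == "individuals":
                raise FileNotFoundError(f"required file missing: {path}")
            tables[kind] = _empty(kind)
            continue
        df = pd.read_csv(path)
        if mapping and kind in mapping:
            df = df.rename(columns=dict(mapping[kind]))
        tables[kind] = _coerce(df, kind)
    ds = ForagingDataset(
        individuals=tables["individuals"],
        shellfish=tables["shellfish"],
        traps=tables["traps"],
        knowledge=tables["knowledge"],
    )
    if validate:
        validate_dataset(ds)
    return ds


def write_dataset(dataset: ForagingDataset, directory: str | Path) -> None:
    """Write the four tables as UTF-8 CSV with empty fields for missing values."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for kind, fname in FILE_NAMES.items():
        getattr(dataset, kind).to_csv(directory / fname, index=False)


def summarize_dataset(dataset: ForagingDataset) -> dict:
    """Participant / trip / outcome counts, age ranges and trait missingness."""
    ind = dataset.individuals
    sf = dataset.shellfish
    tr = dataset.traps
    kn = dataset.knowledge

    def _age_stats(ids):
        ages = ind.loc[ind["individual_id"].isin(ids), "age"] if len(ind) else pd.Series(dtype=float)
        if not len(ages):
            return {"mean_age": float("nan"), "min_age": float("nan"), "max_age": float("nan")}
        return {
            "mean_age": float(ages.mean()),
            "min_age": float(ages.min()),
            "max_age": float(ages.max()),
        }

    with_knowledge = set(kn["individual_id"]) if len(kn) else set()
    n_ind = len(ind)
    summary = {
        "n_individuals": n_ind,
        "shellfish": {
            "n_participants": int(sf["individual_id"].nunique()) if len(sf) else 0,
            "n_trips": int(sf["trip_id"].nunique()) if len(sf) else 0,
            "n_outcomes": int(len(sf)),
            **_age_stats(set(sf["individual_id"]) if len(sf) else set()),
        },
        "traps": {
            "n_participants": int(tr["installer_id"].nunique()) if len(tr) else 0,
            # the generator records which foraging trip installed each trap
            "n_trips": int(tr["trip_id"].nunique()) if "trip_id" in tr.columns and len(tr) else 0,
            "n_outcomes": int(len(tr)),
            "n_successes": int((tr["captures"] > 0).sum()) if len(tr) else 0,
            **_age_stats(set(tr["installer_id"]) if len(tr) else set()),
        },
        "missingness": {
            "height": float(ind["height_obs"].isna().mean()) if n_ind else 0.0,
            "grip": float(ind["grip_obs"].isna().mean()) if n_ind else 0.0,
            "knowledge": (
                float(np.mean([i not in with_knowledge for i in ind["individual_id"]]))
                if n_ind
                else 0.0
            ),
        },
    }
    return summary
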