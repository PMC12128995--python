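"""Readers/writers and cohort-selection rules.

Expression matrices are tab-separated text (probe sets in rows, samples in
columns, log2 intensities); biopsy metadata is CSV with an explicit schema
(empty string = missing, no numeric sentinels); gene sets use the GMT dialect
(name, description, then member probe-set ids, tab-separated).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Documented metadata schema. ``sample_id`` is the index on load.
METADATA_COLUMNS = [
    "sample_id",
    "kidney_id",
    "txbx_days",
    "egfr",
    "donor_age",
    "proteinuria_pos",
    "ci_score",
    "ct_score",
    "pct_cortex",
    "rejection_group",
    "followup_days",
    "graft_failed",
    "died_with_function",
]

#: Epoch conventions used throughout: early biopsies are taken within six
#: weeks of transplantation, late biopsies after the first year.
EARLY_TXBX_DAYS = 42.0
LATE_TXBX_DAYS = 365.0


class CohortValidationError(ValueError):
    """Raised when inputs would silently corrupt downstream analyses."""


@dataclass
class ExpressionMatrix:
    """Log2 expression values, probe sets x samples, plus control designation.

    Parameters
    ----------
    values : pandas.DataFrame
        Probe sets in rows, samples in columns, finite log2 intensities.
    control_ids : list of str
        Samples that form the control baseline (e.g. nephrectomy samples);
        must be a subset of the matrix columns.
    """

    values: pd.DataFrame
    control_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise CohortValidationError(f"duplicate probe ids: {dups[:5]}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].tolist()
            raise CohortValidationError(f"duplicate sample ids: {dups[:5]}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            bad = _first_non_numeric(self.values)
            raise CohortValidationError(f"non-numeric expression value at {bad}")
        if not np.isfinite(arr).all():
            i, j = np.argwhere(~np.isfinite(arr))[0]
            raise CohortValidationError(
                "non-finite expression value at probe "
                f"{self.values.index[i]!r}, sample {self.values.columns[j]!r}"
            )
        missing = set(self.control_ids) - set(self.values.columns)
        if missing:
            raise CohortValidationError(f"control ids not in matrix: {sorted(missing)}")
        self.control_ids = list(self.control_ids)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def biopsy_ids(self) -> list[str]:
        """Sample ids that are not controls, in matrix order."""
        ctrl = set(self.control_ids)
        return [s for s in self.values.columns if s not in ctrl]


@dataclass
class SampleMetadata:
    """Per-biopsy clinical metadata with one row per biopsy.

    Wraps a DataFrame indexed by ``sample_id``; missing values stay missing
    (NaN) rather than being imputed at load time.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        if self.df.index.duplicated().any():
            dups = self.df.index[self.df.index.duplicated()].tolist()
            raise CohortValidationError(f"duplicate biopsy ids in metadata: {dups[:5]}")
        if "followup_days" in self.df.columns:
            fup = pd.to_numeric(self.df["followup_days"], errors="coerce")
            if (fup.dropna() < 0).any():
                raise CohortValidationError("negative followup_days")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.index)

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class GeneSetCollection:
    """Named probe-set lists with a role tag per set.

    ``tags`` maps each set name to one of ``"input-PBT"``, ``"new-gene-set"``
    or ``"other"``; sets without an explicit tag default to ``"other"``.
    """

    sets: dict[str, list[str]]
    tags: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise CohortValidationError(f"gene set {name!r} is empty")
        for name in self.sets:
            self.tags.setdefault(name, "other")

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def names(self, tag: str | None = None) -> list[str]:
        if tag is None:
            return list(self.sets)
        return [n for n in self.sets if self.tags.get(n) == tag]


def _first_non_numeric(df: pd.DataFrame) -> str:
    for j, col in enumerate(df.columns):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            i = np.argmax(bad.to_numpy())
            return f"probe {df.index[i]!r}, sample {col!r}"
    return "unknown position"


# ---------------------------------------------------------------------------
# GMT

def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: one set per line, ``name<TAB>description<TAB>ids...``.

    Member order is preserved; duplicate members within a set are removed with
    a warning. An empty set or a repeated set name is an error.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise CohortValidationError(
                    f"{path}:{lineno}: gene set {parts[0]!r} has no members"
                )
            name = parts[0]
            if name in sets:
                raise CohortValidationError(f"duplicate gene set name {name!r}")
            members, seen = [], set()
            for m in parts[2:]:
                if not m:
                    continue
                if m in seen:
                    continue
                seen.add(m)
                members.append(m)
            if len(members) < len(parts[2:]) - parts[2:].count(""):
                warnings.warn(f"gene set {name!r}: duplicate members removed")
            if not members:
                raise CohortValidationError(f"gene set {name!r} is empty")
            sets[name] = members
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.tags.get(name, "other")
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# Expression / metadata tables

def read_expression(path, control_ids: list[str] | None = None) -> ExpressionMatrix:
    """Read a TSV expression matrix (probes x samples, header of sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    # validate cell-level numerics before casting, for a coordinate-bearing error
    non_num = df.select_dtypes(exclude="number")
    if len(non_num.columns):
        raise CohortValidationError(
            f"non-numeric expression value at {_first_non_numeric(df)}"
        )
    return ExpressionMatrix(df.astype(float), control_ids=control_ids or [])


def write_expression(expr: ExpressionMatrix, path) -> None:
    expr.values.to_csv(path, sep="\t")


def read_metadata(path) -> SampleMetadata:
    """Read the biopsy metadata CSV; empty strings load as missing values."""
    df = pd.read_csv(path, index_col="sample_id")
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.df.to_csv(path, index_label="sample_id")


def load_cohort(expr_path, meta_path, control_ids: list[str] | None = None):
    """Load expression + metadata together, cross-validating sample ids.

    Every non-control sample in the expression matrix must appear in the
    metadata; otherwise an error lists the offending ids.
    """
    expr = read_expression(expr_path, control_ids=control_ids)
    meta = read_metadata(meta_path)
    validate_ids(expr, meta)
    return expr, meta


def validate_ids(expr: ExpressionMatrix, meta: SampleMetadata) -> None:
    missing = [s for s in expr.biopsy_ids if s not in set(meta.sample_ids)]
    if missing:
        raise CohortValidationError(
            f"{len(missing)} expression samples absent from metadata: {missing[:10]}"
        )


# ---------------------------------------------------------------------------
# Cohort selection rules

def filter_cortex(
    meta: SampleMetadata,
    threshold: float = 10.0,
    missing: str = "keep",
) -> SampleMetadata:
    """Retain biopsies with strictly more than ``threshold`` percent cortex.

    Samples that are mostly medulla give less reliable injury readings, hence
    the cortex-content gate. ``missing`` controls biopsies with no recorded
    %cortex: ``"keep"`` (default, with a warning) or ``"drop"``.
    """
    if "pct_cortex" not in meta.df.columns:
        raise CohortValidationError("metadata lacks pct_cortex")
    if missing not in ("keep", "drop"):
        raise ValueError("missing must be 'keep' or 'drop'")
    cortex = pd.to_numeric(meta.df["pct_cortex"], errors="coerce")
    keep = cortex > threshold
    n_missing = int(cortex.isna().sum())
    if n_missing and missing == "keep":
        warnings.warn(f"{n_missing} biopsies lack pct_cortex; kept")
        keep = keep | cortex.isna()
    n_dropped = int((~keep).sum())
    logger.info(
        "cortex filter (> %.3g%%): kept %d, dropped %d",
        threshold, int(keep.sum()), n_dropped,
    )
    return SampleMetadata(meta.df.loc[keep].copy())


def one_biopsy_per_kidney(meta: SampleMetadata, seed: int) -> SampleMetadata:
    """Select one biopsy per kidney uniformly at random (seed-deterministic).

    Only biopsies with recorded follow-up are eligible; kidneys with no
    eligible biopsy are dropped with a log entry. Used to avoid correlated
    repeat biopsies in survival analyses.
    """
    df = meta.df
    if "kidney_id" not in df.columns:
        raise CohortValidationError("metadata lacks kidney_id")
    eligible = df[pd.to_numeric(df.get("followup_days"), errors="coerce").notna()]
    n_dropped_kidneys = df["kidney_id"].nunique() - eligible["kidney_id"].nunique()
    if n_dropped_kidneys:
        logger.info("dropped %d kidneys with no follow-up data", n_dropped_kidneys)
    rng = np.random.default_rng(seed)
    chosen = []
    # iterate kidneys in sorted order so the draw sequence is reproducible
    for kidney in sorted(eligible["kidney_id"].astype(str).unique()):
        rows = eligible.index[eligible["kidney_id"].astype(str) == kidney]
        chosen.append(rows[rng.integers(len(rows))])
    return SampleMetadata(df.loc[chosen].copy())
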