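"""Cohort tables and preprocessing.

A cohort is a flat subject-visit table carrying a diagnostic group label,
demographic covariates (age, sex, education), a block of cognitive test
scores and a block of atlas-based regional brain measures (e.g. deformation
based morphometry values summarised over an anatomical parcellation).
This module owns reading/writing those tables and the normalisation steps
that precede the latent-variable analysis: group-mean imputation,
complete-case filtering, column z-scoring (optionally against reference
statistics, e.g. baseline statistics applied to follow-up visits) and
control-referenced w-scores.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CohortTable",
    "StandardizationStats",
    "ExclusionReport",
    "SchemaError",
    "read_cohort",
    "write_cohort",
    "impute_group_mean",
    "complete_case_filter",
    "zscore_columns",
    "inverse_zscore",
    "wscore_adjust",
    "select_followup_closest_to",
]

#: canonical metadata columns, in output order
META_COLS = ["subject_id", "visit", "years_since_baseline", "group", "site",
             "age", "sex", "education"]

VISITS = ("baseline", "followup")


class SchemaError(ValueError):
    """Raised when a cohort file or table violates its declared schema."""


@dataclass
class CohortTable:
    """Subject-visit table with declared cognition / brain column roles.

    Parameters
    ----------
    data:
        One row per subject-visit.  Must contain the metadata columns
        (``subject_id``, ``visit``, ``years_since_baseline``, ``group``,
        ``age``, ``sex``, ``education``; ``site`` optional) plus the named
        cognition and brain columns.
    cognition_cols, brain_cols:
        Names of the columns forming the cognition block (X) and the brain
        block (Y).
    """

    data: pd.DataFrame
    cognition_cols: list[str]
    brain_cols: list[str]
    covariate_cols: list[str] = field(default_factory=lambda: ["age", "sex", "education"])

    def __post_init__(self) -> None:
        self.cognition_cols = list(self.cognition_cols)
        self.brain_cols = list(self.brain_cols)
        self.covariate_cols = list(self.covariate_cols)
        self.validate()

    # -- structural invariants -------------------------------------------------
    def validate(self) -> None:
        df = self.data
        missing = [c for c in ("subject_id", "visit", "years_since_baseline", "group")
                   if c not in df.columns]
        missing += [c for c in self.cognition_cols + self.brain_cols + self.covariate_cols
                    if c not in df.columns]
        if missing:
            raise SchemaError(f"missing mandatory columns: {missing}")
        bad_visit = set(df["visit"].unique()) - set(VISITS)
        if bad_visit:
            raise SchemaError(f"unknown visit labels: {sorted(bad_visit)}")
        # baseline is unique per subject; several follow-up visits may coexist
        # if their timings differ (a selection rule later picks one)
        dup = df.duplicated(subset=["subject_id", "visit", "years_since_baseline"],
                            keep=False)
        if dup.any():
            pairs = df.loc[dup, ["subject_id", "visit"]].drop_duplicates()
            raise SchemaError(
                "duplicated (subject, visit) pairs: "
                + ", ".join(f"({r.subject_id}, {r.visit})" for r in pairs.itertuples())
            )
        base = set(df.loc[df["visit"] == "baseline", "subject_id"])
        orphans = set(df.loc[df["visit"] == "followup", "subject_id"]) - base
        if orphans:
            raise SchemaError(f"followup rows without a baseline row: {sorted(orphans)[:5]}")
        ysb = df["years_since_baseline"].to_numpy(dtype=float)
        at_base = (df["visit"] == "baseline").to_numpy()
        if np.any(ysb[at_base] != 0):
            raise SchemaError("baseline rows must have years_since_baseline == 0")
        if np.any(ysb[~at_base] <= 0):
            raise SchemaError("followup rows must have years_since_baseline > 0")

    # -- convenience accessors -------------------------------------------------
    @property
    def schema(self) -> dict:
        return {"cognition": list(self.cognition_cols), "brain": list(self.brain_cols),
                "covariates": list(self.covariate_cols)}

    def baseline(self) -> "CohortTable":
        return self._subset(self.data["visit"] == "baseline")

    def followup(self) -> "CohortTable":
        df = self.data
        fu = df[df["visit"] == "followup"]
        keep = df["subject_id"].isin(fu["subject_id"])
        return self._subset(keep)

    def patients(self) -> "CohortTable":
        return self._subset(self.data["group"] != "control")

    def controls(self) -> "CohortTable":
        return self._subset(self.data["group"] == "control")

    def _subset(self, mask) -> "CohortTable":
        return CohortTable(self.data[mask].reset_index(drop=True),
                           self.cognition_cols, self.brain_cols, self.covariate_cols)

    def cognition(self) -> pd.DataFrame:
        return self.data[self.cognition_cols].astype(float)

    def brain(self) -> pd.DataFrame:
        return self.data[self.brain_cols].astype(float)

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.data)


@dataclass
class StandardizationStats:
    """Per-column mean/SD with the population they were estimated on.

    ``reference`` is one of ``self`` (estimated from the block itself),
    ``baseline`` (baseline visits, applied to follow-up data) or
    ``control`` (control group).  SDs use the unbiased (n-1) estimator.
    """

    mean: pd.Series
    sd: pd.Series
    reference: str = "self"

    def __post_init__(self) -> None:
        if (self.sd <= 0).any():
            bad = list(self.sd.index[self.sd <= 0])
            raise ValueError(f"non-positive SD for columns: {bad}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.mean, "sd": self.sd})


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def write_cohort(cohort: CohortTable, path: str | Path, with_schema: bool = False) -> Path:
    """Write a cohort to CSV or TSV (chosen from the file extension).

    With ``with_schema`` a ``<path>.schema.json`` sidecar records the column
    roles so the table can be read back without a run config.
    """
    path = Path(path)
    meta = [c for c in META_COLS if c in cohort.data.columns]
    cols = meta + cohort.cognition_cols + cohort.brain_cols
    cohort.data[cols].to_csv(path, sep=_sep_for(path), index=False)
    if with_schema:
        Path(str(path) + ".schema.json").write_text(json.dumps(cohort.schema, indent=1))
    return path


def read_cohort(path: str | Path, schema: Mapping[str, Sequence[str]] | None = None) -> CohortTable:
    """Read a CSV/TSV cohort file against a declared column-role schema.

    ``schema`` maps ``cognition`` / ``brain`` (and optionally ``covariates``)
    to column-name lists; if omitted, a ``<path>.schema.json`` sidecar is
    required.  Raises :class:`SchemaError` listing offending columns when the
    header or cell types do not match.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if schema is None:
        sidecar = Path(str(path) + ".schema.json")
        if not sidecar.exists():
            raise SchemaError(f"no schema given and no sidecar at {sidecar}")
        schema = json.loads(sidecar.read_text())
    df = pd.read_csv(path, sep=_sep_for(path))
    numeric = list(schema["cognition"]) + list(schema["brain"]) + [
        "years_since_baseline", "age", "education"]
    offenders = []
    for col in numeric:
        if col not in df.columns:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        newly_bad = coerced.isna() & df[col].notna()
        if newly_bad.any():
            offenders.append(col)
        df[col] = coerced
    if offenders:
        raise SchemaError(f"non-numeric cells in numeric columns: {offenders}")
    return CohortTable(df, list(schema["cognition"]), list(schema["brain"]),
                       list(schema.get("covariates", ["age", "sex", "education"])))


# ---------------------------------------------------------------------------
# Missing data
# ---------------------------------------------------------------------------

def impute_group_mean(cohort: CohortTable, columns: Iterable[str] = ("education",)) -> CohortTable:
    """Fill missing values with the mean of the row's diagnostic group.

    Only the named columns are touched (education by default, matching its
    role as a covariate rather than an outcome).  A group with no observed
    value in a named column is an error: there is no within-group mean to
    impute from.
    """
    df = cohort.data.copy()
    for col in columns:
        if col not in df.columns:
            raise KeyError(f"no such column: {col}")
        vals = pd.to_numeric(df[col], errors="raise")
        means = vals.groupby(df["group"]).transform("mean")
        empty = vals.isna().groupby(df["group"]).all()
        if empty.any():
            raise ValueError(
                f"group(s) {list(empty.index[empty])} have no observed values in '{col}'")
        df[col] = vals.fillna(means)
    return replace(cohort, data=df)


@dataclass
class ExclusionReport:
    """Bookkeeping for complete-case filtering."""

    n_input: int
    n_retained: int
    removed_per_group: dict[str, int]
    removed_per_column: dict[str, int]
    orphaned_followups: int = 0

    @property
    def n_removed(self) -> int:
        return self.n_input - self.n_retained


def complete_case_filter(cohort: CohortTable,
                         required_columns: Sequence[str]) -> tuple[CohortTable, ExclusionReport]:
    """Drop rows missing any required value; report exclusions per group/column.

    Follow-up rows whose baseline row was excluded are dropped too (the
    baseline-linkage invariant), counted under ``orphaned_followups``.
    """
    df = cohort.data
    for col in required_columns:
        if col not in df.columns:
            raise KeyError(f"required column not present: {col}")
    miss = df[list(required_columns)].isna()
    drop = miss.any(axis=1)
    kept = df[~drop]
    # re-establish followup -> baseline linkage
    base_ids = set(kept.loc[kept["visit"] == "baseline", "subject_id"])
    orphan = (kept["visit"] == "followup") & ~kept["subject_id"].isin(base_ids)
    result = kept[~orphan].reset_index(drop=True)
    if len(result) == 0:
        raise ValueError("complete-case filtering removed every row; "
                         "relax the required-column schema")
    report = ExclusionReport(
        n_input=len(df),
        n_retained=len(result),
        removed_per_group=df.loc[drop, "group"].value_counts().to_dict(),
        removed_per_column={c: int(miss[c].sum()) for c in required_columns if miss[c].any()},
        orphaned_followups=int(orphan.sum()),
    )
    return replace(cohort, data=result), report


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------

def zscore_columns(block: pd.DataFrame,
                   stats: StandardizationStats | None = None,
                   ) -> tuple[pd.DataFrame, StandardizationStats]:
    """Z-score each column; optionally against supplied reference statistics.

    In self mode (``stats is None``) means/SDs are estimated from ``block``
    itself (SD with divisor n-1) and each output column has mean 0, SD 1.
    Supplying ``stats`` applies those means/SDs instead — the
    baseline-referenced mode used to place follow-up visits on the baseline
    scale.
    """
    if stats is None:
        mean = block.mean()
        sd = block.std(ddof=1)
        zero = sd[~(sd > 0)]
        if len(zero):
            raise ValueError(f"zero-SD column(s) in self mode: {list(zero.index)}")
        stats = StandardizationStats(mean=mean, sd=sd, reference="self")
    else:
        missing = [c for c in block.columns if c not in stats.mean.index]
        if missing:
            raise KeyError(f"columns absent from supplied stats: {missing}")
    z = (block - stats.mean[block.columns]) / stats.sd[block.columns]
    return z, stats


def inverse_zscore(z: pd.DataFrame, stats: StandardizationStats) -> pd.DataFrame:
    return z * stats.sd[z.columns] + stats.mean[z.columns]


# ---------------------------------------------------------------------------
# w-scores
# ---------------------------------------------------------------------------

def _encode_sex(s: pd.Series) -> pd.Series:
    if s.dtype == object:
        mapping = {"F": 0.0, "M": 1.0}
        bad = set(s.dropna().unique()) - set(mapping)
        if bad:
            raise ValueError(f"unrecognised sex codes: {sorted(bad)}")
        return s.map(mapping)
    return s.astype(float)


def wscore_adjust(patients: pd.DataFrame,
                  controls: pd.DataFrame,
                  variables: Sequence[str],
                  covariates: Sequence[str] = ("age", "sex", "education"),
                  ) -> pd.DataFrame:
    """Demographically adjusted w-scores referenced to the control group.

    For every variable an ordinary least-squares model with intercept plus
    the covariates is fitted on controls; a patient's w-score is the residual
    from the control-based prediction divided by the control residual
    standard error (divisor n_controls - p - 1).  A w-score is a
    covariate-adjusted z-score: controls score ~N(0, 1) by construction.
    """
    for df, who in ((controls, "controls"), (patients, "patients")):
        missing = [c for c in list(variables) + list(covariates) if c not in df.columns]
        if missing:
            raise KeyError(f"{who} lack columns: {missing}")
    if controls[list(variables) + list(covariates)].isna().any().any():
        raise ValueError("controls must be complete-case on variables and covariates")
    p = len(covariates)
    if len(controls) < p + 2:
        raise ValueError(f"need at least {p + 2} controls for {p} covariates")

    def design(df: pd.DataFrame) -> np.ndarray:
        cols = [np.ones(len(df))]
        for c in covariates:
            cols.append(_encode_sex(df[c]).to_numpy() if c == "sex"
                        else df[c].to_numpy(dtype=float))
        return np.column_stack(cols)

    Xc = design(controls)
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        raise ValueError("rank-deficient covariate design in controls")
    Yc = controls[list(variables)].to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
    resid = Yc - Xc @ beta
    dof = len(controls) - p - 1
    resid_sd = np.sqrt((resid ** 2).sum(axis=0) / dof)
    tol = 1e-12 * (1.0 + np.abs(Yc).max(axis=0))
    zero = np.asarray(variables)[resid_sd <= tol]
    if len(zero):
        raise ValueError(f"zero control residual SD for: {list(zero)}")
    Xp = design(patients)
    W = (patients[list(variables)].to_numpy(dtype=float) - Xp @ beta) / resid_sd
    return pd.DataFrame(W, columns=list(variables), index=patients.index)


# ---------------------------------------------------------------------------
# Visit selection
# ---------------------------------------------------------------------------

def select_followup_closest_to(cohort: CohortTable, target_years: float = 1.0) -> CohortTable:
    """Keep, per subject, the follow-up visit closest to ``target_years``.

    Baseline rows are always retained; among multiple follow-up rows of one
    subject the one minimising |years_since_baseline - target| survives.
    """
    df = cohort.data
    fu = df[df["visit"] == "followup"].copy()
    if fu.empty:
        return cohort
    fu["_dist"] = (fu["years_since_baseline"] - target_years).abs()
    keep_idx = fu.sort_values(["_dist", "years_since_baseline"]).groupby("subject_id").head(1).index
    mask = (df["visit"] == "baseline") | df.index.isin(keep_idx)
    return replace(cohort, data=df[mask].reset_index(drop=True))
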