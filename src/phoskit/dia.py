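"""DIA time-course differential analysis.

The label-free arm of the study: protein quantities over meiotic stages
in two conditions, two biological and three technical replicates each.
Precursor-level report rows are q-value filtered (PSM-level q <= 0.001
and protein-group q <= 0.05), quantities are log10-transformed, technical
replicates averaged within each (condition, stage, biological replicate)
unit so the model's observations are biological replicates, and missing
cells are conservatively imputed by the minimum observed replicate
intensity within the protein's (condition, stage) group (protein-wide
minimum as fallback), carrying a down-weight of 0.05 against weight 1 for
observed cells.  Per-stage treatment-vs-control contrasts reuse the
weighted moderated-t machinery; a protein is called reliably changed iff
adjusted p <= 0.05 and |log2 fold change| >= 0.5, where the fitted log10
difference is converted to log2 units.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import diffstats
from .errors import ConfigError, ConsistencyError
from .ingest import Design

logger = logging.getLogger(__name__)

LOG2_PER_LOG10 = math.log2(10.0)

IMPUTED_WEIGHT = 0.05


# ---------------------------------------------------------------------------
# report filtering


DIA_REPORT_COLUMNS = ["run_id", "protein_group_id", "precursor_id", "psm_q", "pg_q", "quantity"]


def read_dia_report(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in DIA_REPORT_COLUMNS if c not in df.columns]
    if missing:
        raise ConsistencyError(f"DIA report lacks column(s): {missing}")
    return df


def filter_dia(
    rows: pd.DataFrame, psm_q_max: float = 0.001, pg_q_max: float = 0.05
) -> tuple[pd.DataFrame, dict]:
    """Keep rows with psm_q <= psm_q_max and pg_q <= pg_q_max (both
    inclusive).  Returns (retained rows, report dict)."""
    for name, v in (("psm_q_max", psm_q_max), ("pg_q_max", pg_q_max)):
        if not 0.0 < v <= 1.0:
            raise ConfigError(f"{name} must lie in (0, 1], got {v}")
    ok = (rows["psm_q"] <= psm_q_max) & (rows["pg_q"] <= pg_q_max)
    report = {
        "n_input": int(len(rows)),
        "n_retained": int(ok.sum()),
        "n_removed": int((~ok).sum()),
    }
    return rows[ok].reset_index(drop=True), report


# ---------------------------------------------------------------------------
# design and matrix


@dataclass
class TimeCourseDesign:
    """Run-level design: run -> (condition, stage, bio, tech)."""

    table: pd.DataFrame  # run_id, condition, stage, bio_replicate, tech_replicate

    def __post_init__(self) -> None:
        needed = {"run_id", "condition", "stage", "bio_replicate", "tech_replicate"}
        missing = needed - set(self.table.columns)
        if missing:
            raise ConfigError(f"time-course design lacks column(s): {sorted(missing)}")
        counts = self.table.groupby(["condition", "stage", "bio_replicate"]).size()
        if (counts < 1).any():
            raise ConfigError("each (condition, stage, bio) unit needs >= 1 technical replicate")

    @property
    def stages(self) -> list[str]:
        return list(dict.fromkeys(self.table["stage"]))

    def units(self) -> pd.DataFrame:
        """Biological units: one row per (condition, stage, bio)."""
        u = self.table[["condition", "stage", "bio_replicate"]].drop_duplicates()
        u = u.reset_index(drop=True)
        u["unit_id"] = [
            f"{c[:3]}_{s}_b{b}" for c, s, b in zip(u["condition"], u["stage"], u["bio_replicate"])
        ]
        return u

    @classmethod
    def read(cls, path) -> "TimeCourseDesign":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass
class ProteinQuantMatrix:
    """Log10 protein quantities per biological unit, with weights.

    ``values`` holds log10 intensities with NaN for missing cells before
    imputation; after ``impute_and_weight`` the matrix is complete and
    ``weights`` is 1 for observed units and 0.05 for imputed ones, with
    the imputed mask retained.
    """

    values: pd.DataFrame  # proteins x unit_id
    weights: pd.DataFrame
    imputed: pd.DataFrame  # boolean mask
    units: pd.DataFrame  # unit_id, condition, stage, bio_replicate

    def centered(self) -> pd.DataFrame:
        """Per-protein centering (subtract the row mean over non-missing
        cells), the heatmap display convention."""
        X = self.values.to_numpy(dtype=float)
        return pd.DataFrame(
            X - np.nanmean(X, axis=1, keepdims=True),
            index=self.values.index,
            columns=self.values.columns,
        )


def build_matrix(
    quantities: pd.DataFrame,
    design: TimeCourseDesign,
    from_report: bool = False,
) -> ProteinQuantMatrix:
    """Log10-transform and average technical replicates into biological units.

    ``quantities`` is either a proteins x runs matrix of linear-scale
    quantities (NaN/0 = missing) or, with ``from_report=True``, filtered
    DIA report rows whose per-run protein quantity is taken as the median
    over precursors.  Every data run must appear in the design.
    """
    if from_report:
        mat = (
            quantities.groupby(["protein_group_id", "run_id"])["quantity"]
            .median()
            .unstack("run_id")
        )
    else:
        mat = quantities
    known = set(design.table["run_id"])
    unknown = [r for r in mat.columns if r not in known]
    if unknown:
        raise ConfigError(f"run(s) absent from design: {unknown}")

    X = mat.to_numpy(dtype=float)
    X = np.where(np.isfinite(X) & (X > 0), X, np.nan)
    log10 = np.log10(X, where=np.isfinite(X), out=np.full_like(X, np.nan))
    logmat = pd.DataFrame(log10, index=mat.index, columns=mat.columns)

    units = design.units()
    run_to_unit = {}
    for _, row in design.table.iterrows():
        key = (row["condition"], row["stage"], row["bio_replicate"])
        unit_id = units.loc[
            (units["condition"] == key[0])
            & (units["stage"] == key[1])
            & (units["bio_replicate"] == key[2]),
            "unit_id",
        ].iloc[0]
        run_to_unit[row["run_id"]] = unit_id
    grouped = logmat.T.groupby([run_to_unit[r] for r in logmat.columns]).mean().T
    grouped = grouped[units["unit_id"].tolist()]  # deterministic unit order

    weights = pd.DataFrame(
        np.where(np.isfinite(grouped.to_numpy()), 1.0, 0.0),
        index=grouped.index,
        columns=grouped.columns,
    )
    imputed = pd.DataFrame(False, index=grouped.index, columns=grouped.columns)
    return ProteinQuantMatrix(grouped, weights, imputed, units)


def impute_and_weight(matrix: ProteinQuantMatrix) -> ProteinQuantMatrix:
    """Min-replicate imputation with 0.05 down-weighting.

    Each missing cell takes the minimum observed value among the protein's
    replicates within the same (condition, stage) group; if the group has
    no observation, the protein-wide minimum.  Imputed cells get weight
    0.05; observed cells keep weight 1 and are never altered.  Proteins
    observed nowhere are dropped and reported.
    """
    X = matrix.values.to_numpy(dtype=float).copy()
    observed = np.isfinite(X)
    any_obs = observed.any(axis=1)
    n_dropped = int((~any_obs).sum())
    if n_dropped:
        logger.info("%d proteins with no observation dropped", n_dropped)
    X = X[any_obs]
    observed = observed[any_obs]
    index = matrix.values.index[any_obs]
    units = matrix.units

    group_cols: dict[tuple, list[int]] = {}
    for j, uid in enumerate(matrix.values.columns):
        row = units.loc[units["unit_id"] == uid].iloc[0]
        group_cols.setdefault((row["condition"], row["stage"]), []).append(j)

    with np.errstate(invalid="ignore"):
        protein_min = np.nanmin(np.where(observed, X, np.nan), axis=1)
    filled = X.copy()
    for cols in group_cols.values():
        sub = np.where(observed[:, cols], X[:, cols], np.inf)
        gmin = sub.min(axis=1)  # +inf marks a group with no observation
        gmin = np.where(np.isfinite(gmin), gmin, protein_min)
        for j in cols:
            miss = ~observed[:, j]
            filled[miss, j] = gmin[miss]

    values = pd.DataFrame(filled, index=index, columns=matrix.values.columns)
    weights = pd.DataFrame(
        np.where(observed, 1.0, IMPUTED_WEIGHT), index=index, columns=matrix.values.columns
    )
    imputed = pd.DataFrame(~observed, index=index, columns=matrix.values.columns)
    return ProteinQuantMatrix(values, weights, imputed, units)


# ---------------------------------------------------------------------------
# differential testing


def differential_dia(
    matrix: ProteinQuantMatrix,
    stage: str,
    alpha: float = 0.05,
    lfc_min: float = 0.5,
) -> pd.DataFrame:
    """Weighted moderated-t contrast of treatment vs control at one stage.

    The fitted log10 difference is converted to log2 units; a protein is
    ``called`` iff p_adj <= alpha and |log2fc| >= lfc_min (both bounds
    inclusive).
    """
    units = matrix.units
    stage_units = units[units["stage"] == stage]
    if stage_units.empty:
        raise ConfigError(f"stage {stage!r} absent from design")
    cols = stage_units["unit_id"].tolist()
    conditions = dict(zip(stage_units["unit_id"], stage_units["condition"]))
    design = Design(
        conditions={c: conditions[c] for c in cols},
        replicates={c: str(b) for c, b in zip(stage_units["unit_id"], stage_units["bio_replicate"])},
    )
    sub = matrix.values[cols]
    w = matrix.weights[cols]
    results, _prior = diffstats.run_differential(sub, design, weights=w, alpha=alpha)
    results["log2fc_log10"] = results["log2fc"]
    results["log2fc"] = results["log2fc_log10"] * LOG2_PER_LOG10
    results["direction"] = np.where(results["log2fc"] >= 0, "up", "down")
    results["called"] = results["significant"] & (results["log2fc"].abs() >= lfc_min)
    results["stage"] = stage
    return results


def differential_all_stages(
    matrix: ProteinQuantMatrix, alpha: float = 0.05, lfc_min: float = 0.5
) -> pd.DataFrame:
    frames = [
        differential_dia(matrix, stage, alpha=alpha, lfc_min=lfc_min)
        for stage in matrix.units["stage"].unique()
    ]
    return pd.concat(frames)
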