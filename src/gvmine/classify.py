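"""Linear-discriminant classification of scaffolds from evidence counts.

A scaffold with viral-ORF count v and cellular-match count c is called
Nucleocytoviricota iff

    v > slope * c + intercept        (strictly above the line)

— points on or under the line are excluded.  The boundary is calibrated on a
labeled control set by exhaustive grid search, maximizing sensitivity among
boundaries whose eukaryotic false-positive rate stays strictly below a hard
cap (default 1%); the eukaryotic class is the one constrained because
eukaryotic contamination is what a giant-virus catalog can least afford.
An alternative proportions mode divides both counts by the scaffold's ORF
count before applying the same rule shape.

Contamination post-filters remove externally flagged scaffolds (rRNA
detected, manual exclusion) after classification; endogenization flags only
annotate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VIRAL_LABEL",
    "NON_VIRAL_LABEL",
    "TRUTH_LABELS",
    "DecisionBoundary",
    "CalibrationSpec",
    "PerformanceReport",
    "PostFilterFlags",
    "FilterResult",
    "classify",
    "classify_table",
    "evaluate",
    "calibrate",
    "apply_post_filters",
    "read_flags_table",
]

VIRAL_LABEL = "nucleocytoviricota"
NON_VIRAL_LABEL = "non_viral"
TRUTH_LABELS = ("viral", "bacterial", "archaeal", "eukaryotic")


@dataclass(frozen=True)
class DecisionBoundary:
    """(slope, intercept) of the discriminating line, with the on-line
    exclusion rule: viral iff v > slope*c + intercept."""

    slope: float = 0.1
    intercept: float = 1.0
    mode: str = "counts"

    def __post_init__(self) -> None:
        if self.slope < 0 or self.intercept < 0:
            raise ValueError("slope and intercept must be non-negative")
        if self.mode not in ("counts", "proportions"):
            raise ValueError("mode must be 'counts' or 'proportions'")


def _coords(v, c, n_orfs, mode: str):
    v = np.asarray(v, dtype=float)
    c = np.asarray(c, dtype=float)
    if (v < 0).any() or (c < 0).any():
        raise ValueError("evidence counts must be non-negative")
    if mode == "proportions":
        if n_orfs is None:
            raise ValueError("proportions mode requires n_orfs")
        n = np.asarray(n_orfs, dtype=float)
        if (n <= 0).any():
            raise ValueError("proportions mode requires n_orfs > 0")
        return v / n, c / n
    return v, c


def _is_viral(v, c, boundary: DecisionBoundary, n_orfs=None) -> np.ndarray:
    v, c = _coords(v, c, n_orfs, boundary.mode)
    return v > boundary.slope * c + boundary.intercept


def classify(
    viral_orf_count: float,
    cellular_match_count: float,
    boundary: DecisionBoundary = DecisionBoundary(),
    n_orfs: int | None = None,
) -> str:
    """Classify a single scaffold's evidence pair; strict inequality, so a
    point on the line is non-viral."""
    flag = _is_viral(
        np.array([viral_orf_count]),
        np.array([cellular_match_count]),
        boundary,
        None if n_orfs is None else np.array([n_orfs]),
    )[0]
    return VIRAL_LABEL if flag else NON_VIRAL_LABEL


def classify_table(
    evidence: pd.DataFrame, boundary: DecisionBoundary = DecisionBoundary()
) -> pd.Series:
    """Vectorized classification of an evidence table (columns
    ``viral_orf_count``, ``cellular_match_count`` and, in proportions mode,
    ``n_orfs``)."""
    n_orfs = evidence["n_orfs"] if boundary.mode == "proportions" else None
    flags = _is_viral(
        evidence["viral_orf_count"], evidence["cellular_match_count"], boundary, n_orfs
    )
    return pd.Series(
        np.where(flags, VIRAL_LABEL, NON_VIRAL_LABEL),
        index=evidence.index,
        name="label",
    )


@dataclass(frozen=True)
class CalibrationSpec:
    """Grid and constraint for boundary calibration.  The eukaryotic
    false-positive cap is strict: a rate exactly equal to ``max_euk_fp``
    is infeasible."""

    slope_grid: tuple[float, ...] = tuple(np.round(np.arange(0.0, 0.5001, 0.01), 10))
    intercept_grid: tuple[float, ...] = tuple(np.round(np.arange(0.0, 10.001, 0.5), 10))
    max_euk_fp: float = 0.01
    mode: str = "counts"

    def __post_init__(self) -> None:
        if not self.slope_grid or not self.intercept_grid:
            raise ValueError("grids must be non-empty")
        if not 0.0 < self.max_euk_fp < 1.0:
            raise ValueError("max_euk_fp must be in (0, 1)")


@dataclass
class PerformanceReport:
    """Sensitivity over viral records and one specificity per non-viral
    class, with exact confusion counts."""

    sensitivity: float
    specificity: dict[str, float]
    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def summary(self) -> dict[str, float]:
        out = {
            "sensitivity": self.sensitivity,
            "tp": self.tp,
            "fn": self.fn,
            "fp": self.fp,
            "tn": self.tn,
            "n": self.n,
        }
        for label, value in self.specificity.items():
            out[f"specificity_{label}"] = value
        return out


def _check_labels(labels: pd.Series) -> None:
    unknown = sorted(set(labels) - set(TRUTH_LABELS))
    if unknown:
        raise ValueError(f"unknown truth labels: {unknown}")


def evaluate(
    evidence: pd.DataFrame, boundary: DecisionBoundary = DecisionBoundary()
) -> PerformanceReport:
    """Score a boundary on a labeled evidence table (``truth_class`` column
    with labels viral/bacterial/archaeal/eukaryotic)."""
    truth = evidence["truth_class"]
    _check_labels(truth)
    n_orfs = evidence["n_orfs"] if boundary.mode == "proportions" else None
    pred = _is_viral(
        evidence["viral_orf_count"], evidence["cellular_match_count"], boundary, n_orfs
    )
    is_viral_truth = (truth == "viral").to_numpy()
    tp = int((pred & is_viral_truth).sum())
    fn = int((~pred & is_viral_truth).sum())
    fp = int((pred & ~is_viral_truth).sum())
    tn = int((~pred & ~is_viral_truth).sum())
    specificity = {}
    for label in TRUTH_LABELS[1:]:
        mask = (truth == label).to_numpy()
        if mask.any():
            specificity[label] = float((~pred[mask]).sum() / mask.sum())
    sensitivity = tp / (tp + fn) if (tp + fn) else float("nan")
    return PerformanceReport(sensitivity, specificity, tp, fn, fp, tn)


def calibrate(
    evidence: pd.DataFrame, spec: CalibrationSpec = CalibrationSpec()
) -> tuple[DecisionBoundary, PerformanceReport]:
    """Exhaustive grid search for the boundary maximizing sensitivity under
    the strict eukaryotic false-positive cap.

    Ties in sensitivity are broken toward the more conservative boundary:
    higher intercept first, then higher slope.  Raises if no grid point is
    feasible, stating the smallest achievable eukaryotic FP rate.
    """
    truth = evidence["truth_class"]
    _check_labels(truth)
    if not (truth == "viral").any() or not (truth == "eukaryotic").any():
        raise ValueError(
            "calibration needs at least one viral and one eukaryotic record"
        )
    n_orfs = evidence["n_orfs"] if spec.mode == "proportions" else None
    v, c = _coords(
        evidence["viral_orf_count"], evidence["cellular_match_count"], n_orfs, spec.mode
    )
    is_viral = (truth == "viral").to_numpy()
    is_euk = (truth == "eukaryotic").to_numpy()

    best_key = None
    best_boundary = None
    min_euk_fp = np.inf
    for intercept in spec.intercept_grid:
        for slope in spec.slope_grid:
            pred = v > slope * c + intercept
            euk_fp = float(pred[is_euk].mean())
            min_euk_fp = min(min_euk_fp, euk_fp)
            if euk_fp >= spec.max_euk_fp:
                continue
            sens = float(pred[is_viral].mean())
            key = (sens, intercept, slope)
            if best_key is None or key > best_key:
                best_key = key
                best_boundary = DecisionBoundary(slope, intercept, mode=spec.mode)
    if best_boundary is None:
        raise ValueError(
            f"no grid point satisfies eukaryotic FP < {spec.max_euk_fp}; "
            f"minimal achievable eukaryotic FP rate is {min_euk_fp:.6f}"
        )
    return best_boundary, evaluate(evidence, best_boundary)


# --------------------------------------------------------------------------
# Contamination post-filters


@dataclass(frozen=True)
class PostFilterFlags:
    """Externally produced contamination flags for one scaffold.  rRNA and
    manual-exclusion flags remove the scaffold; the endogenization flag only
    annotates it."""

    scaffold_id: str
    has_rrna: bool = False
    manual_exclusion: bool = False
    reason: str = ""
    endogenization_flag: bool = False


@dataclass
class FilterResult:
    kept: list[str]
    removed: list[tuple[str, str]] = field(default_factory=list)
    endogenization_flagged: list[str] = field(default_factory=list)


def apply_post_filters(
    scaffold_ids: Sequence[str], flags: Iterable[PostFilterFlags]
) -> FilterResult:
    """Remove flagged scaffolds from a classified set, logging every removal
    with its reason.  Flags for scaffolds not in the input produce a warning
    and are otherwise ignored; filtering only ever removes scaffolds."""
    scaffold_ids = list(scaffold_ids)
    present = set(scaffold_ids)
    by_id: dict[str, PostFilterFlags] = {}
    for f in flags:
        if f.scaffold_id not in present:
            warnings.warn(
                f"flag for unknown scaffold {f.scaffold_id!r} ignored", stacklevel=2
            )
            continue
        by_id[f.scaffold_id] = f
    result = FilterResult(kept=[])
    for sid in scaffold_ids:
        f = by_id.get(sid)
        if f is None:
            result.kept.append(sid)
            continue
        if f.has_rrna:
            result.removed.append((sid, "rRNA detected"))
        elif f.manual_exclusion:
            result.removed.append((sid, f.reason or "manual exclusion"))
        else:
            result.kept.append(sid)
        if f.endogenization_flag:
            result.endogenization_flagged.append(sid)
    return result


def read_flags_table(path: str | Path) -> list[PostFilterFlags]:
    """Read flags from TSV (scaffold_id, has_rrna, manual_exclusion, reason,
    endogenization_flag)."""
    df = pd.read_csv(path, sep="\t", dtype={"reason": str}, keep_default_na=False)
    required = {"scaffold_id", "has_rrna", "manual_exclusion"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")

    def as_bool(x) -> bool:
        if isinstance(x, str):
            return x.strip().lower() in ("true", "1", "yes")
        return bool(x)

    return [
        PostFilterFlags(
            scaffold_id=str(r["scaffold_id"]),
            has_rrna=as_bool(r["has_rrna"]),
            manual_exclusion=as_bool(r["manual_exclusion"]),
            reason=str(r.get("reason", "") or ""),
            endogenization_flag=as_bool(r.get("endogenization_flag", False)),
        )
        for _, r in df.iterrows()
    ]
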