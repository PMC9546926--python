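"""Coverage-based abundance and virus–eukaryote co-occurrence statistics.

Relative abundance of a taxonomic group in a sample is the summed mean read
coverage of its scaffolds divided by the summed coverage of ALL scaffolds of
at least 10 kb in that sample; shorter scaffolds enter neither numerator nor
denominator.  Virus–eukaryote co-occurrence is tested by Spearman rank
correlation of abundances across samples, restricted to pairs whose members
are each present (non-zero) in at least two samples, with Benjamini–Hochberg
FDR correction over all tested pairs as one family.

With ~11 samples the t-approximation to the Spearman null sits at the edge
of its validity, so an exact tie-aware permutation p-value is used for n
below 10 and available on request for larger n via ``method``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "relative_abundance",
    "group_ratio",
    "GroupRatio",
    "spearman_with_p",
    "benjamini_hochberg",
    "cooccurrence",
    "presence_calls",
    "read_taxonomy_table",
]


def relative_abundance(
    coverage: pd.DataFrame,
    taxonomy: Mapping[str, str],
    scaffold_lengths: Mapping[str, int],
    min_len: int = 10_000,
) -> pd.DataFrame:
    """Sample × group relative-abundance matrix.

    ``coverage`` has columns scaffold_id, sample_id, mean_coverage.  Only
    scaffolds of length ≥ ``min_len`` are considered.  The denominator of a
    sample is the coverage sum over all such scaffolds, including scaffolds
    with no taxonomy assignment (they dilute every group but form no column).
    Rows over an exhaustive, disjoint grouping therefore sum to 1.  A sample
    whose denominator is zero is an error.
    """
    df = coverage.copy()
    missing = sorted(set(df["scaffold_id"]) - set(scaffold_lengths))
    if missing:
        raise ValueError(f"no length known for scaffold(s): {missing[:10]}")
    df["length"] = df["scaffold_id"].map(scaffold_lengths)
    df = df[df["length"] >= min_len]
    denom = df.groupby("sample_id")["mean_coverage"].sum()
    zero = sorted(denom.index[denom <= 0])
    if zero or denom.empty:
        raise ValueError(f"zero total coverage in sample(s): {zero or 'all'}")
    df["group"] = df["scaffold_id"].map(taxonomy)
    grouped = (
        df.dropna(subset=["group"])
        .groupby(["sample_id", "group"])["mean_coverage"]
        .sum()
        .unstack(fill_value=0.0)
    )
    grouped = grouped.reindex(denom.index, fill_value=0.0)
    return grouped.div(denom, axis=0)


@dataclass
class GroupRatio:
    """Per-sample abundance ratio between two groups; samples with a zero
    denominator are flagged and excluded from the mean/sd (sample sd,
    n−1 denominator)."""

    per_sample: pd.Series
    mean: float
    sd: float
    excluded: list[str] = field(default_factory=list)


def group_ratio(matrix: pd.DataFrame, num_group: str, den_group: str) -> GroupRatio:
    for g in (num_group, den_group):
        if g not in matrix.columns:
            raise ValueError(f"group {g!r} not in abundance matrix")
    den = matrix[den_group]
    ok = den > 0
    ratio = (matrix.loc[ok, num_group] / den[ok]).rename("ratio")
    excluded = list(matrix.index[~ok])
    mean = float(ratio.mean()) if len(ratio) else float("nan")
    sd = float(ratio.std(ddof=1)) if len(ratio) > 1 else float("nan")
    return GroupRatio(ratio, mean, sd, excluded)


# --------------------------------------------------------------------------
# Spearman correlation and FDR


def _exact_spearman_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact permutation p-value for Spearman's rho with midrank
    tie handling, by full enumeration of the n! pairings."""
    n = len(x)
    if n > 9:
        raise ValueError("exact enumeration supported for n <= 9; use method='t'")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    cx = rx - rx.mean()
    cy = ry - ry.mean()
    denom = math.sqrt((cx**2).sum() * (cy**2).sum())
    if denom == 0:
        return float("nan")
    observed = abs(float(cx @ cy) / denom)
    perms = np.array(list(itertools.permutations(range(n))))
    rhos = (cy[perms] @ cx) / denom
    return float(np.mean(np.abs(rhos) >= observed - 1e-12))


def spearman_with_p(
    x: Sequence[float], y: Sequence[float], method: str = "auto"
) -> tuple[float, float]:
    """Spearman rho and two-sided p-value.

    ``method="t"`` uses the t-distribution approximation (scipy);
    ``"exact"`` enumerates all pairings (n ≤ 9); ``"auto"`` picks exact
    below n=10 and the approximation otherwise.  A constant input yields
    (nan, nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    if method == "auto":
        method = "exact" if len(x) < 10 else "t"
    rho_t, p_t = stats.spearmanr(x, y)
    if method == "t":
        return float(rho_t), float(p_t)
    if method == "exact":
        return float(rho_t), _exact_spearman_p(x, y)
    raise ValueError("method must be 'auto', 't' or 'exact'")


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values for one family of tests."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def cooccurrence(
    matrix: pd.DataFrame,
    virus_taxa: Sequence[str],
    euk_taxa: Sequence[str],
    min_presence: int = 2,
    method: str = "auto",
) -> pd.DataFrame:
    """Virus × eukaryote co-occurrence across samples.

    A pair is tested iff each member is non-zero in at least
    ``min_presence`` samples; the correlation itself is computed over ALL
    samples, zeros included.  Pairs with a constant abundance vector are
    emitted with undefined rho and excluded from the BH family, which
    otherwise spans every tested pair of the run.
    """
    if len(matrix) < 3:
        raise ValueError("co-occurrence needs at least 3 samples")
    for t in list(virus_taxa) + list(euk_taxa):
        if t not in matrix.columns:
            raise ValueError(f"taxon {t!r} not in abundance matrix")
    rows = []
    for virus in virus_taxa:
        for euk in euk_taxa:
            x = matrix[virus].to_numpy(dtype=float)
            y = matrix[euk].to_numpy(dtype=float)
            tested = (
                int((x > 0).sum()) >= min_presence
                and int((y > 0).sum()) >= min_presence
            )
            if not tested:
                rows.append((virus, euk, len(x), False, np.nan, np.nan, ""))
                continue
            rho, p = spearman_with_p(x, y, method=method)
            note = "constant abundance vector" if np.isnan(rho) else ""
            rows.append((virus, euk, len(x), True, rho, p, note))
    out = pd.DataFrame(
        rows,
        columns=["virus", "eukaryote", "n_samples", "tested", "rho", "p_value", "note"],
    )
    out["q_value"] = np.nan
    family = out["tested"] & out["p_value"].notna()
    if family.any():
        out.loc[family, "q_value"] = benjamini_hochberg(
            out.loc[family, "p_value"].to_numpy()
        )
    return out


# --------------------------------------------------------------------------
# Presence and cross-sample sharing


def presence_calls(
    covered: pd.DataFrame, min_covered: int = 10_000
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Presence of scaffolds per sample and the sample-sharing matrix.

    ``covered`` has columns scaffold_id, sample_id, covered_length, where
    covered lengths were computed under the cross-sample mapping filters
    (MAPQ ≥ 30, reads > 30 nt).  A scaffold is present in a sample iff
    strictly more than ``min_covered`` nucleotides are covered.  The sharing
    matrix counts scaffolds present in both samples of each pair; its
    diagonal is the per-sample presence count.
    """
    calls = covered.copy()
    calls["present"] = calls["covered_length"] > min_covered
    samples = sorted(calls["sample_id"].unique())
    present_sets = {
        s: set(calls.loc[(calls["sample_id"] == s) & calls["present"], "scaffold_id"])
        for s in samples
    }
    sharing = pd.DataFrame(
        [
            [len(present_sets[a] & present_sets[b]) for b in samples]
            for a in samples
        ],
        index=samples,
        columns=samples,
        dtype=int,
    )
    return calls, sharing


def read_taxonomy_table(path: str | Path) -> dict[str, str]:
    """Read a scaffold→group map from TSV (columns scaffold_id, group)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"scaffold_id", "group"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return dict(zip(df["scaffold_id"].astype(str), df["group"].astype(str)))
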