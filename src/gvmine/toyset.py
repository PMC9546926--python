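"""A tiny hand-constructed worked example shipped with the package.

Twelve synthetic scaffolds with hand-written ORF, profile-hit, cellular-hit,
marker-hit and coverage tables exercise every stated filter of the pipeline
(ORFs ≥50 aa; profile hits at E ≤ 1e-10; cellular hits at identity ≥35% and
E ≤ 1e-5 in the three cellular domains; the ≥10 kb length cut; the marker
initial cutoff, stringent thresholds and ≥3/≥1-marker partitions; the
>10 kb-covered presence rule).  ``manifest.json`` records the hand-computed
number of records surviving each filter, and :func:`bookkeeping_counts`
recomputes them all by running the package, so the two can be compared
exactly.
"""

from __future__ import annotations

import json
import warnings
from importlib import resources
from pathlib import Path

import pandas as pd

from . import abundance, classify, evidence, markers

__all__ = ["toyset_path", "load_manifest", "bookkeeping_counts"]


def toyset_path(name: str = "") -> Path:
    base = resources.files("gvmine") / "data" / "toyset"
    return Path(str(base / name if name else base))


def load_manifest() -> dict[str, int]:
    with open(toyset_path("manifest.json")) as fh:
        return json.load(fh)


def _count_rows(path: Path, comment: str | None = "#", header: bool = False) -> int:
    n = 0
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            if comment and line.startswith(comment):
                continue
            n += 1
    return n - (1 if header else 0)


def bookkeeping_counts() -> dict[str, int]:
    """Recompute every manifest quantity by running the pipeline filters on
    the toy tables."""
    out: dict[str, int] = {}

    scaffolds = pd.read_csv(toyset_path("scaffolds.tsv"), sep="\t")
    lengths = dict(zip(scaffolds["scaffold_id"], scaffolds["length"]))
    out["n_scaffolds"] = len(scaffolds)
    out["scaffolds_ge_10kb"] = int((scaffolds["length"] >= 10_000).sum())

    out["orf_rows"] = _count_rows(toyset_path("orfs.tsv"), header=True)
    orfs = evidence.read_orf_table(toyset_path("orfs.tsv"), min_aa=50)
    out["orfs_min_50aa"] = len(orfs)

    out["profile_hit_rows"] = _count_rows(toyset_path("profile_hits.tbl"))
    profile_hits = evidence.load_profile_hits(
        toyset_path("profile_hits.tbl"), max_evalue=1e-10
    )
    out["profile_hits_retained"] = len(profile_hits)

    out["cellular_hit_rows"] = _count_rows(toyset_path("cellular_hits.tsv"))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # one hit has a non-cellular domain
        cellular_hits = evidence.load_cellular_hits(toyset_path("cellular_hits.tsv"))
    out["cellular_hits_retained"] = len(cellular_hits)

    table = evidence.count_evidence(orfs, profile_hits, cellular_hits, lengths)
    labels = classify.classify_table(table, classify.DecisionBoundary())
    out["classified_viral"] = int((labels == classify.VIRAL_LABEL).sum())

    out["marker_hit_rows"] = _count_rows(toyset_path("marker_hits.tsv"), header=True)
    hits = markers.read_marker_hits(toyset_path("marker_hits.tsv"))
    ranked = markers.rank_marker_hits(hits, initial_evalue=1e-5)
    out["marker_hits_within_initial_cutoff"] = len(ranked)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # single-copy markers fall back
        thresholds = markers.stringent_thresholds(ranked)
    selected = markers.select_marker_hits(ranked, thresholds)
    partition = markers.partition_by_marker_count(selected)
    out["high_confidence_scaffolds"] = len(partition.high_confidence)
    out["extended_scaffolds"] = len(partition.extended)

    out["coverage_rows"] = _count_rows(toyset_path("coverage.tsv"), header=True)
    covered = pd.read_csv(toyset_path("coverage.tsv"), sep="\t")
    calls, sharing = abundance.presence_calls(covered, min_covered=10_000)
    out["present_calls"] = int(calls["present"].sum())
    out["shared_between_samples"] = int(sharing.loc["A", "B"])
    return out
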