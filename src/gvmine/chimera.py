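"""Assembly chimera assessment against reference genomes.

Assembled contigs, bins and scaffolds are validated by aligning them back to
the reference genomes they should derive from (mock communities or simulated
contigs with known provenance).  Near-perfect alignments are processed in
order of decreasing quality; each alignment is trimmed by the query intervals
already claimed by better alignments, and the surviving fragments are retained
only if long enough.  A query whose retained fragments name two or more
distinct reference genomes is a chimera.

The module only reports chimerism; it never corrects or splits sequences.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "AlignmentMatch",
    "RetainedSegment",
    "ChimeraReport",
    "trim_overlaps",
    "label_chimera",
    "assess_queries",
    "chimera_report",
    "load_alignments",
    "read_bin_table",
    "write_verdicts",
]


@dataclass(frozen=True)
class AlignmentMatch:
    """One nucleotide alignment of a query to a reference genome.

    Query coordinates are 1-based inclusive, as in BLAST tabular output.
    """

    query_id: str
    reference_genome_id: str
    qstart: int
    qend: int
    percent_identity: float
    score: float
    evalue: float = 0.0

    def __post_init__(self) -> None:
        if self.qstart > self.qend:
            raise ValueError(
                f"inverted query interval {self.qstart}-{self.qend} "
                f"for {self.query_id}"
            )
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError(f"percent identity out of range: {self.percent_identity}")

    @property
    def length(self) -> int:
        return self.qend - self.qstart + 1


@dataclass(frozen=True)
class RetainedSegment:
    """A trimmed alignment fragment that survived the retention rules."""

    query_id: str
    reference_genome_id: str
    qstart: int
    qend: int

    @property
    def length(self) -> int:
        return self.qend - self.qstart + 1


@dataclass
class ChimeraReport:
    """Chimera proportions at one level (contig, bin or scaffold).

    ``proportion`` uses only assessed items (those with at least one retained
    alignment segment) in the denominator; ``proportion_of_total`` additionally
    counts unassessed items, since published chimera rates do not always state
    which denominator was used.
    """

    level: str
    n_assessed: int
    n_chimeric: int
    n_unassessed: int
    verdicts: dict[str, str] = field(default_factory=dict)

    @property
    def proportion(self) -> float:
        return self.n_chimeric / self.n_assessed if self.n_assessed else float("nan")

    @property
    def proportion_of_total(self) -> float:
        total = self.n_assessed + self.n_unassessed
        return self.n_chimeric / total if total else float("nan")


def _match_order(m: AlignmentMatch):
    # "previous better matches": descending score, then ascending e-value,
    # ascending start, reference id as the final deterministic tie-break.
    return (-m.score, m.evalue, m.qstart, m.reference_genome_id)


def _subtract(interval: tuple[int, int], claimed: Iterable[tuple[int, int]]):
    """Remove every claimed interval from ``interval`` (1-based inclusive)."""
    fragments = [interval]
    for s, e in claimed:
        nxt = []
        for a, b in fragments:
            if e < a or s > b:
                nxt.append((a, b))
                continue
            if a < s:
                nxt.append((a, s - 1))
            if b > e:
                nxt.append((e + 1, b))
        fragments = nxt
        if not fragments:
            break
    return fragments


def trim_overlaps(
    matches: Iterable[AlignmentMatch],
    min_identity: float = 99.99,
    min_len: int = 500,
) -> list[RetainedSegment]:
    """Apply the trim-and-retain rules to the matches of a single query.

    Matches below ``min_identity`` are discarded.  The rest are processed in
    descending score order; each match loses the query intervals already
    claimed by previously retained segments, and every surviving fragment is
    kept iff it spans at least ``min_len`` nucleotides.  Retained segments are
    therefore mutually non-overlapping.
    """
    matches = list(matches)
    queries = {m.query_id for m in matches}
    if len(queries) > 1:
        raise ValueError(f"matches span multiple queries: {sorted(queries)}")

    retained: list[tuple[int, int]] = []
    segments: list[RetainedSegment] = []
    candidates = [m for m in matches if m.percent_identity >= min_identity]
    for m in sorted(candidates, key=_match_order):
        for a, b in _subtract((m.qstart, m.qend), retained):
            if b - a + 1 >= min_len:
                retained.append((a, b))
                segments.append(
                    RetainedSegment(m.query_id, m.reference_genome_id, a, b)
                )
    return sorted(segments, key=lambda s: s.qstart)


def label_chimera(segments: Iterable[RetainedSegment]) -> str:
    """Verdict for one query: ``chimeric`` iff its retained segments name at
    least two distinct reference genomes, ``unassessed`` if nothing was
    retained, ``clean`` otherwise."""
    refs = {s.reference_genome_id for s in segments}
    if not refs:
        return "unassessed"
    return "chimeric" if len(refs) >= 2 else "clean"


def assess_queries(
    matches: Iterable[AlignmentMatch],
    query_ids: Iterable[str] | None = None,
    *,
    min_identity: float = 99.99,
    min_len: int = 500,
) -> dict[str, list[RetainedSegment]]:
    """Group matches by query and trim each query independently.

    ``query_ids`` may list queries with no alignments at all; they appear in
    the result with an empty segment list (verdict ``unassessed``).
    """
    by_query: dict[str, list[AlignmentMatch]] = defaultdict(list)
    for m in matches:
        by_query[m.query_id].append(m)
    out: dict[str, list[RetainedSegment]] = {}
    for qid in query_ids or ():
        out[qid] = []
    for qid, ms in by_query.items():
        out[qid] = trim_overlaps(ms, min_identity=min_identity, min_len=min_len)
    return out


def chimera_report(
    segments_by_query: Mapping[str, list[RetainedSegment]],
    bin_membership: Mapping[str, str] | Iterable[tuple[str, str]] | None = None,
) -> dict[str, ChimeraReport]:
    """Summarize chimerism at the contig level and, if a bin membership is
    given, at the bin level.

    A bin is chimeric if the retained segments of its member contigs span two
    or more reference genomes.  Bins with a single contig are excluded from
    the bin-level assessment, and queries (or bins) with no retained segments
    are counted as unassessed rather than clean.
    """
    ref_sets = {
        q: {s.reference_genome_id for s in segs}
        for q, segs in segments_by_query.items()
    }

    reports: dict[str, ChimeraReport] = {}
    verdicts = {
        q: ("unassessed" if not refs else "chimeric" if len(refs) >= 2 else "clean")
        for q, refs in ref_sets.items()
    }
    n_un = sum(v == "unassessed" for v in verdicts.values())
    n_chi = sum(v == "chimeric" for v in verdicts.values())
    reports["contig"] = ChimeraReport(
        level="contig",
        n_assessed=len(verdicts) - n_un,
        n_chimeric=n_chi,
        n_unassessed=n_un,
        verdicts=verdicts,
    )

    if bin_membership is not None:
        if not isinstance(bin_membership, Mapping):
            pairs = list(bin_membership)
            seen: dict[str, str] = {}
            for contig, bin_id in pairs:
                if contig in seen and seen[contig] != bin_id:
                    raise ValueError(f"contig {contig!r} assigned to multiple bins")
                seen[contig] = bin_id
            bin_membership = seen
        bins: dict[str, set[str]] = defaultdict(set)
        sizes: dict[str, int] = defaultdict(int)
        for contig, bin_id in bin_membership.items():
            sizes[bin_id] += 1
            bins[bin_id].update(ref_sets.get(contig, set()))
        bin_verdicts = {}
        for bin_id, refs in bins.items():
            if sizes[bin_id] < 2:
                continue  # single-contig bins carry no binning information
            if not refs:
                bin_verdicts[bin_id] = "unassessed"
            else:
                bin_verdicts[bin_id] = "chimeric" if len(refs) >= 2 else "clean"
        n_un = sum(v == "unassessed" for v in bin_verdicts.values())
        n_chi = sum(v == "chimeric" for v in bin_verdicts.values())
        reports["bin"] = ChimeraReport(
            level="bin",
            n_assessed=len(bin_verdicts) - n_un,
            n_chimeric=n_chi,
            n_unassessed=n_un,
            verdicts=bin_verdicts,
        )
    return reports


def load_alignments(path: str | Path) -> list[AlignmentMatch]:
    """Read 12-column BLAST tabular alignments (qseqid sseqid pident length
    mismatch gapopen qstart qend sstart send evalue bitscore)."""
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(f"{path}: line {i}: expected 12 columns, got {len(fields)}")
            try:
                out.append(
                    AlignmentMatch(
                        query_id=fields[0],
                        reference_genome_id=fields[1],
                        percent_identity=float(fields[2]),
                        qstart=int(fields[6]),
                        qend=int(fields[7]),
                        evalue=float(fields[10]),
                        score=float(fields[11]),
                    )
                )
            except ValueError as err:
                raise ValueError(f"{path}: line {i}: {err}") from None
    if not out:
        warnings.warn(f"{path}: no alignments parsed", stacklevel=2)
    return out


def read_bin_table(path: str | Path) -> dict[str, str]:
    """Read contig→bin membership from a two-column TSV (header optional)."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "contig_id":
                continue
            if len(fields) < 2:
                raise ValueError(f"{path}: line {i}: expected 2 columns")
            contig, bin_id = fields[0], fields[1]
            if contig in mapping and mapping[contig] != bin_id:
                raise ValueError(f"contig {contig!r} assigned to multiple bins")
            mapping[contig] = bin_id
    return mapping


def write_verdicts(reports: Mapping[str, ChimeraReport], path: str | Path) -> None:
    """Write per-item verdicts for every level as a TSV."""
    with open(path, "w") as fh:
        fh.write("level\titem_id\tverdict\n")
        for level, report in reports.items():
            for item, verdict in sorted(report.verdicts.items()):
                fh.write(f"{level}\t{item}\t{verdict}\n")
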