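"""Per-scaffold evidence from upstream search results.

The giant-virus discriminator works on two numbers per scaffold: the number
of distinct ORFs matching a Nucleocytoviricota-specific profile (viral
matches) and the number of protein-similarity matches against a cellular
reference database (cellular matches).  This module parses the standard
upstream formats, applies the stated filters (ORFs ≥50 aa; profile hits at
E ≤ 1e-10; cellular hits at identity ≥35% and E ≤ 1e-5 restricted to the
Bacteria/Archaea/Eukaryota domains) and reduces them to an evidence table,
plus per-scaffold read coverage from SAM mappings.

Profile/similarity searches themselves (hmmsearch, DIAMOND, BLAST) are
upstream producers of the files read here and are never run by this package.
"""

from __future__ import annotations

import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "OrfRecord",
    "ProfileHit",
    "CellularHit",
    "ScaffoldEvidence",
    "CoverageRecord",
    "extract_orfs",
    "load_profile_hits",
    "load_cellular_hits",
    "count_evidence",
    "coverage_from_sam",
    "read_orf_table",
    "write_orf_table",
    "read_evidence_table",
    "write_evidence_table",
    "read_coverage_table",
    "write_coverage_table",
    "coverage_to_frame",
]

CELLULAR_DOMAINS = frozenset({"Bacteria", "Archaea", "Eukaryota"})

EVIDENCE_COLUMNS = [
    "scaffold_id",
    "length",
    "n_orfs",
    "viral_orf_count",
    "cellular_match_count",
]


@dataclass(frozen=True)
class OrfRecord:
    """A predicted protein-coding ORF; coordinates are 0-based half-open on
    the scaffold's forward strand."""

    orf_id: str
    scaffold_id: str
    start: int
    end: int
    strand: str
    aa_length: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad ORF interval [{self.start}, {self.end})")


@dataclass(frozen=True)
class ProfileHit:
    orf_id: str
    profile_id: str
    evalue: float
    score: float


@dataclass(frozen=True)
class CellularHit:
    orf_id: str
    subject_id: str
    percent_identity: float
    evalue: float
    subject_domain: str


@dataclass(frozen=True)
class ScaffoldEvidence:
    """The coordinate pair of the discriminator, per scaffold."""

    scaffold_id: str
    length: int
    n_orfs: int
    viral_orf_count: int
    cellular_match_count: int


@dataclass(frozen=True)
class CoverageRecord:
    scaffold_id: str
    sample_id: str
    mean_coverage: float
    covered_length: int


# --------------------------------------------------------------------------
# ORF extraction


def _orfs_from_protein(
    prot: str, frame: int, strand: str, seq_len: int, min_aa: int
):
    """Yield (start, end, aa_len, fragment) for stop-to-stop fragments of a
    translated frame.  Coordinates are on the translated strand; the caller
    maps minus-strand coordinates back to the forward strand."""
    aa_pos = 0
    for frag in prot.split("*"):
        if len(frag) >= min_aa and any(c != "X" for c in frag):
            ts = frame + 3 * aa_pos
            te = frame + 3 * (aa_pos + len(frag))
            if strand == "+":
                yield ts, te, len(frag), frag
            else:
                yield seq_len - te, seq_len - ts, len(frag), frag
        aa_pos += len(frag) + 1


def extract_orfs(
    scaffolds, min_aa: int = 50
) -> tuple[list[OrfRecord], dict[str, str]]:
    """Six-frame stop-to-stop ORF extraction (standard genetic code, no start
    codon required), keeping ORFs of at least ``min_aa`` residues.

    This is deterministic plumbing for when no external gene caller output is
    available; externally predicted ORFs can be supplied through
    :func:`read_orf_table` instead.  Fragments translating entirely to
    ambiguous residues (e.g. runs of N) are not ORFs, so an all-N scaffold
    yields none.  Returns the ORF records and an ``orf_id → protein`` map.

    ``scaffolds`` may be a FASTA path or an iterable of Bio.SeqRecord.
    """
    if isinstance(scaffolds, (str, Path)):
        records = SeqIO.parse(str(scaffolds), "fasta")
    else:
        records = scaffolds
    orfs: list[OrfRecord] = []
    proteins: dict[str, str] = {}
    for rec in records:
        seq = str(rec.seq).upper()
        if not seq:
            continue
        L = len(seq)
        found = []
        for strand in ("+", "-"):
            s = seq if strand == "+" else str(Seq(seq).reverse_complement())
            for frame in range(3):
                usable = (L - frame) // 3
                if usable < min_aa:
                    continue
                prot = str(Seq(s[frame : frame + 3 * usable]).translate())
                found.extend(
                    (start, end, strand, aa_len, frag)
                    for start, end, aa_len, frag in _orfs_from_protein(
                        prot, frame, strand, L, min_aa
                    )
                )
        found.sort(key=lambda t: (t[0], t[1], t[2]))
        for i, (start, end, strand, aa_len, frag) in enumerate(found, 1):
            orf_id = f"{rec.id}_orf{i}"
            orfs.append(OrfRecord(orf_id, rec.id, start, end, strand, aa_len))
            proteins[orf_id] = frag
    return orfs, proteins


# --------------------------------------------------------------------------
# Tabular hit parsers


def load_profile_hits(path: str | Path, max_evalue: float = 1e-10) -> list[ProfileHit]:
    """Read profile-search hits from an hmmsearch-style per-sequence table
    (whitespace-delimited; ``#`` lines are comments; columns 1/3/5/6 are
    target, query profile, full-sequence E-value and score).

    Hits with E-value above ``max_evalue`` are discarded and only the best
    hit (lowest E-value, then highest score) is kept per (ORF, profile).
    """
    best: dict[tuple[str, str], ProfileHit] = {}
    n_rows = 0
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise ValueError(f"{path}: line {i}: expected >=6 fields, got {len(fields)}")
            try:
                hit = ProfileHit(
                    orf_id=fields[0],
                    profile_id=fields[2],
                    evalue=float(fields[4]),
                    score=float(fields[5]),
                )
            except ValueError:
                raise ValueError(f"{path}: line {i}: unparseable numeric field") from None
            n_rows += 1
            if hit.evalue > max_evalue:
                continue
            key = (hit.orf_id, hit.profile_id)
            cur = best.get(key)
            if cur is None or (hit.evalue, -hit.score) < (cur.evalue, -cur.score):
                best[key] = hit
    if n_rows == 0:
        warnings.warn(f"{path}: no profile hits parsed", stacklevel=2)
    return sorted(best.values(), key=lambda h: (h.orf_id, h.profile_id))


def load_cellular_hits(
    path: str | Path,
    min_identity: float = 35.0,
    max_evalue: float = 1e-5,
    domains: frozenset[str] | set[str] = CELLULAR_DOMAINS,
    domain_map: Mapping[str, str] | None = None,
    unknown_domain: str = "drop",
) -> list[CellularHit]:
    """Read protein-similarity hits from 12-column BLAST/DIAMOND tabular
    output, optionally with a 13th subject-domain column (otherwise the
    domain comes from ``domain_map``: subject id → domain).

    Retained hits satisfy identity ≥ ``min_identity`` AND E-value ≤
    ``max_evalue`` AND domain ∈ ``domains``.  Subjects with no resolvable
    domain are dropped with a warning (``unknown_domain="error"`` raises).
    """
    if unknown_domain not in ("drop", "error"):
        raise ValueError("unknown_domain must be 'drop' or 'error'")
    out: list[CellularHit] = []
    n_unknown = 0
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(f"{path}: line {i}: expected 12 columns, got {len(fields)}")
            try:
                orf_id, subject = fields[0], fields[1]
                pident = float(fields[2])
                evalue = float(fields[10])
            except ValueError:
                raise ValueError(f"{path}: line {i}: unparseable numeric field") from None
            domain = fields[12] if len(fields) > 12 else None
            if domain is None and domain_map is not None:
                domain = domain_map.get(subject)
            if pident < min_identity or evalue > max_evalue:
                continue
            if domain not in domains:
                if unknown_domain == "error":
                    raise ValueError(
                        f"{path}: line {i}: subject {subject!r} has "
                        f"unknown/excluded domain {domain!r}"
                    )
                n_unknown += 1
                continue
            out.append(CellularHit(orf_id, subject, pident, evalue, domain))
    if n_unknown:
        warnings.warn(
            f"{path}: dropped {n_unknown} hit(s) with unknown or excluded domain",
            stacklevel=2,
        )
    return out


# --------------------------------------------------------------------------
# Evidence counting


def count_evidence(
    orfs: Iterable[OrfRecord],
    profile_hits: Iterable[ProfileHit],
    cellular_hits: Iterable[CellularHit],
    scaffold_lengths: Mapping[str, int] | None = None,
    cellular_mode: str = "rows",
    per_orf_cap: int | None = 25,
) -> pd.DataFrame:
    """Reduce filtered hits to one evidence row per scaffold.

    The viral count is the number of DISTINCT ORFs on the scaffold with at
    least one qualifying profile hit (an ORF matching several profiles still
    counts once).  The cellular count is, by default, the number of
    qualifying similarity-hit rows, optionally capped at ``per_orf_cap`` rows
    per ORF since raw row counts inherit the upstream tool's reporting limit;
    ``cellular_mode="distinct_orfs"`` counts distinct matched ORFs instead.
    Scaffolds with no hits are still emitted with zero counts.
    """
    if cellular_mode not in ("rows", "distinct_orfs"):
        raise ValueError("cellular_mode must be 'rows' or 'distinct_orfs'")
    orfs = list(orfs)
    orf_to_scaffold: dict[str, str] = {}
    for o in orfs:
        if o.orf_id in orf_to_scaffold:
            raise ValueError(f"duplicate orf_id {o.orf_id!r}")
        orf_to_scaffold[o.orf_id] = o.scaffold_id

    profile_hits = list(profile_hits)
    cellular_hits = list(cellular_hits)
    orphans = sorted(
        {h.orf_id for h in profile_hits if h.orf_id not in orf_to_scaffold}
        | {h.orf_id for h in cellular_hits if h.orf_id not in orf_to_scaffold}
    )
    if orphans:
        raise ValueError(f"hits reference unknown ORF ids: {orphans}")

    n_orfs = Counter(o.scaffold_id for o in orfs)
    viral_orfs: dict[str, set[str]] = defaultdict(set)
    for h in profile_hits:
        viral_orfs[orf_to_scaffold[h.orf_id]].add(h.orf_id)

    cellular: Counter[str] = Counter()
    if cellular_mode == "rows":
        per_orf = Counter(h.orf_id for h in cellular_hits)
        for orf_id, n in per_orf.items():
            if per_orf_cap is not None:
                n = min(n, per_orf_cap)
            cellular[orf_to_scaffold[orf_id]] += n
    else:
        matched: dict[str, set[str]] = defaultdict(set)
        for h in cellular_hits:
            matched[orf_to_scaffold[h.orf_id]].add(h.orf_id)
        for scaffold, orf_set in matched.items():
            cellular[scaffold] = len(orf_set)

    scaffolds = sorted(set(orf_to_scaffold.values()) | set(scaffold_lengths or {}))
    lengths = scaffold_lengths or {}
    return pd.DataFrame(
        {
            "scaffold_id": scaffolds,
            "length": [lengths.get(s, np.nan) for s in scaffolds],
            "n_orfs": [n_orfs.get(s, 0) for s in scaffolds],
            "viral_orf_count": [len(viral_orfs.get(s, ())) for s in scaffolds],
            "cellular_match_count": [cellular.get(s, 0) for s in scaffolds],
        }
    )


# --------------------------------------------------------------------------
# Coverage


def coverage_from_sam(
    path: str | Path,
    sample_id: str = "sample",
    min_mapq: int = 3,
    min_read_len: int = 31,
) -> list[CoverageRecord]:
    """Per-scaffold mean coverage and covered length from a SAM mapping.

    Alignments are excluded if unmapped, secondary, supplementary, below
    ``min_mapq`` (samtools -q semantics: MAPQ < threshold is dropped) or from
    reads shorter than ``min_read_len`` nucleotides (the default keeps reads
    >30 nt).  Mean coverage is aligned bases divided by scaffold length;
    covered length is the number of positions with depth ≥ 1.  Every scaffold
    declared in the header is reported, including uncovered ones.
    """
    with pysam.AlignmentFile(str(path), "r") as sam:
        if sam.nreferences == 0:
            raise ValueError(f"{path}: SAM header declares no reference sequences")
        depth = {
            name: np.zeros(length, dtype=np.int32)
            for name, length in zip(sam.references, sam.lengths)
        }
        for read in sam:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.mapping_quality < min_mapq:
                continue
            qlen = read.query_length or read.infer_query_length() or 0
            if qlen < min_read_len:
                continue
            arr = depth[read.reference_name]
            for s, e in read.get_blocks():
                arr[s:e] += 1
    return [
        CoverageRecord(
            scaffold_id=name,
            sample_id=sample_id,
            mean_coverage=float(arr.sum()) / len(arr),
            covered_length=int((arr > 0).sum()),
        )
        for name, arr in depth.items()
    ]


def coverage_to_frame(records: Iterable[CoverageRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.scaffold_id, r.sample_id, r.mean_coverage, r.covered_length)
            for r in records
        ],
        columns=["scaffold_id", "sample_id", "mean_coverage", "covered_length"],
    )


# --------------------------------------------------------------------------
# TSV round-trips

_ORF_COLUMNS = ["orf_id", "scaffold_id", "start", "end", "strand", "aa_length"]


def read_orf_table(path: str | Path, min_aa: int = 50) -> list[OrfRecord]:
    """Read externally predicted ORFs from TSV, applying the ≥``min_aa``
    filter (so upstream callers need not have filtered)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(_ORF_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        OrfRecord(
            str(r.orf_id), str(r.scaffold_id), int(r.start), int(r.end),
            str(r.strand), int(r.aa_length),
        )
        for r in df.itertuples()
        if int(r.aa_length) >= min_aa
    ]


def write_orf_table(orfs: Iterable[OrfRecord], path: str | Path) -> None:
    pd.DataFrame(
        [(o.orf_id, o.scaffold_id, o.start, o.end, o.strand, o.aa_length) for o in orfs],
        columns=_ORF_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def write_evidence_table(evidence: pd.DataFrame, path: str | Path) -> None:
    evidence.to_csv(path, sep="\t", index=False)


def read_evidence_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "scaffold_id" not in df.columns and "contig_id" in df.columns:
        df = df.rename(columns={"contig_id": "scaffold_id"})
    missing = {"scaffold_id", "viral_orf_count", "cellular_match_count"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_coverage_table(records, path: str | Path) -> None:
    df = records if isinstance(records, pd.DataFrame) else coverage_to_frame(records)
    df.to_csv(path, sep="\t", index=False)


def read_coverage_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"scaffold_id", "sample_id", "mean_coverage"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df
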