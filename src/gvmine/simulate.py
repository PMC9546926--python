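"""Synthetic inputs for the giant-virus mining pipeline.

Real surveys of Nucleocytoviricota in soil start from multi-gigabase read
sets and curated genome databases that are impractical to ship or rebuild.
This module generates labeled stand-ins with the statistical structure the
downstream analysis assumes, so every stage can be exercised offline:

* simulated metagenomic contigs cut as non-overlapping fragments from source
  genomes, following a configurable (default truncated lognormal) length
  distribution — the way control databases for classifier calibration are
  built from reference genomes;
* planted chimeric contigs joining material from two distinct genomes, the
  ground truth for assembly QC;
* class-conditional viral-ORF and cellular-match counts per contig,
  emulating the two-population scatter that separates viral from cellular
  sequences;
* sample × taxon abundance matrices with planted monotone virus–eukaryote
  associations, the ground truth for co-occurrence statistics.

Every stochastic operation takes an explicit seed and is bit-reproducible.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .chimera import AlignmentMatch

__all__ = [
    "CLASS_LABELS",
    "Segment",
    "SourceGenome",
    "SimulatedContig",
    "LengthDistribution",
    "HitCountModel",
    "random_genome",
    "shred_genome",
    "plant_chimeras",
    "simulate_hit_counts",
    "simulate_abundance_matrix",
    "simulate_control_dataset",
    "truth_alignments",
    "spawn_seeds",
    "write_contigs_fasta",
    "write_truth_table",
    "write_manifest",
]

CLASS_LABELS = ("viral", "bacterial", "archaeal", "eukaryotic")
_ALPHABET = frozenset("ACGTN")


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Fan a run seed out into ``n`` independent child seeds (< 2**31)."""
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


@dataclass(frozen=True)
class Segment:
    """Half-open 0-based interval on a source genome."""

    genome_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad segment interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SourceGenome:
    """A reference genome a simulated contig can be cut from."""

    genome_id: str
    class_label: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("genome sequence must be non-empty")
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {self.class_label!r}")
        extra = set(self.sequence.upper()) - _ALPHABET
        if extra:
            raise ValueError(f"non-ACGTN characters in sequence: {sorted(extra)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SimulatedContig:
    """A simulated metagenomic contig with full provenance.

    ``is_chimera`` is true exactly when the segments come from two or more
    distinct source genomes; ``truth_class`` is the class of the first
    (majority) segment's genome.
    """

    contig_id: str
    segments: tuple[Segment, ...]
    truth_class: str
    is_chimera: bool

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("contig must have at least one segment")
        n_genomes = len({s.genome_id for s in self.segments})
        if self.is_chimera != (n_genomes >= 2):
            raise ValueError("is_chimera inconsistent with segment provenance")

    @property
    def length(self) -> int:
        return sum(s.length for s in self.segments)

    @property
    def source_genome_ids(self) -> tuple[str, ...]:
        seen: list[str] = []
        for s in self.segments:
            if s.genome_id not in seen:
                seen.append(s.genome_id)
        return tuple(seen)


@dataclass(frozen=True)
class LengthDistribution:
    """Contig length distribution, truncated to [min_len, max_len].

    The default is lognormal with log-mean 9.8 and log-sd 0.6 truncated to
    [10 kb, 200 kb]: the downstream analyses consider sequences of at least
    10 kb, and assembled giant-virus scaffolds rarely exceed a couple of
    hundred kb outside near-complete genomes.  An ``empirical`` family draws
    uniformly from a supplied pool of observed lengths instead.
    """

    family: str = "lognormal"
    log_mean: float = 9.8
    log_sd: float = 0.6
    min_len: int = 10_000
    max_len: int = 200_000
    lengths: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.family not in ("lognormal", "empirical"):
            raise ValueError(f"unknown length distribution family {self.family!r}")
        if self.min_len < 1 or self.max_len < self.min_len:
            raise ValueError("require 1 <= min_len <= max_len")
        if self.family == "empirical":
            if not self.lengths:
                raise ValueError("empirical family needs a pool of lengths")
            if any(not self.min_len <= x <= self.max_len for x in self.lengths):
                raise ValueError("empirical lengths outside [min_len, max_len]")

    def draw(self, rng: np.random.Generator) -> int:
        if self.family == "empirical":
            return int(rng.choice(self.lengths))
        # truncation by rejection; the default parameters accept >80% of draws
        for _ in range(10_000):
            x = rng.lognormal(self.log_mean, self.log_sd)
            if self.min_len <= x <= self.max_len:
                return int(x)
        return int(min(max(x, self.min_len), self.max_len))


def random_genome(
    genome_id: str, class_label: str, length: int, seed: int = 0
) -> SourceGenome:
    """Generate a uniform-random ACGT genome (no compositional signal; the
    class signal in this simulator lives in the hit counts, not the bases)."""
    rng = np.random.default_rng(seed)
    alphabet = np.frombuffer(b"ACGT", dtype="S1")
    seq = alphabet[rng.integers(0, 4, size=length)].tobytes().decode("ascii")
    return SourceGenome(genome_id, class_label, seq)


def shred_genome(
    genome: SourceGenome,
    dist: LengthDistribution | None = None,
    seed: int = 0,
) -> list[SimulatedContig]:
    """Cut a genome into non-overlapping simulated contigs.

    Fragments are taken left to right; each drawn length is capped by the
    remaining genome, and the final leftover shorter than ``dist.min_len`` is
    discarded.  A genome shorter than ``min_len`` yields an empty list with a
    warning.  Deterministic under ``seed``.
    """
    dist = dist or LengthDistribution()
    rng = np.random.default_rng(seed)
    total = len(genome)
    if total < dist.min_len:
        warnings.warn(
            f"genome {genome.genome_id} ({total} nt) shorter than "
            f"min_len={dist.min_len}; no contigs produced",
            stacklevel=2,
        )
        return []
    contigs: list[SimulatedContig] = []
    pos = 0
    while total - pos >= dist.min_len:
        n = min(dist.draw(rng), total - pos)
        contigs.append(
            SimulatedContig(
                contig_id=f"{genome.genome_id}_c{len(contigs) + 1}",
                segments=(Segment(genome.genome_id, pos, pos + n),),
                truth_class=genome.class_label,
                is_chimera=False,
            )
        )
        pos += n
    return contigs


def plant_chimeras(
    contigs: Sequence[SimulatedContig],
    rate: float,
    seed: int = 0,
    min_segment: int | None = None,
) -> list[SimulatedContig]:
    """Replace an expected fraction ``rate`` of contigs by two-genome joins.

    Each selected contig keeps a prefix of its own segment and is completed
    with material from a donor contig of a different source genome, so total
    contig count and per-contig length are preserved and ``is_chimera`` flags
    remain truthful.  The junction point is uniform over
    [min_segment, length − min_segment] so both halves are long enough to be
    recovered by the trim-and-retain QC rules; ``min_segment`` defaults to
    half the shortest input contig.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"rate must be in [0, 1], got {rate}")
    contigs = list(contigs)
    if rate == 0.0 or not contigs:
        return contigs
    if any(c.is_chimera for c in contigs):
        raise ValueError("input contigs must be single-genome (is_chimera False)")
    genomes = {c.segments[0].genome_id for c in contigs}
    if len(genomes) < 2:
        raise ValueError("planting chimeras requires at least two source genomes")
    if min_segment is None:
        min_segment = min(c.length for c in contigs) // 2

    rng = np.random.default_rng(seed)
    flags = rng.random(len(contigs)) < rate
    by_genome: dict[str, list[int]] = {}
    for i, c in enumerate(contigs):
        by_genome.setdefault(c.segments[0].genome_id, []).append(i)

    out: list[SimulatedContig] = []
    for i, contig in enumerate(contigs):
        if not flags[i]:
            out.append(contig)
            continue
        own_genome = contig.segments[0].genome_id
        donor_pool = [j for g, idx in by_genome.items() if g != own_genome for j in idx]
        donor = contigs[int(rng.choice(donor_pool))]
        L = contig.length
        lo = max(min_segment, L - donor.length)
        hi = L - min_segment
        if lo > hi:  # contig too short to host two recoverable halves
            out.append(contig)
            continue
        junction = int(rng.integers(lo, hi + 1))
        own = contig.segments[0]
        dseg = donor.segments[0]
        out.append(
            SimulatedContig(
                contig_id=contig.contig_id,
                segments=(
                    Segment(own.genome_id, own.start, own.start + junction),
                    Segment(dseg.genome_id, dseg.start, dseg.start + (L - junction)),
                ),
                truth_class=contig.truth_class,
                is_chimera=True,
            )
        )
    return out


@dataclass(frozen=True)
class HitCountModel:
    """Class-conditional rates for viral-ORF and cellular-match counts.

    Rates are counts per kilobase of contig; the expected count of a contig
    scales linearly with its length.  Counts are Poisson, or negative
    binomial (gamma-mixed Poisson) when ``dispersion`` is finite — count
    overdispersion is the norm in metagenomic hit data.  ``dispersion`` is
    the gamma shape: variance = m + m²/dispersion, Poisson as it → ∞.
    """

    viral_rate_per_kb: Mapping[str, float]
    cellular_rate_per_kb: Mapping[str, float]
    dispersion: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for rates in (self.viral_rate_per_kb, self.cellular_rate_per_kb):
            if any(r < 0 for r in rates.values()):
                raise ValueError("rates must be non-negative")
        if self.dispersion is not None and self.dispersion <= 0:
            raise ValueError("dispersion must be positive (or None for Poisson)")

    @staticmethod
    def well_separated(seed: int = 0, dispersion: float | None = None) -> "HitCountModel":
        """The default two-population setting: viral contigs carry 5
        viral-ORF matches and 1 cellular match per 10 kb, cellular contigs
        0.05 viral-ORF matches and 20 cellular matches per 10 kb."""
        return HitCountModel(
            viral_rate_per_kb={
                "viral": 0.5,
                "bacterial": 0.005,
                "archaeal": 0.005,
                "eukaryotic": 0.005,
            },
            cellular_rate_per_kb={
                "viral": 0.1,
                "bacterial": 2.0,
                "archaeal": 2.0,
                "eukaryotic": 2.0,
            },
            dispersion=dispersion,
            seed=seed,
        )


def _sample_counts(
    rng: np.random.Generator, means: np.ndarray, dispersion: float | None
) -> np.ndarray:
    if dispersion is None or math.isinf(dispersion):
        return rng.poisson(means)
    lam = rng.gamma(shape=dispersion, scale=means / dispersion)
    return rng.poisson(lam)


def simulate_hit_counts(
    contigs: Sequence[SimulatedContig], model: HitCountModel
) -> pd.DataFrame:
    """Draw per-contig evidence counts from the class-conditional model.

    Returns a table with columns ``contig_id, length, truth_class,
    is_chimera, n_orfs, viral_orf_count, cellular_match_count``; ``n_orfs``
    (total predicted ORFs, roughly one per kb plus the viral matches) is
    plumbing for the classifier's proportions mode.
    """
    classes = {c.truth_class for c in contigs}
    for rates, name in (
        (model.viral_rate_per_kb, "viral"),
        (model.cellular_rate_per_kb, "cellular"),
    ):
        missing = sorted(classes - set(rates))
        if missing:
            raise ValueError(f"no {name} hit rate defined for class(es): {missing}")

    rng = np.random.default_rng(model.seed)
    kb = np.array([c.length for c in contigs], dtype=float) / 1000.0
    v_rate = np.array([model.viral_rate_per_kb[c.truth_class] for c in contigs])
    c_rate = np.array([model.cellular_rate_per_kb[c.truth_class] for c in contigs])
    viral = _sample_counts(rng, v_rate * kb, model.dispersion)
    cellular = _sample_counts(rng, c_rate * kb, model.dispersion)
    other_orfs = rng.poisson(0.9 * kb)
    return pd.DataFrame(
        {
            "contig_id": [c.contig_id for c in contigs],
            "length": [c.length for c in contigs],
            "truth_class": [c.truth_class for c in contigs],
            "is_chimera": [c.is_chimera for c in contigs],
            "n_orfs": np.maximum(viral + other_orfs, 1),
            "viral_orf_count": viral,
            "cellular_match_count": cellular,
        }
    )


def simulate_abundance_matrix(
    taxa: Sequence[str],
    planted_pairs: Sequence[tuple[str, str, float]] = (),
    n_samples: int = 11,
    seed: int = 0,
    log_sd: float = 1.0,
) -> pd.DataFrame:
    """Sample × taxon abundance matrix with planted monotone associations.

    Abundances are lognormal.  Each planted pair ``(virus, eukaryote,
    strength)`` rewrites the virus column as a Gaussian-copula mixture of the
    eukaryote column with correlation ``strength``; at strength ±1 the two
    columns are exact monotone transforms of each other (identical/reversed
    ranks), while non-planted taxa stay mutually independent.  The default of
    11 samples matches a realistic small soil survey.
    """
    taxa = list(taxa)
    if len(set(taxa)) != len(taxa):
        dupes = sorted({t for t in taxa if taxa.count(t) > 1})
        raise ValueError(f"duplicate taxon names: {dupes}")
    if n_samples < 3:
        raise ValueError("need at least 3 samples")
    index = {t: i for i, t in enumerate(taxa)}
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_samples, len(taxa)))
    for virus, euk, strength in planted_pairs:
        if not -1.0 <= strength <= 1.0:
            raise ValueError(f"association strength must be in [-1, 1], got {strength}")
        if virus == euk:
            raise ValueError("a planted pair must involve two distinct taxa")
        iv, ie = index[virus], index[euk]
        eps = rng.standard_normal(n_samples)
        z[:, iv] = strength * z[:, ie] + math.sqrt(1.0 - strength**2) * eps
    abundance = np.exp(log_sd * z)
    return pd.DataFrame(
        abundance,
        index=[f"sample_{i + 1:02d}" for i in range(n_samples)],
        columns=taxa,
    )


def simulate_control_dataset(
    n_per_class: int = 500,
    seed: int = 0,
    dist: LengthDistribution | None = None,
    model: HitCountModel | None = None,
    genome_length: int = 3_000_000,
    class_labels: Sequence[str] = CLASS_LABELS,
) -> tuple[pd.DataFrame, list[SimulatedContig]]:
    """Build a labeled control evidence set the way calibration databases
    are built: shred per-class source genomes into simulated contigs, then
    draw class-conditional hit counts for each contig.

    Returns ``(evidence, contigs)`` where ``evidence`` is the table produced
    by :func:`simulate_hit_counts` with exactly ``n_per_class`` contigs per
    class.  All randomness fans out from ``seed``.
    """
    dist = dist or LengthDistribution()
    seeds = spawn_seeds(seed, len(class_labels) + 1)
    contigs: list[SimulatedContig] = []
    for label, class_seed in zip(class_labels, seeds):
        genome_seeds = iter(spawn_seeds(class_seed, 256))
        collected: list[SimulatedContig] = []
        g = 0
        while len(collected) < n_per_class:
            g += 1
            if g > 128:
                raise RuntimeError("genome budget exhausted; increase genome_length")
            gseed = next(genome_seeds)
            genome = random_genome(f"{label}_g{g}", label, genome_length, seed=gseed)
            collected.extend(shred_genome(genome, dist, seed=next(genome_seeds)))
        contigs.extend(collected[:n_per_class])
    if model is None:
        model = HitCountModel.well_separated(seed=seeds[-1])
    return simulate_hit_counts(contigs, model), contigs


def truth_alignments(
    contigs: Iterable[SimulatedContig], score_per_nt: float = 2.0
) -> list[AlignmentMatch]:
    """Idealized aligner output derived from contig provenance: one perfect
    full-length match per segment, for validating the chimera QC rules."""
    out = []
    for contig in contigs:
        offset = 0
        for seg in contig.segments:
            out.append(
                AlignmentMatch(
                    query_id=contig.contig_id,
                    reference_genome_id=seg.genome_id,
                    qstart=offset + 1,
                    qend=offset + seg.length,
                    percent_identity=100.0,
                    score=score_per_nt * seg.length,
                    evalue=0.0,
                )
            )
            offset += seg.length
    return out


def contig_sequence(
    contig: SimulatedContig, genomes: Mapping[str, SourceGenome]
) -> str:
    return "".join(
        genomes[s.genome_id].sequence[s.start : s.end] for s in contig.segments
    )


def write_contigs_fasta(
    contigs: Iterable[SimulatedContig],
    genomes: Mapping[str, SourceGenome],
    path: str | Path,
) -> None:
    from Bio import SeqIO

    records = (
        SeqRecord(
            Seq(contig_sequence(c, genomes)),
            id=c.contig_id,
            description=f"class={c.truth_class} chimera={c.is_chimera}",
        )
        for c in contigs
    )
    SeqIO.write(records, str(path), "fasta")


def write_truth_table(contigs: Iterable[SimulatedContig], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("contig_id\tlength\ttruth_class\tis_chimera\tsegments\n")
        for c in contigs:
            segs = ";".join(f"{s.genome_id}:{s.start}-{s.end}" for s in c.segments)
            fh.write(f"{c.contig_id}\t{c.length}\t{c.truth_class}\t{c.is_chimera}\t{segs}\n")


def write_manifest(path: str | Path, **params) -> None:
    """Record seeds and generator parameters alongside the outputs."""
    with open(path, "w") as fh:
        yaml.safe_dump(params, fh, sort_keys=True)
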