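# Methods

## Problem and overall design

Giant viruses (phylum *Nucleocytoviricota*, historically NCLDV) are large
double-stranded DNA viruses of eukaryotes.  In soil metagenomes their
assembled scaffolds are a needle in a bacterial haystack, and the classical
bait — the major capsid protein — misses the non-icosahedral families
(*Pithoviridae*, *Pandoraviridae*).  `gvmine` implements the
evidence-counting alternative: score every scaffold by two numbers, the
count of distinct ORFs matching a *Nucleocytoviricota*-specific profile
collection and the count of protein-similarity matches against a cellular
reference database, and separate the two populations with a straight line
in that plane.

The package deliberately stops at well-defined seams.  Upstream tools
(assembler, binner, mapper, gene caller, hmmsearch, DIAMOND, BLASTN)
produce its input files; downstream tools (aligners, tree builders) consume
its exported marker sets.  Everything in between — filtering, counting,
classification, calibration, chimera QC, paralog suppression, abundance and
co-occurrence statistics — is implemented and tested here, together with a
synthetic-data generator that reproduces the statistical structure of the
inputs so the full pipeline runs offline.

## Evidence counting (`gvmine.evidence`)

* ORFs: six-frame stop-to-stop extraction under the standard genetic code,
  no start codon required, keeping ORFs ≥ 50 amino acids.  This is plumbing
  for when no external gene caller output exists; ORF tables from real gene
  callers can be supplied instead and pass through the same ≥50 aa filter.
  A stop-to-stop fragment translating entirely to ambiguous residues (runs
  of N) is not an ORF, so an all-N scaffold yields none.
* Viral matches: profile hits are kept at E ≤ 1e-10 (best hit per ORF and
  profile), and the per-scaffold viral count is the number of **distinct**
  ORFs with at least one qualifying hit — an ORF matching five profiles
  counts once.
* Cellular matches: similarity hits are kept at identity ≥ 35% and
  E ≤ 1e-5, restricted to subjects from Bacteria, Archaea and Eukaryota
  (a 13th column or a sidecar subject→domain map; unknown domains are
  dropped with a warning).  The per-scaffold cellular count is the number
  of qualifying hit **rows**, optionally capped per ORF (default 25)
  because raw row counts inherit the upstream search tool's reporting
  limit; a distinct-ORF mode is available when that limit is unknown.
* Threshold semantics are inclusive (≤ E, ≥ identity) and configurable;
  sources differ on strict-vs-inclusive at exactly the cutoff, and the
  difference only matters for hits exactly at the boundary.
* Coverage from SAM: alignments below MAPQ 3, reads ≤ 30 nt, and
  secondary/supplementary/unmapped records are excluded.  Mean coverage is
  aligned bases over scaffold length; covered length counts positions with
  depth ≥ 1.

## Classification and calibration (`gvmine.classify`)

A scaffold with viral count v and cellular count c is called
*Nucleocytoviricota* iff

    v > slope · c + intercept

with **strict** inequality: points on the line are excluded.  The reference
operating point is slope = 0.1, intercept = 1.  A proportions mode divides
both counts by the scaffold's ORF count first; it is kept as a non-default
alternative because it has not been observed to improve separation.

Calibration is an exhaustive grid search (defaults: slope 0–0.5 step 0.01,
intercept 0–10 step 0.5) over a labeled control set built like the real
control databases: reference genomes shredded into simulated contigs.  A
grid point is feasible iff its **eukaryotic** false-positive rate is
strictly below 1% (so 1 FP in 100 eukaryotic contigs fails); among feasible
points the one maximizing sensitivity wins, with ties broken toward the
more conservative boundary (higher intercept, then higher slope).  The
two-parameter problem is small enough that exhaustive search is exact and
auditable; the eukaryotic class alone is constrained because eukaryotic
contamination is the failure mode a giant-virus catalog can least afford,
while bacterial/archaeal FP rates are reported but unconstrained.

Performance is reported as sensitivity over viral records and one
specificity per non-viral class, with exact confusion counts.
Contamination post-filters consume externally produced flags (rRNA
detected, manual exclusion); they only ever remove scaffolds, every removal
is logged with a reason, and endogenization flags annotate without
removing.

## Chimera QC (`gvmine.chimera`)

Assemblies are validated against reference genomes through near-perfect
nucleotide alignments (identity ≥ 99.99%).  Matches are processed in
descending score order (ties: ascending E-value, ascending query start,
reference id); each match loses the query intervals already claimed by
previously **retained** segments, and each surviving fragment is kept iff
≥ 500 nt, each fragment tested independently.  A query whose retained
segments name ≥ 2 reference genomes is chimeric; a query with no retained
segment is unassessed and excluded from the default denominator (an
unaligned sequence carries no evidence either way), but the report also
carries the proportion over all queries since published chimera rates do
not always state their denominator.  At the bin level a bin is chimeric if
its contigs' retained segments jointly span ≥ 2 genomes, and single-contig
bins are excluded because they carry no binning information.

## Marker genes (`gvmine.markers`)

Seven default markers (DNA polymerase B, the two largest RNA polymerase
subunits, VLTF3, the major capsid protein, the A32 packaging ATPase, the D5
primase); TFIIS is excluded by default because its phylogeny breaks
well-established clades.  Hits enter at an initial cutoff of E ≤ 1e-5.
Per marker, the stringent threshold is the first quartile of the ascending
rank-2 (second-best copy) E-values over scaffolds with multiple copies,
computed as the nearest-rank order statistic at index ⌈n/4⌉ — a scale-free
choice; interpolating on raw E-values spanning 40 orders of magnitude would
be dominated by the largest values.  An interpolated quartile on log10(E)
is available as an alternative.  A marker with no multi-copy scaffold falls
back to the initial cutoff (no paralog evidence, no extra stringency).
Only the best hit per (scaffold, marker) is exported, and only if strictly
below the marker's stringent threshold.  Scaffolds then partition into a
≥3-marker high-confidence set (for concatenated trees, robust to split
genomes) and a ≥1-marker extended set; the presence/absence matrix is
emitted alongside.

Whether "second matches" pool per marker (as here) or across markers is an
open convention; pooling per marker keeps thresholds comparable to the
per-marker selection they gate.

## Abundance and co-occurrence (`gvmine.abundance`)

Relative abundance of a group in a sample = Σ mean coverage of the group's
scaffolds ≥ 10 kb ÷ Σ mean coverage of **all** scaffolds ≥ 10 kb in the
sample.  Group ratios use the sample (n−1) standard deviation and flag and
exclude zero-denominator samples.

Co-occurrence: a virus–eukaryote pair is tested iff each member is
non-zero in ≥ 2 samples; the Spearman correlation is then computed over
all samples, zeros included (excluding zeros would silently change n per
pair).  p-values come from the t-approximation for n ≥ 10 and from exact
tie-aware enumeration of all pairings for n < 10; both are selectable.
The BH correction treats all tested pairs of a run as one family; pairs
with a constant abundance vector are reported but excluded from the
family.  Presence for cross-sample sharing requires strictly more than
10 kb covered at MAPQ ≥ 30, and the sharing matrix counts scaffolds
present in each sample pair.

## Synthetic data (`gvmine.simulate`)

What it emulates: (a) control-database construction — genomes shredded
into non-overlapping contigs, left to right, with lengths drawn from a
lognormal (log-mean 9.8, log-sd 0.6) truncated to [10 kb, 200 kb], i.e.
median ≈ 18 kb, matching the ≥ 10 kb analysis regime (the true empirical
length distribution of any given survey is not reconstructible, so this is
a configurable stand-in, including an empirical-pool family); (b) the
two-population evidence scatter, with per-kb class-conditional rates —
defaults: viral contigs 0.5 viral-ORF and 0.1 cellular matches per kb,
cellular contigs 0.005 viral-ORF and 2 cellular matches per kb — drawn
Poisson, or negative-binomial (gamma-mixed Poisson) when overdispersion is
requested, since overdispersion is the norm in real hit counts;
(c) planted chimeras: a Bernoulli-selected fraction of contigs is replaced
by two-genome joins with the junction uniform over
[min_len/2, L − min_len/2] so both halves exceed the 500 nt retention rule
and planted labels are recoverable by construction; (d) abundance matrices
(default 11 samples) with lognormal marginals and Gaussian-copula planted
virus–eukaryote associations: at strength ±1 the pair's ranks are exactly
identical/reversed, and non-planted taxa stay independent.

What it does **not** emulate: raw reads, base-calling error, assembly
graphs, compositional (k-mer) signal, database incompleteness, or the
correlated hit structure of real homology searches.  Passing tests
therefore demonstrate that the *rules* are implemented exactly and that
the statistical machinery recovers planted truth under its own
assumptions — not that the operating point (0.1, 1) or the published
performance numbers transfer to any particular real survey, which depends
on the profile collection and control database actually used.

Every stochastic operation takes an explicit seed; run seeds fan out via
`numpy.random.SeedSequence.spawn`, so all outputs are bit-reproducible.

## Numerical and degenerate-case choices

* Strictness: classification (`>`), marker selection ("better than" = `<`),
  presence (`>` 10 kb covered) and the eukaryotic FP cap (`<` 1%) are
  strict; evidence filters (≤ E, ≥ identity, ≥ 50 aa, ≥ 10 kb length,
  ≤ 1.1 mean copies) are inclusive.  All are configurable.
* Deterministic tie-breaks everywhere a sort feeds a decision (match
  trimming, marker ranking, calibration), so permuting input rows never
  changes output.
* Zero cases: empty hit files warn and return empty; a genome shorter than
  the minimum contig length warns and yields nothing; a marker with no
  paralog evidence falls back to the initial cutoff; a sample with zero
  total coverage is an error rather than a silent NaN row.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic or
hand-written data: an exhaustive 1001×1001 integer grid for boundary
exactness, 50 random 500-record sets for calibration-oracle equivalence,
2,000 contigs (500 per class) for end-to-end recovery, 1,000 contigs with
5% planted chimeras for QC recovery, 1,000 random instances per statistic
oracle, and a hand-computed 12-scaffold worked example for filter
bookkeeping.  These sizes were chosen so each property is measured with
comfortable statistical margin while the whole suite stays fast enough to
run on every change.
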