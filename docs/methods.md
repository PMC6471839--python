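# Methods

This note documents the models, rules and numerical choices behind each
pipeline stage, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Target-decoy FDR filtering

Every target protein has a reversed-sequence decoy twin in the database.
A PSM is a *decoy hit* when all of its matched accessions are decoys.
The estimator is the classical ratio `FDR(t) = n_decoy(t) / max(n_target(t), 1)`
over PSMs with score ≥ t; we deliberately use the simple ratio rather
than 2d/(t+d), as the conservative classical choice. The filter scans
candidate thresholds (the observed scores, ascending) and keeps the
lowest threshold meeting the target (default α = 0.016); decoy PSMs are
then removed from the retained set. If no threshold qualifies the
retained set is empty and a warning is logged — this is a data statement,
not an error.

The α is applied at PSM level. An *achieved* protein-level FDR — decoy
protein groups over reported target groups at the same threshold — is
written to the run manifest for QC. Note that with decoy hits spread
thinly over many decoy sequences this group-count ratio is a very
pessimistic summary (each stray decoy PSM founds its own "group" while
target groups are parsimony-collapsed); probabilistic protein-level
scoring is out of scope.

## Parsimony protein inference

Three deterministic steps over the retained peptides:

1. proteins with identical observed-peptide sets merge into one group
   (they are indistinguishable on the evidence);
2. groups whose peptide set is a strict subset of another group's are
   removed — their peptides remain explained;
3. greedy set cover over the remaining groups: repeatedly take the group
   covering the most uncovered peptides, breaking ties by
   lexicographically smallest member accession so runs are reproducible.

Greedy set cover is within the usual logarithmic factor of optimal; on
random instances with ≤10 proteins the tests verify it is within one
group of the exhaustive minimum, and that step 2 exactly equals a
maximal-antichain oracle. Spectral counts are then assigned per subject:
one count per PSM to *every* reported group containing its peptide —
shared peptides count in each covering group, because uniqueness is
handled downstream independently per level.

## Metaclustering

Protein groups are joined by an edge when (a) two member proteins share a
characterized gene name (case-insensitive), (b) their peptide sets
intersect (minimum shared-peptide count configurable, default 1), or (c)
two members share a UniRef50 id. Metaclusters are the connected
components under the union of these relations — "and/or" is read as
transitive closure, since mixed chains (gene edge then UniRef edge) are
unavoidable and a single partition is needed for accounting.

Rules and consequences:

- **Characterized gene names.** A gene name is characterized when
  non-empty and not matching the auto-locus-tag pattern
  `^[A-Z]{1,4}_?\d{3,}$` (configurable). Locus tags neither form edges
  nor count as useful annotation.
- **Host/microbial separation.** The two strata are clustered
  independently, so host peptide evidence never bridges into bacterial
  clusters; a metacluster mixing the strata is rejected at accounting
  time. A short tryptic peptide can still occur, by sequence coincidence,
  in both a host and a microbial protein; such cross-stratum peptides are
  assigned to the microbial metacluster only (host is treated as
  contaminant background), which keeps the peptide→metacluster map a
  function and spectral counts conserved.
- **Counting.** Because shared-peptide edges are absorbed into
  components, each peptide belongs to exactly one metacluster and each
  spectrum contributes exactly one count; column sums of the metacluster
  count matrix equal the retained spectrum count (asserted on every run).
- The accounting table stratifies spectra, distinct peptide sequences and
  metacluster counts by source (bacterial/human) and annotation status.
  At real-study scale such tables can carry internal tensions (abstracts
  rounding differently than strata sums — e.g. a published total of 2154
  vs strata summing to 2134); this package always reports strata sums.

## Per-rank taxonomic profiling

Uniqueness is evaluated against the full non-decoy database — possible
assignment, not the parsimonious list. Unique-at-rank-r implies unique at
every coarser rank, so per-subject totals grow monotonically from strain
to family (asserted). Host-unique peptides are excluded from microbial
profiles (optionally reported as a separate `host` QC row). Derived
views: strain detection tiers (strains with ≥1/≥2/≥5 unique spectra per
subject), species rollups by summing strain counts (optionally restricted
to one genus and normalized), and an abundant-strain filter (default:
≥20 spectra in at least one subject).

## Community comparison

The proteomic genus profile and the 16S read-count table are aligned on
the union of taxa (zeros where one method misses a taxon), optionally
after collapsing the *Enterobacteriaceae* genera into one family row —
16S often cannot resolve genera within that family. Spearman and Pearson
coefficients are computed over the flattened taxon × subject cells of raw
counts (log-free; a log1p option exists), with average ranks for ties;
"unknown/others" rows are excluded by default. Pairwise subject
comparisons use Pearson r over metaclusters detected in at least one of
the two subjects (union support). Fewer than 3 paired observations, or a
constant vector, is an error rather than a NaN.

## Pathway contrasts

Only metaclusters with useful annotation join pathways, via an offline
two-column gene→pathway table (no web service; the synthetic generator
emits a three-pathway table over its generated gene names). Metacluster
counts enter with peptide redundancy removed at genus level: within a
metacluster, a peptide matching several proteins of the same genus
contributes its spectra once per genus, never once per protein. For a
treated-vs-untreated contrast, each member feature reports the treated
count (sum if several treated subjects) against the untreated mean ± SD
(n−1 denominator); a member is "higher"/"lower" outside the ±1 SD band,
and the pathway verdict requires a strict majority (default >50%) of
members to agree. The band-and-majority rule is this package's own
operationalization — published figure classifications rarely state a
machine rule — and is configuration-exposed.

## Synthetic-data generator

What it emulates: a multi-subject infant gut community with strain-level
structure (default preset: eight subjects, most *Bifidobacterium*-
dominated with subject-specific species emphasis, one identical-profile
twin pair, one *Enterobacteriaceae*-dominated antibiotic-treated subject,
host spectra at 18% of the total); cross-taxon homolog families
(UniRef50-like, members ≥80% identical by point mutation of a family
template, sharing most tryptic peptides); characterized gene names on a
configurable fraction of families (default 0.54, matching typical useful-
annotation rates); reversed decoys for every target; tryptic digestion
with up to 2 missed cleavages, peptide length 6–30; Gaussian search
scores (targets μ=60, decoys μ=30, σ=8 — arbitrary units, only the
separation matters); decoy hits at 5% of spectra, so the 1.6% FDR filter
genuinely operates on a raw stream; 16S genus reads as multinomial draws
of truth × lognormal noise (σ = 0.3 log-units by default).

What it does not emulate: real spectra, m/z, retention times or
modifications; peptide detectability/ionization bias; database
incompleteness (every sampled peptide exists in the searched database);
protein length effects (peptides are drawn uniformly per protein
regardless of length); chimeric reads or primer bias in 16S. Passing
recovery tests therefore demonstrates correctness of the counting and
inference logic under the stated sampling model, not robustness to those
real-data artifacts.

A known mild bias: peptides shared across genera are discarded at genus
rank, and the discarded fraction differs between genera (large
multi-strain genera lose more), so genus-profile fractions deviate from
truth by up to ~2 percentage points at 20,000 spectra per subject even
without noise.

## Problem sizes and numerics

Tests run the full pipeline at 2,000 spectra × 8 subjects (unit scale)
and 20,000 spectra × 8 subjects (recovery scale); the twin-ordering
property uses 100 replicate studies of five subjects at 2,000 spectra
each. The acceptance script uses the full preset at 20,000 spectra per
subject. All randomness flows through numpy Generators seeded from the
user seed plus fixed stream offsets, so identical spec + seed yields
byte-identical FASTA/TSV/JSON outputs. Scores are rounded to 4 decimals
on write; thresholds compare with ≥ so round-tripping does not change
filter decisions. Ties in greedy cover and cluster ids resolve by
lexicographic accession order.

## Limitations

- No probabilistic protein inference or LCA-style fractional assignment
  of shared peptides; counts are raw spectral counts without length or
  proteome-size normalization.
- Pathway verdicts carry no significance statistics (no p-values); they
  are descriptive bands, suited to small cohorts where formal testing
  would be underpowered anyway.
- The metacluster relation is sensitive to annotation quality: absent
  gene names and UniRef ids fragment clusters (monotonicity under
  annotation enrichment is tested — adding ids can only merge, never
  split).
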