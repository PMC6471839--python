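# metaproteo

Spectral-count metaproteomics of microbial communities: from
peptide-spectrum matches (PSMs) to taxonomic profiles, cross-species
protein "metaclusters", and pathway-level comparisons between subjects.

## The problem

Shotgun metaproteomics of a stool sample identifies tens of thousands of
tandem-MS spectra against a database spanning hundreds of bacterial
strains plus host proteins. Turning those identifications into biology
poses three coupled problems that this package solves downstream of the
search engine:

1. **Confidence.** Search scores must be filtered against a reversed-decoy
   database to control the false discovery rate (FDR), and the observed
   peptides explained by the *simplest* list of proteins (parsimony
   inference), because high inter-protein homology makes most peptides
   ambiguous.
2. **Taxonomy.** A peptide only carries taxonomic signal at the rank where
   it is *unique*: a peptide found in two strains of one species says
   nothing at strain rank but still counts at species rank. Uniqueness is
   therefore evaluated independently per rank (strain, species, genus,
   family), and spectral counts of unique peptides build the abundance
   profile at each rank.
3. **Function.** Homologous proteins from different taxa are merged into
   **metaclusters** — connected components of protein groups linked by a
   shared characterized gene name, shared peptide evidence, or a shared
   UniRef50 cluster id — so the community can be compared across subjects
   as a set of common functional features, and mapped onto metabolic
   pathways through a gene-to-pathway table.

A synthetic-data module generates complete study inputs (protein FASTA
with decoys, per-subject PSM tables, a 16S genus read-count table, a
pathway table) from a declarative community specification with retained
ground truth, so every stage is testable as a parameter-recovery problem.
The default preset emulates an eight-infant cohort: *Bifidobacterium*-
dominated subjects, a monozygotic twin pair with identical communities,
one *Enterobacteriaceae*-dominated antibiotic-treated subject, and ~18%
host-protein spectra.

## Core definitions

- Spectral count of a feature f in subject s:
  `SC(f, s) = #{spectra whose peptide is assigned to f in s}`.
- Target-decoy FDR at score threshold t:
  `FDR(t) = #decoy PSMs ≥ t / max(#target PSMs ≥ t, 1)`; the filter keeps
  the lowest t with `FDR(t) ≤ α` (default α = 0.016) and discards decoys.
- Parsimony inference: merge proteins with identical observed peptide
  sets, drop groups whose evidence is a strict subset of another's, then
  greedy set cover (largest uncovered-peptide count first, deterministic
  ties).
- Metaclusters: connected components under the union of the three
  relations above, computed separately for host and microbial proteins.
- Per-rank uniqueness: peptide p is unique at rank r iff all non-decoy
  database proteins containing p share one taxon at r.

## Worked example

```python
import metaproteo as mp

spec, taxonomy = mp.default_community(seed=42, depth=5000)
proteomes = mp.synthesize_proteomes(
    taxonomy, spec.proteins_per_strain, spec.homolog_family_count,
    spec.gene_annotation_rate, spec.seed)
db = mp.ProteinDatabase(proteomes)
psms_by_subject, truth = mp.sample_psms(spec, db, taxonomy)
psms = [p for rows in psms_by_subject.values() for p in rows]

retained, fdr = mp.fdr_filter(psms, db, target_fdr=0.016)
groups = mp.infer_protein_groups(retained, db)
clusters = mp.build_metaclusters(groups, db)
counts = mp.count_metacluster_spectra(clusters, retained)
print(f"retained {len(retained)}/{len(psms)} PSMs at FDR {fdr.fdr:.4f}")
print(f"{len(groups)} protein groups -> {len(clusters)} metaclusters")

twins = mp.pairwise_metacluster_correlation(counts, "M", "N")
anti = mp.pairwise_metacluster_correlation(counts, "R", "C")
print(f"twin pair M-N:       r^2 = {twins.r_squared:.2f}")
print(f"antibiotic pair R-C: r^2 = {anti.r_squared:.2f}")

reads = mp.sample_16s(truth, read_depth=20000,
                      noise_sd_16s=spec.noise_sd_16s, seed=spec.seed)
genus = mp.build_rank_profile(retained, db, "genus").matrix
entero = ("Klebsiella", "Escherichia", "Citrobacter")
res = mp.cross_method_correlation(
    mp.merge_family(genus, "Enterobacteriaceae", entero),
    mp.merge_family(reads, "Enterobacteriaceae", entero))
print(f"proteomics vs 16S: Spearman {res.spearman_rho:.3f}, "
      f"Pearson {res.pearson_r:.3f}")
```

Output:

```
retained 37986/40000 PSMs at FDR 0.0160
790 protein groups -> 161 metaclusters
twin pair M-N:       r^2 = 0.85
antibiotic pair R-C: r^2 = 0.28
proteomics vs 16S: Spearman 0.856, Pearson 0.986
```

The FDR filter lands exactly on the 1.6% target; the identical-community
twins correlate far more strongly at the metacluster level than the
antibiotic-treated subject does against a normal subject; and the genus
profile agrees with the (noisy) simulated 16S counts after collapsing the
*Enterobacteriaceae* genera into their family.

## Command line

```
metaproteo simulate --outdir run/inputs --seed 3 --depth 20000
metaproteo infer --psms run/inputs/psms_all.tsv \
    --db run/inputs/database.fasta --fdr 0.016 --outdir run/out
metaproteo run-all --outdir run --seed 3     # every stage + reports
```

`run-all` writes the accounting table (spectra / distinct peptides /
metaclusters by source and annotation status), strain detection tiers
(strains with ≥1/≥2/≥5 unique spectra per subject), per-rank profiles,
metacluster counts, correlation tables, pathway contrasts and a run
manifest.

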