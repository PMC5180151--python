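# edna

A desk-scale pipeline for **eDNA metabarcoding community bioassessment**:
from tagged COI amplicon reads to molecular operational taxonomic units
(MOTUs), taxonomy, community statistics and habitat-signature
classification — together with a ground-truthed synthetic-data generator
so that every stage is testable without sequencing data.

## Who this is for

Freshwater ecologists and molecular-ecology methods developers who want a
transparent, fully tested reference implementation of the standard
metabarcoding analysis chain used to compare whole metazoan communities
between water bodies from environmental DNA.

## What it computes

The pipeline emulates a two-reservoir study design (2 habitats × 7 sites
× 2 depths × 5 replicate PCRs per water sample; 313-bp COI amplicons
framed by degenerate metazoan primers and 9-bp sample tags) and runs:

1. **Demultiplexing** by exact 9-bp tag pairs, degenerate-primer trimming
   (IUPAC semantics, inosine as N).
2. **Retention filtering**: amplicon length; abundance-ratio error
   pruning within each PCR replicate; best-hit identity prescreen
   (discard if best metazoan identity < 80% or best hit non-metazoan);
   mitochondrial translation check (a frame must be stop-free under the
   vertebrate *or* invertebrate code — they differ at AGA/AGG); and the
   replicate-consistency rule keeping sequences seen in ≥ 3 of 5
   replicate PCRs.
3. **MOTU delimitation** by objective clustering: sequences share a MOTU
   iff chained by uncorrected pairwise distances *p* ≤ *t* (single
   linkage; default *t* = 0.03), with a stability scan over thresholds.
4. **Taxonomy** by identity bands against a reference barcode set:
   species when identity ≥ 97% *and* overlap ≥ 310 bp; phylum-level flag
   for 90–97%; otherwise retained unidentified.
5. **Community statistics**: sample-based accumulation curves, Chao2

   `S_Chao2 = S_obs + ((m−1)/m) · Q₁²/(2Q₂)`

   and ICE incidence-based richness estimators, Jaccard / Morisita–Horn /
   Renkonen (dis)similarities, non-metric multidimensional scaling
   (Kruskal stress-1), and Spearman ρ against survey abundances.
6. **Habitat signatures**: binary reference profile per habitat
   (1 iff a MOTU occurs in ≥ 1 of its samples), Jaccard dissimilarity of
   every sample profile to every habitat profile, nearest-profile
   assignment, and a two-sided Mann–Whitney U comparison of own- vs
   other-habitat dissimilarities.
7. **Survey comparison**: detection fractions of eDNA vs conventional
   checklists, site-by-site tables, percent excess richness.

## Worked example

```python
from edna import generate_species_pool, simulate_reads
from edna.seqio import tag_lookup_from_design
from edna.pipeline import run_reads_pipeline

pool = generate_species_pool(n_a_only=8, n_b_only=6, n_shared=4, seed=3)
reads, truth = simulate_reads(pool, depth_per_replicate=60, seed=3)
res = run_reads_pipeline(
    reads,
    tag_lookup_from_design(pool.design.tag_map),
    pool.reference_records(),
    pool.design.metadata(),
)
```

prints (via the snippet in `docs/methods.md`):

```
reads: 8400
MOTUs: 18
threshold scan: {0.02: 18, 0.03: 18, 0.04: 18}
species-level assignments: 18
Bedok: S_obs=12 Chao2=12.0 ICE=12.0
Pandan: S_obs=10 Chao2=10.0 ICE=10.0
habitat assignment accuracy: 1.0
Mann-Whitney p: 1.30e-10
```

All 18 simulated species come back as exactly 18 MOTUs (the count is
stable across the 2–4% threshold scan), every MOTU is identified to its
source species, the per-reservoir observed richness matches the ground
truth (so the estimators add nothing), and each of the 28 water samples
is assigned to its reservoir of origin with a decisive group separation.

The same stages are available from a shell:

```bash
edna simulate --out sim/ --seed 3 --n-a-only 8 --n-b-only 6 --n-shared 4
edna run-all --config pipeline.yaml
edna classify --table out/motu_table.tsv --meta sim/metadata.tsv
```

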