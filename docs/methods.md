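# Methods

This note documents the models, rules and numerical choices behind the
package, what the synthetic-data generator does and does not emulate, and
the design decisions taken where the problem was genuinely open.

## The analysis model

The pipeline treats a metabarcoding run as a chain of typed tables:

reads → (sample, replicate) bins → unique-sequence × replicate count
table → retained sequences per sample → MOTU × sample table → community
statistics.

Record counts are conserved at every stage (binned + discarded = input;
retained + per-rule discards = unique sequences), and a run manifest
exposes the counts so the conservation can be audited.

### Demultiplexing and trimming

Tags are 9-bp sequences at the 5′ end of each primer; on a merged read
the forward tag is the first 9 bases and the reverse tag is the reverse
complement of the last 9. Matching is **exact**: with tags this short a
mismatch tolerance costs specificity and the expected number of
tag-damaged reads is small; they are counted in the discard bin instead.
Primer matching honours IUPAC degeneracy (inosine treated as N);
degenerate positions must be compatible, and up to 2 mismatches are
tolerated at non-degenerate positions. Reads are tried in the given
orientation and then reverse-complemented. Coordinates are 0-based,
half-open throughout.

Read merging (for paired input) picks the longest suffix–prefix overlap
with mismatch fraction ≤ 0.1 and at least 10 bp, keeping the forward base
inside the overlap; there is no quality model, which is adequate for the
constant-quality reads the generator emits and for any pre-merged input.

### Retention rules

Order: length (313 ± 0) → error pruning → identity prescreen →
translation → replicate consistency. Cheap, high-specificity rules run
first; the replicate rule runs last because it is defined on whatever
survives within each replicate.

*Error pruning* is an abundance-ratio absorption rule: within one
replicate, a sequence is absorbed into the most abundant sequence within
edit distance 1 holding at least 10× its count, iterated to a fixpoint in
descending-count order. The exact parameters of the original
OBITools-style denoising are not public; this rule is an explicit,
configurable stand-in with the same intent (collapse polymerase and
sequencing errors into their parent) and conserves total read count.

*Identity prescreen*: best global-alignment identity against the
reference collection; discard if the best hit is non-metazoan or the best
metazoan identity is < 0.80.

*Translation*: keep iff some frame (offsets 0/1/2, given strand) is
stop-free under the vertebrate (NCBI table 2) or invertebrate (table 5)
mitochondrial code. The two codes differ at AGA/AGG (stop vs serine), so
a sequence clean only under the invertebrate code still passes.

*Replicate consistency*: a sequence counts for a sample iff present in
≥ 3 of that sample's 5 replicate PCRs. This acts on exact unique
sequences, before clustering, and is the main chimera defence: a chimera
formed independently in one replicate rarely recurs in three.

### Identity, overlap and p-distance

One contract serves all modules: equal-length sequences are compared
positionally with **pairwise deletion** (positions with a gap or N in
either sequence are excluded); unequal lengths are globally aligned
(match +1, mismatch −1, gap open −5, extend −2, free end gaps) and
end-gap columns are excluded. Overlap is the number of compared columns.
For the fixed-length 313-bp amplicons this positional comparison is exact
and fast (vectorised over a uint8 encoding). A pair with zero comparable
positions raises an explicit undefined-distance signal; clustering treats
such pairs as above-threshold and logs them.

### MOTU delimitation

Objective clustering at an uncorrected p-distance threshold with
**single-linkage** semantics: MOTUs are the connected components of the
graph joining pairs at distance ≤ *t*. Single linkage is the only linkage
for which the MOTU count is provably non-increasing in *t*, which is what
makes the 2%/3%/4% stability scan meaningful. Representatives are the
highest-read-count member (lexicographic tie-break), and MOTU ids are
canonicalised by (descending total count, representative), so the
partition is invariant to input order. All-pairs computation is
acceptable at the intended scale (~10³ retained uniques).

### Taxonomy bands

Species: identity ≥ 0.97 **and** overlap ≥ 310 (conjunctive: a
high-identity hit over a short overlap is not a species call and cascades
to the higher-taxon flag). Higher-taxon flag: identity in [0.90, 0.97) —
the reference's phylum is propagated deterministically and marked as a
stand-in provenance (the original analysis used a Bayesian assignment
requiring live database access). Identities in [0.80, 0.90) stay
retained but unidentified; < 0.80 never reaches this module. Ties in the
best hit break by larger overlap, then lexicographic reference id.

### Community statistics

The sampling unit is one water sample (site × depth): m = 14 units per
habitat under the default design. Chao2 uses the (m−1)/m small-sample
factor in both branches and the bias-corrected form when Q₂ = 0. ICE
splits MOTUs at 10 incidences; since the incidence summary retains only
(S_obs, m, Q₁..Q_m), the number of units containing an infrequent MOTU is
approximated by m in the coverage CV term — with 14 units and the default
cutoff the distinction is negligible, and the convention is fixed so the
estimator is exactly testable. ICE falls back to Chao2 when estimated
coverage is zero.

NMDS wraps non-metric SMACOF (scikit-learn) with 20 random restarts, 500
iterations and tolerance 1e-7, then reports Kruskal stress-1 computed by
isotonic regression of configuration distances on dissimilarity ranks.
Renkonen similarity is computed on relative read counts pooled per
sampling point, with a rank-transform option exposed because either
convention is defensible for read counts.

### Habitat signatures

A habitat's reference profile marks every MOTU seen in ≥ 1 of its
samples. By construction a sample's presences are a subset of its own
habitat's profile, so the own-habitat Jaccard dissimilarity reduces to
1 − |sample|/|profile| — this containment identity is asserted in the
tests. Because the focal sample contributes to its own profile, the
default construction is circular as a classification experiment; a
leave-one-out mode rebuilds the focal habitat's profile without the
sample and is tested alongside. The group comparison uses a two-sided
Mann–Whitney U (dissimilarities are bounded and non-normal; the original
analysis reports p-values without naming a test); a t-test alternative
would be easy to add but the rank test is the safe default.

## The synthetic-data generator

The generator emulates the *statistical structure* of a two-reservoir
eDNA study, not its chemistry:

- **Barcodes**: 313 nt = 104 codons + 1 nt, codons drawn uniformly from
  the 62 sense codons of the invertebrate mitochondrial code, frame 0 —
  every true barcode passes the translation filter by construction.
  Candidate barcodes closer than p-distance 0.08 to an existing species
  are redrawn; generation fails explicitly if spacing cannot be met.
  Haplotypes differ from their base barcode by ≤ 4 single-nucleotide
  codon swaps that preserve translatability (intra-species distances
  < 0.03, inter-species > 0.08, so the 3% threshold separates species
  exactly).
- **Design**: 2 habitats × 7 sites × 2 depths × 5 replicate PCRs, unique
  9-bp tag pairs per (sample, replicate). Species belong to habitat A,
  habitat B, or both; contaminants are flagged non-metazoan and occupy
  samples like shared species. Each species occupies each sample of its
  habitat(s) with probability 0.7 (at least one sample guaranteed) — a
  middle ground between site-restricted and ubiquitous taxa.
- **Reads**: forward-orientation merged reads
  (tag + primer + barcode + rc(primer) + rc(tag)), with degenerate primer
  positions realised per read (a degenerate primer pool is a mixture).
  Abundances are lognormal(0, 1) per species; per replicate, each
  non-dropped species receives one guaranteed read plus a multinomial
  share of the remaining depth. The guaranteed read makes
  `dropout_prob` the *sole* detection-failure channel, so ground-truth
  replicate presence equals read-level presence and the zero-noise
  pipeline run must recover the true incidence matrix exactly — the
  closure property the test suite leans on.
- **Noise**: per-base substitution errors at `error_rate`; chimeras
  replace a fraction of reads with single-breakpoint splices of two
  parent barcodes from the same replicate (breakpoint uniform in
  [50, 263]).

Not emulated: quality-score structure, indels and length variation,
polymerase bias, tag jumps, cross-contamination. Passing tests therefore
demonstrate the correctness of the analysis logic under the stated
statistical model, not robustness to every artefact of real sequencing
runs.

## Problem sizes and scaling choices

- The study-scale closure run uses 281 + 140 + 95 = 516 species and a
  per-replicate depth of 450 reads (enough to cover the largest
  per-sample species load under 0.7 occupancy), i.e. 63 000 reads —
  large enough to exercise every stage at the study's structure while
  remaining a desk-scale computation (~30 s).
- The 100-seed habitat-signature trial runs on the replicate-detection
  layer directly (`simulate_incidence`): post-filter incidence depends
  only on which replicates detected a species, because singleton error
  variants are pruned or fail the 3-of-5 rule, so repeating the read
  layer 100 times would re-measure the same thing at much higher cost.
  The read-level path with errors, dropout and chimeras is exercised
  separately in the pipeline tests.
- The Chao2 bias-reduction check uses 100 species over 5 sampling units
  with detection probability drawn from [0.3, 0.7]: a regime chosen so
  that detection is genuinely incomplete — with many more units
  essentially every species is observed and the estimator has nothing to
  correct.

## Known limitations

- The error-pruning rule is a stand-in; real denoising algorithms model
  quality scores and per-base error profiles.
- Higher-taxon assignment propagates the best hit's phylum rather than a
  posterior over homologues; it is marked as stand-in provenance in the
  output.
- Jaccard-profile classification with the default (non-leave-one-out)
  profiles overstates separability for small sample counts; use
  `leave_one_out=True` for honest accuracy estimates.
- The generator's equal-length, indel-free world means the alignment
  path (unequal lengths) is exercised only by targeted unit tests.
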