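# Methods

## Scope

`gad` implements a conservative desk-scale pipeline for estimating global
archaeal (or any amplicon-surveyed) molecular diversity from taxonomically
labeled 16S rRNA OTU sequences: reference replacement, common-region
extraction, dereplication, tiered greedy clustering into molecular species /
genus / family OTUs (SOTU / GOTU / FOTU at 97 / 93 / 89 % identity),
threshold calibration from a labeled reference set, diversity estimators
(conservative lower bound, rarefaction discovery rate, per-environment
novelty scores), and occupancy-stratified verification against a second,
metagenome-style sequence collection.  A synthetic-community generator with
full ground truth supplies test data at every stage, so the pipeline is
exercised end to end without any external download.

## Percent identity

All modules share one identity contract: overlap (semi-global) pairwise
alignment in which gaps before the first and after the last aligned column
are free and excluded from the denominator, interior columns scored
match +1 / mismatch −1 / gap −1, and

    identity = matched columns / interior alignment columns.

The overlap dialect is chosen because amplicon collections mix primer sets,
so two valid sequences may share only part of their region; terminal
overhangs carry no signal.  IUPAC ambiguity codes match only on exact
symbol equality — an `N` against an `A` is a mismatch, so ambiguity can
only lower identity, which is the conservative direction for clustering.

Among equal-score alignments the implementation reports the one with the
most matched columns (the DP maximises the pair `(score, matches)`
lexicographically).  This replaces a pointer-preference traceback rule: it
makes the reported identity a well-defined function of the two sequences,
independent of path conventions, and makes `identity(a, b) == identity(b, a)`
hold exactly, because the alignment search space itself is symmetric.  The
interior column count follows as `columns = 2·matches − score`, so no
traceback is needed.  The kernel is a numba-compiled rolling-row DP with
both values packed into one integer.  It is verified against an independent
exhaustive-alignment oracle (suffix recursion, plus raw path enumeration at
tiny lengths) in the test suite.

One property of the dialect deserves a caveat: for two sequences with *no*
substantial homologous overlap, the best-scoring alignment can be a short
perfect terminal overlap, and the reported identity is then high over very
few columns (the defined behaviour for a contained fragment, e.g. `ACGT`
inside `TTACGTTT` is 100 %).  Identity values are therefore meaningful for
globally alignable sequences — the situation of every comparison the
pipeline performs, since all inputs are fragments of one marker gene — and
`scored_columns` is exposed on every result so callers can check coverage.

## Funnel stages

* **Reference replacement** — a dataset record whose best reference hit is
  *strictly* above 98 % identity takes the reference's sequence (curated
  references are longer and of higher quality); provenance is retained and
  records replaced by the same reference merge.  References that nothing in
  the dataset matches above the threshold are appended (abundance 1,
  pseudo-sample `refdb`), since they represent biodiversity absent from the
  survey.
* **Region extraction** — a fixed window of alignment columns (1-based
  inclusive; defaults 10300–25300 in SILVA/SINA coordinates) is cut from
  each aligned record and its gaps collapsed.
* **Information filter** — records keep ≥ `min_informative_bases` non-gap
  characters inside the window (default 244, the number of E. coli bases in
  the default window).  The boundary is inclusive, and ambiguity codes
  count: the filter measures information quantity, not quality.
* **Dereplication** — exact full-length sequence equality; the survivor
  takes the id of the most abundant member (ties: smallest id) and the
  per-sample counts are summed.  Full-length matching is the conservative
  reading; prefix dereplication would merge fragments of unequal length.

## Tiered clustering

Greedy centroid clustering processes records in decreasing abundance order
(ties: decreasing length, then id), the UPARSE/VSEARCH size-ordering
convention; a record joins the *first* centroid at ≥ threshold (a
`match="best"` variant is available) or founds a new cluster.  The internal
sort makes the partition invariant to input file order.

Genus clusters are built over species *centroids* (each weighted by its
cluster's total abundance), and family clusters over genus centroids.
Centroid propagation guarantees strict nesting — every SOTU belongs to
exactly one GOTU, every GOTU to one FOTU — which re-clustering all members
at the looser thresholds would not.  The cost is that higher-tier counts
depend on centroid choice; the fragmentation scan (below) quantifies the
related effect that similarity clustering shatters taxonomy-defined
families.

Occupancy classes per species cluster follow the distinct-sample count:
singleton (1), doubleton (2), tripleton (3), moreton (≥ 4).  Singleton
*removal* deletes species clusters holding exactly one member record from
exactly one sample, then drops genus/family clusters left empty.

## Threshold calibration

For each rank (species, genus, family) the intra-rank identity distribution
collects all pairs sharing that rank label and differing at every rank
below it, so each distribution measures exactly one taxonomic boundary.
The recommended threshold per rank is the rounded median; rank medians must
be monotone (species ≥ genus ≥ family) or calibration aborts, since
non-monotone medians signal mislabeled references.  The median is used
rather than a mode or tail percentile for robustness at the small pair
counts a curated reference set yields.  A mirror check compares medians
computed on full sequences and on the extracted sub-region (pass: within 2
percentage points), reproducing the justification for analysing a
sub-region at all.

## Diversity estimators

* **Conservative lower bound** — per (sample, GOTU) pair only the most
  abundant SOTU in that sample is trusted (ties: smallest SOTU id); the
  bound is the number of distinct SOTUs kept.  Two same-GOTU SOTUs seen in
  one sample are assumed to differ by sequencing noise or batch effects, so
  this deliberately undercounts.  The bound is bracketed by construction:
  occupied-GOTU count ≤ bound ≤ SOTU count.
* **Rarefaction / d_sotu** — sample-accumulation curves averaged over `R`
  random permutations of samples (default `R=10`, seed 42).  `d_sotu` is
  the mean count of SOTUs first contributed by the final sample of a
  permutation — the empirical version of "expected new species per
  additional sample", equivalently `S(n) − E[S(n−1)]`.  The curve is
  non-decreasing and its endpoint is permutation-invariant.
* **Novelty score** — per environment, the number of distinct clusters at
  each level observed in ≥ 1 of the environment's samples, divided by the
  environment's sample count.  Clusters are counted in every environment
  where they occur (no unique assignment), so the three per-level scores
  obey SOTU ≥ GOTU ≥ FOTU within an environment.
* **Environment assignment** — per cluster, `by_abundance` is the
  environment of the sample contributing the single highest-abundance
  member occurrence; `by_majority` is the most frequent environment over
  member occurrences (ties: alphabetical).

## Verification table

Each species-cluster representative is searched against the target
collection once; its best-hit identity is thresholded at 99 / 97 / 93 / 89 %
afterwards, which makes matched counts monotone across decreasing cutoffs
by construction.  Counts are stratified by occupancy class and summed into
a Total row (always the column-wise sum of the class rows).

Percentages are *truncated*, not rounded: one decimal place below 1 %,
whole percent otherwise (0.749 % → "0.7%", 61.94 % → "61%", 67.53 % →
"67%").  The convention is derived from internal evidence of the published
table this module reproduces; naive rounding produces different strings for
several cells.

## Synthetic communities

The generator emulates the statistical structure the analysis assumes,
with substitution-only mutation so identity is predictable from
substitution counts (indel robustness is covered separately by the
alignment oracle tests):

* **Reference taxonomy** — a random root sequence (default length 250 nt,
  matching the ~244-informative-base analysis region); family ancestors at
  3.6 % substitutions per branch, genus ancestors at 2 %, species at 3.2 %,
  optional within-species variants at 2.8 %.  These branch lengths place
  leaf pairs in the *upper half* of the rank identity bands — within-species
  ≥ 97 %, within-genus [93, 97), within-family [89, 93), cross-family
  < 89 % — because with integer substitution counts at length 250 the band
  interiors cannot all be hit centrally while every pair provably stays
  inside its half-open band.  Every generated set is verified by measuring
  pairwise identities (Hamming prescreen, exact alignment near band edges)
  and resampling offending branches, up to 100 rounds.  Consequently
  calibration on a generated reference set recovers thresholds
  (97, 94, 90) — within the ±1 tolerance of the nominal (97, 93, 89).
  Within-species variants revert half of their substitutions toward the
  genus ancestor so that cross-species distances are unchanged; at most two
  records per species keep all within-species pairs inside their band.
* **Samples** — five environments (default 10 samples each); species are
  either environment-exclusive (allocated in family/genus blocks, since
  endemic diversity is clade-structured — this is what makes a "novel"
  environment lead at genus and family level, not only species level;
  defaults give saline water the largest endemic pool, then soil) or
  cosmopolitan with Dirichlet(0.5) affinities.  Each sample draws 12
  species by affinity weight; per-(sample, species) abundances are
  ⌈lognormal(μ=1, σ=1)⌉; reads carry per-base substitution noise (default
  0.002, a residual post-denoising rate — at 250 nt this leaves species
  assignment intact but fragments genus/family tiers slightly, the
  overestimation effect the lower bound exists to correct).  A configured
  singleton fraction of species (default 0.10) is planted into exactly one
  sample each — exact planting, not sampling — and a coverage sweep places
  every remaining unsampled species into one sample so planted taxon counts
  are recoverable.
* **Metagenome target set** — each observed species enters with a coverage
  probability set by its occupancy class (defaults 0.05 / 0.30 / 0.35 /
  0.60 for singleton / doubleton / tripleton / moreton — cosmopolitan taxa
  are overrepresented in metagenome collections), with light substitution
  noise (0.002) so matches land near but not at 100 %.

Identical configurations (including seed) produce byte-identical output;
all randomness derives from `SimulationConfig.seed` via per-stage
`SeedSequence` streams.

What the generator does *not* emulate: PCR primer bias, chimeras, indels,
length variation, realistic rRNA secondary-structure evolution, and
taxonomies whose rank boundaries overlap in identity space (real archaeal
families do overlap, which is why the fragmentation scan exists).  Passing
tests therefore demonstrate correctness of the pipeline's logic under its
stated model, not robustness to every artefact of real surveys.

## Problem sizes and numerical choices

The default test community is 10 families × 3 genera × 4 species
(120 species, 50 samples, ~600 reads), which runs the full pipeline in
seconds; the verification-gradient suite uses 20 replicate surveys of 20
families (240 species) so that every occupancy class holds enough members
for binomial rate comparisons to have power (per-replicate failure < 1 %).
Ties are broken deterministically throughout (smallest id / alphabetical
environment); degenerate inputs (empty target set, empty rank
distribution, zero samples) warn or raise as documented per function.
Floating point enters only through the final division in identity and the
rarefaction means; all alignment arithmetic is integer.

## Known limitations

* Best-hit search is exhaustive (no k-mer prefilter); the package is a
  desk-scale reference implementation, not a competitor to VSEARCH on
  millions of sequences.
* Centroid propagation at higher tiers is one defensible construction;
  counts are not comparable to pipelines that re-cluster all members.
* The identity dialect's behaviour on non-overlapping sequences (see above)
  makes raw identity unsuitable as a similarity measure for arbitrary,
  non-homologous inputs.
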