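# gad — tiered molecular-OTU clustering and diversity estimation

Most archaeal diversity has never been cultivated: it is visible only as
16S rRNA gene fragments scattered across public amplicon surveys.  `gad`
is a desk-scale, fully tested implementation of a conservative pipeline
for turning such taxonomically labeled OTU sequences into an estimate of
how many molecular species, genera and families a survey actually
contains — and for asking which environments still hold the most
undescribed diversity.

The pipeline, in order:

1. **Reference replacement** — OTUs matching a curated reference at
   > 98 % identity take the reference sequence; unmatched references are
   appended so known diversity absent from the survey still counts.
2. **Common-region extraction** — a fixed window of alignment columns is
   cut from every sequence and gaps collapsed; records with fewer than a
   minimum number of bases in the window (default 244) are dropped.
3. **Dereplication** — exact duplicates merge, summing per-sample counts.
4. **Tiered clustering** — greedy centroid clustering at 97 % builds
   species OTUs (SOTUs); clustering the species centroids at 93 % builds
   genus OTUs (GOTUs) and those centroids at 89 % family OTUs (FOTUs),
   giving a strictly nested partition.  Identity is overlap-alignment
   identity (terminal gaps free, match +1 / mismatch −1 / gap −1,
   identity = matches / interior columns).
5. **Estimators** —
   * a *conservative lower bound*: per sample and GOTU only the most
     abundant SOTU is trusted (same-GOTU co-occurrences in one sample are
     treated as noise), so the bound undercounts deliberately;
   * *rarefaction* with `d_sotu`, the expected number of new SOTUs one
     additional sample of an environment would contribute;
   * per-environment *novelty scores* (distinct clusters per sample at
     each level);
   * an occupancy-stratified *verification table*: match rates of SOTU
     representatives against a second (metagenome-derived) collection at
     99/97/93/89 % cutoffs, where SOTUs are classed by how many samples
     they occur in (singleton/doubleton/tripleton/moreton).

The clustering thresholds are not taken on faith: a calibration module
re-derives them as rounded medians of intra-rank identity distributions
from a labeled reference set, and checks that the extracted sub-region
mirrors full-length identity structure.

Because real inputs at survey scale (hundreds of thousands of samples)
are not shippable, the package includes a first-class synthetic-community
generator: a hierarchical taxonomy whose ranks separate at the calibrated
identity bands, environment-structured sampling with lognormal
abundances, planted singletons, and a partially overlapping
metagenome-style target set — all with ground truth, so parameter
recovery is testable end to end.  See `docs/methods.md` for the model and
its limits.

## Worked example

```python
from gad import SimulationConfig, simulate_study, tiered_cluster, dereplicate
from gad.clustering import occupancy_classes
from gad.diversity import (conservative_lower_bound, rarefaction,
                           sotu_sample_abundance, sotus_by_sample,
                           novelty_scores)
from gad.verification import match_rates

config = SimulationConfig(seed=1)          # 10 families x 3 genera x 4 species
db, reads, prov, meta, targets, truth = simulate_study(config)
records = dereplicate(reads)
tiered = tiered_cluster(records, thresholds=(97, 93, 89))
print("clusters:", tiered.counts())

bound, _ = conservative_lower_bound(tiered, sotu_sample_abundance(tiered, records))
print("conservative lower bound:", bound)

by_sample = sotus_by_sample(tiered, records)
saline = {s: v for s, v in by_sample.items() if meta[s] == "saline_water"}
print("d_sotu (saline water):", rarefaction(saline, R=10, seed=42).d_sotu)

best = max(novelty_scores(tiered, meta), key=lambda s: s.sotu_score)
print(f"most novel environment: {best.environment} "
      f"({best.sotu_score:.1f} SOTUs/sample)")

table = match_rates(
    [next(r for r in records if r.id == c.centroid_id)
     for c in tiered.species_clusters],
    occupancy_classes(tiered), targets)
print(table.to_tsv())
```

prints

```
clusters: {'species': 120, 'genus': 44, 'family': 14}
conservative lower bound: 117
d_sotu (saline water): 1.8
most novel environment: saline_water (5.2 SOTUs/sample)
	SOTUs	99	97	93	89
Singleton	21	0 (0%)	0 (0%)	12 (57%)	20 (95%)
Doubleton	10	2 (20%)	2 (20%)	6 (60%)	10 (100%)
Tripleton	17	4 (23%)	5 (29%)	14 (82%)	17 (100%)
Moreton	72	41 (56%)	44 (61%)	67 (93%)	72 (100%)
Total	120	47 (39%)	51 (42%)	99 (82%)	119 (99%)
```

Reading the numbers: all 120 planted species are recovered as SOTUs.
Read-level noise (0.2 % per base by default) splits some genus- and
family-level clusters (44 GOTUs and 14 FOTUs against 30 and 10 planted) —
exactly the overestimation effect that motivates the conservative lower
bound, which lands at 117, between the occupied-GOTU count and the SOTU
count.  Saline water, given the largest endemic species pool by the
generator, leads the novelty ranking, and the verification table shows
the occupancy gradient: single-sample SOTUs are the hardest to confirm in
the metagenome-style collection at high identity, while cosmopolitan
("moreton") SOTUs match most often.  Percentages are truncated, not
rounded (57.1 % prints as `57%`, and values below 1 % keep one decimal),
matching the convention of the published table this module reproduces.

A `gad` command-line tool wraps every stage
(`gad simulate | trim | derep | replace | cluster | calibrate |
lower-bound | rarefy | novelty | verify | run`); `gad run --config
pipeline.json` chains them and writes per-stage record counts, cluster
sets and all estimator reports as JSON.

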