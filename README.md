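# phylocore

Dynamic phylogenetic core detection for 16S rRNA pan-microbiome datasets.

## The problem

A central question in host-associated microbiome research is whether a
*compositional core* exists: bacterial groups present in every healthy
individual. Defining that core in terms of taxonomic labels inherits the
biases of reference databases, and defining it with a single OTU identity
threshold (e.g. 97%) misses groups that are universal only at a broader
phylogenetic depth. `phylocore` implements the *dynamic* alternative: it
searches for core units across a whole ladder of clustering thresholds, so
the core it reports is a set of discrete sequence clusters of *varying*
phylogenetic depth, each present in 100% of subjects.

The package is aimed at microbial ecologists analysing multi-subject
amplicon surveys (gut, soil, any pan-microbiome), and ships a synthetic
community generator with planted ground truth so the whole method is
testable without downloading cohort data.

## The method

Given demultiplexed reads attributed to subjects:

1. **Rarefaction** — every subject is subsampled to the common minimum
   depth *d* (uniform, without replacement).
2. **Multi-step clustering ladder** — reads are clustered de novo into OTUs
   at identity *t* = 0.97, then the representatives of each level are
   re-clustered at *t* − 0.01, down to *t* = 0.75 (23 levels; membership
   maps are composed back to the original reads). Clustering is greedy
   centroid assignment: items in decreasing abundance order join the best
   centroid with identity ≥ *t*, else found a new OTU. Pairwise identity is
   a semi-global alignment (match +1, mismatch −1, gap −2; the shorter
   sequence spans end-to-end, terminal gaps of the other are free):
   identity = matches / alignment columns.
3. **Dynamic core detection** — walking the ladder from 0.97 down, an OTU
   present in 100% of subjects is a **core OTU**, *after masking every read
   already claimed by a core at a higher threshold*. Masking makes the core
   units disjoint: a species-level core claimed at 0.97 cannot also pad out
   a family-level core at 0.85. The union over the ladder is the
   **phylogenetic core**.
4. **Significance** — per level, the number of core OTUs is compared to a
   null distribution built from 100 matrices in which each subject's
   abundance values are shuffled across OTUs (preserving each subject's
   richness, read total, and abundance multiset);
   p = (1 + #{null ≥ observed}) / (1 + 100).
5. **Summaries** — pooled core frequency per subject (% of reads in any
   core unit, mean ± sd and range across subjects), per-core relative
   abundance, coefficient of variation, and abundance percentile within its
   detection level; optional consensus taxonomy from external per-sequence
   classifier calls, and best-identity matching of within-core 0.97
   representatives against a reference 16S collection.

## Worked example

```python
from phylocore import (default_community, simulate_dataset, run_dynamic_core,
                       evaluate_recovery, core_summary, permutation_core_test)
from phylocore.stats import format_summary_table

# 10 subjects at depth 500; 5 planted universal lineages of mixed
# phylogenetic depth + 15 sporadic lineages at 50% occupancy
specs = default_community(seed=0)
dataset, truth = simulate_dataset(specs, n_subjects=10, depth_per_subject=500, seed=0)
core = run_dynamic_core(dataset)

print(format_summary_table(core_summary(core, dataset)))
for c in core.cores:
    print(c.otu_id, f"detected at {c.detection_threshold:.2f}, "
          f"{len(c.masked_member_ids)} reads over {sum(v > 0 for v in c.per_sample_counts.values())}/10 subjects")

res = permutation_core_test(core.masked_tables[0.97], n_permutations=100, seed=1)
print(f"0.97 level: {res.observed_core_count} core OTUs, p = {res.p_value:.4f}")
print("recovered:", evaluate_recovery(core, truth).recovered_lineages)
```

prints

```
Frequency: 50.1 +/- 15.4%
Range: 26.0-69.0%
Core OTUs: 5
Core groups per clustering threshold: 97:2, 94:1, 88:1, 80:1

T97_1 detected at 0.97, 584 reads over 10/10 subjects
T97_6 detected at 0.97, 373 reads over 10/10 subjects
T94_5 detected at 0.94, 431 reads over 10/10 subjects
T88_7 detected at 0.88, 335 reads over 10/10 subjects
T80_3 detected at 0.80, 783 reads over 10/10 subjects
0.97 level: 2 core OTUs, p = 0.0099
recovered: ('core04', 'core05', 'core03', 'core02', 'core01')
```

Half the reads of every subject belong to one of five disjoint core units.
The two tight (≤ 3% intra-divergence) planted lineages surface at the 0.97
"species" level; the three broader ones are invisible at 0.97 — no single
variant cluster is universal — but are recovered intact at 0.94, 0.88 and
0.80. The chance of even two universal OTUs at 0.97 under the
richness-preserving null is below 0.01. All five planted universal
lineages, and nothing else, are recovered.

## Command line

```sh
phylocore simulate --n-subjects 10 --depth 500 --seed 42 --out-dir sim/
phylocore run-all --input sim/seqs.fasta --map sim/samples.tsv --seed 1 --out-dir results/
phylocore core --input sim/seqs.fasta --map sim/samples.tsv --out core.json
phylocore permute --table results/tables/level_097.tsv --n 100 --seed 7 --out perm.json
```

`run-all` writes `core.json`, per-level OTU tables, representative FASTA,
permutation p-values, the summary, and a manifest; one seed reproduces
every output byte-for-byte.

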