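# Methods notes

This note records the modelling choices behind `phylocore`, the defaults
and why they hold, what the synthetic data generator does and does not
emulate, and the numerical corner cases that required a decision.

## The core-detection model

The unit of analysis is the OTU: a cluster of 16S fragments within a given
identity of a centroid, used as a proxy for a phylogenetic group whose
depth is set by the clustering threshold. The method assumes that

* presence of an OTU in a subject is read as presence of the lineage
  (hence rarefaction to a common depth first — prevalence is
  depth-sensitive, and unequal depths would bias presence calls);
* a lineage that is universal only at a broad phylogenetic depth is still
  biologically meaningful (traits are substantially phylogenetically
  conserved, even in deep clades);
* disjointness matters: once a read belongs to a core unit found at a high
  threshold, it must not also count toward a deeper unit, or pooled
  frequencies would double-count and deep cores would be artifacts of
  shallow ones. This is the masking rule.

Masking is applied to the precomputed per-level tables of a single chained
clustering ladder, rather than physically re-clustering the surviving
reads at every level. The chained ladder preserves centroid structure
(each level clusters the previous level's representatives), so the two
readings agree on cleanly separated data; `run_dynamic_core(...,
recluster_after_mask=True)` implements the literal iterate–remove–recluster
variant for comparison. The masking reading is the default because it is
deterministic given the ladder and makes the per-level tables, the
permutation test, and the core memberships mutually consistent.

An OTU whose masked counts vanish entirely still anchors chaining at lower
levels (its representative persists in the ladder); its column is kept,
zero-filled, so column identity is stable across masking.

## Pairwise identity

Identity is computed from an optimal pairwise alignment scored
match +1, mismatch −1, gap −2, with the *glocal* (semi-global) convention:
one sequence is aligned end-to-end while terminal gaps of the other are
free and uncounted; both orientations are evaluated and the better-scoring
one used, making the measure symmetric. Identity is matches divided by
alignment columns between the first and last column touching the spanned
sequence (internal gap columns count).

Why glocal rather than free gaps at both ends of both sequences: under
this scoring a full alignment of two unrelated 250-nt fragments scores
negative, so with both ends free the optimum degenerates into a one- or
two-column exact micro-overlap and identity saturates at 1.0 for *any*
pair. Requiring one sequence to be spanned removes the degeneracy (random
250-mers then measure ≈ 0.52, maximum ≈ 0.58 over thousands of pairs —
safely below the 0.75 ladder floor) while keeping the desirable behaviour
that a read contained verbatim in a longer reference scores 1.0.

Tie-breaking is fully pinned so results are bit-reproducible: among
co-optimal alignments the one with the most match columns is used, and a
residual tie on matches resolves to the fewest columns (identity can
differ between co-optimal alignments, e.g. one mismatch versus an
insertion–deletion pair, so this third criterion is load-bearing).
`N` and other non-ACGT codes never match anything, including themselves.
Empty sequences are rejected.

## Clustering

Greedy centroid clustering with deterministic rules: items are processed
in decreasing weight (abundance) order, ties by ascending id; each item is
compared against *all* existing centroids and joins the best hit with
identity ≥ threshold (identity ties to the earliest-created centroid),
else founds a new OTU. Best-hit assignment replaces the
first-acceptable-hit heuristic of the usual greedy tools deliberately:
the method's output should not depend on centroid search order.

Exact duplicates are collapsed before the first level (weights
accumulated); this is a pure speedup with identical results, and on
amplicon data (many identical reads) it is the difference between seconds
and hours. Identity computations are memoized because the chained ladder
revisits the same representative pairs at up to 23 consecutive levels.

The ladder grid is 0.97 down to 0.75 in steps of 0.01, both endpoints
included (23 levels): 0.97 is the conventional species-level proxy, and
below ~0.75 nucleotide alignments of the 16S fragment lose reliability.

## Permutation null

The null preserves each subject's richness: within every row of the
subjects × OTUs table the full value multiset (zeros included) is permuted
uniformly across columns. Row sums, per-row nonzero counts, and value
multisets are exactly invariant; only the *joint* column structure is
destroyed, which is precisely what core detection exploits. The p-value
uses the add-one empirical rank, p = (1+k)/(1+n), so p is never 0 and at
n = 100 the strongest attainable claim is p ≈ 0.0099 — consistent with
reporting "p < 0.01". The test is applied to the per-level masked tables,
matching how cores are counted.

The p-value is discrete and conservative on small tables: if the null
core count is almost surely zero and the observed count is zero, p = 1.
Calibration checks therefore use tables dense enough that the null count
distribution has a fine-grained tail (the test suite uses 6 × 150 at 50%
fill, where the fraction of p ≤ 0.05 under the null lands near 0.035).

## Summary statistics

Pooled core frequency per subject is the percentage of the subject's
(post-rarefaction) reads inside any core unit; because masked memberships
are disjoint, frequencies are additive over cores and bounded by 100%.
The reported dispersion is the sample standard deviation (n−1) across
subjects. Per-core coefficients of variation are computed on relative
(depth-normalized) abundances; after rarefaction depths are equal, so this
is a formality, but it keeps the statistic meaningful if rarefaction is
skipped. The abundance percentile of a core is its position in the
right-continuous ECDF of mean relative abundances over all OTUs with
nonzero masked counts at its detection level.

## Consensus taxonomy

The classifier itself is external; the module consumes per-sequence
lineages with bootstrap confidences (mothur `.taxonomy` dialect). Each
lineage is truncated at the first rank below the 0.80 confidence floor;
the consensus walk keeps a taxon while ≥ 51% of *all* inputs (not just
surviving ones) carry it, stopping at the first rank without a majority.
A tie (possible only with a cutoff ≤ 0.5) stops the walk; an empty
consensus reports support 1.0, read as vacuous agreement at the root.
Raising the cutoff can only shorten the consensus, and the result is
always a prefix of at least one input lineage.

## Reference matching

Each core's masked members are re-clustered at 0.97 and every
representative is aligned exhaustively against the reference set; best
identity per representative, mean ± sd per core. Exhaustive glocal
alignment replaces heuristic short-read mapping: it is deterministic,
needs no index, and the representative sets are small. The
region-spanning requirement on references is a length filter
(`min_coverage`, default 1.0 — a reference must be at least as long as the
query), appropriate because the glocal kernel lets a read sit inside a
full-length 16S reference at no cost.

## Synthetic communities

The generator emulates the structure the method assumes: discrete
lineages separated by ≥ 25% divergence at the ancestor level, some planted
universal (the ground-truth core) and some sporadic (per-subject occupancy
0.5), log-normal between-subject abundance jitter (σ = 1 on the log
scale), and a fixed per-subject depth. Reads are exact copies of lineage
variants; variants derive from the ancestor by i.i.d. substitutions (no
indels by default, so expected pairwise identities are analytically
predictable; substitution-only data also exercises the kernel's ungapped
optimum, while indel robustness is exercised separately in kernel tests).

Lineage layout is divergence-dependent, mirroring the two regimes the
method distinguishes:

* **shallow** (intra-divergence ≤ 0.03): a dominant variant identical to
  the ancestor carries ~50% of the lineage's reads in every subject and
  the other variants stay within the divergence bound of it, so the whole
  lineage forms one 0.97 cluster — detectable at the species level;
* **deep** (> 0.03): only mutated variants exist (per-variant rates in
  [d/2, d]) and each subject carries a private random subset of 2 of the 8
  variants, so no 0.97 variant cluster is universal (the chance any
  variant reaches all 10 subjects is ~10⁻⁵) and the lineage can only
  surface as the variants merge further down the ladder.

Universal lineages are guaranteed ≥ 1 read per subject: at finite depth a
"universal" lineage that happened to be unsequenced somewhere would make
the ground truth ill-defined. Disabling this (`force_universal=False`)
reproduces depth-driven core loss, a real phenomenon in shallow surveys.

Default study conditions — 10 subjects, depth 500, 5 universal + 15
sporadic lineages, intra-divergences sampled from {0, 0.02, 0.06, 0.10},
250-nt fragments — are desk-scale stand-ins for cohort surveys (hundreds
of subjects, 10⁴–10⁵ reads/subject, 100–250 bp). What passing tests show:
the algorithmic pipeline recovers planted structure exactly and its
statistics behave as designed. What they do not show: robustness to
sequencing error, chimeras, primer/PCR bias, length heterogeneity within a
run, or compositional effects of real communities — none of which the
generator emulates. With 15 sporadic lineages at occupancy 0.5 over 10
subjects there is a ~1.5% chance per simulation that some sporadic lineage
is present in all subjects by honest chance and is then (correctly, for
that realization) reported as core; recovery checks therefore tolerate one
such seed in twenty.

## Reproducibility

All randomness flows from one master seed; each pipeline stage derives its
own stream by hashing `"<seed>:<stage>"` (BLAKE2, < 2³¹). Outputs are
JSON with sorted keys, TSV, and FASTA without timestamps, so a rerun with
the same configuration is byte-identical (verified in the test suite).

## Known limitations

* Greedy clustering is not transitive; different orderings can shift OTU
  boundaries. The deterministic rules make this reproducible, not absent.
* The masking reading and the literal recluster-after-mask variant can
  differ on data without clean lineage separation; only the former is
  characterized by the test suite.
* Prevalence is exact presence (count > 0) at 100% of subjects by
  default; single-read presence counts fully, which is depth-sensitive —
  hence mandatory rarefaction in the default pipeline.
* The quadratic alignment kernel is meant for desk-scale and
  representative-set workloads, not for clustering millions of unique
  reads; no k-mer prescreen is implemented.
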