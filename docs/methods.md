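# Methods

This note records the models, parameter choices, and numerical conventions
behind `stalkscape`, and what the synthetic-data generators do and do not
emulate.

## Study design and data model

The sampling unit is the internode. The reference design has 19 internode
groups across four stages — FS (1 internode), SS (3), TS (6), LS (9) —
each with two biological replicates, giving a 38-column TPM matrix.
Replicate agreement is Pearson r between the two replicate columns of each
internode on the log2(TPM+1) scale; Pearson (rather than Spearman) is used
because log-scale expression is approximately linear between technical
replicates and r is invariant to the affine shifts that global depth
differences produce. All downstream analyses run on the replicate-averaged
19-column matrix after the log2(TPM+1) transform; averaging is done on the
matrix's stored scale, and the log offset of 1 keeps zeros at zero.

## High-variation genes

MAD(g) = median_j |x_gj − median_j x_gj| on the log matrix, with the
default cutoff 1 and **no** 1.4826 normal-consistency factor: the cutoff is
meant as "varies by about one log2 unit across internodes in the median
sense", which the unscaled definition states directly. Selection is
monotone in the cutoff; an empty result is a warning, not an error,
because a permissive rerun is the natural next step.

## Developmental zones

Internode columns of the gene-standardized HVG matrix are clustered by
average-linkage hierarchical clustering on Euclidean distance and cut into
k = 4 groups. Zones are not contiguous along the stalk: basal internodes
of later stages cluster together regardless of stage, which is exactly the
point of the zone concept. Zone labels I–IV are assigned by the mean
(stage, internode) rank of each cluster's members, earliest first, so the
naming is reproducible. PCA variance fractions come from the singular
value spectrum of the same standardized matrix with sample-mean centering;
the fractions are reported, never asserted against any particular dataset.

## Fuzzy c-means

Standard alternating optimization of J = Σ u_gi^m d_gi² on per-gene
z-scores: centroids v_i = Σ u^m x / Σ u^m, memberships
u_gi = 1/Σ_k (d_gi/d_gk)^{2/(m−1)}. A gene exactly on a centroid takes
membership 1 there (the documented degenerate rule). The fuzzifier default
is the Schwämmle–Jensen dimension/size heuristic (the rule behind Mfuzz's
`mestimate`), giving m ≈ 1.1–1.2 for thousands of genes over 19 samples.
Initialization samples c distinct genes as starting centroids — the same
scheme as `e1071::cmeans`, the engine underneath Mfuzz — because
initializing from random memberships collapses every starting centroid
onto the global mean (the classic random-partition failure mode of
k-means). `n_init` restarts (default 4) are scored by the final objective
and the objective is recorded per iteration, which the tests assert to be
non-increasing. Cluster names C1..Cc are ordered by centroid peak position
so labels are stable across runs. The seed is mandatory.

## Weighted co-expression network

Unsigned adjacency a_ij = |cor|^β. The soft power is chosen by the
smallest β with scale-free fit R² > 0.85 (log-binned log10 frequency vs
log10 connectivity, negative slope required) and mean connectivity below a
threshold; the conventional "connectivity < 100" criterion refers to a
~20k-gene network, so the default threshold rescales proportionally
(100·n/20000) for smaller matrices. β = 9 is the configuration default and
can always be re-derived from the scan.

TOM_ij = (l_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij) with
l_ij = Σ_{u≠i,j} a_iu a_uj, computed as one matrix product; a brute-force
triple-loop oracle pins it to 1e-12 in the tests.

Module detection is a deliberately simplified dynamic hybrid cut:
average-linkage on 1 − TOM, a static cut at height 0.95 to obtain branch
cores, cores of ≥ `min_module_size` (default 50) genes become modules, and
then **every** gene's membership is refined by topological proximity — a
gene joins the core with its highest mean TOM provided that mean reaches
half the core's median member-to-core similarity. The refinement both
reattaches genes split off on small branches and, critically, rejects
weakly attached passengers: at n = 19 samples, a pure-noise gene has a
~9% chance of |r| > 0.4 with any given module profile, and without the
rejection step such genes chain into module branches below any practical
static cut height. The 0.95/0.5 defaults were fixed during development on
planted-block simulations and are insensitive over cut heights 0.93–0.97.
Exact replication of the reference tree-cut heuristics (branch PAM stage,
gap criteria) is out of scope; no eigengene-similarity module merging is
performed. Undersized post-refinement modules dissolve into the unassigned
pool (label 0, "grey").

Module eigengenes are the first right singular vector of the
gene-standardized module submatrix (unit norm over samples), sign-aligned
to the module's mean profile, falling back to the first gene when the mean
profile is degenerate, and zero (with a warning) for rank-0 modules.
Module–trait statistics are Pearson r with the two-sided Student-t p on
n − 2 df; MM is a gene's correlation with its own eigengene and GS its
correlation with the trait. Hub networks rank module members by
intramodular connectivity k_i = Σ_{j∈module} TOM_ij, keep the top 100 plus
any flagged genes, and export edges above a TOM-weight quantile.

A note on the permutation check of the p-values: a permutation estimate
converges to the data-conditional permutation null, which at n = 19
differs from the unconditional t p-value by a real O(1/n) term (relative
deviations of ~10–25% at p ≈ 0.01). The test suite therefore compares the
two within Monte-Carlo error plus a 25% relative allowance — that is the
agreement the statistics permit, not an implementation tolerance.

## TF analysis

Family ratios are HVTF count over TF count per family from a gene→family
table in which each gene has at most one family. HVTF expression groups
are average-linkage hierarchical clusters (k = 6) of standardized
profiles, named G1..Gk by mean peak position. Overrepresentation of a
family inside a group is a one-sided hypergeometric tail against the HVTF
background with Benjamini–Hochberg q-values; the hypergeometric is the
natural fixed-margins test for "is this family concentrated in this
group", and the tests verify it against explicit enumeration.

## SELEX k-mer analysis

Reads are 101-bp double-stranded ligands, so every 10-mer window is
counted on both strands; counts and enrichments are then exactly
reverse-complement symmetric, and total window count is
2·reads·(L − k + 1). Exact-sequence duplicates (PCR repeats) are removed
before analysis. The null library is the per-read mononucleotide shuffle,
which preserves each read's length and base composition. The pipeline
default pools 10–20 independent shuffles: a single shuffle gives each
10-mer a Poisson null count with mean ~2–4 at sequencing-scale depth, and
that denominator noise — not signal — would otherwise order the top of the
enrichment ranking. Pooling only sharpens the Monte-Carlo estimate of the
null frequency; the null model is unchanged. Enrichment is
(f_sel + ε)/(f_null + ε) with ε = one null window (1/total_null) by
default; the final-round-vs-shuffled comparison is the default, with
round-0 input as an alternative null.

Motif construction is seed-and-count: the seed is a locally maximal
enriched 10-mer (no single-substitution neighbor more enriched; seeds too
similar to a chosen one under shifted/reverse-complement alignment are
skipped, so distinct motifs yield distinct seeds). Core PWM columns are
the background-corrected selected-library counts of single-substitution
variants of the seed; flanking columns (±`extend`) come from base
frequencies at aligned exact seed occurrences. Consensus letters are the
IUPAC code of bases at ≥ 25% column probability. Because enrichment is
strand-symmetric, motifs are discovered up to reverse complement; all
comparisons and site orientation account for this. The motif match
threshold defaults to half the PWM's maximum achievable log-odds score
(base 2, against the library base composition): soft selection flattens
discovered PWMs, and the permissive "any positive log-odds" rule matches
tens of percent of random windows, washing fold changes out to ~1. The
permissive rule remains available by passing `match_threshold=0.0`.
Replicate agreement is the Pearson correlation of log enrichment over
10-mers with ≥ 10 selected-library counts in both replicates; below that
the log ratio is pure small-count noise.

## Genome scanning

Each position's affinity is the enrichment of its 10-mer, taking the
better of the forward and reverse-complement orientation; windows touching
non-ACGT bases score 0, and 10-mers unseen in both libraries fall back to
the pseudocount-only score. Promoters are strand-aware: a + gene at
(1-based) TSS t spans 0-based [t − span, t) and a − gene [t, t + span),
with span = 2000 by default ("TSS + 2 kb" read as the upstream 2 kb;
downstream and both-sided modes are available because the convention
varies). GFF3 input is 1-based closed, BED output 0-based half-open, and
the conversion is unit-tested explicitly. Site calling thresholds at a
genome-wide score quantile (default 0.999), keeps the local maximum of
each run of consecutive above-threshold positions, and annotates each site
with its owning gene and signed TSS distance. By the definition of an
empirical quantile, roughly 0.1% of genome positions exceed the default
threshold regardless of how well the libraries separate signal from
background, so on a 1 Mb genome with 40 kb of promoters a handful of
background promoter positions will always be called alongside planted
sites; planted sites separate by score (severalfold above the strongest
background call in the test fixture), so rank, not the bare call set, is
the reliable readout at this threshold. Because the affinity track is
strand-symmetric, site strand is only meaningful relative to a motif; pass
the genome and a motif to `call_sites` to orient sites by the better-
scoring orientation of the site 10-mer under the motif core.

## Synthetic data

All generators hang off a single master seed through independently spawned
streams, so every output is bit-reproducible and ground truth round-trips
through pipeline outputs without manual matching.

**Expression.** Twelve cluster archetypes assign one of four graded log2
levels (a distinct permutation of 0..3, scaled to a 4.5 log2-unit range)
to each of the four zones, plus a small deterministic within-zone tilt.
Gene log2 profiles are baseline (uniform 2–8) + scaled archetype +
biological noise (sd 0.4, shared between replicates); replicates add
technical noise (sd 0.25), calibrated so replicate r comfortably exceeds
0.97. A fifth of genes are flat (baseline + noise only) and fail the MAD
cutoff. Linear TPM is 2^x − 1 clipped at 0. This emulates zone structure,
cluster structure, and replicate noise — not count-based sampling noise
(no negative-binomial layer), library-size artifacts, or batch effects, so
passing tests speak to the analysis math, not to robustness against
RNA-seq count pathologies.

**Modules and traits.** Planted modules (default sizes 100/80/60 among
1500 genes) follow x_g = λ_g f_m + √(1 − λ_g²)ε with loadings λ uniform in
(0.85, 0.95) around smooth latent profiles: a Zone-IV-peaked factor
(elongation-like), a monotone bottom-to-top decreasing factor, and
mid-stalk bumps. Internode length couples to factor 1 and diameter to
factor 2 at population correlation r_target = 0.9 via
t = r·z_f + √(1 − r²)·g, so the realized r at n = 19 follows the ordinary
Pearson sampling distribution around the target. The factors themselves
correlate (|r| ≈ 0.6), as real stalk traits do.

**SELEX.** The hidden PWM has dominant-base probability 0.85 over the
MYB-like AC-element consensus TCACCTAACT. The initial pool is a virtual
library of 8 million distinct uniform ligands, generated and scored in
chunks and never held in memory; each ligand's occupancy is logistic in
its best double-strand PWM log-odds window (midpoint 0.75 and width 0.15
of the maximum score). One round of selection plus amplification to depth
multiplies a ligand's abundance by its occupancy, so the round-r sequenced
sample is a with-replacement draw ∝ occupancy^r; amplification duplicates
arise naturally and are what the dedupe step removes. The virtual-library
size matters: a small explicit pool caps the number of distinct reads that
can carry any 10-mer, and after duplicate removal enrichment would reduce
to round-0 lineage-count noise. The model is occupancy of the single best
window with a logistic link — no full thermodynamic partition function, no
PCR bias, no sequencing error.

**Genome.** 1 Mb of i.i.d. sequence, 20 genes on random strands with
spaced TSSs, consensus instances (reverse-complemented for − genes)
written at known offsets inside the upstream promoter windows of 3 genes;
the truth table is returned in BED-like coordinates.

## Problem sizes used in the checks

The test suite and `scripts/acceptance.py` run at: 2000-gene expression
simulations for zone/cluster recovery; 1500-gene, 19-sample simulations
for module detection, with the module–trait recovery averaged over 200
seeds; SELEX at 4 rounds × 20,000 reads of 101 bp from an 8M-ligand
virtual pool, two independent replicates; and a 1 Mb genome with 20
annotated genes. These sizes exercise every code path at study-like
per-sample dimensions while keeping a full run to a couple of minutes on
one CPU.
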