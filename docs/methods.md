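# Methods

This note records the models implemented, the defaults and why, and the
boundaries of what the bundled simulations can and cannot demonstrate.

## Synthetic data: structured coalescent with migration

The generator produces the only data the package ships: per-OTU aligned read
sets with known history.

**Genealogy.** A backward-time structured coalescent over `n_demes` island
populations. With `n_i` lineages in deme *i*, coalescences occur at total
rate `n_i (n_i − 1) / θ_i` and each lineage migrates (backward) from *i* to
*j* at rate `M[i][j]/2`; waiting times are exponential and participants
uniform. Under this scaling the expected pairwise coalescence time within a
deme is θ/2.

**Vicariance.** A migration matrix with several closed communicating classes
(e.g. a complete barrier) can never bring all lineages into one deme, so a
common ancestor would not exist. The generator therefore supports an
optional `split_time`: at that time all remaining lineages merge into a
single panmictic ancestral pool (mean θ). This is the standard vicariance
reading of a hard oceanographic barrier — present-day isolation with a
shared deep ancestor. Without `split_time`, an upfront reachability check on
the migration digraph raises a `DisconnectedHistoryError` rather than
looping forever.

**Mutation.** Finite sites: each branch receives Poisson(θ/2 × length)
mutations, each hitting a uniform site and substituting a uniformly chosen
*different* base; the root sequence is uniform over ACGT. Finite sites keeps
sequences fixed-length (no alignment step) and lets entropy decomposition
encounter recurrent-hit columns, at the price of a small deficit of observed
differences on deep branches. With this scaling the expected pairwise
difference in a panmictic deme is θ²/2 (two branches of expected length θ/2,
each mutating at rate θ/2).

**Reads.** Per deme (or per host, when `hosts_per_deme` splits a deme's
depth across individual hosts), reads are drawn multinomially from the
lineage haplotype frequencies and corrupted site-wise with iid uniform
substitution errors — no indels and no quality scores, so the alignment is
preserved by construction. Defaults follow the study design the simulator
emulates: four sites in three provinces, 370 bp (a V4–V5 amplicon),
error rate 0.1% per base, and site depths proportional to the gut-tissue
sample sizes 31/15/10/14 (scaled up ×10 in the demonstration run to sit in
the 10³-per-site regime; depths up to 10⁵ remain desk-scale).

**What the simulations do not emulate:** selection of any kind, recombination,
demographic change, chimeras, indel/alignment error, and the
overdispersion of real sequencer error profiles. A passing test therefore
shows the *inference machinery* is correct and calibrated on its stated
model, not that real 16S data satisfy that model.

## Minimum Entropy Decomposition

Column entropy is Shannon entropy in bits over the five residue states
`A C G T -` (the gap is a genuine state; `N` is missing and excluded from
the denominator). Decomposition recursively splits each node at its top
`d` highest-entropy positions (default `d = 1`; ties to the lowest index)
while the node's maximum entropy exceeds `m`, then tallies per-site counts
of terminal nodes.

* `m` defaults to **0.0965 bits**. The original MED software computes this
  threshold dynamically; the rule is internal to that implementation, so the
  package ships the conventional constant and leaves it configurable.
* The minimum substantive abundance defaults to **1% of the OTU's reads**
  (absolute counts also accepted). A 2% per-OTU floor is sometimes quoted
  for MED, but it is arithmetically incompatible with catalogs of ~100
  oligotypes per OTU (100 × 2% > 100%), suggesting that floor is applied
  per sample or per node in practice; 1% per OTU is a deliberately
  conservative noise filter and the flag accepts any value.
* Noise nodes are **reassigned** to the surviving oligotype whose
  representative is closest in Hamming distance (ties to the
  lexicographically smallest representative); `discard` is available and
  the filtered count is reported either way.
* A read with `N` at a splitting column follows the majority child.
* The representative of an oligotype is its most abundant unique sequence
  (ties lexicographic).

Error robustness at the defaults: at 0.1% per-base error a contaminating
base at one column reaches frequency ≈ 0.03%, contributing ≈ 0.01 bits —
an order of magnitude below `m` — while a true variant at ≥ 5% frequency
contributes ≥ 0.29 bits, an order above it. This separation is what the
identifiability tests exercise at depth 10⁴.

## Population statistics

All statistics operate on the oligotype × site count matrix and the
oligotype sequences, never on expanded reads; the test suite proves exact
equivalence to per-sequence brute force on small instances.

* **H and Π** use the small-sample correction n/(n−1). Π is reported in
  units of mean pairwise *differences* (not per-site), the scale on which
  oligotype data are conventionally tabulated.
* **Rarefaction** subsamples every site without replacement (multivariate
  hypergeometric) to the smallest site's depth, B times (default 1000);
  point estimate = mean, CI = 2.5/97.5 percentiles.
* **AMOVA.** For each site pair, SSD_total = (1/2N)ΣΣd², SSD_within =
  Σ_p (1/2n_p)ΣΣ_{i,j∈p} d², σ²_w = SSD_within/(N−P), σ²_a =
  (SSD_among/(P−1) − σ²_w)/n′; the statistic σ²_a/(σ²_a+σ²_w) is truncated
  to [0,1]. F_ST uses the 0/1 identity metric, Φ_ST squared Hamming
  distances. Negative variance components are truncated to zero (standard
  convention). Note the df corrections make the statistic exactly
  scale-invariant only asymptotically in N.
* **Permutation tests** reshuffle sequence-to-site assignments on the count
  matrix (sequential multivariate hypergeometric draws preserving both
  margins — identical in law to permuting pooled read labels, tractable at
  N ≈ 10⁵). p = (#null ≥ obs + 1)/(P + 1), so p is never 0; a reported
  "p = 0" from other software is read as "below resolution".
* **S_nn**: a sequence's nearest neighbours are all other sequences at
  minimal distance (identical copies included, self excluded); ties share
  proportionally. Computed in closed form from counts.
* **Nm surrogate**: (1 − F_ST)/(2 F_ST), the haploid equilibrium island
  model. It is an order-of-magnitude connectivity summary — symmetric, not
  directional, and exact only under island-model assumptions; F_ST = 0 maps
  to +∞, F_ST = 1 to 0.

## Median-joining networks

Node weights use the frequency-sum convention: each site's counts are
normalised before summing, so unequal sequencing depths do not let one deep
site dominate circle sizes; weights over all oligotypes sum to the number
of sites. The network iterates (ε-relaxed minimum spanning network → add
the majority median of a connected triplet that most reduces total MST
cost → repeat), then prunes unsampled medians of degree ≤ 2. ε defaults to
0 (the union-of-MSTs network). Determinism: ties in medians and additions
are broken by lexicographic sequence order; a 3-way tied column keeps the
state of the lexicographically first member of its triplet.

## Assembly-process partitioning

The phylogeny is a neighbour-joining tree on inter-oligotype Hamming
distances (negative branch lengths clamped to 0) — a deliberate desk-scale
choice over likelihood tree inference, adequate because only nearest-taxon
patristic distances enter βMNTD. βMNTD is abundance-weighted; its null
shuffles oligotype labels across tree tips (999 randomizations by default),
and a degenerate null with zero spread yields βNTI = 0 (drift-compatible)
rather than NaN. RC_Bray draws null communities preserving each sample's
richness (taxa ∝ occupancy) and total abundance (multinomial ∝
metacommunity relative abundance). Thresholds: |βNTI| > 2 for selection,
|RC| > 0.95 for dispersal classes, else drift. Communities default to
individual host samples; a site-pooled mode exists because either level of
replication is defensible and they can disagree.

## Matrix regression

Geographic distances are great-circle (haversine, R = 6371.0088 km). The
workflow replicated here Hellinger-transforms the geographic distance
matrix before regression; this is unusual (the transform was designed for
community tables) but is kept, faithfully, behind a flag
(`hellinger_geography=False` disables it). Environmental distance is |ΔPC1|
of the standardized site × variable table (constant variables dropped), and
the PC1 variance-explained is reported so users can verify the 1-D
reduction is warranted. Predictors stay on their supplied scales (a
standardization flag exists). Site-level predictor matrices are expanded to
sample pairs (between-site pairs take the site distance, within-site pairs
0). Inference jointly permutes rows and columns of the response (default
10⁴ permutations; the pipeline demo uses 10³).

## Problem sizes and determinism

The demonstration run uses 700 reads over 13 host samples at four sites
(θ = 2, 20 lineages per deme), 199-fold permutation/null tests, 200
bootstrap resamples and 10³ MMRR permutations; it completes in seconds and
is byte-identical across repeats of one seed. The test suite runs the
heavier calibration checks (200-dataset type-I error panels, 100-replicate
barrier recovery, 50-replicate neutral end-to-end) at comparably small
per-replicate sizes. A single run seed fans out to per-stage generators via
`SeedSequence` spawn keys, so stages are independently reproducible.

## Known limitations

* The dynamic entropy-threshold rule of the original MED software is not
  re-derived; `m` is a constant default.
* The Nm surrogate cannot resolve direction or non-equilibrium gene flow;
  coalescent-likelihood migration estimation is out of scope.
* AMOVA p-values inherit the discreteness of count reshuffles; with few
  sequences the tests are conservative.
* βNTI on very shallow or star-like trees is degenerate (handled, but
  uninformative).
* The vicariant `split_time` merges *all* demes into one ancestral pool;
  staged splits (province trees) are not modelled.
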