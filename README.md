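# oligogeo

Population-genetic and phylogeographic analysis of **oligotypes** — sub-OTU
16S rRNA amplicon sequence variants resolved by Minimum Entropy Decomposition
(MED) — treating each variant as a haplotype and each sampling site as a
population. The package targets "metaphylogeography": applying the toolkit of
macro-organism phylogeography (fixation indices, haplotype networks,
migration surrogates, assembly-process partitioning, matrix regression) to
uncultured bacterial populations surveyed by metabarcoding, for example gut
symbionts of benthic invertebrates sampled across oceanographic provinces
separated by dispersal barriers and connected by currents.

Because real surveys start from large read archives, the package bundles a
structured-coalescent simulator that generates aligned, site-labelled read
sets with known genealogy, migration history and sequencing error, so every
statistic can be validated against ground truth end to end.

## What it computes

* **Oligotyping (MED).** Reads positionally homologous reads for one OTU and
  recursively partitions them at the alignment column of maximal Shannon
  entropy, H_p = −Σ_b f_b log₂ f_b over b ∈ {A,C,G,T,−}, until every node's
  residual entropy is below a threshold *m*; nodes below a minimum
  substantive abundance are noise-filtered (reassigned to the nearest
  surviving oligotype, or discarded).
* **Diversity.** Per site: N, number of oligotypes *k*, discriminant
  (segregating) sites *S*, oligotype diversity
  H = n/(n−1)·(1 − Σ pᵢ²), and mean pairwise differences
  Π = n/(n−1)·Σ_{i<j} 2 pᵢ pⱼ d_ij, with composite bootstrap rarefaction to
  the smallest site (95% CIs).
* **Structure.** Pairwise F_ST (haplotype-identity metric) and Φ_ST
  (nucleotide-distance metric) from two-level AMOVA with permutation
  p-values; Hudson's nearest-neighbour statistic S_nn with a permutation
  test; an island-model migration surrogate Nm = (1 − F_ST)/(2 F_ST).
* **Networks.** Median-joining haplotype networks with node weights given by
  per-site frequencies summed per OTU.
* **Assembly processes.** Abundance-weighted βMNTD against a tip-shuffle
  null (βNTI) and abundance-weighted Raup–Crick Bray–Curtis (RC_Bray),
  classified into homogeneous/variable selection, homogenizing dispersal,
  dispersal limitation and ecological drift.
* **Isolation by distance vs environment.** Multiple matrix regression with
  randomization (MMRR) of Bray–Curtis composition on great-circle geographic
  distance (optionally Hellinger-transformed) and environmental-PC1
  distance.

All population statistics are computed frequency-weighted from the
oligotype × site count matrix — reads are never expanded — and are exactly
equivalent to per-sequence computations (verified against brute-force
oracles in the test suite).

## Worked example

The bundled demonstration simulates four sites in three provinces with a
complete dispersal barrier isolating the Antarctic site and an eastward
route linking Kerguelen to Patagonia, then runs every stage:

```sh
oligogeo all --out demo_run --seed 1
```

prints

```
outputs in demo_run
oligotypes: 12; Snn = 0.7972 (p = 0.0050); drift = 38.5%
```

and writes, among others, `pairwise_phist.tsv` (estimates below the
diagonal, permutation p-values above), `process_partition.tsv`, `mmrr.tsv`
and a median-joining network. In this run the mean Φ_ST across the barrier
is 0.91 against 0.25 within the connected group, S_nn = 0.80 is highly
significant, and MMRR attributes most compositional turnover to geographic
distance (IBD coefficient 0.583 vs IBE 0.090, R² = 0.82) — the qualitative
signature of a dispersal barrier plus current-mediated connectivity, with
environmental PC1 capturing >99% of the (province-structured) environmental
variance.

Every stage is also available programmatically:

```python
from oligogeo.simulate import barrier_scenario, generate_dataset
from oligogeo.io import read_labelled_fasta
from oligogeo.oligotyping import med_decompose, build_count_matrix
from oligogeo.popgen import pairwise_structure

paths = generate_dataset(barrier_scenario(seed=1), "data")
reads = read_labelled_fasta(paths["reads"])
catalog = med_decompose(reads)
counts = build_count_matrix(catalog)
structure = pairwise_structure(counts, catalog.sequences(), P=999)
```

## Layout

```
src/oligogeo/
  simulate.py     structured-coalescent synthetic data with ground truth
  oligotyping.py  Minimum Entropy Decomposition
  popgen.py       diversity, AMOVA Fst/Phi-st, Snn, Nm surrogate
  hapnet.py       median-joining networks
  assembly.py     NJ tree, betaMNTD/betaNTI, RC_Bray, process partition
  mmrr.py         geographic/environmental distances, MMRR
  io.py           labelled FASTA, TSV, Newick, GraphML
  pipeline.py     orchestration, seeding, manifest
  cli.py          `oligogeo` subcommands
docs/methods.md   model assumptions, parameter choices, limitations
```
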