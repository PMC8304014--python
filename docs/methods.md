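# Methods

## The generative model

`truthseq` simulates the tag-based (UMI) single-cell RNA-seq protocol in
four explicit stages, each with its own recorded randomness.

### Ground truth

A *reference panel* stores, for each gene g and each subcategory s of a
two-level cell-type hierarchy (major categories → subcategories), the
mean and variance of an independent normal distribution of expression.
Panels can be

* **fit** from a labelled genes × samples matrix: a subcategory needs at
  least 3 samples to receive its own per-gene sample mean and unbiased
  (n−1) variance; smaller subcategories fall back to the gene's overall
  mean/variance across all samples (the `source` flag records which). A
  subcategory named but represented by zero samples is an error, never a
  silent fallback.
* **synthesized** hierarchically: per-gene log-scale baselines
  `N(baseline_mean, baseline_sd)`, plus per-major and per-sub effects
  (`N(0, major_effect_sd)`, `N(0, sub_effect_sd)`), exponentiated to
  means; each subcategory owns a disjoint block of marker genes whose
  mean is set to `marker_fold ×` the gene's largest other-subcategory
  mean, so marker dominance holds by construction. Variances follow a
  constant coefficient of variation: `var = noise_var_scale · mu²`.

True copy numbers are drawn per cell as `round(N(mu, var))` clipped at
zero. The mapping from expression units to integer copies is not
something array-intensity data pins down; round-and-clip is the minimal
choice and is stated here as an artifact decision. Whether source data
should be log-transformed before fitting is likewise left to the caller
(the fit operates on the values it is given).

Randomness is split into one `SeedSequence` stream per cell, so per-cell
sampling is independent of evaluation order.

**Defaults** (the study conditions of the synthetic panel): 500 genes,
4 majors × 3 subs, 5 markers per subcategory at fold 4,
`baseline_mean = 0.5`, `baseline_sd = 0.8` (natural-log scale, i.e.
typical means of a few copies per gene), `major_effect_sd = 0.6`,
`sub_effect_sd = 0.25`, `noise_var_scale = 1.0`. The effect/noise scales
were chosen once so that, under the default analysis workflow, major
categories separate essentially perfectly at moderate depth while
subcategories remain only partially separable — the qualitative regime
the benchmark is meant to probe. The default 50 cells per subcategory
(42 × 50 = 2100 cells at the 14 × 3 panel size) matches the scale of the
reference design.

### Library building

* **Fragmentation.** Each of the k true copies of gene g in cell c
  yields one fragment. Head and tail losses are independent
  `Geometric(p)` draws with support {0, 1, …} whose means default to 10%
  of transcript length each; a draw with `start ≥ end` is redrawn up to
  10 times, then the copy is emitted full-length. Coordinates are
  0-based half-open on the forward strand (simulated cDNA; no strand
  flips).
* **Barcodes.** Rejection sampling of random 16-mers under a minimum
  pairwise Hamming distance (default 2), with a bounded attempt budget
  (10⁴ per barcode) so infeasible requests fail loudly. The constraint
  is verified exhaustively on every returned bank.
* **UMIs.** One uniform random 10-mer per *original* fragment; all PCR
  copies of a fragment share its UMI (this is what makes UMI collapsing
  meaningful). Collisions between fragments are allowed, as uniform
  assignment implies; at default length they are rare within any
  (cell, gene) group.
* **PCR.** Per fragment, a branching process: starting from one
  molecule, each cycle every molecule duplicates with probability
  `efficiency` (default 0.9, 3 cycles); each base of a newly synthesized
  strand substitutes with probability `mutation_rate` (default 1e-5),
  and daughters inherit all parental mutations. Copy numbers are
  therefore bounded by 2^cycles with mean (1+efficiency)^cycles.
  Implementation note: molecule *counts* are drawn vectorized across all
  fragments; the rare fragments that acquire substitutions get their
  duplication tree (which parent duplicated when, where the new strand
  mutated) resolved exactly from a dedicated per-fragment stream —
  given the counts, that choice is uniform, so the joint law equals the
  per-molecule model. Full provenance (molecule, offset, ref → alt,
  cycle) is stored in the PCR control library.

The on-disk library is plain text: one fragment TSV per cell, TSV banks,
and a flat key=value manifest holding every parameter, seed, and the
reference checksum. Reading is strictly non-mutating; a checksum mismatch
at sequencing time logs a warning.

### Sequencing

Each read pair samples one molecule with replacement, with probability
proportional to its PCR copy number (cluster sampling on a flow cell).
Read 1 is `barcode ‖ UMI`; read 2 is the fragment's 5′ end with its
molecule's PCR substitutions applied, truncated or padded to
`read2_len`. Fragments shorter than read 2 read through into a repeated
`AGATCGGAAGAGC` adapter (N-padding is available as a toggle) so
downstream trimming behaviour stays realistic.

Substitution errors follow an error profile `p(position, ref, alt)`
(tab-separated files, `*` wildcards; a flat total rate is split evenly
over the three alternatives; uncovered cells fall back to a uniform
default of 1e-3 per base with a logged warning). Qualities are
`round(N(mean, sd))` clamped to [2, 41] from a quality profile indexed
by position, observed base, and whether the base was substituted
(defaults 37±2 correct / 25±5 error). N bases are never substituted and
receive quality 2.

Reads are generated in fixed 65,536-read chunks, each with an RNG stream
derived from `(seed, chunk_index)`; threads only parallelize chunk
construction and output is written in chunk order, so FASTQ output is
byte-identical for a given seed at any thread count (gzip mtime and
filename fields are pinned for this reason). Read ids are
`SIM:<run>:<read_index>` and the header comment carries
`cell|gene|copy|molecule` — standard tools ignore it, the truth-aware
quantifier uses it.

### Quantification

* **Demultiplexing**: exact barcode lookup, then unique-Hamming-1
  correction. At bank distance ≥ 3 the neighbour is provably unique; at
  distance 2 ties are possible and are conservatively discarded.
* **Gene assignment**: `truth_tag` mode reads the header tag (an oracle
  mapper standing in for an external alignment chain, which is out of
  scope here); `align` mode does exact unique-31-mer voting against the
  transcript set, capped at 10 Mb of reference — a convenience for toy
  references only.
* **UMI collapsing**: per (cell, gene), the directional single-mismatch
  rule — a UMI is absorbed by a Hamming-1 neighbour seen at least twice
  as often, cascading through the absorbing representative; exact-match
  counting is available as a flag. Raw (per-read) counting is the
  `dedup=False` path and always dominates the deduplicated counts
  elementwise.
* A rank/count knee estimator (`estimate_whitelist`) places the cell
  cutoff at the steepest drop of the log-count curve; it is bypassed
  whenever the true bank is supplied.

### Evaluation

Normalizations operate on genes × cells matrices: identity, classic
quantile (each column becomes a permutation of the shared
order-statistic means; ties broken by stable order so the defining
identity holds exactly), per-gene z-score, library-size scaling to the
median cell total, `log10(x+1)` (the pseudocount is required for zeros
and is the documented choice), per-cell ranks with average ties, and
within-cell TPM `(X_g/l_g) / Σ_g(X_g/l_g) · 10⁶` (all-zero cells stay
zero with a warning).

Clustering methods are standard algorithms invoked as plumbing: k-means
and Ward hierarchical (scikit-learn), a kNN-graph + Louvain scheme
(igraph; Python's global RNG is pinned around the Louvain call for
determinism), a minimal batch SOM on a near-square grid (no SOM
implementation exists in the supported dependency set, so a compact one
is provided), and density-peak clustering (Gaussian-kernel densities at
the 2%-quantile cutoff distance, centres ranked by density × separation).

Accuracy: clusters are annotated with their modal true label (ties break
toward the globally more frequent label, then lexicographically);
accuracy is the fraction of cells whose cluster annotation equals their
own label, computed independently at major and sub level — for nested
labels, major accuracy always dominates sub accuracy. The chance
baseline is the mean accuracy over uniform permutations of the
cluster-index vector (default 100 permutations). Matrix sparsity is
summarized by the dropout ratio (zero fraction) and low-count ratio
(entries in (0, t], default t = 1).

The benchmark harness runs the full
normalization × reduction × feature-count × clustering × seed grid
(feature ladder 100/70/40/10; the default single-run workflow uses
library-size normalization, log, PCA-30, kNN+Louvain), records failures
per grid cell without aborting, and offers variance-across-conditions
summaries per clustering method. The differential-expression step that
would feed `filter_cluster_specific_genes` (a one-vs-rest model fit) is
intentionally external; the filter itself removes genes reported as
differential in more than four clusters.

## Problem sizes used in the shipped experiments

The experiment harnesses run at desk scale, chosen as the smallest sizes
at which the qualitative claims are statistically comfortable: the
saturation round trip uses 5 subcategories × 20 cells × 50 genes with
UMI length 14 (a near-saturating UMI space, so the exact-equality oracle
is not confounded by random UMI collisions) and a coupon-collector depth
bound targeting < 1e-6 miss probability; the UMI-correction comparison
runs 20 replicates of a 60-gene × 30-cell library at efficiency 0.7 and
4 cycles; the depth ladder runs the default 500-gene panel at 30 cells
per subcategory over 30/100/300/900 reads per cell and 5 seeds.

## Known limitations

* The intensity→copy-number mapping, truncation distribution, PCR
  efficiency, and profile schemas are artifact choices where the
  underlying protocol leaves them open; all are parameters, and all land
  in manifests.
* The synthetic panel draws genes independently — no gene–gene
  correlation structure, no sequence-dependent capture or mapping bias,
  no doublets/ambient RNA, no indels. Passing tests therefore certify
  the machinery (conservation, provenance, calibration, reproducibility)
  and the qualitative depth/normalization trends, not distributional
  realism of any particular tissue.
* `align` mode is exact-match voting, not an aligner; real-data users
  should quantify with a standard external chain and only use the
  truth-tag oracle for simulator validation.
* Sampling with replacement means one molecule can be read twice; at the
  shipped depths this matches the intended flow-cell analogy but is not
  a model of library exhaustion.
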