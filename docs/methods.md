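# Methods

## Model

The package predicts a community's relative KEGG Ortholog (KO) profile as a
linear function of its 16S rRNA marker profile. The underlying assumption
is compositional: a community's gene content is approximately the
cell-abundance-weighted mixture of the gene repertoires of its member
genomes, and a 16S profile against a marker reference database is an
adequate (copy-number-biased) estimate of those cell abundances whenever
the detected references have close sequenced relatives. The prediction is
therefore only as complete as the genome database's coverage of the
community — which is why the unmapped-mass fraction is a first-class output
rather than a hidden detail: a high rank correlation with a shotgun profile
measures correspondence on the shared repertoire, not completeness.

Pipeline, for an input profile **x** over marker references:

1. **y** = **A x**, where column r of **A** assigns reference r to the
   genome(s) with maximal global-alignment identity to r, provided that
   identity ≥ `min_identity`. Mass on references with all-zero columns (or
   absent from the matrix — treated identically, both mean "no neighbor
   above threshold") is dropped, reported as `fraction_otus_unmapped`, and
   the remainder renormalized. Renormalize-and-report was chosen over
   carrying the deficit into the KO profile because the evaluation operates
   on relative profiles; the deficit stays visible in the coverage report.
2. ŷ(g) ∝ y(g)/c(g) with c(g) the genome's 16S gene copy number (positive
   integer). A missing copy number for an abundant genome is an error;
   `assume_missing_copy_number_one` (CLI: `--assume-copy-number-1`) opts
   into a default of 1 explicitly, because silent defaults corrupt the
   correction invisibly.
3. **f** = Σ_g ŷ(g)·**p**_g, a convex combination of the genomes' relative
   KO profiles (each row sums to 1 by construction), so **f** is itself a
   relative profile.

Profiles carry absolute counts until a stage explicitly normalizes;
renormalization happens after stages 1 and 2. Stage boundaries and all
containers are validated (nonnegativity, uniqueness, row/column
stochasticity) at construction time.

## Alignment identity

The reference→genome matching uses global (end-to-end) Needleman–Wunsch
alignment with linear gap costs, default scoring match +1, mismatch −1,
gap −1, and identity defined as matches / alignment columns. Global
identity is the standard measure for rRNA similarity radii (the default
threshold 0.97 is the conventional species-level OTU radius); the scoring
triple is configurable.

Two numerical subtleties:

* **Co-optimal alignments.** Alignments sharing the optimal score can have
  different identities. The package reports the *maximum* identity over all
  optimal alignments, which is well defined, symmetric, and testable
  against exhaustive enumeration. It is computed exactly: for fixed total
  score s on sequences of total length c, the mismatch count is an affine
  function of the match count M, so identity M/L(M) is monotone in M and
  only the extremal M over optimal DP paths (a second, tightness-restricted
  DP pass) is needed. Scoring triples with mismatch = 2·gap are rejected —
  there a mismatch column and a gap pair cost the same, M no longer
  determines L, and the closed form (and arguably "identity" itself) is
  ill-defined.
* **Ambiguity codes.** U equals T; N scores as a mismatch against every
  symbol including N, keeping identity a conservative lower bound. Other
  IUPAC codes are rejected with the offending symbol named.

Ties at the maximum identity (within 1e−12) split the column weight
uniformly — winner-take-all would be arbitrary — and the last tied weight
is adjusted by ≤ 1 ulp so every column sums to exactly 1.0 in doubles.
Genomes with multiple 16S copies score as the maximum over their copies, so
intra-genome operon divergence never penalizes a genome. The builder is
fully deterministic.

## Evaluation statistics

* **Spearman correlation**: Pearson on mid-ranks (average ranks for ties),
  computed from `scipy.stats.rankdata`. Constant vectors are an explicit
  error (zero rank variance), not a NaN.
* **Zero-dimension exclusion**: before correlating, profile pairs are
  aligned over their feature union and dimensions zero in *both* are
  dropped. Scope is per sample pair by default — the stricter,
  self-contained reading — with `exclusion_scope="dataset"` pooling support
  across all samples of a collection instead; both are exposed because
  either convention is defensible for collections of heterogeneous samples.
* **Sign test**: exact two-sided binomial, p = 2·min(P(X≤k), P(X≥k)) capped
  at 1 with X ~ Bin(n, ½) over the n nonzero per-sample differences; exact
  zeros are dropped and their count reported. Exactness beats the normal
  approximation at the small sample counts typical of paired benchmark
  collections.

## Synthetic data generator

`FixtureSpec`/`generate_reference_fixture` emulate the structural
relationship the method depends on: each mock genome has a random 16S-like
sequence (uniform over ACGT); its marker-database reference is that
sequence with point substitutions at `mutation_rate` per site (default
0.01 — a typical intra-species divergence, comfortably inside the 0.97
radius at the default length 500); `n_extra_silva_refs` unrelated random
references emulate marker diversity with no sequenced relative (two
unrelated random 500-mers align at ≈ 0.55 identity under the default
scoring, far below any sensible threshold). Genomes draw
`n_kos_per_organism` = 30 KOs with counts uniform in [1, 50) from a
universe of `ko_universe_size` = 150, so repertoires overlap heavily, as
real KO cores do; copy numbers are uniform over `copy_number_range` =
(1, 5), the realistic bacterial range.

`generate_paired_sample` draws the 16S side multinomially with read
probability ∝ mixing weight × copy number — the copy-number bias is
injected on purpose so stage 2 is exercised — and computes the metagenome
side exactly as the convex combination of KO rows, optionally perturbed by
i.i.d. multiplicative log-normal factors (log-sd = `noise_rate`) and
renormalized; log-normal noise is simple, positive and rank-perturbing.
`exact=True` replaces the multinomial draw with expected counts, making the
no-noise rank-agreement property exactly testable. The paired-sample
generator takes the fixture object rather than a built database because the
organism→reference placement of reads is ground-truth knowledge. Substitution-only
mutation keeps the generator's intended-identity arithmetic exact while the
aligner still sees gapped optima for unrelated pairs.

What the generator does **not** emulate: rRNA secondary structure and
conserved/variable region architecture, chimeras, primer and amplification
bias, within-genome operon divergence, and phylogenetic correlation between
genomes (mock genomes are mutually unrelated). Passing recovery tests
therefore demonstrate the pipeline's correctness and its behavior under
sampling and measurement noise — not predictive accuracy on real
communities, which is dominated by database coverage.

## Benchmark problem sizes

The recovery benchmark runs 10 independent worlds (seeds 1–10 in the test
suite; seed-offset in the acceptance script) of 10 genomes × 500 nt, one
paired sample each at 10⁴ reads, Dirichlet(5) community composition (keeps
all genomes comfortably present). These sizes make multinomial noise the
only error source at noise 0, where the median per-sample Spearman is
≈ 0.999; log-normal noise at σ = 0.2 and 0.5 degrades it monotonically
(≈ 0.96, ≈ 0.83).

## Numerical conventions

* "Sums to 1" tolerance: 1e−9 absolute (far above double rounding, far
  below signal). Normalization is idempotent to ≤ 1e−12.
* Canonical feature order is lexicographic wherever an order must be
  chosen (serialization, feature unions); in-memory builders preserve
  input order, so permuting organism input order permutes matrix rows and
  nothing else.
* All serialized floats use 17 significant digits (lossless double
  round-trip); database serialization is canonical, so equal databases are
  byte-identical on disk.
* Tiny negative unmapped fractions from matvec round-off (> −1e−12) are
  clamped to 0; genuine deficits pass through exactly (a 20% decoy share is
  reported as exactly 0.2).

## Known limitations

* The association matrix recomputes all pairwise alignments at build time;
  for realistically sized marker databases a k-mer prescreen would be
  needed. Out of scope here.
* KO reference profiles are an *input* (per-genome KO counts); deriving
  them from genome sequence is a separate annotation problem.
* No taxonomy-aware aggregation: the method operates on flat
  reference/genome/KO universes by design.
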