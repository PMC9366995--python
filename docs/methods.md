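# Methods

## Compression model

The compressor is a mixture of adaptive order-k finite-context models over
the quaternary alphabet {A, C, G, T} (A=0, C=1, G=2, T=3; complement(b) =
3 − b). Each model keeps sparse integer counts of (context, symbol)
occurrences and predicts

P(s | ctx) = (n(ctx, s) + α) / (Σ_s' n(ctx, s') + 4α).

Counts are unbounded and never halved: the intended inputs are small genomes
(tens of kilobases), where counter saturation is not a concern. Context
registers initialize to the all-A context and tables start empty, so the
first symbol of any sequence costs exactly 2 bits under a fresh single
model. This initialization is a convention, not a claim; any fixed choice
would do, and tests pin this one.

**Mixing.** Model predictions are combined with weights maintained by
exponential performance decay: the mixture probability uses the weights
*before* the symbol is observed, then

w_m ← w_m^{γ_m} · P_m(observed), renormalized.

γ near 1 remembers performance over long ranges; γ = 0 makes the weight
depend only on the last symbol. This is a classical weighted-expert scheme
chosen for transparency and determinism; it is not a neural mixer, and no
claim of equivalence to any particular external compressor is made.

**Code length.** The output is the ideal code length Σ −log2 p, not an
arithmetic-coded bitstream. A real coder would add O(1) bits of framing;
every downstream measure needs only C(x) in bits, so the accumulator is the
honest quantity. Determinism: identical (sequence, configuration) pairs give
bit-identical results.

**Inverted repeats.** IR detection is an update-rule variant. For each
(k+1)-mer window (x_{i−k}, …, x_i) the model can record, besides (or instead
of) the forward pair (context, symbol), the reverse-complemented reading of
the same window: the IR word (comp(x_i), …, comp(x_{i−k})), split into its
first k symbols (IR context) and last symbol (IR symbol). Lookups always use
the forward context. Under this construction the forward windows of a region
are exactly the reverse-complemented windows of its inverted-repeat partner,
so text seeded by an earlier segment makes its downstream inverted copy
cheap — verified by an involution property test over all windows. Mode 0
writes forward counts only, mode 1 writes both into the same table, mode 2
writes reverse-complement counts only.

**Default configuration (`level16`).** Order-1 (α = 1, γ = 0.7, no IR) mixed
with order-12 (α = 1/50, γ = 0.97, IR mode 1). A shallow fast-adapting model
plus a deep IR-aware model fits small compact genomes where repeats sit close
together. The NC variants NC_IR0/1/2 are this configuration with every
model's IR mode overridden to 0, 1, 2; NC_best is the configuration as-is.
An order-16 cap (memory guard) and a γ ≤ 0.99 cap (stability guard) are
enforced on model specs.

## Measures

* NC(x) = C(x) / (2|x|); NR = 1 − NC.
* NCC = 1 − NC_IR2, kept only when **strictly** positive. A non-positive
  value means the IR-only mode could not beat the 2-bits-per-base capacity,
  which happens for essentially all IR-free sequences; such values carry no
  signal and are excluded from aggregation (NaN in tables).
* DIFF = NC_IR0 − NC_IR1. Negative values (the IR machinery very slightly
  hurting an IR-free sequence) are retained and reported.
* GC-content in percent; SL = |x| in bases.

## Profiles

The per-position series of −log2 p is the forward profile; the backward
profile compresses the *reversed* sequence (direction of reading, not
strand) and is re-mirrored into original coordinates; B(x_i) is the
pointwise minimum. A reverse-complement backward pass is available behind a
flag but is not the default, since inverted-repeat structure is already
captured by the IR modes.

Smoothing uses a Blackman window (default size 501 in the CLI), normalized
to unit sum, with mirror padding so constants are preserved and output
length equals input length. The filter family and width are visualization
choices with no downstream numeric role; both are parameters. Low-complexity
regions are maximal runs of the smoothed series strictly below a threshold,
at least `min_len` long, reported as 1-based closed intervals (converted to
0-based half-open on BED export).

## Synthetic generators

The generators define the conditions under which the package's claims are
tested:

* `random_sequence` — i.i.d. uniform DNA, the incompressible null
  (NC ≈ 1.00 at 10 kb under `level16`).
* `make_ir_construct` — n/2 random bases followed by their reverse
  complement; default n = 10,000, matching the ~9.8 kb median genome length
  of the intended input class.
* `mutate` — independent per-base substitution; a hit becomes one of the
  *other* three bases uniformly. Substitution-only by design: the benchmark
  isolates how point mutation erodes inverted repeats, and indels would
  confound position bookkeeping. Each benchmark rate is generated
  independently (not by accumulating mutations on one sequence); replicate r
  uses construct seed `seed + r`.
* `synthetic_feature_table` — class-conditional unit-covariance Gaussians
  over the feature axes. Class means are random points rescaled so the
  minimum pairwise distance equals `separation` (in within-class standard
  deviations); this guarantees the nominal separation holds for *every*
  class pair, so separation 0 is exactly class-blind and separation ~10 is
  essentially disjoint.

What the generators do not emulate: real genomes have skewed base
composition, shared phylogenetic structure, repeat families beyond a single
exact inverted repeat, and feature distributions that are neither Gaussian
nor independent of class size. Tests passing on these fixtures demonstrate
that the machinery is correct and calibrated, not that any particular
accuracy will be reached on survey data.

## Filtering and aggregation

The outlier filter computes μ and population σ (ddof = 0) per measure
(default SL, GC, NC_best) **once** over the full table and removes rows
strictly outside [μ − kσ, μ + kσ] (k = 3 default); boundary values survive.
It is deliberately single-pass — re-running on the kept rows could remove
more, and the one-pass semantics keeps the removal set a pure function of
the input table. Taxonomy filtering retains only records with a non-empty
lineage at every rank realm→genus and no rank containing the token
"unclassified" (case-insensitive).

Per-rank aggregation reports mean and count per group, counting only
non-missing values, so NCC means cover exactly the strictly-positive subset.
The cladogram is the rank tree realm→genus; every node carries the mean of
the chosen measure over the genome rows beneath it (hence leaf-count-weighted
consistency at every level), with children ordered lexicographically.
Export is Newick with internal node labels (names with spaces quoted)
plus a TSV of per-node statistics.

## Classification harness

Classes with fewer than 4 members are dropped once, before any splitting.
Each repetition r (default 50) performs a stratified 80/20 train/test split
with seed `task.seed + r`, standardizes features on the training fold, fits
the named classifier family with library-default hyperparameters (recorded
in the result for audit), and scores accuracy (percent) and a hand-computed
support-weighted F1 (cross-checked against scikit-learn in tests). A
degenerate split is re-drawn with the next seed and logged. The analytic
baseline p_hit = Σ_i p(c_i)·(1/N) collapses to 100/N percent for N classes
regardless of imbalance; it is reported rounded to 2 decimals.

The default feature set is (SL, GC, NC_best, NC_IR0, NC_IR1, NC_IR2); DIFF
and NCC are carried as extra columns and any feature subset can be selected
per task.

## Numerical choices and degenerate inputs

* Ties in level sweeps go to the lowest config index (order-stable).
* Empty sequences, empty tables, non-ACGT symbols reaching the compressor,
  even or oversized smoothing windows, unknown ranks, and sub-2-class tasks
  raise errors rather than guessing.
* A measure with zero spread removes nothing in the outlier filter.
* Sanitization draws one uniform base per non-ACGT symbol from a
  per-file seeded generator, consumed in sequence order, making ingestion
  reproducible and idempotent (a clean sequence consumes no randomness).
* All mixer weights stay normalized to 1 within 1e−9; per-symbol bits are
  non-negative and sum to the total within 1e−6 relative.

## Problem sizes

The test suite and the acceptance script use 10 kb constructs with 5
replicates for the IR benchmark, 2–4 kb sequences for profile checks,
exhaustive enumeration of all 4^8 length-8 sequences for the oracle
equivalence check, and 240-sample Gaussian tables for harness calibration —
sizes at which every claimed effect is comfortably detectable and the whole
suite runs in well under a minute of compute per component.

## Known limitations

* The mixer is a decayed weighted-expert scheme; compressors with trained
  nonlinear mixers can achieve lower absolute NC. Comparisons should
  therefore be within-package (between IR modes, between sequences), where
  the measures are internally consistent.
* NCC and DIFF quantify *exact and near-exact* inverted-repeat content;
  heavily diverged repeats (>~10% substitution) fade below detection, as the
  benchmark curve shows.
* The outlier filter assumes roughly unimodal measure distributions; on
  strongly multimodal data μ ± 3σ may remove legitimate groups.
* Survey-scale results (accuracies on real taxonomies, removal counts on
  specific snapshots) depend on the input collection and are not reproduced
  by the synthetic fixtures.
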