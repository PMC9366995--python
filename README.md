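# nucomp

Compression-based complexity analysis of nucleotide sequences.

`nucomp` is for researchers who want to quantify how much information a
DNA/RNA sequence carries — and where that information sits — without aligning
it to anything. It targets small, compact genomes (viruses are the motivating
case) and answers questions like: how redundant is this genome? does it carry
inverted repeats, and how many? which regions are low-complexity? can simple
compression-derived features separate taxonomic groups?

## The model

The engine is a mixture of adaptive finite-context models (FCMs). An order-k
model predicts the next base from smoothed occurrence counts,

    P(s | ctx) = (n(ctx, s) + α) / (Σ_s' n(ctx, s') + 4α),

and the mixture blends model predictions with performance-derived weights
that decay as `w_m ← w_m^γ_m · P_m(observed)` (renormalized) after every
symbol. The compressed size is the ideal code length `C(x) = Σ_i −log2
p_mix(x_i)` in bits. The default configuration (`level16`) mixes an order-1
model (α = 1, γ = 0.7) with an order-12 model (α = 1/50, γ = 0.97) that also
performs inverted-repeat detection.

From `C(x)` the package derives, per genome of length `|x|`:

* **NC** = C(x) / (2|x|) — normalized compression; ≈1 incompressible, ≈0
  fully redundant;
* **NR** = 1 − NC — normalized redundancy;
* **NC_IR0 / NC_IR1 / NC_IR2** — NC with the inverted-repeat subprogram off /
  alongside the regular context model / alone. An inverted repeat is scored
  by counting the reverse-complemented reading of each (k+1)-mer window, so
  a region whose reverse complement occurred earlier becomes cheap;
* **NCC** = 1 − NC_IR2 (kept only when positive) and **DIFF** = NC_IR0 −
  NC_IR1, both of which quantify inverted-repeat content;
* **GC** and **SL** — GC-content percent and sequence length;
* **B(x_i)** = min(C_fwd(x_i), C_bwd(x_i)) — the minimal bidirectional
  complexity profile, a per-position information map.

A classification harness feeds these features to five classifier families
(LDA, GNB, KNN, SVM, XGB) under a repeated stratified 80/20 holdout and
compares them with the analytic random baseline `p_hit = 100/N %` for N
classes. Dataset-level helpers filter outliers at μ ± 3σ, aggregate measures
per taxonomic rank, and export annotated cladograms (Newick + TSV).

## Worked example

Build a 10 kb synthetic sequence whose second half is the reverse complement
of its first half (an exact inverted repeat), and measure it:

```python
from nucomp import make_ir_construct, mutate
from nucomp.io_seq import GenomeRecord
from nucomp.measures import feature_vector

seq = make_ir_construct(10_000, seed=7)
fv = feature_vector(GenomeRecord(accession="ir_demo", residues=seq))
print(fv)
```

prints (abridged):

```
SL      = 10000
GC      = 50.24
NC_best = 0.5259
NC_IR0  = 1.0016
NC_IR1  = 0.5255
NC_IR2  = 0.5258
NCC     = 0.4742
DIFF    = 0.4760
```

Read: without IR detection the sequence looks incompressible (NC_IR0 ≈ 1.0),
but any IR-aware mode compresses it to ≈0.53 — the 5,000-base second half
costs almost nothing once the first half is known, so NCC ≈ 0.47 of the
sequence's information capacity is inverted-repeat redundancy. Mutating 10%
of the bases erodes the signal:

```
after 10% mutation: NC_IR2 = 0.9843, DIFF = 0.0175
```

The same measures run from the shell:

```bash
nucomp features --fasta genomes.fa --meta taxonomy.tsv --out features.tsv
nucomp bench-ir --n 10000 --rates 0:0.10:0.01 --reps 5 --seed 7 --out curve.tsv
nucomp profile --fasta genomes.fa --window 501 --out profile.tsv
nucomp classify --features features.tsv --target family --classifier XGB --out results.tsv
```

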