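# normcov

Replicon copy-number, plasmid-stability and within-culture heterogeneity
analysis for multi-replicon bacterial genomes, built around the genome of
*Aminobacter* sp. MSH1 — a strain with one 5.30 Mb chromosome and seven
plasmids (pBAM1, pBAM2, pUSP1–pUSP5; 6,321,606 bp in total).

## The problem

Sequencing a bacterial culture and mapping reads back to its assembled genome
gives each replicon a depth relative to the chromosome:

> **NormCov** = mean window depth of a replicon ÷ per-base mean depth of the
> chromosome.

NormCov 1 means one replicon copy per chromosome copy. For MSH1 grown in
broth, six of the seven plasmids sit at NormCov ≈ 0.3–0.6, which is
ambiguous between two biological explanations:

* **chromosome polyploidy** — every cell carries the plasmids, but the
  chromosome is present at P > 1 copies per cell (a single-copy plasmid then
  shows NormCov 1/P);
* **unstable inheritance** — the chromosome is at one copy, but only a
  fraction c < 1 of cells still carry each plasmid.

A panel of n clonal colonies (each founded by a single cell) separates the
two. Under instability, each founder lacks the plasmid with probability
1 − c, so with c = 0.5 and n = 14 one expects 7 losses per plasmid. The
package formalizes this as a one-sided exact binomial test plus a likelihood
ratio against a small background loss rate ε:

```
p_value_loss = P(X ≤ k | X ~ Binomial(n, 1 − ĉ)),   ĉ = min(NormCov, 1)
log_lr       = log10 [ Binom(k; n, ε) / Binom(k; n, 1 − ĉ) ]
```

with verdict `polyploidy_supported` iff `p_value_loss < α` and `log_lr > 0`.
Observing k = 1 loss in 14 colonies at ĉ = 0.5 gives
p = 15/16384 ≈ 9.2·10⁻⁴: strong support for polyploidy.

The package also includes the companion within-culture heterogeneity screen:
pileup-based allele counting with a variant call whenever the
alternate-allele fraction reaches the consensus cutoff τ = 0.35, and a
two-sample classifier separating fixed differences between cultures from
shared or private heterogeneity within them.

Everything is driven either by real alignments (any SAM whose records use
M/=/X CIGAR operations) or by the built-in generators: registry-shaped
random genomes, cell-population models (ploidy, per-plasmid copy number,
carriage fractions), clonal colony founders, and a paired-end read simulator
(2 × 151 bp, per-replicon abundance ∝ copy number × length) that emits
FASTQ plus truth alignments in minimal SAM.

## Worked example

Estimate copy numbers for a diploid-chromosome population with single-copy
plasmids (`examples/02_copy_number_from_reads.py`):

```python
from normcov import (
    PopulationModel, ReadPairSpec, attach_random_sequences, msh1_registry,
    normcov_tracks, simulate_reads, summarize_copy_numbers, windowed_depth,
)

genome = attach_random_sequences(msh1_registry(), seed=1)
model = PopulationModel(genome=genome, ploidy=2.0)
spec = ReadPairSpec(n_pairs=100_000, seed=1, fragment_mean=400, fragment_sd=40)
alignments = simulate_reads(model, spec)
normcov = normcov_tracks(windowed_depth(alignments, window_bp=1000), "chromosome")
print(summarize_copy_numbers(normcov, seed=1).round(3).to_string(index=False))
```

prints

```
  replicon  normcov_mean  normcov_median  ci95_low  ci95_high  n_windows
chromosome         1.000           0.991     0.994      1.017       5302
     pBAM1         0.500           0.484     0.455      0.544         41
     pBAM2         0.522           0.517     0.477      0.564         54
     pUSP1         0.509           0.500     0.492      0.525        368
     pUSP2         0.492           0.489     0.476      0.507        366
     pUSP3         0.483           0.480     0.453      0.514         98
     pUSP4         0.522           0.509     0.486      0.559         65
     pUSP5         0.460           0.447     0.411      0.509         32
```

Every plasmid lands near NormCov 0.5 — one plasmid copy per two chromosome
copies — and the chromosome self-normalizes to exactly 1. Feeding the 0.5
estimate and a panel with one loss among 14 colonies to the stability test
(`examples/03_colony_panel_inference.py`) prints

```
observed k=1 of n=14, implied carriage c_hat=0.5
P(X <= 1 | Binomial(14, 0.5)) = 9.155e-04
log10 LR (polyploidy vs instability)  = 2.40
verdict: polyploidy_supported
```

The other example scripts cover the replicon registry and GC-skew tracks
(`01`), the heterogeneity screen on an engineered 60/40 haplotype mixture
(`04`), and the end-to-end experiment driver with per-colony sequencing
(`05`).

## Command line

A thin CLI mirrors the library for file-based pipelines:

```bash
normcov simulate-genome --seed 1 --out genome.fasta
normcov simulate-population --ploidy 2 --genome genome.fasta --out pop.json
normcov simulate-reads --genome genome.fasta --population pop.json \
    --n-pairs 100000 --seed 1 --sam reads.sam
normcov infer-cn --sam reads.sam --out copy_number.tsv
normcov colony-test --summary copy_number.tsv --panel panel.tsv --out verdicts.tsv
```

plus `coverage`, `normcov`, `het-call`, `replicon-stats`, `validate-registry`
and `experiment` (run `normcov --help`).

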