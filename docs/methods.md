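# Methods

## Replicon model and coordinates

A genome is an ordered set of replicons with exactly one chromosome.
Coordinates are 0-based half-open everywhere inside the package; SAM and VCF
outputs convert to their 1-based conventions at the boundary. Circular
topology is recorded but windows and simulated fragments never wrap the
origin: this matches the semantics of the standard depth tools
(samtools/bedtools) whose window statistics the coverage module reproduces,
and at the depths used here it biases only the terminal window of each
replicon. Windows tile each replicon; the trailing window may be partial and
all window statistics are per-base means over the window's actual width, so
partial windows are unbiased.

The MSH1 substrain DK1 registry is sequence-free: it carries the published
lengths (chromosome 5,301,518 bp; pBAM1 40,559; pBAM2 53,893; pUSP1 367,423;
pUSP2 365,485; pUSP3 97,029; pUSP4 64,122; pUSP5 31,577; total
6,321,606 bp) and GC percentages. `attach_random_sequences` equips it with
i.i.d. random sequences at those lengths and GC targets;
`validate_registry` cross-checks computed lengths/GC against the registry
when real accession FASTA files are supplied. N bases count toward length
but are excluded from both numerator and denominator of GC and GC-skew;
windows with no G or C report skew 0.

## Population model

A population is (P, {CN_p}, {c_p}): chromosome ploidy P > 0, per-plasmid
copies per *carrying* cell CN_p, and carriage fractions c_p ∈ [0, 1].
Design choices, each made once:

* Ploidy is a population constant. The biology of interest is
  medium-dependent ploidy, not cell-to-cell ploidy variance, so no per-cell
  ploidy distribution is modelled.
* Fractional copy numbers (e.g. 2.5) are abundance weights — averages over
  carrying cells — realized at read-simulation time, never rounded to
  per-cell integers. Bulk sequencing cannot distinguish "2.5 copies in every
  cell" from mixtures of integer copy numbers, and the package does not
  claim to.
* Plasmid presence events in colony founders are independent across plasmids
  (the null model). A `shared_loss_prob` hook couples losses for sensitivity
  exploration but defaults off.

## Read simulation

Each fragment independently picks a replicon with probability ∝ effective
copies × length, where effective copies are P for the chromosome and
c_p·CN_p for plasmids (presence·CN_p when simulating a single colony
founder). Drawing replicons per fragment rather than per cell is equivalent
in expectation and simpler. Fragment lengths are normal (default
400 ± 40 bp) truncated to [read length, replicon length]; starts are uniform;
mate orientation is randomized per pair; reads are 151 bp; substitution
errors (default 0) are applied after placement so recorded coordinates stay
the truth. Qualities are constant Q40 because no downstream step uses them.
Replicons shorter than the read length are excluded with a warning. Fixed
seeds give byte-identical FASTQ/SAM. Indel and quality-model realism, and
actual read mapping, are out of scope — truth alignments stand in for the
mapping step, and any externally mapped SAM restricted to M/=/X CIGAR
records can be substituted.

## Coverage and NormCov

Depth accumulates every aligned base of every record; overlapping mates
double-count by default, matching the default of the standard depth tooling
(`double_count=False` subtracts each pair's overlap once). The chromosome
mean μ_chr is total aligned bases on the chromosome divided by chromosome
length — a per-base mean, which coincides with the mean of window means for
full windows and stays well-defined with a partial trailing window. NormCov
of a window is its mean depth divided by μ_chr.

The replicon-level point estimate is the width-weighted mean of window
NormCov values, algebraically equal to the replicon's total-depth ratio; it
is therefore exactly invariant to window size (1, 1000, 10000 bp agree to
float precision), which the tests assert. The median is reported for
robustness but is not the primary estimate. The 95% CI is a percentile
bootstrap over windows (default 1000 replicates, seeded); when all windows
are equal the CI collapses to a point. The default window is 1000 bp, the
resolution at which the underlying experiment was analysed.

## Stability inference

With ĉ = min(bulk NormCov, 1) as the carriage the instability hypothesis
implies, and k losses among n colonies:

* `p_value_loss` = P(X ≤ k | X ~ Binomial(n, 1 − ĉ)), a one-sided exact tail
  computed by direct pmf summation (no normal approximation) — few losses
  contradict the instability null, and the argument is directional.
* `log_lr` = log10 of Binom(k; n, ε)/Binom(k; n, 1 − ĉ), comparing a
  background loss rate ε under polyploidy (default 0.02) against the
  instability likelihood.
* verdict: `polyploidy_supported` iff p < α (default 0.05) and log_lr > 0;
  `instability_supported` iff p ≥ α and log_lr < 0; otherwise
  `inconclusive`.

Degenerate case: when ĉ = 1 the instability null predicts zero losses, so
any observed loss has null probability 0 and `p_value_loss` is reported as
0 (the plain tail sum would give 1, which would misrepresent an impossible
outcome). NormCov > 1 cannot arise from instability; carriage is capped at
1 with a warning. The lower-tail p-value is monotone **non-decreasing** in
ĉ away from that degenerate point: higher implied carriage makes losses
rarer under the null, so observing few losses becomes less surprising.

ε is not identified by a single panel, so `epsilon_sensitivity` sweeps it
(0.005–0.2 by default) and the experiment driver writes the sweep next to
the verdicts. No multiple-testing correction is applied across plasmids by
default; a Bonferroni flag exists. `expected_losses` returns both the
per-plasmid expectation n(1 − c) and the any-plasmid expectation
n(1 − Πc), since "how many colonies lose something" and "how many lose
plasmid p" differ sharply when several plasmids are unstable at once.

The package reports 1/NormCov as a descriptive ploidy only; it does not
model ploidy regulation across growth media.

## Heterogeneity screen

Pileup columns count A/C/G/T per reference position from M/=/X segments
(N bases skipped); I/D CIGAR operations bump a per-site indel tally that is
reported but never called — indel alleles are outside the caller's scope. A
substitution allele is called when its fraction of the column depth is
≥ τ = 0.35 (the cutoff is on the alternate-allele fraction, boundary
inclusive) and depth ≥ 10 (configurable; the depth floor is this package's
choice). Multiple alternate alleles at one site are evaluated
independently.

Two-sample classification over the union of called sites, on the pair of
alternate fractions (f_A, f_B):

| class | condition |
|---|---|
| fixed_difference | one ≥ 0.95 and the other ≤ 0.05 |
| shared_heterogeneity | both in [τ, 0.95) |
| private_heterogeneity | exactly one in [τ, 0.95), the other ≤ 0.05 |
| ambiguous | anything else |

The 0.05/0.95 fences are this package's operational choices for "absent"
and "fixed". No realignment, base-quality weighting, phasing or structural
variants.

## Experiment driver

`run_experiment` chains the stages: build a registry-shaped genome, simulate
a bulk library, estimate copy numbers, sample n colony founders from the
same population (under full carriage the background rate ε acts as a small
per-colony loss probability), sequence each colony, call plasmid presence at
a NormCov floor of 0.05, and run the stability test per plasmid. All
randomness derives from one seed through independent spawned streams;
reruns are byte-identical, and every output carries a provenance header
(version, seed, config hash).

## What the generators do and do not emulate

The synthetic data reproduces the *structure* of the experiment: relative
replicon abundances, colony founder sampling, binomial loss statistics,
engineered allele mixtures at known sites. It does not emulate GC-coverage
bias, mappability artifacts, duplicate reads, indel or quality-dependent
errors, plasmid fitness effects or per-generation segregation dynamics.
Passing tests therefore demonstrate that the estimators and tests recover
the parameters of this generative model, not that real libraries are free
of those biases; on real data the NormCov estimates inherit whatever depth
biases the mapping carries.

## Problem sizes and numerical choices

Full-scale analyses (the acceptance script, the NormCov band checks) use
the complete 6.32 Mb registry genome with 100,000 read pairs — about 9.5×
chromosome depth at ploidy 2 — where plasmid-level NormCov has a relative
standard error of a few percent even for the 31.6 kb pUSP5. The test
suite's parameter-recovery grid (ploidy 1–3 × copy number 0.5–2.5) runs on
a proportionally scaled genome (300 kb chromosome, 40 kb plasmid, 40,000
pairs), which preserves the per-window depth regime while keeping the suite
fast; recovery there is within 5% relative error. Simulation-calibration
checks (p-value uniformity on its discrete support, >95% verdict power at
ε = 0.02) use 10,000 panels. Chi-square goodness-of-fit checks on read
multinomials use α = 0.001 at 50,000 pairs. All stochastic tests fix their
seeds.
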