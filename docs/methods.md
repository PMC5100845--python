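# Methods

## Scope and model

`sdbias` quantifies anti-Shine-Dalgarno (aSD) binding of hexamer windows
inside bacterial coding sequences, tests whole genomes for SD depletion
against a codon-shuffled null, and relates the scores to expression and
growth-rate data. Coding sequences are taken at face value from FASTA or
GenBank input (start through stop, coding strand); 5'-UTR initiation-site SD
usage, positional trends within genes, and temperature effects are out of
scope. The aSD core is fixed at 5'-CCUCCU-3' by default because that core is
nearly universal and lineage-specific 16S tails are poorly annotated; it is
a parameter for users who know their lineage's tail.

## Hexamer energies

The built-in energy backend is a nearest-neighbor ungapped hybridization
model, not a full secondary-structure fold. For a hexamer/aSD pair it scans
all antiparallel offsets, scores each maximal run of ≥ 2 canonical pairs as

    ΔG = ΔG_init + Σ stack ΔG°37 + terminal penalties,

and keeps the most favorable run. Watson-Crick stacks use the standard
37 °C RNA/RNA values (Xia-Turner set); a stack containing a G·U wobble is
scored by substituting the corresponding A·U pair plus a +1.0 kcal/mol
penalty per wobble pair; duplex initiation is +4.09 kcal/mol and terminal
A·U or G·U pairs add +0.45 each. Bulges, internal loops, dangling ends and
intramolecular structure are ignored. The design target is rank fidelity,
not thermodynamic precision: all downstream statistics are rank- or
sign-based, and the model provably places the perfect aSD complement
(AGGAGG for CCUCCU) at the unique global minimum (−8.49 kcal/mol) with
every hexamer ≤ 0 after clamping. Users wanting parity with a specific
thermodynamic engine can load a precomputed 4096-row TSV
(`hexamer\tdelta_g`); positive values are clamped to 0 on load with a
logged count.

Clamping is deliberate: the affinity transform uses |ΔG|, so an unfavorable
(positive) raw energy would otherwise masquerade as strong binding. A
clamped window has affinity exp(0) = 1, i.e. "no binding". This choice is
echoed in every output's metadata header.

## Scores

Window affinity A = exp(|ΔG|) (Eq. form: natural exponential); gene score
S = ln Ā over all L−5 windows, including windows overlapping the start and
stop codons (the simplest reading of "every hexamer in the coding region";
exclusion is possible by trimming input). Windows containing ambiguous
bases are masked and logged, never silently zeroed. S ≥ 0 under a clamped
table, because every affinity is ≥ 1.

Genome aggregates are unweighted means over genes (not windows), so long
genes do not dominate. The ribosomal SD bias

    B_SD = (S̄_ribosomal − S_genome) / S_genome × 100%

is reported only when ribosomal genes are identified (GenBank `product`
matching the case-insensitive regex `ribosomal (subunit )?protein` by
default — annotation vocabularies vary, so the pattern is user-overridable)
and S_genome > 0. Canonical-motif counts include overlapping AGGAGG
occurrences.

## Codon-shuffled null model

Each randomized gene redistributes its own codons: for every amino acid,
the codons the gene actually uses are dealt back to that amino acid's
positions without replacement (a uniform random permutation). Translation
and the per-gene codon multiset are exactly conserved; start and stop
codons never move. Genes with internal stops or non-standard codons under
the configured genetic code (NCBI table 11 by default; a parameter for
e.g. Mycoplasma, table 4) are passed through unshuffled with a warning
rather than dropped, so genome-level statistics stay comparable.

The Monte Carlo test computes the statistic (S_genome or total canonical
motif count) on the observed genome and on n replicates; z = (obs − null
mean)/null SD, and the one-sided (depletion) p-value uses the add-one
estimator p = (1 + #{null ≤ obs})/(n + 1), which cannot return 0 and is
well-calibrated for rank-based testing; a two-sided option doubles the
smaller tail. A single master seed spawns one independent substream per
replicate, so results do not depend on evaluation order. When the null SD
is 0 (no synonymous freedom) z is reported as NaN and p comes from ranks
(p = 1 in the fully degenerate case).

## Nc′ (codon usage covariate)

Nc′ is the effective number of codons with the chi-square
background-composition correction: per synonymous family of size k observed
n ≥ 2 times, F̂′ = (χ² + n − k)/(k(n − 1)) with expected proportions e_i
given by the product of background nucleotide frequencies of each codon's
three positions, renormalized within the family; Nc′ = 2 + 9/F̄′₂ + 1/F̄′₃ +
5/F̄′₄ + 3/F̄′₆ (multiplicities derived from the genetic code in use),
capped at 61. The background is the gene's own composition by default
(start/stop excluded, mirroring the codons the null model can move) and can
be overridden with explicit frequencies (e.g. genome-wide or uniform).
Numerical guards: families with n < 2, any e_i = 0, or F̂′ ≤ 0 (possible at
tiny n, where χ² + n − k can be negative) are excluded from the class mean
with a log message; a missing 3-fold class (Ile) is imputed as the mean of
the 2- and 4-fold classes, the conventional fallback; any other missing
class leaves Nc′ undefined (NaN) and the gene is dropped from regressions.
Note that Nc′ = 20 for a one-codon-per-amino-acid gene holds exactly only
when the within-family expected proportions are uniform; under a gene-level
background such a gene skews its own expectations.

## Regressions

Expression is log-transformed (natural log) before regression by default —
abundances span orders of magnitude — with non-positive values dropped and
counted; the transform is configurable. OLS, adjusted R², AIC and BIC come
from statsmodels (k counts intercept, slopes and error variance); model
comparisons (ΔRadj², ΔAIC, ΔBIC) are only computed on identical observation
sets and refuse otherwise. Negative coefficients on S mean "fewer internal
SD sites → higher expression"; no sign conventions are applied. Spearman ρ
uses average ranks with the large-n p approximation.

PGLS: the residual covariance is V(λ) = Brownian tree covariance C (entries
= root-to-MRCA shared path length) with off-diagonals multiplied by
λ ∈ [0, 1]. λ̂ maximizes the profile Gaussian (ML) likelihood by bounded
scalar search (tolerance 1e-4), compared against both boundaries; boundary
optima are flagged and reported as exactly 0 or 1. Coefficient SEs use the
residual-dof variance estimate; R² is computed against the intercept-only
GLS fit under the same V(λ). On an ultrametric tree V(0) is proportional to
the identity, so the λ = 0 fit coincides with OLS; a saturated fit (n =
p, e.g. two tips) returns coefficients with NaN SEs rather than erroring.
The fit is cross-checked in the test suite against R's `ape`/`nlme`
(`gls` + `corPagel` at fixed λ): slope and log-likelihood agree to ≤ 1e-5.
Either regression direction (doubling time on B_SD or the reverse) is
possible; the pipeline default regresses log doubling time on B_SD.

## Synthetic data

The generators emulate the statistical structure of a multi-genome
depletion study so every stage has a closed-loop test with known truth.

* **Genomes.** Amino acids uniform over the 20 (start Met, stop TAA); inner
  length Poisson or negative-binomial, default mean 300 codons (typical
  bacterial gene length), dispersion 0.3; default 100 genes per genome — a
  scaled-down genome that keeps simulation studies tractable. Codons are
  drawn within each family from base weights given by the GC target
  (default 0.5), with codon bias strength b multiplying one deterministic
  preferred codon per family by exp(b) (b = 0: no bias beyond composition;
  Nc′ decreases monotonically in b). About 5% of genes are flagged
  ribosomal by default (of the order of real genomes' ribosomal-protein
  fraction).
* **Planted S shifts.** `plant_sd_shift` hill-climbs over *position swaps*
  of synonymous codons — two positions coding the same amino acid exchange
  their different codons when the swap moves S toward the target (tolerance
  0.02, best-effort with the achieved shift reported). Swaps preserve both
  the protein and the per-gene codon multiset, so planted genes remain
  inside the orbit of the codon-shuffle null: the planted effect is exactly
  the arrangement-level signal the null model measures. (Substitution moves
  that alter the codon multiset would shift the null distribution along
  with the observation and cancel the planted signal.) The achievable shift
  is bounded by the gene's synonymous arrangement space, so tests assert
  against realized behavior, not the requested target.
* **Expression.** log abundance = β₀ + β_S·S + β_Nc·Nc′ + N(0, σ);
  defaults β₀ = 5, β_S = −0.5, β_Nc = −0.05, σ = 1 — a moderate effect in
  the direction observed for real genomes (more internal SD → lower
  expression; stronger codon bias, i.e. lower Nc′, → higher expression).
* **Trees and traits.** Pure-birth trees via dendropy with GSA sampling
  (stopping exactly at a birth event would create zero-length terminal
  branches and a singular covariance). Tip B_SD values are drawn
  independently of the tree (normal, mean −10%, SD 5 — most genomes
  SD-depleted in ribosomal genes); log doubling time = intercept +
  slope·B_SD + residuals with covariance σ²(λ·C̃ + (1−λ)·I), C̃ the
  depth-normalized Brownian matrix. Keeping B_SD tree-independent makes the
  slope and λ separately identifiable.

What the generators do **not** emulate: operon structure, overlapping
genes, intergenic regions, 5'-UTRs, realistic amino-acid composition,
genome-wide GC heterogeneity, or correlated evolution of B_SD with the
tree. Passing tests therefore demonstrate the statistical machinery is
correct and calibrated under the stated generative models — not that real
genomes satisfy those models.

## Problem sizes and determinism

Simulation studies in the test suite use: 200 genomes × 25 genes (~60
codons) × 200 replicates for null calibration; 100 genomes × 100 genes
(~300 codons) for planted-depletion power; one 2000-gene genome × 100
expression draws for regression power; 100 × 200-tip trees for PGLS
recovery — sizes chosen to make the statistical assertions sharp while
keeping the default test run fast. All generators and tests are pure
functions of their seeds; every pipeline output embeds the tool version, a
config hash and the seed, and reruns are byte-identical.

## Known limitations

* The built-in energy model ranks hexamers sensibly but its absolute ΔG
  values are not those of a full folding engine; quantitative comparisons
  across energy backends should use rank statistics or a shared external
  table.
* Whether the original analyses included windows spanning the stop codon,
  or how positive cofold energies were handled, is not documented in the
  source material this package models; both choices here (include;
  clamp-to-zero) are recorded in output metadata.
* Nc′ is undefined for very short or compositionally extreme genes; such
  genes are excluded from regressions with a log message.
* PGLS assumes the tree's branch lengths are meaningful and the trait
  model Gaussian; λ is searched only in [0, 1].
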