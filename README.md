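# sdbias

Shine-Dalgarno (SD) sequence depletion analysis within bacterial coding
regions.

In bacteria, purine-rich SD motifs (canonically 5'-AGGAGG-3') in the 5' UTR
recruit the ribosome by pairing with the anti-SD (aSD) tail of the 16S rRNA
(core 5'-CCUCCU-3'). The same pairing *inside* coding sequences can slow or
derail elongating ribosomes, so selection is expected to purge SD-like sites
from ORFs — most strongly from highly expressed genes. `sdbias` quantifies
this signal and tests it:

* **Per-gene aSD binding score.** Every 6-nt window of a coding sequence is
  assigned a hybridization free energy ΔG (kcal/mol) to the aSD core, its
  affinity is A = exp(|ΔG|), and the gene score is

      S = log Ā

  the natural log of the mean window affinity. Strong binders dominate;
  non-binding windows contribute 1. Energies come from a built-in
  nearest-neighbor RNA/RNA duplex model (Watson-Crick + G·U wobble stacks at
  37 °C, duplex-initiation penalty, positive energies clamped to 0), or from
  any externally computed 4096-hexamer TSV table.
* **Codon-shuffled null model.** Each gene's synonymous codons are permuted
  without replacement (translation and per-gene codon usage preserved,
  start/stop fixed), giving randomized genomes. A genome statistic —
  S_genome = mean S over genes, or the total count of canonical AGGAGG
  motifs — is compared to its null distribution via a z-score and a
  rank-based Monte Carlo p-value.
* **Ribosomal SD bias.** B_SD = (S̄_ribosomal − S_genome)/S_genome × 100%;
  negative values mean ribosomal-protein genes are depleted of internal SD
  sites relative to the genome.
* **Association analyses.** OLS of log expression on S and the
  composition-corrected effective number of codons Nc′, with adjusted R² and
  AIC/BIC model comparison; Spearman rank correlation; and phylogenetic
  generalized least squares (PGLS) of growth rate on B_SD with Pagel's λ
  estimated by maximum likelihood.
* **Synthetic data generators** for closed-loop testing: multi-gene genomes
  with controllable GC content, codon usage bias and planted S shifts;
  expression tables from a log-linear model; pure-birth trees with
  λ-structured trait covariance.

## Worked example

```python
from sdbias import (GenomeSimSpec, build_energy_table, monte_carlo_test,
                    simulate_genome)
from sdbias.io import score_genome_table

table = build_energy_table()          # aSD = CCUCCU
print("Strongest binder:", table.argmin(), f"{table.min():.2f} kcal/mol")

# a genome whose ribosomal genes carry planted SD depletion
spec = GenomeSimSpec(n_genes=200, gene_length_codons=(300.0, 0.3),
                     sd_shift=-0.3, shift_targets="ribosomal",
                     ribosomal_fraction=0.1, seed=42)
genome = simulate_genome(spec, table)
gene_df, genome_df = score_genome_table(genome, table)
print(genome_df.round(4).to_string(index=False))
```

prints

```
Strongest binder: AGGAGG -8.49 kcal/mol
genome_id  n_genes  s_genome  s_ribosomal  b_sd_percent
   genome      200    1.5355       1.3444      -12.4408
```

AGGAGG, the perfect aSD complement, is the strongest of all 4096 hexamers;
the planted depletion shows up as B_SD ≈ −12%, i.e. ribosomal-protein genes
average ~12% lower aSD binding score than the genome.

Testing a genome with depletion planted in *all* genes against the
codon-shuffle null:

```python
spec = GenomeSimSpec(n_genes=100, gene_length_codons=(300.0, 0.3),
                     sd_shift=-0.2, seed=7)
genome = simulate_genome(spec, table)
res = monte_carlo_test(genome, "s_genome", n_replicates=1000, seed=7,
                       table=table)
print(f"z = {res.z_score:.2f}, one-sided p = {res.p_value:.4f}")
```

```
z = -1.74, one-sided p = 0.0420
```

The observed S_genome (1.4101) sits below the null mean (1.4983): the genome
carries fewer/weaker internal SD sites than its own codon usage predicts.

The same analyses are available from the shell:

```sh
sdbias simulate genome --n-genes 100 --sd-shift -0.2 --seed 7 --out data/
sdbias nulltest --fasta data/synthetic_genome.fasta --replicates 1000 --seed 7 --out out/
sdbias regress  --fasta data/synthetic_genome.fasta --expression expr.tsv --out out/
sdbias pgls     --tree tree.nwk --traits traits.tsv --out out/
```

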