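"""Synthetic genomes, expression tables and phylogenies with known truth.

These generators emulate the statistical structure of a multi-genome SD
depletion study so the whole pipeline can be exercised end-to-end without
external data:

* :func:`simulate_genome` — multi-gene coding sequences with controllable GC
  content, within-family codon usage bias, and an optional planted shift of
  the expected per-gene aSD binding score S in designated gene sets;
* :func:`simulate_expression` — abundances from a log-linear model on S and
  Nc' with Gaussian noise;
* :func:`simulate_tree_and_traits` — pure-birth trees with doubling times
  linked to B_SD through a slope, residuals phylogenetically structured with
  strength λ.

Every generator is a pure function of its spec (seed included); planted
shifts never alter the encoded protein sequence.
"""

from __future__ import annotations

import logging
import random as _pyrandom
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .association import brownian_covariance
from .energy_model import EnergyTable, build_energy_table
from .codon_usage import synonymous_families
from .null_model import translate_codons
from .sd_metrics import (
    GeneRecord,
    affinity_as_array,
    encode_dna,
    score_gene,
    window_codes,
)

__all__ = [
    "GenomeSimSpec",
    "ExpressionSimSpec",
    "ComparativeSimSpec",
    "PlantResult",
    "simulate_genome",
    "plant_sd_shift",
    "simulate_expression",
    "simulate_tree_and_traits",
]

logger = logging.getLogger(__name__)

_AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class GenomeSimSpec:
    """Parameters of one synthetic genome.

    ``gene_length_codons`` is (mean, dispersion) of the inner codon count:
    Poisson at dispersion 0, negative binomial with variance mean·(1 +
    dispersion) otherwise.  ``codon_bias_strength`` b tilts each synonymous
    family toward one deterministic preferred codon with weight ∝ exp(b);
    b = 0 leaves usage at the GC-driven background.  ``sd_shift`` is the
    target change in expected S for the designated genes (0 = unbiased
    genome), planted by synonymous hill-climbing.
    """

    n_genes: int = 100
    gene_length_codons: tuple[float, float] = (300.0, 0.3)
    gc_target: float = 0.5
    codon_bias_strength: float = 0.0
    sd_shift: float = 0.0
    shift_targets: str = "all"  # "all" | "ribosomal"
    ribosomal_fraction: float = 0.05
    genetic_code_id: int = 11
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be ≥ 1")
        for name in ("gc_target", "ribosomal_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.shift_targets not in ("all", "ribosomal"):
            raise ValueError("shift_targets must be 'all' or 'ribosomal'")


@dataclass
class ExpressionSimSpec:
    """Log-linear expression model: log(abundance) = β₀ + β_S·S + β_Nc·Nc' + ε."""

    beta_0: float = 5.0
    beta_s: float = -0.5
    beta_nc: float = -0.05
    noise_sd: float = 1.0
    seed: int = 0


@dataclass
class ComparativeSimSpec:
    """Pure-birth tree with a B_SD → doubling-time relationship.

    Tip B_SD values are drawn independently of the tree; only the residuals
    of log doubling time carry phylogenetic covariance λ_true·V_Brownian
    (off-diagonal), scaled to ``noise_sd``.
    """

    n_tips: int = 200
    lambda_true: float = 1.0
    slope_true: float = 0.05
    noise_sd: float = 0.3
    birth_rate: float = 1.0
    b_sd_mean: float = -10.0
    b_sd_sd: float = 5.0
    intercept: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.lambda_true <= 1.0:
            raise ValueError("lambda_true must lie in [0, 1]")
        if self.n_tips < 2:
            raise ValueError("n_tips must be ≥ 2")
        if self.noise_sd <= 0 or self.birth_rate <= 0:
            raise ValueError("noise_sd and birth_rate must be positive")


@dataclass
class PlantResult:
    gene: GeneRecord
    achieved_shift: float
    converged: bool


def _codon_sampler(
    spec: GenomeSimSpec,
) -> dict[str, tuple[tuple[str, ...], np.ndarray]]:
    """Per-amino-acid codon alternatives and sampling probabilities."""
    q = {
        "G": spec.gc_target / 2.0,
        "C": spec.gc_target / 2.0,
        "A": (1.0 - spec.gc_target) / 2.0,
        "T": (1.0 - spec.gc_target) / 2.0,
    }
    samplers = {}
    for aa, codons in synonymous_families(spec.genetic_code_id).items():
        w = np.array([q[c[0]] * q[c[1]] * q[c[2]] for c in codons])
        if w.sum() == 0:
            w = np.ones(len(codons))
        # deterministic preferred codon (first in sorted order) gains exp(b)
        if spec.codon_bias_strength != 0 and len(codons) > 1:
            w = w.copy()
            w[0] *= np.exp(spec.codon_bias_strength)
        samplers[aa] = (codons, w / w.sum())
    return samplers


def simulate_genome(
    spec: GenomeSimSpec, table: EnergyTable | None = None
) -> list[GeneRecord]:
    """Generate a synthetic genome of valid coding sequences.

    Amino acids are uniform over the 20 (start Met, one stop appended);
    codons are drawn per family from the GC- and bias-tilted preference
    distribution.  Genes designated by ``shift_targets`` receive the planted
    S shift when ``sd_shift`` ≠ 0.  Fully reproducible from the spec.
    """
    rng = np.random.default_rng(spec.seed)
    samplers = _codon_sampler(spec)
    mean, disp = spec.gene_length_codons
    if disp <= 0:
        lengths = rng.poisson(mean, spec.n_genes)
    else:
        # negative binomial with mean `mean`, variance mean·(1 + disp)
        r = mean / disp
        lengths = rng.negative_binomial(r, 1.0 / (1.0 + disp), spec.n_genes)
    lengths = np.maximum(lengths, 10)

    n_rib = int(round(spec.ribosomal_fraction * spec.n_genes))
    rib_idx = set(rng.choice(spec.n_genes, size=n_rib, replace=False).tolist())

    if spec.sd_shift != 0 and table is None:
        table = build_energy_table()

    genes = []
    width = len(str(spec.n_genes))
    for i in range(spec.n_genes):
        aa_seq = "".join(rng.choice(list(_AA20), size=int(lengths[i])))
        parts = ["ATG"]
        for aa in aa_seq:
            codons, p = samplers[aa]
            parts.append(codons[rng.choice(len(codons), p=p)])
        parts.append("TAA")
        is_rib = i in rib_idx
        gene = GeneRecord(
            gene_id=f"gene{i + 1:0{width}d}",
            sequence="".join(parts),
            product=(
                f"50S ribosomal subunit protein L{i + 1}"
                if is_rib
                else "hypothetical protein"
            ),
            is_ribosomal=is_rib,
        )
        if spec.sd_shift != 0 and (spec.shift_targets == "all" or is_rib):
            result = plant_sd_shift(gene, spec.sd_shift, table, rng)
            if not result.converged:
                logger.warning(
                    "gene %s: requested shift %.3f, achieved %.3f",
                    gene.gene_id, spec.sd_shift, result.achieved_shift,
                )
            gene = result.gene
        genes.append(gene)
    return genes


def plant_sd_shift(
    gene: GeneRecord,
    target_shift: float,
    table: EnergyTable,
    rng: np.random.Generator,
    max_iter: int = 2000,
    tol: float = 0.02,
    genetic_code_id: int = 11,
) -> PlantResult:
    """Move a gene's S score by ``target_shift`` via synonymous codon swaps.

    Greedy hill-climbing over position swaps of synonymous codons: two
    positions coding the same amino acid exchange their (different) codons
    whenever the exchange brings S closer to the target.  This keeps both
    the protein sequence and the per-gene codon multiset intact, so planted
    genes stay inside the orbit of the codon-shuffle null model — the
    planted depletion (or enrichment) is exactly the arrangement-level
    signal that null model measures.  Stops within ``tol`` of the target or
    after ``max_iter`` proposals (best effort, flagged); the achievable
    range is bounded by the gene's synonymous arrangement space.
    """
    if target_shift == 0:
        return PlantResult(gene=gene, achieved_shift=0.0, converged=True)
    families = synonymous_families(genetic_code_id)
    aa_of = {c: aa for aa, codons in families.items() for c in codons}
    seq = gene.sequence.upper()
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    by_aa: dict[str, list[int]] = {}
    for i in range(1, len(codons) - 1):
        aa = aa_of.get(codons[i])
        if aa is not None and len(families[aa]) > 1:
            by_aa.setdefault(aa, []).append(i)
    # an amino acid offers moves only if it occupies ≥ 2 positions with ≥ 2
    # distinct codons among them
    movable = [
        positions for positions in by_aa.values()
        if len(positions) > 1 and len({codons[i] for i in positions}) > 1
    ]
    s0 = score_gene(gene, table).s_gene
    target = s0 + target_shift
    current = s0
    if not movable:
        return PlantResult(gene=gene, achieved_shift=0.0, converged=False)

    # fast rescoring on base-encoded codons
    codes = encode_dna(seq)
    if (codes < 0).any():
        logger.warning("gene %s: ambiguous bases, cannot plant shift",
                       gene.gene_id)
        return PlantResult(gene=gene, achieved_shift=0.0, converged=False)
    codon_arr = codes.reshape(-1, 3).copy()
    affinity_arr = affinity_as_array(table)

    def current_s() -> float:
        return float(np.log(affinity_arr[window_codes(codon_arr.reshape(-1))].mean()))

    for _ in range(max_iter):
        if abs(current - target) <= tol:
            break
        positions = movable[rng.integers(len(movable))]
        i = positions[rng.integers(len(positions))]
        j = positions[rng.integers(len(positions))]
        if codons[i] == codons[j]:
            continue
        codon_arr[[i, j]] = codon_arr[[j, i]]
        s_new = current_s()
        if abs(s_new - target) < abs(current - target):
            current = s_new
            codons[i], codons[j] = codons[j], codons[i]
        else:
            codon_arr[[i, j]] = codon_arr[[j, i]]
    converged = abs(current - target) <= tol
    planted = GeneRecord(gene.gene_id, "".join(codons), gene.product,
                         gene.is_ribosomal)
    return PlantResult(gene=planted, achieved_shift=current - s0, converged=converged)


def simulate_expression(
    scores: pd.DataFrame, spec: ExpressionSimSpec
) -> pd.DataFrame:
    """Draw an expression table from the log-linear model on S and Nc'.

    ``scores`` must carry columns ``gene_id``, ``s_gene`` and ``nc_prime``.
    Returns a frame with ``gene_id``, ``abundance`` and the latent
    ``log_abundance``.
    """
    required = {"gene_id", "s_gene", "nc_prime"}
    missing = required - set(scores.columns)
    if missing:
        raise ValueError(f"scores table lacks column(s): {sorted(missing)}")
    rng = np.random.default_rng(spec.seed)
    log_abund = (
        spec.beta_0
        + spec.beta_s * scores["s_gene"].to_numpy(dtype=float)
        + spec.beta_nc * scores["nc_prime"].to_numpy(dtype=float)
        + rng.normal(0.0, spec.noise_sd, len(scores))
    )
    return pd.DataFrame(
        {
            "gene_id": scores["gene_id"].to_numpy(),
            "abundance": np.exp(log_abund),
            "log_abundance": log_abund,
        }
    )


def simulate_tree_and_traits(
    spec: ComparativeSimSpec,
) -> tuple[str, pd.DataFrame]:
    """Pure-birth tree plus per-species B_SD and doubling-time traits.

    Returns (newick string with branch lengths, trait table with columns
    ``species_id``, ``b_sd_percent``, ``log_doubling_time``,
    ``min_doubling_time_hr``).
    """
    rng = np.random.default_rng(spec.seed)
    tree_rng = _pyrandom.Random(int(rng.integers(2**31 - 1)))
    # GSA sampling avoids stopping exactly at a birth event, which would
    # leave zero-length terminal branches and a singular covariance
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=spec.birth_rate,
        death_rate=0.0,
        num_extant_tips=spec.n_tips,
        gsa_ntax=spec.n_tips + 2,
        rng=tree_rng,
    )
    taxa = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    C = brownian_covariance(tree, taxa)
    scale = float(np.mean(np.diag(C)))
    C_norm = C / scale if scale > 0 else C
    n = len(taxa)
    cov = spec.noise_sd**2 * (
        spec.lambda_true * (C_norm - np.diag(np.diag(C_norm)))
        + np.diag(np.diag(C_norm))
    )
    b_sd = rng.normal(spec.b_sd_mean, spec.b_sd_sd, n)
    resid = rng.multivariate_normal(np.zeros(n), cov, method="eigh")
    log_dt = spec.intercept + spec.slope_true * b_sd + resid
    traits = pd.DataFrame(
        {
            "species_id": taxa,
            "b_sd_percent": b_sd,
            "log_doubling_time": log_dt,
            "min_doubling_time_hr": np.exp(log_dt),
        }
    )
    newick = tree.as_string(schema="newick", suppress_rooting=True).strip()
    return newick, traits
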