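"""Effective number of codons corrected for background nucleotide composition.

Nc' measures codon usage bias on the scale of "how many codons are
effectively in use": 61 means every synonymous codon is used as expected
from the gene's nucleotide composition, 20 means one codon per amino acid.
For each synonymous family of k codons observed n times with counts n_i and
background-expected proportions e_i, the corrected homozygosity is

    χ² = Σ_i (n_i − n·e_i)² / (n·e_i)
    F̂' = (χ² + n − k) / (k·(n − 1))

and, averaging F̂' over computable families within each size class k,

    Nc' = 2 + 9/F̄'₂ + 1/F̄'₃ + 5/F̄'₄ + 3/F̄'₆        (standard code)

with family-class multiplicities taken from the genetic code in use.  The
expected proportions e_i are the products of the background frequencies of a
codon's three nucleotides, renormalized within the family; by default the
background is the gene's own composition (start and stop codons excluded),
so compositional skew — e.g. high GC — does not masquerade as codon bias.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable

from .sd_metrics import GeneRecord

__all__ = [
    "CodonUsageStats",
    "codon_counts",
    "background_composition",
    "family_homozygosity_corrected",
    "nc_prime",
]

logger = logging.getLogger(__name__)

NC_CAP = 61.0


@lru_cache(maxsize=4)
def synonymous_families(genetic_code_id: int = 11) -> dict[str, tuple[str, ...]]:
    """Amino acid → tuple of its sense codons (DNA alphabet), sorted."""
    table = CodonTable.unambiguous_dna_by_id[genetic_code_id]
    families: dict[str, list[str]] = {}
    for codon, aa in table.forward_table.items():
        families.setdefault(aa, []).append(codon)
    return {aa: tuple(sorted(codons)) for aa, codons in families.items()}


@dataclass
class CodonUsageStats:
    gene_id: str
    nc_prime: float  # NaN when undefined
    family_homozygosity: dict[int, float] = field(default_factory=dict)
    n_codons: int = 0


def codon_counts(gene: GeneRecord, genetic_code_id: int = 11) -> dict[str, int]:
    """Counts over the sense codons, start and stop codons excluded.

    The first and last codon mirror the positions held fixed by the
    codon-shuffle null model, so Nc' is invariant under shuffling.
    """
    seq = gene.sequence.upper()
    sense = {c for codons in synonymous_families(genetic_code_id).values()
             for c in codons}
    counts: dict[str, int] = {}
    for i in range(3, len(seq) - 3, 3):
        codon = seq[i : i + 3]
        if codon in sense:
            counts[codon] = counts.get(codon, 0) + 1
    return counts


def background_composition(
    gene: GeneRecord, genetic_code_id: int = 11
) -> dict[str, float]:
    """Nucleotide frequencies of A,C,G,T over the counted codons; sums to 1."""
    counts = codon_counts(gene, genetic_code_id)
    tally = {b: 0 for b in "ACGT"}
    for codon, n in counts.items():
        for base in codon:
            tally[base] += n
    total = sum(tally.values())
    if total == 0:
        raise ValueError(f"gene {gene.gene_id}: no countable codons")
    return {b: tally[b] / total for b in "ACGT"}


def family_homozygosity_corrected(
    counts: np.ndarray | list[int], expected: np.ndarray | list[float]
) -> float:
    """Chi-square-corrected homozygosity F̂' of one synonymous family.

    ``counts`` are the observed codon counts, ``expected`` the background
    proportions (must sum to 1 within the family).  Returns NaN (exclusion
    marker) when the family is observed fewer than 2 times or any expected
    proportion is 0.
    """
    counts = np.asarray(counts, dtype=float)
    e = np.asarray(expected, dtype=float)
    if counts.shape != e.shape:
        raise ValueError("counts and expected proportions differ in length")
    n = counts.sum()
    k = len(counts)
    if n < 2 or np.any(e <= 0):
        return float("nan")
    e = e / e.sum()
    chi2 = float(((counts - n * e) ** 2 / (n * e)).sum())
    return (chi2 + n - k) / (k * (n - 1))


def _codon_expected(codon: str, freqs: dict[str, float]) -> float:
    p = 1.0
    for base in codon:
        p *= freqs[base]
    return p


def nc_prime(
    gene: GeneRecord,
    genetic_code_id: int = 11,
    background: dict[str, float] | None = None,
) -> CodonUsageStats:
    """Compute Nc' for one gene.

    Parameters
    ----------
    background
        Nucleotide frequencies used for the expected proportions.  ``None``
        (default) uses the gene's own composition; pass explicit frequencies
        (e.g. genome-wide, or uniform 0.25) to fix the background.

    Returns a :class:`CodonUsageStats`; ``nc_prime`` is NaN when no family
    in some required size class is computable (gene flagged for exclusion
    from regressions).
    """
    families = synonymous_families(genetic_code_id)
    counts = codon_counts(gene, genetic_code_id)
    n_codons = sum(counts.values())
    freqs = background if background is not None else (
        background_composition(gene, genetic_code_id) if n_codons else None
    )
    if freqs is None:
        return CodonUsageStats(gene.gene_id, float("nan"), {}, 0)

    class_multiplicity: dict[int, int] = {}
    f_values: dict[int, list[float]] = {}
    n_singletons = 0
    for aa, codons in families.items():
        k = len(codons)
        if k == 1:
            n_singletons += 1
            continue
        class_multiplicity[k] = class_multiplicity.get(k, 0) + 1
        obs = np.array([counts.get(c, 0) for c in codons], dtype=float)
        expected = np.array([_codon_expected(c, freqs) for c in codons])
        if expected.sum() == 0:
            continue
        f_hat = family_homozygosity_corrected(obs, expected / expected.sum())
        # F̂' ≤ 0 can occur at tiny n (numerator χ² + n − k negative); such
        # families carry no usable signal and are excluded like n < 2 ones
        if not np.isnan(f_hat) and f_hat > 0:
            f_values.setdefault(k, []).append(f_hat)

    f_bar = {k: float(np.mean(v)) for k, v in f_values.items()}
    # impute a missing 3-fold class (Ile only, standard code) from its
    # neighbors; any other missing class leaves Nc' undefined
    if 3 in class_multiplicity and 3 not in f_bar:
        if 2 in f_bar and 4 in f_bar:
            f_bar[3] = (f_bar[2] + f_bar[4]) / 2.0
            logger.info("gene %s: 3-fold class imputed from 2- and 4-fold",
                        gene.gene_id)
    missing = [k for k in class_multiplicity if k not in f_bar]
    if missing:
        logger.warning("gene %s: Nc' undefined (no computable family of size %s)",
                       gene.gene_id, missing)
        return CodonUsageStats(gene.gene_id, float("nan"), f_bar, n_codons)

    nc = n_singletons + sum(
        mult / f_bar[k] for k, mult in class_multiplicity.items()
    )
    return CodonUsageStats(gene.gene_id, min(nc, NC_CAP), f_bar, n_codons)
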