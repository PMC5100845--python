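"""Codon-shuffled null genomes and Monte Carlo tests for SD depletion.

The null model asks: given each gene's amino-acid sequence and its own codon
usage, how much anti-SD binding would we expect by chance?  Each randomized
gene keeps its translation and its per-gene codon multiset; only the
arrangement of synonymous codons changes (the pool of codons the gene
actually uses for each amino acid is dealt back out without replacement,
i.e. uniformly permuted).  Start and stop codons stay fixed.  Repeating this
for every gene yields one randomized genome; a genome-level statistic
(S_genome or the total canonical-motif count) computed over many randomized
genomes gives a null mean/SD, a z-score for the real genome, and a
rank-based Monte Carlo p-value.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from Bio.Data import CodonTable

from .energy_model import EnergyTable
from .sd_metrics import (
    CANONICAL_SD,
    GeneRecord,
    _POWERS,
    affinity_as_array,
    encode_dna,
    table_as_array,
    window_codes,
    window_energies,
)

__all__ = [
    "NullTestResult",
    "shuffle_gene_codons",
    "shuffle_genome",
    "monte_carlo_test",
    "translate_codons",
]

logger = logging.getLogger(__name__)

STATISTICS = ("s_genome", "canonical_sd_total")


def _codon_to_aa(genetic_code_id: int) -> dict[str, str]:
    """Codon → amino-acid map (stops mapped to '*') for an NCBI table id."""
    table = CodonTable.unambiguous_dna_by_id[genetic_code_id]
    mapping = dict(table.forward_table)
    for stop in table.stop_codons:
        mapping[stop] = "*"
    return mapping


@dataclass
class NullTestResult:
    """Observed statistic versus its codon-shuffled null distribution."""

    statistic_name: str
    observed: float
    null_mean: float
    null_sd: float
    z_score: float  # NaN when null_sd == 0
    p_value: float  # add-one Monte Carlo estimate, in (0, 1]
    n_replicates: int
    seed: int
    alternative: str = "less"
    null_values: np.ndarray | None = None


# ---------------------------------------------------------------------------
# public, record-level shuffling


def shuffle_gene_codons(
    gene: GeneRecord,
    rng: np.random.Generator,
    genetic_code_id: int = 11,
) -> GeneRecord:
    """Return a synonymous-codon permutation of one gene.

    Translation and per-gene codon multiset are preserved; the first (start)
    and last (stop) codons are left untouched.  Genes with internal stops or
    non-standard codons are passed through unchanged with a warning.
    """
    seq = gene.sequence.upper()
    codon_map = _codon_to_aa(genetic_code_id)
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    inner = codons[1:-1]
    aas = []
    for codon in inner:
        aa = codon_map.get(codon)
        if aa is None:
            logger.warning("gene %s: non-standard codon %s, not shuffled",
                           gene.gene_id, codon)
            return gene
        if aa == "*":
            logger.warning("gene %s: internal stop codon, not shuffled",
                           gene.gene_id)
            return gene
        aas.append(aa)
    groups: dict[str, list[int]] = {}
    for idx, aa in enumerate(aas):
        groups.setdefault(aa, []).append(idx)
    shuffled = list(inner)
    for positions in groups.values():
        if len(positions) > 1:
            perm = rng.permutation(len(positions))
            for dst, src in zip(positions, perm):
                shuffled[dst] = inner[positions[src]]
    new_seq = codons[0] + "".join(shuffled) + codons[-1]
    return GeneRecord(
        gene_id=gene.gene_id,
        sequence=new_seq,
        product=gene.product,
        is_ribosomal=gene.is_ribosomal,
    )


def shuffle_genome(
    genome: list[GeneRecord],
    rng: np.random.Generator,
    genetic_code_id: int = 11,
) -> list[GeneRecord]:
    """Shuffle every gene independently; gene order is preserved."""
    return [shuffle_gene_codons(g, rng, genetic_code_id) for g in genome]


def translate_codons(sequence: str, genetic_code_id: int = 11) -> str:
    """Translate a CDS (including stop as '*'); raises on non-standard codons."""
    codon_map = _codon_to_aa(genetic_code_id)
    seq = sequence.upper()
    return "".join(codon_map[seq[i : i + 3]] for i in range(0, len(seq), 3))


# ---------------------------------------------------------------------------
# fast encoded path for Monte Carlo loops


class _EncodedGene:
    """Base-encoded gene with synonymous-position groups for fast shuffling."""

    __slots__ = ("codes", "codons", "groups", "shuffleable", "clean")

    def __init__(self, gene: GeneRecord, genetic_code_id: int):
        self.codes = encode_dna(gene.sequence)
        self.clean = bool((self.codes >= 0).all())
        n_codons = len(gene.sequence) // 3
        self.codons = self.codes[: n_codons * 3].reshape(n_codons, 3)
        self.groups: list[np.ndarray] = []
        self.shuffleable = True
        codon_map = _codon_to_aa(genetic_code_id)
        seq = gene.sequence.upper()
        aas = []
        for i in range(1, n_codons - 1):
            aa = codon_map.get(seq[3 * i : 3 * i + 3])
            if aa is None or aa == "*":
                self.shuffleable = False
                return
            aas.append(aa)
        by_aa: dict[str, list[int]] = {}
        for idx, aa in enumerate(aas, start=1):
            by_aa.setdefault(aa, []).append(idx)
        self.groups = [
            np.asarray(p, dtype=np.int64) for p in by_aa.values() if len(p) > 1
        ]

    def shuffled_codes(self, rng: np.random.Generator) -> np.ndarray:
        if not self.shuffleable or not self.groups:
            return self.codes
        codons = self.codons.copy()
        for positions in self.groups:
            codons[positions] = self.codons[positions[rng.permutation(len(positions))]]
        return codons.reshape(-1)


def _gene_s(codes: np.ndarray, table_arr: np.ndarray,
            affinity_arr: np.ndarray | None = None, clean: bool = False) -> float:
    if clean and affinity_arr is not None:
        return float(np.log(affinity_arr[window_codes(codes)].mean()))
    dg = window_energies(codes, table_arr)
    dg = dg[~np.isnan(dg)]
    return float(np.log(np.mean(np.exp(-dg))))


_MOTIF_CODE = int(encode_dna(CANONICAL_SD) @ _POWERS)


def _gene_motif_count(codes: np.ndarray) -> int:
    win = np.lib.stride_tricks.sliding_window_view(codes, 6)
    idx = win.clip(min=0) @ _POWERS
    valid = (win >= 0).all(axis=1)
    return int(((idx == _MOTIF_CODE) & valid).sum())


def _genome_statistic(
    gene_codes: list[tuple[np.ndarray, bool]],
    statistic: str,
    table_arr: np.ndarray | None,
    affinity_arr: np.ndarray | None,
) -> float:
    if statistic == "s_genome":
        return float(
            np.mean([_gene_s(c, table_arr, affinity_arr, clean)
                     for c, clean in gene_codes])
        )
    return float(sum(_gene_motif_count(c) for c, _ in gene_codes))


def monte_carlo_test(
    genome: list[GeneRecord],
    statistic: str,
    n_replicates: int,
    seed: int,
    table: EnergyTable | None = None,
    genetic_code_id: int = 11,
    alternative: str = "less",
    keep_null_values: bool = False,
) -> NullTestResult:
    """Monte Carlo test of a genome statistic against the codon-shuffled null.

    Parameters
    ----------
    statistic
        ``"s_genome"`` (mean per-gene aSD binding score; requires ``table``)
        or ``"canonical_sd_total"`` (total AGGAGG count over all genes).
    alternative
        ``"less"`` (depletion, the default): p = (1 + #{null ≤ obs}) / (n+1).
        ``"two-sided"``: doubled smaller tail, capped at 1.
    seed
        Master seed; each replicate draws from an independent spawned
        substream, so results do not depend on evaluation order.
    """
    if statistic not in STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}; choose from {STATISTICS}")
    if n_replicates < 1:
        raise ValueError("n_replicates must be ≥ 1")
    if statistic == "s_genome" and table is None:
        raise ValueError("statistic 's_genome' requires an energy table")
    table_arr = table_as_array(table) if table is not None else None
    affinity_arr = affinity_as_array(table) if table is not None else None

    encoded = [_EncodedGene(g, genetic_code_id) for g in genome]
    for gene, enc in zip(genome, encoded):
        if not enc.shuffleable:
            logger.warning(
                "gene %s: internal stop or non-standard codon; passed through "
                "unshuffled in null replicates", gene.gene_id,
            )

    observed = _genome_statistic(
        [(e.codes, e.clean) for e in encoded], statistic, table_arr, affinity_arr
    )
    streams = [np.random.default_rng(s) for s in
               np.random.SeedSequence(seed).spawn(n_replicates)]
    null = np.empty(n_replicates)
    for r, rng in enumerate(streams):
        codes = [(e.shuffled_codes(rng), e.clean) for e in encoded]
        null[r] = _genome_statistic(codes, statistic, table_arr, affinity_arr)

    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1)) if n_replicates > 1 else 0.0
    z = (observed - null_mean) / null_sd if null_sd > 0 else math.nan
    p_low = (1 + int((null <= observed).sum())) / (n_replicates + 1)
    if alternative == "less":
        p = p_low
    elif alternative == "two-sided":
        p_high = (1 + int((null >= observed).sum())) / (n_replicates + 1)
        p = min(1.0, 2 * min(p_low, p_high))
    else:
        raise ValueError("alternative must be 'less' or 'two-sided'")
    return NullTestResult(
        statistic_name=statistic,
        observed=observed,
        null_mean=null_mean,
        null_sd=null_sd,
        z_score=z,
        p_value=p,
        n_replicates=n_replicates,
        seed=seed,
        alternative=alternative,
        null_values=null if keep_null_values else None,
    )
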