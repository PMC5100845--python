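"""Per-gene and per-genome anti-SD binding scores.

A 6-nt window slides (stride 1) across the coding strand of each gene; each
window is transcribed to RNA and assigned a hybridization free energy ΔG from
an :class:`~sdbias.energy_model.EnergyTable`.  The window's affinity is

    A = exp(|ΔG|)

so a non-binding window contributes 1 and strong SD-like windows are
exponentially amplified.  A gene's aSD binding score is

    S = log(mean A)

(natural log of the arithmetic mean affinity over all retained windows), and
a genome's score S_genome is the unweighted mean of S over its genes.  The
normalized SD bias of a genome is the percent excess of the ribosomal-protein
mean score over the genome mean:

    B_SD = (S̄_ribosomal − S_genome) / S_genome × 100

Negative B_SD means ribosomal-protein genes carry fewer/weaker internal
SD-like sites than the genome average.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .energy_model import EnergyTable

__all__ = [
    "GeneRecord",
    "AffinityProfile",
    "GeneScore",
    "GenomeScore",
    "hexamer_affinity",
    "gene_affinity_profile",
    "gene_score",
    "score_gene",
    "genome_score",
    "count_canonical_sd",
    "table_as_array",
    "affinity_as_array",
    "encode_dna",
    "window_codes",
    "window_energies",
    "UndefinedScoreError",
]

logger = logging.getLogger(__name__)

DNA_ALPHABET = frozenset("ACGT")
CANONICAL_SD = "AGGAGG"

_BASE_INDEX = np.full(128, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _BASE_INDEX[ord(_b)] = _i
    _BASE_INDEX[ord(_b.lower())] = _i
_BASE_INDEX[ord("U")] = 3  # RNA input tolerated; T and U are equivalent here
_BASE_INDEX[ord("u")] = 3

_POWERS = 4 ** np.arange(5, -1, -1)


@dataclass
class GeneRecord:
    """One protein-coding sequence (coding strand, 5'→3', start through stop)."""

    gene_id: str
    sequence: str
    product: str = ""
    is_ribosomal: bool = False

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty if valid)."""
        problems = []
        if len(self.sequence) < 9:
            problems.append(f"length {len(self.sequence)} < 9")
        if len(self.sequence) % 3 != 0:
            problems.append(f"length {len(self.sequence)} not a multiple of 3")
        bad = set(self.sequence.upper()) - DNA_ALPHABET
        if bad:
            problems.append(f"non-ACGT character(s) {sorted(bad)}")
        return problems


@dataclass
class AffinityProfile:
    """Windowed ΔG and affinity along one gene (retained windows only)."""

    gene_id: str
    positions: np.ndarray  # 0-based window start indices
    delta_g: np.ndarray  # kcal/mol, ≤ 0
    affinity: np.ndarray  # exp(|ΔG|), ≥ 1
    n_masked: int = 0


@dataclass
class GeneScore:
    gene_id: str
    s_gene: float
    n_windows: int


@dataclass
class GenomeScore:
    genome_id: str
    s_genome: float
    s_ribosomal: float | None
    b_sd: float | None  # percent
    n_genes: int = 0
    n_ribosomal: int = 0


class UndefinedScoreError(ValueError):
    """A score could not be defined (no retained windows / zero denominator)."""


def hexamer_affinity(delta_g: float | np.ndarray):
    """Affinity A = exp(|ΔG|) of a (clamped, ≤ 0) window energy."""
    return np.exp(np.abs(delta_g))


def encode_dna(sequence: str) -> np.ndarray:
    """Encode a DNA/RNA string as base indices; unknown characters become -1."""
    return _BASE_INDEX[np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)]


# keeps a reference to each cached table so its id() stays valid
_TABLE_ARRAY_CACHE: dict[int, tuple[EnergyTable, np.ndarray]] = {}


def table_as_array(table: EnergyTable) -> np.ndarray:
    """Flatten an EnergyTable to a 4096-vector indexed by base-4 hexamer code.

    The code of hexamer n1..n6 is Σ idx(n_j)·4^(6−j) with A,C,G,U → 0..3.
    Cached by table identity (tables are immutable).
    """
    cached = _TABLE_ARRAY_CACHE.get(id(table))
    if cached is not None:
        return cached[1]
    arr = np.empty(4096, dtype=float)
    for hexamer, dg in table.entries.items():
        code = int(encode_dna(hexamer) @ _POWERS)
        arr[code] = dg
    if len(_TABLE_ARRAY_CACHE) > 32:
        _TABLE_ARRAY_CACHE.clear()
    _TABLE_ARRAY_CACHE[id(table)] = (table, arr)
    return arr


def window_codes(codes: np.ndarray) -> np.ndarray:
    """Base-4 hexamer code of every window; only valid for clean (≥ 0) codes."""
    c = codes
    return (
        ((((c[:-5] * 4 + c[1:-4]) * 4 + c[2:-3]) * 4 + c[3:-2]) * 4 + c[4:-1]) * 4
        + c[5:]
    )


_AFFINITY_CACHE: dict[int, tuple[EnergyTable, np.ndarray]] = {}


def affinity_as_array(table: EnergyTable) -> np.ndarray:
    """exp(|ΔG|) per hexamer code; cached companion of :func:`table_as_array`."""
    cached = _AFFINITY_CACHE.get(id(table))
    if cached is not None:
        return cached[1]
    arr = np.exp(-table_as_array(table))
    if len(_AFFINITY_CACHE) > 32:
        _AFFINITY_CACHE.clear()
    _AFFINITY_CACHE[id(table)] = (table, arr)
    return arr


def window_energies(codes: np.ndarray, table_arr: np.ndarray) -> np.ndarray:
    """ΔG for every 6-nt window of an encoded sequence (NaN where masked)."""
    win = np.lib.stride_tricks.sliding_window_view(codes, 6)
    valid = (win >= 0).all(axis=1)
    idx = win.clip(min=0) @ _POWERS
    dg = table_arr[idx]
    dg[~valid] = np.nan
    return dg


def gene_affinity_profile(gene: GeneRecord, table: EnergyTable) -> AffinityProfile:
    """Slide a 6-nt window across the full coding sequence and score each one.

    Windows overlapping the start and stop codons are included; windows
    containing a non-ACGT character are masked out (excluded, counted).
    """
    dg = window_energies(encode_dna(gene.sequence), table_as_array(table))
    keep = ~np.isnan(dg)
    n_masked = int((~keep).sum())
    if n_masked:
        logger.warning("gene %s: %d window(s) masked (ambiguous bases)",
                       gene.gene_id, n_masked)
    dg = dg[keep]
    return AffinityProfile(
        gene_id=gene.gene_id,
        positions=np.flatnonzero(keep),
        delta_g=dg,
        affinity=hexamer_affinity(dg),
        n_masked=n_masked,
    )


def gene_score(profile: AffinityProfile) -> GeneScore:
    """S = log(mean affinity) over the profile's retained windows."""
    if profile.affinity.size == 0:
        raise UndefinedScoreError(
            f"gene {profile.gene_id}: no retained windows, S undefined"
        )
    return GeneScore(
        gene_id=profile.gene_id,
        s_gene=float(np.log(np.mean(profile.affinity))),
        n_windows=int(profile.affinity.size),
    )


def score_gene(gene: GeneRecord, table: EnergyTable) -> GeneScore:
    """Convenience: profile + score in one call."""
    return gene_score(gene_affinity_profile(gene, table))


def genome_score(
    scores: list[GeneScore],
    ribosomal_ids: set[str] | frozenset[str] = frozenset(),
    genome_id: str = "genome",
) -> GenomeScore:
    """Aggregate gene scores into S_genome, S̄_ribosomal and B_SD (percent).

    Means are unweighted over genes.  B_SD is reported only when the
    ribosomal set is nonempty; S_genome = 0 with a ribosomal set present is a
    division-undefined error.
    """
    if not scores:
        raise ValueError("genome_score requires at least one gene score")
    ribosomal_ids = set(ribosomal_ids)
    missing = ribosomal_ids - {s.gene_id for s in scores}
    if missing:
        raise ValueError(f"ribosomal id(s) not among scores: {sorted(missing)[:5]}")
    # fsum: exact summation makes the mean independent of gene order
    s_genome = math.fsum(s.s_gene for s in scores) / len(scores)
    s_ribosomal = None
    b_sd = None
    if ribosomal_ids:
        rib_scores = [s.s_gene for s in scores if s.gene_id in ribosomal_ids]
        s_ribosomal = math.fsum(rib_scores) / len(rib_scores)
        if s_genome == 0.0:
            raise UndefinedScoreError(
                "B_SD undefined: genome mean score is exactly zero"
            )
        b_sd = (s_ribosomal - s_genome) / s_genome * 100.0
    return GenomeScore(
        genome_id=genome_id,
        s_genome=s_genome,
        s_ribosomal=s_ribosomal,
        b_sd=b_sd,
        n_genes=len(scores),
        n_ribosomal=len(ribosomal_ids),
    )


def count_canonical_sd(gene: GeneRecord, motif: str = CANONICAL_SD) -> int:
    """Count (possibly overlapping) exact motif occurrences on the coding strand."""
    if not motif:
        raise ValueError("motif must be nonempty")
    seq = gene.sequence.upper()
    motif = motif.upper()
    count = 0
    start = seq.find(motif)
    while start != -1:
        count += 1
        start = seq.find(motif, start + 1)
    return count
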