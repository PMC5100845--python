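"""Hybridization free energies between mRNA hexamers and the anti-Shine-Dalgarno core.

The 3' tail of the 16S rRNA (core anti-SD sequence, 5'-CCUCCU-3') base-pairs
with SD-like hexamers in the message.  This module estimates the free energy
of that duplex, ΔG at 37 °C in kcal/mol, for every possible hexamer with a
nearest-neighbor ungapped hybridization model:

* the hexamer is slid antiparallel across the aSD at every offset;
* contiguous runs (length ≥ 2) of Watson-Crick or G·U wobble pairs are scored
  as the sum of nearest-neighbor stack energies, plus a duplex-initiation
  penalty and terminal A·U / G·U penalties;
* the most favorable run over all offsets is taken, and finally clamped to
  ``min(ΔG, 0)`` so that an unfavorable duplex counts as "no binding".

Watson-Crick stack parameters are the standard 37 °C RNA/RNA values of the
Xia-Turner set; a stack containing a wobble pair is scored by substituting
the corresponding A·U pair and adding a fixed destabilization penalty per
wobble pair.  The model ignores bulges, internal loops, dangling ends and
intramolecular structure: downstream statistics are rank- and sign-based, so
what matters is that stronger SD-like hexamers score more negative ΔG, with
the perfect aSD complement (AGGAGG for CCUCCU) the strongest of all 4096.

An :class:`EnergyTable` computed by any external thermodynamic engine can be
loaded from TSV instead, for exact parity with that engine.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

__all__ = [
    "EnergyTable",
    "nn_duplex_energy",
    "build_energy_table",
    "load_energy_table",
    "write_energy_table",
    "AlphabetError",
    "EnergyTableFormatError",
]

logger = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGU")

#: duplex initiation penalty, kcal/mol (intermolecular)
INITIATION_PENALTY = 4.09
#: per-end penalty for a terminal A·U or G·U pair, kcal/mol
TERMINAL_AU_PENALTY = 0.45
#: added per G·U wobble pair participating in a stack, kcal/mol
WOBBLE_STACK_PENALTY = 1.00

# Watson-Crick pairs written top-strand-base + bottom-strand-base.
_WC_PAIRS = {"AU", "UA", "GC", "CG"}
_WOBBLE_PAIRS = {"GU", "UG"}
_ALL_PAIRS = _WC_PAIRS | _WOBBLE_PAIRS

# 37 °C Watson-Crick stack free energies, kcal/mol.  Key (p1, p2) denotes the
# motif 5'-t1 t2-3' / 3'-b1 b2-5' with p1 = t1+b1 the 5'-side pair.  The ten
# unique motifs; the rest follow from strand-flip symmetry below.
_WC_STACKS = {
    ("AU", "AU"): -0.93,  # 5'AA/3'UU
    ("AU", "UA"): -1.10,  # 5'AU/3'UA
    ("UA", "AU"): -1.33,  # 5'UA/3'AU
    ("CG", "UA"): -2.08,  # 5'CU/3'GA
    ("CG", "AU"): -2.11,  # 5'CA/3'GU
    ("GC", "UA"): -2.24,  # 5'GU/3'CA
    ("GC", "AU"): -2.35,  # 5'GA/3'CU
    ("CG", "GC"): -2.36,  # 5'CG/3'GC
    ("GC", "GC"): -3.26,  # 5'GG/3'CC
    ("GC", "CG"): -3.42,  # 5'GC/3'CG
}


def _flip(pair: str) -> str:
    return pair[1] + pair[0]


def _wc_stack(p1: str, p2: str) -> float:
    if (p1, p2) in _WC_STACKS:
        return _WC_STACKS[(p1, p2)]
    # reading the motif from the other strand: (p1, p2) == (flip(p2), flip(p1))
    return _WC_STACKS[(_flip(p2), _flip(p1))]


def _stack_energy(p1: str, p2: str) -> float:
    """Stack free energy for two adjacent pairs, wobble pairs substituted."""
    penalty = 0.0
    subbed = []
    for p in (p1, p2):
        if p in _WOBBLE_PAIRS:
            penalty += WOBBLE_STACK_PENALTY
            p = "AU" if p == "GU" else "UA"  # G·U behaves as a weakened A·U
        subbed.append(p)
    return _wc_stack(subbed[0], subbed[1]) + penalty


def _check_rna(seq: str, what: str) -> str:
    seq = seq.upper()
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise AlphabetError(
            f"{what} contains non-RNA character(s) {sorted(bad)}: {seq!r}"
        )
    return seq


class AlphabetError(ValueError):
    """A sequence contained characters outside the RNA alphabet {A,C,G,U}."""


class EnergyTableFormatError(ValueError):
    """An external energy-table file violated the expected TSV format."""


def nn_duplex_energy(hexamer: str, asd: str = "CCUCCU") -> float:
    """Nearest-neighbor hybridization ΔG (kcal/mol) of ``hexamer`` to ``asd``.

    Scans all antiparallel ungapped offsets of the two strands, scores each
    maximal contiguous run of ≥ 2 canonical (Watson-Crick or G·U) pairs, and
    returns the most favorable run energy clamped to ≤ 0.  Deterministic.

    Parameters
    ----------
    hexamer, asd
        RNA strings over {A,C,G,U}, written 5'→3'.  ``asd`` defaults to the
        canonical core anti-SD sequence.
    """
    top = _check_rna(hexamer, "hexamer")
    bottom = _check_rna(asd, "aSD sequence")[::-1]  # 3'→5' left to right
    n, m = len(top), len(bottom)
    best = 0.0
    for offset in range(-(m - 2), n - 1):
        # column i of the alignment pairs top[i] with bottom[i - offset]
        lo = max(0, offset)
        hi = min(n, m + offset)
        pairs: list[str | None] = [
            (top[i] + bottom[i - offset])
            if (top[i] + bottom[i - offset]) in _ALL_PAIRS
            else None
            for i in range(lo, hi)
        ]
        # score each maximal run of consecutive pairs
        i = 0
        while i < len(pairs):
            if pairs[i] is None:
                i += 1
                continue
            j = i
            while j + 1 < len(pairs) and pairs[j + 1] is not None:
                j += 1
            if j > i:  # run length ≥ 2
                run = pairs[i : j + 1]
                e = INITIATION_PENALTY
                for a, b in zip(run, run[1:]):
                    e += _stack_energy(a, b)
                for terminal in (run[0], run[-1]):
                    if terminal in ("AU", "UA", "GU", "UG"):
                        e += TERMINAL_AU_PENALTY
                best = min(best, e)
            i = j + 1
    return min(best, 0.0)


@dataclass(frozen=True)
class EnergyTable:
    """ΔG (kcal/mol) of every RNA hexamer bound to one anti-SD sequence.

    Invariants: exactly 4096 entries covering all hexamers over {A,C,G,U};
    every value ≤ 0 (clamped).
    """

    asd_sequence: str
    entries: dict[str, float] = field(repr=False)
    source_tag: str = "builtin-nn"

    def __post_init__(self) -> None:
        if len(self.entries) != 4096:
            raise ValueError(f"expected 4096 entries, got {len(self.entries)}")

    def __getitem__(self, hexamer: str) -> float:
        return self.entries[hexamer]

    def argmin(self) -> str:
        return min(self.entries, key=self.entries.get)

    def min(self) -> float:
        return min(self.entries.values())


def _all_hexamers() -> list[str]:
    return ["".join(p) for p in itertools.product("ACGU", repeat=6)]


@lru_cache(maxsize=8)
def build_energy_table(asd: str = "CCUCCU") -> EnergyTable:
    """Apply :func:`nn_duplex_energy` to all 4096 hexamers; cached per aSD."""
    asd = _check_rna(asd, "aSD sequence")
    if len(asd) != 6:
        raise ValueError(f"aSD sequence must be length 6, got {len(asd)}")
    entries = {h: nn_duplex_energy(h, asd) for h in _all_hexamers()}
    return EnergyTable(asd_sequence=asd, entries=entries)


def write_energy_table(table: EnergyTable, path: str | Path) -> None:
    """Write the table as TSV: header ``hexamer\\tdelta_g``, 4096 data rows.

    Energies are written to 2 decimal places (kcal/mol).
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write("hexamer\tdelta_g\n")
        for hexamer in _all_hexamers():
            fh.write(f"{hexamer}\t{table.entries[hexamer]:.2f}\n")


def load_energy_table(path: str | Path, asd_sequence: str = "CCUCCU") -> EnergyTable:
    """Load an energy table from TSV, validating completeness and clamping.

    Positive energies are clamped to 0.0 with a logged count; missing or
    duplicate hexamers and unparsable values raise
    :class:`EnergyTableFormatError` naming the offending line.
    """
    path = Path(path)
    entries: dict[str, float] = {}
    n_clamped = 0
    with path.open() as fh:
        header = fh.readline().rstrip("\n")
        if header.split("\t")[:2] != ["hexamer", "delta_g"]:
            raise EnergyTableFormatError(
                f"{path}: expected header 'hexamer\\tdelta_g', got {header!r}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise EnergyTableFormatError(
                    f"{path}:{lineno}: expected 2 tab-separated fields"
                )
            hexamer = _check_rna(fields[0], f"{path}:{lineno} hexamer")
            if len(hexamer) != 6:
                raise EnergyTableFormatError(
                    f"{path}:{lineno}: hexamer {hexamer!r} is not length 6"
                )
            if hexamer in entries:
                raise EnergyTableFormatError(
                    f"{path}:{lineno}: duplicate hexamer {hexamer}"
                )
            try:
                dg = float(fields[1])
            except ValueError as exc:
                raise EnergyTableFormatError(
                    f"{path}:{lineno}: unparsable delta_g {fields[1]!r}"
                ) from exc
            if dg > 0:
                dg = 0.0
                n_clamped += 1
            entries[hexamer] = dg
    missing = set(_all_hexamers()) - set(entries)
    if missing:
        raise EnergyTableFormatError(
            f"{path}: missing hexamer(s), e.g. {sorted(missing)[:5]} "
            f"({len(missing)} total)"
        )
    if n_clamped:
        logger.warning("%s: clamped %d positive delta_g value(s) to 0", path, n_clamped)
    return EnergyTable(
        asd_sequence=asd_sequence, entries=entries, source_tag=f"external:{path.name}"
    )
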