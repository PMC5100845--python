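import numpy as np
import pytest

from sdbias import GeneRecord, GenomeSimSpec, build_energy_table, simulate_genome
from sdbias.energy_model import EnergyTable


@pytest.fixture(scope="session")
def table():
    """Built-in energy table for the canonical aSD core."""
    return build_energy_table("CCUCCU")


@pytest.fixture(scope="session")
def small_genome():
    spec = GenomeSimSpec(n_genes=20, gene_length_codons=(60.0, 0.3), seed=11)
    return simulate_genome(spec)


def make_toy_table(energies: dict[str, float]) -> EnergyTable:
    """Energy table that is 0 everywhere except the given hexamers."""
    import itertools

    entries = {"".join(h): 0.0 for h in itertools.product("ACGU", repeat=6)}
    entries.update(energies)
    return EnergyTable(asd_sequence="CCUCCU", entries=entries, source_tag="toy")


def random_toy_table(rng: np.random.Generator) -> EnergyTable:
    import itertools

    hexamers = ["".join(h) for h in itertools.product("ACGU", repeat=6)]
    values = -rng.exponential(2.0, size=4096)
    return EnergyTable(
        asd_sequence="CCUCCU",
        entries=dict(zip(hexamers, values)),
        source_tag="random-toy",
    )


def random_gene(rng: np.random.Generator, n_codons: int = 10) -> GeneRecord:
    """Random valid CDS: ATG + uniform non-stop codons + TAA."""
    stops = {"TAA", "TAG", "TGA"}
    codons = []
    while len(codons) < n_codons:
        c = "".join(rng.choice(list("ACGT"), size=3))
        if c not in stops:
            codons.append(c)
    return GeneRecord(
        gene_id=f"rand{rng.integers(1_000_000)}",
        sequence="ATG" + "".join(codons) + "TAA",
    )
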