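"""Ground-truth generators: structure, determinism, planted effects."""

import numpy as np
import pandas as pd
import pytest

from sdbias import (
    ComparativeSimSpec,
    ExpressionSimSpec,
    GeneRecord,
    GenomeSimSpec,
    fit_ols,
    pgls_fit,
    plant_sd_shift,
    score_gene,
    simulate_expression,
    simulate_genome,
    simulate_tree_and_traits,
)
from sdbias.null_model import translate_codons


class TestGenomeSim:
    def test_minimal_gene_structure(self):
        spec = GenomeSimSpec(n_genes=1, gene_length_codons=(10.0, 0.0), seed=0)
        genes = simulate_genome(spec)
        assert len(genes) == 1
        gene = genes[0]
        assert len(gene.sequence) % 3 == 0
        assert gene.sequence.startswith("ATG")
        assert gene.sequence.endswith("TAA")
        assert not gene.validate()

    def test_determinism(self):
        spec = GenomeSimSpec(n_genes=10, gene_length_codons=(40.0, 0.3), seed=7)
        a = simulate_genome(spec)
        b = simulate_genome(spec)
        assert [g.sequence for g in a] == [g.sequence for g in b]
        c = simulate_genome(GenomeSimSpec(n_genes=10,
                                          gene_length_codons=(40.0, 0.3), seed=8))
        assert [g.sequence for g in a] != [g.sequence for g in c]

    def test_gc_target_shifts_composition(self):
        def gc(genes):
            seq = "".join(g.sequence for g in genes)
            return (seq.count("G") + seq.count("C")) / len(seq)

        low = simulate_genome(GenomeSimSpec(n_genes=20, gc_target=0.3, seed=1))
        high = simulate_genome(GenomeSimSpec(n_genes=20, gc_target=0.7, seed=1))
        assert gc(high) - gc(low) > 0.1

    def test_ribosomal_fraction_flagged(self):
        spec = GenomeSimSpec(n_genes=40, ribosomal_fraction=0.25, seed=2,
                             gene_length_codons=(30.0, 0.0))
        genes = simulate_genome(spec)
        flagged = [g for g in genes if g.is_ribosomal]
        assert len(flagged) == 10
        assert all("ribosomal" in g.product for g in flagged)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            GenomeSimSpec(n_genes=0)
        with pytest.raises(ValueError):
            GenomeSimSpec(gc_target=1.5)


class TestPlantShift:
    def test_zero_target_is_identity(self, table):
        gene = GeneRecord("g", "ATG" + "CTGGCACGT" * 5 + "TAA")
        rng = np.random.default_rng(0)
        res = plant_sd_shift(gene, 0.0, table, rng)
        assert res.gene.sequence == gene.sequence
        assert res.converged

    def test_negative_shift_lowers_score(self, table):
        spec = GenomeSimSpec(n_genes=1, gene_length_codons=(80.0, 0.0), seed=3)
        gene = simulate_genome(spec)[0]
        rng = np.random.default_rng(1)
        s0 = score_gene(gene, table).s_gene
        res = plant_sd_shift(gene, -0.2, table, rng)
        s1 = score_gene(res.gene, table).s_gene
        assert s1 < s0
        assert res.achieved_shift == pytest.approx(s1 - s0, abs=1e-9)

    def test_translation_invariant(self, table):
        spec = GenomeSimSpec(n_genes=5, gene_length_codons=(50.0, 0.0), seed=4)
        rng = np.random.default_rng(2)
        for gene in simulate_genome(spec):
            res = plant_sd_shift(gene, -0.3, table, rng)
            assert translate_codons(res.gene.sequence) == translate_codons(
                gene.sequence
            )


@pytest.fixture(scope="module")
def scores():
    rng = np.random.default_rng(5)
    return pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(500)],
            "s_gene": rng.normal(1.0, 0.5, 500),
            "nc_prime": rng.uniform(30, 61, 500),
        }
    )


class TestExpressionSim:
    def test_noiseless_identifiability(self, scores):
        spec = ExpressionSimSpec(beta_0=2.0, beta_s=-1.0, beta_nc=0.0,
                                 noise_sd=0.0, seed=0)
        expr = simulate_expression(scores, spec)
        df = scores.set_index("gene_id").join(expr.set_index("gene_id"))
        fit = fit_ols(df["log_abundance"], df[["s_gene", "nc_prime"]])
        assert fit.coefficients["s_gene"][0] == pytest.approx(-1.0, abs=1e-8)
        assert fit.coefficients["nc_prime"][0] == pytest.approx(0.0, abs=1e-8)
        assert fit.coefficients["const"][0] == pytest.approx(2.0, abs=1e-8)

    def test_abundance_is_exp_of_log(self, scores):
        expr = simulate_expression(scores, ExpressionSimSpec(seed=1))
        assert np.allclose(expr["abundance"], np.exp(expr["log_abundance"]))

    def test_determinism(self, scores):
        a = simulate_expression(scores, ExpressionSimSpec(seed=2))
        b = simulate_expression(scores, ExpressionSimSpec(seed=2))
        pd.testing.assert_frame_equal(a, b)

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="lacks column"):
            simulate_expression(pd.DataFrame({"gene_id": []}),
                                ExpressionSimSpec())


class TestTreeSim:
    def test_two_tip_tree_valid_and_fittable(self):
        spec = ComparativeSimSpec(n_tips=2, seed=0)
        newick, traits = simulate_tree_and_traits(spec)
        assert newick.count(",") == 1
        assert len(traits) == 2
        t = traits.set_index("species_id")
        res = pgls_fit_smoke = pgls_fit(
            __import__("dendropy").Tree.get(data=newick, schema="newick"),
            t["log_doubling_time"], t[["b_sd_percent"]], lambda_value=1.0,
        )
        assert res.n_obs == 2

    def test_determinism_and_columns(self):
        spec = ComparativeSimSpec(n_tips=10, seed=3)
        a_newick, a_traits = simulate_tree_and_traits(spec)
        b_newick, b_traits = simulate_tree_and_traits(spec)
        assert a_newick == b_newick
        pd.testing.assert_frame_equal(a_traits, b_traits)
        assert set(a_traits.columns) >= {
            "species_id", "b_sd_percent", "log_doubling_time",
            "min_doubling_time_hr",
        }

    def test_positive_branch_lengths(self):
        newick, _ = simulate_tree_and_traits(ComparativeSimSpec(n_tips=30, seed=4))
        import dendropy

        tree = dendropy.Tree.get(data=newick, schema="newick")
        lengths = [e.length for e in tree.edges() if e.length is not None]
        assert min(lengths) > 0

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            ComparativeSimSpec(lambda_true=1.5)
        with pytest.raises(ValueError):
            ComparativeSimSpec(n_tips=1)
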