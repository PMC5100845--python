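"""Readers, writers and the pipeline orchestrator.

Formats: FASTA (in-frame CDS, one record per gene), GenBank flat files (CDS
features; the ``product`` annotation identifies ribosomal proteins), TSV
(tab-separated, UTF-8, "." decimal, ``#``-prefixed metadata lines before the
header row), and Newick trees.  All internal positions are 0-based,
half-open.

Every output TSV begins with a metadata block echoing the tool version, a
hash of the effective configuration, the seed, and the analysis conventions
in force (energy clamping, boundary-window inclusion, overlap counting, the
add-one Monte Carlo estimator), so results are reproducible from any output
file plus its inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from . import __version__
from .association import fit_ols, compare_models, pgls_fit, spearman_correlation
from .codon_usage import nc_prime
from .energy_model import EnergyTable, build_energy_table, load_energy_table
from .null_model import monte_carlo_test
from .sd_metrics import (
    GeneRecord,
    count_canonical_sd,
    gene_affinity_profile,
    gene_score,
    genome_score,
)

__all__ = [
    "RunConfig",
    "DEFAULT_RIBOSOMAL_PATTERN",
    "read_cds_fasta",
    "write_cds_fasta",
    "read_genbank_cds",
    "read_expression_tsv",
    "read_traits_tsv",
    "write_tsv",
    "read_tsv",
    "score_genome_table",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

# operationalizes "ribosomal subunit" product annotations and common variants
DEFAULT_RIBOSOMAL_PATTERN = r"ribosomal (subunit )?protein"


@dataclass
class RunConfig:
    """Effective configuration of a pipeline run; echoed into all outputs."""

    genetic_code_id: int = 11
    asd_sequence: str = "CCUCCU"
    include_boundary_windows: bool = True
    log_transform_expression: bool = True
    ribosomal_product_pattern: str = DEFAULT_RIBOSOMAL_PATTERN
    seed: int = 0
    output_dir: str = "."
    energy_table_path: str | None = None
    n_replicates: int = 1000
    statistic: str = "s_genome"

    def config_hash(self) -> str:
        fields = dataclasses.asdict(self)
        fields.pop("output_dir")  # where results land does not affect them
        payload = json.dumps(fields, sort_keys=True)
        return hashlib.md5(payload.encode()).hexdigest()[:12]

    def metadata(self) -> dict[str, str]:
        return {
            "tool": f"sdbias {__version__}",
            "config_hash": self.config_hash(),
            "seed": str(self.seed),
            "genetic_code_id": str(self.genetic_code_id),
            "asd_sequence": self.asd_sequence,
            "positive_energies_clamped_to_zero": "true",
            "boundary_windows_included": str(self.include_boundary_windows).lower(),
            "overlapping_motifs_counted": "true",
            "monte_carlo_p_estimator": "add-one",
            "coordinates": "0-based, half-open",
        }

    def energy_table(self) -> EnergyTable:
        if self.energy_table_path:
            return load_energy_table(self.energy_table_path, self.asd_sequence)
        return build_energy_table(self.asd_sequence)


# ---------------------------------------------------------------------------
# sequence input


def _validated(records: list[GeneRecord], source: str) -> list[GeneRecord]:
    kept = []
    for rec in records:
        problems = rec.validate()
        if problems:
            logger.warning("%s: skipping %s (%s)", source, rec.gene_id,
                           "; ".join(problems))
        else:
            kept.append(rec)
    return kept


def read_cds_fasta(path: str | Path) -> list[GeneRecord]:
    """One GeneRecord per FASTA record; invalid records skipped with a log."""
    path = Path(path)
    records = [
        GeneRecord(gene_id=rec.id, sequence=str(rec.seq).upper(),
                   product=rec.description)
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return _validated(records, str(path))


def write_cds_fasta(genes: list[GeneRecord], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for gene in genes:
            fh.write(f">{gene.gene_id} {gene.product}\n{gene.sequence}\n")


def read_genbank_cds(
    path: str | Path,
    product_pattern: str = DEFAULT_RIBOSOMAL_PATTERN,
) -> list[GeneRecord]:
    """Extract every CDS feature of a GenBank file as a GeneRecord.

    Joins are spliced and minus-strand features reverse-complemented, so each
    sequence is the coding strand 5'→3'.  Gene ids prefer locus_tag, then
    protein_id, then a positional fallback.  ``is_ribosomal`` is set when the
    product annotation matches ``product_pattern`` (case-insensitive).  CDS
    with fuzzy coordinates are skipped with a warning.
    """
    path = Path(path)
    pattern = re.compile(product_pattern, re.IGNORECASE)
    records: list[GeneRecord] = []
    n_seen = 0
    for rec in SeqIO.parse(str(path), "genbank"):
        for feature in rec.features:
            if feature.type != "CDS":
                continue
            n_seen += 1
            loc = str(feature.location)
            if "<" in loc or ">" in loc:
                logger.warning("%s: skipping CDS with fuzzy location %s",
                               path, loc)
                continue
            quals = feature.qualifiers
            gene_id = (
                quals.get("locus_tag", [None])[0]
                or quals.get("protein_id", [None])[0]
                or f"{rec.id}_cds{n_seen}"
            )
            product = quals.get("product", [""])[0]
            seq = str(feature.extract(rec.seq)).upper()
            records.append(
                GeneRecord(
                    gene_id=gene_id,
                    sequence=seq,
                    product=product,
                    is_ribosomal=bool(pattern.search(product)),
                )
            )
    if not records:
        raise ValueError(f"{path}: no CDS features found")
    return _validated(records, str(path))


# ---------------------------------------------------------------------------
# tabular I/O


def write_tsv(df: pd.DataFrame, path: str | Path,
              metadata: dict[str, str] | None = None) -> None:
    """Write a TSV with '#'-prefixed metadata lines before the header."""
    path = Path(path)
    with path.open("w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Expression table: columns gene_id, abundance (positive units)."""
    df = read_tsv(path)
    missing = {"gene_id", "abundance"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return df


def read_traits_tsv(path: str | Path) -> pd.DataFrame:
    """Species-trait table: species_id plus trait columns."""
    df = read_tsv(path)
    if "species_id" not in df.columns:
        raise ValueError(f"{path}: missing column 'species_id'")
    return df


# ---------------------------------------------------------------------------
# orchestration


def score_genome_table(
    genes: list[GeneRecord],
    table: EnergyTable,
    genetic_code_id: int = 11,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene score table and one-row genome summary.

    Returns (gene table with gene_id, n_windows, s_gene, canonical_sd_count,
    nc_prime, is_ribosomal; genome table with genome_id, n_genes, s_genome,
    s_ribosomal, b_sd_percent).
    """
    rows = []
    scores = []
    for gene in genes:
        profile = gene_affinity_profile(gene, table)
        gs = gene_score(profile)
        scores.append(gs)
        usage = nc_prime(gene, genetic_code_id)
        rows.append(
            {
                "gene_id": gene.gene_id,
                "n_windows": gs.n_windows,
                "s_gene": gs.s_gene,
                "canonical_sd_count": count_canonical_sd(gene),
                "nc_prime": usage.nc_prime,
                "is_ribosomal": gene.is_ribosomal,
            }
        )
    rib_ids = {g.gene_id for g in genes if g.is_ribosomal}
    gscore = genome_score(scores, rib_ids)
    genome_df = pd.DataFrame(
        [
            {
                "genome_id": gscore.genome_id,
                "n_genes": gscore.n_genes,
                "s_genome": gscore.s_genome,
                "s_ribosomal": gscore.s_ribosomal,
                "b_sd_percent": gscore.b_sd,
            }
        ]
    )
    return pd.DataFrame(rows), genome_df


def run_pipeline(
    config: RunConfig,
    genes: list[GeneRecord] | None = None,
    fasta: str | Path | None = None,
    genbank: str | Path | None = None,
    expression: str | Path | None = None,
    tree: str | Path | None = None,
    traits: str | Path | None = None,
    run_nulltest: bool = False,
) -> dict[str, Path]:
    """Score → null test → regression/PGLS, as requested by the inputs given.

    Writes TSVs under ``config.output_dir`` and returns their paths.  Reruns
    with identical config, seed and inputs are byte-identical.
    """
    if genes is None:
        if fasta is not None:
            genes = read_cds_fasta(fasta)
        elif genbank is not None:
            genes = read_genbank_cds(genbank, config.ribosomal_product_pattern)
        else:
            raise ValueError("run_pipeline needs genes, a FASTA or a GenBank input")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = config.metadata()
    table = config.energy_table()
    outputs: dict[str, Path] = {}

    gene_df = None
    if genes:
        gene_df, genome_df = score_genome_table(genes, table, config.genetic_code_id)
        outputs["gene_scores"] = outdir / "gene_scores.tsv"
        write_tsv(gene_df, outputs["gene_scores"], meta)
        outputs["genome_summary"] = outdir / "genome_summary.tsv"
        write_tsv(genome_df, outputs["genome_summary"], meta)

    if run_nulltest:
        result = monte_carlo_test(
            genes,
            statistic=config.statistic,
            n_replicates=config.n_replicates,
            seed=config.seed,
            table=table,
            genetic_code_id=config.genetic_code_id,
        )
        null_df = pd.DataFrame(
            [
                {
                    "statistic": result.statistic_name,
                    "observed": result.observed,
                    "null_mean": result.null_mean,
                    "null_sd": result.null_sd,
                    "z_score": result.z_score,
                    "p_value": result.p_value,
                    "n_replicates": result.n_replicates,
                    "seed": result.seed,
                }
            ]
        )
        outputs["nulltest"] = outdir / "nulltest.tsv"
        write_tsv(null_df, outputs["nulltest"], meta)

    if expression is not None:
        if gene_df is None:
            raise ValueError("expression regression requested but no genes given")
        expr = read_expression_tsv(expression)
        merged = expr.merge(gene_df, on="gene_id").set_index("gene_id")
        if config.log_transform_expression:
            import numpy as np

            n_bad = int((merged["abundance"] <= 0).sum())
            if n_bad:
                logger.warning("dropping %d non-positive abundance value(s)", n_bad)
            merged = merged[merged["abundance"] > 0]
            merged["response"] = np.log(merged["abundance"])
        else:
            merged["response"] = merged["abundance"]
        merged = merged.dropna(subset=["response", "s_gene", "nc_prime"])
        base = fit_ols(merged["response"], merged[["nc_prime"]])
        full = fit_ols(merged["response"], merged[["nc_prime", "s_gene"]])
        comparison = compare_models(base, full)
        rho, rho_p = spearman_correlation(merged["s_gene"], merged["response"])
        reg_df = pd.DataFrame(
            [
                {
                    "model": full.model_spec,
                    "coef_s_gene": full.coefficients["s_gene"][0],
                    "p_s_gene": full.coefficients["s_gene"][2],
                    "coef_nc_prime": full.coefficients["nc_prime"][0],
                    "r2_adj_full": full.r2_adj,
                    "r2_adj_base": base.r2_adj,
                    "delta_r2_adj": comparison.delta_r2_adj,
                    "delta_aic": comparison.delta_aic,
                    "delta_bic": comparison.delta_bic,
                    "spearman_rho": rho,
                    "spearman_p": rho_p,
                    "n_obs": full.n_obs,
                }
            ]
        )
        outputs["regression"] = outdir / "regression.tsv"
        write_tsv(reg_df, outputs["regression"], meta)

    if tree is not None:
        if traits is None:
            raise ValueError("PGLS requested (tree given) but no traits table")
        tr = read_traits_tsv(traits).set_index("species_id")
        response_col = (
            "log_doubling_time"
            if "log_doubling_time" in tr.columns
            else "min_doubling_time_hr"
        )
        result = pgls_fit(tree, tr[response_col], tr[["b_sd_percent"]])
        pgls_df = pd.DataFrame(
            [
                {
                    "response": response_col,
                    "predictor": "b_sd_percent",
                    "lambda_hat": result.lambda_hat,
                    "slope": result.coefficients["b_sd_percent"][0],
                    "p_slope": result.p_slope,
                    "r2_adj": result.r2_adj,
                    "log_likelihood": result.log_likelihood,
                    "n_obs": result.n_obs,
                }
            ]
        )
        outputs["pgls"] = outdir / "pgls.tsv"
        write_tsv(pgls_df, outputs["pgls"], meta)

    return outputs
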