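"""End-to-end synthetic-panel pipeline.

Glues the stages together in the order a real analysis would run them:
simulate (or load) catalogs -> population-AF filter -> mutation counts ->
motif annotation -> kataegis clusters and abundance measures under the
5/1000 and 6/10000 criteria -> correlation of expression and
motif/count measures against drug response with BH FDR -> significance
filter.  Used by the examples, the CLI and the acceptance script; every
output is written as deterministic TSV so two runs with one seed are
byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import catalog as cat
from . import correlation as corr
from . import kataegis as kat
from . import motifs as mot
from .phenotype import write_category_map, write_matrix_tsv
from .simulate import (
    CatalogTruth,
    PhenotypeTruth,
    SimulationConfig,
    simulate_catalog,
    simulate_genome,
    simulate_phenotypes,
)

CRITERIA = (kat.CRITERION_5_1000, kat.CRITERION_6_10000)


@dataclass
class PipelineResult:
    config: SimulationConfig
    counts: pd.DataFrame  # cell line x 7 count categories
    measures: pd.DataFrame  # (cell_line, motif, criterion) x 4 measures
    clusters: pd.DataFrame
    expression: pd.DataFrame  # cell line x gene
    response: pd.DataFrame  # cell line x drug (log10 IC50)
    category_map: dict[str, str]
    results: list[corr.CorrelationResult]
    significant: list[corr.CorrelationResult]
    catalog_truth: CatalogTruth
    phenotype_truth: PhenotypeTruth


def measures_matrix(measures: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long measures table to cell line x (motif:criterion:measure)."""
    long = measures.melt(
        id_vars=["cell_line", "motif", "criterion"],
        value_vars=[
            "total_motifs",
            "motifs_in_clusters",
            "n_clusters",
            "combined_length_bp",
        ],
        var_name="measure",
    )
    long["column"] = (
        long["motif"] + ":" + long["criterion"] + ":" + long["measure"]
    )
    wide = long.pivot(index="cell_line", columns="column", values="value")
    return wide.sort_index(axis=1).sort_index()


def run_pipeline(
    config: SimulationConfig, outdir: str | Path | None = None
) -> PipelineResult:
    """Run the full synthetic analysis for one configuration."""
    genome = simulate_genome(config)
    catalogs, catalog_truth = simulate_catalog(config, genome)
    expression, response, cat_map, pheno_truth = simulate_phenotypes(config)

    counts_rows = []
    all_clusters: list[kat.KataegisCluster] = []
    all_measures: list[kat.ApobecMeasures] = []
    for cell in config.cell_line_ids:
        records = cat.filter_common_variants(catalogs[cell])
        counts_rows.append(cat.mutation_counts(records))
        events = mot.annotate_events(records)
        for criterion in CRITERIA:
            clusters = kat.find_clusters(events, criterion)
            all_clusters.extend(clusters)
            all_measures.extend(
                kat.apobec_measures(events, clusters, criterion, cell).values()
            )

    counts = cat.counts_to_frame(counts_rows)
    measures = kat.measures_to_frame(all_measures)
    clusters_df = kat.clusters_to_frame(all_clusters)

    right = pd.concat(
        [measures_matrix(measures), counts], axis=1
    ).loc[config.cell_line_ids]

    strata = [corr.PAN_CANCER] + sorted(config.categories)
    fam_expr_drug = corr.TestFamily(
        "expression_vs_drug",
        left=list(expression.values.columns),
        right=list(response.values.columns),
        strata=strata,
    )
    fam_meas_drug = corr.TestFamily(
        "measures_vs_drug",
        left=list(right.columns),
        right=list(response.values.columns),
        strata=strata,
    )
    results = corr.run_family(
        fam_expr_drug, expression.values, response.values, cat_map
    ) + corr.run_family(fam_meas_drug, right, response.values, cat_map)
    hits = corr.significant(results)

    out = PipelineResult(
        config=config,
        counts=counts,
        measures=measures,
        clusters=clusters_df,
        expression=expression.values,
        response=response.values,
        category_map=cat_map,
        results=results,
        significant=hits,
        catalog_truth=catalog_truth,
        phenotype_truth=pheno_truth,
    )
    if outdir is not None:
        write_outputs(out, outdir)
    return out


def write_outputs(result: PipelineResult, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.counts.to_csv(outdir / "mutation_counts.tsv", sep="\t")
    result.measures.to_csv(outdir / "apobec_measures.tsv", sep="\t", index=False)
    result.clusters.to_csv(outdir / "kataegis_clusters.tsv", sep="\t", index=False)
    write_matrix_tsv(result.expression, outdir / "expression.tsv")
    write_matrix_tsv(result.response, outdir / "drug_response.tsv")
    write_category_map(result.category_map, outdir / "categories.tsv")
    corr.write_results_tsv(result.results, outdir / "correlations.tsv")
    corr.write_results_tsv(result.significant, outdir / "significant.tsv")
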