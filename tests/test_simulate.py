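"""Synthetic-data generator: determinism, composition, planted ground truth."""

import numpy as np
import pytest

from apokat.catalog import filter_common_variants
from apokat.correlation import spearman
from apokat.kataegis import CRITERION_5_1000, find_clusters
from apokat.motifs import annotate_events, classify
from apokat.simulate import (
    AssocSpec,
    GeneModel,
    PlantedClusterSpec,
    SimulationConfig,
    simulate_catalog,
    simulate_genome,
    simulate_phenotypes,
    write_genome_fasta,
)

SMALL_GENOME = {"chr1": 120_000}


def small_config(seed=0, **kwargs):
    defaults = dict(
        seed=seed,
        chromosomes=dict(SMALL_GENOME),
        categories={"A": 2},
        background_rate=0.0,
        af_common_fraction=0.0,
        planted_clusters=[PlantedClusterSpec("TCKW", "+", 6, 800, 1)],
        n_drugs=4,
        planted_assoc=[],
    )
    defaults.update(kwargs)
    return SimulationConfig(**defaults)


class TestSimulateGenome:
    def test_deterministic_given_seed(self, tmp_path):
        cfg = small_config(seed=1)
        f1, f2 = tmp_path / "a.fa", tmp_path / "b.fa"
        write_genome_fasta(simulate_genome(cfg), f1)
        write_genome_fasta(simulate_genome(cfg), f2)
        assert f1.read_bytes() == f2.read_bytes()

    def test_different_seeds_differ(self):
        g1 = simulate_genome(small_config(seed=1))
        g2 = simulate_genome(small_config(seed=2))
        assert g1["chr1"] != g2["chr1"]

    def test_composition_within_one_percent(self):
        cfg = SimulationConfig(seed=3, chromosomes={"chr1": 1_000_000})
        seq = simulate_genome(cfg)["chr1"]
        for base in "ACGT":
            assert 0.24 <= seq.count(base) / len(seq) <= 0.26

    def test_zero_length_chromosome_is_error(self):
        with pytest.raises(ValueError):
            simulate_genome(small_config(chromosomes={"chr1": 0}))

    def test_fasta_is_indexed(self, tmp_path):
        import pysam

        cfg = small_config()
        path = tmp_path / "g.fa"
        simulate_genome(cfg, path)
        fa = pysam.FastaFile(str(path))
        assert fa.get_reference_length("chr1") == 120_000
        fa.close()


class TestSimulateCatalog:
    def test_noiseless_planted_cluster_is_the_whole_catalog(self):
        cfg = small_config(categories={"A": 1})
        genome = simulate_genome(cfg)
        catalogs, truth = simulate_catalog(cfg, genome)
        (records,) = catalogs.values()
        assert len(records) == 6
        for r in records:
            assert ("TCKW", "+") in classify(r.context5, r.ref, r.alt, r.context3)
        assert all(
            truth.origins[(r.cell_line_id, r.chrom, r.pos)] == "planted"
            for r in records
        )

    def test_deterministic_catalogs(self):
        cfg = small_config(background_rate=5e-4, af_common_fraction=0.1)
        genome = simulate_genome(cfg)
        c1, _ = simulate_catalog(cfg, genome)
        c2, _ = simulate_catalog(cfg, genome)
        assert c1 == c2

    def test_af_flagged_fraction_is_removed_by_filter(self):
        cfg = small_config(
            categories={"A": 3}, background_rate=2e-3, af_common_fraction=0.25
        )
        genome = simulate_genome(cfg)
        catalogs, truth = simulate_catalog(cfg, genome)
        for cell, records in catalogs.items():
            flagged = {
                (c, ch, p)
                for (c, ch, p), o in truth.origins.items()
                if o == "common-AF" and c == cell
            }
            kept = filter_common_variants(records)
            removed = {(r.cell_line_id, r.chrom, r.pos) for r in records} - {
                (r.cell_line_id, r.chrom, r.pos) for r in kept
            }
            assert removed == flagged

    def test_planted_context_not_mutated_into_genome(self):
        cfg = small_config(categories={"A": 1})
        genome = simulate_genome(cfg)
        catalogs, _ = simulate_catalog(cfg, genome)
        (records,) = catalogs.values()
        for r in records:
            seq = genome[r.chrom]
            assert seq[r.pos - 1] == r.ref
            assert seq[r.pos - 2] == r.context5 and seq[r.pos] == r.context3

    def test_insufficient_context_is_hard_error(self):
        cfg = small_config(
            chromosomes={"chr1": 2_000},
            planted_clusters=[PlantedClusterSpec("TCKW", "+", 50, 60, 1)],
        )
        genome = simulate_genome(cfg)
        with pytest.raises(RuntimeError, match="longer genome"):
            simulate_catalog(cfg, genome)

    def test_end_to_end_planted_recovery_event_bounded(self):
        cfg = small_config(
            categories={"A": 2},
            planted_clusters=[
                PlantedClusterSpec("TCKW", "+", 6, 800, 1),
                PlantedClusterSpec("TCDR", "-", 5, 900, 1),
            ],
        )
        genome = simulate_genome(cfg)
        catalogs, truth = simulate_catalog(cfg, genome)
        detected = set()
        for cell, records in catalogs.items():
            events = annotate_events(filter_common_variants(records))
            for c in find_clusters(events, CRITERION_5_1000):
                detected.add(
                    (c.cell_line_id, c.chrom, c.strand, c.motif, c.start, c.end, c.n_motifs)
                )
        assert detected == truth.expected_clusters(5, 1000)


class TestSimulatePhenotypes:
    def test_target_rho_one_zero_noise_is_exact(self):
        cfg = small_config(
            categories={"A": 40},
            planted_assoc=[AssocSpec("APOBEC3B", "drug01", rho=1.0)],
        )
        expr, resp, _, _ = simulate_phenotypes(cfg)
        rho, _ = spearman(expr.values["APOBEC3B"], resp.values["drug01"])
        assert rho == 1.0

    def test_mixture_gene_is_bimodal(self):
        cfg = small_config(
            categories={"A": 400},
            expression_models={
                "G": GeneModel("mixture", (4.0, 10.0), (0.5, 0.5), weight_low=0.5)
            },
            planted_assoc=[],
        )
        expr, _, _, _ = simulate_phenotypes(cfg)
        values = expr.values["G"].to_numpy()
        low = values[values < 7].mean()
        high = values[values >= 7].mean()
        assert high - low > 4 * 0.5  # modes separated by > 4 sd
        assert 0.4 < (values < 7).mean() < 0.6

    def test_stratum_scoped_association(self):
        cfg = SimulationConfig(
            seed=7,
            chromosomes=dict(SMALL_GENOME),
            categories={"A": 60, "B": 60},
            n_drugs=2,
            planted_assoc=[AssocSpec("APOBEC3B", "drug01", rho=0.9, stratum="A")],
        )
        expr, resp, cat_map, _ = simulate_phenotypes(cfg)
        in_a = [c for c, label in cat_map.items() if label == "A"]
        in_b = [c for c, label in cat_map.items() if label == "B"]
        rho_a, _ = spearman(
            expr.values.loc[in_a, "APOBEC3B"], resp.values.loc[in_a, "drug01"]
        )
        rho_b, _ = spearman(
            expr.values.loc[in_b, "APOBEC3B"], resp.values.loc[in_b, "drug01"]
        )
        assert rho_a > 0.7 and abs(rho_b) < 0.4

    def test_deterministic_phenotypes(self):
        cfg = small_config(categories={"A": 20})
        e1, r1, _, _ = simulate_phenotypes(cfg)
        e2, r2, _, _ = simulate_phenotypes(cfg)
        assert e1.values.equals(e2.values) and r1.values.equals(r2.values)

    def test_infeasible_target_rho_rejected(self):
        with pytest.raises(ValueError):
            AssocSpec("APOBEC3B", "drug01", rho=1.5)

    def test_category_map_partitions_cell_lines(self):
        cfg = small_config(categories={"A": 3, "B": 4})
        _, _, cat_map, _ = simulate_phenotypes(cfg)
        assert len(cat_map) == 7
        assert sorted(set(cat_map.values())) == ["A", "B"]

    def test_config_yaml_round_trip(self, tmp_path):
        cfg = small_config(background_rate=1e-3, af_common_fraction=0.2)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        back = SimulationConfig.from_yaml(path)
        assert back.to_dict() == cfg.to_dict()
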