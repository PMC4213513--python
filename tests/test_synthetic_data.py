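"""Generator determinism, round-tripping, and planted-signal bookkeeping."""

import numpy as np
import pandas as pd
import pytest

from pocketprior.cepin import clean_ppi, quantile_normalize, read_expression_matrix, read_ppi_edges
from pocketprior.drug_response import read_pharmacology
from pocketprior.enrichment_stats import read_gmt
from pocketprior.mutation_mapping import map_mutations, read_mutation_catalog, summarize_by_class
from pocketprior.pocket_annotation import load_pocket_annotations
from pocketprior.survival import read_cohort
from pocketprior.synthetic_data import (
    GeneratorConfig,
    generate_mutations,
    generate_structures,
    generate_survival,
    paper_fixture,
    paper_fixture_mapped,
    write_bundle,
    write_paper_fixture,
)

SMALL = dict(
    n_proteins=20, n_samples=100, n_network_genes=80, n_ppi_edges=200,
    n_tissues=30, n_cell_lines=50, n_patients=60,
)


class TestDeterminism:
    def test_bundle_is_byte_identical_across_runs(self, tmp_path):
        cfg = GeneratorConfig(seed=5, **SMALL)
        b1 = write_bundle(cfg, tmp_path / "one")
        b2 = write_bundle(cfg, tmp_path / "two")
        files1 = sorted(p for p in (tmp_path / "one").rglob("*") if p.is_file())
        assert files1
        for f1 in files1:
            f2 = tmp_path / "two" / f1.relative_to(tmp_path / "one")
            assert f1.read_bytes() == f2.read_bytes(), f1.name

    def test_different_seed_changes_catalog(self):
        a = generate_mutations(GeneratorConfig(seed=1, **SMALL), generate_structures(GeneratorConfig(seed=1, **SMALL)))[0]
        b = generate_mutations(GeneratorConfig(seed=2, **SMALL), generate_structures(GeneratorConfig(seed=2, **SMALL)))[0]
        assert not a.equals(b)


class TestStructures:
    def test_pocket_fraction_within_configured_band(self):
        cfg = GeneratorConfig(seed=3, **SMALL)
        s = generate_structures(cfg)
        per_protein = s.pocket_residues.groupby("uniprot_acc")["position"].nunique()
        lengths = s.proteins.set_index("accession")["length"]
        fractions = per_protein / lengths.loc[per_protein.index]
        # tolerance for rounding and the minimum-size floor on short chains
        assert (fractions >= cfg.pocket_fraction[0] - 0.03).all()
        assert (fractions <= cfg.pocket_fraction[1] + 0.03).all()

    def test_full_coverage_means_zero_unmapped(self, tmp_path):
        cfg = GeneratorConfig(seed=3, mapping_coverage=1.0, **SMALL)
        b = write_bundle(cfg, tmp_path)
        _, report = load_pocket_annotations(b.pdb_dir, b.sifts)
        assert report.unmapped == 0 and report.mismatched == 0

    def test_pkt_residues_consistent_with_mapping(self, tmp_path):
        # parse -> translate on generated files must recover the generator's
        # own mapped pocket table exactly
        cfg = GeneratorConfig(seed=6, **SMALL)
        b = write_bundle(cfg, tmp_path)
        s = generate_structures(cfg)
        annotations, report = load_pocket_annotations(b.pdb_dir, b.sifts)
        expected = (
            s.pocket_residues[s.pocket_residues["mapped"]]
            .drop(columns="mapped").sort_values(["uniprot_acc", "pocket_id", "position"])
            .reset_index(drop=True)
        )
        got = annotations.residues.sort_values(["uniprot_acc", "pocket_id", "position"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(got, expected)
        assert report.mismatched == 0


class TestMutations:
    def test_class_mix_within_three_sigma(self):
        cfg = GeneratorConfig(seed=8, n_proteins=150, planted_genes=[])
        s = generate_structures(cfg, build_files=False)
        catalog, _ = generate_mutations(cfg, s)
        mapped = map_mutations(catalog, s.annotation_set())
        classes = mapped.records["mclass"]
        n = len(classes)
        for mclass, target in cfg.class_mix.items():
            observed = (classes == mclass).mean()
            sigma = np.sqrt(target * (1 - target) / n)
            assert abs(observed - target) < 3 * sigma + 1e-9, mclass

    def test_null_pocket_rate_matches_pocket_fraction(self):
        cfg = GeneratorConfig(seed=12, n_proteins=150, planted_genes=[])
        s = generate_structures(cfg, build_files=False)
        catalog, _ = generate_mutations(cfg, s)
        mapped = map_mutations(catalog, s.annotation_set())
        pocket_rate = mapped.records["in_pocket"].mean()
        ann = s.annotation_set().residues
        frac = (
            ann.groupby("uniprot_acc")["position"].nunique()
            / s.proteins.set_index("accession")["length"]
        ).reindex(s.proteins["accession"]).mean()
        n = len(mapped)
        sigma = np.sqrt(frac * (1 - frac) / n)
        assert abs(pocket_rate - frac) < 4 * sigma

    def test_truth_lists_exactly_planted_genes(self):
        cfg = GeneratorConfig(seed=4, **SMALL)
        s = generate_structures(cfg, build_files=False)
        _, truth = generate_mutations(cfg, s)
        assert list(truth["gene"]) == [p.gene for p in cfg.planted_genes]

    def test_wild_types_match_sequences(self):
        cfg = GeneratorConfig(seed=4, **SMALL)
        s = generate_structures(cfg, build_files=False)
        catalog, _ = generate_mutations(cfg, s)
        for row in catalog.sample(50, random_state=0).itertuples(index=False):
            assert s.sequences[row.uniprot_acc][row.pos - 1] == row.wt


class TestBundleRoundTrip:
    def test_every_file_parses_through_its_consumer(self, tmp_path):
        cfg = GeneratorConfig(seed=9, **SMALL)
        b = write_bundle(cfg, tmp_path)
        annotations, _ = load_pocket_annotations(b.pdb_dir, b.sifts)
        assert len(annotations.proteins) == cfg.n_proteins
        catalog = read_mutation_catalog(b.mutations)
        mapped = map_mutations(catalog, annotations)
        assert len(mapped) > 0
        sets = read_gmt(b.gene_sets)
        assert {s.name for s in sets} == {"synthetic_cancer_drivers", "synthetic_random_set"}
        edges, _ = clean_ppi(read_ppi_edges(b.ppi))
        assert len(edges) == cfg.n_ppi_edges
        expr = quantile_normalize(read_expression_matrix(b.expression))
        assert expr.shape == (cfg.n_network_genes, cfg.n_tissues)
        read_mutation_catalog(b.cl_mutations)
        pharm = read_pharmacology(b.pharmacology)
        assert set(pharm["drug"]) == set(cfg.drugs)
        cohort = read_cohort(b.survival)
        assert len(cohort) == cfg.n_patients

    def test_seed_recorded_in_headers(self, tmp_path):
        cfg = GeneratorConfig(seed=31, **SMALL)
        b = write_bundle(cfg, tmp_path)
        for path in (b.mutations, b.ppi, b.expression, b.pharmacology, b.survival):
            assert "seed: 31" in path.read_text().splitlines()[0]


class TestSurvivalGenerator:
    def test_truncation_reduces_event_count_monotonically(self):
        from pocketprior.survival import truncate

        cfg = GeneratorConfig(seed=2, **SMALL)
        cohort = generate_survival(cfg)
        full = int(cohort["event"].sum())
        t2000 = int(truncate(cohort, 2000)["event"].sum())
        t500 = int(truncate(cohort, 500)["event"].sum())
        assert full >= t2000 >= t500


class TestPaperFixture:
    def test_counts_total_and_partition(self):
        catalog, pockets = paper_fixture()
        assert len(catalog) == 2262
        assert catalog["uniprot_acc"].nunique() == 369
        assert len(pockets.proteins) == 369

    def test_fixture_maps_entirely_in_pocket(self):
        mset = paper_fixture_mapped()
        assert int(mset.records["in_pocket"].sum()) == 2262

    def test_fixture_class_counts(self):
        mset = paper_fixture_mapped()
        counts = summarize_by_class(mset).set_index("mclass")["count"]
        assert counts["missense"] == 1603
        assert counts["silent"] == 467
        assert counts["nonsense"] == 115

    def test_fixture_parses_through_standard_reader(self, tmp_path):
        mpath, _ = write_paper_fixture(tmp_path)
        catalog = read_mutation_catalog(mpath)
        assert len(catalog) == 2262
        assert catalog["mclass"].value_counts()["missense"] == 1603


class TestConfigValidation:
    def test_bad_class_mix_rejected(self):
        with pytest.raises(ValueError, match="class_mix"):
            GeneratorConfig(class_mix={"missense": 0.5, "silent": 0.4})

    def test_bad_pocket_fraction_rejected(self):
        with pytest.raises(ValueError, match="pocket_fraction"):
            GeneratorConfig(pocket_fraction=(0.5, 0.2))

    def test_yaml_round_trip(self, tmp_path):
        cfg = GeneratorConfig(seed=77, **SMALL)
        cfg.to_yaml(tmp_path / "c.yaml")
        assert GeneratorConfig.from_yaml(tmp_path / "c.yaml") == cfg
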