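"""Fixture generator: planted structure, determinism, truth verification."""

import json

import pytest

from metnet.errors import ConfigError
from metnet.synthetic_data import (
    FixtureConfig,
    FixtureTruth,
    generate_fixture,
    null_fixture_config,
    simulate,
    verify_truth,
)


def small_config(**overrides) -> FixtureConfig:
    base = dict(
        n_genes=80,
        n_diseases=8,
        genes_per_disease=(4, 8),
        n_metabolites=3,
        genes_per_metabolite=(4, 8),
        planted_pairs=(("M0001", "AD biomarkers", 0.5),),
        background_overlap=0.05,
        n_pathways=10,
        genes_per_pathway=(5, 10),
        seed=21,
    )
    base.update(overrides)
    return FixtureConfig(**base)


class TestPlanting:
    def test_no_planted_pairs_gives_empty_truth(self):
        fx = simulate(null_fixture_config(seed=2))
        assert fx.truth.planted == []

    def test_planted_overlap_is_exact(self):
        cfg = small_config(
            genes_per_disease=(10, 10),
            planted_pairs=(("M0001", "AD biomarkers", 0.5),),
        )
        fx = simulate(cfg)
        met = fx.chemical_gene.gene_sets()["M0001"]
        dis = fx.disease_gene.gene_sets()["AD biomarkers"]
        assert len(dis) == 10
        assert len(met & dis) == 5
        assert fx.truth.planted[0]["realized_overlap"] == 5
        assert fx.truth.overlap_counts["M0001"]["AD biomarkers"] == 5

    def test_truth_matches_emitted_tables(self):
        fx = simulate(small_config())
        dsets = fx.disease_gene.gene_sets()
        msets = fx.chemical_gene.gene_sets()
        for mid, per_disease in fx.truth.overlap_counts.items():
            for d, count in per_disease.items():
                assert len(msets[mid] & dsets[d]) == count

    def test_planted_fraction_must_exceed_background(self):
        with pytest.raises(ConfigError, match="background"):
            simulate(
                small_config(
                    planted_pairs=(("M0001", "AD biomarkers", 0.04),),
                    background_overlap=0.05,
                )
            )

    def test_unknown_planted_entities_rejected(self):
        with pytest.raises(ConfigError):
            simulate(small_config(planted_pairs=(("M9999", "AD biomarkers", 0.5),)))
        with pytest.raises(ConfigError):
            simulate(small_config(planted_pairs=(("M0001", "no trait", 0.5),)))

    def test_infeasible_gene_counts_rejected(self):
        with pytest.raises(ConfigError):
            simulate(small_config(genes_per_disease=(50, 200)))


class TestDeterminism:
    def test_same_seed_byte_identical_bundle(self, tmp_path):
        cfg = small_config(seed=7)
        generate_fixture(cfg, tmp_path / "a")
        generate_fixture(cfg, tmp_path / "b")
        man_a = json.loads((tmp_path / "a" / "manifest.json").read_text())
        man_b = json.loads((tmp_path / "b" / "manifest.json").read_text())
        assert man_a == man_b

    def test_different_seed_differs(self, tmp_path):
        generate_fixture(small_config(seed=7), tmp_path / "a")
        generate_fixture(small_config(seed=8), tmp_path / "b")
        man_a = json.loads((tmp_path / "a" / "manifest.json").read_text())
        man_b = json.loads((tmp_path / "b" / "manifest.json").read_text())
        assert man_a != man_b


class TestVerifyTruth:
    def test_unmodified_bundle_verifies(self, tmp_path):
        _, truth = generate_fixture(small_config(), tmp_path)
        assert verify_truth(tmp_path, truth) is True

    def test_deleted_row_detected(self, tmp_path):
        paths, truth = generate_fixture(small_config(), tmp_path)
        lines = paths["chemical_gene"].read_text().splitlines(keepends=True)
        paths["chemical_gene"].write_text("".join(lines[:-1]))
        assert verify_truth(tmp_path, truth) is False

    def test_regenerated_bundle_verifies_against_saved_truth(self, tmp_path):
        _, truth = generate_fixture(small_config(), tmp_path / "a")
        generate_fixture(small_config(), tmp_path / "b")
        reloaded = FixtureTruth.from_json(tmp_path / "a" / "truth.json")
        assert verify_truth(tmp_path / "b", reloaded) is True


def test_default_bundle_loads_through_readers(tmp_path):
    """The emitted files parse with the standard readers at default
    thresholds without losing any generated record."""
    from metnet.io_formats import (
        read_chemical_gene_table,
        read_disease_gene_table,
        read_gmt,
        read_metabolite_catalog,
        read_ppi,
    )

    cfg = small_config()
    paths, truth = generate_fixture(cfg, tmp_path)
    disease = read_disease_gene_table(paths["disease_gene"], dialect="gwas")
    chem = read_chemical_gene_table(paths["chemical_gene"], min_score=0.4)
    ppi = read_ppi(paths["ppi"], min_confidence=0.7)
    gmt = read_gmt(paths["pathways"])
    cat = read_metabolite_catalog(paths["catalog"])
    assert len(disease.entities()) == cfg.n_diseases
    assert len(chem.entities()) == cfg.n_metabolites
    assert {m: len(s) for m, s in chem.gene_sets().items()} == truth.metabolite_sizes
    assert len(gmt) == cfg.n_pathways
    assert len(cat) == cfg.n_metabolites
    assert len(ppi) > 0
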