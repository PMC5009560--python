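"""Self-contained synthetic fixtures for the whole pipeline.

The generator emulates the five input families (disease-gene table,
chemical-gene table with evidence scores, PPI table, GMT pathway
collection, metabolite catalog) with controllable planted structure, so
network construction, ranking, and significance testing are exercisable
without any database download.

Construction model
------------------
* Disease gene sets are uniform random subsets of a gene universe of
  ``n_genes`` symbols (``G000001`` ...); overlapping draws create the
  disease-disease edges of the GDN.
* Metabolite gene sets combine three ingredients, which keeps the
  ground truth exactly countable:

  - *decoy* genes drawn from a reserved pool disjoint from the disease
    universe (labels continue the numbering beyond ``n_genes``),
  - *background* genes: for every non-planted (metabolite, disease)
    pair, each of the disease's genes is included independently with
    probability ``background_overlap``,
  - *planted* genes: for a planted pair with overlap fraction f, exactly
    ceil(f x |disease genes|) of that disease's genes.

* Evidence scores for chemical-gene rows are uniform on [0.4, 1.0] and
  PPI confidences uniform on [0.7, 1.0], so default loading thresholds
  retain all generated signal.

The first disease labels are AD-like multi-trait names ("AD
biomarkers", "AD cognitive decline", ...) so profile operations across
traits are exercised realistically.  The same seed always yields a
byte-identical file bundle.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .errors import ConfigError
from .io_formats import (
    AssociationRecord,
    AssociationTable,
    InteractionNetwork,
    MetaboliteCatalog,
    PathwayCollection,
    read_chemical_gene_table,
    read_disease_gene_table,
    read_gmt,
    read_metabolite_catalog,
    read_ppi,
    write_association_table,
    write_gmt,
    write_interaction_network,
    write_metabolite_catalog,
)

__all__ = [
    "FixtureConfig",
    "FixtureTruth",
    "Fixture",
    "null_fixture_config",
    "simulate",
    "generate_fixture",
    "verify_truth",
]

_AD_TRAITS = (
    "AD biomarkers",
    "AD cognitive decline",
    "AD (age of onset)",
    "AD (late onset)",
    "AD, susceptibility to",
)

_METABOLITE_NAMES = (
    "trimethylamine N-oxide",
    "mannitol",
    "succinic acid",
    "3,4-dihydroxybenzeneacetic acid",
    "d-proline",
    "putrescine",
    "cadaverine",
    "trehalose",
)


def disease_labels(n: int) -> list[str]:
    labels = list(_AD_TRAITS[:n])
    labels += [f"trait {i:03d}" for i in range(len(labels) + 1, n + 1)]
    return labels


def metabolite_ids(n: int) -> list[str]:
    return [f"M{i:04d}" for i in range(1, n + 1)]


def _metabolite_names(n: int) -> list[str]:
    names = list(_METABOLITE_NAMES[:n])
    names += [f"metabolite {i}" for i in range(len(names) + 1, n + 1)]
    return names


@dataclass
class FixtureConfig:
    """Knobs of the synthetic-data generator.

    ``planted_pairs`` lists (metabolite_id, disease_label,
    overlap_fraction) triples; each planted overlap fraction must
    strictly exceed ``background_overlap``.
    """

    n_genes: int = 200
    n_diseases: int = 40
    genes_per_disease: tuple[int, int] = (5, 15)
    n_metabolites: int = 20
    genes_per_metabolite: tuple[int, int] = (5, 15)
    planted_pairs: tuple[tuple[str, str, float], ...] = (
        ("M0001", "AD biomarkers", 0.5),
    )
    background_overlap: float = 0.02
    ppi_density: float = 0.01
    n_pathways: int = 50
    genes_per_pathway: tuple[int, int] = (10, 30)
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_genes", "n_diseases", "n_metabolites", "n_pathways"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be positive")
        for name in (
            "genes_per_disease",
            "genes_per_metabolite",
            "genes_per_pathway",
        ):
            lo, hi = getattr(self, name)
            if not (1 <= lo <= hi):
                raise ConfigError(f"{name} must satisfy 1 <= lo <= hi")
        if not 0.0 <= self.background_overlap <= 1.0:
            raise ConfigError("background_overlap must lie in [0, 1]")
        if not 0.0 <= self.ppi_density <= 1.0:
            raise ConfigError("ppi_density must lie in [0, 1]")
        if self.genes_per_disease[1] > self.n_genes:
            raise ConfigError(
                "genes_per_disease upper bound exceeds the gene universe"
            )
        if self.genes_per_metabolite[1] > self.n_genes:
            raise ConfigError(
                "genes_per_metabolite upper bound exceeds the decoy pool"
            )
        dlabels = set(disease_labels(self.n_diseases))
        mids = set(metabolite_ids(self.n_metabolites))
        for mid, disease, frac in self.planted_pairs:
            if mid not in mids:
                raise ConfigError(f"planted metabolite {mid!r} not generated")
            if disease not in dlabels:
                raise ConfigError(f"planted disease {disease!r} not generated")
            if not 0.0 < frac <= 1.0:
                raise ConfigError(
                    f"planted overlap fraction must lie in (0, 1], got {frac}"
                )
            if frac <= self.background_overlap:
                raise ConfigError(
                    "planted overlap_fraction must strictly exceed "
                    f"background_overlap ({frac} <= {self.background_overlap})"
                )


def null_fixture_config(seed: int = 0) -> FixtureConfig:
    """A background-only configuration (no planted pairs).

    Sized for calibration studies: 40 diseases drawing small gene sets
    from a 600-gene universe keeps the GDN sparse, and a 5 % background
    overlap gives the single metabolite a handful of random edges.
    """
    return FixtureConfig(
        n_genes=600,
        n_diseases=40,
        genes_per_disease=(5, 10),
        n_metabolites=1,
        genes_per_metabolite=(5, 10),
        planted_pairs=(),
        background_overlap=0.05,
        seed=seed,
    )


@dataclass
class FixtureTruth:
    """Exact ground truth of a generated bundle."""

    planted: list[dict] = field(default_factory=list)
    disease_sizes: dict[str, int] = field(default_factory=dict)
    metabolite_sizes: dict[str, int] = field(default_factory=dict)
    overlap_counts: dict[str, dict[str, int]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "FixtureTruth":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))


@dataclass
class Fixture:
    """In-memory bundle: the five parsed inputs plus the ground truth."""

    config: FixtureConfig
    disease_gene: AssociationTable
    chemical_gene: AssociationTable
    ppi: InteractionNetwork
    pathways: PathwayCollection
    catalog: MetaboliteCatalog
    truth: FixtureTruth


def _gene_label(i: int) -> str:
    return f"G{i:06d}"


def simulate(config: FixtureConfig) -> Fixture:
    """Generate the full fixture in memory (deterministic in the seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    disease_pool = np.array(
        [_gene_label(i) for i in range(1, config.n_genes + 1)]
    )
    decoy_pool = np.array(
        [_gene_label(i) for i in range(config.n_genes + 1, 2 * config.n_genes + 1)]
    )
    dlabels = disease_labels(config.n_diseases)
    mids = metabolite_ids(config.n_metabolites)

    lo, hi = config.genes_per_disease
    disease_sets: dict[str, frozenset[str]] = {}
    for d in dlabels:
        size = int(rng.integers(lo, hi + 1))
        disease_sets[d] = frozenset(
            rng.choice(disease_pool, size=size, replace=False)
        )

    planted_by_met: dict[str, list[tuple[str, float]]] = {}
    for mid, disease, frac in config.planted_pairs:
        planted_by_met.setdefault(mid, []).append((disease, frac))

    mlo, mhi = config.genes_per_metabolite
    met_sets: dict[str, frozenset[str]] = {}
    planted_records: list[dict] = []
    for mid in mids:
        genes: set[str] = set()
        forbidden: set[str] = set()
        planted_diseases: set[str] = set()
        for disease, frac in planted_by_met.get(mid, []):
            dset = sorted(disease_sets[disease])
            k = math.ceil(frac * len(dset))
            if k > len(dset):
                raise ConfigError(
                    f"planted overlap for ({mid}, {disease}) exceeds the "
                    "disease's gene count"
                )
            chosen = set(rng.choice(np.array(dset), size=k, replace=False))
            genes.update(chosen)
            forbidden.update(set(dset) - chosen)
            planted_diseases.add(disease)
            planted_records.append(
                {
                    "metabolite_id": mid,
                    "disease": disease,
                    "overlap_fraction": frac,
                    "realized_overlap": k,
                }
            )
        size = int(rng.integers(mlo, mhi + 1))
        genes.update(rng.choice(decoy_pool, size=size, replace=False))
        if config.background_overlap > 0.0:
            for d in dlabels:
                if d in planted_diseases:
                    continue
                dset = sorted(disease_sets[d])
                mask = rng.random(len(dset)) < config.background_overlap
                genes.update(
                    g
                    for g, keep in zip(dset, mask)
                    if keep and g not in forbidden
                )
        met_sets[mid] = frozenset(genes - forbidden)

    overlap_counts = {
        mid: {d: len(met_sets[mid] & disease_sets[d]) for d in dlabels}
        for mid in mids
    }
    truth = FixtureTruth(
        planted=planted_records,
        disease_sizes={d: len(s) for d, s in disease_sets.items()},
        metabolite_sizes={m: len(s) for m, s in met_sets.items()},
        overlap_counts=overlap_counts,
    )

    disease_records = [
        AssociationRecord(d, g)
        for d in dlabels
        for g in sorted(disease_sets[d])
    ]
    chem_records = []
    for mid in mids:
        for g in sorted(met_sets[mid]):
            score = float(rng.uniform(0.4, 1.0))
            chem_records.append(AssociationRecord(mid, g, round(score, 6)))

    # PPI over the disease-gene universe
    n_pairs_wanted = round(
        config.ppi_density * config.n_genes * (config.n_genes - 1) / 2
    )
    ppi_edges: dict[tuple[str, str], float] = {}
    seen_pairs: set[tuple[int, int]] = set()
    while len(ppi_edges) < n_pairs_wanted:
        i = int(rng.integers(0, config.n_genes))
        j = int(rng.integers(0, config.n_genes))
        if i == j:
            continue
        if i > j:
            i, j = j, i
        if (i, j) in seen_pairs:
            continue
        seen_pairs.add((i, j))
        ppi_edges[(str(disease_pool[i]), str(disease_pool[j]))] = round(
            float(rng.uniform(0.7, 1.0)), 6
        )

    plo, phi = config.genes_per_pathway
    all_genes = np.concatenate([disease_pool, decoy_pool])
    pw: dict[str, frozenset[str]] = {}
    desc: dict[str, str] = {}
    for i in range(1, config.n_pathways + 1):
        name = f"PW{i:03d}"
        size = int(rng.integers(plo, phi + 1))
        pw[name] = frozenset(rng.choice(all_genes, size=size, replace=False))
        desc[name] = "synthetic pathway"

    catalog = MetaboliteCatalog(
        list(zip(mids, _metabolite_names(config.n_metabolites)))
    )
    return Fixture(
        config=config,
        disease_gene=AssociationTable(disease_records),
        chemical_gene=AssociationTable(chem_records),
        ppi=InteractionNetwork(ppi_edges),
        pathways=PathwayCollection(pw, desc),
        catalog=catalog,
        truth=truth,
    )


_FILE_NAMES = {
    "disease_gene": "disease_gene.tsv",
    "chemical_gene": "chemical_gene.tsv",
    "ppi": "ppi.tsv",
    "pathways": "pathways.gmt",
    "catalog": "metabolites.tsv",
}


def generate_fixture(
    config: FixtureConfig, out_dir: str | Path
) -> tuple[dict[str, Path], FixtureTruth]:
    """Emit the five fixture files plus truth.json and a checksum manifest.

    Returns the path of each emitted input file keyed by family.  The
    same seed yields byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fx = simulate(config)
    paths = {k: out_dir / v for k, v in _FILE_NAMES.items()}
    write_association_table(
        fx.disease_gene, paths["disease_gene"], entity_col="disease_trait"
    )
    write_association_table(
        fx.chemical_gene, paths["chemical_gene"], entity_col="chemical"
    )
    write_interaction_network(fx.ppi, paths["ppi"])
    write_gmt(fx.pathways, paths["pathways"])
    write_metabolite_catalog(fx.catalog, paths["catalog"])
    fx.truth.to_json(out_dir / "truth.json")
    manifest = {
        name: hashlib.sha256(path.read_bytes()).hexdigest()
        for name, path in sorted(paths.items())
    }
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths, fx.truth


def verify_truth(bundle_dir: str | Path, truth: FixtureTruth) -> bool:
    """Re-parse an emitted bundle and check it against recorded truth.

    True iff every disease/metabolite gene-set size and every pairwise
    overlap count match the truth record exactly.
    """
    bundle_dir = Path(bundle_dir)
    disease = read_disease_gene_table(
        bundle_dir / _FILE_NAMES["disease_gene"], dialect="gwas"
    )
    chem = read_chemical_gene_table(
        bundle_dir / _FILE_NAMES["chemical_gene"], min_score=0.0
    )
    # readable at all is part of the contract for the remaining files
    read_ppi(bundle_dir / _FILE_NAMES["ppi"], min_confidence=0.0)
    read_gmt(bundle_dir / _FILE_NAMES["pathways"])
    read_metabolite_catalog(bundle_dir / _FILE_NAMES["catalog"])

    disease_sets = disease.gene_sets()
    met_sets = chem.gene_sets()
    if {d: len(s) for d, s in disease_sets.items()} != truth.disease_sizes:
        return False
    if {m: len(s) for m, s in met_sets.items()} != truth.metabolite_sizes:
        return False
    for mid, per_disease in truth.overlap_counts.items():
        mset = met_sets.get(mid, frozenset())
        for d, count in per_disease.items():
            if len(mset & disease_sets.get(d, frozenset())) != count:
                return False
    return True
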