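"""Readers and writers for the tabular inputs and result tables.

Five input families are supported:

* disease-gene association tables (GWAS-catalog-style or OMIM-style TSV),
* chemical-gene association tables with evidence scores (STITCH-style TSV),
* protein-protein interaction tables with confidence scores (STRING-style TSV),
* gene-set collections (GMT),
* metabolite catalogs (HMDB-style TSV of id/name pairs).

Gene symbols are normalized to uppercase, whitespace-trimmed strings on
load; entity labels (trait names, metabolite ids) are kept verbatim apart
from surrounding whitespace.  All writers emit UTF-8, tab-delimited tables
with a single header line and "." as the decimal mark.

Column names for the disease-gene dialects are resolved from a small set
of header aliases (real GWAS-catalog / OMIM exports vary by release); an
explicit ``column_map`` always wins over the built-in aliases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import FormatError

__all__ = [
    "AssociationRecord",
    "AssociationTable",
    "InteractionNetwork",
    "PathwayCollection",
    "MetaboliteCatalog",
    "normalize_gene",
    "read_disease_gene_table",
    "read_chemical_gene_table",
    "read_ppi",
    "read_gmt",
    "read_metabolite_catalog",
    "write_association_table",
    "write_interaction_network",
    "write_gmt",
    "write_metabolite_catalog",
    "write_edge_list",
    "read_edge_list",
    "write_node_table",
]


def normalize_gene(symbol: str) -> str:
    """Normalize a gene symbol: strip surrounding whitespace and uppercase.

    Idempotent; unrecognized characters are kept verbatim.
    """
    return str(symbol).strip().upper()


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AssociationRecord:
    """One (entity, gene) association, optionally with an evidence score."""

    entity_id: str
    gene: str
    score: float | None = None


@dataclass
class AssociationTable:
    """A deduplicated list of entity-gene associations.

    ``entity_id`` is a disease/trait label or a metabolite/chemical id;
    genes are normalized symbols.  Scores, when present, lie in [0, 1].
    """

    records: list[AssociationRecord]

    def __len__(self) -> int:
        return len(self.records)

    def entities(self) -> list[str]:
        """Entity labels in first-seen order."""
        seen: dict[str, None] = {}
        for rec in self.records:
            seen.setdefault(rec.entity_id, None)
        return list(seen)

    def gene_sets(self) -> dict[str, frozenset[str]]:
        """Map each entity to its gene set, preserving entity order."""
        sets: dict[str, set[str]] = {}
        for rec in self.records:
            sets.setdefault(rec.entity_id, set()).add(rec.gene)
        return {e: frozenset(g) for e, g in sets.items()}

    def score_map(self) -> dict[tuple[str, str], float]:
        """(entity, gene) -> score for records that carry a score."""
        return {
            (r.entity_id, r.gene): r.score
            for r in self.records
            if r.score is not None
        }


@dataclass
class InteractionNetwork:
    """Undirected gene-gene interaction set with confidences in [0, 1].

    Edge keys are lexicographically sorted gene pairs; self-loops are
    never stored.
    """

    edges: dict[tuple[str, str], float]
    _adjacency: dict[str, set[str]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        adj: dict[str, set[str]] = {}
        for (a, b) in self.edges:
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)
        self._adjacency = adj

    def __len__(self) -> int:
        return len(self.edges)

    def neighbors(self, gene: str) -> set[str]:
        return self._adjacency.get(gene, set())

    def genes(self) -> set[str]:
        return set(self._adjacency)


@dataclass
class PathwayCollection:
    """Named gene sets (pathways) with optional free-text descriptions."""

    pathways: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pathways)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.pathways[name]

    def __contains__(self, name: str) -> bool:
        return name in self.pathways

    def items(self):
        return self.pathways.items()

    def gene_to_pathways(self) -> dict[str, set[str]]:
        """Inverse index: gene -> names of pathways containing it."""
        index: dict[str, set[str]] = {}
        for name, genes in self.pathways.items():
            for g in genes:
                index.setdefault(g, set()).add(name)
        return index


@dataclass
class MetaboliteCatalog:
    """Ordered metabolite (id, name) list; ids unique."""

    entries: list[tuple[str, str]]

    def __len__(self) -> int:
        return len(self.entries)

    def ids(self) -> list[str]:
        return [i for i, _ in self.entries]

    def name_of(self, metabolite_id: str) -> str:
        for i, n in self.entries:
            if i == metabolite_id:
                return n
        raise KeyError(metabolite_id)


# ---------------------------------------------------------------------------
# column resolution
# ---------------------------------------------------------------------------

_DIALECT_ALIASES: dict[str, dict[str, tuple[str, ...]]] = {
    "gwas": {
        "entity": ("disease/trait", "disease_trait", "trait", "disease"),
        "gene": ("mapped_gene", "reported gene(s)", "reported_gene", "gene"),
    },
    "omim": {
        "entity": ("phenotype", "disorder", "disease", "disease_trait"),
        "gene": ("gene_symbol", "gene symbols", "approved symbol", "gene"),
    },
    "generic": {
        "entity": ("entity_id", "entity", "disease_trait", "trait"),
        "gene": ("gene", "gene_symbol", "mapped_gene"),
        "score": ("score", "combined_score", "confidence"),
    },
    "stitch": {
        "entity": ("chemical", "metabolite", "metabolite_id", "entity_id"),
        "gene": ("gene", "protein", "gene_symbol"),
        "score": ("combined_score", "score", "confidence"),
    },
    "string": {
        "gene1": ("protein1", "gene1", "node1"),
        "gene2": ("protein2", "gene2", "node2"),
        "score": ("combined_score", "score", "confidence"),
    },
    "catalog": {
        "id": ("metabolite_id", "hmdb_id", "id"),
        "name": ("name", "metabolite_name", "metabolite"),
    },
}


def _resolve_column(
    df: pd.DataFrame,
    logical: str,
    aliases: Mapping[str, tuple[str, ...]],
    column_map: Mapping[str, str] | None,
    *,
    required: bool = True,
    path: str | Path = "",
) -> str | None:
    if column_map and logical in column_map:
        col = column_map[logical]
        if col not in df.columns:
            raise FormatError(
                f"{path}: mapped column {col!r} for {logical!r} not found "
                f"(columns: {list(df.columns)})"
            )
        return col
    lower = {c.lower(): c for c in df.columns}
    for alias in aliases.get(logical, ()):
        if alias in lower:
            return lower[alias]
    if required:
        raise FormatError(
            f"{path}: required column for {logical!r} not found; expected one "
            f"of {list(aliases.get(logical, ()))} (columns: {list(df.columns)})"
        )
    return None


def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: file is empty") from None
    return df


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_disease_gene_table(
    path: str | Path,
    dialect: str = "generic",
    column_map: Mapping[str, str] | None = None,
) -> AssociationTable:
    """Load a disease/trait-gene association TSV.

    One record is kept per unique (trait, gene) pair; the trait label is
    kept verbatim (case preserved) and the gene symbol normalized.
    """
    if dialect not in ("gwas", "omim", "generic"):
        raise FormatError(f"unknown disease-gene dialect {dialect!r}")
    df = _read_tsv(path)
    aliases = _DIALECT_ALIASES[dialect]
    ecol = _resolve_column(df, "entity", aliases, column_map, path=path)
    gcol = _resolve_column(df, "gene", aliases, column_map, path=path)
    records: list[AssociationRecord] = []
    seen: set[tuple[str, str]] = set()
    for ent, gene in zip(df[ecol], df[gcol]):
        ent = str(ent).strip()
        gene = normalize_gene(gene)
        if not ent or not gene:
            continue
        key = (ent, gene)
        if key in seen:
            continue
        seen.add(key)
        records.append(AssociationRecord(ent, gene))
    if not records:
        raise FormatError(f"{path}: no disease-gene associations found")
    return AssociationTable(records)


def _parse_scores(raw: Sequence[str], path: str | Path) -> list[float]:
    scores: list[float] = []
    for i, s in enumerate(raw):
        try:
            scores.append(float(s))
        except (TypeError, ValueError):
            # +2: one for the header line, one for 1-based numbering
            raise FormatError(
                f"{path}: non-numeric score {s!r} at line {i + 2}"
            ) from None
    return scores


def _rescale_scores(scores: list[float]) -> list[float]:
    # STITCH/STRING-style integer scores live on a 0-1000 scale
    if scores and max(scores) > 1.0:
        return [s / 1000.0 for s in scores]
    return scores


def read_chemical_gene_table(
    path: str | Path,
    min_score: float = 0.4,
    column_map: Mapping[str, str] | None = None,
) -> AssociationTable:
    """Load a chemical/metabolite-gene association TSV with evidence scores.

    Scores on a 0-1000 integer scale are rescaled to [0, 1]; records with
    score < ``min_score`` are dropped; duplicate pairs keep the maximum
    score.
    """
    if not 0.0 <= min_score <= 1.0:
        raise FormatError(f"min_score must be in [0, 1], got {min_score}")
    df = _read_tsv(path)
    aliases = _DIALECT_ALIASES["stitch"]
    ecol = _resolve_column(df, "entity", aliases, column_map, path=path)
    gcol = _resolve_column(df, "gene", aliases, column_map, path=path)
    scol = _resolve_column(df, "score", aliases, column_map, path=path)
    scores = _rescale_scores(_parse_scores(list(df[scol]), path))
    best: dict[tuple[str, str], float] = {}
    order: list[tuple[str, str]] = []
    for ent, gene, score in zip(df[ecol], df[gcol], scores):
        ent = str(ent).strip()
        gene = normalize_gene(gene)
        if not ent or not gene:
            continue
        key = (ent, gene)
        if key not in best:
            order.append(key)
            best[key] = score
        else:
            best[key] = max(best[key], score)
    records = [
        AssociationRecord(e, g, best[(e, g)])
        for (e, g) in order
        if best[(e, g)] >= min_score
    ]
    return AssociationTable(records)


def read_ppi(
    path: str | Path,
    min_confidence: float = 0.7,
    column_map: Mapping[str, str] | None = None,
) -> InteractionNetwork:
    """Load a protein-protein interaction TSV into an undirected network.

    Self-loops are discarded, duplicate/reciprocal rows are collapsed
    keeping the maximum confidence, and edges below ``min_confidence``
    are dropped after 0-1000 rescaling.
    """
    if not 0.0 <= min_confidence <= 1.0:
        raise FormatError(
            f"min_confidence must be in [0, 1], got {min_confidence}"
        )
    df = _read_tsv(path)
    aliases = _DIALECT_ALIASES["string"]
    c1 = _resolve_column(df, "gene1", aliases, column_map, path=path)
    c2 = _resolve_column(df, "gene2", aliases, column_map, path=path)
    sc = _resolve_column(df, "score", aliases, column_map, path=path)
    scores = _rescale_scores(_parse_scores(list(df[sc]), path))
    edges: dict[tuple[str, str], float] = {}
    for a, b, s in zip(df[c1], df[c2], scores):
        a, b = normalize_gene(a), normalize_gene(b)
        if not a or not b or a == b:
            continue
        key = (a, b) if a < b else (b, a)
        edges[key] = max(edges.get(key, 0.0), s)
    edges = {k: v for k, v in edges.items() if v >= min_confidence}
    return InteractionNetwork(edges)


def read_gmt(path: str | Path) -> PathwayCollection:
    """Load a GMT gene-set file: name <TAB> description <TAB> gene...

    Genes are normalized and deduplicated per pathway; a line with fewer
    than three fields or a repeated pathway name is a format error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    pathways: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: GMT lines need >= 3 tab-separated "
                    f"fields (name, description, genes...), got {len(fields)}"
                )
            name = fields[0].strip()
            if name in pathways:
                raise FormatError(
                    f"{path}: line {lineno}: duplicate pathway name {name!r}"
                )
            genes = frozenset(
                normalize_gene(g) for g in fields[2:] if g.strip()
            )
            if not genes:
                raise FormatError(
                    f"{path}: line {lineno}: pathway {name!r} has no genes"
                )
            pathways[name] = genes
            descriptions[name] = fields[1]
    if not pathways:
        raise FormatError(f"{path}: no pathways found")
    return PathwayCollection(pathways, descriptions)


def read_metabolite_catalog(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> MetaboliteCatalog:
    """Load a metabolite id/name TSV, preserving file order."""
    df = _read_tsv(path)
    aliases = _DIALECT_ALIASES["catalog"]
    icol = _resolve_column(df, "id", aliases, column_map, path=path)
    ncol = _resolve_column(df, "name", aliases, column_map, path=path)
    entries: list[tuple[str, str]] = []
    seen: set[str] = set()
    for mid, name in zip(df[icol], df[ncol]):
        mid = str(mid).strip()
        if not mid:
            continue
        if mid in seen:
            raise FormatError(f"{path}: duplicate metabolite id {mid!r}")
        seen.add(mid)
        entries.append((mid, str(name).strip()))
    if not entries:
        raise FormatError(f"{path}: empty metabolite catalog")
    return MetaboliteCatalog(entries)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def _fmt(x: float) -> str:
    return f"{x:.6f}"


def write_association_table(
    table: AssociationTable, path: str | Path, entity_col: str = "entity_id"
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{entity_col}\tgene\tscore\n")
        for rec in table.records:
            score = "" if rec.score is None else _fmt(rec.score)
            fh.write(f"{rec.entity_id}\t{rec.gene}\t{score}\n")


def write_interaction_network(
    network: InteractionNetwork, path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("protein1\tprotein2\tcombined_score\n")
        for (a, b), conf in network.edges.items():
            fh.write(f"{a}\t{b}\t{_fmt(conf)}\n")


def write_gmt(collection: PathwayCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in collection.pathways.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


def write_metabolite_catalog(
    catalog: MetaboliteCatalog, path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("metabolite_id\tname\n")
        for mid, name in catalog.entries:
            fh.write(f"{mid}\t{name}\n")


def write_edge_list(
    edges: Iterable[tuple[str, str, float]], path: str | Path
) -> None:
    """Serialize a weighted graph as a node1/node2/weight TSV."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("node1\tnode2\tweight\n")
        for a, b, w in edges:
            fh.write(f"{a}\t{b}\t{w!r}\n")


def read_edge_list(path: str | Path) -> list[tuple[str, str, float]]:
    df = _read_tsv(path)
    for col in ("node1", "node2", "weight"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    weights = _parse_scores(list(df["weight"]), path)
    out: list[tuple[str, str, float]] = []
    for a, b, w in zip(df["node1"], df["node2"], weights):
        if not math.isfinite(w) or w <= 0:
            raise FormatError(f"{path}: non-positive edge weight {w}")
        out.append((str(a), str(b), w))
    return out


def write_node_table(
    gene_sets: Mapping[str, frozenset[str]], path: str | Path
) -> None:
    """Node-attribute TSV: node label and its ';'-joined gene set."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("node\tgenes\n")
        for node, genes in gene_sets.items():
            fh.write(f"{node}\t{';'.join(sorted(genes))}\n")
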