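"""Readers, writers and filtering rules for the pipeline's external formats.

Formats handled here: expression TSV (genes x samples, log2 intensities) with a
two-column phenotype sidecar, seed gene lists (one symbol per line), GMT
pathway catalogs, SNP annotation TSVs, and weighted edge-list / SIF network
files.  Gene identity throughout is the case-sensitive symbol string; no alias
resolution is attempted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .network import WeightedNetwork

DISEASED = "diseased"
CONTROL = "control"
PHENOTYPE_LABELS = frozenset({DISEASED, CONTROL})

_CATEGORY_RE = re.compile(r"^[1-7][a-f]?$")


class FormatError(ValueError):
    """Malformed input file."""


@dataclass
class ExpressionMatrix:
    """Genes x samples log2 expression with a phenotype label per sample."""

    gene_ids: List[str]
    sample_ids: List[str]
    values: np.ndarray  # shape (n_genes, n_samples)
    phenotype: List[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(self.phenotype) != len(self.sample_ids):
            raise ValueError("one phenotype label required per sample")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite (no NaN/Inf)")
        bad = set(self.phenotype) - PHENOTYPE_LABELS
        if bad:
            raise ValueError(f"unknown phenotype label(s): {sorted(bad)}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def row(self, gene: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class SeedList:
    """Ordered, duplicate-free gene list with per-gene provenance tags."""

    genes: List[str]
    provenance: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("seed list contains duplicates")
        for g in self.genes:
            self.provenance.setdefault(g, "initial")

    def __contains__(self, gene: str) -> bool:
        return gene in self.provenance

    def __len__(self) -> int:
        return len(self.genes)

    def as_set(self) -> Set[str]:
        return set(self.genes)

    def extended(self, new_genes: Sequence[str], tag: str) -> "SeedList":
        """A new SeedList with `new_genes` appended (duplicates ignored)."""
        out = SeedList(list(self.genes), dict(self.provenance))
        for g in new_genes:
            if g not in out.provenance:
                out.genes.append(g)
                out.provenance[g] = tag
        return out


@dataclass
class GeneSetCatalog:
    """Named pathway gene sets (GMT-style): pathway_id -> (name, members)."""

    sets: Dict[str, Tuple[str, FrozenSet[str]]]

    def __post_init__(self) -> None:
        for pid, (_, members) in self.sets.items():
            if not members:
                raise ValueError(f"pathway {pid!r} has no member genes")

    @property
    def universe(self) -> Set[str]:
        out: Set[str] = set()
        for _, members in self.sets.values():
            out |= members
        return out

    def members(self, pathway_id: str) -> FrozenSet[str]:
        return self.sets[pathway_id][1]

    def __contains__(self, pathway_id: str) -> bool:
        return pathway_id in self.sets

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class VariantAnnotationTable:
    """SNP -> gene annotations with a RegulomeDB category and per-source scores.

    `frame` columns: snp_id, gene, regulomedb, then one numeric column per
    annotation source (e.g. regdb, dbsnp, vep, regfeat).  An optional
    `ld_proxy_of` column carries LD-expansion provenance and is ignored by
    scoring.
    """

    frame: pd.DataFrame

    REQUIRED = ("snp_id", "gene", "regulomedb")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"variant table missing column(s): {missing}")
        for i, cat in enumerate(self.frame["regulomedb"].astype(str)):
            if not _CATEGORY_RE.match(cat):
                raise FormatError(
                    f"row {i}: invalid RegulomeDB category {cat!r}"
                )
        for col in self.source_columns:
            vals = pd.to_numeric(self.frame[col], errors="coerce")
            if vals.isna().any() or not np.all(np.isfinite(vals)):
                raise ValueError(f"non-numeric or non-finite score in column {col!r}")
            if (vals < 0).any():
                raise ValueError(f"negative score in column {col!r}")

    @property
    def source_columns(self) -> List[str]:
        skip = set(self.REQUIRED) | {"ld_proxy_of"}
        return [c for c in self.frame.columns if c not in skip]

    def __len__(self) -> int:
        return len(self.frame)


# ---------------------------------------------------------------------------
# expression


def read_expression(path: str, phenotype_path: str) -> ExpressionMatrix:
    """Load a genes-x-samples TSV plus its sample -> phenotype sidecar.

    The TSV's first column is the gene/probe id and the header row carries
    sample ids.  Every sample must have a phenotype label; duplicate sample
    ids, ragged rows and non-numeric cells are rejected with the offending
    location in the message.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(header) < 2:
        raise FormatError(f"{path}: expected gene-id column plus >=1 sample column")
    sample_ids = header[1:]
    dup = [s for s in set(sample_ids) if sample_ids.count(s) > 1]
    if dup:
        raise FormatError(f"{path}: duplicate sample id(s): {sorted(dup)}")

    gene_ids: List[str] = []
    rows: List[List[float]] = []
    with open(path) as fh:
        fh.readline()
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise FormatError(
                    f"{path}: line {lineno}: expected {len(header)} fields, got {len(parts)}"
                )
            gene_ids.append(parts[0])
            row = []
            for col, cell in zip(sample_ids, parts[1:]):
                try:
                    row.append(float(cell))
                except ValueError:
                    raise FormatError(
                        f"{path}: line {lineno} (gene {parts[0]!r}), sample {col!r}: "
                        f"non-numeric value {cell!r}"
                    ) from None
            rows.append(row)

    phen = _read_phenotype(phenotype_path)
    missing = [s for s in sample_ids if s not in phen]
    if missing:
        raise FormatError(
            f"{phenotype_path}: no phenotype label for sample(s): {missing}"
        )
    phenotype = [phen[s] for s in sample_ids]
    return ExpressionMatrix(gene_ids, sample_ids, np.asarray(rows, dtype=float), phenotype)


def _read_phenotype(path: str) -> Dict[str, str]:
    out: Dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}: line {lineno}: expected 'sample<TAB>label'")
            sample, label = parts
            if label not in PHENOTYPE_LABELS:
                raise FormatError(
                    f"{path}: line {lineno}: unknown phenotype label {label!r} "
                    f"(expected one of {sorted(PHENOTYPE_LABELS)})"
                )
            if sample in out:
                raise FormatError(f"{path}: line {lineno}: duplicate sample {sample!r}")
            out[sample] = label
    return out


def write_expression(matrix: ExpressionMatrix, path: str, phenotype_path: str) -> None:
    with open(path, "w") as fh:
        fh.write("gene\t" + "\t".join(matrix.sample_ids) + "\n")
        for gene, row in zip(matrix.gene_ids, matrix.values):
            fh.write(gene + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
    with open(phenotype_path, "w") as fh:
        for sample, label in zip(matrix.sample_ids, matrix.phenotype):
            fh.write(f"{sample}\t{label}\n")


def collapse_duplicates(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """One row per gene symbol: duplicates averaged, unmapped rows dropped.

    Multiple probes mapping to the same symbol are collapsed to the
    per-sample arithmetic mean of their log2 intensities; rows whose symbol is
    empty (unmapped probes) are excluded.  First-occurrence order is kept.
    """
    order: List[str] = []
    groups: Dict[str, List[int]] = {}
    for i, g in enumerate(matrix.gene_ids):
        if g == "" or g is None:
            continue
        if g not in groups:
            groups[g] = []
            order.append(g)
        groups[g].append(i)
    values = np.array(
        [matrix.values[groups[g]].mean(axis=0) for g in order], dtype=float
    ).reshape(len(order), matrix.n_samples)
    return ExpressionMatrix(order, list(matrix.sample_ids), values, list(matrix.phenotype))


def filter_phenotype(matrix: ExpressionMatrix, label: str) -> ExpressionMatrix:
    """Restrict to the samples carrying `label` (inference runs on diseased only)."""
    idx = [i for i, ph in enumerate(matrix.phenotype) if ph == label]
    if not idx:
        raise ValueError(f"no samples with phenotype {label!r}")
    return ExpressionMatrix(
        list(matrix.gene_ids),
        [matrix.sample_ids[i] for i in idx],
        matrix.values[:, idx],
        [matrix.phenotype[i] for i in idx],
    )


def restrict_to_seed(matrix: ExpressionMatrix, seed: SeedList) -> Tuple[ExpressionMatrix, int]:
    """Keep only the seed genes measured in the matrix (matrix order preserved).

    Returns the restricted matrix and the number of seed genes the matrix does
    not measure.
    """
    seed_set = seed.as_set()
    idx = [i for i, g in enumerate(matrix.gene_ids) if g in seed_set]
    if not idx:
        raise ValueError("no seed gene is measured in the matrix")
    n_unmeasured = len(seed_set - set(matrix.gene_ids))
    restricted = ExpressionMatrix(
        [matrix.gene_ids[i] for i in idx],
        list(matrix.sample_ids),
        matrix.values[idx],
        list(matrix.phenotype),
    )
    return restricted, n_unmeasured


# ---------------------------------------------------------------------------
# seed / GMT / variants


def read_seed(path: str, tag: str = "initial") -> SeedList:
    genes: List[str] = []
    seen: Set[str] = set()
    with open(path) as fh:
        for line in fh:
            g = line.strip()
            if not g or g.startswith("#"):
                continue
            if g not in seen:
                seen.add(g)
                genes.append(g)
    return SeedList(genes, {g: tag for g in genes})


def write_seed(seed: SeedList, path: str) -> None:
    with open(path, "w") as fh:
        for g in seed.genes:
            fh.write(g + "\n")


def read_gmt(path: str) -> GeneSetCatalog:
    """GMT: tab-separated pathway id, description, then member gene symbols."""
    sets: Dict[str, Tuple[str, FrozenSet[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: GMT needs id, description and >=1 member"
                )
            pid, desc = parts[0], parts[1]
            members = frozenset(p for p in parts[2:] if p)
            if not members:
                raise FormatError(f"{path}: line {lineno}: pathway {pid!r} is empty")
            if pid in sets:
                raise FormatError(f"{path}: line {lineno}: duplicate pathway id {pid!r}")
            sets[pid] = (desc, members)
    return GeneSetCatalog(sets)


def write_gmt(catalog: GeneSetCatalog, path: str) -> None:
    with open(path, "w") as fh:
        for pid, (desc, members) in catalog.sets.items():
            fh.write("\t".join([pid, desc, *sorted(members)]) + "\n")


def read_variants(path: str) -> VariantAnnotationTable:
    frame = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "gene": str, "regulomedb": str})
    return VariantAnnotationTable(frame)


def write_variants(table: VariantAnnotationTable, path: str) -> None:
    table.frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# networks


def write_network(net: WeightedNetwork, path: str, dialect: str = "edgelist") -> None:
    """Write a network as weighted edge-list TSV (round-trippable) or SIF.

    The edge-list dialect lists edges in canonical order (lexicographic on the
    sorted endpoint pair) and appends isolated nodes in a trailing section so
    the node set round-trips exactly.
    """
    if dialect == "edgelist":
        connected = {u for e in net.edges for u in e}
        with open(path, "w") as fh:
            fh.write("gene_a\tgene_b\tweight\tprovenance\n")
            for (u, v), w in net.sorted_edges():
                tag = net.provenance.get((u, v), "")
                fh.write(f"{u}\t{v}\t{w!r}\t{tag}\n")
            for node in sorted(net.nodes - connected):
                fh.write(f"{node}\t.\t.\t.\n")
    elif dialect == "sif":
        with open(path, "w") as fh:
            for (u, v), _ in net.sorted_edges():
                fh.write(f"{u}\tco\t{v}\n")
    else:
        raise ValueError(f"unknown network dialect {dialect!r}")


def read_network(path: str) -> WeightedNetwork:
    """Read the weighted edge-list TSV dialect written by `write_network`."""
    net = WeightedNetwork()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["gene_a", "gene_b", "weight"]:
            raise FormatError(f"{path}: not a weighted edge-list file")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise FormatError(f"{path}: line {lineno}: expected 4 fields")
            u, v, w, tag = parts
            if v == "." and w == ".":
                net.nodes.add(u)
                continue
            try:
                weight = float(w)
            except ValueError:
                raise FormatError(
                    f"{path}: line {lineno}: non-numeric weight {w!r}"
                ) from None
            net.add_edge(u, v, weight, tag if tag else None)
    return net
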