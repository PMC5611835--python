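"""Synthetic data with the statistical structure the pipeline assumes.

The generator emulates the pipeline's four inputs at desk scale: block-
correlated log2 expression matrices with planted co-expression modules
(equicorrelated multivariate normal blocks built from a shared latent factor),
pathway catalogs whose "signal" sets align with those blocks (plus decoys),
and SNP annotation tables with a realistic RegulomeDB category mix.  The
planted blocks double as ground truth for precision/recall scoring of
inferred networks.

Block co-expression is planted in the diseased samples only; control samples
are independent noise, mimicking disease-specific co-regulation (the
inference stage only ever sees diseased samples anyway).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import numpy as np

from .io import CONTROL, DISEASED, ExpressionMatrix, GeneSetCatalog, VariantAnnotationTable
from .network import WeightedNetwork, edge_key

import pandas as pd

#: RegulomeDB category mix for simulated SNPs.  Real annotation snapshots are
#: heavily skewed toward the weak-evidence categories 4-7; the strong 1x/2x
#: categories are rare.
DEFAULT_CATEGORY_DIST: Dict[str, float] = {
    "1a": 0.005, "1b": 0.01, "1d": 0.01, "1f": 0.025,
    "2a": 0.02, "2b": 0.04, "2c": 0.02, "3a": 0.05,
    "4": 0.17, "5": 0.25, "6": 0.15, "7": 0.25,
}


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions for one simulated expression dataset.

    Defaults mirror the scaled-down regime used throughout the test suite:
    300 genes of which 4 blocks of 20 are equicorrelated at rho = 0.8, with
    80 diseased and 40 control samples on a log2-intensity-like scale.
    """

    n_genes: int = 300
    n_samples_diseased: int = 80
    n_samples_control: int = 40
    blocks: Tuple[Tuple[int, float], ...] = ((20, 0.8), (20, 0.8), (20, 0.8), (20, 0.8))
    noise_sd: float = 1.0
    baseline: float = 8.0
    n_decoy_pathways: int = 10
    pathway_size_range: Tuple[int, int] = (10, 40)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if sum(size for size, _ in self.blocks) > self.n_genes:
            raise ValueError("block sizes exceed n_genes")
        for size, rho in self.blocks:
            if size < 2:
                raise ValueError("blocks need at least 2 genes")
            if not (0.0 <= rho < 1.0):
                raise ValueError("within-block correlation must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    @property
    def gene_ids(self) -> List[str]:
        return [f"G{i:04d}" for i in range(self.n_genes)]

    @property
    def block_gene_ids(self) -> List[List[str]]:
        """Gene ids per block; blocks occupy the first genes in order."""
        genes = self.gene_ids
        out, start = [], 0
        for size, _ in self.blocks:
            out.append(genes[start : start + size])
            start += size
        return out

    @property
    def noise_gene_ids(self) -> List[str]:
        n_block = sum(size for size, _ in self.blocks)
        return self.gene_ids[n_block:]


def simulate_expression(spec: SimulationSpec, rng: Optional[np.random.Generator] = None) -> ExpressionMatrix:
    """Draw one expression matrix under the spec's study conditions.

    Block genes in diseased samples follow an equicorrelated normal built
    from a shared latent factor: x = sqrt(rho) * z_block + sqrt(1-rho) * eps,
    which hits the target within-block correlation exactly in expectation.
    Everything is scaled by noise_sd and shifted to a log2-plausible baseline.
    """
    if rng is None:
        rng = np.random.default_rng(spec.rng_seed)
    n_d, n_c = spec.n_samples_diseased, spec.n_samples_control
    values = rng.standard_normal((spec.n_genes, n_d + n_c))
    start = 0
    for size, rho in spec.blocks:
        z = rng.standard_normal(n_d)
        block = values[start : start + size, :n_d]
        values[start : start + size, :n_d] = np.sqrt(rho) * z + np.sqrt(1.0 - rho) * block
        start += size
    values = spec.baseline + spec.noise_sd * values
    sample_ids = [f"D{i:03d}" for i in range(n_d)] + [f"C{i:03d}" for i in range(n_c)]
    phenotype = [DISEASED] * n_d + [CONTROL] * n_c
    return ExpressionMatrix(spec.gene_ids, sample_ids, values, phenotype)


def simulate_catalog(
    spec: SimulationSpec,
    n_extra: int = 10,
    chain: bool = True,
    decoys_disjoint_from_blocks: bool = True,
    rng: Optional[np.random.Generator] = None,
) -> GeneSetCatalog:
    """A pathway catalog aligned with the spec's planted blocks.

    One "signal" pathway per block (ids S1, S2, ...) contains the block's
    genes plus `n_extra` extra genes — the future enriched candidates.  With
    ``chain=True`` the extras are the first genes of the *next* block
    (cyclically, so every signal pathway has the same size and the same
    relation to the planted structure); the chained nesting lets the
    seed-expansion loop walk one block per iteration.  With ``chain=False``
    extras are drawn from the noise genes.  Decoy pathways partition the
    shuffled noise pool (at least `n_decoy_pathways` of them, more if needed
    to respect the upper pathway size bound), so the catalog universe covers
    every simulated gene — mirroring a genome-wide pathway catalog, whose
    background is what the enrichment universe intersects with.  With
    ``decoys_disjoint_from_blocks`` False each decoy additionally absorbs a
    few random block genes.
    """
    if rng is None:
        rng = np.random.default_rng(spec.rng_seed + 1)
    blocks = spec.block_gene_ids
    noise = list(spec.noise_gene_ids)
    sets: Dict[str, Tuple[str, FrozenSet[str]]] = {}
    noise_cursor = 0
    for b, block in enumerate(blocks):
        if chain:
            extras = blocks[(b + 1) % len(blocks)][:n_extra]
        else:
            extras = noise[noise_cursor : noise_cursor + n_extra]
            noise_cursor += n_extra
        sets[f"S{b + 1}"] = (f"signal pathway for block {b + 1}", frozenset(block) | frozenset(extras))
    pool = [g for g in noise[noise_cursor:]]
    if pool:
        shuffled = list(rng.permutation(pool))
        _, hi = spec.pathway_size_range
        n_decoys = max(spec.n_decoy_pathways, -(-len(shuffled) // hi))
        chunks = np.array_split(np.asarray(shuffled), n_decoys)
        for d, chunk in enumerate(chunks):
            members = set(chunk.tolist())
            if not decoys_disjoint_from_blocks:
                block_pool = [g for blk in blocks for g in blk]
                members |= set(rng.choice(block_pool, size=2).tolist())
            if members:
                sets[f"D{d + 1}"] = (f"decoy pathway {d + 1}", frozenset(members))
    return GeneSetCatalog(sets)


def signal_pathway_ids(spec: SimulationSpec) -> List[str]:
    return [f"S{b + 1}" for b in range(len(spec.blocks))]


def simulate_variants(
    genes: Sequence[str],
    spec: SimulationSpec,
    mean_snps_per_gene: float = 2.0,
    category_dist: Optional[Dict[str, float]] = None,
    rng: Optional[np.random.Generator] = None,
) -> VariantAnnotationTable:
    """Poisson SNP counts per gene with categorical RegulomeDB labels and
    non-negative per-source component scores (regdb, dbsnp, vep, regfeat)."""
    if rng is None:
        rng = np.random.default_rng(spec.rng_seed + 2)
    dist = category_dist or DEFAULT_CATEGORY_DIST
    cats = list(dist)
    probs = np.asarray([dist[c] for c in cats], dtype=float)
    probs = probs / probs.sum()
    rows = []
    snp_counter = 0
    for gene in genes:
        for _ in range(int(rng.poisson(mean_snps_per_gene))):
            cat = cats[int(rng.choice(len(cats), p=probs))]
            scores = rng.exponential(1.0, size=4).round(4)
            rows.append((f"rs{snp_counter:07d}", gene, cat, *scores))
            snp_counter += 1
    frame = pd.DataFrame(
        rows, columns=["snp_id", "gene", "regulomedb", "regdb", "dbsnp", "vep", "regfeat"]
    )
    return VariantAnnotationTable(frame)


def planted_pairs(spec: SimulationSpec) -> Set[Tuple[str, str]]:
    """All within-block gene pairs — the ground-truth positive edges."""
    truth: Set[Tuple[str, str]] = set()
    for block in spec.block_gene_ids:
        for i in range(len(block)):
            for j in range(i + 1, len(block)):
                truth.add(edge_key(block[i], block[j]))
    return truth


def planted_edge_recovery(
    inferred: WeightedNetwork, spec: SimulationSpec
) -> Tuple[float, float]:
    """(precision, recall) of the inferred edge set against within-block pairs.

    An empty inferred network scores precision 0 by convention.  Note the
    one-strongest-partner selection rule bounds the number of inferred edges
    by the gene count, so recall against all within-block pairs is
    structurally limited; precision is the informative number.
    """
    truth = planted_pairs(spec)
    edges = inferred.edge_set()
    if not edges:
        return 0.0, 0.0
    tp = len(edges & truth)
    precision = tp / len(edges)
    recall = tp / len(truth) if truth else 0.0
    return precision, recall
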