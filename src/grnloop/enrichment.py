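"""The iterative pathway-enrichment seed-expansion loop.

One iteration, per dataset: restrict the expression matrix to the current
seed, keep diseased samples only, infer a BC3Net10 network, threshold it at
the edge-weight cutoff, and test the surviving subnetwork's genes for pathway
enrichment with a one-sided Fisher (hypergeometric tail) test.  Pathways
significant in *every* dataset contribute their member genes; members not yet
in the seed are the iteration's enriched candidates and are fed forward.  The
loop runs until an iteration adds no candidate (saturation), and the
per-iteration thresholded networks are finally merged per dataset into an
aggregated network.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import stats

from .inference import InferenceParams, bc3net10
from .io import ExpressionMatrix, GeneSetCatalog, SeedList, filter_phenotype, restrict_to_seed
from .io import DISEASED
from .network import WeightedNetwork


@dataclass
class EnrichmentResult:
    """One pathway's one-sided Fisher test against a gene-set query."""

    pathway_id: str
    overlap: int
    set_size: int
    query_size: int
    universe_size: int
    p_value: float
    significant: bool

    def __post_init__(self) -> None:
        if self.overlap > min(self.set_size, self.query_size):
            raise ValueError("overlap cannot exceed set or query size")
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError("p-value must be in (0, 1]")


@dataclass
class IterationRecord:
    """One pass of the loop: the Table-2-style row plus its networks."""

    index: int
    seed_size_in: int
    overlapping_pathways: Set[str]
    new_candidates: Set[str]
    per_dataset_networks: Dict[str, WeightedNetwork]
    per_dataset_enrichments: Dict[str, List[EnrichmentResult]] = field(default_factory=dict)
    seed_out: Optional[SeedList] = None


def threshold_subnetwork(net: WeightedNetwork, tau: float, mode: str = "gt") -> WeightedNetwork:
    """Edges with weight > tau (or >= tau with mode='ge'); nodes restricted to
    the surviving edge endpoints."""
    if not (0.0 <= tau < 1.0):
        raise ValueError("tau must be in [0, 1)")
    if mode not in ("gt", "ge"):
        raise ValueError("mode must be 'gt' or 'ge'")
    keep = {
        e: w
        for e, w in net.edges.items()
        if (w > tau if mode == "gt" else w >= tau)
    }
    sub = WeightedNetwork()
    for (u, v), w in keep.items():
        sub.add_edge(u, v, w, net.provenance.get((u, v)))
    return sub


def fisher_enrichment(
    query: Set[str],
    catalog: GeneSetCatalog,
    universe: Set[str],
    alpha: float = 0.05,
) -> List[EnrichmentResult]:
    """One-sided Fisher's exact test of every catalog pathway against `query`.

    p = P(X >= overlap) under Hypergeometric(N=|universe|, K=|set∩universe|,
    n=|query∩universe|); unadjusted, flagged significant when p < alpha.
    Catalog sets are intersected with the universe before testing.
    """
    if not universe:
        raise ValueError("empty universe")
    q = query & universe
    N = len(universe)
    n = len(q)
    results: List[EnrichmentResult] = []
    for pid, (_, members) in catalog.sets.items():
        K = len(members & universe)
        k = len(members & q)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        p = min(p, 1.0)
        results.append(
            EnrichmentResult(
                pathway_id=pid,
                overlap=k,
                set_size=K,
                query_size=n,
                universe_size=N,
                p_value=p,
                significant=p < alpha,
            )
        )
    return results


def overlapping_pathways(per_dataset: Mapping[str, Set[str]]) -> Set[str]:
    """Pathways significant in every dataset (intersection across datasets)."""
    if not per_dataset:
        raise ValueError("need at least one dataset")
    sets = list(per_dataset.values())
    return set.intersection(*map(set, sets))


def expand_seed(
    seed: SeedList, pathways: Set[str], catalog: GeneSetCatalog, tag: str = "expansion"
) -> Tuple[SeedList, Set[str]]:
    """Add to the seed every member of the given pathways not yet present."""
    members: Set[str] = set()
    for pid in pathways:
        members |= set(catalog.members(pid))
    new = members - seed.as_set()
    return seed.extended(sorted(new), tag), new


def _dataset_rng(master_seed: Optional[int], iteration: int, dataset_index: int) -> np.random.Generator:
    # stable stream per (iteration, dataset) regardless of execution order
    ss = np.random.SeedSequence(master_seed, spawn_key=(iteration, dataset_index))
    return np.random.default_rng(ss)


def run_iteration(
    datasets: Mapping[str, ExpressionMatrix],
    seed: SeedList,
    catalog: GeneSetCatalog,
    params: InferenceParams = InferenceParams(),
    tau: float = 0.5,
    alpha: float = 0.05,
    iteration: int = 1,
    tau_mode: str = "gt",
) -> IterationRecord:
    """One loop pass over all datasets; see the module docstring.

    The enrichment universe per dataset is the catalog universe intersected
    with the genes that dataset measures, and the query is the thresholded
    subnetwork's node set.
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    sig_per_dataset: Dict[str, Set[str]] = {}
    nets: Dict[str, WeightedNetwork] = {}
    enr: Dict[str, List[EnrichmentResult]] = {}
    for ds_index, (ds_id, matrix) in enumerate(sorted(datasets.items())):
        restricted, _ = restrict_to_seed(matrix, seed)
        diseased = filter_phenotype(restricted, DISEASED)
        rng = _dataset_rng(params.rng_seed, iteration, ds_index)
        net = bc3net10(diseased, params, rng)
        sub = threshold_subnetwork(net, tau, tau_mode)
        nets[ds_id] = sub
        universe = catalog.universe & set(matrix.gene_ids)
        results = fisher_enrichment(set(sub.nodes), catalog, universe, alpha)
        enr[ds_id] = results
        sig_per_dataset[ds_id] = {r.pathway_id for r in results if r.significant}

    common = overlapping_pathways(sig_per_dataset)
    new_seed, new_candidates = expand_seed(seed, common, catalog, tag=f"iteration-{iteration}")
    return IterationRecord(
        index=iteration,
        seed_size_in=len(seed),
        overlapping_pathways=common,
        new_candidates=new_candidates,
        per_dataset_networks=nets,
        per_dataset_enrichments=enr,
        seed_out=new_seed,
    )


def run_until_saturation(
    datasets: Mapping[str, ExpressionMatrix],
    initial_seed: SeedList,
    catalog: GeneSetCatalog,
    params: InferenceParams = InferenceParams(),
    tau: float = 0.5,
    alpha: float = 0.05,
    max_iterations: int = 25,
    tau_mode: str = "gt",
) -> List[IterationRecord]:
    """Iterate `run_iteration`, feeding the grown seed forward, until an
    iteration contributes zero new candidates (the terminal record included).

    Termination is guaranteed because the seed can only grow within the
    finite catalog universe, but a `max_iterations` guard is kept against
    misconfiguration.
    """
    records: List[IterationRecord] = []
    seed = initial_seed
    for it in range(1, max_iterations + 1):
        record = run_iteration(datasets, seed, catalog, params, tau, alpha, it, tau_mode)
        records.append(record)
        if not record.new_candidates:
            return records
        seed = record.seed_out
    raise RuntimeError(
        f"seed expansion did not saturate within {max_iterations} iterations"
    )


def aggregate_iterations(records: Sequence[IterationRecord], dataset_id: str) -> WeightedNetwork:
    """Merge one dataset's thresholded networks across iterations.

    Node and edge sets are unions; an edge's weight is its maximum over the
    iterations containing it, and its provenance lists those iterations (which
    supports the first-appearance stratification).
    """
    relevant = [r for r in records if dataset_id in r.per_dataset_networks]
    if not relevant:
        raise KeyError(f"no iteration contains dataset {dataset_id!r}")
    agg = WeightedNetwork()
    contributors: Dict[Tuple[str, str], List[int]] = {}
    for rec in relevant:
        net = rec.per_dataset_networks[dataset_id]
        agg.nodes |= net.nodes
        for e, w in net.edges.items():
            contributors.setdefault(e, []).append(rec.index)
            if w > agg.edges.get(e, 0.0):
                agg.edges[e] = w
                agg.nodes.update(e)
    for e, its in contributors.items():
        agg.provenance[e] = "iterations=" + ",".join(str(i) for i in its)
    return agg


def iteration_stratification(
    records: Sequence[IterationRecord], dataset_id: str
) -> Dict[int, Tuple[float, float]]:
    """Fraction of the aggregated network's nodes and edges first appearing in
    each iteration; both fraction families sum to 1."""
    relevant = [r for r in records if dataset_id in r.per_dataset_networks]
    if not relevant:
        raise KeyError(f"no iteration contains dataset {dataset_id!r}")
    first_node: Dict[str, int] = {}
    first_edge: Dict[Tuple[str, str], int] = {}
    for rec in relevant:
        net = rec.per_dataset_networks[dataset_id]
        for node in net.nodes:
            first_node.setdefault(node, rec.index)
        for e in net.edges:
            first_edge.setdefault(e, rec.index)
    n_nodes = len(first_node)
    n_edges = len(first_edge)
    out: Dict[int, Tuple[float, float]] = {}
    for rec in relevant:
        fn = sum(1 for it in first_node.values() if it == rec.index)
        fe = sum(1 for it in first_edge.values() if it == rec.index)
        out[rec.index] = (
            fn / n_nodes if n_nodes else 0.0,
            fe / n_edges if n_edges else 0.0,
        )
    return out
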