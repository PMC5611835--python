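"""C3Net edge selection, bagged ensembles (BC3Net) and the repeat-averaged
BC3Net10 ensemble.

The inference chain is:

* ``c3net`` — every gene nominates its single strongest mutual-information
  partner, provided the pair is significant against a permutation null after
  Bonferroni correction over all gene pairs; the network is the union of
  nominations (so it has at most one edge per gene).
* ``bc3net`` — C3Net applied to B bootstrap resamples of the samples.  An
  ensemble edge's raw score is its appearance frequency k/B across bootstrap
  networks; edges are kept when a one-sided binomial tail test against the
  mean bootstrap edge density passes Bonferroni correction over the candidate
  edges.
* ``bc3net10`` — BC3Net repeated R times (default 10) with independent RNG
  streams on the same data; the final weight of an edge is the mean of its
  per-run scores, counting absence as 0.  Repetition recovers reproducible but
  lower-frequency edges a single bagged run drops.

All randomness flows through an explicit ``numpy.random.Generator``; repeat
runs use ``Generator.spawn`` so results are reproducible and independent of
evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .io import ExpressionMatrix
from .mi import MIMatrix, default_bins, empirical_mi, equalwidth_discretize, mi_matrix
from .network import WeightedNetwork


@dataclass(frozen=True)
class InferenceParams:
    """Knobs of the ensemble inference.

    B: bootstrap resamples per bagged run; R: bagged runs averaged by
    bc3net10; alpha1/alpha2: significance levels of the per-pair MI test and
    the ensemble binomial test (both Bonferroni-corrected); n_perm: size of
    the pooled permutation null; estimator/bins: see the MI layer.
    """

    B: int = 100
    R: int = 10
    alpha1: float = 0.05
    alpha2: float = 0.05
    mtc: str = "bonferroni"
    n_perm: int = 10_000
    estimator: str = "pearson"
    bins: Optional[int] = None
    rng_seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.B < 1 or self.R < 1:
            raise ValueError("B and R must be >= 1")
        for a in (self.alpha1, self.alpha2):
            if not (0.0 < a <= 1.0):
                raise ValueError("alpha must be in (0, 1]")
        if self.mtc != "bonferroni":
            raise ValueError("only Bonferroni correction is supported")


def required_null_size(n_genes: int, alpha1: float) -> int:
    """Smallest null sample for which the add-one empirical p-value can still
    reject after Bonferroni correction over all gene pairs.

    The smallest achievable p is 1/(N+1); it must not exceed
    alpha1 / (p*(p-1)/2), so N >= n_pairs/alpha1 - 1 (rounded up).
    """
    n_pairs = n_genes * (n_genes - 1) // 2
    return max(0, int(np.ceil(n_pairs / alpha1)) - 1)


def _pearson_null_chunk(
    values: np.ndarray, ii: np.ndarray, jj: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    n, m = ii.size, values.shape[1]
    X = values[ii]
    Y = values[jj]
    # independent sample permutation of every row of X and Y
    X = np.take_along_axis(X, rng.random((n, m)).argsort(axis=1), axis=1)
    Y = np.take_along_axis(Y, rng.random((n, m)).argsort(axis=1), axis=1)
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    denom = np.sqrt((Xc * Xc).sum(axis=1)) * np.sqrt((Yc * Yc).sum(axis=1))
    r = np.zeros(n)
    ok = denom > 0
    r[ok] = (Xc * Yc).sum(axis=1)[ok] / denom[ok]
    r2 = np.clip(r * r, 0.0, 1.0 - 1e-12)
    return -0.5 * np.log1p(-r2)


def mi_null(
    matrix: ExpressionMatrix,
    n_perm: int,
    rng: np.random.Generator,
    estimator: str = "pearson",
    bins: Optional[int] = None,
) -> np.ndarray:
    """Pooled permutation null of pairwise MI, sorted ascending.

    Each draw picks a random gene pair, independently permutes each profile's
    sample order and records the pair's MI; under the permutation the profiles
    are independent, so the pooled sample approximates the no-association MI
    distribution for this dataset's margins.
    """
    if matrix.n_genes < 2:
        raise ValueError("need at least 2 genes")
    if n_perm < 1000:
        raise ValueError("n_perm must be >= 1000")
    p, m = matrix.n_genes, matrix.n_samples
    ii = rng.integers(0, p, size=n_perm)
    jj = rng.integers(0, p - 1, size=n_perm)
    jj = np.where(jj >= ii, jj + 1, jj)  # uniform pair with i != j

    if estimator == "pearson":
        chunks = []
        chunk_size = 100_000
        for start in range(0, n_perm, chunk_size):
            sl = slice(start, min(start + chunk_size, n_perm))
            chunks.append(_pearson_null_chunk(matrix.values, ii[sl], jj[sl], rng))
        null = np.concatenate(chunks)
    else:
        b = bins if bins is not None else default_bins(m)
        disc = np.array([equalwidth_discretize(row, b) for row in matrix.values])
        null = np.empty(n_perm)
        for k in range(n_perm):
            dx = disc[ii[k]][rng.permutation(m)]
            dy = disc[jj[k]][rng.permutation(m)]
            null[k] = empirical_mi(dx, dy)
    null.sort()
    return null


def edge_pvalue(mi: float, null: np.ndarray) -> float:
    """Add-one empirical tail probability p = (1 + #{null >= mi}) / (1 + N)."""
    null = np.asarray(null)
    if null.size == 0:
        raise ValueError("null sample is empty")
    n_ge = null.size - int(np.searchsorted(null, mi, side="left"))
    return (1 + n_ge) / (1 + null.size)


def c3net(mim: MIMatrix, null: np.ndarray, alpha1: float = 0.05) -> WeightedNetwork:
    """One-strongest-significant-partner selection on an MI matrix.

    Each gene i nominates j* = argmax_j MI(i, j) among the partners whose
    Bonferroni-corrected empirical p-value (factor = number of gene pairs) is
    <= alpha1; the network is the union of nominations with weight 1.0.  Every
    gene of the matrix stays a node even when isolated.  Argmax ties break
    toward the lexicographically smallest partner symbol.
    """
    p = mim.n_genes
    if p < 2:
        raise ValueError("need at least 2 genes")
    null = np.asarray(null)
    n_pairs = p * (p - 1) // 2
    # largest MI still insignificant: corrected p > alpha1
    n_ge = null.size - np.searchsorted(null, mim.values, side="left")
    pvals = (1 + n_ge) / (1 + null.size)
    sig = (pvals * n_pairs) <= alpha1
    np.fill_diagonal(sig, False)

    order = np.argsort(np.asarray(mim.gene_ids))  # lexicographic tie-break
    net = WeightedNetwork(nodes=mim.gene_ids)
    for i in range(p):
        row = np.where(sig[i], mim.values[i], -np.inf)
        best = row.max()
        if not np.isfinite(best):
            continue
        ties = np.flatnonzero(row == best)
        if ties.size == 1:
            j = int(ties[0])
        else:
            tie_set = set(ties.tolist())
            j = next(int(k) for k in order if int(k) in tie_set)
        net.add_edge(mim.gene_ids[i], mim.gene_ids[j], 1.0)
    return net


def ensemble_edge_pvalue(k: int, B: int, p0: float) -> float:
    """One-sided binomial tail P(X >= k | B, p0) for an ensemble edge count."""
    if k <= 0:
        return 1.0
    return float(stats.binom.sf(k - 1, B, p0))


def bc3net(
    matrix: ExpressionMatrix,
    params: InferenceParams = InferenceParams(),
    rng: Optional[np.random.Generator] = None,
) -> WeightedNetwork:
    """Bagged C3Net: B bootstrap networks aggregated by appearance frequency.

    A single pooled permutation null is drawn from the input matrix and shared
    by all B bootstrap C3Net calls.  Candidate edges (those appearing in at
    least one bootstrap network) are tested with a one-sided binomial tail
    against p0 = mean bootstrap edge density, Bonferroni-corrected over the
    candidate count; retained edges carry weight k/B.
    """
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)
    if matrix.n_samples < 3:
        raise ValueError("need at least 3 samples")
    m = matrix.n_samples
    # the null must be large enough that the add-one empirical p-value can
    # survive Bonferroni correction over all gene pairs at alpha1
    n_perm = max(params.n_perm, required_null_size(matrix.n_genes, params.alpha1))
    null = mi_null(matrix, n_perm, rng, params.estimator, params.bins)

    counts: dict = {}
    for _ in range(params.B):
        idx = rng.integers(0, m, size=m)
        boot = ExpressionMatrix(
            list(matrix.gene_ids),
            [f"b{t}" for t in range(m)],
            matrix.values[:, idx],
            [matrix.phenotype[i] for i in idx],
        )
        mim = mi_matrix(boot, params.estimator, params.bins)
        net_b = c3net(mim, null, params.alpha1)
        for e in net_b.edges:
            counts[e] = counts.get(e, 0) + 1

    net = WeightedNetwork(nodes=matrix.gene_ids)
    if not counts:
        return net
    p = matrix.n_genes
    n_pairs = p * (p - 1) // 2
    p0 = sum(counts.values()) / (params.B * n_pairs)
    n_candidates = len(counts)
    for (u, v), k in counts.items():
        tail = ensemble_edge_pvalue(k, params.B, p0)
        if tail * n_candidates <= params.alpha2:
            net.add_edge(u, v, k / params.B, provenance=f"k={k}/B={params.B}")
    return net


def bc3net10(
    matrix: ExpressionMatrix,
    params: InferenceParams = InferenceParams(),
    rng: Optional[np.random.Generator] = None,
) -> WeightedNetwork:
    """R independent bagged runs averaged edge-wise (absent runs count as 0).

    Edge provenance records in how many of the R runs the edge appeared.
    """
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)
    streams = rng.spawn(params.R)
    totals: dict = {}
    present: dict = {}
    nodes: set = set()
    for stream in streams:
        run = bc3net(matrix, params, stream)
        nodes |= run.nodes
        for e, w in run.edges.items():
            totals[e] = totals.get(e, 0.0) + w
            present[e] = present.get(e, 0) + 1
    net = WeightedNetwork(nodes=nodes)
    for (u, v), total in totals.items():
        net.add_edge(u, v, total / params.R, provenance=f"runs={present[(u, v)]}/{params.R}")
    return net


def network_overlap(
    nets: Sequence[WeightedNetwork], weight_cutoff: float = 0.0
) -> Tuple[float, float]:
    """Intersection-over-union agreement of edge sets and node sets.

    Edges below `weight_cutoff` (strictly: kept when weight >= cutoff) are
    dropped before comparing; node sets are the networks' declared node sets,
    which single-run inference keeps equal to the full gene universe.
    """
    if len(nets) < 2:
        raise ValueError("need at least 2 networks")
    edge_sets = [
        {e for e, w in net.edges.items() if w >= weight_cutoff} for net in nets
    ]
    node_sets = [net.nodes for net in nets]
    edge_union = set.union(*edge_sets)
    node_union = set.union(*node_sets)
    if not edge_union and not node_union:
        raise ValueError("all networks are empty")
    edge_overlap = (
        len(set.intersection(*edge_sets)) / len(edge_union) if edge_union else 1.0
    )
    node_overlap = (
        len(set.intersection(*node_sets)) / len(node_union) if node_union else 1.0
    )
    return edge_overlap, node_overlap
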