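"""Mutual-information estimation between gene expression profiles.

Two estimators are provided, matching the two modes the inference layer can
run in:

* ``pearson`` — the Gaussian closed form MI = -1/2 * ln(1 - r^2) applied to the
  Pearson correlation r of the raw profiles.  It is strictly increasing in |r|,
  which is all the one-strongest-partner selection rule downstream needs.
* ``empirical`` — maximum-likelihood plug-in MI on equal-width-discretized
  profiles, sum over cells of p(a,b) ln[p(a,b) / (p(a) p(b))].

All values are in nats.  Zero-variance profiles get MI 0 to every partner so
matrices stay finite; such genes can never win an argmax.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from .io import ExpressionMatrix

#: r^2 is clamped to at most 1 - R2_CLAMP so perfectly correlated profiles map
#: to a large finite value instead of +inf.
R2_CLAMP = 1e-12

ESTIMATORS = ("pearson", "empirical")


@dataclass
class MIMatrix:
    """Symmetric gene x gene mutual-information matrix (diagonal ignored)."""

    gene_ids: List[str]
    values: np.ndarray
    estimator_tag: str
    n_samples: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        p = len(self.gene_ids)
        if self.values.shape != (p, p):
            raise ValueError("MI matrix must be square over gene_ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("MI values must be finite")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


def pearson_mi(x: np.ndarray, y: np.ndarray) -> float:
    """Gaussian mutual information -1/2 ln(1 - r^2) of two profiles.

    Returns 0.0 when either profile has zero variance; r^2 is clamped below 1
    so the result is always finite.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("profiles must be 1-D and of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = math.sqrt(float(xc @ xc))
    sy = math.sqrt(float(yc @ yc))
    if sx == 0.0 or sy == 0.0:
        return 0.0
    r = float(xc @ yc) / (sx * sy)
    r2 = min(r * r, 1.0 - R2_CLAMP)
    return -0.5 * math.log1p(-r2)


def equalwidth_discretize(v: np.ndarray, bins: int) -> np.ndarray:
    """Assign each value to one of `bins` equal-width intervals over [min, max].

    Intervals are half-open [lo, hi) except the last, which is closed so the
    maximum lands in bin ``bins - 1``.  A constant vector maps to all zeros.
    """
    if bins < 1:
        raise ValueError("bins must be >= 1")
    v = np.asarray(v, dtype=float)
    lo, hi = float(v.min()), float(v.max())
    if lo == hi or bins == 1:
        return np.zeros(v.shape, dtype=np.int64)
    edges = np.linspace(lo, hi, bins + 1)
    # interior edges only: x < edges[1] -> 0, ..., x >= edges[-2] -> bins-1
    return np.digitize(v, edges[1:-1], right=False).astype(np.int64)


def empirical_mi(dx: np.ndarray, dy: np.ndarray) -> float:
    """Maximum-likelihood plug-in MI of two discrete vectors, in nats."""
    dx = np.asarray(dx)
    dy = np.asarray(dy)
    if dx.shape != dy.shape or dx.ndim != 1:
        raise ValueError("discretized vectors must be 1-D and of equal length")
    n = dx.size
    if n == 0:
        raise ValueError("empty vectors")
    _, xi = np.unique(dx, return_inverse=True)
    _, yi = np.unique(dy, return_inverse=True)
    kx = int(xi.max()) + 1
    ky = int(yi.max()) + 1
    joint = np.bincount(xi * ky + yi, minlength=kx * ky).reshape(kx, ky) / n
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    outer = np.outer(px, py)
    mi = float(np.sum(joint[nz] * np.log(joint[nz] / outer[nz])))
    return max(mi, 0.0)  # guard tiny negative round-off


def default_bins(n_samples: int) -> int:
    """Equal-width bin count heuristic: ceil(sqrt(m)) for m samples."""
    return int(math.ceil(math.sqrt(n_samples)))


def _pearson_mi_matrix(values: np.ndarray) -> np.ndarray:
    sd = values.std(axis=1)
    ok = sd > 0
    r = np.zeros((values.shape[0], values.shape[0]))
    if ok.sum() >= 2:
        sub = np.corrcoef(values[ok])
        sub = np.atleast_2d(sub)
        idx = np.flatnonzero(ok)
        r[np.ix_(idx, idx)] = sub
    r2 = np.clip(r * r, 0.0, 1.0 - R2_CLAMP)
    mim = -0.5 * np.log1p(-r2)
    np.fill_diagonal(mim, 0.0)
    return mim


def mi_matrix(
    matrix: ExpressionMatrix,
    estimator: str = "pearson",
    bins: Optional[int] = None,
) -> MIMatrix:
    """Full pairwise MI matrix of an expression matrix.

    ``estimator='pearson'`` applies the Gaussian closed form to the raw
    profiles (``bins`` accepted and ignored); ``'empirical'`` equal-width
    discretizes each gene (default bins = ceil(sqrt(m))) and applies the
    plug-in estimator.
    """
    if estimator not in ESTIMATORS:
        raise ValueError(f"unknown estimator {estimator!r}")
    if matrix.n_genes < 2:
        raise ValueError("need at least 2 genes")
    if matrix.n_samples < 3:
        raise ValueError("need at least 3 samples")
    if estimator == "pearson":
        vals = _pearson_mi_matrix(matrix.values)
    else:
        b = bins if bins is not None else default_bins(matrix.n_samples)
        disc = [equalwidth_discretize(row, b) for row in matrix.values]
        p = matrix.n_genes
        vals = np.zeros((p, p))
        for i in range(p):
            for j in range(i + 1, p):
                vals[i, j] = vals[j, i] = empirical_mi(disc[i], disc[j])
    return MIMatrix(list(matrix.gene_ids), vals, estimator, matrix.n_samples)
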