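"""Cumulative-score gene prioritization from SNP annotation evidence.

Genes are mapped to their annotated SNPs, scored by summing per-source
annotation scores over all of their SNPs (equal source weights by default),
and ranked primarily by their best (minimum) RegulomeDB category — the ordinal
1a (strongest regulatory evidence) to 7 (weakest) — with the cumulative score
breaking ties within a category.  A category cutoff restricts the final list;
curated genes from external studies can be appended regardless of the cutoff.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import total_ordering
from typing import Dict, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd

from .io import VariantAnnotationTable

_CATEGORY_RE = re.compile(r"^([1-7])([a-f])?$")


@total_ordering
@dataclass(frozen=True)
class RegulomeCategory:
    """Ordinal SNP regulatory-evidence category: major 1-7, optional minor a-f.

    Ordering is lexicographic on (major, minor): "1a" < "1b" < "2a" < "7".
    Majors 4-7 carry no minor letter.
    """

    major: int
    minor: Optional[str] = None

    def __post_init__(self) -> None:
        if not (1 <= self.major <= 7):
            raise ValueError(f"major category must be 1-7, got {self.major}")
        if self.minor is not None:
            if self.minor not in "abcdef":
                raise ValueError(f"minor category must be a-f, got {self.minor!r}")
            if self.major > 3:
                raise ValueError(f"major {self.major} carries no minor letter")

    def _key(self) -> Tuple[int, str]:
        return (self.major, self.minor or "")

    def __lt__(self, other: "RegulomeCategory") -> bool:
        return self._key() < other._key()

    def __str__(self) -> str:
        return f"{self.major}{self.minor or ''}"


def parse_category(text: str) -> RegulomeCategory:
    """Parse a printed RegulomeDB category like "1b", "2a" or "5"."""
    m = _CATEGORY_RE.match(text.strip())
    if not m:
        raise ValueError(f"invalid RegulomeDB category {text!r}")
    major = int(m.group(1))
    minor = m.group(2)
    if minor is not None and major > 3:
        raise ValueError(f"invalid RegulomeDB category {text!r}: major {major} takes no minor")
    return RegulomeCategory(major, minor)


def map_genes_to_snps(
    genes: Set[str], table: VariantAnnotationTable
) -> Dict[str, pd.DataFrame]:
    """Per-gene SNP annotation rows; genes without any SNP are dropped."""
    sub = table.frame[table.frame["gene"].isin(genes)]
    return {gene: rows.reset_index(drop=True) for gene, rows in sub.groupby("gene")}


def gene_score(
    rows: pd.DataFrame,
    source_columns: Sequence[str],
    weights: Optional[Mapping[str, float]] = None,
) -> Tuple[RegulomeCategory, float]:
    """Best (minimum) category and weighted cumulative score over a gene's SNPs.

    cumulative_score = sum over SNPs of sum over sources of
    weight(source) * score(source); all weights default to 1.
    """
    if len(rows) == 0:
        raise ValueError("gene has no SNP rows")
    best = min(parse_category(c) for c in rows["regulomedb"].astype(str))
    score = 0.0
    for col in source_columns:
        w = 1.0 if weights is None else float(weights.get(col, 1.0))
        score += w * float(rows[col].sum())
    return best, score


@dataclass
class RankedGeneTable:
    """Final prioritized list: rank, gene, best category, cumulative score."""

    frame: pd.DataFrame  # columns: rank, gene, category, score, n_snps, curated


def rank_genes(
    gene_scores: Mapping[str, Tuple[RegulomeCategory, float, int]],
    category_cutoff: RegulomeCategory | str = "3a",
    curated: Optional[Set[str]] = None,
) -> RankedGeneTable:
    """Apply the category cutoff, merge curated genes, sort and rank.

    `gene_scores` maps gene -> (best_category, cumulative_score, n_snps).
    Genes with best category <= cutoff are retained; curated genes are kept
    regardless of their category (flagged).  Sort order: category ascending,
    then score descending, then symbol; ranks are 1..n.
    """
    if isinstance(category_cutoff, str):
        category_cutoff = parse_category(category_cutoff)
    curated = curated or set()
    rows = []
    for gene, (cat, score, n_snps) in gene_scores.items():
        keep = cat <= category_cutoff
        if keep or gene in curated:
            rows.append((gene, cat, score, n_snps, gene in curated))
    rows.sort(key=lambda r: (r[1], -r[2], r[0]))
    frame = pd.DataFrame(
        [
            (i + 1, gene, str(cat), score, n_snps, flag)
            for i, (gene, cat, score, n_snps, flag) in enumerate(rows)
        ],
        columns=["rank", "gene", "category", "score", "n_snps", "curated"],
    )
    return RankedGeneTable(frame)


def prioritize(
    genes: Set[str],
    table: VariantAnnotationTable,
    category_cutoff: RegulomeCategory | str = "3a",
    curated: Optional[Set[str]] = None,
    weights: Optional[Mapping[str, float]] = None,
) -> RankedGeneTable:
    """Full prioritization: map genes to SNPs, score, cut off and rank."""
    mapped = map_genes_to_snps(genes, table)
    scores = {
        gene: (*gene_score(rows, table.source_columns, weights), len(rows))
        for gene, rows in mapped.items()
    }
    return rank_genes(scores, category_cutoff, curated)
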