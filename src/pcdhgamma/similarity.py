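"""Pairwise similarity of neurons' variable-isoform combinations.

Two neurons' combinatorial expression is compared on the 19 variable
isoforms only -- the near-ubiquitous C-type isoforms (C3, C4, C5) carry no
combinatorial information and are excluded by construction. The primary
statistic is the similarity level |A intersect B| / |A union B| (the Jaccard
index of the two binarized isoform sets). Quantitative profiles can instead
be compared by Euclidean distance in the 19-dimensional UMI space, plain or
after normalizing each cell's variable-isoform total to 1; the normalized
distance lies in [0, sqrt(2)].
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .matrix import BinaryExpressionMatrix

#: Default similarity-level bins: a dedicated exact-zero bin followed by
#: ten equal-width bins (0, 0.1], ..., (0.9, 1.0].
DEFAULT_BIN_LABELS: tuple[str, ...] = ("0",) + tuple(
    f"({i / 10:.1f},{(i + 1) / 10:.1f}]" for i in range(10))


@dataclass
class DistanceResult:
    value: float
    normalized: bool


@dataclass
class SimilarityDistribution:
    """Binned distribution of pairwise similarity levels."""

    bin_labels: tuple[str, ...]
    fractions: np.ndarray
    n_pairs: int
    n_excluded: int  # pairs where both cells express no variable isoform
    similarities: np.ndarray  # raw per-pair values, in enumeration order


def similarity_level(set_a, set_b, registry=None) -> float:
    """Jaccard similarity |A&B|/|A|B| of two variable-isoform sets.

    Both sets must contain variable isoforms only; C-type members are
    rejected, and the value is undefined (error) when both sets are empty.
    Returns a fraction in [0, 1]: 1 for identical non-empty sets
    ("complete overlap"), 0 for disjoint sets ("complete dissimilarity").
    """
    a, b = frozenset(set_a), frozenset(set_b)
    if registry is not None:
        bad = sorted(n for n in (a | b) if registry.is_ctype(n))
        if bad:
            raise ValueError(f"C-type isoforms are excluded from similarity: {bad}")
    if not a and not b:
        raise ValueError("similarity level is undefined when both sets are empty (0/0)")
    return len(a & b) / len(a | b)


def euclidean_distance(vec_a, vec_b, normalized: bool = False) -> DistanceResult:
    """Euclidean distance between two variable-isoform UMI vectors.

    With ``normalized=True`` each vector is first divided by its own sum
    (total variable-isoform expression scaled to 1), which bounds the
    distance by sqrt(2); an all-zero vector is then rejected.
    """
    a = np.asarray(vec_a, dtype=float)
    b = np.asarray(vec_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("vectors must be 1-D and of equal length")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("UMI vectors must be non-negative")
    if normalized:
        sa, sb = a.sum(), b.sum()
        if sa == 0 or sb == 0:
            raise ValueError("normalized distance requires a positive vector sum")
        a = a / sa
        b = b / sb
    return DistanceResult(value=float(np.sqrt(np.sum((a - b) ** 2))),
                          normalized=normalized)


def pairwise_similarity_distribution(
    binary: BinaryExpressionMatrix,
    cluster_labels=None,
    n_bins: int = 10,
) -> SimilarityDistribution:
    """Similarity levels over all unordered cell pairs, binned.

    Pairs are enumerated within each cluster when ``cluster_labels`` is
    given (one label per cell), otherwise over the whole population. Pairs
    in which *both* cells express no variable isoform are excluded (the
    Jaccard value is undefined there) and counted in ``n_excluded``.

    Binning uses a dedicated bin for exact zero followed by ``n_bins``
    equal-width bins covering (0, 1].
    """
    sets = binary.isoform_sets("variable")
    n = len(sets)
    if n < 2:
        raise ValueError("need at least 2 cells for pairwise similarity")
    if cluster_labels is not None and len(cluster_labels) != n:
        raise ValueError("cluster_labels must have one label per cell")

    sims: list[float] = []
    n_excluded = 0
    for i, j in combinations(range(n), 2):
        if cluster_labels is not None and cluster_labels[i] != cluster_labels[j]:
            continue
        if not sets[i] and not sets[j]:
            n_excluded += 1
            continue
        sims.append(similarity_level(sets[i], sets[j]))
    if not sims:
        raise ValueError("fewer than 1 eligible pair (all pairs have empty sets)")

    values = np.asarray(sims)
    counts = np.zeros(n_bins + 1, dtype=np.int64)
    counts[0] = int(np.sum(values == 0))
    nonzero = values[values > 0]
    # right-closed bins (0, 1/n_bins], ..., ((n_bins-1)/n_bins, 1]
    idx = np.ceil(nonzero * n_bins).astype(int)
    for k in idx:
        counts[k] += 1
    labels = ("0",) + tuple(
        f"({i / n_bins:g},{(i + 1) / n_bins:g}]" for i in range(n_bins))
    return SimilarityDistribution(
        bin_labels=labels,
        fractions=counts / len(values),
        n_pairs=len(values),
        n_excluded=n_excluded,
        similarities=values,
    )
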