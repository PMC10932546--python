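"""Co-occurrence test: do isoforms express independently across cells?

The statistic is the population variance of k, the number of isoform types
expressed per cell. Under independent expression at the observed
per-isoform frequencies p_i, k is a sum of independent Bernoulli(p_i)
indicators with variance

    sigma^2_expected = sum_i p_i (1 - p_i).

A shuffled null is built by independently permuting each isoform's
expression column across cells (preserving every p_i exactly while
destroying cross-isoform dependence); the Z statistic compares the observed
variance to sigma^2_expected in units of the SD of the shuffled-ensemble
variances. Observed variance significantly *above* expectation indicates
co-occurrence (positive coupling between isoforms).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .matrix import BinaryExpressionMatrix, FrequencyVector, Subset


@dataclass
class IsoformCountDistribution:
    """Distribution of the per-cell number of expressed isoform types."""

    k_values: np.ndarray       # 0 .. n_isoforms
    fractions: np.ndarray      # fraction of cells at each k
    observed_variance: float   # population variance (divide by N) of k
    mean_k: float
    n_cells: int


@dataclass
class NullEnsemble:
    """Variances of per-cell k over independently column-shuffled matrices."""

    n_shuffles: int
    variances: np.ndarray
    mean_fractions: np.ndarray  # average shuffled k-distribution, same grid
    k_values: np.ndarray
    seed: int | None


@dataclass
class CooccurrenceResult:
    observed_variance: float
    expected_variance: float
    shuffled_mean_variance: float
    z: float
    p: float              # two-sided
    p_one_sided: float    # upper tail: evidence for co-occurrence
    co_occurring: bool
    alpha: float

    @property
    def variance_excess_over_expected(self) -> float:
        return self.observed_variance - self.expected_variance

    @property
    def variance_excess_over_shuffled(self) -> float:
        return self.observed_variance - self.shuffled_mean_variance


def _k_distribution(mask: np.ndarray, n_isoforms: int):
    k = mask.sum(axis=1)
    counts = np.bincount(k, minlength=n_isoforms + 1)
    return k, counts / len(k)


def isoform_count_distribution(
    binary: BinaryExpressionMatrix, subset: Subset = "all"
) -> IsoformCountDistribution:
    """Per-cell expressed-isoform-type counts and their population variance."""
    if binary.n_cells == 0:
        raise ValueError("cannot compute a count distribution over zero cells")
    mask = binary.subset_matrix(subset)
    k, fractions = _k_distribution(mask, mask.shape[1])
    return IsoformCountDistribution(
        k_values=np.arange(mask.shape[1] + 1),
        fractions=fractions,
        observed_variance=float(np.var(k)),  # population variance, ddof=0
        mean_k=float(k.mean()),
        n_cells=binary.n_cells,
    )


def expected_variance(freqs: FrequencyVector) -> float:
    """Independence-model variance of k: sum_i p_i (1 - p_i)."""
    p = freqs.p
    return float(np.sum(p * (1.0 - p)))


def shuffle_null(
    binary: BinaryExpressionMatrix,
    n_shuffles: int = 100,
    seed: int | None = None,
    subset: Subset = "all",
) -> NullEnsemble:
    """Null ensemble from independent per-column permutations.

    Each shuffle permutes every isoform column independently across cells,
    which keeps each isoform's expression frequency exactly fixed while
    removing any dependence between isoforms. The per-shuffle population
    variance of k and the average shuffled k-distribution are recorded.
    """
    if n_shuffles < 2:
        raise ValueError("n_shuffles must be at least 2")
    if binary.n_cells < 2:
        raise ValueError("shuffling a single-cell matrix is vacuous")
    mask = binary.subset_matrix(subset)
    rng = np.random.default_rng(seed)
    n_iso = mask.shape[1]
    variances = np.empty(n_shuffles)
    frac_sum = np.zeros(n_iso + 1)
    for s in range(n_shuffles):
        shuffled = rng.permuted(mask, axis=0)  # independent within-column perms
        k, frac = _k_distribution(shuffled, n_iso)
        variances[s] = np.var(k)
        frac_sum += frac
    return NullEnsemble(
        n_shuffles=n_shuffles,
        variances=variances,
        mean_fractions=frac_sum / n_shuffles,
        k_values=np.arange(n_iso + 1),
        seed=seed,
    )


def cooccurrence_z_test(
    observed: IsoformCountDistribution,
    expected: float,
    ensemble: NullEnsemble,
    alpha: float = 0.05,
) -> CooccurrenceResult:
    """Z-test of observed vs expected variance of per-cell isoform counts.

    z = (observed variance - expected variance) / SD(shuffled variances).
    Both the two-sided normal p-value and the upper-tail p-value are
    reported. Excess variance is the signature of positive coupling, so the
    co-occurrence call is directional: it requires observed > expected and
    tests at level ``alpha`` in the upper tail (keeping the call's type-I
    error at the nominal level).
    """
    sd = float(np.std(ensemble.variances, ddof=1))
    if sd == 0:
        raise ValueError(
            "degenerate null ensemble: shuffled variances have zero SD, "
            "z statistic undefined")
    z = (observed.observed_variance - expected) / sd
    p = float(2.0 * stats.norm.sf(abs(z)))
    p_one = float(stats.norm.sf(z))
    return CooccurrenceResult(
        observed_variance=observed.observed_variance,
        expected_variance=expected,
        shuffled_mean_variance=float(ensemble.variances.mean()),
        z=float(z),
        p=p,
        p_one_sided=p_one,
        co_occurring=bool(observed.observed_variance > expected and p_one < alpha),
        alpha=alpha,
    )


def run_cooccurrence(
    binary: BinaryExpressionMatrix,
    subset: Subset = "all",
    n_shuffles: int = 100,
    seed: int | None = None,
    alpha: float = 0.05,
) -> tuple[CooccurrenceResult, IsoformCountDistribution, NullEnsemble]:
    """Full pipeline: distribution, analytic expectation, shuffled null, Z-test."""
    from .matrix import expression_frequencies

    observed = isoform_count_distribution(binary, subset=subset)
    expected = expected_variance(expression_frequencies(binary, subset=subset))
    ensemble = shuffle_null(binary, n_shuffles=n_shuffles, seed=seed, subset=subset)
    result = cooccurrence_z_test(observed, expected, ensemble, alpha=alpha)
    return result, observed, ensemble
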