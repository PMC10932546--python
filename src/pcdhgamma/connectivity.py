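"""Group-level connectivity probabilities and their statistical comparison.

A connectivity experiment yields, per tested neuron pair, two directed
outcomes (a->b and b->a), a group label (genotype, overexpression design,
similarity level, ...), and covariates (inter-soma distance, vertical vs
horizontal alignment, age). Connection probability is connected/tested,
counted either per unordered pair (connected if either direction responds;
default) or per ordered pair. Groups are compared by Pearson chi-square on
2x2 [connected, unconnected] x group tables with Benjamini-Hochberg FDR
control across an explicitly declared family; uncertainty on single
probabilities comes from bootstrap resampling of pair outcomes (default
100 resamples); the similarity-vs-connectivity relationship is summarized
by a least-squares line with a bootstrap confidence band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class PairRecord:
    """Outcome of one tested neuron pair."""

    pair_id: str
    group: str
    connected_ab: bool
    connected_ba: bool | None = None  # None = direction untested
    soma_distance_um: float = math.nan
    axis: str = "unspecified"  # "vertical" | "horizontal" | "unspecified"
    age_days: int | None = None

    def __post_init__(self) -> None:
        if not math.isnan(self.soma_distance_um) and self.soma_distance_um < 0:
            raise ValueError("soma distance must be non-negative")
        if self.axis not in ("vertical", "horizontal", "unspecified"):
            raise ValueError(f"unknown axis label: {self.axis!r}")

    @property
    def pair_connected(self) -> bool:
        """Unordered-pair outcome: connected if either direction is."""
        return bool(self.connected_ab or self.connected_ba)


@dataclass
class PairTable:
    records: list[PairRecord]

    def __post_init__(self) -> None:
        ids = [r.pair_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("pair_ids must be unique")

    def __len__(self) -> int:
        return len(self.records)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "pair_id": r.pair_id, "group": r.group,
            "connected_ab": r.connected_ab, "connected_ba": r.connected_ba,
            "soma_distance_um": r.soma_distance_um, "axis": r.axis,
            "age_days": r.age_days} for r in self.records])

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_dataframe().to_csv(path, sep="\t", index=False)
        return path

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "PairTable":
        records = []
        for _, row in df.iterrows():
            ba = row.get("connected_ba")
            records.append(PairRecord(
                pair_id=str(row["pair_id"]), group=str(row["group"]),
                connected_ab=bool(row["connected_ab"]),
                connected_ba=None if pd.isna(ba) else bool(ba),
                soma_distance_um=float(row.get("soma_distance_um", math.nan)),
                axis=str(row.get("axis", "unspecified")),
                age_days=None if pd.isna(row.get("age_days")) else int(row["age_days"]),
            ))
        return cls(records=records)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PairTable":
        return cls.from_dataframe(pd.read_csv(path, sep="\t"))


@dataclass
class ProbabilityEstimate:
    connected: int
    tested: int
    bootstrap_mean: float | None = None
    bootstrap_sd: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.connected <= self.tested:
            raise ValueError("need 0 <= connected <= tested")

    @property
    def probability(self) -> float:
        return self.connected / self.tested

    @property
    def percent(self) -> float:
        return 100.0 * self.probability


@dataclass
class GroupComparison:
    group_a: str
    group_b: str
    chi2: float
    p_raw: float
    p_adjusted: float
    significant: bool


def _filter_records(table: PairTable, group: str | None,
                    max_distance: float | None = None,
                    min_distance: float | None = None,
                    axis: str | None = None,
                    age_range: tuple[int, int] | None = None) -> list[PairRecord]:
    recs = table.records
    if group is not None:
        recs = [r for r in recs if r.group == group]
    if max_distance is not None:
        recs = [r for r in recs if r.soma_distance_um <= max_distance]
    if min_distance is not None:
        recs = [r for r in recs if r.soma_distance_um >= min_distance]
    if axis is not None:
        recs = [r for r in recs if r.axis == axis]
    if age_range is not None:
        recs = [r for r in recs if r.age_days is not None
                and age_range[0] <= r.age_days <= age_range[1]]
    return recs


def _count(recs: list[PairRecord], mode: str) -> tuple[int, int]:
    if mode == "pair":
        return sum(r.pair_connected for r in recs), len(recs)
    if mode == "directed":
        connected = tested = 0
        for r in recs:
            tested += 1
            connected += int(r.connected_ab)
            if r.connected_ba is not None:
                tested += 1
                connected += int(r.connected_ba)
        return connected, tested
    raise ValueError(f"mode must be 'pair' or 'directed', got {mode!r}")


def connection_probability(
    table: PairTable,
    group: str | None = None,
    mode: str = "pair",
    max_distance: float | None = None,
    min_distance: float | None = None,
    axis: str | None = None,
    age_range: tuple[int, int] | None = None,
) -> ProbabilityEstimate:
    """Connected/tested fraction for a group, optionally stratified.

    ``mode='pair'`` counts unordered pairs (connected if either direction
    responds); ``mode='directed'`` counts ordered pairs.
    """
    recs = _filter_records(table, group, max_distance, min_distance, axis, age_range)
    if not recs:
        raise ValueError(
            f"no records in stratum (group={group!r}, max_distance={max_distance}, "
            f"min_distance={min_distance}, axis={axis!r}, age_range={age_range})")
    connected, tested = _count(recs, mode)
    return ProbabilityEstimate(connected=connected, tested=tested)


def chi_square_2x2(a: ProbabilityEstimate, b: ProbabilityEstimate,
                   yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square on the [connected, unconnected] x group table."""
    tbl = np.array([[a.connected, a.tested - a.connected],
                    [b.connected, b.tested - b.connected]])
    if np.any(tbl.sum(axis=0) == 0) or np.any(tbl.sum(axis=1) == 0):
        raise ValueError("chi-square undefined: a table margin is zero")
    chi2, p, _, _ = stats.chi2_contingency(tbl, correction=yates)
    return float(chi2), float(p)


def compare_groups(
    estimates: dict[str, ProbabilityEstimate],
    comparisons: list[tuple[str, str]] | None = None,
    alpha: float = 0.05,
    yates: bool = False,
) -> list[GroupComparison]:
    """Chi-square tests with BH-FDR adjustment over a declared family.

    ``comparisons`` names the (group_a, group_b) pairs forming the FDR
    family -- typically the comparisons of one figure panel. When omitted,
    all unordered pairs of groups are compared.
    """
    names = list(estimates)
    if comparisons is None:
        comparisons = [(names[i], names[j])
                       for i in range(len(names)) for j in range(i + 1, len(names))]
    if not comparisons:
        raise ValueError("no comparisons declared")
    raw = []
    chis = []
    for a, b in comparisons:
        chi2, p = chi_square_2x2(estimates[a], estimates[b], yates=yates)
        chis.append(chi2)
        raw.append(p)
    reject, p_adj, _, _ = multipletests(raw, alpha=alpha, method="fdr_bh")
    return [GroupComparison(group_a=a, group_b=b, chi2=c, p_raw=p,
                            p_adjusted=float(q), significant=bool(r))
            for (a, b), c, p, q, r in zip(comparisons, chis, raw, p_adj, reject)]


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH-adjusted p-values (monotone, never below the raw values)."""
    _, p_adj, _, _ = multipletests(list(p_values), method="fdr_bh")
    return p_adj


def bootstrap_probability(
    table: PairTable,
    group: str | None = None,
    mode: str = "pair",
    nboot: int = 100,
    seed: int | None = None,
    **strata,
) -> ProbabilityEstimate:
    """Connection probability with bootstrap mean and SD over pair outcomes."""
    if nboot < 2:
        raise ValueError("nboot must be at least 2")
    recs = _filter_records(table, group, **strata)
    if len(recs) < 2:
        raise ValueError("need at least 2 records in the group to bootstrap")
    connected, tested = _count(recs, mode)
    rng = np.random.default_rng(seed)
    n = len(recs)
    probs = np.empty(nboot)
    for b in range(nboot):
        resampled = [recs[i] for i in rng.integers(0, n, n)]
        c, t = _count(resampled, mode)
        probs[b] = c / t
    return ProbabilityEstimate(connected=connected, tested=tested,
                               bootstrap_mean=float(probs.mean()),
                               bootstrap_sd=float(probs.std(ddof=1)))


@dataclass
class SimilarityConnectivityFit:
    slope: float
    intercept: float
    similarity: np.ndarray
    probability: np.ndarray
    ci_lower: np.ndarray  # 95% band at the fitted similarity levels
    ci_upper: np.ndarray
    correlation_sign: int  # sign of the fitted slope
    boot_slopes: np.ndarray


def similarity_connectivity_fit(
    points: list[tuple[float, ProbabilityEstimate]],
    nboot: int = 100,
    seed: int | None = None,
) -> SimilarityConnectivityFit:
    """Least-squares line of connection probability on similarity level.

    Each point is (similarity level, probability estimate). The 95%
    confidence band comes from refitting after binomially resampling each
    point's pair outcomes (a parametric bootstrap of connected counts at
    fixed tested counts), evaluated at the input similarity levels.
    """
    if len({s for s, _ in points}) < 3:
        raise ValueError("need at least 3 distinct similarity levels to fit")
    s = np.array([p[0] for p in points], dtype=float)
    prob = np.array([p[1].probability for p in points])
    tested = np.array([p[1].tested for p in points])
    slope, intercept = np.polyfit(s, prob, 1)

    rng = np.random.default_rng(seed)
    boot_lines = np.empty((nboot, len(s)))
    boot_slopes = np.empty(nboot)
    for b in range(nboot):
        resampled = rng.binomial(tested, prob) / tested
        m, c = np.polyfit(s, resampled, 1)
        boot_slopes[b] = m
        boot_lines[b] = m * s + c
    lo, hi = np.percentile(boot_lines, [2.5, 97.5], axis=0)
    return SimilarityConnectivityFit(
        slope=float(slope), intercept=float(intercept),
        similarity=s, probability=prob,
        ci_lower=lo, ci_upper=hi,
        correlation_sign=int(np.sign(slope)),
        boot_slopes=boot_slopes,
    )
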