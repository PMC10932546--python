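"""Cell x isoform UMI count matrices: construction, filtering, binarization.

The quantitative object is a matrix of deduplicated UMI counts per
(cell barcode, isoform). Downstream combinatorial analyses consume a
binarized version: a cell is kept when its total Pcdhg UMI count exceeds a
quality cutoff (default: more than 10 UMIs summed over all 22 isoforms) and
an isoform is called "expressed" in a cell when its own count exceeds a
per-isoform cutoff (default: more than 1 UMI).
"""

from __future__ import annotations

from collections.abc import Collection, Iterable
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .registry import DEFAULT_REGISTRY, IsoformRegistry

Subset = str  # "variable" | "ctype" | "all"


def _subset_indices(registry: IsoformRegistry, subset: Subset) -> np.ndarray:
    nv, nc = registry.n_variable, registry.n_ctype
    if subset == "variable":
        return np.arange(nv)
    if subset == "ctype":
        return np.arange(nv, nv + nc)
    if subset == "all":
        return np.arange(nv + nc)
    raise ValueError(f"subset must be 'variable', 'ctype' or 'all', got {subset!r}")


def _subset_names(registry: IsoformRegistry, subset: Subset) -> tuple[str, ...]:
    return tuple(registry.all_names[i] for i in _subset_indices(registry, subset))


@dataclass(frozen=True)
class ReadRecord:
    """A single aligned read: cell barcode, UMI sequence, isoform identity."""

    barcode: str
    umi: str
    isoform: str

    def __post_init__(self) -> None:
        if not (self.barcode and self.umi and self.isoform):
            raise ValueError("ReadRecord fields must be non-empty")


@dataclass
class IsoformCountMatrix:
    """Cells x isoforms matrix of deduplicated UMI counts."""

    cell_ids: list[str]
    registry: IsoformRegistry
    counts: np.ndarray  # int, shape (n_cells, n_isoforms)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-dimensional")
        if self.counts.shape != (len(self.cell_ids), self.registry.n_isoforms):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.cell_ids)} cells x {self.registry.n_isoforms} isoforms")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("cell_ids must be unique")
        self.counts = self.counts.astype(np.int64, copy=False)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def total_umi(self) -> np.ndarray:
        """Per-cell UMI total over all isoforms (variable + C-type)."""
        return self.counts.sum(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=pd.Index(self.cell_ids, name="barcode"),
                            columns=list(self.registry.all_names))


@dataclass(frozen=True)
class FilterParams:
    per_isoform_min_umi: int = 1
    total_min_umi: int = 10


@dataclass
class BinaryExpressionMatrix:
    """Filtered, binarized expression: the combinatorial isoform barcode."""

    cell_ids: list[str]
    registry: IsoformRegistry
    expressed: np.ndarray  # bool, shape (n_cells, n_isoforms)
    filter_params: FilterParams = field(default_factory=FilterParams)

    def __post_init__(self) -> None:
        self.expressed = np.asarray(self.expressed, dtype=bool)
        if self.expressed.shape != (len(self.cell_ids), self.registry.n_isoforms):
            raise ValueError("expressed matrix shape does not match cells x isoforms")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("cell_ids must be unique")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def subset_matrix(self, subset: Subset = "all") -> np.ndarray:
        return self.expressed[:, _subset_indices(self.registry, subset)]

    def isoform_sets(self, subset: Subset = "variable") -> list[frozenset[str]]:
        """Per-cell set of expressed isoform identifiers in ``subset``."""
        names = np.array(_subset_names(self.registry, subset))
        sub = self.subset_matrix(subset)
        return [frozenset(names[row]) for row in sub]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.expressed,
                            index=pd.Index(self.cell_ids, name="barcode"),
                            columns=list(self.registry.all_names))


@dataclass
class FrequencyVector:
    """Per-isoform expression probability p_i over a cell population."""

    names: tuple[str, ...]
    p: np.ndarray
    n_cells: int

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != (len(self.names),):
            raise ValueError("p must have one entry per isoform name")
        if np.any((self.p < 0) | (self.p > 1)):
            raise ValueError("expression probabilities must lie in [0, 1]")


def build_count_matrix(
    records: Collection[ReadRecord],
    registry: IsoformRegistry = DEFAULT_REGISTRY,
    whitelist: Iterable[str] | None = None,
) -> IsoformCountMatrix:
    """Tabulate deduplicated UMI counts from (barcode, umi, isoform) records.

    Each matrix entry is the number of *distinct* UMI sequences observed for
    that (barcode, isoform); PCR duplicates of the same UMI collapse to one.

    Parameters
    ----------
    records
        Read records; every isoform must belong to ``registry``.
    registry
        Isoform registry fixing column identity and order.
    whitelist
        Optional barcode whitelist (e.g. the intersection of the gene
        expression and enrichment libraries); records with other barcodes
        are dropped. Default: keep all barcodes.

    Raises
    ------
    ValueError
        If ``records`` is empty (or empty after whitelist filtering), or an
        isoform identifier is not in the registry.
    """
    if not records:
        raise ValueError("record set is empty")
    wl = set(whitelist) if whitelist is not None else None

    seen: dict[tuple[str, str], set[str]] = {}
    cell_index: dict[str, int] = {}
    for rec in records:
        if rec.isoform not in registry:
            raise ValueError(f"unknown isoform identifier: {rec.isoform!r}")
        if wl is not None and rec.barcode not in wl:
            continue
        cell_index.setdefault(rec.barcode, len(cell_index))
        seen.setdefault((rec.barcode, rec.isoform), set()).add(rec.umi)

    if not cell_index:
        raise ValueError("no records remain after whitelist filtering")

    order = list(cell_index)
    counts = np.zeros((len(order), registry.n_isoforms), dtype=np.int64)
    for (barcode, isoform), umis in seen.items():
        counts[cell_index[barcode], registry.index(isoform)] = len(umis)
    return IsoformCountMatrix(cell_ids=order, registry=registry, counts=counts)


def filter_binarize(
    matrix: IsoformCountMatrix,
    per_isoform_min_umi: int = 1,
    total_min_umi: int = 10,
) -> BinaryExpressionMatrix:
    """Drop low-depth cells and binarize expression.

    A cell is retained iff its total UMI count over all isoforms (variable
    plus C-type) is strictly greater than ``total_min_umi``; an isoform is
    "expressed" iff its count is strictly greater than
    ``per_isoform_min_umi``. Both thresholds are strict so the defaults
    implement "more than 10 UMIs in total" and "more than 1 UMI per isoform".
    An empty result (zero retained cells) is valid.
    """
    keep = matrix.total_umi() > total_min_umi
    expressed = matrix.counts[keep] > per_isoform_min_umi
    cell_ids = [c for c, k in zip(matrix.cell_ids, keep) if k]
    return BinaryExpressionMatrix(
        cell_ids=cell_ids,
        registry=matrix.registry,
        expressed=expressed,
        filter_params=FilterParams(per_isoform_min_umi, total_min_umi),
    )


def expression_frequencies(
    binary: BinaryExpressionMatrix, subset: Subset = "all"
) -> FrequencyVector:
    """Fraction of cells expressing each isoform of ``subset``."""
    if binary.n_cells == 0:
        raise ValueError("cannot compute frequencies over zero cells")
    sub = binary.subset_matrix(subset)
    return FrequencyVector(
        names=_subset_names(binary.registry, subset),
        p=sub.mean(axis=0),
        n_cells=binary.n_cells,
    )
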