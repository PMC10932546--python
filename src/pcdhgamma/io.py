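"""Readers and writers for count matrices and read records.

Two on-disk matrix layouts are supported, both with bit-exact integer
round-trip: Matrix Market (``.mtx``) with sidecar ``barcodes.tsv`` /
``isoforms.tsv`` name files (cells are rows), and a dense tab-delimited
table with a header row of isoform names and a leading barcode column.
Raw read records are 3-column delimited text (barcode, umi, isoform),
optionally gzip-compressed.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .matrix import IsoformCountMatrix, ReadRecord
from .registry import DEFAULT_REGISTRY, IsoformRegistry


def write_mtx(matrix: IsoformCountMatrix, out_dir: str | Path) -> Path:
    """Write ``matrix.mtx`` + ``barcodes.tsv`` + ``isoforms.tsv`` into a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(out / "matrix.mtx", scipy.sparse.coo_matrix(matrix.counts))
    (out / "barcodes.tsv").write_text("".join(f"{b}\n" for b in matrix.cell_ids))
    (out / "isoforms.tsv").write_text(
        "".join(f"{n}\t{'ctype' if matrix.registry.is_ctype(n) else 'variable'}\n"
                for n in matrix.registry.all_names))
    return out / "matrix.mtx"


def read_mtx(in_dir: str | Path) -> IsoformCountMatrix:
    """Read a matrix written by :func:`write_mtx`."""
    src = Path(in_dir)
    counts = np.asarray(scipy.io.mmread(src / "matrix.mtx").todense()).astype(np.int64)
    barcodes = (src / "barcodes.tsv").read_text().splitlines()
    iso = pd.read_csv(src / "isoforms.tsv", sep="\t", header=None,
                      names=["name", "kind"])
    registry = IsoformRegistry(
        variable_names=tuple(iso.loc[iso["kind"] == "variable", "name"]),
        ctype_names=tuple(iso.loc[iso["kind"] == "ctype", "name"]),
    )
    return IsoformCountMatrix(cell_ids=barcodes, registry=registry, counts=counts)


def write_tsv(matrix: IsoformCountMatrix, path: str | Path) -> Path:
    path = Path(path)
    matrix.to_dataframe().to_csv(path, sep="\t")
    return path


def read_tsv(path: str | Path,
             registry: IsoformRegistry | None = None) -> IsoformCountMatrix:
    """Read a dense barcode x isoform table.

    If ``registry`` is omitted, columns matching the default registry are
    used in registry order; otherwise all columns must match ``registry``.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if registry is None:
        registry = DEFAULT_REGISTRY
    missing = [n for n in registry.all_names if n not in df.columns]
    if missing:
        raise ValueError(f"table is missing isoform columns: {missing}")
    counts = df[list(registry.all_names)].to_numpy(dtype=np.int64)
    return IsoformCountMatrix(cell_ids=[str(i) for i in df.index],
                              registry=registry, counts=counts)


def read_records(path: str | Path) -> list[ReadRecord]:
    """Read (barcode, umi, isoform) records from delimited text.

    Tab- or comma-delimited; a header line is detected and skipped when its
    first field is 'barcode'. Files ending in ``.gz`` are gunzipped.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    records: list[ReadRecord] = []
    with opener(path, "rt") as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t") if "\t" in line else line.split(",")
            if len(fields) != 3:
                raise ValueError(f"{path}:{i + 1}: expected 3 fields, got {len(fields)}")
            if i == 0 and fields[0].lower() == "barcode":
                continue
            records.append(ReadRecord(*fields))
    if not records:
        raise ValueError(f"{path}: no records")
    return records
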