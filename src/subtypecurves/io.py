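"""Plain-text readers/writers for the pipeline's tabular formats.

Count and expression matrices travel as tab-delimited tables with a
``gene_id`` first column and sample ids in the header; annotations as
tab-delimited tables indexed by ``sample_id``; gene panels as one id per
line.  Sparse MatrixMarket output (``.mtx`` plus gene/sample index files)
is available for large count matrices.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .errors import StructuralError

FLOAT_FORMAT = "%.10g"  # fixed formatting keeps reruns byte-identical


def write_matrix(matrix: pd.DataFrame, path: str) -> None:
    matrix.rename_axis("gene_id").to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_matrix(path: str, dtype=None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any() or df.columns.duplicated().any():
        raise StructuralError(f"duplicate gene or sample identifiers in {path}")
    if dtype is not None:
        df = df.astype(dtype)
    return df


def read_counts(path: str) -> pd.DataFrame:
    counts = read_matrix(path, dtype=np.int64)
    if (counts.to_numpy() < 0).any():
        raise StructuralError(f"negative counts in {path}")
    return counts


def write_annotation(annotation: pd.DataFrame, path: str) -> None:
    annotation.rename_axis("sample_id").to_csv(path, sep="\t")


def read_annotation(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_panel(path: str) -> list[str]:
    with open(path) as fh:
        genes = [line.strip() for line in fh if line.strip()]
    if not genes:
        raise StructuralError(f"empty gene panel: {path}")
    return genes


def write_panel(genes: list[str], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(genes) + "\n")


def write_counts_mtx(counts: pd.DataFrame, prefix: str) -> None:
    """Sparse MatrixMarket export: ``<prefix>.mtx`` + gene/sample index files."""
    from scipy.io import mmwrite
    from scipy.sparse import csr_matrix

    mmwrite(f"{prefix}.mtx", csr_matrix(counts.to_numpy()))
    write_panel(list(counts.index), f"{prefix}.genes.txt")
    write_panel(list(counts.columns), f"{prefix}.samples.txt")


def read_counts_mtx(prefix: str) -> pd.DataFrame:
    from scipy.io import mmread

    matrix = np.asarray(mmread(f"{prefix}.mtx").todense(), dtype=np.int64)
    genes = read_panel(f"{prefix}.genes.txt")
    samples = read_panel(f"{prefix}.samples.txt")
    if matrix.shape != (len(genes), len(samples)):
        raise StructuralError(f"{prefix}.mtx dimensions do not match index files")
    return pd.DataFrame(matrix, index=pd.Index(genes, name="gene_id"),
                        columns=samples)
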