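"""Plain-text readers and writers for the pipeline's tables.

Counts travel as Matrix Market (MTX) with gene and cell TSV sidecars; cell
tables as TSV with the canonical column set; codebooks as JSON (see
:mod:`merfishpipe.codebook`); gene sets as one-gene-per-line text files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as sio
from scipy import sparse

from .celltable import CellTable

__all__ = [
    "write_counts_mtx",
    "read_counts_mtx",
    "write_cell_table",
    "read_cell_table",
    "write_gene_set",
    "read_gene_set",
]

CELL_COLUMNS = [
    "x_um",
    "y_um",
    "volume_um3",
    "age",
    "condition",
    "section",
    "true_type",
    "true_domain",
]


def write_counts_mtx(counts: pd.DataFrame, prefix: str | Path) -> None:
    """Write cells x genes counts as ``<prefix>.mtx`` + gene/cell TSVs."""
    prefix = Path(prefix)
    sio.mmwrite(str(prefix.with_suffix(".mtx")), sparse.csr_matrix(counts.to_numpy()))
    prefix.with_name(prefix.name + "_genes.tsv").write_text(
        "\n".join(map(str, counts.columns)) + "\n"
    )
    prefix.with_name(prefix.name + "_cells.tsv").write_text(
        "\n".join(map(str, counts.index)) + "\n"
    )


def read_counts_mtx(prefix: str | Path) -> pd.DataFrame:
    prefix = Path(prefix)
    mat = sio.mmread(str(prefix.with_suffix(".mtx"))).toarray()
    genes = prefix.with_name(prefix.name + "_genes.tsv").read_text().splitlines()
    cells = prefix.with_name(prefix.name + "_cells.tsv").read_text().splitlines()
    return pd.DataFrame(
        np.asarray(mat), index=pd.Index(cells, name="cell_id"), columns=genes
    )


def write_cell_table(table: CellTable, prefix: str | Path) -> None:
    """Write obs as ``<prefix>_cells.tsv`` and counts as MTX sidecars."""
    prefix = Path(prefix)
    obs = table.obs.copy()
    obs.index.name = "cell_id"
    obs.to_csv(prefix.with_name(prefix.name + "_obs.tsv"), sep="\t")
    write_counts_mtx(table.counts, prefix)


def read_cell_table(prefix: str | Path) -> CellTable:
    prefix = Path(prefix)
    obs = pd.read_csv(
        prefix.with_name(prefix.name + "_obs.tsv"), sep="\t", index_col="cell_id"
    )
    counts = read_counts_mtx(prefix)
    counts.index = obs.index  # cell ids round-trip through the obs TSV
    return CellTable(counts=counts, obs=obs)


def write_gene_set(genes, path: str | Path) -> None:
    Path(path).write_text("\n".join(genes) + "\n")


def read_gene_set(path: str | Path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]
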