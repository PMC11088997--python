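"""Readers and writers for the pipeline's on-disk formats.

FASTQ (Phred+33) via Biopython, with the cell barcode and UMI either
encoded in the read description (``CB:<cell> UMI:<umi>``) or supplied as
a separate read↔cell TSV; clone tables and composition tables as TSV;
expression as MatrixMarket MTX with genes.tsv / cells.tsv sidecars.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy import io as spio
from scipy import sparse

from .barcode import ReadRecord

CLONE_TABLE_COLUMNS = ["cell_id", "clone_id", "cell_class", "arm", "batch"]


def write_fastq(reads: list[ReadRecord], path) -> None:
    """Write reads as FASTQ with cell/UMI in the description line."""
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.read_id, description=f"CB:{r.cell_id} UMI:{r.umi}")
        rec.letter_annotations["phred_quality"] = list(r.qualities)
        records.append(rec)
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fastq")


def read_fastq(path, read_map: pd.DataFrame | None = None) -> list[ReadRecord]:
    """Read FASTQ back into ReadRecords.

    Cell and UMI come from ``read_map`` (columns read_id, cell_id, umi)
    when given, otherwise from ``CB:``/``UMI:`` tags in the description.
    """
    mapping = None
    if read_map is not None:
        mapping = read_map.set_index("read_id")[["cell_id", "umi"]]
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        if mapping is not None:
            cell, umi = mapping.loc[rec.id]
        else:
            tags = dict(t.split(":", 1) for t in rec.description.split()[1:] if ":" in t)
            cell, umi = tags.get("CB", "NA"), tags.get("UMI", "NA")
        out.append(
            ReadRecord(
                read_id=rec.id,
                sequence=str(rec.seq),
                qualities=rec.letter_annotations["phred_quality"],
                cell_id=cell,
                umi=umi,
            )
        )
    return out


def write_clone_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_clone_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(CLONE_TABLE_COLUMNS[:2]) - set(table.columns)
    if missing:
        raise ValueError(f"clone table missing columns: {sorted(missing)}")
    return table


def write_expression_mtx(adata, out_dir) -> None:
    """AnnData → matrix.mtx + genes.tsv + cells.tsv (cells × genes)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    X = adata.X if sparse.issparse(adata.X) else sparse.csr_matrix(np.asarray(adata.X))
    spio.mmwrite(str(out / "matrix.mtx"), X)
    pd.Series(adata.var_names).to_csv(out / "genes.tsv", sep="\t", index=False, header=False)
    adata.obs.reset_index(names="cell_id").to_csv(out / "cells.tsv", sep="\t", index=False)


def read_expression_mtx(in_dir):
    """matrix.mtx + genes.tsv + cells.tsv → AnnData (cells × genes)."""
    import anndata as ad

    p = Path(in_dir)
    X = sparse.csr_matrix(spio.mmread(str(p / "matrix.mtx")))
    genes = pd.read_csv(p / "genes.tsv", sep="\t", header=None)[0].tolist()
    cells = pd.read_csv(p / "cells.tsv", sep="\t")
    obs = cells.set_index("cell_id")
    obs.index.name = None
    return ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=genes))


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_matrix_tsv(matrix: np.ndarray, labels: list, path) -> None:
    pd.DataFrame(matrix, index=labels, columns=labels).to_csv(path, sep="\t")
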