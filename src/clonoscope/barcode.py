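"""From raw barcode reads to a clone table.

The pipeline is: anchored extraction of the fixed-length lineage barcode
from each read, Phred-quality filtering (mean Q >= 30 by default), UMI
collapsing to remove PCR-jackpot duplicates, single-linkage Hamming
clustering of the distinct barcode sequences (cluster distance 3 by
default), and finally grouping cells into clones as connected components
of the bipartite cell <-> barcode-cluster graph within each batch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .layout import ReadStructure

#: reason codes attached to rejected reads
REASON_TOO_SHORT = "too_short"
REASON_NO_ANCHOR5 = "no_anchor5"
REASON_NO_ANCHOR3 = "no_anchor3"


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read with its cell barcode and UMI."""

    read_id: str
    sequence: str
    qualities: list  # integer Phred per base
    cell_id: str
    umi: str

    def __post_init__(self) -> None:
        if len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"{self.read_id}: {len(self.qualities)} qualities for "
                f"{len(self.sequence)} bases"
            )


@dataclass(frozen=True)
class ExtractedBarcode:
    """A fixed-length lineage barcode pulled out of one read."""

    cell_id: str
    umi: str
    barcode: str
    barcode_qualities: tuple
    read_id: str


def _mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def extract_lineage_barcode(
    read: ReadRecord,
    structure: ReadStructure = ReadStructure(),
    anchor_mismatch_tol: int = 0,
):
    """Extract the barcode between the 5' and 3' anchors, or return None.

    The 5' anchor is searched at offsets 0..max_anchor_offset; at the first
    offset where it matches within ``anchor_mismatch_tol`` substitutions,
    the following ``barcode_length`` bases are taken as the barcode and the
    3' anchor is verified (also within tolerance) immediately after it.

    Returns ``(ExtractedBarcode, None)`` on success or ``(None, reason)``
    with a reason code on rejection.
    """
    seq = read.sequence
    a5, a3 = structure.anchor5, structure.anchor3
    if len(seq) < structure.min_read_length:
        return None, REASON_TOO_SHORT
    for off in range(min(structure.max_anchor_offset, len(seq) - structure.min_read_length) + 1):
        if _mismatches(seq[off : off + len(a5)], a5) <= anchor_mismatch_tol:
            bc_start = off + len(a5)
            bc_end = bc_start + structure.barcode_length
            if len(seq) < bc_end + len(a3):
                return None, REASON_TOO_SHORT
            if _mismatches(seq[bc_end : bc_end + len(a3)], a3) > anchor_mismatch_tol:
                return None, REASON_NO_ANCHOR3
            return (
                ExtractedBarcode(
                    cell_id=read.cell_id,
                    umi=read.umi,
                    barcode=seq[bc_start:bc_end],
                    barcode_qualities=tuple(read.qualities[bc_start:bc_end]),
                    read_id=read.read_id,
                ),
                None,
            )
    return None, REASON_NO_ANCHOR5


def filter_by_quality(
    records: list[ExtractedBarcode], min_q: int = 30, mode: str = "mean"
) -> list[ExtractedBarcode]:
    """Keep barcodes whose quality statistic is at least ``min_q``.

    ``mode="mean"`` (default) uses the mean Phred over the barcode bases;
    ``mode="min"`` requires every base to reach ``min_q``.  Order is
    preserved.
    """
    if min_q < 0:
        raise ValueError("min_q must be >= 0")
    if mode == "mean":
        stat = lambda q: float(np.mean(q))
    elif mode == "min":
        stat = lambda q: float(np.min(q))
    else:
        raise ValueError(f"mode must be 'mean' or 'min', got {mode!r}")
    return [r for r in records if stat(r.barcode_qualities) >= min_q]


def collapse_umis(records: list[ExtractedBarcode]) -> pd.DataFrame:
    """Count distinct UMIs per (cell, barcode); PCR duplicates collapse.

    Returns a tidy table (cell_id, barcode, umi_count) sorted by cell then
    barcode.
    """
    if not records:
        return pd.DataFrame(columns=["cell_id", "barcode", "umi_count"])
    df = pd.DataFrame(
        {
            "cell_id": [r.cell_id for r in records],
            "barcode": [r.barcode for r in records],
            "umi": [r.umi for r in records],
        }
    )
    out = (
        df.groupby(["cell_id", "barcode"], sort=True)["umi"]
        .nunique()
        .rename("umi_count")
        .reset_index()
    )
    return out


def hamming_matrix(barcodes: list[str]) -> np.ndarray:
    """All-pairs Hamming distances between equal-length strings."""
    if not barcodes:
        return np.zeros((0, 0), dtype=int)
    lengths = {len(b) for b in barcodes}
    if len(lengths) != 1:
        raise ValueError(f"barcodes must share one length, got lengths {sorted(lengths)}")
    arr = np.frombuffer("".join(barcodes).encode(), dtype=np.uint8).reshape(len(barcodes), -1)
    return (arr[:, None, :] != arr[None, :, :]).sum(axis=2)


def cluster_barcodes(barcodes: list[str], d: int = 3) -> dict:
    """Single-linkage Hamming clustering of barcode sequences.

    Clusters are the connected components of the graph joining every pair
    at Hamming distance <= ``d``.  The cluster id is the lexicographically
    smallest member sequence, so the mapping is deterministic and invariant
    to input order.  Duplicate inputs are allowed and map with their
    cluster.
    """
    if d < 0:
        raise ValueError("cluster distance must be >= 0")
    uniq = sorted(set(barcodes))
    if not uniq:
        return {}
    dist = hamming_matrix(uniq)
    adj = coo_matrix(dist <= d)
    n_comp, labels = connected_components(adj, directed=False)
    rep = {}
    for comp in range(n_comp):
        members = [uniq[i] for i in np.nonzero(labels == comp)[0]]
        rep[comp] = min(members)
    return {bc: rep[labels[i]] for i, bc in enumerate(uniq)}


@dataclass
class CloneCallReport:
    """Bookkeeping emitted by :func:`build_clone_table`."""

    n_cells_in: int = 0
    n_cells_assigned: int = 0
    cells_dropped: list = field(default_factory=list)  # no surviving barcode
    n_pairs_below_min_umi: int = 0

    def to_dict(self) -> dict:
        return {
            "n_cells_in": self.n_cells_in,
            "n_cells_assigned": self.n_cells_assigned,
            "n_cells_dropped": len(self.cells_dropped),
            "cells_dropped": list(self.cells_dropped),
            "n_pairs_below_min_umi": self.n_pairs_below_min_umi,
        }


def build_clone_table(
    cell_barcode_counts: pd.DataFrame,
    clusters: dict,
    cell_metadata: pd.DataFrame,
    min_umi: int = 1,
) -> tuple[pd.DataFrame, CloneCallReport]:
    """Group cells into clones via shared barcode clusters.

    Within each batch, cells and barcode clusters form a bipartite graph
    (an edge whenever a cell carries a cluster with umi_count >= min_umi);
    its connected components are the clones, so a cell carrying two
    clusters merges them into one clone.  Clone ids are scoped per batch
    (``batch:c<k>``): the same library barcode seen in two batches is two
    clones, guarding against barcode collisions between embryos.

    ``cell_metadata`` must be indexed by (or contain) cell_id with columns
    cell_class, arm, batch; a cell present in the counts but absent from
    the metadata is an error.  Cells with no surviving barcode are dropped
    and listed in the report.
    """
    meta = cell_metadata.set_index("cell_id") if "cell_id" in cell_metadata.columns else cell_metadata
    report = CloneCallReport(n_cells_in=cell_barcode_counts["cell_id"].nunique())

    counts = cell_barcode_counts.copy()
    report.n_pairs_below_min_umi = int((counts["umi_count"] < min_umi).sum())
    counts = counts[counts["umi_count"] >= min_umi]
    counts["cluster"] = counts["barcode"].map(clusters)
    if counts["cluster"].isna().any():
        missing = sorted(counts.loc[counts["cluster"].isna(), "barcode"].unique())
        raise ValueError(f"barcodes missing from the cluster map: {missing[:5]}")

    unknown = sorted(set(counts["cell_id"]) - set(meta.index))
    if unknown:
        raise ValueError(f"cells present in counts but missing from metadata: {unknown[:10]}")

    surviving = set(counts["cell_id"])
    report.cells_dropped = sorted(set(cell_barcode_counts["cell_id"]) - surviving)

    counts = counts.join(meta[["batch"]], on="cell_id")
    rows = []
    for batch, sub in counts.groupby("batch", sort=True):
        cells = sorted(sub["cell_id"].unique())
        clus = sorted(sub["cluster"].unique())
        cell_ix = {c: i for i, c in enumerate(cells)}
        clu_ix = {c: i + len(cells) for i, c in enumerate(clus)}
        n = len(cells) + len(clus)
        i = [cell_ix[c] for c in sub["cell_id"]]
        j = [clu_ix[c] for c in sub["cluster"]]
        graph = coo_matrix((np.ones(len(i)), (i, j)), shape=(n, n))
        _, labels = connected_components(graph, directed=False)
        # deterministic clone numbering: by smallest member cell id
        comp_cells: dict[int, list[str]] = {}
        for c in cells:
            comp_cells.setdefault(labels[cell_ix[c]], []).append(c)
        for k, comp in enumerate(sorted(comp_cells.values(), key=lambda cs: cs[0])):
            clone_id = f"{batch}:c{k:05d}"
            for c in comp:
                rows.append((c, clone_id))

    table = pd.DataFrame(rows, columns=["cell_id", "clone_id"])
    table = table.join(meta, on="cell_id")
    keep = [c for c in ["cell_id", "clone_id", "cell_class", "arm", "batch"] if c in table.columns]
    table = table[keep].sort_values("cell_id", ignore_index=True)
    report.n_cells_assigned = len(table)
    return table, report


def process_reads(
    reads: list[ReadRecord],
    structure: ReadStructure = ReadStructure(),
    anchor_mismatch_tol: int = 1,
    min_q: int = 30,
    quality_mode: str = "mean",
    cluster_distance: int = 3,
    min_umi: int = 1,
    cell_metadata: pd.DataFrame | None = None,
):
    """Run the full read→clone pipeline; returns (clone_table, qc dict).

    When ``cell_metadata`` is None a minimal metadata frame (batch
    "batch1", unknown class/arm) is synthesized from the cell ids so the
    clone structure can still be called.
    """
    extracted = []
    reasons: dict[str, int] = {}
    for read in reads:
        rec, reason = extract_lineage_barcode(read, structure, anchor_mismatch_tol)
        if rec is None:
            reasons[reason] = reasons.get(reason, 0) + 1
        else:
            extracted.append(rec)
    kept = filter_by_quality(extracted, min_q=min_q, mode=quality_mode)
    counts = collapse_umis(kept)
    clusters = cluster_barcodes(counts["barcode"].tolist(), d=cluster_distance)
    if cell_metadata is None:
        cells = sorted({r.cell_id for r in reads})
        cell_metadata = pd.DataFrame(
            {"cell_id": cells, "cell_class": "NA", "arm": "NA", "batch": "batch1"}
        )
    table, report = build_clone_table(counts, clusters, cell_metadata, min_umi=min_umi)
    qc = {
        "reads_in": len(reads),
        "anchor_failures": reasons,
        "extracted": len(extracted),
        "quality_dropped": len(extracted) - len(kept),
        "distinct_barcodes": int(counts["barcode"].nunique()) if len(counts) else 0,
        "n_clusters": len(set(clusters.values())),
        **report.to_dict(),
    }
    return table, qc
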