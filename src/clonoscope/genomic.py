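"""ChIP-peak annotation against TSSs and enhancer catalogs.

All coordinates are BED-style: 0-based, half-open [start, end).  Peaks
may carry a summit offset (narrowPeak column 10); distances are measured
from the summit when present, otherwise from the interval midpoint.
Operations: signed nearest-TSS distance (negative upstream, respecting
gene strand), promoter assignment within a fixed window around each TSS,
any-overlap classification of two binding-site sets into shared and
exclusive sites, Pearson Chi-square enrichment on the resulting 3x2
table, and peak→target-gene assignment through either a promoter or a
linked enhancer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import chi2_contingency


@dataclass(frozen=True)
class GenomicInterval:
    """One interval in 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    name: str = "."
    strand: str = "."
    summit: int | None = None  # offset from start, as in narrowPeak column 10

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"{self.name}: need 0 <= start < end, got [{self.start}, {self.end})")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"strand must be +, - or ., got {self.strand!r}")
        if self.summit is not None and not 0 <= self.summit < self.end - self.start:
            raise ValueError(f"{self.name}: summit offset {self.summit} outside [0, {self.end - self.start})")

    @property
    def anchor(self) -> int:
        """Summit position when known, else the interval midpoint."""
        if self.summit is not None:
            return self.start + self.summit
        return (self.start + self.end) // 2


_BED_COLS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path, narrow_peak: bool = False) -> pd.DataFrame:
    """Read BED3/BED6 (or narrowPeak with its summit column) into a frame.

    Returns columns chrom, start, end, name, strand, summit (summit is the
    narrowPeak offset-from-start, NaN when absent or -1).
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    ncol = df.shape[1]
    names = _BED_COLS[: min(ncol, 6)] + [f"col{i}" for i in range(7, ncol + 1)]
    df.columns = names
    if "name" not in df:
        df["name"] = [f"iv{i}" for i in range(len(df))]
    if "strand" not in df:
        df["strand"] = "."
    if narrow_peak and ncol >= 10:
        summit = df["col10"].astype(float)
        df["summit"] = summit.where(summit >= 0, np.nan)
    elif "summit" not in df:
        df["summit"] = np.nan
    out = df[["chrom", "start", "end", "name", "strand", "summit"]].copy()
    _validate_frame(out)
    return out


def _validate_frame(df: pd.DataFrame) -> None:
    if (df["start"] < 0).any() or (df["end"] <= df["start"]).any():
        bad = df[(df["start"] < 0) | (df["end"] <= df["start"])]["name"].tolist()
        raise ValueError(f"invalid intervals (need 0 <= start < end): {bad[:5]}")


def as_frame(intervals) -> pd.DataFrame:
    """Normalize a list of GenomicInterval or a DataFrame to a frame."""
    if isinstance(intervals, pd.DataFrame):
        df = intervals.copy()
        if "name" not in df:
            df["name"] = [f"iv{i}" for i in range(len(df))]
        if "strand" not in df:
            df["strand"] = "."
        if "summit" not in df:
            df["summit"] = np.nan
        _validate_frame(df)
        return df
    rows = [
        (iv.chrom, iv.start, iv.end, iv.name, iv.strand, np.nan if iv.summit is None else iv.summit)
        for iv in intervals
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "strand", "summit"])


def _anchors(df: pd.DataFrame) -> np.ndarray:
    mid = (df["start"].to_numpy() + df["end"].to_numpy()) // 2
    summit = df["summit"].to_numpy(dtype=float)
    has = ~np.isnan(summit)
    out = mid.astype(np.int64)
    out[has] = df["start"].to_numpy()[has] + summit[has].astype(np.int64)
    return out


def nearest_tss(peaks, tss) -> pd.DataFrame:
    """Signed distance from each peak to its nearest TSS.

    The peak anchor (summit or midpoint) is compared with every TSS
    position on the same chromosome; the nearest wins, ties broken toward
    the lexicographically smallest TSS id.  The sign follows the gene:
    negative means the peak lies upstream of the TSS on the gene's strand.
    Peaks on chromosomes without any TSS get NaN distance and
    ``no_tss=True``.
    """
    peaks = as_frame(peaks)
    tss = as_frame(tss)
    if peaks.empty or tss.empty:
        raise ValueError("peaks and tss must both be non-empty")
    tss = tss.assign(pos=_anchors(tss))

    results = []
    by_chrom = {c: g.sort_values(["pos", "name"]).reset_index(drop=True) for c, g in tss.groupby("chrom")}
    anchors = _anchors(peaks)
    for (_, peak), anchor in zip(peaks.iterrows(), anchors):
        g = by_chrom.get(peak["chrom"])
        if g is None:
            results.append((peak["name"], None, np.nan, True))
            continue
        pos = g["pos"].to_numpy()
        i = np.searchsorted(pos, anchor)
        cand = [j for j in (i - 1, i) if 0 <= j < len(pos)]
        dmin = min(abs(pos[j] - anchor) for j in cand)
        lo = np.searchsorted(pos, anchor - dmin, side="left")
        hi = np.searchsorted(pos, anchor + dmin, side="right")
        ties = g.iloc[lo:hi]
        ties = ties[(ties["pos"] - anchor).abs() == dmin]
        best = ties.sort_values("name").iloc[0]
        signed = int(anchor - best["pos"])
        if best["strand"] == "-":
            signed = -signed
        results.append((peak["name"], best["name"], signed, False))
    return pd.DataFrame(results, columns=["peak", "tss", "distance", "no_tss"])


def _window_tree(tss: pd.DataFrame, half_width: int) -> dict:
    trees: dict[str, IntervalTree] = {}
    pos = _anchors(tss)
    for (_, row), p in zip(tss.iterrows(), pos):
        lo = max(0, p - half_width)
        hi = p + half_width
        if hi > lo:
            trees.setdefault(row["chrom"], IntervalTree()).addi(lo, hi, row["name"])
    return trees


def promoter_assignment(peaks, tss, half_width: int = 5000) -> pd.DataFrame:
    """Assign peaks to genes whose promoter window they overlap.

    The promoter of a gene is the half-open window
    [TSS - half_width, TSS + half_width); a peak is assigned to *every*
    gene whose window it overlaps by >= 1 bp (whole-interval overlap, not
    summit containment).  Returns one row per peak with the sorted list of
    assigned genes (empty list when none).
    """
    if half_width <= 0:
        raise ValueError("half_width must be positive")
    peaks = as_frame(peaks)
    tss = as_frame(tss)
    trees = _window_tree(tss, half_width)
    rows = []
    for _, peak in peaks.iterrows():
        tree = trees.get(peak["chrom"])
        hits = sorted({iv.data for iv in tree.overlap(peak["start"], peak["end"])}) if tree else []
        rows.append((peak["name"], hits))
    return pd.DataFrame(rows, columns=["peak", "genes"])


def classify_overlap(sites_a, sites_b) -> dict:
    """Label two binding-site sets as shared or exclusive by any-overlap.

    A site is *shared* when it overlaps (>= 1 bp) any site of the other
    set.  Counting is a-site-centric: ``n_shared`` is the number of
    a-sites labeled shared, so fractions like "shared / total a-sites"
    are well defined even for one-to-many overlaps.
    """
    a = as_frame(sites_a)
    b = as_frame(sites_b)
    trees_b: dict[str, IntervalTree] = {}
    for _, row in b.iterrows():
        trees_b.setdefault(row["chrom"], IntervalTree()).addi(row["start"], row["end"], row["name"])
    trees_a: dict[str, IntervalTree] = {}
    for _, row in a.iterrows():
        trees_a.setdefault(row["chrom"], IntervalTree()).addi(row["start"], row["end"], row["name"])

    def _label(df, trees):
        lab = []
        for _, row in df.iterrows():
            tree = trees.get(row["chrom"])
            lab.append("shared" if tree and tree.overlap(row["start"], row["end"]) else "exclusive")
        return lab

    labels_a = _label(a, trees_b)
    labels_b = _label(b, trees_a)
    return {
        "labels_a": pd.Series(labels_a, index=a["name"].tolist(), name="label"),
        "labels_b": pd.Series(labels_b, index=b["name"].tolist(), name="label"),
        "n_shared": int(sum(l == "shared" for l in labels_a)),
        "n_a_exclusive": int(sum(l == "exclusive" for l in labels_a)),
        "n_b_exclusive": int(sum(l == "exclusive" for l in labels_b)),
    }


def enhancer_enrichment(class_counts: np.ndarray) -> dict:
    """Pearson Chi-square on the 3x2 (site class) x (enhancer overlap) table.

    Rows are shared / a-exclusive / b-exclusive, columns enhancer-
    overlapping yes/no; no continuity correction; dof = 2.  A zero
    expected cell aborts with advice to merge categories.
    """
    table = np.asarray(class_counts, dtype=float)
    if table.shape != (3, 2):
        raise ValueError(f"expected a 3x2 table, got {table.shape}")
    if (table < 0).any():
        raise ValueError("counts must be nonnegative")
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        raise ValueError("zero row or column total: merge categories before testing")
    stat, p, dof, expected = chi2_contingency(table, correction=False)
    if (expected == 0).any():
        raise ValueError("zero expected cell: merge categories before testing")
    return {"chi2": float(stat), "dof": int(dof), "p": float(p)}


def assign_target_genes(
    peaks, tss, enhancer_links: pd.DataFrame, half_width: int = 5000
) -> tuple[pd.DataFrame, list]:
    """Target genes per peak via promoters and linked enhancers.

    A peak targets gene G when it overlaps G's promoter window or any
    enhancer linked to G (``enhancer_links``: chrom, start, end, gene; one
    row per enhancer-gene pair).  Returns the per-peak gene sets and the
    global deduplicated, sorted target-gene list.
    """
    peaks = as_frame(peaks)
    promoters = promoter_assignment(peaks, tss, half_width=half_width)

    trees: dict[str, IntervalTree] = {}
    for _, row in enhancer_links.iterrows():
        if row["end"] > row["start"]:
            trees.setdefault(str(row["chrom"]), IntervalTree()).addi(
                int(row["start"]), int(row["end"]), row["gene"]
            )
    rows = []
    for (_, peak), (_, prom) in zip(peaks.iterrows(), promoters.iterrows()):
        genes = set(prom["genes"])
        tree = trees.get(peak["chrom"])
        if tree:
            genes |= {iv.data for iv in tree.overlap(peak["start"], peak["end"])}
        rows.append((peak["name"], sorted(genes)))
    per_peak = pd.DataFrame(rows, columns=["peak", "genes"])
    global_list = sorted({g for gs in per_peak["genes"] for g in gs})
    return per_peak, global_list
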