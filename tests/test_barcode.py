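"""Read→clone pipeline: extraction, filtering, collapsing, clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest

import clonoscope as cs
from clonoscope.barcode import (
    REASON_NO_ANCHOR5,
    REASON_TOO_SHORT,
    ExtractedBarcode,
    ReadRecord,
)
from clonoscope.layout import ReadStructure

RS = ReadStructure()
BC37 = cs.DEFAULT_LAYOUT.render("ACGT" * 6 + "A")  # arbitrary valid 37-mer


def read_with(seq, cell="cellA", umi="AAAACCCC", q=40):
    return ReadRecord(read_id="r1", sequence=seq, qualities=[q] * len(seq), cell_id=cell, umi=umi)


def brute_force_extract(seq, structure, tol):
    """Exhaustive sliding-window matcher used as the extraction oracle."""
    for off in range(len(seq)):
        a5 = seq[off : off + len(structure.anchor5)]
        if len(a5) < len(structure.anchor5) or off > structure.max_anchor_offset:
            continue
        if sum(x != y for x, y in zip(a5, structure.anchor5)) > tol:
            continue
        s = off + len(structure.anchor5)
        e = s + structure.barcode_length
        a3 = seq[e : e + len(structure.anchor3)]
        if len(a3) < len(structure.anchor3):
            return None
        if sum(x != y for x, y in zip(a3, structure.anchor3)) > tol:
            return None
        return seq[s:e]
    return None


class TestExtraction:
    def test_exact_template(self):
        rec, reason = cs.extract_lineage_barcode(read_with(RS.anchor5 + BC37 + RS.anchor3), RS, 0)
        assert reason is None and rec.barcode == BC37

    def test_missing_5prime_anchor_rejected(self):
        rec, reason = cs.extract_lineage_barcode(read_with("T" * 60), RS, 0)
        assert rec is None and reason == REASON_NO_ANCHOR5

    def test_short_read_rejected(self):
        rec, reason = cs.extract_lineage_barcode(read_with("ACGT"), RS, 0)
        assert rec is None and reason == REASON_TOO_SHORT

    def test_one_anchor_mismatch_tolerated(self):
        a5 = "T" + RS.anchor5[1:]
        rec, _ = cs.extract_lineage_barcode(read_with(a5 + BC37 + RS.anchor3), RS, 1)
        assert rec is not None and rec.barcode == BC37
        rec0, _ = cs.extract_lineage_barcode(read_with(a5 + BC37 + RS.anchor3), RS, 0)
        assert rec0 is None

    @pytest.mark.parametrize("tol", [0, 1, 2])
    def test_matches_sliding_window_oracle(self, rng, tol):
        bases = np.array(list("ACGT"))
        for _ in range(60):
            prefix = "".join(rng.choice(bases, size=rng.integers(0, 6)))
            # randomly corrupt anchors and/or drop them entirely
            a5 = list(RS.anchor5)
            for pos in rng.choice(len(a5), size=rng.integers(0, 3), replace=False):
                a5[pos] = rng.choice(bases)
            seq = prefix + "".join(a5) + BC37 + RS.anchor3 + "".join(rng.choice(bases, size=5))
            read = read_with(seq)
            rec, _ = cs.extract_lineage_barcode(read, RS, tol)
            expected = brute_force_extract(seq, RS, tol)
            assert (rec.barcode if rec else None) == expected

    def test_extracted_qualities_align_with_barcode(self):
        seq = RS.anchor5 + BC37 + RS.anchor3
        quals = list(range(len(seq)))
        read = ReadRecord("r", seq, quals, "c", "u")
        rec, _ = cs.extract_lineage_barcode(read, RS, 0)
        assert list(rec.barcode_qualities) == quals[len(RS.anchor5) : len(RS.anchor5) + 37]


def xb(cell, umi, bc, quals):
    return ExtractedBarcode(cell_id=cell, umi=umi, barcode=bc, barcode_qualities=tuple(quals),
                            read_id=f"{cell}:{umi}")


class TestQualityFilter:
    def test_all_q40_kept_both_modes(self):
        recs = [xb("c", "u", BC37, [40] * 37)]
        assert cs.filter_by_quality(recs, 30, "mean") == recs
        assert cs.filter_by_quality(recs, 30, "min") == recs

    def test_mean_vs_min_semantics(self):
        # mean 29.5 -> dropped in mean mode
        low_mean = xb("c", "u1", BC37, [29, 30] * 18 + [29])
        assert np.mean(low_mean.barcode_qualities) < 30
        assert cs.filter_by_quality([low_mean], 30, "mean") == []
        # one Q29 base among Q40s -> dropped only in min mode
        one_low = xb("c", "u2", BC37, [40] * 36 + [29])
        assert cs.filter_by_quality([one_low], 30, "mean") == [one_low]
        assert cs.filter_by_quality([one_low], 30, "min") == []

    def test_order_preserved(self):
        recs = [xb("c", f"u{i}", BC37, [40] * 37) for i in range(5)]
        assert cs.filter_by_quality(recs, 30) == recs


class TestUmiCollapse:
    def test_jackpot_collapses_to_one(self):
        recs = [xb("c1", "AAAA", BC37, [40] * 37) for _ in range(5)]
        out = cs.collapse_umis(recs)
        assert out["umi_count"].tolist() == [1]

    def test_distinct_umis_counted(self):
        recs = [xb("c1", "AAAA", BC37, [40] * 37), xb("c1", "CCCC", BC37, [40] * 37)]
        assert cs.collapse_umis(recs)["umi_count"].tolist() == [2]

    def test_mixed_set_matches_enumeration_oracle(self, rng):
        cells = ["c1", "c2"]
        umis = ["AA", "CC", "GG"]
        bcs = [BC37, cs.DEFAULT_LAYOUT.render("T" * 25)]
        recs = [
            xb(rng.choice(cells), rng.choice(umis), bcs[rng.integers(0, 2)], [40] * 37)
            for _ in range(30)
        ]
        out = cs.collapse_umis(recs)
        expected = {}
        for r in recs:
            expected.setdefault((r.cell_id, r.barcode), set()).add(r.umi)
        assert len(out) == len(expected)
        for _, row in out.iterrows():
            assert row["umi_count"] == len(expected[(row["cell_id"], row["barcode"])])


def oracle_union_find(barcodes, d):
    """Brute-force all-pairs union-find clustering oracle."""
    uniq = sorted(set(barcodes))
    parent = list(range(len(uniq)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(len(uniq)), 2):
        if sum(a != b for a, b in zip(uniq[i], uniq[j])) <= d:
            parent[find(i)] = find(j)
    groups = {}
    for i, b in enumerate(uniq):
        groups.setdefault(find(i), []).append(b)
    return {b: min(members) for members in groups.values() for b in members}


class TestClustering:
    def test_identical_barcodes_one_cluster(self):
        out = cs.cluster_barcodes([BC37, BC37], d=3)
        assert out == {BC37: BC37}

    def test_distance_threshold_boundary(self):
        other = list(BC37)
        for pos in cs.DEFAULT_LAYOUT.random_positions[:4]:
            other[pos] = "T" if BC37[pos] != "T" else "G"
        other = "".join(other)
        out = cs.cluster_barcodes([BC37, other], d=3)
        assert out[BC37] != out[other]  # distance 4 > 3: two clusters
        out2 = cs.cluster_barcodes([BC37, other], d=4)
        assert out2[BC37] == out2[other]

    def test_chain_merges_transitively(self):
        b1 = list(BC37)
        pos = cs.DEFAULT_LAYOUT.random_positions
        b2, b3 = list(b1), list(b1)
        for p in pos[:2]:
            b2[p] = "T" if b1[p] != "T" else "G"
        b3 = list(b2)
        for p in pos[2:4]:
            b3[p] = "T" if b2[p] != "T" else "G"
        b1, b2, b3 = map("".join, (b1, b2, b3))
        out = cs.cluster_barcodes([b1, b2, b3], d=2)
        assert len(set(out.values())) == 1

    def test_matches_union_find_oracle_on_random_sets(self, rng):
        for trial in range(20):
            n = int(rng.integers(5, 31))
            barcodes = ["".join(rng.choice(list("ACGT"), size=37)) for _ in range(n)]
            # seed near-duplicates so clusters actually form
            for _ in range(n // 2):
                src = barcodes[int(rng.integers(0, len(barcodes)))]
                mutated = list(src)
                for p in rng.choice(37, size=int(rng.integers(1, 4)), replace=False):
                    mutated[p] = rng.choice(list("ACGT"))
                barcodes.append("".join(mutated))
            assert cs.cluster_barcodes(barcodes, d=3) == oracle_union_find(barcodes, 3)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            cs.cluster_barcodes(["ACGT", "ACG"], d=1)

    def test_idempotence_on_cluster_ids(self, rng):
        barcodes = ["".join(rng.choice(list("ACGT"), size=37)) for _ in range(25)]
        first = cs.cluster_barcodes(barcodes, d=3)
        ids = sorted(set(first.values()))
        second = cs.cluster_barcodes(ids, d=0)
        assert second == {b: b for b in ids}

    def test_input_order_invariance(self, rng):
        barcodes = ["".join(rng.choice(list("ACGT"), size=20)) for _ in range(15)]
        shuffled = list(barcodes)
        rng.shuffle(shuffled)
        assert cs.cluster_barcodes(barcodes, d=3) == cs.cluster_barcodes(shuffled, d=3)


class TestBuildCloneTable:
    def _meta(self, cells, batch="b1"):
        return pd.DataFrame(
            {"cell_id": cells, "cell_class": "PN", "arm": "gLacZ", "batch": batch}
        )

    def test_shared_cluster_joins_cells(self):
        counts = pd.DataFrame(
            {"cell_id": ["A", "B"], "barcode": ["bc1", "bc1"], "umi_count": [2, 3]}
        )
        table, _ = cs.build_clone_table(counts, {"bc1": "bc1"}, self._meta(["A", "B"]))
        assert table["clone_id"].nunique() == 1

    def test_multibarcode_cell_merges_clusters(self):
        # {A: bc1}, {B: bc1, bc2}, {C: bc2} -> one 3-cell clone
        counts = pd.DataFrame(
            {
                "cell_id": ["A", "B", "B", "C"],
                "barcode": ["bc1", "bc1", "bc2", "bc2"],
                "umi_count": [1, 1, 1, 1],
            }
        )
        clusters = {"bc1": "bc1", "bc2": "bc2"}
        table, _ = cs.build_clone_table(counts, clusters, self._meta(["A", "B", "C"]))
        assert table["clone_id"].nunique() == 1
        assert sorted(table["cell_id"]) == ["A", "B", "C"]

    def test_matches_networkx_components_oracle(self, rng):
        import networkx as nx

        cells = [f"c{i}" for i in range(20)]
        bcs = [f"bc{i}" for i in range(8)]
        rows = []
        for c in cells:
            for b in rng.choice(bcs, size=rng.integers(1, 3), replace=False):
                rows.append((c, b, 1))
        counts = pd.DataFrame(rows, columns=["cell_id", "barcode", "umi_count"])
        table, _ = cs.build_clone_table(
            counts, {b: b for b in bcs}, self._meta(cells)
        )
        g = nx.Graph()
        g.add_edges_from(zip(counts["cell_id"], "B:" + counts["barcode"]))
        oracle = {}
        for comp in nx.connected_components(g):
            comp_cells = sorted(c for c in comp if not c.startswith("B:"))
            for c in comp_cells:
                oracle[c] = comp_cells[0]
        ours = table.groupby("clone_id")["cell_id"].agg(lambda s: sorted(s)[0])
        mapped = table.set_index("cell_id")["clone_id"].map(ours)
        assert mapped.to_dict() == oracle

    def test_min_umi_drops_pairs_and_reports_cells(self):
        counts = pd.DataFrame(
            {"cell_id": ["A", "B"], "barcode": ["bc1", "bc2"], "umi_count": [5, 1]}
        )
        table, report = cs.build_clone_table(
            counts, {"bc1": "bc1", "bc2": "bc2"}, self._meta(["A", "B"]), min_umi=2
        )
        assert table["cell_id"].tolist() == ["A"]
        assert report.cells_dropped == ["B"]
        assert report.n_pairs_below_min_umi == 1

    def test_missing_metadata_is_loud(self):
        counts = pd.DataFrame({"cell_id": ["A", "Z"], "barcode": ["bc1", "bc1"], "umi_count": [1, 1]})
        with pytest.raises(ValueError, match="Z"):
            cs.build_clone_table(counts, {"bc1": "bc1"}, self._meta(["A"]))

    def test_same_barcode_in_two_batches_two_clones(self):
        counts = pd.DataFrame(
            {"cell_id": ["A", "B"], "barcode": ["bc1", "bc1"], "umi_count": [1, 1]}
        )
        meta = pd.DataFrame(
            {"cell_id": ["A", "B"], "cell_class": "PN", "arm": "gLacZ", "batch": ["b1", "b2"]}
        )
        table, _ = cs.build_clone_table(counts, {"bc1": "bc1"}, meta)
        assert table["clone_id"].nunique() == 2


class TestPipeline:
    def test_read_order_permutation_invariance(self, small_config):
        data = cs.simulate_dataset(small_config)
        meta = data["clone_table"][["cell_id", "cell_class", "arm", "batch"]]
        t1, _ = cs.process_reads(data["reads"], cell_metadata=meta)
        shuffled = list(data["reads"])
        np.random.default_rng(1).shuffle(shuffled)
        t2, _ = cs.process_reads(shuffled, cell_metadata=meta)
        pd.testing.assert_frame_equal(t1, t2)
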