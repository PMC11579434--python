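"""D-statistic pipeline: concatenation, SNP extraction, thinning, pattern
counting, jackknife, trio arrangement, scan consistency."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from introscan.alignio import Alignment
from introscan.dstat import (
    PatternCounts,
    SNPTable,
    arrange_trio,
    block_jackknife,
    concatenate,
    count_patterns,
    d_statistic,
    dstat_results_to_frame,
    dstat_scan,
    enumerate_trios,
    extract_biallelic_snps,
    thin_snps,
    _thinned_codes,
    _classify,
)
from introscan.errors import (
    AlignmentFormatError,
    BlockCountError,
    UndefinedStatisticError,
)
from introscan.treeio import TripletSpec, parse_newick


def aln(seqs):
    return Alignment.from_sequences(seqs)


def snp_table(rows, taxa=("P1", "P2", "P3", "O")):
    """rows: list of (pos, 'ACGT' string of 4 alleles)"""
    pos = np.array([r[0] for r in rows], dtype=np.int64)
    from introscan.alignio import encode

    alleles = np.vstack([encode("".join(r[1][i] for r in rows)) for i in range(4)])
    return SNPTable(tuple(taxa), pos, alleles)


class TestConcatenate:
    def test_intervals(self):
        c = concatenate(
            [
                ("L1", aln({"A": "A" * 100, "B": "C" * 100})),
                ("L2", aln({"A": "G" * 200, "B": "T" * 200})),
            ]
        )
        assert c.length == 300
        assert c.partitions == [("L1", 0, 100), ("L2", 100, 300)]

    def test_missing_taxon_padded_with_gaps(self):
        c = concatenate(
            [
                ("L1", aln({"A": "ACGT", "B": "ACGT"})),
                ("L2", aln({"A": "GGGG"})),
            ]
        )
        from introscan.alignio import GAP

        assert (c.row("B")[4:] == GAP).all()
        assert (c.row("B")[:4] <= 3).all()

    def test_single_locus_identity(self):
        a = aln({"A": "ACGT", "B": "TGCA"})
        c = concatenate([("L1", a)])
        assert (c.row("A") == a.row("A")).all()

    def test_ragged_locus_rejected(self):
        with pytest.raises(AlignmentFormatError):
            aln({"A": "ACGT", "B": "ACG"})


class TestExtract:
    def test_monomorphic_dropped(self):
        c = concatenate([("L1", aln({"P1": "A", "P2": "A", "P3": "A", "O": "A"}))])
        assert len(extract_biallelic_snps(c, ["P1", "P2", "P3", "O"])) == 0

    def test_triallelic_dropped(self):
        c = concatenate([("L1", aln({"P1": "A", "P2": "C", "P3": "G", "O": "C"}))])
        assert len(extract_biallelic_snps(c, ["P1", "P2", "P3", "O"])) == 0

    def test_biallelic_kept(self):
        c = concatenate([("L1", aln({"P1": "A", "P2": "C", "P3": "C", "O": "A"}))])
        assert len(extract_biallelic_snps(c, ["P1", "P2", "P3", "O"])) == 1

    def test_gap_or_ambiguity_excluded(self):
        c = concatenate(
            [("L1", aln({"P1": "AA", "P2": "C-", "P3": "CN", "O": "AA"}))]
        )
        assert len(extract_biallelic_snps(c, ["P1", "P2", "P3", "O"])) == 1


class TestThin:
    def test_greedy_rule(self):
        t = snp_table([(0, "ACCA"), (100, "ACCA"), (600, "ACCA")])
        kept = thin_snps(t, 500)
        assert list(kept.positions) == [0, 600]

    def test_empty(self):
        t = snp_table([])
        assert len(thin_snps(t, 500)) == 0

    def test_dense_cluster_keeps_one(self):
        t = snp_table([(i, "ACCA") for i in range(0, 499, 50)])
        assert len(thin_snps(t, 500)) == 1

    @settings(max_examples=50, derandomize=True)
    @given(
        st.lists(st.integers(min_value=0, max_value=20000), min_size=0, max_size=80, unique=True),
        st.integers(min_value=1, max_value=1000),
    )
    def test_spacing_and_idempotence_properties(self, positions, spacing):
        t = snp_table([(p, "ACCA") for p in sorted(positions)])
        kept = thin_snps(t, spacing)
        assert len(kept) <= len(t)
        if len(kept) > 1:
            assert (np.diff(kept.positions) >= spacing).all()
        again = thin_snps(kept, spacing)
        assert list(again.positions) == list(kept.positions)

    def test_idempotent_and_never_grows(self):
        rng = np.random.default_rng(1)
        pos = np.unique(rng.integers(0, 10000, 300))
        t = snp_table([(int(p), "ACCA") for p in pos])
        once = thin_snps(t, 500)
        assert len(once) <= len(t)
        twice = thin_snps(once, 500)
        assert list(twice.positions) == list(once.positions)


class TestPatterns:
    @pytest.mark.parametrize(
        "col,pattern",
        [("ACCA", "abba"), ("CACA", "baba"), ("CCAA", "bbaa")],
    )
    def test_classification(self, col, pattern):
        t = snp_table([(0, col)])
        c = count_patterns(t)
        assert getattr(c, pattern) == 1

    def test_singletons_ignored_but_counted(self):
        t = snp_table([(0, "CAAA"), (1, "ACCA")])
        c = count_patterns(t)
        assert (c.abba, c.baba, c.bbaa) == (1, 0, 0)
        assert c.n_snps_used == 2

    def test_d_statistic_values(self):
        assert d_statistic(PatternCounts(30, 10, 0, 40)) == pytest.approx(0.5)
        assert d_statistic(PatternCounts(7, 7, 0, 14)) == 0.0
        assert d_statistic(PatternCounts(0, 25, 0, 25)) == -1.0
        with pytest.raises(UndefinedStatisticError):
            d_statistic(PatternCounts(0, 0, 5, 5))


class TestJackknife:
    def test_four_block_hand_oracle(self):
        # 8 SNPs -> 4 blocks of 2; patterns chosen so delete-one D varies
        cols = ["ACCA", "ACCA", "CACA", "ACCA", "ACCA", "ACCA", "CACA", "ACCA"]
        t = snp_table([(i, c) for i, c in enumerate(cols)])
        se, z, p = block_jackknife(t, n_blocks=4)
        abba, baba = 6, 2
        d = (abba - baba) / (abba + baba)
        d_del = []
        for j in range(4):
            blk = cols[2 * j : 2 * j + 2]
            a = abba - sum(1 for c in blk if c == "ACCA")
            b = baba - sum(1 for c in blk if c == "CACA")
            d_del.append((a - b) / (a + b))
        var = (4 - 1) / 4 * sum((x - np.mean(d_del)) ** 2 for x in d_del)
        assert se == pytest.approx(math.sqrt(var))
        assert z == pytest.approx(d / se)

    def test_identical_blocks_zero_se_handled(self):
        cols = ["ACCA", "CACA"] * 8
        t = snp_table([(i, c) for i, c in enumerate(cols)])
        se, z, p = block_jackknife(t, n_blocks=4)
        assert se == 0.0 and z == 0.0 and p == 1.0  # D = 0 exactly

    def test_zero_se_nonzero_d_flagged_infinite(self):
        cols = ["ACCA", "ACCA"] * 8
        t = snp_table([(i, c) for i, c in enumerate(cols)])
        se, z, p = block_jackknife(t, n_blocks=4)
        assert se == 0.0 and math.isinf(z) and p == 0.0

    def test_too_few_snps_raises(self):
        t = snp_table([(i, "ACCA") for i in range(10)])
        with pytest.raises(BlockCountError):
            block_jackknife(t, n_blocks=40)


class TestArrange:
    def test_example(self):
        tree = parse_newick("((A,B),C);")
        out = arrange_trio(TripletSpec("A", "C", "B", "O"), tree)
        assert (out.p1, out.p2, out.p3) == ("A", "B", "C")

    def test_already_arranged_identity(self):
        tree = parse_newick("((A,B),C);")
        out = arrange_trio(TripletSpec("A", "B", "C", "O"), tree)
        assert (out.p1, out.p2, out.p3) == ("A", "B", "C")

    def test_oracle_on_random_trees(self):
        from conftest import random_tree_newick

        rng = np.random.default_rng(7)
        for _ in range(5):
            tree = parse_newick(random_tree_newick(rng, 10))
            depth = tree.topo_depth()
            for trio in itertools.combinations(sorted(tree.taxa), 3):
                out = arrange_trio(TripletSpec(*trio, "X"), tree)
                # brute-force: the arranged pair must have the deepest MRCA
                dpair = depth[tree.mrca(out.p1, out.p2)]
                d13 = depth[tree.mrca(out.p1, out.p3)]
                d23 = depth[tree.mrca(out.p2, out.p3)]
                assert dpair >= max(d13, d23)


class TestScan:
    def test_trio_enumeration_counts(self):
        assert len(enumerate_trios([f"t{i}" for i in range(8)])) == 56

    def test_kernel_matches_snp_table_path(self, planted_10taxon):
        net, _, gts, alns = planted_10taxon
        concat = concatenate(alns)
        spec = arrange_trio(TripletSpec("sp01", "sp03", "sp05", "OUT"), net.tree)
        pos, code = _thinned_codes(concat, spec, 500)
        table = extract_biallelic_snps(
            concat, [spec.p1, spec.p2, spec.p3, spec.outgroup]
        )
        thinned = thin_snps(table, 500)
        assert list(pos) == list(thinned.positions)
        assert list(code) == list(_classify(thinned.alleles))

    def test_swap_p1_p2_negates_d(self, planted_10taxon):
        net, _, gts, alns = planted_10taxon
        concat = concatenate(alns)
        spec = TripletSpec("sp01", "sp03", "sp05", "OUT")
        c1 = count_patterns(extract_biallelic_snps(concat, ["sp01", "sp03", "sp05", "OUT"]))
        c2 = count_patterns(extract_biallelic_snps(concat, ["sp03", "sp01", "sp05", "OUT"]))
        assert c1.abba == c2.baba and c1.baba == c2.abba
        if c1.abba + c1.baba:
            assert d_statistic(c1) == pytest.approx(-d_statistic(c2))

    def test_scan_on_planted_edge(self, planted_10taxon):
        net, edge, gts, alns = planted_10taxon
        concat = concatenate(alns)
        results = dstat_scan(concat, net.tree, "OUT", min_spacing=200, n_blocks=20)
        assert results  # scan produced trios
        frame = dstat_results_to_frame(results)
        assert (frame["Dstatistic"] >= 0).all()  # oriented
        sig = frame[frame["p-adj"] < 0.001]
        # the gamma-bearing trio (recipient, sister, donor) has strong signal
        strong = frame[(frame["P3"] == edge.donor) & (frame["P2"] == edge.recipient)]
        if len(strong):
            assert strong["Z-score"].max() > 3

    def test_d_from_counts_equals_blockwise_aggregation(self, planted_10taxon):
        net, _, gts, alns = planted_10taxon
        concat = concatenate(alns)
        spec = arrange_trio(TripletSpec("sp02", "sp05", "sp08", "OUT"), net.tree)
        _, code = _thinned_codes(concat, spec, 300)
        abba, baba = int((code == 1).sum()), int((code == 2).sum())
        bounds = np.linspace(0, code.size, 11).astype(int)
        a2 = sum(int((code[bounds[i]:bounds[i+1]] == 1).sum()) for i in range(10))
        b2 = sum(int((code[bounds[i]:bounds[i+1]] == 2).sum()) for i in range(10))
        assert (abba, baba) == (a2, b2)
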