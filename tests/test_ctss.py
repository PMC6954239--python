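"""Unit and property tests for CTSS ingestion, classification and clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dualinit import ctss
from oracles import union_find_clusters


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

class TestReadCtssTable:
    def test_duplicate_keys_are_summed(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text("chr1\t100\t+\t3\nchr1\t100\t+\t2\nchr1\t105\t-\t1\n")
        df = ctss.read_ctss_table(p)
        assert len(df) == 2
        row = df[(df["pos"] == 100) & (df["strand"] == "+")]
        assert row["count"].item() == 5

    def test_empty_file(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("")
        assert ctss.read_ctss_table(p).empty

    @pytest.mark.parametrize("line", [
        "chr1\t100\t.\t3",          # invalid strand
        "chr1\t0\t+\t3",            # pos < 1
        "chr1\t100\t+",             # wrong field count
        "chr1\tx\t+\t3",            # non-integer pos
    ])
    def test_malformed_lines_raise_with_line_number(self, tmp_path, line):
        p = tmp_path / "bad.tsv"
        p.write_text("chr1\t10\t+\t1\n" + line + "\n")
        with pytest.raises(ctss.CtssParseError, match=":2"):
            ctss.read_ctss_table(p)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

class TestNormalization:
    def test_tpm_arithmetic(self):
        np.testing.assert_allclose(
            ctss.normalize_tpm([1, 1, 2]), [250000, 250000, 500000])

    def test_single_position_gets_full_million(self):
        np.testing.assert_allclose(ctss.normalize_tpm([7]), [1e6])

    def test_tpm_sums_to_million(self, rng):
        counts = rng.integers(1, 1000, size=500)
        assert ctss.normalize_tpm(counts).sum() == pytest.approx(1e6, rel=1e-9)

    def test_zero_total_raises(self):
        with pytest.raises(ValueError):
            ctss.normalize_tpm([0, 0])

    def test_powerlaw_monotone_and_total(self, rng):
        # counts from a discrete power law so the fit window is populated
        u = rng.random(20000)
        counts = np.floor((1 - u) ** (-1 / 1.5)).astype(int)
        counts = counts[counts >= 1]
        norm = ctss.powerlaw_normalize(counts)
        order = np.argsort(counts, kind="stable")
        assert np.all(np.diff(norm[order]) >= -1e-9)
        assert norm.sum() == pytest.approx(1e6, rel=1e-9)

    def test_powerlaw_equal_counts_stay_equal(self, rng):
        u = rng.random(5000)
        counts = np.floor((1 - u) ** (-1 / 1.2)).astype(int)
        counts[:10] = 50
        norm = ctss.powerlaw_normalize(counts)
        assert len(set(np.round(norm[:10], 9))) == 1

    def test_powerlaw_falls_back_to_tpm(self, caplog):
        counts = np.array([1, 2, 3, 4, 5])     # nothing in [10, 1000]
        with caplog.at_level("WARNING"):
            norm = ctss.powerlaw_normalize(counts)
        np.testing.assert_allclose(norm, ctss.normalize_tpm(counts))
        assert "falling back" in caplog.text


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

class TestClassifyInitiator:
    GENOME = {"chr1": "ACGTACGTTA" + "CCGGTTAAGG"}

    def test_partition_of_all_dinucleotides(self):
        classes = {"YR": 0, "YC": 0, "OTHER": 0}
        for d in map("".join, itertools.product("ACGT", repeat=2)):
            classes[ctss.classify_dinucleotide(d)] += 1
        assert classes == {"YR": 4, "YC": 2, "OTHER": 10}
        assert not (ctss.YR_DINUCS & ctss.YC_DINUCS)

    @pytest.mark.parametrize("dinuc,expected", [
        ("TA", "YR"), ("CA", "YR"), ("CG", "YR"), ("TG", "YR"),
        ("TC", "YC"), ("CC", "YC"),
        ("GG", "OTHER"), ("AA", "OTHER"), ("NT", "OTHER"),
    ])
    def test_named_contexts(self, dinuc, expected):
        assert ctss.classify_dinucleotide(dinuc) == expected

    def test_plus_strand_reads_upstream_base(self):
        genome = {"c": "ATAG"}     # pos 3 (+): -1 = T, +1 = A -> YR
        iclass, dinuc = ctss.classify_initiator(genome, "c", 3, "+")
        assert (iclass, dinuc) == ("YR", "TA")

    def test_minus_strand_reverse_complement(self):
        # plus-strand "TG" at (pos, pos+1) reads CA on the minus strand
        genome = {"c": "AATGAA"}
        iclass, dinuc = ctss.classify_initiator(genome, "c", 3, "-")
        assert (iclass, dinuc) == ("YR", "CA")

    def test_contig_edge_is_other(self):
        genome = {"c": "CAAA"}
        assert ctss.classify_initiator(genome, "c", 1, "+")[0] == "OTHER"
        assert ctss.classify_initiator(genome, "c", 4, "-")[0] == "OTHER"

    def test_n_base_is_other(self):
        genome = {"c": "ANCA"}
        assert ctss.classify_initiator(genome, "c", 3, "+")[0] == "OTHER"


# ---------------------------------------------------------------------------
# expression filter
# ---------------------------------------------------------------------------

class TestFilterCtss:
    def _frame(self, rows):
        df = pd.DataFrame(rows, columns=["s1", "s2", "s3"])
        df.insert(0, "chrom", "chr1")
        df.insert(1, "pos", range(100, 100 + len(df)))
        df.insert(2, "strand", "+")
        return df

    def test_rescue_rule(self):
        df = self._frame([(1.2, 0.7, 0.3)])
        out = ctss.filter_ctss(df, ["s1", "s2", "s3"])
        np.testing.assert_allclose(
            out[["s1", "s2", "s3"]].to_numpy()[0], [1.2, 0.7, 0.0])

    def test_below_primary_dropped(self):
        df = self._frame([(0.9, 0.8, 0.7)])
        assert len(ctss.filter_ctss(df, ["s1", "s2", "s3"])) == 0

    def test_zero_primary_keeps_everything(self):
        df = self._frame([(0.1, 0.0, 0.2), (0.9, 0.8, 0.7)])
        out = ctss.filter_ctss(df, ["s1", "s2", "s3"], primary_tpm=0.0,
                               rescue_tpm=0.0)
        assert len(out) == 2


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def _cluster_frame(positions, iclass="YR", strand="+", tpm=1.0):
    df = pd.DataFrame({
        "chrom": "chr1", "pos": positions, "strand": strand,
        "iclass": iclass, "s1": tpm,
    })
    return df


class TestClusterCtss:
    def test_gap_rule_splits_clusters(self):
        clusters = ctss.cluster_ctss(_cluster_frame([100, 112, 135]), ["s1"])
        spans = sorted((c.start, c.end) for c in clusters)
        assert spans == [(100, 112), (135, 135)]

    def test_singleton_width(self):
        (cl,) = ctss.cluster_ctss(_cluster_frame([500]), ["s1"])
        assert cl.width == 1 and cl.n_ctss == 1

    def test_classes_cluster_separately(self):
        df = pd.concat([_cluster_frame([100], "YR"),
                        _cluster_frame([101], "YC")])
        clusters = ctss.cluster_ctss(df, ["s1"])
        assert len(clusters) == 2

    def test_other_class_ignored(self):
        df = pd.concat([_cluster_frame([100], "YR"),
                        _cluster_frame([105], "OTHER")])
        clusters = ctss.cluster_ctss(df, ["s1"])
        assert len(clusters) == 1 and clusters[0].n_ctss == 1

    @given(st.lists(st.integers(1, 2000), min_size=1, max_size=50),
           st.integers(1, 60))
    @settings(max_examples=200, deadline=None)
    def test_matches_union_find_oracle(self, positions, max_gap):
        positions = sorted(set(positions))
        clusters = ctss.cluster_ctss(_cluster_frame(positions), ["s1"],
                                     max_gap=max_gap)
        got = sorted(sorted(c.positions.tolist()) for c in clusters)
        assert got == union_find_clusters(positions, max_gap)

    @given(st.lists(st.tuples(st.integers(1, 500), st.floats(0.1, 100)),
                    min_size=1, max_size=40, unique_by=lambda t: t[0]))
    @settings(max_examples=100, deadline=None)
    def test_tpm_conservation_and_separation(self, items):
        pos = [p for p, _ in items]
        tpm = [t for _, t in items]
        df = pd.DataFrame({"chrom": "chr1", "pos": pos, "strand": "+",
                           "iclass": "YR", "s1": tpm})
        clusters = ctss.cluster_ctss(df, ["s1"], max_gap=20)
        assert sum(c.pooled_tpm for c in clusters) == pytest.approx(sum(tpm))
        spans = sorted((c.start, c.end) for c in clusters)
        for (_, e1), (s2, _) in zip(spans, spans[1:]):
            assert s2 - e1 > 20


class TestDominantCtss:
    def test_argmax(self):
        (cl,) = ctss.cluster_ctss(
            pd.DataFrame({"chrom": "chr1", "pos": [100, 112], "strand": "+",
                          "iclass": "YR", "s1": [5.0, 9.0]}), ["s1"])
        assert ctss.dominant_ctss(cl) == 112

    @pytest.mark.parametrize("strand,expected", [("+", 100), ("-", 112)])
    def test_tie_breaks_to_5prime_in_transcript_orientation(
            self, strand, expected):
        (cl,) = ctss.cluster_ctss(
            pd.DataFrame({"chrom": "chr1", "pos": [100, 112],
                          "strand": strand, "iclass": "YR",
                          "s1": [5.0, 5.0]}), ["s1"])
        assert ctss.dominant_ctss(cl) == expected

    def test_per_stage_dominant(self):
        (cl,) = ctss.cluster_ctss(
            pd.DataFrame({"chrom": "chr1", "pos": [100, 110], "strand": "+",
                          "iclass": "YR", "s1": [9.0, 1.0],
                          "s2": [1.0, 9.0]}), ["s1", "s2"])
        assert ctss.dominant_ctss(cl, "s1") == 100
        assert ctss.dominant_ctss(cl, "s2") == 110
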