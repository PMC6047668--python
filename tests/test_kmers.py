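"""K-mer catalogs, ranking, degenerate classes, and rank-KS statistics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from epikmer import generate_genome
from epikmer.kmers import (
    P_FLOOR,
    DegenerateClass,
    KmerCatalog,
    best_class_rank,
    class_rank_ks,
    compare_class,
    count_kmers,
    decode_kmer,
    encode_kmer,
    expand_pattern,
    extract_windows,
    rank_catalog,
    revcomp,
    top_summary,
)


def naive_count(windows, k, strand_mode):
    """Independent string-scan oracle over the complete 4^k catalog."""
    counts = {"".join(p): 0 for p in itertools.product("ACGT", repeat=k)}
    for window in windows:
        seqs = [window]
        if strand_mode == "both":
            seqs.append(revcomp(window))
        for seq in seqs:
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if set(kmer) <= set("ACGT"):
                    counts[kmer] += 1
    return counts


def catalog_from_counts(count_map, k):
    counts = np.zeros(4**k, dtype=np.int64)
    for kmer, c in count_map.items():
        counts[encode_kmer(kmer)] = c
    return rank_catalog(
        KmerCatalog(k=k, counts=counts, n_windows=1, strand_mode="forward")
    )


class TestExtractWindows:
    GENOME = {"chr1": generate_genome(1000, 0.5, seed=1)}

    def test_window_length_is_501_at_default_half_width(self):
        windows = extract_windows(self.GENOME, [("chr1", 400)], 250)
        assert [len(w) for w in windows] == [501]

    def test_boundary_crossing_center_dropped(self, caplog):
        windows = extract_windows(self.GENOME, [("chr1", 10), ("chr1", 500)], 250)
        assert len(windows) == 1
        assert "crosses contig boundary" in caplog.text

    def test_window_matches_direct_slice(self):
        (window,) = extract_windows(self.GENOME, [("chr1", 333)], 100)
        assert window == self.GENOME["chr1"][233:434]

    def test_unknown_contig_rejected(self):
        with pytest.raises(ValueError):
            extract_windows(self.GENOME, [("chrX", 400)], 250)


class TestCountKmers:
    def test_spec_example_acgtacgt(self):
        catalog = count_kmers(["ACGTACGT"], 4, "forward")
        assert catalog.count("ACGT") == 2
        for kmer in ("CGTA", "GTAC", "TACG"):
            assert catalog.count(kmer) == 1
        assert catalog.counts.sum() == 5
        assert (catalog.counts > 0).sum() == 4

    def test_catalog_complete_for_6mers(self):
        catalog = count_kmers(["ACGTACGTAC"], 6, "forward")
        assert catalog.size == 4096
        assert len(catalog.counts) == 4096

    @pytest.mark.parametrize("k", [4, 6])
    @pytest.mark.parametrize("strand_mode", ["forward", "both"])
    def test_matches_naive_oracle(self, k, strand_mode):
        rng = np.random.default_rng(42)
        windows = []
        for _ in range(30):
            n = int(rng.integers(k, 60))
            seq = "".join(rng.choice(list("ACGTN"), size=n, p=[0.24] * 4 + [0.04]))
            windows.append(seq)
        catalog = count_kmers(windows, k, strand_mode)
        assert catalog.counts_by_kmer() == naive_count(windows, k, strand_mode)

    def test_reverse_complement_symmetry(self):
        windows = [generate_genome(300, 0.4, seed=s) for s in range(5)]
        catalog = count_kmers(windows, 4, "both")
        forward = count_kmers(windows, 4, "forward")
        assert catalog.counts.sum() == 2 * forward.counts.sum()
        for kmer in ("ACGT", "AAAA", "GGCC", "ATCG"):
            assert catalog.count(kmer) == catalog.count(revcomp(kmer))

    def test_k_larger_than_every_window_rejected(self):
        with pytest.raises(ValueError):
            count_kmers(["ACG", "TTA"], 6, "forward")


class TestRankCatalog:
    def test_distinct_counts_give_permutation(self):
        rng = np.random.default_rng(0)
        counts = rng.permutation(256)
        catalog = rank_catalog(
            KmerCatalog(k=4, counts=counts, n_windows=1, strand_mode="forward")
        )
        assert sorted(catalog.ranks) == list(range(1, 257))

    def test_midranks_for_ties(self):
        catalog = catalog_from_counts({"AAAA": 5, "CCCC": 5}, 4)
        assert catalog.rank("AAAA") == 1.5
        assert catalog.rank("CCCC") == 1.5
        assert catalog.rank("GGGG") == (3 + 256) / 2

    def test_rank_sum_conserved(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            counts = rng.integers(0, 10, size=256)
            catalog = rank_catalog(
                KmerCatalog(k=4, counts=counts, n_windows=1, strand_mode="forward")
            )
            assert catalog.ranks.sum() == 256 * 257 / 2

    def test_strictly_most_frequent_kmer_displays_first(self):
        catalog = catalog_from_counts({"TGCA": 9, "AAAA": 2}, 4)
        assert catalog.top(1) == ["TGCA"]
        assert catalog.display_position("TGCA") == 1

    def test_display_ties_broken_lexicographically(self):
        catalog = catalog_from_counts({"CCCC": 5, "AAAA": 5}, 4)
        assert catalog.top(2) == ["AAAA", "CCCC"]

    def test_unranked_catalog_rejected_by_statistics(self):
        catalog = count_kmers(["ACGTACGT"], 4, "forward")
        cls = expand_pattern("WWWW")
        with pytest.raises(RuntimeError, match="not ranked"):
            class_rank_ks(catalog, cls)


class TestExpandPattern:
    def test_wwcgww_has_16_members(self):
        cls = expand_pattern("WWCGWW")
        assert len(cls.member_set) == 16
        assert "AACGAA" in cls.member_set

    def test_wwcgww_closed_under_reverse_complement(self):
        cls = expand_pattern("WWCGWW")
        assert {revcomp(m) for m in cls.member_set} == set(cls.member_set)

    def test_composite_rule_matches_brute_force(self):
        cls = expand_pattern("SSSSSS or five S and one W")
        brute = {
            "".join(p)
            for p in itertools.product("ACGT", repeat=6)
            if sum(b in "CG" for b in p) >= 5
        }
        assert set(cls.member_set) == brute
        assert len(cls.member_set) == 448

    def test_concrete_pattern(self):
        assert expand_pattern("ACGT").member_set == frozenset({"ACGT"})

    def test_unsupported_letter_rejected(self):
        with pytest.raises(ValueError, match="unsupported"):
            expand_pattern("WWNGWW")


class TestClassRankKs:
    def test_entire_catalog_gives_closed_form_d(self):
        # distinct counts -> ranks are exactly 1..N, evenly spaced on (0,1]
        rng = np.random.default_rng(1)
        counts = rng.permutation(256)
        catalog = rank_catalog(
            KmerCatalog(k=4, counts=counts, n_windows=1, strand_mode="forward")
        )
        full = DegenerateClass(
            "all", frozenset(decode_kmer(i, 4) for i in range(256)), "all"
        )
        result = class_rank_ks(catalog, full)
        assert result.ks_statistic == pytest.approx(1 / 256)
        assert result.direction == "none"

    def test_class_planted_at_top(self):
        # all 64 all-W 6-mers at ranks 1..64: D is the closed-form CDF gap
        counts = np.zeros(4096, dtype=np.int64)
        w_class = expand_pattern("WWWWWW")
        for i, kmer in enumerate(sorted(w_class.member_set)):
            counts[encode_kmer(kmer)] = 1000 - i
        catalog = rank_catalog(
            KmerCatalog(k=6, counts=counts, n_windows=1, strand_mode="forward")
        )
        result = class_rank_ks(catalog, w_class)
        assert result.ks_statistic == pytest.approx(1 - 64 / 4096, abs=1e-3)
        assert result.p_value == P_FLOOR
        assert result.direction == "upward"

    def test_d_matches_reference_ks_routine(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            counts = rng.permutation(4096)
            catalog = rank_catalog(
                KmerCatalog(k=6, counts=counts, n_windows=1, strand_mode="forward")
            )
            members = frozenset(
                decode_kmer(int(i), 6) for i in rng.choice(4096, 50, replace=False)
            )
            cls = DegenerateClass("random", members, "random")
            result = class_rank_ks(catalog, cls)
            sample = np.array(sorted(catalog.rank(m) / 4096 for m in members))
            reference = stats.kstest(sample, "uniform")
            assert result.ks_statistic == pytest.approx(
                reference.statistic, rel=1e-9
            )


class TestCompareClass:
    def _catalog(self, class_at_top, cls):
        counts = np.zeros(4096, dtype=np.int64) + 10
        members = sorted(cls.member_set)
        for i, kmer in enumerate(members):
            counts[encode_kmer(kmer)] = (5000 - i) if class_at_top else (5 - i % 5)
        return rank_catalog(
            KmerCatalog(k=6, counts=counts, n_windows=1, strand_mode="forward")
        )

    def test_identical_catalogs(self):
        cls = expand_pattern("WWCGWW")
        catalog = self._catalog(True, cls)
        result = compare_class(catalog, catalog, cls)
        assert result.ks_statistic == 0.0
        assert result.p_value == 1.0
        assert result.direction == "none"

    def test_top_to_bottom_shift_is_downward(self):
        cls = expand_pattern("WWWWWW")
        top = self._catalog(True, cls)
        bottom = self._catalog(False, cls)
        result = compare_class(top, bottom, cls)
        assert result.direction == "downward"
        assert result.p_value == P_FLOOR
        reverse = compare_class(bottom, top, cls)
        assert reverse.direction == "upward"

    def test_identical_classes_within_catalog(self):
        cls = expand_pattern("WWCGWW")
        catalog = self._catalog(True, cls)
        result = compare_class(catalog, cls, cls, mode="class_vs_class")
        assert result.ks_statistic == 0.0
        assert result.p_value == 1.0

    def test_k_mismatch_rejected(self):
        cls4 = expand_pattern("WWWW")
        catalog6 = self._catalog(True, expand_pattern("WWWWWW"))
        with pytest.raises(ValueError):
            compare_class(catalog6, catalog6, cls4)


class TestTopSummary:
    def test_hand_computed_mean_and_se(self):
        catalog = catalog_from_counts({"GCGCGC": 9, "ATATAT": 8}, 6)
        summary = top_summary(catalog, 2)
        assert summary.kmers == ("GCGCGC", "ATATAT")
        assert summary.gc_mean == pytest.approx(50.0)
        assert summary.gc_se == pytest.approx(50.0)

    def test_all_w_top_has_zero_gc(self):
        catalog = catalog_from_counts(
            {m: 100 - i for i, m in enumerate(sorted(expand_pattern("WWWWWW").member_set))},
            6,
        )
        summary = top_summary(catalog, 10)
        assert summary.gc_mean == 0.0
        assert summary.gc_se == 0.0

    def test_single_kmer_se_is_zero(self):
        catalog = catalog_from_counts({"ACGTAC": 3}, 6)
        summary = top_summary(catalog, 1)
        assert summary.gc_se == 0.0

    def test_n_beyond_catalog_rejected(self):
        catalog = catalog_from_counts({"ACGT": 1}, 4)
        with pytest.raises(ValueError):
            top_summary(catalog, 257)


class TestBestClassRank:
    def test_class_containing_most_frequent_kmer(self):
        catalog = catalog_from_counts({"AACGAA": 50, "GGGGGG": 10}, 6)
        assert best_class_rank(catalog, expand_pattern("WWCGWW")) == 1

    def test_zero_count_class_ranks_below_all_nonzero(self):
        nonzero = {
            "".join(p): 5
            for p in itertools.product("CG", repeat=6)
        }
        catalog = catalog_from_counts(nonzero, 6)
        rank = best_class_rank(catalog, expand_pattern("WWWWWW"))
        assert rank > len(nonzero)

    def test_agrees_with_linear_scan(self):
        rng = np.random.default_rng(9)
        counts = rng.integers(0, 50, size=4096)
        catalog = rank_catalog(
            KmerCatalog(k=6, counts=counts, n_windows=1, strand_mode="forward")
        )
        cls = expand_pattern("WWCGWW")
        order = catalog.top(4096)
        scan = next(i + 1 for i, kmer in enumerate(order) if kmer in cls.member_set)
        assert best_class_rank(catalog, cls) == scan


@settings(max_examples=30, derandomize=True, deadline=None)
@given(st.lists(st.integers(0, 30), min_size=256, max_size=256))
def test_rank_sum_invariant_property(counts):
    """Midrank sum is N(N+1)/2 for every catalog, however tied."""
    catalog = rank_catalog(
        KmerCatalog(
            k=4, counts=np.array(counts), n_windows=1, strand_mode="forward"
        )
    )
    assert catalog.ranks.sum() == pytest.approx(256 * 257 / 2)
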