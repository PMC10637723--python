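"""Interval algebra against hand counts and per-base brute-force oracles."""

import numpy as np
import pytest

from mpracensus.interval_ops import (
    AbcConnection,
    GeneModel,
    GenomicInterval,
    IntervalError,
    Peak,
    annotate_context,
    fraction_shared,
    jaccard,
    link_abc,
    merge_peaks,
    overlap_composition,
    recurrent_promoter_genes,
)


def mk_peak(start, end, chrom="chr1", summit=None, score=1.0, source=""):
    return Peak(
        GenomicInterval(chrom, start, end),
        summit=summit if summit is not None else (start + end) // 2,
        score=score,
        source=source,
    )


def random_peaks(rng, n, span=10_000, max_len=120):
    out = []
    for _ in range(n):
        s = int(rng.integers(0, span - max_len))
        e = s + int(rng.integers(1, max_len))
        out.append(mk_peak(s, e))
    return out


# ---------------------------------------------------------------------------
# brute-force per-base oracles (kept independent of the implementation)


def oracle_union_find_merge(interval_lists):
    """O(n^2) pairwise-overlap transitive closure."""
    items = [
        (iv, label)
        for label, ivs in interval_lists
        for iv in ivs
    ]
    parent = list(range(len(items)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            a, b = items[i][0], items[j][0]
            if a.chrom == b.chrom and min(a.end, b.end) > max(a.start, b.start):
                parent[find(i)] = find(j)
    groups = {}
    for i, (iv, label) in enumerate(items):
        groups.setdefault(find(i), []).append((iv, label))
    merged = []
    for members in groups.values():
        chrom = members[0][0].chrom
        start = min(iv.start for iv, _ in members)
        end = max(iv.end for iv, _ in members)
        labels = {label for _, label in members}
        merged.append((chrom, start, end, labels))
    return sorted(merged)


def oracle_base_set(intervals, span):
    mask = np.zeros(span, dtype=bool)
    for iv in intervals:
        mask[iv.start : iv.end] = True
    return mask


class TestMergePeaks:
    def test_overlapping_pair_merges_with_both_members(self):
        merged = merge_peaks(
            [("A", [mk_peak(0, 100, source="A")]), ("B", [mk_peak(50, 150, source="B")])]
        )
        assert len(merged) == 1
        m = merged[0]
        assert (m.interval.start, m.interval.end) == (0, 150)
        assert m.members == {"A": True, "B": True}

    def test_bookended_intervals_stay_separate(self):
        merged = merge_peaks([("A", [mk_peak(0, 100), mk_peak(100, 200)])])
        assert len(merged) == 2

    def test_matches_union_find_oracle_on_random_sets(self):
        rng = np.random.default_rng(7)
        sets = [(lab, random_peaks(rng, 333)) for lab in ("A", "B", "C")]
        merged = merge_peaks(sets)
        got = sorted(
            (
                m.interval.chrom,
                m.interval.start,
                m.interval.end,
                {k for k, v in m.members.items() if v},
            )
            for m in merged
        )
        expected = oracle_union_find_merge(
            [(lab, [p.interval for p in ps]) for lab, ps in sets]
        )
        assert got == expected

    def test_output_nonoverlapping_and_bp_conserving(self):
        rng = np.random.default_rng(11)
        sets = [(lab, random_peaks(rng, 200)) for lab in ("A", "B")]
        merged = merge_peaks(sets)
        for a, b in zip(merged, merged[1:]):
            assert (
                a.interval.chrom != b.interval.chrom
                or a.interval.end <= b.interval.start
            )
        mask = oracle_base_set(
            [p.interval for _, ps in sets for p in ps], 10_000
        )
        merged_mask = oracle_base_set([m.interval for m in merged], 10_000)
        assert (mask == merged_mask).all()


class TestFractionShared:
    def test_identical_sets_fully_shared(self):
        ps = [mk_peak(0, 100), mk_peak(500, 600)]
        out = fraction_shared([("A", ps), ("B", list(ps))])
        assert out == {"A": 1.0, "B": 1.0}

    def test_disjoint_sets_unshared(self):
        out = fraction_shared(
            [("A", [mk_peak(0, 100)]), ("B", [mk_peak(500, 600)])]
        )
        assert out == {"A": 0.0, "B": 0.0}

    def test_one_of_three_shared(self):
        a = [mk_peak(0, 100), mk_peak(1000, 1100), mk_peak(2000, 2100)]
        b = [mk_peak(50, 150)]
        out = fraction_shared([("A", a), ("B", b)])
        assert out["A"] == pytest.approx(1 / 3)
        assert out["B"] == 1.0

    def test_empty_set_reported_missing(self):
        out = fraction_shared([("A", [mk_peak(0, 10)]), ("B", [])])
        assert out["B"] is None

    def test_peak_overlapping_two_others_counts_once(self):
        a = [mk_peak(0, 300)]
        b = [mk_peak(0, 50), mk_peak(200, 250)]
        assert fraction_shared([("A", a), ("B", b)])["A"] == 1.0


class TestJaccard:
    def test_identical_sets_give_one(self):
        ps = [mk_peak(0, 100), mk_peak(500, 700)]
        assert jaccard(ps, list(ps)) == 1.0

    def test_hand_computed_overlap(self):
        assert jaccard([mk_peak(0, 100)], [mk_peak(50, 150)]) == pytest.approx(
            50 / 150
        )

    def test_symmetric_on_random_sets(self):
        rng = np.random.default_rng(3)
        a = random_peaks(rng, 100)
        b = random_peaks(rng, 80)
        assert jaccard(a, b) == pytest.approx(jaccard(b, a))

    def test_empty_sets_give_zero(self):
        assert jaccard([], []) == 0.0

    def test_resize_recentres_intervals(self):
        # same centres after resize -> identical
        a = [mk_peak(100, 200)]
        b = [mk_peak(50, 250)]
        assert jaccard(a, b, resize_halfwidth=100) == 1.0

    def test_matches_base_level_oracle(self):
        rng = np.random.default_rng(13)
        a = random_peaks(rng, 150)
        b = random_peaks(rng, 150)
        ma = oracle_base_set([p.interval for p in a], 10_000)
        mb = oracle_base_set([p.interval for p in b], 10_000)
        expected = (ma & mb).sum() / (ma | mb).sum()
        assert jaccard(a, b) == pytest.approx(expected)


GENES = [
    GeneModel("gplus", "chr1", tss=10_000, strand="+",
              exons=((10_000, 10_200), (12_000, 12_300), (14_800, 15_000))),
    GeneModel("gminus", "chr1", tss=30_000, strand="-",
              exons=((25_000, 25_300), (29_800, 30_001))),
]


class TestAnnotateContext:
    @pytest.mark.parametrize(
        "summit,expected",
        [
            (9_500, "promoter"),    # 500 bp upstream of the + TSS
            (12_100, "exon"),
            (13_000, "intron"),
            (15_500, "TTS"),
            (50_000, "intergenic"),
            (29_700, "promoter"),   # within 1 kb of the - strand TSS
        ],
    )
    def test_summit_labels(self, summit, expected):
        peak = mk_peak(summit - 50, summit + 50, summit=summit)
        assert annotate_context([peak], GENES) == [expected]

    def test_labels_partition_random_peaks(self):
        rng = np.random.default_rng(23)
        peaks = random_peaks(rng, 200, span=60_000)
        labels = annotate_context(peaks, GENES)
        assert len(labels) == len(peaks)
        assert set(labels) <= {"promoter", "exon", "intron", "TTS", "intergenic"}


class TestRecurrentPromoterGenes:
    def make_sets(self, hits_per_label):
        out = []
        for lab, hit in hits_per_label.items():
            peaks = [mk_peak(9_400, 9_800, summit=9_600)] if hit else [
                mk_peak(40_000, 40_400)
            ]
            out.append((lab, peaks))
        return out

    def test_threshold_inclusion_and_exclusion(self):
        sets = self.make_sets(
            {f"L{i}": i < 4 for i in range(7)}  # 4 of 7 labels hit the promoter
        )
        out = recurrent_promoter_genes(sets, GENES, k=4)
        assert list(out.index) == ["gplus"]
        assert out.loc["gplus", "n_sets"] == 4
        out5 = recurrent_promoter_genes(sets, GENES, k=5)
        assert out5.empty

    def test_k_above_label_count_warns_empty(self):
        sets = self.make_sets({"L0": True})
        with pytest.warns(UserWarning):
            out = recurrent_promoter_genes(sets, GENES, k=2)
        assert out.empty

    def test_k1_matches_promoter_context_labels(self):
        rng = np.random.default_rng(31)
        peaks = random_peaks(rng, 300, span=40_000)
        labels = annotate_context(peaks, GENES)
        promoter_hit_expected = any(lab == "promoter" for lab in labels)
        out = recurrent_promoter_genes([("only", peaks)], GENES, k=1)
        assert (len(out) > 0) == promoter_hit_expected


class TestLinkAbc:
    CONNS = [
        AbcConnection(GenomicInterval("chr1", 0, 200), "g1", 0.02),
        AbcConnection(GenomicInterval("chr1", 0, 200), "g2", 0.01),   # low score
        AbcConnection(GenomicInterval("chr1", 160, 400), "g3", 0.5),  # 40 bp overlap
        AbcConnection(GenomicInterval("chr1", 0, 200), "g4", 0.03),
        AbcConnection(GenomicInterval("chr1", 0, 200), "g5", 0.03),
        AbcConnection(GenomicInterval("chr1", 0, 200), "g6", 0.03),
        AbcConnection(GenomicInterval("chr1", 0, 200), "g7", 0.9),
    ]

    def test_score_and_overlap_thresholds(self):
        links = link_abc([mk_peak(0, 200)], self.CONNS[:3])
        assert list(links["gene_id"]) == ["g1"]

    def test_top_three_by_score_with_lexical_ties(self):
        links = link_abc([mk_peak(0, 200)], self.CONNS)
        # g7 (0.9) then the 0.03 tie broken lexically: g4, g5
        assert list(links["gene_id"]) == ["g7", "g4", "g5"]


class TestOverlapComposition:
    SEG = [
        (GenomicInterval("chr1", 0, 500), "enhancer"),
        (GenomicInterval("chr1", 500, 2_000), "quiescent"),
    ]

    def test_peak_inside_single_state(self):
        peak_frac, _ = overlap_composition([mk_peak(100, 200)], self.SEG)
        assert peak_frac == {"enhancer": 1.0}

    def test_half_and_half(self):
        peak_frac, _ = overlap_composition([mk_peak(400, 600)], self.SEG)
        assert peak_frac == {"enhancer": 0.5, "quiescent": 0.5}

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(17)
        peaks = random_peaks(rng, 50, span=2_000)
        peak_frac, genome_frac = overlap_composition(peaks, self.SEG)
        assert sum(peak_frac.values()) == pytest.approx(1.0, abs=1e-9)
        assert sum(genome_frac.values()) == pytest.approx(1.0, abs=1e-9)

    def test_matches_base_counting_oracle(self):
        rng = np.random.default_rng(19)
        seg = []
        cursor = 0
        labels = ["s1", "s2", "s3"]
        while cursor < 9_000:
            ln = int(rng.integers(100, 600))
            lab = labels[int(rng.integers(0, 3))]
            # leave occasional unannotated gaps
            if rng.random() < 0.3:
                cursor += int(rng.integers(10, 200))
            seg.append((GenomicInterval("chr1", cursor, cursor + ln), lab))
            cursor += ln
        peaks = random_peaks(rng, 100, span=cursor)
        peak_frac, genome_frac = overlap_composition(peaks, seg)

        span = max(cursor, max(p.interval.end for p in peaks))
        state = np.array(["unannotated"] * span, dtype=object)
        for iv, lab in seg:
            state[iv.start : iv.end] = lab
        peak_mask = oracle_base_set([p.interval for p in peaks], span)
        for lab in set(state):
            exp_g = (state == lab).sum() / span
            assert genome_frac.get(lab, 0.0) == pytest.approx(exp_g)
            exp_p = ((state == lab) & peak_mask).sum() / peak_mask.sum()
            assert peak_frac.get(lab, 0.0) == pytest.approx(exp_p)


def test_interval_invariants():
    with pytest.raises(IntervalError):
        GenomicInterval("chr1", 10, 10)
    with pytest.raises(IntervalError):
        Peak(GenomicInterval("chr1", 0, 10), summit=10)
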