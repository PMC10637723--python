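"""Allelic/treatment statistics, FDR, concordance and preference summaries."""

import numpy as np
import pandas as pd
import pytest

from mpracensus.motif_scan import MotifHit, Variant, VariantMotifCall
from mpracensus.mpra_stats import (
    StatsError,
    af_divergence,
    allelic_effect_test,
    bh_adjust,
    concordance,
    enrichment_fold,
    floor_zeros,
    position_preference,
    treatment_effect_test,
)
from mpracensus.mpra_quant import SampleInfo


class TestAllelicEffect:
    def test_identical_alleles_null_result(self):
        act = np.array([[1.0, 2.0], [2.0, 1.0], [1.5, 1.5]])
        res = allelic_effect_test(act, act.copy(), rsid="x")
        assert res["log2fc"] == pytest.approx(0.0)
        assert res["p_value"] == pytest.approx(1.0)

    def test_planted_ratio_recovered_exactly_without_noise(self):
        ref = np.full((4, 3), 4.0)
        alt = np.full((4, 3), 1.0)
        res = allelic_effect_test(ref, alt)
        assert res["log2fc"] == pytest.approx(2.0)
        assert res["p_value"] == pytest.approx(0.0)

    def test_too_few_barcodes_is_untestable(self):
        res = allelic_effect_test(np.ones((1, 3)), np.ones((4, 3)))
        assert np.isnan(res["log2fc"]) and np.isnan(res["p_value"])

    def test_zero_activities_floored_and_flagged(self):
        ref = np.array([[0.0, 2.0], [1.0, 1.0]])
        alt = np.ones((2, 2))
        res = allelic_effect_test(ref, alt)
        assert res["floored"]
        assert np.isfinite(res["log2fc"])

    def test_all_zero_raises(self):
        with pytest.raises(StatsError):
            floor_zeros(np.zeros(4))


def oracle_bh(p):
    """Textbook step-up: sort, scale by m/rank, cumulative min from the top."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    scaled = p[order] * m / np.arange(1, m + 1)
    cummin = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(cummin, 1.0)
    return out


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_computed_ladder(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_matches_sort_and_cummin_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 50))
            assert bh_adjust(p) == pytest.approx(oracle_bh(p))

    def test_monotone_in_raw_ranks(self):
        rng = np.random.default_rng(1)
        p = np.sort(rng.uniform(size=30))
        fdr = bh_adjust(p)
        assert (np.diff(fdr) >= -1e-12).all()

    def test_nan_passthrough(self):
        out = bh_adjust([0.01, np.nan, 0.5])
        assert np.isnan(out[1]) and not np.isnan(out[0])


def call(rsid, category, intact):
    return VariantMotifCall(rsid, category, intact, {"ref": (), "alt": ()})


class TestConcordance:
    def frame(self, rows):
        return pd.DataFrame(rows, columns=["rsid", "log2fc", "fdr"])

    def test_intact_allele_higher_is_concordant(self):
        allelic = self.frame([("v1", -1.0, 0.01)])  # alt higher
        records, summary = concordance(allelic, {"v1": call("v1", "disruption", "alt")})
        assert records.iloc[0]["verdict"] == "concordant"
        assert summary["fraction_concordant"] == 1.0

    def test_intact_allele_lower_is_discordant(self):
        allelic = self.frame([("v1", 1.0, 0.01)])  # ref higher, intact alt
        records, _ = concordance(allelic, {"v1": call("v1", "disruption", "alt")})
        assert records.iloc[0]["verdict"] == "discordant"

    def test_switch_and_lenient_not_applicable(self):
        allelic = self.frame([("v1", 1.0, 0.001), ("v2", 1.0, 0.001)])
        calls = {
            "v1": call("v1", "switch", "both"),
            "v2": call("v2", "lenient_change", "both"),
        }
        records, summary = concordance(allelic, calls)
        assert set(records["verdict"]) == {"not_applicable"}
        assert summary["n_applicable"] == 0

    def test_nonsignificant_disruptions_count_in_denominator(self):
        allelic = self.frame([("v1", -2.0, 0.001), ("v2", -2.0, 0.9)])
        calls = {
            "v1": call("v1", "disruption", "alt"),
            "v2": call("v2", "disruption", "alt"),
        }
        _, summary = concordance(allelic, calls)
        assert summary["n_predicted_disrupting"] == 2
        assert summary["fraction_validated"] == 0.5

    def test_invariant_to_joint_relabelling(self):
        """Swapping ref/alt labels together with the log2FC sign flips nothing."""
        allelic = self.frame([("v1", 1.5, 0.01)])
        rec1, _ = concordance(allelic, {"v1": call("v1", "disruption", "ref")})
        flipped = self.frame([("v1", -1.5, 0.01)])
        rec2, _ = concordance(flipped, {"v1": call("v1", "disruption", "alt")})
        assert rec1.iloc[0]["verdict"] == rec2.iloc[0]["verdict"] == "concordant"


def hit(rsid, allele, pos, strand="+", motif="CEBP-ATF"):
    return MotifHit(rsid, allele, motif, strand, 0, "N" * 10, pos)


class TestPositionPreference:
    def test_pseudocount_arithmetic(self):
        # three variants, position 4, intact allele carries T (the motif base)
        sig = pd.DataFrame(
            {"rsid": ["a", "b", "c"], "log2fc": [1.0, 1.0, 1.0], "fdr": [0.0] * 3}
        )
        hits = [hit(r, "ref", 4) for r in "abc"]
        variants = {
            r: Variant(r, "T", alt, "C" * 9, "C" * 9)
            for r, alt in zip("abc", ["A", "C", "G"])
        }
        pref = position_preference(sig, hits, variants)
        t_row = "ACGT".index("T")
        assert pref.hi_counts[t_row, 3] == 3
        assert pref.log2_ratio[t_row, 3] == pytest.approx(np.log2(4 / 1))

    def test_balanced_counts_give_all_n(self):
        sig = pd.DataFrame(
            {"rsid": ["a", "b"], "log2fc": [1.0, -1.0], "fdr": [0.0, 0.0]}
        )
        hits = [hit("a", "ref", 5), hit("b", "ref", 5)]
        variants = {
            "a": Variant("a", "T", "G", "C" * 9, "C" * 9),
            "b": Variant("b", "T", "G", "C" * 9, "C" * 9),
        }
        pref = position_preference(sig, hits, variants)
        assert (pref.log2_ratio == 0).all()
        assert pref.preferred_10mer == "N" * 10

    def test_minus_strand_bases_are_complemented(self):
        sig = pd.DataFrame({"rsid": ["a"], "log2fc": [1.0], "fdr": [0.0]})
        hits = [hit("a", "ref", 2, strand="-")]
        variants = {"a": Variant("a", "A", "C", "G" * 9, "G" * 9)}
        pref = position_preference(sig, hits, variants)
        assert pref.hi_counts["ACGT".index("T"), 1] == 1  # complement of A

    def test_shared_position_used_when_both_alleles_hit(self):
        sig = pd.DataFrame({"rsid": ["a"], "log2fc": [-1.0], "fdr": [0.0]})
        hits = [
            hit("a", "ref", 1),
            hit("a", "alt", 1),
            MotifHit("a", "ref", "CEBP-ATF", "+", 3, "N" * 10, 7),
        ]
        variants = {"a": Variant("a", "G", "A", "C" * 9, "C" * 9)}
        pref = position_preference(sig, hits, variants)
        assert pref.hi_counts["ACGT".index("A"), 0] == 1
        assert pref.hi_counts.sum() == 1


class TestEnrichment:
    def test_hand_computed_two_fold(self):
        res = enrichment_fold(20, 100, 1000, 10_000)
        assert res.fold == pytest.approx(2.0)
        assert 0 <= res.p_value <= 1

    def test_degenerate_fold_of_one(self):
        res = enrichment_fold(50, 50, 200, 200)
        assert res.fold == pytest.approx(1.0)

    def test_undefined_fold_reported_missing(self):
        res = enrichment_fold(0, 0, 10, 100)
        assert np.isnan(res.fold)

    def test_inconsistent_table_rejected(self):
        with pytest.raises(StatsError):
            enrichment_fold(30, 20, 10, 100)

    def test_independent_annotation_is_null(self):
        rng = np.random.default_rng(4)
        folds, ps = [], []
        for _ in range(50):
            annotated = rng.random(4000) < 0.25
            flagged = rng.random(4000) < 0.20
            res = enrichment_fold(
                int((annotated & flagged).sum()),
                int(annotated.sum()),
                int(flagged.sum()),
                4000,
            )
            folds.append(res.fold)
            ps.append(res.p_value)
        assert np.mean(folds) == pytest.approx(1.0, abs=0.05)
        # p-values roughly uniform under the null
        assert 0.3 < np.mean(ps) < 0.7


class TestAfDivergence:
    def test_population_divergent_variant_flagged(self):
        table = pd.DataFrame(
            {"NFE": [0.026], "AFR": [0.279], "EAS": [0.003]}, index=["rs7011846"]
        )
        flags = af_divergence(table)
        row = flags.loc["rs7011846"]
        assert bool(row["common_and_rare"])
        assert bool(row["fold_up"])  # 0.279 / 0.026 > 5

    def test_uniform_frequencies_unflagged(self):
        table = pd.DataFrame({"NFE": [0.2], "AFR": [0.2], "EAS": [0.2]})
        row = af_divergence(table).iloc[0]
        assert not row["common_and_rare"]
        assert not row["fold_up"] and not row["fold_down"]

    def test_boundary_frequencies_use_strict_inequality(self):
        table = pd.DataFrame({"NFE": [0.05], "AFR": [0.05]})
        assert not af_divergence(table).iloc[0]["common_and_rare"]

    def test_zero_reference_leaves_fold_up_undefined(self):
        table = pd.DataFrame({"NFE": [0.0], "AFR": [0.3]})
        assert af_divergence(table).iloc[0]["fold_up"] is pd.NA


class TestTreatmentEffect:
    SAMPLES = [
        SampleInfo(f"rna_{c}_{r}", "RNA", c, r)
        for c in ("ctrl", "tun")
        for r in (1, 2, 3)
    ]

    def make_table(self, ctrl, tun):
        idx = pd.MultiIndex.from_tuples([("q0", "ref")], names=["query_id", "allele"])
        cols = [s.sample_id for s in self.SAMPLES]
        return pd.DataFrame([list(ctrl) + list(tun)], index=idx, columns=cols)

    def test_identical_conditions_null(self):
        table = self.make_table([1.0, 2.0, 1.5], [1.0, 2.0, 1.5])
        res = treatment_effect_test(table, self.SAMPLES)
        assert res.iloc[0]["log2fc"] == pytest.approx(0.0)

    def test_uniform_twofold_induction(self):
        table = self.make_table([1.0, 1.2, 0.9], [2.0, 2.4, 1.8])
        res = treatment_effect_test(table, self.SAMPLES)
        assert res.iloc[0]["log2fc"] == pytest.approx(1.0)
        assert res.iloc[0]["p_value"] < 0.01

    def test_missing_condition_reported_nan(self):
        table = self.make_table([1.0, 1.0, 1.0], [np.nan, np.nan, np.nan])
        res = treatment_effect_test(table, self.SAMPLES)
        assert np.isnan(res.iloc[0]["log2fc"])
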