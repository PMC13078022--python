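"""Pair-class framework, correlations, concordance and unit metrics."""

import numpy as np
import pytest

from mfclone.clonality import ClonalityResult, PairKey, score_all_pairs
from mfclone.similarity import (
    categorical_concordance,
    driver_alteration_count,
    enumerate_pair_classes,
    first_biopsy_filter,
    fraction_genome_altered,
    gene_set_score,
    profile_correlation,
    shared_mutation_fraction,
    tumor_mutational_burden,
    PairClassRecord,
    CLASS_CLONAL,
    CLASS_INTER,
    CLASS_NONCLONAL,
)
from mfclone.types import (
    BiopsySample,
    CopyNumberProfile,
    ExpressionProfile,
    GenomeBins,
)

import pandas as pd

from conftest import profile_from_labels


def _result(a, b, call):
    return ClonalityResult(pair=PairKey.make(a, b), score=0.4,
                           p_value=0.01 if call == "clonal" else 0.5,
                           n_perm=99, call=call, seed=0)


class TestEnumeratePairClasses:
    def test_classes_and_inter_sampling(self, sim_cohort):
        cohort, _ = sim_cohort
        results = score_all_pairs(cohort, n_perm=99, master_seed=3)
        records = enumerate_pair_classes(cohort, results, n_inter=10, seed=1)
        by_class = {}
        for r in records:
            by_class.setdefault(r.pair_class, []).append(r)
        assert len(by_class[CLASS_INTER]) == 10
        assert len(records) == len(results) + 10
        by_id = {s.biopsy_id: s for s in cohort.samples}
        for r in by_class[CLASS_INTER]:
            assert by_id[r.pair.biopsy_a].patient_id != by_id[r.pair.biopsy_b].patient_id
        for cls in (CLASS_CLONAL, CLASS_NONCLONAL):
            for r in by_class.get(cls, []):
                assert by_id[r.pair.biopsy_a].patient_id == by_id[r.pair.biopsy_b].patient_id

    def test_sampling_deterministic(self, sim_cohort):
        cohort, _ = sim_cohort
        results = score_all_pairs(cohort, n_perm=99, master_seed=3)
        r1 = enumerate_pair_classes(cohort, results, n_inter=10, seed=5)
        r2 = enumerate_pair_classes(cohort, results, n_inter=10, seed=5)
        assert [r.pair for r in r1] == [r.pair for r in r2]

    def test_too_many_inter_pairs_rejected(self, sim_cohort):
        cohort, _ = sim_cohort
        with pytest.raises(ValueError):
            enumerate_pair_classes(cohort, [], n_inter=10**6, seed=0)


class TestFirstBiopsyFilter:
    def _samples(self):
        mk = lambda b, n, t: BiopsySample(patient_id="P1", nodule_id=n,
                                          biopsy_id=b, tissue="tumor", timepoint=t)
        return [mk("a1", "N1", 0.0), mk("a2", "N1", 2.0), mk("b1", "N2", 1.0)]

    def test_keeps_first_first_pairs_only(self):
        samples = self._samples()
        records = [
            PairClassRecord(pair=PairKey.make("a1", "b1"), pair_class=CLASS_CLONAL),
            PairClassRecord(pair=PairKey.make("a2", "b1"), pair_class=CLASS_CLONAL),
        ]
        kept = first_biopsy_filter(records, samples)
        assert [r.pair.biopsy_a for r in kept] == ["a1"]

    def test_identity_on_single_biopsy_nodules(self):
        samples = [s for s in self._samples() if s.biopsy_id != "a2"]
        records = [PairClassRecord(pair=PairKey.make("a1", "b1"),
                                   pair_class=CLASS_CLONAL)]
        assert first_biopsy_filter(records, samples) == records


class TestProfileCorrelation:
    def test_identical_profiles(self):
        x = [1.0, 4.0, 2.0, 8.0]
        assert profile_correlation(x, x, "pearson") == pytest.approx(1.0)
        assert profile_correlation(x, x, "spearman") == pytest.approx(1.0)

    def test_hand_computed_spearman(self):
        # ranks of y against x=(1,2,3): d=(2,-1,-1) -> rho = 1 - 6*6/(3*8)
        assert profile_correlation([1, 2, 3], [3, 1, 2], "spearman") == pytest.approx(-0.5)

    def test_constant_profile_returns_missing(self):
        assert profile_correlation([1, 1, 1], [1, 2, 3], "pearson") is None

    def test_pearson_affine_invariance_spearman_monotone_invariance(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=20), rng.normal(size=20)
        r_p = profile_correlation(x, y, "pearson")
        assert profile_correlation(3 * x + 1, y, "pearson") == pytest.approx(r_p)
        r_s = profile_correlation(x, y, "spearman")
        assert profile_correlation(np.exp(x), y, "spearman") == pytest.approx(r_s)


class TestConcordance:
    def _pair(self, **kw):
        defaults = dict(patient_id="P1", tissue="tumor", timepoint=0.0)
        a = BiopsySample(biopsy_id="a", nodule_id="N1", **defaults, **kw.get("a", {}))
        b = BiopsySample(biopsy_id="b", nodule_id="N2", **defaults, **kw.get("b", {}))
        return a, b

    def test_grade_same_different_missing(self):
        a, b = self._pair(a={"grade": "II"}, b={"grade": "II"})
        assert categorical_concordance(a, b, "grade") == "same"
        a, b = self._pair(a={"grade": "II"}, b={"grade": "III"})
        assert categorical_concordance(a, b, "grade") == "different"
        a, b = self._pair(a={"grade": "II"})
        assert categorical_concordance(a, b, "grade") == "missing"

    def test_neighboring_liver_segments_count_as_same(self):
        a, b = self._pair(a={"liver_segment": 5}, b={"liver_segment": 6})
        assert categorical_concordance(a, b, "liver_segment") == "same"
        a, b = self._pair(a={"liver_segment": 2}, b={"liver_segment": 7})
        assert categorical_concordance(a, b, "liver_segment") == "different"

    def test_unknown_feature_rejected(self):
        a, b = self._pair()
        with pytest.raises(ValueError):
            categorical_concordance(a, b, "shoe_size")


class TestGenomicMetrics:
    def test_fga_all_neutral_zero_all_altered_one(self, small_bins):
        neutral = CopyNumberProfile(biopsy_id="b", bins=small_bins,
                                    states=np.full(5, 2))
        assert fraction_genome_altered(neutral) == 0.0
        altered = CopyNumberProfile(biopsy_id="b", bins=small_bins,
                                    states=np.full(5, 3))
        assert fraction_genome_altered(altered) == 1.0

    def test_fga_length_weighted(self):
        bins = GenomeBins(chroms=("1", "1"), starts=(0, 100), ends=(100, 400))
        # second bin is 3x longer; altering only it gives 300/400
        p = CopyNumberProfile(biopsy_id="b", bins=bins, states=np.array([2, 5]))
        assert fraction_genome_altered(p) == pytest.approx(0.75)

    def test_fga_invariant_to_bin_refinement(self):
        coarse = GenomeBins(chroms=("1",), starts=(0,), ends=(100,))
        fine = GenomeBins(chroms=("1", "1"), starts=(0, 40), ends=(40, 100))
        p_c = CopyNumberProfile(biopsy_id="b", bins=coarse, states=np.array([3]))
        p_f = CopyNumberProfile(biopsy_id="b", bins=fine, states=np.array([3, 3]))
        assert fraction_genome_altered(p_c) == fraction_genome_altered(p_f)

    def test_tmb(self, label_universe):
        calls, freqs = label_universe
        profile = profile_from_labels("b", ["v1", "v2"], freqs, calls)
        assert tumor_mutational_burden(profile, callable_mb=2.0) == pytest.approx(1.0)
        assert tumor_mutational_burden(70, callable_mb=35.0) == pytest.approx(2.0)
        with pytest.raises(ValueError):
            tumor_mutational_burden(profile, callable_mb=0.0)

    def test_driver_count_gene_level_dedup(self, label_universe):
        calls, freqs = label_universe
        # v1: CTNNB1, v2: TP53, v3: ALB, v4: no gene
        profile = profile_from_labels("b", ["v1", "v2", "v4"], freqs, calls)
        assert driver_alteration_count(profile.variants, ["CTNNB1", "TP53"]) == 2
        assert driver_alteration_count(profile.variants, ["ALB"]) == 0
        with pytest.raises(ValueError):
            driver_alteration_count(profile.variants, [])


class TestSharedMutationFraction:
    def _records_profiles(self, label_universe):
        calls, freqs = label_universe
        profiles = {
            "a1": profile_from_labels("a1", ["v1", "v2"], freqs, calls),  # CTNNB1, TP53
            "a2": profile_from_labels("a2", ["v1"], freqs, calls),        # CTNNB1
            "b1": profile_from_labels("b1", ["v2"], freqs, calls),        # TP53 (v2)
            "b2": profile_from_labels("b2", ["v3"], freqs, calls),        # ALB
        }
        records = [
            PairClassRecord(pair=PairKey.make("a1", "a2"), pair_class=CLASS_CLONAL),
            PairClassRecord(pair=PairKey.make("b1", "b2"), pair_class=CLASS_NONCLONAL),
        ]
        return records, profiles

    def test_pooled_and_per_pair_fractions(self, label_universe):
        records, profiles = self._records_profiles(label_universe)
        s = shared_mutation_fraction(records, profiles, ["CTNNB1", "TP53", "ALB"])
        # clonal pair a1/a2: v1 shared, v2 private -> pooled 1/2
        assert s.pooled_shared_fraction == pytest.approx(0.5)
        assert s.mean_pair_shared_fraction == pytest.approx(0.5)
        per_gene = s.per_gene.set_index("gene")
        assert per_gene.loc["CTNNB1", "shared_fraction"] == 1.0
        assert per_gene.loc["TP53", "shared_fraction"] == 0.0

    def test_same_gene_different_variant_detection(self, label_universe):
        calls, freqs = label_universe
        # two different TP53 variants: v2 and a second one
        from mfclone.types import VariantCall
        calls = dict(calls)
        calls["v6"] = VariantCall(chrom="2", pos=999, ref="A", alt="C", gene="TP53")
        freqs = dict(freqs, v6=0.05)
        profiles = {
            "x1": profile_from_labels("x1", ["v2"], freqs, calls),
            "x2": profile_from_labels("x2", ["v6"], freqs, calls),
            "y1": profile_from_labels("y1", ["v1"], freqs, calls),
            "y2": profile_from_labels("y2", ["v1"], freqs, calls),
        }
        records = [
            PairClassRecord(pair=PairKey.make("y1", "y2"), pair_class=CLASS_CLONAL),
            PairClassRecord(pair=PairKey.make("x1", "x2"), pair_class=CLASS_NONCLONAL),
        ]
        s = shared_mutation_fraction(records, profiles, ["CTNNB1", "TP53"])
        co = s.cooccurrence.set_index("pair_class")
        assert co.loc[CLASS_NONCLONAL, "same_gene_diff_variant"] == 1
        assert co.loc[CLASS_NONCLONAL, "any_driver"] == 1

    def test_no_clonal_pairs_rejected(self, label_universe):
        records, profiles = self._records_profiles(label_universe)
        only_non = [r for r in records if r.pair_class != CLASS_CLONAL]
        with pytest.raises(ValueError):
            shared_mutation_fraction(only_non, profiles, ["TP53"])


class TestGeneSetScore:
    def _profiles(self):
        genes = pd.Index(["g1", "g2", "g3"], name="gene_id")
        ref = [
            ExpressionProfile(biopsy_id=f"r{i}", values=pd.Series(v, index=genes))
            for i, v in enumerate([[0.0, 0, 0], [2.0, 2, 2], [4.0, 4, 4]])
        ]
        # reference per-gene mean 2, SD (population) sqrt(8/3)
        return genes, ref

    def test_reference_mean_scores_zero(self):
        genes, ref = self._profiles()
        p = ExpressionProfile(biopsy_id="t", values=pd.Series([2.0, 2, 2], index=genes))
        assert gene_set_score(p, ["g1", "g2"], ref) == pytest.approx(0.0)

    def test_one_sd_scores_one(self):
        genes, ref = self._profiles()
        sd = np.sqrt(8 / 3)
        p = ExpressionProfile(biopsy_id="t",
                              values=pd.Series([2 + sd, 2 + sd, 2.0], index=genes))
        assert gene_set_score(p, ["g1", "g2"], ref) == pytest.approx(1.0)

    def test_mean_of_gene_zscores(self):
        genes, ref = self._profiles()
        sd = np.sqrt(8 / 3)
        p = ExpressionProfile(biopsy_id="t",
                              values=pd.Series([2 + 2 * sd, 2.0, 2.0], index=genes))
        assert gene_set_score(p, ["g1", "g2"], ref) == pytest.approx(1.0)

    def test_absent_set_rejected(self):
        genes, ref = self._profiles()
        p = ExpressionProfile(biopsy_id="t", values=pd.Series([1.0, 1, 1], index=genes))
        with pytest.raises(ValueError):
            gene_set_score(p, ["nope"], ref)
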