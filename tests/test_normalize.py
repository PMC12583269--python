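"""Background subtraction, RPM scaling, housekeeping ratio, percentile
ranks and the low/moderate/high categorization."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from immunorank.normalize import (
    CATEGORY_HIGH,
    CATEGORY_LOW,
    CATEGORY_MODERATE,
    RawPanelCounts,
    ReferenceModel,
    ZeroDepthError,
    build_reference_model,
    categorize,
    compute_nrpm,
    normalization_ratio,
    percentile_rank,
    percentile_rank_vector,
    percentile_table,
    subtract_background,
    to_rpm,
)

HK = [f"HK{i}" for i in range(10)]


class TestSubtractBackground:
    @pytest.mark.parametrize(
        "sample,ntc,expected",
        [([100], [10], [90]), ([5], [9], [0]), ([0, 7, 3], [0, 7, 9], [0, 0, 0])],
    )
    def test_examples(self, sample, ntc, expected):
        np.testing.assert_array_equal(
            subtract_background(np.array(sample), np.array(ntc)), expected
        )

    def test_matches_elementwise_loop_oracle(self):
        rng = np.random.default_rng(0)
        s = rng.integers(0, 500, size=200)
        n = rng.integers(0, 50, size=200)
        oracle = np.array([max(si - ni, 0) for si, ni in zip(s, n)])
        np.testing.assert_array_equal(subtract_background(s, n), oracle)

    def test_rejects_length_mismatch_and_negatives(self):
        with pytest.raises(ValueError):
            subtract_background(np.array([1, 2]), np.array([1]))
        with pytest.raises(ValueError):
            subtract_background(np.array([-1]), np.array([0]))


class TestToRpm:
    def test_closed_form(self):
        np.testing.assert_allclose(
            to_rpm(np.array([1, 1, 2])), [250000.0, 250000.0, 500000.0]
        )

    def test_scale_invariance(self):
        v = np.array([3, 9, 18, 70])
        np.testing.assert_allclose(to_rpm(v), to_rpm(2 * v))

    def test_exact_rational_oracle(self):
        rng = np.random.default_rng(1)
        v = rng.integers(1, 10_000, size=40)
        total = int(v.sum())
        oracle = [float(Fraction(int(x) * 10**6, total)) for x in v]
        np.testing.assert_allclose(to_rpm(v), oracle, rtol=1e-12)

    def test_zero_depth(self):
        with pytest.raises(ZeroDepthError):
            to_rpm(np.zeros(5))


class TestNormalizationRatio:
    def test_identity(self):
        profile = {g: float(i + 1) for i, g in enumerate(HK)}
        assert normalization_ratio(profile, profile) == pytest.approx(1.0)

    def test_even_count_median_is_mean_of_central(self):
        profile = {"a": 1.0, "b": 1.0, "c": 1.0, "d": 1.0}
        sample = {"a": 0.5, "b": 1.0, "c": 2.0, "d": 4.0}
        assert normalization_ratio(sample, profile) == pytest.approx(1.5)

    def test_single_dropout_is_robust(self):
        profile = {g: 1.0 for g in HK}
        sample = {g: 1.0 for g in HK}
        sample[HK[0]] = 0.0
        assert normalization_ratio(sample, profile) == pytest.approx(1.0)

    def test_all_zero_sample_is_qc_failure(self):
        profile = {g: 1.0 for g in HK}
        with pytest.raises(ZeroDepthError):
            normalization_ratio({g: 0.0 for g in HK}, profile)


class TestComputeNrpm:
    def _model(self, profile_vals):
        ref = {g: np.array([0.0, 1.0]) for g in ["X", *HK]}
        return ReferenceModel(
            hk_genes=HK,
            hk_rpm_profile=dict(zip(HK, profile_vals)),
            reference_nrpm=ref,
            reference_size=2,
        )

    def test_ratio_one_identity(self):
        # counts chosen so HK RPMs equal the profile exactly
        genes = ["X", *HK]
        counts = np.array([100, *[10] * 10])  # total 200
        rpm = counts * 1e6 / 200
        model = self._model([rpm[i + 1] for i in range(10)])
        nrpm = compute_nrpm(counts, np.zeros(11, dtype=int), genes, model)
        np.testing.assert_allclose([nrpm[g] for g in genes], rpm)

    def test_depth_invariance(self):
        genes = ["X", *HK]
        counts = np.array([123, *np.arange(10, 110, 10)])
        ntc = np.array([3, *[1] * 10])
        model = self._model(np.linspace(100.0, 1000.0, 10))
        a = compute_nrpm(counts, ntc, genes, model)
        b = compute_nrpm(3 * counts, 3 * ntc, genes, model)
        for g in genes:
            assert a[g] == pytest.approx(b[g], rel=1e-12)

    def test_hand_worked_chain(self):
        """3 assay genes + 10 HK genes, worked with exact rationals."""
        genes = ["A", "B", "C", *HK]
        counts = np.array([120, 45, 5, *[100] * 10])
        ntc = np.array([20, 5, 9, *[0] * 10])
        adj = [100, 40, 0, *[100] * 10]  # background-subtracted, floored
        total = sum(adj)  # 1140
        rpm = [Fraction(x * 10**6, total) for x in adj]
        profile = [float(2 * r) for r in rpm[3:]]  # sample ratios all 1/2
        model = self._model(profile)
        nrpm = compute_nrpm(counts, ntc, genes, model)
        for g, r in zip(genes, rpm):
            assert nrpm[g] == pytest.approx(float(r / Fraction(1, 2)), rel=1e-12)


class TestPercentileRank:
    def test_below_all(self):
        assert percentile_rank(-1.0, np.array([1.0, 2.0])) == 0.0

    def test_midrank_single_element(self):
        assert percentile_rank(5.0, np.array([5.0])) == 50.0

    def test_counting_oracle_99(self):
        ref = np.arange(1.0, 100.0)
        assert percentile_rank(75.0, ref) == pytest.approx(100 * 74.5 / 99)

    def test_brute_force_counting_oracle(self):
        rng = np.random.default_rng(2)
        ref = np.sort(rng.integers(0, 20, size=57).astype(float))
        for q in rng.uniform(-2, 22, size=50):
            less = (ref < q).sum()
            equal = (ref == q).sum()
            assert percentile_rank(q, ref) == pytest.approx(
                100 * (less + 0.5 * equal) / ref.size
            )

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(st.floats(0, 100, allow_nan=False), min_size=1, max_size=30),
        st.floats(-10, 110, allow_nan=False),
        st.floats(0, 10, allow_nan=False),
    )
    def test_monotone_nondecreasing(self, ref, q, delta):
        ref = np.sort(np.asarray(ref))
        assert percentile_rank(q, ref) <= percentile_rank(q + delta, ref)

    def test_empty_reference(self):
        with pytest.raises(ValueError):
            percentile_rank(1.0, np.array([]))


class TestCategorize:
    @pytest.mark.parametrize(
        "rank,expected",
        [
            (75.0, CATEGORY_HIGH),
            (74.999, CATEGORY_MODERATE),
            (25.0, CATEGORY_MODERATE),
            (24.999, CATEGORY_LOW),
            (0.0, CATEGORY_LOW),
            (100.0, CATEGORY_HIGH),
        ],
    )
    def test_boundaries(self, rank, expected):
        assert categorize(rank) == expected

    def test_rejects_out_of_range(self):
        for bad in (-0.1, 100.1):
            with pytest.raises(ValueError):
                categorize(bad)


class TestReferenceModel:
    def test_json_round_trip_bit_identical(self, tiny_panel, tmp_path):
        _, model = tiny_panel
        path = tmp_path / "model.json"
        model.to_json(path)
        loaded = ReferenceModel.from_json(path)
        assert loaded.hk_genes == model.hk_genes
        assert loaded.hk_rpm_profile == model.hk_rpm_profile
        assert loaded.reference_size == model.reference_size
        for g in model.reference_nrpm:
            np.testing.assert_array_equal(loaded.reference_nrpm[g], model.reference_nrpm[g])

    def test_requires_ten_hk_genes(self):
        with pytest.raises(ValueError):
            ReferenceModel(
                hk_genes=["a"],
                hk_rpm_profile={"a": 1.0},
                reference_nrpm={"a": np.array([0.0, 1.0])},
                reference_size=2,
            )


class TestCohortRanking:
    def test_self_ranking_splits_quartiles(self, tiny_panel):
        raw, model = tiny_panel
        table, failures = percentile_table(raw, model)
        assert not failures
        # every gene's self-ranks are the mid-ranks of its own reference
        for gene, sub in table.groupby("gene"):
            assert sorted(sub["rank"]) == pytest.approx(
                sorted(
                    percentile_rank_vector(
                        np.sort(model.reference_nrpm[gene]), model.reference_nrpm[gene]
                    )
                )
            )

    def test_depth_invariance_of_table(self, tiny_panel):
        raw, model = tiny_panel
        scaled = RawPanelCounts(
            sample_ids=raw.sample_ids,
            gene_ids=raw.gene_ids,
            counts=raw.counts * 4,
            batch_of=raw.batch_of,
            ntc_of={b: v * 4 for b, v in raw.ntc_of.items()},
        )
        a, _ = percentile_table(raw, model)
        b, _ = percentile_table(scaled, model)
        np.testing.assert_allclose(a["nrpm"], b["nrpm"], rtol=1e-9)
        np.testing.assert_array_equal(a["rank"], b["rank"])

    def test_degenerate_reference_rejected(self):
        genes = ["X", *HK]
        counts = np.tile(np.array([50, *[100] * 10]), (5, 1))
        sids = [f"S{i}" for i in range(5)]
        raw = RawPanelCounts(
            sample_ids=sids,
            gene_ids=genes,
            counts=counts,
            batch_of={s: "b" for s in sids},
            ntc_of={"b": np.zeros(11, dtype=int)},
        )
        from immunorank.normalize import DegenerateReferenceError

        with pytest.raises(DegenerateReferenceError):
            build_reference_model(raw, HK)
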