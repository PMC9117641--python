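import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from strvar.errors import EmptySubsetError, InputError, InsufficientDataError, NormalizationError
from strvar.variability import (
    TIERS,
    classify,
    compute_rdi,
    decile_distribution,
    normal_range,
    normalize_rdi,
    repeat_histogram,
    score_loci,
    tier_proportions,
    trim_counts,
)

from oracles import population_sd_oracle, trim_oracle, trimmed_rdi_oracle

int_vectors = st.lists(st.integers(min_value=1, max_value=100),
                       min_size=2, max_size=80)


class TestTrimCounts:
    def test_one_to_twenty(self):
        kept, p5, p95 = trim_counts(list(range(1, 21)))
        assert (p5, p95) == (1, 19)
        assert kept == list(range(1, 20))  # 20 removed

    def test_degenerate_distribution(self):
        kept, p5, p95 = trim_counts([7] * 9)
        assert kept == [7] * 9
        assert (p5, p95) == (7, 7)

    def test_small_n_upper_outlier_removed(self):
        # 0.95*8 is non-integer, so the upper rank is capped at n-1 and the
        # lone maximum outlier is excluded (frozen from the trim oracle).
        assert trim_oracle([5, 5, 5, 5, 5, 5, 5, 100]) == ([5] * 7, 5, 5)
        kept, p5, p95 = trim_counts([5, 5, 5, 5, 5, 5, 5, 100])
        assert kept == [5] * 7
        assert (p5, p95) == (5, 5)

    def test_ties_at_bounds_retained(self):
        kept, p5, p95 = trim_counts([1, 1, 1, 9, 9, 9, 9, 9, 9, 9])
        assert p95 == 9 and 9 in kept

    def test_order_preserved(self):
        kept, _, _ = trim_counts([3, 1, 2, 3, 1, 2, 2, 3, 1, 2])
        assert kept == [3, 1, 2, 3, 1, 2, 2, 3, 1, 2]

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            trim_counts([5])

    @given(int_vectors)
    def test_matches_oracle(self, values):
        kept, p5, p95 = trim_counts(values)
        okept, op5, op95 = trim_oracle(values)
        assert (kept, p5, p95) == (okept, op5, op95)


class TestComputeRdi:
    def test_zero_dispersion(self):
        assert compute_rdi([7, 7, 7, 7]) == 0.0

    def test_half_split(self):
        assert compute_rdi([10, 10, 12, 12]) == pytest.approx(1.0)

    def test_one_to_five(self):
        assert compute_rdi([1, 2, 3, 4, 5]) == pytest.approx(math.sqrt(2))

    def test_divisor_is_n_not_n_minus_1(self):
        # sample SD of [1,3] is sqrt(2); population SD is 1
        assert compute_rdi([1, 3]) == pytest.approx(1.0)

    def test_empty_error(self):
        with pytest.raises(InsufficientDataError):
            compute_rdi([])

    @given(int_vectors, st.integers(min_value=-50, max_value=50))
    def test_shift_invariance(self, values, c):
        assert compute_rdi([v + c for v in values]) == pytest.approx(
            compute_rdi(values), abs=1e-9
        )

    @given(int_vectors, st.integers(min_value=1, max_value=10))
    def test_positive_scaling(self, values, k):
        assert compute_rdi([v * k for v in values]) == pytest.approx(
            k * compute_rdi(values), rel=1e-9
        )

    def test_pipeline_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            n = int(rng.integers(8, 201))
            values = rng.integers(1, 101, size=n).tolist()
            kept, _, _ = trim_counts(values)
            assert compute_rdi(kept) == pytest.approx(
                trimmed_rdi_oracle(values), abs=1e-12
            )


class TestNormalizeRdi:
    def test_three_distinct(self):
        assert normalize_rdi({"a": 0.1, "b": 0.5, "c": 0.9}) == pytest.approx(
            {"a": 0.0, "b": 0.5, "c": 1.0}
        )

    def test_midrank_ties(self):
        # midranks (1.5, 1.5, 3) -> ((r-1)/2) = (0.25, 0.25, 1.0)
        assert normalize_rdi({"a": 0.2, "b": 0.2, "c": 0.8}) == pytest.approx(
            {"a": 0.25, "b": 0.25, "c": 1.0}
        )

    def test_single_locus_error(self):
        with pytest.raises(NormalizationError):
            normalize_rdi({"a": 0.3})

    @given(st.dictionaries(st.text(min_size=1, max_size=4),
                           st.floats(min_value=0, max_value=100,
                                     allow_nan=False),
                           min_size=2, max_size=40))
    def test_range_and_monotonicity(self, rdis):
        nrdi = normalize_rdi(rdis)
        assert all(0.0 <= v <= 1.0 for v in nrdi.values())
        ids = list(rdis)
        for i in ids:
            for j in ids:
                if rdis[i] < rdis[j]:
                    assert nrdi[i] < nrdi[j]
                elif rdis[i] == rdis[j]:
                    assert nrdi[i] == nrdi[j]


class TestClassify:
    @pytest.mark.parametrize("value,tier", [
        (0.0, "vlSTR"), (0.1, "vlSTR"), (0.2, "lSTR"), (0.39, "lSTR"),
        (0.4, "mSTR"), (0.6, "hSTR"), (0.79, "hSTR"), (0.8, "vhSTR"),
        (0.85, "vhSTR"), (1.0, "vhSTR"),
    ])
    def test_bins(self, value, tier):
        assert classify(value) == tier

    def test_out_of_range(self):
        with pytest.raises(InputError):
            classify(1.01)
        with pytest.raises(InputError):
            classify(-0.01)

    def test_uniform_tier_counts_with_distinct_rdis(self):
        nrdi = normalize_rdi({f"L{i}": float(i) for i in range(1000)})
        props = tier_proportions(nrdi.values())
        assert np.allclose(props, 0.2, atol=1.5 / 1000)


class TestDecileDistribution:
    @staticmethod
    def records(nrdis):
        return pd.DataFrame({"locus_id": [f"L{i}" for i in range(len(nrdis))],
                             "nrdi": nrdis})

    def test_uniform_over_full_scored_set(self):
        nrdi = normalize_rdi({f"L{i}": float(i) for i in range(1000)})
        props = decile_distribution(self.records(list(nrdi.values())))
        assert props.sum() == pytest.approx(1.0)
        assert np.allclose(props, 0.1, atol=1.5 / 1000)

    def test_top_decile_subset(self):
        nrdis = [i / 99 for i in range(100)]
        frame = self.records(nrdis)
        top = {f"L{i}" for i in range(90, 100)}
        props = decile_distribution(frame, top)
        assert props[9] == pytest.approx(1.0)
        assert props[:9].sum() == 0

    def test_empty_subset_error(self):
        with pytest.raises(EmptySubsetError):
            decile_distribution(self.records([0.5, 0.6]), set())

    def test_unscored_loci_ignored(self):
        frame = self.records([0.05, np.nan, 0.95])
        props = decile_distribution(frame)
        assert props[0] == pytest.approx(0.5)
        assert props[9] == pytest.approx(0.5)


class TestNormalRange:
    def test_two_sided_hundred(self):
        assert normal_range(list(range(1, 101)), "two_sided") == (5, 95)

    def test_upper_trim_hundred(self):
        assert normal_range(list(range(1, 101)), "upper_trim") == (1, 95)

    def test_all_equal(self):
        assert normal_range([4] * 10, "two_sided") == (4, 4)
        assert normal_range([4] * 10, "upper_trim") == (4, 4)

    def test_unknown_mode(self):
        with pytest.raises(InputError):
            normal_range([1, 2, 3], "median")

    def test_insufficient(self):
        with pytest.raises(InsufficientDataError):
            normal_range([3], "two_sided")

    @given(int_vectors)
    def test_low_le_high(self, values):
        low, high = normal_range(values, "two_sided")
        assert low <= high
        low_u, high_u = normal_range(values, "upper_trim")
        assert low_u == min(values) and high_u == high


class TestRepeatHistogram:
    def test_pooled_bin(self):
        hist = repeat_histogram([5, 5, 5, 40])
        assert hist["5"] == pytest.approx(0.75)
        assert hist["30+"] == pytest.approx(0.25)

    def test_no_overflow(self):
        hist = repeat_histogram([1, 2, 30])
        assert hist["30+"] == 0.0

    def test_boundary_value_not_pooled(self):
        assert repeat_histogram([30] * 4)["30"] == pytest.approx(1.0)

    @given(st.lists(st.integers(min_value=1, max_value=60), min_size=1,
                    max_size=50))
    def test_sums_to_one(self, values):
        assert repeat_histogram(values).sum() == pytest.approx(1.0, abs=1e-9)


class TestScoreLoci:
    @pytest.fixture
    def genotypes(self):
        rng = np.random.default_rng(17)
        values = rng.integers(5, 40, size=(30, 20)).astype(float)
        frame = pd.DataFrame(values, index=[f"L{i:02d}" for i in range(30)],
                             columns=[f"s{j}" for j in range(20)])
        frame.iloc[0, :10] = np.nan  # 50% coverage -> unscored at 0.8
        return frame

    def test_min_fraction_rule(self, genotypes):
        records = score_loci(genotypes, min_fraction=0.8)
        assert np.isnan(records.loc["L00", "rdi"])
        assert records.loc["L00", "n_total"] == 10
        assert records["rdi"].notna().sum() == 29

    def test_min_fraction_configurable(self, genotypes):
        records = score_loci(genotypes, min_fraction=0.5)
        assert records["rdi"].notna().sum() == 30

    def test_nrdi_only_over_scored(self, genotypes):
        records = score_loci(genotypes)
        nrdi = records["nrdi"].dropna()
        assert nrdi.min() == 0.0 and nrdi.max() == 1.0
        assert set(records.loc[nrdi.index, "tier"]) <= set(TIERS)

    def test_matches_scalar_pipeline(self, genotypes):
        records = score_loci(genotypes)
        row = genotypes.loc["L05"].dropna().to_numpy()
        kept, p5, p95 = trim_counts(row)
        assert records.loc["L05", "rdi"] == pytest.approx(compute_rdi(kept))
        assert records.loc["L05", "p5"] == p5
        assert records.loc["L05", "p95"] == p95
        assert records.loc["L05", "n_used"] == len(kept)
        assert population_sd_oracle(kept) == pytest.approx(
            records.loc["L05", "rdi"], abs=1e-12
        )
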