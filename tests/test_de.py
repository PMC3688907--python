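from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from complexdyn.de import (
    DEFAULT_Q_MIN,
    de_call,
    noiseq_probability,
    normalize_median_deviation,
)
from complexdyn.errors import ConfigError, FormatError
from oracle_utils import brute_q


def counts_frame(values, samples=None):
    values = np.asarray(values, dtype=float)
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return pd.DataFrame(
        values,
        index=[f"T{i:03d}" for i in range(values.shape[0])],
        columns=samples,
    )


class TestNormalization:
    def test_single_sample_is_identity(self):
        counts = counts_frame([[3.0], [0.0], [7.0]])
        out = normalize_median_deviation(counts)
        pd.testing.assert_frame_equal(out, counts)

    def test_doubled_sample_offset_is_log_two(self):
        rng = np.random.default_rng(1)
        a = rng.lognormal(3, 1, 50)
        counts = counts_frame(np.column_stack([a, 2 * a]), ["a", "b"])
        out = normalize_median_deviation(counts)
        med_a = np.median(np.log(out["a"][out["a"] > 0]))
        med_b = np.median(np.log(out["b"][out["b"] > 0]))
        assert med_a == pytest.approx(med_b)
        # the doubled sample is scaled down by sqrt(2), the other up by sqrt(2)
        assert (out["b"] / out["a"]).median() == pytest.approx(1.0)

    def test_per_sample_medians_equal_after_normalization(self):
        rng = np.random.default_rng(2)
        counts = counts_frame(rng.lognormal(2, 1, (100, 5)) * rng.lognormal(0, 0.5, 5))
        out = normalize_median_deviation(counts)
        medians = [
            np.median(np.log(out[c][out[c] > 0])) for c in out.columns
        ]
        assert np.allclose(medians, medians[0])

    def test_zeros_stay_zero(self):
        counts = counts_frame([[0.0, 5.0], [2.0, 0.0], [3.0, 4.0]])
        out = normalize_median_deviation(counts)
        assert out.iloc[0, 0] == 0.0 and out.iloc[1, 1] == 0.0

    def test_all_zero_sample_is_an_error(self):
        counts = counts_frame([[0.0, 1.0], [0.0, 2.0]])
        with pytest.raises(FormatError):
            normalize_median_deviation(counts)


def two_group(counts, n_control, n_case):
    cols = list(counts.columns)
    return {s: ("control" if i < n_control else "case") for i, s in enumerate(cols)}


class TestProbability:
    def test_identical_group_means_give_zero_q(self):
        counts = counts_frame(
            [[10, 10, 10, 10], [5, 7, 5, 7]], ["c1", "c2", "k1", "k2"]
        )
        groups = two_group(counts, 2, 2)
        result = noiseq_probability(counts, groups)
        assert result.table.loc["T000", "M"] == 0.0
        assert result.table.loc["T000", "D"] == 0.0
        assert result.table.loc["T000", "q"] == 0.0

    def test_planted_eightfold_transcript_called(self):
        rng = np.random.default_rng(8)
        n = 300
        mu = rng.lognormal(5, 0.5, n)
        size = 1 / 0.02  # low dispersion
        data = np.empty((n, 10))
        for j in range(10):
            mean = mu.copy()
            if j >= 5:
                mean = mu.copy()
                mean[0] *= 8.0  # planted high-abundance 8-fold change
            p = size / (size + mean)
            data[:, j] = rng.negative_binomial(size, p)
        counts = counts_frame(data)
        groups = two_group(counts, 5, 5)
        result = noiseq_probability(counts, groups)
        assert result.table["q"].iloc[0] > 0.9
        assert "T000" in de_call(result, q_min=0.9)
        # verify against the explicit noise pool with a loop oracle
        row = result.table.iloc[0]
        expected = brute_q(
            [abs(row["M"])], [row["D"]], np.abs(result.noise_m), result.noise_d
        )[0]
        assert row["q"] == pytest.approx(expected)

    def test_q_matches_brute_force_on_all_transcripts(self):
        rng = np.random.default_rng(3)
        counts = counts_frame(rng.lognormal(3, 1, (40, 6)))
        groups = two_group(counts, 3, 3)
        result = noiseq_probability(counts, groups)
        expected = brute_q(
            np.abs(result.table["M"].to_numpy()),
            result.table["D"].to_numpy(),
            np.abs(result.noise_m),
            result.noise_d,
        )
        assert np.allclose(result.table["q"].to_numpy(), expected)

    def test_q_invariant_under_within_group_relabeling(self):
        rng = np.random.default_rng(4)
        counts = counts_frame(rng.lognormal(3, 1, (30, 6)))
        groups = two_group(counts, 3, 3)
        base = noiseq_probability(counts, groups)
        shuffled = counts[["s1", "s0", "s2", "s5", "s3", "s4"]]
        out = noiseq_probability(shuffled, groups)
        assert np.allclose(base.table["q"], out.table["q"])

    def test_label_swap_negates_m_preserves_d_and_q(self):
        rng = np.random.default_rng(5)
        counts = counts_frame(rng.lognormal(3, 1, (30, 6)))
        groups = two_group(counts, 3, 3)
        swapped = {
            s: ("case" if g == "control" else "control") for s, g in groups.items()
        }
        a = noiseq_probability(counts, groups)
        b = noiseq_probability(counts, swapped)
        assert np.allclose(a.table["M"], -b.table["M"])
        assert np.allclose(a.table["D"], b.table["D"])
        assert np.allclose(a.table["q"], b.table["q"])

    def test_singleton_groups_without_simulation_raise(self):
        counts = counts_frame([[1, 2], [3, 4]], ["a", "b"])
        groups = {"a": "control", "b": "case"}
        with pytest.raises(ConfigError, match="replicate"):
            noiseq_probability(counts, groups, simulate=False)

    def test_singleton_groups_auto_simulate(self):
        rng = np.random.default_rng(6)
        counts = counts_frame(rng.lognormal(4, 1, (50, 2)), ["a", "b"])
        groups = {"a": "control", "b": "case"}
        result = noiseq_probability(counts, groups, seed=1)
        assert result.mode == "simulated"
        assert ((result.table["q"] >= 0) & (result.table["q"] <= 1)).all()

    def test_simulation_is_seed_deterministic(self):
        rng = np.random.default_rng(7)
        counts = counts_frame(rng.lognormal(4, 1, (50, 2)), ["a", "b"])
        groups = {"a": "control", "b": "case"}
        a = noiseq_probability(counts, groups, seed=11)
        b = noiseq_probability(counts, groups, seed=11)
        assert np.allclose(a.table["q"], b.table["q"])


class TestDECall:
    def test_threshold_and_monotonicity(self):
        rng = np.random.default_rng(9)
        counts = counts_frame(rng.lognormal(3, 1, (30, 6)))
        result = noiseq_probability(counts, two_group(counts, 3, 3))
        sets = [de_call(result, q_min=q) for q in (0.5, 0.8, 0.9, 0.99)]
        for smaller, larger in zip(sets[1:], sets[:-1]):
            assert smaller <= larger

    def test_simple_vector_thresholding(self):
        table = pd.DataFrame(
            {"M": [1, 1], "D": [1, 1], "q": [0.95, 0.5]}, index=["A", "B"]
        )
        from complexdyn.de import DEResult

        result = DEResult(
            table=table,
            noise_m=np.zeros(1),
            noise_d=np.zeros(1),
            groups=pd.Series(dtype=str),
            mode="replicate",
        )
        assert de_call(result, q_min=0.9) == {"A"}
        assert de_call(result, q_min=0.99) == frozenset()

    def test_dataset_defaults_match_declared_thresholds(self):
        assert DEFAULT_Q_MIN == {
            "breast": 0.9,
            "colon": 0.9,
            "lung": 0.99,
            "prostate": 0.8,
        }

    def test_q_min_validation(self):
        table = pd.DataFrame({"M": [1], "D": [1], "q": [0.5]}, index=["A"])
        from complexdyn.de import DEResult

        result = DEResult(
            table=table,
            noise_m=np.zeros(1),
            noise_d=np.zeros(1),
            groups=pd.Series(dtype=str),
            mode="replicate",
        )
        with pytest.raises(ConfigError):
            de_call(result, q_min=1.5)
        with pytest.raises(ConfigError):
            de_call(result)
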