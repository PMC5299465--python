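import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from assayrepeat import (
    ReplicateTable,
    anova_decompose,
    ba_repeatability_coefficient,
    decompose_all,
    estimate_dynamic_range,
    repeatability,
    simulate_dataset,
    truncate_negative,
    SimulationConfig,
)
from assayrepeat.errors import DataError, DesignError, DomainError


def oracle_anova(groups):
    """Definitional sums-of-squares oracle, written independently of the
    implementation (explicit loops, no shared code path)."""
    all_vals = [v for g in groups for v in g]
    N = len(all_vals)
    I = len(groups)
    grand = sum(all_vals) / N
    ssw = 0.0
    msb_acc = 0.0
    sq_n = 0
    for g in groups:
        m = sum(g) / len(g)
        ssw += sum((v - m) ** 2 for v in g)
        msb_acc += len(g) * (m - grand) ** 2
        sq_n += len(g) ** 2
    msw = ssw / (N - I)
    msb = msb_acc / (I - 1)
    n0p = (N - sq_n / N) / (I - 1)
    return (msb - msw) / n0p, msw, grand


class TestAnovaDecompose:
    def test_worked_unbalanced_example(self):
        cells = {"A": (1.0, 1.2), "B": (2.0, 2.2), "C": (3.1,)}
        v_b, v_e, mean = anova_decompose(cells)
        assert v_e == pytest.approx(0.02)
        assert v_b == pytest.approx(0.8625)
        assert mean == pytest.approx(1.9)

    def test_zero_within_sample_spread(self):
        cells = {"A": (1.0, 1.0), "B": (2.0, 2.0)}
        _, v_e, _ = anova_decompose(cells)
        assert v_e == 0.0

    def test_negative_v_b_when_means_coincide(self):
        cells = {"A": (0.0, 2.0), "B": (1.5, 0.5)}
        v_b, v_e, _ = anova_decompose(cells)
        assert v_e > 0
        assert v_b < 0

    def test_preconditions(self):
        with pytest.raises(DesignError):
            anova_decompose({"A": (1.0, 1.1)})
        with pytest.raises(DesignError):
            anova_decompose({"A": (1.0,), "B": (2.0,)})
        with pytest.raises(DataError):
            anova_decompose({"A": (1.0, np.nan), "B": (2.0, 2.1)})

    def test_agrees_with_oracle_on_random_unbalanced_designs(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            I = rng.integers(2, 12)
            sizes = rng.integers(1, 5, size=I)
            while sizes.max() < 2:
                sizes = rng.integers(1, 5, size=I)
            groups = [rng.normal(rng.normal(0, 2), 1, size=s).tolist() for s in sizes]
            cells = {f"s{i}": g for i, g in enumerate(groups)}
            got = anova_decompose(cells)
            want = oracle_anova(groups)
            for g, w in zip(got, want):
                assert g == pytest.approx(w, rel=1e-10, abs=1e-12)


class TestScalarOps:
    @pytest.mark.parametrize("v,expect", [(-0.013, 0.0), (0.5, 0.5), (0.0, 0.0)])
    def test_truncate_negative(self, v, expect):
        assert truncate_negative(v) == expect

    def test_truncate_rejects_non_finite(self):
        with pytest.raises(DataError):
            truncate_negative(float("nan"))

    @pytest.mark.parametrize(
        "v_b,v_e,expect",
        [(0.3, 0.0, 1.0), (0.0, 0.2, 0.0), (0.8625, 0.02, 0.8625 / 0.8825), (0.0, 0.0, 0.0)],
    )
    def test_repeatability_values(self, v_b, v_e, expect):
        assert repeatability(v_b, v_e) == pytest.approx(expect)

    def test_repeatability_rejects_negative(self):
        with pytest.raises(DomainError):
            repeatability(-0.1, 0.2)

    @given(
        v_b=st.floats(0.0, 10.0), v_e=st.floats(1e-6, 10.0),
        bump=st.floats(1e-6, 5.0),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_repeatability_monotone(self, v_b, v_e, bump):
        # within float tolerance: increasing in v_b, decreasing in v_e
        assert repeatability(v_b + bump, v_e) >= repeatability(v_b, v_e) - 1e-12
        if v_b > 0:
            assert repeatability(v_b, v_e + bump) <= repeatability(v_b, v_e) + 1e-12

    def test_repeatability_strictly_monotone_on_grid(self):
        grid = np.linspace(0.05, 2.0, 20)
        along_vb = [repeatability(v, 0.3) for v in grid]
        along_ve = [repeatability(0.3, v) for v in grid]
        assert np.all(np.diff(along_vb) > 0)
        assert np.all(np.diff(along_ve) < 0)

    @pytest.mark.parametrize(
        "v_e,expect", [(0.5, 1.96), (0.0, 0.0), (0.06, 1.96 * math.sqrt(0.12))]
    )
    def test_ba_coefficient(self, v_e, expect):
        assert ba_repeatability_coefficient(v_e) == pytest.approx(expect, abs=1e-4)

    def test_ba_coefficient_rejects_negative(self):
        with pytest.raises(DomainError):
            ba_repeatability_coefficient(-1.0)


class TestDynamicRange:
    def test_equal_means_give_zero(self):
        assert estimate_dynamic_range([2.0, 2.0, 2.0], [0.0, 0.0, 0.0]) == 0.0

    def test_two_point_variance(self):
        assert estimate_dynamic_range([0.0, 2.0], [0.0, 0.0]) == pytest.approx(2.0)

    def test_correction_subtracted_and_truncated(self):
        assert estimate_dynamic_range([0.0, 2.0], [0.5, 0.5]) == pytest.approx(1.5)
        assert estimate_dynamic_range([0.0, 0.1], [1.0, 1.0]) == 0.0

    def test_requires_two_analytes(self):
        with pytest.raises(DesignError):
            estimate_dynamic_range([1.0], [0.0])

    def test_recovers_true_v_d_on_simulation(self):
        config = SimulationConfig(
            p=1624, n_samples=69, n_replicated=69, v_d=3.57,
            v_b_law=0.05, v_e_law=0.07, seed=11,
        )
        table, _ = simulate_dataset(config)
        dec, _ = decompose_all(table)
        # MC sd of a variance estimate from p analytes ~ v_d*sqrt(2/p) ~ 0.125
        assert dec.v_d == pytest.approx(3.57, abs=3 * 3.57 * math.sqrt(2 / 1624))


class TestDecomposeAll:
    def test_zero_noise_gives_R_one(self):
        from conftest import identical_replicate_table

        table = identical_replicate_table(p=15, seed=3)
        dec, prof = decompose_all(table)
        assert np.allclose(dec.v_e, 0.0)
        assert np.allclose(prof.R, 1.0)

    def test_parameter_recovery_mean_R(self):
        config = SimulationConfig(
            p=500, n_samples=200, n_replicated=200, v_d=2.0,
            v_b_law=0.05, v_e_law=0.05, seed=5,
        )
        table, _ = simulate_dataset(config)
        _, prof = decompose_all(table)
        assert abs(float(np.mean(prof.R)) - 0.5) < 0.05

    def test_failing_analyte_excluded_not_fatal(self, small_frame):
        # analyte m9 observed on a single sample: inestimable, must be flagged
        extra = pd.DataFrame(
            [("m9", "s1", 1, 1.0), ("m9", "s1", 2, 1.1)],
            columns=["analyte_id", "sample_id", "replicate_id", "value"],
        )
        table = ReplicateTable.from_frame(pd.concat([small_frame, extra]))
        dec, prof = decompose_all(table)
        assert "m9" in prof.excluded
        assert len(prof) == 3
        assert set(dec.analyte_ids) == {"m1", "m2", "m3"}

    def test_truncation_bias_upward_at_zero_signal(self):
        config = SimulationConfig(
            p=400, n_samples=60, n_replicated=60, v_d=1.0,
            v_b_law=0.0, v_e_law=0.05, seed=9,
        )
        table, _ = simulate_dataset(config)
        dec, _ = decompose_all(table)
        assert float(np.mean(dec.v_b)) > 0.0        # truncated estimates
        assert abs(float(np.mean(dec.v_b_raw))) < 0.01  # raw ones stay centred

    def test_averages_are_exact_means(self, pilot_table):
        table, _ = pilot_table
        dec, _ = decompose_all(table)
        assert dec.v_b_bar == pytest.approx(float(np.mean(dec.v_b)), rel=1e-14)
        assert dec.v_e_bar == pytest.approx(float(np.mean(dec.v_e)), rel=1e-14)
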