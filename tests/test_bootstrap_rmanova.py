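"""Bootstrap pairwise ANOVA: resampling contracts, enumeration oracles,
percentile CIs and the zero-in-CI significance rule."""

from itertools import product

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from evaphysio import (
    BootstrapSpec,
    bootstrap_replicate,
    observed_lsd,
    pairwise_all,
    pairwise_ci,
    pairwise_from_strata,
)
from evaphysio.bootstrap_rmanova import replicate_level_means


def case_means(values_by_task, parameter="HR"):
    rows = []
    for task, vals in values_by_task.items():
        for i, v in enumerate(vals):
            rows.append(
                {
                    "participant": 1,
                    "deployment": "ID",
                    "eva": 0,
                    "task_code": task,
                    "occurrence_index": i + 1,
                    "parameter": parameter,
                    "mean_value": float(v),
                    "n_samples": 60,
                }
            )
    return pd.DataFrame(rows)


class TestSpec:
    def test_tail_percentiles(self):
        lo, hi = BootstrapSpec(n_replicates=100_000, ci_level=99.98).tail_percentiles
        assert lo == pytest.approx(0.01) and hi == pytest.approx(99.99)

    def test_thin_tails_warn(self):
        with pytest.warns(UserWarning, match="order statistics"):
            BootstrapSpec(n_replicates=2000, ci_level=99.98)

    def test_invalid_level_rejected(self):
        with pytest.raises(ValueError):
            BootstrapSpec(ci_level=100.0)


class TestObservedLsd:
    def test_sign_convention_first_minus_second(self):
        m = case_means({"ET": [10, 20], "EO": [5]})
        assert observed_lsd(m, "ET", "EO") == 10.0
        assert observed_lsd(m, "EO", "ET") == -10.0

    def test_same_task_is_zero(self):
        m = case_means({"ET": [10, 20]})
        assert observed_lsd(m, "ET", "ET") == 0.0

    def test_absent_task_yields_nan_not_error(self):
        m = case_means({"ET": [10.0]})
        assert np.isnan(observed_lsd(m, "ET", "EI"))

    @given(
        st.lists(st.floats(-100, 100), min_size=1, max_size=10),
        st.lists(st.floats(-100, 100), min_size=1, max_size=10),
    )
    def test_antisymmetry(self, a, b):
        m = case_means({"ET": a, "EO": b})
        assert observed_lsd(m, "ET", "EO") == pytest.approx(
            -observed_lsd(m, "EO", "ET"), abs=1e-9
        )


class TestReplicates:
    def test_per_stratum_counts_preserved(self, rng):
        strata = {"ET": np.arange(7.0), "EO": np.arange(3.0), "BR": np.array([5.0])}
        rep = bootstrap_replicate(strata, rng)
        assert {t: len(v) for t, v in rep.items()} == {"ET": 7, "EO": 3, "BR": 1}
        for t, v in rep.items():
            assert set(v) <= set(strata[t])

    def test_singleton_stratum_is_degenerate(self, rng):
        rep = bootstrap_replicate({"BR": np.array([4.2])}, rng)
        assert rep["BR"].tolist() == [4.2]

    def test_three_point_stratum_matches_exhaustive_enumeration(self, rng):
        # all 27 equally likely with-replacement draws of a 3-point stratum
        v = np.array([1.0, 2.0, 4.0])
        enum_means = [np.mean(t) for t in product(v, repeat=3)]
        enum_vals, enum_counts = np.unique(np.round(enum_means, 9), return_counts=True)
        B = 100_000
        sim = replicate_level_means([v], B, rng)[:, 0]
        sim_counts = np.array(
            [(np.abs(sim - x) < 1e-9).sum() for x in enum_vals]
        )
        from scipy.stats import chisquare

        res = chisquare(sim_counts, B * enum_counts / 27)
        assert sim_counts.sum() == B
        assert res.pvalue > 0.01


class TestPairwiseCi:
    def test_degenerate_identical_means(self):
        m = case_means({t: [50.0, 50.0] for t in ("ET", "EO", "BR")})
        spec = BootstrapSpec(n_replicates=200, ci_level=95.0, seed=1)
        out = pairwise_ci(m, spec, case_id=1, parameter="HR")
        done = out[out["n_a"] > 0]
        performed = done[done["n_b"] > 0]
        assert (performed["lsd"] == 0).all()
        assert (performed["ci_low"] == 0).all() and (performed["ci_high"] == 0).all()
        assert not performed["significant"].any()

    def test_all_15_contrasts_emitted_with_6_levels(self, rng):
        m = case_means({t: rng.normal(80, 5, 10) for t in ("Base", "ET", "EO", "EI", "BR", "BS")})
        spec = BootstrapSpec(n_replicates=500, ci_level=95.0, seed=0)
        out = pairwise_ci(m, spec)
        assert len(out) == 15
        assert out["lsd"].notna().all()

    def test_unperformed_task_leaves_blank_rows(self, rng):
        m = case_means({t: rng.normal(80, 5, 10) for t in ("Base", "ET", "EO", "BR", "BS")})
        out = pairwise_ci(m, BootstrapSpec(n_replicates=500, ci_level=95.0, seed=0))
        assert len(out) == 15
        ei_rows = out[(out["task_a"] == "EI") | (out["task_b"] == "EI")]
        assert ei_rows["lsd"].isna().all()
        assert not ei_rows["significant"].any()

    def test_single_level_case_skipped(self, rng):
        m = case_means({"ET": rng.normal(size=5)})
        out = pairwise_ci(m, BootstrapSpec(n_replicates=100, ci_level=95.0, seed=0))
        assert out.empty

    def test_seed_determinism(self, rng):
        m = case_means({"ET": rng.normal(80, 5, 8), "EO": rng.normal(75, 5, 8)})
        spec = BootstrapSpec(n_replicates=1000, ci_level=95.0, seed=42)
        pd.testing.assert_frame_equal(pairwise_ci(m, spec), pairwise_ci(m, spec))

    def test_percentile_nesting_same_draws(self, rng):
        m = case_means({"ET": rng.normal(80, 5, 12), "EO": rng.normal(75, 5, 12)})
        def row(spec):
            out = pairwise_ci(m, spec)
            return out[out["contrast"] == "EO-ET"].iloc[0]

        wide = row(BootstrapSpec(n_replicates=2000, ci_level=99.0, seed=9))
        narrow = row(BootstrapSpec(n_replicates=2000, ci_level=90.0, seed=9))
        assert wide["ci_low"] <= narrow["ci_low"] <= narrow["ci_high"] <= wide["ci_high"]

    def test_separated_strata_significant(self, rng):
        m = case_means({"ET": rng.normal(100, 1, 25), "EO": rng.normal(80, 1, 25)})
        out = pairwise_ci(m, BootstrapSpec(n_replicates=5000, ci_level=99.0, seed=2))
        row = out[out["contrast"] == "EO-ET"].iloc[0]
        # EO sits 20 units below ET, so the EO-ET difference is negative
        assert row["significant"] and row["ci_high"] < 0
        assert row["lsd"] == pytest.approx(-20, abs=1)

    def test_ci_on_small_data_matches_exhaustive_enumeration(self):
        # every with-replacement resample of two 4-point strata (4^4 x 4^4
        # outcomes) gives the exact replicate-difference distribution
        a = np.array([0.0, 1.0, 2.0, 3.0])
        b = np.array([0.5, 1.5, 2.5, 4.0])
        means_a = np.array([np.mean(t) for t in product(a, repeat=4)])
        means_b = np.array([np.mean(t) for t in product(b, repeat=4)])
        # canonical orientation is EO-ET: mean(EO stratum) - mean(ET stratum)
        diffs = (means_b[:, None] - means_a[None, :]).ravel()
        exact_lo, exact_hi = np.percentile(diffs, [2.5, 97.5])
        spec = BootstrapSpec(n_replicates=100_000, ci_level=95.0, seed=3)
        res = pairwise_from_strata({"ET": a, "EO": b}, spec)[0]
        assert (res.task_a, res.task_b) == ("EO", "ET")
        rng_width = diffs.max() - diffs.min()
        assert abs(res.ci_low - exact_lo) <= 0.02 * rng_width
        assert abs(res.ci_high - exact_hi) <= 0.02 * rng_width

    def test_pairwise_all_isolated_per_case_seed(self, means):
        from evaphysio import assemble_cases

        cases = assemble_cases(means)
        spec = BootstrapSpec(n_replicates=300, ci_level=95.0, seed=5)
        first = pairwise_all(means, cases, spec)
        again = pairwise_all(means, cases.sample(frac=1, random_state=0), spec)
        merged = first.merge(
            again, on=["case_id", "parameter", "contrast"], suffixes=("_1", "_2")
        )
        assert len(merged) == len(first)
        np.testing.assert_allclose(merged["ci_low_1"], merged["ci_low_2"])
        np.testing.assert_allclose(merged["ci_high_1"], merged["ci_high_2"])
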