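"""Effect-size computation: d_s, d_av, Hedges correction, orientation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from metamem import AnalysisConfig
from metamem.effects import (DegenerateInputError, OutcomeSelectionError,
                             cohens_d_between, cohens_d_within_av, compute_effect,
                             compute_effect_table, hedges_correct, orient_sign,
                             select_outcome)


class TestBetween:
    def test_null_effect(self):
        eff = cohens_d_between(5.0, 2.0, 20, 5.0, 3.0, 20)
        assert eff.g == 0.0
        assert eff.v == pytest.approx(40 / 400)

    def test_worked_example(self):
        eff = cohens_d_between(10, 4, 20, 8, 4, 20)
        assert eff.g == pytest.approx(0.5)
        assert eff.v == pytest.approx(0.103125)
        assert eff.df == 38

    def test_unequal_n_equal_means(self):
        eff = cohens_d_between(5, 1, 10, 5, 1, 30)
        assert eff.v == pytest.approx(40 / 300)

    def test_zero_pooled_sd_raises(self):
        with pytest.raises(DegenerateInputError):
            cohens_d_between(1, 0.0, 10, 2, 0.0, 10)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(d=st.floats(-3, 3), n=st.integers(2, 200))
    def test_variance_minimised_at_null(self, d, n):
        base = cohens_d_between(0, 1, n, 0, 1, n).v
        shifted = cohens_d_between(d, 1, n, 0, 1, n).v
        assert shifted >= base


class TestWithinAv:
    def test_worked_example(self):
        eff = cohens_d_within_av(0.5, 1.2, 0.8, 20, 0.5)
        assert eff.g == pytest.approx(0.5)
        assert eff.v == pytest.approx(0.05625)
        assert eff.df == 19

    def test_zero_diff(self):
        assert cohens_d_within_av(0.0, 1, 1, 10, 0.3).g == 0.0

    def test_perfect_correlation_kills_variance(self):
        assert cohens_d_within_av(0.5, 1, 1, 10, 1.0).v == 0.0

    def test_zero_average_sd_raises(self):
        with pytest.raises(DegenerateInputError):
            cohens_d_within_av(0.5, 0.0, 0.0, 10, 0.5)


class TestHedges:
    def test_worked_example_df38(self):
        eff = hedges_correct(cohens_d_between(10, 4, 20, 8, 4, 20))
        assert eff.J == pytest.approx(1 - 3 / 151)
        assert eff.g == pytest.approx(0.5 * (1 - 3 / 151))
        assert eff.v == pytest.approx(0.103125 * (1 - 3 / 151) ** 2)

    def test_correction_vanishes_asymptotically(self):
        eff = hedges_correct(cohens_d_between(10, 4, 100000, 8, 4, 100000))
        assert eff.J == pytest.approx(1.0, abs=1e-5)
        assert eff.g == pytest.approx(eff.d_raw, rel=1e-4)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(d=st.floats(-3, 3).filter(lambda x: abs(x) > 1e-6),
           n=st.integers(3, 500))
    def test_strict_shrinkage_for_finite_df(self, d, n):
        eff = hedges_correct(cohens_d_within_av(d, 1, 1, n, 0.5))
        assert abs(eff.g) < abs(eff.d_raw)
        assert 0 < eff.J < 1


class TestSelectOutcome:
    @pytest.mark.parametrize("candidates,winner", [
        (["accuracy-at-test", "rt-at-test"], "accuracy-at-test"),
        (["rt-retention", "accuracy-retention"], "accuracy-retention"),
        (["d-prime", "proportion-correct"], "d-prime"),
        (["rt-at-test"], "rt-at-test"),
    ])
    def test_hierarchy(self, candidates, winner):
        assert select_outcome(candidates) == winner

    def test_pairs_carry_payload(self):
        chosen = select_outcome([("rt-at-test", 1), ("accuracy-at-test", 2)])
        assert chosen == ("accuracy-at-test", 2)

    def test_unrecognised_labels_raise(self):
        with pytest.raises(OutcomeSelectionError):
            select_outcome(["banana"])
        with pytest.raises(OutcomeSelectionError):
            select_outcome([])


class TestOrientation:
    def test_lower_better_flips(self):
        eff = cohens_d_between(8, 4, 20, 10, 4, 20)  # deprivation slower (RT)
        oriented = orient_sign(eff, "lower_better")
        assert oriented.g > 0
        assert oriented.v == eff.v

    def test_zero_unchanged(self):
        eff = cohens_d_between(5, 1, 10, 5, 1, 10)
        assert orient_sign(eff, "lower_better").g == 0.0

    def test_unknown_direction_raises(self):
        with pytest.raises(ValueError):
            orient_sign(cohens_d_between(5, 1, 10, 5, 1, 10), "sideways")

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(m1=st.floats(-5, 5), m2=st.floats(-5, 5))
    def test_label_swap_antisymmetry(self, m1, m2):
        """Swapping groups and flipping direction leaves oriented g fixed."""
        a = orient_sign(cohens_d_between(m1, 1, 20, m2, 1, 20), "higher_better")
        b = orient_sign(cohens_d_between(m2, 1, 20, m1, 1, 20), "lower_better")
        assert a.g == pytest.approx(b.g, abs=1e-12)


class TestEffectTable:
    def test_matches_per_record_ops(self, toy_summary_dataset, cfg):
        ds = compute_effect_table(toy_summary_dataset, cfg)
        for rec_in, rec_out in zip(toy_summary_dataset.records, ds.records):
            eff = compute_effect(rec_in, cfg)
            assert rec_out.g == pytest.approx(eff.g)
            assert rec_out.v == pytest.approx(eff.v)

    def test_precomputed_rows_pass_through(self, cfg):
        from conftest import make_gv_dataset
        ds = make_gv_dataset([0.1, 0.2], [0.04, 0.05])
        out = compute_effect_table(ds, cfg)
        assert [r.g for r in out.records] == [0.1, 0.2]
        assert [r.v for r in out.records] == [0.04, 0.05]

    def test_within_missing_r_uses_config_default(self):
        from metamem import EffectSizeRecord, StudyDataset
        rec = EffectSizeRecord("r", "r.1", "within",
                               m1=1.0, sd1=1.0, n1=20, m2=0.5, sd2=1.0)
        ds = StudyDataset([rec])
        v_half = compute_effect_table(ds, AnalysisConfig(default_r_within=0.5)).records[0].v
        v_zero = compute_effect_table(ds, AnalysisConfig(default_r_within=0.0)).records[0].v
        assert v_zero == pytest.approx(2 * v_half)
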