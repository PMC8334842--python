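"""Fisher-Z transforms, sampling variances, SMD conversion, table building."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings as hyp_settings
from hypothesis import strategies as st

from phylometa import effect_sizes as es


class TestFisherZ:
    def test_zero_is_fixed_point(self):
        assert es.fisher_z(0.0) == 0.0
        assert es.inv_fisher_z(0.0) == 0.0

    def test_half_log_three(self):
        # atanh(0.5) = 0.5 * ln(3)
        assert es.fisher_z(0.5) == pytest.approx(0.549306, abs=1e-6)
        assert es.inv_fisher_z(0.549306) == pytest.approx(0.5, abs=1e-6)

    @pytest.mark.parametrize("r", [0.1, 0.3, 0.9])
    def test_antisymmetry(self, r):
        assert es.fisher_z(-r) == -es.fisher_z(r)

    def test_round_trip_grid(self):
        for r in np.linspace(-0.999, 0.999, 100):
            assert es.inv_fisher_z(es.fisher_z(r)) == pytest.approx(r, abs=1e-12)

    @given(st.floats(-0.999, 0.999))
    @hyp_settings(max_examples=50, deadline=None)
    def test_round_trip_property(self, r):
        assert es.inv_fisher_z(es.fisher_z(r)) == pytest.approx(r, abs=1e-12)

    def test_boundary_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            z = es.fisher_z(1.0)
        assert math.isfinite(z) and z > 6

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            es.fisher_z(1.5)
        with pytest.raises(ValueError):
            es.inv_fisher_z(float("nan"))


class TestSamplingVariance:
    @pytest.mark.parametrize("n,expected", [(4, 1.0), (103, 0.01)])
    def test_values(self, n, expected):
        assert es.sampling_variance(n) == expected

    @pytest.mark.parametrize("n", [10, 50])
    def test_weight_is_n_minus_3(self, n):
        assert 1.0 / es.sampling_variance(n) == pytest.approx(n - 3)

    def test_small_n_instructs_exclusion(self):
        with pytest.raises(ValueError, match="exclude"):
            es.sampling_variance(3)


class TestSmdToR:
    def test_equal_means_give_zero(self):
        eff = es.smd_to_r(1.0, 1.0, 0.5, 0.5, 10, 10)
        assert eff.zr_depression == 0.0

    def test_hand_worked_example(self):
        # means 0 vs 1, sd 1, n = 10 per group: d = -1 exactly,
        # a = 400/100 = 4, r = -1/sqrt(5); orientation flips the sign
        eff = es.smd_to_r(0.0, 1.0, 1.0, 1.0, 10, 10)
        r_expected = 1.0 / math.sqrt(5.0)
        assert es.inv_fisher_z(eff.zr_depression) == pytest.approx(r_expected, abs=1e-10)
        assert eff.zr_depression > 0  # inbreeding reduced fitness here

    def test_doubling_balanced_groups_keeps_r(self):
        e1 = es.smd_to_r(0.2, 0.8, 1.0, 1.0, 10, 10)
        e2 = es.smd_to_r(0.2, 0.8, 1.0, 1.0, 20, 20)
        assert es.inv_fisher_z(e1.zr_depression) == pytest.approx(
            es.inv_fisher_z(e2.zr_depression), abs=1e-12)

    def test_against_arbitrary_precision_oracle(self):
        # recompute d, a, r, v_d and the delta-method variance in sympy
        import sympy as sp

        rng = np.random.default_rng(42)
        for _ in range(20):
            m1, m2 = rng.normal(0, 2, 2)
            s1, s2 = rng.uniform(0.2, 3, 2)
            n1, n2 = rng.integers(2, 60, 2)
            eff = es.smd_to_r(m1, m2, s1, s2, n1, n2)
            M1, M2, S1, S2 = [sp.Float(x, 30) for x in (m1, m2, s1, s2)]
            N1, N2 = sp.Integer(int(n1)), sp.Integer(int(n2))
            sp_pool = sp.sqrt(((N1 - 1) * S1 ** 2 + (N2 - 1) * S2 ** 2) / (N1 + N2 - 2))
            d = (M1 - M2) / sp_pool
            a = (N1 + N2) ** 2 / (N1 * N2)
            r = d / sp.sqrt(d ** 2 + a)
            vd = sp.Rational(1, 1) * (N1 + N2) / (N1 * N2) + d ** 2 / (2 * (N1 + N2))
            drdd = a / (d ** 2 + a) ** sp.Rational(3, 2)
            vz = (drdd ** 2 * vd) / (1 - r ** 2) ** 2
            z = -sp.atanh(r)
            assert eff.zr_depression == pytest.approx(float(z), abs=1e-10)
            assert eff.var == pytest.approx(float(vz), rel=1e-10)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError):
            es.smd_to_r(0, 1, 0.0, 0.0, 10, 10)
        with pytest.raises(ValueError):
            es.smd_to_r(0, 1, 1.0, 1.0, 1, 10)


def _row(species="sp1", **kw):
    base = dict(
        species_id=species, class_name="Aves", r_pairs=0.1, n_pairs=20,
        r_average=0.05, n_average=50, depression_reported="yes",
        mechanism="none", random_mating="no", cooperative="no", year=2005,
        dep_r=np.nan, dep_n=np.nan, dep_mean_in=np.nan, dep_sd_in=np.nan,
        dep_n_in=np.nan, dep_mean_out=np.nan, dep_sd_out=np.nan,
        dep_n_out=np.nan, fitness_category="",
    )
    base.update(kw)
    return base


class TestBuildSpeciesTable:
    def test_duplicate_populations_averaged_on_r_scale(self):
        raw = pd.DataFrame([
            _row(r_pairs=0.10), _row(r_pairs=0.20),
            _row(species="sp2", r_pairs=0.3),
        ])
        out = es.build_species_table(raw)
        assert len(out) == 2
        merged = out[out.species_id == "sp1"].iloc[0]
        assert merged.r_pairs == pytest.approx(0.15)
        assert merged.zr_pairs == pytest.approx(math.atanh(0.15), abs=1e-12)

    def test_conflicting_categoricals_raise(self):
        raw = pd.DataFrame([
            _row(mechanism="none"), _row(mechanism="active_mate_choice"),
        ])
        with pytest.raises(ValueError, match="sp1"):
            es.build_species_table(raw)

    def test_not_mentioned_recoded_nondestructively(self):
        raw = pd.DataFrame([_row(depression_reported="not_mentioned")])
        out = es.build_species_table(raw)
        assert out.depression_analysis.iloc[0] == "yes"
        assert out.depression_reported.iloc[0] == "not_mentioned"

    def test_variance_columns_are_inverse_n_minus_3(self):
        raw = pd.DataFrame([_row(), _row(species="sp2", n_pairs=8, n_average=13)])
        out = es.build_species_table(raw)
        assert np.allclose(out.var_pairs, 1.0 / (out.n_pairs - 3))
        assert np.allclose(out.var_average, 1.0 / (out.n_average - 3))

    def test_mechanism_without_depression_flags(self):
        raw = pd.DataFrame([
            _row(depression_reported="no", mechanism="sex_biased_dispersal"),
        ])
        with pytest.warns(UserWarning, match="mechanism"):
            es.build_species_table(raw)

    def test_unknown_level_raises(self):
        raw = pd.DataFrame([_row(mechanism="telepathy")])
        with pytest.raises(ValueError, match="telepathy"):
            es.build_species_table(raw)

    def test_depression_effect_from_correlation(self):
        raw = pd.DataFrame([_row(dep_r=-0.4, dep_n=23)])
        out = es.build_species_table(raw)
        assert out.zr_depression.iloc[0] == pytest.approx(math.atanh(0.4), abs=1e-12)
        assert out.var_depression.iloc[0] == pytest.approx(1.0 / 20)

    def test_synthetic_table_passes_cleanly(self, synthetic_dataset):
        raw, table, _, _ = synthetic_dataset
        assert len(table) == len(raw) == 41
        assert not es.validate_species_table(raw)

    def test_idempotent_on_clean_table(self, synthetic_dataset):
        _, table, _, _ = synthetic_dataset
        again = es.build_species_table(table)
        pd.testing.assert_frame_equal(
            again[table.columns].reset_index(drop=True), table)
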