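import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from robustrbe.grids import ScalarGrid, UnitError
from robustrbe.radiobiology import (CONSTANT_RBE, EQDParams, P0, P1, P2, P3,
                                    RBEParams, convert_constraint_table,
                                    eqd_convert, rbe_mcnamara,
                                    rbe_weighted_dose)
from robustrbe.metrics import d95_percent


def oracle_rbe(dose_per_fx: float, letd: float, ab: float) -> float:
    """Scalar closed-form evaluation, written independently of the
    vectorized implementation (math module, explicit steps)."""
    rbe_max = P0 + P1 * letd / ab
    rbe_min = P2 + P3 * math.sqrt(ab) * letd
    if rbe_min < 0:
        rbe_min = 0.0
    if dose_per_fx == 0:
        return rbe_max
    disc = (ab * ab + 4.0 * dose_per_fx * ab * rbe_max
            + 4.0 * dose_per_fx ** 2 * rbe_min ** 2)
    return (math.sqrt(disc) - ab) / (2.0 * dose_per_fx)


class TestMcNamara:
    def test_zero_let_reduces_to_fit_intercepts(self):
        d, ab = 2.0, 3.0
        expected = (math.sqrt(ab * ab + 4 * d * ab * P0
                              + 4 * d * d * P2 * P2) - ab) / (2 * d)
        assert rbe_mcnamara(d, 0.0, ab) == pytest.approx(expected, rel=1e-12)

    def test_low_alpha_beta_gives_higher_rbe(self):
        assert rbe_mcnamara(2.0, 8.0, 2.0) > rbe_mcnamara(2.0, 8.0, 10.0)

    def test_matches_scalar_oracle_on_grid(self):
        doses = np.linspace(0.0, 6.0, 10)
        lets = np.linspace(0.0, 15.0, 10)
        abs_ = np.linspace(0.5, 10.0, 10)
        D, L, A = np.meshgrid(doses, lets, abs_, indexing="ij")
        ours = rbe_mcnamara(D, L, A)
        for i in np.ndindex(D.shape):
            assert ours[i] == pytest.approx(
                oracle_rbe(D[i], L[i], A[i]), rel=1e-12, abs=1e-12)

    def test_zero_dose_limit_is_rbe_max(self):
        assert rbe_mcnamara(0.0, 6.0, 2.0) == pytest.approx(
            P0 + P1 * 6.0 / 2.0, rel=1e-12)

    @given(st.floats(0.1, 6.0), st.floats(1.0, 15.0), st.floats(0.5, 10.0))
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_monotone_increasing_in_let(self, d, L, ab):
        assert rbe_mcnamara(d, L + 0.5, ab) >= rbe_mcnamara(d, L, ab) - 1e-12

    @given(st.floats(0.1, 6.0), st.floats(1.0, 15.0), st.floats(0.5, 9.0))
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_monotone_decreasing_in_alpha_beta(self, d, L, ab):
        assert rbe_mcnamara(d, L, ab + 0.5) <= rbe_mcnamara(d, L, ab) + 1e-12

    def test_large_dose_asymptote_is_rbe_min(self):
        L, ab = 8.0, 2.0
        rbe_min = max(P2 + P3 * math.sqrt(ab) * L, 0.0)
        assert rbe_mcnamara(1e5, L, ab) == pytest.approx(rbe_min, rel=1e-3)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            rbe_mcnamara(-1.0, 2.0, 2.0)
        with pytest.raises(ValueError):
            rbe_mcnamara(1.0, 2.0, 0.0)


class TestWeightedDose:
    def test_constant_model_is_exactly_1p1(self, nominal, adult_phantom):
        n_fx = adult_phantom.prescription.n_fractions
        g = rbe_weighted_dose(nominal.dose, None,
                              RBEParams("constant_1p1"), n_fx)
        assert np.allclose(g.values,
                           nominal.dose.values * n_fx * CONSTANT_RBE,
                           rtol=0, atol=1e-12)
        assert g.unit == "Gy(RBE)"

    def test_variable_rbe_raises_ctv_dose_above_constant(self, nominal,
                                                         adult_phantom):
        n_fx = adult_phantom.prescription.n_fractions
        var = rbe_weighted_dose(nominal.dose, nominal.letd,
                                RBEParams("mcnamara", 2.0), n_fx,
                                excluded=nominal.let_excluded)
        const = rbe_weighted_dose(nominal.dose, None,
                                  RBEParams("constant_1p1"), n_fx)
        ctv = adult_phantom.structures["CTV"]
        assert var.values[ctv].mean() > const.values[ctv].mean()

    def test_excluded_voxels_fall_back_to_1p1(self, nominal, adult_phantom):
        n_fx = adult_phantom.prescription.n_fractions
        var = rbe_weighted_dose(nominal.dose, nominal.letd,
                                RBEParams("mcnamara", 2.0), n_fx,
                                excluded=nominal.let_excluded)
        exc = nominal.let_excluded
        assert np.allclose(var.values[exc],
                           nominal.dose.values[exc] * n_fx * 1.1,
                           rtol=0, atol=1e-12)

    def test_tumor_alpha_beta_override_lowers_target_d95(self, nominal,
                                                         adult_phantom):
        presc = adult_phantom.prescription
        ctv = adult_phantom.structures["CTV"]
        common = dict(excluded=nominal.let_excluded)
        matched = rbe_weighted_dose(nominal.dose, nominal.letd,
                                    RBEParams("mcnamara", 2.0),
                                    presc.n_fractions, **common)
        override = rbe_weighted_dose(nominal.dose, nominal.letd,
                                     RBEParams("mcnamara", 2.0),
                                     presc.n_fractions,
                                     override={"CTV": 10.0},
                                     structures=adult_phantom.structures,
                                     **common)
        assert d95_percent(override, ctv, presc) \
            < d95_percent(matched, ctv, presc)

    def test_unit_mismatch_rejected(self, adult_phantom):
        g = ScalarGrid(np.ones(adult_phantom.grid_shape), "Gy(RBE)",
                       adult_phantom.voxel_size)
        with pytest.raises(UnitError):
            rbe_weighted_dose(g, None, RBEParams("constant_1p1"), 39)


class TestEQDConvert:
    def test_identity_when_fractionation_matches(self):
        assert eqd_convert(EQDParams(60.0, 2.0, 2.0, 3.0)) == 60.0

    def test_adult_scheme_conversion_value(self):
        # 60 Gy(RBE) at 2 Gy/fx moved to the 1.67 Gy(RBE)/fx scheme,
        # (a/b)x = 2: direct arithmetic gives 60 * 2 / 1.835
        d1 = 65.13 / 39
        out = eqd_convert(EQDParams(60.0, 2.0, d1, 2.0))
        assert out == pytest.approx(65.39509536784741, rel=1e-12)

    def test_large_alpha_beta_limit(self):
        out = eqd_convert(EQDParams(60.0, 2.0, 1.67, 1e6))
        assert abs(out - 60.0) / 60.0 < 1e-3

    @given(st.floats(10.0, 80.0), st.floats(1.0, 4.0), st.floats(1.0, 4.0),
           st.floats(0.5, 10.0))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_roundtrip_recovers_source_constraint(self, D2, d2, d1, ab):
        D1 = eqd_convert(EQDParams(D2, d2, d1, ab))
        back = eqd_convert(EQDParams(D1, d1, d2, ab))
        assert back == pytest.approx(D2, rel=1e-12)

    def test_invalid_alpha_beta_rejected(self):
        with pytest.raises(ValueError):
            EQDParams(60.0, 2.0, 2.0, 0.0)

    def test_constraint_table_conversion(self):
        d1 = 65.13 / 39
        table = convert_constraint_table(d1)
        assert set(table["structure"]) >= {"brainstem", "optic_chiasm"}
        # hypofractionated source (2 Gy) moved to a finer scheme: limits rise
        assert (table["D1_gy_rbe"] > table["D2_gy_rbe"]).all()
        row = table.set_index("structure").loc["brainstem"]
        assert row["D1_gy_rbe"] == pytest.approx(
            eqd_convert(EQDParams(row["D2_gy_rbe"], 2.0, d1, 2.0)))
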