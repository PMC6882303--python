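import numpy as np
import pytest

from robustrbe.grids import LET_UNIT, ScalarGrid, UnitError
from robustrbe.proton_dose import (ALPHA_CM_MEV, P_EXPONENT, BeamSpec,
                                   PlanningError, ProtonPlan,
                                   compute_plan_letd, default_star_beams,
                                   pristine_curve, sobp_weights)


def oracle_track_let(depth_cm, range_cm):
    """Independent LET oracle: residual energy from the power-law
    range-energy relation R = alpha E^p integrated to depth, LET as the
    local dE/dx (keV/um).  Coded from scratch, no straggling."""
    import math
    out = []
    for z in np.atleast_1d(depth_cm):
        r = range_cm - z
        if r <= 0:
            out.append(float("nan"))
            continue
        energy = (r / ALPHA_CM_MEV) ** (1.0 / P_EXPONENT)
        dedx_mev_cm = energy / (P_EXPONENT * r)
        out.append(dedx_mev_cm * 0.1)
    return np.array(out)


class TestPristineCurve:
    @pytest.mark.parametrize("range_cm", [2.0, 5.0, 10.0, 15.0, 25.0, 35.0])
    def test_contract(self, range_cm):
        c = pristine_curve(range_cm)
        z, d, L = c.depth_cm, c.dose, c.let_kev_um
        # peak at the requested range
        assert abs(z[d.argmax()] - range_cm) <= 0.2
        # entrance LET in the physical window
        assert 0.3 <= L[0] <= 1.5
        # LET at the distal-80% dose depth is end-of-range-like
        post = d[d.argmax():]
        j80 = d.argmax() + np.nonzero(post < 0.8)[0][0]
        assert L[j80] >= 5.0
        # negligible dose beyond the straggling falloff
        tail = d[z > range_cm * 1.06 + 0.3]
        if tail.size:
            assert tail.max() < 1e-3
        # LET rises monotonically over the last 80% of range
        sel = (z >= 0.2 * range_cm) & (z <= range_cm)
        assert np.all(np.diff(L[sel]) > 0)
        assert L[0] < L[d.argmax()]

    def test_let_matches_stopping_power_oracle(self):
        c = pristine_curve(10.0)
        sel = (c.depth_cm >= 0.5) & (c.depth_cm <= 8.5)
        ours = c.let_kev_um[sel]
        ref = oracle_track_let(c.depth_cm[sel], 10.0)
        assert np.all(np.abs(ours - ref) / ref < 0.10)

    def test_range_bounds_enforced(self):
        with pytest.raises(ValueError):
            pristine_curve(0.5)
        with pytest.raises(ValueError):
            pristine_curve(40.0)


class TestSOBP:
    def test_degenerate_single_peak(self):
        w, r = sobp_weights(10.0, 0.0, 1)
        assert np.array_equal(w, [1.0])
        assert np.array_equal(r, [10.0])

    @pytest.mark.parametrize("range_cm,mod_cm,n", [
        (12.0, 4.0, 12), (10.0, 6.0, None), (6.0, 2.0, None)])
    def test_plateau_flat_within_2pct(self, range_cm, mod_cm, n):
        w, ranges = sobp_weights(range_cm, mod_cm, n)
        assert (w >= 0).all()
        # independent composition on a fresh depth grid
        sigma = 0.012 * range_cm
        z = np.arange(0.0, range_cm + 1.0, 0.02)
        comp = sum(
            wk * pristine_curve(rk, 0.2, sigma_cm=sigma,
                                max_depth_cm=z[-1] + 0.05).dose_at(z)
            for wk, rk in zip(w, ranges))
        sel = (z >= range_cm - mod_cm + 0.2) & (z <= range_cm - 0.3)
        plateau = comp[sel]
        assert np.abs(plateau - plateau.mean()).max() / plateau.mean() <= 0.02

    @pytest.mark.parametrize("range_cm,mod_cm", [(12.0, 4.0), (8.0, 3.0)])
    def test_distal_peak_heaviest(self, range_cm, mod_cm):
        w, ranges = sobp_weights(range_cm, mod_cm)
        assert ranges[0] == max(ranges)
        assert w.argmax() == 0

    def test_least_squares_oracle_cannot_do_much_better(self):
        """The returned weights achieve a plateau deviation within a factor
        ~2 of an independently solved bounded least-squares fit."""
        from scipy.optimize import lsq_linear
        range_cm, mod_cm, n = 12.0, 4.0, 12
        w, ranges = sobp_weights(range_cm, mod_cm, n)
        sigma = 0.012 * range_cm
        z = np.arange(0.0, range_cm + 1.0, 0.05)
        A = np.column_stack([
            pristine_curve(r, 0.5, sigma_cm=sigma,
                           max_depth_cm=z[-1] + 0.1).dose_at(z)
            for r in ranges])
        sel = (z >= range_cm - mod_cm + 0.2) & (z <= range_cm - 0.3)
        ref = lsq_linear(A[sel], np.ones(int(sel.sum())),
                         bounds=(0, np.inf)).x

        def dev(weights):
            p = A[sel] @ weights
            return np.abs(p - p.mean()).max() / p.mean()

        assert dev(w) <= max(2.0 * dev(ref), 0.02)

    def test_infeasible_flatness_reported(self):
        with pytest.raises(PlanningError):
            sobp_weights(12.0, 6.0, n_peaks=3)  # far too sparse a stack


class TestPlan:
    def test_median_ctv_rbe11_hits_prescription(self, adult_phantom,
                                                nominal):
        presc = adult_phantom.prescription
        med = np.median(nominal.dose.values[adult_phantom.structures["CTV"]])
        assert med * 1.1 == pytest.approx(presc.per_fraction_gy_rbe,
                                          rel=0.005)

    def test_weight_scaling_invariance(self, adult_phantom, nominal):
        beams = [BeamSpec(b.gantry_angle, b.couch_angle,
                          field_weight=2.0 * b.field_weight)
                 for b in default_star_beams()]
        doubled = ProtonPlan(adult_phantom, beams=beams).nominal()
        assert np.allclose(doubled.dose.values, nominal.dose.values,
                           rtol=1e-9, atol=1e-12)

    def test_single_beam_axis_follows_sobp_curve(self, water_phantom,
                                                 single_beam_plan):
        nom = single_beam_plan.nominal()
        fm = single_beam_plan.fields[0]
        shape = water_phantom.grid_shape
        i, k = shape[0] // 2, shape[2] // 2
        axis_dose = nom.dose.values[i, :, k]
        ys = water_phantom.voxel_centers_mm()[1]
        # water-equivalent depth from the anterior grid face
        wed_cm = (ys - ys[0] + water_phantom.voxel_size[1] / 2.0) / 10.0
        z, dcurve, _ = fm.depth_curves()
        expected = np.interp(wed_cm, z, dcurve, right=0.0)
        # proportionality holds tightly away from the steep distal falloff,
        # where voxel-scale resampling dominates
        sel = (expected > 0.05) & (wed_cm < fm.range_cm - 0.3)
        ratio = axis_dose[sel] / expected[sel]
        assert ratio.std() / ratio.mean() < 0.01

    def test_empty_beam_list_rejected(self, adult_phantom):
        with pytest.raises(PlanningError):
            ProtonPlan(adult_phantom, beams=[])

    def test_plan_parameters_serializable(self, adult_plan):
        import json
        blob = json.dumps(adult_plan.to_dict())
        assert "fields" in json.loads(blob)


@pytest.fixture(scope="module")
def pristine_plan(water_phantom):
    beam = BeamSpec(0.0, 0.0, sobp_range_cm=10.0, modulation_cm=0.0)
    return ProtonPlan(water_phantom, beams=[beam])


class TestLETd:
    def test_two_equal_contributions_average(self):
        d = [np.full((4, 4, 4), 1.0), np.full((4, 4, 4), 1.0)]
        L = [np.full((4, 4, 4), 2.0), np.full((4, 4, 4), 6.0)]
        grid, excluded = compute_plan_letd(d, L, (2.0, 2.0, 2.0))
        assert np.allclose(grid.values, 4.0)
        assert not excluded.any()

    def test_threshold_excludes_exactly_below_half_percent(self):
        rng = np.random.default_rng(0)
        d1 = rng.uniform(0, 1.0, (6, 6, 6))
        d2 = rng.uniform(0, 1.0, (6, 6, 6))
        d1[0, 0, :] = 1e-5  # force sub-threshold voxels
        d2[0, 0, :] = 1e-5
        L1 = rng.uniform(1, 5, (6, 6, 6))
        L2 = rng.uniform(1, 10, (6, 6, 6))
        grid, excluded = compute_plan_letd([d1, d2], [L1, L2],
                                           (2.0, 2.0, 2.0))
        total = d1 + d2
        assert np.array_equal(excluded, total < 0.005 * total.max())
        assert (grid.values[excluded] == 0).all()

    def test_matches_bruteforce_accumulation_oracle(self):
        rng = np.random.default_rng(42)
        shape = (5, 6, 7)
        ds = [rng.uniform(0, 2, shape) for _ in range(3)]
        Ls = [rng.uniform(0.5, 12, shape) for _ in range(3)]
        grid, excluded = compute_plan_letd(ds, Ls, (3.0, 3.0, 3.0))
        # voxel-by-voxel python accumulation, written independently
        tot = np.zeros(shape)
        num = np.zeros(shape)
        for d, L in zip(ds, Ls):
            for idx in np.ndindex(shape):
                tot[idx] += d[idx]
                num[idx] += d[idx] * L[idx]
        thresh = 0.005 * tot.max()
        for idx in np.ndindex(shape):
            if tot[idx] < thresh:
                assert grid.values[idx] == 0
            else:
                assert grid.values[idx] == pytest.approx(
                    num[idx] / tot[idx], rel=1e-12)

    def test_mixture_convexity(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            ds = [rng.uniform(0.1, 2, (4, 4, 4)) for _ in range(4)]
            Ls = [rng.uniform(0.3, 15, (4, 4, 4)) for _ in range(4)]
            grid, excluded = compute_plan_letd(ds, Ls, (2.0, 2.0, 2.0))
            lo = np.minimum.reduce(Ls)
            hi = np.maximum.reduce(Ls)
            ok = ~excluded
            assert (grid.values[ok] >= lo[ok] - 1e-12).all()
            assert (grid.values[ok] <= hi[ok] + 1e-12).all()

    def test_mismatched_rasters_rejected(self):
        with pytest.raises(ValueError):
            compute_plan_letd([np.ones((3, 3, 3)), np.ones((4, 3, 3))],
                              [np.ones((3, 3, 3)), np.ones((4, 3, 3))],
                              (2.0, 2.0, 2.0))

    def test_single_field_letd_monotone_to_distal_edge(self, water_phantom,
                                                       pristine_plan):
        nom = pristine_plan.nominal()
        shape = water_phantom.grid_shape
        i, k = shape[0] // 2, shape[2] // 2
        let_axis = nom.letd.values[i, :, k]
        dose_axis = nom.dose.values[i, :, k]
        ys = water_phantom.voxel_centers_mm()[1]
        wed_cm = (ys - ys[0] + water_phantom.voxel_size[1] / 2.0) / 10.0
        in_beam = dose_axis >= 0.005 * nom.dose.values.max()
        pre_falloff = wed_cm <= pristine_plan.fields[0].range_cm
        sel = in_beam & pre_falloff
        assert np.all(np.diff(let_axis[sel]) >= -1e-6)

    def test_pristine_beam_letd_equals_pristine_curve(self, water_phantom,
                                                      pristine_plan):
        nom = pristine_plan.nominal()
        shape = water_phantom.grid_shape
        i, k = shape[0] // 2, shape[2] // 2
        let_axis = nom.letd.values[i, :, k]
        ys = water_phantom.voxel_centers_mm()[1]
        wed_cm = (ys - ys[0] + water_phantom.voxel_size[1] / 2.0) / 10.0
        curve = pristine_curve(10.0)
        expected = curve.let_at(wed_cm)
        sel = (wed_cm > 0.5) & (wed_cm < 9.0)  # clear of the falloff
        assert np.allclose(let_axis[sel], expected[sel], rtol=0.05)

    def test_high_let_rim_sits_distal_to_target(self, water_phantom,
                                                single_beam_plan):
        nom = single_beam_plan.nominal()
        fm = single_beam_plan.fields[0]
        ys = water_phantom.voxel_centers_mm()[1]
        wed_cm = (ys - ys[0] + water_phantom.voxel_size[1] / 2.0) / 10.0
        shell = (wed_cm > fm.range_cm) & (wed_cm <= fm.range_cm + 0.5)
        ctv = water_phantom.structures["CTV"]
        let = nom.letd.values
        shell_mask = np.zeros_like(ctv)
        shell_mask[:, shell, :] = True
        shell_mask &= ~nom.let_excluded
        assert let[shell_mask].mean() > let[ctv].mean()


class TestUnits:
    def test_adding_mismatched_units_raises(self):
        a = ScalarGrid(np.ones((2, 2, 2)), "Gy", (1, 1, 1))
        b = ScalarGrid(np.ones((2, 2, 2)), "Gy(RBE)", (1, 1, 1))
        with pytest.raises(UnitError):
            a + b

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            ScalarGrid(-np.ones((2, 2, 2)), "Gy", (1, 1, 1))

    def test_unknown_unit_rejected(self):
        with pytest.raises(UnitError):
            ScalarGrid(np.ones((2, 2, 2)), "furlong", (1, 1, 1))

    def test_grid_io_roundtrip(self, tmp_path):
        from robustrbe.grids import load_grid, save_grid
        g = ScalarGrid(np.random.default_rng(0).uniform(0, 2, (4, 5, 6)),
                       LET_UNIT, (3.0, 3.0, 3.0), {"plan": 0})
        save_grid(g, tmp_path / "g.nii.gz")
        back = load_grid(tmp_path / "g.nii.gz")
        assert back.unit == LET_UNIT
        assert np.allclose(back.values, g.values, atol=1e-6)
        assert back.meta["plan"] == 0
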