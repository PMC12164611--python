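"""Isotemporal substitution: reallocation arithmetic, predicted changes,
change matrices and smallest-worthwhile-change thresholds."""

import numpy as np
import pandas as pd
import pytest

from coda24 import (Composition, InfeasibleReallocation, OutcomeModelFit,
                    OutcomeSpec, ReallocationSpec, change_matrix, close,
                    compute_swc, fit_compositional_model, ilr_transform,
                    pivot_basis, predict_change, reallocate,
                    reallocation_volume_percent)
from coda24.models import PART_COLUMNS, PivotCoefficient
from coda24.reallocation import swc_by_sex

PARTS = ("SED", "LPA", "MPA", "VPA", "Sleep")
BOYS_MEAN = close([342.1, 350.7, 40.5, 14.0, 692.7])
GIRLS_MEAN = close([365.8, 348.5, 30.2, 11.5, 681.1])


def make_fit(ilr_coef, transform="identity", outcome_mean=50.0,
             basis=None) -> OutcomeModelFit:
    """Minimal fitted-model stand-in with chosen coefficients."""
    basis = basis or pivot_basis("SED")
    ilr_coef = np.asarray(ilr_coef, float)
    return OutcomeModelFit(
        outcome=OutcomeSpec("toy", transform), n=100, model_f=1.0,
        model_p=0.5, r_squared=0.1, r_squared_total=0.2,
        r_squared_increment=0.1, behaviours={}, covariate_coefficients={},
        residual_sd=1.0, ilr_coef=ilr_coef,
        clr_coef=basis.contrast_matrix.T @ ilr_coef, basis=basis,
        outcome_mean=outcome_mean)


class TestReallocate:
    def test_zero_delta_identity(self):
        spec = ReallocationSpec("VPA", "SED", 0.0)
        assert np.allclose(reallocate(BOYS_MEAN, spec).values,
                           BOYS_MEAN.values)

    def test_boys_vpa_to_sed_arithmetic(self):
        moved = reallocate(BOYS_MEAN, ReallocationSpec("VPA", "SED", 10.0))
        assert moved["SED"] == pytest.approx(352.1)
        assert moved["VPA"] == pytest.approx(4.0)
        assert moved["LPA"] == pytest.approx(BOYS_MEAN["LPA"])
        assert moved.values.sum() == pytest.approx(1440.0)

    def test_girls_vpa_feasibility_boundary(self):
        # 11.5 min mean VPA: taking 10 leaves 1.5 > 0; taking 12 fails
        reallocate(GIRLS_MEAN, ReallocationSpec("VPA", "Sleep", 10.0))
        with pytest.raises(InfeasibleReallocation):
            reallocate(GIRLS_MEAN, ReallocationSpec("VPA", "Sleep", 12.0))

    def test_chaining_equals_direct(self):
        # A->B then B->C from the intermediate equals A->C directly
        ab = reallocate(BOYS_MEAN, ReallocationSpec("SED", "LPA", 10.0))
        abc = reallocate(ab, ReallocationSpec("LPA", "MPA", 10.0))
        direct = reallocate(BOYS_MEAN, ReallocationSpec("SED", "MPA", 10.0))
        assert np.allclose(abc.values, direct.values, atol=1e-12)


class TestPredictChange:
    def test_zero_coefficients_zero_change(self):
        fit = make_fit(np.zeros(4))
        ch = predict_change(fit, BOYS_MEAN,
                            ReallocationSpec("SED", "VPA", 10.0))
        assert ch.percent == 0.0 and ch.absolute == 0.0

    def test_single_coordinate_hand_computation(self):
        # beta = (1,0,0,0): prediction is the change in the first pivot
        # coordinate, sqrt(4/5) * ln(SED'/SED) - sqrt(1/20)*sum ln(rest'/rest)
        fit = make_fit([1.0, 0, 0, 0], outcome_mean=100.0)
        spec = ReallocationSpec("LPA", "SED", 10.0)
        moved = reallocate(BOYS_MEAN, spec)
        expected = (np.sqrt(4 / 5) * np.log(moved["SED"] / BOYS_MEAN["SED"])
                    - np.sqrt(1 / 20) * np.log(moved["LPA"]
                                               / BOYS_MEAN["LPA"]))
        ch = predict_change(fit, BOYS_MEAN, spec)
        assert ch.delta_model == pytest.approx(expected, abs=1e-9)
        assert ch.percent == pytest.approx(expected, abs=1e-9)  # mean 100

    def test_clr_space_oracle_equivalence(self, rng):
        # beta' (z1 - z0) equals clr-coefficient dot clr difference
        for _ in range(5):
            coef = rng.normal(size=4)
            basis = pivot_basis(rng.choice(PARTS))
            fit = make_fit(coef, basis=basis)
            spec = ReallocationSpec(*rng.choice(PARTS, 2, replace=False),
                                    delta=5.0)
            moved = reallocate(BOYS_MEAN, spec)
            from coda24.composition import clr
            oracle = float(fit.clr_coef @ (clr(moved.values)
                                           - clr(BOYS_MEAN.values)))
            ch = predict_change(fit, BOYS_MEAN, spec)
            assert ch.delta_model == pytest.approx(oracle, abs=1e-9)

    def test_model_space_antisymmetry_move_then_undo(self):
        # moving time and moving it back negate exactly in model space
        fit = make_fit([0.6, -0.2, 0.9, 0.1], transform="log")
        spec = ReallocationSpec("SED", "VPA", 10.0)
        moved = reallocate(BOYS_MEAN, spec)
        fwd = predict_change(fit, BOYS_MEAN, spec)
        undo = predict_change(fit, moved, ReallocationSpec("VPA", "SED",
                                                           10.0))
        assert fwd.delta_model == pytest.approx(-undo.delta_model,
                                                abs=1e-12)

    def test_same_reference_swap_opposes_but_differs(self):
        # from a common reference the swapped reallocation has opposite
        # sign but unequal magnitude (log-ratio nonlinearity), the
        # asymmetric pattern the change matrices show
        fit = make_fit([1.0, 0, 0, 0], basis=pivot_basis("VPA"),
                       transform="log")
        fwd = predict_change(fit, BOYS_MEAN,
                             ReallocationSpec("SED", "VPA", 10.0))
        rev = predict_change(fit, BOYS_MEAN,
                             ReallocationSpec("VPA", "SED", 10.0))
        assert np.sign(fwd.delta_model) == -np.sign(rev.delta_model)
        assert abs(fwd.delta_model) != pytest.approx(abs(rev.delta_model),
                                                     rel=1e-3)

    def test_log_percent_exact_vs_approximate(self):
        fit = make_fit([0.6, -0.2, 0.9, 0.1], transform="log")
        spec = ReallocationSpec("SED", "VPA", 10.0)
        exact = predict_change(fit, BOYS_MEAN, spec, exact_percent=True)
        approx = predict_change(fit, BOYS_MEAN, spec, exact_percent=False)
        assert exact.percent == pytest.approx(
            100 * np.expm1(exact.delta_model))
        assert approx.percent == pytest.approx(100 * exact.delta_model)

    def test_covariate_cancellation(self, validation_cohort):
        # full-model predictions at two covariate profiles give the same
        # change for the same reallocation
        rec = validation_cohort["records"]
        spec_out = validation_cohort["cfg"].outcomes[0].spec
        fit = fit_compositional_model(rec, spec_out)
        spec = ReallocationSpec("SED", "VPA", 10.0)
        moved = reallocate(BOYS_MEAN, spec)
        from coda24.models import CompositionalRegression
        est = CompositionalRegression().fit(rec, rec[spec_out.column])
        deltas = []
        for age, sex, eth, month in [(8.0, "male", "White", 1),
                                     (15.0, "female", "Asian", 7)]:
            rows = pd.DataFrame(
                [dict(zip(PART_COLUMNS, BOYS_MEAN.values), age=age, sex=sex,
                      ethnicity=eth, month=month),
                 dict(zip(PART_COLUMNS, moved.values), age=age, sex=sex,
                      ethnicity=eth, month=month)])
            pred = est.predict(rows)
            deltas.append(pred[1] - pred[0])
        assert deltas[0] == pytest.approx(deltas[1], abs=1e-9)
        direct = predict_change(fit, BOYS_MEAN, spec)
        assert deltas[0] == pytest.approx(direct.delta_model, abs=1e-9)


class TestSwc:
    def test_sd_five_gives_one(self):
        vals = np.array([0, 5, 10, 15, 20], float)
        sd = vals.std(ddof=1)
        swc = compute_swc(vals * 5 / sd, "toy")  # rescale to SD exactly 5
        assert swc.value == pytest.approx(1.0)

    def test_girls_bmi_hand_case(self, rng):
        # group SD 3.4 around mean 18.8 -> SWC 0.68 kg/m^2 = 3.62% of mean
        vals = rng.normal(0, 1, 5000)
        vals = (vals - vals.mean()) / vals.std(ddof=1) * 3.4 + 18.8
        swc = compute_swc(vals, "bmi", "female")
        assert swc.value == pytest.approx(0.68, abs=1e-9)
        assert swc.as_percent_of_mean == pytest.approx(3.617, abs=0.01)

    def test_scale_equivariance(self, rng):
        vals = rng.normal(10, 2, 100)
        assert compute_swc(2 * vals, "x").value == pytest.approx(
            2 * compute_swc(vals, "x").value)

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError):
            compute_swc(np.ones(10), "x")

    def test_by_sex_keys(self, panel_records):
        swcs = swc_by_sex(panel_records["records"], "bmi")
        assert set(swcs) == {"male", "female"}
        assert all(s.value > 0 for s in swcs.values())


class TestChangeMatrix:
    def test_zero_fit_all_zero_no_flags(self):
        fit = make_fit(np.zeros(4))
        cm = change_matrix(fit, BOYS_MEAN,
                           compute_swc(np.arange(10.0), "toy"))
        off = ~np.eye(5, dtype=bool)
        assert np.allclose(cm.percent.to_numpy()[off], 0.0)
        assert not cm.flags.to_numpy().any()
        assert np.isnan(np.diag(cm.percent.to_numpy())).all()

    def test_planted_vpa_effect_flags_vpa_cells_only(self, rng):
        # big VPA pivot coefficient: only cells moving VPA time exceed SWC
        basis = pivot_basis("VPA")
        fit = make_fit([5.0, 0, 0, 0], basis=basis, outcome_mean=50.0)
        swc = compute_swc(rng.normal(50, 5, 500), "toy")
        cm = change_matrix(fit, GIRLS_MEAN, swc)
        flags = cm.flags
        vpa_cells = flags.loc["VPA"].to_numpy().any() or \
            flags["VPA"].to_numpy().any()
        non_vpa = flags.drop(index="VPA", columns="VPA").to_numpy()
        assert vpa_cells and not non_vpa.any()

    def test_infeasible_cell_missing(self):
        fit = make_fit([1.0, 0.5, -0.5, 0.2])
        cm = change_matrix(fit, GIRLS_MEAN,
                           compute_swc(np.arange(10.0), "toy"), delta=12.0)
        assert cm.percent["VPA"].drop("VPA").isna().all()  # VPA as donor
        assert cm.percent.loc["VPA"].drop("VPA").notna().all()  # as receiver

    def test_flag_monotone_in_coefficients(self, rng):
        swc = compute_swc(rng.normal(50, 5, 500), "toy")
        coef = np.array([0.8, -0.5, 0.3, 0.2])
        small = change_matrix(make_fit(coef), BOYS_MEAN, swc).flags
        big = change_matrix(make_fit(4 * coef), BOYS_MEAN, swc).flags
        assert (big.to_numpy() | ~small.to_numpy()).all()

    def test_extreme_percent_warning_near_zero_mean(self):
        fit = make_fit([0.8, -0.5, 0.3, 0.2], outcome_mean=0.05)
        swc = compute_swc(np.arange(10.0), "bmi_z")
        cm = change_matrix(fit, BOYS_MEAN, swc)
        assert cm.extreme_percent_warning
        assert np.nanmax(np.abs(cm.percent.to_numpy())) > 100.0


class TestVolumePercent:
    def test_boys_vpa_share(self):
        # 10 min against the boys' 16.8 min/day mean VPA
        assert round(reallocation_volume_percent(10, 16.8), 1) == 59.5

    def test_girls_vpa_share_computed_from_inputs(self):
        # computed from the girls' 10.6 min/day mean, not the published
        # 92.6% figure (which does not follow from the printed inputs)
        assert reallocation_volume_percent(10, 10.6) == pytest.approx(
            94.34, abs=0.01)
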