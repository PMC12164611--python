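"""Compositional regression: recovery, basis invariance, CLR consistency."""

import numpy as np
import pandas as pd
import pytest

from coda24 import (CompositionalRegression, IlrTransformer, OutcomeSpec,
                    fit_compositional_model, ilr_transform, pivot_basis,
                    summarize_models)
from coda24.models import PART_COLUMNS
from coda24.simulate import pivot_coefficients_from_clr

from conftest import random_compositions

PARTS = ("SED", "LPA", "MPA", "VPA", "Sleep")


def synthetic_records(rng, n=600, clr_coef=(1.0, 0.5, -0.3, -0.7, -0.5),
                      noise_sd=1.0):
    """Records with outcome exactly linear in ILR coordinates."""
    mat = random_compositions(rng, n)
    basis = pivot_basis("SED")
    Z = ilr_transform(mat, basis)
    b = basis.contrast_matrix @ np.asarray(clr_coef, float)
    rec = pd.DataFrame(mat, columns=list(PART_COLUMNS))
    rec["age"] = rng.normal(11, 2, n)
    rec["sex"] = rng.choice(["male", "female"], n)
    rec["ethnicity"] = rng.choice(["White", "Asian", "Black"], n)
    rec["month"] = rng.integers(1, 13, n)
    rec["y"] = (10.0 + Z @ b + 0.4 * rec["age"]
                + 0.8 * (rec["sex"] == "female")
                + rng.normal(0, noise_sd, n))
    return rec, b


class TestIlrTransformer:
    def test_round_trip_through_sklearn_api(self, rng):
        X = random_compositions(rng, 20)
        tr = IlrTransformer().fit(X)
        assert np.allclose(tr.inverse_transform(tr.transform(X)), X,
                           rtol=1e-9)

    def test_get_set_params(self):
        tr = IlrTransformer(pivot_first="VPA")
        assert tr.get_params()["pivot_first"] == "VPA"
        tr.set_params(pivot_first="Sleep").fit(np.ones((2, 5)) * 288)
        assert tr.basis_.contrast_matrix[0, 4] == pytest.approx(
            np.sqrt(4 / 5))

    def test_pipeline_compatible(self, rng):
        from sklearn.linear_model import LinearRegression
        from sklearn.pipeline import make_pipeline
        X = random_compositions(rng, 50)
        y = rng.normal(size=50)
        pipe = make_pipeline(IlrTransformer(), LinearRegression()).fit(X, y)
        assert pipe.predict(X).shape == (50,)


class TestPlantedRecovery:
    def test_exact_recovery_at_zero_noise(self, rng):
        clr_coef = np.array([1.0, 0.5, -0.3, -0.7, -0.5])
        rec, _ = synthetic_records(rng, clr_coef=clr_coef, noise_sd=1e-10)
        fit = fit_compositional_model(rec, OutcomeSpec("y"))
        true_piv = pivot_coefficients_from_clr(clr_coef)
        for b, pc in fit.behaviours.items():
            assert pc.coefficient == pytest.approx(true_piv[b], abs=1e-6)
        assert fit.model_p < 1e-100

    def test_sign_monotonicity(self, rng):
        rec, _ = synthetic_records(rng, n=2000, noise_sd=0.5)
        fit = fit_compositional_model(rec, OutcomeSpec("y"))
        true_piv = pivot_coefficients_from_clr(
            np.array([1.0, 0.5, -0.3, -0.7, -0.5]))
        for b, pc in fit.behaviours.items():
            assert np.sign(pc.coefficient) == np.sign(true_piv[b])


class TestBasisInvariance:
    def test_model_p_r2_residuals_invariant(self, rng):
        rec, _ = synthetic_records(rng)
        fits = []
        for lead in PARTS:
            order = (lead, *[p for p in PARTS if p != lead])
            cols = tuple(PART_COLUMNS[PARTS.index(p)] for p in order)
            est = CompositionalRegression(parts=order, part_columns=cols)
            est.fit(rec, rec["y"].to_numpy())
            fits.append(est)
        base = fits[0]
        for other in fits[1:]:
            assert other.model_p_ == pytest.approx(base.model_p_, abs=1e-10)
            assert other.r_squared_ == pytest.approx(base.r_squared_,
                                                     abs=1e-10)
            assert np.allclose(other.results_.fittedvalues,
                               base.results_.fittedvalues, atol=1e-10)

    def test_pivot_refits_share_fit_statistics(self, rng):
        # all five rotations are reparameterisations of one model
        rec, _ = synthetic_records(rng)
        est = CompositionalRegression().fit(rec, rec["y"].to_numpy())
        for b in PARTS:
            b_est = CompositionalRegression(
                parts=(b, *[p for p in PARTS if p != b]),
                part_columns=tuple(PART_COLUMNS[PARTS.index(p)]
                                   for p in (b, *[q for q in PARTS
                                                  if q != b])))
            b_est.fit(rec, rec["y"].to_numpy())
            assert b_est.r_squared_total_ == pytest.approx(
                est.r_squared_total_, abs=1e-12)

    def test_clr_projection_consistency(self, rng):
        # the five pivot coefficients are projections of one zero-sum
        # CLR vector: pivot_b = first pivot row . clr_coef
        rec, _ = synthetic_records(rng)
        fit = fit_compositional_model(rec, OutcomeSpec("y"))
        assert fit.clr_coef.sum() == pytest.approx(0.0, abs=1e-10)
        for b, pc in fit.behaviours.items():
            v1 = pivot_basis(b).contrast_matrix[0]
            assert pc.coefficient == pytest.approx(float(v1 @ fit.clr_coef),
                                                   abs=1e-8)


class TestModelContracts:
    def test_log_transform_positivity_check(self, rng):
        rec, _ = synthetic_records(rng, n=50)
        rec["y"] = -rec["y"].abs()
        with pytest.raises(ValueError, match="positive"):
            fit_compositional_model(rec, OutcomeSpec("y", "log"))

    def test_n_le_p_rejected(self, rng):
        rec, _ = synthetic_records(rng, n=12)
        with pytest.raises(ValueError):
            fit_compositional_model(rec, OutcomeSpec("y"))

    def test_listwise_deletion_per_outcome(self, rng):
        rec, _ = synthetic_records(rng, n=300)
        rec.loc[rec.index[:60], "y"] = np.nan
        fit = fit_compositional_model(rec, OutcomeSpec("y"))
        assert fit.n == 240

    def test_r_squared_modes(self, rng):
        rec, _ = synthetic_records(rng)
        inc = fit_compositional_model(rec, OutcomeSpec("y"),
                                      r_squared_mode="increment")
        tot = fit_compositional_model(rec, OutcomeSpec("y"),
                                      r_squared_mode="total")
        assert inc.r_squared < tot.r_squared  # covariates explain extra
        assert 0 <= inc.r_squared <= 1 and 0 <= tot.r_squared <= 1

    def test_summary_range(self, rng):
        recs = []
        for sd, name in ((0.6, "y_strong"), (4.0, "y_weak")):
            rec, _ = synthetic_records(rng, noise_sd=sd)
            rec = rec.rename(columns={"y": name})
            recs.append(fit_compositional_model(rec, OutcomeSpec(name)))
        table, (lo, hi) = summarize_models(recs)
        assert lo == min(f.r_squared for f in recs)
        assert hi == max(f.r_squared for f in recs)
        assert list(table["outcome"]) == ["y_strong", "y_weak"]
        assert {"Y_SED", "p_Sleep"} <= set(table.columns)

    def test_planted_r2_reproduced(self, validation_cohort):
        # pipeline increment R^2 matches the generator's realized share
        truth = validation_cohort["truth"]
        fit = fit_compositional_model(
            validation_cohort["records"],
            validation_cohort["cfg"].outcomes[0].spec)
        planted = truth.outcome_params["cmr_score"]["increment_r2_realized"]
        # 3x the large-sample SD of an R^2 estimate at this n
        tol = 3 * np.sqrt(4 * planted * (1 - planted) ** 2 / fit.n)
        assert fit.r_squared == pytest.approx(planted, abs=tol)
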