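"""Isotemporal reallocation: grid, simplex arithmetic, predicted changes."""

import math

import numpy as np
import pandas as pd
import pytest

from coda24 import (
    Behavior,
    InfeasibleReallocation,
    ReallocationSpec,
    Rotation,
    apply_reallocation,
    build_grid,
    close,
    fit_cross_sectional,
    predict_delta,
    reallocation_curves,
)
from coda24.composition import ilr_array
from coda24.models import ModelFit
from coda24.reallocation import ORDERED_PAIRS, one_by_one_table


def toy_fit(beta_ilr1=2.0, beta_ilr2=0.0, rotation=Rotation.PA, df_resid=60.0):
    """Hand-built linear ModelFit with known ilr coefficients and a small
    diagonal coefficient covariance."""
    names = ["intercept", "ilr1", "ilr2", "age_months", "sex"]
    params = pd.Series([0.0, beta_ilr1, beta_ilr2, 0.0, 0.0], index=names)
    cov = pd.DataFrame(np.eye(5) * 1e-4, index=names, columns=names)
    return ModelFit(
        model_class="linear",
        rotation=rotation,
        params=params,
        cov_params=cov,
        llf=0.0,
        sigma2=1.0,
        nobs=int(df_resid) + 5,
        n_children=int(df_resid) + 5,
        df_resid=df_resid,
        term_names=tuple(names),
    )


class TestBuildGrid:
    def test_default_grid_sizes(self):
        prop = build_grid("proportional")
        one = build_grid("one_by_one")
        assert len(prop) == 3 * 13  # 3 focal curves x 13 points incl. zero
        assert len(one) == 6 * 13  # 6 ordered pairs x 13 points
        deltas = sorted({s.delta for s in prop})
        assert deltas == [float(d) for d in range(-60, 70, 10)]

    def test_pairs_match_table_columns(self):
        labels = [f"{a.value}->{b.value}" for a, b in ORDERED_PAIRS]
        assert labels == [
            "PA->SB", "PA->SLEEP", "SB->PA", "SB->SLEEP", "SLEEP->PA", "SLEEP->SB",
        ]

    def test_increment_must_divide_range(self):
        with pytest.raises(ValueError, match="divide"):
            build_grid("one_by_one", increment=7)

    def test_grid_must_straddle_zero(self):
        with pytest.raises(ValueError, match="straddle"):
            build_grid("proportional", lo=10, hi=60)


class TestApplyReallocation:
    def test_proportional_equal_split_worked_example(self):
        base = close((480, 480, 480))
        spec = ReallocationSpec("proportional", -10.0, focal=Behavior.PA)
        new = apply_reallocation(base, spec)
        assert new.as_array() == pytest.approx([470, 485, 485])

    def test_one_by_one_direct_shift(self):
        base = close((480, 480, 480))
        spec = ReallocationSpec(
            "one_by_one", 10.0, from_behavior=Behavior.SB, to_behavior=Behavior.PA
        )
        assert apply_reallocation(base, spec).as_array() == pytest.approx(
            [490, 470, 480]
        )

    def test_proportional_to_base_split(self):
        base = close((240, 400, 800))
        spec = ReallocationSpec(
            "proportional", -12.0, focal=Behavior.PA, split="proportional_to_base"
        )
        new = apply_reallocation(base, spec)
        assert new.as_array() == pytest.approx([228, 404, 808])

    def test_total_conserved(self):
        base = close((224.3, 401.0, 807.0))
        for spec in build_grid("proportional") + build_grid("one_by_one"):
            try:
                new = apply_reallocation(base, spec)
            except InfeasibleReallocation:
                continue
            assert new.as_array().sum() == pytest.approx(1440, rel=1e-12)

    def test_infeasible_shift_names_behavior(self):
        base = close((30, 700, 710))
        spec = ReallocationSpec(
            "one_by_one", 60.0, from_behavior=Behavior.PA, to_behavior=Behavior.SB
        )
        with pytest.raises(InfeasibleReallocation, match="PA"):
            apply_reallocation(base, spec)

    def test_from_equals_to_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            ReallocationSpec(
                "one_by_one", 10.0, from_behavior=Behavior.PA, to_behavior=Behavior.PA
            )


class TestPredictDelta:
    def test_zero_delta_exact_zero(self):
        base = close((480, 480, 480))
        spec = ReallocationSpec("proportional", 0.0, focal=Behavior.SB)
        est = predict_delta(toy_fit(), base, spec)
        assert est.change == 0.0
        assert est.ci_low == est.ci_high == 0.0
        assert not est.significant

    def test_hand_derived_toy_case(self):
        # beta_ilr1 = 2 on the PA pivot; moving 10 min SB -> PA around an
        # equal-thirds day changes ilr1 by sqrt(2/3) ln(490/sqrt(470*480))
        base = close((480, 480, 480))
        spec = ReallocationSpec(
            "one_by_one", 10.0, from_behavior=Behavior.SB, to_behavior=Behavior.PA
        )
        est = predict_delta(toy_fit(beta_ilr1=2.0), base, spec)
        d_ilr1 = math.sqrt(2 / 3) * math.log(490 / math.sqrt(470 * 480))
        assert est.change == pytest.approx(2 * d_ilr1, abs=1e-12)
        assert est.change == pytest.approx(0.0508, abs=1e-3)

    def test_brute_force_oracle_equivalence(self, default_records):
        # prediction difference through the full design row must agree
        fit = fit_cross_sectional(default_records, "gm_raw", Rotation.SB)
        base = close((224.3, 401.0, 807.0))
        rng = np.random.default_rng(8)
        for spec in build_grid("one_by_one") + build_grid("proportional"):
            try:
                new = apply_reallocation(base, spec)
            except InfeasibleReallocation:
                continue
            est = predict_delta(fit, base, spec)
            age, sex = rng.uniform(0, 48), rng.integers(0, 2)
            rows = np.array(
                [[*new.as_array(), age, sex], [*base.as_array(), age, sex]]
            )
            z = ilr_array(rows[:, :3], fit.rotation)
            design = np.column_stack([np.ones(2), z, rows[:, 3:]])
            preds = design @ fit.params.to_numpy()
            assert est.change == pytest.approx(preds[0] - preds[1], abs=1e-10)

    def test_rotation_invariant_predictions(self, default_records):
        base = close((224.3, 401.0, 807.0))
        spec = ReallocationSpec(
            "one_by_one", 30.0, from_behavior=Behavior.SLEEP, to_behavior=Behavior.PA
        )
        ests = [
            predict_delta(fit_cross_sectional(default_records, "gm_raw", rot), base, spec)
            for rot in Rotation
        ]
        for e in ests[1:]:
            assert e.change == pytest.approx(ests[0].change, abs=1e-8)
            assert e.ci_low == pytest.approx(ests[0].ci_low, abs=1e-8)
            assert e.ci_high == pytest.approx(ests[0].ci_high, abs=1e-8)

    def test_mixed_fit_rejected(self, default_records):
        from coda24 import fit_longitudinal

        fit = fit_longitudinal(default_records, "gm_raw")
        spec = ReallocationSpec("proportional", 10.0, focal=Behavior.PA)
        with pytest.raises(ValueError, match="cross-sectional"):
            predict_delta(fit, close((480, 480, 480)), spec)


class TestCurves:
    def test_curve_passes_through_zero(self, default_records):
        fit = fit_cross_sectional(default_records, "gm_raw")
        comps = [close((224.3, 401.0, 807.0))]
        curves = reallocation_curves(fit, comps, scheme="one_by_one")
        at_zero = curves[curves["delta_min"] == 0]
        assert (at_zero["estimate"] == 0).all()
        assert (at_zero["ci_low"] == 0).all() and (at_zero["ci_high"] == 0).all()

    def test_sign_flip_and_asymmetry(self):
        # +d and -d give opposite-sign estimates of slightly different
        # magnitude (the log-ratio contrast is nonlinear in minutes)
        base = close((480, 480, 480))
        fit = toy_fit(beta_ilr1=2.0, beta_ilr2=0.7)
        plus = predict_delta(
            fit,
            base,
            ReallocationSpec("proportional", 30.0, focal=Behavior.PA),
        )
        minus = predict_delta(
            fit,
            base,
            ReallocationSpec("proportional", -30.0, focal=Behavior.PA),
        )
        assert plus.change > 0 > minus.change
        assert abs(abs(plus.change) - abs(minus.change)) > 1e-6

    def test_ci_width_minimal_at_zero_and_monotone(self, default_records):
        fit = fit_cross_sectional(default_records, "zbmi")
        comps = [close((224.3, 401.0, 807.0))]
        curves = reallocation_curves(fit, comps, scheme="one_by_one")
        for _, sub in curves.groupby("curve"):
            sub = sub.sort_values("delta_min")
            width = (sub["ci_high"] - sub["ci_low"]).to_numpy()
            d = sub["delta_min"].to_numpy()
            assert width[d == 0][0] == min(width)
            pos = width[d >= 0]
            assert (np.diff(pos) >= -1e-12).all()

    def test_infeasible_grid_points_are_gaps(self):
        base = close((40, 600, 800))
        curves = reallocation_curves(toy_fit(), base, scheme="one_by_one")
        sub = curves[
            (curves["from"] == "PA")
            & (curves["to"] == "SB")
            & (curves["delta_min"] == 60)
        ]
        assert not sub["feasible"].item()
        assert np.isnan(sub["estimate"].item())
        assert curves[curves["delta_min"] == 0]["feasible"].all()

    def test_one_by_one_equals_proportional_with_degenerate_split(self):
        # proportional into focal B with all time drawn from A is exactly the
        # one-by-one A -> B shift
        base = close((300, 400, 740))
        fit = toy_fit(beta_ilr1=1.5, beta_ilr2=-0.8, rotation=Rotation.SB)
        one = predict_delta(
            fit,
            base,
            ReallocationSpec(
                "one_by_one", 20.0, from_behavior=Behavior.PA, to_behavior=Behavior.SB
            ),
        )
        prop = predict_delta(
            fit,
            base,
            ReallocationSpec(
                "proportional",
                20.0,
                focal=Behavior.SB,
                split=((Behavior.PA, 1.0), (Behavior.SLEEP, 0.0)),
            ),
        )
        assert prop.change == pytest.approx(one.change, abs=1e-12)


def test_one_by_one_table_shape(default_records):
    fit = fit_cross_sectional(default_records, "gm_raw")
    comps = [close((224.3, 401.0, 807.0))]
    table = one_by_one_table({"gm_raw": fit}, {"gm_raw": comps})
    assert list(table.index) == ["gm_raw"]
    assert len(table.columns) == 6
    assert table.loc["gm_raw", "SB to PA"].startswith(("-", "0", "1"))
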