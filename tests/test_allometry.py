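import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from paleosnake.allometry import (
    AllometricModel,
    ComparativeDataset,
    ModelForm,
    Provenance,
    builtin_models,
    fit_allometry,
    get_builtin,
    inverse_width,
    meters,
    prediction_interval,
    predict_tbl,
)
from paleosnake.errors import DegenerateDesignError, ValidationError
from paleosnake.synthetic import AllometryConfig, SimulationConfig, sim_allometric


class TestBuiltins:
    def test_three_models_with_published_coefficients(self):
        models = {m.model_id: m for m in builtin_models()}
        assert len(models) == 3
        assert models["A60"].slope == 100.72 and models["A60"].intercept == 436.24
        assert models["A65"].slope == 105.98 and models["A65"].intercept == 390.0
        assert models["C"].form is ModelForm.LOG10LOG10
        assert models["C"].slope == 1.0739 and models["C"].intercept == 1.9842
        assert all(m.provenance is Provenance.BUILTIN for m in models.values())

    def test_max_width_gives_15_2_m(self):
        # the log-log prW model at the largest observed width
        tbl = predict_tbl(get_builtin("C"), 111.4)
        assert meters(tbl) == 15.2

    def test_linear_model_algebra(self):
        # y = 100.72x + 436.24 inverted at y = 11,600 mm = 11.6 m
        width = (11600 - 436.24) / 100.72
        assert predict_tbl(get_builtin("A60"), width) == pytest.approx(11600, abs=1e-9)
        assert meters(11600) == 11.6

    def test_json_round_trip(self):
        m = get_builtin("C")
        back = AllometricModel.from_json(m.to_json())
        assert back == m


class TestPredictInverse:
    def test_nonpositive_width_rejected(self):
        for model in builtin_models():
            with pytest.raises(ValidationError):
                predict_tbl(model, 0.0)

    def test_unit_step_inverse(self):
        assert inverse_width(get_builtin("A60"), 436.24 + 100.72) == pytest.approx(1.0)

    def test_inverse_of_worked_example(self):
        assert inverse_width(get_builtin("C"), 15222.0) == pytest.approx(111.4, abs=0.05)

    def test_tbl_at_intercept_rejected(self):
        with pytest.raises(ValidationError):
            inverse_width(get_builtin("A65"), 390.0)

    @given(width=st.floats(min_value=0.1, max_value=500.0))
    def test_round_trip_identity(self, width):
        for model in builtin_models():
            tbl = predict_tbl(model, width)
            assert inverse_width(model, tbl) == pytest.approx(width, rel=1e-9)

    @given(
        width=st.floats(min_value=1.0, max_value=200.0),
        c=st.floats(min_value=0.1, max_value=10.0),
    )
    def test_power_law_scale_property(self, width, c):
        model = get_builtin("C")
        ratio = predict_tbl(model, c * width) / predict_tbl(model, width)
        assert ratio == pytest.approx(c**model.slope, rel=1e-9)

    def test_strictly_increasing(self):
        for model in builtin_models():
            widths = np.linspace(1, 200, 50)
            preds = [predict_tbl(model, w) for w in widths]
            assert all(b > a for a, b in zip(preds, preds[1:]))


class TestFitting:
    def _dataset(self, rows):
        import pandas as pd

        return ComparativeDataset(
            frame=pd.DataFrame(rows, columns=["taxon", "width_mm", "tbl_mm"])
        )

    def test_exact_collinearity(self):
        data = self._dataset([("a", 10, 1000), ("b", 20, 2000), ("c", 30, 3000)])
        model = fit_allometry(data, ModelForm.LINEAR)
        assert model.slope == pytest.approx(100.0)
        assert model.intercept == pytest.approx(0.0, abs=1e-9)
        assert model.r2 == pytest.approx(1.0)

    def test_parameter_recovery_on_synthetic(self):
        cfg = SimulationConfig(seed=11)
        data = sim_allometric(cfg)
        assert len(data) == 21
        model = fit_allometry(data, ModelForm.LOG10LOG10)
        assert model.slope == pytest.approx(1.0739, abs=0.05)
        assert model.p_slope < 0.05 and model.r2 > 0.9

    def test_degenerate_design_rejected(self):
        data = self._dataset([("a", 10, 1000), ("b", 10, 2000), ("c", 10, 1500)])
        with pytest.raises(DegenerateDesignError):
            fit_allometry(data, ModelForm.LINEAR)

    def test_too_few_rows_rejected(self):
        data = self._dataset([("a", 10, 1000), ("b", 20, 2000)])
        with pytest.raises(ValidationError):
            fit_allometry(data, ModelForm.LINEAR)

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ValidationError):
            self._dataset([("a", -10, 1000), ("b", 20, 2000), ("c", 30, 3000)])

    def test_three_sigma_recovery_rate(self):
        # slope/intercept within 3 SE of truth in >= 99% of 200 replicates
        hits = 0
        for rep in range(200):
            cfg = SimulationConfig(seed=5000 + rep)
            model = fit_allometry(sim_allometric(cfg), ModelForm.LOG10LOG10)
            ok = (
                abs(model.slope - 1.0739) <= 3 * model.se_slope
                and abs(model.intercept - 1.9842) <= 3 * model.se_intercept
            )
            hits += ok
        assert hits >= 198


class TestPredictionInterval:
    def test_builtin_without_data_unsupported(self):
        cfg = SimulationConfig(seed=1)
        data = sim_allometric(cfg)
        with pytest.raises(ValidationError):
            prediction_interval(get_builtin("C"), data, 100.0)

    def test_level_out_of_range_rejected(self):
        cfg = SimulationConfig(seed=1)
        data = sim_allometric(cfg)
        model = fit_allometry(data, ModelForm.LOG10LOG10)
        with pytest.raises(ValidationError):
            prediction_interval(model, data, 100.0, level=1.2)

    def test_exact_collinear_interval_is_degenerate(self):
        import pandas as pd

        data = ComparativeDataset(
            frame=pd.DataFrame(
                [("a", 10, 1000), ("b", 20, 2000), ("c", 30, 3000), ("d", 40, 4000)],
                columns=["taxon", "width_mm", "tbl_mm"],
            )
        )
        model = fit_allometry(data, ModelForm.LINEAR)
        lo, hi = prediction_interval(model, data, 25.0, level=0.95)
        assert hi - lo == pytest.approx(0.0, abs=1e-6)

    def test_coverage_of_fresh_points(self):
        # ~95% of newly simulated observations fall inside the 95% interval
        cfg = SimulationConfig(seed=21, allometry=AllometryConfig(noise_sd=0.05))
        data = sim_allometric(cfg)
        model = fit_allometry(data, ModelForm.LOG10LOG10)
        rng = np.random.default_rng(99)
        inside = 0
        n_draws = 1000
        for _ in range(n_draws):
            w = 10 ** rng.uniform(math.log10(5), math.log10(120))
            y = 10 ** (1.0739 * math.log10(w) + 1.9842 + rng.normal(0, 0.05))
            lo, hi = prediction_interval(model, data, w, level=0.95)
            inside += lo <= y <= hi
        assert 0.90 <= inside / n_draws <= 0.99
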