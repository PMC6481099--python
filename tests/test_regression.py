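import numpy as np
import pandas as pd
import pytest

import colorquant as cq
from colorquant.exceptions import ContractError, NumericalError


def _table(x: pd.DataFrame, y: np.ndarray, mode: str = "full83",
           scaled: bool = False) -> cq.FeatureTable:
    data = x.copy()
    data.insert(0, "role", "train")
    data.insert(0, "level", y)
    data.insert(0, "pack_id", "p")
    return cq.FeatureTable(data, mode=mode, scaled=scaled)


EQ3_TERMS = (("-cRGB a*", 0.195), ("-cRGB C", 0.0798), ("-cRGB Y", 0.0569))
EQ3_CONSTANT = -30.9


@pytest.fixture(scope="module")
def eq3_model() -> cq.LinearModel:
    return cq.LinearModel(terms=EQ3_TERMS, constant=EQ3_CONSTANT)


class TestMLP:
    def test_seed_determinism(self, cod_study):
        cfg = cq.MLPConfig(input_dim=83, epochs=25, seed=5)
        m1 = cq.train_mlp(cod_study.train, cfg)
        m2 = cq.train_mlp(cod_study.train, cfg)
        for w1, w2 in zip(m1.weights, m2.weights):
            np.testing.assert_array_equal(w1, w2)

    def test_constant_target_degenerate_fit(self):
        rng = np.random.default_rng(0)
        x = pd.DataFrame(rng.uniform(0, 1, (20, 4)), columns=list("abcd"))
        table = _table(x, np.full(20, 3.5), mode="base10", scaled=True)
        model = cq.train_mlp(table, cq.MLPConfig(input_dim=4, epochs=10, seed=0))
        np.testing.assert_allclose(cq.predict(model, table), 3.5, atol=1e-6)

    def test_noiseless_monotone_recovery(self, noiseless_library):
        """With zero simulated noise the network should quantify the
        standard series to well under 1% normalized error."""
        design = cq.cod_design()
        study = cq.simulate_study(noiseless_library, design, seed=3)
        model = cq.train_mlp(study.train, cq.MLPConfig(input_dim=83, seed=3),
                             validation=study.validation)
        est = cq.predict(model, study.validation)
        err = cq.nmae(est, study.validation.levels, design.level_range)
        assert err < 1.0
        # loss history retained for overtraining inspection, and training
        # made actual progress
        hist = model.loss_history["train"]
        assert len(hist) == 3000
        assert hist[-1] < hist[0] / 100
        assert len(model.loss_history["validation"]) == 3000

    def test_requires_scaled_features(self, cod_study):
        with pytest.raises(ContractError):
            cq.train_mlp(cod_study.train.unscale(),
                         cq.MLPConfig(input_dim=83, epochs=1))

    def test_predict_bounded_and_finite(self, cod_study):
        cfg = cq.MLPConfig(input_dim=83, epochs=5, seed=1)
        model = cq.train_mlp(cod_study.train, cfg)
        rng = np.random.default_rng(0)
        x = pd.DataFrame(rng.uniform(0, 1, (50, 83)),
                         columns=list(cod_study.train.channel_names))
        est = cq.predict(model, _table(x, np.zeros(50), scaled=True))
        assert np.isfinite(est).all()

    def test_inverse_target_mapping_midpoint(self, cod_study):
        cfg = cq.MLPConfig(input_dim=83, epochs=1, seed=0)
        model = cq.train_mlp(cod_study.train, cfg)
        lo, hi = cfg.target_range
        mid = model.unscale_target(np.array([(lo + hi) / 2]))[0]
        assert mid == pytest.approx((model.level_min + model.level_max) / 2)

    def test_column_mismatch_rejected(self, cod_study):
        cfg = cq.MLPConfig(input_dim=83, epochs=1, seed=0)
        model = cq.train_mlp(cod_study.train, cfg)
        rng = np.random.default_rng(0)
        x = pd.DataFrame(rng.uniform(0, 1, (4, 3)), columns=list("xyz"))
        with pytest.raises(ContractError):
            cq.predict(model, _table(x, np.zeros(4), scaled=True))

    def test_serialization_roundtrip(self, cod_study):
        cfg = cq.MLPConfig(input_dim=83, epochs=5, seed=2)
        model = cq.train_mlp(cod_study.train, cfg)
        back = cq.MLPModel.from_dict(model.to_dict())
        np.testing.assert_allclose(
            cq.predict(back, cod_study.validation),
            cq.predict(model, cod_study.validation))


class TestStepwise:
    def test_selects_true_predictor(self):
        rng = np.random.default_rng(0)
        x1 = rng.uniform(0, 10, 60)
        x2 = rng.uniform(0, 10, 60)
        y = 2.0 * x1 + rng.normal(0, 0.1, 60)
        model = cq.stepwise_fit(_table(pd.DataFrame({"x1": x1, "x2": x2}), y))
        assert model.channel_names == ("x1",)
        coef = dict(model.terms)["x1"]
        assert coef == pytest.approx(2.0, rel=0.05)
        # independent oracle: plain least squares on x1 alone
        slope = np.polyfit(x1, y, 1)[0]
        assert coef == pytest.approx(slope, rel=1e-9)

    def test_duplicate_column_enters_once(self):
        rng = np.random.default_rng(5)
        x1 = rng.uniform(0, 255, 80)
        y = 0.5 * x1 + rng.normal(0, 1, 80)
        x = pd.DataFrame({"x1": x1, "copy": x1.copy()})
        model = cq.stepwise_fit(_table(x, y))
        assert len(model.terms) == 1
        assert all(v < 10 for v in model.vifs.values())

    def test_recovers_published_ammonium_structure(self):
        """Parameter recovery on data generated from the published
        three-channel ammonium model at the study's n = 180."""
        rng = np.random.default_rng(5)
        n = 180
        x = pd.DataFrame({name: rng.uniform(0, 255, n)
                          for name, _ in EQ3_TERMS})
        for j in range(3):
            x[f"distractor{j}"] = rng.uniform(0, 255, n)
        y = EQ3_CONSTANT + sum(c * x[name] for name, c in EQ3_TERMS)
        y = y + rng.normal(0, 1.5, n)
        model = cq.stepwise_fit(_table(x, y.to_numpy()))
        recovered = dict(model.terms)
        for name, coef in EQ3_TERMS:
            assert name in recovered
            assert recovered[name] == pytest.approx(coef, rel=0.10)
        assert all(v < 10 for v in model.vifs.values())

    def test_pure_noise_gives_empty_model(self):
        rng = np.random.default_rng(1)
        x = pd.DataFrame({"a": rng.normal(size=40), "b": rng.normal(size=40)})
        y = rng.normal(size=40)
        model = cq.stepwise_fit(x.pipe(_table, y))
        assert model.empty
        assert model.terms == ()
        assert model.constant == pytest.approx(float(y.mean()))


class TestApplyLinearModel:
    def test_published_constant_at_zero_intensity(self, eq3_model):
        zeros = pd.DataFrame({name: [0.0] for name, _ in EQ3_TERMS})
        assert cq.apply_linear_model(eq3_model, zeros)[0] == pytest.approx(-30.9)

    def test_hand_arithmetic_examples(self, eq3_model):
        x = pd.DataFrame({"-cRGB a*": [1.0, 100.0], "-cRGB C": [0.0, 100.0],
                          "-cRGB Y": [0.0, 60.1]})
        est = cq.apply_linear_model(eq3_model, x)
        assert est[0] == pytest.approx(-30.705)
        assert est[1] == pytest.approx(0.0, abs=0.01)

    def test_exact_linearity(self, eq3_model):
        rng = np.random.default_rng(2)
        xa = rng.uniform(0, 255, (1, 3))
        xb = rng.uniform(0, 255, (1, 3))
        cols = [name for name, _ in EQ3_TERMS]
        alpha = 0.3
        fa = cq.apply_linear_model(eq3_model, pd.DataFrame(xa, columns=cols))[0]
        fb = cq.apply_linear_model(eq3_model, pd.DataFrame(xb, columns=cols))[0]
        mix = cq.apply_linear_model(
            eq3_model, pd.DataFrame(alpha * xa + (1 - alpha) * xb, columns=cols))[0]
        assert mix == pytest.approx(alpha * fa + (1 - alpha) * fb)

    def test_missing_channel_rejected(self, eq3_model):
        with pytest.raises(ContractError):
            cq.apply_linear_model(eq3_model, pd.DataFrame({"-cRGB a*": [0.0]}))


class TestRestrictRange:
    def test_phosphate_zero_exclusion(self):
        design = cq.phosphate_design()
        n = design.n_val_rows
        levels = np.repeat(design.levels, design.packs_per_level
                           * design.val_pixels_per_pack)
        est = levels + 1.0
        kept, kept_levels, record = cq.restrict_range(est, levels, design, (0.0,))
        assert record.effective_range == (13.0, 105.0)
        assert record.n_removed == design.packs_per_level * design.val_pixels_per_pack
        assert len(kept) == n - record.n_removed
        assert 0.0 not in kept_levels

    def test_empty_exclusion_is_identity(self):
        design = cq.phosphate_design()
        levels = np.array(design.levels)
        est = levels * 1.1
        kept, kept_levels, record = cq.restrict_range(est, levels, design, ())
        np.testing.assert_array_equal(kept, est)
        assert record.n_removed == 0

    def test_excluding_all_levels_fails(self):
        design = cq.phosphate_design()
        levels = np.array(design.levels)
        with pytest.raises(NumericalError):
            cq.restrict_range(levels, levels, design, design.levels)
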