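"""Composite construction and recursive path-coefficient recovery."""

import numpy as np
import pandas as pd
import pytest

from riverdom.pathmodel import (PathModelError, PathSpec, build_composites,
                                dry_season_spec, export_path_diagram,
                                fit_path_model, significance_stars,
                                wet_season_spec)


def toy_spec():
    return PathSpec(composites={"X": ["x1"], "Y": ["y1"]},
                    paths=[("X", "Y")])


def simulate_recursive(n=1000, seed=0):
    """Y = 0.7 X + e; Z = -0.6 Y + 0.3 X + e (standardized truth)."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    y = 0.7 * x + rng.normal(size=n) * np.sqrt(1 - 0.7 ** 2)
    ez = np.sqrt(max(1e-6, 1 - (0.36 + 0.09 + 2 * (-0.6) * 0.3 * 0.7)))
    z = -0.6 * y + 0.3 * x + rng.normal(size=n) * ez
    return pd.DataFrame({"x1": x, "y1": y, "z1": z})


class TestComposites:
    def test_single_indicator_equals_zscore(self):
        data = pd.DataFrame({"x1": [1.0, 2, 3, 4, 10],
                             "y1": [2.0, 1, 5, 3, 4]})
        comp = build_composites(data, toy_spec())
        x = data["x1"]
        np.testing.assert_allclose(comp["X"],
                                   (x - x.mean()) / x.std(ddof=1),
                                   atol=1e-12)

    def test_duplicate_indicators_match_single(self):
        data = pd.DataFrame({"x1": [1.0, 2, 3, 4, 10]})
        data["x2"] = data["x1"]
        spec2 = PathSpec(composites={"X": ["x1", "x2"], "Y": ["x1"]},
                         paths=[("X", "Y")])
        comp = build_composites(data, spec2)
        np.testing.assert_allclose(comp["X"], comp["Y"])

    def test_composites_standardized(self):
        rng = np.random.default_rng(0)
        data = pd.DataFrame(rng.normal(size=(30, 2)),
                            columns=["x1", "y1"])
        comp = build_composites(data, toy_spec())
        np.testing.assert_allclose(comp.mean(), 0.0, atol=1e-12)
        np.testing.assert_allclose(comp.std(ddof=1), 1.0)

    def test_ratio_composite_uses_raw_scale(self):
        data = pd.DataFrame({"p": [2.0, 4, 6, 8, 12],
                             "h": [1.0, 2, 2, 4, 3],
                             "m": [0.5, 1, 2, 3, 4]})
        spec = PathSpec(
            composites={"M": ["m"], "P": ["p"]},
            paths=[("M", "P"), ("P", "H")],
            ratio_composite={"name": "H", "numerator": ["p"],
                             "denominator": ["h"]})
        comp = build_composites(data, spec)
        ratio = data["p"] / data["h"]
        np.testing.assert_allclose(
            comp["H"], (ratio - ratio.mean()) / ratio.std(ddof=1))

    def test_missing_indicator_named(self):
        data = pd.DataFrame({"x1": np.arange(6.0)})
        with pytest.raises(PathModelError, match="y1"):
            build_composites(data, toy_spec())

    def test_cycle_rejected(self):
        with pytest.raises(PathModelError, match="cycle"):
            PathSpec(composites={"A": ["a"], "B": ["b"]},
                     paths=[("A", "B"), ("B", "A")])


class TestFit:
    def test_bivariate_beta_equals_pearson_correlation(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=50)
        y = 0.5 * x + rng.normal(size=50)
        data = pd.DataFrame({"x1": x, "y1": y})
        comp = build_composites(data, toy_spec())
        model = fit_path_model(comp, toy_spec())
        assert model.coefficient("X", "Y") == pytest.approx(
            np.corrcoef(x, y)[0, 1])

    def test_recursive_system_recovery_within_3se(self):
        spec = PathSpec(composites={"X": ["x1"], "Y": ["y1"], "Z": ["z1"]},
                        paths=[("X", "Y"), ("Y", "Z"), ("X", "Z")])
        data = simulate_recursive(n=1000, seed=3)
        model = fit_path_model(build_composites(data, spec), spec)
        truth = {("X", "Y"): 0.7, ("Y", "Z"): -0.6, ("X", "Z"): 0.3}
        for _, row in model.coefficients.iterrows():
            t = truth[(row["from"], row["to"])]
            assert abs(row["beta"] - t) < 3 * row["se"]

    def test_null_data_betas_small(self):
        spec = PathSpec(composites={"X": ["x1"], "Y": ["y1"], "Z": ["z1"]},
                        paths=[("X", "Y"), ("Y", "Z"), ("X", "Z")])
        maxima = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            data = pd.DataFrame(rng.normal(size=(500, 3)),
                                columns=["x1", "y1", "z1"])
            model = fit_path_model(build_composites(data, spec), spec)
            maxima.append(model.coefficients["beta"].abs().max())
        assert np.median(maxima) < 0.15

    def test_indicator_scaling_invariance(self):
        data = simulate_recursive(n=200, seed=5)
        spec = PathSpec(composites={"X": ["x1"], "Y": ["y1"]},
                        paths=[("X", "Y")])
        m1 = fit_path_model(build_composites(data, spec), spec)
        data2 = data.copy()
        data2["x1"] *= 1000.0
        m2 = fit_path_model(build_composites(data2, spec), spec)
        assert m1.coefficient("X", "Y") == pytest.approx(
            m2.coefficient("X", "Y"))

    def test_sign_flip_of_indicator_flips_path(self):
        data = simulate_recursive(n=200, seed=6)
        spec = PathSpec(composites={"X": ["x1"], "Y": ["y1"]},
                        paths=[("X", "Y")])
        m1 = fit_path_model(build_composites(data, spec), spec)
        data2 = data.copy()
        data2["x1"] = -data2["x1"]
        m2 = fit_path_model(build_composites(data2, spec), spec)
        assert m2.coefficient("X", "Y") == pytest.approx(
            -m1.coefficient("X", "Y"))

    def test_collinear_parents_rejected(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=30)
        data = pd.DataFrame({"x1": x, "x2": x * 2.0,
                             "y1": rng.normal(size=30)})
        spec = PathSpec(composites={"A": ["x1"], "B": ["x2"], "Y": ["y1"]},
                        paths=[("A", "Y"), ("B", "Y")])
        with pytest.raises(PathModelError, match="collinear"):
            fit_path_model(build_composites(data, spec), spec)


class TestDiagram:
    def test_strong_negative_path_label(self):
        # path coefficient -0.62 at p<0.001 renders as "-0.62***"
        rng = np.random.default_rng(8)
        x = rng.normal(size=400)
        y = -0.62 * x + np.sqrt(1 - 0.62 ** 2) * rng.normal(size=400)
        data = pd.DataFrame({"x1": x, "y1": y})
        spec = toy_spec()
        model = fit_path_model(build_composites(data, spec), spec)
        row = model.coefficients.iloc[0]
        dot = export_path_diagram(model)
        expected = f"{row['beta']:.2f}{significance_stars(row['p'])}"
        assert f'label="{expected}"' in dot
        assert expected.endswith("***")
        assert expected.startswith("-0.6")

    def test_empty_paths_header_only(self):
        model = fit_path_model(
            build_composites(pd.DataFrame({"x1": np.arange(6.0),
                                           "y1": np.arange(6.0) ** 2}),
                             toy_spec()),
            toy_spec())
        model.coefficients = model.coefficients.iloc[0:0]
        dot = export_path_diagram(model)
        assert dot.startswith("digraph")
        assert "->" not in dot

    def test_season_presets_are_valid_dags(self):
        for spec in (dry_season_spec(), wet_season_spec()):
            assert "Humification" in [b for _, b in spec.paths]

    def test_yaml_presets_match_python_presets(self):
        import yaml
        from pathlib import Path
        cfg_dir = Path(__file__).resolve().parent.parent / "configs"
        for fname, preset in [("path_model_dry.yaml", dry_season_spec()),
                              ("path_model_wet.yaml", wet_season_spec())]:
            loaded = PathSpec.from_dict(
                yaml.safe_load((cfg_dir / fname).read_text()))
            assert loaded.composites == preset.composites
            assert loaded.paths == preset.paths
            assert loaded.ratio_composite == preset.ratio_composite
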