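import numpy as np
import pandas as pd
import pytest

from rhizograd import (
    SensitivityDesign,
    binned_prcc,
    depth_regression,
    prcc,
    run_ensemble,
    sobol_design,
)
from .oracles import prcc_matrix_oracle


def unit_design(n, names):
    bounds = {k: (0.0, 1.0) for k in names}
    return sobol_design(SensitivityDesign(n_samples=n, parameters=bounds))


def test_sobol_base_points_and_marginals():
    """The unscrambled Sobol sequence (zero point skipped) starts at the
    center and the quarter points, and fills each margin uniformly."""
    d = unit_design(64, ["a", "b"])
    assert np.allclose(d.iloc[0], [0.5, 0.5])
    assert np.allclose(d.iloc[1], [0.75, 0.25])
    assert np.allclose(d.iloc[2], [0.25, 0.75])
    for c in d.columns:
        assert d[c].min() >= 0 and d[c].max() <= 1
        # balanced coverage: mean near 1/2, low-discrepancy
        assert abs(d[c].mean() - 0.5) < 0.02


def test_sobol_design_scales_to_bounds():
    bounds = {"x": (2.0, 4.0), "y": (-1.0, 0.0)}
    d = sobol_design(SensitivityDesign(n_samples=20, parameters=bounds))
    assert np.allclose(d.iloc[0], [3.0, -0.5])
    assert d["x"].between(2, 4).all() and d["y"].between(-1, 0).all()


def test_design_validation():
    with pytest.raises(ValueError, match="n >= 10"):
        SensitivityDesign(n_samples=5, parameters={"a": (0, 1)})
    with pytest.raises(ValueError, match="bad bounds"):
        SensitivityDesign(n_samples=64, parameters={"a": (1.0, 0.0)})


def test_prcc_matches_matrix_inverse_oracle():
    """PRCC via residual regressions equals the textbook partial correlation
    from the inverse rank-correlation matrix, on a 20-row table."""
    rng = np.random.default_rng(7)
    t = pd.DataFrame(rng.uniform(size=(20, 3)), columns=["a", "b", "c"])
    t["y"] = np.exp(t["a"]) - 0.5 * t["b"] + 0.1 * rng.normal(size=20)
    got = prcc(t, "y", parameters=["a", "b", "c"])
    want = prcc_matrix_oracle(t, ["a", "b", "c"], "y")
    for k in ("a", "b", "c"):
        assert got[k] == pytest.approx(want[k], abs=1e-10)


def test_prcc_monotone_and_null_responses():
    d = unit_design(200, ["x1", "x2", "x3"])
    d["y"] = np.exp(3.0 * d["x1"])  # strictly monotone in x1 only
    coef = prcc(d, "y")
    assert coef["x1"] > 0.99
    assert abs(coef["x2"]) < 0.2 and abs(coef["x3"]) < 0.2


def test_prcc_invariant_under_monotone_transforms():
    d = unit_design(100, ["x1", "x2"])
    d["y"] = d["x1"] ** 2 + 0.3 * d["x2"] + 0.05
    base = prcc(d, "y")
    d2 = d.copy()
    d2["y"] = np.log(d2["y"])  # monotone transform of the response
    d2["x1"] = np.exp(5 * d2["x1"])  # and of a parameter
    after = prcc(d2, "y")
    assert np.allclose(base.to_numpy(), after.to_numpy())


def test_prcc_guards():
    d = unit_design(30, ["a", "b"])
    d["y"] = d["a"]
    with pytest.raises(ValueError, match="at least"):
        prcc(d.head(4), "y")
    d["b"] = d["a"]  # rank-collinear pair
    with pytest.raises(ValueError, match="collinear"):
        prcc(d, "y")


def test_prcc_drops_non_converged_rows():
    d = unit_design(60, ["a", "b"])
    d["y"] = d["a"]
    d["converged"] = True
    d.loc[:9, "y"] = -99.0  # poisoned rows
    d.loc[:9, "converged"] = False
    assert prcc(d, "y")["a"] > 0.999


def test_run_ensemble_smoke_and_outputs():
    """A tiny ensemble wires every sampled parameter into a converged run."""
    bounds = {
        "depth": (10.0, 30.0),
        "D_inf": (6e-6, 7e-6),
        "Smax": (0.5, 0.7),
        "Ks": (0.5, 0.9),
        "kd": (0.8, 1.6),
        "Ccyto": (5.0, 20.0),
        "P": (1.15e-4, 2e-4),
        "Imax": (0.01, 0.03),
        "KI": (0.05, 0.3),
        "v0": (1e-9, 1e-7),
        "Q10": (2.0, 2.7),
    }
    m = sobol_design(SensitivityDesign(n_samples=128, parameters=bounds)).head(2)
    out = run_ensemble(m, numerics={"advection": True})
    assert len(out) == 2
    assert out["converged"].all()
    for col in ("rhizoplane_C", "extent_mm", "net_exudation"):
        assert (out[col] > 0).all()


def test_depth_regression_recovers_linear_trend():
    rng = np.random.default_rng(11)
    depth = rng.uniform(10, 100, 200)
    t = pd.DataFrame({"depth": depth, "rhizoplane_C": 2.0 + 0.05 * depth})
    reg = depth_regression(t)
    assert reg["slope"] == pytest.approx(0.05, rel=1e-6)
    assert reg["r_squared"] == pytest.approx(1.0)
    assert reg["n"] == 200


def test_binned_prcc_bins_and_sparse_warning():
    rng = np.random.default_rng(13)
    n = 240
    t = pd.DataFrame(
        {
            "depth": rng.uniform(10, 30, n),
            "a": rng.uniform(size=n),
            "b": rng.uniform(size=n),
        }
    )
    t["y"] = t["a"] + 0.01 * rng.normal(size=n)
    out = binned_prcc(t, "y")
    assert len(out) == 2  # [10,20) and [20,30)
    assert (out["a"] > 0.9).all()
    # a nearly empty bin is skipped with a warning
    sparse = pd.concat([t, t.head(2).assign(depth=95.0)], ignore_index=True)
    with pytest.warns(UserWarning, match="skipped"):
        out2 = binned_prcc(sparse, "y")
    assert len(out2) == 2
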