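import json
import math
from dataclasses import replace

import numpy as np
import pytest

from rhizograd import (
    RootParams,
    SimConfig,
    build_grid,
    depth_properties,
    depth_sweep,
    effective_mineralization_rate,
    get_fixture,
    rhizosphere_extent,
    run_to_equilibrium,
)
from .oracles import bessel_steady_state

ROOT = RootParams(r0=0.0642)
FAST = {"n_annuli": 250, "dr": 0.04, "dt": 30.0}


def run(solute, depth=10.0, **kw):
    return run_to_equilibrium(
        SimConfig(solute=solute, root=ROOT, depth=depth, **kw)
    )


def test_bessel_steady_state_oracle():
    """Pure diffusion + decay equilibrium matches the analytic K0 profile
    within 2% over the entire resolved gradient."""
    s = replace(get_fixture("glucose"), Imax=0.0, KI=0.0, Smax=0.0, Ks=0.0, kd=1.0)
    res = run(s, dt=1.0, sorption_enabled=False, retardation_enabled=False)
    assert res.converged
    dp = depth_properties(10.0)
    k_eff = effective_mineralization_rate(s, dp)
    where = res.C_umol_cm3 > 1e-4 * res.C_umol_cm3[0]
    analytic = bessel_steady_state(s, ROOT, dp, k_eff, res.r_cm[where])
    assert np.allclose(res.C_umol_cm3[where], analytic, rtol=0.02)
    assert res.mass_ledger_error() < 1e-6


def test_zero_sink_equilibrium_is_cytoplasm_concentration():
    """With no sinks and no recapture the soil must equilibrate with the
    cytoplasm pool (zero net flux fixed point)."""
    s = replace(
        get_fixture("glucose"), P=10.0, Imax=0.0, KI=0.0, Smax=0.0, Ks=0.0, kd=0.0
    )
    res = run(s, n_annuli=2, dr=0.05, dt=1.0, sorption_enabled=False)
    assert res.converged
    assert np.allclose(res.C_umol_cm3, s.Ccyto, rtol=1e-4)
    # residual net flux is negligible against the zero-concentration efflux
    scale = ROOT.A * s.P * s.Ccyto * 1e3  # nmol cm^-1 hr^-1
    assert abs(res.net_exudation_nmol_cm_hr) / scale < 1e-4


def test_equilibrium_budget_identity():
    """At equilibrium, net exudation balances the mineralization sink and the
    trajectory mass ledger closes."""
    s = get_fixture("glycine")
    res = run(s, **FAST)
    assert res.converged
    assert res.mass_ledger_error() < 1e-6
    net = res.net_exudation_nmol_cm_hr
    assert net == pytest.approx(res.mineralization_rate_nmol_cm_hr, rel=5e-3)
    assert res.efflux_nmol_cm_hr - res.influx_nmol_cm_hr == pytest.approx(net)
    assert 0 < res.recapture_pct < 100


def test_grid_and_step_refinement_below_one_percent():
    """Halving the annulus width and the time step moves every reported
    equilibrium quantity by < 1% at the production resolution."""
    s = get_fixture("glycine")
    base = run(s, n_annuli=500, dr=0.02, dt=1.0)
    fine = run(s, n_annuli=1000, dr=0.01, dt=0.5)
    for attr in (
        "rhizoplane_C_nmol_cm3",
        "extent_mm",
        "net_exudation_nmol_cm_hr",
        "influx_nmol_cm_hr",
        "efflux_nmol_cm_hr",
    ):
        a, b = getattr(base, attr), getattr(fine, attr)
        assert abs(a - b) / b < 0.01, attr


def test_deeper_layers_accumulate_more():
    """Colder, microbially poorer deep peat mineralizes exudate more slowly,
    so the same root builds a higher rhizoplane concentration and a wider
    rhizosphere at depth."""
    s = get_fixture("glucose")
    rows = depth_sweep(
        SimConfig(solute=s, root=ROOT, **FAST), depths=[10.0, 40.0, 80.0]
    )
    C = rows["rhizoplane_C_nmol_cm3"].to_numpy()
    ext = rows["extent_mm"].to_numpy()
    assert np.all(np.diff(C) > 0)
    assert np.all(np.diff(ext) > 0)
    assert np.all(rows["converged"])
    # recapture strengthens with the larger pool
    rec = rows["recapture_pct"].to_numpy()
    assert np.all(np.diff(rec) > 0)


def test_depth_sweep_rejects_out_of_range_depth():
    s = get_fixture("glycine")
    with pytest.raises(ValueError, match="outside the working range"):
        depth_sweep(SimConfig(solute=s, root=ROOT, **FAST), depths=[0.5])


def test_charged_solute_no_recapture_and_stable_efflux():
    """Anions are exported by the membrane potential and never recaptured;
    their gross efflux barely senses depth (the soil concentration stays far
    below the GHK reversal point)."""
    m = get_fixture("malate")
    effl = []
    for d in (10.0, 40.0, 80.0):
        res = run(m, depth=d, **FAST)
        assert res.converged
        assert res.influx_nmol_cm_hr == 0.0
        assert res.mass_ledger_error() < 1e-6
        effl.append(res.efflux_nmol_cm_hr)
    effl = np.array(effl)
    assert np.all(effl > 0)
    assert np.ptp(effl) / effl.mean() < 0.10


def test_class_ordering_organic_acids_exude_fastest():
    """Per unit cytoplasm pool, the charged pathway exports faster than
    passive leakage (higher permeability and field enhancement)."""
    sugar = run(get_fixture("glucose"), **FAST)
    acid = run(get_fixture("malate"), **FAST)
    assert (
        acid.efflux_nmol_cm_hr / get_fixture("malate").Ccyto
        > sugar.efflux_nmol_cm_hr / get_fixture("glucose").Ccyto
    )


def test_advection_term_enters_ledger():
    s = get_fixture("glycine")
    root = RootParams(r0=0.0642, v0=2e-6)
    res = run_to_equilibrium(
        SimConfig(solute=s, root=root, depth=10.0, advection=True, **FAST)
    )
    assert res.converged
    assert res.cum_advected_umol > 0
    assert res.mass_ledger_error() < 1e-6
    base = run(s, **FAST)
    # water converging on the root carries solute back: smaller gradient
    assert res.rhizoplane_C_nmol_cm3 < base.rhizoplane_C_nmol_cm3


def test_secant_retardation_variant_runs():
    s = get_fixture("glucose")
    res = run(s, retardation="secant", **FAST)
    assert res.converged
    assert res.mass_ledger_error() < 1e-6


def test_dt_auto_reduced_to_stability_bound():
    s = get_fixture("glycine")
    res = run(s, n_annuli=100, dr=0.1, dt=1e6)
    assert res.dt_s <= 0.5 * 0.1**2 / s.D_inf
    assert res.converged


def test_non_convergence_is_flagged_not_raised():
    s = get_fixture("glucose")
    res = run(s, max_sim_time=120.0, **FAST)
    assert not res.converged
    assert res.time_to_equilibrium_s <= 150.0


def test_rhizosphere_extent_edge_cases():
    g = build_grid(r0=0.0642, n=50, dr=0.02)
    assert rhizosphere_extent(np.zeros(g.n), g) == 0.0
    with pytest.warns(UserWarning, match="capped"):
        full = rhizosphere_extent(np.full(g.n, 1.0), g)
    assert full == pytest.approx(g.n * g.dr * 10.0)
    with pytest.warns(UserWarning, match="monotone"):
        rhizosphere_extent(np.linspace(0.0, 1.0, g.n), g)
    # interpolated crossing sits between the bracketing annulus centers
    C = np.geomspace(1.0, 1e-8, g.n)
    ext = rhizosphere_extent(C, g, threshold_nmol_cm3=0.01)
    i = int(np.nonzero(C < 0.01 * 1e-3)[0][0])
    assert (g.r_center[i - 1] - g.r0) * 10 < ext < (g.r_center[i] - g.r0) * 10


def test_result_summary_serializable_and_profile_frame():
    s = get_fixture("glycine")
    res = run(s, **FAST)
    blob = json.loads(json.dumps(res.summary()))
    assert blob["depth_cm"] == 10.0
    assert "rhizoplane_C_nmol_cm3" in blob
    frame = res.profile_frame()
    assert list(frame.columns) == [
        "r_cm", "C_umol_cm3", "sorbed_umol", "mineralized_cum_umol",
    ]
    assert len(frame) == FAST["n_annuli"]
    # interpolation accessor agrees with the stored profile at the centers
    assert res.concentration_at(res.r_cm[3]) == pytest.approx(res.C_umol_cm3[3])


def test_sim_config_validation():
    s = get_fixture("glucose")
    with pytest.raises(ValueError):
        SimConfig(solute=s, root=ROOT, eq_rel_tol=0.0)
    with pytest.raises(ValueError):
        SimConfig(solute=s, root=ROOT, rhizosphere_threshold=-1.0)
    with pytest.raises(ValueError):
        SimConfig(solute=s, root=ROOT, retardation="chord")
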