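"""PBK core: Vmax scaling, ODE construction, integration, mass balance, metrics."""

import numpy as np
import pytest

import pbkra
from pbkra.errors import ConfigurationError, InputError
from pbkra.model import Compartment, PBKModel, mass_balance_error, summary_metrics


@pytest.fixture(scope="module")
def es_result(physiology, estragole, realistic_dose):
    system = pbkra.build_model(physiology, estragole, realistic_dose)
    return system, pbkra.simulate(system)


# -- scaling and construction -------------------------------------------------

def test_scale_vmax_hand_arithmetic(physiology, estragole):
    # 0.7 nmol/min/mg x 32 mg/g x 1560 g x 60 / 1000 and the S9 analogue
    assert pbkra.scale_vmax(estragole.pathway("HE"), physiology) == pytest.approx(2096.64)
    assert pbkra.scale_vmax(estragole.pathway("HEG"), physiology) == pytest.approx(3881.592)
    zero = pbkra.MetabolicPathway("Z", "none", 1, 0.0, 10.0)
    assert pbkra.scale_vmax(zero, physiology) == 0.0


def test_initial_gut_amount_from_dose_and_mw(physiology, methyleugenol, realistic_dose):
    system = pbkra.build_model(physiology, methyleugenol, realistic_dose)
    assert system.dose_total_umol == pytest.approx(0.07 * 60 / 178.2 * 1000, rel=1e-12)
    assert system.dose_total_umol == pytest.approx(23.57, abs=0.005)


def test_flow_conservation_at_build_time(physiology, estragole, realistic_dose):
    system = pbkra.build_model(physiology, estragole, realistic_dose)
    total = system.liver.flow + sum(t.flow for t in system.tissues)
    assert total == pytest.approx(system.cardiac_output, abs=1e-9 * system.cardiac_output)


def test_negative_dose_is_a_range_error():
    with pytest.raises(InputError, match="oral_dose"):
        pbkra.DoseRegimen(oral_dose=-1.0)


def test_kidney_handling(physiology, safrole, realistic_dose):
    # strict request fails without kidney fractions; default lumps with a warning
    with pytest.raises(ConfigurationError, match="kidney"):
        pbkra.build_model(physiology, safrole, realistic_dose, include_kidney=True)
    with pytest.warns(UserWarning, match="lumped"):
        system = pbkra.build_model(physiology, safrole, realistic_dose)
    assert [t.name for t in system.tissues] == ["fat", "richly", "slowly"]


# -- trajectories -------------------------------------------------------------

def test_zero_dose_gives_identically_zero_trajectories(physiology, estragole):
    dose = pbkra.DoseRegimen(oral_dose=0.0, duration=4.0)
    system = pbkra.build_model(physiology, estragole, dose)
    result = pbkra.simulate(system)
    assert float(result.amounts.abs().to_numpy().max()) == 0.0
    assert result.mass_balance_error == 0.0  # convention for zero dose


def test_mass_balance_below_1e6_for_all_fixtures(physiology, realistic_dose):
    import warnings

    for name in pbkra.BUILTIN_CHEMICALS:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            system = pbkra.build_model(
                physiology, pbkra.builtin_chemical(name), realistic_dose)
        result = pbkra.simulate(system)
        assert result.mass_balance_error < 1e-6, name


def test_disabling_a_tracker_shows_up_as_its_metabolised_share(es_result):
    system, result = es_result
    share = result.trackers["EE"].iloc[-1] / system.dose_total_umol
    broken = pbkra.SimulationResult(
        time=result.time, amounts=result.amounts,
        venous_concentration=result.venous_concentration,
        trackers=result.trackers.assign(EE=0.0),
        tracker_phase=result.tracker_phase, hydroxy_id=result.hydroxy_id,
        dose_total_umol=result.dose_total_umol, label=result.label,
    )
    assert mass_balance_error(broken) == pytest.approx(share, rel=1e-6)
    assert share > 0.1  # the epoxide route is a substantial pathway


def test_trackers_non_decreasing_and_gut_non_increasing(es_result):
    _, result = es_result
    for col in result.trackers.columns:
        assert np.all(np.diff(result.trackers[col].to_numpy()) >= -1e-9)
    assert np.all(np.diff(result.amounts["gut"].to_numpy()) <= 1e-9)
    assert float(result.amounts.to_numpy().min()) > -1e-9


def test_every_metabolic_rate_bounded_by_its_scaled_vmax(es_result):
    system, result = es_result
    dt = np.diff(result.time)
    for tid, vmax, _ in system.phase1 + system.phase2:
        rates = np.diff(result.trackers[tid].to_numpy()) / dt
        assert rates.max() <= vmax * 1.001, tid


def test_halving_tolerances_changes_amounts_by_less_than_0p1pct(
        physiology, methyleugenol, realistic_dose):
    system = pbkra.build_model(physiology, methyleugenol, realistic_dose)
    a = pbkra.simulate(system, rel_tol=1e-8, abs_tol=1e-10)
    b = pbkra.simulate(system, rel_tol=5e-9, abs_tol=5e-11)
    for col in ("liver", "metabolite_liver"):
        xa, xb = a.amounts[col].to_numpy(), b.amounts[col].to_numpy()
        assert np.max(np.abs(xa - xb)) < 1e-3 * max(xa.max(), 1e-12)
    ta = np.array(list(summary_metrics(a)["terminal_trackers"].values()))
    tb = np.array(list(summary_metrics(b)["terminal_trackers"].values()))
    assert np.all(np.abs(ta - tb) <= 1e-3 * np.maximum(ta, 1e-12))


def test_low_dose_linearity_doubling_dose_doubles_terminal_trackers(
        physiology, methyleugenol):
    def terminal(dose_mg):
        dose = pbkra.DoseRegimen(oral_dose=dose_mg, duration=24.0)
        result = pbkra.simulate(pbkra.build_model(physiology, methyleugenol, dose))
        return np.array(list(summary_metrics(result)["terminal_trackers"].values()))

    lo, hi = terminal(0.035), terminal(0.07)
    assert np.all(np.abs(hi / lo - 2.0) < 0.1)  # within 5% of doubling


# -- reduced-instance solver verification -------------------------------------

def _reduced_system(dose_umol=20.0, ka=1.0, ql=70.0, vl=1.56, pl=6.2,
                    vmax=2000.0, km=50.0, plh=1.4, vrest=58.0):
    """Gut + liver instance: the only perfused tissue is the liver."""
    dose = pbkra.DoseRegimen(oral_dose=1.0, absorption_rate=ka, duration=2.0)
    system = PBKModel(
        cardiac_output=ql,
        liver=Compartment("liver", ql, vl, pl),
        tissues=[],
        phase1=[("HYD", vmax, km)],
        phase2=[],
        hydroxy_id="HYD",
        metabolite_liver_partition=plh,
        metabolite_rest_volume=vrest,
        blood_volume=4.7,
        dose=dose,
        mw_parent=1000.0 / dose_umol * 60.0,  # makes dose_total_umol == dose_umol
        body_weight=60.0,
    )
    return system


def _rk4_oracle(dose_umol, ka, ql, vl, pl, vmax, km, plh, vrest, t_end, dt=1e-4):
    """Independent fixed-step 4th-order integrator of the reduced equations."""
    def rhs(y):
        agi, al, alm, abm, trk = y
        cvl = al / (vl * pl)
        v = vmax * cvl / (km + cvl)
        cvlm = alm / (vl * plh)
        cam = abm / vrest
        return np.array([
            -ka * agi,
            ka * agi - v,            # arterial equals liver venous: flow term cancels
            v + ql * (cam - cvlm),
            ql * (cvlm - cam),
            v,
        ])

    y = np.array([dose_umol, 0.0, 0.0, 0.0, 0.0])
    n = int(round(t_end / dt))
    for _ in range(n):
        k1 = rhs(y)
        k2 = rhs(y + 0.5 * dt * k1)
        k3 = rhs(y + 0.5 * dt * k2)
        k4 = rhs(y + dt * k3)
        y = y + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
    return y


def test_stiff_solver_matches_fixed_step_oracle_on_reduced_instance():
    kwargs = dict(dose_umol=20.0, ka=1.0, ql=70.0, vl=1.56, pl=6.2,
                  vmax=2000.0, km=50.0, plh=1.4, vrest=58.0)
    system = _reduced_system(**kwargs)
    result = pbkra.simulate(system, duration=2.0)
    oracle = _rk4_oracle(**kwargs, t_end=2.0)
    stiff = np.array([
        result.amounts["gut"].iloc[-1],
        result.amounts["liver"].iloc[-1],
        result.amounts["metabolite_liver"].iloc[-1],
        result.amounts["metabolite_rest"].iloc[-1],
        result.trackers["HYD"].iloc[-1],
    ])
    scale = max(abs(oracle).max(), 1e-12)
    assert np.max(np.abs(stiff - oracle)) < 1e-3 * scale


# -- summary metrics ----------------------------------------------------------

def test_summary_metrics_on_known_trajectories(es_result):
    import pandas as pd

    _, result = es_result
    m = summary_metrics(result)
    assert m["cmax"]["liver"] == pytest.approx(result.amounts["liver"].max())
    assert m["tmax"]["liver"] == result.time[int(np.argmax(result.amounts["liver"]))]
    # closed form: unit-amount constant trajectory integrates to the duration
    t = np.linspace(0.0, 24.0, 25)
    flat = pbkra.SimulationResult(
        time=t, amounts=pd.DataFrame({"liver": np.ones_like(t)}),
        venous_concentration=np.zeros_like(t),
        trackers=pd.DataFrame({"HE": np.zeros_like(t)}),
        tracker_phase={"HE": 1}, hydroxy_id="HE", dose_total_umol=1.0, label="flat",
    )
    fm = summary_metrics(flat)
    assert fm["auc"]["liver"] == pytest.approx(24.0)
    assert fm["cmax"]["liver"] == 1.0 and fm["tmax"]["liver"] == 0.0


def test_empty_grid_is_an_input_error(es_result):
    import pandas as pd

    empty = pbkra.SimulationResult(
        time=np.array([]), amounts=pd.DataFrame(),
        venous_concentration=np.array([]), trackers=pd.DataFrame(),
        tracker_phase={}, hydroxy_id="HE", dose_total_umol=1.0, label="empty",
    )
    with pytest.raises(InputError):
        summary_metrics(empty)


def test_tidy_export_round_trip(tmp_path, es_result):
    import pandas as pd

    _, result = es_result
    path = tmp_path / "out.csv"
    result.to_csv(path)
    frame = pd.read_csv(path)
    assert set(frame.columns) == {"time_h", "variable", "value", "units"}
    liver = frame[frame.variable == "liver"]
    assert liver.value.max() == pytest.approx(result.amounts["liver"].max())
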