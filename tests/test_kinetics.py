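"""Rate conversion, Michaelis-Menten fitting, Dixon analysis, activation."""

import numpy as np
import pytest

from glyi.kinetics import (EPSILON_TNB_412NM, KineticParams, KineticsDataset,
                           KineticsError, competitive_rate, dixon_ki,
                           fit_competitive, fit_mm, linearize,
                           metal_activation, mm_rate, rate_from_absorbance)
from glyi.synthetic import (DIXON_DESIGN_I, DIXON_DESIGN_S, DWM_PARAMS,
                            MM_DESIGN_S, make_kinetics)


# ---------------------------------------------------------------------------
# absorbance -> specific activity
# ---------------------------------------------------------------------------

def test_rate_from_absorbance_standard_assay():
    rec = rate_from_absorbance(0.0286, 2.86, 1.0, 0.4, 0.025)
    assert rec.specific_activity == pytest.approx(0.16, rel=1e-12)
    assert rate_from_absorbance(0.0, protein=1.0).specific_activity == 0.0


def test_rate_from_absorbance_glutathione_assay_coefficient():
    rec = rate_from_absorbance(0.0136, EPSILON_TNB_412NM, 1.0, 0.5, 1.0)
    assert rec.specific_activity == pytest.approx(0.0005, rel=1e-12)


def test_rate_from_absorbance_scaling_and_sign():
    base = rate_from_absorbance(0.01, protein=0.1).specific_activity
    assert rate_from_absorbance(0.02, protein=0.1).specific_activity == \
        pytest.approx(2 * base)
    assert rate_from_absorbance(0.01, volume=0.8, protein=0.1
                                ).specific_activity == pytest.approx(2 * base)
    assert rate_from_absorbance(0.01, protein=0.2).specific_activity == \
        pytest.approx(base / 2)
    assert rate_from_absorbance(-0.01, protein=0.1).specific_activity == \
        pytest.approx(base)
    with pytest.raises(KineticsError):
        rate_from_absorbance(0.01, protein=0.0)


# ---------------------------------------------------------------------------
# rate laws
# ---------------------------------------------------------------------------

def test_mm_rate_anchor_points():
    p = DWM_PARAMS
    assert mm_rate(p, p.km) == pytest.approx(p.vmax / 2)
    assert mm_rate(p, 0.0) == 0.0
    assert mm_rate(p, 0.75) == pytest.approx(0.519 * 0.75 / (0.092 + 0.75),
                                             rel=1e-12)


def test_competitive_rate_definitions():
    p = DWM_PARAMS
    assert competitive_rate(p, 0.3, 0.0) == pytest.approx(mm_rate(p, 0.3))
    # at I = Ki the apparent Km doubles
    half_shifted = p.vmax * 0.3 / (2 * p.km + 0.3)
    assert competitive_rate(p, 0.3, p.ki) == pytest.approx(half_shifted)
    expected = 0.519 * 0.5 / (0.092 * (1 + 5 / 6.5) + 0.5)
    assert competitive_rate(p, 0.5, 5.0) == pytest.approx(expected, rel=1e-12)
    with pytest.raises(KineticsError):
        competitive_rate(KineticParams(vmax=1, km=1), 1.0, 1.0)


def test_competitive_rate_monotonicity():
    p = DWM_PARAMS
    s = np.linspace(0.01, 1.0, 20)
    for i_low, i_high in [(0.0, 1.0), (1.0, 5.0)]:
        assert (np.asarray(competitive_rate(p, s, i_high)) <=
                np.asarray(competitive_rate(p, s, i_low)) + 1e-15).all()
    v = np.asarray(mm_rate(p, s))
    assert (np.diff(v) >= 0).all()


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def test_fit_mm_recovers_study_parameters_exactly():
    data, _ = make_kinetics(noise_sigma=0.0)
    fit = fit_mm(data)
    assert fit.km == pytest.approx(0.092, rel=1e-6)
    assert fit.vmax == pytest.approx(0.519, rel=1e-6)
    assert fit.converged


def test_fit_mm_unit_parameters():
    s = np.array([0.1, 0.3, 1.0, 3.0, 10.0])
    data = KineticsDataset(s=s, v=s / (1 + s))
    fit = fit_mm(data)
    assert fit.vmax == pytest.approx(1.0, rel=1e-9)
    assert fit.km == pytest.approx(1.0, rel=1e-9)


@pytest.mark.parametrize("vmax, km", [(0.01, 0.05), (0.5, 0.1), (2.0, 1.0),
                                      (10.0, 0.01), (1.0, 10.0)])
def test_fit_mm_recovery_sweep(vmax, km):
    """Noise-free recovery across the parameter plane."""
    s = np.geomspace(km / 10, km * 10, 12)
    data = KineticsDataset(s=s, v=vmax * s / (km + s))
    fit = fit_mm(data)
    assert fit.vmax == pytest.approx(vmax, rel=1e-6)
    assert fit.km == pytest.approx(km, rel=1e-6)


def test_fit_mm_noisy_within_three_se():
    data, _ = make_kinetics(noise_sigma=0.02, replicates=3, seed=11)
    fit = fit_mm(data)
    assert abs(fit.km - 0.092) < 3 * fit.km_se
    assert abs(fit.vmax - 0.519) < 3 * fit.vmax_se


# ---------------------------------------------------------------------------
# linearizations
# ---------------------------------------------------------------------------

def test_linearize_parameter_interpretation():
    data, _ = make_kinetics(noise_sigma=0.0)
    lb = linearize(data, "lineweaver_burk")
    assert lb.intercept == pytest.approx(1 / 0.519, rel=1e-9)
    assert lb.slope == pytest.approx(0.092 / 0.519, rel=1e-9)
    hanes = linearize(data, "hanes")
    assert hanes.slope == pytest.approx(1 / 0.519, rel=1e-9)


def test_linearize_cross_method_consistency():
    data, _ = make_kinetics(noise_sigma=0.0)
    fits = [linearize(data, kind) for kind in
            ("lineweaver_burk", "eadie_hofstee", "eadie_scatchard", "hanes")]
    for fit in fits:
        assert fit.vmax == pytest.approx(0.519, rel=1e-9)
        assert fit.km == pytest.approx(0.092, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)


def test_linearize_excludes_zero_rates():
    data = KineticsDataset(s=np.array([0.0, 0.1, 0.5, 1.0]),
                           v=np.array([0.0, 0.2, 0.4, 0.45]))
    with pytest.warns(UserWarning, match="excluded"):
        fit = linearize(data, "lineweaver_burk")
    assert fit.n_excluded == 1
    with pytest.raises(KineticsError):
        linearize(data, "semilog")


# ---------------------------------------------------------------------------
# Dixon analysis
# ---------------------------------------------------------------------------

def test_dixon_recovers_study_ki_exactly():
    data, _ = make_kinetics(s_design=DIXON_DESIGN_S, i_design=DIXON_DESIGN_I,
                            noise_sigma=0.0)
    res = dixon_ki(data)
    assert res.ki == pytest.approx(6.5, rel=1e-6)
    assert res.global_fit.ki == pytest.approx(6.5, rel=1e-6)
    assert res.ki == pytest.approx(res.global_fit.ki, rel=1e-6)


def test_dixon_closed_form_two_lines():
    params = KineticParams(vmax=1.0, km=1.0, ki=2.0)
    data, _ = make_kinetics(params=params, s_design=(0.5, 2.0),
                            i_design=(0.5, 1.0, 2.0), noise_sigma=0.0)
    res = dixon_ki(data, with_global_fit=False)
    assert res.ki == pytest.approx(2.0, rel=1e-9)   # intersection at I = -Ki


def test_dixon_degenerate_designs():
    params = KineticParams(vmax=1.0, km=1.0, ki=2.0)
    with pytest.raises(KineticsError, match="fewer than 2 inhibitor"):
        data, _ = make_kinetics(params=params, s_design=(0.5, 2.0),
                                i_design=(1.0,), noise_sigma=0.0)
        dixon_ki(data)
    # parallel 1/v lines (shared slope): the non-competitive pattern
    i = np.tile([0.5, 1.0, 2.0], 2)
    s = np.repeat([0.5, 2.0], 3)
    inv_v = (1 + 1 / s) + 0.7 * i
    with pytest.raises(KineticsError, match="parallel"):
        dixon_ki(KineticsDataset(s=s, v=1 / inv_v, i=i),
                 with_global_fit=False)


def test_dixon_agrees_with_global_fit_under_noise():
    diffs = []
    for seed in range(30):
        data, _ = make_kinetics(s_design=DIXON_DESIGN_S,
                                i_design=DIXON_DESIGN_I, noise_sigma=0.02,
                                replicates=3, seed=4000 + seed)
        res = dixon_ki(data)
        diffs.append(res.ki - res.global_fit.ki)
    diffs = np.array(diffs)
    # the two estimators are mutually consistent: mean discrepancy within
    # 3 SE of zero
    assert abs(diffs.mean()) < 3 * diffs.std(ddof=1) / np.sqrt(len(diffs))


# ---------------------------------------------------------------------------
# metal activation
# ---------------------------------------------------------------------------

def test_metal_activation_two_point_slope():
    fit = metal_activation([0.125, 1.5], [5.0, 75.0])
    assert fit.slope == pytest.approx(70 / 1.375, rel=1e-12)
    assert fit.predict(1.5) == pytest.approx(75.0)


def test_metal_activation_flat_and_errors():
    fit = metal_activation([0.125, 0.5, 1.5], [30.0, 30.0, 30.0])
    assert fit.slope == pytest.approx(0.0, abs=1e-12)
    assert fit.intercept == pytest.approx(30.0)
    with pytest.raises(KineticsError):
        metal_activation([0.5], [10.0])
    with pytest.warns(UserWarning, match="outside"):
        metal_activation([0.125, 1.5], [5.0, 75.0]).predict(3.0)
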