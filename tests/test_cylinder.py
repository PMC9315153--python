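import numpy as np
import pytest

from polarscope.cylinder import (
    DEFAULT_MEDIUM,
    STUDY_RADII_NM,
    CylinderSpec,
    MediumSpec,
    ScatteringTable,
    acceptance_half_angle,
    amplitude_to_mueller,
    cylinder_amplitudes,
    cylinder_coefficients,
    forward_fraction,
    phase_function,
    single_scatter_mueller,
    size_parameter,
)


def test_acceptance_half_angle_values():
    assert acceptance_half_angle(0.25) == pytest.approx(14.4775, abs=1e-3)
    assert acceptance_half_angle(0.8) == pytest.approx(53.1301, abs=1e-3)
    assert acceptance_half_angle(0.0) == 0.0
    with pytest.raises(ValueError):
        acceptance_half_angle(1.2)


def test_size_parameter():
    x = size_parameter(CylinderSpec(100.0, 1.43), DEFAULT_MEDIUM)
    assert x == pytest.approx(2 * np.pi * 100 * 1.35 / 633)


def test_phase_function_normalized_and_symmetric():
    pf = phase_function(CylinderSpec(200.0, 1.43), DEFAULT_MEDIUM)
    assert np.trapezoid(pf.density, pf.theta_grid_deg) == pytest.approx(1.0)
    # normal incidence: scattering is symmetric in +/- Theta
    assert np.allclose(pf.density, pf.density[::-1], rtol=1e-10)


def test_forward_fraction_increases_with_radius():
    fracs = [
        forward_fraction(phase_function(CylinderSpec(r, 1.43), DEFAULT_MEDIUM), 15.0)
        for r in STUDY_RADII_NM
    ]
    assert all(b > a for a, b in zip(fracs, fracs[1:]))


def test_rayleigh_wire_limit():
    # sub-wavelength cylinder: parallel mode uniform, perpendicular cos^2
    spec = CylinderSpec(5.0, 1.43)
    par = phase_function(spec, DEFAULT_MEDIUM, mode="parallel")
    uniform = np.full_like(par.density, 1.0 / 360.0)
    assert np.max(np.abs(par.density - uniform)) / uniform.max() < 0.01
    perp = phase_function(spec, DEFAULT_MEDIUM, mode="perpendicular")
    th = np.radians(perp.theta_grid_deg)
    cos2 = np.cos(th) ** 2
    cos2 /= np.trapezoid(cos2, perp.theta_grid_deg)
    assert np.max(np.abs(perp.density - cos2)) / cos2.max() < 0.01


def test_series_convergence_independent_of_truncation():
    spec = CylinderSpec(1500.0, 1.43)
    T1 = cylinder_amplitudes(spec, DEFAULT_MEDIUM, 90.0, np.array([0.0, 30.0, 90.0]))
    from polarscope.cylinder import _truncation_order

    n_hi = 2 * _truncation_order(size_parameter(spec, DEFAULT_MEDIUM))
    T2 = cylinder_amplitudes(spec, DEFAULT_MEDIUM, 90.0, np.array([0.0, 30.0, 90.0]), n_max=n_hi)
    assert np.max(np.abs(T1 - T2)) < 1e-10


def test_normal_incidence_has_no_cross_coupling():
    aI, aII, bI, bII = cylinder_coefficients(CylinderSpec(200.0, 1.43), DEFAULT_MEDIUM, 90.0)
    assert np.max(np.abs(aI)) < 1e-14
    assert np.max(np.abs(bII)) < 1e-14


def test_single_scatter_mueller_is_pure():
    # single-scattering Mueller matrices preserve the degree of
    # polarization: Gil-Bernabeu purity index equals 1
    M = single_scatter_mueller(CylinderSpec(1000.0, 1.43), DEFAULT_MEDIUM, 90.0, 25.0)
    purity = np.sqrt((np.sum(M * M) - M[0, 0] ** 2) / (3.0 * M[0, 0] ** 2))
    assert purity == pytest.approx(1.0, abs=1e-10)


def test_amplitude_to_mueller_identity_amplitude():
    M = amplitude_to_mueller(np.array([1.0 + 0j, 1.0 + 0j, 0j, 0j]))
    assert np.allclose(M, np.eye(4) * M[0, 0])


def test_invalid_inputs_rejected():
    with pytest.raises(ValueError):
        CylinderSpec(-1.0, 1.43)
    with pytest.raises(ValueError):
        MediumSpec(n_med=1.35, wavelength_vac_nm=-5.0)
    with pytest.raises(ValueError):
        cylinder_coefficients(CylinderSpec(100.0, 1.43), DEFAULT_MEDIUM, 0.0)


def test_scattering_table_lookup_and_sampling(rng):
    table = ScatteringTable(
        CylinderSpec(200.0, 1.43), DEFAULT_MEDIUM, zeta_step_deg=30.0, theta_step_deg=2.0
    )
    zi = table.zeta_index(90.0)
    assert table.zeta_grid[zi] == pytest.approx(90.0)
    draws = table.sample_theta(np.full(2000, zi), rng.uniform(size=2000))
    assert np.all(np.abs(draws) <= 180.0)
    # sampled angles follow the unpolarized density: compare forward mass
    pf = phase_function(CylinderSpec(200.0, 1.43), DEFAULT_MEDIUM)
    want = forward_fraction(pf, 30.0)
    got = np.mean(np.abs(draws) <= 30.0)
    assert got == pytest.approx(want, abs=0.05)
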