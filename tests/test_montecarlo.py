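import numpy as np
import pytest

from polarscope.cylinder import CylinderSpec, MediumSpec, DEFAULT_MEDIUM, ScatteringTable
from polarscope.montecarlo import (
    OrientationDistribution,
    SimConfig,
    d_vs_angle,
    run_simulation,
    sample_free_path,
    sample_orientation,
)


def _config(radius_nm=200.0, mu_s=200.0, n_photons=2000, seed=0, **kw):
    med = MediumSpec(n_med=1.35, wavelength_vac_nm=633.0, mu_s_per_cm=mu_s)
    return SimConfig(
        spec=CylinderSpec(radius_nm, 1.43), med=med, n_photons=n_photons, seed=seed, **kw
    )


def test_free_path_statistics(rng):
    u = rng.uniform(size=200_000)
    paths = sample_free_path(200.0, u)
    # mean free path 1/mu_s = 50 um
    assert np.mean(paths) == pytest.approx(50.0, rel=0.02)
    with pytest.raises(ValueError):
        sample_free_path(0.0, 0.5)
    with pytest.raises(ValueError):
        sample_free_path(200.0, 0.0)


def test_orientation_distribution(rng):
    axes = sample_orientation(OrientationDistribution(30.0), rng, size=50_000)
    assert np.allclose(np.linalg.norm(axes, axis=1), 1.0)
    # mean axis is +x; in-plane and out-of-plane angle spreads ~30 deg
    # two independent 30 deg tilts: E[x] ~ exp(-sigma^2) ~ 0.76
    assert np.mean(axes[:, 0]) > 0.7
    inplane = np.degrees(np.arctan2(axes[:, 1], axes[:, 0]))
    assert np.std(inplane) == pytest.approx(30.0, rel=0.1)
    exact = sample_orientation(OrientationDistribution(0.0), rng)
    assert np.allclose(exact, [1.0, 0.0, 0.0])


def test_empty_medium_identity_and_conservation():
    res = run_simulation(_config(mu_s=0.0, n_photons=500))
    assert res.n_transmitted + res.n_reflected == res.n_launched
    assert res.n_reflected == 0
    M = res.cumulative_mueller(90.0)
    assert np.allclose(M / M[0, 0], np.eye(4), atol=1e-12)


def test_photon_count_conserved_with_scattering():
    res = run_simulation(_config(n_photons=3000))
    assert res.n_transmitted + res.n_reflected == res.n_launched


def test_simulation_deterministic_per_seed():
    table = ScatteringTable(CylinderSpec(200.0, 1.43), DEFAULT_MEDIUM)
    a = run_simulation(_config(seed=11), table=table)
    b = run_simulation(_config(seed=11), table=table)
    c = run_simulation(_config(seed=12), table=table)
    assert np.array_equal(a.basis_sums, b.basis_sums)
    assert not np.array_equal(a.basis_sums, c.basis_sums)


def test_transmission_mueller_physical():
    res = run_simulation(_config(n_photons=20_000, seed=4))
    M = res.cumulative_mueller(55.0)
    Mn = M / M[0, 0]
    assert Mn[0, 0] == 1.0
    assert np.all(np.abs(Mn) <= 1.0 + 1e-9)
    # forward transmission through weak scattering stays near identity
    assert Mn[1, 1] > 0.9 and Mn[2, 2] > 0.9 and Mn[3, 3] > 0.9


def test_d_vs_angle_modes_and_errors():
    res = run_simulation(_config(n_photons=20_000, seed=4))
    D_cum = d_vs_angle(res, [5.0, 30.0, 55.0], mode="cumulative")
    assert np.all(np.isfinite(D_cum)) and np.all(D_cum >= 0)
    D_ann = d_vs_angle(res, [30.0, 55.0], mode="annular")
    assert np.all(np.isfinite(D_ann))
    with pytest.raises(ValueError):
        d_vs_angle(res, [5.0], mode="sideways")


def test_store_photons_round_trip():
    res = run_simulation(_config(n_photons=2000, seed=9), store_photons=True)
    assert res.photon_angles is not None
    assert len(res.photon_angles) == res.n_transmitted
    assert res.photon_stokes.shape == (res.n_transmitted, 4, 6)
    # re-binning stored photons reproduces the accumulated sums
    edges = res.bin_edges_deg
    which = np.clip(np.digitize(res.photon_angles, edges) - 1, 0, len(edges) - 2)
    rebinned = np.zeros_like(res.basis_sums)
    np.add.at(rebinned, which, res.photon_stokes)
    assert np.allclose(rebinned, res.basis_sums)


def test_differential_extinction_creates_forward_diattenuation():
    on = run_simulation(_config(radius_nm=100.0, n_photons=20_000, seed=2))
    off = run_simulation(
        _config(radius_nm=100.0, n_photons=20_000, seed=2, differential_extinction=False)
    )
    D_on = d_vs_angle(on, [5.0])[0]
    D_off = d_vs_angle(off, [5.0])[0]
    assert D_on > 10 * max(D_off, 1e-6)


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        _config(n_photons=0)
    with pytest.raises(ValueError):
        _config(bin_edges_deg=(0.0, 45.0))
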