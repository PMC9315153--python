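import numpy as np
import pytest

from polarscope.decomposition import decompose_image
from polarscope.phantom import (
    STUDY_MAGNIFICATIONS,
    MagnificationConfig,
    OpticalCoefficients,
    degrade_resolution,
    fiber_map_to_mueller,
    generate_fiber_map,
    generate_region_set,
)
from polarscope.stokes import is_physical_mueller


def test_fiber_map_fields_and_determinism():
    a = generate_fiber_map(64, 64, 6, seed=3)
    b = generate_fiber_map(64, 64, 6, seed=3)
    c = generate_fiber_map(64, 64, 6, seed=4)
    assert np.array_equal(a.density, b.density)
    assert not np.array_equal(a.density, c.density)
    assert a.density.min() >= 0 and a.density.max() <= 1
    assert np.all((0 <= a.orientation_rad) & (a.orientation_rad < np.pi))
    assert np.all(a.radius_nm > 0)


def test_mmpd_recovers_planted_truth_exactly(small_fiber_image):
    maps = decompose_image(small_fiber_image)
    truth = small_fiber_image.meta["truth"]
    assert np.nanmax(np.abs(maps.D_map - truth["D"])) < 1e-9
    assert np.nanmax(np.abs(maps.delta_map - truth["delta"])) < 1e-9
    assert np.nanmax(np.abs(maps.Delta_map - truth["Delta"])) < 1e-9


def test_native_pixels_are_physical(small_fiber_image):
    M = small_fiber_image.mueller
    sub = M[::13, ::13]
    for px in sub.reshape(-1, 4, 4):
        assert is_physical_mueller(px, tol=1e-8)


def test_study_magnifications_table():
    labels = [m.label for m in STUDY_MAGNIFICATIONS]
    assert labels == ["4x", "10x", "20x", "40x", "60x"]
    assert [m.NA for m in STUDY_MAGNIFICATIONS] == [0.10, 0.25, 0.40, 0.65, 0.80]
    assert [m.glcm_d for m in STUDY_MAGNIFICATIONS] == [1, 3, 5, 11, 15]
    assert STUDY_MAGNIFICATIONS[-1].target_pitch_um == pytest.approx(3.45 / 60)


def test_degrade_resolution_shapes_and_physicality(small_fiber_image):
    for cfg in STUDY_MAGNIFICATIONS[:3]:
        out = degrade_resolution(small_fiber_image, cfg)
        expect = round(96 * small_fiber_image.pixel_pitch_um / cfg.target_pitch_um)
        assert out.shape == (expect, expect)
        assert out.pixel_pitch_um == pytest.approx(cfg.target_pitch_um)
        for px in out.mueller[:: max(out.shape[0] // 4, 1), :: max(out.shape[1] // 4, 1)].reshape(-1, 4, 4):
            assert is_physical_mueller(px, tol=1e-8)


def test_degrade_rejects_upsampling(small_fiber_image):
    toofine = MagnificationConfig("200x", 0.9, 200.0, 1)
    with pytest.raises(ValueError):
        degrade_resolution(small_fiber_image, toofine)


def test_blur_reduces_spatial_variation(small_fiber_image):
    native_delta = decompose_image(small_fiber_image).delta_map
    low = degrade_resolution(small_fiber_image, STUDY_MAGNIFICATIONS[0])
    low_delta = decompose_image(low).delta_map
    grad_native = np.mean(np.abs(np.diff(native_delta, axis=0)))
    grad_low = np.mean(np.abs(np.diff(low_delta, axis=0)))
    # per-pixel variation at 4x (coarse pixels after heavy blur) exceeds
    # the native per-pixel step, but total variation across the field drops
    assert np.ptp(low_delta) <= np.ptp(native_delta) + 1e-9
    assert grad_native < 1.0 and grad_low < 1.0


def test_optical_coefficients_validation():
    with pytest.raises(ValueError):
        OpticalCoefficients(Delta0=0.8, c_Delta=0.3)
    with pytest.raises(ValueError):
        OpticalCoefficients(c_delta=4.0)


def test_region_set_reproducible_and_coupled_variants():
    a = generate_region_set(n_regions=3, seed=1, height=48, width=48)
    b = generate_region_set(n_regions=3, seed=1, height=48, width=48)
    assert all(np.array_equal(x.mueller, y.mueller) for x, y in zip(a, b))
    dec = generate_region_set(
        n_regions=3, seed=1, height=48, width=48, coupled_depolarization=False
    )
    # decoupled generator uses constant per-region Delta floors
    t = dec[0].meta["truth"]
    assert np.ptp(t["Delta"]) < 1e-12
    tc = a[0].meta["truth"]
    assert np.ptp(tc["Delta"]) > 0.01
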