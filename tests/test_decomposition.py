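import numpy as np
import pytest

from polarscope.decomposition import (
    decompose_image,
    lu_chipman,
    mueller_depolarizer,
    mueller_diattenuator,
    mueller_linear_retarder,
    retarder_axis,
)
from polarscope.stokes import mueller_of_polarizer


def _random_product(rng):
    D = rng.uniform(0.0, 0.95)
    dax = rng.uniform(0.0, 180.0)
    delta = rng.uniform(0.0, np.pi - 0.05)
    rax = rng.uniform(0.0, 180.0)
    a, b, c = rng.uniform(0.1, 1.0, size=3)
    M = mueller_depolarizer(a, b, c) @ mueller_linear_retarder(delta, rax) @ mueller_diattenuator(D, dax)
    truth = {"D": D, "delta": delta, "Delta": 1.0 - (a + b + c) / 3.0}
    return M, truth


def test_identity_decomposes_to_zeros():
    res = lu_chipman(np.eye(4))
    assert res.D == pytest.approx(0.0, abs=1e-12)
    assert res.delta == pytest.approx(0.0, abs=1e-6)
    assert res.Delta == pytest.approx(0.0, abs=1e-12)


def test_ideal_polarizer_gives_unit_diattenuation():
    res = lu_chipman(mueller_of_polarizer(20.0))
    assert res.D == pytest.approx(1.0, abs=1e-9)


def test_qwp_gives_quarter_wave_retardance():
    res = lu_chipman(mueller_linear_retarder(np.pi / 2, 35.0))
    assert res.delta == pytest.approx(np.pi / 2, abs=1e-12)
    assert retarder_axis(res.M_R) == pytest.approx(np.radians(35.0), abs=1e-9)


def test_random_products_recover_parameters(rng):
    worst = 0.0
    for _ in range(200):
        M, truth = _random_product(rng)
        res = lu_chipman(M)
        worst = max(
            worst,
            abs(res.D - truth["D"]),
            abs(res.delta - truth["delta"]),
            abs(res.Delta - truth["Delta"]),
        )
    assert worst < 1e-8


def test_factorization_reassembles(rng):
    M, _ = _random_product(rng)
    res = lu_chipman(M)
    assert np.allclose(res.M_Delta @ res.M_R @ res.M_D, M / M[0, 0], atol=1e-10)


def test_decompose_image_matches_scalar(rng):
    stack = np.empty((2, 3, 4, 4))
    truths = np.empty((2, 3, 3))
    for i in range(2):
        for j in range(3):
            M, truth = _random_product(rng)
            stack[i, j] = M
            truths[i, j] = truth["D"], truth["delta"], truth["Delta"]
    maps = decompose_image(stack)
    assert np.allclose(maps.D_map, truths[..., 0], atol=1e-9)
    assert np.allclose(maps.delta_map, truths[..., 1], atol=1e-9)
    assert np.allclose(maps.Delta_map, truths[..., 2], atol=1e-9)
    assert maps.valid.all()


def test_decompose_image_rejects_bad_shape():
    with pytest.raises(ValueError):
        decompose_image(np.zeros((3, 3)))


def test_depolarizer_parameter_range():
    with pytest.raises(ValueError):
        mueller_diattenuator(1.5)
    with pytest.raises(ValueError):
        mueller_depolarizer(1.5)
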