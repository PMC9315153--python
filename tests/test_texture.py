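import numpy as np
import pytest

from polarscope.texture import (
    DEFAULT_DIRECTIONS_DEG,
    GrayImage,
    compute_glcm,
    first_order_moments,
    glcm_features,
    normalize_to_gray,
    texture_summary,
)

# displacement offsets (drow, dcol) matching the pooled direction set,
# in the symmetric convention (each pair counted in both orders)
_OFFSETS = {
    0.0: (0, 1),
    45.0: (-1, 1),
    90.0: (-1, 0),
    135.0: (-1, -1),
}


def brute_force_glcm(z, d, Ng, directions=DEFAULT_DIRECTIONS_DEG):
    """Independent oracle: explicit pair enumeration."""
    q = (z.astype(np.int64) * Ng // 256).astype(int)
    H, W = q.shape
    counts = np.zeros((Ng, Ng))
    for ang in directions:
        dr, dc = _OFFSETS[ang]
        dr, dc = dr * d, dc * d
        for r in range(H):
            for c in range(W):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < H and 0 <= c2 < W:
                    counts[q[r, c], q[r2, c2]] += 1
                    counts[q[r2, c2], q[r, c]] += 1
    return counts / counts.sum()


def brute_force_features(p):
    Ng = p.shape[0]
    idx = np.arange(1, Ng + 1)
    contrast = sum(
        (i - j) ** 2 * p[i - 1, j - 1] for i in idx for j in idx
    )
    energy = (p**2).sum()
    homog = sum(p[i - 1, j - 1] / (1 + (i - j) ** 2) for i in idx for j in idx)
    px, py = p.sum(1), p.sum(0)
    mx, my = (idx * px).sum(), (idx * py).sum()
    sx = np.sqrt(((idx - mx) ** 2 * px).sum())
    sy = np.sqrt(((idx - my) ** 2 * py).sum())
    corr = (
        float("nan")
        if sx * sy == 0
        else (sum(i * j * p[i - 1, j - 1] for i in idx for j in idx) - mx * my) / (sx * sy)
    )
    return contrast, corr, energy, homog


@pytest.mark.parametrize("seed", [0, 1, 2])
@pytest.mark.parametrize("d", [1, 2])
def test_glcm_matches_brute_force_oracle(seed, d):
    rng = np.random.default_rng(seed)
    z = rng.integers(0, 256, size=(4, 4)).astype(np.uint8)
    got = compute_glcm(GrayImage(z), d=d, Ng=8)
    want = brute_force_glcm(z, d=d, Ng=8)
    assert np.allclose(got.p, want)
    feats = glcm_features(got)
    c, r, e, h = brute_force_features(want)
    assert feats.contrast == pytest.approx(c)
    assert feats.energy == pytest.approx(e)
    assert feats.homogeneity == pytest.approx(h)
    if np.isnan(r):
        assert np.isnan(feats.correlation)
    else:
        assert feats.correlation == pytest.approx(r)


def test_hand_counted_two_by_two():
    # image [[0, 0], [0, 255]] at Ng=2: levels [[0,0],[0,1]]
    z = np.array([[0, 0], [0, 255]], dtype=np.uint8)
    got = compute_glcm(GrayImage(z), d=1, Ng=2)
    # 0 deg pairs: (0,0),(0,1); 90 deg: (0,0),(0,1); 135 deg: (0,1); 45 deg: (0,0)
    # symmetric double counting, total 12 ordered pairs
    want = np.array([[6, 3], [3, 0]]) / 12.0
    assert np.allclose(got.p, want)


def test_constant_image_boundary_cases():
    z = np.full((5, 5), 7, dtype=np.uint8)
    feats = glcm_features(compute_glcm(GrayImage(z), d=1, Ng=64))
    assert feats.contrast == 0.0
    assert feats.energy == 1.0
    assert feats.homogeneity == 1.0
    assert np.isnan(feats.correlation)


def test_checkerboard_maximal_contrast_at_d1():
    z = np.indices((6, 6)).sum(0) % 2 * 255
    feats = glcm_features(compute_glcm(GrayImage(z.astype(np.uint8)), d=1, Ng=2))
    # axial neighbors differ (120 ordered pairs), diagonal ones are
    # equal (100), so contrast = 120/220 and levels anti-correlate
    assert feats.contrast == pytest.approx(120 / 220)
    assert feats.correlation < 0


def test_normalize_to_gray_range_and_rounding():
    g = normalize_to_gray(np.array([[0.0, 0.5, 1.0]]))
    assert g.pixels.tolist() == [[0, 128, 255]]
    with pytest.raises(ValueError):
        normalize_to_gray(np.ones((2, 2)), lo=1.0, hi=1.0)


def test_constant_map_normalizes_to_zero():
    g = normalize_to_gray(np.full((3, 3), 4.2))
    assert not g.pixels.any()


def test_first_order_moments_hand_computed():
    g = GrayImage(np.array([[0, 0], [255, 255]], dtype=np.uint8))
    mean, entropy = first_order_moments(g)
    assert mean == pytest.approx(127.5)
    assert entropy == pytest.approx(1.0)


def test_displacement_larger_than_image_rejected():
    with pytest.raises(ValueError):
        compute_glcm(GrayImage(np.zeros((3, 3), np.uint8)), d=3)


def test_texture_summary_combines_both_families(rng):
    v = rng.uniform(size=(16, 16))
    s = texture_summary(v, d=1)
    assert np.isfinite(s.mean) and np.isfinite(s.contrast)
    assert 0 < s.energy <= 1
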