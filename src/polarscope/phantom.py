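"""Synthetic Mueller-matrix images of collagen-like fibrous regions.

The generator emulates thin tissue sections rich in birefringent
fibers.  A region is a set of smooth random fiber strokes (correlated
random walks with Gaussian cross-profiles) on a high-resolution canvas;
each pixel carries a fiber density in [0, 1], a local axial orientation,
and a characteristic fiber radius drawn from a thin/coarse mixture
echoing real collagen populations.  The optical model composes, per
pixel and in this exact order,

    M = M_Delta(Delta) @ M_R(delta, axis) @ M_D(D, axis)

so that polar decomposition of the synthetic image recovers the planted
ground truth exactly at native resolution:

* linear retardance  delta = c_delta * density  aligned with the fiber,
* weak diattenuation D = D(radius) * density, where D(radius) follows
  the dichroism of the cylinder-scattering cross sections (thin fibers
  diattenuate more),
* depolarization Delta = Delta0 + c_Delta * density (a constant floor
  plus a density-coupled term, so delta and Delta correlate across
  regions with a known planted coupling).

An imaging model then degrades the native image to each objective:
Gaussian PSF of sigma = 0.21 lambda / NA at the sample plane, followed
by resampling to the camera pixel pitch divided by the magnification.
Both steps are convex pixel combinations, so degraded images remain
physical Mueller images.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.transform import resize

from polarscope.cylinder import CylinderSpec, MediumSpec, ScatteringTable

__all__ = [
    "FiberMap",
    "MuellerImage",
    "MagnificationConfig",
    "OpticalCoefficients",
    "STUDY_MAGNIFICATIONS",
    "generate_fiber_map",
    "fiber_map_to_mueller",
    "degrade_resolution",
    "generate_region_set",
]

#: Native canvas defaults: 360 x 360 pixels at the 60x sample-plane
#: pitch (3.45 um camera pixels / 60), i.e. a 20.7 um field of view.
NATIVE_SIZE = 360
NATIVE_PITCH_UM = 3.45 / 60.0


@dataclass(frozen=True)
class MagnificationConfig:
    """One objective: magnification label, NA, and analysis settings."""

    label: str
    NA: float
    magnification: float
    glcm_d: int
    camera_pitch_um: float = 3.45

    def __post_init__(self):
        if not 0 < self.NA < 1:
            raise ValueError("NA must be in (0, 1)")

    @property
    def target_pitch_um(self) -> float:
        """Sample-plane pixel pitch of the rendered image."""
        return self.camera_pitch_um / self.magnification


#: The five objectives of the study with their GLCM displacements.
STUDY_MAGNIFICATIONS = (
    MagnificationConfig("4x", 0.10, 4.0, 1),
    MagnificationConfig("10x", 0.25, 10.0, 3),
    MagnificationConfig("20x", 0.40, 20.0, 5),
    MagnificationConfig("40x", 0.65, 40.0, 11),
    MagnificationConfig("60x", 0.80, 60.0, 15),
)


@dataclass
class FiberMap:
    """Per-pixel fiber density, axial orientation and radius."""

    density: np.ndarray  # [0, 1]
    orientation_rad: np.ndarray  # axial, mod pi
    radius_nm: np.ndarray
    pixel_pitch_um: float
    seed: int

    def __post_init__(self):
        if self.density.shape != self.orientation_rad.shape or self.density.shape != self.radius_nm.shape:
            raise ValueError("all planes must share one shape")


@dataclass
class MuellerImage:
    """A pixel grid of 4x4 Mueller matrices with imaging metadata."""

    mueller: np.ndarray  # (H, W, 4, 4)
    pixel_pitch_um: float
    meta: dict = field(default_factory=dict)

    @property
    def shape(self):
        return self.mueller.shape[:2]


@dataclass(frozen=True)
class OpticalCoefficients:
    """Density-to-polarization coupling of the synthetic tissue.

    ``c_delta``: retardance (radians) at unit fiber density;
    ``d_scale``: overall diattenuation scale multiplying the
    radius-dependent dichroism factor; ``Delta0`` / ``c_Delta``:
    depolarization floor and density coupling.  Values are generator
    configuration, chosen for plausibility of thin fibrous sections
    (retardance up to ~1.2 rad, diattenuation below ~0.15, moderate
    depolarization).
    """

    c_delta: float = 1.2
    d_scale: float = 0.35
    Delta0: float = 0.05
    c_Delta: float = 0.35

    def __post_init__(self):
        if not 0 <= self.c_delta < np.pi:
            raise ValueError("c_delta must keep delta in [0, pi)")
        if self.Delta0 < 0 or self.c_Delta < 0 or self.Delta0 + self.c_Delta >= 1:
            raise ValueError("need 0 <= Delta0, 0 <= c_Delta, Delta0 + c_Delta < 1")
        if not 0 <= self.d_scale < 1:
            raise ValueError("d_scale must keep D in [0, 1)")


def generate_fiber_map(
    height: int,
    width: int,
    n_fibers: int,
    radius_mix: dict | None = None,
    orientation_field_params: dict | None = None,
    seed: int = 0,
    pixel_pitch_um: float = NATIVE_PITCH_UM,
) -> FiberMap:
    """Draw ``n_fibers`` smooth random strokes on a blank canvas.

    ``radius_mix`` keys: ``thin_frac`` (probability of a thin fiber),
    ``thin_range_nm`` and ``coarse_range_nm`` (uniform radius ranges).
    ``orientation_field_params`` keys: ``mean_deg`` (mean stroke
    direction), ``spread_deg`` (fiber-to-fiber spread), ``curliness_deg``
    (per-step direction noise).  Deterministic per seed.
    """
    if height <= 0 or width <= 0:
        raise ValueError("canvas dimensions must be positive")
    if n_fibers < 0:
        raise ValueError("n_fibers must be >= 0")
    mix = {"thin_frac": 0.5, "thin_range_nm": (100.0, 200.0), "coarse_range_nm": (1000.0, 1500.0)}
    if radius_mix:
        mix.update(radius_mix)
    ori = {"mean_deg": 0.0, "spread_deg": 25.0, "curliness_deg": 4.0}
    if orientation_field_params:
        ori.update(orientation_field_params)

    rng = np.random.default_rng(seed)
    density = np.zeros((height, width))
    cos2 = np.zeros((height, width))
    sin2 = np.zeros((height, width))
    rad_w = np.zeros((height, width))
    wsum = np.zeros((height, width))

    diag = float(np.hypot(height, width))
    step = 2.0  # pixels per walk step
    n_steps = int(diag / step * 1.4) + 4

    for _ in range(n_fibers):
        thin = rng.uniform() < mix["thin_frac"]
        lo, hi = mix["thin_range_nm"] if thin else mix["coarse_range_nm"]
        radius = rng.uniform(lo, hi)
        # cross-profile sigma in pixels; thin fibers bounded below so
        # they remain visible on the grid
        sigma_px = max(radius * 1e-3 / pixel_pitch_um, 0.7)
        strength = rng.uniform(0.55, 1.0)

        ang = np.radians(ori["mean_deg"] + rng.normal(0.0, ori["spread_deg"]))
        y = rng.uniform(-0.2 * height, 1.2 * height)
        x = rng.uniform(-0.2 * width, 1.2 * width)
        # walk both ways from the seed point so fibers cross the canvas
        amp = np.zeros((height, width))
        c2f = np.zeros((height, width))
        s2f = np.zeros((height, width))
        for direction in (1.0, -1.0):
            yy, xx, a = y, x, ang
            for _ in range(n_steps // 2):
                a += np.radians(rng.normal(0.0, ori["curliness_deg"]))
                yy += direction * step * np.sin(a)
                xx += direction * step * np.cos(a)
                iy, ix = int(round(yy)), int(round(xx))
                if 0 <= iy < height and 0 <= ix < width:
                    amp[iy, ix] = 1.0
                    c2f[iy, ix] = np.cos(2 * a)
                    s2f[iy, ix] = np.sin(2 * a)
        if not amp.any():
            continue
        amp_b = gaussian_filter(amp, sigma_px)
        c2_b = gaussian_filter(c2f, sigma_px)
        s2_b = gaussian_filter(s2f, sigma_px)
        peak = amp_b.max()
        if peak <= 0:
            continue
        amp_b = amp_b / peak * strength
        density += amp_b
        cos2 += c2_b / peak * strength
        sin2 += s2_b / peak * strength
        rad_w += amp_b * radius
        wsum += amp_b

    # soft saturation: overlapping fibers approach full density smoothly
    # instead of clipping to a flat plateau, preserving spatial texture
    density = 1.0 - np.exp(-density)
    orientation = 0.5 * np.arctan2(sin2, cos2) % np.pi
    mean_thin = float(np.mean(mix["thin_range_nm"]))
    radius_map = np.where(wsum > 1e-9, rad_w / np.where(wsum > 0, wsum, 1.0), mean_thin)
    return FiberMap(
        density=density,
        orientation_rad=orientation,
        radius_nm=radius_map,
        pixel_pitch_um=pixel_pitch_um,
        seed=seed,
    )


# memoized dichroism curve: a fixed physical function of fiber radius
_DICHROISM_CACHE: dict = {}


def _dichroism_factor(radius_nm: np.ndarray) -> np.ndarray:
    """Relative diattenuation strength of fibers of given radius.

    The normalized dichroism (q_par - q_perp) / (q_par + q_perp) of the
    cylinder scattering cross sections at normal incidence, interpolated
    on a log-radius grid; thin (sub-wavelength) fibers approach the
    Rayleigh-wire asymmetry, coarse fibers are diffraction dominated and
    nearly polarization neutral.
    """
    if "curve" not in _DICHROISM_CACHE:
        med = MediumSpec(n_med=1.35, wavelength_vac_nm=633.0)
        grid = np.geomspace(60.0, 2500.0, 14)
        dich = np.empty_like(grid)
        for i, r in enumerate(grid):
            t = ScatteringTable(
                CylinderSpec(float(r), 1.43), med, zeta_step_deg=90.0, theta_step_deg=2.0
            )
            i90 = int(np.argmin(np.abs(t.zeta_grid - 90.0)))
            qp, qs = t.q_par[i90], t.q_perp[i90]
            dich[i] = (qp - qs) / (qp + qs)
        _DICHROISM_CACHE["curve"] = (np.log(grid), dich)
    lg, vals = _DICHROISM_CACHE["curve"]
    return np.interp(np.log(np.clip(radius_nm, 1.0, None)), lg, vals)


def _batched_rotation(angle_rad: np.ndarray) -> np.ndarray:
    c = np.cos(2 * angle_rad)
    s = np.sin(2 * angle_rad)
    R = np.zeros(angle_rad.shape + (4, 4))
    R[..., 0, 0] = 1.0
    R[..., 3, 3] = 1.0
    R[..., 1, 1] = c
    R[..., 1, 2] = -s
    R[..., 2, 1] = s
    R[..., 2, 2] = c
    return R


def fiber_map_to_mueller(
    fmap: FiberMap, coeffs: OpticalCoefficients | None = None
) -> MuellerImage:
    """Compose the per-pixel Mueller image from a fiber map.

    The composition order is depolarizer @ retarder @ diattenuator, so
    :func:`polarscope.decomposition.decompose_image` inverts it exactly.
    Ground-truth parameter maps are stored under ``meta["truth"]``.
    """
    if coeffs is None:
        coeffs = OpticalCoefficients()
    den = fmap.density
    if np.any(den < 0) or np.any(den > 1):
        raise ValueError("density must lie in [0, 1]")
    delta = coeffs.c_delta * den
    Delta = coeffs.Delta0 + coeffs.c_Delta * den
    D = coeffs.d_scale * _dichroism_factor(fmap.radius_nm) * den
    if np.any(D >= 1.0) or np.any(Delta >= 1.0) or np.any(delta >= np.pi):
        raise ValueError("optical coefficients push parameters out of range")
    axis = fmap.orientation_rad

    R = _batched_rotation(axis)
    Rt = np.swapaxes(R, -1, -2)

    # diattenuator at axis
    r = np.sqrt(1.0 - D * D)
    MD0 = np.zeros(den.shape + (4, 4))
    MD0[..., 0, 0] = 1.0
    MD0[..., 0, 1] = D
    MD0[..., 1, 0] = D
    MD0[..., 1, 1] = 1.0
    MD0[..., 2, 2] = r
    MD0[..., 3, 3] = r
    MD = R @ MD0 @ Rt

    cd, sd = np.cos(delta), np.sin(delta)
    MR0 = np.zeros(den.shape + (4, 4))
    MR0[..., 0, 0] = 1.0
    MR0[..., 1, 1] = 1.0
    MR0[..., 2, 2] = cd
    MR0[..., 2, 3] = sd
    MR0[..., 3, 2] = -sd
    MR0[..., 3, 3] = cd
    MR = R @ MR0 @ Rt

    k = 1.0 - Delta
    M = MR @ MD
    M[..., 1, :] *= k[..., None]
    M[..., 2, :] *= k[..., None]
    M[..., 3, :] *= k[..., None]

    truth = {"D": D, "delta": delta, "Delta": Delta, "axis": axis}
    return MuellerImage(
        mueller=M,
        pixel_pitch_um=fmap.pixel_pitch_um,
        meta={"seed": fmap.seed, "truth": truth, "label": "native"},
    )


def degrade_resolution(
    img: MuellerImage, cfg: MagnificationConfig, lambda_nm: float = 633.0
) -> MuellerImage:
    """Render a native Mueller image as seen by one objective.

    Each of the 16 element maps is convolved with a shared Gaussian PSF
    of sample-plane sigma ``0.21 * lambda / NA`` and resampled (area-
    style, anti-aliased linear) to the objective's sample-plane pixel
    pitch.  Every output pixel is a convex combination of input pixels,
    so physical inputs stay physical.
    """
    native_pitch = img.pixel_pitch_um
    target_pitch = cfg.target_pitch_um
    if target_pitch < native_pitch * (1.0 - 1e-9):
        raise ValueError(
            f"target pitch {target_pitch:.4f} um finer than native {native_pitch:.4f} um"
        )
    sigma_um = 0.21 * (lambda_nm * 1e-3) / cfg.NA
    sigma_px = sigma_um / native_pitch
    H, W = img.shape
    planes = img.mueller.reshape(H, W, 16)
    blurred = np.empty_like(planes)
    for i in range(16):
        blurred[..., i] = gaussian_filter(planes[..., i], sigma_px, mode="nearest")
    out_h = max(int(round(H * native_pitch / target_pitch)), 1)
    out_w = max(int(round(W * native_pitch / target_pitch)), 1)
    if (out_h, out_w) == (H, W):
        resampled = blurred
    else:
        resampled = resize(
            blurred, (out_h, out_w), order=1, anti_aliasing=True, mode="edge"
        )
    meta = dict(img.meta)
    meta.update({"label": cfg.label, "NA": cfg.NA, "magnification": cfg.magnification})
    meta.pop("truth", None)  # ground truth is native-resolution only
    return MuellerImage(
        mueller=resampled.reshape(out_h, out_w, 4, 4),
        pixel_pitch_um=target_pitch,
        meta=meta,
    )


def generate_region_set(
    n_regions: int = 27,
    seed: int = 0,
    height: int = NATIVE_SIZE,
    width: int = NATIVE_SIZE,
    pixel_pitch_um: float = NATIVE_PITCH_UM,
    coupled_depolarization: bool = True,
    coeffs: OpticalCoefficients | None = None,
) -> list[MuellerImage]:
    """Generate the study's region set at native resolution.

    Regions vary in fiber count, thin/coarse mixture and mean
    orientation, reproducibly from the master seed.  With
    ``coupled_depolarization`` the depolarization floor is fixed and
    Delta tracks fiber density (the planted delta-Delta coupling);
    without it the density coupling is removed and the floor varies
    independently across regions.
    """
    if n_regions < 1:
        raise ValueError("need at least one region")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_regions)
    master = np.random.default_rng(ss.spawn(1)[0])
    out = []
    for i, child in enumerate(children):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        rng = np.random.default_rng(sub_seed)
        n_fibers = int(rng.integers(10, 42))
        mix = {"thin_frac": float(rng.uniform(0.25, 0.75))}
        orient = {
            "mean_deg": float(rng.uniform(0.0, 180.0)),
            "spread_deg": float(rng.uniform(12.0, 30.0)),
        }
        fmap = generate_fiber_map(
            height, width, n_fibers, mix, orient, seed=sub_seed, pixel_pitch_um=pixel_pitch_um
        )
        if coeffs is not None:
            c = coeffs
        elif coupled_depolarization:
            c = OpticalCoefficients()
        else:
            c = OpticalCoefficients(
                c_Delta=0.0, Delta0=float(rng.uniform(0.03, 0.35))
            )
        img = fiber_map_to_mueller(fmap, c)
        img.meta.update({"region_id": i, "n_fibers": n_fibers, "seed": sub_seed})
        out.append(img)
    return out
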