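"""Polarized photon Monte Carlo through a slab of oriented cylinders.

The medium is a plane-parallel slab (normal along +z) filled with
infinitely long cylindrical scatterers whose axes lie near the x
direction with Gaussian angular fluctuation, in and out of the slab
plane.  Photons are launched along +z; free paths are exponential with
the stated (unpolarized) scattering coefficient; each scattering event
deflects the photon onto the specular cone of the cylinder (exit angle
to the axis equals the incidence angle) with the azimuth drawn from the
unpolarized single-scattering phase function, and multiplies the
tracked Stokes vectors by the M11-normalized single-scattering Mueller
matrix (importance weighting, so the polarization dependence of the
event is carried in the Stokes components).

Because the scatterers are oriented, extinction itself is
polarization dependent: light polarized in the plane of the cylinder
axis is scattered out of the beam at a different rate than the
orthogonal component (for thin cylinders, roughly the classical
(m^2+1)^2/4-fold asymmetry of a Rayleigh wire).  Each path segment
therefore applies a differential-attenuation diattenuator
``exp(-(mu_par - mu0) l)`` / ``exp(-(mu_perp - mu0) l)`` in the frame
of a cylinder-axis draw, where ``mu0`` is the unpolarized sampling
rate; the unscattered (ballistic) beam thus emerges linearly
diattenuated, which is what makes the forward-collected diattenuation
of finely fibrous media exceed that of coarse fibers.  The linear
birefringence of the coherent beam (the retarding counterpart of the
same forward-scattering physics) is not modeled.

Transmitted photons are binned by exit polar angle.  All six canonical
input states (H, V, +45, -45, R, L) ride along every photon path (the
sampling law is polarization independent, so the basis states share
common random numbers) and the per-bin Mueller matrix is the
least-squares solution of ``S_out = M S_in`` over the basis.

Reference frames: each photon carries an explicit orthonormal pair
``(e_par, e_perp)`` perpendicular to its direction; Stokes vectors are
expressed in that pair (s1 = parallel minus perpendicular).  At every
interaction the frame is rotated to the relevant cylinder frame
(parallel = in the plane containing the cylinder axis and the
propagation direction); at detection it is rotated to the projected
laboratory x/y basis so anisotropy tied to the mean fiber direction
stays coherent across the photons of a bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from polarscope.cylinder import CylinderSpec, MediumSpec, ScatteringTable
from polarscope.decomposition import diattenuation
from polarscope.stokes import BASIS_6

__all__ = [
    "OrientationDistribution",
    "PhotonState",
    "SimConfig",
    "AngleResolvedMueller",
    "sample_free_path",
    "sample_orientation",
    "scatter_event",
    "run_simulation",
    "d_vs_angle",
]

_DEGENERATE_TOL = 1e-9
_UM_PER_CM = 1e4


@dataclass(frozen=True)
class OrientationDistribution:
    """Cylinder axes near +x with Gaussian angular fluctuation.

    ``std_deg`` is the standard deviation of two independent normal
    rotation angles applied to the mean +x axis: one in the slab plane
    (about z) and one out of plane.
    """

    std_deg: float = 30.0

    def __post_init__(self):
        if self.std_deg < 0:
            raise ValueError("std must be >= 0")


@dataclass
class PhotonState:
    """Scalar-photon state for single-event inspection and tests; the
    transport itself runs on packed arrays."""

    position_um: np.ndarray
    direction: np.ndarray
    stokes: np.ndarray
    e_par: np.ndarray
    e_perp: np.ndarray
    n_scatter: int = 0
    alive: bool = True


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one slab simulation.

    Medium defaults mirror the study's simulation conditions (633 nm
    in an n = 1.35 medium, scattering coefficient 200 / cm, 6 um slab,
    30 deg orientation fluctuation); ``n_photons`` is the caller's
    choice.  ``differential_extinction`` switches the oriented-
    scatterer dichroic attenuation of path segments (on by default;
    without it the unscattered beam carries no diattenuation).
    """

    spec: CylinderSpec
    med: MediumSpec
    orientation: OrientationDistribution = OrientationDistribution()
    n_photons: int = 100_000
    seed: int = 0
    bin_edges_deg: tuple = tuple(np.arange(0.0, 91.0, 1.0))
    differential_extinction: bool = True

    def __post_init__(self):
        if self.n_photons < 1:
            raise ValueError("need at least one photon")
        edges = np.asarray(self.bin_edges_deg, dtype=float)
        if edges[0] != 0.0 or edges[-1] < 89.0 or np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must increase from 0 to cover [0, 90)")


@dataclass
class AngleResolvedMueller:
    """Accumulated per-exit-angle-bin transmission Mueller matrices.

    ``basis_sums[b]`` is the 4x6 sum of output Stokes vectors of the six
    input basis states over photons exiting in bin ``b``; ``weights[b]``
    the photon count.  ``photon_angles`` / ``photon_stokes`` are kept
    when requested, for resampling-based error analysis.
    """

    bin_edges_deg: np.ndarray
    basis_sums: np.ndarray  # (n_bins, 4, 6)
    weights: np.ndarray  # (n_bins,)
    n_launched: int
    n_reflected: int
    config: SimConfig
    photon_angles: np.ndarray | None = None
    photon_stokes: np.ndarray | None = None

    @property
    def n_transmitted(self) -> int:
        return int(self.weights.sum())

    def bin_mueller(self, b: int) -> np.ndarray:
        """Least-squares Mueller estimate of one bin (unnormalized)."""
        if self.weights[b] == 0:
            raise ValueError(f"bin {b} is empty")
        return _solve_mueller(self.basis_sums[b])

    def cumulative_mueller(self, half_angle_deg: float) -> np.ndarray:
        """Mueller of all photons with exit angle <= half_angle_deg."""
        sel = self.bin_edges_deg[:-1] < half_angle_deg
        if not sel.any() or self.weights[sel].sum() == 0:
            raise ValueError(f"no photons within {half_angle_deg} deg")
        return _solve_mueller(self.basis_sums[sel].sum(axis=0))


def _solve_mueller(out_sums: np.ndarray) -> np.ndarray:
    """Least squares M from M s_k = o_k over the 6-state basis."""
    B = BASIS_6.T  # 4 x 6
    return out_sums @ B.T @ np.linalg.inv(B @ B.T)


def sample_free_path(mu_s_per_cm: float, u) -> float | np.ndarray:
    """Exponential free path in micrometers from uniform(0,1) draws."""
    if mu_s_per_cm <= 0:
        raise ValueError("mu_s must be positive")
    u = np.asarray(u, dtype=float)
    if np.any(u <= 0) or np.any(u >= 1):
        raise ValueError("u must lie strictly inside (0, 1)")
    out = -np.log(u) / mu_s_per_cm * _UM_PER_CM
    return float(out) if out.ndim == 0 else out


def sample_orientation(
    dist: OrientationDistribution,
    rng: np.random.Generator,
    size: int | None = None,
) -> np.ndarray:
    """Draw cylinder-axis unit vector(s) around +x.

    Two independent normal angles tilt the mean axis: an out-of-plane
    rotation followed by an in-plane rotation (about z), each with the
    distribution's standard deviation.  ``std = 0`` returns exactly +x.
    """
    n = 1 if size is None else size
    a_in = rng.normal(0.0, np.radians(dist.std_deg), n)
    a_out = rng.normal(0.0, np.radians(dist.std_deg), n)
    ca, sa = np.cos(a_out), np.sin(a_out)
    ci, si = np.cos(a_in), np.sin(a_in)
    axes = np.stack([ci * ca, si * ca, -sa], axis=1)
    axes /= np.linalg.norm(axes, axis=1, keepdims=True)
    return axes[0] if size is None else axes


def _normalize_rows(v):
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def _rotate_stokes_to_frame(S, e_par, e_perp, new_par, new_perp):
    """Re-express Stokes stacks (..., 4, m) in a rotated transverse frame."""
    cb = np.einsum("...i,...i->...", e_par, new_par)
    sb = np.einsum("...i,...i->...", e_perp, new_par)
    c2 = (cb * cb - sb * sb)[..., None]
    s2 = (2.0 * sb * cb)[..., None]
    s1 = S[..., 1, :].copy()
    s2c = S[..., 2, :].copy()
    S[..., 1, :] = c2 * s1 + s2 * s2c
    S[..., 2, :] = -s2 * s1 + c2 * s2c
    return S


def _cylinder_frames(u, axes, cosg):
    """(par, perp) transverse bases tied to the (axis, direction) plane."""
    perp = _normalize_rows(np.cross(u, axes))
    par = np.cross(perp, u)
    return par, perp


def _draw_nondegenerate_axes(u, dist, rng, n):
    """Axis draws, resampled where the direction is along the axis."""
    axes = sample_orientation(dist, rng, size=n)
    cosg = np.einsum("ij,ij->i", u, axes)
    sing = np.sqrt(np.clip(1.0 - cosg * cosg, 0.0, None))
    bad = sing < _DEGENERATE_TOL
    while bad.any():
        axes[bad] = sample_orientation(dist, rng, size=int(bad.sum()))
        cosg = np.einsum("ij,ij->i", u, axes)
        sing = np.sqrt(np.clip(1.0 - cosg * cosg, 0.0, None))
        bad = sing < _DEGENERATE_TOL
    return axes, cosg, sing


def scatter_event(
    photon: PhotonState,
    axis: np.ndarray,
    table: ScatteringTable,
    rng: np.random.Generator,
) -> PhotonState:
    """Single-photon scattering event (the transport inlines this).

    The outgoing direction honors the specular cone of the cylinder;
    the Stokes vector is rotated into the scattering frame, multiplied
    by the event Mueller factor, and the outgoing frame is kept.
    """
    u = photon.direction
    axis = np.asarray(axis, dtype=float)
    S = photon.stokes.reshape(4, -1).copy()
    cosg = float(u @ axis)
    sing = np.sqrt(max(1.0 - cosg * cosg, 0.0))
    while sing < _DEGENERATE_TOL:
        axis = sample_orientation(OrientationDistribution(45.0), rng)
        cosg = float(u @ axis)
        sing = np.sqrt(max(1.0 - cosg * cosg, 0.0))
    gamma_deg = np.degrees(np.arccos(np.clip(cosg, -1.0, 1.0)))
    zi = int(table.zeta_index(gamma_deg))
    theta = float(table.sample_theta(np.array([zi]), rng.uniform(size=1))[0])

    e1 = (u - cosg * axis) / sing
    e2 = _normalize_rows(np.cross(axis, e1))
    th = np.radians(theta)
    u_new = cosg * axis + sing * (np.cos(th) * e1 + np.sin(th) * e2)
    u_new /= np.linalg.norm(u_new)

    par_i, perp_i = _cylinder_frames(u[None], axis[None], None)
    S = _rotate_stokes_to_frame(
        S[None], photon.e_par[None], photon.e_perp[None], par_i, perp_i
    )[0]
    M = table.mueller[zi, int(table.theta_index(theta))]
    S = (table.q_unpol[zi] / table.q_ref) * (M @ S)
    par_s, perp_s = _cylinder_frames(u_new[None], axis[None], None)
    return PhotonState(
        position_um=photon.position_um,
        direction=u_new,
        stokes=S.reshape(photon.stokes.shape),
        e_par=par_s[0],
        e_perp=perp_s[0],
        n_scatter=photon.n_scatter + 1,
        alive=True,
    )


def run_simulation(
    cfg: SimConfig,
    store_photons: bool = False,
    table: ScatteringTable | None = None,
) -> AngleResolvedMueller:
    """Transport ``cfg.n_photons`` photons through the slab.

    Deterministic given the seed.  With ``store_photons`` the per-photon
    exit records are kept for bootstrap analysis.
    """
    if table is None:
        table = ScatteringTable(cfg.spec, cfg.med)
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_photons
    thickness = cfg.med.thickness_um
    mu0_um = cfg.med.mu_s_per_cm / _UM_PER_CM

    z = np.zeros(n)
    u = np.tile(np.array([0.0, 0.0, 1.0]), (n, 1))
    e_par = np.tile(np.array([1.0, 0.0, 0.0]), (n, 1))
    e_perp = np.tile(np.array([0.0, 1.0, 0.0]), (n, 1))
    S = np.tile(BASIS_6.T[None], (n, 1, 1))  # (n, 4, 6)
    active = np.ones(n, dtype=bool)
    transmitted = np.zeros(n, dtype=bool)
    reflected = np.zeros(n, dtype=bool)

    while active.any():
        idx = np.flatnonzero(active)
        k = len(idx)
        if mu0_um > 0:
            eps = np.nextafter(0.0, 1.0)
            l_col = -np.log(rng.uniform(low=eps, high=1.0, size=k)) / mu0_um
        else:
            l_col = np.full(k, np.inf)
        uz = u[idx, 2]
        with np.errstate(divide="ignore"):
            l_bound = np.where(
                uz > 0,
                (thickness - z[idx]) / np.where(uz > 0, uz, 1.0),
                np.where(uz < 0, -z[idx] / np.where(uz < 0, uz, 1.0), np.inf),
            )
        exits = l_col >= l_bound
        seg = np.minimum(l_col, l_bound)

        if cfg.differential_extinction and mu0_um > 0:
            # dichroic attenuation of the segment in the frame of an
            # ensemble axis draw; exponents are relative to the
            # unpolarized sampling rate mu0
            axes_s, cosg_s, sing_s = _draw_nondegenerate_axes(
                u[idx], cfg.orientation, rng, k
            )
            zi_s = table.zeta_index(
                np.degrees(np.arccos(np.clip(cosg_s, -1.0, 1.0)))
            )
            mu_par = mu0_um * table.q_par[zi_s] / table.q_ref
            mu_perp = mu0_um * table.q_perp[zi_s] / table.q_ref
            t_par = np.exp(-(mu_par - mu0_um) * seg)
            t_perp = np.exp(-(mu_perp - mu0_um) * seg)
            par_a, perp_a = _cylinder_frames(u[idx], axes_s, cosg_s)
            S[idx] = _rotate_stokes_to_frame(S[idx], e_par[idx], e_perp[idx], par_a, perp_a)
            e_par[idx] = par_a
            e_perp[idx] = perp_a
            a = 0.5 * (t_par + t_perp)[:, None]
            b = 0.5 * (t_par - t_perp)[:, None]
            c = np.sqrt(t_par * t_perp)[:, None]
            s0 = S[idx, 0, :].copy()
            s1 = S[idx, 1, :].copy()
            S[idx, 0, :] = a * s0 + b * s1
            S[idx, 1, :] = b * s0 + a * s1
            S[idx, 2, :] *= c
            S[idx, 3, :] *= c

        transmitted[idx[exits & (uz > 0)]] = True
        reflected[idx[exits & (uz < 0)]] = True
        active[idx[exits]] = False

        sc = idx[~exits]
        if len(sc) == 0:
            continue
        z[sc] = z[sc] + u[sc, 2] * seg[~exits]

        axes, cosg, sing = _draw_nondegenerate_axes(u[sc], cfg.orientation, rng, len(sc))
        gamma = np.degrees(np.arccos(np.clip(cosg, -1.0, 1.0)))
        zi = table.zeta_index(gamma)
        theta = table.sample_theta(zi, rng.uniform(size=len(sc)))

        e1 = (u[sc] - cosg[:, None] * axes) / sing[:, None]
        e2 = _normalize_rows(np.cross(axes, e1))
        th = np.radians(theta)
        u_new = (
            cosg[:, None] * axes
            + sing[:, None] * (np.cos(th)[:, None] * e1 + np.sin(th)[:, None] * e2)
        )
        u_new = _normalize_rows(u_new)

        par_i, perp_i = _cylinder_frames(u[sc], axes, cosg)
        S[sc] = _rotate_stokes_to_frame(S[sc], e_par[sc], e_perp[sc], par_i, perp_i)
        M = table.mueller[zi, table.theta_index(theta)]
        rate = (table.q_unpol[zi] / table.q_ref)[:, None, None]
        S[sc] = rate * (M @ S[sc])
        par_s, perp_s = _cylinder_frames(u_new, axes, None)
        u[sc] = u_new
        e_par[sc] = par_s
        e_perp[sc] = perp_s

    # detection: rotate transmitted photons to the projected lab x/y frame
    ti = np.flatnonzero(transmitted)
    ut = u[ti]
    ex = np.tile(np.array([1.0, 0.0, 0.0]), (len(ti), 1))
    proj = ex - ut * ut[:, [0]]
    nrm = np.linalg.norm(proj, axis=1, keepdims=True)
    proj = proj / np.where(nrm > 0, nrm, 1.0)
    ey = np.cross(ut, proj)
    S[ti] = _rotate_stokes_to_frame(S[ti], e_par[ti], e_perp[ti], proj, ey)

    angles = np.degrees(np.arccos(np.clip(ut[:, 2], -1.0, 1.0)))
    edges = np.asarray(cfg.bin_edges_deg, dtype=float)
    n_bins = len(edges) - 1
    which = np.clip(np.digitize(angles, edges) - 1, 0, n_bins - 1)
    basis_sums = np.zeros((n_bins, 4, 6))
    np.add.at(basis_sums, which, S[ti])
    weights = np.bincount(which, minlength=n_bins).astype(float)

    return AngleResolvedMueller(
        bin_edges_deg=edges,
        basis_sums=basis_sums,
        weights=weights,
        n_launched=n,
        n_reflected=int(reflected.sum()),
        config=cfg,
        photon_angles=angles if store_photons else None,
        photon_stokes=S[ti] if store_photons else None,
    )


def d_vs_angle(result: AngleResolvedMueller, angles_deg, mode: str = "cumulative"):
    """Diattenuation versus collection angle.

    ``cumulative`` uses the weight-combined Mueller matrix of all
    photons within the acceptance cone (what an objective of that
    half-angle collects); ``annular`` uses only the photons between the
    previous requested angle and this one.  Angles with no photons
    yield NaN.  Returns an array of D values aligned with ``angles_deg``.
    """
    angles_deg = list(angles_deg)
    out = np.full(len(angles_deg), np.nan)
    prev = 0.0
    for i, a in enumerate(angles_deg):
        try:
            if mode == "cumulative":
                M = result.cumulative_mueller(a)
            elif mode == "annular":
                sel = (result.bin_edges_deg[:-1] >= prev) & (
                    result.bin_edges_deg[:-1] < a
                )
                if not sel.any() or result.weights[sel].sum() == 0:
                    raise ValueError("empty annulus")
                M = _solve_mueller(result.basis_sums[sel].sum(axis=0))
            else:
                raise ValueError(f"unknown mode {mode!r}")
            out[i] = diattenuation(M)
        except ValueError as err:
            if "unknown mode" in str(err):
                raise
        prev = a
    return out
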