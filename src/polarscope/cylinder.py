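"""Exact light scattering by an infinite circular cylinder.

Series solution for a plane wave obliquely incident on an infinitely
long homogeneous dielectric cylinder, in the classical formulation with
cylindrical harmonics and Bessel-function boundary conditions.  The
incident direction makes a zenith angle ``zeta`` with the cylinder
axis (``zeta = 90 deg`` is normal incidence); scattered light leaves on
the cone of half-angle ``zeta`` around the axis, parametrized by the
azimuthal scattering angle ``Theta`` (``Theta = 0`` is forward).

The 2x2 amplitude matrix acts on field components parallel /
perpendicular to the plane containing the cylinder axis and the
propagation direction:

    [E_par_s]   [T1  T4] [E_par_i]
    [E_perp_s] ~ [T3  T2] [E_perp_i]

All lengths are entered in physical units (radius in nm, vacuum
wavelength in nm); the series uses the relative refractive index
``m = n_cyl / n_med`` and the medium wavelength ``lambda_vac / n_med``,
i.e. size parameter ``x = 2 pi a n_med / lambda_vac``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import h1vp, hankel1, jv, jvp

__all__ = [
    "CylinderSpec",
    "MediumSpec",
    "PhaseFunction",
    "size_parameter",
    "cylinder_coefficients",
    "cylinder_amplitudes",
    "amplitude_to_mueller",
    "single_scatter_mueller",
    "phase_function",
    "forward_fraction",
    "acceptance_half_angle",
    "ScatteringTable",
]


@dataclass(frozen=True)
class CylinderSpec:
    """An infinite circular cylinder scatterer."""

    radius_nm: float
    n_cyl: float

    def __post_init__(self):
        if self.radius_nm <= 0:
            raise ValueError("radius must be positive")
        if self.n_cyl <= 0:
            raise ValueError("refractive index must be positive")


@dataclass(frozen=True)
class MediumSpec:
    """Host medium and slab geometry."""

    n_med: float
    wavelength_vac_nm: float
    mu_s_per_cm: float = 200.0
    thickness_um: float = 6.0

    def __post_init__(self):
        for v in (self.n_med, self.wavelength_vac_nm, self.thickness_um):
            if v <= 0:
                raise ValueError("all medium parameters must be positive")
        if self.mu_s_per_cm < 0:
            raise ValueError("scattering coefficient must be >= 0")


#: Configuration matching the study's simulations: 633 nm light in an
#: n = 1.35 medium, scattering coefficient 200 / cm, 6 um slab.
DEFAULT_MEDIUM = MediumSpec(n_med=1.35, wavelength_vac_nm=633.0)

#: Cylinder radii of the study (nm): two fine-fiber and two coarse-fiber sizes.
STUDY_RADII_NM = (100.0, 200.0, 1000.0, 1500.0)


def size_parameter(spec: CylinderSpec, med: MediumSpec) -> float:
    return 2.0 * np.pi * spec.radius_nm * med.n_med / med.wavelength_vac_nm


def _truncation_order(x: float) -> int:
    # the classical bound plus a small safety margin so the convergence
    # check has decayed terms to verify even at very small x
    return int(np.ceil(x + 4.0 * x ** (1.0 / 3.0) + 2.0)) + 3


def cylinder_coefficients(
    spec: CylinderSpec,
    med: MediumSpec,
    zeta_deg: float,
    n_max: int | None = None,
    check_convergence: bool = True,
):
    """Series coefficients (a_I, a_II, b_I, b_II) for orders 0..n_max.

    ``a_I[n]`` couples perpendicular scattered field to parallel
    incident field (cross term, zero at normal incidence), ``b_I`` the
    parallel co-term, ``a_II`` the perpendicular co-term, ``b_II`` the
    second cross term.
    """
    if not 0.0 < zeta_deg < 180.0:
        raise ValueError(f"zenith angle must be in (0, 180) degrees, got {zeta_deg}")
    x = size_parameter(spec, med)
    m = spec.n_cyl / med.n_med
    zr = np.radians(zeta_deg)
    xi = x * np.sin(zr)
    eta = x * np.sqrt(m * m - np.cos(zr) ** 2)
    if n_max is None:
        n_max = _truncation_order(x)
    n = np.arange(0, n_max + 1)

    Jn_eta = jv(n, eta)
    Jnp_eta = jvp(n, eta)
    Jn_xi = jv(n, xi)
    Jnp_xi = jvp(n, xi)
    Hn_xi = hankel1(n, xi)
    Hnp_xi = h1vp(n, xi)

    An = 1j * xi * (xi * Jnp_eta * Jn_xi - eta * Jn_eta * Jnp_xi)
    Bn = xi * (m * m * xi * Jnp_eta * Jn_xi - eta * Jn_eta * Jnp_xi)
    Cn = n * np.cos(zr) * eta * Jn_eta * Jn_xi * (xi * xi / (eta * eta) - 1.0)
    Dn = n * np.cos(zr) * eta * Jn_eta * Hn_xi * (xi * xi / (eta * eta) - 1.0)
    Vn = xi * (m * m * xi * Jnp_eta * Hn_xi - eta * Jn_eta * Hnp_xi)
    Wn = 1j * xi * (eta * Jn_eta * Hnp_xi - xi * Jnp_eta * Hn_xi)

    den = Wn * Vn + 1j * Dn * Dn
    aI = (Cn * Vn - Bn * Dn) / den
    bI = (Wn * Bn + 1j * Dn * Cn) / den
    aII = -(An * Vn - 1j * Cn * Dn) / den
    bII = -1j * (Cn * Wn + An * Dn) / den

    if check_convergence:
        lead = max(np.abs(bI).max(), np.abs(aII).max())
        tail = max(np.abs(bI[-1]), np.abs(aII[-1]), np.abs(aI[-1]), np.abs(bII[-1]))
        if lead > 0 and tail > 1e-12 * lead:
            raise RuntimeError(
                f"cylinder series not converged at order {n_max}: "
                f"tail/leading = {tail / lead:.2e} (x = {x:.3g}, zeta = {zeta_deg} deg); "
                "increase n_max"
            )
    return aI, aII, bI, bII


def cylinder_amplitudes(
    spec: CylinderSpec,
    med: MediumSpec,
    zeta_deg: float,
    Theta_deg,
    n_max: int | None = None,
) -> np.ndarray:
    """Amplitude matrix elements (T1, T2, T3, T4) at azimuth ``Theta_deg``.

    ``Theta_deg`` may be a scalar or array; the result has shape
    ``Theta.shape + (4,)`` ordered (T1, T2, T3, T4).
    """
    aI, aII, bI, bII = cylinder_coefficients(spec, med, zeta_deg, n_max=n_max)
    Theta = np.atleast_1d(np.asarray(Theta_deg, dtype=float))
    th = np.radians(Theta)[..., None]
    ns = np.arange(1, len(bI))
    cos_n = np.cos(ns * th)
    sin_n = np.sin(ns * th)
    T1 = bI[0] + 2.0 * (bI[1:] * cos_n).sum(axis=-1)
    T2 = aII[0] + 2.0 * (aII[1:] * cos_n).sum(axis=-1)
    T3 = -2j * (aI[1:] * sin_n).sum(axis=-1)
    T4 = -2j * (bII[1:] * sin_n).sum(axis=-1)
    out = np.stack([T1, T2, T3, T4], axis=-1)
    if np.isscalar(Theta_deg):
        return out[0]
    return out


# Jones -> Mueller change of basis (in the parallel/perpendicular field
# basis, s1 = I_par - I_perp).
_A = np.array(
    [
        [1, 0, 0, 1],
        [1, 0, 0, -1],
        [0, 1, 1, 0],
        [0, 1j, -1j, 0],
    ],
    dtype=complex,
)
_A_INV = np.linalg.inv(_A)


def amplitude_to_mueller(T: np.ndarray) -> np.ndarray:
    """Mueller matrix of the 2x2 amplitude (Jones) matrix
    ``[[T1, T4], [T3, T2]]`` via the coherency transformation.

    Accepts a trailing-axis-(4,) stack of (T1, T2, T3, T4) values and
    returns a matching stack of real 4x4 matrices.
    """
    T = np.asarray(T)
    J = np.empty(T.shape[:-1] + (2, 2), dtype=complex)
    J[..., 0, 0] = T[..., 0]
    J[..., 0, 1] = T[..., 3]
    J[..., 1, 0] = T[..., 2]
    J[..., 1, 1] = T[..., 1]
    JJ = np.einsum("...ij,...kl->...ikjl", J, J.conj()).reshape(T.shape[:-1] + (4, 4))
    M = _A @ JJ @ _A_INV
    return M.real


def single_scatter_mueller(
    spec: CylinderSpec,
    med: MediumSpec,
    zeta_deg: float,
    Theta_deg: float,
    n_max: int | None = None,
) -> np.ndarray:
    """Unnormalized single-scattering Mueller matrix at (zeta, Theta)."""
    return amplitude_to_mueller(
        cylinder_amplitudes(spec, med, zeta_deg, Theta_deg, n_max=n_max)
    )


@dataclass
class PhaseFunction:
    """Normalized angular scattering density over the azimuth Theta.

    ``density`` integrates to 1 over ``theta_grid_deg`` (per-degree
    units, trapezoid rule).
    """

    theta_grid_deg: np.ndarray
    density: np.ndarray
    zeta_deg: float
    mode: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.theta_grid_deg = np.asarray(self.theta_grid_deg, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.theta_grid_deg.shape != self.density.shape:
            raise ValueError("grid and density must have equal length")

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {"theta_deg": self.theta_grid_deg, "density": self.density}
        )


def phase_function(
    spec: CylinderSpec,
    med: MediumSpec,
    zeta_deg: float = 90.0,
    mode: str = "unpolarized",
    theta_step_deg: float = 1.0,
    n_max: int | None = None,
) -> PhaseFunction:
    """Phase function of the cylinder over the full azimuth (-180, 180].

    ``mode`` selects the incident polarization channel: ``"parallel"``
    (E in the plane containing the axis), ``"perpendicular"``, or their
    average ``"unpolarized"``.
    """
    grid = np.arange(-180.0, 180.0 + 0.5 * theta_step_deg, theta_step_deg)
    T = cylinder_amplitudes(spec, med, zeta_deg, grid, n_max=n_max)
    i_par = np.abs(T[:, 0]) ** 2 + np.abs(T[:, 2]) ** 2
    i_perp = np.abs(T[:, 1]) ** 2 + np.abs(T[:, 3]) ** 2
    if mode == "parallel":
        intensity = i_par
    elif mode == "perpendicular":
        intensity = i_perp
    elif mode == "unpolarized":
        intensity = 0.5 * (i_par + i_perp)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    norm = np.trapezoid(intensity, grid)
    return PhaseFunction(
        theta_grid_deg=grid,
        density=intensity / norm,
        zeta_deg=zeta_deg,
        mode=mode,
        meta={"radius_nm": spec.radius_nm, "x": size_parameter(spec, med)},
    )


def forward_fraction(pf: PhaseFunction, half_angle_deg: float) -> float:
    """Fraction of scattered light within ``|Theta| <= half_angle_deg``."""
    if not 0.0 < half_angle_deg <= 180.0:
        raise ValueError(f"half angle must be in (0, 180], got {half_angle_deg}")
    g, d = pf.theta_grid_deg, pf.density
    mask = np.abs(g) <= half_angle_deg + 1e-12
    return float(np.trapezoid(d[mask], g[mask]))


def acceptance_half_angle(NA: float, n_immersion: float = 1.0) -> float:
    """Half-angle (degrees) of an objective's acceptance cone,
    ``arcsin(NA / n_immersion)``."""
    if not 0.0 <= NA < n_immersion:
        raise ValueError(f"need 0 <= NA < n_immersion, got NA={NA}, n={n_immersion}")
    return float(np.degrees(np.arcsin(NA / n_immersion)))


class ScatteringTable:
    """Precomputed per-zenith-angle scattering tables for the Monte Carlo.

    For each zenith angle on a uniform grid the table stores the
    single-scattering Mueller matrices over the azimuth grid, the
    unpolarized (M11) sampling density, and its inverse CDF — so a
    transport loop can look up events without re-summing the series.
    """

    def __init__(
        self,
        spec: CylinderSpec,
        med: MediumSpec,
        zeta_step_deg: float = 1.0,
        theta_step_deg: float = 1.0,
    ):
        self.spec = spec
        self.med = med
        # open interval: the transport resamples degenerate axial incidence
        self.zeta_grid = np.arange(zeta_step_deg, 180.0, zeta_step_deg)
        self.theta_grid = np.arange(-180.0, 180.0 + 0.5 * theta_step_deg, theta_step_deg)
        n_z, n_t = len(self.zeta_grid), len(self.theta_grid)
        self.mueller = np.empty((n_z, n_t, 4, 4))
        self.cdf = np.empty((n_z, n_t))
        self.density = np.empty((n_z, n_t))
        # channel-integrated scattered powers (arbitrary common units):
        # incident parallel / perpendicular to the axis-direction plane
        self.q_par = np.empty(n_z)
        self.q_perp = np.empty(n_z)
        for i, z in enumerate(self.zeta_grid):
            T = cylinder_amplitudes(spec, med, z, self.theta_grid)
            M = amplitude_to_mueller(T)
            self.q_par[i] = np.trapezoid(
                np.abs(T[:, 0]) ** 2 + np.abs(T[:, 2]) ** 2, self.theta_grid
            )
            self.q_perp[i] = np.trapezoid(
                np.abs(T[:, 1]) ** 2 + np.abs(T[:, 3]) ** 2, self.theta_grid
            )
            w = M[:, 0, 0]
            cdf = np.concatenate(
                [[0.0], np.cumsum(0.5 * (w[1:] + w[:-1]) * np.diff(self.theta_grid))]
            )
            total = cdf[-1]
            self.density[i] = w / total
            self.cdf[i] = cdf / total
            # store M11-normalized matrices: when Theta is drawn from the
            # M11 density, the importance-weighted per-event factor is
            # exactly M(Theta) / M11(Theta)
            self.mueller[i] = M / w[:, None, None]

    @property
    def q_unpol(self) -> np.ndarray:
        """Unpolarized channel-averaged scattered power per zenith row."""
        return 0.5 * (self.q_par + self.q_perp)

    @property
    def q_ref(self) -> float:
        """Normalization: unpolarized scattered power at normal incidence.

        The medium's stated scattering coefficient is interpreted as
        the unpolarized coefficient at normal (90 deg) incidence; the
        per-channel, per-zenith coefficients scale as q / q_ref.
        """
        i90 = int(np.argmin(np.abs(self.zeta_grid - 90.0)))
        return float(self.q_unpol[i90])

    def zeta_index(self, zeta_deg) -> np.ndarray:
        """Nearest table row(s) for zenith angle(s)."""
        step = self.zeta_grid[1] - self.zeta_grid[0]
        idx = np.rint((np.asarray(zeta_deg) - self.zeta_grid[0]) / step).astype(int)
        return np.clip(idx, 0, len(self.zeta_grid) - 1)

    def sample_theta(self, zeta_idx: np.ndarray, u: np.ndarray) -> np.ndarray:
        """Inverse-CDF draw of Theta (degrees) for each photon."""
        out = np.empty(len(zeta_idx))
        for k in range(len(zeta_idx)):
            row = self.cdf[zeta_idx[k]]
            j = np.searchsorted(row, u[k], side="right")
            j = min(max(j, 1), len(row) - 1)
            # linear interpolation inside the bin
            c0, c1 = row[j - 1], row[j]
            t0, t1 = self.theta_grid[j - 1], self.theta_grid[j]
            frac = 0.0 if c1 == c0 else (u[k] - c0) / (c1 - c0)
            out[k] = t0 + frac * (t1 - t0)
        return out

    def theta_index(self, theta_deg) -> np.ndarray:
        step = self.theta_grid[1] - self.theta_grid[0]
        idx = np.rint((np.asarray(theta_deg) - self.theta_grid[0]) / step).astype(int)
        return np.clip(idx, 0, len(self.theta_grid) - 1)
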