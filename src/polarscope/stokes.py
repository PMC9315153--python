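"""Stokes vectors, Mueller matrices, and ideal optical elements.

Conventions (used consistently throughout the package):

* Stokes vector ``(s0, s1, s2, s3)``: ``s0`` total intensity,
  ``s1`` = horizontal - vertical linear, ``s2`` = +45 deg - (-45 deg)
  linear, ``s3`` = right - left circular.
* Angles of transmission/fast axes are measured counterclockwise from
  horizontal, looking toward the source.
* An ideal polarizer has maximum transmittance 1 for light polarized
  along its axis, i.e. M11 = 1/2 for unpolarized input.
* A waveplate of retardance ``phi`` with fast axis at 0 deg maps
  ``(1, 0, 1, 0)`` to ``(1, 0, cos phi, -sin phi)`` (a quarter-wave
  plate turns +45 deg linear into left circular under this sign
  convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "StokesVector",
    "stokes",
    "is_physical_stokes",
    "is_physical_mueller",
    "mueller_rotation",
    "mueller_of_polarizer",
    "mueller_of_waveplate",
]


@dataclass(frozen=True)
class StokesVector:
    """A polarization state; intensity units are arbitrary."""

    s0: float
    s1: float
    s2: float
    s3: float

    def as_array(self) -> np.ndarray:
        return np.array([self.s0, self.s1, self.s2, self.s3], dtype=float)

    @classmethod
    def from_array(cls, a) -> "StokesVector":
        a = np.asarray(a, dtype=float)
        if a.shape != (4,):
            raise ValueError(f"Stokes vector needs 4 components, got shape {a.shape}")
        return cls(*a)

    @property
    def degree_of_polarization(self) -> float:
        if self.s0 == 0:
            return 0.0
        return float(np.sqrt(self.s1**2 + self.s2**2 + self.s3**2) / self.s0)


def stokes(s0, s1, s2, s3) -> np.ndarray:
    """Convenience constructor returning a plain length-4 float array."""
    return np.array([s0, s1, s2, s3], dtype=float)


UNPOLARIZED = stokes(1.0, 0.0, 0.0, 0.0)

#: The 6-state polarization basis: H, V, +45, -45, right, left circular.
BASIS_6 = np.array(
    [
        [1.0, 1.0, 0.0, 0.0],
        [1.0, -1.0, 0.0, 0.0],
        [1.0, 0.0, 1.0, 0.0],
        [1.0, 0.0, -1.0, 0.0],
        [1.0, 0.0, 0.0, 1.0],
        [1.0, 0.0, 0.0, -1.0],
    ]
)


def is_physical_stokes(s, tol: float = 1e-9) -> bool:
    """True if s0 >= 0 and the polarized part does not exceed s0."""
    s = np.asarray(s, dtype=float)
    s0 = s[..., 0]
    pol = np.sqrt(s[..., 1] ** 2 + s[..., 2] ** 2 + s[..., 3] ** 2)
    scale = np.maximum(np.abs(s0), 1.0)
    return bool(np.all(s0 >= -tol * scale) and np.all(pol <= s0 + tol * scale))


# Fixed probe set covering the 6 pure basis states plus partially
# polarized and unpolarized input; used for physicality spot checks.
_PROBE_STATES = np.vstack(
    [
        UNPOLARIZED,
        BASIS_6,
        stokes(1.0, 0.3, 0.4, 0.5),
        stokes(1.0, -0.5, 0.5, -0.5),
    ]
)


def is_physical_mueller(M, tol: float = 1e-9) -> bool:
    """Spot-check that M maps physical Stokes vectors to physical ones.

    This is a necessary condition checked on a fixed probe set of pure
    and partially polarized states, not a full Cloude positivity test.
    """
    M = np.asarray(M, dtype=float)
    out = _PROBE_STATES @ M.T
    return is_physical_stokes(out, tol=tol)


def mueller_rotation(angle_deg: float) -> np.ndarray:
    """Mueller rotation matrix R(angle): frame rotation of the s1/s2 plane.

    An element with axis at ``a`` degrees is ``R(a) @ M0 @ R(-a)`` where
    ``M0`` is the element at 0 degrees.
    """
    c = np.cos(2 * np.radians(angle_deg))
    s = np.sin(2 * np.radians(angle_deg))
    return np.array(
        [
            [1.0, 0.0, 0.0, 0.0],
            [0.0, c, -s, 0.0],
            [0.0, s, c, 0.0],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )


def mueller_of_polarizer(axis_angle_deg: float) -> np.ndarray:
    """Ideal linear polarizer with transmission axis at ``axis_angle_deg``.

    Normalized so unpolarized light is attenuated by 1/2 (M11 = 1/2).
    The matrix is singular (a projector up to scale).
    """
    P0 = 0.5 * np.array(
        [
            [1.0, 1.0, 0.0, 0.0],
            [1.0, 1.0, 0.0, 0.0],
            [0.0, 0.0, 0.0, 0.0],
            [0.0, 0.0, 0.0, 0.0],
        ]
    )
    R = mueller_rotation(axis_angle_deg)
    return R @ P0 @ R.T


def mueller_of_waveplate(retardance_rad: float, fast_axis_deg: float) -> np.ndarray:
    """Linear retarder of given retardance with fast axis at ``fast_axis_deg``.

    Determinant 1; leaves s0 unchanged. Sign convention documented in
    the module docstring.
    """
    c = np.cos(retardance_rad)
    s = np.sin(retardance_rad)
    W0 = np.array(
        [
            [1.0, 0.0, 0.0, 0.0],
            [0.0, 1.0, 0.0, 0.0],
            [0.0, 0.0, c, s],
            [0.0, 0.0, -s, c],
        ]
    )
    R = mueller_rotation(fast_axis_deg)
    return R @ W0 @ R.T
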