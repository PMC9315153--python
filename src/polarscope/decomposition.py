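"""Lu-Chipman polar decomposition of Mueller matrices.

A Mueller matrix is factored as ``M = M_Delta @ M_R @ M_D``:
a diattenuator ``M_D`` (polarization-dependent transmittance),
a retarder ``M_R`` (phase between eigenmodes), and a depolarizer
``M_Delta``, applied in that order to the incoming light.  The three
scalar summaries used throughout the package are

* diattenuation  ``D  = sqrt(M12^2 + M13^2 + M14^2) / M11``  in [0, 1],
* linear retardance
  ``delta = arccos{ sqrt[(MR22 + MR33)^2 + (MR32 - MR23)^2] - 1 }``
  in [0, pi] radians,
* depolarization  ``Delta = 1 - |tr(M_Delta) - 1| / 3``  in [0, 1].

The depolarizer block is the signed principal square root of
``m' m'^T`` with the sign of ``det m'``, following the original
prescription.  All arccos/sqrt arguments are clamped; pixels whose
clamping exceeds a tolerance are flagged rather than silently accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from polarscope.stokes import mueller_of_waveplate, mueller_rotation

__all__ = [
    "MMPDResult",
    "PolarParamMaps",
    "diattenuation",
    "lu_chipman",
    "linear_retardance",
    "retarder_axis",
    "depolarization",
    "decompose_image",
    "mueller_diattenuator",
    "mueller_linear_retarder",
    "mueller_depolarizer",
]

_CLAMP_TOL = 1e-6
_EIG_TOL = 1e-9


# ---------------------------------------------------------------------------
# Elementary factor constructors (also used by the synthetic generator)

def mueller_diattenuator(D: float, axis_deg: float = 0.0) -> np.ndarray:
    """Linear diattenuator of diattenuation ``D`` with high-transmission
    axis at ``axis_deg``; M11 = 1."""
    if not 0.0 <= D <= 1.0:
        raise ValueError(f"diattenuation must be in [0, 1], got {D}")
    r = np.sqrt(1.0 - D * D)
    M0 = np.array(
        [
            [1.0, D, 0.0, 0.0],
            [D, 1.0, 0.0, 0.0],
            [0.0, 0.0, r, 0.0],
            [0.0, 0.0, 0.0, r],
        ]
    )
    R = mueller_rotation(axis_deg)
    return R @ M0 @ R.T


def mueller_linear_retarder(delta_rad: float, axis_deg: float = 0.0) -> np.ndarray:
    """Pure linear retarder (alias of the waveplate constructor)."""
    return mueller_of_waveplate(delta_rad, axis_deg)


def mueller_depolarizer(a: float, b: float | None = None, c: float | None = None) -> np.ndarray:
    """Diagonal depolarizer diag(1, a, b, c); ``a`` alone gives an
    isotropic depolarizer diag(1, a, a, a)."""
    if b is None:
        b = a
    if c is None:
        c = b
    for v in (a, b, c):
        if not -1.0 <= v <= 1.0:
            raise ValueError(f"depolarizer diagonal entries must be in [-1, 1], got {v}")
    return np.diag([1.0, a, b, c]).astype(float)


# ---------------------------------------------------------------------------
# Scalar extractions

def diattenuation(M: np.ndarray) -> float:
    """Diattenuation of a Mueller matrix from its first row, normalized
    by M11 so the result is scale invariant."""
    M = np.asarray(M, dtype=float)
    if M[0, 0] <= 0:
        raise ValueError(f"M11 must be positive, got {M[0, 0]}")
    D = np.sqrt(M[0, 1] ** 2 + M[0, 2] ** 2 + M[0, 3] ** 2) / M[0, 0]
    return float(np.clip(D, 0.0, 1.0))


def linear_retardance(M_R: np.ndarray) -> float:
    """Linear retardance (radians, in [0, pi]) of a pure retarder matrix.

    The arccos argument is clamped to [-1, 1] against numerical
    overshoot.
    """
    M_R = np.asarray(M_R, dtype=float)
    arg = (
        np.sqrt(
            (M_R[1, 1] + M_R[2, 2]) ** 2 + (M_R[2, 1] - M_R[1, 2]) ** 2
        )
        - 1.0
    )
    return float(np.arccos(np.clip(arg, -1.0, 1.0)))


def retarder_axis(M_R: np.ndarray) -> float:
    """Fast-axis orientation (radians, axial mod pi) of a linear retarder.

    Extracted from the antisymmetric part of the 3x3 retarder block.
    Undefined (returns 0) for retardance 0 or pi where the axis is
    degenerate or ambiguous.
    """
    M_R = np.asarray(M_R, dtype=float)
    m = M_R[1:, 1:]
    # components of the retardance vector, up to the common 1/(2 sin R)
    r1 = m[1, 2] - m[2, 1]
    r2 = m[2, 0] - m[0, 2]
    if r1 == 0.0 and r2 == 0.0:
        return 0.0
    return float(0.5 * np.arctan2(r2, r1) % np.pi)


def depolarization(M_Delta: np.ndarray) -> float:
    """Depolarization power Delta = 1 - |tr(M_Delta) - 1| / 3 in [0, 1]."""
    M_Delta = np.asarray(M_Delta, dtype=float)
    return float(np.clip(1.0 - abs(np.trace(M_Delta) - 1.0) / 3.0, 0.0, 1.0))


# ---------------------------------------------------------------------------
# The decomposition

@dataclass
class MMPDResult:
    """Factors and scalar parameters of one decomposition.

    ``flagged`` is True when the numerics required clamping beyond
    tolerance (negative eigenvalues of m'm'^T, arccos overshoot) and the
    pixel should be excluded from aggregate statistics.
    """

    M_D: np.ndarray
    M_R: np.ndarray
    M_Delta: np.ndarray
    D: float
    delta: float
    Delta: float
    flagged: bool = False


def _assemble_MD(Dvec: np.ndarray) -> np.ndarray:
    """(..., 3) diattenuation vector -> (..., 4, 4) diattenuator."""
    D = np.linalg.norm(Dvec, axis=-1)
    D = np.clip(D, 0.0, 1.0)
    r = np.sqrt(np.clip(1.0 - D * D, 0.0, None))
    shape = Dvec.shape[:-1]
    M_D = np.zeros(shape + (4, 4))
    M_D[..., 0, 0] = 1.0
    M_D[..., 0, 1:] = Dvec
    M_D[..., 1:, 0] = Dvec
    eye3 = np.eye(3)
    safe = np.where(D > 0, D, 1.0)
    Dhat = Dvec / safe[..., None]
    outer = Dhat[..., :, None] * Dhat[..., None, :]
    mD = r[..., None, None] * eye3 + (1.0 - r)[..., None, None] * outer
    M_D[..., 1:, 1:] = mD
    return M_D


def _lu_chipman_batch(M: np.ndarray):
    """Vectorized decomposition of an (..., 4, 4) stack.

    Returns (M_D, M_R, M_Delta, D, delta, Delta, flagged); all leading
    dimensions are preserved.
    """
    M = np.asarray(M, dtype=float)
    m11 = M[..., 0, 0]
    if np.any(m11 <= 0):
        raise ValueError("every Mueller matrix must have M11 > 0")
    Mn = M / m11[..., None, None]

    Dvec = Mn[..., 0, 1:].copy()
    D = np.linalg.norm(Dvec, axis=-1)
    flagged = D > 1.0 + _CLAMP_TOL
    # clamp D slightly inside 1 so M_D stays invertible; an ideal
    # polarizer (D = 1) is handled by this regularized inverse, which
    # acts as a pseudo-inverse on the transmitted subspace
    over = D > 1.0 - 1e-9
    if np.any(over):
        Dvec = np.where(
            over[..., None], Dvec * ((1.0 - 1e-9) / np.where(D > 0, D, 1.0))[..., None], Dvec
        )
        D = np.minimum(D, 1.0 - 1e-9)
    M_D = _assemble_MD(Dvec)
    Mp = Mn @ np.linalg.inv(M_D)

    mp = Mp[..., 1:, 1:]
    PDelta = Mp[..., 1:, 0]
    mm = mp @ np.swapaxes(mp, -1, -2)
    lam, V = np.linalg.eigh(mm)
    flagged = flagged | (lam[..., 0] < -_EIG_TOL)
    lam = np.clip(lam, 0.0, None)
    sgn = np.sign(np.linalg.det(mp))
    sgn = np.where(sgn == 0, 1.0, sgn)
    sq = np.sqrt(lam)
    mDelta = (V * sq[..., None, :]) @ np.swapaxes(V, -1, -2)
    mDelta = sgn[..., None, None] * mDelta

    M_Delta = np.zeros_like(M_D)
    M_Delta[..., 0, 0] = 1.0
    M_Delta[..., 1:, 0] = PDelta
    M_Delta[..., 1:, 1:] = mDelta

    # m_R = m_Delta^{-1} m'; fall back to pseudo-inverse for strongly
    # depolarizing pixels where m_Delta is singular
    near_sing = sq[..., 0] < 1e-12
    if np.any(near_sing):
        inv = np.linalg.pinv(mDelta)
    else:
        inv = np.linalg.inv(mDelta)
    mR = inv @ mp
    M_R = np.zeros_like(M_D)
    M_R[..., 0, 0] = 1.0
    M_R[..., 1:, 1:] = mR

    D_out = np.clip(np.linalg.norm(Mn[..., 0, 1:], axis=-1), 0.0, 1.0)
    arg = (
        np.sqrt(
            (mR[..., 0, 0] + mR[..., 1, 1]) ** 2
            + (mR[..., 1, 0] - mR[..., 0, 1]) ** 2
        )
        - 1.0
    )
    flagged = flagged | (np.abs(arg) > 1.0 + _CLAMP_TOL)
    delta = np.arccos(np.clip(arg, -1.0, 1.0))
    tr = 1.0 + mDelta[..., 0, 0] + mDelta[..., 1, 1] + mDelta[..., 2, 2]
    Delta = np.clip(1.0 - np.abs(tr - 1.0) / 3.0, 0.0, 1.0)
    return M_D, M_R, M_Delta, D_out, delta, Delta, flagged


def lu_chipman(M: np.ndarray) -> MMPDResult:
    """Decompose one Mueller matrix; see the module docstring.

    The input is normalized to M11 = 1 internally; the factors returned
    are those of the normalized matrix and satisfy
    ``M_Delta @ M_R @ M_D ~= M / M11``.
    """
    M_D, M_R, M_Delta, D, delta, Delta, flagged = _lu_chipman_batch(
        np.asarray(M, dtype=float)[None]
    )
    return MMPDResult(
        M_D=M_D[0],
        M_R=M_R[0],
        M_Delta=M_Delta[0],
        D=float(D[0]),
        delta=float(delta[0]),
        Delta=float(Delta[0]),
        flagged=bool(flagged[0]),
    )


# ---------------------------------------------------------------------------
# Image-level decomposition

@dataclass
class PolarParamMaps:
    """Per-pixel D / delta / Delta images plus a validity mask.

    ``delta_map`` is in radians.  ``valid`` marks pixels whose
    decomposition required no out-of-tolerance clamping; downstream
    statistics should exclude invalid pixels.
    """

    D_map: np.ndarray
    delta_map: np.ndarray
    Delta_map: np.ndarray
    valid: np.ndarray
    pixel_pitch_um: float = float("nan")
    meta: dict = field(default_factory=dict)

    @property
    def shape(self):
        return self.D_map.shape

    def parameter(self, name: str) -> np.ndarray:
        return {"D": self.D_map, "delta": self.delta_map, "Delta": self.Delta_map}[name]


def decompose_image(img) -> PolarParamMaps:
    """Per-pixel Lu-Chipman decomposition of a Mueller-matrix image.

    ``img`` is either a ``MuellerImage`` (from :mod:`polarscope.phantom`)
    or a bare ``(H, W, 4, 4)`` array.  Failed pixels are recorded in the
    validity mask, not raised.
    """
    pitch = float("nan")
    meta: dict = {}
    stack = img
    if hasattr(img, "mueller"):
        stack = img.mueller
        pitch = img.pixel_pitch_um
        meta = dict(img.meta)
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 4 or stack.shape[-2:] != (4, 4):
        raise ValueError(f"expected an (H, W, 4, 4) stack, got shape {stack.shape}")
    if stack.size == 0:
        raise ValueError("empty image")
    _, _, _, D, delta, Delta, flagged = _lu_chipman_batch(stack)
    return PolarParamMaps(
        D_map=D,
        delta_map=delta,
        Delta_map=Delta,
        valid=~flagged,
        pixel_pitch_um=pitch,
        meta=meta,
    )
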