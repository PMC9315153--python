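"""Dual-rotating-retarder (DRR) Mueller polarimeter: forward model and
reconstruction.

The instrument modeled here is a transmission polarimeter whose
polarization state generator (PSG) is a fixed horizontal polarizer
followed by a rotating quarter-wave plate at angle ``theta``, and whose
analyzer (PSA) mirrors it with the quarter-wave plate at ``5 * theta``
followed by a horizontal polarizer.  Rotating both plates in 30 steps
of 6 degrees (PSG span 180 degrees) produces an intensity trace that is
a trigonometric polynomial in ``psi = 2 * theta`` with harmonics up to
n = 12:

    I(psi) = alpha0 + sum_{n=1..12} [alpha_n cos(n psi) + beta_n sin(n psi)]

All 16 Mueller elements of the sample are linear in the trace, so the
sample matrix is recovered either by least squares on the 30x16
polarimetric measurement matrix (default) or from the Fourier
coefficients (the classical route; implemented as a linear solve on the
harmonic vector and algebraically identical for ideal components).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from polarscope.stokes import UNPOLARIZED, mueller_of_polarizer, mueller_of_waveplate

__all__ = [
    "IntensityTrace",
    "drr_intensity",
    "simulate_measurement",
    "reconstruct_mueller",
    "trace_harmonics",
    "trace_to_dataframe",
]

#: PSA-to-PSG rotation rate ratio.
RATE_RATIO = 5

#: Highest harmonic of psi = 2*theta present in an ideal trace.
N_HARMONICS = 12

_QWP = np.pi / 2


@dataclass
class IntensityTrace:
    """A measured (or simulated) DRR intensity series.

    ``harmonics`` is filled by :func:`reconstruct_mueller` (or
    :func:`trace_harmonics`) as the vector
    ``[alpha0, alpha_1..alpha_12, beta_1..beta_12]``.
    """

    step_angles_deg: np.ndarray
    intensities: np.ndarray
    rate_ratio: int = RATE_RATIO
    harmonics: np.ndarray | None = field(default=None)

    def __post_init__(self):
        self.step_angles_deg = np.asarray(self.step_angles_deg, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.step_angles_deg.shape != self.intensities.shape:
            raise ValueError("step_angles_deg and intensities must have equal length")

    def __len__(self) -> int:
        return len(self.intensities)


def _psg_state(theta_deg: float) -> np.ndarray:
    """Stokes vector produced by the PSG at retarder angle theta."""
    return (
        mueller_of_waveplate(_QWP, theta_deg)
        @ mueller_of_polarizer(0.0)
        @ UNPOLARIZED
    )


def _psa_row(theta_deg: float) -> np.ndarray:
    """Analyzer row vector: detected intensity = row . S_sample_out."""
    A = mueller_of_polarizer(0.0) @ mueller_of_waveplate(_QWP, RATE_RATIO * theta_deg)
    return A[0]


def drr_intensity(sample: np.ndarray, theta_deg: float) -> float:
    """Detected intensity for PSG retarder at ``theta_deg``, PSA at 5x.

    Unit-intensity unpolarized input; ``sample`` is the 4x4 Mueller
    matrix between the PSG and the PSA.
    """
    sample = np.asarray(sample, dtype=float)
    return float(_psa_row(theta_deg) @ sample @ _psg_state(theta_deg))


def _step_angles(n_steps: int, span_deg: float) -> np.ndarray:
    return np.arange(n_steps) * (span_deg / n_steps)


def simulate_measurement(
    sample: np.ndarray, n_steps: int = 30, span_deg: float = 180.0
) -> IntensityTrace:
    """Forward-simulate the full rotation series for one sample matrix.

    ``n_steps`` must be at least 16 so the 16 Mueller elements are
    determined; the default 30 steps of 6 degrees matches the
    instrument's measurement scheme.
    """
    if n_steps < 16:
        raise ValueError(
            f"n_steps={n_steps} under-determines the 16 Mueller elements; need >= 16"
        )
    sample = np.asarray(sample, dtype=float)
    thetas = _step_angles(n_steps, span_deg)
    intensities = np.array([drr_intensity(sample, t) for t in thetas])
    return IntensityTrace(step_angles_deg=thetas, intensities=intensities)


@lru_cache(maxsize=8)
def _design_matrix(thetas_key: tuple) -> np.ndarray:
    """K x 16 matrix A with I_k = A[k] . vec(M) (row-major vec)."""
    rows = []
    for t in thetas_key:
        rows.append(np.outer(_psa_row(t), _psg_state(t)).ravel())
    return np.asarray(rows)


def trace_harmonics(trace: IntensityTrace) -> np.ndarray:
    """Fourier coefficients [alpha0, alpha_1..12, beta_1..12] of a trace.

    Computed by discrete projection on cos/sin of ``n * psi`` with
    ``psi = 2 * theta``; exact for ideal traces sampled on a uniform
    grid with more than ``2 * N_HARMONICS`` steps.
    """
    psi = 2.0 * np.radians(trace.step_angles_deg)
    I = trace.intensities
    n_samp = len(I)
    if n_samp <= 2 * N_HARMONICS:
        raise ValueError(
            f"{n_samp} steps cannot resolve {N_HARMONICS} harmonics; need > {2*N_HARMONICS}"
        )
    alpha0 = I.mean()
    ns = np.arange(1, N_HARMONICS + 1)[:, None]
    alphas = 2.0 / n_samp * (I * np.cos(ns * psi)).sum(axis=1)
    betas = 2.0 / n_samp * (I * np.sin(ns * psi)).sum(axis=1)
    return np.concatenate([[alpha0], alphas, betas])


@lru_cache(maxsize=8)
def _harmonic_design_matrix(thetas_key: tuple) -> np.ndarray:
    """25 x 16 linear map from vec(M) to the harmonic vector."""
    thetas = np.asarray(thetas_key)
    cols = []
    for idx in range(16):
        M = np.zeros(16)
        M[idx] = 1.0
        tr = IntensityTrace(
            step_angles_deg=thetas,
            intensities=_design_matrix(thetas_key) @ M,
        )
        cols.append(trace_harmonics(tr))
    return np.asarray(cols).T


def reconstruct_mueller(trace: IntensityTrace, method: str = "lstsq") -> np.ndarray:
    """Recover the sample Mueller matrix from a DRR intensity trace.

    ``method="lstsq"`` inverts the polarimetric measurement matrix
    directly; ``method="fourier"`` first reduces the trace to its
    harmonic coefficients and inverts the element-to-harmonic map.  The
    two agree to machine precision for ideal traces.  In both cases the
    ``harmonics`` field of ``trace`` is populated as a side effect.
    """
    thetas_key = tuple(trace.step_angles_deg.tolist())
    trace.harmonics = trace_harmonics(trace)
    if method == "lstsq":
        A = _design_matrix(thetas_key)
        rank = np.linalg.matrix_rank(A, tol=1e-10)
        if rank < 16:
            raise np.linalg.LinAlgError(
                f"polarimetric measurement matrix is rank {rank} < 16; "
                "the retarder angle set does not determine the Mueller matrix"
            )
        m, *_ = np.linalg.lstsq(A, trace.intensities, rcond=None)
    elif method == "fourier":
        H = _harmonic_design_matrix(thetas_key)
        rank = np.linalg.matrix_rank(H, tol=1e-10)
        if rank < 16:
            raise np.linalg.LinAlgError(
                f"harmonic design matrix is rank {rank} < 16; "
                "the harmonic set does not determine the Mueller matrix"
            )
        m, *_ = np.linalg.lstsq(H, trace.harmonics, rcond=None)
    else:
        raise ValueError(f"unknown method {method!r}; use 'lstsq' or 'fourier'")
    return m.reshape(4, 4)


def trace_to_dataframe(trace: IntensityTrace):
    """Trace as a tidy table (step_index, theta_deg, intensity)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "step_index": np.arange(len(trace)),
            "theta_deg": trace.step_angles_deg,
            "intensity": trace.intensities,
        }
    )
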