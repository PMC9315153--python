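"""First-order moments and GLCM texture features of parameter images.

The analysis chain mirrors common practice for polarization-parameter
images: a floating-point map (D, delta or Delta) is normalized to 8-bit
gray levels [0, 255]; Mean and Entropy are computed from the 256-level
histogram; the gray-level co-occurrence matrix (GLCM) is built after
re-quantizing to ``Ng = 64`` levels at an inter-pixel displacement ``d``
chosen per magnification, and summarized by the Haralick features
Contrast, Correlation, Energy and Homogeneity.

Conventions:

* Energy here is the angular second moment ``sum p(i,j)^2`` (some
  libraries call its square root "energy").
* Level indices ``i, j`` in the feature formulas are 1-based quantized
  levels ``1..Ng``.  Contrast and Correlation are invariant to this
  offset; it is fixed so hand-computed examples are exact.
* Pair counts are accumulated symmetrically (both pixel orders) and
  pooled over the direction set before normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import isnan

import numpy as np
from skimage.feature import graycomatrix

__all__ = [
    "GrayImage",
    "GLCMatrix",
    "TextureSummary",
    "normalize_to_gray",
    "first_order_moments",
    "compute_glcm",
    "glcm_features",
    "texture_summary",
    "DEFAULT_DIRECTIONS_DEG",
]

#: Haralick direction set pooled by default (degrees).
DEFAULT_DIRECTIONS_DEG = (0.0, 45.0, 90.0, 135.0)


@dataclass
class GrayImage:
    """An 8-bit image produced by the documented normalization."""

    pixels: np.ndarray  # uint8
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        p = np.asarray(self.pixels)
        if p.size and (p.min() < 0 or p.max() > 255):
            raise ValueError("gray values must lie in [0, 255]")
        self.pixels = p.astype(np.uint8)

    @property
    def shape(self):
        return self.pixels.shape


@dataclass
class GLCMatrix:
    """Normalized co-occurrence frequencies p(i, j) at one displacement."""

    p: np.ndarray  # (Ng, Ng), sums to 1
    Ng: int
    d: int
    directions_deg: tuple

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != (self.Ng, self.Ng):
            raise ValueError("GLCM shape must be (Ng, Ng)")

    @property
    def px(self) -> np.ndarray:
        """Row marginal p_x(i)."""
        return self.p.sum(axis=1)

    @property
    def py(self) -> np.ndarray:
        """Column marginal p_y(j)."""
        return self.p.sum(axis=0)


@dataclass
class TextureSummary:
    """The six statistics reported per parameter image.

    ``correlation`` is NaN when undefined (zero marginal variance,
    e.g. a constant image); such values are excluded from aggregates.
    """

    mean: float
    entropy: float
    contrast: float
    correlation: float
    energy: float
    homogeneity: float

    def as_dict(self) -> dict:
        return {
            "mean": self.mean,
            "entropy": self.entropy,
            "contrast": self.contrast,
            "correlation": self.correlation,
            "energy": self.energy,
            "homogeneity": self.homogeneity,
        }


def normalize_to_gray(
    map_values: np.ndarray,
    lo: float | None = None,
    hi: float | None = None,
    provenance: dict | None = None,
) -> GrayImage:
    """Affinely map [lo, hi] to gray levels [0, 255] (round half-up, clipped).

    ``lo``/``hi`` default to the map's own min/max.  A constant map
    under the automatic range maps to all zeros by convention.
    """
    v = np.asarray(map_values, dtype=float)
    auto_lo = float(np.min(v)) if lo is None else float(lo)
    auto_hi = float(np.max(v)) if hi is None else float(hi)
    if lo is not None and hi is not None and auto_hi <= auto_lo:
        raise ValueError(f"need hi > lo, got lo={lo}, hi={hi}")
    if auto_hi <= auto_lo:  # constant map with automatic range
        g = np.zeros_like(v)
    else:
        scaled = (v - auto_lo) / (auto_hi - auto_lo) * 255.0
        g = np.clip(np.floor(scaled + 0.5), 0, 255)
    return GrayImage(pixels=g, provenance=provenance or {})


def first_order_moments(img: GrayImage, levels: int = 256) -> tuple[float, float]:
    """(Mean, Entropy) of the gray-level histogram.

    Mean = sum z_i p(z_i); Entropy = -sum p log2 p with 0 log 0 := 0.
    Computed on the full 256-level image by default (``levels=64``
    re-quantizes first, for parity with the GLCM quantization).
    """
    z = np.asarray(img.pixels if isinstance(img, GrayImage) else img)
    if z.size == 0:
        raise ValueError("empty image")
    if levels != 256:
        z = _requantize(z, levels)
    counts = np.bincount(z.ravel(), minlength=levels).astype(float)
    p = counts / counts.sum()
    mean = float((np.arange(levels) * p).sum())
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    return mean, entropy


def _requantize(z: np.ndarray, Ng: int) -> np.ndarray:
    """Uniformly re-bin 256 gray levels into Ng levels 0..Ng-1."""
    return (z.astype(np.int64) * Ng // 256).astype(np.uint8)


def compute_glcm(
    img: GrayImage,
    d: int,
    Ng: int = 64,
    directions_deg=DEFAULT_DIRECTIONS_DEG,
) -> GLCMatrix:
    """Symmetric co-occurrence matrix at displacement ``d``.

    Counts are pooled over ``directions_deg`` and normalized to sum 1.
    The underlying pair enumeration is scikit-image's; the neighbor
    convention is Haralick's: a 45 or 135 degree neighbor at distance
    ``d`` is the pixel offset by ``(d, d)`` diagonally (Chebyshev
    distance), realized by scaling the per-angle Euclidean distance.
    The direction sign convention does not matter because accumulation
    is symmetric.
    """
    if d < 1:
        raise ValueError(f"displacement must be >= 1, got {d}")
    if not 2 <= Ng <= 256:
        raise ValueError(f"Ng must be in 2..256, got {Ng}")
    z = np.asarray(img.pixels if isinstance(img, GrayImage) else img)
    if z.ndim != 2:
        raise ValueError("GLCM needs a 2-D image")
    if min(z.shape) <= d:
        raise ValueError(
            f"image of shape {z.shape} too small for displacement d={d}"
        )
    q = _requantize(z, Ng)
    pooled = np.zeros((Ng, Ng))
    for a in directions_deg:
        ang = np.radians(a)
        # scale the Euclidean distance so the rounded row/column offsets
        # equal d (Chebyshev convention for diagonal neighbors)
        scale = max(abs(np.sin(ang)), abs(np.cos(ang)))
        glcm = graycomatrix(
            q,
            distances=[d / scale],
            angles=[ang],
            levels=Ng,
            symmetric=True,
            normed=False,
        )
        pooled += glcm[:, :, 0, 0].astype(float)
    total = pooled.sum()
    if total == 0:
        raise ValueError("no pixel pairs at this displacement")
    return GLCMatrix(
        p=pooled / total, Ng=Ng, d=d, directions_deg=tuple(directions_deg)
    )


def glcm_features(P: GLCMatrix) -> TextureSummary:
    """Contrast, Correlation, Energy, Homogeneity of a normalized GLCM.

    Returned as a :class:`TextureSummary` whose ``mean`` and ``entropy``
    fields are NaN (first-order moments are computed from the gray image
    itself, not the co-occurrence matrix).
    """
    p = P.p
    Ng = P.Ng
    idx = np.arange(1, Ng + 1, dtype=float)  # 1-based level indices
    ii, jj = np.meshgrid(idx, idx, indexing="ij")
    diff = np.abs(ii - jj)
    contrast = float((diff**2 * p).sum())
    energy = float((p**2).sum())
    homogeneity = float((p / (1.0 + (ii - jj) ** 2)).sum())
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mx = float((idx * px).sum())
    my = float((idx * py).sum())
    sx = float(np.sqrt(((idx - mx) ** 2 * px).sum()))
    sy = float(np.sqrt(((idx - my) ** 2 * py).sum()))
    if sx * sy == 0:
        correlation = float("nan")
    else:
        correlation = float(((ii * jj * p).sum() - mx * my) / (sx * sy))
    return TextureSummary(
        mean=float("nan"),
        entropy=float("nan"),
        contrast=contrast,
        correlation=correlation,
        energy=energy,
        homogeneity=homogeneity,
    )


def texture_summary(
    map_values: np.ndarray,
    d: int,
    Ng: int = 64,
    lo: float | None = None,
    hi: float | None = None,
    directions_deg=DEFAULT_DIRECTIONS_DEG,
) -> TextureSummary:
    """Full six-statistic summary of one floating-point parameter map."""
    gray = normalize_to_gray(map_values, lo=lo, hi=hi)
    mean, entropy = first_order_moments(gray)
    feats = glcm_features(compute_glcm(gray, d=d, Ng=Ng, directions_deg=directions_deg))
    return TextureSummary(
        mean=mean,
        entropy=entropy,
        contrast=feats.contrast,
        correlation=feats.correlation,
        energy=feats.energy,
        homogeneity=feats.homogeneity,
    )
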