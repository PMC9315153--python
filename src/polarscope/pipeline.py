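"""End-to-end resolution study over synthetic fibrous regions.

The study mirrors a multi-magnification Mueller microscopy experiment:
a fixed set of regions is rendered at each objective configuration,
every rendering is polar-decomposed into diattenuation ``D``, linear
retardance ``delta`` and depolarization ``Delta`` maps, and each map is
summarized by six texture statistics (Mean, Entropy from first-order
moments; Contrast, Correlation, Energy, Homogeneity from a 64-level
GLCM at the magnification-specific displacement).  Aggregations:

* tidy per-(region, magnification, parameter) feature table,
* per-parameter Pearson correlation matrices of each feature across
  magnifications (how well does a statistic at 4x predict it at 60x?),
* the delta-Delta correlation across regions per magnification.

Texture statistics use the per-image min/max 8-bit normalization (each
parameter map stretched to gray levels 0-255 before quantization), so
they measure relative spatial structure; absolute parameter levels are
tracked separately through the physical ``mean_value`` column.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from polarscope.decomposition import decompose_image
from polarscope.phantom import (
    STUDY_MAGNIFICATIONS,
    MagnificationConfig,
    MuellerImage,
    OpticalCoefficients,
    degrade_resolution,
    generate_region_set,
)
from polarscope.texture import first_order_moments, compute_glcm, glcm_features, normalize_to_gray

__all__ = [
    "StudyConfig",
    "StudyResult",
    "PARAMETER_RANGES",
    "FEATURE_NAMES",
    "analyze_region",
    "pearson_matrix",
    "delta_Delta_correlation",
    "run_study",
]

#: Physical value ranges of the polar-decomposition parameters (used
#: for validation and display; texture normalization is per-image).
PARAMETER_RANGES = {"D": (0.0, 1.0), "delta": (0.0, float(np.pi)), "Delta": (0.0, 1.0)}

FEATURE_NAMES = ("mean", "entropy", "contrast", "correlation", "energy", "homogeneity")


@dataclass(frozen=True)
class StudyConfig:
    """Reproducible configuration of one full study run."""

    n_regions: int = 27
    seed: int = 0
    magnifications: tuple = STUDY_MAGNIFICATIONS
    Ng: int = 64
    native_size: int = 360
    coupled_depolarization: bool = True

    def __post_init__(self):
        if self.n_regions < 2:
            raise ValueError("a correlation study needs at least 2 regions")
        if not self.magnifications:
            raise ValueError("need at least one magnification")


@dataclass
class StudyResult:
    """Feature table plus derived correlation summaries."""

    features: pd.DataFrame  # tidy rows
    config: StudyConfig
    runtime_s: float = float("nan")
    meta: dict = field(default_factory=dict)

    def feature_pivot(self, parameter: str, feature: str) -> pd.DataFrame:
        """Regions x magnifications table of one statistic."""
        sub = self.features[self.features["parameter"] == parameter]
        return sub.pivot(index="region_id", columns="magnification", values=feature)

    def pearson(self, parameter: str, feature: str) -> pd.DataFrame:
        return pearson_matrix(self, parameter, feature)

    def boxplot_stats(self) -> pd.DataFrame:
        """Quartile summary of each statistic per (parameter, magnification)."""
        rows = []
        for (par, mag), g in self.features.groupby(["parameter", "magnification"], sort=False):
            for feat in FEATURE_NAMES:
                v = g[feat].to_numpy(dtype=float)
                v = v[np.isfinite(v)]
                if v.size == 0:
                    continue
                q1, med, q3 = np.percentile(v, [25, 50, 75])
                rows.append(
                    {
                        "parameter": par,
                        "magnification": mag,
                        "feature": feat,
                        "min": float(v.min()),
                        "q1": float(q1),
                        "median": float(med),
                        "q3": float(q3),
                        "max": float(v.max()),
                        "n": int(v.size),
                    }
                )
        return pd.DataFrame(rows)

    def to_csv(self, out_dir) -> dict:
        """Write the feature table and derived summaries; return paths."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        p = out / "features.csv"
        self.features.to_csv(p, index=False)
        paths["features"] = p
        p = out / "boxplot_stats.csv"
        self.boxplot_stats().to_csv(p, index=False)
        paths["boxplot_stats"] = p
        corr_rows = []
        for par in PARAMETER_RANGES:
            for feat in FEATURE_NAMES:
                mat = pearson_matrix(self, par, feat)
                for a in mat.index:
                    for b in mat.columns:
                        corr_rows.append(
                            {
                                "parameter": par,
                                "feature": feat,
                                "mag_a": a,
                                "mag_b": b,
                                "pearson_r": mat.loc[a, b],
                            }
                        )
        p = out / "pearson_across_magnifications.csv"
        pd.DataFrame(corr_rows).to_csv(p, index=False)
        paths["pearson"] = p
        dd = {
            mag: delta_Delta_correlation(self, magnification=mag)
            for mag in self.features["magnification"].unique()
        }
        p = out / "delta_Delta_correlation.csv"
        pd.DataFrame(
            [{"magnification": m, "pearson_r": r} for m, r in dd.items()]
        ).to_csv(p, index=False)
        paths["delta_Delta"] = p
        return paths


def analyze_region(
    img: MuellerImage,
    magnifications=STUDY_MAGNIFICATIONS,
    Ng: int = 64,
    region_id: int | None = None,
) -> pd.DataFrame:
    """Degrade one native region to every objective and summarize it.

    Returns tidy rows with columns ``region_id, magnification, NA,
    glcm_d, parameter, mean_value`` plus the six texture statistics.
    ``mean_value`` is the physical (un-normalized) spatial mean of the
    parameter map, used for cross-magnification parameter tracking.
    """
    rid = img.meta.get("region_id", -1) if region_id is None else region_id
    rows = []
    for cfg in magnifications:
        degraded = degrade_resolution(img, cfg)
        maps = decompose_image(degraded)
        for par in PARAMETER_RANGES:
            values = maps.parameter(par)
            gray = normalize_to_gray(values)
            mean, entropy = first_order_moments(gray)
            feats = glcm_features(compute_glcm(gray, d=cfg.glcm_d, Ng=Ng))
            rows.append(
                {
                    "region_id": rid,
                    "magnification": cfg.label,
                    "NA": cfg.NA,
                    "glcm_d": cfg.glcm_d,
                    "parameter": par,
                    "mean_value": float(np.nanmean(values)),
                    "mean": mean,
                    "entropy": entropy,
                    "contrast": feats.contrast,
                    "correlation": feats.correlation,
                    "energy": feats.energy,
                    "homogeneity": feats.homogeneity,
                }
            )
    return pd.DataFrame(rows)


def pearson_matrix(result: StudyResult, parameter: str, feature: str) -> pd.DataFrame:
    """Across-region Pearson correlation of one statistic between magnifications.

    Entry (a, b) correlates the per-region values of ``feature`` on the
    ``parameter`` map at magnification ``a`` with those at ``b``.
    """
    if parameter not in PARAMETER_RANGES:
        raise ValueError(f"unknown parameter {parameter!r}")
    if feature not in FEATURE_NAMES and feature != "mean_value":
        raise ValueError(f"unknown feature {feature!r}")
    pivot = result.features[result.features["parameter"] == parameter].pivot(
        index="region_id", columns="magnification", values=feature
    )
    labels = [m.label for m in result.config.magnifications if m.label in pivot.columns]
    return pivot[labels].corr(method="pearson")


def delta_Delta_correlation(result: StudyResult, magnification: str | None = None) -> float:
    """Across-region Pearson correlation of mean delta vs mean Delta.

    ``magnification`` defaults to the highest-resolution configuration.
    """
    if magnification is None:
        magnification = result.config.magnifications[-1].label
    sub = result.features[result.features["magnification"] == magnification]
    if sub.empty:
        raise ValueError(f"no rows for magnification {magnification!r}")
    d = sub[sub["parameter"] == "delta"].set_index("region_id")["mean_value"]
    D = sub[sub["parameter"] == "Delta"].set_index("region_id")["mean_value"]
    joined = pd.concat([d, D], axis=1, keys=["delta", "Delta"]).dropna()
    if len(joined) < 2:
        return float("nan")
    return float(np.corrcoef(joined["delta"], joined["Delta"])[0, 1])


def run_study(config: StudyConfig | None = None, out_dir=None, regions=None) -> StudyResult:
    """Run the full multi-magnification texture study deterministically.

    ``regions`` overrides generation with a pre-built list of native
    :class:`MuellerImage` regions (used by tests and the CLI's staged
    mode); otherwise :func:`generate_region_set` builds them from
    ``config.seed``.  If ``out_dir`` is given, CSV summaries are written
    there.
    """
    if config is None:
        config = StudyConfig()
    t0 = time.perf_counter()
    if regions is None:
        regions = generate_region_set(
            n_regions=config.n_regions,
            seed=config.seed,
            height=config.native_size,
            width=config.native_size,
            coupled_depolarization=config.coupled_depolarization,
        )
    tables = [
        analyze_region(img, magnifications=config.magnifications, Ng=config.Ng, region_id=i)
        for i, img in enumerate(regions)
    ]
    features = pd.concat(tables, ignore_index=True)
    result = StudyResult(
        features=features,
        config=config,
        runtime_s=time.perf_counter() - t0,
        meta={"n_regions": len(regions)},
    )
    if out_dir is not None:
        result.to_csv(out_dir)
    return result
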