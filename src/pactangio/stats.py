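"""ROI-vs-healthy statistics on windowed metric maps.

Metric maps (relative vessel density, windowed entropy, anisotropy) are
sampled over non-overlapping windows tiling the region of interest (the
cancer-affected area outlined at baseline) and a healthy reference region,
so samples are numerically independent.  Group differences are tested with
a one-tailed Welch (unequal variances) t-test under the null hypothesis
that the ROI population mean does not exceed the healthy one.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .irregularity import TumorMask, tumor_dimensions
from .preprocess import MapImage

__all__ = [
    "RoiDefinition",
    "WindowSamples",
    "TestResult",
    "window_samples",
    "welch_one_tailed",
    "amplitude_ratio",
    "longitudinal_report",
]


@dataclass
class RoiDefinition:
    """Cancer-affected ROI (fixed at baseline) and the healthy reference."""

    roi_mask: np.ndarray
    healthy_mask: np.ndarray

    def __post_init__(self) -> None:
        self.roi_mask = np.asarray(self.roi_mask, dtype=bool)
        self.healthy_mask = np.asarray(self.healthy_mask, dtype=bool)
        if (self.roi_mask & self.healthy_mask).any():
            raise ValueError("ROI and healthy masks must be disjoint")


@dataclass
class WindowSamples:
    """Per-window means of one metric within one region."""

    values: np.ndarray
    window_mm: float
    tile_origins: list[tuple[int, int]] = field(default_factory=list)
    tile_px: int = 0

    @property
    def n(self) -> int:
        return len(self.values)

    def assert_disjoint(self) -> None:
        """Verify the sampled tiles are pairwise non-overlapping."""
        w = self.tile_px
        for a in range(len(self.tile_origins)):
            for b in range(a + 1, len(self.tile_origins)):
                (ia, ja), (ib, jb) = self.tile_origins[a], self.tile_origins[b]
                if abs(ia - ib) < w and abs(ja - jb) < w:
                    raise AssertionError("window tiles overlap")


def window_samples(
    metric_map: np.ndarray,
    mask: np.ndarray,
    window_mm: float,
    pixel_size_mm: float,
    min_inside_fraction: float = 0.5,
) -> WindowSamples:
    """Tile the mask bounding box with non-overlapping windows and average.

    A tile contributes one sample — the mean of the metric over its pixels
    inside the mask — when at least ``min_inside_fraction`` of the tile lies
    inside the mask.  NaN metric pixels (windows where the metric is
    undefined, e.g. anisotropy over empty background) are ignored; a tile
    with no defined pixels contributes nothing.
    """
    metric_map = np.asarray(metric_map, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty region mask")
    w = max(int(round(window_mm / pixel_size_mm)), 1)
    ii, jj = np.nonzero(mask)
    values: list[float] = []
    origins: list[tuple[int, int]] = []
    for i0 in range(ii.min(), ii.max() + 1, w):
        for j0 in range(jj.min(), jj.max() + 1, w):
            tile_mask = mask[i0:i0 + w, j0:j0 + w]
            if tile_mask.shape != (w, w):  # clipped at the image border
                continue
            inside = tile_mask.sum()
            if inside < min_inside_fraction * w * w:
                continue
            tile = metric_map[i0:i0 + w, j0:j0 + w][tile_mask]
            tile = tile[np.isfinite(tile)]
            if tile.size == 0:
                continue
            values.append(float(tile.mean()))
            origins.append((i0, j0))
    if not values:
        raise ValueError("no window tiles qualify inside the mask")
    return WindowSamples(np.array(values), window_mm, origins, w)


@dataclass
class TestResult:
    """Welch's one-tailed t-test summary for ROI vs healthy samples."""

    roi_mean: float
    roi_se: float
    healthy_mean: float
    healthy_se: float
    t: float
    df: float
    p_one_tailed: float
    n_roi: int
    n_healthy: int
    alternative: str = "roi mean > healthy mean"
    degenerate: bool = False


def welch_one_tailed(roi: WindowSamples, healthy: WindowSamples) -> TestResult:
    """Welch's unequal-variances t-test, one-tailed for ROI > healthy.

    Uses the Welch t statistic with Satterthwaite degrees of freedom.  When
    both groups are constant with equal means the test is degenerate and
    p = 0.5 is reported with a flag.
    """
    a, b = roi.values, healthy.values
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 samples")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se = math.sqrt(va / na + vb / nb)
    if se == 0.0:
        degenerate = a.mean() == b.mean()
        p = 0.5 if degenerate else (0.0 if a.mean() > b.mean() else 1.0)
        if degenerate:
            warnings.warn("zero variance in both groups with equal means; p = 0.5",
                          stacklevel=2)
        return TestResult(float(a.mean()), 0.0, float(b.mean()), 0.0,
                          0.0 if degenerate else math.inf * np.sign(a.mean() - b.mean()),
                          float(na + nb - 2), p, na, nb, degenerate=True)
    t = (a.mean() - b.mean()) / se
    df = (va / na + vb / nb) ** 2 / (
        (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
    )
    p = float(sps.t.sf(t, df))
    return TestResult(
        roi_mean=float(a.mean()),
        roi_se=float(math.sqrt(va / na)),
        healthy_mean=float(b.mean()),
        healthy_se=float(math.sqrt(vb / nb)),
        t=float(t),
        df=float(df),
        p_one_tailed=p,
        n_roi=na,
        n_healthy=nb,
    )


def amplitude_ratio(
    map_image: MapImage, roi_mask: np.ndarray, healthy_mask: np.ndarray
) -> float:
    """Mean PA amplitude in the ROI over the depth-matched healthy region."""
    roi_mask = np.asarray(roi_mask, bool)
    healthy_mask = np.asarray(healthy_mask, bool)
    if not roi_mask.any() or not healthy_mask.any():
        raise ValueError("amplitude_ratio requires non-empty masks")
    healthy_mean = float(map_image.pixels[healthy_mask].mean())
    if healthy_mean == 0.0:
        raise ZeroDivisionError("healthy region has zero mean amplitude")
    return float(map_image.pixels[roi_mask].mean() / healthy_mean)


def longitudinal_report(
    time_points: list[dict],
    roi: RoiDefinition,
    window_mm: float = 2.0,
    pixel_size_mm: float = 0.1,
) -> pd.DataFrame:
    """Per-time-point, per-metric ROI-vs-healthy summary table.

    Each element of ``time_points`` is a dict with a ``label`` and metric
    maps under ``metrics`` (metric name -> 2D array), plus optionally a
    ``tumor_mask`` (:class:`TumorMask`) whose caliper dimensions are
    appended.  The same ROI definition is applied to every time point
    (scenes are generated coregistered).  Columns: time_point, metric,
    region, n_windows, mean, se, t, df, p_one_tailed.
    """
    rows = []
    for tp in time_points:
        label = tp["label"]
        for metric, arr in tp["metrics"].items():
            try:
                s_roi = window_samples(arr, roi.roi_mask, window_mm, pixel_size_mm)
                s_h = window_samples(arr, roi.healthy_mask, window_mm, pixel_size_mm)
            except ValueError as exc:
                warnings.warn(f"{label}/{metric}: {exc}; skipped", stacklevel=2)
                continue
            res = welch_one_tailed(s_roi, s_h)
            for region, mean, se, nw in (
                ("roi", res.roi_mean, res.roi_se, res.n_roi),
                ("healthy", res.healthy_mean, res.healthy_se, res.n_healthy),
            ):
                rows.append(dict(time_point=label, metric=metric, region=region,
                                 n_windows=nw, mean=mean, se=se, t=res.t,
                                 df=res.df, p_one_tailed=res.p_one_tailed))
        tmask = tp.get("tumor_mask")
        if isinstance(tmask, TumorMask) and tmask.mask.any():
            dims = tumor_dimensions(tmask)
            for name, val in (("tumor_LA_cm", dims.la_cm),
                              ("tumor_SA_cm", dims.sa_cm),
                              ("tumor_volume_cm3", dims.volume_cm3)):
                rows.append(dict(time_point=label, metric=name, region="roi",
                                 n_windows=np.nan, mean=val, se=np.nan,
                                 t=np.nan, df=np.nan, p_one_tailed=np.nan))
    return pd.DataFrame(rows, columns=["time_point", "metric", "region", "n_windows",
                                       "mean", "se", "t", "df", "p_one_tailed"])
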