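"""Condensate image quantification and FRAP kinetics.

Droplets are segmented by a Phansalkar-style auto-local threshold
(radius 15 px, canonical shape parameters), a 3x3 median noise filter on
the binary mask, connected-component labeling, and size (>= 4 px) and
circularity (4*pi*A/P^2 >= 0.85) filters. The partition coefficient is the
ratio of integrated intensity inside droplets to integrated intensity
outside. FRAP traces are normalized to the pre-bleach intensity and
corrected for acquisition photobleaching with the reference-condensate
factor f_t = I_Ref_pre / (I_Bleach_pre * I_Ref_t), then fitted to the
asymptotic regression model y(t) = y_inf + (y0 - y_inf) exp(-k t).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, stats
from skimage import measure
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "SegmentationConfig",
    "DropletSegmentation",
    "PartitionResult",
    "FrapTrace",
    "FrapFit",
    "DropletSegmenter",
    "FrapRecoveryModel",
    "segment_droplets",
    "partition_coefficient",
    "frap_correct",
    "frap_fit",
    "timecourse_auc",
    "compare_groups",
]


@dataclass(frozen=True)
class SegmentationConfig:
    """Droplet-segmentation parameters.

    ``radius`` is the local-threshold window radius in px; ``param1`` and
    ``param2`` are the Phansalkar shape parameters k and r (the method's
    canonical defaults); droplets below ``min_size`` px or circularity
    below ``min_circularity`` are rejected.
    """

    radius: int = 15
    param1: float = 0.25  # Phansalkar k
    param2: float = 0.5  # Phansalkar r
    min_size: int = 4
    min_circularity: float = 0.85
    noise_filter: bool = True

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValueError("radius must be >= 1")
        if not 0.0 <= self.min_circularity <= 1.0:
            raise ValueError("circularity threshold must be in [0, 1]")


@dataclass
class DropletSegmentation:
    """Labeled droplet mask with per-droplet area, intensity and circularity."""

    labels: np.ndarray
    table: pd.DataFrame

    @property
    def n_droplets(self) -> int:
        return int(self.table.shape[0])

    @property
    def mask(self) -> np.ndarray:
        return self.labels > 0


def _phansalkar_threshold(image: np.ndarray, radius: int, k: float, r: float) -> np.ndarray:
    """Phansalkar local threshold: t = m (1 + p e^{-q m} + k (s/r - 1)).

    Operates on the image normalized to [0, 1]; p = 2 and q = 10 are the
    method's fixed constants, k and r its two tunable shape parameters.
    """
    img = image.astype(float)
    lo, hi = img.min(), img.max()
    norm = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)
    size = 2 * radius + 1
    mean = ndimage.uniform_filter(norm, size=size, mode="reflect")
    sq_mean = ndimage.uniform_filter(norm**2, size=size, mode="reflect")
    sd = np.sqrt(np.clip(sq_mean - mean**2, 0.0, None))
    p, q = 2.0, 10.0
    threshold = mean * (1 + p * np.exp(-q * mean) + k * (sd / r - 1))
    # epsilon guards against float noise in the box filters on flat regions
    return norm > threshold + 1e-9


def _circularity(region) -> float:
    # Fiji convention: 4*pi*area/perimeter^2, clamped at 1 for small objects
    if region.perimeter == 0:
        return 1.0
    return min(4.0 * np.pi * region.area / region.perimeter**2, 1.0)


class DropletSegmenter(BaseEstimator):
    """Sklearn-style droplet segmenter (parameters as in SegmentationConfig).

    :meth:`segment` returns a :class:`DropletSegmentation`; :meth:`fit`
    stores the result of segmenting the given image as ``segmentation_``.
    """

    def __init__(
        self,
        radius: int = 15,
        param1: float = 0.25,
        param2: float = 0.5,
        min_size: int = 4,
        min_circularity: float = 0.85,
        noise_filter: bool = True,
    ):
        self.radius = radius
        self.param1 = param1
        self.param2 = param2
        self.min_size = min_size
        self.min_circularity = min_circularity
        self.noise_filter = noise_filter

    def segment(self, image: np.ndarray) -> DropletSegmentation:
        image = np.asarray(image, dtype=float)
        if image.ndim != 2:
            raise ValueError(f"expected a single-channel 2-D image, got shape {image.shape}")
        binary = _phansalkar_threshold(image, self.radius, self.param1, self.param2)
        if self.noise_filter:
            binary = ndimage.median_filter(binary.astype(np.uint8), size=3).astype(bool)
        labeled = measure.label(binary, connectivity=2)
        rows = []
        keep = np.zeros(labeled.max() + 1, dtype=bool)
        for region in measure.regionprops(labeled, intensity_image=image):
            circ = _circularity(region)
            if region.area >= self.min_size and circ >= self.min_circularity:
                keep[region.label] = True
                rows.append(
                    {
                        "label": region.label,
                        "area_px": int(region.area),
                        "integrated_intensity": float(region.image_intensity[region.image].sum()),
                        "circularity": circ,
                        "centroid_y": region.centroid[0],
                        "centroid_x": region.centroid[1],
                    }
                )
        out = np.where(keep[labeled], labeled, 0)
        # relabel consecutively, preserving order
        out = measure.label(out > 0, connectivity=2)
        table = pd.DataFrame(
            rows,
            columns=[
                "label", "area_px", "integrated_intensity",
                "circularity", "centroid_y", "centroid_x",
            ],
        )
        table["label"] = np.arange(1, len(table) + 1)
        return DropletSegmentation(labels=out, table=table)

    def fit(self, X, y=None) -> "DropletSegmenter":
        self.segmentation_ = self.segment(X)
        return self

    def transform(self, X) -> np.ndarray:
        return self.segment(X).labels


def segment_droplets(
    image: np.ndarray, config: SegmentationConfig = SegmentationConfig()
) -> DropletSegmentation:
    """Segment condensates in a single-channel image (see module docstring)."""
    return DropletSegmenter(
        radius=config.radius,
        param1=config.param1,
        param2=config.param2,
        min_size=config.min_size,
        min_circularity=config.min_circularity,
        noise_filter=config.noise_filter,
    ).segment(image)


@dataclass(frozen=True)
class PartitionResult:
    """Integrated-intensity partition between droplets and dilute phase."""

    i_droplet: float
    i_outside: float
    coefficient: float
    n_droplets: int
    mean_size_px: float

    def mean_size_um2(self, pixel_size_um: float) -> float:
        return self.mean_size_px * pixel_size_um**2


def partition_coefficient(
    image: np.ndarray, segmentation: DropletSegmentation | np.ndarray
) -> PartitionResult:
    """Ratio of integrated intensity inside droplets to outside.

    ``segmentation`` may be a :class:`DropletSegmentation` or a labeled/
    boolean mask of the same shape as ``image``.
    """
    image = np.asarray(image, dtype=float)
    if isinstance(segmentation, DropletSegmentation):
        labels = segmentation.labels
    else:
        labels = np.asarray(segmentation)
    if labels.shape != image.shape:
        raise ValueError("mask and image shapes differ")
    mask = labels > 0
    if mask.all():
        raise ZeroDivisionError("mask covers the entire image; no outside phase")
    n = int(labels.max()) if labels.dtype != bool else int(mask.any())
    areas = (
        np.bincount(labels[mask].ravel())[1:]
        if labels.dtype != bool
        else np.array([mask.sum()]) if mask.any() else np.array([])
    )
    i_in = float(image[mask].sum())
    i_out = float(image[~mask].sum())
    return PartitionResult(
        i_droplet=i_in,
        i_outside=i_out,
        coefficient=i_in / i_out if i_out else np.inf,
        n_droplets=int((areas > 0).sum()),
        mean_size_px=float(areas.mean()) if areas.size else 0.0,
    )


@dataclass
class FrapTrace:
    """A FRAP measurement: bleached and reference ROI series plus pre-bleach.

    ``time_s`` < 0 marks pre-bleach frames (the bleach occurs at t = 0).
    """

    time_s: np.ndarray
    bleach: np.ndarray
    reference: np.ndarray

    @staticmethod
    def from_frame(df: pd.DataFrame) -> "FrapTrace":
        return FrapTrace(
            time_s=df["time_s"].to_numpy(dtype=float),
            bleach=df["bleach"].to_numpy(dtype=float),
            reference=df["reference"].to_numpy(dtype=float),
        )

    def prebleach_means(self) -> tuple[float, float]:
        pre = self.time_s < 0
        if not pre.any():
            raise ValueError("trace has no pre-bleach frames")
        return float(self.bleach[pre].mean()), float(self.reference[pre].mean())


def frap_correct(
    trace: FrapTrace | pd.DataFrame, subtract_baseline: bool = False
) -> pd.DataFrame:
    """Normalize to pre-bleach intensity and correct acquisition bleaching.

    Each post-bleach point is multiplied by
    f_t = I_Ref_pre / (I_Bleach_pre * I_Ref_t): division by the pre-bleach
    bleached-ROI mean normalizes the curve, and the reference ratio undoes
    the shared acquisition decay. With ``subtract_baseline`` the first
    post-bleach bleached value is subtracted from all points beforehand
    (an alternative reading of the protocol; off by default).
    """
    if isinstance(trace, pd.DataFrame):
        trace = FrapTrace.from_frame(trace)
    i_bleach_pre, i_ref_pre = trace.prebleach_means()
    if i_bleach_pre <= 0:
        raise ValueError("pre-bleach bleached intensity must be > 0")
    if np.any(trace.reference <= 0):
        raise ValueError("reference intensities must be > 0 at all time points")
    post = trace.time_s >= 0
    t = trace.time_s[post]
    bleach = trace.bleach[post].astype(float)
    if subtract_baseline:
        bleach = bleach - bleach[0]
    f_t = i_ref_pre / (i_bleach_pre * trace.reference[post])
    return pd.DataFrame({"time_s": t, "recovery": bleach * f_t})


@dataclass(frozen=True)
class FrapFit:
    """Fitted asymptotic-regression parameters.

    ``k`` (1/s) is parametrized internally as lrc = ln k, which enforces
    k > 0; ``y_inf`` is the maximum relative recovery (mobile-fraction
    plateau) and ``y0`` the normalized intensity immediately after bleach.
    ``identifiable`` is False for degenerate (flat) curves where k carries
    no information.
    """

    k: float
    y_inf: float
    y0: float
    residual_norm: float
    identifiable: bool = True


class FrapRecoveryModel(RegressorMixin, BaseEstimator):
    """Least-squares fit of y(t) = y_inf + (y0 - y_inf) exp(-k t).

    Self-starting: y_inf from the mean of the last 10% of points, y0 from
    the first point, lrc = ln k from a log-linear fit of (y_inf - y).
    Fitted attributes: ``k_``, ``y_inf_``, ``y0_``, ``residual_norm_``,
    ``identifiable_``.
    """

    def __init__(self, max_nfev: int = 10000):
        self.max_nfev = max_nfev

    @staticmethod
    def _model(t: np.ndarray, params: np.ndarray) -> np.ndarray:
        y_inf, y0, lrc = params
        return y_inf + (y0 - y_inf) * np.exp(-np.exp(lrc) * t)

    def fit(self, X, y) -> "FrapRecoveryModel":
        t = np.asarray(X, dtype=float).reshape(-1)
        yv = np.asarray(y, dtype=float).reshape(-1)
        if t.size < 5:
            raise ValueError("need at least 5 post-bleach points")
        t0 = t[0]
        ts = t - t0  # fit is invariant to a uniform time shift
        n_tail = max(1, int(0.1 * ts.size))
        y_inf0 = float(yv[-n_tail:].mean())
        y00 = float(yv[0])
        span = yv.max() - yv.min()
        if span < 1e-12 or abs(y_inf0 - y00) < 1e-9 * max(abs(y_inf0), 1.0):
            # flat curve: k unidentifiable
            self.k_ = np.nan
            self.y_inf_ = self.y0_ = float(yv.mean())
            self.residual_norm_ = float(np.linalg.norm(yv - yv.mean()))
            self.identifiable_ = False
            return self
        resid0 = np.clip((y_inf0 - yv) / (y_inf0 - y00), 1e-9, None)
        with np.errstate(divide="ignore"):
            mask = resid0 > 1e-6
            slope = np.polyfit(ts[mask], np.log(resid0[mask]), 1)[0]
        lrc0 = float(np.log(max(-slope, 1e-4)))
        result = optimize.least_squares(
            lambda p: self._model(ts, p) - yv,
            x0=np.array([y_inf0, y00, lrc0]),
            max_nfev=self.max_nfev,
        )
        if not result.success:
            raise RuntimeError(f"FRAP fit did not converge: {result.message}")
        y_inf, y0, lrc = result.x
        self.k_ = float(np.exp(lrc))
        self.y_inf_ = float(y_inf)
        self.y0_ = float(y0)
        self.residual_norm_ = float(np.linalg.norm(result.fun))
        self.identifiable_ = True
        self._t0 = t0
        return self

    def predict(self, X) -> np.ndarray:
        t = np.asarray(X, dtype=float).reshape(-1) - getattr(self, "_t0", 0.0)
        return self._model(t, np.array([self.y_inf_, self.y0_, np.log(self.k_)]))


def frap_fit(curve: pd.DataFrame) -> FrapFit:
    """Fit a corrected recovery curve; returns (k, y_inf, y0, residual norm)."""
    model = FrapRecoveryModel().fit(curve["time_s"].to_numpy(), curve["recovery"].to_numpy())
    return FrapFit(
        k=model.k_,
        y_inf=model.y_inf_,
        y0=model.y0_,
        residual_norm=model.residual_norm_,
        identifiable=model.identifiable_,
    )


def timecourse_auc(
    series: Sequence[tuple[float, float]] | pd.DataFrame,
    normalize_to_first: bool = False,
) -> float:
    """Trapezoidal area under a time course, optionally normalized to t[0].

    Used for nuclease-digestion and precipitation time courses where
    intensities are normalized to the 0-min time point before the AUC is
    taken.
    """
    if isinstance(series, pd.DataFrame):
        times = series.iloc[:, 0].to_numpy(dtype=float)
        values = series.iloc[:, 1].to_numpy(dtype=float)
    else:
        arr = np.asarray(series, dtype=float)
        times, values = arr[:, 0], arr[:, 1]
    if times.size < 2:
        raise ValueError("need at least two time points")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if normalize_to_first:
        if values[0] == 0:
            raise ZeroDivisionError("first time-point value is zero")
        values = values / values[0]
    return float(np.trapezoid(values, times))


def compare_groups(
    values: Mapping[str, Sequence[float]],
    test: Literal["two_sample_t", "anova_tukey", "rm_anova_tukey"] = "two_sample_t",
) -> pd.DataFrame:
    """Group comparison statistics used across the quantitative assays.

    ``two_sample_t``: Welch-free two-sample t-test per pair against the
    first group. ``anova_tukey``: one-way ANOVA plus Tukey HSD pairwise
    p-values. ``rm_anova_tukey``: repeated-measures ANOVA (samples of equal
    length treated as matched subjects) with Tukey HSD on subject-demeaned
    values. Degenerate (zero-variance everywhere) inputs are flagged with
    ``degenerate=True`` rows.
    """
    names = list(values)
    if len(names) < 2 or any(len(values[g]) < 2 for g in names):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    arrays = {g: np.asarray(values[g], dtype=float) for g in names}
    degenerate = all(a.std(ddof=1) == 0 for a in arrays.values())
    rows = []
    if test == "two_sample_t":
        ref = names[0]
        for other in names[1:]:
            if degenerate:
                rows.append({"comparison": f"{ref} vs {other}", "statistic": np.nan,
                             "p": np.nan, "degenerate": True})
                continue
            t, p = stats.ttest_ind(arrays[ref], arrays[other])
            rows.append({"comparison": f"{ref} vs {other}", "statistic": float(t),
                         "p": float(p), "degenerate": False})
        return pd.DataFrame(rows)
    if test in ("anova_tukey", "rm_anova_tukey"):
        data = arrays
        if test == "rm_anova_tukey":
            sizes = {len(a) for a in arrays.values()}
            if len(sizes) != 1:
                raise ValueError("repeated-measures design requires equal group sizes")
            # remove per-subject means (subject = position within group)
            stacked = np.stack([arrays[g] for g in names])
            subject_means = stacked.mean(axis=0, keepdims=True)
            grand = stacked.mean()
            stacked = stacked - subject_means + grand
            data = {g: stacked[i] for i, g in enumerate(names)}
        if degenerate:
            return pd.DataFrame(
                [{"comparison": "omnibus", "statistic": np.nan, "p": np.nan, "degenerate": True}]
            )
        f, p_omni = stats.f_oneway(*[data[g] for g in names])
        rows.append({"comparison": "omnibus", "statistic": float(f), "p": float(p_omni),
                     "degenerate": False})
        flat = np.concatenate([data[g] for g in names])
        labels = np.concatenate([[g] * len(data[g]) for g in names])
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        tukey = pairwise_tukeyhsd(flat, labels, alpha=0.05)
        res = tukey.summary().data[1:]
        for row in res:
            rows.append(
                {
                    "comparison": f"{row[0]} vs {row[1]}",
                    "statistic": float(row[2]),
                    "p": float(row[3]),
                    "degenerate": False,
                }
            )
        return pd.DataFrame(rows)
    raise ValueError(f"unknown test {test!r}")
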