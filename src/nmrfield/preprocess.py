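"""Spectral preprocessing: from phased real spectra to the model-ready matrix.

The pipeline order is fixed and mirrors standard tissue-NMR practice:

    reference_align -> baseline_correct -> exclude_regions ->
    segmental_align -> total_area_normalize -> glog_transform -> mean_center

Every step is deterministic and appends its parameters to the set's
processing log, so a run can be replayed exactly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import uniform_filter1d

from .dataset import SpectrumSet

__all__ = [
    "PreprocessConfig", "reference_align", "baseline_correct",
    "exclude_regions", "segmental_align", "total_area_normalize",
    "glog", "glog_inverse", "glog_transform", "mean_center",
    "preprocess_pipeline",
]

#: Segments aligned by default: lactate/3-hydroxybutyrate, glutamine/succinate,
#: creatine/choline/taurine, and the purine aromatic region.
DEFAULT_SEGMENTS = ((1.10, 1.55), (2.00, 2.55), (2.95, 3.50), (8.10, 8.60))


@dataclass
class PreprocessConfig:
    """Parameters of the preprocessing chain.

    Defaults encode the study's choices: water 4.49-5.89 ppm and TSP < 0.14
    ppm excluded; generalized-log with y0 = 1e-7, lambda = 5e-4.
    """

    tsp_search_window: tuple = (-0.25, 0.25)
    exclusion_regions: tuple = ((-math.inf, 0.14), (4.49, 5.89))
    alignment_segments: tuple = DEFAULT_SEGMENTS
    max_segment_shift: int = 15
    baseline_knot_spacing: float = 0.25
    glog_y0: float = 1e-7
    glog_lambda: float = 5e-4

    def __post_init__(self) -> None:
        if self.glog_lambda <= 0:
            raise ValueError("glog_lambda must be > 0")
        for regions in (self.exclusion_regions, self.alignment_segments):
            ivs = sorted(regions)
            for (a1, b1), (a2, b2) in zip(ivs, ivs[1:]):
                if b1 > a2:
                    raise ValueError(
                        f"overlapping intervals ({a1},{b1}) and ({a2},{b2})")


def _shift_row(row: np.ndarray, k: int) -> np.ndarray:
    """Shift right by k points (left for negative k), edge-value fill."""
    if k == 0:
        return row.copy()
    out = np.empty_like(row)
    if k > 0:
        out[k:] = row[:-k]
        out[:k] = row[0]
    else:
        out[:k] = row[-k:]
        out[k:] = row[-1]
    return out


def reference_align(sset: SpectrumSet,
                    config: PreprocessConfig | None = None) -> SpectrumSet:
    """Shift each spectrum so the TSP apex sits at the point nearest 0 ppm.

    Shifts are whole grid points with edge-value fill; a flat search window
    (no detectable maximum) yields a warning and zero shift.
    """
    config = config or PreprocessConfig()
    lo, hi = config.tsp_search_window
    mask = (sset.ppm >= lo) & (sset.ppm <= hi)
    if not mask.any():
        raise ValueError("TSP search window contains no grid points")
    widx = np.flatnonzero(mask)
    target = int(np.argmin(np.abs(sset.ppm)))
    out = sset.intensities.copy()
    shifts = []
    for i in range(sset.n_samples):
        win = sset.intensities[i, widx]
        if np.ptp(win) == 0:
            warnings.warn(
                f"sample {sset.metadata['sample_id'].iloc[i]!r}: flat TSP "
                "window, no detectable maximum; zero shift applied")
            shifts.append(0)
            continue
        apex = int(widx[np.argmax(win)])
        k = target - apex
        out[i] = _shift_row(sset.intensities[i], k)
        shifts.append(k)
    return sset.replace(intensities=out).logged(
        "reference_align", window=[lo, hi], shifts=shifts)


def baseline_correct(sset: SpectrumSet,
                     knot_spacing: float = 0.25) -> SpectrumSet:
    """Subtract a cubic-spline baseline anchored at local window minima.

    The spectrum is lightly smoothed, the minimum of each ``knot_spacing``-wide
    window gives one anchor (position and smoothed value), and a natural cubic
    spline through the anchors is subtracted.  Negative intensities in the
    result are retained (the glog transform handles them downstream).
    """
    spacing = float(np.median(np.diff(sset.ppm)))
    if knot_spacing <= 3 * spacing:
        raise ValueError("knot_spacing must exceed a few grid spacings")
    span = sset.ppm[-1] - sset.ppm[0]
    if knot_spacing >= span:
        raise ValueError("knot_spacing wider than the spectral range")
    n_win = max(int(round(span / knot_spacing)), 4)
    edges = np.linspace(sset.ppm[0], sset.ppm[-1], n_win + 1)
    win_of = np.clip(np.searchsorted(edges, sset.ppm, side="right") - 1,
                     0, n_win - 1)
    out = np.empty_like(sset.intensities)
    smooth_pts = max(5, int(round(knot_spacing / spacing / 24)) | 1)
    for i in range(sset.n_samples):
        row = sset.intensities[i]
        smooth = uniform_filter1d(row, size=smooth_pts, mode="nearest")
        anchors_x, anchors_y = [], []
        for w in range(n_win):
            idx = np.flatnonzero(win_of == w)
            if idx.size == 0:
                continue
            j = idx[np.argmin(smooth[idx])]
            anchors_x.append(sset.ppm[j])
            anchors_y.append(smooth[j])
        if len(anchors_x) < 4:
            raise ValueError("too few baseline anchors; reduce knot_spacing")
        spline = CubicSpline(anchors_x, anchors_y, bc_type="natural")
        base = spline(np.clip(sset.ppm, anchors_x[0], anchors_x[-1]))
        out[i] = row - base
    return sset.replace(intensities=out).logged(
        "baseline_correct", knot_spacing=knot_spacing)


def exclude_regions(sset: SpectrumSet,
                    config: PreprocessConfig | None = None) -> SpectrumSet:
    """Drop columns whose ppm lies in any exclusion region (water, TSP)."""
    config = config or PreprocessConfig()
    drop = np.zeros(sset.n_points, dtype=bool)
    for lo, hi in config.exclusion_regions:
        drop |= (sset.ppm >= lo) & (sset.ppm <= hi)
    keep = ~drop
    if not keep.any():
        raise ValueError("exclusion regions remove every column")
    return sset.replace(intensities=sset.intensities[:, keep],
                        ppm=sset.ppm[keep]).logged(
        "exclude_regions",
        regions=[[float(a), float(b)] for a, b in config.exclusion_regions],
        n_removed=int(drop.sum()))


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def segmental_align(sset: SpectrumSet,
                    config: PreprocessConfig | None = None) -> SpectrumSet:
    """Interval-wise integer-shift alignment against the mean spectrum.

    For each configured segment and spectrum, the shift within
    ``±max_segment_shift`` points maximizing Pearson correlation with the mean
    spectrum's segment is applied (edge-value fill inside the segment).  Ties
    prefer the smallest |shift|, so already-aligned data is untouched.
    """
    config = config or PreprocessConfig()
    if config.max_segment_shift < 1:
        raise ValueError("max_segment_shift must be >= 1")
    target = sset.intensities.mean(axis=0)   # fixed target, computed once
    out = sset.intensities.copy()
    logged_shifts = []
    for lo, hi in config.alignment_segments:
        idx = np.flatnonzero((sset.ppm >= lo) & (sset.ppm <= hi))
        if idx.size == 0:
            continue
        if idx.size < 3:
            raise ValueError(f"segment ({lo}, {hi}) shorter than 3 points")
        tseg = target[idx]
        seg_shifts = []
        ks = sorted(range(-config.max_segment_shift,
                          config.max_segment_shift + 1),
                    key=lambda k: (abs(k), k))
        for i in range(sset.n_samples):
            seg = sset.intensities[i, idx]
            best_k, best_c = 0, -np.inf
            for k in ks:
                c = _pearson(_shift_row(seg, k), tseg)
                if c > best_c:
                    best_k, best_c = k, c
            out[i, idx] = _shift_row(seg, best_k)
            seg_shifts.append(best_k)
        logged_shifts.append({"segment": [float(lo), float(hi)],
                              "shifts": seg_shifts})
    return sset.replace(intensities=out).logged(
        "segmental_align", max_shift=config.max_segment_shift,
        segments=logged_shifts)


def total_area_normalize(sset: SpectrumSet) -> SpectrumSet:
    """Divide each spectrum by its own total area so every row sums to 1."""
    sums = sset.intensities.sum(axis=1)
    bad = np.flatnonzero(sums <= 0)
    if bad.size:
        names = sset.metadata["sample_id"].iloc[bad].tolist()
        raise ValueError(f"non-positive total area for sample(s): {names}")
    return sset.replace(intensities=sset.intensities / sums[:, None]).logged(
        "total_area_normalize")


def glog(y, y0: float = 1e-7, lam: float = 5e-4):
    """Generalized logarithm g(y) = ln((y - y0 + sqrt((y - y0)^2 + lam)) / 2).

    Behaves like ln(y) for y >> sqrt(lam), is finite for all real y
    (negatives included), and up-weights weak resonances.  Evaluated in a
    cancellation-safe form for large negative arguments.
    """
    if lam <= 0:
        raise ValueError("lambda must be > 0")
    s = np.asarray(y, dtype=float) - y0
    root = np.sqrt(s * s + lam)
    neg = s < 0
    denom = np.where(neg, root - s, 1.0)     # guarded: only used where s < 0
    inner = np.where(neg, lam / denom, s + root)
    return np.log(inner / 2.0)


def glog_inverse(g, y0: float = 1e-7, lam: float = 5e-4):
    """Analytic inverse of :func:`glog`: y = y0 + e^g - lam / (4 e^g)."""
    if lam <= 0:
        raise ValueError("lambda must be > 0")
    z = np.exp(np.asarray(g, dtype=float))
    return y0 + z - lam / (4.0 * z)


def glog_transform(sset: SpectrumSet,
                   config: PreprocessConfig | None = None) -> SpectrumSet:
    """Apply the generalized-log transform elementwise."""
    config = config or PreprocessConfig()
    return sset.replace(
        intensities=glog(sset.intensities, config.glog_y0,
                         config.glog_lambda)).logged(
        "glog_transform", y0=config.glog_y0, lam=config.glog_lambda)


def mean_center(X: np.ndarray):
    """Column-center a matrix; returns (centered, means).

    The returned means are applied to held-out data at prediction time;
    centering a single row is refused because its column means are the row
    itself.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("mean_center requires a matrix with >= 2 rows")
    means = X.mean(axis=0)
    return X - means, means


def preprocess_pipeline(sset: SpectrumSet,
                        config: PreprocessConfig | None = None
                        ) -> SpectrumSet:
    """Run the full chain (everything except the final mean-centering, which
    belongs to model fitting so held-out data can reuse training means)."""
    config = config or PreprocessConfig()
    s = reference_align(sset, config)
    s = baseline_correct(s, config.baseline_knot_spacing)
    s = exclude_regions(s, config)
    s = segmental_align(s, config)
    s = total_area_normalize(s)
    s = glog_transform(s, config)
    return s
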