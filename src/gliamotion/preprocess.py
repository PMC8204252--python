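"""From raw time-lapse stack to a registered, corrected, binarized mask series.

The processing chain mirrors the standard semi-automated workflow for
single-microglia motility assays: maximum-intensity z-projection,
translation-only x-y registration, cropping to the cell via a temporal
color-code overlay, background removal, median filtering, photobleach
correction, contrast normalization, and global-threshold binarization.

Two choices are load-bearing for everything downstream:

* the binarization threshold is computed ONCE from the pooled multi-frame
  histogram, never per frame — per-frame thresholds convert residual
  intensity drift into spurious "motility";
* every frame's mask is reduced to the single connected component holding
  the soma seed, so disconnected specks cannot inflate turnover areas.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage
from skimage import filters, morphology as skmorph, restoration, transform
from skimage.registration import phase_cross_correlation

from gliamotion.stack_io import Calibration, ProjectionSeries, TimeLapseStack


class PreprocessError(RuntimeError):
    """Raised when a correction or segmentation step cannot proceed."""


@dataclass
class PreprocessConfig:
    """Tunable parameters of the correction and binarization chain.

    Defaults follow common practice for this vocabulary of steps: a 2 px
    median filter, rolling-ball background subtraction with a ball much
    larger than any process (50 px), ratio-mode bleach correction, and
    0.35 % tail saturation for contrast normalization.
    """

    median_radius_px: int = 2
    background_ball_radius_px: int = 50
    bleach_model: str = "ratio"  # "ratio" | "exponential-fit" | "none"
    contrast_saturation_frac: float = 0.0035
    contrast_enhance: bool = True
    threshold_method: str = "otsu-global"  # "otsu-global" | "fixed"
    fixed_threshold: Optional[float] = None
    min_object_px: int = 25
    crop_margin_px: int = 10
    seed_snap_px: int = 10

    def __post_init__(self) -> None:
        if self.median_radius_px < 0:
            raise ValueError("median_radius_px must be ≥ 0")
        if not 0.0 <= self.contrast_saturation_frac <= 0.05:
            raise ValueError("contrast_saturation_frac must be in [0, 0.05]")
        if self.bleach_model not in ("ratio", "exponential-fit", "none"):
            raise ValueError(f"unknown bleach_model {self.bleach_model!r}")
        if self.threshold_method not in ("otsu-global", "fixed"):
            raise ValueError(f"unknown threshold_method {self.threshold_method!r}")
        if self.threshold_method == "fixed" and self.fixed_threshold is None:
            raise ValueError("fixed threshold_method requires fixed_threshold")


@dataclass
class BinaryMaskSeries:
    """Per-frame binary cell masks — the substrate of all dynamics math.

    Each frame is a single 8-connected component containing ``soma_seed``
    and is non-empty; both are enforced at construction.
    """

    masks: np.ndarray
    calibration: Optional[Calibration]
    soma_seed: Tuple[int, int]
    threshold: Optional[float] = None

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks, dtype=bool)
        if self.masks.ndim != 3:
            raise ValueError("masks must be T×Y×X")
        sy, sx = self.soma_seed
        for t, m in enumerate(self.masks):
            if not m.any():
                raise ValueError(f"frame {t}: empty mask")
            labels, _ = ndimage.label(m, structure=np.ones((3, 3), int))
            lab = labels[int(round(sy)), int(round(sx))]
            if lab == 0:
                raise ValueError(f"frame {t}: soma_seed {self.soma_seed} outside foreground")
            if (labels[m] != lab).any():
                raise ValueError(f"frame {t}: foreground is not a single seed component")

    @property
    def n_frames(self) -> int:
        return self.masks.shape[0]


# ---------------------------------------------------------------------------
# Projection and registration
# ---------------------------------------------------------------------------


def max_z_project(stack: TimeLapseStack) -> ProjectionSeries:
    """Maximum-intensity z-projection of each time point."""
    frames = stack.data.max(axis=1)
    return ProjectionSeries(frames=np.asarray(frames, dtype=float), calibration=stack.calibration)


def register_translation(
    series: ProjectionSeries, upsample_factor: int = 20
) -> ProjectionSeries:
    """Align all frames to frame-0 coordinates by pure x-y translation.

    Each frame ``t ≥ 1`` is registered to its predecessor by maximizing the
    plain image cross-correlation (subpixel, via Fourier upsampling);
    frame-to-previous offsets are accumulated so that every frame shares
    frame-0 coordinates.  Plain rather than phase-normalized correlation is
    used deliberately: phase normalization whitens the spectrum and lets
    shot noise at high frequencies masquerade as motion on low-texture
    fluorescence frames.  Pixels shifted in from outside the field are
    filled with 0.

    Raises
    ------
    PreprocessError
        If any frame is constant-intensity ("no registration signal").
    """
    frames = np.asarray(series.frames, dtype=float)
    t_total = frames.shape[0]
    for t in range(t_total):
        if np.ptp(frames[t]) == 0:
            raise PreprocessError(f"frame {t}: no registration signal (constant intensity)")
    offsets = np.zeros((t_total, 2))
    registered = np.empty_like(frames)
    registered[0] = frames[0]
    for t in range(1, t_total):
        shift, _, _ = phase_cross_correlation(
            frames[t - 1], frames[t], upsample_factor=upsample_factor, normalization=None
        )
        offsets[t] = offsets[t - 1] + shift  # frame-to-previous, accumulated to frame 0
        registered[t] = ndimage.shift(frames[t], offsets[t], order=1, mode="constant", cval=0.0)
    return ProjectionSeries(
        frames=registered, calibration=series.calibration, registration_offsets=offsets
    )


# ---------------------------------------------------------------------------
# Temporal color code and cropping
# ---------------------------------------------------------------------------


def temporal_color_code(
    series: ProjectionSeries, crop_margin_px: int = 10
) -> Tuple[np.ndarray, Tuple[int, int, int, int]]:
    """Max-over-time composite with frame index encoded as hue, plus crop box.

    Returns ``(overlay, (y0, y1, x0, x1))`` where the overlay is an RGB
    float image (time of the per-pixel maximum mapped through a cyclic
    colormap, brightness = normalized maximum) and the box is the bounding
    box of above-background pixels across all frames, expanded by
    ``crop_margin_px`` and clipped to the field (half-open bounds).
    """
    from matplotlib import colormaps

    frames = np.asarray(series.frames, dtype=float)
    t_total, h, w = frames.shape
    peak = frames.max(axis=0)
    t_of_peak = frames.argmax(axis=0)
    hue = colormaps["hsv"](t_of_peak / max(t_total, 2))[..., :3]
    lo, hi = peak.min(), peak.max()
    value = (peak - lo) / (hi - lo) if hi > lo else np.zeros_like(peak)
    overlay = hue * value[..., None]

    thresh = filters.threshold_otsu(frames.ravel()) if hi > lo else hi
    above = (frames > thresh).any(axis=0)
    if not above.any():  # fall back to the brightest pixel
        above = peak >= hi
    ys, xs = np.nonzero(above)
    y0 = max(0, int(ys.min()) - crop_margin_px)
    y1 = min(h, int(ys.max()) + 1 + crop_margin_px)
    x0 = max(0, int(xs.min()) - crop_margin_px)
    x1 = min(w, int(xs.max()) + 1 + crop_margin_px)
    return overlay, (y0, y1, x0, x1)


def crop_cell(series: ProjectionSeries, box: Tuple[int, int, int, int]) -> ProjectionSeries:
    """Crop all frames identically to the half-open box ``(y0, y1, x0, x1)``."""
    y0, y1, x0, x1 = box
    t_total, h, w = series.frames.shape
    if not (0 <= y0 < y1 <= h and 0 <= x0 < x1 <= w):
        raise ValueError(f"crop box {box} outside field of shape {(h, w)}")
    return ProjectionSeries(
        frames=series.frames[:, y0:y1, x0:x1],
        calibration=series.calibration,
        registration_offsets=series.registration_offsets,
    )


# ---------------------------------------------------------------------------
# Intensity corrections
# ---------------------------------------------------------------------------


def _rolling_ball_background(frame: np.ndarray, radius: int) -> np.ndarray:
    """Rolling-ball background estimate with shrink acceleration.

    For large ball radii the image is first reduced with a block-minimum
    filter, the ball rolled on the reduced image, and the background
    bilinearly expanded back — the same speed/accuracy trade ImageJ's
    Subtract Background makes.  The estimate is clamped to the frame so
    subtraction never produces negative intensities.
    """
    shrink = 1 if radius <= 10 else 2 if radius <= 30 else 4 if radius <= 100 else 8
    if shrink == 1:
        bg = restoration.rolling_ball(frame, radius=radius)
    else:
        small = _block_min(frame, shrink)
        bg_small = restoration.rolling_ball(small, radius=max(1, radius // shrink))
        bg = transform.resize(bg_small, frame.shape, order=1, anti_aliasing=False)
    return np.minimum(bg, frame)


def _block_min(frame: np.ndarray, block: int) -> np.ndarray:
    h, w = frame.shape
    ph, pw = (-h) % block, (-w) % block
    padded = np.pad(frame, ((0, ph), (0, pw)), mode="edge")
    return padded.reshape(
        padded.shape[0] // block, block, padded.shape[1] // block, block
    ).min(axis=(1, 3))


def _foreground_mean(frame: np.ndarray) -> float:
    """Mean intensity over above-background pixels (per-frame Otsu split)."""
    if np.ptp(frame) == 0:
        raise PreprocessError("frame has zero above-background pixels")
    thresh = filters.threshold_otsu(frame)
    fg = frame > thresh
    if not fg.any():
        raise PreprocessError("frame has zero above-background pixels")
    return float(frame[fg].mean())


def correct_frames(series: ProjectionSeries, cfg: PreprocessConfig) -> ProjectionSeries:
    """Background removal, median filter, bleach correction, contrast rescale.

    Steps in order:

    1. rolling-ball background subtraction (``background_ball_radius_px``;
       0 disables);
    2. median filter with a disk of ``median_radius_px`` (0 disables);
    3. photobleach correction — ``ratio`` mode scales frame ``t`` by
       ``mean(frame 0) / mean(frame t)`` over above-background pixels;
       ``exponential-fit`` mode fits ``exp(-k t)`` to the foreground-mean
       series and scales frame ``t`` by ``exp(+k t)``;
    4. contrast normalization — linear rescale to [0, 1] with
       ``contrast_saturation_frac`` of pixels clipped at each tail, the two
       clip points computed ONCE from the pooled time-series histogram and
       applied identically to every frame.
    """
    frames = np.asarray(series.frames, dtype=float).copy()

    if cfg.background_ball_radius_px > 0:
        for t in range(frames.shape[0]):
            frames[t] -= _rolling_ball_background(frames[t], cfg.background_ball_radius_px)

    if cfg.median_radius_px > 0:
        footprint = skmorph.disk(cfg.median_radius_px)
        for t in range(frames.shape[0]):
            frames[t] = ndimage.median_filter(frames[t], footprint=footprint)

    if cfg.bleach_model == "ratio":
        ref = _foreground_mean(frames[0])
        for t in range(1, frames.shape[0]):
            frames[t] = frames[t] * (ref / _foreground_mean(frames[t]))
    elif cfg.bleach_model == "exponential-fit":
        means = np.array([_foreground_mean(f) for f in frames])
        t_idx = np.arange(frames.shape[0])
        k = -np.polyfit(t_idx, np.log(means), 1)[0]
        frames *= np.exp(k * t_idx)[:, None, None]

    if cfg.contrast_enhance:
        p = cfg.contrast_saturation_frac * 100.0
        lo, hi = np.percentile(frames, [p, 100.0 - p])
        if hi <= lo:
            raise PreprocessError("degenerate intensity range for contrast rescale")
        frames = np.clip((frames - lo) / (hi - lo), 0.0, 1.0)

    return ProjectionSeries(
        frames=frames,
        calibration=series.calibration,
        registration_offsets=series.registration_offsets,
    )


# ---------------------------------------------------------------------------
# Binarization
# ---------------------------------------------------------------------------


def _remove_specks(mask: np.ndarray, min_px: int) -> np.ndarray:
    """Drop 8-connected foreground objects smaller than ``min_px`` pixels."""
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), int))
    if n == 0:
        return mask
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_px
    keep[0] = False
    return keep[labels]


def binarize_series(
    series: ProjectionSeries,
    cfg: PreprocessConfig,
    soma_seed: Optional[Tuple[int, int]] = None,
) -> BinaryMaskSeries:
    """Threshold all frames with one global threshold and keep the soma component.

    The threshold is Otsu's on the pooled intensity histogram of every frame
    (or ``cfg.fixed_threshold``), so masks remain comparable across time.
    Objects smaller than ``cfg.min_object_px`` are removed; per frame only
    the 8-connected component containing the soma seed is retained.  The
    seed defaults to the largest-inscribed-disk center of frame 0
    (:func:`gliamotion.morphology.detect_soma`); in frames where the exact
    seed pixel is background it is snapped to the nearest foreground pixel
    within ``cfg.seed_snap_px``.
    """
    frames = np.asarray(series.frames, dtype=float)
    if cfg.threshold_method == "fixed":
        threshold = float(cfg.fixed_threshold)
    else:
        if np.ptp(frames) == 0:
            raise PreprocessError("constant series: no threshold signal")
        threshold = float(filters.threshold_otsu(frames.ravel()))
    raw = frames > threshold
    if not raw.any():
        raise PreprocessError(f"empty mask: threshold {threshold} above all intensities")

    if soma_seed is None:
        from gliamotion.morphology import detect_soma

        first = raw[0]
        if cfg.min_object_px > 1:
            first = _remove_specks(first, cfg.min_object_px)
        if not first.any():
            raise PreprocessError("empty mask after speck removal in frame 0")
        soma_seed = detect_soma(first).center
    sy, sx = int(round(soma_seed[0])), int(round(soma_seed[1]))

    structure = np.ones((3, 3), int)
    masks = np.empty_like(raw)
    for t in range(raw.shape[0]):
        m = raw[t]
        if cfg.min_object_px > 1:
            m = _remove_specks(m, cfg.min_object_px)
        if not m.any():
            raise PreprocessError(f"frame {t}: empty mask after filtering")
        labels, _ = ndimage.label(m, structure=structure)
        lab = labels[sy, sx]
        if lab == 0:
            ys, xs = np.nonzero(m)
            d2 = (ys - sy) ** 2 + (xs - sx) ** 2
            i = int(np.argmin(d2))
            if d2[i] > cfg.seed_snap_px**2:
                raise PreprocessError(
                    f"frame {t}: soma seed ({sy}, {sx}) outside any component"
                )
            lab = labels[ys[i], xs[i]]
        masks[t] = labels == lab
    return BinaryMaskSeries(
        masks=masks,
        calibration=series.calibration,
        soma_seed=(sy, sx),
        threshold=threshold,
    )
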