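"""Motility, surveillance and area readouts from binary mask series.

All dynamics math reduces to pixel-set differences between consecutive
binarized frames.  For a transition t_n → t_n+1:

* retraction area  = pixels occupied at t_n but not at t_n+1,
* extension area   = pixels newly occupied at t_n+1,
* relative values  = those counts divided by the cell area at t_n.

The per-transition motility (relative retraction + relative extension) is
the fraction of the cell footprint that turned over; its mean across the
recording is the cell's motility index.  Summing the absolute retraction
and extension areas over the recording gives the surveillance index — the
total tissue area sampled by the processes.  The conservation identity

    |mask t_n| − retraction_px + extension_px = |mask t_n+1|

holds exactly for every transition and is asserted in tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from gliamotion.preprocess import BinaryMaskSeries


@dataclass(frozen=True)
class FrameTransition:
    """Pixel turnover between consecutive masks t_n → t_n+1."""

    t: int
    retraction_px: int
    extension_px: int
    retraction_rel: float
    extension_rel: float

    @property
    def motility_t(self) -> float:
        """Fraction of the t_n footprint that turned over in this transition."""
        return self.retraction_rel + self.extension_rel


@dataclass
class DynamicsResult:
    """Per-recording summary of process dynamics.

    ``motility_index`` is the mean (or, if configured, the sum) of the
    per-transition motility values.  ``surveillance_index_px`` is the exact
    integer sum of absolute retraction and extension areas; the µm²
    denomination is attached only when a calibration is available.
    """

    transitions: List[FrameTransition]
    motility_index: float
    surveillance_index_px: int
    area_series_px: np.ndarray
    surveillance_index_um2: Optional[float] = None
    mean_area_um2: Optional[float] = None
    is_noise_floor: bool = False
    motility_summary: str = "mean"

    @property
    def motility_series(self) -> np.ndarray:
        return np.array([tr.motility_t for tr in self.transitions])


def transition(mask_a: np.ndarray, mask_b: np.ndarray, t: int = 0) -> FrameTransition:
    """Set-difference turnover between two masks of identical shape.

    Raises ``ValueError`` on shape mismatch or an empty ``mask_a`` (the
    relative values divide by ``|mask_a|``; an empty cell mask is always an
    upstream failure, never a zero).
    """
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shape mismatch: {a.shape} vs {b.shape}")
    n_a = int(a.sum())
    if n_a == 0:
        raise ValueError("empty mask at t_n: relative areas undefined")
    retraction = int(np.count_nonzero(a & ~b))
    extension = int(np.count_nonzero(b & ~a))
    return FrameTransition(
        t=t,
        retraction_px=retraction,
        extension_px=extension,
        retraction_rel=retraction / n_a,
        extension_rel=extension / n_a,
    )


def compute_dynamics(
    series: BinaryMaskSeries | np.ndarray,
    motility_summary: str = "mean",
) -> DynamicsResult:
    """Compute all transitions and summary readouts for a mask series.

    Accepts either a :class:`~gliamotion.preprocess.BinaryMaskSeries` (µm²
    fields filled from its calibration) or a bare boolean T×Y×X array
    (pixel-denominated readouts only).
    """
    if motility_summary not in ("mean", "sum"):
        raise ValueError(f"motility_summary must be 'mean' or 'sum', got {motility_summary!r}")
    if isinstance(series, BinaryMaskSeries):
        masks = series.masks
        calibration = series.calibration
    else:
        masks = np.asarray(series, dtype=bool)
        calibration = None
    if masks.ndim != 3 or masks.shape[0] < 2:
        raise ValueError("need a T×Y×X series with T ≥ 2")
    for t, m in enumerate(masks):
        if not m.any():
            raise ValueError(f"frame {t}: empty mask")

    transitions = [transition(masks[t], masks[t + 1], t=t) for t in range(masks.shape[0] - 1)]
    motility = np.array([tr.motility_t for tr in transitions])
    surveillance_px = int(sum(tr.retraction_px + tr.extension_px for tr in transitions))
    areas = masks.sum(axis=(1, 2)).astype(int)

    surveillance_um2 = mean_area_um2 = None
    if calibration is not None:
        px_area = calibration.pixel_area_um2
        surveillance_um2 = surveillance_px * px_area
        mean_area_um2 = float(areas.mean() * px_area)

    return DynamicsResult(
        transitions=transitions,
        motility_index=float(motility.mean() if motility_summary == "mean" else motility.sum()),
        surveillance_index_px=surveillance_px,
        surveillance_index_um2=surveillance_um2,
        area_series_px=areas,
        mean_area_um2=mean_area_um2,
        motility_summary=motility_summary,
    )


def noise_floor(fixed_series: BinaryMaskSeries | np.ndarray, **kwargs) -> DynamicsResult:
    """Dynamics of a motion-free specimen, labeled as a noise-floor run.

    Applied to a chemically fixed sample (or a simulated cell with all
    kinetics disabled), the resulting motility index measures the noise of
    the acquisition + analysis chain itself — residual mask jitter from
    photon noise, registration error and stage drift — and is reported
    alongside experimental values as the pipeline's detection floor.
    """
    result = compute_dynamics(fixed_series, **kwargs)
    result.is_noise_floor = True
    return result


# ---------------------------------------------------------------------------
# Stability / trend reporting
# ---------------------------------------------------------------------------


@dataclass
class StabilityReport:
    """Linear trends of the readouts against time or slice age.

    ``table`` has one row per readout with columns
    ``readout, slope, intercept, correlation, n``.  For within-recording
    mode, ``motility_trace`` holds the per-transition motility values.
    """

    table: "object"  # pandas.DataFrame
    motility_trace: Optional[np.ndarray] = None


def _linear_trend(x: np.ndarray, y: np.ndarray) -> tuple:
    slope, intercept = np.polyfit(x, y, 1)
    sx, sy = np.std(x), np.std(y)
    corr = 0.0 if sx == 0 or sy == 0 else float(np.corrcoef(x, y)[0, 1])
    return float(slope), float(intercept), corr


def stability_report(
    results: Sequence[DynamicsResult] | DynamicsResult,
    slice_age_min: Optional[Sequence[float]] = None,
):
    """Trend of motility / surveillance / area versus slice age or recording time.

    Two modes:

    * cohort mode — ``results`` is a sequence of per-cell results with
      matching ``slice_age_min`` annotations (≥ 3 cells): each readout is
      regressed against slice age; slope and Pearson correlation are
      reported with no significance machinery attached.
    * within-recording mode — a single result with ≥ 10 transitions: the
      per-transition motility trace is regressed against transition index.
    """
    import pandas as pd

    if isinstance(results, DynamicsResult):
        trace = results.motility_series
        if len(trace) < 10:
            raise ValueError(
                f"insufficient points: need ≥ 10 transitions, got {len(trace)}"
            )
        t = np.arange(len(trace), dtype=float)
        slope, intercept, corr = _linear_trend(t, trace)
        table = pd.DataFrame(
            [
                {
                    "readout": "motility_t",
                    "slope": slope,
                    "intercept": intercept,
                    "correlation": corr,
                    "n": len(trace),
                }
            ]
        )
        return StabilityReport(table=table, motility_trace=trace)

    results = list(results)
    if slice_age_min is None or len(results) != len(slice_age_min):
        raise ValueError("cohort mode requires one slice_age_min per cell")
    if len(results) < 3:
        raise ValueError(f"insufficient points: need ≥ 3 cells, got {len(results)}")
    age = np.asarray(slice_age_min, dtype=float)
    readouts = {
        "motility_index": np.array([r.motility_index for r in results]),
        "surveillance_index_px": np.array(
            [r.surveillance_index_px for r in results], dtype=float
        ),
        "mean_area_px": np.array([r.area_series_px.mean() for r in results]),
    }
    rows = []
    for name, values in readouts.items():
        slope, intercept, corr = _linear_trend(age, values)
        rows.append(
            {
                "readout": name,
                "slope": slope,
                "intercept": intercept,
                "correlation": corr,
                "n": len(results),
            }
        )
    return StabilityReport(table=pd.DataFrame(rows))
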