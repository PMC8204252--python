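"""Synthetic single-microglia time-lapse generator with exact ground truth.

The simulator emulates what the analysis pipeline sees in a slice
recording: one GFP-labelled ramified cell on a dark background, imaged as a
short stack series.  A cell is grown as a soma disk plus a recursively
bifurcating tree of line segments, evolved frame-to-frame by retracting and
extending terminal processes at a configured turnover rate, and rendered
through a simple imaging model (PSF blur, x-y stage drift, exponential
photobleaching, Poisson shot noise).  Because masks, generating segments,
and per-transition pixel counts are all recorded before rendering, every
downstream readout — motility, surveillance, area, Sholl profile — has an
exact ground-truth value to compare against.

Default geometry matches a typical two-photon acquisition of this kind:
a 512×512 field spanning 129.5 µm (0.253 µm/px) recorded for 8 frames.
All randomness flows from the single ``seed``; the same config always
produces bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage
from skimage import draw as skdraw, morphology as skmorph

from gliamotion.stack_io import Calibration, TimeLapseStack


class SynthError(RuntimeError):
    pass


@dataclass
class SynthConfig:
    """Parameters of cell geometry, kinetics and the imaging model.

    ``turnover_q`` is the expected fraction of cell pixels retracted AND
    (independently) re-extended per frame transition; realized per-transition
    pixel counts are measured exactly from the rasterized masks.
    """

    seed: int = 0
    field_px: Tuple[int, int] = (512, 512)
    pixel_size_um: float = 129.5 / 512
    n_frames: int = 8
    frame_interval_s: float = 60.0
    # geometry
    soma_radius_um: float = 4.0
    n_primary_branches: int = 5
    branch_angle_spread_rad: float = 0.7
    mean_branch_length_um: float = 11.0
    branch_width_um: float = 1.3
    max_branch_depth: int = 3
    branch_prob: float = 0.65
    # kinetics
    turnover_q: float = 0.1
    drift_px_per_frame: Tuple[float, float] = (0.0, 0.0)
    bleach_rate_per_frame: float = 0.0
    # imaging model
    noise_model: str = "poisson"  # "poisson" | "gaussian" | "none"
    photons_per_unit: float = 100.0
    gaussian_sigma: float = 0.02
    psf_sigma_um: float = 0.3
    background_intensity: float = 0.05
    cell_intensity: float = 1.0
    z_planes: int = 1
    plane_replicates: int = 2  # two images per plane, averaged during processing

    def __post_init__(self) -> None:
        if not 0.0 <= self.turnover_q <= 0.5:
            raise ValueError("turnover_q must be in [0, 0.5]")
        for name in ("pixel_size_um", "soma_radius_um", "mean_branch_length_um", "branch_width_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be ≥ 1")
        if self.noise_model not in ("poisson", "gaussian", "none"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")

    @property
    def calibration(self) -> Calibration:
        return Calibration(
            pixel_size_um=self.pixel_size_um,
            z_step_um=1.0,
            frame_interval_s=self.frame_interval_s,
        )


@dataclass
class Segment:
    """One process segment in pixel coordinates; part of a rooted tree."""

    start: np.ndarray  # (y, x) float px
    end: np.ndarray
    parent: int  # index into the segment list, −1 for primaries
    depth: int
    alive: bool = True

    @property
    def length_px(self) -> float:
        return float(np.hypot(*(self.end - self.start)))

    @property
    def direction(self) -> np.ndarray:
        v = self.end - self.start
        n = np.hypot(*v)
        return v / n if n > 0 else np.array([0.0, 1.0])


@dataclass
class CellGeometry:
    soma_center: Tuple[float, float]  # (y, x) px
    soma_radius_px: float
    segments: List[Segment]

    def terminal_indices(self) -> List[int]:
        has_child = set()
        for seg in self.segments:
            if seg.alive and seg.parent >= 0:
                has_child.add(seg.parent)
        return [
            i for i, s in enumerate(self.segments) if s.alive and i not in has_child
        ]


@dataclass
class GroundTruth:
    """Everything the pipeline should recover, in frame-0 coordinates."""

    masks: np.ndarray  # bool T×Y×X, pre-noise, pre-drift
    segments_px: List[List[Tuple[Tuple[float, float], Tuple[float, float]]]]
    true_transitions: List[Tuple[int, int]]  # (retraction_px, extension_px)
    true_drift: np.ndarray  # T×2 cumulative (dy, dx)
    soma_center: Tuple[float, float]
    soma_radius_px: float
    config: SynthConfig

    def segments_um(self, t: int):
        """Generating segments of frame ``t`` in µm (for the analytic Sholl oracle)."""
        s = self.config.pixel_size_um
        return [
            ((y0 * s, x0 * s), (y1 * s, x1 * s))
            for (y0, x0), (y1, x1) in self.segments_px[t]
        ]

    @property
    def soma_center_um(self) -> Tuple[float, float]:
        s = self.config.pixel_size_um
        return (self.soma_center[0] * s, self.soma_center[1] * s)


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------


def _rasterize(geom: CellGeometry, shape: Tuple[int, int], width_px: float) -> np.ndarray:
    """Render soma disk + dilated segment skeleton to a boolean mask."""
    canvas = np.zeros(shape, dtype=bool)
    for seg in geom.segments:
        if not seg.alive or seg.length_px < 0.5:
            continue
        rr, cc = skdraw.line(
            int(round(seg.start[0])),
            int(round(seg.start[1])),
            int(round(seg.end[0])),
            int(round(seg.end[1])),
        )
        keep = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
        canvas[rr[keep], cc[keep]] = True
    radius = max(1, int(round(width_px / 2)))
    if canvas.any():
        canvas = ndimage.binary_dilation(canvas, structure=skmorph.disk(radius))
    rr, cc = skdraw.disk(geom.soma_center, geom.soma_radius_px, shape=shape)
    canvas[rr, cc] = True
    return canvas


# ---------------------------------------------------------------------------
# Growth
# ---------------------------------------------------------------------------


def _clip_to_field(
    start: np.ndarray, end: np.ndarray, shape: Tuple[int, int], margin: float
) -> np.ndarray:
    """Truncate a segment so its end stays ``margin`` px inside the field."""
    lo = np.array([margin, margin])
    hi = np.array([shape[0] - 1 - margin, shape[1] - 1 - margin])
    d = end - start
    t_max = 1.0
    for k in range(2):
        if d[k] > 0 and end[k] > hi[k]:
            t_max = min(t_max, (hi[k] - start[k]) / d[k])
        elif d[k] < 0 and end[k] < lo[k]:
            t_max = min(t_max, (lo[k] - start[k]) / d[k])
    return start + max(t_max, 0.0) * d


def grow_cell(cfg: SynthConfig, rng: Optional[np.random.Generator] = None) -> CellGeometry:
    """Grow a soma + recursively bifurcating process tree.

    Primary branches leave the soma at jittered evenly spaced angles;
    segment lengths are exponentially distributed around
    ``mean_branch_length_um``; each segment bifurcates with probability
    ``branch_prob`` up to ``max_branch_depth``, children deviating from the
    parent direction by ± a uniform draw within ``branch_angle_spread_rad``.
    Segments are truncated at the field border so the mask always fits.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    shape = cfg.field_px
    px = cfg.pixel_size_um
    soma_r = cfg.soma_radius_um / px
    width_px = cfg.branch_width_um / px
    margin = width_px / 2 + 2
    center = np.array([shape[0] / 2.0, shape[1] / 2.0])
    if soma_r + cfg.mean_branch_length_um / px / 2 + margin > min(shape) / 2:
        raise SynthError("cell exceeds field: shrink geometry or enlarge field_px")

    segments: List[Segment] = []

    def sprout(start: np.ndarray, angle: float, depth: int, parent: int) -> None:
        length = rng.exponential(cfg.mean_branch_length_um / px)
        length = float(np.clip(length, 2.0 / px, 3.0 * cfg.mean_branch_length_um / px))
        direction = np.array([math.sin(angle), math.cos(angle)])
        end = _clip_to_field(start, start + length * direction, shape, margin)
        segments.append(Segment(start=start.copy(), end=end, parent=parent, depth=depth))
        idx = len(segments) - 1
        if depth < cfg.max_branch_depth and rng.random() < cfg.branch_prob:
            for sign in (-1.0, 1.0):
                child_angle = angle + sign * rng.uniform(0.15, cfg.branch_angle_spread_rad)
                sprout(end, child_angle, depth + 1, idx)

    base = rng.uniform(0, 2 * math.pi)
    for i in range(cfg.n_primary_branches):
        angle = base + 2 * math.pi * i / cfg.n_primary_branches + rng.normal(0, 0.15)
        start = center + soma_r * np.array([math.sin(angle), math.cos(angle)])
        sprout(start, angle, depth=0, parent=-1)

    geom = CellGeometry(
        soma_center=(float(center[0]), float(center[1])),
        soma_radius_px=float(soma_r),
        segments=segments,
    )
    mask = _rasterize(geom, shape, width_px)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), int))
    if n != 1:  # cannot happen for branches rooted at the soma, but assert it
        raise SynthError(f"grown mask has {n} connected components")
    return geom


# ---------------------------------------------------------------------------
# Evolution
# ---------------------------------------------------------------------------


def _kill_or_shorten(seg: Segment, step: float) -> None:
    if seg.length_px <= step:
        seg.alive = False
    else:
        seg.end = seg.end - step * seg.direction


def evolve(
    geom: CellGeometry, cfg: SynthConfig, rng: Optional[np.random.Generator] = None
) -> GroundTruth:
    """Evolve the tree over ``n_frames``, recording masks and exact turnover.

    Per transition the terminal pool is split at random into a retraction
    half and an extension half (so extensions do not simply refill freshly
    retracted corridors): tips in the retraction half are shortened in ~1 µm
    steps until the pixels lost since the previous frame reach
    ``turnover_q × area``, tips in the extension half are elongated (with
    angular jitter, occasionally sprouting a new child or a new primary)
    until the newly gained pixels reach the same target.  Realized counts
    are measured from the rasterized masks, so the recorded ground truth is
    exact by construction.  The soma disk is never modified.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    shape = cfg.field_px
    px = cfg.pixel_size_um
    width_px = cfg.branch_width_um / px
    margin = width_px / 2 + 2
    step = max(1.0, 0.8 / px)
    center = np.array(geom.soma_center)

    masks = [_rasterize(geom, shape, width_px)]
    segments_per_frame = [
        [
            (tuple(s.start), tuple(s.end))
            for s in geom.segments
            if s.alive and s.length_px >= 0.5
        ]
    ]
    transitions: List[Tuple[int, int]] = []

    for _t in range(1, cfg.n_frames):
        prev = masks[-1]
        target = int(round(cfg.turnover_q * prev.sum()))

        terminals = geom.terminal_indices()
        rng.shuffle(terminals)
        half = len(terminals) // 2
        retract_pool = terminals[:half] if half else list(terminals)
        extend_pool = terminals[half:] if half else list(terminals)

        # Between rasterizations a batch of shorten/extend operations is
        # applied, sized from an adaptive pixels-per-operation estimate;
        # batches shrink to single operations as the target is approached,
        # keeping overshoot to one operation's worth of pixels.
        px_per_op = max(4.0, step * width_px)

        # --- retraction ---
        if target > 0:
            lost, ops_done, guard = 0, 0, 0
            while lost < target and guard < 300:
                guard += 1
                n_ops = int(np.clip((target - lost) / px_per_op, 1, 12))
                for _ in range(n_ops):
                    retract_pool = [i for i in retract_pool if geom.segments[i].alive]
                    if not retract_pool:
                        retract_pool = geom.terminal_indices()
                        if not retract_pool:
                            raise SynthError(
                                "turnover_q too large to sustain the tree: "
                                "all processes retracted"
                            )
                    _kill_or_shorten(geom.segments[rng.choice(retract_pool)], step)
                    ops_done += 1
                cur = _rasterize(geom, shape, width_px)
                lost = int(np.count_nonzero(prev & ~cur))
                if lost > 0 and ops_done > 0:
                    px_per_op = max(2.0, lost / ops_done)

        # --- extension ---
        if target > 0:
            gained, ops_done, guard = 0, 0, 0
            px_per_op = max(4.0, step * width_px)
            while gained < target and guard < 300:
                guard += 1
                n_ops = int(np.clip((target - gained) / px_per_op, 1, 12))
                for _ in range(n_ops):
                    extend_pool = [i for i in extend_pool if geom.segments[i].alive]
                    if not extend_pool:
                        extend_pool = geom.terminal_indices()
                    if not extend_pool:
                        # tree fully retracted: sprout a fresh primary from the soma
                        angle = rng.uniform(0, 2 * math.pi)
                        start = center + geom.soma_radius_px * np.array(
                            [math.sin(angle), math.cos(angle)]
                        )
                        geom.segments.append(
                            Segment(start=start, end=start.copy(), parent=-1, depth=0)
                        )
                        extend_pool = [len(geom.segments) - 1]
                    idx = int(rng.choice(extend_pool))
                    seg = geom.segments[idx]
                    if rng.random() < 0.15 and seg.length_px > 2 * step:
                        # sprout a side child instead of elongating the tip
                        angle = math.atan2(*seg.direction) + rng.uniform(
                            -cfg.branch_angle_spread_rad, cfg.branch_angle_spread_rad
                        )
                        d = np.array([math.sin(angle), math.cos(angle)])
                        end = _clip_to_field(seg.end, seg.end + step * d, shape, margin)
                        geom.segments.append(
                            Segment(
                                start=seg.end.copy(), end=end, parent=idx, depth=seg.depth + 1
                            )
                        )
                        extend_pool.append(len(geom.segments) - 1)
                    else:
                        jitter = rng.normal(0, 0.2)
                        angle = math.atan2(seg.direction[0], seg.direction[1]) + jitter
                        d = np.array([math.sin(angle), math.cos(angle)])
                        new_end = _clip_to_field(seg.end, seg.end + step * d, shape, margin)
                        if np.allclose(new_end, seg.end):  # pinned at the border
                            extend_pool.remove(idx)
                            continue
                        seg.end = new_end
                    ops_done += 1
                cur = _rasterize(geom, shape, width_px)
                gained = int(np.count_nonzero(cur & ~prev))
                if gained > 0 and ops_done > 0:
                    px_per_op = max(2.0, gained / ops_done)

        cur = _rasterize(geom, shape, width_px)
        masks.append(cur)
        segments_per_frame.append(
            [
                (tuple(s.start), tuple(s.end))
                for s in geom.segments
                if s.alive and s.length_px >= 0.5
            ]
        )
        ret = int(np.count_nonzero(prev & ~cur))
        ext = int(np.count_nonzero(cur & ~prev))
        assert prev.sum() - ret + ext == cur.sum()  # conservation, by construction
        transitions.append((ret, ext))

    drift = np.outer(np.arange(cfg.n_frames), np.asarray(cfg.drift_px_per_frame, float))
    return GroundTruth(
        masks=np.stack(masks),
        segments_px=segments_per_frame,
        true_transitions=transitions,
        true_drift=drift,
        soma_center=geom.soma_center,
        soma_radius_px=geom.soma_radius_px,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

_QUANT_SCALE = 10_000.0  # counts per intensity unit for noise-free / gaussian renders


def render(
    truth: GroundTruth, cfg: SynthConfig, rng: Optional[np.random.Generator] = None
) -> TimeLapseStack:
    """Render ground-truth masks through the imaging model to a uint16 stack.

    Per frame: mask → intensity (cell vs background level) → Gaussian PSF
    blur → exponential bleach ``exp(−k·t)`` → translation by cumulative
    drift → shot noise → uint16 quantization.  With ``z_planes`` and/or
    ``plane_replicates`` above 1 the plane is duplicated with independent
    noise per copy (replicates stored consecutively), exercising the
    replicate-averaging step of the reader.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    px = cfg.pixel_size_um
    sigma_px = cfg.psf_sigma_um / px
    frames = []
    for t in range(truth.masks.shape[0]):
        img = np.where(truth.masks[t], cfg.cell_intensity, cfg.background_intensity).astype(float)
        if sigma_px > 0:
            img = ndimage.gaussian_filter(img, sigma=sigma_px)
        decay = math.exp(-cfg.bleach_rate_per_frame * t)
        img *= decay
        dy, dx = truth.true_drift[t]
        if dy != 0 or dx != 0:
            img = ndimage.shift(
                img, (dy, dx), order=1, mode="constant", cval=cfg.background_intensity * decay
            )
        planes = []
        for _z in range(cfg.z_planes * cfg.plane_replicates):
            if cfg.noise_model == "poisson":
                plane = rng.poisson(np.clip(img, 0, None) * cfg.photons_per_unit)
            elif cfg.noise_model == "gaussian":
                plane = np.round(
                    np.clip(img + rng.normal(0, cfg.gaussian_sigma, img.shape), 0, None)
                    * _QUANT_SCALE
                )
            else:
                plane = np.round(img * _QUANT_SCALE)
            planes.append(np.clip(plane, 0, 65535).astype(np.uint16))
        frames.append(np.stack(planes))
    return TimeLapseStack(
        data=np.stack(frames),
        calibration=cfg.calibration,
        plane_replicates=cfg.plane_replicates,
    )


def random_planar_tree(
    seed: int,
    soma_radius_um: float = 3.0,
    radial_step_um: float = 1.0,
) -> Tuple[list, Tuple[float, float]]:
    """Random branched tree in general position for Sholl validation.

    Returns ``(segments_um, center_um)`` with ``center_um = (0, 0)``.  The
    tree is constructed so that every crossing of a Sholl circle is
    unambiguous on the pixel grid: tips and branch points sit mid-way
    between sampling radii, sibling branches diverge by at least 0.3 rad,
    each tree uses distinct junction radii, and primary sectors are
    angularly disjoint so subtrees never cross.  Discrete crossing counts
    of such a tree match the analytic segment–circle counts to ±1 at every
    radius; degenerate coincidences (a tip or junction exactly on a circle,
    two junctions in one annulus) are excluded by construction, since there
    the discrete count is not well defined.
    """
    rng = np.random.default_rng(seed)
    n_primary = int(rng.integers(4, 6))
    base = rng.uniform(0, 2 * math.pi)
    mid = lambda k: (k + 0.5) * radial_step_um  # mid-annulus (junction) radius
    tip = lambda k: (k + 0.22) * radial_step_um  # just past a circle (tip radius)
    junction_slots = list(rng.permutation(np.arange(6, 12)))
    tip_slots = np.arange(14, 27)
    segments = []
    for i in range(n_primary):
        theta = base + 2 * math.pi * i / n_primary + rng.uniform(-0.08, 0.08)
        u = np.array([math.sin(theta), math.cos(theta)])
        start = (soma_radius_um + 0.2) * u
        if rng.random() < 0.6 and junction_slots:
            b = mid(junction_slots.pop())
            junction = b * u
            segments.append((tuple(start), tuple(junction)))
            for sign in (-1.0, 1.0):
                phi = theta + sign * rng.uniform(0.3, 0.45)
                v = np.array([math.sin(phi), math.cos(phi)])
                tip_r = tip(rng.choice(tip_slots))
                # child extends until its radial distance is near tip_r
                length = max(2.0, tip_r - b + 2.0 * rng.random())
                end = junction + length * v
                # keep the tip radius just past a circle (0.12–0.40 fractional),
                # clear of the knife edge where pixel rounding flips the count
                for _ in range(4):
                    frac = (float(np.hypot(*end)) % radial_step_um) / radial_step_um
                    if 0.12 <= frac <= 0.40:
                        break
                    length += 0.25 * radial_step_um
                    end = junction + length * v
                segments.append((tuple(junction), tuple(end)))
        else:
            tip_r = tip(rng.choice(tip_slots))
            segments.append((tuple(start), tuple(tip_r * u)))
    return segments, (0.0, 0.0)


def simulate(cfg: SynthConfig) -> Tuple[TimeLapseStack, GroundTruth]:
    """Grow, evolve and render one cell; the canonical seeded entry point."""
    rng = np.random.default_rng(cfg.seed)
    geom = grow_cell(cfg, rng)
    truth = evolve(geom, cfg, rng)
    stack = render(truth, cfg, rng)
    return stack, truth
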