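"""Soma localization, process skeletonization and Sholl ramification analysis.

Sholl analysis counts, for concentric circles of increasing radius around
the soma, how many processes cross each circle; the profile of counts
versus radius summarizes the cell's ramification.  Here circles are
realized as thin annuli on the skeletonized cell, and crossings are counted
as connected angular arcs of skeleton pixels within each annulus — robust
to the pixel aliasing of discrete circles.  Externally traced morphologies
can be imported from SWC files and analyzed with exact segment–circle
intersection counts instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from skimage import morphology as skmorph


@dataclass(frozen=True)
class SomaDetection:
    center: Tuple[int, int]  # (y, x) pixel of the inscribed-disk optimum
    radius_px: float
    radius_um: Optional[float] = None


@dataclass
class CellSkeleton:
    """1-px-wide 8-connected medial-axis representation of a cell mask."""

    skeleton_mask: np.ndarray
    soma_center: Tuple[float, float]
    branch_points: List[Tuple[int, int]] = field(default_factory=list)
    end_points: List[Tuple[int, int]] = field(default_factory=list)


@dataclass
class ShollProfile:
    """Intersection counts versus radial distance from the soma.

    ``total_intersections`` is the area under the profile in
    intersections·µm (counts × radial step).  ``critical_radius_um`` is the
    radius of maximal intersection count (smallest such radius on ties).
    """

    radii_um: np.ndarray
    intersections: np.ndarray
    radial_step_um: float

    @property
    def max_intersections(self) -> int:
        return int(self.intersections.max()) if self.intersections.size else 0

    @property
    def critical_radius_um(self) -> float:
        if self.intersections.size == 0:
            return 0.0
        return float(self.radii_um[int(np.argmax(self.intersections))])

    @property
    def total_intersections(self) -> float:
        return float(self.intersections.sum() * self.radial_step_um)


# ---------------------------------------------------------------------------
# Soma detection
# ---------------------------------------------------------------------------


def detect_soma(
    frame: np.ndarray, pixel_size_um: Optional[float] = None
) -> SomaDetection:
    """Locate the soma as the center of the largest inscribed disk.

    ``frame`` may be a binary mask or an intensity image (thresholded with
    Otsu first).  The center is the maximum of the Euclidean distance
    transform of the mask; ties are broken by the smallest (y, x)
    lexicographically, and the inscribed-disk radius is that distance.
    """
    frame = np.asarray(frame)
    if frame.dtype == bool:
        mask = frame
    else:
        from skimage.filters import threshold_otsu

        if np.ptp(frame) == 0:
            raise ValueError("constant intensity frame: no soma signal")
        mask = frame > threshold_otsu(frame)
    if not mask.any():
        raise ValueError("empty mask: cannot detect soma")
    dist = ndimage.distance_transform_edt(mask)
    best = dist.max()
    ys, xs = np.nonzero(dist == best)
    center = (int(ys[0]), int(xs[0]))  # nonzero is row-major → lexicographic min
    return SomaDetection(
        center=center,
        radius_px=float(best),
        radius_um=float(best) * pixel_size_um if pixel_size_um else None,
    )


# ---------------------------------------------------------------------------
# Skeletonization
# ---------------------------------------------------------------------------

_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _degree_map(skel: np.ndarray) -> np.ndarray:
    kernel = np.ones((3, 3), int)
    kernel[1, 1] = 0
    return ndimage.convolve(skel.astype(int), kernel, mode="constant") * skel


def _prune_spurs(skel: np.ndarray, max_len: int) -> np.ndarray:
    """Remove terminal twigs of ``max_len`` pixels or fewer.

    A spur is traced from an end point toward the first branch point; if the
    traced path (excluding the branch point) is no longer than ``max_len``
    it is deleted.  Repeats until no such spur remains.
    """
    skel = skel.copy()
    changed = True
    while changed:
        changed = False
        deg = _degree_map(skel)
        ends = list(zip(*np.nonzero(deg == 1)))
        for ey, ex in ends:
            if not skel[ey, ex]:
                continue
            path = [(ey, ex)]
            prev = None
            while len(path) <= max_len:
                cy, cx = path[-1]
                nbrs = [
                    (cy + dy, cx + dx)
                    for dy, dx in _NEIGHBORS
                    if 0 <= cy + dy < skel.shape[0]
                    and 0 <= cx + dx < skel.shape[1]
                    and skel[cy + dy, cx + dx]
                    and (cy + dy, cx + dx) != prev
                ]
                if len(nbrs) != 1:
                    break  # reached a branch point (or isolated pixel)
                nxt = nbrs[0]
                if deg[nxt] >= 3:
                    # spur shorter than threshold: delete it
                    for py, px in path:
                        skel[py, px] = False
                    changed = True
                    break
                prev = (cy, cx)
                path.append(nxt)
    return skel


def skeletonize_cell(
    mask: np.ndarray,
    soma: Optional[Tuple[float, float]] = None,
    prune_px: int = 2,
) -> CellSkeleton:
    """Topology-preserving thinning of a cell mask with short-spur pruning.

    Branch points are skeleton pixels with 8-neighborhood degree ≥ 3, end
    points those with degree 1.  Spurs of ``prune_px`` pixels or fewer —
    thinning artifacts of boundary roughness — are removed.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask: cannot skeletonize")
    if soma is None:
        soma = detect_soma(mask).center
    skel = skmorph.skeletonize(mask)
    if prune_px > 0:
        pruned = _prune_spurs(skel, prune_px)
        if pruned.any():
            skel = pruned
    deg = _degree_map(skel)
    # adjacent degree-≥3 pixels belong to one junction: merge into clusters
    junctions, n_j = ndimage.label(deg >= 3, structure=np.ones((3, 3), int))
    centers = ndimage.center_of_mass(deg >= 3, junctions, range(1, n_j + 1))
    return CellSkeleton(
        skeleton_mask=skel,
        soma_center=(float(soma[0]), float(soma[1])),
        branch_points=[(int(round(y)), int(round(x))) for y, x in centers],
        end_points=[(int(y), int(x)) for y, x in zip(*np.nonzero(deg == 1))],
    )


# ---------------------------------------------------------------------------
# Sholl analysis
# ---------------------------------------------------------------------------


def _arc_labels(angles: np.ndarray, radius_px: float) -> np.ndarray:
    """Group pixel angles at one radius into connected angular arcs.

    Pixels belong to the same arc when their angular gap corresponds to a
    chord of at most ~2 px (8-connected neighbors on the annulus); the scan
    wraps around at angle 0.  Returns an arc id per input angle.
    """
    labels = np.zeros(angles.size, dtype=int)
    if angles.size == 0:
        return labels
    gap_thresh = 2.0 * math.asin(min(1.0, 1.0 / max(radius_px, 1.0)))
    order = np.argsort(angles)
    sorted_angles = angles[order]
    arc = 0
    labels[order[0]] = 0
    for k in range(1, angles.size):
        if sorted_angles[k] - sorted_angles[k - 1] > gap_thresh:
            arc += 1
        labels[order[k]] = arc
    # wrap-around: merge last arc into first
    if arc > 0 and (sorted_angles[0] + 2 * math.pi) - sorted_angles[-1] <= gap_thresh:
        labels[labels == arc] = 0
    return labels


def _count_crossings(
    ys: np.ndarray,
    xs: np.ndarray,
    dist_px: np.ndarray,
    theta: np.ndarray,
    r_px: float,
    half_w_px: float,
) -> int:
    """Crossing count at one radius: arcs, split by outward continuations.

    Each connected angular arc inside the annulus counts at least once;
    when several distinct skeleton lines pass through one arc (a branch
    point or a crossing inside the annulus), the arc is counted once per
    8-connected group of skeleton pixels just outside the annulus that
    touches it.
    """
    in_annulus = (dist_px >= r_px - half_w_px) & (dist_px < r_px + half_w_px)
    n_in = int(np.count_nonzero(in_annulus))
    if n_in == 0:
        return 0
    labels = _arc_labels(theta[in_annulus], r_px)
    outer = (dist_px >= r_px + half_w_px) & (dist_px < r_px + half_w_px + 1.6)
    if not outer.any():
        return labels.max() + 1
    arc_of = {
        (int(y), int(x)): int(l)
        for y, x, l in zip(ys[in_annulus], xs[in_annulus], labels)
    }
    # group outer-shell pixels into 8-connected components
    outer_px = list(zip(ys[outer].tolist(), xs[outer].tolist()))
    outer_set = set(outer_px)
    comp_of: dict = {}
    n_comp = 0
    for p in outer_px:
        if p in comp_of:
            continue
        stack = [p]
        comp_of[p] = n_comp
        while stack:
            cy, cx = stack.pop()
            for dy, dx in _NEIGHBORS:
                q = (cy + dy, cx + dx)
                if q in outer_set and q not in comp_of:
                    comp_of[q] = n_comp
                    stack.append(q)
        n_comp += 1
    # outward continuations per arc
    continuations = [set() for _ in range(labels.max() + 1)]
    for (py, px), comp in comp_of.items():
        for dy, dx in _NEIGHBORS:
            q = (py + dy, px + dx)
            if q in arc_of:
                continuations[arc_of[q]].add(comp)
    return sum(max(1, len(c)) for c in continuations)


def sholl(
    skeleton: CellSkeleton | np.ndarray,
    pixel_size_um: float,
    radial_step_um: float = 1.0,
    max_radius_um: Optional[float] = None,
    center: Optional[Tuple[float, float]] = None,
) -> ShollProfile:
    """Count process crossings of concentric circles around the soma.

    For each radius ``r`` (multiples of ``radial_step_um``) the crossings
    are the connected angular arcs of skeleton pixels inside the annulus
    ``[r − w/2, r + w/2)`` with ``w`` one pixel diagonal.  Counts are zero
    beyond the cell's maximal radial extent.
    """
    if isinstance(skeleton, CellSkeleton):
        skel = skeleton.skeleton_mask
        cy, cx = skeleton.soma_center if center is None else center
    else:
        skel = np.asarray(skeleton, dtype=bool)
        if center is None:
            raise ValueError("center required when passing a bare skeleton mask")
        cy, cx = center
    if radial_step_um <= 0:
        raise ValueError("radial_step_um must be positive")
    if radial_step_um < pixel_size_um / 2:
        raise ValueError(
            f"radial step {radial_step_um} µm below half the pixel size "
            f"({pixel_size_um} µm): circles would alias"
        )

    ys, xs = np.nonzero(skel)
    if ys.size == 0:
        raise ValueError("empty skeleton")
    dy = ys - cy
    dx = xs - cx
    dist_px = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)  # in (−π, π]
    theta = np.where(theta < 0, theta + 2 * math.pi, theta)

    max_extent_um = dist_px.max() * pixel_size_um
    if max_radius_um is None:
        max_radius_um = max_extent_um + 2 * radial_step_um
    radii_um = np.arange(radial_step_um, max_radius_um + 1e-9, radial_step_um)
    half_w_px = math.sqrt(2.0) / 2.0
    counts = np.zeros(len(radii_um), dtype=int)
    for i, r_um in enumerate(radii_um):
        r_px = r_um / pixel_size_um
        counts[i] = _count_crossings(ys, xs, dist_px, theta, r_px, half_w_px)
    return ShollProfile(radii_um=radii_um, intersections=counts, radial_step_um=radial_step_um)


# ---------------------------------------------------------------------------
# Analytic segment-based Sholl (SWC import and simulator oracle)
# ---------------------------------------------------------------------------


def sholl_from_segments(
    segments: Sequence[Tuple[Tuple[float, float], Tuple[float, float]]],
    center: Tuple[float, float],
    radii_um: Sequence[float],
) -> ShollProfile:
    """Exact circle–segment intersection counts for line-segment morphology.

    ``segments`` are ``((y0, x0), (y1, x1))`` pairs in µm, ``center`` the
    soma origin in µm.  Each segment is half-open at its distal end point so
    that chained parent/child segments sharing a junction on a circle are
    not double counted.
    """
    radii_um = np.asarray(radii_um, dtype=float)
    counts = np.zeros(len(radii_um), dtype=int)
    cy, cx = center
    for (y0, x0), (y1, x1) in segments:
        p = np.array([y0 - cy, x0 - cx])
        d = np.array([y1 - y0, x1 - x0])
        a = float(d @ d)
        if a == 0:
            continue
        b = 2.0 * float(p @ d)
        c0 = float(p @ p)
        for i, r in enumerate(radii_um):
            disc = b * b - 4 * a * (c0 - r * r)
            if disc <= 0:
                continue
            sq = math.sqrt(disc)
            for tval in ((-b - sq) / (2 * a), (-b + sq) / (2 * a)):
                if 0.0 <= tval < 1.0:
                    counts[i] += 1
    step = float(radii_um[1] - radii_um[0]) if len(radii_um) > 1 else float(radii_um[0])
    return ShollProfile(radii_um=radii_um, intersections=counts, radial_step_um=step)


def read_swc(path: str | Path):
    """Parse an SWC morphology file into segments and a soma center (µm).

    Returns ``(segments, center)`` where segments are ``((y0, x0), (y1, x1))``
    µm pairs (one per parent–child link, z ignored: the assay is 2D) and the
    center is the first soma-type node, falling back to the root node.
    SWC columns: index, type, x, y, z, radius, parent.
    """
    nodes = {}
    soma_center = None
    root_center = None
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 7:
            raise ValueError(f"malformed SWC line: {line!r}")
        idx, ntype, x, y, _z, _r, parent = (
            int(parts[0]),
            int(parts[1]),
            float(parts[2]),
            float(parts[3]),
            float(parts[4]),
            float(parts[5]),
            int(parts[6]),
        )
        nodes[idx] = ((y, x), parent)
        if ntype == 1 and soma_center is None:
            soma_center = (y, x)
        if parent == -1 and root_center is None:
            root_center = (y, x)
    if not nodes:
        raise ValueError(f"no nodes in SWC file {path}")
    segments = []
    for idx, ((y, x), parent) in nodes.items():
        if parent != -1 and parent in nodes:
            (py, px), _ = nodes[parent]
            segments.append(((py, px), (y, x)))
    return segments, soma_center if soma_center is not None else root_center
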