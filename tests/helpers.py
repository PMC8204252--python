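"""Shared test utilities: scaled study configs and brute-force oracles."""

from __future__ import annotations

import numpy as np

from gliamotion import synth


def small_cfg(seed: int, **overrides) -> synth.SynthConfig:
    """Scaled-down single-cell recording used throughout the test suite.

    Geometry and kinetics mirror the canonical acquisition (8 consecutive
    stacks of one ramified cell, two images per plane, Poisson counting
    noise) on a 160 px / 0.4 µm-per-pixel field (64 µm) so a full
    simulate + analyze cycle stays well under a second.
    """
    base = dict(
        field_px=(160, 160),
        pixel_size_um=0.4,
        soma_radius_um=3.5,
        mean_branch_length_um=8.0,
        n_frames=8,
    )
    base.update(overrides)
    return synth.SynthConfig(seed=seed, **base)


def random_mask_series(rng: np.random.Generator, t: int = 4, shape=(16, 16)) -> np.ndarray:
    """Random boolean T×Y×X series with every frame non-empty."""
    masks = rng.random((t,) + shape) > 0.5
    for m in masks:
        if not m.any():
            m[0, 0] = True
    return masks


def brute_force_transition(a: np.ndarray, b: np.ndarray):
    """Double-loop pixel enumeration of retraction / extension counts."""
    ret = ext = 0
    for i in range(a.shape[0]):
        for j in range(a.shape[1]):
            if a[i, j] and not b[i, j]:
                ret += 1
            if b[i, j] and not a[i, j]:
                ext += 1
    return ret, ext


def brute_force_readouts(masks: np.ndarray):
    """Motility index (mean) and surveillance index by pixel enumeration."""
    motilities = []
    surveillance = 0
    for t in range(masks.shape[0] - 1):
        ret, ext = brute_force_transition(masks[t], masks[t + 1])
        n_a = int(masks[t].sum())
        motilities.append((ret + ext) / n_a)
        surveillance += ret + ext
    return float(np.mean(motilities)), surveillance
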