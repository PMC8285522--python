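"""Particle averaging of topography movies: drift correction,
cross-correlation picking, C2 symmetrization, mean and std maps.

The analysis follows the classic correlation-averaging recipe for
membrane-protein lattices: (i) choose a seed molecule, (ii) two-fold
symmetrize it and use it as reference for a first round of normalized
cross-correlation searches, (iii) average the picked particles, (iv)
symmetrize the average and re-pick, (v) compute the final per-pixel mean
(average map) and standard deviation (std map) over the aligned stack.
The std map highlights mobile domains — a gating loop that toggles
between positions lights up while the rigid barrel rim stays dark.

Correlation metric: Pearson (mean-subtracted, normalized) cross-
correlation; sub-pixel peak localization by 3-point parabolic
interpolation.  Windows are square with odd side so the symmetrization
axis is the center pixel.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import match_template, peak_local_max

from .movie import Movie

__all__ = [
    "ParticleStack",
    "AverageMap",
    "StdMap",
    "register_frames",
    "pick_particles",
    "symmetrize_c2",
    "average_and_std",
    "iterative_average",
    "write_map",
]

log = logging.getLogger(__name__)


@dataclass
class ParticleStack:
    """Aligned square particle windows with their pick records."""

    windows: np.ndarray          # (n, k, k)
    records: pd.DataFrame        # frame, row, col, score
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=float)
        if self.windows.ndim != 3 or \
           self.windows.shape[1] != self.windows.shape[2]:
            raise ValueError("windows must be (n, k, k)")

    @property
    def n_particles(self) -> int:
        return self.windows.shape[0]

    @property
    def window_px(self) -> int:
        return self.windows.shape[1]


@dataclass
class AverageMap:
    """Per-pixel mean over an aligned particle stack (nm)."""
    data: np.ndarray
    n: int
    pixel_size: float = 1.0


@dataclass
class StdMap:
    """Per-pixel population standard deviation over the stack (nm)."""
    data: np.ndarray
    n: int
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        if np.any(self.data < 0):
            raise ValueError("std map must be non-negative")


def _parabolic_offset(cm1: float, c0: float, cp1: float) -> float:
    """Sub-pixel offset of a peak from 3 samples (clipped to ±0.5)."""
    denom = cm1 - 2.0 * c0 + cp1
    if denom == 0:
        return 0.0
    return float(np.clip(0.5 * (cm1 - cp1) / denom, -0.5, 0.5))


def _ncc_shift(ref: np.ndarray, frame: np.ndarray):
    """Translation of ``frame`` relative to ``ref`` maximizing the
    normalized cross-correlation, with parabolic sub-pixel refinement.

    The central part of ``ref`` is matched inside ``frame`` (Pearson
    correlation at every placement), which avoids the wrap-around bias
    of circular correlation.  Returns (dy, dx): ``frame`` content sits
    at ``ref`` content + (dy, dx).
    """
    my = max(ref.shape[0] // 4, 1)
    mx = max(ref.shape[1] // 4, 1)
    crop = ref[my:-my, mx:-mx]
    if crop.std() == 0 or frame.std() == 0:
        return 0.0, 0.0, 0.0
    ncc = match_template(frame, crop, pad_input=False)
    iy, ix = np.unravel_index(int(np.argmax(ncc)), ncc.shape)
    peak = float(ncc[iy, ix])
    dy, dx = float(iy - my), float(ix - mx)
    if peak > 1.0 - 1e-7:   # perfect match: alignment is already exact
        return dy, dx, peak
    if 0 < iy < ncc.shape[0] - 1:
        dy += _parabolic_offset(ncc[iy - 1, ix], ncc[iy, ix],
                                ncc[iy + 1, ix])
    if 0 < ix < ncc.shape[1] - 1:
        dx += _parabolic_offset(ncc[iy, ix - 1], ncc[iy, ix],
                                ncc[iy, ix + 1])
    return dy, dx, peak


def register_frames(movie: Movie):
    """Drift-correct a movie by aligning every frame to the first.

    Each frame is shifted by the translation maximizing the normalized
    cross-correlation with frame 0 (parabolic sub-pixel refinement).
    Returns ``(aligned_movie, drifts)`` where ``drifts[f] = (dy, dx)`` is
    the cumulative drift trajectory in pixels.
    """
    if movie.n_frames < 2:
        raise ValueError("need at least 2 frames to register")
    ref = movie.frames[0]
    drifts = np.zeros((movie.n_frames, 2))
    aligned = np.empty_like(movie.frames)
    aligned[0] = ref
    for f in range(1, movie.n_frames):
        frame = movie.frames[f]
        if frame.std() == 0 or ref.std() == 0:
            log.warning("frame %d is flat; keeping identity shift", f)
            aligned[f] = frame
            continue
        dy, dx, _ = _ncc_shift(ref, frame)
        drifts[f] = (dy, dx)
        aligned[f] = ndimage.shift(frame, (-dy, -dx), order=3,
                                   mode="nearest")
    out = Movie(aligned, movie.pixel_size, movie.frame_interval,
                dict(movie.metadata, registered=True))
    return out, drifts


def _extract_window(frame: np.ndarray, row: float, col: float,
                    k: int):
    """Extract a k×k window centered at sub-pixel (row, col), or None
    near the border."""
    half = k // 2
    ri, ci = int(round(row)), int(round(col))
    pad = 2  # spline support for the sub-pixel shift
    if ri - half - pad < 0 or ri + half + pad + 1 > frame.shape[0] or \
       ci - half - pad < 0 or ci + half + pad + 1 > frame.shape[1]:
        return None
    patch = frame[ri - half - pad: ri + half + pad + 1,
                  ci - half - pad: ci + half + pad + 1]
    resid = (row - ri, col - ci)
    if resid != (0.0, 0.0):
        # ndimage.shift: output[i] = input[i - s]; sampling the patch at
        # center+resid therefore needs s = -resid
        patch = ndimage.shift(patch, (-resid[0], -resid[1]), order=3,
                              mode="nearest")
    return patch[pad:pad + k, pad:pad + k]


def pick_particles(movie: Movie, reference: np.ndarray,
                   threshold: float = 0.7) -> ParticleStack:
    """Find reference-like particles in every frame by normalized
    cross-correlation.

    Local correlation maxima above ``threshold`` are kept after
    non-maximum suppression within one reference radius; windows are
    extracted with sub-pixel alignment to the correlation peak.
    """
    ref = np.asarray(reference, dtype=float)
    if ref.ndim != 2 or ref.shape[0] != ref.shape[1]:
        raise ValueError("reference must be square")
    k = ref.shape[0]
    if k % 2 == 0:
        raise ValueError("reference side must be odd")
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    if k >= min(movie.shape):
        raise ValueError("reference must be smaller than the frames")

    windows, rows = [], []
    for f in range(movie.n_frames):
        frame = movie.frames[f]
        ncc = match_template(frame, ref, pad_input=True)
        peaks = peak_local_max(ncc, min_distance=max(k // 2, 1),
                               threshold_abs=threshold, exclude_border=False)
        for (pi, pj) in peaks:
            row, col = float(pi), float(pj)
            if 0 < pi < ncc.shape[0] - 1:
                row += _parabolic_offset(ncc[pi - 1, pj], ncc[pi, pj],
                                         ncc[pi + 1, pj])
            if 0 < pj < ncc.shape[1] - 1:
                col += _parabolic_offset(ncc[pi, pj - 1], ncc[pi, pj],
                                         ncc[pi, pj + 1])
            win = _extract_window(frame, row, col, k)
            if win is None:
                continue
            windows.append(win)
            rows.append({"frame": f, "row": row, "col": col,
                         "score": float(ncc[pi, pj])})
    if not windows:
        log.warning("no particles above correlation threshold %.2f",
                    threshold)
        return ParticleStack(np.empty((0, k, k)),
                             pd.DataFrame(columns=["frame", "row", "col",
                                                   "score"]),
                             movie.pixel_size)
    return ParticleStack(np.stack(windows), pd.DataFrame(rows),
                         movie.pixel_size)


def symmetrize_c2(map_or_array):
    """Two-fold symmetrize a square odd-sized map:
    ``(map + rotate180(map)) / 2`` about the center pixel.  Idempotent."""
    arr = map_or_array.data if isinstance(map_or_array, AverageMap) \
        else np.asarray(map_or_array, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("map must be square")
    if arr.shape[0] % 2 == 0:
        raise ValueError("map side must be odd (center-pixel symmetry axis)")
    sym = 0.5 * (arr + np.rot90(arr, 2))
    if isinstance(map_or_array, AverageMap):
        return AverageMap(sym, map_or_array.n, map_or_array.pixel_size)
    return sym


def average_and_std(stack: ParticleStack):
    """Per-pixel arithmetic mean and population std over the stack."""
    if stack.n_particles < 2:
        raise ValueError("need >= 2 particles for a std map")
    mean = stack.windows.mean(axis=0)
    std = stack.windows.std(axis=0, ddof=0)
    return (AverageMap(mean, stack.n_particles, stack.pixel_size),
            StdMap(std, stack.n_particles, stack.pixel_size))


def iterative_average(movie: Movie, seed_window: np.ndarray,
                      rounds: int = 2, threshold: float = 0.7):
    """Iterative correlation averaging with C2 symmetrization.

    Seed → symmetrize → pick → average → symmetrize → re-pick → final
    average + std map.  Returns ``(AverageMap, StdMap, ParticleStack,
    diagnostics)``; diagnostics reports the particle count and mean
    correlation score per round.
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    ref = symmetrize_c2(seed_window)
    diagnostics = {"n_particles": [], "mean_score": []}
    stack = None
    for r in range(rounds):
        stack = pick_particles(movie, ref, threshold=threshold)
        if stack.n_particles == 0:
            raise RuntimeError(
                f"empty pick in round {r + 1}/{rounds} "
                f"(threshold={threshold}); diagnostics={diagnostics}")
        diagnostics["n_particles"].append(stack.n_particles)
        diagnostics["mean_score"].append(
            float(stack.records["score"].mean()))
        avg = stack.windows.mean(axis=0)
        if r < rounds - 1:
            ref = symmetrize_c2(avg)
    avg_map, std_map = average_and_std(stack)
    return avg_map, std_map, stack, diagnostics


def write_map(map_obj, path, png: bool = False) -> None:
    """Write a map as single-frame float32 TIFF (optionally + PNG preview)."""
    import tifffile
    path = Path(path)
    tifffile.imwrite(path, np.asarray(map_obj.data, dtype=np.float32),
                     photometric="minisblack")
    if png:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots()
        im = ax.imshow(map_obj.data, cmap="afmhot")
        fig.colorbar(im, ax=ax, label="height (nm)")
        ax.set_xticks([])
        ax.set_yticks([])
        fig.savefig(path.with_suffix(".png"), dpi=150,
                    bbox_inches="tight")
        plt.close(fig)
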