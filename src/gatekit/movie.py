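"""Topography movies: container, TIFF IO, and the synthetic-lattice generator.

The generator emulates HS-AFM movies of a 2D crystal of dimeric β-barrel
pore proteins: each molecule is rendered as a raised rim (the barrel wall,
protruding ~1.25 nm above the membrane) plus a mobile loop blob that sits
over the pore in the closed state and extends outward in the open state.
Molecules are arranged in rows of dimers (the two partners related by a
180° rotation), their gating state resampled every frame from a two-state
Markov chain.  Optional first-order tip convolution (grey dilation with a
spherical-cap structuring element), global frame drift and pixel noise
complete the imaging model.  A ground-truth table of particle centers and
per-frame states is returned for recovery tests.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

__all__ = [
    "Movie",
    "MovieConfig",
    "simulate_afm_movie",
    "render_molecule",
    "render_window",
    "dimer_centers",
    "write_movie",
    "read_movie",
]


@dataclass
class Movie:
    """Ordered stack of 2D height frames sharing geometry.

    ``frames`` has shape (n_frames, rows, cols), heights in nm; pixel
    indexing is 0-based row-major.
    """

    frames: np.ndarray
    pixel_size: float          # nm / pixel
    frame_interval: float      # s
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (n_frames, rows, cols)")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frame heights must be finite")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self):
        return self.frames.shape[1:]


@dataclass
class MovieConfig:
    """Parameters of the synthetic lattice-movie generator.

    Lengths in nm, times in seconds.  ``lattice_a``/``lattice_b`` are the
    unit-cell vectors; each cell holds a dimer whose partners sit at
    ``dimer_sites`` (offsets within the cell) with orientations 0 and
    180°, so every dimer midpoint is an exact two-fold symmetry center
    of the rendered lattice — the natural particle for C2 correlation
    averaging.  The barrel is a ring of radius ``rim_radius`` and height
    ``rim_height``; the gating loop is a Gaussian blob of amplitude
    ``loop_amplitude`` whose center moves between ``loop_offset_closed``
    (over the pore) and ``loop_offset_open`` (extended outward).
    ``tip_radius`` = 0 disables tip dilation.
    """

    lattice_a: tuple = (7.5, 0.0)
    lattice_b: tuple = (0.0, 9.0)
    # partner spacing (3.0 nm) deliberately differs from the gap to the
    # next cell (4.5 nm) so midpoints between dimers are not pseudo-C2
    # matches; site 0 has orientation 0, site 1 is rotated 180 deg
    dimer_sites: tuple = ((4.5, 4.5), (1.5, 4.5))   # (x, y) in cell
    pixel_size: float = 0.25
    shape_px: tuple = (96, 96)                      # (rows, cols)
    frame_interval: float = 0.2
    n_frames: int = 50
    rim_radius: float = 1.7
    rim_height: float = 1.25
    rim_width: float = 0.45
    loop_amplitude: float = 1.5
    loop_width: float = 0.7
    loop_offset_open: tuple = (1.5, 0.0)
    loop_offset_closed: tuple = (0.0, 0.0)
    tau_open: float = 0.4
    tau_closed: float = 0.4
    tip_radius: float = 0.0
    noise_sigma: float = 0.0
    drift_per_frame: tuple = (0.0, 0.0)             # (dx, dy) nm / frame
    seed: int = 0

    def validate(self) -> None:
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not self.rim_height > 0:
            raise ValueError("rim_height must be > 0")
        if not (self.tau_open > 0 and self.tau_closed > 0):
            raise ValueError("tau_open and tau_closed must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.tip_radius < 0:
            raise ValueError("tip_radius must be >= 0")
        fov_x = self.shape_px[1] * self.pixel_size
        fov_y = self.shape_px[0] * self.pixel_size
        if fov_x < abs(self.lattice_a[0]) + abs(self.lattice_b[0]) or \
           fov_y < abs(self.lattice_a[1]) + abs(self.lattice_b[1]):
            raise ValueError("field of view smaller than one unit cell")


def _molecule_height(xx, yy, cx, cy, theta, state, cfg: MovieConfig):
    """Height contribution of one molecule on the (nm) grid xx, yy."""
    dx, dy = xx - cx, yy - cy
    r = np.hypot(dx, dy)
    rim = cfg.rim_height * np.exp(
        -0.5 * ((r - cfg.rim_radius) / cfg.rim_width) ** 2)
    off = (cfg.loop_offset_open if state == "open"
           else cfg.loop_offset_closed)
    ct, st = math.cos(theta), math.sin(theta)
    ox = ct * off[0] - st * off[1]
    oy = st * off[0] + ct * off[1]
    d2 = (dx - ox) ** 2 + (dy - oy) ** 2
    blob = cfg.loop_amplitude * np.exp(-0.5 * d2 / cfg.loop_width ** 2)
    return np.maximum(rim, blob)


def render_molecule(cfg: MovieConfig, state: str = "open",
                    window_px: int = 21) -> np.ndarray:
    """Render one isolated molecule (orientation 0) in a square window.

    Used as a known template in recovery tests; the window center pixel is
    the molecule center.
    """
    if window_px % 2 == 0:
        raise ValueError("window_px must be odd")
    half = window_px // 2
    coords = (np.arange(window_px) - half) * cfg.pixel_size
    xx, yy = np.meshgrid(coords, coords)
    return _molecule_height(xx, yy, 0.0, 0.0, 0.0, state, cfg)


def _enumerate_molecules(cfg: MovieConfig, fov_x: float, fov_y: float,
                         margin: float):
    """Lattice molecules (x, y, theta, pair_id) covering the FOV+margin."""
    ax, ay = cfg.lattice_a
    bx, by = cfg.lattice_b
    n_a = int(math.ceil(fov_x / max(abs(ax), 1e-9))) + 2
    n_b = int(math.ceil(fov_y / max(abs(by), 1e-9))) + 2
    molecules = []
    pair_id = 0
    for i in range(-1, n_a + 1):
        for j in range(-1, n_b + 1):
            ox, oy = i * ax + j * bx, i * ay + j * by
            members = []
            for s, (sx, sy) in enumerate(cfg.dimer_sites):
                x, y = ox + sx, oy + sy
                if -margin <= x <= fov_x + margin and \
                   -margin <= y <= fov_y + margin:
                    members.append((x, y, 0.0 if s == 0 else math.pi,
                                    pair_id))
            molecules.extend(members)
            if members:
                pair_id += 1
    return molecules


def _render_margin(cfg: MovieConfig) -> float:
    return (cfg.rim_radius + 3 * cfg.rim_width
            + abs(max(cfg.loop_offset_open, key=abs)) + 3 * cfg.loop_width)


def render_window(cfg: MovieConfig, center_x_nm: float, center_y_nm: float,
                  window_px: int, state: str = "open") -> np.ndarray:
    """Render a window of the noiseless lattice at an exact sub-pixel
    center, all molecules forced to one state.

    Serves as the generator-known reference image for particle-averaging
    recovery tests: the window grid is centered exactly on
    ``(center_x_nm, center_y_nm)`` (e.g. a dimer midpoint), so no
    interpolation is involved.
    """
    if window_px % 2 == 0:
        raise ValueError("window_px must be odd")
    half = window_px // 2
    xs = center_x_nm + (np.arange(window_px) - half) * cfg.pixel_size
    ys = center_y_nm + (np.arange(window_px) - half) * cfg.pixel_size
    xx, yy = np.meshgrid(xs, ys)
    margin = _render_margin(cfg)
    reach = half * cfg.pixel_size + margin
    out = np.zeros((window_px, window_px))
    fov_x = cfg.shape_px[1] * cfg.pixel_size
    fov_y = cfg.shape_px[0] * cfg.pixel_size
    for (x, y, theta, _pair) in _enumerate_molecules(cfg, fov_x, fov_y,
                                                     margin):
        if abs(x - center_x_nm) > reach or abs(y - center_y_nm) > reach:
            continue
        np.maximum(out, _molecule_height(xx, yy, x, y, theta, state, cfg),
                   out=out)
    return out


def _spherical_cap(radius_nm: float, pixel_size: float) -> np.ndarray:
    """Spherical-cap structuring element for grey tip dilation (<= 0)."""
    r_px = max(int(math.ceil(radius_nm / pixel_size)), 1)
    coords = np.arange(-r_px, r_px + 1) * pixel_size
    xx, yy = np.meshgrid(coords, coords)
    d2 = xx ** 2 + yy ** 2
    cap = np.where(d2 <= radius_nm ** 2,
                   np.sqrt(np.maximum(radius_nm ** 2 - d2, 0.0)) - radius_nm,
                   -1e9)
    return cap


def _markov_states(rng, cfg: MovieConfig, n_frames: int) -> np.ndarray:
    """Per-frame open(1)/closed(0) states of one molecule."""
    lam = 1.0 / cfg.tau_open + 1.0 / cfg.tau_closed
    pi_open = cfg.tau_open / (cfg.tau_open + cfg.tau_closed)
    decay = math.exp(-lam * cfg.frame_interval)
    p_oo = pi_open + (1 - pi_open) * decay
    p_cc = (1 - pi_open) + pi_open * decay
    states = np.empty(n_frames, dtype=np.int8)
    states[0] = 1 if rng.random() < pi_open else 0
    for f in range(1, n_frames):
        stay = p_oo if states[f - 1] == 1 else p_cc
        states[f] = states[f - 1] if rng.random() < stay else 1 - states[f - 1]
    return states


def simulate_afm_movie(cfg: MovieConfig):
    """Render a seeded synthetic lattice movie with ground truth.

    Returns ``(Movie, truth)`` where ``truth`` is a DataFrame with one row
    per molecule per frame: frame, molecule id, center position (pixels,
    including drift), orientation and state.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    rows_px, cols_px = cfg.shape_px
    fov_x = cols_px * cfg.pixel_size
    fov_y = rows_px * cfg.pixel_size

    # enumerate lattice molecules covering the FOV (with a render margin)
    margin = _render_margin(cfg)
    molecules = _enumerate_molecules(cfg, fov_x, fov_y, margin)
    if not molecules:
        raise ValueError("no molecules inside the field of view")

    # per-molecule gating trajectories (one RNG, fixed order: deterministic)
    states = np.stack([_markov_states(rng, cfg, cfg.n_frames)
                       for _ in molecules])

    xs = np.arange(cols_px) * cfg.pixel_size
    ys = np.arange(rows_px) * cfg.pixel_size
    cap = (_spherical_cap(cfg.tip_radius, cfg.pixel_size)
           if cfg.tip_radius > 0 else None)

    frames = np.zeros((cfg.n_frames, rows_px, cols_px))
    truth_rows = []
    for f in range(cfg.n_frames):
        drift_x = cfg.drift_per_frame[0] * f
        drift_y = cfg.drift_per_frame[1] * f
        frame = np.zeros((rows_px, cols_px))
        for m, (x, y, theta, pair) in enumerate(molecules):
            cx, cy = x + drift_x, y + drift_y
            state = "open" if states[m, f] else "closed"
            # render only the local window around the molecule
            j0 = max(int((cx - margin) / cfg.pixel_size), 0)
            j1 = min(int((cx + margin) / cfg.pixel_size) + 2, cols_px)
            i0 = max(int((cy - margin) / cfg.pixel_size), 0)
            i1 = min(int((cy + margin) / cfg.pixel_size) + 2, rows_px)
            if j1 <= j0 or i1 <= i0:
                continue
            xx, yy = np.meshgrid(xs[j0:j1], ys[i0:i1])
            contrib = _molecule_height(xx, yy, cx, cy, theta, state, cfg)
            np.maximum(frame[i0:i1, j0:j1], contrib,
                       out=frame[i0:i1, j0:j1])
            if 0 <= cx < fov_x and 0 <= cy < fov_y:
                truth_rows.append({
                    "frame": f, "molecule": m, "pair": pair,
                    "row_px": cy / cfg.pixel_size,
                    "col_px": cx / cfg.pixel_size,
                    "orientation_rad": theta, "state": state})
        if cap is not None:
            frame = ndimage.grey_dilation(frame, structure=cap)
        if cfg.noise_sigma > 0:
            frame = frame + rng.normal(0.0, cfg.noise_sigma, frame.shape)
        frames[f] = frame

    movie = Movie(frames, cfg.pixel_size, cfg.frame_interval,
                  metadata={"seed": cfg.seed, "generator": "lattice"})
    return movie, pd.DataFrame(truth_rows)


def dimer_centers(truth: pd.DataFrame) -> pd.DataFrame:
    """Per-frame dimer midpoints from a ground-truth molecule table.

    Only pairs with both partners inside the field of view are kept;
    these midpoints are exact C2 centers of the lattice and the natural
    particle positions for correlation averaging.
    """
    rows = []
    for (frame, pair), grp in truth.groupby(["frame", "pair"]):
        if len(grp) != 2:
            continue
        rows.append({"frame": frame, "pair": pair,
                     "row_px": grp["row_px"].mean(),
                     "col_px": grp["col_px"].mean(),
                     "n_open": int((grp["state"] == "open").sum())})
    return pd.DataFrame(rows)


def write_movie(movie: Movie, path) -> None:
    """Write a movie as multi-frame 32-bit float TIFF + JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, movie.frames.astype(np.float32),
                     photometric="minisblack")
    sidecar = {"pixel_size_nm": movie.pixel_size,
               "frame_interval_s": movie.frame_interval,
               "units": "nm",
               "metadata": {k: v for k, v in movie.metadata.items()
                            if isinstance(v, (str, int, float, bool))}}
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)


def read_movie(path) -> Movie:
    """Read a movie written by :func:`write_movie`."""
    path = Path(path)
    frames = np.asarray(tifffile.imread(path), dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    sidecar_path = path.with_suffix(path.suffix + ".json")
    pixel_size, frame_interval, meta = 1.0, 1.0, {}
    if sidecar_path.exists():
        with open(sidecar_path) as fh:
            sc = json.load(fh)
        pixel_size = sc.get("pixel_size_nm", 1.0)
        frame_interval = sc.get("frame_interval_s", 1.0)
        meta = sc.get("metadata", {})
    return Movie(frames, pixel_size, frame_interval, meta)
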