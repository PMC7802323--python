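"""Forward simulators with exact ground truth.

Every analysis stage in the package has a matching generator here:
micropillar-array movies with planted deflections and stage drift,
two-channel laurdan scenes with a known generalized-polarization (GP)
field, single-cell migration tracks with known speeds, and
gene/metabolite tables with planted fold changes.  Each simulator emits
both the raw synthetic data and a truth table, so the downstream
estimators can be scored against known answers.

Conventions
-----------
* Positions are (x, y) in micrometres; pixel (row j, col i) has its
  centre at ``x = i * pixel_size``, ``y = j * pixel_size``.
* Every scene draws all randomness from one ``numpy`` generator seeded
  from its spec, so a fixed seed yields byte-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import i0e


# --------------------------------------------------------------------------
# pillar-array scenes
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PillarSceneSpec:
    """Description of a synthetic micropillar-array movie.

    The defaults reproduce the study conditions this package targets:
    a square PDMS pillar array of 1.8 um pitch and 0.9 um pillar
    diameter, imaged as bright PSF-blurred disks on a dark background.

    Parameters
    ----------
    lattice_pitch : float
        Centre-to-centre pillar distance, um.
    pillar_diameter : float
        Pillar (disk) diameter, um.
    image_shape : (int, int)
        Frame shape in pixels (rows, cols).
    pixel_size : float
        um per pixel.
    n_frames : int
        Number of movie frames.
    psf_sigma : float
        Isotropic Gaussian PSF sigma, pixels.
    photon_level : float
        Expected peak counts at an undeflected pillar centre.
    background : float
        Uniform background expectation, counts.
    shot_noise : bool
        Apply Poisson noise to the expected image.
    read_noise_sd : float
        Additive Gaussian read noise sigma, counts (0 disables).
    drift_per_frame : (float, float)
        Global stage drift per frame, um; frame ``t`` is displaced by
        ``t * drift_per_frame`` (cumulative, zero at frame 0).
    deflections : mapping pillar_id -> vector
        Planted deflection per pillar, um.  A value may be a length-2
        vector (constant in time) or an ``(n_frames, 2)`` array.
    lattice : str
        ``"square"`` or ``"hexagonal"`` packing.
    rotation_deg : float
        Lattice rotation relative to the image axes.
    cell_mask : ndarray or None
        Boolean (rows, cols) mask of the cell footprint.  When given,
        deflections may only be planted on pillars under the mask, and
        the truth table's reference flag is mask-based.
    seed : int
        Seed for the scene's random generator.
    """

    lattice_pitch: float = 1.8
    pillar_diameter: float = 0.9
    image_shape: tuple[int, int] = (192, 192)
    pixel_size: float = 0.2
    n_frames: int = 1
    psf_sigma: float = 1.5
    photon_level: float = 500.0
    background: float = 20.0
    shot_noise: bool = True
    read_noise_sd: float = 2.0
    drift_per_frame: tuple[float, float] = (0.0, 0.0)
    deflections: Mapping[int, object] = field(default_factory=dict)
    lattice: str = "square"
    rotation_deg: float = 0.0
    cell_mask: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.lattice_pitch > self.pillar_diameter > 0):
            raise ValueError("require pitch > diameter > 0")
        if self.lattice not in ("square", "hexagonal"):
            raise ValueError(f"unknown lattice {self.lattice!r}")
        if self.pixel_size <= 0 or self.n_frames < 1:
            raise ValueError("pixel_size must be > 0 and n_frames >= 1")
        if self.cell_mask is not None and self.cell_mask.shape != tuple(self.image_shape):
            raise ValueError("cell_mask shape must match image_shape")


def pillar_rest_positions(spec: PillarSceneSpec) -> pd.DataFrame:
    """Enumerate the lattice nodes (rest positions) of a scene.

    Returns a frame with columns ``pillar_id, n1, n2, rest_x_um,
    rest_y_um, under_cell``.  Pillar ids are assigned row-major over
    lattice indices and are stable for a given spec.  Nodes are kept
    only if the pillar stays fully rendered inside the frame for every
    frame of the movie (accounting for drift).
    """
    p = spec.lattice_pitch
    theta = np.deg2rad(spec.rotation_deg)
    b1 = p * np.array([np.cos(theta), np.sin(theta)])
    if spec.lattice == "square":
        ang2 = theta + np.pi / 2
    else:  # hexagonal: second basis at 60 degrees
        ang2 = theta + np.pi / 3
    b2 = p * np.array([np.cos(ang2), np.sin(ang2)])

    h, w = spec.image_shape
    size = np.array([w, h]) * spec.pixel_size  # (x extent, y extent) um
    total_drift = np.abs(np.asarray(spec.drift_per_frame)) * (spec.n_frames - 1)
    margin = (
        spec.pillar_diameter / 2
        + (4.0 * spec.psf_sigma + 2.0) * spec.pixel_size
        + p / 4
    )
    lo = margin + np.maximum(total_drift, 0)
    hi = size - margin - np.maximum(total_drift, 0)
    if np.any(hi <= lo):
        raise ValueError("image too small for the requested lattice")

    origin = lo + np.array([0.37, 0.61]) * p  # generic sub-pixel offset
    nmax = int(np.ceil(max(size) / p)) + 2
    rows = []
    for n2 in range(-nmax, nmax + 1):
        for n1 in range(-nmax, nmax + 1):
            pos = origin + n1 * b1 + n2 * b2
            if np.all(pos >= lo) and np.all(pos <= hi):
                rows.append((n1, n2, pos[0], pos[1]))
    if not rows:
        raise ValueError("no lattice nodes fit inside the image")
    df = pd.DataFrame(rows, columns=["n1", "n2", "rest_x_um", "rest_y_um"])
    df = df.sort_values(["n2", "n1"]).reset_index(drop=True)
    df.insert(0, "pillar_id", np.arange(len(df)))
    if spec.cell_mask is not None:
        df["under_cell"] = _points_in_mask(
            df[["rest_x_um", "rest_y_um"]].to_numpy(), spec.cell_mask, spec.pixel_size
        )
    else:
        df["under_cell"] = False
    return df


def _points_in_mask(points_um: np.ndarray, mask: np.ndarray, pixel_size: float) -> np.ndarray:
    """True where each (x, y) um point falls on a mask-true pixel."""
    cols = np.clip(np.round(points_um[:, 0] / pixel_size).astype(int), 0, mask.shape[1] - 1)
    rows = np.clip(np.round(points_um[:, 1] / pixel_size).astype(int), 0, mask.shape[0] - 1)
    return mask[rows, cols].astype(bool)


def _disk_psf_profile(radius_px: float, sigma_px: float) -> tuple[np.ndarray, np.ndarray]:
    """Radial intensity profile of a uniform disk convolved with a Gaussian.

    Evaluated by quadrature of the exact polar-coordinate convolution
    integral (modified-Bessel kernel, exponentially scaled for
    stability), normalized to 1 at the centre.
    """
    r_max = radius_px + 5.0 * sigma_px
    r = np.arange(0.0, r_max + 0.02, 0.02)
    s = np.linspace(0.0, radius_px, 400)
    rr = r[:, None]
    ss = s[None, :]
    sig2 = sigma_px**2
    integrand = (ss / sig2) * np.exp(-((rr - ss) ** 2) / (2 * sig2)) * i0e(rr * ss / sig2)
    prof = np.trapezoid(integrand, s, axis=1)
    return r, prof / prof[0]


@dataclass
class PillarScene:
    """A rendered pillar movie plus its ground truth."""

    stack: np.ndarray          # (n_frames, rows, cols) float counts
    truth: pd.DataFrame        # per pillar per frame
    rest: pd.DataFrame         # per pillar (rest positions, flags)
    spec: PillarSceneSpec


def _deflection_series(value: object, n_frames: int) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.shape == (2,):
        return np.tile(arr, (n_frames, 1))
    if arr.shape == (n_frames, 2):
        return arr
    raise ValueError("deflection must be a 2-vector or an (n_frames, 2) array")


def simulate_pillar_sequence(spec: PillarSceneSpec) -> PillarScene:
    """Render a pillar-array movie with planted deflections and drift.

    Each pillar is drawn as a PSF-blurred disk at
    ``rest + deflection(t) + t * drift_per_frame``; Poisson shot noise
    and Gaussian read noise are applied if enabled.  The truth table
    has one row per pillar per frame with the planted deflection, the
    cumulative drift, and reference/under-cell flags.

    Raises
    ------
    ValueError
        If any planted deflection magnitude reaches ``pitch / 2``
        (tracker identifiability) or targets a pillar outside the cell
        mask.
    """
    rest = pillar_rest_positions(spec)
    n = len(rest)
    ids = rest["pillar_id"].to_numpy()
    defl = np.zeros((spec.n_frames, n, 2))
    for pid, value in spec.deflections.items():
        if pid not in ids:
            raise ValueError(f"deflection assigned to unknown pillar id {pid}")
        series = _deflection_series(value, spec.n_frames)
        if np.any(np.hypot(series[:, 0], series[:, 1]) >= spec.lattice_pitch / 2):
            raise ValueError("deflection magnitude must stay below pitch/2")
        if spec.cell_mask is not None and not rest.loc[rest.pillar_id == pid, "under_cell"].item():
            raise ValueError(f"pillar {pid} lies outside the cell mask; cannot deflect it")
        defl[:, np.searchsorted(ids, pid), :] = series

    if spec.cell_mask is not None:
        is_reference = ~rest["under_cell"].to_numpy()
    else:
        is_reference = ~np.any(np.any(defl != 0, axis=2), axis=0)

    rest = rest.copy()
    rest["is_reference"] = is_reference

    rng = np.random.default_rng(spec.seed)
    radius_px = spec.pillar_diameter / 2 / spec.pixel_size
    r_grid, prof = _disk_psf_profile(radius_px, spec.psf_sigma)
    r_max = r_grid[-1]
    half = int(np.ceil(r_max)) + 1
    h, w = spec.image_shape
    rest_xy = rest[["rest_x_um", "rest_y_um"]].to_numpy()
    drift = np.asarray(spec.drift_per_frame, dtype=float)

    stack = np.empty((spec.n_frames, h, w))
    truth_rows = []
    for t in range(spec.n_frames):
        lam = np.full((h, w), float(spec.background))
        cum_drift = t * drift
        pos = rest_xy + defl[t] + cum_drift
        for k in range(n):
            cx = pos[k, 0] / spec.pixel_size
            cy = pos[k, 1] / spec.pixel_size
            ix, iy = int(round(cx)), int(round(cy))
            x0, x1 = max(ix - half, 0), min(ix + half + 1, w)
            y0, y1 = max(iy - half, 0), min(iy + half + 1, h)
            yy, xx = np.mgrid[y0:y1, x0:x1]
            rr = np.hypot(xx - cx, yy - cy)
            lam[y0:y1, x0:x1] += spec.photon_level * np.interp(rr, r_grid, prof, right=0.0)
        img = rng.poisson(lam).astype(float) if spec.shot_noise else lam
        if spec.read_noise_sd > 0:
            img = img + rng.normal(0.0, spec.read_noise_sd, size=img.shape)
        stack[t] = img
        frame_truth = pd.DataFrame(
            {
                "pillar_id": ids,
                "frame": t,
                "rest_x_um": rest_xy[:, 0],
                "rest_y_um": rest_xy[:, 1],
                "defl_x_um": defl[t, :, 0],
                "defl_y_um": defl[t, :, 1],
                "drift_x_um": cum_drift[0],
                "drift_y_um": cum_drift[1],
                "is_reference": is_reference,
                "under_cell": rest["under_cell"].to_numpy(),
            }
        )
        truth_rows.append(frame_truth)

    truth = pd.concat(truth_rows, ignore_index=True)
    return PillarScene(stack=stack, truth=truth, rest=rest, spec=spec)


def disk_mask(shape: tuple[int, int], center_px: tuple[float, float], radius_px: float) -> np.ndarray:
    """Boolean disk mask; ``center_px`` is (col, row)."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    return (xx - center_px[0]) ** 2 + (yy - center_px[1]) ** 2 <= radius_px**2


def add_random_deflections(
    spec: PillarSceneSpec,
    n_deflected: int,
    magnitude_range: tuple[float, float],
) -> PillarSceneSpec:
    """Plant random constant deflections on pillars under the cell mask.

    Magnitudes are uniform in ``magnitude_range`` (um) with uniformly
    random directions, drawn deterministically from ``spec.seed``.
    Returns a new spec; the input is unchanged.
    """
    if spec.cell_mask is None:
        raise ValueError("add_random_deflections requires a cell_mask")
    rest = pillar_rest_positions(spec)
    under = rest.loc[rest.under_cell, "pillar_id"].to_numpy()
    if len(under) < n_deflected:
        raise ValueError(f"only {len(under)} pillars under the cell; cannot deflect {n_deflected}")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 7]))
    chosen = rng.choice(under, size=n_deflected, replace=False)
    mags = rng.uniform(*magnitude_range, size=n_deflected)
    angles = rng.uniform(0, 2 * np.pi, size=n_deflected)
    deflections = dict(spec.deflections)
    for pid, m, a in zip(chosen, mags, angles):
        deflections[int(pid)] = (m * np.cos(a), m * np.sin(a))
    return dataclasses.replace(spec, deflections=deflections)


# --------------------------------------------------------------------------
# laurdan GP scenes
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LaurdanSceneSpec:
    """Two-channel laurdan scene with a known per-pixel GP field.

    The emission channels are constructed so the ratiometric GP formula
    inverts them exactly at zero noise::

        I420 = T * (1 + GP) / 2,   I473 = T * (1 - GP) / 2

    where ``T`` is the total intensity field.

    Parameters
    ----------
    gp_field : ndarray
        True per-pixel GP in [-1, 1].
    total_intensity_field : ndarray
        Expected total counts (I420 + I473) per pixel.
    np_channel_field : ndarray or None
        Expected counts of the nanoparticle channel, if simulated.
    shot_noise : bool
        Poisson noise on each channel.
    read_noise_sd : float
        Additive Gaussian read noise sigma per channel.
    """

    gp_field: np.ndarray
    total_intensity_field: np.ndarray
    np_channel_field: np.ndarray | None = None
    shot_noise: bool = True
    read_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        gp = np.asarray(self.gp_field)
        if np.any(gp < -1) or np.any(gp > 1):
            raise ValueError("gp_field must lie in [-1, 1]")
        if np.asarray(self.total_intensity_field).shape != gp.shape:
            raise ValueError("total_intensity_field shape must match gp_field")
        if np.any(np.asarray(self.total_intensity_field) < 0):
            raise ValueError("total intensity must be non-negative")


@dataclass
class LaurdanScene:
    i420: np.ndarray
    i473: np.ndarray
    np_channel: np.ndarray | None
    truth_gp: np.ndarray
    spec: LaurdanSceneSpec


def simulate_laurdan_cell(spec: LaurdanSceneSpec) -> LaurdanScene:
    """Render the two emission channels (and optional NP channel)."""
    gp = np.asarray(spec.gp_field, dtype=float)
    total = np.asarray(spec.total_intensity_field, dtype=float)
    i420 = total * (1 + gp) / 2
    i473 = total * (1 - gp) / 2
    np_ch = None if spec.np_channel_field is None else np.asarray(spec.np_channel_field, float)

    rng = np.random.default_rng(spec.seed)
    channels = []
    for ch in (i420, i473) + (() if np_ch is None else (np_ch,)):
        img = rng.poisson(ch).astype(float) if spec.shot_noise else ch.copy()
        if spec.read_noise_sd > 0:
            img = img + rng.normal(0.0, spec.read_noise_sd, size=img.shape)
        channels.append(img)
    out_np = channels[2] if np_ch is not None else None
    return LaurdanScene(i420=channels[0], i473=channels[1], np_channel=out_np,
                        truth_gp=gp.copy(), spec=spec)


def two_domain_gp_field(
    shape: tuple[int, int],
    inside_gp: float,
    outside_gp: float,
    center_px: tuple[float, float],
    radius_px: float,
) -> np.ndarray:
    """GP field with an ordered (high-GP) disk domain in a fluid background."""
    mask = disk_mask(shape, center_px, radius_px)
    return np.where(mask, inside_gp, outside_gp)


# --------------------------------------------------------------------------
# migration tracks
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TrackSpec:
    """Persistent-random-walk cell tracks sampled at fixed intervals.

    Per cell, a speed is drawn from a normal distribution truncated at
    zero; each step has length ``speed * interval`` and the heading
    turns by a normal increment of sd ``turning_sd_rad``.  With
    ``speed_sd = turning_sd_rad = 0`` the tracks are straight lines at
    exactly ``speed_mean``.
    """

    n_cells: int = 20
    sampling_interval_min: float = 5.0
    duration_h: float = 6.0
    speed_mean: float = 0.5       # um/min
    speed_sd: float = 0.15
    turning_sd_rad: float = 0.4
    arena_um: float = 400.0       # initial positions uniform in this box
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_interval_min <= 0:
            raise ValueError("sampling interval must be > 0")
        if self.duration_h <= 0 or self.n_cells < 1:
            raise ValueError("duration must be > 0 and n_cells >= 1")


def simulate_tracks(spec: TrackSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate cell tracks; return (positions, truth).

    positions: ``cell_id, t_min, x_um, y_um`` sampled every
    ``sampling_interval_min`` over ``duration_h``.
    truth: per-cell ``speed_um_per_min`` (path length / duration) and
    ``path_length_um``.
    """
    rng = np.random.default_rng(spec.seed)
    n_steps = int(round(spec.duration_h * 60 / spec.sampling_interval_min))
    t = np.arange(n_steps + 1) * spec.sampling_interval_min
    pos_rows, truth_rows = [], []
    for cid in range(spec.n_cells):
        speed = rng.normal(spec.speed_mean, spec.speed_sd) if spec.speed_sd > 0 else spec.speed_mean
        speed = abs(speed)
        heading = rng.uniform(0, 2 * np.pi)
        xy = np.empty((n_steps + 1, 2))
        xy[0] = rng.uniform(0, spec.arena_um, size=2)
        step_len = speed * spec.sampling_interval_min
        for k in range(n_steps):
            if spec.turning_sd_rad > 0:
                heading += rng.normal(0.0, spec.turning_sd_rad)
            xy[k + 1] = xy[k] + step_len * np.array([np.cos(heading), np.sin(heading)])
        path = float(np.sum(np.hypot(*np.diff(xy, axis=0).T)))
        pos_rows.append(pd.DataFrame({"cell_id": cid, "t_min": t, "x_um": xy[:, 0], "y_um": xy[:, 1]}))
        truth_rows.append((cid, path / (spec.duration_h * 60), path))
    positions = pd.concat(pos_rows, ignore_index=True)
    truth = pd.DataFrame(truth_rows, columns=["cell_id", "speed_um_per_min", "path_length_um"])
    return positions, truth


# --------------------------------------------------------------------------
# omics tables
# --------------------------------------------------------------------------

def simulate_omics_table(
    n_genes: int,
    n_metabolites: int,
    planted_gene_fc: Mapping[int, float] | None = None,
    planted_metabolite_change: Mapping[int, float] | None = None,
    noise_sd: float = 0.0,
    gene_cutoff: float = 3.0,
    metabolite_cutoff: float = 0.20,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate paired control/treated gene and metabolite level tables.

    ``planted_gene_fc`` maps a gene index to its true treated/control
    ratio (unlisted genes are at 1.0); ``planted_metabolite_change``
    maps a metabolite index to its true fractional change (e.g. +0.25
    for a 25% increase).  ``noise_sd`` is a multiplicative log-normal
    sigma (natural-log space) applied independently to each measured
    level.  The ``truth_flag`` column marks features whose *noise-free*
    change exceeds the stated cutoff (symmetric 3-fold for genes, 20%
    absolute relative change for metabolites by default).
    """
    planted_gene_fc = dict(planted_gene_fc or {})
    planted_metabolite_change = dict(planted_metabolite_change or {})
    if any(fc <= 0 for fc in planted_gene_fc.values()):
        raise ValueError("gene fold changes must be > 0")
    if any(1 + d <= 0 for d in planted_metabolite_change.values()):
        raise ValueError("metabolite changes must keep levels positive")

    rng = np.random.default_rng(seed)

    def noisy(levels: np.ndarray) -> np.ndarray:
        if noise_sd <= 0:
            return levels.copy()
        return levels * rng.lognormal(0.0, noise_sd, size=levels.shape)

    gene_base = rng.lognormal(mean=5.0, sigma=1.0, size=n_genes)
    gene_fc = np.ones(n_genes)
    for idx, fc in planted_gene_fc.items():
        gene_fc[idx] = fc
    genes = pd.DataFrame(
        {
            "feature_id": [f"gene_{i:04d}" for i in range(n_genes)],
            "feature_class": "gene",
            "control": noisy(gene_base),
            "treated": noisy(gene_base * gene_fc),
            "true_fold_change": gene_fc,
        }
    )
    genes["truth_flag"] = np.maximum(gene_fc, 1 / gene_fc) > gene_cutoff

    met_base = rng.lognormal(mean=3.0, sigma=0.5, size=n_metabolites)
    met_delta = np.zeros(n_metabolites)
    for idx, d in planted_metabolite_change.items():
        met_delta[idx] = d
    metabolites = pd.DataFrame(
        {
            "feature_id": [f"met_{i:04d}" for i in range(n_metabolites)],
            "feature_class": "metabolite",
            "control": noisy(met_base),
            "treated": noisy(met_base * (1 + met_delta)),
            "true_change": met_delta,
        }
    )
    metabolites["truth_flag"] = np.abs(met_delta) > metabolite_cutoff
    return genes, metabolites
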