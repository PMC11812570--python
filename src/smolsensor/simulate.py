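"""Synthetic single-molecule microscopy data with known ground truth.

Everything the analysis pipeline consumes can be generated here, seeded and
reproducible: lognormal monomer spot intensities and c-mer mixtures, rendered
TIRF frames and movies (Gaussian PSF, Poisson shot noise, Gaussian read
noise, Bernoulli photobleaching), two-phase Hill recruitment traces, and
multichannel immunofluorescence fields with a non-transfected background
population for gating.

Spot intensities are in camera ADU after background subtraction; positions
in micrometres; times in minutes unless stated otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinetics import KineticParams, TimeCourse, model_eval

__all__ = [
    "MonomerModel",
    "SceneSpec",
    "IFFieldSpec",
    "GenerationError",
    "gen_monomer_intensities",
    "gen_multimer_mixture",
    "gen_spot_positions",
    "render_tirf_frame",
    "render_movie",
    "gen_timecourse",
    "gen_if_field",
]


class GenerationError(RuntimeError):
    """Raised when a requested synthetic scene cannot be constructed."""


@dataclass(frozen=True)
class MonomerModel:
    """Lognormal model of the single-fluorophore spot-intensity distribution.

    The empirical intensity distribution of a calibration construct (a
    membrane-anchored monomeric fluorescent protein imaged at single-molecule
    density) is mono-modal and lognormal; ``log_mean``/``log_sd`` are the
    location and scale of log-intensity.  Defaults give a median of 1000 ADU,
    a plausible sCMOS/EMCCD scale.
    """

    log_mean: float = math.log(1000.0)
    log_sd: float = 0.4

    def __post_init__(self) -> None:
        if self.log_sd <= 0:
            raise ValueError("log_sd must be positive")


@dataclass(frozen=True)
class SceneSpec:
    """Camera/optics parameters for rendered TIRF scenes.

    fov_size: (width, height) in um; pixel_size in um; psf_sigma is the
    Gaussian PSF standard deviation in um; background and read_noise_sd in
    ADU; photon_scale in ADU per photoelectron; spot_density in spots per
    100 um^2; bleach_prob_per_frame is the per-spot Bernoulli disappearance
    probability per frame.
    """

    fov_size: tuple[float, float] = (10.0, 10.0)
    pixel_size: float = 0.0867
    psf_sigma: float = 0.09
    background: float = 100.0
    read_noise_sd: float = 2.0
    photon_scale: float = 0.5
    spot_density: float = 25.0
    bleach_prob_per_frame: float = 0.02

    def __post_init__(self) -> None:
        if min(self.fov_size) <= 0 or self.pixel_size <= 0 or self.psf_sigma <= 0:
            raise ValueError("geometry parameters must be positive")
        if self.background < 0 or self.read_noise_sd < 0 or self.photon_scale <= 0:
            raise ValueError("camera parameters must be non-negative (photon_scale positive)")
        if self.spot_density < 0 or not (0 <= self.bleach_prob_per_frame <= 1):
            raise ValueError("invalid spot_density or bleach probability")
        if self.psf_sigma < self.pixel_size / 4:
            raise ValueError("psf_sigma must be >= pixel_size/4 (resolvable PSF)")

    @property
    def shape(self) -> tuple[int, int]:
        """Image shape (rows, cols)."""
        return (
            int(round(self.fov_size[1] / self.pixel_size)),
            int(round(self.fov_size[0] / self.pixel_size)),
        )

    @property
    def area_um2(self) -> float:
        return self.fov_size[0] * self.fov_size[1]


def gen_monomer_intensities(n: int, model: MonomerModel = MonomerModel(), seed=None) -> np.ndarray:
    """Draw ``n`` monomer spot intensities (ADU) from the lognormal model."""
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = np.random.default_rng(seed)
    return rng.lognormal(model.log_mean, model.log_sd, size=int(n))


def _check_fractions(fractions) -> np.ndarray:
    fr = np.asarray(fractions, dtype=float)
    if fr.ndim != 1 or fr.size < 1:
        raise ValueError("fractions must be a 1-D simplex vector")
    if np.any(fr < 0) or abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must be non-negative and sum to 1")
    return fr


def gen_multimer_mixture(
    n: int,
    fractions,
    model: MonomerModel = MonomerModel(),
    mode: str = "scale",
    seed=None,
) -> pd.DataFrame:
    """Draw a labelled mixture of c-mer spot intensities.

    ``fractions[c-1]`` is the population fraction of order-c puncta.  In
    ``scale`` mode an order-c intensity is c times one monomer draw (axis
    scaling of the monomer distribution); in ``convolve`` mode it is the sum
    of c independent monomer draws (independent emitters).

    Returns a DataFrame with columns ``intensity`` and ``order`` (ground
    truth label).
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    fr = _check_fractions(fractions)
    if mode not in ("scale", "convolve"):
        raise ValueError("mode must be 'scale' or 'convolve'")
    rng = np.random.default_rng(seed)
    orders = rng.choice(np.arange(1, fr.size + 1), size=int(n), p=fr)
    intensity = np.empty(int(n))
    for c in np.unique(orders):
        idx = orders == c
        k = int(idx.sum())
        if mode == "scale":
            intensity[idx] = c * rng.lognormal(model.log_mean, model.log_sd, size=k)
        else:
            intensity[idx] = rng.lognormal(model.log_mean, model.log_sd, size=(k, int(c))).sum(axis=1)
    return pd.DataFrame({"intensity": intensity, "order": orders})


def gen_spot_positions(
    n: int, spec: SceneSpec, seed=None, min_separation: float | None = None, max_tries: int = 10000
) -> np.ndarray:
    """Uniform random (x, y) positions in the FOV, optionally with a minimum
    pairwise separation (um) to emulate the resolvable single-molecule regime.
    """
    rng = np.random.default_rng(seed)
    w, h = spec.fov_size
    margin = 3 * spec.psf_sigma  # keep the PSF core inside the frame
    if min_separation is None:
        xy = np.column_stack([
            rng.uniform(margin, w - margin, int(n)),
            rng.uniform(margin, h - margin, int(n)),
        ])
        return xy
    pts: list[np.ndarray] = []
    tries = 0
    while len(pts) < n:
        cand = np.array([rng.uniform(margin, w - margin), rng.uniform(margin, h - margin)])
        if all(np.hypot(*(cand - p)) >= min_separation for p in pts):
            pts.append(cand)
        tries += 1
        if tries > max_tries:
            raise GenerationError(f"could not place {n} spots with separation {min_separation}")
    return np.array(pts).reshape(int(n), 2)


def render_tirf_frame(
    positions: np.ndarray,
    intensities: np.ndarray,
    spec: SceneSpec,
    seed=None,
    noiseless: bool = False,
) -> np.ndarray:
    """Render one TIRF frame: background + Gaussian spots (+ camera noise).

    Each spot contributes a 2-D Gaussian whose background-subtracted
    integral equals its ``intensity`` (ADU).  With ``noiseless=False``,
    Poisson shot noise is applied to (background + signal) photoelectrons
    and Gaussian read noise added.  Pixel (r, c) is centred at
    ((c + 0.5), (r + 0.5)) * pixel_size.
    """
    positions = np.asarray(positions, dtype=float).reshape(-1, 2)
    intensities = np.atleast_1d(np.asarray(intensities, dtype=float))
    if positions.shape[0] != intensities.size:
        raise ValueError("positions and intensities must have matching length")
    w, h = spec.fov_size
    if positions.size and (
        positions[:, 0].min() < 0 or positions[:, 0].max() > w
        or positions[:, 1].min() < 0 or positions[:, 1].max() > h
    ):
        raise ValueError("spot positions must lie inside the FOV")

    nrow, ncol = spec.shape
    img = np.full((nrow, ncol), float(spec.background))
    s_px = spec.psf_sigma / spec.pixel_size
    half = int(np.ceil(5 * s_px)) + 1
    for (x, y), amp_int in zip(positions, intensities):
        cx = x / spec.pixel_size - 0.5  # column coordinate of the centre
        cy = y / spec.pixel_size - 0.5
        r0, r1 = max(0, int(cy) - half), min(nrow, int(cy) + half + 1)
        c0, c1 = max(0, int(cx) - half), min(ncol, int(cx) + half + 1)
        rr = np.arange(r0, r1)[:, None]
        cc = np.arange(c0, c1)[None, :]
        g = np.exp(-((rr - cy) ** 2 + (cc - cx) ** 2) / (2 * s_px**2))
        # integral over pixels ~ amplitude * 2*pi*s_px^2 = intensity
        img[r0:r1, c0:c1] += amp_int / (2 * np.pi * s_px**2) * g
    if noiseless:
        return img
    rng = np.random.default_rng(seed)
    photons = rng.poisson(img / spec.photon_scale)
    return photons * spec.photon_scale + rng.normal(0.0, spec.read_noise_sd, size=img.shape)


def render_movie(
    spec: SceneSpec,
    model: MonomerModel,
    n_frames: int,
    seed=None,
    density_per_frame=None,
    bleach: bool = False,
    min_separation: float | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a TIRF movie with per-frame ground truth.

    Two regimes:

    * ``bleach=True``: a fixed initial population (spec.spot_density) whose
      members disappear with probability ``bleach_prob_per_frame`` per frame
      and no arrivals — the photobleaching decline seen under video-rate
      imaging.
    * ``density_per_frame`` given (spots per 100 um^2 per frame): each frame
      draws an independent Poisson-count population at that density — a
      recruitment time course at low duty cycle.

    Returns (stack, truth) where truth has columns frame, x, y, intensity.
    """
    rng = np.random.default_rng(seed)
    area = spec.area_um2
    frames = []
    records = []
    if bleach:
        n0 = int(round(spec.spot_density * area / 100.0))
        pos = gen_spot_positions(n0, spec, seed=rng.integers(2**31), min_separation=min_separation)
        inten = rng.lognormal(model.log_mean, model.log_sd, size=n0)
        alive = np.ones(n0, dtype=bool)
        for fidx in range(n_frames):
            frames.append(render_tirf_frame(pos[alive], inten[alive], spec, seed=rng.integers(2**31)))
            for x, y, i in zip(pos[alive, 0], pos[alive, 1], inten[alive]):
                records.append((fidx, x, y, i))
            alive &= rng.random(n0) >= spec.bleach_prob_per_frame
    else:
        if density_per_frame is None:
            density_per_frame = np.full(n_frames, spec.spot_density)
        density_per_frame = np.asarray(density_per_frame, dtype=float)
        if density_per_frame.size != n_frames:
            raise ValueError("density_per_frame must have length n_frames")
        for fidx in range(n_frames):
            k = int(round(density_per_frame[fidx] * area / 100.0))
            pos = gen_spot_positions(k, spec, seed=rng.integers(2**31), min_separation=min_separation)
            inten = rng.lognormal(model.log_mean, model.log_sd, size=k)
            frames.append(render_tirf_frame(pos, inten, spec, seed=rng.integers(2**31)))
            for x, y, i in zip(pos[:, 0], pos[:, 1], inten):
                records.append((fidx, x, y, i))
    truth = pd.DataFrame(records, columns=["frame", "x", "y", "intensity"])
    return np.stack(frames), truth


def gen_timecourse(params: KineticParams, t_grid, noise_sd: float = 0.0, seed=None) -> TimeCourse:
    """Sample the two-phase Hill model on ``t_grid`` (minutes) with i.i.d.
    Gaussian noise of sd ``noise_sd * F_max``."""
    t = np.asarray(t_grid, dtype=float)
    if t.size >= 2 and not np.all(np.diff(t) > 0):
        raise ValueError("t_grid must be strictly increasing")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    f = model_eval(params, t)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        f = f + rng.normal(0.0, noise_sd * params.F_max, size=t.shape)
    return TimeCourse(t, f)


@dataclass(frozen=True)
class IFFieldSpec:
    """Geometry of a rendered immunofluorescence field.

    Cells are concentric disks: a bright nucleus (DAPI) inside a larger cell
    body (CellMask).  Morphological realism is deliberately out of scope;
    the fields exist to exercise segmentation and gating logic.
    """

    shape: tuple[int, int] = (512, 512)
    pixel_size: float = 0.65  # um, 20x air objective scale
    nucleus_radius: float = 6.0  # um
    cell_radius: float = 11.0  # um
    background: float = 20.0  # ADU (12-bit convention)
    nucleus_level: float = 1200.0
    cellbody_level: float = 600.0
    noise_sd: float = 5.0

    def __post_init__(self) -> None:
        if self.nucleus_radius <= 0 or self.cell_radius <= self.nucleus_radius:
            raise ValueError("need 0 < nucleus_radius < cell_radius")


def gen_if_field(
    n_cells: int,
    untransfected_model: tuple[float, float] = (50.0, 15.0),
    transfected_offset: float = 300.0,
    frac_transfected: float = 0.0,
    spec: IFFieldSpec = IFFieldSpec(),
    stain_level: float = 400.0,
    seed=None,
    max_tries: int = 20000,
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Render a 4-channel IF field (dapi, cellbody, reporter, stain).

    Untransfected cells draw their reporter level from
    Gaussian(mu, sigma) = ``untransfected_model``; transfected cells add
    ``transfected_offset``.  Nuclei are non-overlapping and whole cells stay
    clear of the image border so every cell survives border exclusion.

    Returns (channels, truth); truth columns: cell, x_px, y_px, transfected,
    reporter_level, stain_level.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be non-negative")
    rng = np.random.default_rng(seed)
    nrow, ncol = spec.shape
    r_nuc = spec.nucleus_radius / spec.pixel_size
    r_cell = spec.cell_radius / spec.pixel_size
    margin = r_cell + 2
    if nrow - 2 * margin <= 0 or ncol - 2 * margin <= 0:
        raise GenerationError("FOV too small for the requested cell geometry")

    centers: list[tuple[float, float]] = []
    tries = 0
    min_sep = 2 * r_cell + 2  # disjoint cell bodies -> clean segmentation truth
    while len(centers) < n_cells:
        cy = rng.uniform(margin, nrow - margin)
        cx = rng.uniform(margin, ncol - margin)
        if all(np.hypot(cy - y0, cx - x0) >= min_sep for y0, x0 in centers):
            centers.append((cy, cx))
        tries += 1
        if tries > max_tries:
            raise GenerationError(f"could not place {n_cells} non-overlapping cells")

    mu, sd = untransfected_model
    yy, xx = np.mgrid[0:nrow, 0:ncol]
    dapi = np.full(spec.shape, spec.background)
    cellbody = np.full(spec.shape, spec.background)
    reporter = np.full(spec.shape, spec.background)
    stain = np.full(spec.shape, spec.background)
    records = []
    for i, (cy, cx) in enumerate(centers):
        transfected = bool(rng.random() < frac_transfected)
        rep_level = rng.normal(mu, sd) + (transfected_offset if transfected else 0.0)
        st_level = rng.normal(stain_level, 0.1 * stain_level)
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        body = d2 <= r_cell**2
        # graded radial profiles: real nuclei/cytoplasm are not flat plateaus,
        # and a textured histogram is what intensity thresholds rely on
        level = spec.nucleus_level * rng.uniform(0.7, 1.3)
        dapi += level * np.exp(-d2 / (2 * (0.55 * r_nuc) ** 2))
        cellbody += spec.cellbody_level / (1.0 + np.exp((np.sqrt(d2) - 0.9 * r_cell) / (0.08 * r_cell)))
        reporter[body] += rep_level
        stain[body] += st_level
        records.append((i, cx, cy, transfected, rep_level, st_level))
    channels = {}
    for name, img in (("dapi", dapi), ("cellbody", cellbody), ("reporter", reporter), ("stain", stain)):
        noisy = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
        channels[name] = np.clip(noisy, 0, 4095)  # 12-bit convention
    truth = pd.DataFrame(
        records, columns=["cell", "x_px", "y_px", "transfected", "reporter_level", "stain_level"]
    )
    return channels, truth
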