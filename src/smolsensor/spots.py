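"""Single-molecule spot detection and density quantification in TIRF frames.

The detector approximates a standard single-molecule localization workflow
(difference-of-Gaussians band-pass, local-maxima candidates above a robust
noise threshold, sub-pixel refinement by 2-D Gaussian least squares).  It is
a stand-in for dedicated localization plugins; exact parity with any of them
is a non-goal.  Densities are reported per 100 um^2 of membrane footprint,
the natural unit for plasma-membrane recruitment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from skimage.feature import peak_local_max
from skimage.filters import difference_of_gaussians

from .kinetics import TimeCourse

__all__ = [
    "detect_spots",
    "detect_spots_stack",
    "spot_density",
    "rolling_mean",
    "normalize_to_baseline",
    "subtract_modal_background",
    "write_spot_table",
    "read_spot_table",
]

def _robust_sigma(x: np.ndarray) -> float:
    med = np.median(x)
    return 1.4826 * float(np.median(np.abs(x - med)))


def _fit_gaussian_spot(window: np.ndarray, s0: float):
    """LSQ fit of A*exp(-r^2/2s^2)+b to a small window; returns
    (amplitude, dy, dx, sigma, offset) with dy/dx relative to the centre."""
    h, w = window.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    cy0, cx0 = (h - 1) / 2.0, (w - 1) / 2.0
    b0 = float(np.median(window))
    a0 = float(window[int(cy0), int(cx0)] - b0)

    def resid(p):
        a, cy, cx, s, b = p
        g = a * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * s**2)) + b
        return (g - window).ravel()

    lb = [0.0, cy0 - 2, cx0 - 2, 0.3 * s0, -np.inf]
    ub = [np.inf, cy0 + 2, cx0 + 2, 3.0 * s0, np.inf]
    x0 = np.clip([max(a0, 1e-3), cy0, cx0, s0, b0], lb, ub)
    sol = least_squares(resid, x0, bounds=(lb, ub), xtol=1e-10, ftol=1e-10)
    a, cy, cx, s, b = sol.x
    return a, cy - cy0, cx - cx0, s, b, sol.success


def detect_spots(
    image: np.ndarray,
    pixel_size: float,
    min_snr: float = 5.0,
    psf_sigma: float = 0.09,
    frame: int = 0,
) -> pd.DataFrame:
    """Detect diffraction-limited spots in one 2-D frame.

    Candidates are 8-connected local maxima of the DoG-filtered image above
    ``min_snr`` times the robust (MAD) noise of the filtered image, refined
    by a 2-D Gaussian fit for sub-pixel position and integrated intensity.
    Maxima closer than 2 * psf_sigma are merged keeping the brighter spot.

    Returns a SpotTable DataFrame: frame, x (um), y (um), intensity (ADU),
    sigma_fit (um).
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("detect_spots expects a 2-D image")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    s_px = psf_sigma / pixel_size
    dog = difference_of_gaussians(image, s_px, 2 * s_px)
    noise = _robust_sigma(dog)
    if noise <= 0:
        noise = max(float(dog.std()), 1e-12)
    thresh = float(np.median(dog)) + min_snr * noise
    min_dist = max(1, int(round(2 * s_px)))
    coords = peak_local_max(dog, min_distance=min_dist, threshold_abs=thresh, exclude_border=1)

    half = max(3, int(np.ceil(3 * s_px)))
    padded = np.pad(image, half, mode="reflect")  # windows near edges stay full-size
    rows = []
    for r, c in coords:
        window = padded[r: r + 2 * half + 1, c: c + 2 * half + 1]
        a, dy, dx, s_fit, _, ok = _fit_gaussian_spot(window, s_px)
        if not ok or a <= 0 or abs(dy) > 2 or abs(dx) > 2:
            continue
        cy, cx = r + dy, c + dx
        intensity = a * 2 * np.pi * s_fit**2
        rows.append((frame, (cx + 0.5) * pixel_size, (cy + 0.5) * pixel_size,
                     intensity, s_fit * pixel_size))
    table = pd.DataFrame(rows, columns=["frame", "x", "y", "intensity", "sigma_fit"])
    if len(table) > 1:
        table = _merge_duplicates(table, 2 * psf_sigma)
    return table.reset_index(drop=True)


def _merge_duplicates(table: pd.DataFrame, min_sep: float) -> pd.DataFrame:
    """Drop the dimmer of any pair closer than ``min_sep`` (um)."""
    order = np.argsort(-table["intensity"].to_numpy())
    xy = table[["x", "y"]].to_numpy()
    keep: list[int] = []
    for i in order:
        if all(np.hypot(*(xy[i] - xy[j])) >= min_sep for j in keep):
            keep.append(i)
    return table.iloc[sorted(keep)]


def detect_spots_stack(stack: np.ndarray, pixel_size: float, **kw) -> pd.DataFrame:
    """Run :func:`detect_spots` on every frame of a (T, H, W) stack."""
    stack = np.asarray(stack)
    if stack.ndim == 2:
        stack = stack[None]
    tables = [detect_spots(fr, pixel_size, frame=i, **kw) for i, fr in enumerate(stack)]
    return pd.concat(tables, ignore_index=True)


def spot_density(table: pd.DataFrame, roi_area: float, per_frame: bool = False,
                 n_frames: int | None = None):
    """Convert spot counts to density per 100 um^2.

    Pooled (default): returns a single density from all rows.  With
    ``per_frame``, returns a DataFrame (frame, density) covering frames
    0..n_frames-1 (inferred from the table if not given), zeros included.
    """
    if roi_area <= 0:
        raise ValueError("roi_area must be positive")
    if not per_frame:
        return len(table) / roi_area * 100.0
    if n_frames is None:
        n_frames = int(table["frame"].max()) + 1 if len(table) else 0
    counts = table.groupby("frame").size() if len(table) else pd.Series(dtype=int)
    frames = np.arange(n_frames)
    dens = np.array([counts.get(f, 0) for f in frames], dtype=float) / roi_area * 100.0
    return pd.DataFrame({"frame": frames, "density": dens})


def rolling_mean(tc: TimeCourse, window: float) -> TimeCourse:
    """Centred moving average over a time ``window`` (same units as tc.t).

    The series must be uniformly sampled; edges use shrunken windows so the
    length is preserved.  window equal to one sample interval is identity.
    """
    dt = np.diff(tc.t)
    if dt.size and not np.allclose(dt, dt[0]):
        raise ValueError("rolling_mean requires uniform sampling")
    step = float(dt[0]) if dt.size else 1.0
    n = int(round(window / step))
    if n < 1:
        raise ValueError("window must be at least one sample interval")
    f = pd.Series(tc.f).rolling(n, center=True, min_periods=1).mean().to_numpy()
    return TimeCourse(tc.t, f)


def normalize_to_baseline(tc: TimeCourse, baseline_window: int | None = None) -> TimeCourse:
    """F/F0 normalization: divide by the mean over the pre-stimulus window.

    The baseline is the t < 0 samples by default, or the first
    ``baseline_window`` samples.  F0 must be positive (subtract the camera
    background first).
    """
    if baseline_window is not None:
        if baseline_window < 1 or baseline_window > tc.t.size:
            raise ValueError("invalid baseline_window")
        base = tc.f[:baseline_window]
    else:
        base = tc.f[tc.baseline_mask]
        if base.size == 0:
            raise ValueError("no pre-stimulus samples to define F0")
    f0 = float(np.mean(base))
    if f0 <= 0:
        raise ValueError("baseline mean F0 must be positive")
    return TimeCourse(tc.t, tc.f / f0)


def subtract_modal_background(data):
    """Subtract the modal value (histogram mode at 1-ADU bin width).

    In TIRF fields most pixels lie outside cells, so the mode estimates the
    camera background.  Works on images or 1-D series; needs >= 100 values.
    """
    arr = np.asarray(data, dtype=float)
    if arr.size < 100:
        raise ValueError("need at least 100 values to estimate the mode")
    if arr.min() == arr.max():
        return arr - arr.min()
    edges = np.arange(np.floor(arr.min()), np.ceil(arr.max()) + 1)  # 1-ADU bins
    counts, _ = np.histogram(arr, bins=edges)
    mode = edges[np.argmax(counts)]
    return arr - mode


def write_spot_table(table: pd.DataFrame, path) -> None:
    """Write a SpotTable CSV with localization-software-compatible headers
    ("x [nm]", "y [nm]", "intensity [photon]") alongside native columns."""
    out = table.copy()
    out["x [nm]"] = out["x"] * 1000.0
    out["y [nm]"] = out["y"] * 1000.0
    out["intensity [photon]"] = out["intensity"]
    out.to_csv(path, index=False)


def read_spot_table(path) -> pd.DataFrame:
    """Read a SpotTable CSV (native or nm-unit localization columns)."""
    df = pd.read_csv(path)
    if "x" not in df.columns and "x [nm]" in df.columns:
        df["x"] = df["x [nm]"] / 1000.0
        df["y"] = df["y [nm]"] / 1000.0
    if "intensity" not in df.columns and "intensity [photon]" in df.columns:
        df["intensity"] = df["intensity [photon]"]
    if "frame" not in df.columns:
        df["frame"] = 0
    return df
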