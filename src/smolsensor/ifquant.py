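"""Single-cell immunofluorescence quantification.

Nucleus-seeded segmentation and intensity gating: Huang fuzzy-entropy
thresholding of the nuclear (DAPI) channel, distance-transform watershed to
split touching nuclei, a label-based Voronoi partition of the thresholded
cell-body channel into per-nucleus territories, size/border ROI filtering,
staining-background subtraction, and a mean + 3*SD transfection-positivity
cutoff estimated from non-transfected control cells.  Intensities follow a
raw 12-bit convention so cutoffs are comparable across images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.morphology import h_maxima
from skimage.segmentation import watershed

__all__ = [
    "GatingResult",
    "huang_threshold",
    "segment_cells",
    "filter_rois",
    "gate_positive",
    "subtract_staining_background",
]


def huang_threshold(image, nbins: int = 256) -> float:
    """Huang-Wang fuzzy-entropy threshold over a 256-bin histogram.

    For each candidate threshold t, pixels are assigned fuzzy membership to
    the fore/background class based on distance from the class mean, and the
    Shannon entropy of the membership is accumulated over the histogram; the
    threshold minimising this fuzziness is returned (exhaustive scan).
    Shift-equivariant: thresholding image + c gives threshold + c.
    """
    vals = np.asarray(image, dtype=float).ravel()
    vmin, vmax = float(vals.min()), float(vals.max())
    if vmax == vmin:
        raise ValueError("constant image has no threshold")
    hist, edges = np.histogram(vals, bins=nbins, range=(vmin, vmax))
    centers = 0.5 * (edges[:-1] + edges[1:])
    C = centers[-1] - centers[0]
    w = hist.astype(float)
    cw = np.cumsum(w)
    cwx = np.cumsum(w * centers)
    total_w, total_wx = cw[-1], cwx[-1]

    best_t, best_s = None, np.inf
    for t in range(nbins - 1):
        w0, w1 = cw[t], total_w - cw[t]
        if w0 == 0 or w1 == 0:
            continue
        mu0 = cwx[t] / w0
        mu1 = (total_wx - cwx[t]) / w1
        u = np.empty(nbins)
        u[: t + 1] = 1.0 / (1.0 + np.abs(centers[: t + 1] - mu0) / C)
        u[t + 1:] = 1.0 / (1.0 + np.abs(centers[t + 1:] - mu1) / C)
        uc = np.clip(u, 1e-12, 1 - 1e-12)
        s = float(np.sum(w * (-uc * np.log(uc) - (1 - uc) * np.log(1 - uc))))
        if s < best_s:
            best_s, best_t = s, t
    return float(edges[best_t + 1])


def _segment_nuclei(dapi: np.ndarray, min_size_px: int, h: float = 2.0) -> np.ndarray:
    thr = huang_threshold(dapi)
    mask = dapi > thr
    if mask.mean() > 0.45:
        # a threshold splitting a unimodal (empty-field) histogram labels
        # half the noise as foreground; treat as "no nuclei found"
        return np.zeros(dapi.shape, dtype=int)
    mask = ndi.binary_fill_holes(mask)
    lab, k = ndi.label(mask)
    if k:
        sizes = ndi.sum_labels(mask, lab, index=np.arange(1, k + 1))
        mask = np.isin(lab, 1 + np.flatnonzero(sizes >= min_size_px))
    if not mask.any():
        return np.zeros(dapi.shape, dtype=int)
    dist = ndi.distance_transform_edt(mask)
    # light smoothing so ragged mask edges cannot carve spurious EDT maxima
    dist = ndi.gaussian_filter(dist, 1.0)
    peaks = h_maxima(dist, h)
    markers, _ = ndi.label(peaks)
    if markers.max() == 0:
        markers, _ = ndi.label(mask)
    return watershed(-dist, markers, mask=mask)


def segment_cells(
    dapi: np.ndarray,
    cellbody: np.ndarray,
    pixel_size: float,
    channels: dict[str, np.ndarray] | None = None,
    min_nucleus_area_um2: float = 4.0,
    return_labels: bool = False,
):
    """Nucleus-seeded single-cell segmentation with per-channel means.

    Nuclei: Huang-thresholded DAPI, holes filled, split by distance-transform
    watershed (h-maxima seeds, h = 2 px).  Cell territory: Huang-thresholded
    cell-body mask, each pixel assigned to its nearest labelled nucleus (the
    label-image analogue of a Voronoi partition).  One ROI per nucleus.

    Returns a CellROI DataFrame: label, area_um2, touches_border and one
    ``mean_<name>`` column per entry of ``channels``.  Empty if no nuclei.
    """
    dapi = np.asarray(dapi, dtype=float)
    cellbody = np.asarray(cellbody, dtype=float)
    if dapi.shape != cellbody.shape:
        raise ValueError("channels must be registered to the same shape")
    channels = channels or {}
    min_size_px = max(1, int(round(min_nucleus_area_um2 / pixel_size**2)))
    nuclei = _segment_nuclei(dapi, min_size_px)
    cols = ["label", "area_um2", "touches_border"] + [f"mean_{k}" for k in channels]
    if nuclei.max() == 0:
        empty = pd.DataFrame(columns=cols)
        return (empty, np.zeros(dapi.shape, dtype=int)) if return_labels else empty

    body_mask = (cellbody > huang_threshold(cellbody)) | (nuclei > 0)
    # nearest-labelled-nucleus assignment of every cell-body pixel
    _, (iy, ix) = ndi.distance_transform_edt(nuclei == 0, return_indices=True)
    territory = nuclei[iy, ix] * body_mask

    rows = []
    border = np.zeros(territory.shape, dtype=bool)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    for lab in range(1, int(nuclei.max()) + 1):
        region = territory == lab
        npx = int(region.sum())
        if npx == 0:
            continue
        row = {
            "label": lab,
            "area_um2": npx * pixel_size**2,
            "touches_border": bool((region & border).any()),
        }
        for name, img in channels.items():
            row[f"mean_{name}"] = float(np.asarray(img, dtype=float)[region].mean())
        rows.append(row)
    table = pd.DataFrame(rows, columns=cols)
    return (table, territory) if return_labels else table


def filter_rois(rois: pd.DataFrame, min_area: float = 10.0, exclude_border: bool = True) -> pd.DataFrame:
    """Keep ROIs strictly larger than ``min_area`` um^2 and, if requested,
    not touching the image periphery."""
    keep = rois["area_um2"] > min_area
    if exclude_border:
        keep &= ~rois["touches_border"].astype(bool)
    return rois[keep].reset_index(drop=True)


@dataclass(frozen=True)
class GatingResult:
    """Transfection-positivity gate derived from control cells."""

    cutoff: float
    control_mean: float
    control_sd: float
    positive: np.ndarray  # bool, one per gated cell

    @property
    def fraction_positive(self) -> float:
        return float(np.mean(self.positive)) if self.positive.size else 0.0


def gate_positive(reporter_means, control_means, cutoff: float | None = None) -> GatingResult:
    """Gate cells as reporter-positive against a non-transfected control.

    The default cutoff is control mean + 3 * control SD; a cell is positive
    when its reporter mean exceeds the cutoff.  A manual ``cutoff`` override
    bypasses the rule (the control statistics are still reported).
    """
    reporter = np.asarray(reporter_means, dtype=float)
    control = np.asarray(control_means, dtype=float)
    if control.size < 10:
        raise ValueError("need at least 10 control cells to set a cutoff")
    mu = float(control.mean())
    sd = float(control.std(ddof=1))
    cut = mu + 3.0 * sd if cutoff is None else float(cutoff)
    return GatingResult(cutoff=cut, control_mean=mu, control_sd=sd, positive=reporter > cut)


def subtract_staining_background(values, no_primary_control_mean: float) -> np.ndarray:
    """Subtract the no-primary-antibody control mean from per-cell staining
    values.  Results may be negative; they are not clipped."""
    if no_primary_control_mean < 0:
        raise ValueError("control mean must be non-negative")
    return np.asarray(values, dtype=float) - no_primary_control_mean
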